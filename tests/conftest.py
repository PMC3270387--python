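import numpy as np
import pytest

from qnspec import datasets
from qnspec.pipeline import priors_from_table, truth_components


@pytest.fixture(scope="session")
def analysed_compositions():
    return datasets.load_compositions("analysed")


@pytest.fixture(scope="session")
def pristine_tables():
    """Pristine single-pulse speciation tables, keyed by sample."""
    return {s: datasets.pristine_table(s, "single_pulse") for s in datasets.SAMPLES}


@pytest.fixture(scope="session")
def cpmas_series():
    return {s: datasets.load_series(s, "cpmas") for s in datasets.SAMPLES}


@pytest.fixture(scope="session")
def policies():
    return {s: datasets.default_policy(s) for s in datasets.SAMPLES}


def truth_init(table):
    """Starting values at the ground-truth parameters of a table."""
    return np.array([[c.center, c.fwhm, c.area] for c in truth_components(table)])


def neutral_init(priors, total_area=100.0):
    """Uninformative start: prior centers, mid-range FWHM, equal areas."""
    return np.array([[p.center0, 0.5 * (p.fwhm_lo + p.fwhm_hi), total_area / len(priors)]
                     for p in priors])
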