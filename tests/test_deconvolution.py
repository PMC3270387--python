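import itertools
import math

import numpy as np
import pytest
from scipy.optimize import least_squares, nnls

from qnspec import datasets
from qnspec.deconvolution import SpeciesPrior, deconvolve, fit_once, fractions
from qnspec.errors import AnalysisError
from qnspec.lineshape import FWHM_TO_SIGMA, PeakComponent, synthesize_spectrum
from qnspec.pipeline import priors_from_table, truth_components

from conftest import neutral_init, truth_init


def brute_force_sse(spectrum, priors, center_step=1.0, fwhm_step=1.0):
    """Independent oracle: exhaustive (center, fwhm) lattice with non-negative
    linear least-squares areas at each node, then a local polish from the
    best node.  Returns the refined SSE."""
    grids = []
    for p in priors:
        lo, hi = p.center_box
        centers = np.arange(lo, hi + 1e-9, center_step)
        widths = np.arange(p.fwhm_lo, p.fwhm_hi + 1e-9, fwhm_step)
        grids.append(list(itertools.product(centers, widths)))
    y = spectrum.intensity
    best = (np.inf, None)
    for combo in itertools.product(*grids):
        cols = []
        for c, w in combo:
            s = w * FWHM_TO_SIGMA
            cols.append(np.exp(-0.5 * ((spectrum.ppm - c) / s) ** 2) / (s * math.sqrt(2 * math.pi)))
        A = np.column_stack(cols)
        areas, rnorm = nnls(A, y)
        if rnorm**2 < best[0]:
            best = (rnorm**2, np.array([[c, w, a] for (c, w), a in zip(combo, areas)]))
    x0 = best[1].ravel()
    lo = np.ravel([[p.center_box[0], p.fwhm_lo, 0.0] for p in priors])
    hi = np.ravel([[p.center_box[1], p.fwhm_hi, np.inf] for p in priors])
    x0 = np.clip(x0, lo + 1e-9, np.where(np.isfinite(hi), hi - 1e-9, x0 + 1))

    def resid(x):
        out = np.zeros_like(y)
        for i in range(0, x.size, 3):
            s = x[i + 1] * FWHM_TO_SIGMA
            out += x[i + 2] / (s * math.sqrt(2 * math.pi)) * np.exp(
                -0.5 * ((spectrum.ppm - x[i]) / s) ** 2
            )
        return out - y
    res = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    return 2.0 * res.cost


class TestFitOnce:
    def test_exact_recovery_of_single_gaussian(self):
        truth = PeakComponent("Q3_H", -101.0, 8.5, 1.0)
        spec = synthesize_spectrum([truth], noise_sd=0.0)
        prior = SpeciesPrior("Q3_H", center0=-100.0)
        fit = fit_once(spec, [prior], np.array([[-100.0, 10.0, 0.5]]))
        assert fit.converged
        c = fit.components[0]
        assert c.center == pytest.approx(truth.center, rel=1e-6)
        assert c.fwhm == pytest.approx(truth.fwhm, rel=1e-6)
        assert c.area == pytest.approx(truth.area, rel=1e-6)

    def test_two_peak_noiseless_matches_brute_force_oracle(self):
        comps = [
            PeakComponent("Q4", -109.7, 11.2, 75.1),
            PeakComponent("Q3_H", -100.2, 8.5, 17.8),
        ]
        spec = synthesize_spectrum(comps, noise_sd=0.0)
        priors = [SpeciesPrior("Q4", -109.7), SpeciesPrior("Q3_H", -100.2)]
        fit = fit_once(spec, priors, neutral_init(priors))
        assert fit.converged
        for c, t in zip(fit.components, comps):
            assert c.area == pytest.approx(t.area, abs=0.5)
        oracle = brute_force_sse(spec, priors)
        assert fit.sse == pytest.approx(oracle, abs=1e-6)

    def test_one_peak_noisy_matches_brute_force_oracle_sse(self):
        spec = synthesize_spectrum(
            [PeakComponent("Q4", -110.0, 10.0, 5.0)], noise_sd=0.01, seed=3
        )
        priors = [SpeciesPrior("Q4", -110.0)]
        fit = fit_once(spec, priors, neutral_init(priors, total_area=5.0))
        assert fit.sse == pytest.approx(brute_force_sse(spec, priors), abs=1e-6)

    def test_start_at_bound_stays_inside_box(self):
        spec = synthesize_spectrum([PeakComponent("Q4", -110.0, 10.0, 5.0)], noise_sd=0.0)
        prior = SpeciesPrior("Q4", -112.0)  # box [-116, -108]
        fit = fit_once(spec, [prior], np.array([[-116.0, 7.0, 0.0]]))
        c = fit.components[0]
        assert -116.0 <= c.center <= -108.0
        assert 7.0 <= c.fwhm <= 13.0
        assert c.area >= 0

    def test_too_few_grid_points_rejected(self):
        spec = synthesize_spectrum([PeakComponent("Q4", -110, 10, 1)],
                                   window=(-100.0, -103.2), step=0.05)
        priors = [SpeciesPrior(f"Q{i}", -110.0) for i in range(22)]
        with pytest.raises(ValueError, match="free parameters"):
            fit_once(spec, priors, np.tile([-110.0, 10.0, 1.0], (22, 1)))


class TestDeconvolve:
    def test_noiseless_ensemble_collapses_to_unique_optimum(self):
        table = datasets.pristine_table("S85")
        spec = synthesize_spectrum(truth_components(table), noise_sd=0.0, label="S85")
        ens = deconvolve(spec, priors_from_table(table), n_restarts=12, seed=5)
        assert ens.n_converged == 12
        assert np.all(ens.param_sd < 1e-3 * np.abs(ens.param_mean) + 1e-9)
        for mean_c, t in zip(ens.mean_components(), truth_components(table)):
            assert mean_c.area == pytest.approx(t.area, rel=1e-4)

    def test_same_seed_gives_identical_ensemble(self):
        table = datasets.pristine_table("S85")
        spec = synthesize_spectrum(truth_components(table), noise_sd=0.01, seed=2, label="S85")
        priors = priors_from_table(table)
        a = deconvolve(spec, priors, n_restarts=4, seed=9)
        b = deconvolve(spec, priors, n_restarts=4, seed=9)
        assert a.best_index == b.best_index
        assert np.array_equal(a.param_mean, b.param_mean)
        assert np.array_equal(a.param_sd, b.param_sd)

    def test_best_fit_has_minimal_sse(self):
        table = datasets.pristine_table("S90")
        spec = synthesize_spectrum(truth_components(table), noise_sd=0.02, seed=4, label="S90")
        ens = deconvolve(spec, priors_from_table(table), n_restarts=6, seed=1)
        assert all(ens.best.sse <= f.sse for f in ens.fits if f.converged)

    def test_flat_spectrum_is_an_analysis_error(self):
        spec = synthesize_spectrum([PeakComponent("Q4", -110, 10, 1)], noise_sd=0.0)
        spec.intensity[:] = 0.0
        with pytest.raises(AnalysisError, match="no signal"):
            deconvolve(spec, [SpeciesPrior("Q4", -110.0)], n_restarts=2, seed=0)

    def test_restart_count_validated(self):
        spec = synthesize_spectrum([PeakComponent("Q4", -110, 10, 1)], noise_sd=0.0)
        with pytest.raises(ValueError, match="n_restarts"):
            deconvolve(spec, [SpeciesPrior("Q4", -110.0)], n_restarts=1)


class TestFractions:
    def test_area_ratios(self):
        fit = fit_once(
            synthesize_spectrum(
                [PeakComponent("Q4", -110, 10, 3.0), PeakComponent("Q3_H", -100, 9, 1.0)],
                noise_sd=0.0,
            ),
            [SpeciesPrior("Q4", -110), SpeciesPrior("Q3_H", -100)],
            np.array([[-110, 10, 1], [-100, 9, 1]]),
        )
        table = fractions(fit, sample="x")
        assert table.fraction("Q4") == pytest.approx(75.0, abs=0.1)
        assert table.fraction("Q3_H") == pytest.approx(25.0, abs=0.1)
        assert sum(r.fraction_pct for r in table.records) == pytest.approx(100.0, abs=1e-9)

    def test_single_component_is_100_percent(self):
        from qnspec.deconvolution import FitResult

        fit = FitResult([PeakComponent("Q4", -110, 10, 2.5)], sse=0.0, converged=True)
        assert fractions(fit, "x").fraction("Q4") == 100.0

    def test_zero_total_area_is_an_analysis_error(self):
        from qnspec.deconvolution import FitResult

        fit = FitResult([PeakComponent("Q4", -110, 10, 0.0)], sse=0.0, converged=True)
        with pytest.raises(AnalysisError, match="zero"):
            fractions(fit, "x")


class TestRecoveryStatistics:
    def test_median_fraction_error_below_one_unit_at_1pct_noise(self):
        """Over Dirichlet-perturbed versions of the bundled speciation rows,
        the pooled median absolute fraction-recovery error stays <= 1 pp."""
        rng = np.random.default_rng(7)
        tabs = list(datasets.load_speciation("single_pulse").items()) + list(
            datasets.load_speciation("cpmas").items()
        )
        errs = []
        for i in range(50):
            _, tab = tabs[i % len(tabs)]
            fr = np.array([r.fraction_pct for r in tab.records])
            draw = 100 * rng.dirichlet(fr * 2)
            comps = [
                PeakComponent(r.species, r.delta_ppm, r.fwhm_ppm, a)
                for r, a in zip(tab.records, draw)
            ]
            spec = synthesize_spectrum(comps, noise_sd=0.01, seed=rng)
            priors = priors_from_table(tab)
            fit = fit_once(spec, priors, neutral_init(priors))
            got = fractions(fit, "x").fractions()
            errs.extend(abs(got[r.species] - a) for r, a in zip(tab.records, draw))
        assert np.median(errs) <= 1.0

    def test_recovery_error_degrades_monotonically_with_noise(self):
        """Pooled fraction RMSE is non-decreasing across noise levels
        0 / 0.5% / 2% / 5%."""
        table = datasets.pristine_table("S85")
        comps = truth_components(table)
        truth = table.fractions()
        priors = priors_from_table(table)
        rmse = []
        for noise in (0.0, 0.005, 0.02, 0.05):
            sq = []
            for seed in range(6):
                spec = synthesize_spectrum(comps, noise_sd=noise, seed=seed)
                got = fractions(fit_once(spec, priors, truth_init(table)), "x").fractions()
                sq.extend((got[s] - truth[s]) ** 2 for s in truth)
            rmse.append(math.sqrt(np.mean(sq)))
        assert all(a <= b + 1e-9 for a, b in zip(rmse, rmse[1:]))
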