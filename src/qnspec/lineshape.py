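"""Gaussian lineshape model and synthetic 29Si MAS spectrum generator.

Disordered silicate glasses give Gaussian 29Si resonances, 7-13 ppm wide,
so a spectrum is modelled as a sum of area-parameterized Gaussians on a
uniform ppm grid (stored descending, the NMR display convention) plus
additive white noise.  The generator stands in for spectrometer output:
ground-truth components are known exactly, which is what the deconvolution
recovery tests require.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Spectrum",
    "PeakComponent",
    "FWHM_TO_SIGMA",
    "default_axis",
    "gaussian_profile",
    "synthesize_spectrum",
    "apodize",
]

# sigma = FWHM / (2 sqrt(2 ln 2))
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: default acquisition window: covers Q1..Q4 resonances (-60 to -130 ppm)
DEFAULT_WINDOW = (-60.0, -130.0)
DEFAULT_STEP = 0.05


@dataclass(frozen=True)
class PeakComponent:
    """One Gaussian signal component: species label, center (ppm), FWHM (ppm), area."""

    species: str
    center: float
    fwhm: float
    area: float

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"{self.species}: FWHM must be > 0, got {self.fwhm}")
        if self.area < 0:
            raise ValueError(f"{self.species}: area must be >= 0, got {self.area}")

    @property
    def sigma(self) -> float:
        return self.fwhm * FWHM_TO_SIGMA

    @property
    def height(self) -> float:
        """Peak maximum of the unit-normalized Gaussian times area."""
        return self.area / (self.sigma * math.sqrt(2.0 * math.pi))


@dataclass
class Spectrum:
    """A 1D trace on a uniform, strictly descending ppm grid."""

    ppm: np.ndarray
    intensity: np.ndarray
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.ppm.size < 64:
            raise ValueError("ppm axis must be 1D with >= 64 points")
        if self.ppm.shape != self.intensity.shape:
            raise ValueError("ppm axis and intensity must have equal length")
        steps = np.diff(self.ppm)
        if not np.all(steps < 0):
            raise ValueError("ppm axis must be strictly descending")
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-9 * abs(steps[0])):
            raise ValueError("ppm axis must be uniform")

    @property
    def step(self) -> float:
        """Grid step magnitude in ppm (positive)."""
        return float(abs(self.ppm[1] - self.ppm[0]))

    def integral(self) -> float:
        """Trapezoidal integral over ppm, oriented high->low as positive."""
        return float(np.trapezoid(self.intensity, -self.ppm))


def default_axis(
    window: tuple[float, float] = DEFAULT_WINDOW, step: float = DEFAULT_STEP
) -> np.ndarray:
    """Uniform descending ppm grid over ``window = (high_ppm, low_ppm)``."""
    high, low = window
    if high <= low:
        raise ValueError(f"window must be (high_ppm, low_ppm), got {window}")
    n = int(round((high - low) / step)) + 1
    return high - step * np.arange(n)


def gaussian_profile(component: PeakComponent, ppm: np.ndarray) -> np.ndarray:
    """Evaluate one Gaussian component on a ppm grid.

    The trace integrates (trapezoid) to ``component.area`` provided the grid
    spans at least ~5 FWHM on both sides of the center.
    """
    ppm = np.asarray(ppm, dtype=float)
    s = component.sigma
    z = (ppm - component.center) / s
    return component.area / (s * math.sqrt(2.0 * math.pi)) * np.exp(-0.5 * z * z)


def synthesize_spectrum(
    components: list[PeakComponent],
    window: tuple[float, float] = DEFAULT_WINDOW,
    step: float = DEFAULT_STEP,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    label: str = "synthetic",
) -> Spectrum:
    """Sum of Gaussian components plus i.i.d. Gaussian noise.

    ``noise_sd`` is the noise standard deviation as a fraction of the
    noiseless maximum, so 0.01 means a peak signal-to-noise ratio of 100.
    Bit-reproducible for a fixed integer seed.
    """
    if not components:
        raise ValueError("need at least one component to synthesize a spectrum")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    ppm = default_axis(window, step)
    clean = np.zeros_like(ppm)
    for c in components:
        clean += gaussian_profile(c, ppm)
    intensity = clean
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        intensity = clean + rng.normal(0.0, noise_sd * clean.max(), size=ppm.size)
    return Spectrum(
        ppm=ppm,
        intensity=intensity,
        label=label,
        meta={"noise_sd": noise_sd, "truth": list(components)},
    )


def apodize(spectrum: Spectrum, gaussian_broadening_hz: float, larmor_mhz: float = 79.5) -> Spectrum:
    """Gaussian signal apodization, applied as a spectral-domain convolution.

    Time-domain Gaussian apodization of ``b`` Hz convolves the spectrum with
    a unit-area Gaussian kernel of FWHM ``b / larmor_mhz`` ppm, so component
    widths add in quadrature.  Total integrated intensity is conserved
    (kernel is renormalized on the discrete grid).
    """
    if gaussian_broadening_hz < 0:
        raise ValueError("broadening must be >= 0 Hz")
    if gaussian_broadening_hz == 0:
        return Spectrum(spectrum.ppm.copy(), spectrum.intensity.copy(), spectrum.label, dict(spectrum.meta))
    kernel_fwhm = gaussian_broadening_hz / larmor_mhz
    sigma = kernel_fwhm * FWHM_TO_SIGMA
    step = spectrum.step
    half = int(math.ceil(6.0 * sigma / step))
    x = step * np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()  # discrete unit area -> conserves integral
    smoothed = np.convolve(spectrum.intensity, kernel, mode="same")
    meta = dict(spectrum.meta)
    meta["apodization_fwhm_ppm"] = kernel_fwhm
    return Spectrum(spectrum.ppm.copy(), smoothed, spectrum.label, meta)
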