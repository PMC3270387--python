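# Methods

This note documents the models, defaults, and numerical choices behind
`qnspec`, and what the synthetic-data tests do and do not demonstrate about
real spectra.

## Composition model (split-network algebra)

A CaO–SiO₂–(P₂O₅) glass is written per silicon as Ca_q Si P_p O_o with the
oxygen coefficient derived from charge balance, o = 2 + q + 5p/2, never
stored independently. Phosphorus is assumed to be present exclusively as a
separate calcium orthophosphate phase of fixed Ca₃⁄₂PO₄ stoichiometry, so
the composition splits as

    Ca_q Si P_p O_{2+q+5p/2}  =  [Ca_c SiO_{2+c}]  +  p [Ca_{3/2}PO_4],
    c = q − 3p/2.

Each orthophosphate unit consumes 3/2 Ca per P; the silicate subnetwork
keeps only the residual c Ca per Si. Each such Ca²⁺ converts one Si–O–Si
bridge into two non-bridging oxygens, giving the average bridging-oxygen
count

    n̄_BO = 4 − 2c = 8 − 2m,   m = 2 + c,

where m is the silicate phase's oxygen coefficient (its average
polymerization degree). The valid domain is 0 ≤ c ≤ 2 (pure Q⁴ silica down
to fully depolymerized Q⁰); c < 0 means the phosphate Ca demand exceeds the
inventory and is a domain error. The Ca:P ratio of the phosphate phase is
deliberately not a free parameter: the qualitative argument is insensitive
to it over the plausible 1.0–1.7 range, and fixing it keeps the model
one-line falsifiable. Surface proton content is ignored in compositions.

Display rounding is half-up (0.0485 → 0.049), applied only at report time;
raw values are retained internally.

## Lineshape model and synthetic spectra

Each Qⁿ resonance is a Gaussian parameterized by center δ (ppm), FWHM
(ppm; σ = FWHM / (2√(2 ln 2))) and integrated area. Spectra live on a
uniform ppm grid stored descending (NMR display convention); the default
acquisition window is −60 to −130 ppm with a 0.05 ppm step (1401 points),
covering all Q¹–Q⁴ resonances.

The generator sums component Gaussians and adds i.i.d. zero-mean Gaussian
noise whose SD is specified relative to the noiseless maximum; the default
1% (peak S/N 100) emulates good single-pulse spectra of these materials,
and 0.5–2% spans the plausible range. The baseline is fixed at zero and no
Lorentzian/Voigt component, spinning sidebands, or CP transfer-efficiency
weighting is modelled. Gaussian apodization of b Hz (150 Hz typical at a
79.5 MHz ²⁹Si Larmor frequency) is applied as a spectral convolution with a
unit-area Gaussian kernel of FWHM b/ν₀ ppm, so component widths add in
quadrature and total intensity is conserved; the synthetic path applies it
before fitting.

What the generator does *not* emulate: baseline roll, t₁ noise,
non-Gaussian lineshape tails, shift/width correlations across a soaking
series, and partial overlap with sidebands. Recovery results on synthetic
data therefore bound what the fit can do when its model is exactly right;
they say nothing about model misspecification on real spectra.

## Deconvolution

The fit minimizes the pointwise sum of squared residuals over
(center, FWHM, area) per species, under box constraints: centers within
±4 ppm of their priors (the `center_halfwidth` default), FWHM in
[7, 13] ppm, areas ≥ 0. The optimizer is SciPy's trust-region reflective
bounded least squares with tight tolerances (xtol = ftol = gtol = 1e−12);
the contract is the SSE objective and the box constraints, not the
algorithm, and the test suite holds it to agreement with an exhaustive
grid-plus-refine search on 1–2 peak problems to 1e−6 in SSE.

The fit is restarted 12 times (default) from starting points drawn
uniformly inside each box (areas log-uniformly between 1% and 200% of the
spectrum integral), with the center box edges independently jittered by
±1 ppm per restart to emulate varied shift boundaries (toggleable via
`edge_jitter_ppm=0`). Reported parameters are means over converged fits,
with the restart SD as the uncertainty; fractions come from the mean areas
renormalized to 100%. The minimum-SSE converged fit is retained (ties break
to the lowest restart index); a flat or zero spectrum and an ensemble with
no converged fit are analysis errors, not zero-area results.

Identifiability caveat: for five heavily overlapping peaks (adjacent
centers ~2σ apart), the fraction of the merged −91 ppm peak is weakly
identified when centers and widths are free. At 1% noise the Cramér–Rao
bound on that fraction reaches ~10 percentage units (S58-like rows), so
recovered fractions for such spectra carry several-unit uncertainty however
good the optimizer; the 3-peak Ca-poor spectra recover to well under
2 units. The restart-spread SD measures reproducibility of the optimum, not
this statistical error.

## Species assignment and the connectivity statistic

Fitted centers map to species through half-open shift windows
(lo < δ ≤ hi, ppm): Q⁴ (−120, −105], Q³_H (−105, −97], merged Q²_H/Q³_Ca
(−97, −87], Q²_Ca (−87, −79], Q¹_Ca (−79, −71]; centers outside every
window are an error, and the windows are configurable. The merged window's
label depends on the policy's sharing factor: wholly Q²_H at 0 (Ca-poor
glasses), wholly Q³_Ca at 1, the explicit merged label in between (0.5 for
the Ca-rich S58 glass). The −83 and −75 ppm peaks are attributed wholly to
Q²_Ca and Q¹_Ca even though mixed Ca²⁺/H⁺ charge balance is conceivable.

The NMR-derived connectivity n̄_BO excludes the protonated species, splits
a merged entry by the sharing factor, renormalizes the surviving
{Q⁴, Qⁿ_Ca} fractions to a unit sum, and returns Σ n·xₙ. It is invariant
under uniform rescaling of the fractions and bounded to [1, 4] for Q¹–Q⁴
inputs. The sharing factor is per-sample and constant over a soaking series
by default. Agreement with the composition route is quantified as
100·|derived − predicted|/predicted.

## SBF soaking series

A series is an ordered list of (τ_SBF in hours, speciation table) points
for one glass and one acquisition mode (τ = 0 is pristine; day-labelled
samples convert as 1 d = 24 h). Later tables may drop fully depleted
species; a missing species counts as 0%.

Group balance tracks the gain of (Q⁴ + Q³_H) against the loss of the
low-connectivity group (Q²_H, Q²_Ca, Q¹_Ca, Q³_Ca and the merged peak,
which belongs to the loss group under either attribution). Because
fractions are compositional the two sums cancel exactly for exactly closed
tables; printed rounding leaves up to ~0.3 units.

The net process over the full span is classified from Δ(Q⁴ + Q³_H) with a
±2 percentage-unit dead band — the stated uncertainty of the fitted
fractions; the threshold is configurable and the value is a design choice,
not a measured constant. Evidence flags, not rate constants, are reported
for the three schematic reactions: Ca²⁺ release (full-span Qⁿ_Ca loss
beyond the threshold), Ca²⁺/H⁺ exchange (Q²_H rising above pristine by more
than the threshold within the first 24 h), and silanol condensation
(Q³_H gain beyond the threshold with a concurrent Q²_H decrease). No
kinetic model is fitted because the reactions are schematic and coupled.

## Pipeline, determinism, and problem sizes

All randomness flows from one config seed through
`numpy.random.default_rng`; child streams are derived per sample and stage,
so equal configs give byte-identical CSV outputs. The bundled reference
data (compositions and both speciation tables for S90/S85/S58) ship as
plain CSV and are the default inputs; synthetic spectra are generated from
them at run time rather than stored.

Test problem sizes: the stochastic recovery suites use the three pristine
single-pulse rows at 20 noise seeds with 12 restarts each, and a 50-spectrum
Dirichlet-perturbed ensemble for the median-error statistic — sizes chosen
to make the statistics stable at interactive runtimes. The acceptance
script averages the recovered Q⁴ fraction over 5 derived seeds.

## Known limitations

* Gaussian-only lineshapes and a zero baseline; no sideband or CP-dynamics
  modelling, so CPMAS fractions are taken as given rather than corrected
  for transfer efficiency.
* The merged-peak sharing factor is an assumption, not an inference; the
  package cannot resolve Q²_H from Q³_Ca spectrally.
* The split-network prediction assumes all P is orthophosphate with fixed
  Ca₃⁄₂PO₄ stoichiometry and ignores surface protons.
* Fraction recovery for ≥5 overlapping free-parameter peaks is
  identifiability-limited at realistic noise (see the deconvolution
  caveat); conclusions for such samples should lean on the restart SD and
  on constrained refits rather than single-fit point estimates.
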