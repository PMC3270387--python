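# qnspec

Quantitative Qⁿ-speciation analysis of ²⁹Si MAS NMR spectra of
CaO–SiO₂–(P₂O₅) mesoporous bioactive glasses (MBGs): constrained Gaussian
spectral deconvolution with restart ensembles, split-network prediction of
silicate connectivity, and surface-reaction bookkeeping over
simulated-body-fluid (SBF) soaking series.

## Who it is for

Solid-state NMR spectroscopists and biomaterials researchers who quantify
silicate speciation in bioactive glasses. The package covers the full
analysis chain from a 1D spectrum (or a synthetic stand-in with known
ground truth) to fractional Qⁿ populations, network-connectivity
statistics, and the classification of surface reactions during in vitro
SBF assays.

## The science in brief

A silicate tetrahedron with *n* bridging oxygens (BO) is a **Qⁿ** unit;
subscripts H/Ca mark whether its non-bridging oxygens are charge-balanced
by protons (silanols) or Ca²⁺. In disordered glasses each Qⁿ species gives
a Gaussian ²⁹Si resonance 7–13 ppm wide — Q⁴ near −110 ppm, Q³_H near
−101 ppm, Q²_H/Q³_Ca overlapping near −91 ppm, Q²_Ca near −83 ppm, Q¹_Ca
near −75 ppm — so a spectrum is deconvoluted into bounded Gaussians
(positions boxed within ±4 ppm, FWHM restricted to 7–13 ppm), refitted
from >10 random starts, and summarized by per-parameter mean ± SD.

Two independent routes to the average BO number n̄_BO are compared:

* **Composition route.** A glass Ca_q Si P_p O₂₊q₊₅p/₂ splits into a
  silicate subnetwork and a Ca₃⁄₂PO₄ orthophosphate reservoir
  ("split-network" analysis). The silicate phase keeps q − 3p/2 Ca per Si,
  each of which breaks one Si–O–Si bridge, so
  **n̄_BO = 4 − 2(q − 3p/2)**.
* **NMR route.** Drop the protonated species, renormalize the measured
  {Q⁴, Qⁿ_Ca} fractions {xₙ} to a unit sum, and evaluate **Σ n·xₙ**, with
  the merged −91 ppm peak attributed by a per-sample sharing policy.

Over SBF soaking, population changes are book-kept against three schematic
surface reactions (Ca²⁺ release, Ca²⁺/H⁺ exchange, silanol condensation
2 Q²_H → Q³_H + H₂O) and the net process is classified as
repolymerization, depolymerization, or stationary from the full-span change
of the Q⁴ + Q³_H population.

## Worked example

```python
import qnspec as q
from qnspec import datasets

# composition route: analysed Ca-rich glass (q = 0.659 Ca/Si, p = 0.148 P/Si)
comp = datasets.load_compositions("analysed")["S58"]
print(round(q.split_representation(comp).silicate_ca, 3))  # 0.437
print(round(q.predicted_nbo(comp), 3))                     # 3.126

# NMR route: pristine speciation table, merged peak shared 50/50 with Q3_Ca
table = datasets.pristine_table("S58")
nbo = q.nmr_nbo(table, datasets.default_policy("S58"))
print(round(nbo, 2))                             # 3.28
print(round(q.compare_connectivity(nbo, q.predicted_nbo(comp)), 2))  # 4.91 (%)
```

The two estimates, 3.28 BO per SiO₄ from NMR and 3.13 from the analysed
composition, agree to 4.9% — within the 5% band expected from the
compositional and fitting uncertainties.

Deconvolution of a synthetic spectrum with known ground truth:

```python
from qnspec.pipeline import truth_components, priors_from_table

table = datasets.pristine_table("S85")          # Q4/Q3_H/Q2_H = 75.1/17.8/7.1
spec = q.synthesize_spectrum(truth_components(table), noise_sd=0.01, seed=1)
ens = q.deconvolve(spec, priors_from_table(table), n_restarts=12, seed=2)
print({k: round(v, 2) for k, v in ens.fractions(sample="S85").fractions().items()})
# {'Q4': 74.92, 'Q3_H': 17.95, 'Q2_H': 7.12}
```

From the shell, the same pipeline end to end:

```sh
qnspec connectivity         # derived vs predicted BO table for S90/S85/S58
qnspec series               # classify the SBF soaking series
qnspec all --seed 7 --out-dir out/   # synthesis -> fit -> reports
```

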