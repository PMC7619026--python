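# cgmr — chirped guided-mode resonance biosensor array analysis

`cgmr` is a Python toolkit for reading out and analysing **chirped
guided-mode resonance (cGMR) photonic biosensor arrays**: chips that tile
hundreds of sub-wavelength grating pairs whose grating period varies
("chirps") along one axis, so that the optical resonance appears as a bright
bar in a camera image whose *position* encodes the resonance *wavelength*.
Molecular binding at the sensor surface shifts the effective refractive
index, the resonance wavelength, and therefore the bar — turning label-free
binding kinetics into a sub-pixel image-tracking problem across an entire
array at once.

The package is aimed at people building or analysing such imaging
biosensors: it provides the chip geometry model, a seeded synthetic-image
generator with stored ground truth, the robust tracking algorithm, the
calibration and noise-floor statistics, kinetic model fitting, and
multiplexed fingerprint classification.

## The method in brief

**Readout.** Each sensor is a *mirrored pair* of gratings chirped in
opposite directions. Every pixel row of a grating's ROI is fitted with a
Gaussian `A·exp(−(x−x₀)²/2w²) + b` (an efficient approximation to the
underlying Fano lineshape); the **median** of the ~150 row centres is the
bar position `x_med` and their IQR is a per-read quality metric. The pair's
differential shift

```
Δ = ( sign_a·(x_a − ref_a) + sign_b·(x_b − ref_b) ) / 2
```

adds equal-and-opposite spectral motion while cancelling common-mode
mechanical translation (vibration, drift). Pixels convert to nm through the
per-sensor wavelength sensitivity `s` (px/nm, from a sweep calibration;
nominally `px_per_window/4`), and nm to refractive-index units through the
bulk sensitivity (default 100 nm/RIU).

**Calibration & detection limits.** A wavelength sweep gives a per-sensor
OLS slope of bar shift vs λ; the array is summarised by mean, SD and CV.
The noise floor σ is the mean per-sensor temporal SD of a baseline RIU
trace; LOD = 3σ and LOQ = 10σ.

**Kinetics.** Binding steps follow `y(t) = ΔRIU·(1 − e^(−k_app·t))`;
heterogeneous/multivalent binding uses a two-phase (fast + slow) exponential
in both association and dissociation, with effective rates taken as
amplitude-weighted means, `k_on = (k_obs − k_off)/C` under the
pseudo-first-order 1:1 approximation and `K_D = k_off/k_on`. Equilibrium
dose-response data fit a Langmuir isotherm `R(c) = R_max·c/(K_D + c)` with a
3σ concentration LOD.

**Classification.** Per-channel step shifts (mean of 20 points after minus
20 before a binding step) form fingerprint vectors classified by Fisher LDA
(generalized eigenproblem `Sb·v = λ·Sw·v`), with leave-one-out
cross-validation and hold-out validation.

## Worked example

Simulate a calibration sweep, track it, and calibrate — all from the shell:

```sh
$ cgmr simulate --mode sweep --n-pairs 8 --seed 42 --out sweep.tiff
wrote 11-frame sweep stack (8 pairs) to sweep.tiff
$ cgmr track --stack sweep.tiff --layout sweep.layout.json --out traces.csv
tracked 8 pairs x 11 frames -> traces.csv
$ cgmr calibrate --traces traces.csv --out calibration.json
calibrated 8 sensors: mean 36.80 px/nm (SD 0.01, CV 0.01%) -> calibration.json
```

The generator moved the bars at a true sensitivity of 36.8 px/nm; tracking
plus per-sensor regression recovers 36.80 px/nm. The tiny SD reflects that
these 8 sensors share one true sensitivity — on a real chip the CV
additionally carries fabrication spread.

Kinetics through the library API (statsmodels-style model → `fit()` →
results):

```python
>>> import numpy as np
>>> from cgmr import SingleExponentialModel, BindingScenario
>>> t = np.arange(0.0, 300.0, 1.0)
>>> sc = BindingScenario.single_step(9.76e-4, 0.0649, baseline_s=0.0, duration_s=300.0)
>>> y = sc.response(t) + np.random.default_rng(42).normal(0, 0.05 * 9.76e-4, t.size)
>>> print(SingleExponentialModel((t, y)).fit(bootstrap=199, seed=0).summary())
single_exp fit
==============================
n = 300, RSS = 6.134e-07
   delta_riu = 0.000991985   [90% CI 0.000960989, 0.00102058]
       k_app = 0.0675826   [90% CI 0.0642389, 0.0709005]
      offset = -1.91632e-05   [90% CI -5.23818e-05, 1.13538e-05]
```

The generator's amplitude (9.76×10⁻⁴ RIU) and apparent rate (0.0649 s⁻¹)
sit inside the bootstrap confidence intervals recovered from the 5%-noise
trace.

Fingerprint classification:

```sh
$ cgmr simulate --mode fingerprints --seed 42 --out fp.csv
$ cgmr classify --fingerprints fp.csv --out-dir lda
...
  F1: eigenvalue      70.76  ( 71.5% between-class variance)
  F2: eigenvalue      27.69  ( 28.0% between-class variance)
...
LOOCV accuracy: 100.0%
```

Five lectin classes across six glycopolymer channels separate completely in
the first two canonical factors; the score plot with 95% confidence
ellipses is written to `lda/scores.png`.

## Layout

```
src/cgmr/
  layout.py     chip geometry, designs, optical setups, unit conversions
  simulate.py   seeded synthetic stacks, binding scenarios, fingerprints
  track.py      row-wise Gaussian fitting, ROI detection, differential traces
  calibrate.py  sweep calibration, noise floor, LOD/LOQ, dynamic range
  kinetics.py   single-/two-phase exponential models, affinity, dose-response
  classify.py   Fisher LDA, LOOCV, hold-out, fingerprint assembly
  io.py, cli.py TIFF+sidecar and CSV formats, run logs, `cgmr` CLI
docs/methods.md the model assumptions, defaults and their rationale
```
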