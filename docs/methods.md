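# Methods

This note documents the models implemented in `cgmr`, the defaults chosen
where the design was genuinely open, and what the synthetic-data generator
does and does not emulate.

## Forward model of the array image

A chirped grating maps resonance wavelength to position. We model each
grating's ROI as a uniform *pedestal* (the patterned region reflects above
the unpatterned chip background) plus a resonance bar with Gaussian
cross-section along the chirp (column) axis, constant along rows:

    I(row, col) = background + pedestal + A · exp(−(col − c)² / 2σ²)

with the bar centre

    c = ROI centre + chirp_sign · s · (λ_res − λ₀) + jitter

where `s` is the pixel scale (px/nm), `λ₀` the centre of the design's 4 nm
spectral window, and `λ_res = λ₀ + S_bulk · ΔRIU` during binding
experiments (`S_bulk` = bulk sensitivity, 100 nm/RIU by default, from the
correspondence of a 2 nm scan with a 2×10⁻² RIU dynamic range). For
wavelength sweeps `λ_res` is the illumination wavelength itself.

Pixel conventions: rectangles are 0-based and half-open; the column axis is
spectral; `chirp_sign = +1` means the bar moves to higher columns when the
resonance red-shifts. Pair members are mirrored (`sign_a = −sign_b`), so a
rigid translation is common-mode in pixels while a spectral shift is
antisymmetric — the differential cancels the former and keeps the latter.
The differential is defined as the *average* of the sign-corrected member
shifts (not their difference), so 1 px of differential equals 1 px of
spectral motion per grating; the sign convention makes increasing RIU
(increasing surface mass) positive.

Noise model, applied in order signal → Poisson (shot) → Gaussian (read):
defaults are 25 counts read noise, shot noise on, common-mode jitter 0.3 px
SD per frame, no drift. Jitter and the optional linear drift are rigid
translations of the whole field — mechanical motion of chip or camera —
and are therefore cancelled by construction in the differential readout;
per-sensor spectral drift is not modelled. Bar defaults: FWHM 12 px
(plausible for a 1 nm FWHM bandpass filter at these pixel scales) and
amplitude 20:1 against read noise; the tracking tests exercise FWHM 6–24 px
and SNR 5–50.

**Fano option.** Real GMR lineshapes are asymmetric (Fano); the renderer
can produce `((q+ξ)²/(1+ξ²))/(1+q²)` profiles with the *intensity maximum*
placed at the mapped resonance column (the tracked quantity is the
intensity maximum, so this is the convention under which "bar position" is
well defined). Gaussian-fitting such a bar leaves a static offset — about
1 px at q=5 for a 12 px FWHM bar, 0.36 px at q=20 — which is constant under
bar motion, so baseline-referenced *shifts* track truth to < 0.05 px. The
offset therefore does not propagate into any differential quantity.

## Tracking

Each ROI row is fitted by nonlinear least squares with
`A·exp(−(x−x₀)²/2w²) + b`; starts are x₀ = argmax, A = max−min, b = min,
w = FWHM/2.355. Rows are mutually independent; the implementation batches
them through one damped Gauss–Newton (Levenberg–Marquardt) iteration with
per-row damping and acceptance, which is exactly equivalent to fitting rows
one at a time (verified against `scipy.optimize.curve_fit` in the tests)
but vectorised. Fits run inside a common window centred on the bar (located
from the column-median profile, half-width max(25 px, 4·FWHM estimate)) to
keep them fast and away from ROI edges. A row whose peak prominence is
below 5× a difference-based robust noise estimate is marked unconverged
rather than fitted.

Per read: `x_med` = median of converged row centres, `iqr` their
interquartile range. Quality control: a read passes with ≥ `min_rows`
(default 50 of ~150) converged rows and IQR ≤ `iqr_max` (default 2 px);
with 3–min_rows rows the position is still reported but flagged. Flagged
frames carry their value with `qc=False`; values are never silently
interpolated.

Baseline referencing: per-grating reference positions are the mean `x_med`
over the baseline window (all frames before the first binding step; the
first frame for sweeps), and the differential trace is additionally zeroed
on that window.

**ROI detection.** The grating pedestals are segmented with a 3-class
multi-Otsu threshold (lowest cut) — plain Otsu would segment the bright but
narrow bars instead — followed by connected-component labelling, area
filtering, row-band grouping and left/right pairing. With a layout hint the
hint is registered to the image by integer-pixel phase correlation and
translated instead.

## Calibration, noise floor, dynamic range

Sensitivity is the per-sensor OLS slope of differential pixel shift vs
illumination wavelength over a sweep (≥ 3 wavelengths); the array is
summarised by mean, sample SD and CV = 100·SD/mean. The regression is run
on the pair differential, not per grating, because sensitivity is reported
per sensor pair. Measured sensitivities take precedence over the nominal
chirp map `px_per_window/4` in all pixel→nm conversions: the two differ on
real instruments (36.8 vs 45.5 px/nm on the characterisation setup).

Noise floor: σ = mean over sensors of the per-sensor temporal SD of a
baseline RIU trace (≥ 30 frames). The averaging order (mean-of-SDs vs
pooled residual SD) is not uniquely determined by the convention's usual
statement; mean-of-SDs is the default and the pooled variant is available
behind a flag. LOD = 3σ, LOQ = 10σ, fixed: the printed pair
(4.93×10⁻⁴, 1.64×10⁻³ RIU) satisfies the 10/3 ratio, confirming the
convention. Whether σ should be computed on differential or single-grating
traces is likewise unstated; default is differential.

Dynamic range is span/S_bulk for a given scan span, or the union width of
the designs' spectral windows (5 nm for the default dual-design chip,
i.e. 5×10⁻² RIU) otherwise.

The two chirp designs are carried with both their period ranges
(420–424 / 421–425 nm) and their usable spectral windows; the default
windows are 4 nm wide, offset by 1 nm and centred on the 647.1 nm
illumination line (645.1–649.1 and 646.1–650.1 nm). The union/overlap
arithmetic (5 nm / 3 nm) depends only on the 4-nm-width/1-nm-offset
structure. The number of pairs in a field of view is data on the setup
object, not a constant — published counts for the same instrument differ
(77 vs 79) — and a pair is modelled as two mirrored gratings of the *same*
design with designs alternating between adjacent pairs; the source material
does not pin this down, and any assignment with mirrored chirp within a
pair gives identical differential behaviour.

## Kinetics

Single-step binding under continuous flow:
`y(t) = ΔRIU·(1 − e^(−k_app(t−t₀))) + c`, fitted by least squares with the
rate initialised from a log-linearised early/late slope. Flat segments
(peak-to-peak below 3× a difference-based noise estimate) are rejected
rather than fitted.

Two-phase binding (heterogeneous, multivalent surfaces):

    association:   y(t) = A_f(1−e^(−k_obs,f t)) + A_s(1−e^(−k_obs,s t))
    dissociation:  y(t) = B_f e^(−k_off,f t) + B_s e^(−k_off,s t)

all parameters non-negative, phases ordered fast-first. A single effective
rate pair is derived as the **amplitude-weighted mean** of the phase rates
(the four-parameter→one-K_D reduction is not uniquely defined anywhere
authoritative; amplitude weighting is the declared default and a
fast-phase-only alternative is available). Then, under the
pseudo-first-order 1:1 approximation at known analyte concentration C —
itself a phenomenological approximation for multivalent glycopolymer
systems — `k_on = (k_obs − k_off)/C` and `K_D = k_off/k_on`. If the fitted
`k_obs ≤ k_off` the result is flagged and K_D withheld. If a segment's two
rates are within a factor 1.5 the phases are not identifiable: the fit
collapses to a single phase with a warning (and reproduces the
single-exponential analysis exactly).

Parameter uncertainty: residual-resampling bootstrap (default 500 draws,
seeded; percentile intervals, 90% by default). Coverage of the 90%
intervals was verified at 0.85–0.95 empirically.

Dose-response: Langmuir `R(c) = R_max·c/(K_D + c)` (≥ 4 concentrations over
≥ 1 decade); the concentration LOD solves `R(c) = 3σ_blank` exactly,
`c = 3σK_D/(R_max − 3σ)`, with a not-detectable sentinel (∞) when the curve
never clears the threshold.

## Fingerprints and LDA

A fingerprint row is one analyte exposure × replicate: per-channel step
shifts computed as mean(20 points after) − mean(20 points before) the
binding step. Rows are per-sensor replicates by default (per-polymer means
are a flag away); rows missing a channel are dropped with a warning.

Fisher LDA solves `Sb v = λ Sw v` via a generalized symmetric eigensolver,
with Sw the pooled within-class covariance and Sb the prior-weighted
between-class scatter (equal priors by default — replicates are balanced by
design). When cond(Sw) > 10⁸ a shrinkage ridge `δ·trace(Sw)/p` (δ = 10⁻⁶)
is added. Axes are Sw-orthonormal, so nearest-centroid classification in
canonical space is the Gaussian equal-covariance rule on the discriminant
subspace; the reported "confidence" is the max posterior under that model
(a model-based quantity — "100% confidence" means the posterior rounds to
1, not a frequentist guarantee). Score-plot confidence ellipses use the
per-class score covariance with the χ²(2 df) quantile.

The fingerprint generator draws class mean + iid Gaussian channel noise.
Class means follow a two-latent-trait construction (a GlcNAc-like and a
Gal/GalNAc-like affinity axis with channel loadings, plus small
class-specific tertiary cross-reactivities), scaled so the *minimum*
pairwise class-mean distance equals the requested separation (default 8
within-class SDs, noise SD 10⁻⁴ RIU). The trait structure makes the first
two canonical factors carry nearly all between-class variance, as in
well-behaved lectin panels.

## What the generator does and does not emulate

Emulated: the chip tiling (322 pairs, two overlapping 4 nm designs, three
optical setups at 182/354/255 px per window), near-Gaussian or Fano bars,
shot/read noise, common-mode jitter and drift, exponential binding-driven
resonance motion, surface-heterogeneity amplitude scaling, and fingerprint
class structure. Not emulated: optical point-spread, vignetting and lens
distortion; hot pixels and rolling shutter; source-spectrum intensity
variation across a sweep; temperature-driven spectral drift;
mass-transport-limited binding; matrix fouling. Passing tests therefore
demonstrate the correctness and robustness of the *analysis* under the
stated noise structure, not instrument-level performance on real chips.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at sizes chosen to
exercise the pipeline end to end while staying desk-scale: full-chip
detection uses the complete 322-pair frame (~43 MP) once; sensitivity
recovery uses 50 pairs × 11 wavelengths through the image pipeline;
kinetic Monte-Carlo statements use 100–150 trace-level repeats (bootstrap
coverage at 99 draws); classification uses the 5 × 8 replicate design. Seeds
are fixed everywhere; identical seeds give bit-identical stacks. Degenerate
inputs (flat profiles, blank images, empty stacks, singleton classes in
LOOCV refits, non-physical rate orderings) return flagged results or
explicit errors rather than silent numbers.

## Known limitations

- The pseudo-first-order K_D is an effective, phenomenological quantity for
  multivalent analytes; it requires the analyte concentration as input.
- The Gaussian row fit carries a static sub-pixel offset on strongly
  asymmetric (low-q Fano) lineshapes; differentials are unaffected.
- ROI detection assumes the synthetic pedestal contrast; real-chip label
  OCR is out of scope (a layout hint covers that case).
- Per-sensor sensitivity calibration assumes linearity of the chirp map
  over the scanned range.
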