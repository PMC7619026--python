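"""Seeded synthetic-data generator for cGMR array experiments.

Produces image stacks (binding time series and wavelength sweeps), kinetic
ground-truth traces and fingerprint matrices with the statistical structure
the readout assumes: a bright resonance bar of near-Gaussian cross-section in
each grating ROI, common-mode mechanical jitter shared by both members of a
pair, shot and read noise, and resonance motion driven by exponential binding
curves.  Every generator takes a seed and is bit-deterministic for a given
seed.

The forward model per grating is

    column(t) = ROI centre + chirp_sign * s * (lambda_res(t) - lambda_0) + jitter(t)

with ``s`` the pixel scale (px/nm), ``lambda_0`` the centre of the design's
spectral window and ``lambda_res(t) = lambda_0 + bulk_sensitivity * RIU(t)``
for binding experiments (or the illumination wavelength for sweeps).  Jitter
is a rigid per-frame translation, identical for both members of a pair, so it
cancels exactly in the differential readout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import FingerprintMatrix
from .layout import (
    DEFAULT_BULK_SENSITIVITY_NM_PER_RIU,
    DEFAULT_DESIGNS,
    ArrayLayout,
    OpticalSetup,
    SensorPairGeom,
)
from .stack import FrameStack

__all__ = [
    "NoiseModel",
    "BindingStep",
    "BindingScenario",
    "FingerprintModel",
    "render_frame",
    "simulate_stack",
    "simulate_sweep",
    "simulate_fingerprints",
    "default_fingerprint_model",
    "DEFAULT_BAR_FWHM_PX",
    "DEFAULT_BAR_AMPLITUDE",
]

_DESIGN_BY_ID = {d.design_id: d for d in DEFAULT_DESIGNS}

# Bar rendering defaults: FWHM plausible for a 1 nm FWHM bandpass filter on
# these pixel scales; amplitude 20:1 against the default read noise.
DEFAULT_BAR_FWHM_PX = 12.0
DEFAULT_BAR_AMPLITUDE = 500.0
DEFAULT_PEDESTAL = 300.0
DEFAULT_BACKGROUND = 200.0


@dataclass(frozen=True)
class NoiseModel:
    """Camera and mechanical noise applied to rendered frames.

    ``jitter_sd_px`` and ``drift_px_per_frame`` are rigid translations of the
    whole field (common-mode within every pair); read noise is additive
    Gaussian in counts; shot noise is Poisson on the signal.  Order:
    signal -> Poisson -> Gaussian.
    """

    read_noise_sd: float = 25.0
    shot_noise: bool = True
    jitter_sd_px: float = 0.3
    drift_px_per_frame: float = 0.0

    def __post_init__(self) -> None:
        if self.read_noise_sd < 0 or self.jitter_sd_px < 0:
            raise ValueError("noise SDs must be non-negative")


QUIET = NoiseModel(read_noise_sd=0.0, shot_noise=False, jitter_sd_px=0.0)


@dataclass(frozen=True)
class BindingStep:
    """One functionalisation/binding step driving the resonance.

    ``model`` selects the response shape:

    * ``single_exp`` — ``dRIU * (1 - exp(-k_app * (t - t_start)))``; params:
      ``k_app`` and optionally ``k_off`` for an exponential dissociation
      after ``t_end``.
    * ``two_phase`` — fast + slow association, each phase dissociating with
      its own off-rate after ``t_end``; params: ``frac_fast, k_obs_fast,
      k_obs_slow, k_off_fast, k_off_slow``.
    """

    label: str
    delta_riu: float
    model: str
    params: dict
    t_start: float
    t_end: float | None = None

    def __post_init__(self) -> None:
        if self.model not in ("single_exp", "two_phase"):
            raise ValueError(f"unknown kinetic model {self.model!r}")
        if not math.isfinite(self.delta_riu):
            raise ValueError("amplitude must be finite")
        for k, v in self.params.items():
            if k.startswith(("k_",)) and not v > 0:
                raise ValueError(f"rate {k} must be positive")
        if self.t_end is not None and self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")

    def response(self, t: np.ndarray) -> np.ndarray:
        """RIU contribution of this step at times ``t`` (seconds)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        tau = t - self.t_start
        on = tau > 0
        if self.model == "single_exp":
            k = self.params["k_app"]
            assoc = self.delta_riu * (1.0 - np.exp(-k * tau[on]))
            out[on] = assoc
            if self.t_end is not None and "k_off" in self.params:
                td = t - self.t_end
                off = td > 0
                y_end = self.delta_riu * (1.0 - math.exp(-k * (self.t_end - self.t_start)))
                out[off] = y_end * np.exp(-self.params["k_off"] * td[off])
        else:
            f = self.params["frac_fast"]
            kf, ks = self.params["k_obs_fast"], self.params["k_obs_slow"]
            af, aslow = f * self.delta_riu, (1.0 - f) * self.delta_riu
            out[on] = af * (1.0 - np.exp(-kf * tau[on])) + aslow * (1.0 - np.exp(-ks * tau[on]))
            if self.t_end is not None:
                td = t - self.t_end
                off = td > 0
                te = self.t_end - self.t_start
                bf = af * (1.0 - math.exp(-kf * te))
                bs = aslow * (1.0 - math.exp(-ks * te))
                out[off] = bf * np.exp(-self.params["k_off_fast"] * td[off]) + bs * np.exp(
                    -self.params["k_off_slow"] * td[off]
                )
        return out


@dataclass(frozen=True)
class BindingScenario:
    """Ordered binding steps plus a pre-step baseline."""

    steps: tuple[BindingStep, ...] = ()
    baseline_s: float = 60.0
    duration_s: float | None = None

    def __post_init__(self) -> None:
        starts = [s.t_start for s in self.steps]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("step start times must be strictly increasing")
        if self.baseline_s < 0:
            raise ValueError("baseline must be non-negative")

    @property
    def total_duration_s(self) -> float:
        if self.duration_s is not None:
            return self.duration_s
        if not self.steps:
            return self.baseline_s
        last = max(s.t_end if s.t_end is not None else s.t_start for s in self.steps)
        return last + 300.0

    def response(self, t: np.ndarray) -> np.ndarray:
        """Total RIU signal (sum of step responses) at times ``t``."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for s in self.steps:
            out += s.response(t)
        return out

    @classmethod
    def single_step(
        cls,
        delta_riu: float,
        k_app: float,
        *,
        baseline_s: float = 60.0,
        duration_s: float | None = None,
        label: str = "step",
    ) -> "BindingScenario":
        step = BindingStep(label, delta_riu, "single_exp", {"k_app": k_app}, t_start=baseline_s)
        return cls(steps=(step,), baseline_s=baseline_s, duration_s=duration_s)


# -- frame rendering -------------------------------------------------------


def _bar_profile(x: np.ndarray, centre: float, fwhm: float, fano_q: float | None) -> np.ndarray:
    """Unit-peak bar cross-section along the chirp axis.

    Gaussian by default; with ``fano_q`` an asymmetric Fano profile whose
    intensity maximum is placed at ``centre`` (the tracked bar position is
    the intensity maximum).
    """
    if fano_q is None:
        sigma = fwhm / 2.3548200450309493
        return np.exp(-0.5 * ((x - centre) / sigma) ** 2)
    q = fano_q
    gamma = fwhm / 2.0
    # the raw Fano (q+xi)^2/(1+xi^2) peaks at xi = 1/q with value 1+q^2
    xi = (x - centre) / gamma + 1.0 / q
    return ((q + xi) ** 2 / (1.0 + xi**2)) / (1.0 + q * q)


def _grating_centre_col(
    geom: SensorPairGeom,
    member: str,
    lambda_nm: float,
    px_per_nm: float,
) -> float:
    design = _DESIGN_BY_ID[geom.design_id]
    roi = geom.roi_a if member == "a" else geom.roi_b
    sign = geom.chirp_sign_a if member == "a" else geom.chirp_sign_b
    return roi.centre_col + sign * px_per_nm * (lambda_nm - design.window_centre_nm)


def _resolve_lambda(resonance_nm, pair_id: str, member: str, design_id: int) -> float:
    if np.isscalar(resonance_nm):
        return float(resonance_nm)
    if isinstance(resonance_nm, dict):
        v = resonance_nm.get((pair_id, member), resonance_nm.get(pair_id))
        if v is None:
            raise ValueError(f"no resonance given for pair {pair_id!r}")
        if isinstance(v, (tuple, list)):
            return float(v[0] if member == "a" else v[1])
        return float(v)
    raise TypeError("resonance_nm must be a scalar or a dict keyed by pair id")


def render_frame(
    layout: ArrayLayout,
    resonance_nm,
    setup: OpticalSetup,
    noise: NoiseModel | None = None,
    *,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    jitter_px: float = 0.0,
    sensitivity_px_per_nm: float | None = None,
    bar_fwhm_px: float = DEFAULT_BAR_FWHM_PX,
    amplitude: float = DEFAULT_BAR_AMPLITUDE,
    pedestal: float = DEFAULT_PEDESTAL,
    background: float = DEFAULT_BACKGROUND,
    fano_q: float | None = None,
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Render one array image for given per-grating resonance wavelengths.

    ``resonance_nm`` is a scalar (all gratings; interpreted relative to each
    design's window) or a dict ``pair_id -> lambda`` / ``(lambda_a,
    lambda_b)`` / ``(pair_id, member) -> lambda``.  Each ROI gets a uniform
    pedestal (the grating reflects above the unpatterned background, which is
    what ROI detection segments) plus the resonance bar.  ``jitter_px`` is a
    rigid translation added to every bar centre — common-mode by
    construction.

    Returns the uint16 image and a list of ``(pair_id, member)`` whose bar
    centre fell outside its ROI (clipped, flagged, still rendered).
    """
    if noise is not None and (noise.shot_noise or noise.read_noise_sd > 0) and rng is None:
        rng = np.random.default_rng(seed)
    s = sensitivity_px_per_nm if sensitivity_px_per_nm is not None else setup.nominal_px_per_nm
    img = np.full(layout.image_shape, background, dtype=float)
    flagged: list[tuple[str, str]] = []
    for geom in layout.pairs:
        for member, roi in (("a", geom.roi_a), ("b", geom.roi_b)):
            lam = _resolve_lambda(resonance_nm, geom.pair_id, member, geom.design_id)
            centre = _grating_centre_col(geom, member, lam, s) + jitter_px
            if not (roi.col0 <= centre < roi.col1):
                flagged.append((geom.pair_id, member))
            x = np.arange(roi.col0, roi.col1, dtype=float)
            profile = pedestal - background + amplitude * _bar_profile(x, centre, bar_fwhm_px, fano_q)
            img[roi.row0 : roi.row1, roi.col0 : roi.col1] += profile[None, :]
    if noise is not None:
        if noise.shot_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if noise.read_noise_sd > 0:
            img = img + rng.normal(0.0, noise.read_noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16), flagged


# -- stacks ----------------------------------------------------------------


def _jitter_series(noise: NoiseModel | None, n: int, rng: np.random.Generator) -> np.ndarray:
    if noise is None:
        return np.zeros(n)
    j = np.zeros(n)
    if noise.jitter_sd_px > 0:
        j = rng.normal(0.0, noise.jitter_sd_px, size=n)
    return j + noise.drift_px_per_frame * np.arange(n)


def _truth_frame(layout: ArrayLayout, shift_nm: np.ndarray, px_per_nm: float, bulk: float) -> pd.DataFrame:
    """Long-format ground-truth differential trace, identical for every pair."""
    n = len(shift_nm)
    recs = []
    for geom in layout.pairs:
        recs.append(
            pd.DataFrame(
                {
                    "pair_id": geom.pair_id,
                    "frame": np.arange(n),
                    "shift_px": shift_nm * px_per_nm,
                    "shift_nm": shift_nm,
                    "shift_riu": shift_nm / bulk,
                }
            )
        )
    return pd.concat(recs, ignore_index=True)


def simulate_stack(
    layout: ArrayLayout,
    scenario: BindingScenario,
    setup: OpticalSetup,
    noise: NoiseModel | None = None,
    *,
    frame_period_s: float = 1.0,
    seed: int = 0,
    bulk_sensitivity: float = DEFAULT_BULK_SENSITIVITY_NM_PER_RIU,
    sensitivity_px_per_nm: float | None = None,
    amplitude_scale: dict[str, float] | None = None,
    **render_kw,
) -> FrameStack:
    """Simulate a binding time series: resonance follows the scenario's RIU curve.

    ``amplitude_scale`` optionally scales the RIU response per pair
    (surface-heterogeneity emulation).  The ground-truth differential trace
    (jitter-free, noise-free) is stored on the returned stack.
    """
    if frame_period_s <= 0:
        raise ValueError("frame_period_s must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, scenario.total_duration_s + 0.5 * frame_period_s, frame_period_s)
    riu = scenario.response(t)
    s = sensitivity_px_per_nm if sensitivity_px_per_nm is not None else setup.nominal_px_per_nm
    jitter = _jitter_series(noise, len(t), rng)
    frames = np.empty((len(t), *layout.image_shape), dtype=np.uint16)
    flagged: set[tuple[str, str]] = set()
    scale = amplitude_scale or {}
    truth_recs = []
    for geom in layout.pairs:
        a = scale.get(geom.pair_id, 1.0)
        nm = riu * bulk_sensitivity * a
        truth_recs.append(
            pd.DataFrame(
                {
                    "pair_id": geom.pair_id,
                    "frame": np.arange(len(t)),
                    "shift_px": nm * s,
                    "shift_nm": nm,
                    "shift_riu": riu * a,
                }
            )
        )
    for i, ti in enumerate(t):
        res = {
            geom.pair_id: _DESIGN_BY_ID[geom.design_id].window_centre_nm
            + riu[i] * bulk_sensitivity * scale.get(geom.pair_id, 1.0)
            for geom in layout.pairs
        }
        frame, fl = render_frame(
            layout,
            res,
            setup,
            noise,
            rng=rng,
            jitter_px=jitter[i],
            sensitivity_px_per_nm=sensitivity_px_per_nm,
            **render_kw,
        )
        frames[i] = frame
        flagged.update(fl)
    return FrameStack(
        frames=frames,
        kind="timeseries",
        t_s=t,
        meta={
            "setup": setup.name,
            "seed": seed,
            "layout_hash": layout.content_hash(),
            "baseline_s": scenario.baseline_s,
            "bulk_sensitivity_nm_per_riu": bulk_sensitivity,
            "sensitivity_px_per_nm": s,
            "flagged": sorted(flagged),
            "noise": None if noise is None else vars(noise).copy(),
        },
        ground_truth=pd.concat(truth_recs, ignore_index=True),
    )


def simulate_sweep(
    layout: ArrayLayout,
    wavelengths: np.ndarray,
    true_sensitivity_px_per_nm: float,
    setup: OpticalSetup,
    noise: NoiseModel | None = None,
    *,
    seed: int = 0,
    **render_kw,
) -> FrameStack:
    """Simulate an illumination-wavelength sweep (calibration acquisition).

    Bar positions move linearly with wavelength at
    ``true_sensitivity_px_per_nm`` (sign per chirp direction).  The stored
    ground truth is the differential shift relative to the first wavelength.
    """
    lam = np.asarray(wavelengths, dtype=float)
    if lam.size < 3:
        raise ValueError("a sweep needs at least 3 wavelengths")
    dl = np.diff(lam)
    if not (np.all(dl > 0) or np.all(dl < 0)):
        raise ValueError("wavelengths must be strictly monotone")
    if not true_sensitivity_px_per_nm > 0:
        raise ValueError("true sensitivity must be positive")
    rng = np.random.default_rng(seed)
    jitter = _jitter_series(noise, lam.size, rng)
    frames = np.empty((lam.size, *layout.image_shape), dtype=np.uint16)
    flagged: set[tuple[str, str]] = set()
    for i, li in enumerate(lam):
        frame, fl = render_frame(
            layout,
            float(li),
            setup,
            noise,
            rng=rng,
            jitter_px=jitter[i],
            sensitivity_px_per_nm=true_sensitivity_px_per_nm,
            **render_kw,
        )
        frames[i] = frame
        flagged.update(fl)
    shift_nm = lam - lam[0]
    return FrameStack(
        frames=frames,
        kind="sweep",
        wavelengths_nm=lam,
        meta={
            "setup": setup.name,
            "seed": seed,
            "layout_hash": layout.content_hash(),
            "true_sensitivity_px_per_nm": true_sensitivity_px_per_nm,
            "flagged": sorted(flagged),
            "noise": None if noise is None else vars(noise).copy(),
        },
        ground_truth=_truth_frame(layout, shift_nm, true_sensitivity_px_per_nm, DEFAULT_BULK_SENSITIVITY_NM_PER_RIU),
    )


# -- fingerprints ----------------------------------------------------------


@dataclass(frozen=True)
class FingerprintModel:
    """Generative model of lectin x glycopolymer-channel response fingerprints."""

    class_means: pd.DataFrame  # index: class label, columns: channels, values: dRIU
    noise_sd: float
    n_per_class: int = 8

    def __post_init__(self) -> None:
        if not np.isfinite(self.class_means.to_numpy()).all():
            raise ValueError("class means must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")

    @property
    def min_pairwise_separation_sigma(self) -> float:
        """Smallest between-class mean distance in units of the within-class SD."""
        m = self.class_means.to_numpy()
        d = np.linalg.norm(m[:, None, :] - m[None, :, :], axis=-1)
        iu = np.triu_indices(len(m), k=1)
        return float(d[iu].min() / self.noise_sd) if self.noise_sd > 0 else math.inf


# Relative binding pattern of the five lectins across the backbone control
# (P2) and the five glycopolymers (P3-A..E).  Lectin selectivity is dominated
# by two latent glycan-affinity traits (GlcNAc-like vs Gal/GalNAc-like), each
# loading differently on the polymer channels, plus a small class-specific
# tertiary cross-reactivity; a per-channel offset keeps all mean responses
# non-negative.  The offset shifts no between-class structure, so the
# between-class scatter of the class means is carried almost entirely by the
# first two canonical directions.  Rows are scaled to the requested class
# separation by default_fingerprint_model.
_LECTIN_CHANNELS = ["P2", "P3-A", "P3-B", "P3-C", "P3-D", "P3-E"]
_LECTIN_NAMES = ["WGA", "ConA", "PNA", "SBA", "LTB"]
_TRAIT_SCORES = np.array(
    [
        [1.00, 0.10],  # WGA
        [-0.85, -0.45],  # ConA
        [0.20, 1.00],  # PNA
        [-0.10, -0.95],  # SBA
        [-0.45, 0.55],  # LTB
    ]
)
_TRAIT_LOADINGS = np.array(
    [
        [0.0, 0.90, 0.35, -0.25, 0.10, 0.00],  # GlcNAc-like trait
        [0.0, 0.10, -0.30, 0.15, 0.85, 0.45],  # Gal/GalNAc-like trait
    ]
)
_TERTIARY = 0.10 * np.array(
    [
        [0, 0, 1, 0, 0, 0],
        [0, 0, 0, 0, 0, 1],
        [0, 1, 0, 0, 0, 0],
        [0, 0, 0, 1, 0, 0],
        [0, 0, 0, 0, 1, 0],
    ],
    dtype=float,
)
_PATTERN_RAW = _TRAIT_SCORES @ _TRAIT_LOADINGS + _TERTIARY
_LECTIN_PATTERN = pd.DataFrame(
    _PATTERN_RAW - np.minimum(_PATTERN_RAW.min(axis=0), 0.0),
    index=_LECTIN_NAMES,
    columns=_LECTIN_CHANNELS,
)


def default_fingerprint_model(
    *,
    separation_sigma: float = 8.0,
    noise_sd: float = 1e-4,
    n_per_class: int = 8,
) -> FingerprintModel:
    """Five-lectin, six-channel model with a controlled class separation.

    The lectin pattern matrix is scaled so the *minimum* pairwise distance
    between class means equals ``separation_sigma * noise_sd``.
    """
    m = _LECTIN_PATTERN.to_numpy()
    d = np.linalg.norm(m[:, None, :] - m[None, :, :], axis=-1)
    iu = np.triu_indices(len(m), k=1)
    scale = separation_sigma * noise_sd / d[iu].min()
    return FingerprintModel(
        class_means=_LECTIN_PATTERN * scale,
        noise_sd=noise_sd,
        n_per_class=n_per_class,
    )


def simulate_fingerprints(model: FingerprintModel, seed: int = 0) -> FingerprintMatrix:
    """Draw replicate fingerprints: class mean + iid Gaussian noise per channel."""
    rng = np.random.default_rng(seed)
    rows, labels, ids = [], [], []
    for cls in model.class_means.index:
        mu = model.class_means.loc[cls].to_numpy(dtype=float)
        for r in range(model.n_per_class):
            rows.append(mu + rng.normal(0.0, model.noise_sd, size=mu.size))
            labels.append(str(cls))
            ids.append(f"{cls}-{r + 1:02d}")
    X = pd.DataFrame(np.asarray(rows), index=ids, columns=list(model.class_means.columns))
    return FingerprintMatrix(X=X, y=np.asarray(labels, dtype=object))
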