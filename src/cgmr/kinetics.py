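"""Binding-kinetics models: step shifts, exponential fits, affinity, dose-response.

Model objects follow the construct / ``fit()`` / results pattern:

* :class:`SingleExponentialModel` — ``y(t) = dRIU * (1 - exp(-k_app (t - t0))) + c``
  for a single functionalisation or binding step under continuous flow.
* :class:`TwoPhaseModel` — fast + slow exponential phases in both association
  and dissociation, a phenomenological description of heterogeneous,
  multivalent surface binding.  Effective on/off rates are amplitude-weighted
  means of the phase rates (configurable to fast-phase-only); with the
  pseudo-first-order 1:1 approximation at known analyte concentration C,
  ``k_on = (k_obs - k_off) / C`` and ``K_D = k_off / k_on``.
* :class:`DoseResponseModel` — Langmuir isotherm
  ``R(c) = R_max c / (K_D + c)`` with a 3-sigma concentration LOD.

Parameter uncertainty comes from seeded residual-resampling bootstrap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "KineticsError",
    "KineticFitResults",
    "SingleExponentialModel",
    "TwoPhaseModel",
    "TwoPhaseResults",
    "AffinityResult",
    "DoseResponseModel",
    "DoseResponseResults",
    "extract_step",
    "fit_single_exp",
    "fit_two_phase",
    "kd_distribution",
]

DEFAULT_BOOTSTRAP_DRAWS = 500


class KineticsError(RuntimeError):
    pass


def _as_ty(trace) -> tuple[np.ndarray, np.ndarray]:
    """Accept a SensorTrace (uses the RIU series) or a (t, y) pair."""
    if hasattr(trace, "shift_riu"):
        return np.asarray(trace.axis, dtype=float), np.asarray(trace.shift_riu, dtype=float)
    t, y = trace
    return np.asarray(t, dtype=float), np.asarray(y, dtype=float)


def extract_step(trace, *, t_pre: float, t_post: float, window: int = 20) -> float:
    """Step shift: mean of ``window`` points after minus ``window`` before.

    Uses the last ``window`` frames with ``t <= t_pre`` and the first
    ``window`` frames with ``t >= t_post``.
    """
    t, y = _as_ty(trace)
    if window < 1:
        raise KineticsError("window must be >= 1")
    pre = y[t <= t_pre]
    post = y[t >= t_post]
    if len(pre) < window or len(post) < window:
        raise KineticsError(
            f"need {window} frames on each side; have {len(pre)} pre / {len(post)} post"
        )
    return float(np.mean(post[:window]) - np.mean(pre[-window:]))


# -- results container -----------------------------------------------------


@dataclass
class KineticFitResults:
    """Parameters and diagnostics of an exponential binding fit."""

    model_name: str
    params: dict[str, float]
    rss: float
    n_obs: int
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    ci_level: float = 0.90
    meta: dict = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.params[key]

    def summary(self) -> str:
        lines = [f"{self.model_name} fit", "=" * 30, f"n = {self.n_obs}, RSS = {self.rss:.4g}"]
        for k, v in self.params.items():
            line = f"  {k:>10s} = {v:.6g}"
            if k in self.ci:
                lo, hi = self.ci[k]
                line += f"   [{100 * self.ci_level:.0f}% CI {lo:.6g}, {hi:.6g}]"
            lines.append(line)
        return "\n".join(lines)


def _bootstrap_ci(
    t: np.ndarray,
    fitted: np.ndarray,
    resid: np.ndarray,
    refit,
    names: list[str],
    draws: int,
    seed: int,
    level: float,
) -> dict[str, tuple[float, float]]:
    """Residual-resampling bootstrap percentile CIs."""
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(draws):
        yb = fitted + rng.choice(resid, size=len(resid), replace=True)
        try:
            samples.append(refit(t, yb))
        except Exception:
            continue
    if len(samples) < max(10, draws // 4):
        warnings.warn("bootstrap: most resampled fits failed; CIs unreliable", stacklevel=2)
    if not samples:
        return {}
    arr = np.asarray(samples)
    a = 100 * (1 - level) / 2
    lo = np.percentile(arr, a, axis=0)
    hi = np.percentile(arr, 100 - a, axis=0)
    return {n: (float(lo[i]), float(hi[i])) for i, n in enumerate(names)}


# -- single exponential ----------------------------------------------------


def _single_exp(t, dr, k, c):
    return dr * (1.0 - np.exp(-k * t)) + c


def _init_single_exp(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    c0 = float(y[0])
    dr0 = float(y[-1] - y[0])
    if dr0 == 0:
        dr0 = float(np.ptp(y)) or 1.0
    # log-linearised rate from points in the rising part of the curve
    z = 1.0 - (y - c0) / dr0
    mask = (z > 0.05) & (z < 0.95) & (t > 0)
    if mask.sum() >= 3:
        slope = np.polyfit(t[mask], np.log(z[mask]), 1)[0]
        k0 = max(-slope, 1e-6)
    else:
        k0 = 2.0 / max(t[-1], 1e-6)
    return dr0, k0, c0


class SingleExponentialModel:
    """Single-exponential approach to binding equilibrium.

    Parameters
    ----------
    trace
        SensorTrace or ``(t, y)``; the segment to fit.
    t0
        Step start time; only frames with ``t >= t0`` are fitted, with the
        time origin moved to ``t0``.
    """

    param_names = ["delta_riu", "k_app", "offset"]

    def __init__(self, trace, t0: float = 0.0):
        t, y = _as_ty(trace)
        ok = np.isfinite(y) & (t >= t0)
        self.t = t[ok] - t0
        self.y = y[ok]
        self.t0 = t0
        if len(self.t) < 10:
            raise KineticsError(f"need >= 10 frames after t0; have {len(self.t)}")
        noise = np.std(np.diff(self.y)) / math.sqrt(2.0)
        if np.ptp(self.y) <= max(3.0 * noise, 0.0) or np.ptp(self.y) == 0:
            raise KineticsError("flat segment: no resolvable binding signal")

    @staticmethod
    def _fit_arrays(t: np.ndarray, y: np.ndarray) -> np.ndarray:
        p0 = _init_single_exp(t, y)
        popt, _ = curve_fit(
            _single_exp,
            t,
            y,
            p0=p0,
            bounds=([-np.inf, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        return popt

    def fit(
        self,
        *,
        bootstrap: int = 0,
        seed: int = 0,
        ci_level: float = 0.90,
    ) -> KineticFitResults:
        try:
            popt = self._fit_arrays(self.t, self.y)
        except RuntimeError as e:
            raise KineticsError(f"single-exponential fit did not converge: {e}") from e
        fitted = _single_exp(self.t, *popt)
        resid = self.y - fitted
        ci = {}
        if bootstrap:
            ci = _bootstrap_ci(
                self.t, fitted, resid, type(self)._fit_arrays, self.param_names, bootstrap, seed, ci_level
            )
        return KineticFitResults(
            model_name="single_exp",
            params=dict(zip(self.param_names, map(float, popt))),
            rss=float(np.sum(resid**2)),
            n_obs=len(self.t),
            ci=ci,
            ci_level=ci_level,
            meta={"t0": self.t0},
        )


def fit_single_exp(trace, t0: float = 0.0, **fit_kw) -> KineticFitResults:
    """Convenience wrapper: ``SingleExponentialModel(trace, t0).fit(...)``."""
    return SingleExponentialModel(trace, t0).fit(**fit_kw)


# -- two-phase association/dissociation ------------------------------------


def _biexp_assoc(t, a_f, k_f, a_s, k_s):
    return a_f * (1.0 - np.exp(-k_f * t)) + a_s * (1.0 - np.exp(-k_s * t))


def _biexp_decay(t, b_f, k_f, b_s, k_s):
    return b_f * np.exp(-k_f * t) + b_s * np.exp(-k_s * t)


@dataclass(frozen=True)
class AffinityResult:
    """Effective 1:1 affinity derived from a two-phase fit.

    ``K_D`` is withheld (None) when the observed rate does not exceed the
    off-rate, which would imply a non-physical negative ``k_on``.
    """

    k_on: float | None  # 1/(M s)
    k_off: float  # 1/s
    K_D: float | None  # M
    flags: tuple[str, ...] = ()

    @property
    def valid(self) -> bool:
        return self.K_D is not None


@dataclass
class TwoPhaseResults:
    """Fast/slow phase parameters for association and dissociation."""

    assoc: KineticFitResults
    dissoc: KineticFitResults
    affinity: AffinityResult
    weighting: str
    collapsed: bool = False

    def summary(self) -> str:
        lines = ["two-phase kinetics", "=" * 30]
        lines.append(self.assoc.summary())
        lines.append(self.dissoc.summary())
        a = self.affinity
        lines.append(f"effective k_off = {a.k_off:.4g} 1/s  (weighting: {self.weighting})")
        if a.valid:
            lines.append(f"effective k_on  = {a.k_on:.4g} 1/(M s)")
            lines.append(f"K_D = {1e9 * a.K_D:.4g} nM")
        else:
            lines.append(f"K_D withheld: {', '.join(a.flags)}")
        if self.collapsed:
            lines.append("note: phases indistinguishable; collapsed to a single phase")
        return "\n".join(lines)


def _fit_biexp(t: np.ndarray, y: np.ndarray, kind: str) -> np.ndarray:
    """Fit a two-phase curve, ordering phases fast-first."""
    fun = _biexp_assoc if kind == "assoc" else _biexp_decay
    # start from a single-exponential rate and split it geometrically
    if kind == "assoc":
        dr0, k0, _ = _init_single_exp(t, y)
        plateau = abs(y[-1]) or abs(dr0) or 1.0
    else:
        y0 = abs(y[0]) or 1.0
        frac = np.clip(np.abs(y) / y0, 1e-9, 1.0)
        mask = (frac > 0.05) & (frac < 0.95)
        k0 = max(-np.polyfit(t[mask], np.log(frac[mask]), 1)[0], 1e-6) if mask.sum() >= 3 else 1.0 / max(t[-1], 1.0)
        plateau = y0
    p0 = [0.5 * plateau, 3.0 * k0, 0.5 * plateau, max(k0 / 3.0, 1e-8)]
    popt, _ = curve_fit(fun, t, y, p0=p0, bounds=(0.0, np.inf), maxfev=40000)
    if popt[1] < popt[3]:  # keep fast phase first
        popt = np.array([popt[2], popt[3], popt[0], popt[1]])
    return popt


class TwoPhaseModel:
    """Two-phase exponential association/dissociation with affinity extraction.

    Parameters
    ----------
    assoc, dissoc
        SensorTrace or ``(t, y)`` segments; time origins are moved to each
        segment's first frame, and the dissociation segment is expected to
        start at the end of association.
    analyte_conc_M
        Analyte concentration during association (pseudo-first-order
        approximation).
    """

    def __init__(self, assoc, dissoc, analyte_conc_M: float):
        ta, ya = _as_ty(assoc)
        td, yd = _as_ty(dissoc)
        oka, okd = np.isfinite(ya), np.isfinite(yd)
        self.ta, self.ya = ta[oka] - ta[oka][0], ya[oka]
        self.td, self.yd = td[okd] - td[okd][0], yd[okd]
        if len(self.ta) < 15 or len(self.td) < 15:
            raise KineticsError("both segments need >= 15 frames")
        if not analyte_conc_M > 0:
            raise KineticsError("analyte concentration must be positive")
        self.conc = analyte_conc_M

    def fit(
        self,
        *,
        weighting: str = "amplitude",
        rate_separation_min: float = 1.5,
        bootstrap: int = 0,
        seed: int = 0,
        ci_level: float = 0.90,
    ) -> TwoPhaseResults:
        """Fit both segments and derive the effective (k_on, k_off, K_D).

        ``weighting`` selects how the four phase rates collapse to one
        effective on/off pair: ``"amplitude"`` (amplitude-weighted mean,
        default) or ``"fast"`` (fast phase only).  When the two fitted rates
        of a segment are closer than ``rate_separation_min``, the phases are
        not identifiable: the fit collapses to a single phase with a warning.
        """
        if weighting not in ("amplitude", "fast"):
            raise KineticsError("weighting must be 'amplitude' or 'fast'")
        try:
            pa = _fit_biexp(self.ta, self.ya, "assoc")
            pd_ = _fit_biexp(self.td, self.yd, "dissoc")
        except RuntimeError as e:
            raise KineticsError(f"two-phase fit did not converge: {e}") from e
        collapsed = False
        for p, t, y, kind in ((pa, self.ta, self.ya, "assoc"), (pd_, self.td, self.yd, "dissoc")):
            if p[3] > 0 and p[1] / p[3] < rate_separation_min:
                collapsed = True
        if collapsed:
            warnings.warn(
                "fast and slow rates indistinguishable; collapsing to single phase",
                stacklevel=2,
            )
            ka = self._single_rate(self.ta, self.ya, "assoc")
            kd = self._single_rate(self.td, self.yd, "dissoc")
            pa = np.array([0.5 * ka[0], ka[1], 0.5 * ka[0], ka[1]])
            pd_ = np.array([0.5 * kd[0], kd[1], 0.5 * kd[0], kd[1]])

        assoc_names = ["A_fast", "k_obs_fast", "A_slow", "k_obs_slow"]
        dissoc_names = ["B_fast", "k_off_fast", "B_slow", "k_off_slow"]
        ra = self.ya - _biexp_assoc(self.ta, *pa)
        rd = self.yd - _biexp_decay(self.td, *pd_)
        ci_a = ci_d = {}
        if bootstrap:
            ci_a = _bootstrap_ci(
                self.ta, _biexp_assoc(self.ta, *pa), ra,
                lambda t, y: _fit_biexp(t, y, "assoc"), assoc_names, bootstrap, seed, ci_level,
            )
            ci_d = _bootstrap_ci(
                self.td, _biexp_decay(self.td, *pd_), rd,
                lambda t, y: _fit_biexp(t, y, "dissoc"), dissoc_names, bootstrap, seed + 1, ci_level,
            )
        assoc = KineticFitResults(
            "two_phase_assoc", dict(zip(assoc_names, map(float, pa))),
            float(np.sum(ra**2)), len(self.ta), ci_a, ci_level,
        )
        dissoc = KineticFitResults(
            "two_phase_dissoc", dict(zip(dissoc_names, map(float, pd_))),
            float(np.sum(rd**2)), len(self.td), ci_d, ci_level,
        )
        affinity = self._affinity(pa, pd_, weighting)
        return TwoPhaseResults(assoc=assoc, dissoc=dissoc, affinity=affinity,
                               weighting=weighting, collapsed=collapsed)

    @staticmethod
    def _single_rate(t, y, kind) -> tuple[float, float]:
        if kind == "assoc":
            res = SingleExponentialModel((t, y)).fit()
            return res["delta_riu"], res["k_app"]
        p0 = [abs(y[0]) or 1.0, 1.0 / max(t[-1], 1.0)]
        popt, _ = curve_fit(lambda tt, b, k: b * np.exp(-k * tt), t, y, p0=p0,
                            bounds=(0, np.inf), maxfev=20000)
        return float(popt[0]), float(popt[1])

    def _affinity(self, pa: np.ndarray, pd_: np.ndarray, weighting: str) -> AffinityResult:
        a_f, k_obs_f, a_s, k_obs_s = pa
        b_f, k_off_f, b_s, k_off_s = pd_
        if weighting == "amplitude":
            k_obs = (a_f * k_obs_f + a_s * k_obs_s) / max(a_f + a_s, 1e-300)
            k_off = (b_f * k_off_f + b_s * k_off_s) / max(b_f + b_s, 1e-300)
        else:
            k_obs, k_off = k_obs_f, k_off_f
        flags: list[str] = []
        if k_obs <= k_off:
            flags.append("k_obs <= k_off (non-physical at this concentration)")
            return AffinityResult(k_on=None, k_off=float(k_off), K_D=None, flags=tuple(flags))
        k_on = (k_obs - k_off) / self.conc
        return AffinityResult(k_on=float(k_on), k_off=float(k_off), K_D=float(k_off / k_on))


def fit_two_phase(assoc, dissoc, analyte_conc_M: float, **fit_kw) -> TwoPhaseResults:
    """Convenience wrapper: ``TwoPhaseModel(assoc, dissoc, c).fit(...)``."""
    return TwoPhaseModel(assoc, dissoc, analyte_conc_M).fit(**fit_kw)


def kd_distribution(results) -> dict:
    """Summarise per-pair affinities: median/min/max K_D plus the full table.

    ``results`` is a mapping ``pair_id -> AffinityResult`` or a sequence of
    AffinityResult.  Pairs with withheld K_D are kept in the table but
    excluded from the summary statistics.  An empty input yields n=0.
    """
    if isinstance(results, dict):
        items = list(results.items())
    else:
        items = [(str(i), r) for i, r in enumerate(results)]
    table = pd.DataFrame(
        {
            "pair_id": [k for k, _ in items],
            "k_on": [r.k_on for _, r in items],
            "k_off": [r.k_off for _, r in items],
            "K_D": [r.K_D for _, r in items],
        }
    )
    kds = np.array([r.K_D for _, r in items if r.valid], dtype=float)
    summary = {
        "n": int(len(kds)),
        "median_KD": float(np.median(kds)) if len(kds) else float("nan"),
        "min_KD": float(kds.min()) if len(kds) else float("nan"),
        "max_KD": float(kds.max()) if len(kds) else float("nan"),
        "table": table,
    }
    return summary


# -- dose-response ---------------------------------------------------------


def _langmuir(c, r_max, kd):
    return r_max * c / (kd + c)


@dataclass
class DoseResponseResults:
    """Langmuir fit of equilibrium responses vs concentration."""

    R_max: float
    K_D: float
    rss: float
    n_obs: int
    sigma_blank: float
    conc_lod: float  # M; inf when the curve never clears 3*sigma_blank

    def predict(self, c):
        return _langmuir(np.asarray(c, dtype=float), self.R_max, self.K_D)

    def summary(self) -> str:
        lod = "not detectable" if not math.isfinite(self.conc_lod) else f"{1e9 * self.conc_lod:.4g} nM"
        return "\n".join(
            [
                "Langmuir dose-response fit",
                "=" * 30,
                f"R_max = {self.R_max:.4g}",
                f"K_D   = {1e9 * self.K_D:.4g} nM",
                f"LOD (3 sigma of blank) = {lod}",
                f"n = {self.n_obs}, RSS = {self.rss:.4g}",
            ]
        )


class DoseResponseModel:
    """Equilibrium response vs analyte concentration (1:1 Langmuir isotherm)."""

    def __init__(self, conc_M, response):
        c = np.asarray(conc_M, dtype=float)
        r = np.asarray(response, dtype=float)
        if c.shape != r.shape or c.ndim != 1:
            raise KineticsError("concentrations and responses must be matching 1-D arrays")
        if len(c) < 4:
            raise KineticsError("need >= 4 concentrations")
        if not np.all(c > 0):
            raise KineticsError("concentrations must be positive")
        if np.log10(c.max() / c.min()) < 1.0:
            raise KineticsError("concentrations must span at least one decade")
        order = np.argsort(c)
        self.c, self.r = c[order], r[order]

    def fit(self, sigma_blank: float = 0.0) -> DoseResponseResults:
        """Fit (R_max, K_D); ``conc_lod`` solves ``R(c) = 3 * sigma_blank``."""
        if sigma_blank < 0:
            raise KineticsError("sigma_blank must be non-negative")
        p0 = [max(self.r.max(), 1e-12) * 1.2, float(np.median(self.c))]
        try:
            popt, _ = curve_fit(_langmuir, self.c, self.r, p0=p0,
                                bounds=(1e-300, np.inf), maxfev=20000)
        except RuntimeError as e:
            raise KineticsError(f"Langmuir fit did not converge: {e}") from e
        r_max, kd = map(float, popt)
        resid = self.r - _langmuir(self.c, r_max, kd)
        sd = resid.std(ddof=1) if len(resid) > 2 else 0.0
        if np.any(np.diff(self.r) < -3.0 * max(sd, 1e-300)):
            warnings.warn("responses decrease with concentration beyond noise", stacklevel=2)
        thr = 3.0 * sigma_blank
        if thr >= r_max:
            lod = float("inf")
        else:
            lod = thr * kd / (r_max - thr)  # exact inverse of the Langmuir curve
        return DoseResponseResults(
            R_max=r_max, K_D=kd, rss=float(np.sum(resid**2)), n_obs=len(self.c),
            sigma_blank=sigma_blank, conc_lod=lod,
        )
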