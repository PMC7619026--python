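"""Wavelength-sensitivity calibration, array uniformity, noise floor, LOD/LOQ.

Calibration regresses each pair's differential pixel shift on the
illumination wavelength of a sweep acquisition (ordinary least squares per
sensor); the array is summarised by the mean, SD and coefficient of
variation of the per-sensor slopes.  The noise floor is the mean over
sensors of the per-sensor temporal SD of a baseline RIU trace; the limit of
detection is 3 sigma and the limit of quantification 10 sigma.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .layout import (
    DEFAULT_BULK_SENSITIVITY_NM_PER_RIU,
    DEFAULT_DESIGNS,
    GratingDesign,
    functional_window,
)
from .track import SensorTrace

__all__ = [
    "CalibrationResult",
    "NoiseResult",
    "calibrate_sweep",
    "noise_floor",
    "dynamic_range",
    "CalibrationError",
]


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationResult:
    """Per-sensor wavelength sensitivities (px/nm) and array statistics."""

    per_sensor_sensitivity: dict[str, float]
    r2: dict[str, float]
    mean_sens: float
    sd_sens: float

    @property
    def cv_percent(self) -> float:
        return 100.0 * self.sd_sens / self.mean_sens

    @property
    def n_sensors(self) -> int:
        return len(self.per_sensor_sensitivity)

    def to_dict(self) -> dict:
        return {
            "schema": "cgmr.calibration/1",
            "per_sensor_sensitivity_px_per_nm": self.per_sensor_sensitivity,
            "r2": self.r2,
            "mean_sens_px_per_nm": self.mean_sens,
            "sd_sens_px_per_nm": self.sd_sens,
            "cv_percent": self.cv_percent,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationResult":
        d = json.loads(Path(path).read_text())
        return cls(
            per_sensor_sensitivity=d["per_sensor_sensitivity_px_per_nm"],
            r2=d["r2"],
            mean_sens=d["mean_sens_px_per_nm"],
            sd_sens=d["sd_sens_px_per_nm"],
        )


@dataclass
class NoiseResult:
    """Baseline noise sigma (RIU) with the derived 3-sigma LOD and 10-sigma LOQ."""

    sigma_riu: float
    per_sensor_sigma: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma_riu < 0:
            raise CalibrationError("sigma must be non-negative")

    @property
    def lod_riu(self) -> float:
        return 3.0 * self.sigma_riu

    @property
    def loq_riu(self) -> float:
        return 10.0 * self.sigma_riu

    def to_dict(self) -> dict:
        return {
            "schema": "cgmr.noise/1",
            "sigma_riu": self.sigma_riu,
            "lod_riu": self.lod_riu,
            "loq_riu": self.loq_riu,
            "per_sensor_sigma_riu": self.per_sensor_sigma,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and R^2 of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise CalibrationError("need >= 3 points per sensor")
    if np.ptp(x) == 0:
        raise CalibrationError("constant wavelength axis: regression is rank-deficient")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(r2)


def calibrate_sweep(traces: Sequence[SensorTrace]) -> CalibrationResult:
    """Per-sensor OLS slope of differential pixel shift vs wavelength.

    ``traces`` are sweep traces (axis in nm).  Array statistics use the
    sample SD (ddof=1) when more than one sensor is present.
    """
    if not traces:
        raise CalibrationError("no traces given")
    sens: dict[str, float] = {}
    r2: dict[str, float] = {}
    for tr in traces:
        if tr.axis_kind != "lambda":
            raise CalibrationError(f"trace {tr.pair_id} is not a sweep trace")
        s, r = _ols_slope(tr.axis, tr.shift_px)
        sens[tr.pair_id] = s
        r2[tr.pair_id] = r
    vals = np.array(list(sens.values()))
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return CalibrationResult(per_sensor_sensitivity=sens, r2=r2, mean_sens=mean, sd_sens=sd)


def noise_floor(
    baseline_traces: Sequence[SensorTrace],
    *,
    min_frames: int = 30,
    pooled: bool = False,
) -> NoiseResult:
    """Baseline noise of the array in RIU.

    Default: sigma = mean over sensors of the per-sensor temporal SD of the
    RIU trace.  ``pooled=True`` instead takes the SD of all mean-subtracted
    residuals pooled across sensors.
    """
    if not baseline_traces:
        raise CalibrationError("no traces given")
    per: dict[str, float] = {}
    residuals = []
    for tr in baseline_traces:
        y = np.asarray(tr.shift_riu, dtype=float)
        y = y[np.isfinite(y)]
        if len(y) < 2:
            raise CalibrationError(f"trace {tr.pair_id}: need >= 2 frames")
        if len(y) < min_frames:
            raise CalibrationError(
                f"trace {tr.pair_id}: {len(y)} frames < required {min_frames}"
            )
        per[tr.pair_id] = float(y.std(ddof=1))
        residuals.append(y - y.mean())
    if pooled:
        sigma = float(np.concatenate(residuals).std(ddof=len(baseline_traces)))
    else:
        sigma = float(np.mean(list(per.values())))
    return NoiseResult(sigma_riu=sigma, per_sensor_sigma=per)


def dynamic_range(
    designs: Sequence[GratingDesign] = DEFAULT_DESIGNS,
    bulk_sensitivity_nm_per_riu: float = DEFAULT_BULK_SENSITIVITY_NM_PER_RIU,
    *,
    span_nm: float | None = None,
) -> float:
    """Effective refractive-index dynamic range in RIU.

    With ``span_nm`` given (e.g. the 2 nm of a wavelength scan), the range is
    ``span / bulk_sensitivity``; otherwise the union width of the designs'
    spectral windows is used (5 nm for the default dual-design chip).
    """
    if not bulk_sensitivity_nm_per_riu > 0:
        raise CalibrationError("bulk sensitivity must be positive")
    if span_nm is not None:
        if span_nm < 0:
            raise CalibrationError("span must be non-negative")
        return span_nm / bulk_sensitivity_nm_per_riu
    fw = functional_window(designs)
    return fw.union_nm / bulk_sensitivity_nm_per_riu
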