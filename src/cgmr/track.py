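"""Resonance-bar tracking: image stack -> per-pair differential traces.

Each grating ROI contains a bright resonance bar perpendicular to the chirp
axis.  Every pixel row of the ROI is fitted with a Gaussian
``A * exp(-(x - x0)^2 / (2 w^2)) + b`` (a computationally efficient
approximation to the underlying Fano lineshape); the median of the ~150
fitted centres is the bar position and their interquartile range is the
per-read quality metric.  The differential shift of a mirrored pair,

    d = (sign_a * (x_a - ref_a) + sign_b * (x_b - ref_b)) / 2,

adds equal-and-opposite spectral motion and cancels common-mode translation
(vibration, drift).  Pixel shifts are converted to nm via the measured
sensitivity when a calibration is available (else the nominal chirp map) and
to RIU via the bulk sensitivity.

Row fits are mutually independent: fitting order never affects results, and
the per-row loop is vectorised as a damped (Levenberg-Marquardt) Gauss-Newton
iteration over all rows of an ROI at once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.registration import phase_cross_correlation

from .layout import ArrayLayout, OpticalSetup, Rect, SensorPairGeom
from .stack import FrameStack

__all__ = [
    "RowFit",
    "ResonanceRead",
    "SensorTrace",
    "fit_row_gaussian",
    "read_roi",
    "detect_rois",
    "differential_shift",
    "track_stack",
    "DetectionError",
]

DEFAULT_MIN_ROWS = 50
DEFAULT_IQR_MAX = 2.0


class DetectionError(RuntimeError):
    """ROI detection failed (no fiducials/gratings found and no hint given)."""


@dataclass(frozen=True)
class RowFit:
    """Result of one per-row Gaussian fit (columns in profile coordinates)."""

    row_index: int
    amplitude: float
    centre_px: float
    width_px: float
    offset: float
    rss: float
    converged: bool


@dataclass(frozen=True)
class ResonanceRead:
    """Robust bar position of one ROI in one frame.

    ``x_med`` is the median of the converged row-fit centres in absolute
    image columns; ``iqr_px`` their interquartile range.
    """

    x_med: float
    iqr_px: float
    n_rows_used: int
    qc_pass: bool


# -- batched Gaussian fitting ---------------------------------------------


def _robust_noise_sd(y: np.ndarray, axis: int = -1) -> np.ndarray:
    """Noise SD estimate from first differences (MAD-based, trend-insensitive)."""
    d = np.diff(y, axis=axis)
    return 1.4826 * np.median(np.abs(d - np.median(d, axis=axis, keepdims=True)), axis=axis) / math.sqrt(2.0)


def _init_params(Y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Default starts: x0 = argmax, A = max - min, b = min, w from FWHM."""
    R, _ = Y.shape
    b = Y.min(axis=1)
    A = Y.max(axis=1) - b
    imax = Y.argmax(axis=1)
    x0 = x[imax]
    half = b[:, None] + 0.5 * A[:, None]
    w = np.maximum((Y >= half).sum(axis=1), 3.0) / 2.3548200450309493
    w *= (x[1] - x[0]) if len(x) > 1 else 1.0
    return np.column_stack([A, x0, w, b]).astype(float)


def _batched_gaussian_lm(
    Y: np.ndarray,
    x: np.ndarray,
    p0: np.ndarray,
    *,
    max_iter: int = 80,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Levenberg-Marquardt least squares of a Gaussian+offset, row-batched.

    All rows iterate independently (per-row damping and acceptance), so the
    result is identical to fitting rows one at a time.
    Returns (params (R,4), rss (R,), converged (R,)).
    """
    R, N = Y.shape
    p = p0.copy()
    lam = np.full(R, 1e-3)
    done = np.zeros(R, dtype=bool)

    def model_resid(p):
        A, x0, w, b = p.T
        w = np.maximum(w, 1e-6)
        E = np.exp(-0.5 * ((x[None, :] - x0[:, None]) / w[:, None]) ** 2)
        m = A[:, None] * E + b[:, None]
        return E, m, Y - m

    E, m, r = model_resid(p)
    cost = (r**2).sum(axis=1)
    for _ in range(max_iter):
        if done.all():
            break
        A, x0, w, b = p.T
        w = np.maximum(w, 1e-6)
        dx = x[None, :] - x0[:, None]
        J = np.empty((R, N, 4))
        J[..., 0] = E
        J[..., 1] = A[:, None] * E * dx / (w**2)[:, None]
        J[..., 2] = A[:, None] * E * dx**2 / (w**3)[:, None]
        J[..., 3] = 1.0
        JTJ = np.einsum("rni,rnj->rij", J, J)
        JTr = np.einsum("rni,rn->ri", J, r)
        D = np.einsum("rii->ri", JTJ).copy()
        D = np.maximum(D, 1e-12)
        Amat = JTJ + lam[:, None, None] * D[:, None, :] * np.eye(4)[None, :, :]
        try:
            step = np.linalg.solve(Amat, JTr[..., None])[..., 0]
        except np.linalg.LinAlgError:
            Amat = Amat + 1e-8 * np.eye(4)[None, :, :]
            step = np.linalg.solve(Amat, JTr[..., None])[..., 0]
        p_new = p + step
        p_new[:, 2] = np.abs(p_new[:, 2])
        _, _, r_new = model_resid(p_new)
        cost_new = (r_new**2).sum(axis=1)
        better = (cost_new <= cost) & ~done
        improved = better & (cost - cost_new <= tol * (cost + tol))
        p[better] = p_new[better]
        lam[better] = np.maximum(lam[better] / 3.0, 1e-12)
        worse = ~better & ~done
        lam[worse] = np.minimum(lam[worse] * 5.0, 1e8)
        cost = np.where(better, cost_new, cost)
        done |= improved
        done |= ~better & (lam >= 1e8)
        E, m, r = model_resid(p)
    A, x0, w, b = p.T
    sane = (
        (A > 0)
        & (x0 >= x[0])
        & (x0 <= x[-1])
        & (w > 0.3)
        & (w < (x[-1] - x[0]))
        & np.isfinite(p).all(axis=1)
    )
    return p, cost, done & sane


def _fit_profiles(
    Y: np.ndarray,
    x: np.ndarray,
    *,
    min_prominence_snr: float = 5.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit every row; rows whose peak prominence is below the noise floor are
    marked unconverged without fitting."""
    Y = np.asarray(Y, dtype=float)
    noise = np.atleast_1d(_robust_noise_sd(Y))
    prominence = Y.max(axis=1) - np.median(Y, axis=1)
    flat = prominence < np.maximum(min_prominence_snr * noise, 1e-9)
    p0 = _init_params(Y, x)
    p, rss, conv = _batched_gaussian_lm(Y, x, p0)
    conv &= ~flat
    return p, rss, conv


def fit_row_gaussian(profile: np.ndarray, init: tuple | None = None) -> RowFit:
    """Nonlinear least-squares Gaussian fit of a single row profile.

    ``init`` is an optional ``(A, x0, w, b)`` start; defaults are derived
    from the profile (argmax, max-min, FWHM/2.355, min).  A profile whose
    peak does not rise above the noise floor yields ``converged=False``.
    """
    y = np.asarray(profile, dtype=float)
    if y.ndim != 1 or y.size < 8:
        raise ValueError("profile must be 1-D with length >= 8")
    x = np.arange(y.size, dtype=float)
    Y = y[None, :]
    if init is not None:
        p0 = np.asarray(init, dtype=float)[None, :].copy()
        p, rss, conv = _batched_gaussian_lm(Y, x, p0)
        noise = _robust_noise_sd(Y)[0]
        if (y.max() - np.median(y)) < max(5.0 * noise, 1e-9):
            conv[:] = False
    else:
        p, rss, conv = _fit_profiles(Y, x)
    A, x0, w, b = p[0]
    return RowFit(
        row_index=0,
        amplitude=float(A),
        centre_px=float(x0),
        width_px=float(w),
        offset=float(b),
        rss=float(rss[0]),
        converged=bool(conv[0]),
    )


def read_roi(
    image: np.ndarray,
    roi: Rect,
    *,
    min_rows: int = DEFAULT_MIN_ROWS,
    iqr_max: float = DEFAULT_IQR_MAX,
    fit_halfwidth: int | None = None,
) -> ResonanceRead:
    """Robust bar position of one ROI: per-row Gaussian fits, median + IQR.

    Rows are fitted inside a common window centred on the bar (located from
    the column-median profile) — this speeds fitting and keeps the fits away
    from ROI edges.  ``qc_pass`` requires at least ``min_rows`` converged
    rows and an IQR below ``iqr_max``; with 3..min_rows converged rows the
    position is still reported but flagged.
    """
    if not roi.inside(image.shape):
        raise ValueError("ROI exceeds image")
    sub = np.asarray(image[roi.row0 : roi.row1, roi.col0 : roi.col1], dtype=float)
    med_profile = np.median(sub, axis=0)
    peak = int(np.argmax(med_profile))
    prominence = med_profile.max() - np.median(med_profile)
    half = np.median(med_profile) + 0.5 * prominence
    fwhm_est = max(int((med_profile >= half).sum()), 3)
    hw = fit_halfwidth if fit_halfwidth is not None else max(25, 4 * fwhm_est)
    lo = max(0, peak - hw)
    hi = min(sub.shape[1], peak + hw + 1)
    if hi - lo < 8:
        lo, hi = 0, sub.shape[1]
    x = np.arange(lo, hi, dtype=float)
    p, _, conv = _fit_profiles(sub[:, lo:hi], x)
    centres = p[:, 1]
    interior = conv & (centres > lo + 1) & (centres < hi - 2)
    used = centres[interior]
    n_used = int(interior.sum())
    if n_used >= 3:
        x_med = float(np.median(used)) + roi.col0
        q75, q25 = np.percentile(used, [75, 25])
        iqr = float(q75 - q25)
    else:
        x_med, iqr = float("nan"), float("nan")
    qc = n_used >= min_rows and np.isfinite(iqr) and iqr <= iqr_max
    return ResonanceRead(x_med=x_med, iqr_px=iqr, n_rows_used=n_used, qc_pass=qc)


# -- ROI detection ---------------------------------------------------------


def _binarize(image: np.ndarray) -> np.ndarray:
    """Separate grating pedestals from the unpatterned background.

    The image has three intensity populations — background, grating pedestal
    and resonance bar — so a 3-class multi-Otsu is used and the *lowest*
    threshold segments the (large-area) pedestals; plain Otsu would latch on
    to the bright but narrow bars.
    """
    img = np.asarray(image, dtype=float)
    if img.max() <= img.min():
        raise DetectionError("blank image: nothing to detect")
    try:
        thr = threshold_multiotsu(img, classes=3)[0]
    except ValueError:
        thr = threshold_otsu(img)
    bw = img > thr
    if not bw.any() or bw.all():
        raise DetectionError("thresholding found no grating regions")
    return bw


def detect_rois(
    image: np.ndarray,
    layout_hint: ArrayLayout | None = None,
    *,
    min_area: int = 256,
) -> ArrayLayout:
    """Locate grating ROIs on an array image.

    Without a hint, the grating pedestals (the patterned regions reflect
    above the unpatterned background) are segmented by Otsu thresholding and
    connected-component labelling; component bounding boxes become ROIs,
    grouped into rows and paired left/right.  With ``layout_hint``, the hint
    geometry is registered to the image by integer-pixel cross-correlation
    and translated.
    """
    img = np.asarray(image)
    if layout_hint is not None:
        bw = _binarize(img).astype(float)
        ref = np.zeros(layout_hint.image_shape)
        for geom in layout_hint.pairs:
            for roi in geom.rois:
                ref[roi.row0 : roi.row1, roi.col0 : roi.col1] = 1.0
        if ref.shape != bw.shape:
            raise DetectionError("hint image shape does not match image")
        shift, _, _ = phase_cross_correlation(bw, ref, upsample_factor=1)
        dr, dc = int(round(shift[0])), int(round(shift[1]))
        pairs = [
            SensorPairGeom(
                pair_id=g.pair_id,
                roi_a=Rect(g.roi_a.row0 + dr, g.roi_a.col0 + dc, g.roi_a.height, g.roi_a.width),
                roi_b=Rect(g.roi_b.row0 + dr, g.roi_b.col0 + dc, g.roi_b.height, g.roi_b.width),
                chirp_sign_a=g.chirp_sign_a,
                chirp_sign_b=g.chirp_sign_b,
                design_id=g.design_id,
            )
            for g in layout_hint.pairs
        ]
        return ArrayLayout(
            pairs=pairs,
            image_shape=img.shape,
            setup_name=layout_hint.setup_name,
            meta={"registered_shift": [dr, dc]},
        )

    bw = _binarize(img)
    lab = sk_label(bw, connectivity=1)
    props = [p for p in regionprops(lab) if p.area >= min_area]
    if not props:
        raise DetectionError("no grating regions found")
    areas = np.array([p.area for p in props])
    med_area = np.median(areas)
    boxes = [p.bbox for p in props if 0.3 * med_area <= p.area <= 3.0 * med_area]
    if len(boxes) < 2:
        raise DetectionError("fewer than two grating regions found")
    # group into horizontal bands, then pair left/right within each band
    boxes.sort(key=lambda b: (b[0], b[1]))
    med_h = np.median([b[2] - b[0] for b in boxes])
    bands: list[list[tuple]] = []
    for b in boxes:
        if bands and abs(b[0] - bands[-1][0][0]) < 0.5 * med_h:
            bands[-1].append(b)
        else:
            bands.append([b])
    pairs = []
    idx = 0
    for band in bands:
        band.sort(key=lambda b: b[1])
        if len(band) % 2:
            raise DetectionError(f"odd number of gratings ({len(band)}) in a row band")
        for j in range(0, len(band), 2):
            ba, bb = band[j], band[j + 1]
            idx += 1
            pairs.append(
                SensorPairGeom(
                    pair_id=f"{idx:03d}A",
                    roi_a=Rect(ba[0], ba[1], ba[2] - ba[0], ba[3] - ba[1]),
                    roi_b=Rect(bb[0], bb[1], bb[2] - bb[0], bb[3] - bb[1]),
                    chirp_sign_a=1,
                    chirp_sign_b=-1,
                    design_id=1 + ((idx - 1) % 2),
                )
            )
    return ArrayLayout(pairs=pairs, image_shape=img.shape, meta={"detected": True})


# -- differential readout --------------------------------------------------


def differential_shift(
    read_a: ResonanceRead,
    read_b: ResonanceRead,
    geom: SensorPairGeom,
    ref_a: float,
    ref_b: float,
) -> float:
    """Differential pixel shift of a mirrored pair relative to its baseline.

    Equal-and-opposite spectral motion adds; common translation cancels.
    Returns NaN if either read has no reportable position.
    """
    if not (np.isfinite(read_a.x_med) and np.isfinite(read_b.x_med)):
        return float("nan")
    return 0.5 * (
        geom.chirp_sign_a * (read_a.x_med - ref_a) + geom.chirp_sign_b * (read_b.x_med - ref_b)
    )


@dataclass
class SensorTrace:
    """Per-pair differential resonance trace in px, nm and RIU."""

    pair_id: str
    axis_kind: str  # "t" (seconds) or "lambda" (nm)
    axis: np.ndarray
    shift_px: np.ndarray
    shift_nm: np.ndarray
    shift_riu: np.ndarray
    qc: np.ndarray
    raw_a: np.ndarray | None = None  # absolute x_med of member A (diagnostics)
    raw_b: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.axis)
        for name in ("shift_px", "shift_nm", "shift_riu", "qc"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} length must match axis")
            setattr(self, name, arr)

    @property
    def t(self) -> np.ndarray:
        return self.axis

    def to_frame(self) -> pd.DataFrame:
        col = "t_s" if self.axis_kind == "t" else "lambda_nm"
        return pd.DataFrame(
            {
                "pair_id": self.pair_id,
                "frame": np.arange(len(self.axis)),
                col: self.axis,
                "shift_px": self.shift_px,
                "shift_nm": self.shift_nm,
                "shift_riu": self.shift_riu,
                "qc": self.qc,
            }
        )


def _per_pair_sensitivity(calibration, pair_id: str, setup: OpticalSetup) -> float:
    if calibration is None:
        return setup.nominal_px_per_nm
    if hasattr(calibration, "per_sensor_sensitivity"):
        table = calibration.per_sensor_sensitivity
    else:
        table = calibration
    s = table.get(pair_id)
    if s is None or not np.isfinite(s) or s <= 0:
        return setup.nominal_px_per_nm
    return float(s)


def track_stack(
    stack: FrameStack,
    layout: ArrayLayout,
    setup: OpticalSetup,
    calibration=None,
    *,
    bulk_sensitivity: float | None = None,
    baseline_frames: np.ndarray | None = None,
    min_rows: int = DEFAULT_MIN_ROWS,
    iqr_max: float = DEFAULT_IQR_MAX,
) -> list[SensorTrace]:
    """Track every pair through a stack and return differential traces.

    The per-grating baseline reference is the mean bar position over the
    baseline window: all frames before the first binding step for time
    series (``meta['baseline_s']``, or an explicit boolean ``baseline_frames``
    mask), the first frame for sweeps.  Traces are baseline-zeroed; per-frame
    QC (both reads passing) is propagated, and frames failing QC carry their
    value with ``qc=False`` (NaN only when no position was measurable).
    """
    if stack.frame_shape != tuple(layout.image_shape):
        raise ValueError("layout does not match stack frame shape")
    T = stack.n_frames
    axis_kind = "t" if stack.kind == "timeseries" else "lambda"
    axis = stack.axis
    bulk = bulk_sensitivity
    if bulk is None:
        bulk = stack.meta.get("bulk_sensitivity_nm_per_riu", 100.0)
    if baseline_frames is None:
        if stack.kind == "timeseries" and "baseline_s" in stack.meta:
            baseline_frames = axis < stack.meta["baseline_s"]
        else:
            baseline_frames = np.zeros(T, dtype=bool)
            if T:
                baseline_frames[0] = True
    baseline_frames = np.asarray(baseline_frames, dtype=bool)
    if T and not baseline_frames.any():
        baseline_frames = baseline_frames.copy()
        baseline_frames[0] = True

    xa = np.full((layout.n_pairs, T), np.nan)
    xb = np.full((layout.n_pairs, T), np.nan)
    qc = np.zeros((layout.n_pairs, T), dtype=bool)
    for ti in range(T):
        img = stack.frames[ti]
        for pi, geom in enumerate(layout.pairs):
            ra = read_roi(img, geom.roi_a, min_rows=min_rows, iqr_max=iqr_max)
            rb = read_roi(img, geom.roi_b, min_rows=min_rows, iqr_max=iqr_max)
            xa[pi, ti] = ra.x_med
            xb[pi, ti] = rb.x_med
            qc[pi, ti] = ra.qc_pass and rb.qc_pass

    traces: list[SensorTrace] = []
    for pi, geom in enumerate(layout.pairs):
        if T == 0:
            traces.append(
                SensorTrace(
                    pair_id=geom.pair_id,
                    axis_kind=axis_kind,
                    axis=np.empty(0),
                    shift_px=np.empty(0),
                    shift_nm=np.empty(0),
                    shift_riu=np.empty(0),
                    qc=np.empty(0, dtype=bool),
                )
            )
            continue
        ref_a = np.nanmean(xa[pi, baseline_frames])
        ref_b = np.nanmean(xb[pi, baseline_frames])
        d = 0.5 * (geom.chirp_sign_a * (xa[pi] - ref_a) + geom.chirp_sign_b * (xb[pi] - ref_b))
        base = np.nanmean(d[baseline_frames])
        if np.isfinite(base):
            d = d - base
        s = _per_pair_sensitivity(calibration, geom.pair_id, setup)
        nm = d / s
        traces.append(
            SensorTrace(
                pair_id=geom.pair_id,
                axis_kind=axis_kind,
                axis=np.asarray(axis, dtype=float),
                shift_px=d,
                shift_nm=nm,
                shift_riu=nm / bulk,
                qc=qc[pi],
                raw_a=xa[pi].copy(),
                raw_b=xb[pi].copy(),
                meta={"sensitivity_px_per_nm": s, "bulk_sensitivity_nm_per_riu": bulk},
            )
        )
    return traces
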