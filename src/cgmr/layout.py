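"""Chip geometry, optical setups and unit conversions.

A chirped guided-mode resonance (cGMR) grating encodes wavelength in space:
the grating period varies linearly along one axis, so the resonance condition
is met at a position that moves as the effective refractive index at the
surface (or the illumination wavelength) changes.  The chip tiles 322 mirrored
grating *pairs*; within a pair the chirp runs in opposite directions, so a
rigid mechanical translation moves both resonance bars the same way in pixels
while a spectral shift moves them in opposite directions.  All pixel /
wavelength / refractive-index conversions used downstream hang off the types
in this module.

Conventions
-----------
* Pixel rectangles are 0-based, half-open ``(row0, col0, height, width)``.
* The column axis is the chirp (spectral) axis; rows are the ~150
  independently fitted cross-sections of the bar.
* ``chirp_sign`` is the direction of increasing resonance wavelength along
  the column axis: +1 means the bar moves toward higher column index when the
  resonance red-shifts.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import yaml

__all__ = [
    "GratingDesign",
    "OpticalSetup",
    "Rect",
    "SensorPairGeom",
    "ArrayLayout",
    "FunctionalWindow",
    "DESIGN_1",
    "DESIGN_2",
    "DEFAULT_DESIGNS",
    "SETUPS",
    "DEFAULT_BULK_SENSITIVITY_NM_PER_RIU",
    "make_default_layout",
    "px_to_nm",
    "nm_to_px",
    "nm_to_riu",
    "riu_to_nm",
    "functional_window",
    "get_setup",
]

#: Bulk refractive-index sensitivity of the gratings, nm of resonance shift
#: per refractive-index unit.  A 2 nm wavelength scan corresponds to a
#: dynamic range of ~2e-2 RIU, i.e. 100 nm/RIU.
DEFAULT_BULK_SENSITIVITY_NM_PER_RIU = 100.0


class LayoutError(ValueError):
    """Raised when a geometric description violates its invariants."""


@dataclass(frozen=True)
class GratingDesign:
    """One of the two chirp designs present on the chip.

    Parameters
    ----------
    design_id
        1 or 2.
    period_start_nm, period_end_nm
        Grating period at the two ends of the chirp.
    resonance_window
        ``(lambda_min, lambda_max)`` in nm: the illumination wavelengths for
        which the resonance bar falls inside the grating, i.e. the usable
        spectral window (4 nm wide for both designs).
    """

    design_id: int
    period_start_nm: float
    period_end_nm: float
    resonance_window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.period_end_nm <= self.period_start_nm:
            raise LayoutError("period_end_nm must exceed period_start_nm")
        lo, hi = self.resonance_window
        if hi <= lo:
            raise LayoutError("resonance window must have positive width")

    @property
    def window_width_nm(self) -> float:
        lo, hi = self.resonance_window
        return hi - lo

    @property
    def window_centre_nm(self) -> float:
        lo, hi = self.resonance_window
        return 0.5 * (lo + hi)

    def chirp_extent_px(self, setup: "OpticalSetup") -> int:
        """Pixels spanned by this design's window on the given setup."""
        return setup.px_per_window


# The two designs tile the chip with 4 nm windows offset by 1 nm, centred on
# the 647.1 nm illumination line, giving a 3 nm overlap and a 5 nm union.
DESIGN_1 = GratingDesign(1, 420.0, 424.0, (645.1, 649.1))
DESIGN_2 = GratingDesign(2, 421.0, 425.0, (646.1, 650.1))
DEFAULT_DESIGNS = (DESIGN_1, DESIGN_2)


@dataclass(frozen=True)
class OpticalSetup:
    """An imaging configuration reading the array.

    ``px_per_window`` is the number of camera pixels covering one grating's
    4 nm spectral window; the nominal pixel scale is ``px_per_window / 4``
    px/nm.  ``fov_pairs`` is the number of sensor pairs in the field of view,
    carried as data (it differs between reports for the same instrument).
    """

    name: str
    px_per_window: int
    centre_wavelength_nm: float = 647.1
    fov_pairs: int | None = None

    def __post_init__(self) -> None:
        if self.px_per_window <= 0:
            raise LayoutError("px_per_window must be positive")

    @property
    def nominal_px_per_nm(self) -> float:
        return self.px_per_window / 4.0


SETUPS: dict[str, OpticalSetup] = {
    "setup1": OpticalSetup("setup1", 182, fov_pairs=79),
    "setup2": OpticalSetup("setup2", 354, fov_pairs=322),
    "setup3": OpticalSetup("setup3", 255, fov_pairs=185),
}


def get_setup(name: str) -> OpticalSetup:
    try:
        return SETUPS[name]
    except KeyError:
        raise LayoutError(f"unknown optical setup {name!r}; known: {sorted(SETUPS)}")


@dataclass(frozen=True)
class Rect:
    """Axis-aligned pixel rectangle, 0-based, half-open."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise LayoutError("rectangle must have positive size")
        if self.row0 < 0 or self.col0 < 0:
            raise LayoutError("rectangle origin must be non-negative")

    @property
    def row1(self) -> int:
        return self.row0 + self.height

    @property
    def col1(self) -> int:
        return self.col0 + self.width

    @property
    def centre_col(self) -> float:
        return self.col0 + (self.width - 1) / 2.0

    def intersects(self, other: "Rect") -> bool:
        return not (
            self.row1 <= other.row0
            or other.row1 <= self.row0
            or self.col1 <= other.col0
            or other.col1 <= self.col0
        )

    def inside(self, shape: tuple[int, int]) -> bool:
        return self.row1 <= shape[0] and self.col1 <= shape[1]


@dataclass(frozen=True)
class SensorPairGeom:
    """Geometry of one differential sensor pair (two mirrored gratings)."""

    pair_id: str
    roi_a: Rect
    roi_b: Rect
    chirp_sign_a: int = 1
    chirp_sign_b: int = -1
    design_id: int = 1

    def __post_init__(self) -> None:
        if self.chirp_sign_a not in (-1, 1) or self.chirp_sign_b not in (-1, 1):
            raise LayoutError("chirp signs must be +1 or -1")
        if self.chirp_sign_a != -self.chirp_sign_b:
            raise LayoutError("pair members must be chirped in opposite directions")
        if self.roi_a.intersects(self.roi_b):
            raise LayoutError(f"pair {self.pair_id}: member ROIs overlap")

    @property
    def rois(self) -> tuple[Rect, Rect]:
        return (self.roi_a, self.roi_b)


@dataclass
class ArrayLayout:
    """Positions of every sensor pair on the image, plus the image shape."""

    pairs: list[SensorPairGeom]
    image_shape: tuple[int, int]
    setup_name: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_rois(self) -> int:
        return 2 * len(self.pairs)

    @property
    def labels(self) -> list[str]:
        return [p.pair_id for p in self.pairs]

    def validate(self) -> None:
        shape = tuple(self.image_shape)
        if len(shape) != 2 or shape[0] <= 0 or shape[1] <= 0:
            raise LayoutError("image_shape must be a positive (rows, cols) pair")
        self.image_shape = shape
        seen: set[str] = set()
        rois: list[tuple[Rect, str]] = []
        for p in self.pairs:
            if p.pair_id in seen:
                raise LayoutError(f"duplicate pair_id {p.pair_id!r}")
            seen.add(p.pair_id)
            for roi in p.rois:
                if not roi.inside(shape):
                    raise LayoutError(f"pair {p.pair_id}: ROI exceeds image {shape}")
                rois.append((roi, p.pair_id))
        # sweep over row-sorted ROIs; only neighbours in row range can touch
        rois.sort(key=lambda rp: (rp[0].row0, rp[0].col0))
        for i, (ri, pi) in enumerate(rois):
            for rj, pj in rois[i + 1 :]:
                if rj.row0 >= ri.row1:
                    break
                if ri.intersects(rj) and not (pi == pj and ri is rj):
                    raise LayoutError(f"ROIs of pairs {pi!r} and {pj!r} overlap")

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema": "cgmr.layout/1",
            "image_shape": list(self.image_shape),
            "setup_name": self.setup_name,
            "meta": self.meta,
            "pairs": [
                {
                    "pair_id": p.pair_id,
                    "roi_a": asdict(p.roi_a),
                    "roi_b": asdict(p.roi_b),
                    "chirp_sign_a": p.chirp_sign_a,
                    "chirp_sign_b": p.chirp_sign_b,
                    "design_id": p.design_id,
                }
                for p in self.pairs
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArrayLayout":
        if d.get("schema") != "cgmr.layout/1":
            raise LayoutError("not a cgmr layout document (schema mismatch)")
        pairs = [
            SensorPairGeom(
                pair_id=p["pair_id"],
                roi_a=Rect(**p["roi_a"]),
                roi_b=Rect(**p["roi_b"]),
                chirp_sign_a=p["chirp_sign_a"],
                chirp_sign_b=p["chirp_sign_b"],
                design_id=p.get("design_id", 1),
            )
            for p in d["pairs"]
        ]
        return cls(
            pairs=pairs,
            image_shape=tuple(d["image_shape"]),
            setup_name=d.get("setup_name"),
            meta=d.get("meta", {}),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        doc = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(doc, sort_keys=False))
        else:
            path.write_text(json.dumps(doc, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ArrayLayout":
        path = Path(path)
        text = path.read_text()
        doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(doc)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def make_default_layout(
    setup: OpticalSetup,
    n_pairs: int,
    *,
    roi_height: int = 150,
    roi_width: int | None = None,
    pair_gap: int = 12,
    gap_rows: int = 24,
    gap_cols: int = 24,
    margin: int = 40,
    pairs_per_row: int | None = None,
) -> ArrayLayout:
    """Tile ``n_pairs`` mirrored sensor pairs in a regular grid.

    Each pair occupies two side-by-side ROIs of ``roi_height`` rows by
    ``roi_width`` columns (default: the setup's full 4 nm chirp extent).
    Designs alternate 1/2 between consecutive pairs so both spectral windows
    are represented across the array.  The image shape is computed from the
    tiling; a near-square aspect is chosen unless ``pairs_per_row`` is given.
    """
    if n_pairs < 1:
        raise LayoutError("n_pairs must be >= 1")
    w = roi_width if roi_width is not None else setup.px_per_window
    if w < 8:
        raise LayoutError("roi_width too small to hold a resonance bar")
    block_w = 2 * w + pair_gap + gap_cols
    block_h = roi_height + gap_rows
    if pairs_per_row is None:
        pairs_per_row = max(1, round(math.sqrt(n_pairs * block_h / block_w)))
    n_rows = math.ceil(n_pairs / pairs_per_row)
    image_shape = (
        n_rows * block_h - gap_rows + 2 * margin,
        pairs_per_row * block_w - gap_cols + 2 * margin,
    )
    pairs: list[SensorPairGeom] = []
    for i in range(n_pairs):
        gr, gc = divmod(i, pairs_per_row)
        row0 = margin + gr * block_h
        col0 = margin + gc * block_w
        roi_a = Rect(row0, col0, roi_height, w)
        roi_b = Rect(row0, col0 + w + pair_gap, roi_height, w)
        pairs.append(
            SensorPairGeom(
                pair_id=f"{i + 1:03d}A",
                roi_a=roi_a,
                roi_b=roi_b,
                chirp_sign_a=1,
                chirp_sign_b=-1,
                design_id=1 + (i % 2),
            )
        )
    return ArrayLayout(pairs=pairs, image_shape=image_shape, setup_name=setup.name)


# -- unit conversions ------------------------------------------------------


def _sensitivity(setup: OpticalSetup, sensitivity_px_per_nm: float | None) -> float:
    s = setup.nominal_px_per_nm if sensitivity_px_per_nm is None else sensitivity_px_per_nm
    if not s > 0:
        raise LayoutError("sensitivity must be positive (px/nm)")
    return s


def px_to_nm(shift_px, setup: OpticalSetup, sensitivity_px_per_nm: float | None = None):
    """Convert a pixel shift to a resonance-wavelength shift in nm.

    Uses the measured per-sensor sensitivity when given, else the setup's
    nominal chirp map ``px_per_window / 4``.
    """
    return shift_px / _sensitivity(setup, sensitivity_px_per_nm)


def nm_to_px(shift_nm, setup: OpticalSetup, sensitivity_px_per_nm: float | None = None):
    """Inverse of :func:`px_to_nm`."""
    return shift_nm * _sensitivity(setup, sensitivity_px_per_nm)


def nm_to_riu(shift_nm, bulk_sensitivity_nm_per_riu: float = DEFAULT_BULK_SENSITIVITY_NM_PER_RIU):
    """Convert a wavelength shift to an effective refractive-index change."""
    if not bulk_sensitivity_nm_per_riu > 0:
        raise LayoutError("bulk sensitivity must be positive (nm/RIU)")
    return shift_nm / bulk_sensitivity_nm_per_riu


def riu_to_nm(shift_riu, bulk_sensitivity_nm_per_riu: float = DEFAULT_BULK_SENSITIVITY_NM_PER_RIU):
    """Inverse of :func:`nm_to_riu`."""
    if not bulk_sensitivity_nm_per_riu > 0:
        raise LayoutError("bulk sensitivity must be positive (nm/RIU)")
    return shift_riu * bulk_sensitivity_nm_per_riu


@dataclass(frozen=True)
class FunctionalWindow:
    """Union / overlap structure of the designs' spectral windows (nm)."""

    union_nm: float
    overlap_nm: float
    per_design_nm: tuple[float, ...]
    disjoint: bool


def functional_window(designs: Sequence[GratingDesign] | Iterable[GratingDesign]) -> FunctionalWindow:
    """Width of the union and overlap of the designs' resonance windows.

    The union is the measure of the interval union; the overlap is the
    measure of the region covered by at least two windows (0 for a single
    design).  Disjoint windows are not an error — the result is flagged.
    """
    designs = list(designs)
    if not designs:
        raise LayoutError("at least one design required")
    windows = sorted(d.resonance_window for d in designs)
    per_design = tuple(hi - lo for lo, hi in windows)
    # merge intervals for union; track multiply-covered length via pairwise
    union = 0.0
    cur_lo, cur_hi = windows[0]
    disjoint = False
    for lo, hi in windows[1:]:
        if lo > cur_hi:
            union += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
            disjoint = True
        else:
            cur_hi = max(cur_hi, hi)
    union += cur_hi - cur_lo
    # coverage >= 2 measured on the endpoint grid
    pts = sorted({x for lo, hi in windows for x in (lo, hi)})
    overlap = 0.0
    for a, b in zip(pts, pts[1:]):
        mid = 0.5 * (a + b)
        if sum(1 for lo, hi in windows if lo < mid < hi) >= 2:
            overlap += b - a
    return FunctionalWindow(
        union_nm=union,
        overlap_nm=overlap if len(designs) > 1 else 0.0,
        per_design_nm=per_design,
        disjoint=disjoint,
    )
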