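"""File formats and run configuration.

Stacks travel as multi-page uint16 TIFF plus a JSON sidecar (``<stem>.json``)
carrying the frame axis, seed, layout hash and optional ground truth.  Traces
are CSV with unit-suffixed column names; run logs are JSON with config hash,
seed and software version so every artifact is reproducible bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .stack import FrameStack
from .track import SensorTrace

__all__ = [
    "read_stack",
    "write_stack",
    "traces_to_csv",
    "read_traces",
    "RunConfig",
    "write_run_log",
    "StackIOError",
]

SIDECAR_SCHEMA = "cgmr.stack/1"


class StackIOError(RuntimeError):
    pass


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(stack: FrameStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF + JSON sidecar; returns the TIFF path."""
    path = Path(path)
    if stack.frames.dtype != np.uint16:
        raise StackIOError("stacks are stored as uint16")
    tifffile.imwrite(path, stack.frames, photometric="minisblack")
    doc = {
        "schema": SIDECAR_SCHEMA,
        "kind": stack.kind,
        "n_frames": stack.n_frames,
        "t_s": None if stack.t_s is None else [float(v) for v in stack.t_s],
        "wavelengths_nm": None
        if stack.wavelengths_nm is None
        else [float(v) for v in stack.wavelengths_nm],
        "meta": stack.meta,
        "ground_truth": None
        if stack.ground_truth is None
        else stack.ground_truth.to_dict(orient="list"),
    }
    _sidecar_path(path).write_text(json.dumps(doc))
    return path


def read_stack(path: str | Path) -> FrameStack:
    """Read a TIFF + sidecar pair; the round trip is bit-lossless."""
    path = Path(path)
    side = _sidecar_path(path)
    if not path.exists():
        raise StackIOError(f"stack not found: {path}")
    if not side.exists():
        raise StackIOError(f"sidecar not found: {side}")
    try:
        frames = tifffile.imread(path)
    except Exception as e:
        raise StackIOError(f"cannot read TIFF {path}: {e}") from e
    if frames.ndim == 2:
        frames = frames[None, ...]
    doc = json.loads(side.read_text())
    if doc.get("schema") != SIDECAR_SCHEMA:
        raise StackIOError("sidecar schema mismatch")
    if doc["n_frames"] != frames.shape[0]:
        raise StackIOError(
            f"sidecar declares {doc['n_frames']} frames but TIFF holds {frames.shape[0]}"
        )
    kind = doc["kind"]
    if kind == "sweep" and not doc.get("wavelengths_nm"):
        raise StackIOError("sweep sidecar is missing its wavelengths")
    if kind == "timeseries" and doc.get("t_s") is None:
        raise StackIOError("time-series sidecar is missing its timestamps")
    gt = doc.get("ground_truth")
    return FrameStack(
        frames=frames,
        kind=kind,
        t_s=None if doc.get("t_s") is None else np.asarray(doc["t_s"], dtype=float),
        wavelengths_nm=None
        if doc.get("wavelengths_nm") is None
        else np.asarray(doc["wavelengths_nm"], dtype=float),
        meta=doc.get("meta", {}),
        ground_truth=None if gt is None else pd.DataFrame(gt),
    )


def traces_to_csv(traces: list[SensorTrace], path: str | Path) -> Path:
    path = Path(path)
    pd.concat([tr.to_frame() for tr in traces], ignore_index=True).to_csv(path, index=False)
    return path


def read_traces(path: str | Path) -> list[SensorTrace]:
    df = pd.read_csv(path)
    axis_col = "t_s" if "t_s" in df.columns else "lambda_nm"
    out = []
    for pid, g in df.groupby("pair_id", sort=False):
        out.append(
            SensorTrace(
                pair_id=str(pid),
                axis_kind="t" if axis_col == "t_s" else "lambda",
                axis=g[axis_col].to_numpy(dtype=float),
                shift_px=g["shift_px"].to_numpy(dtype=float),
                shift_nm=g["shift_nm"].to_numpy(dtype=float),
                shift_riu=g["shift_riu"].to_numpy(dtype=float),
                qc=g["qc"].to_numpy(dtype=bool),
            )
        )
    return out


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected on load."""

    setup: str = "setup1"
    layout_path: str | None = None
    seed: int = 0
    min_rows: int = 50
    iqr_max: float = 2.0
    bulk_sensitivity_nm_per_riu: float = 100.0
    bootstrap_draws: int = 500
    lda_priors: str = "equal"
    output_dir: str = "."
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.min_rows < 3:
            raise ValueError("min_rows must be >= 3")
        if self.iqr_max <= 0:
            raise ValueError("iqr_max must be positive")
        if self.bulk_sensitivity_nm_per_riu <= 0:
            raise ValueError("bulk sensitivity must be positive")
        if self.lda_priors not in ("equal", "proportional"):
            raise ValueError("lda_priors must be 'equal' or 'proportional'")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def write_run_log(path: str | Path, *, stage: str, config: RunConfig | None, seed: int | None, counts: dict) -> Path:
    """One structured JSON log per stage: version, seed, config hash, counts."""
    from . import __version__

    doc = {
        "stage": stage,
        "version": __version__,
        "seed": seed,
        "config": None if config is None else config.to_dict(),
        "config_hash": None if config is None else config.content_hash(),
        "counts": counts,
    }
    path = Path(path)
    path.write_text(json.dumps(doc, indent=1))
    return path
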