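"""Time/wavelength-indexed image cube with acquisition metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FrameStack"]


@dataclass
class FrameStack:
    """A stack of array images, one frame per time point or illumination wavelength.

    Attributes
    ----------
    frames
        ``(T, H, W)`` image cube, uint16 counts.
    kind
        ``"timeseries"`` (frames indexed by ``t_s``) or ``"sweep"``
        (frames indexed by ``wavelengths_nm``).
    t_s, wavelengths_nm
        Frame axis, seconds or nm; exactly one is set, matching ``kind``.
    meta
        Acquisition/provenance metadata (setup name, seed, layout hash,
        noise parameters, flagged gratings, free-form notes).
    ground_truth
        For simulated stacks: long-format table of the true differential
        shift per pair and frame (columns ``pair_id, frame, shift_px,
        shift_nm, shift_riu``); ``None`` for stacks read from disk without
        stored truth.
    """

    frames: np.ndarray
    kind: str
    t_s: np.ndarray | None = None
    wavelengths_nm: np.ndarray | None = None
    meta: dict = field(default_factory=dict)
    ground_truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) cube")
        if self.kind not in ("timeseries", "sweep"):
            raise ValueError("kind must be 'timeseries' or 'sweep'")
        axis = self.t_s if self.kind == "timeseries" else self.wavelengths_nm
        if axis is None:
            raise ValueError(f"{self.kind} stack needs its frame axis")
        axis = np.asarray(axis, dtype=float)
        if axis.shape != (self.frames.shape[0],):
            raise ValueError("frame axis length must match number of frames")
        if self.kind == "timeseries":
            self.t_s = axis
        else:
            self.wavelengths_nm = axis

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def axis(self) -> np.ndarray:
        """The frame coordinate: seconds for time series, nm for sweeps."""
        return self.t_s if self.kind == "timeseries" else self.wavelengths_nm
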