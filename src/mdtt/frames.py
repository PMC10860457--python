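"""Fluoroscopy frame containers shared by the simulator and the detector."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FluoroFrame", "FluoroSequence"]


@dataclass
class FluoroFrame:
    """One kV fluoroscopy frame with its acquisition metadata.

    ``pixels`` is a 16-bit (or float) raster of shape (rows, cols) =
    (768, 1024) by default; ``imager_id`` identifies which of the two
    orthogonal tubes acquired it.
    """

    pixels: np.ndarray
    imager_id: str
    time_s: float
    gantry_deg: float = 0.0
    ring_deg: float = 0.0
    frame_id: int = 0

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class FluoroSequence:
    """Time-ordered frames of one imager within a session."""

    frames: list = field(default_factory=list)
    imager_id: str = "A"

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time_s for f in self.frames])
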