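"""The in-memory frame container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DetectorGeometry

__all__ = ["DiffractionFrame"]


@dataclass
class DiffractionFrame:
    """A single 2D detector exposure plus its study metadata.

    ``data`` is a non-negative count matrix (integer for raw detector data;
    real-valued for simulated noiseless means).  ``geometry`` ties the frame
    to a pixel -> (q, phi) mapping.
    """

    data: np.ndarray
    frame_id: str | None = None
    patient_id: str | None = None
    label: str | None = None
    geometry: DetectorGeometry | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"frame data must be 2D, got shape {self.data.shape}")
        if np.any(self.data < 0):
            r, c = np.argwhere(self.data < 0)[0]
            raise ValueError(
                f"frame {self.frame_id!r}: negative count {self.data[r, c]} at ({r}, {c})"
            )
        if self.geometry is not None and self.geometry.shape != self.data.shape:
            raise ValueError(
                f"frame shape {self.data.shape} != geometry shape {self.geometry.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape
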