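"""Fourier log-magnitude image features.

Each masked frame is converted to a feature vector by: 2D discrete Fourier
transform -> complex magnitudes -> normalization by the zero-frequency
(total brightness) magnitude -> centering of the zero-frequency term
(fftshift) -> log map ``ln(x + eps)`` -> row-major flattening.  Magnitudes
are translation-invariant, so directional order shows up in the
spatial-frequency distribution without any explicit alignment of the
pattern; the brightness normalization makes the features invariant to
overall exposure scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .frames import DiffractionFrame

__all__ = ["FeatureMatrix", "fourier_magnitude_features", "build_feature_matrix"]

DEFAULT_LOG_EPS = 1e-6


@dataclass
class FeatureMatrix:
    """Stacked flattened feature vectors, rows aligned to frame ids."""

    values: np.ndarray  # (n_frames, n_features)
    frame_ids: list[str]

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2D")
        if self.values.shape[0] != len(self.frame_ids):
            raise ValueError("row count must equal the number of frame ids")


def fourier_magnitude_features(
    frame: DiffractionFrame | np.ndarray, eps: float = DEFAULT_LOG_EPS
) -> np.ndarray:
    """Flattened, centered log-magnitude 2D Fourier spectrum of one frame.

    The frame must be non-negative with at least one positive pixel (the
    zero-frequency magnitude, i.e. the total brightness, is the
    normalizer).  For non-negative input the zero-frequency term dominates,
    so every feature value is <= ln(1 + eps).
    """
    data = frame.data if isinstance(frame, DiffractionFrame) else np.asarray(frame)
    if data.ndim != 2:
        raise ValueError("expected a 2D frame")
    if np.any(data < 0):
        raise ValueError("frame must be non-negative")
    spectrum = np.abs(np.fft.fft2(data.astype(float)))
    dc = spectrum[0, 0]
    if dc == 0:
        raise ValueError("all-zero frame: zero-frequency normalizer vanishes")
    spectrum /= dc
    spectrum = np.fft.fftshift(spectrum)
    return np.log(spectrum + eps).ravel()


def build_feature_matrix(
    frames: Sequence[DiffractionFrame],
    metadata: pd.DataFrame,
    eps: float = DEFAULT_LOG_EPS,
) -> FeatureMatrix:
    """Feature vectors for all frames, stacked in metadata row order.

    All frames must share one shape; every metadata ``frame_id`` must have
    a matching frame.
    """
    by_id = {}
    for f in frames:
        if f.frame_id is None:
            raise ValueError("every frame needs a frame_id to align with metadata")
        by_id[f.frame_id] = f
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"frames have mixed shapes: {sorted(shapes)}")
    rows = []
    ids = []
    for frame_id in metadata["frame_id"]:
        if frame_id not in by_id:
            raise ValueError(f"metadata frame {frame_id!r} has no matching frame")
        rows.append(fourier_magnitude_features(by_id[frame_id], eps=eps))
        ids.append(frame_id)
    return FeatureMatrix(values=np.vstack(rows), frame_ids=ids)
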