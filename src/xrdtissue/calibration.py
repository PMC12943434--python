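"""Azimuthal integration and sample-to-detector distance calibration.

Integration collapses a 2D pattern to a 1D profile I(q) by *averaging* the
unmasked pixel intensities falling into half-open q bins ``[lo, hi)``.
Empty bins are flagged, never silently reported as zero.

Distance calibration follows the standard powder-laboratory procedure: a
lamellar standard (silver behenate, d(001) = 5.8380 nm) is exposed, the
radial centroid of each visible reflection order is measured on the
detector, and the distance L is the least-squares solution of

    r_n = L * tan(2 * arcsin(n * q1 * lambda / 4 pi)),   q1 = 2 pi / d.

The calibration report carries the mean and standard deviation of the
measured q positions (scaled to a common reference order) and their ratio as
a relative uncertainty in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import DetectorGeometry, expected_q, q_phi_map, q_to_radius_mm

__all__ = [
    "RadialProfile",
    "CalibrationResult",
    "azimuthal_integrate",
    "calibrate_distance",
]


@dataclass
class RadialProfile:
    """Azimuthally integrated intensity profile.

    ``intensity`` holds the mean unmasked counts per bin and is NaN where
    ``empty`` is True (no unmasked pixels fell into the bin).
    """

    q_centers: np.ndarray
    intensity: np.ndarray
    n_pixels: np.ndarray

    @property
    def empty(self) -> np.ndarray:
        return self.n_pixels == 0

    def to_text(self, path) -> None:
        """Two-column delimited text (q_nm_inv, intensity); empty bins omitted."""
        keep = ~self.empty
        np.savetxt(
            path,
            np.column_stack([self.q_centers[keep], self.intensity[keep]]),
            header="q_nm_inv intensity",
        )


@dataclass
class CalibrationResult:
    """Outcome of a powder-standard distance calibration."""

    fitted_distance_mm: float
    measured_q_mean: float
    measured_q_std: float
    orders_used: Sequence[int] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (self.fitted_distance_mm > 0):
            raise ValueError("fitted distance must be positive")

    @property
    def relative_uncertainty_pct(self) -> float:
        """100 * std / mean of the measured q positions, in percent."""
        return 100.0 * self.measured_q_std / self.measured_q_mean


def azimuthal_integrate(
    frame: np.ndarray,
    geometry: DetectorGeometry,
    q_bins: np.ndarray,
    mask: np.ndarray | None = None,
) -> RadialProfile:
    """Mean intensity per half-open q bin ``[lo, hi)`` over unmasked pixels.

    Parameters
    ----------
    frame:
        2D count matrix matching ``geometry.shape``.
    q_bins:
        Strictly increasing bin edges in nm^-1 (``len(q_bins) - 1`` bins).
    mask:
        Optional boolean matrix, True = excluded pixel.
    """
    frame = np.asarray(frame)
    q_bins = np.asarray(q_bins, dtype=float)
    if q_bins.ndim != 1 or q_bins.size < 2 or np.any(np.diff(q_bins) <= 0):
        raise ValueError("q_bins must be strictly increasing edges with >= 2 entries")
    if frame.shape != geometry.shape:
        raise ValueError(f"frame shape {frame.shape} != detector shape {geometry.shape}")
    if mask is not None and mask.shape != frame.shape:
        raise ValueError("mask shape must match frame shape")

    q = q_phi_map(geometry).q.ravel()
    values = frame.ravel().astype(float)
    keep = np.ones(q.size, dtype=bool) if mask is None else ~mask.ravel()
    q, values = q[keep], values[keep]

    idx = np.digitize(q, q_bins) - 1  # half-open [lo, hi)
    inside = (idx >= 0) & (idx < q_bins.size - 1)
    idx, values = idx[inside], values[inside]

    n_bins = q_bins.size - 1
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=values, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        intensity = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if np.all(counts == 0):
        warnings.warn("all pixels masked or outside the q range: profile is empty")
    return RadialProfile(
        q_centers=0.5 * (q_bins[:-1] + q_bins[1:]),
        intensity=intensity,
        n_pixels=counts,
    )


def _radial_profile_px(frame, geometry, bin_width_px=0.5):
    """Intensity vs pixel radius from the beam center (mean per radial bin)."""
    rows = np.arange(geometry.shape[0], dtype=float) - geometry.beam_center[0]
    cols = np.arange(geometry.shape[1], dtype=float) - geometry.beam_center[1]
    r_px = np.hypot(rows[:, None], cols[None, :]).ravel()
    values = np.asarray(frame, dtype=float).ravel()
    edges = np.arange(0.0, r_px.max() + bin_width_px, bin_width_px)
    idx = np.digitize(r_px, edges) - 1
    n_bins = edges.size - 1
    counts = np.bincount(idx, minlength=n_bins)[:n_bins]
    sums = np.bincount(idx, weights=values, minlength=n_bins)[:n_bins]
    centers = 0.5 * (edges[:-1] + edges[1:])
    valid = counts > 0
    return centers[valid], sums[valid] / counts[valid]


def calibrate_distance(
    standard_frames: np.ndarray | Sequence[np.ndarray],
    geometry_prior: DetectorGeometry,
    d_spacing_nm: float = 5.8380,
    orders: Sequence[int] = (1, 2, 3),
    reference_order: int | None = None,
    search_window: float = 0.15,
) -> CalibrationResult:
    """Fit the sample-to-detector distance from powder-standard frames.

    For each frame and order, the radial centroid of the reflection is
    measured within ``+/- search_window`` (fractional) of the radius
    predicted by the prior geometry; the local minimum of the window is
    subtracted before taking the centroid so a smooth background does not
    bias it.  Orders with no detectable peak are dropped with a warning.
    The fitted distance minimizes the squared radius residuals jointly over
    all detected reflections (closed form, since r is linear in L at fixed
    scattering angle).

    The measured q of each detected reflection (at the fitted distance) is
    scaled to ``reference_order`` (default: the largest requested order) so
    that positions from different orders are commensurable; their mean/std
    populate the :class:`CalibrationResult`.
    """
    if isinstance(standard_frames, np.ndarray) and standard_frames.ndim == 2:
        standard_frames = [standard_frames]
    orders = [int(n) for n in orders]
    if not orders or any(n < 1 for n in orders):
        raise ValueError("orders must be a non-empty list of positive integers")
    ref = max(orders) if reference_order is None else int(reference_order)

    # tan(2 theta) per order is distance-independent
    tangents = {
        n: q_to_radius_mm(geometry_prior, expected_q(d_spacing_nm, n))
        / geometry_prior.distance_mm
        for n in orders
    }

    measured_r_mm: list[float] = []
    used_tangents: list[float] = []
    used_orders: list[int] = []
    for frame in standard_frames:
        r_px, intensity = _radial_profile_px(frame, geometry_prior)
        for n in orders:
            r_expected_px = (
                tangents[n] * geometry_prior.distance_mm / geometry_prior.pixel_size_mm
            )
            window = (r_px >= (1 - search_window) * r_expected_px) & (
                r_px <= (1 + search_window) * r_expected_px
            )
            if window.sum() < 3:
                warnings.warn(f"order {n}: expected radius off the detector; dropped")
                continue
            r_w, i_w = r_px[window], intensity[window]
            # subtract the straight line through the window edges; a peak is
            # detected only if its excess clears the local Poisson scale
            baseline = np.interp(r_w, [r_w[0], r_w[-1]], [i_w[0], i_w[-1]])
            local = np.clip(i_w - baseline, 0.0, None)
            peak_excess = local.max()
            if peak_excess <= 5.0 * np.sqrt(max(np.median(i_w), 1.0)):
                warnings.warn(f"order {n}: no detectable peak in the search window; dropped")
                continue
            centroid_px = float(np.sum(r_w * local) / local.sum())
            measured_r_mm.append(centroid_px * geometry_prior.pixel_size_mm)
            used_tangents.append(tangents[n])
            used_orders.append(n)

    if not measured_r_mm:
        raise RuntimeError("no reflection of the standard was detected for any order")

    r = np.asarray(measured_r_mm)
    t = np.asarray(used_tangents)
    fitted_L = float(np.sum(r * t) / np.sum(t * t))

    two_theta = np.arctan2(r, fitted_L)
    lam = geometry_prior.wavelength_nm
    q_measured = 4.0 * np.pi / lam * np.sin(two_theta / 2.0)
    q_scaled = q_measured * (ref / np.asarray(used_orders, dtype=float))
    return CalibrationResult(
        fitted_distance_mm=fitted_L,
        measured_q_mean=float(np.mean(q_scaled)),
        measured_q_std=float(np.std(q_scaled)),
        orders_used=tuple(used_orders),
    )
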