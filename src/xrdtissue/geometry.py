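"""Detector geometry: mapping pixels to scattering coordinates (q, phi).

The scattering-vector magnitude is computed with the exact relation

    q = (4 pi / lambda) * sin(theta),   2*theta = arctan(r / L),

where ``r`` is the radial distance of a pixel from the beam center (in mm)
and ``L`` the sample-to-detector distance.  No small-angle approximation is
used: a laboratory WAXS camera at L ~ 20 mm reaches scattering angles beyond
30 degrees where ``tan(2 theta) != 2 theta``.

Conventions (fixed so ring extraction is reproducible):

* pixel coordinates are 0-based ``(row, col)`` with pixel centers at integer
  coordinates; the beam center may be fractional;
* the azimuth is ``phi = atan2(row - center_row, col - center_col)`` mapped
  into ``[0, 2 pi)``.  The angular origin is a free convention because the
  sinusoid phases fitted downstream are themselves free parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "DetectorGeometry",
    "QPhiMap",
    "expected_q",
    "pixel_to_q",
    "q_to_radius_mm",
    "q_phi_map",
    "read_geometry",
    "write_geometry",
    "LAB_WAXS",
    "SYNCHROTRON_WAXS",
    "SYNCHROTRON_SAXS",
]


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat 2D detector with normal incidence.

    Parameters
    ----------
    wavelength_nm:
        X-ray wavelength in nm.
    distance_mm:
        Sample-to-detector distance in mm.
    pixel_size_mm:
        Square pixel edge in mm.
    beam_center:
        Fractional ``(row, col)`` pixel coordinates of the direct beam.
    shape:
        ``(n_rows, n_cols)`` of the detector array.
    """

    wavelength_nm: float
    distance_mm: float
    pixel_size_mm: float
    beam_center: tuple[float, float]
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        if not (self.wavelength_nm > 0):
            raise ValueError(f"wavelength must be positive, got {self.wavelength_nm}")
        if not (self.distance_mm > 0):
            raise ValueError(f"distance must be positive, got {self.distance_mm}")
        if not (self.pixel_size_mm > 0):
            raise ValueError(f"pixel size must be positive, got {self.pixel_size_mm}")
        r, c = self.shape
        if r < 1 or c < 1:
            raise ValueError(f"detector shape components must be >= 1, got {self.shape}")
        if not np.all(np.isfinite(self.beam_center)):
            raise ValueError(f"beam center must be finite, got {self.beam_center}")


@dataclass(frozen=True)
class QPhiMap:
    """Per-pixel momentum transfer (nm^-1) and azimuth (radians in [0, 2pi))."""

    q: np.ndarray
    phi: np.ndarray


def expected_q(d_spacing_nm: float, order: int) -> float:
    """Reflection position ``q = 2 pi n / d`` of a lamellar powder standard.

    Silver behenate (d(001) = 5.8380 nm) is the usual standard for
    sample-to-detector distance calibration; its 3rd order sits at
    3.2288 nm^-1.
    """
    if order < 1 or int(order) != order:
        raise ValueError(f"reflection order must be a positive integer, got {order}")
    if not (d_spacing_nm > 0):
        raise ValueError(f"d-spacing must be positive, got {d_spacing_nm}")
    return 2.0 * np.pi * order / d_spacing_nm


def _radius_phi(geometry: DetectorGeometry, row, col):
    drow = np.asarray(row, dtype=float) - geometry.beam_center[0]
    dcol = np.asarray(col, dtype=float) - geometry.beam_center[1]
    r_mm = np.hypot(drow, dcol) * geometry.pixel_size_mm
    phi = np.mod(np.arctan2(drow, dcol), 2.0 * np.pi)
    return r_mm, phi


def pixel_to_q(geometry: DetectorGeometry, pixel: tuple[float, float]):
    """Map one fractional pixel coordinate to ``(q [nm^-1], phi [rad])``."""
    if not np.all(np.isfinite(pixel)):
        raise ValueError(f"pixel coordinates must be finite, got {pixel}")
    r_mm, phi = _radius_phi(geometry, pixel[0], pixel[1])
    two_theta = np.arctan2(r_mm, geometry.distance_mm)
    q = 4.0 * np.pi / geometry.wavelength_nm * np.sin(two_theta / 2.0)
    return float(q), float(phi)


def q_to_radius_mm(geometry: DetectorGeometry, q) -> np.ndarray | float:
    """Inverse of the radial part of :func:`pixel_to_q`:
    ``r = L * tan(2 * arcsin(q lambda / 4 pi))`` in mm."""
    q = np.asarray(q, dtype=float)
    s = q * geometry.wavelength_nm / (4.0 * np.pi)
    if np.any(s >= 1.0) or np.any(s < 0):
        raise ValueError("q outside the physically reachable range for this wavelength")
    r = geometry.distance_mm * np.tan(2.0 * np.arcsin(s))
    return float(r) if r.ndim == 0 else r


def q_phi_map(geometry: DetectorGeometry) -> QPhiMap:
    """Full-detector (q, phi) map evaluated at pixel centers."""
    rows = np.arange(geometry.shape[0], dtype=float)
    cols = np.arange(geometry.shape[1], dtype=float)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    r_mm, phi = _radius_phi(geometry, rr, cc)
    two_theta = np.arctan2(r_mm, geometry.distance_mm)
    q = 4.0 * np.pi / geometry.wavelength_nm * np.sin(two_theta / 2.0)
    return QPhiMap(q=q, phi=phi)


_GEOMETRY_KEYS = (
    "wavelength_nm",
    "distance_mm",
    "pixel_size_mm",
    "beam_center_row",
    "beam_center_col",
    "n_rows",
    "n_cols",
)


def write_geometry(geometry: DetectorGeometry, path: str | Path) -> None:
    """Write a key-value geometry config file."""
    values = {
        "wavelength_nm": geometry.wavelength_nm,
        "distance_mm": geometry.distance_mm,
        "pixel_size_mm": geometry.pixel_size_mm,
        "beam_center_row": geometry.beam_center[0],
        "beam_center_col": geometry.beam_center[1],
        "n_rows": geometry.shape[0],
        "n_cols": geometry.shape[1],
    }
    lines = [f"{k} = {values[k]!r}" for k in _GEOMETRY_KEYS]
    Path(path).write_text("\n".join(lines) + "\n")


def read_geometry(path: str | Path) -> DetectorGeometry:
    """Read a key-value geometry config file written by :func:`write_geometry`."""
    values: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        values[key.strip()] = float(value)
    missing = [k for k in _GEOMETRY_KEYS if k not in values]
    if missing:
        raise ValueError(f"{path}: missing geometry keys {missing}")
    return DetectorGeometry(
        wavelength_nm=values["wavelength_nm"],
        distance_mm=values["distance_mm"],
        pixel_size_mm=values["pixel_size_mm"],
        beam_center=(values["beam_center_row"], values["beam_center_col"]),
        shape=(int(values["n_rows"]), int(values["n_cols"])),
    )


#: Bespoke laboratory diffractometer: Cu K-alpha, 256x256 Timepix-class chip,
#: 55 um pixels, nominally 20 mm from the sample.  The beam center sits off
#: one corner so that a single quadrant covers q up to ~23 nm^-1.
LAB_WAXS = DetectorGeometry(
    wavelength_nm=0.154,
    distance_mm=20.0,
    pixel_size_mm=0.055,
    beam_center=(236.0, 20.0),
    shape=(256, 256),
)

#: Synchrotron WAXS endstation: lambda = 0.1 nm, 170 mm camera length,
#: hybrid-pixel detector (172 um pixels), beam centered.
SYNCHROTRON_WAXS = DetectorGeometry(
    wavelength_nm=0.1,
    distance_mm=170.0,
    pixel_size_mm=0.172,
    beam_center=(255.5, 255.5),
    shape=(512, 512),
)

#: Synchrotron SAXS endstation: lambda = 0.1 nm, 5935 mm camera length.  The
#: 3rd-order collagen reflection at q = 0.3 nm^-1 lands ~165 pixels from the
#: beam center.
SYNCHROTRON_SAXS = DetectorGeometry(
    wavelength_nm=0.1,
    distance_mm=5935.0,
    pixel_size_mm=0.172,
    beam_center=(255.5, 255.5),
    shape=(512, 512),
)
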