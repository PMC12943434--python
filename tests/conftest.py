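import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from xrdtissue.geometry import DetectorGeometry

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def lab_geometry():
    """Full-resolution laboratory WAXS camera."""
    from xrdtissue.geometry import LAB_WAXS

    return LAB_WAXS


@pytest.fixture
def centered_geometry():
    """Small detector with the beam center exactly on a pixel, so the
    pattern has exact 4-fold pixel symmetry (useful for rotation tests)."""
    return DetectorGeometry(
        wavelength_nm=0.154,
        distance_mm=20.0,
        pixel_size_mm=0.220,
        beam_center=(64.0, 64.0),
        shape=(129, 129),
    )


@pytest.fixture
def ring_geometry():
    """Long-camera geometry resolving a q = 0.3 nm^-1 ring at ~83 px."""
    return DetectorGeometry(
        wavelength_nm=0.1,
        distance_mm=2995.0,
        pixel_size_mm=0.172,
        beam_center=(127.5, 127.5),
        shape=(256, 256),
    )


@pytest.fixture
def small_metadata():
    """12-patient grouped metadata (8 cancer / 4 fibroadenoma, 4 frames each)."""
    records = []
    for p in range(12):
        label = "cancer" if p < 8 else "fibroadenoma"
        pid = f"P{p:02d}"
        for m in range(4):
            records.append(
                {"frame_id": f"{pid}_s{m}", "patient_id": pid, "label": label}
            )
    return pd.DataFrame.from_records(records)


@pytest.fixture
def separable_scores():
    """Patient score table with clean class separation (18 + 18 patients)."""
    rng = np.random.default_rng(7)
    n = 18
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(2 * n)],
            "score": np.concatenate(
                [
                    np.clip(rng.normal(0.8, 0.1, n), 0, 1),
                    np.clip(rng.normal(0.25, 0.1, n), 0, 1),
                ]
            ),
            "label": ["cancer"] * n + ["fibroadenoma"] * n,
        }
    )
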