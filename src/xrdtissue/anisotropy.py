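"""Two-harmonic azimuthal anisotropy model and the (A1, A2) classifier.

A ring's azimuthal intensity is modeled as

    I(phi) = A0 + A1 * sin(2 phi + phi1) + A2 * sin(4 phi + phi2),

the constant term A0 plus a 2-phi harmonic (preferential fibril
orientation) and a 4-phi harmonic.  The model is exactly linear in the
sine/cosine parameterization ``a * sin(k phi) + b * cos(k phi)``, so the
fit is ordinary least squares on the basis {1, sin 2phi, cos 2phi, sin
4phi, cos 4phi} — no initialization or convergence concerns.  Amplitudes
are reported in canonical non-negative form with the sign absorbed into the
phase: ``A = hypot(a, b)``, ``phase = atan2(b, a)`` in [0, 2 pi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import AzimuthalProfile

__all__ = ["SinusoidFit", "fit_sinusoids", "sinusoid_model", "coefficient_classify"]


@dataclass
class SinusoidFit:
    """Fitted parameters of the two-harmonic azimuthal model."""

    A0: float
    A1: float
    A2: float
    phi1: float
    phi2: float
    rss: float
    n_points: int
    #: delta-method standard errors for (A0, A1, A2); NaN if not estimable
    se: tuple[float, float, float] = (math.nan, math.nan, math.nan)

    def predict(self, phi: np.ndarray) -> np.ndarray:
        return sinusoid_model(phi, self.A0, self.A1, self.A2, self.phi1, self.phi2)


def sinusoid_model(phi, A0, A1, A2, phi1, phi2):
    """Evaluate I(phi) = A0 + A1 sin(2 phi + phi1) + A2 sin(4 phi + phi2)."""
    phi = np.asarray(phi, dtype=float)
    return A0 + A1 * np.sin(2.0 * phi + phi1) + A2 * np.sin(4.0 * phi + phi2)


_HARMONIC_NAMES = {0: "constant", 1: "2-phi", 2: "2-phi", 3: "4-phi", 4: "4-phi"}


def fit_sinusoids(profile: AzimuthalProfile | tuple[np.ndarray, np.ndarray]) -> SinusoidFit:
    """Least-squares fit of the two-harmonic model to an azimuthal profile.

    Accepts an :class:`AzimuthalProfile` (empty bins are excluded) or a
    plain ``(phi, intensity)`` pair.  Bins are weighted equally.

    Raises
    ------
    ValueError
        If fewer than 5 usable bins remain, or if the angular coverage is
        too narrow to separate the harmonics (rank-deficient design); the
        error names the deficient harmonic.
    """
    if isinstance(profile, AzimuthalProfile):
        keep = ~profile.empty & np.isfinite(profile.intensity)
        phi = profile.phi_centers[keep]
        y = profile.intensity[keep]
    else:
        phi = np.asarray(profile[0], dtype=float)
        y = np.asarray(profile[1], dtype=float)
        finite = np.isfinite(y)
        phi, y = phi[finite], y[finite]
    if phi.size < 5:
        raise ValueError(f"need >= 5 non-empty bins to fit 5 parameters, got {phi.size}")

    X = np.column_stack(
        [
            np.ones_like(phi),
            np.sin(2.0 * phi),
            np.cos(2.0 * phi),
            np.sin(4.0 * phi),
            np.cos(4.0 * phi),
        ]
    )
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    if s[0] == 0 or s[-1] / s[0] < 1e-10:
        null = Vt[-1]
        worst = int(np.argmax(np.abs(null)))
        raise ValueError(
            f"angular coverage cannot separate the {_HARMONIC_NAMES[worst]} harmonic "
            "(rank-deficient design)"
        )
    beta = Vt.T @ ((U.T @ y) / s)
    resid = y - X @ beta
    rss = float(resid @ resid)

    c0, a1, b1, a2, b2 = beta
    A1 = float(np.hypot(a1, b1))
    A2 = float(np.hypot(a2, b2))
    phi1 = float(np.mod(np.arctan2(b1, a1), 2.0 * np.pi))
    phi2 = float(np.mod(np.arctan2(b2, a2), 2.0 * np.pi))

    # homoscedastic OLS covariance + delta method for the amplitudes
    dof = phi.size - 5
    se = (math.nan, math.nan, math.nan)
    if dof > 0:
        sigma2 = rss / dof
        cov = (Vt.T / s**2) @ Vt * sigma2
        se0 = math.sqrt(max(cov[0, 0], 0.0))
        se_amp = []
        for A, (ia, ib) in zip((A1, A2), ((1, 2), (3, 4))):
            if A > 0:
                g = np.zeros(5)
                g[ia], g[ib] = beta[ia] / A, beta[ib] / A
                se_amp.append(math.sqrt(max(g @ cov @ g, 0.0)))
            else:
                se_amp.append(math.sqrt(max(cov[ia, ia], 0.0)))
        se = (se0, se_amp[0], se_amp[1])

    return SinusoidFit(
        A0=float(c0), A1=A1, A2=A2, phi1=phi1, phi2=phi2,
        rss=rss, n_points=int(phi.size), se=se,
    )


def coefficient_classify(
    fits: Sequence[SinusoidFit],
    labels: Sequence[str],
    patient_groups: Sequence[str],
    positive_label: str = "cancer",
    k: int = 5,
    seed: int = 0,
    n_bootstrap: int = 2000,
) -> dict:
    """Classify measurements in the (A1, A2) plane.

    Runs the same patient-grouped out-of-fold protocol as the
    Fourier-feature route (standardize -> linear logistic model), aggregates
    out-of-fold probabilities to patients, and reports the Youden operating
    point with patient-level bootstrap 95% intervals on sensitivity and
    specificity.
    """
    from .classify import (
        aggregate_to_patients,
        grouped_stratified_folds,
        oof_probabilities,
        roc_ap_metrics,
        youden_point,
    )
    from .resampling import bootstrap_operating_point

    labels = list(labels)
    if len(set(labels)) < 2:
        raise ValueError("both classes must be present to classify")
    metadata = pd.DataFrame(
        {
            "frame_id": [f"m{i:04d}" for i in range(len(fits))],
            "patient_id": list(patient_groups),
            "label": labels,
        }
    )
    features = np.array([[f.A1, f.A2] for f in fits], dtype=float)
    folds = grouped_stratified_folds(metadata, k=k, seed=seed)
    scores = oof_probabilities(
        features, metadata, folds, n_components=2, positive_label=positive_label, seed=seed
    )
    patient_scores = aggregate_to_patients(scores, metadata)
    roc = roc_ap_metrics(patient_scores)
    thr, sens, spec = youden_point(roc)
    ci = bootstrap_operating_point(patient_scores, B=n_bootstrap, seed=seed)
    return {
        "measurement_scores": scores,
        "patient_scores": patient_scores,
        "roc": roc,
        "youden_threshold": thr,
        "sensitivity": sens,
        "specificity": spec,
        "sensitivity_ci": ci["sensitivity_ci"],
        "specificity_ci": ci["specificity_ci"],
    }
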