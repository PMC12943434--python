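"""End-to-end pipeline: simulate/load -> mask -> correct -> features ->
grouped classification -> patient aggregation -> metrics -> inference.

The configuration is a plain mapping (typically loaded from YAML).  Every
source of randomness derives from the single top-level ``seed``, and the
results bundle records the seed plus a hash of the resolved configuration,
so a run can be reproduced exactly from its own output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import io as xio
from .anisotropy import coefficient_classify, fit_sinusoids
from .classify import (
    aggregate_to_patients,
    grouped_stratified_folds,
    oof_probabilities,
    roc_ap_metrics,
    youden_point,
)
from .features import build_feature_matrix
from .frames import DiffractionFrame
from .preprocess import apply_region_mask, beam_anisotropy_correction, extract_ring_profile
from .resampling import patient_bootstrap, permutation_test
from .simulate import collagen_study_config, default_study_config, generate_study

__all__ = ["run_pipeline", "default_study_aucs", "load_config", "DEFAULT_CONFIG"]

log = logging.getLogger("xrdtissue.pipeline")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "study": {"preset": "default"},
    "mask": {"q_min": 16.0, "q_max": None, "rect": None},
    "correction": {"enabled": False, "shift": 5},
    "features": {"eps": 1e-6},
    "classification": {"k": 5, "n_components": 20, "classifier": "logistic", "C": 1.0},
    "anisotropy": {
        "enabled": False,
        "q_center": 0.3,
        "q_tol": None,
        "n_phi_bins": 72,
        "correction_shift": 5,
    },
    "bootstrap": {"B": 2000},
    "permutation": {"n": 10000},
    "output_dir": None,
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in (override or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def _config_hash(config: dict) -> str:
    # hash only the keys that influence the computation, not where the
    # results land on disk
    relevant = {k: v for k, v in config.items() if k != "output_dir"}
    return hashlib.sha256(
        json.dumps(relevant, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _load_study(config: dict):
    study_cfg = config.get("study") or {}
    seed = int(config.get("seed", 0))
    if "metadata" in study_cfg:  # load measured data from disk
        meta_path = Path(study_cfg["metadata"])
        metadata = xio.read_metadata(meta_path)
        if "path" not in metadata.columns:
            raise ValueError("metadata must carry a 'path' column to load frames")
        from .geometry import read_geometry

        geometry = read_geometry(study_cfg["geometry"])
        frames = []
        for _, row in metadata.iterrows():
            frame = xio.read_frame(meta_path.parent / row["path"])
            frame.frame_id = row["frame_id"]
            frame.patient_id = row["patient_id"]
            frame.label = row["label"]
            frame.geometry = geometry
            frames.append(frame)
        return frames, metadata[["frame_id", "patient_id", "label"]], geometry
    preset = study_cfg.get("preset", "default")
    overrides = {
        k: v for k, v in study_cfg.items() if k not in ("preset",) and v is not None
    }
    if preset == "default":
        cfg = default_study_config(seed=seed, **overrides)
    elif preset == "collagen":
        cfg = collagen_study_config(seed=seed, **overrides)
    else:
        raise ValueError(f"unknown study preset {preset!r}")
    frames, metadata = generate_study(cfg)
    return frames, metadata, cfg.geometry


def _permute_patient_labels(metadata, seed: int):
    """Shuffle labels across patients (null-study construction)."""
    rng = np.random.default_rng(seed)
    patients = metadata[["patient_id", "label"]].drop_duplicates().reset_index(drop=True)
    shuffled = patients["label"].to_numpy()[rng.permutation(len(patients))]
    mapping = dict(zip(patients["patient_id"], shuffled))
    out = metadata.copy()
    out["label"] = out["patient_id"].map(mapping)
    return out


def default_study_aucs(
    seed: int,
    n_components: int = 20,
    k: int = 5,
    permute_frame_labels: bool = False,
    **study_overrides,
) -> tuple[float, float]:
    """Measurement- and patient-level AUC of one default water-region study.

    Generates the default simulated study, keeps q >= 16 nm^-1, computes
    Fourier log-magnitude features and runs the patient-grouped out-of-fold
    protocol.  With ``permute_frame_labels`` the frame labels are shuffled
    before fold construction and training (null-calibration mode; the
    patient-level AUC is not defined there and NaN is returned for it).
    """
    cfg = default_study_config(seed=seed, **study_overrides)
    frames, metadata = generate_study(cfg)
    if permute_frame_labels:
        rng = np.random.default_rng(seed + 15485863)
        metadata = metadata.copy()
        metadata["label"] = metadata["label"].to_numpy()[rng.permutation(len(metadata))]
    masked = [
        apply_region_mask(f, cfg.geometry, q_ranges=[(16.0, np.inf)])[0] for f in frames
    ]
    fm = build_feature_matrix(masked, metadata)
    folds = grouped_stratified_folds(metadata, k=k, seed=seed)
    scores = oof_probabilities(fm, metadata, folds, n_components=n_components, seed=seed)
    measurement_auc = roc_ap_metrics(scores).auc
    if permute_frame_labels:
        return measurement_auc, float("nan")
    patient_auc = roc_ap_metrics(aggregate_to_patients(scores)).auc
    return measurement_auc, patient_auc


def run_pipeline(config: dict | str | Path | None = None) -> dict:
    """Execute the configured analysis and return the results bundle.

    Stages: simulate (or load) -> q-region mask -> optional beam-shape
    correction -> Fourier features (and/or the ring-anisotropy route) ->
    patient-grouped out-of-fold classification -> patient aggregation ->
    ROC/AP/Youden metrics -> patient bootstrap -> permutation test.
    """
    if config is None:
        config = {}
    if isinstance(config, (str, Path)):
        config = load_config(config)
    config = _merge(DEFAULT_CONFIG, config)
    seed = int(config["seed"])

    stage = "simulate/load"
    try:
        frames, metadata, geometry = _load_study(config)
        log.info("study: %d frames, %d patients", len(frames), metadata["patient_id"].nunique())
        if config.get("permute_labels"):
            metadata = _permute_patient_labels(metadata, seed=seed + 104729)
            log.info("patient labels permuted (null-study mode)")

        stage = "mask"
        mask_cfg = config["mask"] or {}
        q_min, q_max = mask_cfg.get("q_min"), mask_cfg.get("q_max")
        rect = mask_cfg.get("rect")
        if q_min is not None or q_max is not None or rect is not None:
            q_ranges = None
            if q_min is not None or q_max is not None:
                q_ranges = [(q_min or 0.0, q_max if q_max is not None else np.inf)]
            masked = []
            for f in frames:
                mf, region = apply_region_mask(f, geometry, q_ranges=q_ranges, rect=rect)
                masked.append(mf)
            frames = masked
            log.info("mask '%s': %d pixels excluded per frame", region.provenance, int(region.mask.sum()))

        stage = "correction"
        corr_cfg = config["correction"] or {}
        corrected_arrays = None
        if corr_cfg.get("enabled"):
            # corrected frames are real-valued and can be negative; shift to
            # non-negative for the Fourier stage (features are shift-sensitive
            # only through the DC term, which the normalization removes)
            corrected_arrays = []
            for f in frames:
                corr, valid = beam_anisotropy_correction(
                    f, geometry, shift=int(corr_cfg.get("shift", 5))
                )
                corr = np.where(valid, corr, 0.0)
                corr -= min(corr.min(), 0.0)
                corrected_arrays.append(corr)

        results: dict = {
            "n_frames": len(frames),
            "n_patients": int(metadata["patient_id"].nunique()),
            "seed": seed,
            "config_hash": _config_hash(config),
        }

        stage = "features"
        feat_frames = frames
        if corrected_arrays is not None:
            feat_frames = [
                DiffractionFrame(
                    data=a, frame_id=f.frame_id, patient_id=f.patient_id,
                    label=f.label, geometry=f.geometry,
                )
                for a, f in zip(corrected_arrays, frames)
            ]
        fm = build_feature_matrix(feat_frames, metadata, eps=float(config["features"]["eps"]))

        stage = "classify"
        cls = config["classification"]
        folds = grouped_stratified_folds(metadata, k=int(cls["k"]), seed=seed)
        scores = oof_probabilities(
            fm,
            metadata,
            folds,
            n_components=int(cls["n_components"]),
            classifier=cls.get("classifier", "logistic"),
            C=float(cls.get("C", 1.0)),
            seed=seed,
        )
        measurement_roc = roc_ap_metrics(scores)
        results["measurement"] = {"auc": measurement_roc.auc, "ap": measurement_roc.ap}

        stage = "aggregate"
        patient_scores = aggregate_to_patients(scores)
        patient_roc = roc_ap_metrics(patient_scores)
        thr, sens, spec = youden_point(patient_roc)
        results["patient"] = {
            "auc": patient_roc.auc,
            "ap": patient_roc.ap,
            "youden_threshold": thr,
            "sensitivity": sens,
            "specificity": spec,
        }

        stage = "bootstrap"
        boot = patient_bootstrap(
            patient_scores, B=int(config["bootstrap"]["B"]), seed=seed
        )
        results["bootstrap"] = {
            "auc_ci": list(boot.auc_ci),
            "ap_ci": list(boot.ap_ci),
            "B": boot.B,
            "n_redrawn": boot.n_redrawn,
        }

        stage = "permutation"
        perm = permutation_test(
            patient_scores, n_permutations=int(config["permutation"]["n"]), seed=seed
        )
        results["permutation"] = {
            "p_value_auc": perm.p_value_auc,
            "p_value_ap": perm.p_value_ap,
            "n_permutations": perm.n_permutations,
        }

        aniso_cfg = config["anisotropy"] or {}
        if aniso_cfg.get("enabled"):
            stage = "anisotropy"
            fits = []
            for f in frames:
                corr, valid = beam_anisotropy_correction(
                    f, geometry, shift=int(aniso_cfg.get("correction_shift", 5))
                )
                profile = extract_ring_profile(
                    corr,
                    geometry,
                    q_center=float(aniso_cfg["q_center"]),
                    q_tol=aniso_cfg.get("q_tol"),
                    n_phi_bins=int(aniso_cfg["n_phi_bins"]),
                    valid=valid,
                )
                fits.append(fit_sinusoids(profile))
            aniso = coefficient_classify(
                fits,
                labels=list(metadata["label"]),
                patient_groups=list(metadata["patient_id"]),
                k=int(cls["k"]),
                seed=seed,
                n_bootstrap=int(config["bootstrap"]["B"]),
            )
            results["anisotropy"] = {
                "measurement_auc": roc_ap_metrics(aniso["measurement_scores"]).auc,
                "patient_auc": aniso["roc"].auc,
                "sensitivity": aniso["sensitivity"],
                "specificity": aniso["specificity"],
                "sensitivity_ci": list(aniso["sensitivity_ci"]),
                "specificity_ci": list(aniso["specificity_ci"]),
            }
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    out_dir = config.get("output_dir")
    if out_dir:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        xio.write_results(results, out_dir / "results.json")
        patient_scores.to_csv(out_dir / "patient_scores.csv", index=False)
        scores.to_csv(out_dir / "measurement_scores.csv", index=False)
        log.info("results written to %s", out_dir)
    return results
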