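#!/usr/bin/env python
"""Uncertainty and significance of the water-region patient classification.

Loads the patient score table written by 04_water_classification.py,
computes the patient-level bootstrap (2000 resamples: 95% percentile
intervals for AUC and AP plus the ROC envelope on a fixed FPR grid) and
the patient-level permutation test (10,000 label shuffles with scores held
fixed).  Writes everything to results/ and prints the headline numbers.
"""

import json
import sys
import warnings
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from xrdtissue.resampling import patient_bootstrap, permutation_test

SEED = 1


def main() -> None:
    warnings.filterwarnings("ignore")
    scores_path = ROOT / "results" / "water_patient_scores.csv"
    if not scores_path.exists():
        raise SystemExit("run analysis/04_water_classification.py first")
    patient_scores = pd.read_csv(scores_path)

    boot = patient_bootstrap(patient_scores, B=2000, seed=SEED)
    perm = permutation_test(patient_scores, n_permutations=10000, seed=SEED)

    out = ROOT / "results"
    payload = {
        "auc": boot.auc,
        "auc_ci_95": list(boot.auc_ci),
        "ap": boot.ap,
        "ap_ci_95": list(boot.ap_ci),
        "bootstrap_resamples": boot.B,
        "single_class_resamples_redrawn": boot.n_redrawn,
        "p_value_auc": perm.p_value_auc,
        "p_value_ap": perm.p_value_ap,
        "n_permutations": perm.n_permutations,
    }
    (out / "inference.json").write_text(json.dumps(payload, indent=2) + "\n")
    envelope = pd.DataFrame(
        {
            "fpr": boot.fpr_grid,
            "tpr_lower": boot.roc_envelope[0],
            "tpr_upper": boot.roc_envelope[1],
        }
    )
    envelope.to_csv(out / "water_roc_envelope.csv", index=False)

    print(f"patient AUC {boot.auc:.3f} (95% CI {boot.auc_ci[0]:.2f}-{boot.auc_ci[1]:.2f}), "
          f"AP {boot.ap:.3f} (95% CI {boot.ap_ci[0]:.2f}-{boot.ap_ci[1]:.2f})")
    print(f"permutation p-values: AUC {perm.p_value_auc:.4f}, AP {perm.p_value_ap:.4f} "
          f"({perm.n_permutations} shuffles)")
    print(f"inference -> {out / 'inference.json'}, "
          f"ROC envelope -> {out / 'water_roc_envelope.csv'}")


if __name__ == "__main__":
    main()
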