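#!/usr/bin/env python
"""Score the analysis against the simulation ground truth: Hungarian-matched
spatial and loading correlations, detected vs planted affected components,
and the achieved AUC next to the AUC of a model on the true loadings.

Reads scratch/ artifacts and results/tables/, writes results/recovery.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    from hipposbm.pipeline import match_components
    from hipposbm.stats import fit_logistic, mancova_loadings, roc_and_classify

    dec_path = ROOT / "scratch" / "decomposition" / "decomposition.npz"
    truth_path = ROOT / "scratch" / "simulated" / "ground_truth.npz"
    if not dec_path.exists() or not truth_path.exists():
        raise SystemExit("missing artifacts; run analysis scripts 01 and 02 first")
    dec = np.load(dec_path)
    truth = np.load(truth_path)
    manifest = json.loads((ROOT / "scratch" / "simulated" / "ground_truth.json").read_text())
    table = pd.read_csv(ROOT / "results" / "tables" / "subjects.tsv", sep="\t")

    assign, spatial = match_components(dec["S"], truth["S_true"])
    loading = [
        abs(np.corrcoef(dec["A"][:, assign[j]], truth["A_true"][:, j])[0, 1])
        for j in range(truth["S_true"].shape[0])
    ]
    gs = mancova_loadings(dec["A"], table)
    sig = [int(c) for c in gs.per_component.loc[gs.per_component.significant, "component"]]
    detected_planted = sorted(int(j) for j in range(len(assign)) if assign[j] in sig)

    roc_est = roc_and_classify(fit_logistic(dec["A"], table))
    roc_true = roc_and_classify(fit_logistic(truth["A_true"], table))

    report = {
        "matched_spatial_corr": spatial.tolist(),
        "mean_matched_spatial_corr": float(spatial.mean()),
        "matched_loading_corr": loading,
        "planted_affected": manifest["affected_components"],
        "significant_components": sig,
        "detected_planted": detected_planted,
        "achieved_auc": roc_est["auc"],
        "planted_model_auc": roc_true["auc"],
    }
    out = ROOT / "results" / "recovery.json"
    out.write_text(json.dumps(report, indent=2))
    print(json.dumps(report, indent=2))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
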