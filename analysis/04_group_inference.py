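#!/usr/bin/env python
"""Group inference on the loading coefficients: demographics (Welch t,
chi-square), per-component covariate-adjusted group F tests with Bonferroni
control (alpha 0.05 / K) plus omnibus Wilks' lambda, and binomial logistic
prediction of diagnosis from the loadings alone with ROC analysis at
cutoff 0.5.

Reads results/tables/, writes the statistics tables under results/tables/.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    from hipposbm.stats import (
        compare_demographics,
        fit_logistic,
        mancova_loadings,
        roc_and_classify,
    )

    tables = ROOT / "results" / "tables"
    loadings_path = tables / "loading_coefficients.tsv"
    if not loadings_path.exists():
        raise SystemExit("no loadings found; run analysis/02_decompose.py first")
    table = pd.read_csv(tables / "subjects.tsv", sep="\t")
    loadings = pd.read_csv(loadings_path, sep="\t")
    A = loadings.drop(columns="subject_id").to_numpy()

    demo = compare_demographics(table)
    demo.to_csv(tables / "demographics.tsv", sep="\t", index=False)
    print("demographics:")
    print(demo.to_string(index=False))

    gs = mancova_loadings(A, table)
    gs.per_component.to_csv(tables / "group_stats.tsv", sep="\t", index=False)
    print(f"\nper-component group tests (Bonferroni alpha {gs.bonferroni_alpha:.4f}):")
    print(gs.per_component.to_string(index=False))
    print(f"omnibus Wilks' lambda {gs.wilks['lambda']:.3f}, p = {gs.wilks['p']:.4f}")

    model = fit_logistic(A, table)
    model.coefficients.to_csv(tables / "logistic.tsv", sep="\t", index=False)
    roc = roc_and_classify(model, cutoff=0.5)
    pd.DataFrame({"fpr": roc["fpr"], "tpr": roc["tpr"]}).to_csv(
        tables / "roc_points.tsv", sep="\t", index=False
    )
    print("\nlogistic regression on loadings only:")
    print(model.coefficients.to_string(index=False))
    print(
        f"AUC {roc['auc']:.3f}; at cutoff 0.5: sensitivity {roc['sensitivity_pct']:.1f}%, "
        f"specificity {roc['specificity_pct']:.1f}%, accuracy {roc['accuracy_pct']:.1f}%"
    )


if __name__ == "__main__":
    main()
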