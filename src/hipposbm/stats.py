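"""Group inference on loading coefficients.

Demographics are compared with Welch t-tests (age, education) and a Pearson
chi-square test (sex). Loadings are tested per component by a
covariate-adjusted linear model (the per-component ANCOVA F inside a
MANCOVA; an omnibus Wilks' lambda is reported alongside), with Bonferroni
control across components. Group membership is then predicted from the
loadings alone by maximum-likelihood binomial logistic regression and
evaluated by ROC analysis (rank-statistic AUC) and a confusion matrix at a
probability cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "GroupStatsResult",
    "LogisticModel",
    "InsufficientDataError",
    "DesignError",
    "SeparationError",
    "compare_demographics",
    "mancova_loadings",
    "bonferroni_alpha",
    "fit_logistic",
    "auc_mann_whitney",
    "roc_points",
    "roc_and_classify",
]


class InsufficientDataError(ValueError):
    """A group has fewer than 2 members."""


class DesignError(ValueError):
    """Rank-deficient design matrix."""


class SeparationError(RuntimeError):
    """Perfect separation in logistic regression; a penalized fit (not
    provided here) would be required."""


def _group_masks(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    g = table["group"].to_numpy()
    mdd, hs = g == "MDD", g == "HS"
    if mdd.sum() < 2 or hs.sum() < 2:
        raise InsufficientDataError("each group needs at least 2 subjects")
    return mdd, hs


def compare_demographics(table: pd.DataFrame) -> pd.DataFrame:
    """Welch two-sample t for age and education; Pearson chi-square (1 df,
    no continuity correction) for sex. Returns one row per variable."""
    mdd, hs = _group_masks(table)
    rows = []
    for var in ("age", "education_years"):
        a, b = table.loc[mdd, var], table.loc[hs, var]
        t, p = sps.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "variable": var,
                "test": "welch_t",
                "statistic": float(t),
                "p": float(p),
                "mdd_mean": float(a.mean()),
                "hs_mean": float(b.mean()),
            }
        )
    obs = pd.crosstab(table["group"], table["sex"]).reindex(
        index=["MDD", "HS"], columns=["F", "M"], fill_value=0
    )
    chi2, p, _, _ = sps.chi2_contingency(obs.to_numpy(), correction=False)
    rows.append(
        {
            "variable": "sex",
            "test": "chi2",
            "statistic": float(chi2),
            "p": float(p),
            "mdd_mean": float(obs.loc["MDD", "F"]),
            "hs_mean": float(obs.loc["HS", "F"]),
        }
    )
    return pd.DataFrame(rows)


@dataclass
class GroupStatsResult:
    per_component: pd.DataFrame    # F, p, partial_eta_sq, significant
    wilks: dict                    # omnibus multivariate test for the group term
    bonferroni_alpha: float
    covariates: tuple[str, ...]


def _design(table: pd.DataFrame, covariates: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(table)), (table["group"] == "MDD").to_numpy(float)]
    names = ["intercept", "group"]
    for cov in covariates:
        if cov == "sex":
            cols.append((table["sex"] == "F").to_numpy(float))  # F=1, M=0
        else:
            cols.append(table[cov].to_numpy(float))
        names.append(cov)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the offending columns for the error message
        bad = []
        for j in range(1, X.shape[1]):
            sub = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(X):
                bad.append(names[j])
        raise DesignError(f"design matrix is rank deficient; collinear columns: {bad}")
    return X, names


def mancova_loadings(
    A: np.ndarray,
    table: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex", "education_years"),
    family_alpha: float = 0.05,
) -> GroupStatsResult:
    """Covariate-adjusted group tests on the loading matrix.

    Per component: least-squares fit of loading ~ intercept + group +
    covariates; F statistic for the group term with (1, N - p) df and
    partial eta squared SS_group / (SS_group + SS_error). Components are
    called significant below the Bonferroni-adjusted alpha
    (family_alpha / K). An omnibus Wilks' lambda for the group term (Rao's F
    approximation) is reported alongside.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if A.shape[0] != len(table):
        raise ValueError("loading rows must match subject table")
    _group_masks(table)
    X, _ = _design(table, covariates)
    N, p = X.shape
    K = A.shape[1]
    X_red = np.delete(X, 1, axis=1)  # drop the group column

    beta_full, *_ = np.linalg.lstsq(X, A, rcond=None)
    R_full = A - X @ beta_full
    beta_red, *_ = np.linalg.lstsq(X_red, A, rcond=None)
    R_red = A - X_red @ beta_red

    sse_full = np.sum(R_full**2, axis=0)
    sse_red = np.sum(R_red**2, axis=0)
    ss_group = np.maximum(sse_red - sse_full, 0.0)
    df2 = N - p
    # a loading explained exactly by the covariates leaves zero residual in
    # both models; the group term then adds nothing (F = 0, p = 1)
    scale = np.sum(A**2, axis=0) + np.finfo(float).tiny
    degenerate = sse_full <= 1e-12 * scale
    ss_group = np.where(degenerate & (ss_group <= 1e-12 * scale), 0.0, ss_group)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(
            sse_full > 0, ss_group / (sse_full / df2), np.where(ss_group > 0, np.inf, 0.0)
        )
        eta = np.where(ss_group + sse_full > 0, ss_group / (ss_group + sse_full), 0.0)
    pvals = sps.f.sf(F, 1, df2)
    alpha = bonferroni_alpha(K, family_alpha)
    per_component = pd.DataFrame(
        {
            "component": np.arange(K),
            "F": F,
            "p": pvals,
            "partial_eta_sq": eta,
            "significant": pvals < alpha,
        }
    )

    # omnibus Wilks' lambda for the group term: Lambda = det(E) / det(E + H)
    E = R_full.T @ R_full
    H = R_red.T @ R_red - E
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = float(np.linalg.det(E) / np.linalg.det(E + H))
    # Rao's F approximation; hypothesis df q = 1, so F is exact here
    q = 1
    ve = N - p
    df1 = K * q
    df2_w = ve - K + 1
    F_w = (1 - lam) / lam * df2_w / df1
    p_w = float(sps.f.sf(F_w, df1, df2_w))
    wilks = {"lambda": lam, "F": float(F_w), "df1": df1, "df2": df2_w, "p": p_w}
    return GroupStatsResult(
        per_component=per_component,
        wilks=wilks,
        bonferroni_alpha=alpha,
        covariates=tuple(covariates),
    )


def bonferroni_alpha(n_tests: int, family_alpha: float = 0.05) -> float:
    """Per-test threshold family_alpha / n_tests (exact value; 0.05/7 displays
    as 0.007)."""
    if n_tests < 1 or not 0 < family_alpha < 1:
        raise ValueError("need n_tests >= 1 and 0 < family_alpha < 1")
    return family_alpha / n_tests


@dataclass
class LogisticModel:
    coefficients: pd.DataFrame      # coef, odds_ratio, ci_low, ci_high, p per predictor
    fitted_probabilities: np.ndarray
    y: np.ndarray                   # 1 = MDD
    predictor_names: list[str] = field(default_factory=list)
    llf: float = float("nan")


def fit_logistic(A: np.ndarray, table: pd.DataFrame) -> LogisticModel:
    """Binomial logistic regression of group (MDD = 1) on the loading
    coefficients only — no demographic predictors, no regularization.
    Wald 95% confidence intervals are reported on the odds-ratio scale."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    _group_masks(table)
    y = (table["group"] == "MDD").to_numpy(int)
    K = A.shape[1]
    names = ["intercept"] + [f"component_{k}" for k in range(K)]
    # constant predictors carry no information: excluded from the likelihood,
    # reported with coefficient 0 (odds ratio 1)
    informative = np.flatnonzero(A.std(axis=0) > 0)
    X = sm.add_constant(A[:, informative], has_constant="add")
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError and kin
        raise SeparationError(f"logistic fit failed ({exc}); data may be separated") from exc
    probs = np.asarray(res.predict(X))
    if np.all(np.abs(probs - y) < 1e-6):
        raise SeparationError("perfect separation: fitted probabilities reproduce the labels")
    ci = res.conf_int()
    coef = np.zeros(K + 1)
    lo = np.full(K + 1, np.nan)
    hi = np.full(K + 1, np.nan)
    pv = np.full(K + 1, np.nan)
    pos = np.r_[0, informative + 1]
    coef[pos] = np.asarray(res.params)
    lo[pos], hi[pos] = ci[:, 0], ci[:, 1]
    pv[pos] = np.asarray(res.pvalues)
    coeffs = pd.DataFrame(
        {
            "predictor": names,
            "coef": coef,
            "odds_ratio": np.exp(coef),
            "ci_low": np.exp(lo),
            "ci_high": np.exp(hi),
            "p": pv,
        }
    )
    return LogisticModel(
        coefficients=coeffs,
        fitted_probabilities=probs,
        y=y,
        predictor_names=names,
        llf=float(res.llf),
    )


def auc_mann_whitney(y: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic (ties counted 1/2)."""
    y = np.asarray(y).astype(bool)
    scores = np.asarray(scores, dtype=float)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("need both classes to compute AUC")
    ranks = sps.rankdata(scores)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_points(y: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ROC curve (FPR, TPR) over all score thresholds."""
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(y, scores)
    return fpr, tpr


def roc_and_classify(
    model: LogisticModel, cutoff: float = 0.5
) -> dict:
    """ROC curve, rank-statistic AUC, and the confusion summary at the
    probability cutoff (predictions at exactly the cutoff count positive).
    Sensitivity/specificity/accuracy are percentages with MDD positive."""
    y = model.y.astype(bool)
    probs = model.fitted_probabilities
    if y.all() or not y.any():
        raise ValueError("need both classes")
    fpr, tpr = roc_points(y, probs)
    auc = auc_mann_whitney(y, probs)
    pred = probs >= cutoff
    tp = int(np.sum(pred & y))
    tn = int(np.sum(~pred & ~y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    return {
        "fpr": fpr,
        "tpr": tpr,
        "auc": auc,
        "cutoff": cutoff,
        "sensitivity_pct": 100.0 * tp / (tp + fn),
        "specificity_pct": 100.0 * tn / (tn + fp),
        "accuracy_pct": 100.0 * (tp + tn) / len(y),
        "confusion": {"tp": tp, "fp": fp, "tn": tn, "fn": fn},
    }
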