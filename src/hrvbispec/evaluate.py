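"""Statistical characterization and diagnostic reporting.

Group differences across the four severity groups use the Kruskal-Wallis test
with Bonferroni correction over the feature family (significance at adjusted
p < 0.01).  Associations with polysomnographic indices use Spearman's partial
correlation controlling for age (first-order formula on ranks, t
approximation with n - 3 degrees of freedom).  Diagnostic performance is
reported as sensitivity, specificity and accuracy at a 0.5 posterior
threshold plus the threshold-free AUC via the rank (Mann-Whitney) identity
with midrank tie handling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DiagnosticReport:
    se: float  # sensitivity, %
    sp: float  # specificity, %
    acc: float  # accuracy, %
    auc: float
    tp: int
    fn: int
    tn: int
    fp: int
    threshold: float


def auc_mann_whitney(y_true: np.ndarray, score: np.ndarray) -> float:
    """AUC via the rank-sum identity, ties handled by midranks."""
    y_true = np.asarray(y_true).astype(int)
    score = np.asarray(score, dtype=float)
    n_pos = int(y_true.sum())
    n_neg = y_true.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes in y_true")
    ranks = stats.rankdata(score)
    u = ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def diagnostic_metrics(
    y_true: np.ndarray, score: np.ndarray, threshold: float = 0.5
) -> DiagnosticReport:
    """Confusion-table metrics at ``threshold`` plus rank-based AUC."""
    y_true = np.asarray(y_true).astype(int)
    score = np.asarray(score, dtype=float)
    pred = (score >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y_true == 1)))
    fn = int(np.sum((pred == 0) & (y_true == 1)))
    tn = int(np.sum((pred == 0) & (y_true == 0)))
    fp = int(np.sum((pred == 1) & (y_true == 0)))
    se = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    sp = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    acc = 100.0 * (tp + tn) / y_true.size
    return DiagnosticReport(
        se=se,
        sp=sp,
        acc=acc,
        auc=auc_mann_whitney(y_true, score),
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        threshold=threshold,
    )


def kruskal_wallis(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and p.

    The degenerate all-identical case (H undefined through 0/0 in the tie
    correction) is reported as H = 0, p = 1: no evidence of group differences.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(s.size == 0 for s in samples):
        raise ValueError("every group must be nonempty")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def group_difference_tests(
    table: pd.DataFrame,
    feature_cols: list[str],
    group_col: str = "severity",
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Kruskal-Wallis per feature with Bonferroni over the feature family.

    Returns a frame with H, raw p, Bonferroni-adjusted p (capped at 1) and a
    significance flag at adjusted p < ``alpha``.
    """
    m = len(feature_cols)
    rows = []
    for col in feature_cols:
        h, p = kruskal_wallis(table[col].to_numpy(), table[group_col].to_numpy())
        p_adj = min(p * m, 1.0)
        rows.append(
            {
                "feature": col,
                "H": h,
                "p": p,
                "p_bonferroni": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def partial_spearman(
    x: np.ndarray, y: np.ndarray, z: np.ndarray
) -> tuple[float, float]:
    """Spearman partial correlation of x and y controlling z.

    Ranks all three variables, applies the first-order partial-correlation
    formula, and derives p from the t approximation with n - 3 degrees of
    freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least four observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y)) and np.all(np.isfinite(z))):
        raise ValueError("inputs must be finite")
    rx, ry, rz = (stats.rankdata(v) for v in (x, y, z))
    if any(np.std(r) == 0 for r in (rx, ry, rz)):
        raise ValueError("zero variance in a ranked variable")
    rxy = np.corrcoef(rx, ry)[0, 1]
    rxz = np.corrcoef(rx, rz)[0, 1]
    ryz = np.corrcoef(ry, rz)[0, 1]
    denom = np.sqrt(max((1 - rxz**2) * (1 - ryz**2), 0.0))
    if not np.isfinite(denom) or denom < 1e-12:
        raise ValueError("degenerate: a variable is a monotone function of z")
    rho = (rxy - rxz * ryz) / denom
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - 3
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1 - rho**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return rho, p


def correlation_report(
    table: pd.DataFrame,
    feature_cols: list[str],
    index_cols: list[str],
    age_col: str = "age",
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Partial Spearman of each feature against each index, controlling age.

    Bonferroni correction spans all feature x index pairs in this report.
    """
    m = len(feature_cols) * len(index_cols)
    rows = []
    for feat in feature_cols:
        for idx in index_cols:
            rho, p = partial_spearman(
                table[feat].to_numpy(), table[idx].to_numpy(), table[age_col].to_numpy()
            )
            rows.append(
                {
                    "feature": feat,
                    "index": idx,
                    "rho_s": rho,
                    "p": p,
                    "p_bonferroni": min(p * m, 1.0),
                    "significant": min(p * m, 1.0) < alpha,
                }
            )
    return pd.DataFrame(rows)


SEVERITY_ORDER = {"none": 0, "mild": 1, "moderate": 2, "severe": 3}


def characterization_report(
    table: pd.DataFrame,
    feature_cols: list[str],
    group_col: str = "severity",
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Boxplot-style summaries plus tests for the selected features.

    One row per feature: per-group median and quartiles, the Kruskal-Wallis
    p-value (Bonferroni over the selected features), and the monotone-trend
    direction across severity (sign of Spearman correlation between the
    feature and the ordered group index).
    """
    groups = table[group_col].map(SEVERITY_ORDER)
    m = len(feature_cols)
    rows = []
    for col in feature_cols:
        v = table[col].to_numpy(dtype=float)
        h, p = kruskal_wallis(v, table[group_col].to_numpy())
        if np.all(v == v[0]):
            trend = 0.0
        else:
            trend, _ = stats.spearmanr(v, groups.to_numpy())
        row: dict[str, object] = {
            "feature": col,
            "H": h,
            "p_bonferroni": min(p * m, 1.0),
            "trend_sign": int(np.sign(trend)) if np.isfinite(trend) else 0,
        }
        for name, code in SEVERITY_ORDER.items():
            sel = v[groups.to_numpy() == code]
            if sel.size:
                q1, med, q3 = np.percentile(sel, [25, 50, 75])
            else:
                q1 = med = q3 = float("nan")
            row[f"{name}_median"] = med
            row[f"{name}_q1"] = q1
            row[f"{name}_q3"] = q3
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")
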