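"""Univariate description of the feature table.

Per feature: a two-sided Mann-Whitney U test between classes with Bonferroni
correction over all tested features, a point-biserial correlation with the
outcome, Spearman correlations with age and with the feature's ROI volume,
and the univariate ROC AUC (orientation folded to >= 0.5).  These screens
describe the data; their results never enter model building.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .features.extract import feature_columns_of, parse_feature_column, volume_column

log = logging.getLogger(__name__)

#: exact Mann-Whitney null distribution is used when n1*n2 <= this and there
#: are no ties; the tie-corrected normal approximation otherwise
_EXACT_LIMIT = 400


def mann_whitney_auc(x: np.ndarray, y01: np.ndarray) -> tuple[float, float, float]:
    """(U statistic, raw two-sided p, AUC) for feature x against labels y."""
    pos = x[y01 == 1]
    neg = x[y01 == 0]
    n1, n2 = len(pos), len(neg)
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes must be present")
    if np.ptp(x) == 0:
        return 0.5 * n1 * n2, 1.0, 0.5
    has_ties = len(np.unique(x)) < len(x)
    method = "exact" if (n1 * n2 <= _EXACT_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided", method=method)
    auc = float(res.statistic) / (n1 * n2)  # P(X_pos > X_neg) + 0.5 ties
    return float(res.statistic), float(res.pvalue), auc


def univariate_screen(
    table: pd.DataFrame,
    alpha: float = 0.01,
    r_cut: float = 0.85,
    auc_cut: float = 0.75,
) -> pd.DataFrame:
    """One row per feature column with the screening statistics and flags.

    Columns: ``u``, ``p_raw``, ``p_corrected`` (Bonferroni over the features
    actually tested), ``rpb_outcome``/``rpb_p``, ``rs_age``, ``rs_volume``,
    ``auc_univar`` (folded to >= 0.5) and boolean flags ``sig_mw``,
    ``flag_rpb``, ``flag_age``, ``flag_volume``, ``flag_auc``.
    """
    features = feature_columns_of(table)
    if not features:
        raise ValueError("table has no feature columns")
    y = table["status"].to_numpy(dtype=int)
    if len(np.unique(y)) != 2 or min(np.bincount(y)) < 2:
        raise ValueError("need two outcome classes with >= 2 subjects each")
    m = len(features)
    age = table["age"].to_numpy(dtype=float)

    rows = []
    for col in features:
        x = table[col].to_numpy(dtype=float)
        _, roi, _ = parse_feature_column(col)
        vol = table[volume_column(roi)].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            log.warning("constant feature %s: p=1, correlations=0 by convention", col)
            u, p_raw, auc = 0.5 * len(x[y == 1]) * len(x[y == 0]), 1.0, 0.5
            rpb = rpb_p = 0.0
            rs_age = rs_vol = 0.0
            rpb_p = 1.0
        else:
            u, p_raw, auc = mann_whitney_auc(x, y)
            rpb, rpb_p = stats.pointbiserialr(y, x)
            rs_age = stats.spearmanr(x, age).statistic
            if np.ptp(vol) == 0:  # constant covariate: correlation undefined
                rs_vol = np.nan
            else:
                rs_vol = stats.spearmanr(x, vol).statistic
            rs_age = 0.0 if np.isnan(rs_age) else float(rs_age)
            rs_vol = 0.0 if np.isnan(rs_vol) else float(rs_vol)
        p_corr = min(1.0, m * p_raw)
        auc_folded = max(auc, 1.0 - auc)
        rows.append(
            {
                "feature": col,
                "u": u,
                "p_raw": p_raw,
                "p_corrected": p_corr,
                "rpb_outcome": float(rpb),
                "rpb_p": float(rpb_p),
                "rs_age": rs_age,
                "rs_volume": rs_vol,
                "auc_univar": auc_folded,
                "sig_mw": p_corr <= alpha,
                "flag_rpb": (abs(rpb) >= r_cut) and (rpb_p <= 0.05),
                "flag_age": abs(rs_age) > r_cut,
                "flag_volume": abs(rs_vol) > r_cut,
                "flag_auc": auc_folded > auc_cut,
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def screen_summary(report: pd.DataFrame) -> pd.DataFrame:
    """Counts of flagged features per (channel, ROI) — the descriptive
    summary table of the univariate screen."""
    parsed = [parse_feature_column(f) for f in report.index]
    df = report.copy()
    df["channel"] = [p[0] for p in parsed]
    df["roi"] = [p[1] for p in parsed]
    flags = ["flag_age", "flag_volume", "flag_rpb", "flag_auc", "sig_mw"]
    return df.groupby(["roi", "channel"])[flags].sum().astype(int)
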