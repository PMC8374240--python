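"""Bootstrap stability feature selection per (channel, ROI).

Each of ``n_iterations`` (default 100) iterations draws a balanced cohort of
``cohort_size`` (default 100) subjects with replacement from the training
subset, then applies, in order: a low-variance filter, Spearman
de-correlation, and random-forest recursive feature elimination (RFE) down
to ``N = max(1, round(n_minor/10))`` features.  Features are ranked by how
often they were selected across iterations; ties break by mean RFE rank and
then by name, so the result is fully reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier


@dataclass
class SelectionConfig:
    n_iterations: int = 100
    cohort_size: int = 100
    distinct_frac_cut: float = 0.10
    freq_ratio_cut: float = 95.0 / 5.0
    rs_cut: float = 0.85
    rf_trees: int = 100
    n_features_final: int | str = "auto"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cohort_size % 2:
            raise ValueError("cohort_size must be even (balanced classes)")
        if min(self.distinct_frac_cut, self.freq_ratio_cut, self.rs_cut) <= 0:
            raise ValueError("cuts must be positive")


@dataclass
class SelectionResult:
    selection_count: dict[str, int]
    final_signature: list[str]
    n_features: int
    iteration_log: list[dict] = field(repr=False, default_factory=list)
    config: SelectionConfig | None = None

    def to_dict(self) -> dict:
        return {
            "final_signature": self.final_signature,
            "n_features": self.n_features,
            "selection_count": self.selection_count,
            "n_iterations": self.config.n_iterations if self.config else None,
            "seed": self.config.seed if self.config else None,
        }


def n_features_rule(n_minor_class: int) -> int:
    """Target signature size from the minor-class sample count: one feature
    per ten minor-class samples, rounded, never below one.  A 36/36 cohort
    split 80/20 has a 28-sample minor training class and yields 3."""
    if n_minor_class < 1:
        raise ValueError("minor class must have at least 1 sample")
    return max(1, round(n_minor_class / 10))


def low_variance_filter(
    X: pd.DataFrame,
    distinct_frac_cut: float = 0.10,
    freq_ratio_cut: float = 95.0 / 5.0,
) -> list[str]:
    """Drop near-constant features.

    A feature is dropped iff BOTH its fraction of distinct values is below
    ``distinct_frac_cut`` AND the ratio of its two most frequent value counts
    exceeds ``freq_ratio_cut``; constant features are always dropped.
    """
    n = len(X)
    if n < 10:
        raise ValueError("low-variance filter needs >= 10 observations")
    kept = []
    for col in X.columns:
        counts = X[col].value_counts().to_numpy()
        if len(counts) == 1:
            continue  # constant
        distinct_frac = len(counts) / n
        freq_ratio = counts[0] / counts[1]
        if distinct_frac < distinct_frac_cut and freq_ratio > freq_ratio_cut:
            continue
        kept.append(col)
    return kept


def decorrelate(X: pd.DataFrame, rs_cut: float = 0.85) -> list[str]:
    """Greedy removal of highly inter-correlated features.

    While some pair has |Spearman rho| above the cut, take the worst pair and
    drop the member with the larger mean |rho| against all other kept
    features (ties drop the lexicographically later name).
    """
    cols = list(X.columns)
    if len(cols) < 2:
        return cols
    rho = np.abs(stats.spearmanr(X.to_numpy()).statistic)
    if np.ndim(rho) == 0:  # two features
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    rho = np.nan_to_num(rho, nan=0.0)
    np.fill_diagonal(rho, 0.0)

    alive = np.ones(len(cols), dtype=bool)
    while True:
        sub = np.where(alive[:, None] & alive[None, :], rho, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= rs_cut:
            break
        mean_i = sub[i, alive].sum() / max(alive.sum() - 1, 1)
        mean_j = sub[j, alive].sum() / max(alive.sum() - 1, 1)
        if mean_i > mean_j:
            drop = i
        elif mean_j > mean_i:
            drop = j
        else:
            drop = max(i, j, key=lambda k: cols[k])
        alive[drop] = False
    return [c for c, a in zip(cols, alive) if a]


def rfe_rf(
    X: pd.DataFrame,
    y: np.ndarray,
    n_target: int,
    rf_trees: int = 100,
    seed: int = 0,
) -> list[str]:
    """Recursive feature elimination with a random-forest ranker.

    Fits an RF (``rf_trees`` trees, sqrt split candidates), drops the least
    important feature, and repeats until ``n_target`` remain; survivors are
    returned ordered by the final fit's importances (descending).
    """
    if len(np.unique(y)) < 2:
        raise ValueError("RFE needs both classes present")
    cols = list(X.columns)
    if n_target > len(cols):
        raise ValueError("n_target exceeds the number of features")
    Xv = X.to_numpy(dtype=np.float64)
    active = list(range(len(cols)))
    rng = np.random.default_rng(seed)

    def fit_importances(idx):
        rf = RandomForestClassifier(
            n_estimators=rf_trees,
            max_features="sqrt",
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(Xv[:, idx], y)
        return rf.feature_importances_

    while len(active) > n_target:
        imp = fit_importances(active)
        active.pop(int(np.argmin(imp)))
    final_imp = fit_importances(active)
    order = np.argsort(-final_imp, kind="stable")
    return [cols[active[k]] for k in order]


def stability_select(
    table: pd.DataFrame,
    feature_columns: list[str],
    config: SelectionConfig | None = None,
) -> SelectionResult:
    """The 100-iteration balanced-bootstrap selection for one feature slice.

    ``table`` is the training subset (rows = subjects) with a ``status``
    column; ``feature_columns`` restricts to one (channel, ROI) slice.
    """
    config = config or SelectionConfig()
    y_all = table["status"].to_numpy(dtype=int)
    pos_idx = np.flatnonzero(y_all == 1)
    neg_idx = np.flatnonzero(y_all == 0)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError("training subset must contain both classes")

    if config.n_features_final == "auto":
        n_final = n_features_rule(min(len(pos_idx), len(neg_idx)))
    else:
        n_final = int(config.n_features_final)

    half = config.cohort_size // 2
    rng = np.random.default_rng(config.seed)
    counts: dict[str, int] = dict.fromkeys(feature_columns, 0)
    rank_sums: dict[str, float] = dict.fromkeys(feature_columns, 0.0)
    logs = []

    for it in range(config.n_iterations):
        rows = np.concatenate(
            [rng.choice(pos_idx, size=half), rng.choice(neg_idx, size=half)]
        )
        boot = table.iloc[rows]
        X = boot[feature_columns]
        y = boot["status"].to_numpy(dtype=int)

        kept = low_variance_filter(X, config.distinct_frac_cut, config.freq_ratio_cut)
        kept = decorrelate(X[kept], config.rs_cut)
        target = min(n_final, len(kept))
        selected = rfe_rf(
            X[kept], y, target, config.rf_trees, seed=int(rng.integers(2**31 - 1))
        )
        for rank, name in enumerate(selected):
            counts[name] += 1
            rank_sums[name] += rank
        logs.append({"iteration": it, "n_kept": len(kept), "selected": selected})

    def sort_key(name):
        mean_rank = rank_sums[name] / counts[name] if counts[name] else np.inf
        return (-counts[name], mean_rank, name)

    ranked = sorted(feature_columns, key=sort_key)
    return SelectionResult(
        selection_count=counts,
        final_signature=ranked[:n_final],
        n_features=n_final,
        iteration_log=logs,
        config=config,
    )
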