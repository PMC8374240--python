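"""Classifier training, bootstrap evaluation, DeLong comparison and audits.

The modelling surface follows the model/results idiom: a
:class:`RadiomicClassifier` is built from a training table, a feature
signature and a model type; ``fit()`` returns :class:`ClassifierResults`
carrying the frozen coefficients (and the training-slice standardization
constants for SVM/LR), which then evaluates itself on held-out data with
balanced bootstrap cohorts, reporting each metric's median and 90% CI
(empirical 5th/95th percentiles of the 100 bootstrap values).

Hyperparameters are fixed — RF: 100 trees, sqrt split candidates; SVM: RBF
kernel, C=1.0, gamma=1/(n_features*Var(X)); LR: L2, C=1.0, liblinear, dual —
there is deliberately no tuning loop.  The positive class is MSP throughout,
so sensitivity is MSP recall.  AUC scores use the predicted probability for
LR, the decision value for SVM and the vote fraction for RF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

MODEL_TYPES = ("RF", "SVM", "LR")
METRICS = ("accuracy", "auc", "sensitivity", "specificity")

#: tie order for model-type selection: fewest parameters wins
_PARSIMONY = ("LR", "SVM", "RF")


@dataclass
class ModelConfig:
    model_type: str = "LR"
    rf_trees: int = 100
    n_boot: int = 100
    cohort_size: int = 100
    ci_level: float = 0.90
    auc_floor: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_type not in MODEL_TYPES:
            raise ValueError(f"model_type must be one of {MODEL_TYPES}")
        if self.cohort_size % 2:
            raise ValueError("cohort_size must be even")


def rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Tie-aware rank (Mann-Whitney) AUC; constant scores give 0.5."""
    y = np.asarray(y, dtype=int)
    n1 = int((y == 1).sum())
    n2 = int((y == 0).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("AUC needs both classes")
    ranks = stats.rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n2))


def _make_estimator(model_type: str, rf_trees: int, seed: int):
    if model_type == "RF":
        return RandomForestClassifier(
            n_estimators=rf_trees, max_features="sqrt", random_state=seed, n_jobs=1
        )
    if model_type == "SVM":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", SVC(C=1.0, kernel="rbf", gamma="scale", random_state=seed)),
            ]
        )
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "clf",
                # L2 penalty (the solver's default), C=1.0, liblinear, dual form
                LogisticRegression(C=1.0, solver="liblinear", dual=True, random_state=seed),
            ),
        ]
    )


@dataclass
class FrozenModel:
    """A fitted classifier with its signature, standardization constants and
    coefficients frozen; applying it never refits anything."""

    model_type: str
    signature: list[str]
    estimator: object = field(repr=False)
    train_subjects: frozenset = field(repr=False)

    def _X(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.signature if c not in table.columns]
        if missing:
            raise KeyError(f"validation table is missing features: {missing}")
        return table[self.signature].to_numpy(dtype=np.float64)

    def decision_scores(self, table: pd.DataFrame) -> np.ndarray:
        X = self._X(table)
        if self.model_type == "SVM":
            return self.estimator.decision_function(X)
        return self.estimator.predict_proba(X)[:, 1]

    def predict_labels(self, table: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(self._X(table)).astype(int)

    @property
    def coefficients(self) -> dict | None:
        """LR/SVM linear-readout parameters (None for RF)."""
        if self.model_type == "LR":
            clf = self.estimator.named_steps["clf"]
            return {
                "intercept": float(clf.intercept_[0]),
                "coef": dict(zip(self.signature, clf.coef_[0].tolist())),
            }
        return None


class RadiomicClassifier:
    """Binary MSP-vs-HCS classifier on a radiomic feature signature.

    Parameters
    ----------
    train_table : DataFrame with a ``status`` column (1 = MSP) and the
        signature's feature columns; rows indexed by subject id.
    signature : ordered feature names entering the model.
    config : hyperparameters (fixed; no tuning loop exists).
    """

    def __init__(self, train_table: pd.DataFrame, signature: list[str],
                 config: ModelConfig | None = None):
        self.train_table = train_table
        self.signature = list(signature)
        self.config = config or ModelConfig()
        y = train_table["status"].to_numpy(dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training slice must contain both classes")

    def fit(self) -> "ClassifierResults":
        cfg = self.config
        est = _make_estimator(cfg.model_type, cfg.rf_trees, cfg.seed)
        X = self.train_table[self.signature].to_numpy(dtype=np.float64)
        y = self.train_table["status"].to_numpy(dtype=int)
        est.fit(X, y)
        frozen = FrozenModel(
            model_type=cfg.model_type,
            signature=self.signature,
            estimator=est,
            train_subjects=frozenset(self.train_table.index),
        )
        return ClassifierResults(frozen, self, cfg)


@dataclass
class EvalFragment:
    """Bootstrap metric distributions with medians and 90% CIs."""

    distributions: pd.DataFrame  # n_boot rows x METRICS columns
    ci_level: float

    @property
    def median(self) -> pd.Series:
        return self.distributions.median()

    @property
    def ci(self) -> pd.DataFrame:
        lo = (1 - self.ci_level) / 2 * 100
        return self.distributions.quantile([lo / 100, 1 - lo / 100]).T

    def summary(self) -> pd.DataFrame:
        lo = (1 - self.ci_level) / 2
        out = pd.DataFrame(
            {
                "median": self.distributions.median(),
                "ci_low": self.distributions.quantile(lo),
                "ci_high": self.distributions.quantile(1 - lo),
            }
        )
        return out

    def to_dict(self) -> dict:
        s = self.summary()
        return {
            m: {
                "median": float(s.loc[m, "median"]),
                "ci": [float(s.loc[m, "ci_low"]), float(s.loc[m, "ci_high"])],
            }
            for m in s.index
        }


class ClassifierResults:
    """Fit results: frozen model plus evaluation, summary and validation."""

    def __init__(self, frozen: FrozenModel, model: RadiomicClassifier, config: ModelConfig):
        self.frozen = frozen
        self.model = model
        self.config = config

    def evaluate_bootstrap(self, test_table: pd.DataFrame, seed: int | None = None,
                           check_disjoint: bool = True) -> EvalFragment:
        """Balanced bootstrap evaluation on a held-out slice."""
        if check_disjoint:
            overlap = self.frozen.train_subjects & set(test_table.index)
            if overlap:
                raise ValueError(f"test slice shares subjects with training: {sorted(overlap)[:5]}")
        return evaluate_bootstrap(self.frozen, test_table,
                                  self.config if seed is None else
                                  ModelConfig(**{**self.config.__dict__, "seed": seed}))

    def summary(self, test_table: pd.DataFrame | None = None) -> str:
        cfg = self.config
        lines = [
            f"RadiomicClassifier results ({cfg.model_type})",
            f"  signature ({len(self.frozen.signature)}): "
            + ", ".join(self.frozen.signature),
            f"  n_train = {len(self.model.train_table)}",
        ]
        coef = self.frozen.coefficients
        if coef is not None:
            lines.append(f"  intercept = {coef['intercept']:+.4f}")
            for name, c in coef["coef"].items():
                lines.append(f"  beta[{name}] = {c:+.4f}")
        if test_table is not None:
            frag = self.evaluate_bootstrap(test_table)
            s = frag.summary()
            lines.append(f"  test metrics (median, {int(cfg.ci_level*100)}% CI, "
                         f"{cfg.n_boot} balanced bootstrap cohorts):")
            for m in s.index:
                lines.append(
                    f"    {m:<12s} {s.loc[m,'median']:.3f} "
                    f"({s.loc[m,'ci_low']:.3f}, {s.loc[m,'ci_high']:.3f})"
                )
        return "\n".join(lines)


def train(train_table: pd.DataFrame, signature: list[str],
          config: ModelConfig | None = None) -> FrozenModel:
    """Functional wrapper: fit and return the frozen model."""
    return RadiomicClassifier(train_table, signature, config).fit().frozen


def evaluate_bootstrap(frozen: FrozenModel, test_table: pd.DataFrame,
                       config: ModelConfig | None = None) -> EvalFragment:
    """Evaluate a frozen model on 100 balanced bootstrap test cohorts."""
    cfg = config or ModelConfig(model_type=frozen.model_type)
    y = test_table["status"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("test slice must contain both classes")
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    half = cfg.cohort_size // 2

    scores = frozen.decision_scores(test_table)
    labels = frozen.predict_labels(test_table)
    rng = np.random.default_rng(cfg.seed)

    rows = []
    for _ in range(cfg.n_boot):
        idx = np.concatenate([rng.choice(pos, half), rng.choice(neg, half)])
        yt, st, lt = y[idx], scores[idx], labels[idx]
        rows.append(
            {
                "accuracy": float((lt == yt).mean()),
                "auc": rank_auc(st, yt),
                "sensitivity": float((lt[yt == 1] == 1).mean()),
                "specificity": float((lt[yt == 0] == 0).mean()),
            }
        )
    return EvalFragment(pd.DataFrame(rows), cfg.ci_level)


# ---------------------------------------------------------------------------
# DeLong test for correlated ROC curves

def _delong_components(scores: np.ndarray, y: np.ndarray):
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    # placement values via midranks
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01


def delong_auc_variance(scores_list, y):
    """AUC vector and covariance matrix for correlated models on one set."""
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("DeLong needs both classes")
    k = len(scores_list)
    m = int((y == 1).sum())
    n = int((y == 0).sum())
    V10 = np.empty((k, m))
    V01 = np.empty((k, n))
    aucs = np.empty(k)
    for r, s in enumerate(scores_list):
        v10, v01 = _delong_components(np.asarray(s, dtype=float), y)
        V10[r], V01[r] = v10, v01
        aucs[r] = v10.mean()
    s10 = np.cov(V10) if k > 1 else np.atleast_2d(np.var(V10, ddof=1))
    s01 = np.cov(V01) if k > 1 else np.atleast_2d(np.var(V01, ddof=1))
    cov = np.atleast_2d(s10) / m + np.atleast_2d(s01) / n
    return aucs, cov


def delong_compare(preds: dict[str, np.ndarray], y) -> dict[tuple[str, str], float]:
    """Pairwise DeLong p-values, Bonferroni-corrected over the pairs."""
    names = list(preds)
    if len(names) < 2:
        raise ValueError("need >= 2 models to compare")
    aucs, cov = delong_auc_variance([preds[n] for n in names], np.asarray(y))
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    out = {}
    for a, b in pairs:
        i, j = names.index(a), names.index(b)
        var = cov[i, i] + cov[j, j] - 2 * cov[i, j]
        if var <= 0:
            p = 1.0
        else:
            z = (aucs[i] - aucs[j]) / np.sqrt(var)
            p = 2.0 * stats.norm.sf(abs(z))
        out[(a, b)] = min(1.0, p * len(pairs))
    return out


def select_model_type(median_aucs: dict[tuple, float], auc_floor: float = 0.7) -> str:
    """Pick the model type with the most highest-median-AUC wins.

    ``median_aucs`` maps ``(combination, model_type)`` to the median test
    AUC.  Types below the floor in a combination are not admissible there;
    ties break toward the fewest parameters (LR > SVM > RF).
    """
    combos = sorted({c for c, _ in median_aucs})
    wins = dict.fromkeys(MODEL_TYPES, 0)
    any_admissible = False
    for combo in combos:
        entries = {
            t: median_aucs[(combo, t)]
            for t in MODEL_TYPES
            if (combo, t) in median_aucs and median_aucs[(combo, t)] >= auc_floor
        }
        if not entries:
            continue
        any_admissible = True
        best = max(entries.values())
        for t, v in entries.items():
            if v == best:
                wins[t] += 1
    if not any_admissible:
        raise ValueError("no admissible model: every type is below the AUC floor everywhere")
    top = max(wins.values())
    return next(t for t in _PARSIMONY if wins[t] == top)


def permute_labels_within(y: np.ndarray, rng) -> np.ndarray:
    """Permute labels preserving the exact class counts."""
    y = np.asarray(y, dtype=int)
    return rng.permutation(y)


def permutation_audit(pipeline, train_table: pd.DataFrame, test_table: pd.DataFrame,
                      seed: int = 0, original: "EvalFragment | None" = None) -> dict:
    """Label-permutation overfitting audit.

    ``pipeline(train_table, test_table)`` must run the complete closure —
    feature selection, training, bootstrap evaluation — and return an
    :class:`EvalFragment`.  Labels are permuted within train and test
    separately (class counts preserved) and the unchanged pipeline is rerun;
    the AUC drop is tested with a one-sided Mann-Whitney U (original > permuted).
    A precomputed ``original`` fragment (from the same pipeline on the
    unpermuted tables) may be supplied to avoid recomputing it.
    """
    rng = np.random.default_rng(seed)
    if original is None:
        original = pipeline(train_table, test_table)

    def permuted(t):
        t2 = t.copy()
        t2["status"] = permute_labels_within(t["status"].to_numpy(), rng)
        return t2

    shuffled = pipeline(permuted(train_table), permuted(test_table))
    a0 = original.distributions["auc"].to_numpy()
    a1 = shuffled.distributions["auc"].to_numpy()
    res = stats.mannwhitneyu(a0, a1, alternative="greater")
    return {
        "original": original,
        "permuted": shuffled,
        "original_median_auc": float(np.median(a0)),
        "permuted_median_auc": float(np.median(a1)),
        "drop_p": float(res.pvalue),
        "significant": bool(res.pvalue <= 0.01),
    }


def external_validate(frozen: FrozenModel, val_table: pd.DataFrame,
                      config: ModelConfig | None = None) -> dict:
    """Apply a frozen model (no refitting) to an external validation table.

    Returns the balanced-bootstrap :class:`EvalFragment` plus, when the table
    carries a ``source`` column, the raw per-source accuracies (for an
    all-negative source this equals the overall specificity, for an
    all-positive source the overall sensitivity).
    """
    frag = evaluate_bootstrap(frozen, val_table, config)
    out = {"fragment": frag}
    if "source" in val_table.columns:
        labels = frozen.predict_labels(val_table)
        y = val_table["status"].to_numpy(dtype=int)
        per_source = {}
        for src, sub in val_table.groupby("source"):
            mask = val_table["source"] == src
            per_source[src] = float((labels[mask.to_numpy()] == y[mask.to_numpy()]).mean())
        out["per_source_accuracy"] = per_source
    return out
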