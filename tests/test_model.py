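"""Modelling layer: training determinism and recovery, bootstrap evaluation,
DeLong comparison, model-type selection, permutation audit mechanics and
external validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from msrad.model import (
    ModelConfig,
    RadiomicClassifier,
    delong_auc_variance,
    delong_compare,
    evaluate_bootstrap,
    external_validate,
    permutation_audit,
    rank_auc,
    select_model_type,
    train,
)
from oracles import auc_paircount


def _toy_table(rng, n_per_class=20, n_features=2, sep=0.0, prefix="s"):
    n = 2 * n_per_class
    y = np.array([0] * n_per_class + [1] * n_per_class)
    X = rng.normal(size=(n, n_features))
    X[:, 0] += sep * y
    t = pd.DataFrame(
        X, columns=[f"MT__WM__f{k}" for k in range(n_features)],
        index=[f"{prefix}{i}" for i in range(n)],
    )
    t["status"] = y
    return t


SIG = ["MT__WM__f0", "MT__WM__f1"]


class TestTrain:
    def test_lr_separable_training_auc_is_one(self):
        rng = np.random.default_rng(0)
        t = _toy_table(rng, sep=10.0)
        frozen = train(t, SIG, ModelConfig(model_type="LR", seed=1))
        assert rank_auc(frozen.decision_scores(t), t["status"]) == 1.0

    def test_same_seed_identical_coefficients(self):
        rng = np.random.default_rng(1)
        t = _toy_table(rng, sep=1.0)
        a = train(t, SIG, ModelConfig(model_type="LR", seed=7))
        b = train(t, SIG, ModelConfig(model_type="LR", seed=7))
        assert a.coefficients == b.coefficients

    def test_lr_recovers_planted_sign_pattern(self):
        rng = np.random.default_rng(2)
        n = 1000
        X = rng.normal(size=(n, 3))
        logit = 2.0 * X[:, 0] - 1.5 * X[:, 1] + 0.0 * X[:, 2]
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        t = pd.DataFrame(X, columns=["MT__WM__f0", "MT__WM__f1", "MT__WM__f2"],
                         index=[f"s{i}" for i in range(n)])
        t["status"] = y
        frozen = train(t, list(t.columns[:3]), ModelConfig(model_type="LR", seed=0))
        coef = frozen.coefficients["coef"]
        assert coef["MT__WM__f0"] > 0.5
        assert coef["MT__WM__f1"] < -0.3
        assert abs(coef["MT__WM__f2"]) < 0.3

    def test_single_class_errors(self):
        rng = np.random.default_rng(3)
        t = _toy_table(rng)
        t["status"] = 0
        with pytest.raises(ValueError):
            RadiomicClassifier(t, SIG)

    @pytest.mark.parametrize("mtype", ["RF", "SVM", "LR"])
    def test_all_model_types_fit_and_score(self, mtype):
        rng = np.random.default_rng(4)
        t = _toy_table(rng, sep=2.0)
        frozen = train(t, SIG, ModelConfig(model_type=mtype, seed=0))
        scores = frozen.decision_scores(t)
        assert np.isfinite(scores).all()
        assert rank_auc(scores, t["status"]) > 0.8


class TestEvaluateBootstrap:
    def test_oracle_scores_give_unit_auc_everywhere(self):
        rng = np.random.default_rng(5)
        test = _toy_table(rng, n_per_class=10, prefix="t")

        class Oracle:
            model_type = "LR"
            signature = SIG
            train_subjects = frozenset()

            def decision_scores(self, t):
                return t["status"].to_numpy(dtype=float)

            def predict_labels(self, t):
                return t["status"].to_numpy(dtype=int)

        frag = evaluate_bootstrap(Oracle(), test, ModelConfig(n_boot=50, seed=0))
        assert (frag.distributions["auc"] == 1.0).all()
        assert tuple(frag.ci.loc["auc"]) == (1.0, 1.0)

    def test_constant_scores_give_half_auc(self):
        rng = np.random.default_rng(6)
        test = _toy_table(rng, n_per_class=10, prefix="t")

        class Constant:
            model_type = "LR"
            signature = SIG
            train_subjects = frozenset()

            def decision_scores(self, t):
                return np.zeros(len(t))

            def predict_labels(self, t):
                return np.zeros(len(t), dtype=int)

        frag = evaluate_bootstrap(Constant(), test, ModelConfig(n_boot=20, seed=0))
        assert (frag.distributions["auc"] == 0.5).all()

    def test_bitwise_reproducible_under_seed(self):
        rng = np.random.default_rng(7)
        tr = _toy_table(rng, sep=1.5)
        te = _toy_table(np.random.default_rng(8), sep=1.5, prefix="t")
        frozen = train(tr, SIG, ModelConfig(model_type="LR", seed=3))
        a = evaluate_bootstrap(frozen, te, ModelConfig(seed=11))
        b = evaluate_bootstrap(frozen, te, ModelConfig(seed=11))
        pd.testing.assert_frame_equal(a.distributions, b.distributions)

    def test_train_test_overlap_rejected(self):
        rng = np.random.default_rng(9)
        t = _toy_table(rng, sep=1.0)
        res = RadiomicClassifier(t, SIG, ModelConfig(model_type="LR", seed=0)).fit()
        with pytest.raises(ValueError, match="shares subjects"):
            res.evaluate_bootstrap(t)


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(10)
        y = np.array([0, 1] * 20)
        s = rng.normal(size=40)
        p = delong_compare({"a": s, "b": s.copy()}, y)
        assert p[("a", "b")] == 1.0

    def test_auc_matches_pair_counting(self):
        rng = np.random.default_rng(11)
        y = np.array([0, 1] * 15)
        s = rng.normal(size=30)
        aucs, _ = delong_auc_variance([s], y)
        assert aucs[0] == pytest.approx(auc_paircount(s, y), abs=1e-12)

    def test_variance_matches_paired_bootstrap_oracle(self):
        rng = np.random.default_rng(12)
        n = 40
        y = np.array([0] * 20 + [1] * 20)
        base = rng.normal(size=n) + 1.0 * y
        s1 = base + rng.normal(scale=0.5, size=n)
        s2 = base + rng.normal(scale=0.5, size=n)
        aucs, cov = delong_auc_variance([s1, s2], y)
        var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]

        boot = []
        brng = np.random.default_rng(99)
        for _ in range(2000):
            idx = np.concatenate(
                [brng.choice(np.flatnonzero(y == 0), 20),
                 brng.choice(np.flatnonzero(y == 1), 20)]
            )
            boot.append(rank_auc(s1[idx], y[idx]) - rank_auc(s2[idx], y[idx]))
        var_boot = np.var(boot, ddof=1)
        assert var_diff == pytest.approx(var_boot, rel=0.15)


class TestSelectModelType:
    def test_dominating_type_wins(self):
        aucs = {(("WM", c), t): (0.9 if t == "SVM" else 0.8)
                for c in ("T1w", "MT") for t in ("RF", "SVM", "LR")}
        assert select_model_type(aucs) == "SVM"

    def test_below_floor_type_never_wins(self):
        aucs = {(("WM", "MT"), "RF"): 0.65, (("WM", "MT"), "LR"): 0.72,
                (("WM", "MT"), "SVM"): 0.71}
        assert select_model_type(aucs) == "LR"

    def test_tie_breaks_toward_fewest_parameters(self):
        aucs = {(("WM", "MT"), "LR"): 0.9, (("WM", "MT"), "RF"): 0.8,
                (("GM", "MT"), "RF"): 0.9, (("GM", "MT"), "LR"): 0.8}
        assert select_model_type(aucs) == "LR"

    def test_all_below_floor_errors(self):
        aucs = {(("WM", "MT"), t): 0.6 for t in ("RF", "SVM", "LR")}
        with pytest.raises(ValueError, match="no admissible"):
            select_model_type(aucs)


class TestPermutationAudit:
    @staticmethod
    def _closure(train_t, test_t):
        frozen = train(train_t, SIG, ModelConfig(model_type="LR", seed=0))
        return evaluate_bootstrap(frozen, test_t, ModelConfig(seed=1, n_boot=50))

    def test_strong_effect_shows_significant_drop(self):
        rng = np.random.default_rng(13)
        tr = _toy_table(rng, sep=4.0)
        te = _toy_table(np.random.default_rng(14), sep=4.0, prefix="t")
        audit = permutation_audit(self._closure, tr, te, seed=2)
        assert audit["drop_p"] <= 0.01
        assert 0.35 <= audit["permuted_median_auc"] <= 0.65

    def test_null_data_shows_no_significant_drop(self):
        rng = np.random.default_rng(15)
        tr = _toy_table(rng, sep=0.0)
        te = _toy_table(np.random.default_rng(16), sep=0.0, prefix="t")
        audit = permutation_audit(self._closure, tr, te, seed=3)
        assert audit["drop_p"] > 0.01

    def test_permutation_preserves_class_counts(self):
        from msrad.model import permute_labels_within

        y = np.array([0] * 7 + [1] * 13)
        perm = permute_labels_within(y, np.random.default_rng(0))
        assert perm.sum() == y.sum() and len(perm) == len(y)


class TestExternalValidate:
    def test_validation_copy_of_test_matches_evaluate(self):
        rng = np.random.default_rng(17)
        tr = _toy_table(rng, sep=2.0)
        te = _toy_table(np.random.default_rng(18), sep=2.0, prefix="t")
        frozen = train(tr, SIG, ModelConfig(model_type="LR", seed=0))
        direct = evaluate_bootstrap(frozen, te, ModelConfig(seed=5))
        via = external_validate(frozen, te, ModelConfig(seed=5))
        pd.testing.assert_frame_equal(direct.distributions, via["fragment"].distributions)

    def test_all_negative_source_accuracy_equals_specificity(self):
        rng = np.random.default_rng(19)
        val = _toy_table(rng, n_per_class=15, sep=1.0, prefix="v")
        val["source"] = np.where(val["status"] == 0, "DS2-like", "DS3-like")
        tr = _toy_table(np.random.default_rng(20), sep=1.0)
        frozen = train(tr, SIG, ModelConfig(model_type="LR", seed=0))
        res = external_validate(frozen, val, ModelConfig(seed=6))
        labels = frozen.predict_labels(val)
        y = val["status"].to_numpy()
        spec = (labels[y == 0] == 0).mean()
        sens = (labels[y == 1] == 1).mean()
        assert res["per_source_accuracy"]["DS2-like"] == pytest.approx(spec)
        assert res["per_source_accuracy"]["DS3-like"] == pytest.approx(sens)

    def test_missing_feature_listed_in_error(self):
        rng = np.random.default_rng(21)
        tr = _toy_table(rng, sep=1.0)
        frozen = train(tr, SIG, ModelConfig(model_type="LR", seed=0))
        bad = tr.drop(columns=["MT__WM__f1"])
        with pytest.raises(KeyError, match="MT__WM__f1"):
            frozen.decision_scores(bad)

    def test_frozen_model_applied_twice_is_identical(self):
        rng = np.random.default_rng(22)
        tr = _toy_table(rng, sep=1.0)
        frozen = train(tr, SIG, ModelConfig(model_type="SVM", seed=0))
        np.testing.assert_array_equal(
            frozen.decision_scores(tr), frozen.decision_scores(tr)
        )
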