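"""Label derivation, minority-class F1, LOOCV and the evaluation grid."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import f1_score

from phenorisk.io import SurveyLabel
from phenorisk.models import (
    RiskPredictionModel,
    TABLE_COMBOS,
    chance_band,
    derive_labels,
    f1_minority,
    labels_frame,
    loocv_evaluate,
    minority_class,
    run_grid,
)


class TestDeriveLabels:
    def _get(self, labels, pid, qid):
        return next(l.value for l in labels if l.participant_id == pid and l.question_id == qid)

    def test_compound_substance_answer_splits(self):
        labels = derive_labels([SurveyLabel("A", "substance_use", "meth_and_idu")])
        assert self._get(labels, "A", "meth_use") == "yes"
        assert self._get(labels, "A", "idu") == "yes"

    def test_no_substances(self):
        labels = derive_labels([SurveyLabel("A", "substance_use", "none")])
        assert self._get(labels, "A", "meth_use") == "no"
        assert self._get(labels, "A", "idu") == "no"

    def test_decline_missing_for_that_question_only(self):
        labels = derive_labels(
            [
                SurveyLabel("A", "substance_use", "decline"),
                SurveyLabel("A", "partners_count", "6_10"),
            ]
        )
        assert self._get(labels, "A", "meth_use") == "missing"
        assert self._get(labels, "A", "partners_6plus") == "yes"

    def test_partner_bands(self):
        labels = derive_labels([SurveyLabel("A", "partners_count", "11_plus")])
        assert self._get(labels, "A", "partners_6plus") == "yes"
        assert self._get(labels, "A", "partners_11plus") == "yes"

    def test_unknown_answer_warns_and_missing(self):
        with pytest.warns(UserWarning, match="unknown answer"):
            labels = derive_labels([SurveyLabel("A", "condomless_receptive", "sometimes")])
        assert self._get(labels, "A", "condomless_receptive") == "missing"

    def test_headline_questions_always_emitted(self):
        labels = derive_labels([SurveyLabel("A", "in_treatment", "no")])
        for q in ("meth_use", "partners_6plus", "condomless_receptive"):
            assert self._get(labels, "A", q) == "missing"


class TestF1Minority:
    def test_enumerated_example(self):
        # minority class is 1 (2 of 5); TP=1, FP=1, FN=1 -> P=R=0.5 -> F1=0.5
        assert f1_minority([1, 1, 0, 0, 0], [1, 0, 0, 0, 1]) == pytest.approx(0.5)

    def test_perfect(self):
        assert f1_minority([0, 1, 1, 0, 0], [0, 1, 1, 0, 0]) == 1.0

    def test_all_majority_prediction_zero(self):
        assert f1_minority([1, 1, 0, 0, 0], [0, 0, 0, 0, 0]) == 0.0

    def test_single_class_flagged(self):
        with pytest.raises(ValueError):
            f1_minority([1, 1, 1], [1, 0, 1])

    def test_tie_treats_yes_as_positive(self):
        y_true = [1, 1, 0, 0]
        y_pred = [1, 0, 0, 0]
        assert minority_class(y_true) == 1
        assert f1_minority(y_true, y_pred) == pytest.approx(
            f1_score(y_true, y_pred, pos_label=1)
        )

    @given(
        st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=4, max_size=40)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_sklearn_confusion_enumeration(self, pairs):
        y_true = np.array([a for a, _ in pairs])
        y_pred = np.array([b for _, b in pairs])
        if len(np.unique(y_true)) < 2:
            return
        pos = minority_class(y_true)
        assert f1_minority(y_true, y_pred) == pytest.approx(
            f1_score(y_true, y_pred, pos_label=pos, zero_division=0)
        )


def _synthetic_xy(n=80, p=6, effect=0.0, seed=0, prevalence=0.3):
    """Feature matrix with optional planted mean shift in the positives."""
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < prevalence).astype(int)
    if y.sum() < 2:
        y[:2] = 1
    if y.sum() > n - 2:
        y[:2] = 0
    X = rng.normal(size=(n, p))
    X[y == 1, : p // 2] += effect
    return pd.DataFrame(X, index=[f"P{i:03d}" for i in range(n)]), y


class TestLoocv:
    def test_permuted_labels_inside_chance_band(self):
        X, y = _synthetic_xy(n=80, effect=2.0, seed=1)
        rng = np.random.default_rng(5)
        y_perm = rng.permutation(y)
        res = loocv_evaluate(X, y_perm, model="logistic", seed=0)
        lo, hi = chance_band(y_perm, res.y_pred, n_permutations=200, seed=3)
        assert lo <= res.f1_minority <= hi

    def test_planted_signal_beats_chance(self):
        X, y = _synthetic_xy(n=80, effect=2.0, seed=2)
        res = loocv_evaluate(X, y, model="gradient_boosting", seed=0)
        lo, hi = chance_band(y, res.y_pred, n_permutations=200, seed=3)
        assert res.f1_minority > hi

    def test_duplicated_column_tree_invariant(self):
        X, y = _synthetic_xy(n=40, effect=1.5, seed=3)
        res1 = loocv_evaluate(X, y, model="gradient_boosting", seed=0)
        X2 = X.copy()
        X2["dup"] = X.iloc[:, 0]
        res2 = loocv_evaluate(X2, y, model="gradient_boosting", seed=0)
        assert res1.f1_minority == pytest.approx(res2.f1_minority, abs=0.15)

    def test_deterministic_given_seed(self):
        X, y = _synthetic_xy(n=30, effect=1.0, seed=4)
        r1 = loocv_evaluate(X, y, model="gradient_boosting", seed=7)
        r2 = loocv_evaluate(X, y, model="gradient_boosting", seed=7)
        assert np.array_equal(r1.y_pred, r2.y_pred)

    def test_needs_two_per_class(self):
        X, _ = _synthetic_xy(n=10)
        with pytest.raises(ValueError):
            loocv_evaluate(X, [1] + [0] * 9)

    def test_fold_internal_vocab_prunes_rare_columns(self):
        rng = np.random.default_rng(6)
        n = 20
        X = pd.DataFrame(
            {
                "w_common": rng.random(n),
                "w_rare": [0.5, 0.2, 0.4] + [0.0] * (n - 3),  # 3 users only
            },
            index=[f"P{i}" for i in range(n)],
        )
        y = np.array([0, 1] * (n // 2))
        res = loocv_evaluate(
            X, y, model="logistic", vocab_columns=["w_common", "w_rare"], vocab_min_users=5
        )
        assert res.n_used == n  # runs despite per-fold pruning


class TestRunGrid:
    def _features(self, n=24, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"P{i:03d}" for i in range(n)]
        return {
            "social_apps": pd.DataFrame(rng.random((n, 3)), index=idx),
            "risky_words": pd.DataFrame(rng.random((n, 4)), index=idx),
        }

    def _labels(self, n=24, seed=0):
        rng = np.random.default_rng(seed + 100)
        rows = []
        for i in range(n):
            rows.append(SurveyLabel(f"P{i:03d}", "substance_use", "meth" if rng.random() < 0.4 else "none"))
            rows.append(
                SurveyLabel(
                    f"P{i:03d}", "partners_count", "6_10" if rng.random() < 0.5 else "2_5"
                )
            )
            rows.append(SurveyLabel(f"P{i:03d}", "condomless_receptive", "yes" if rng.random() < 0.5 else "no"))
        return derive_labels(rows)

    def test_cardinality(self):
        combos = [c for c in TABLE_COMBOS if c.name in ("social_apps", "risky_words")]
        results = run_grid(
            self._features(), self._labels(), combos=combos,
            models=("logistic", "gradient_boosting"),
        )
        assert len(results) == 3 * 2 * 2  # questions x combos x models

    def test_missing_group_skipped_with_warning(self):
        combos = [c for c in TABLE_COMBOS if c.name in ("location", "social_apps")]
        with pytest.warns(UserWarning, match="skipped"):
            results = run_grid(
                self._features(), self._labels(), combos=combos, models=("logistic",),
                questions=["meth_use"],
            )
        assert {r.combo for r in results} == {"social_apps"}

    def test_per_question_missingness(self):
        labels = self._labels()
        labels = [
            SurveyLabel(l.participant_id, l.question_id, "missing")
            if (l.participant_id == "P000" and l.question_id == "meth_use")
            else l
            for l in labels
        ]
        combos = [c for c in TABLE_COMBOS if c.name == "social_apps"]
        results = run_grid(self._features(), labels, combos=combos, models=("logistic",))
        by_q = {r.question_id: r for r in results}
        assert by_q["meth_use"].n_used == 23
        assert by_q["partners_6plus"].n_used == 24

    def test_table_shape_and_determinism(self):
        combos = [c for c in TABLE_COMBOS if c.name in ("social_apps", "risky_words")]
        model = RiskPredictionModel(self._features(), labels_frame(self._labels()))
        fit1 = model.fit(combos=combos, seed=11)
        fit2 = model.fit(combos=combos, seed=11)
        assert fit1.table.equals(fit2.table)
        assert fit1.table.shape == (2, 6)
        assert "best for" in fit1.summary()


def test_table_combos_registry():
    assert len(TABLE_COMBOS) == 13
    names = [c.name for c in TABLE_COMBOS]
    assert len(set(names)) == 13
    assert TABLE_COMBOS[-1].groups == (
        "social_apps", "all_apps", "location", "risky_words", "all_words",
        "dictionary", "embedding",
    )
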