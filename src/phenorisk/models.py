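"""Outcome labels, LOOCV evaluation, and the risk-prediction model surface.

Survey answers are decomposed into independent binary questions (a compound
"substance use" answer yields both a methamphetamine-use and an
injection-drug-use label; "Decline to answer" / "I don't know" become
missing and exclude the participant from that question only).  Classifier ×
feature-set combinations are then evaluated with leave-one-out
cross-validation and scored by the F1 of the minority class — the less
frequent true answer, which for most outcomes is the "yes" one.

Two classifiers are used, an L2-regularized logistic regression
(``max_iter=1000``, features z-scored inside each training fold) and an
80-tree gradient-boosting classifier (other settings at library defaults).
``RiskPredictionModel`` wraps the evaluation grid in a fit/results object
pair; the functional layer (:func:`loocv_evaluate`, :func:`run_grid`)
remains available directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .io import SurveyLabel

__all__ = [
    "FEATURE_GROUPS",
    "HEADLINE_QUESTIONS",
    "FeatureComboSpec",
    "TABLE_COMBOS",
    "EvalResult",
    "derive_labels",
    "labels_frame",
    "f1_minority",
    "minority_class",
    "loocv_evaluate",
    "chance_band",
    "run_grid",
    "RiskPredictionModel",
    "RiskPredictionResults",
]

FEATURE_GROUPS = (
    "social_apps",
    "all_apps",
    "location",
    "risky_words",
    "all_words",
    "dictionary",
    "embedding",
)

#: the outcomes with enough positives and negatives to be informative
HEADLINE_QUESTIONS = ("meth_use", "partners_6plus", "condomless_receptive")

MODELS = ("logistic", "gradient_boosting")


@dataclass(frozen=True)
class FeatureComboSpec:
    name: str
    groups: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.groups)) != len(self.groups):
            raise ValueError(f"duplicate groups in combo {self.name!r}")
        unknown = set(self.groups) - set(FEATURE_GROUPS)
        if unknown:
            raise ValueError(f"unknown feature groups: {sorted(unknown)}")


#: the 13 feature-set rows of the evaluation grid, single groups first,
#: then the non-redundant combinations
TABLE_COMBOS: tuple[FeatureComboSpec, ...] = tuple(
    FeatureComboSpec(name, groups)
    for name, groups in [
        ("social_apps", ("social_apps",)),
        ("all_apps", ("all_apps",)),
        ("location", ("location",)),
        ("risky_words", ("risky_words",)),
        ("all_words", ("all_words",)),
        ("dictionary", ("dictionary",)),
        ("embedding", ("embedding",)),
        ("risky_words+dictionary", ("risky_words", "dictionary")),
        ("social_apps+risky_words", ("social_apps", "risky_words")),
        ("social_apps+risky_words+dictionary", ("social_apps", "risky_words", "dictionary")),
        ("social_apps+risky_words+location", ("social_apps", "risky_words", "location")),
        (
            "social_apps+risky_words+location+dictionary",
            ("social_apps", "risky_words", "location", "dictionary"),
        ),
        ("all", FEATURE_GROUPS),
    ]
)


@dataclass
class EvalResult:
    question_id: str
    combo: str
    model: str
    f1_minority: float
    precision: float
    recall: float
    n_used: int
    y_pred: np.ndarray = field(repr=False, default=None)
    participant_ids: tuple[str, ...] = field(repr=False, default=())


# ---------------------------------------------------------------------------
# survey-answer decomposition

_MISSING_RESPONSES = {"decline", "decline_to_answer", "dont_know", "i_dont_know"}

_SUBSTANCE_RESPONSES = {
    "none": {"meth_use": "no", "idu": "no"},
    "meth": {"meth_use": "yes", "idu": "no"},
    "idu": {"meth_use": "no", "idu": "yes"},
    "meth_and_idu": {"meth_use": "yes", "idu": "yes"},
}

_PARTNER_RESPONSES = {
    "0_1": {"partners_6plus": "no", "partners_11plus": "no"},
    "2_5": {"partners_6plus": "no", "partners_11plus": "no"},
    "6_10": {"partners_6plus": "yes", "partners_11plus": "no"},
    "11_plus": {"partners_6plus": "yes", "partners_11plus": "yes"},
}

_YESNO_QUESTIONS = {
    "condomless_receptive": "condomless_receptive",
    "in_treatment": "in_treatment",
}


def derive_labels(raw: Iterable[SurveyLabel]) -> list[SurveyLabel]:
    """Decompose raw wellness-survey answers into binary outcome labels.

    Compound answer options map to several independent questions (e.g. a
    single substance-use answer yields ``meth_use`` and ``idu``); the
    partner-count bands yield ``partners_6plus`` and ``partners_11plus``.
    Decline/don't-know answers, and unknown answer codes (with a warning),
    become ``missing`` for the affected questions only.  The headline
    outcomes are always emitted for every participant seen.
    """
    per_participant: dict[str, dict[str, str]] = {}

    def put(pid: str, qid: str, value: str) -> None:
        per_participant.setdefault(pid, {})[qid] = value

    for rec in raw:
        resp = rec.value.strip().lower().replace(" ", "_").replace("'", "")
        q = rec.question_id
        if q == "substance_use":
            mapped = _SUBSTANCE_RESPONSES.get(resp)
            targets = ("meth_use", "idu")
        elif q == "partners_count":
            mapped = _PARTNER_RESPONSES.get(resp)
            targets = ("partners_6plus", "partners_11plus")
        elif q in _YESNO_QUESTIONS:
            targets = (_YESNO_QUESTIONS[q],)
            mapped = {targets[0]: resp} if resp in ("yes", "no") else None
        else:
            warnings.warn(f"unknown survey question {q!r}; ignored")
            continue
        if mapped is None:
            if resp not in _MISSING_RESPONSES:
                warnings.warn(f"unknown answer {rec.value!r} to {q!r}; treated as missing")
            mapped = {t: "missing" for t in targets}
        for qid, val in mapped.items():
            put(rec.participant_id, qid, val)

    out: list[SurveyLabel] = []
    for pid in sorted(per_participant):
        answers = per_participant[pid]
        for qid in HEADLINE_QUESTIONS:
            answers.setdefault(qid, "missing")
        for qid in sorted(answers):
            out.append(SurveyLabel(pid, qid, answers[qid]))
    return out


def labels_frame(labels: Iterable[SurveyLabel]) -> pd.DataFrame:
    """Participant × question frame with values 1.0/0.0/NaN."""
    rows: dict[str, dict[str, float]] = {}
    for lab in labels:
        v = {"yes": 1.0, "no": 0.0}.get(lab.value, np.nan)
        rows.setdefault(lab.participant_id, {})[lab.question_id] = v
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index = df.index.astype(str)
    return df


# ---------------------------------------------------------------------------
# scoring

def minority_class(y_true: np.ndarray) -> int:
    """The less frequent class in ``y_true`` (tie → the positive class 1)."""
    y = np.asarray(y_true).astype(int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("y_true contains a single class; minority F1 undefined")
    return 1 if n1 <= n0 else 0


def _prf(y_true: np.ndarray, y_pred: np.ndarray, pos: int) -> tuple[float, float, float]:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(((y_true == pos) & (y_pred == pos)).sum())
    fp = int(((y_true != pos) & (y_pred == pos)).sum())
    fn = int(((y_true == pos) & (y_pred != pos)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def f1_minority(y_true: Sequence[int], y_pred: Sequence[int]) -> float:
    """F1 with the less frequent true class as the positive class."""
    return _prf(y_true, y_pred, minority_class(y_true))[2]


# ---------------------------------------------------------------------------
# models and LOOCV

def make_classifier(name: str, seed: int = 0):
    if name == "logistic":
        return make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=1000, random_state=seed)
        )
    if name == "gradient_boosting":
        return GradientBoostingClassifier(n_estimators=80, random_state=seed)
    raise ValueError(f"unknown model {name!r}")


def _fold_columns(
    X: pd.DataFrame, train_idx: np.ndarray, vocab_columns: list[str], min_users: int
) -> list[str]:
    """Columns kept for one fold under fold-internal vocabulary.

    A vocabulary lemma is kept when at least ``min_users`` *training*
    participants used it (usage ⇔ nonzero day-share frequency), so the test
    participant never influences the vocabulary.
    """
    if not vocab_columns:
        return list(X.columns)
    sub = X.iloc[train_idx][vocab_columns]
    used = (sub.fillna(0.0) != 0).sum(axis=0)
    keep_vocab = set(used[used >= min_users].index)
    return [c for c in X.columns if c not in set(vocab_columns) or c in keep_vocab]


def loocv_evaluate(
    X: pd.DataFrame,
    y: Sequence[int],
    model: str = "logistic",
    seed: int = 0,
    question_id: str = "",
    combo: str = "",
    vocab_columns: list[str] | None = None,
    vocab_min_users: int = 5,
) -> EvalResult:
    """Leave-one-out evaluation of one classifier on one feature matrix.

    Each participant is predicted by a model fitted on all others; all
    preprocessing (z-scoring for the logistic model, fold-internal
    vocabulary pruning when ``vocab_columns`` is given) happens inside the
    training fold.  The pooled out-of-fold predictions are scored with
    minority-class F1.  A degenerate one-class training fold predicts its
    single class (with a warning).
    """
    y = np.asarray(y).astype(int)
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 examples of each class")
    Xv = X.fillna(0.0)
    n = len(y)
    y_pred = np.empty(n, dtype=int)
    warned = False
    for i in range(n):
        train = np.array([j for j in range(n) if j != i])
        cols = _fold_columns(Xv, train, vocab_columns or [], vocab_min_users)
        Xtr = Xv.iloc[train][cols].to_numpy(dtype=float)
        ytr = y[train]
        if len(np.unique(ytr)) < 2:
            if not warned:
                warnings.warn("one-class training fold; predicting its single class")
                warned = True
            y_pred[i] = ytr[0]
            continue
        clf = make_classifier(model, seed)
        clf.fit(Xtr, ytr)
        y_pred[i] = int(clf.predict(Xv.iloc[[i]][cols].to_numpy(dtype=float))[0])
    pos = minority_class(y)
    precision, recall, f1 = _prf(y, y_pred, pos)
    return EvalResult(
        question_id=question_id,
        combo=combo,
        model=model,
        f1_minority=f1,
        precision=precision,
        recall=recall,
        n_used=n,
        y_pred=y_pred,
        participant_ids=tuple(map(str, X.index)),
    )


def chance_band(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    n_permutations: int = 200,
    seed: int = 0,
    coverage: float = 0.95,
) -> tuple[float, float]:
    """Permutation chance band for minority-class F1.

    Labels are permuted against the fixed pooled out-of-fold predictions
    and the minority-F1 recomputed each time (the minority class is fixed
    from the unpermuted labels; permutation preserves class frequencies).
    Returns the central ``coverage`` interval of the permuted scores.
    """
    rng = np.random.default_rng(seed)
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    pos = minority_class(y_true)
    scores = np.empty(n_permutations)
    for b in range(n_permutations):
        scores[b] = _prf(rng.permutation(y_true), y_pred, pos)[2]
    lo = (1.0 - coverage) / 2.0
    return float(np.quantile(scores, lo)), float(np.quantile(scores, 1.0 - lo))


def run_grid(
    features: Mapping[str, pd.DataFrame],
    labels: pd.DataFrame | Iterable[SurveyLabel],
    combos: Sequence[FeatureComboSpec] = TABLE_COMBOS,
    models: Sequence[str] = MODELS,
    questions: Sequence[str] | None = None,
    seed: int = 0,
    fold_internal_vocab: bool = True,
    vocab_min_users: int = 5,
) -> list[EvalResult]:
    """Evaluate every question × combo × model cell.

    ``features`` maps group name → participant-indexed DataFrame.  A combo
    referencing an absent group is skipped with a warning.  Missing labels
    exclude a participant from that question only.  With
    ``fold_internal_vocab`` (the default) the all-words vocabulary's
    minimum-user filter is re-applied inside each training fold; pass
    ``False`` for the full-corpus variant matching the original analysis.
    """
    if not isinstance(labels, pd.DataFrame):
        labels = labels_frame(labels)
    if questions is None:
        questions = [q for q in HEADLINE_QUESTIONS if q in labels.columns]
    results: list[EvalResult] = []
    for question in questions:
        lab = labels[question].dropna()
        for combo in combos:
            missing = [g for g in combo.groups if g not in features]
            if missing:
                warnings.warn(f"combo {combo.name!r} skipped; missing groups {missing}")
                continue
            X = pd.concat(
                [features[g].add_prefix(f"{g}|") for g in combo.groups], axis=1
            )
            ids = X.index.intersection(lab.index)
            Xq, yq = X.loc[ids], lab.loc[ids].to_numpy()
            vocab_cols = (
                [c for c in Xq.columns if c.startswith("all_words|")]
                if fold_internal_vocab and "all_words" in combo.groups
                else None
            )
            for model in models:
                results.append(
                    loocv_evaluate(
                        Xq,
                        yq,
                        model=model,
                        seed=seed,
                        question_id=question,
                        combo=combo.name,
                        vocab_columns=vocab_cols,
                        vocab_min_users=vocab_min_users,
                    )
                )
    return results


def results_table(results: Sequence[EvalResult]) -> pd.DataFrame:
    """Grid-shaped table: rows = feature combos, columns = question × model."""
    rows: dict[str, dict[tuple[str, str], float]] = {}
    for r in results:
        rows.setdefault(r.combo, {})[(r.question_id, r.model)] = r.f1_minority
    df = pd.DataFrame.from_dict(rows, orient="index")
    if not df.empty:
        df.columns = pd.MultiIndex.from_tuples(df.columns, names=["question", "model"])
        df = df.sort_index(axis=1)
    combo_order = [c.name for c in TABLE_COMBOS if c.name in df.index]
    extra = [c for c in df.index if c not in combo_order]
    return df.loc[combo_order + extra]


# ---------------------------------------------------------------------------
# model/results surface

class RiskPredictionModel:
    """Risk-behavior prediction study on a fixed cohort.

    Built from per-group feature matrices and survey labels; ``fit()`` runs
    the LOOCV evaluation grid and returns a :class:`RiskPredictionResults`.

    Parameters
    ----------
    features : mapping of feature-group name to DataFrame
        Participant-indexed matrices for the groups in :data:`FEATURE_GROUPS`.
    labels : DataFrame or iterable of SurveyLabel
        Binary outcomes; NaN/"missing" excludes a participant per question.
    """

    def __init__(self, features: Mapping[str, pd.DataFrame], labels) -> None:
        self.features = dict(features)
        self.labels = labels if isinstance(labels, pd.DataFrame) else labels_frame(labels)

    @classmethod
    def from_feature_matrix(cls, matrix: pd.DataFrame, labels) -> "RiskPredictionModel":
        """Split a flat prefixed feature matrix (``app.``, ``loc.``, ...)
        into the named feature groups."""
        from .featurize import split_feature_matrix

        return cls(split_feature_matrix(matrix), labels)

    def fit(
        self,
        combos: Sequence[FeatureComboSpec] = TABLE_COMBOS,
        models: Sequence[str] = MODELS,
        questions: Sequence[str] | None = None,
        seed: int = 0,
        fold_internal_vocab: bool = True,
        n_permutations: int = 0,
    ) -> "RiskPredictionResults":
        results = run_grid(
            self.features,
            self.labels,
            combos=combos,
            models=models,
            questions=questions,
            seed=seed,
            fold_internal_vocab=fold_internal_vocab,
        )
        bands = {}
        if n_permutations:
            for r in results:
                y = self.labels[r.question_id].dropna().loc[list(r.participant_ids)]
                bands[(r.question_id, r.combo, r.model)] = chance_band(
                    y.to_numpy(), r.y_pred, n_permutations=n_permutations, seed=seed
                )
        return RiskPredictionResults(self, results, bands)


class RiskPredictionResults:
    """LOOCV evaluation grid with minority-F1 scores and chance bands."""

    def __init__(self, model: RiskPredictionModel, results: list[EvalResult], bands: dict):
        self.model = model
        self.results = results
        self.chance_bands = bands

    @property
    def table(self) -> pd.DataFrame:
        return results_table(self.results)

    def to_frame(self) -> pd.DataFrame:
        """One row per (question, combo, model) with scores and counts."""
        rows = []
        for r in self.results:
            band = self.chance_bands.get((r.question_id, r.combo, r.model))
            rows.append(
                {
                    "question": r.question_id,
                    "combo": r.combo,
                    "model": r.model,
                    "f1_minority": r.f1_minority,
                    "precision": r.precision,
                    "recall": r.recall,
                    "n_used": r.n_used,
                    "chance_lo": band[0] if band else np.nan,
                    "chance_hi": band[1] if band else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Risk-behavior prediction (LOOCV minority-class F1)", ""]
        table = self.table
        lines.append(table.round(3).to_string())
        lines.append("")
        for question in table.columns.get_level_values("question").unique():
            sub = table[question]
            best_combo = sub.max(axis=1).idxmax()
            best_model = sub.loc[best_combo].idxmax()
            lines.append(
                f"best for {question}: {best_combo} / {best_model} "
                f"(F1={sub.loc[best_combo, best_model]:.3f})"
            )
        return "\n".join(lines)
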