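"""Group contrasts: independent t-tests of features between outcome groups.

For each requested feature, participants answering "yes" and "no" to an
outcome are compared with an independent two-sample t-test — Welch's
unequal-variance test by default (a ``student=True`` option gives the
pooled-variance variant) — two-sided, significant at P < .05.  No
multiple-testing correction is applied by default (the analysis is
exploratory); Benjamini–Hochberg is available as an option.  A max-scaling
helper reproduces the display convention in which the largest value of each
feature becomes 1 so features of different scales share one axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import SurveyLabel
from .models import labels_frame

__all__ = [
    "ContrastResult",
    "t_test_feature",
    "contrast_suite",
    "scale_for_display",
    "GroupContrast",
    "GroupContrastResults",
]


@dataclass
class ContrastResult:
    feature: str
    mean_yes: float
    mean_no: float
    n_yes: int
    n_no: int
    t: float
    p: float
    significant: bool
    testable: bool = True


def t_test_feature(
    values_yes: Sequence[float],
    values_no: Sequence[float],
    alpha: float = 0.05,
    feature: str = "",
    student: bool = False,
) -> ContrastResult:
    """Two-sided independent two-sample t-test between outcome groups.

    Welch's statistic with Welch–Satterthwaite degrees of freedom unless
    ``student`` requests the pooled-variance test.  Groups with fewer than
    two observations or zero pooled variance are marked untestable.
    """
    ys = np.asarray(values_yes, dtype=float)
    ns = np.asarray(values_no, dtype=float)
    ys, ns = ys[~np.isnan(ys)], ns[~np.isnan(ns)]
    base = dict(
        feature=feature,
        mean_yes=float(ys.mean()) if len(ys) else float("nan"),
        mean_no=float(ns.mean()) if len(ns) else float("nan"),
        n_yes=len(ys),
        n_no=len(ns),
    )
    if len(ys) < 2 or len(ns) < 2 or (ys.var(ddof=1) == 0 and ns.var(ddof=1) == 0):
        return ContrastResult(
            **base, t=float("nan"), p=float("nan"), significant=False, testable=False
        )
    res = stats.ttest_ind(ys, ns, equal_var=student)
    t, p = float(res.statistic), float(res.pvalue)
    return ContrastResult(**base, t=t, p=p, significant=bool(p < alpha))


def contrast_suite(
    features: pd.DataFrame,
    labels: pd.DataFrame | Iterable[SurveyLabel],
    outcome: str,
    feature_names: Sequence[str] | None = None,
    alpha: float = 0.05,
    student: bool = False,
    bh_correct: bool = False,
) -> list[ContrastResult]:
    """One t-test per feature between the outcome's yes and no groups.

    Participants with a missing outcome label are excluded.  Unknown
    feature names are skipped with a warning.  With ``bh_correct`` the
    significance flags use Benjamini–Hochberg adjusted p-values at the same
    alpha (raw p-values are still reported).
    """
    if not isinstance(labels, pd.DataFrame):
        labels = labels_frame(labels)
    if outcome not in labels.columns:
        raise ValueError(f"unknown outcome {outcome!r}")
    lab = labels[outcome].dropna()
    ids = features.index.intersection(lab.index)
    lab = lab.loc[ids]
    if feature_names is None:
        feature_names = list(features.columns)
    results: list[ContrastResult] = []
    for name in feature_names:
        if name not in features.columns:
            warnings.warn(f"unknown feature {name!r}; skipped")
            continue
        col = features.loc[ids, name]
        results.append(
            t_test_feature(
                col[lab == 1.0].to_numpy(),
                col[lab == 0.0].to_numpy(),
                alpha=alpha,
                feature=name,
                student=student,
            )
        )
    if bh_correct:
        testable = [r for r in results if r.testable and not np.isnan(r.p)]
        if testable:
            order = np.argsort([r.p for r in testable])
            m = len(testable)
            adj = np.empty(m)
            prev = 1.0
            for rank_pos in range(m - 1, -1, -1):
                i = order[rank_pos]
                prev = min(prev, testable[i].p * m / (rank_pos + 1))
                adj[i] = prev
            for r, a in zip(testable, adj):
                r.significant = bool(a < alpha)
    return results


def scale_for_display(values: Sequence[float]) -> list[float]:
    """Divide by the maximum absolute value so the largest value becomes 1.

    All-zero (or empty) input is returned unchanged; NaNs pass through.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return []
    m = np.nanmax(np.abs(arr)) if not np.all(np.isnan(arr)) else 0.0
    if m == 0 or np.isnan(m):
        return [float(v) for v in arr]
    return [float(v / m) for v in arr]


class GroupContrast:
    """Feature contrasts between the yes/no groups of one outcome.

    statsmodels-style surface: construct from data, ``fit()`` runs the
    tests and returns a results object with a summary table.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        labels,
        outcome: str,
        feature_names: Sequence[str] | None = None,
    ) -> None:
        self.features = features
        self.labels = labels if isinstance(labels, pd.DataFrame) else labels_frame(labels)
        self.outcome = outcome
        self.feature_names = feature_names

    def fit(
        self, alpha: float = 0.05, student: bool = False, bh_correct: bool = False
    ) -> "GroupContrastResults":
        results = contrast_suite(
            self.features,
            self.labels,
            self.outcome,
            feature_names=self.feature_names,
            alpha=alpha,
            student=student,
            bh_correct=bh_correct,
        )
        return GroupContrastResults(self, results, alpha)


class GroupContrastResults:
    def __init__(self, model: GroupContrast, results: list[ContrastResult], alpha: float):
        self.model = model
        self.results = results
        self.alpha = alpha

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "feature": r.feature,
                    "mean_yes": r.mean_yes,
                    "mean_no": r.mean_no,
                    "n_yes": r.n_yes,
                    "n_no": r.n_no,
                    "t": r.t,
                    "p": r.p,
                    "significant": r.significant,
                    "testable": r.testable,
                }
                for r in self.results
            ]
        )

    @property
    def significant(self) -> list[ContrastResult]:
        return [r for r in self.results if r.significant]

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            f"Group contrasts for outcome {self.model.outcome!r} "
            f"(Welch t-tests, alpha={self.alpha})",
            "",
            df.round(4).to_string(index=False),
            "",
        ]
        sig = self.significant
        if sig:
            lines.append("significant: " + ", ".join(r.feature for r in sig))
        else:
            lines.append("none significant")
        return "\n".join(lines)
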