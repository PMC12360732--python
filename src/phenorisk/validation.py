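"""Simulation-based validation experiments for the whole pipeline.

These are the package's own end-to-end checks: worked examples for the
dedup rules, oracle agreement for the edit distance, planted-place recovery
for the clustering, type-I/power calibration for the group contrasts, and
permutation-based no-leakage / signal-recovery checks for the LOOCV models.
They run on synthetic cohorts from :mod:`phenorisk.simulate` and are used
by both the test suite and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .contrasts import t_test_feature
from .dedup import levenshtein_distance
from .featurize import extract_features
from .mobility import StayPoint, assign_home, haversine_miles, mean_shift_cluster
from .models import (
    TABLE_COMBOS,
    chance_band,
    derive_labels,
    labels_frame,
    loocv_evaluate,
    run_grid,
)
from .simulate import SimConfig, generate_cohort

__all__ = [
    "reference_distance",
    "distance_oracle_agreement",
    "meanshift_recovery_rate",
    "ttest_null_rejection_rate",
    "dating_contrast_power",
    "cohort_features",
    "no_leakage_scores",
    "signal_recovery_rate",
]


def reference_distance(a: str, b: str) -> int:
    """Edit distance by the direct recursive definition (independent oracle)."""

    @lru_cache(maxsize=None)
    def rec(a: str, b: str) -> int:
        if not a:
            return len(b)
        if not b:
            return len(a)
        if a[0] == b[0]:
            return rec(a[1:], b[1:])
        return 1 + min(rec(a[1:], b), rec(a, b[1:]), rec(a[1:], b[1:]))

    return rec(a, b)


def distance_oracle_agreement(n_pairs: int = 10_000, seed: int = 0) -> float:
    """Fraction of random short string pairs where the DP distance equals the
    recursive definition (pairs of length ≤ 6 over a 3-letter alphabet)."""
    rng = np.random.default_rng(seed)
    alphabet = "abc"
    agree = 0
    for _ in range(n_pairs):
        la, lb = int(rng.integers(0, 7)), int(rng.integers(0, 7))
        a = "".join(alphabet[i] for i in rng.integers(0, 3, size=la))
        b = "".join(alphabet[i] for i in rng.integers(0, 3, size=lb))
        agree += levenshtein_distance(a, b) == reference_distance(a, b)
    return agree / n_pairs


def meanshift_recovery_rate(n_instances: int = 100, seed: int = 0, radius_m: float = 100.0) -> float:
    """Share of planted-place instances where mean shift recovers exactly k
    clusters and flags the planted (most visited) home.

    Each instance plants k ∈ {1..5} places separated by ~50× the radius,
    with the home receiving strictly the most visits.
    """
    rng = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_instances):
        k = int(rng.integers(1, 6))
        home = (float(rng.uniform(30, 45)), float(rng.uniform(-120, -75)))
        centers = [home] + [
            (home[0] + (i + 1) * 5_000 / 111_000.0, home[1]) for i in range(k - 1)
        ]
        pts, t = [], 0
        for i, c in enumerate(centers):
            n = 8 if i == 0 else int(rng.integers(2, 6))
            for _ in range(n):
                pts.append(
                    StayPoint(
                        "S",
                        t,
                        c[0] + rng.normal(0, 5) / 111_000.0,
                        c[1] + rng.normal(0, 5) / 111_000.0,
                    )
                )
                t += 1_800_000
        clusters, _ = mean_shift_cluster(pts, radius_m=radius_m)
        clusters = assign_home(clusters)
        home_cl = next(c for c in clusters if c.is_home)
        if len(clusters) == k and (
            haversine_miles((home_cl.lat, home_cl.lon), home) * 1609.34 < radius_m
        ):
            ok += 1
    return ok / n_instances


def ttest_null_rejection_rate(
    n_reps: int = 1000, seed: int = 0, n_yes: int = 15, n_no: int = 65, alpha: float = 0.05
) -> float:
    """Empirical type-I error of the Welch test under a simulated null with
    cohort-like unbalanced group sizes."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        r = t_test_feature(rng.normal(size=n_yes), rng.normal(size=n_no), alpha=alpha)
        rejections += r.significant
    return rejections / n_reps


def dating_contrast_power(
    n_seeds: int = 100,
    config: SimConfig | None = None,
    alpha: float = 0.05,
) -> float:
    """Power of the group contrast to detect the planted dating-app elevation.

    Each replicate draws labels and per-participant dating-app day fractions
    from the generator's own daily-use process (a Bernoulli day process at
    the base rate, ratio-elevated for positives) and Welch-tests the
    fractions between groups — the day-level mechanism behind the app
    category features, simulated directly so many replicates stay cheap.
    """
    cfg = config or SimConfig()
    detected = 0
    for s in range(n_seeds):
        rng = np.random.default_rng([cfg.seed % (2**31), 7_000 + s])
        pos = rng.random(cfg.n_participants) < cfg.p_meth
        rate = np.where(
            pos,
            min(0.95, cfg.base_dating_day_rate * cfg.dating_ratio),
            cfg.base_dating_day_rate,
        )
        frac = rng.binomial(cfg.n_days, rate) / cfg.n_days
        if pos.sum() < 2 or (~pos).sum() < 2:
            continue
        r = t_test_feature(frac[pos], frac[~pos], alpha=alpha)
        detected += r.significant and r.mean_yes > r.mean_no
    return detected / n_seeds


@dataclass
class CohortFeatures:
    groups: dict[str, pd.DataFrame]
    labels: pd.DataFrame
    flat: pd.DataFrame


def cohort_features(config: SimConfig) -> CohortFeatures:
    """Generate a cohort and run the full feature-extraction chain on it."""
    cohort = generate_cohort(config)
    fs = extract_features(cohort.keystrokes, cohort.fixes, apply_min_days=True)
    labels = labels_frame(derive_labels(cohort.survey))
    labels = labels.loc[labels.index.intersection(fs.flat().index)]
    return CohortFeatures(groups=fs.groups, labels=labels, flat=fs.flat())


def no_leakage_scores(
    config: SimConfig | None = None,
    question: str = "meth_use",
    n_permutations: int = 200,
    models: tuple[str, ...] = ("logistic", "gradient_boosting"),
) -> pd.DataFrame:
    """Permuted-label LOOCV for every combo × model against its chance band.

    The outcome labels are randomly permuted across participants (severing
    any feature-label association), the full LOOCV is re-run per combo ×
    model, and each score is compared with the range of ``n_permutations``
    label permutations against the pooled predictions.  Any preprocessing
    leak across folds would inflate the scores above the band.
    """
    cfg = config or SimConfig()
    cf = cohort_features(cfg)
    y = cf.labels[question].dropna()
    rng = np.random.default_rng(cfg.seed + 1)
    y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
    rows = []
    for combo in TABLE_COMBOS:
        X = pd.concat([cf.groups[g].add_prefix(f"{g}|") for g in combo.groups], axis=1)
        ids = X.index.intersection(y_perm.index)
        Xq, yq = X.loc[ids], y_perm.loc[ids].to_numpy().astype(int)
        vocab_cols = [c for c in Xq.columns if c.startswith("all_words|")] or None
        for model in models:
            res = loocv_evaluate(
                Xq, yq, model=model, seed=cfg.seed, question_id=question,
                combo=combo.name, vocab_columns=vocab_cols,
            )
            lo, hi = chance_band(
                yq, res.y_pred, n_permutations=n_permutations, seed=cfg.seed,
                coverage=1.0,  # full range of the permuted scores
            )
            rows.append(
                {
                    "combo": combo.name,
                    "model": model,
                    "f1": res.f1_minority,
                    "band_lo": lo,
                    "band_hi": hi,
                    "inside": lo <= res.f1_minority <= hi,
                }
            )
    return pd.DataFrame(rows)


def signal_recovery_rate(
    n_seeds: int = 20,
    questions: tuple[str, ...] = ("meth_use", "partners_6plus"),
    combo_name: str = "risky_words",
    base_config: SimConfig | None = None,
    n_permutations: int = 200,
) -> dict[str, float]:
    """Share of seeded cohorts where the gradient-boosted model beats chance.

    For each seed a full cohort is generated at the default planted effect
    ratios, features are extracted through the complete pipeline, and the
    LOOCV minority-F1 of the boosted model on the given feature combo is
    compared with the upper edge of its 95% permutation chance band.
    """
    base = base_config or SimConfig()
    combo = next(c for c in TABLE_COMBOS if c.name == combo_name)
    wins = {q: 0 for q in questions}
    usable = {q: 0 for q in questions}
    for s in range(n_seeds):
        cfg = SimConfig(
            **{
                **{f.name: getattr(base, f.name) for f in base.__dataclass_fields__.values()},
                "seed": base.seed + 1000 + s,
            }
        )
        cf = cohort_features(cfg)
        X = pd.concat([cf.groups[g].add_prefix(f"{g}|") for g in combo.groups], axis=1)
        for q in questions:
            y = cf.labels[q].dropna()
            ids = X.index.intersection(y.index)
            yq = y.loc[ids].to_numpy().astype(int)
            if min(np.bincount(yq, minlength=2)) < 2:
                continue
            usable[q] += 1
            res = loocv_evaluate(X.loc[ids], yq, model="gradient_boosting", seed=cfg.seed)
            _, hi = chance_band(yq, res.y_pred, n_permutations=n_permutations, seed=cfg.seed)
            wins[q] += res.f1_minority > hi
    return {q: (wins[q] / usable[q] if usable[q] else float("nan")) for q in questions}
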