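"""End-to-end orchestration: simulate → dedup → featurize → train → contrast → report.

Each stage persists its output under the run directory, so a failed or
deleted later stage can be recomputed without redoing earlier ones, and a
rerun with the same config and seed reproduces every output byte for byte.
A run manifest records the config snapshot, per-stage record counts and the
software version (timestamps live only in the manifest, never in stage
outputs, to keep outputs deterministic).

Every analysis constant is a named config key with its standard value as
default: the 0.6 dedup similarity threshold, the 30-day inclusion minimum,
the 5-participant vocabulary floor, the 100 m clustering radius, the
50-mile travel cutoff, α=.05, 80 boosting trees and the 1000-iteration cap
for logistic regression.
"""

from __future__ import annotations

import json
import logging
from datetime import date, datetime, timezone
from pathlib import Path

import pandas as pd

from ._version import __version__
from .apps import AppCategoryMap
from .contrasts import GroupContrast
from .dedup import dedup_stream
from .featurize import FeatureSet, GROUP_PREFIX, canonicalize_events, split_feature_matrix
from .io import (
    CohortConfig,
    MessageLine,
    filter_min_days,
    read_event_log,
    read_feature_matrix,
    write_event_log,
    write_feature_matrix,
)
from .models import (
    HEADLINE_QUESTIONS,
    RiskPredictionModel,
    TABLE_COMBOS,
    derive_labels,
    labels_frame,
)
from .simulate import SimConfig, generate_cohort
from .text import HashingEmbedder

log = logging.getLogger("phenorisk")

__all__ = ["DEFAULT_CONFIG", "run_pipeline", "report"]

DEFAULT_CONFIG: dict = {
    "seed": 7,
    "simulate": {"enabled": True},  # extra keys forwarded to SimConfig
    "inputs": {},  # keystrokes/locations/survey paths when simulate is off
    "dedup": {"similarity_threshold": 0.6},
    "inclusion": {"min_days": 30},
    "featurize": {
        "mean_shift_radius_m": 100.0,
        "gap_max_s": 300.0,
        "min_users_vocab": 5,
        "embedding_dim": 64,
    },
    "train": {
        "models": ["logistic", "gradient_boosting"],
        "questions": list(HEADLINE_QUESTIONS),
        "n_permutations": 200,
        "fold_internal_vocab": True,
    },
    "contrast": {
        "alpha": 0.05,
        "outcomes": ["meth_use", "partners_6plus"],
        "student": False,
    },
}


def _merged_config(config: dict | str | Path | None) -> dict:
    if config is None:
        config = {}
    elif not isinstance(config, dict):
        with open(config) as fh:
            config = json.load(fh)
    out = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in config.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key].update(val)
        else:
            out[key] = val
    return out


def _write_lines(lines: list[MessageLine], path: Path) -> None:
    with path.open("w") as fh:
        for ln in lines:
            fh.write(
                json.dumps(
                    {
                        "participant_id": ln.participant_id,
                        "day": ln.day.isoformat(),
                        "package": ln.package,
                        "text": ln.text,
                    }
                )
                + "\n"
            )


def _read_lines(path: Path) -> list[MessageLine]:
    out = []
    with path.open() as fh:
        for raw in fh:
            obj = json.loads(raw)
            out.append(
                MessageLine(
                    obj["participant_id"],
                    date.fromisoformat(obj["day"]),
                    obj["package"],
                    obj["text"],
                )
            )
    return out


def run_pipeline(
    config: dict | str | Path | None = None,
    out_dir: str | Path = "run",
    seed: int | None = None,
    resume: bool = False,
) -> dict:
    """Execute all stages, persisting each intermediate under ``out_dir``.

    With ``resume`` a stage whose output files already exist is skipped and
    its output reloaded, so deleting only a late output and rerunning
    reproduces it without recomputing earlier stages.  Returns the run
    manifest (also written to ``manifest.json``).
    """
    cfg = _merged_config(config)
    if seed is not None:
        cfg["seed"] = seed
    seed = int(cfg["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg,
        "version": __version__,
        "started": datetime.now(timezone.utc).isoformat(),
        "stages": {},
    }
    category_map = AppCategoryMap.default()

    # --- stage: simulate -------------------------------------------------
    ks_path = out / "keystrokes.jsonl"
    loc_path = out / "locations.jsonl"
    survey_path = out / "survey.jsonl"
    if cfg["simulate"].get("enabled", True):
        if resume and ks_path.exists() and loc_path.exists() and survey_path.exists():
            log.info("simulate: outputs exist, skipping")
        else:
            sim_kwargs = {k: v for k, v in cfg["simulate"].items() if k != "enabled"}
            sim_kwargs.setdefault("seed", seed)
            cohort = generate_cohort(SimConfig(**sim_kwargs))
            write_event_log(cohort.keystrokes, ks_path, "keystroke")
            write_event_log(cohort.fixes, loc_path, "location")
            write_event_log(cohort.survey, survey_path, "survey")
            with (out / "ground_truth.json").open("w") as fh:
                json.dump(cohort.ground_truth, fh, indent=1, default=str)
            manifest["stages"]["simulate"] = {
                "keystrokes": len(cohort.keystrokes),
                "fixes": len(cohort.fixes),
                "survey_rows": len(cohort.survey),
            }
    else:
        inputs = cfg["inputs"]
        for key, target in [("keystrokes", ks_path), ("locations", loc_path), ("survey", survey_path)]:
            src = inputs.get(key)
            if not src or not Path(src).exists():
                raise FileNotFoundError(f"input log {key!r} missing: {src}")
            if Path(src).resolve() != target.resolve():
                target.write_bytes(Path(src).read_bytes())

    # --- stage: dedup ----------------------------------------------------
    lines_path = out / "lines.jsonl"
    ks = read_event_log(ks_path, "keystroke")
    events = canonicalize_events(ks.records, category_map)
    retained = filter_min_days(events, int(cfg["inclusion"]["min_days"]))
    events = [e for e in events if e.participant_id in retained]
    if resume and lines_path.exists():
        log.info("dedup: output exists, skipping")
        lines = _read_lines(lines_path)
    else:
        threshold = float(cfg["dedup"]["similarity_threshold"])
        by_pid: dict[str, list] = {}
        for e in events:
            by_pid.setdefault(e.participant_id, []).append(e)
        lines = []
        for pid in sorted(by_pid):
            lines.extend(dedup_stream(by_pid[pid], threshold))
        _write_lines(lines, lines_path)
    manifest["stages"]["dedup"] = {
        "events_in": len(ks.records),
        "malformed": ks.n_malformed,
        "rejected": ks.n_rejected,
        "participants_retained": len(retained),
        "lines_out": len(lines),
    }

    # --- stage: featurize -------------------------------------------------
    feat_path = out / "features.csv"
    fz = cfg["featurize"]
    if resume and feat_path.exists():
        log.info("featurize: output exists, skipping")
        flat = read_feature_matrix(feat_path)
    else:
        locs = read_event_log(loc_path, "location")
        cohort_cfg = CohortConfig(
            min_days=int(cfg["inclusion"]["min_days"]),
            similarity_threshold=float(cfg["dedup"]["similarity_threshold"]),
            mean_shift_radius_m=float(fz["mean_shift_radius_m"]),
            min_users_vocab=int(fz["min_users_vocab"]),
            gap_max_s=float(fz["gap_max_s"]),
        )
        fs = _features_from_lines(
            lines,
            [f for f in locs.records if f.participant_id in retained],
            cohort_cfg,
            category_map,
            HashingEmbedder(dim=int(fz["embedding_dim"]), seed=seed),
        )
        flat = fs.flat()
        write_feature_matrix(flat, feat_path)
    manifest["stages"]["featurize"] = {
        "participants": int(len(flat)),
        "features": int(len(flat.columns)),
    }

    # --- stage: train ------------------------------------------------------
    results_path = out / "results.csv"
    table_path = out / "results_table.csv"
    labels = labels_frame(derive_labels(read_event_log(survey_path, "survey").records))
    labels = labels.loc[labels.index.intersection(flat.index)]
    tr = cfg["train"]
    if resume and results_path.exists() and table_path.exists():
        log.info("train: outputs exist, skipping")
        results_df = pd.read_csv(results_path)
    else:
        model = RiskPredictionModel(split_feature_matrix(flat), labels)
        fit = model.fit(
            combos=TABLE_COMBOS,
            models=tuple(tr["models"]),
            questions=[q for q in tr["questions"] if q in labels.columns],
            seed=seed,
            fold_internal_vocab=bool(tr["fold_internal_vocab"]),
            n_permutations=int(tr["n_permutations"]),
        )
        results_df = fit.to_frame()
        results_df.to_csv(results_path, index=False)
        fit.table.to_csv(table_path)
    manifest["stages"]["train"] = {"rows": int(len(results_df))}

    # --- stage: contrast ---------------------------------------------------
    contrasts_path = out / "contrasts.csv"
    ct = cfg["contrast"]
    display_cols = [
        c
        for c in flat.columns
        if c.startswith(("cat.", "loc.", "dict."))
        or c.startswith("risky.category:")
    ]
    if resume and contrasts_path.exists():
        log.info("contrast: output exists, skipping")
        contrasts_df = pd.read_csv(contrasts_path)
    else:
        frames = []
        for outcome in ct["outcomes"]:
            if outcome not in labels.columns:
                continue
            res = GroupContrast(flat, labels, outcome, feature_names=display_cols).fit(
                alpha=float(ct["alpha"]), student=bool(ct.get("student", False))
            )
            df = res.to_frame()
            df.insert(0, "outcome", outcome)
            frames.append(df)
        contrasts_df = (
            pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        )
        contrasts_df.to_csv(contrasts_path, index=False)
    manifest["stages"]["contrast"] = {"rows": int(len(contrasts_df))}

    # --- stage: report -----------------------------------------------------
    report_path = out / "report.md"
    report_text = report(results_df, contrasts_df, alpha=float(ct["alpha"]))
    report_path.write_text(report_text)
    manifest["stages"]["report"] = {"bytes": len(report_text)}

    manifest["finished"] = datetime.now(timezone.utc).isoformat()
    with (out / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _features_from_lines(lines, fixes, cohort_cfg, category_map, embedder) -> FeatureSet:
    """Feature extraction from already-deduplicated lines (pipeline staging)."""
    from .apps import app_frequency_features, category_day_fraction, communication_lines
    from .mobility import assign_home, mean_shift_cluster, mobility_features, retain_stationary
    from .text import (
        CategoryDictionary,
        PhraseLexicon,
        build_vocab,
        dictionary_scores,
        embed_days,
        risky_phrase_features,
        word_frequency_features,
    )

    lexicon = PhraseLexicon.default()
    dictionary = CategoryDictionary.default()
    by_pid: dict[str, list] = {}
    for ln in lines:
        by_pid.setdefault(ln.participant_id, []).append(ln)
    participants = tuple(sorted(by_pid))
    comm = {pid: communication_lines(lns, category_map) for pid, lns in by_pid.items()}
    vocab = build_vocab(
        [ln for lns in comm.values() for ln in lns], min_users=cohort_cfg.min_users_vocab
    )
    fixes_by_pid: dict[str, list] = {}
    for f in fixes:
        fixes_by_pid.setdefault(f.participant_id, []).append(f)

    groups: dict[str, dict] = {g: {} for g in GROUP_PREFIX}
    cats: dict[str, dict] = {}
    for pid in participants:
        plines, pcomm = by_pid[pid], comm[pid]
        groups["all_apps"][pid] = app_frequency_features(plines)
        groups["social_apps"][pid] = app_frequency_features(pcomm)
        cats[pid] = {
            c: category_day_fraction(plines, category_map, c)
            for c in ("messaging", "social_media", "dating")
        }
        groups["risky_words"][pid] = risky_phrase_features(pcomm, lexicon)
        groups["all_words"][pid] = word_frequency_features(pcomm, vocab)
        groups["dictionary"][pid] = dictionary_scores(pcomm, dictionary)
        vec = embed_days(pcomm, embedder)
        groups["embedding"][pid] = (
            {f"e{i:03d}": float(v) for i, v in enumerate(vec)} if vec is not None else {}
        )
        pfixes = sorted(fixes_by_pid.get(pid, []), key=lambda f: f.timestamp)
        if pfixes:
            sps = retain_stationary(pfixes, gap_max_s=cohort_cfg.gap_max_s)
            clusters, assignment = mean_shift_cluster(sps, cohort_cfg.mean_shift_radius_m)
            clusters = assign_home(clusters)
            groups["location"][pid] = mobility_features(sps, clusters, assignment)
        else:
            groups["location"][pid] = {}

    def frame(rows: dict) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index = df.index.astype(str)
        return df[sorted(df.columns)].sort_index() if len(df.columns) else df.sort_index()

    return FeatureSet(
        groups={g: frame(rows) for g, rows in groups.items()},
        category_fractions=frame(cats),
        lines=list(lines),
        participants=participants,
    )


def report(results: pd.DataFrame, contrasts: pd.DataFrame, alpha: float = 0.05) -> str:
    """Markdown run report: F1 grid, chance bands, significant contrasts."""
    lines = ["# Run report", "", "## LOOCV minority-class F1", ""]
    if len(results):
        grid = results.pivot_table(
            index="combo", columns=["question", "model"], values="f1_minority"
        )
        combo_order = [c.name for c in TABLE_COMBOS if c.name in grid.index]
        grid = grid.loc[combo_order + [c for c in grid.index if c not in combo_order]]
        lines.append("```")
        lines.append(grid.round(3).to_string())
        lines.append("```")
        lines.append("")
        for question in sorted(results["question"].unique()):
            sub = results[results["question"] == question]
            best = sub.loc[sub["f1_minority"].idxmax()]
            extra = ""
            if "chance_hi" in sub.columns and pd.notna(best.get("chance_hi")):
                above = "above" if best["f1_minority"] > best["chance_hi"] else "within"
                extra = (
                    f"; chance band [{best['chance_lo']:.3f}, {best['chance_hi']:.3f}]"
                    f" ({above})"
                )
            lines.append(
                f"- best for **{question}**: {best['combo']} / {best['model']}"
                f" (F1={best['f1_minority']:.3f}{extra})"
            )
    else:
        lines.append("no evaluation results")
    lines += ["", f"## Group contrasts (alpha={alpha})", ""]
    if len(contrasts) and "significant" in contrasts.columns:
        sig = contrasts[contrasts["significant"] == True]  # noqa: E712
        if len(sig):
            for _, row in sig.iterrows():
                lines.append(
                    f"- {row['outcome']}: **{row['feature']}** "
                    f"(yes={row['mean_yes']:.4f}, no={row['mean_no']:.4f}, "
                    f"t={row['t']:.2f}, p={row['p']:.4f})"
                )
        else:
            lines.append("none significant")
    else:
        lines.append("none significant")
    lines.append("")
    return "\n".join(lines)
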