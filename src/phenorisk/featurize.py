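"""End-to-end feature extraction: event logs → per-participant matrices.

Order of operations per participant: canonicalize app/URL keys, deduplicate
the keystroke stream into message lines, then compute the seven feature
groups used by the prediction models —

======================  ========  =======================================
group                   prefix    content
======================  ========  =======================================
``social_apps``         sapp.     day-share frequency per communication app
``all_apps``            app.      day-share frequency per app
``location``            loc.      mobility features relative to home
``risky_words``         risky.    lexicon phrase/category day-shares
``all_words``           word.     vocabulary lemma day-shares
``dictionary``          dict.     daily dictionary-category token shares
``embedding``           emb.      day-averaged text embedding
======================  ========  =======================================

plus the communication-category day fractions (prefix ``cat.``) used by
the group-contrast analysis.  Text features use communication-app lines
only.  The flat prefixed matrix written to CSV and the per-group mapping
are interconvertible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .apps import (
    AppCategoryMap,
    app_frequency_features,
    canonical_app_key,
    category_day_fraction,
    communication_lines,
)
from .dedup import dedup_stream
from .io import CohortConfig, KeystrokeEvent, LocationFix, MessageLine, filter_min_days
from .mobility import assign_home, mean_shift_cluster, mobility_features, retain_stationary
from .text import (
    CategoryDictionary,
    HashingEmbedder,
    PhraseLexicon,
    build_vocab,
    dictionary_scores,
    embed_days,
    risky_phrase_features,
    word_frequency_features,
)

__all__ = [
    "GROUP_PREFIX",
    "FeatureSet",
    "canonicalize_events",
    "extract_features",
    "flatten_features",
    "split_feature_matrix",
]

GROUP_PREFIX = {
    "social_apps": "sapp.",
    "all_apps": "app.",
    "location": "loc.",
    "risky_words": "risky.",
    "all_words": "word.",
    "dictionary": "dict.",
    "embedding": "emb.",
}
_CATEGORY_PREFIX = "cat."


@dataclass
class FeatureSet:
    """Per-group feature matrices plus the contrast-only category fractions."""

    groups: dict[str, pd.DataFrame]
    category_fractions: pd.DataFrame
    lines: list[MessageLine] = field(repr=False, default_factory=list)
    participants: tuple[str, ...] = ()

    def flat(self) -> pd.DataFrame:
        return flatten_features(self.groups, self.category_fractions)


def canonicalize_events(
    events: Iterable[KeystrokeEvent], category_map: AppCategoryMap
) -> list[KeystrokeEvent]:
    """Rewrite each event's package to its canonical app key (browser URLs
    collapse onto the matching app where curated)."""
    out = []
    for ev in events:
        try:
            key = canonical_app_key(ev.package, ev.url, category_map)
        except ValueError:
            continue
        out.append(ev if key == ev.package else replace(ev, package=key))
    return out


def _by_participant(records) -> dict[str, list]:
    grouped: dict[str, list] = {}
    for r in records:
        grouped.setdefault(r.participant_id, []).append(r)
    return grouped


def extract_features(
    keystrokes: Iterable[KeystrokeEvent],
    fixes: Iterable[LocationFix] = (),
    config: CohortConfig | None = None,
    category_map: AppCategoryMap | None = None,
    lexicon: PhraseLexicon | None = None,
    dictionary: CategoryDictionary | None = None,
    embedder=None,
    apply_min_days: bool = True,
) -> FeatureSet:
    """Run the full feature-extraction pipeline on raw event streams.

    Participants failing the minimum-days inclusion filter (counted on
    keystroke days) are dropped unless ``apply_min_days`` is False.  The
    vocabulary for the all-words group is built on the retained cohort's
    communication-app corpus.
    """
    config = config or CohortConfig()
    category_map = category_map or AppCategoryMap.default()
    lexicon = lexicon or PhraseLexicon.default()
    dictionary = dictionary or CategoryDictionary.default()
    embedder = embedder or HashingEmbedder()

    events = canonicalize_events(keystrokes, category_map)
    if apply_min_days:
        retained = filter_min_days(events, config.min_days)
        events = [e for e in events if e.participant_id in retained]
    by_pid = _by_participant(events)
    participants = tuple(sorted(by_pid))

    lines: list[MessageLine] = []
    for pid in participants:
        lines.extend(dedup_stream(by_pid[pid], config.similarity_threshold))
    lines_by_pid = _by_participant(lines)
    comm_by_pid = {
        pid: communication_lines(lns, category_map) for pid, lns in lines_by_pid.items()
    }

    vocab = build_vocab(
        [ln for lns in comm_by_pid.values() for ln in lns],
        min_users=config.min_users_vocab,
    )

    fixes_by_pid = _by_participant(
        [f for f in fixes if not participants or f.participant_id in set(participants)]
    )

    app_rows, sapp_rows, loc_rows = {}, {}, {}
    risky_rows, word_rows, dict_rows, emb_rows, cat_rows = {}, {}, {}, {}, {}
    for pid in participants:
        plines = lines_by_pid.get(pid, [])
        pcomm = comm_by_pid.get(pid, [])
        app_rows[pid] = app_frequency_features(plines)
        sapp_rows[pid] = app_frequency_features(pcomm)
        cat_rows[pid] = {
            cat: category_day_fraction(plines, category_map, cat)
            for cat in ("messaging", "social_media", "dating")
        }
        risky_rows[pid] = risky_phrase_features(pcomm, lexicon)
        word_rows[pid] = word_frequency_features(pcomm, vocab)
        dict_rows[pid] = dictionary_scores(pcomm, dictionary)
        vec = embed_days(pcomm, embedder)
        emb_rows[pid] = (
            {f"e{i:03d}": float(v) for i, v in enumerate(vec)} if vec is not None else {}
        )
        pfixes = sorted(fixes_by_pid.get(pid, []), key=lambda f: f.timestamp)
        if pfixes:
            sps = retain_stationary(pfixes, gap_max_s=config.gap_max_s)
            clusters, assignment = mean_shift_cluster(sps, config.mean_shift_radius_m)
            clusters = assign_home(clusters)
            loc_rows[pid] = mobility_features(sps, clusters, assignment)
        else:
            loc_rows[pid] = {}

    def frame(rows: Mapping[str, Mapping[str, float]]) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index = df.index.astype(str)
        return df[sorted(df.columns)].sort_index() if len(df.columns) else df.sort_index()

    groups = {
        "all_apps": frame(app_rows),
        "social_apps": frame(sapp_rows),
        "location": frame(loc_rows),
        "risky_words": frame(risky_rows),
        "all_words": frame(word_rows),
        "dictionary": frame(dict_rows),
        "embedding": frame(emb_rows),
    }
    return FeatureSet(
        groups=groups,
        category_fractions=frame(cat_rows),
        lines=lines,
        participants=participants,
    )


def flatten_features(
    groups: Mapping[str, pd.DataFrame], category_fractions: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Single participant-indexed matrix with group prefixes on columns."""
    parts = [groups[g].add_prefix(GROUP_PREFIX[g]) for g in GROUP_PREFIX if g in groups]
    if category_fractions is not None and len(category_fractions.columns):
        parts.append(category_fractions.add_prefix(_CATEGORY_PREFIX))
    flat = pd.concat(parts, axis=1).sort_index()
    return flat


def split_feature_matrix(matrix: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Inverse of :func:`flatten_features`; unknown prefixes are ignored."""
    groups: dict[str, pd.DataFrame] = {}
    for group, prefix in GROUP_PREFIX.items():
        cols = [c for c in matrix.columns if c.startswith(prefix)]
        if cols:
            sub = matrix[cols].copy()
            sub.columns = [c[len(prefix):] for c in cols]
            groups[group] = sub
    return groups
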