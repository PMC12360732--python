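"""Collapse incremental keystroke snapshots into final typed lines.

The keyboard logger stores the full text-field contents at every keypress,
so one typed line "Hello" arrives as the rows "H", "He", "Hel", "Hell",
"Hello" — and, with autocorrect or mid-line edits, the earlier row is not
always a substring of the next one ("H", "He", "Hel", "Helo", "Hello").

Deduplication repeats a two-rule pass over consecutive rows until a
fixpoint is reached:

1. if row *i*'s text is a substring of row *i+1*'s text, drop row *i*;
2. if the Levenshtein similarity of rows *i* and *i+1* exceeds the
   threshold (default 0.6), drop row *i*.

Similarity normalizes the unit-cost edit distance:
``sim(a, b) = 1 - dist(a, b) / max(len(a), len(b))``, with sim = 1 for two
empty strings.  Comparisons are consecutive-only, and runs are bounded by
app-package changes: rows typed in different apps belong to different text
fields and are never compared.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .io import KeystrokeEvent, MessageLine

__all__ = [
    "levenshtein_distance",
    "levenshtein_similarity",
    "dedup_pass",
    "dedup_stream",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 0.6


def levenshtein_distance(a: str, b: str) -> int:
    """Minimum number of single-character insertions, deletions and
    substitutions turning ``a`` into ``b``.

    Computed by the standard two-row dynamic program; O(len(a)*len(b)).
    """
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    if len(a) < len(b):  # keep the inner row short
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def levenshtein_similarity(a: str, b: str) -> float:
    """Normalized similarity ``1 - dist(a, b) / max(len(a), len(b))``.

    Two empty strings are identical by convention (similarity 1).
    """
    m = max(len(a), len(b))
    if m == 0:
        return 1.0
    return 1.0 - levenshtein_distance(a, b) / m


def _similar(a: str, b: str, threshold: float) -> bool:
    """True when sim(a, b) strictly exceeds ``threshold``.

    dist >= |len(a) - len(b)|, so sim <= 1 - |Δlen|/maxlen; when that upper
    bound already fails the threshold the DP is skipped.
    """
    m = max(len(a), len(b))
    if m == 0:
        return True
    if 1.0 - abs(len(a) - len(b)) / m <= threshold:
        return False
    return levenshtein_similarity(a, b) > threshold


def dedup_pass(rows: Sequence[str], threshold: float = DEFAULT_THRESHOLD) -> list[str]:
    """One two-rule pass over timestamp-ordered rows of one text-field run.

    Applies the substring rule along the whole sequence, then the similarity
    rule on the survivors; returns surviving rows in their original order.
    """
    kept = [r for i, r in enumerate(rows) if i == len(rows) - 1 or r not in rows[i + 1]]
    out = [
        r
        for i, r in enumerate(kept)
        if i == len(kept) - 1 or not _similar(r, kept[i + 1], threshold)
    ]
    return out


def _dedup_fixpoint(rows: list[str], threshold: float) -> tuple[list[str], int]:
    """Iterate dedup_pass to a fixpoint; returns (rows, passes)."""
    passes = 0
    while True:
        reduced = dedup_pass(rows, threshold)
        passes += 1
        if len(reduced) == len(rows):
            return reduced, passes
        rows = reduced


def dedup_stream(
    events: Iterable[KeystrokeEvent],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[MessageLine]:
    """Reduce one participant's timestamp-sorted keystroke stream to
    final :class:`MessageLine` records.

    The stream is segmented into runs of consecutive events in the same app
    package; within each run the two-rule pass iterates to a fixpoint.  Rows
    with empty text are dropped before deduplication.  Each surviving text
    becomes a MessageLine dated by its source event's UTC day.
    """
    events = [e for e in events if e.text]
    out: list[MessageLine] = []
    run: list[KeystrokeEvent] = []

    def flush() -> None:
        if not run:
            return
        texts = [e.text for e in run]
        survivors, _ = _dedup_fixpoint(texts, threshold)
        # survivors are a subsequence of the run's texts; align greedily so
        # each line is dated by a consistent source event
        cursor = 0
        for text in survivors:
            while run[cursor].text != text:
                cursor += 1
            ev = run[cursor]
            cursor += 1
            out.append(MessageLine(ev.participant_id, ev.day, ev.package, text))
        run.clear()

    prev_pkg: str | None = None
    for ev in events:
        if prev_pkg is not None and ev.package != prev_pkg:
            flush()
        run.append(ev)
        prev_pkg = ev.package
    flush()
    return out
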