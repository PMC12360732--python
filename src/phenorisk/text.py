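"""Text feature families from deduplicated communication-app lines.

Four families, all computed per participant from lines typed in messaging,
social-media and dating apps only:

* **word frequencies** — for each vocabulary lemma, the share of text days
  on which it was used: ``freq(w) = (# days with w) / (# days with text)``.
  The vocabulary excludes stop words, common placeholder texts, and lemmas
  used by fewer than ``min_users`` participants.
* **risky-phrase frequencies** — the same day-share statistic for phrases
  from a lexicon of drug- and sex-related terms, reported per phrase, per
  category and per subcategory.
* **dictionary scores** — daily proportion of tokens matching wildcard
  word-pattern categories (social, affect, drives, cognitive processes, in
  the packaged demonstration dictionary), averaged over days.  The format
  is open; licensed dictionaries drop in as JSON.
* **day-averaged embeddings** — each day's concatenated text is embedded by
  a pluggable embedder and the day vectors averaged.  The default embedder
  is a deterministic signed token-hashing projection (a test stub standing
  in for a transformer encoder, which plugs in through the same interface).

Lemmatization is injected; the default is a small exception table plus
regular suffix rules — deterministic and dependency-free.
"""

from __future__ import annotations

import csv
import hashlib
import json
import re
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .io import MessageLine

__all__ = [
    "RuleLemmatizer",
    "normalize_tokens",
    "VocabSpec",
    "build_vocab",
    "word_frequency_features",
    "PhraseLexicon",
    "risky_phrase_features",
    "CategoryDictionary",
    "dictionary_scores",
    "HashingEmbedder",
    "embed_days",
    "default_stopwords",
    "default_placeholders",
]

_TOKEN_RE = re.compile(r"[a-z0-9']+")

# irregular forms the suffix rules cannot reach
_LEMMA_EXCEPTIONS = {
    "better": "good",
    "best": "good",
    "worse": "bad",
    "worst": "bad",
    "went": "go",
    "gone": "go",
    "ran": "run",
    "running": "run",
    "came": "come",
    "said": "say",
    "made": "make",
    "got": "get",
    "gotten": "get",
    "took": "take",
    "taken": "take",
    "saw": "see",
    "seen": "see",
    "met": "meet",
    "felt": "feel",
    "men": "man",
    "women": "woman",
    "children": "child",
    "people": "people",
    "feet": "foot",
    "teeth": "tooth",
    "mice": "mouse",
    "parties": "party",
}

_DOUBLED = set("bdfglmnprt")


class RuleLemmatizer:
    """Deterministic lemmatizer: exception table + regular suffix stripping.

    Handles the regular inflections (plural -s/-es/-ies, progressive -ing,
    past -ed) and a table of common irregulars; out-of-table irregulars pass
    through unchanged.  Callable: ``lemmatizer(token) -> lemma``.
    """

    def __init__(self, extra_exceptions: dict[str, str] | None = None):
        self.exceptions = dict(_LEMMA_EXCEPTIONS)
        if extra_exceptions:
            self.exceptions.update(extra_exceptions)

    def __call__(self, token: str) -> str:
        if token in self.exceptions:
            return self.exceptions[token]
        t = token
        if t.endswith("ies") and len(t) > 4:
            return t[:-3] + "y"
        if t.endswith("sses"):
            return t[:-2]
        if t.endswith(("shes", "ches", "xes", "zes")) and len(t) > 4:
            return t[:-2]
        if t.endswith("s") and not t.endswith(("ss", "us", "'s")) and len(t) > 3:
            return t[:-1]
        for suf in ("ing", "ed"):
            if t.endswith(suf) and len(t) - len(suf) >= 3:
                stem = t[: -len(suf)]
                if len(stem) >= 4 and stem[-1] == stem[-2] and stem[-1] in _DOUBLED:
                    stem = stem[:-1]  # running -> run, stopped -> stop
                return stem
        return t


def normalize_tokens(text: str, lemmatizer: Callable[[str], str] | None = None) -> list[str]:
    """Lowercase, strip punctuation (apostrophes kept inside tokens),
    whitespace-tokenize, lemmatize.  Duplicates are kept."""
    if lemmatizer is None:
        lemmatizer = RuleLemmatizer()
    tokens = _TOKEN_RE.findall(text.lower())
    tokens = [t.strip("'") for t in tokens]
    return [lemmatizer(t) for t in tokens if t]


def _read_text_resource(name: str) -> list[str]:
    ref = importlib_resources.files("phenorisk.resources").joinpath(name)
    return [line.strip() for line in ref.read_text().splitlines() if line.strip()]


def default_stopwords() -> frozenset[str]:
    return frozenset(_read_text_resource("stopwords.txt"))


def default_placeholders() -> frozenset[str]:
    """UI placeholder strings the keyboard logger picks up without any typing."""
    return frozenset(_read_text_resource("placeholders.txt"))


@dataclass
class VocabSpec:
    lemmas: frozenset[str]
    stopwords: frozenset[str]
    placeholders: frozenset[str]
    min_users: int = 5


def _content_lines(
    lines: Iterable[MessageLine], placeholders: frozenset[str]
) -> list[MessageLine]:
    return [ln for ln in lines if ln.text.strip() and ln.text.strip() not in placeholders]


def build_vocab(
    corpus: Iterable[MessageLine],
    min_users: int = 5,
    stopwords: frozenset[str] | None = None,
    placeholders: frozenset[str] | None = None,
    lemmatizer: Callable[[str], str] | None = None,
) -> VocabSpec:
    """Vocabulary of lemmas surviving the stopword, placeholder and
    minimum-user filters.

    ``min_users`` counts distinct participants who ever used the lemma; the
    boundary is inclusive (a lemma used by exactly ``min_users`` people is
    kept).  The corpus must already be restricted to communication apps.
    """
    stopwords = default_stopwords() if stopwords is None else stopwords
    placeholders = default_placeholders() if placeholders is None else placeholders
    users: dict[str, set[str]] = {}
    for ln in _content_lines(corpus, placeholders):
        for tok in set(normalize_tokens(ln.text, lemmatizer)):
            users.setdefault(tok, set()).add(ln.participant_id)
    lemmas = frozenset(
        w for w, u in users.items() if w not in stopwords and len(u) >= min_users
    )
    return VocabSpec(lemmas, stopwords, placeholders, min_users)


def _day_tokens(
    lines: Iterable[MessageLine],
    placeholders: frozenset[str],
    lemmatizer: Callable[[str], str] | None,
) -> dict:
    """Day -> list of lemmatized token lists (one per line)."""
    per_day: dict = {}
    for ln in _content_lines(lines, placeholders):
        per_day.setdefault(ln.day, []).append(normalize_tokens(ln.text, lemmatizer))
    return per_day


def word_frequency_features(
    lines: Iterable[MessageLine],
    vocab: VocabSpec,
    lemmatizer: Callable[[str], str] | None = None,
) -> dict[str, float]:
    """Day-share frequency of each vocabulary lemma for one participant.

    A lemma appearing twice in one day still counts that day once; the
    denominator is the number of distinct days with any text.  Zero text
    days → empty dict.
    """
    per_day = _day_tokens(lines, vocab.placeholders, lemmatizer)
    if not per_day:
        return {}
    n_days = len(per_day)
    counts: dict[str, int] = {w: 0 for w in vocab.lemmas}
    for _, token_lists in per_day.items():
        seen = set().union(*[set(toks) for toks in token_lists]) if token_lists else set()
        for w in seen & vocab.lemmas:
            counts[w] += 1
    return {w: counts[w] / n_days for w in sorted(vocab.lemmas)}


@dataclass
class PhraseLexicon:
    """Risky-phrase list: (lemmatized phrase tokens, category, subcategory).

    The packaged lexicon is an openly reconstructed demonstration covering
    sex-related and drug-related categories with finer subcategories; the
    original study's list is not public, and the file is user-replaceable.
    """

    entries: list[tuple[tuple[str, ...], str, str]] = field(default_factory=list)

    @classmethod
    def from_rows(
        cls, rows: Iterable[dict], lemmatizer: Callable[[str], str] | None = None
    ) -> "PhraseLexicon":
        seen = set()
        entries = []
        for r in rows:
            toks = tuple(normalize_tokens(r["phrase"], lemmatizer))
            if not toks:
                continue
            key = (toks, r["category"], r.get("subcategory", ""))
            if key in seen:
                continue
            seen.add(key)
            entries.append((toks, r["category"], r.get("subcategory", "")))
        return cls(entries)

    @classmethod
    def from_csv(cls, path: str | Path, lemmatizer=None) -> "PhraseLexicon":
        with open(path, newline="") as fh:
            return cls.from_rows(csv.DictReader(fh), lemmatizer)

    @classmethod
    def default(cls, lemmatizer=None) -> "PhraseLexicon":
        ref = importlib_resources.files("phenorisk.resources").joinpath("risky_lexicon.csv")
        with ref.open(newline="") as fh:
            return cls.from_rows(csv.DictReader(fh), lemmatizer)

    @property
    def categories(self) -> list[str]:
        return sorted({c for _, c, _ in self.entries})


def _phrase_in(tokens: Sequence[str], phrase: tuple[str, ...]) -> bool:
    n, m = len(tokens), len(phrase)
    return any(tuple(tokens[i : i + m]) == phrase for i in range(n - m + 1))


def risky_phrase_features(
    lines: Iterable[MessageLine],
    lexicon: PhraseLexicon,
    lemmatizer: Callable[[str], str] | None = None,
    placeholders: frozenset[str] | None = None,
) -> dict[str, float]:
    """Day-share frequencies for phrases, categories and subcategories.

    A phrase matches a day when its full lemmatized token sequence occurs
    contiguously inside a single line that day (phrases never span lines).
    Keys: ``phrase:<tokens>``, ``category:<name>``, ``subcategory:<cat>/<sub>``.
    """
    placeholders = default_placeholders() if placeholders is None else placeholders
    per_day = _day_tokens(lines, placeholders, lemmatizer)
    n_days = len(per_day)
    phrase_days: dict[tuple[str, ...], set] = {p: set() for p, _, _ in lexicon.entries}
    for day, token_lists in per_day.items():
        for phrase in phrase_days:
            if any(_phrase_in(toks, phrase) for toks in token_lists):
                phrase_days[phrase].add(day)
    cat_days: dict[str, set] = {}
    sub_days: dict[str, set] = {}
    for phrase, cat, sub in lexicon.entries:
        cat_days.setdefault(cat, set()).update(phrase_days[phrase])
        if sub:
            sub_days.setdefault(f"{cat}/{sub}", set()).update(phrase_days[phrase])
    feats: dict[str, float] = {}
    for phrase, cat, sub in lexicon.entries:
        feats[f"phrase:{' '.join(phrase)}"] = (
            len(phrase_days[phrase]) / n_days if n_days else 0.0
        )
    for cat in sorted(cat_days):
        feats[f"category:{cat}"] = len(cat_days[cat]) / n_days if n_days else 0.0
    for sub in sorted(sub_days):
        feats[f"subcategory:{sub}"] = len(sub_days[sub]) / n_days if n_days else 0.0
    return feats


class CategoryDictionary:
    """Named categories of lowercase word patterns with optional terminal
    wildcard (``friend*`` matches ``friend``, ``friends``, ``friendly``).

    An open stand-in format for proprietary closed-vocabulary scoring
    dictionaries; the packaged file is a small demonstration dictionary.
    """

    def __init__(self, categories: dict[str, list[str]]):
        self.exact: dict[str, frozenset[str]] = {}
        self.prefixes: dict[str, tuple[str, ...]] = {}
        for name, patterns in categories.items():
            ex, pre = set(), []
            for p in patterns:
                p = p.lower()
                if "*" in p[:-1]:
                    raise ValueError(f"wildcard must be terminal: {p!r}")
                if p.endswith("*"):
                    pre.append(p[:-1])
                else:
                    ex.add(p)
            self.exact[name] = frozenset(ex)
            self.prefixes[name] = tuple(sorted(pre))

    @classmethod
    def from_json(cls, path: str | Path) -> "CategoryDictionary":
        with open(path) as fh:
            return cls(json.load(fh))

    @classmethod
    def default(cls) -> "CategoryDictionary":
        ref = importlib_resources.files("phenorisk.resources").joinpath("dictionary.json")
        return cls(json.loads(ref.read_text()))

    @property
    def names(self) -> list[str]:
        return sorted(self.exact)

    def matches(self, name: str, token: str) -> bool:
        return token in self.exact[name] or any(
            token.startswith(p) for p in self.prefixes[name]
        )


def dictionary_scores(
    lines: Iterable[MessageLine],
    dictionary: CategoryDictionary,
    placeholders: frozenset[str] | None = None,
) -> dict[str, float]:
    """Per-category daily token proportions, averaged over days.

    Daily score = matching tokens / total tokens that day; the participant
    feature is the unweighted mean over days with at least one token.
    Tokens are matched unlemmatized (wildcards absorb inflection).
    """
    placeholders = default_placeholders() if placeholders is None else placeholders
    identity = lambda t: t  # noqa: E731 — patterns match surface forms
    per_day = _day_tokens(lines, placeholders, identity)
    daily: dict[str, list[float]] = {name: [] for name in dictionary.names}
    for _, token_lists in per_day.items():
        tokens = [t for toks in token_lists for t in toks]
        if not tokens:
            continue
        for name in dictionary.names:
            n_hit = sum(dictionary.matches(name, t) for t in tokens)
            daily[name].append(n_hit / len(tokens))
    return {
        name: (float(np.mean(vals)) if vals else float("nan"))
        for name, vals in daily.items()
    }


class HashingEmbedder:
    """Deterministic signed token-hashing embedder (transformer stand-in).

    Each token is hashed (MD5, salted by the seed) to a bucket and a sign;
    a day's vector is the normalized signed bucket count.  Same text and
    seed always give the identical vector, which makes embedding features
    fully reproducible in tests; a real sentence encoder plugs in through
    the same ``embed(text) -> vector`` interface.
    """

    def __init__(self, dim: int = 64, seed: int = 0):
        if dim < 1:
            raise ValueError("dim must be positive")
        self.dim = dim
        self.seed = seed

    def embed(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dim, dtype=float)
        for tok in normalize_tokens(text, lemmatizer=lambda t: t):
            h = hashlib.md5(f"{self.seed}:{tok}".encode()).digest()
            bucket = int.from_bytes(h[:4], "little") % self.dim
            sign = 1.0 if h[4] % 2 == 0 else -1.0
            vec[bucket] += sign
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec

    __call__ = embed


def embed_days(
    lines: Iterable[MessageLine],
    embedder: HashingEmbedder | Callable[[str], np.ndarray] | None = None,
    placeholders: frozenset[str] | None = None,
) -> np.ndarray | None:
    """Average of per-day embeddings of the concatenated day text.

    Days with no tokens are skipped; no text days at all → None (the
    missing marker).
    """
    if embedder is None:
        embedder = HashingEmbedder()
    placeholders = default_placeholders() if placeholders is None else placeholders
    per_day: dict = {}
    for ln in _content_lines(lines, placeholders):
        per_day.setdefault(ln.day, []).append(ln.text)
    embed = embedder.embed if hasattr(embedder, "embed") else embedder
    day_vecs = []
    for day in sorted(per_day):
        text = " ".join(per_day[day])
        if normalize_tokens(text, lemmatizer=lambda t: t):
            day_vecs.append(embed(text))
    if not day_vecs:
        return None
    return np.mean(np.stack(day_vecs), axis=0)
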