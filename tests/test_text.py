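"""Tokenization, vocabulary, and the four text feature families."""

import numpy as np
import pytest

from phenorisk.text import (
    CategoryDictionary,
    HashingEmbedder,
    PhraseLexicon,
    RuleLemmatizer,
    build_vocab,
    dictionary_scores,
    embed_days,
    normalize_tokens,
    risky_phrase_features,
    word_frequency_features,
)


class TestNormalizeTokens:
    def test_lemmatized_examples(self):
        assert normalize_tokens("Walking better!") == ["walk", "good"]

    def test_empty(self):
        assert normalize_tokens("") == []

    def test_duplicates_kept(self):
        assert normalize_tokens("hello hello") == ["hello", "hello"]

    def test_apostrophes_kept_inside_tokens(self):
        assert normalize_tokens("don't stop", lemmatizer=lambda t: t) == ["don't", "stop"]

    def test_punctuation_stripped(self):
        assert normalize_tokens("hey!!! (you)", lemmatizer=lambda t: t) == ["hey", "you"]


class TestRuleLemmatizer:
    @pytest.mark.parametrize(
        "word,lemma",
        [
            ("walking", "walk"),
            ("better", "good"),
            ("parties", "party"),
            ("stopped", "stop"),
            ("cats", "cat"),
            ("glasses", "glass"),
            ("run", "run"),
        ],
    )
    def test_cases(self, word, lemma):
        assert RuleLemmatizer()(word) == lemma


class TestBuildVocab:
    def _corpus(self, make_line, word, n_users):
        return [make_line(f"{word} filler", pid=f"P{i}") for i in range(n_users)]

    def test_min_users_boundary(self, make_line):
        corpus = self._corpus(make_line, "zebra", 4) + self._corpus(make_line, "yak", 5)
        vocab = build_vocab(corpus, min_users=5)
        assert "yak" in vocab.lemmas
        assert "zebra" not in vocab.lemmas

    def test_placeholder_never_enters(self, make_line):
        corpus = [make_line("Enter message", pid=f"P{i}") for i in range(10)]
        vocab = build_vocab(corpus, min_users=1)
        assert "enter" not in vocab.lemmas and "message" not in vocab.lemmas

    def test_stopwords_excluded(self, make_line):
        corpus = [make_line("the cat", pid=f"P{i}") for i in range(6)]
        vocab = build_vocab(corpus, min_users=5)
        assert "the" not in vocab.lemmas and "cat" in vocab.lemmas

    def test_empty_corpus(self):
        assert build_vocab([], min_users=5).lemmas == frozenset()


class TestWordFrequency:
    def test_day_share(self, make_line):
        vocab = build_vocab(
            [make_line("cat dog", pid=f"P{i}") for i in range(5)], min_users=5
        )
        lines = [make_line("cat", day=1), make_line("cat", day=2)]
        lines += [make_line("dog", day=d) for d in range(1, 9)]
        freq = word_frequency_features(lines, vocab)
        assert freq["cat"] == pytest.approx(2 / 8)
        assert freq["dog"] == pytest.approx(1.0)

    def test_twice_in_one_day_counts_once(self, make_line):
        vocab = build_vocab([make_line("cat x", pid=f"P{i}") for i in range(5)], min_users=5)
        lines = [make_line("cat cat cat", day=1), make_line("x", day=2)]
        freq = word_frequency_features(lines, vocab)
        assert freq["cat"] == pytest.approx(0.5)

    def test_zero_text_days_empty(self, make_line):
        vocab = build_vocab([make_line("cat", pid=f"P{i}") for i in range(5)], min_users=5)
        assert word_frequency_features([], vocab) == {}

    def test_brute_force_recount(self, make_line):
        rng = np.random.default_rng(2)
        words = ["alpha", "bravo", "charlie", "delta"]
        lines, day_words = [], {}
        for day in range(1, 11):
            chosen = [w for w in words if rng.random() < 0.5] or ["alpha"]
            day_words[day] = set(chosen)
            lines.append(make_line(" ".join(chosen), day=day))
        vocab = build_vocab(
            [make_line(" ".join(words), pid=f"P{i}") for i in range(5)], min_users=5
        )
        freq = word_frequency_features(lines, vocab)
        for w in words:
            expected = sum(w in s for s in day_words.values()) / 10
            assert freq[w] == pytest.approx(expected)


class TestRiskyPhrases:
    @pytest.fixture
    def lexicon(self):
        return PhraseLexicon.from_rows(
            [
                {"phrase": "party and play", "category": "drug_related", "subcategory": "party"},
                {"phrase": "tina", "category": "drug_related", "subcategory": "stimulant"},
                {"phrase": "hookup", "category": "sex_related", "subcategory": ""},
            ]
        )

    def test_phrase_must_be_contiguous_within_line(self, make_line, lexicon):
        lines = [make_line("party and", day=1), make_line("play", day=1)]
        feats = risky_phrase_features(lines, lexicon)
        assert feats["phrase:party and play"] == 0.0

    def test_category_day_union(self, make_line, lexicon):
        lines = [make_line("going to party and play", day=1)]
        lines += [make_line("got tina", day=d) for d in (2, 3)]
        lines += [make_line("nothing here", day=d) for d in range(4, 11)]
        feats = risky_phrase_features(lines, lexicon)
        assert feats["category:drug_related"] == pytest.approx(0.3)
        assert feats["subcategory:drug_related/party"] == pytest.approx(0.1)

    def test_absent_phrase_zero(self, make_line, lexicon):
        feats = risky_phrase_features([make_line("hello there", day=1)], lexicon)
        assert feats["phrase:hookup"] == 0.0
        assert feats["category:sex_related"] == 0.0

    def test_inflected_form_matches_lemmatized_phrase(self, make_line, lexicon):
        feats = risky_phrase_features([make_line("looking for hookups", day=1)], lexicon)
        assert feats["phrase:hookup"] == 1.0


class TestDictionaryScores:
    @pytest.fixture
    def dictionary(self):
        return CategoryDictionary({"social": ["friend*", "party"], "affect": ["happy"]})

    def test_daily_proportion(self, make_line, dictionary):
        scores = dictionary_scores([make_line("my friend was here", day=1)], dictionary)
        assert scores["social"] == pytest.approx(0.25)

    def test_wildcard_matches_inflections(self, make_line, dictionary):
        scores = dictionary_scores([make_line("friends friendly fiend", day=1)], dictionary)
        assert scores["social"] == pytest.approx(2 / 3)

    def test_mean_over_days(self, make_line, dictionary):
        lines = [
            make_line("happy sad mad bad x", day=1),   # 1/5
            make_line("happy happy glum glum glum", day=2),  # 2/5... see below
        ]
        # day 1: 1 of 5 tokens matches affect; day 2: 2 of 5
        scores = dictionary_scores(lines, dictionary)
        assert scores["affect"] == pytest.approx((0.2 + 0.4) / 2)

    def test_nonterminal_wildcard_rejected(self):
        with pytest.raises(ValueError):
            CategoryDictionary({"bad": ["fr*end"]})


class TestEmbedding:
    def test_single_day_equals_day_vector(self, make_line):
        emb = HashingEmbedder(dim=16, seed=1)
        lines = [make_line("hello world", day=1)]
        vec = embed_days(lines, emb)
        assert np.allclose(vec, emb.embed("hello world"))

    def test_two_days_average(self, make_line):
        emb = HashingEmbedder(dim=16, seed=1)
        lines = [make_line("aaa bbb", day=1), make_line("ccc ddd", day=2)]
        vec = embed_days(lines, emb)
        expected = (emb.embed("aaa bbb") + emb.embed("ccc ddd")) / 2
        assert np.allclose(vec, expected)

    def test_deterministic(self, make_line):
        lines = [make_line("same text here", day=1)]
        v1 = embed_days(lines, HashingEmbedder(dim=32, seed=7))
        v2 = embed_days(lines, HashingEmbedder(dim=32, seed=7))
        assert np.array_equal(v1, v2)
        v3 = embed_days(lines, HashingEmbedder(dim=32, seed=8))
        assert not np.array_equal(v1, v3)

    def test_no_text_days_missing(self):
        assert embed_days([], HashingEmbedder(dim=8)) is None


def test_frequency_features_all_bounded(make_line):
    rng = np.random.default_rng(9)
    pool = ["cat", "dog", "fish", "bird", "tina", "hookup"]
    lines = [
        make_line(" ".join(rng.choice(pool, size=4)), day=int(rng.integers(1, 12)))
        for _ in range(40)
    ]
    lex = PhraseLexicon.default()
    feats = risky_phrase_features(lines, lex)
    assert all(0.0 <= v <= 1.0 for v in feats.values())
    vocab = build_vocab([make_line(" ".join(pool), pid=f"P{i}") for i in range(5)], min_users=5)
    wf = word_frequency_features(lines, vocab)
    assert all(0.0 <= v <= 1.0 for v in wf.values())
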