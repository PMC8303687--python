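"""Synthetic-world generator: embedding clusters, corpora, style pairs."""

from dataclasses import replace

import numpy as np
import pytest

from flavorlex.corpus import segment_and_tag
from flavorlex.exceptions import ValidationError
from flavorlex.sequences import instances_from_gold, sentence_words
from flavorlex.synthetic import (SynthConfig, build_vocabulary,
                                 generate_corpus, generate_embedding_space,
                                 generate_style_pair, make_tagger)


class TestEmbeddingSpace:
    def test_shapes_and_labels(self, small_world):
        store, labels = (small_world["store"], small_world["type_labels"])
        cfg = small_world["config"]
        for token in list(store.table)[:20]:
            assert store.table[token].shape == (cfg.embedding_dim,)
        assert set(labels.values()) <= {0, 1}
        assert sum(labels.values()) == cfg.n_descriptor_types

    def test_same_seed_identical_store(self, small_config):
        s1, _ = generate_embedding_space(small_config)
        s2, _ = generate_embedding_space(small_config)
        for token in s1.table:
            np.testing.assert_array_equal(s1.table[token], s2.table[token])

    def test_separation_zero_collapses_clusters(self):
        cfg = SynthConfig(n_descriptor_types=200, n_nondescriptor_types=200,
                          embedding_dim=12, separation=0.0, seed=3)
        store, labels = generate_embedding_space(cfg)
        pos = np.stack([store.table[t] for t, l in labels.items() if l == 1])
        neg = np.stack([store.table[t] for t, l in labels.items() if l == 0])
        gap = np.linalg.norm(pos.mean(axis=0) - neg.mean(axis=0))
        assert gap < 0.5  # within sampling noise of a single cloud

    def test_separation_matches_request(self):
        cfg = SynthConfig(n_descriptor_types=300, n_nondescriptor_types=300,
                          embedding_dim=16, separation=4.0, seed=4)
        store, labels = generate_embedding_space(cfg)
        pos = np.stack([store.table[t] for t, l in labels.items() if l == 1])
        neg = np.stack([store.table[t] for t, l in labels.items() if l == 0])
        gap = np.linalg.norm(pos.mean(axis=0) - neg.mean(axis=0))
        assert gap == pytest.approx(4.0, abs=0.5)


class TestCorpus:
    def test_same_seed_identical_corpus(self, small_config):
        r1, g1 = generate_corpus(small_config)
        r2, g2 = generate_corpus(small_config)
        assert [r.text for r in r1] == [r.text for r in r2]
        assert g1 == g2

    def test_zero_density_means_no_positives(self):
        cfg = SynthConfig(n_reviews=20, descriptor_density=0.0, seed=5,
                          n_descriptor_types=10, n_nondescriptor_types=10,
                          embedding_dim=8)
        _, gold = generate_corpus(cfg)
        assert set(gold.values()) == {0}

    def test_positive_count_within_binomial_bound(self, small_world):
        gold = small_world["gold"]
        n = len(gold)
        observed = sum(gold.values())
        expected = 0.44 * n
        sd = np.sqrt(n * 0.44 * 0.56)
        assert abs(observed - expected) <= 3 * sd

    def test_gold_covers_every_word_token(self, small_world):
        tokens = {r.review_id: segment_and_tag(r, small_world["tagger"])
                  for r in small_world["reviews"]}
        n_words = sum(len(s) for toks in tokens.values()
                      for s in sentence_words(toks).values())
        assert n_words == len(small_world["gold"])

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            SynthConfig(descriptor_density=1.5)
        with pytest.raises(ValidationError):
            SynthConfig(separation=-1)
        with pytest.raises(ValidationError):
            SynthConfig(sentence_length=(5, 3))


@pytest.fixture(scope="module")
def amb_world():
    cfg = SynthConfig(n_descriptor_types=40, n_nondescriptor_types=60,
                      n_reviews=150, embedding_dim=12,
                      ambiguous_fraction=0.5, seed=9)
    vocab = build_vocabulary(cfg)
    reviews, gold = generate_corpus(cfg, vocab)
    return cfg, vocab, reviews, gold


class TestAmbiguousMode:

    def test_ambiguous_occurrences_carry_both_labels(self, amb_world):
        cfg, vocab, reviews, gold = amb_world
        tokens = {r.review_id: segment_and_tag(r, make_tagger(vocab))
                  for r in reviews}
        instances = instances_from_gold(tokens, gold)
        by_type: dict[str, set[int]] = {}
        for inst in instances:
            if inst.token_type.startswith("ambig"):
                by_type.setdefault(inst.token_type, set()).add(inst.label)
        both = [t for t, labels in by_type.items() if labels == {0, 1}]
        assert len(both) > 0

    def test_cued_iff_positive(self, amb_world):
        """Ambiguous tokens are gold-positive exactly when a full cue phrase
        immediately precedes them (a lone "of" from ordinary function-word
        sampling is not a cue)."""
        cfg, vocab, reviews, gold = amb_world
        cue_seqs = [p.split() for p in vocab.cue_phrases]
        tagger = make_tagger(vocab)
        checked = 0
        for r in reviews:
            sentences = sentence_words(segment_and_tag(r, tagger))
            for s_idx, sent in sentences.items():
                words = [t.surface for t in sent]
                for tok in sent:
                    if not tok.surface.startswith("ambig"):
                        continue
                    i = tok.filtered_position
                    cued = any(words[max(0, i - len(seq)):i] == seq
                               for seq in cue_seqs)
                    label = gold[(r.review_id, s_idx, i)]
                    assert label == (1 if cued else 0)
                    checked += 1
        assert checked > 50


@pytest.fixture(scope="module")
def pair():
    cfg = SynthConfig(n_descriptor_types=30, n_nondescriptor_types=40,
                      n_reviews=60, embedding_dim=10,
                      ambiguous_fraction=0.4, seed=17)
    return generate_style_pair(cfg)


class TestStylePair:

    def test_descriptor_vocabulary_shared(self, pair):
        vocab_a = {w for r in pair.reviews_a for w in r.text.replace(".", "").split()}
        vocab_b = {w for r in pair.reviews_b for w in r.text.replace(".", "").split()}
        descriptors = set(pair.vocab.descriptor_types)
        assert vocab_a & descriptors and vocab_b & descriptors
        assert (vocab_a & descriptors) & (vocab_b & descriptors)

    def test_cue_inventories_disjoint_on_content_words(self, pair):
        from flavorlex.synthetic import FUNCTION_WORDS
        cues_a = {w for p in pair.config_a.cue_phrases for w in p.split()}
        cues_b = {w for p in pair.config_b.cue_phrases for w in p.split()}
        assert not (cues_a & cues_b) - set(FUNCTION_WORDS)

    def test_store_embeds_both_corpora(self, pair):
        for reviews in (pair.reviews_a, pair.reviews_b):
            for r in reviews[:10]:
                for w in r.text.replace(".", "").split():
                    assert w in pair.store

    def test_styles_differ_in_sentence_length(self, pair):
        def mean_len(reviews):
            lens = [len(s.split()) for r in reviews
                    for s in r.text.split(".") if s.strip()]
            return np.mean(lens)
        assert mean_len(pair.reviews_b) > mean_len(pair.reviews_a) + 1
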