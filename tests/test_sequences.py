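"""Instance indexing, context windows, example assembly, and splitting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from flavorlex.annotation import LabeledTokenType
from flavorlex.corpus import Review, segment_and_tag
from flavorlex.embeddings import PAD
from flavorlex.exceptions import ValidationError
from flavorlex.sequences import (assemble_examples, class_ratio,
                                 examples_to_arrays, extract_context,
                                 index_instances, instances_from_gold,
                                 read_instance_table, sentence_words,
                                 split_examples, type_overlap_fraction,
                                 write_instance_table)


def naive_context(sentence, position, n):
    """Brute-force oracle: slice then pad explicitly."""
    before = [sentence[i] if i >= 0 else PAD
              for i in range(position - n, position)]
    after = [sentence[i] if i < len(sentence) else PAD
             for i in range(position + 1, position + 1 + n)]
    return before, after


class TestExtractContext:
    def test_sentence_initial_word_has_all_pad_before(self):
        before, after = extract_context(["rich", "sweet", "vanilla"], 0, 3)
        assert before == [PAD, PAD, PAD]
        assert after == ["sweet", "vanilla", PAD]

    def test_single_token_sentence_all_pad(self):
        before, after = extract_context(["vanilla"], 0, 3)
        assert before == [PAD] * 3 and after == [PAD] * 3

    def test_mid_sentence_full_window(self):
        sentence = ["rich", "sweet", "vanilla", "cream", "finish", "lingers", "nicely"]
        before, after = extract_context(sentence, 3, 3)
        assert before == ["rich", "sweet", "vanilla"]
        assert after == ["finish", "lingers", "nicely"]

    def test_position_out_of_range(self):
        with pytest.raises(IndexError):
            extract_context(["a", "b"], 2, 3)

    @given(st.integers(1, 12), st.integers(1, 5), st.data())
    def test_agrees_with_naive_oracle(self, length, n, data):
        sentence = [f"w{i}" for i in range(length)]
        position = data.draw(st.integers(0, length - 1))
        assert extract_context(sentence, position, n) == \
            naive_context(sentence, position, n)


class TestIndexing:
    def test_occurrences_counted_across_reviews(self):
        reviews = [Review("r1", "Sweet vanilla. Vanilla cream."),
                   Review("r2", "More vanilla here.")]
        tokens = {r.review_id: segment_and_tag(r) for r in reviews}
        types = {"vanilla": LabeledTokenType("vanilla", "vanilla", 1)}
        instances = index_instances(tokens, types)
        assert len(instances) == 3
        assert len({(i.review_id, i.sentence_index, i.filtered_position)
                    for i in instances}) == 3

    def test_absent_type_yields_no_instances(self):
        tokens = {"r": segment_and_tag(Review("r", "Sweet vanilla."))}
        assert index_instances(
            tokens, {"oak": LabeledTokenType("oak", "oak", 1)}) == []

    def test_addresses_round_trip_to_surfaces(self, small_world):
        tokens = {r.review_id: segment_and_tag(r, small_world["tagger"])
                  for r in small_world["reviews"][:10]}
        gold = {k: v for k, v in small_world["gold"].items() if k[0] in tokens}
        for inst in instances_from_gold(tokens, gold):
            sent = sentence_words(tokens[inst.review_id])[inst.sentence_index]
            assert sent[inst.filtered_position].surface.lower() == inst.token_type

    def test_instance_table_round_trip(self, tmp_path):
        tokens = {"r1": segment_and_tag(Review("r1", "Sweet vanilla."))}
        instances = index_instances(
            tokens, {"vanilla": LabeledTokenType("vanilla", "vanilla", 1)})
        p = tmp_path / "instances.csv"
        write_instance_table(instances, p)
        loaded = read_instance_table(p)
        assert [(i.token_type, i.review_id, i.sentence_index,
                 i.filtered_position, i.label) for i in loaded] == \
               [(i.token_type, i.review_id, i.sentence_index,
                 i.filtered_position, i.label) for i in instances]


class TestAssembly:
    def test_counts_and_shapes(self, small_examples, small_world):
        d = small_world["config"].embedding_dim
        gold = small_world["gold"]
        assert len(small_examples) == len(gold)
        for e in small_examples[:50]:
            assert e.context_vectors.shape == (6, d)
            assert e.word_vector.shape == (d,)

    def test_sentence_initial_instance_has_zero_leading_context(self, small_examples):
        first = [e for e in small_examples if e.provenance.filtered_position == 0]
        assert first, "expected sentence-initial instances in the fixture"
        for e in first[:20]:
            assert np.all(e.context_vectors[:3] == 0)

    def test_arrays_shapes(self, small_examples):
        x_ctx, x_word, y = examples_to_arrays(small_examples)
        n, d = len(small_examples), small_examples[0].word_vector.shape[0]
        assert x_ctx.shape == (n, 6, d)
        assert x_word.shape == (n, 1, d)
        assert set(np.unique(y)) <= {0, 1}


class TestSplit:
    def test_sizes_80_20(self, small_examples):
        examples = small_examples[:100]
        train, test = split_examples(examples, 0.2, seed=3)
        assert (len(train), len(test)) == (80, 20)

    def test_same_seed_identical_partition(self, small_examples):
        a = split_examples(small_examples, 0.2, seed=11)
        b = split_examples(small_examples, 0.2, seed=11)
        assert [id(e) for e in a[0]] == [id(e) for e in b[0]]
        assert [id(e) for e in a[1]] == [id(e) for e in b[1]]

    def test_partition_disjoint_and_exhaustive(self, small_examples):
        train, test = split_examples(small_examples, 0.25, seed=5)
        ids_train = {id(e) for e in train}
        ids_test = {id(e) for e in test}
        assert not ids_train & ids_test
        assert ids_train | ids_test == {id(e) for e in small_examples}

    def test_fraction_bounds(self, small_examples):
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValidationError):
                split_examples(small_examples, bad, seed=0)

    def test_type_level_split_separates_types(self, small_examples):
        train, test = split_examples(small_examples, 0.2, seed=5, level="type")
        assert type_overlap_fraction(train, test) == 0.0
        assert len(train) + len(test) == len(small_examples)

    def test_instance_level_overlap_is_high(self, small_examples):
        train, test = split_examples(small_examples, 0.2, seed=5)
        assert type_overlap_fraction(train, test) > 0.5


class TestClassRatio:
    def test_known_counts(self, small_examples):
        pos, neg = class_ratio(small_examples[:25])
        k = sum(e.label for e in small_examples[:25])
        assert pos == pytest.approx(k / 25)
        assert pos + neg == pytest.approx(1.0)

    def test_all_positive_boundary(self, small_examples):
        positives = [e for e in small_examples if e.label == 1][:10]
        assert class_ratio(positives) == (1.0, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            class_ratio([])

    def test_density_targets_44_percent(self, small_examples):
        """Generator at density 0.44 produces ~44% positive instances."""
        pos, _ = class_ratio(small_examples)
        n = len(small_examples)
        tol = 3 * np.sqrt(0.44 * 0.56 / n)
        assert abs(pos - 0.44) < max(tol, 0.03)
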