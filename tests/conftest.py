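"""Shared fixtures: small synthetic worlds exercising the full pipeline."""

from dataclasses import replace

import pytest
from hypothesis import settings

from flavorlex.corpus import segment_and_tag
from flavorlex.sequences import assemble_examples, instances_from_gold
from flavorlex.synthetic import (SynthConfig, build_vocabulary,
                                 generate_corpus, generate_embedding_space,
                                 make_tagger)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """A small, well-separated synthetic world (seconds to generate)."""
    return SynthConfig(n_descriptor_types=40, n_nondescriptor_types=60,
                       n_reviews=80, separation=4.0, embedding_dim=16, seed=7)


@pytest.fixture(scope="session")
def small_world(small_config):
    """(config, vocab, store, type_labels, reviews, gold, tagger)."""
    vocab = build_vocabulary(small_config)
    store, type_labels = generate_embedding_space(small_config, vocab)
    reviews, gold = generate_corpus(replace(small_config, seed=8), vocab)
    return {
        "config": small_config, "vocab": vocab, "store": store,
        "type_labels": type_labels, "reviews": reviews, "gold": gold,
        "tagger": make_tagger(vocab),
    }


@pytest.fixture(scope="session")
def small_examples(small_world):
    """Assembled SequenceExamples for the small world (n = 3 context)."""
    tokens_by_review = {
        r.review_id: segment_and_tag(r, small_world["tagger"])
        for r in small_world["reviews"]
    }
    instances = instances_from_gold(tokens_by_review, small_world["gold"])
    examples = assemble_examples(instances, tokens_by_review,
                                 small_world["store"], n=3)
    return examples
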