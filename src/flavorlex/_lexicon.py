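"""Small built-in English lexicon for the rule-based fallback tagger.

Maps lowercase lemmas to coarse universal POS tags. This is intentionally a
starter vocabulary (function words plus common whisky tasting-note terms);
synthetic corpora supply their own exact lexicons, and real deployments are
expected to bind a statistical tagger through the ``PosTagger`` protocol.
"""

DEFAULT_LEXICON: dict[str, str] = {
    # determiners / pronouns / conjunctions / adpositions
    "the": "DET", "a": "DET", "an": "DET", "this": "DET", "that": "DET",
    "these": "DET", "those": "DET", "some": "DET", "any": "DET", "no": "DET",
    "i": "PRON", "you": "PRON", "he": "PRON", "she": "PRON", "it": "PRON",
    "we": "PRON", "they": "PRON", "its": "PRON", "my": "PRON", "your": "PRON",
    "and": "CCONJ", "or": "CCONJ", "but": "CCONJ", "nor": "CCONJ",
    "of": "ADP", "in": "ADP", "on": "ADP", "with": "ADP", "at": "ADP",
    "by": "ADP", "from": "ADP", "to": "ADP", "into": "ADP", "over": "ADP",
    "under": "ADP", "through": "ADP", "as": "ADP", "for": "ADP",
    "if": "SCONJ", "while": "SCONJ", "because": "SCONJ", "than": "SCONJ",
    # auxiliaries / common verbs
    "be": "AUX", "is": "AUX", "are": "AUX", "was": "AUX", "were": "AUX",
    "been": "AUX", "am": "AUX", "has": "AUX", "have": "AUX", "had": "AUX",
    "do": "AUX", "does": "AUX", "did": "AUX", "will": "AUX", "would": "AUX",
    "can": "AUX", "could": "AUX", "may": "AUX", "might": "AUX",
    "get": "VERB", "give": "VERB", "take": "VERB", "make": "VERB",
    "come": "VERB", "go": "VERB", "open": "VERB", "linger": "VERB",
    "fade": "VERB", "develop": "VERB", "lead": "VERB", "follow": "VERB",
    "taste": "VERB", "smell": "VERB", "drink": "VERB", "pour": "VERB",
    "find": "VERB", "note": "NOUN", "think": "VERB", "say": "VERB",
    # adverbs / particles
    "not": "PART", "very": "ADV", "quite": "ADV", "really": "ADV",
    "slightly": "ADV", "nicely": "ADV", "well": "ADV", "here": "ADV",
    "there": "ADV", "then": "ADV", "also": "ADV", "just": "ADV",
    "more": "ADV", "most": "ADV", "too": "ADV", "so": "ADV",
    # tasting-note adjectives
    "sweet": "ADJ", "dry": "ADJ", "smoky": "ADJ", "peaty": "ADJ",
    "rich": "ADJ", "spicy": "ADJ", "fruity": "ADJ", "floral": "ADJ",
    "oaky": "ADJ", "creamy": "ADJ", "smooth": "ADJ", "bitter": "ADJ",
    "sour": "ADJ", "salty": "ADJ", "nutty": "ADJ", "malty": "ADJ",
    "herbal": "ADJ", "earthy": "ADJ", "buttery": "ADJ", "light": "ADJ",
    "dark": "ADJ", "long": "ADJ", "short": "ADJ", "warm": "ADJ",
    "young": "ADJ", "old": "ADJ", "new": "ADJ", "good": "ADJ",
    "great": "ADJ", "fine": "ADJ", "complex": "ADJ", "balanced": "ADJ",
    "medicinal": "ADJ", "briny": "ADJ", "waxy": "ADJ", "tart": "ADJ",
    "crisp": "ADJ", "mellow": "ADJ", "robust": "ADJ", "delicate": "ADJ",
    # tasting-note nouns
    "vanilla": "NOUN", "caramel": "NOUN", "honey": "NOUN", "oak": "NOUN",
    "smoke": "NOUN", "peat": "NOUN", "fruit": "NOUN", "apple": "NOUN",
    "pear": "NOUN", "orange": "NOUN", "lemon": "NOUN", "cherry": "NOUN",
    "raisin": "NOUN", "fig": "NOUN", "date": "NOUN", "plum": "NOUN",
    "banana": "NOUN", "coconut": "NOUN", "almond": "NOUN", "walnut": "NOUN",
    "hazelnut": "NOUN", "chocolate": "NOUN", "coffee": "NOUN",
    "toffee": "NOUN", "butterscotch": "NOUN", "molasses": "NOUN",
    "maple": "NOUN", "cream": "NOUN", "butter": "NOUN", "bread": "NOUN",
    "toast": "NOUN", "cereal": "NOUN", "malt": "NOUN", "barley": "NOUN",
    "corn": "NOUN", "rye": "NOUN", "wheat": "NOUN", "grain": "NOUN",
    "spice": "NOUN", "cinnamon": "NOUN", "nutmeg": "NOUN", "clove": "NOUN",
    "ginger": "NOUN", "pepper": "NOUN", "anise": "NOUN", "licorice": "NOUN",
    "mint": "NOUN", "leather": "NOUN", "tobacco": "NOUN", "tar": "NOUN",
    "iodine": "NOUN", "brine": "NOUN", "salt": "NOUN", "seaweed": "NOUN",
    "sherry": "NOUN", "wine": "NOUN", "port": "NOUN", "bourbon": "NOUN",
    "whisky": "NOUN", "whiskey": "NOUN", "scotch": "NOUN", "dram": "NOUN",
    "cask": "NOUN", "barrel": "NOUN", "wood": "NOUN", "char": "NOUN",
    "finish": "NOUN", "palate": "NOUN", "nose": "NOUN", "mouth": "NOUN",
    "body": "NOUN", "aroma": "NOUN", "flavor": "NOUN", "year": "NOUN",
    "bottle": "NOUN", "glass": "NOUN", "water": "NOUN", "ice": "NOUN",
    "review": "NOUN", "hint": "NOUN", "touch": "NOUN", "wave": "NOUN",
    "aftertaste": "NOUN", "citrus": "NOUN", "sugar": "NOUN", "syrup": "NOUN",
}
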