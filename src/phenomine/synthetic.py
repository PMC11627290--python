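"""Synthetic abstract corpora with known ground truth.

Downstream stages — matching, filtering, enrichment, normalization,
clustering — are all statistical procedures over a huge third-party corpus
that cannot ship with a package. This module generates corpora whose
structure is known exactly, so every stage can be validated against planted
truth: per-term enrichment factors in "aging" abstracts, co-occurrence
blocks of terms driven by a shared latent switch, synonym usage, and filler
vocabulary guaranteed disjoint from all dictionary surface forms.

Generative model, per abstract:

1. draw an aging flag ~ Bernoulli(keyword_rate);
2. for each co-occurrence block, draw a latent activation
   ~ Bernoulli(block_activation_rate); each member term is then present with
   probability ``block_member_prob`` given activation;
3. independently, each term is present with probability
   ``base_rate * (enrichment_factor if aging flag else 1)``, clipped to 1;
4. the text embeds one surface form per planted mention (a random synonym
   with probability ``synonym_use_rate``, else the canonical form), one
   aging-keyword surface form when the flag is set, and seeded distractor
   tokens, all inside fixed sentence templates so multi-word forms are never
   split by punctuation.

The same spec and seed reproduce the corpus byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import Abstract, Corpus, TermDictionary, TermEntry

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "default_aging_keywords",
    "generate_corpus",
    "annotate_gold",
]


def default_aging_keywords() -> TermDictionary:
    """The default 12-keyword dictionary marking abstracts as aging-related.

    Users studying a real corpus supply their own keyword dictionary; this
    default covers the standard gerontological vocabulary ("aging" and the
    British "ageing" spelling, life-stage words, and common cohort
    descriptors).
    """
    keywords = [
        ("aging", ["aging related", "aging-related"]),
        ("ageing", ["ageing related", "ageing-related"]),
        ("aged", []),
        ("old age", []),
        ("older adults", []),
        ("elderly", []),
        ("geriatric", []),
        ("gerontology", []),
        ("senescence", []),
        ("senior citizens", []),
        ("retirement", ["retired"]),
        ("oldest old", []),
    ]
    return TermDictionary(
        [TermEntry(c, syns) for c, syns in keywords], name="aging_keywords"
    )


@dataclass
class SyntheticSpec:
    """Parameters of the generative model (all probabilities in [0, 1])."""

    n_abstracts: int
    keyword_rate: float = 0.02
    term_base_rate: dict[str, float] = field(default_factory=dict)
    enrichment_factor: dict[str, float] = field(default_factory=dict)
    blocks: list[list[str]] = field(default_factory=list)
    block_activation_rate: float = 0.05
    block_member_prob: float = 0.8
    synonym_use_rate: float = 0.3
    distractor_vocab_size: int = 500
    seed: int = 0

    def validate(self, dictionary: TermDictionary) -> None:
        if self.n_abstracts <= 0:
            raise ValueError("n_abstracts must be positive")
        probs = [
            self.keyword_rate,
            self.block_activation_rate,
            self.block_member_prob,
            self.synonym_use_rate,
            *self.term_base_rate.values(),
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if any(e < 0 for e in self.enrichment_factor.values()):
            raise ValueError("enrichment factors must be non-negative")
        for term in self.term_base_rate:
            if term not in dictionary:
                raise ValueError(f"term {term!r} has a base rate but is not in the dictionary")
        seen: set[str] = set()
        for block in self.blocks:
            for term in block:
                if term not in dictionary:
                    raise ValueError(f"block term {term!r} not in the dictionary")
                if term in seen:
                    raise ValueError(f"term {term!r} appears in two blocks")
                seen.add(term)


@dataclass
class GroundTruth:
    """Everything the generator decided, for use as a gold standard."""

    keyword_flags: dict[str, bool]
    mentions: dict[str, dict[str, int]]  # abstract id -> term -> count
    enrichment: dict[str, float]
    blocks: list[list[str]]

    def gold_terms(self) -> dict[str, set[str]]:
        """Per-abstract planted term sets (presence level)."""
        return {aid: set(m) for aid, m in self.mentions.items()}


_TERM_TEMPLATES = [
    "We observed {} in the study population.",
    "Patients frequently presented with {}.",
    "The analysis revealed an association with {}.",
    "Cases of {} were recorded during follow-up.",
]

_KEYWORD_TEMPLATES = [
    "This work concerns {} populations.",
    "The cohort was recruited in the context of {}.",
]


def _distractor_vocab(size: int, dictionary: TermDictionary, keywords: TermDictionary) -> list[str]:
    forbidden = {
        w
        for d in (dictionary, keywords)
        for e in d
        for form in e.surface_forms
        for w in form.casefold().split()
    }
    vocab = []
    i = 0
    while len(vocab) < size:
        tok = f"zq{i:04d}x"
        if tok not in forbidden:
            vocab.append(tok)
        i += 1
    return vocab


def generate_corpus(
    spec: SyntheticSpec,
    dictionary: TermDictionary,
    keyword_dictionary: TermDictionary | None = None,
) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus plus its ground truth under the model above.

    ``dictionary`` supplies the clinical terms (those with a base rate are
    planted); ``keyword_dictionary`` the aging keywords (default: the
    built-in 12-keyword list). Every planted mention is literally present as
    a surface form in the abstract text.
    """
    spec.validate(dictionary)
    keywords = keyword_dictionary or default_aging_keywords()
    rng = np.random.default_rng(spec.seed)
    vocab = _distractor_vocab(spec.distractor_vocab_size, dictionary, keywords)

    term_block = {t: b for b, block in enumerate(spec.blocks) for t in block}
    terms = [t for t in dictionary.canonical_terms if t in spec.term_base_rate or t in term_block]
    base = np.array([spec.term_base_rate.get(t, 0.0) for t in terms])
    enr = np.array([spec.enrichment_factor.get(t, 1.0) for t in terms])
    kw_forms = [f for e in keywords for f in e.surface_forms]

    n, T, B = spec.n_abstracts, len(terms), len(spec.blocks)
    flags = rng.random(n) < spec.keyword_rate
    block_active = rng.random((n, B)) < spec.block_activation_rate if B else np.zeros((n, 0), bool)
    u_base = rng.random((n, T))
    u_block = rng.random((n, T))
    p_aging = np.minimum(base * enr, 1.0)

    abstracts: list[Abstract] = []
    mentions: dict[str, dict[str, int]] = {}
    keyword_flags: dict[str, bool] = {}
    for i in range(n):
        aid = f"S{i:07d}"
        p = p_aging if flags[i] else base
        present = u_base[i] < p
        for j, t in enumerate(terms):
            b = term_block.get(t)
            if b is not None and block_active[i, b] and u_block[i, j] < spec.block_member_prob:
                present[j] = True
        planted = {terms[j]: 1 for j in np.flatnonzero(present)}
        sentences: list[str] = []
        for term, count in planted.items():
            entry = dictionary[term]
            for _ in range(count):
                if entry.synonyms and rng.random() < spec.synonym_use_rate:
                    form = entry.synonyms[rng.integers(len(entry.synonyms))]
                else:
                    form = entry.canonical
                tmpl = _TERM_TEMPLATES[rng.integers(len(_TERM_TEMPLATES))]
                sentences.append(tmpl.format(form))
        if flags[i]:
            tmpl = _KEYWORD_TEMPLATES[rng.integers(len(_KEYWORD_TEMPLATES))]
            sentences.append(tmpl.format(kw_forms[rng.integers(len(kw_forms))]))
        n_filler = int(rng.integers(2, 6))
        filler = " ".join(vocab[rng.integers(len(vocab))] for _ in range(n_filler))
        sentences.append(f"Additional context: {filler}.")
        order = rng.permutation(len(sentences))
        text = " ".join(sentences[k] for k in order)
        abstracts.append(Abstract(aid, text))
        mentions[aid] = planted
        keyword_flags[aid] = bool(flags[i])

    truth = GroundTruth(
        keyword_flags=keyword_flags,
        mentions=mentions,
        enrichment={t: spec.enrichment_factor.get(t, 1.0) for t in terms},
        blocks=[list(b) for b in spec.blocks],
    )
    return Corpus(abstracts, source_label="synthetic"), truth


def annotate_gold(truth: GroundTruth, abstract_id: str) -> dict[str, int]:
    """Planted (term -> mention count) map for one abstract."""
    try:
        return dict(truth.mentions[abstract_id])
    except KeyError:
        raise KeyError(f"unknown abstract id {abstract_id!r}") from None
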