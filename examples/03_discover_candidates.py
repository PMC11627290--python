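"""Discover candidate terms in a selected sub-corpus from a big vocabulary.

After narrowing a corpus to abstracts with >=2 clinical terms and an aging
keyword, a large tagged vocabulary is mined for frequent terms; candidates
are dropped if mentioned fewer than 100 times, carry an uninformative
ontology tag (e.g. "procedure"), or look like a '/'-separated unit string.
"""

import phenomine as pm

big_vocab = pm.TermDictionary(
    [
        pm.TermEntry("frailty", semantic_tag="finding"),
        pm.TermEntry("sarcopenia", semantic_tag="disorder"),
        pm.TermEntry("appendectomy", semantic_tag="procedure"),
        pm.TermEntry("creatinine level", ["mg/dl"], semantic_tag="finding"),
        pm.TermEntry("rarely mentioned thing", semantic_tag="finding"),
    ]
)

# a sub-corpus in which the first four vocabulary terms are common
texts = (
    ["Elderly cohorts showed frailty and sarcopenia after appendectomy."] * 120
    + ["Creatinine level in mg/dl rose; frailty persisted."] * 60
    + ["A rarely mentioned thing occurred."] * 5
)
corpus = pm.Corpus([pm.Abstract(str(i), t) for i, t in enumerate(texts)])

candidates = pm.discover_candidates(corpus, big_vocab, min_count=100)
for c in sorted(candidates, key=lambda c: -c.total_count):
    status = "ACCEPTED" if c.accepted else f"rejected ({c.rejected_reason})"
    print(f"{c.canonical:25s} count={c.total_count:4d} tag={c.semantic_tag:10s} {status}")
print("\nOnly frequent, informative, unit-free terms survive as candidates.")
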