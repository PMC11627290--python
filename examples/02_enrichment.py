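"""Measure term enrichment in aging-keyword abstracts against a
resampling null.

Terms are planted with a 3-fold higher presence rate in aging-flagged
abstracts. The aging-count (keyword-positive abstracts containing the
term) is compared with the expected-count (mean over 100 equal-size random
subsets of the whole corpus); their ratio estimates the enrichment, and a
chi-squared test on the 2x2 presence x keyword table gives a p-value.
"""

import phenomine as pm

terms = [f"Clinical term {i:02d}" for i in range(8)]
dictionary = pm.TermDictionary([pm.TermEntry(t) for t in terms])

spec = pm.SyntheticSpec(
    n_abstracts=10_000,
    keyword_rate=0.05,
    term_base_rate={t: 0.02 for t in terms},
    enrichment_factor={t: (3.0 if i < 4 else 1.0) for i, t in enumerate(terms)},
    seed=11,
)
corpus, _ = pm.generate_corpus(spec, dictionary)

term_matrix = pm.build_presence_matrix(corpus, dictionary)
kw_matrix = pm.build_presence_matrix(corpus, pm.default_aging_keywords())
report = pm.filter_abstracts(term_matrix, kw_matrix, min_terms=0, require_keyword=False)

results = pm.run_enrichment(term_matrix, report.ids_keyword, n_resamples=100, seed=12)
print(f"{'term':18s} {'aging':>6s} {'expect':>7s} {'ratio':>6s} {'p':>9s}")
for r in results:
    print(f"{r.term:18s} {r.aging_count:6d} {r.expected_count:7.1f} "
          f"{r.ratio:6.2f} {r.p_value:9.2e}")
print("\nThe first four terms were planted 3-fold enriched: their ratios sit")
print("near 3 with small p-values; the null terms sit near 1.")
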