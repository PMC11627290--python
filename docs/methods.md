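# Methods

This note records the models, algorithmic conventions and design choices
behind phenomine, in the order the pipeline runs.

## Corpus and dictionary model

An abstract is an opaque identifier plus free text. When reading
MEDLINE/PubMed XML the text is the article title concatenated with all
abstract sections joined by single spaces; section labels are discarded.
Whether titles belong in the searched text is a corpus-construction
choice with no single right answer — titles are dense in disease terms
but are not "the abstract" — so it is a flag (`include_title`, default
on, the inclusive reading). Records with no abstract body keep the title
alone and simply match little.

A term dictionary maps canonical terms to surface forms (the canonical
label plus synonyms and spelling analogues, e.g. "Graying of hair" /
"Gray Hair"). All matching is surface-form based; a synonym match is
always counted toward its canonical term, so every downstream matrix and
statistic sees canonical terms only. Ambiguity — one surface form under
two canonicals — is rejected at load time rather than resolved silently,
because silent resolution would make counts depend on dictionary order.

The default aging-keyword list bundles 12 standard gerontological
keywords ("aging"/"ageing" with their "-related" variants, "aged", "old
age", "older adults", "elderly", "geriatric", "gerontology",
"senescence", "senior citizens", "retirement"/"retired", "oldest old").
It is a plain dictionary object and fully replaceable; any serious corpus
study should curate its own.

## Matching semantics

The matcher is an Aho–Corasick automaton over all surface forms, so one
pass over the text finds every occurrence of every form regardless of
dictionary size. Three conventions, all held in a `MatchProfile`:

* **case folding** (default on): "DEMENTIA" ≡ "dementia";
* **word boundaries** (default on): a match may not be flanked by letters
  or digits, so "dementia" does not fire inside "haemodementiaX";
* **nested-match suppression** (default on): a form strictly contained in
  a longer match at the same position is dropped ("hair" inside "graying
  of hair"); partially overlapping distinct forms all count ("gray hair"
  and "hair loss" in "gray hair loss").

No stemming or lemmatization is applied: synonym lists are the intended
mechanism for form variation, and stemming would silently change what a
dictionary means. Occurrence counts include repeats within an abstract;
stages that need presence/absence binarize explicitly.

Matcher evaluation (precision/recall/F1) is scored at the
(abstract, term) presence level, micro-averaged over abstracts; a macro
(per-abstract mean F1) option exists.

## Synthetic corpora

The generator exists so that every statistical stage can be checked
against planted truth. Per abstract: an aging flag ~ Bernoulli(keyword
rate); per co-occurrence block a latent activation ~ Bernoulli(block
activation rate), with members present w.p. 0.8 given activation (the
shared switch is what creates the block correlation that clustering must
recover); independently each term present w.p. base rate × enrichment
factor (aging abstracts only; clipped to 1). Planted mentions are
rendered inside fixed sentence templates — so multi-word forms are never
split by punctuation — using a random synonym at the synonym-use rate,
plus one keyword surface form when flagged, plus seeded filler tokens
guaranteed disjoint from every dictionary form. Identical spec and seed
reproduce the corpus byte for byte.

Default study conditions used throughout the tests (20,000 abstracts,
2% keyword rate, 1% term base rate, enrichment factor 3, blocks of 10
terms at 5% activation) are chosen so that keyword-positive sets (~400
abstracts) and per-term counts sit in the sparse regime a real corpus
narrowing produces, while keeping any single test run in seconds.

What the generator deliberately does not emulate: real linguistic
context, negation and hedging ("no evidence of dementia" counts as a
mention — the matcher has no negation handling), abbreviations,
ambiguous polysemous terms, and correlated keyword/term usage beyond the
planted mechanisms. Passing tests therefore demonstrate the statistical
machinery is correct given matcher-visible mentions; they do not certify
precision on real prose.

## Enrichment and its null

Aging-count: presence-based count of the term over keyword-positive
abstracts. Expected-count: mean over R = 100 draws of the same-size
subset taken uniformly *without replacement* from the whole corpus
("random subsets of the data set", not a bootstrap). The ratio's
estimand is not exactly the planted factor e: because the null pool
includes the enriched keyword abstracts, the population ratio is
e / (1 + k(e − 1)) for keyword rate k — 2.885 for e = 3, k = 0.02 — a
~4% dilution worth remembering when reading recovery numbers.

Each of the R draws uses an independent counter-derived RNG stream
(`seed, draw-index`), so per-term results are independent of term order
and R can be extended without reshuffling earlier draws.

The χ² test is Pearson's on the 2×2 presence × keyword table, 1 df, no
Yates correction (a correction flag exists); tables with a zero marginal
are flagged NaN rather than tested. No multiple-testing correction is
applied by default — the per-term tests are reported as-is, and users
who need FDR control can apply it to the returned p-values.

## Normalization

Standard scores are per term (row), population (ddof = 0) SD. Two sign
conventions are implemented: `zscore_conventional` is `(x − μ)/σ`;
`zscore_inverted` is its negation `(μ − x)/σ`, a convention that appears
in published mining workflows and is kept as the default so existing
matrices normalized that way reproduce exactly. The sign is irrelevant
to every distance-based stage (Euclidean distances are
negation-invariant, and the tests assert the dendrograms agree), but it
does flip raw-vector views such as t-SNE input; hence both schemes.
Constant rows have no signal, are flagged, and are zero-filled with a
warning rather than dropped, preserving row indexing.

tf-idf wraps scikit-learn's `TfidfTransformer` defaults, codified as
formulas: binary tf, smoothed idf `ln((1+N)/(1+df)) + 1`, L2 document
columns. Smoothing and norming are parameters.

Hallmark attribution: restrict to abstracts mentioning ≥1 hallmark
concept; count abstracts containing both term and hallmark; divide each
hallmark column by its total (otherwise heavily-studied hallmarks
dominate every term); rescale each row to percentages (sum 100). Terms
with no hallmark co-occurrence are flagged and left at zero rather than
renormalized from nothing.

## Candidate discovery

On the narrowed sub-corpus (≥ 2 distinct clinical terms and ≥ 1 keyword
by default — "distinct terms" rather than "total mentions" is the
implemented reading, with a mentions-based alternative behind a flag),
a large tagged vocabulary is matched and each matched term is accepted
or rejected by three filters applied in a fixed priority order:
total-mention count below the cutoff (default 100, counted with repeats,
applied first), excluded semantic tag (default list of 12 administrative
categories such as "procedure", "qualifier value", "body structure"),
and the '/' rule (any surface form containing '/', which marks unit
strings like "mg/dl"). The priority order is a reporting convention —
all three filters are conjunctive for acceptance — but fixing it makes
rejection reasons deterministic and mutually exclusive.

## Clustering and support values

Average-linkage agglomerative clustering via SciPy on either Euclidean
distance or uncentered distance `1 − Σxᵢyᵢ/√(Σxᵢ²Σyᵢ²)`. The uncentered
metric is undefined for zero-norm rows; that is an error naming the row,
not a silent fix. For prevalence matrices with missing cells the
similarity is computed pairwise-complete (over columns where both rows
are present); no imputation is performed.

Bootstrap support resamples the *feature axis* (the columns: abstracts
when clustering terms, features when clustering conditions) with
replacement, mirroring the convention of resampling observations when
clustering variables. BP for a node is the percentage of bootstrap trees
containing its exact leaf set. AU uses the multiscale bootstrap: the
resample size is scaled by r over a 10-point grid 0.5…1.4 (which
includes 1, where BP is read off); per node the scale-wise bootstrap
probabilities are transformed to probits z(r) = Φ⁻¹(1 − BP(r)) and
fitted with z(r) = v√r + c/√r by weighted least squares (binomial
weights n·φ(z)²/(p(1−p))); AU = Φ(−(v − c)). Scales where the node
appeared never or always carry no probit information and are dropped;
nodes with fewer than two informative scales fall back to AU = BP with
an explicit flag and a warning. AU ≥ BP is *not* asserted anywhere — it
is not guaranteed — only range and seed-determinism are.

All resampling randomness is counter-derived from one integer seed
(`seed, scale-index, replicate-index`), so results are independent of
evaluation order and reproducible.

t-SNE (scikit-learn, random init, fixed seed) defaults to perplexity 9
and learning rate 10 — values suited to embedding on the order of a
hundred term vectors — with 1,000 iterations by default; embeddings are
evaluated only structurally (separation, determinism), because t-SNE
coordinates are not comparable across implementations. k-means on the
2-D embedding defaults to k = 14 with 10 seeded restarts, best inertia
kept.

Dendrograms export to Newick with branch lengths from merge heights and
internal labels "AU|BP"; the writer round-trips through standard Newick
parsers (checked against dendropy).

## Prevalence

The 2-SD abnormality rule is two-sided by default ("more than 2 SD
different" read as either direction); a one-sided option serves
direction-specific features (e.g. "lactate accumulation"). Feature
merging (e.g. creatinine increase + kidney disease → one combined
feature) renames via an explicit merge map and sums cohort sizes for
reporting; the combined prevalence must come from the input — records
merging to one cell with different prevalences are an error, since any
automatic pooling formula would invent data.

## Numerical conventions and degenerate inputs

Ties in term-frequency ranking break alphabetically (stable). Similarity
values are clipped to [−1, 1] before forming distances. Empty corpora,
empty keyword sets, all-zero rows and zero marginals each have a defined
behaviour (empty matrix, zero counts, flagged/NaN, or a named error) and
are tested. Degenerate bootstrap resamples under the uncentered metric
(a zero-norm row after resampling) are skipped, slightly reducing the
effective replicate count for the affected scale.

## Known limitations

* The matcher is purely lexical: no negation, abbreviation expansion or
  sense disambiguation. F1 = 1.0 on synthetic corpora reflects the
  generator's guarantee that mentions are literal surface forms.
* Expected-count resampling holds the keyword-set *size* fixed, not its
  composition; with very small keyword sets the ratio is noisy (SEM
  scales like 1/√(count)), which the tests' tolerance bands reflect.
* AU values from 100 bootstrap replicates per scale are coarse (±
  several points); they stabilize with larger `n_boot`.
* Matching, filtering and enrichment operate on sparse matrices, but
  both normalizations return dense arrays sized for the curated-term
  scale (~10³ terms × ~10⁴ abstracts); normalizing millions of raw
  abstracts without prior narrowing is out of scope.
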