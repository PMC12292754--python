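# Methods

This note records the models, conventions, and design choices behind
`biblionorm`, in the spirit of a statistical package's methods
documentation: what each component assumes, which knobs matter, and what
the synthetic-data tests do and do not demonstrate.

## Corpus model and filtering

A corpus is an ordered list of publication records parsed from the Web
of Science "Tab-delimited (UTF-8)" export dialect: a header row of field
tags (`UT DT LA TI SO DE ID C1 PY TC`, order-free), one row per record,
multi-valued fields joined with `"; "`. The line-tagged "plain text"
dialect is deliberately unsupported: one bit-exact dialect with a
round-tripping writer is more useful than two approximate readers.

Inclusion filtering retains a record iff (a) any semicolon-split
component of its document type is allowed — so `"Article; Early
Access"` counts as an Article, matching WoS refinement behavior — (b)
its language is allowed, and (c) its year is in range. Each removal is
attributed to the first failing rule in the order type → language →
year; the filter report conserves counts exactly
(`retained + Σ removals = input`) and defines percent reduction as 0
for an empty input. Records missing citations parse as 0 with a logged
warning; records missing a year are kept but excluded from year-based
metrics — least-surprise defaults, never silent drops.

Countries come from the last comma-separated token of each `"; "`-
separated address in the affiliation field (reprint address as
fallback), with bracketed author lists skipped. A variant→canonical
mapping table normalizes known alternate spellings (e.g. Turkiye →
Turkey); UK constituents (England, Scotland, Wales, Northern Ireland)
merge to "United Kingdom" by default, and the merge is switchable off
because country-level tables and collaboration networks legitimately
differ on this convention. Unknown labels pass through verbatim and are
logged, never guessed.

## The synonym cascade

**Cleaning** lowercases, maps Unicode dashes to `-` and curly quotes to
straight quotes, collapses whitespace, and strips edge punctuation.
All-punctuation input is an error naming the term, not an empty string.

**Component extraction** recognizes concentrations as number+unit with
units from a configurable lexicon (`mg, g, µg, ml, %, mg/ml, iu,
iu/ml`; longest-first matching so `iu/ml` wins over `iu`) and dosage
forms from a word lexicon (`tablet, capsule, injection, solution,
cream, patch, suspension`). Recognized spans are removed to leave the
core name; a term that is nothing but components keeps its full
cleaned string as core, preserving the non-empty invariant. The
lexicons are configuration with documented defaults, not claims of
completeness.

**Exact tier.** Signature equality after deleting hyphens and spaces.
Score is always 1; identical spellings never self-pair.

**Semantic tier.** Embeddings come from a provider contract: unit-norm
vectors (within 1e-6), dimension ≥ 2, deterministic for identical
input. DBSCAN runs once over the full vocabulary on the precomputed
distance matrix `1 − cos`, with `eps = 1 − t` derived from the cosine
threshold `t` (default 0.85 ⇒ eps 0.15) and `min_samples = 2` so a
single similar pair can form a cluster. Within each non-noise cluster
only pairs whose own cosine meets `t` are emitted, with the cosine as
score; this keeps the emission criterion pairwise and prevents density
chaining from linking sub-threshold pairs (a property the tests check
explicitly with a three-term chain at cosine 0.90/0.62).

The default provider is character 3-gram TF-IDF (scikit-learn,
`char_wb`, L2-normalized), fitted per input batch — deterministic,
download-free, and adequate for surface-level similarity. Transformer
encoders can be wrapped in the same contract; nothing downstream
changes.

**Fuzzy tier.** Pairs are scored by `difflib.SequenceMatcher.ratio` on
core names — the matching-blocks ratio `2M/(|a|+|b|)`, e.g.
`statins`/`statin` → 12/13 ≈ 0.923 — and emitted when the score (as a
percentage) reaches the threshold (default 90). Before scoring, a pair
is *blocked* if both terms carry concentrations that differ or dosage
forms that differ: component conflicts are treated as hard negative
evidence regardless of string similarity, which is what makes the
matching pharmaceutical-context-aware rather than merely lexical.

**Merging.** Evidence from all tiers forms an undirected graph
(duplicate edges collapse keeping the best score per tier); synonym
groups are the connected components, verified against a union-find
oracle on random evidence sets in the tests. Components below the
minimum group size (default 2) are discarded. Canonical selection is
frequency → shortest string → lexicographically smallest: frequency
because the corpus's dominant spelling is the least surprising label,
with deterministic tie-breaks so reruns are byte-identical. This rule
is an interpretation — the selection criterion is configurable in
principle and documented as a choice, not a discovery.

**Thesaurus.** The output maps each non-canonical member to its
group's canonical. Invariants enforced at construction: no term in two
groups (raises, signaling a merge bug), no canonical appearing as a
variant key (chain-freedom), no self-mapping. Together these make one
application of the mapping a fixed point, so applying the thesaurus to
a corpus is idempotent — property-tested. Serialization is VOSviewer's
tab-separated `label` / `replace by` dialect (rows sorted by variant
for determinism); a strict-CSV writer exists behind a flag because the
tab dialect is what VOSviewer actually reads.

## Validation harness

The precision protocol draws a stratified random sample of detected
pairs — strata are the detection tiers, with largest-remainder
allocation proportional to tier evidence counts (an explicit choice;
any fixed rounding rule would do, this one is exact in total and never
oversamples a stratum) — and scores *unanimity precision*: a pair is
correct only if every rater (default 3) labels it correct. With the
default 300-pair sample, 283 unanimous-correct labels give precision
94.3%, the arithmetic the acceptance script reproduces. Sampling is
seeded and deterministic; if fewer pairs exist than requested, all are
returned. Inter-rater agreement statistics (kappa) are out of scope.

## Indicators

All age-based rates use the inclusive-year denominator
`reference_year − start_year + 1`. This convention is forced by
self-consistency of the standard printed tables (h 71 since 1977 at
reference 2025 gives m = 71/49 = 1.449; TC 2534 from 2008 gives
TC/Year = 2534/18 = 140.78); the convention without +1 does not
reproduce them. The reference year is configuration (default 2025, the
dataset end year), never inferred from the wall clock.

The g-index is capped at the number of papers (no zero-padding), so
`g ≥ h` always but a single highly cited paper has g = 1; conventions
differ on this point, hence the explicit note. Table rounding is
decimal half-up to the printed precision (2 decimals for rates, 3 for
the m-index). Trend-topic quartiles use nearest-rank (`ceil(p·n)`,
lower-median) on each keyword's per-document publication years, since
interpolation conventions differ across tools and nearest-rank is the
only one that always returns an observed year.

## Networks

Edge link strength counts documents containing both labels (binary per
document — a keyword repeated within a record counts once), matching
the document-level co-authorship convention of mapping tools. TLS is
the sum of incident edge weights, so `Σ_nodes TLS = 2 Σ_edges w`
identically (tested). Occurrence thresholds (default minimum 5
documents for countries, 100 for keywords) apply *before* edge
construction. Fractional country counting assigns 1/k per document
with k distinct countries, so per-document credits sum to 1 and total
fractional credit equals the number of documents with at least one
country. Association strength is `2·m·c_ab/(w_a·w_b)` (m = total edge
weight); published variants differ by a constant factor, which leaves
rankings unchanged. Cluster assignment and layout are out of scope;
`cluster_id` is populated only when supplied externally.

Exports: VOSviewer map (`id label weight`, with header) + network
(`id id strength`, headerless) pair, and Pajek `.net`. The VOSviewer
pair round-trips exactly through the bundled reader; Pajek preserves
topology and edge weights but not node occurrence weights, because
Pajek vertex lines carry none.

## The simulator

The generator defines the study conditions for every test. Defaults:
50 concepts from a built-in pool of multi-word pharmaceutical surfaces,
3 variants per concept from the noise operations {hyphen/space swap,
plural toggle, case change, single-character deletion}, with
punctuation, dosage-suffix, and abbreviation ops available; 2000
documents over 1975–2025 with uniform years; a 15-country pool with
collaboration probability 0.3 (2–4 distinct countries when
collaborative); 3–8 keywords per document sampled
frequency-proportionally; citations negative-binomial with mean
`1.5 × inclusive age` and dispersion 1, so older documents accumulate
more citations in expectation, mimicking citation lag. These values
are what a scientist would call a realistic small-scale corpus; they
are configuration, not fits to any real dataset. Variant surfaces that
would collide across concepts after cleaning are regenerated so ground
truth stays single-valued; identical config+seed yields byte-identical
exports (numpy `default_rng` throughout; term hashing uses CRC32
because Python's salted `hash` is not stable across processes).

The mock embedding provider realizes exact geometry: concept anchors
`√inter·u + √(1−inter)·e_i` over an orthonormal basis give anchor
cosines of exactly `inter`; members `√intra·anchor + √(1−intra)·r_t`
with per-term orthonormal noise give within-concept cosines of exactly
`intra` and cross-concept cosines `intra·inter ≤ inter`. Dimension
feasibility (`1 + #concepts + #terms + 4`) is checked and violated
requests raise. Terms outside the ground truth embed into a reserved
orthogonal subspace, so they can never join a planted concept.

**What passing tests show — and don't.** With the mock provider at
intra 0.95 / inter 0.20, the semantic tier alone links every
within-concept pair, so end-to-end planted-group recovery (pairwise
F1 ≥ 0.92 over 20 seeds; observed 1.0) demonstrates that the plumbing —
cleaning, tiering, merging, thesaurus application — loses nothing and
invents nothing. It does *not* demonstrate that real transformer
embeddings separate real drug vocabularies that cleanly; on real data
the semantic tier's recall depends entirely on the provider, and the
fallback TF-IDF provider captures only surface similarity (it will
find "aspirine"/"aspirin" but never "aspirin"/"acetylsalicylic acid").
The simulator likewise does not model topical keyword correlation,
realistic journal profiles, or non-English records.

## Numerical and degenerate-input choices

Cosines are clipped to [−1, 1] before distances; the distance matrix
diagonal is forced to 0. Unit-norm tolerance for providers is 1e-6.
Empty corpora, empty thesauri, empty networks, and header-only exports
are all legal and round-trip. Zero-document averages, percent change
from zero, zero cohort means, and absent years raise informative
errors rather than returning NaN. All randomness flows from explicit
seeds; there is no wall-clock or environment dependence anywhere in
the computation path.

## Problem sizes used in checks

Oracle equivalences run 1000 random trials (h/g-index vectors up to
length 50; evidence graphs up to 50 terms); counting/TLS identities
use one 2000-document simulated corpus; recovery runs 20 seeds of
250-document, 15-concept corpora; the validation harness samples 300
pairs from a 55-concept vocabulary. These sizes were chosen as the
package's own test conditions: large enough to exercise every code
path and make coincidental agreement implausible, small enough that
the whole suite runs in seconds.

## Known limitations

- Only the tab-delimited WoS dialect; no Scopus/PubMed readers.
- Country extraction trusts the WoS address grammar; free-form
  affiliations degrade to verbatim pass-through.
- The fuzzy tier is O(n²) in vocabulary size; fine to ~10⁴ terms,
  beyond which blocking by first character or length band would be the
  next step.
- No multilingual normalization, no MeSH/UMLS linking, no embedding
  fine-tuning.
- DBSCAN runs once over the whole vocabulary; per-block clustering for
  very large vocabularies is future work.
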