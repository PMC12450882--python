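# Methods

## Problem and overall model

The package quantifies mechanistic connectivity between an occupational
respiratory exposure and a disease endpoint by projecting both into the
Gene Ontology Biological Process (GO BP) vocabulary and measuring set
overlap. Three term-set sources are distinguished by provenance:

- `aop_curated` — expert tables mapping Adverse Outcome Pathway (AOP)
  events (MIE/KE/AO) to GO terms, expanded with child terms and
  deduplicated;
- `disgenet_derived` — GO BPs overrepresented among disease-associated
  genes;
- `enrichment_derived` — GO BPs enriched in one exposure condition's
  ranked differential-expression profile.

Overlap is reported as Venn counts and the Jaccard index
J(A,B) = |A∩B|/|A∪B|, which normalises for set size so conditions with
differently sized enriched sets remain comparable. No significance is
attached to overlaps: the counts and indices are the result, matching the
descriptive character of the comparison.

## Ontology handling

The OBO reader keeps `[Term]` stanzas with `is_a` and
`relationship: part_of` edges only, resolves `alt_id`s silently to their
canonical term, retains obsolete terms flagged but edge-free (warning
logged), and fails loudly — naming the line — on malformed stanzas or
duplicate ids. "Child GO terms" means the **full descendant closure** by
default (mode `descendants`); a `children` mode restricting to direct
children exists because public ontology browsers offer both views. The
expanded set always includes the parent term itself. Traversal defaults
to `is_a` only: `part_of` in the BP namespace can cross semantic intent,
so it is opt-in. Closures are namespace-restricted and exclude obsolete
terms.

## Curation

`derive_aop_term_set` reports both the pre-dedup expansion size
(`raw_count`, the "parents + linked children" count) and the deduplicated
`unique_count`; the gap between them is itself informative about how
strongly AOP events converge on shared biology. Terms mapped outside the
BP namespace are filtered with a logged count; terms missing from the
ontology are skipped with a warning (strict mode raises). Gene symbols
are matched case-insensitively; no evidence-score cut-off is applied to
gene–disease tables unless `min_score` is passed. `vocabulary_coverage`
truncates (rather than rounds) to the requested decimals so a set
covering 8.15% of the vocabulary is reported as 8.1%, never overstated.

## Enrichment engines

### GSEA

The ranked-list statistic is the weighted Kolmogorov–Smirnov running sum
with weight exponent p on |fold change| (default p = 1, the canonical
weighted form; p = 0 gives the classic KS variant). The ranking metric is
the supplied fold change as-is, sorted descending with lexicographic
gene-id tie-break, so results are deterministic also under ties.
Duplicate gene ids keep the record with the largest |fold change|
(probe-collapse convention, logged).

The null is **gene-set permutation**: the inputs are per-condition
two-column fold-change tables without sample-level replicates, so a
phenotype permutation is not available. One seeded permutation pool of
`n_permutations` (default 1000) full rank-permutations is shared across
terms; the first k entries of each row form a uniform random k-subset,
which makes results independent of collection iteration order and lets
one pool serve every set size. Null ES values are evaluated with a
closed-form candidate scan (extrema occur at or immediately before hit
positions), identical to the step-by-step running sum to 1e-12.

NES = ES / mean(|null ES| of the same sign); p-values are empirical
same-sign tail fractions with an add-one correction. FDR uses the pooled
normalised null across all terms per sign, clipped to [0, 1] and made
monotone (a more extreme NES never receives a larger q). Selection is
**strictly** FDR < threshold, default 0.25.

Two calibration facts, established by simulation in the test suite, set
expectations for users:

- Under a complete null (effect shift 0), the procedure behaves like
  calibrated FDR-0.25 control: most datasets yield zero calls, but a
  minority legitimately yield a few — under a global null, FDR control at
  q admits ≥1 false call with probability up to q. Empirically 7/10 null
  seeds are clean with a <1% overall null call fraction.
- With nested (true-path propagated) GO collections, gene-set permutation
  ignores inter-term correlation, so correlated clades occasionally pass
  together; this anti-conservatism is a documented property of the
  canonical pooled-FDR scheme, not of this implementation.

### ORA

One-sided hypergeometric upper-tail tests (over-representation only),
Benjamini–Hochberg FDR across tested terms, sample odds ratio reported
per term. The default universe is every gene with at least one BP
annotation after true-path propagation; an explicit background can be
supplied. Term sizes outside [`min_set_size`, `max_set_size`] (defaults
5, 2000) are not tested — both engines share this window.

## Overlap and signature

J(∅,∅) is defined as 0 with a warning; 0 avoids a spurious "complete
overlap" for a degenerate case the analysis never produces. Jaccard is
computed on deduplicated sets only. The cross-chemical signature
intersects each chemical's disease-overlapping terms and emits a boolean
term × chemical membership matrix; outputs are count tables and TSVs, not
images — bit-exact counts are the contract.

## Dosimetry

Concentrations canonicalise to µM: mM ×1000; µg/mL via a supplied molar
mass; creatinine-normalised urinary values (µmol/mmol creatinine) via an
assumed urinary creatinine concentration in mmol/L (must be supplied —
8.2 mmol/L is a typical spot-urine value). Air concentrations (µg/m³)
are deliberately *not* convertible: they are external-exposure scenario
metadata, and translating them into internal doses is the job of a
kinetic (PBK) model, which this package consumes as plain records rather
than re-implements. Fold = in vitro / in vivo; report rounding is
integer for folds ≥ 100 and one decimal below, matching how such ratios
are conventionally quoted. Chemicals with only qualitative in vivo
evidence (for MA, antibody detection without a concentration) yield a
fold-absent row carrying the reason. The packaged sensitiser table
reproduces printed source values verbatim, including urinary PA
estimates whose magnitude the original source itself flags as likely
overestimated.

## Synthetic benchmark

The generators emulate the study conditions end to end: a rooted is_a
DAG of 200 BP terms (≤4 children per node, 10% of nodes get a second
parent so the graph is a genuine DAG), 2000 genes assigned to leaf terms
(uniform 5–50 genes per leaf, every gene annotated at least once so the
universe is exactly 2000), true-path propagation, AOP event tables with
controlled term duplication, and per-condition fold changes
Normal(0, noise_sd = 1) plus an additive shift δ = 1.5 for members of
any planted term. The additive Gaussian effect keeps the null symmetric
and the power property analytically predictable. Five planted terms are
auto-picked among **leaf** terms with 20–50 genes: planting at leaves
keeps ground truth unambiguous (a planted internal term would make every
descendant a fully planted "non-planted" term), while ancestors still
receive diluted signal — which is faithful to how real GO enrichment
behaves. In multi-condition bundles all conditions share the planted
terms (one disease, several chemicals) with independent noise draws.

Randomness is stream-split: one base seed, fixed per-generator stream
ids, so adding a generator call never perturbs another module's draws.
Every generator is byte-deterministic in (config, seed).

What the generator does **not** emulate: gene–gene correlation,
multiplicative/heteroscedastic effects, probe-level artefacts, and
realistic GO term-size distributions. Passing the recovery tests
therefore demonstrates correctness of the machinery under clean planted
signal, not expected sensitivity on real microarray/RNA-seq data.

At the default conditions, all five planted terms pass FDR < 0.25 in
every one of 10 seeds, and ≈92% of non-planted terms stay above the
threshold (aggregated across seeds; the sub-threshold remainder is
dominated by ancestors of planted terms).

## Pipeline and reports

Conditions are processed independently — no cross-condition FDR pooling,
matching per-chemical/per-timepoint treatment. `run_workflow` composes
only public stage functions; the report bundle (overlap matrix,
intersection terms with AOP event back-mapping, per-condition enrichment
tables, signature membership, JSON summary with seed/config-hash/version
metadata) is byte-identical across re-runs with equal config and seed.
Stage failures abort with a stage-named message and partially written
report files are removed.

## Problem sizes in the test suite

Unit tests run on reduced synthetic studies (60–80 terms, 300–400
genes, 100–200 permutations); the recovery, calibration and power
properties run at the full default conditions (200 terms, 2000 genes,
1000 permutations, 10–20 seeds), which completes in well under a minute
on one CPU. These sizes are the package's own benchmark definition.

## Known limitations

- Headline counts from the original curated analyses (e.g. specific
  overlap counts against expert-curated disease sheets) depend on
  version-pinned ontologies, annotation releases and expert spreadsheets;
  the package reproduces the *procedures* and verifies them against
  synthetic manifests and closed-form oracles instead.
- The GSEA FDR is an empirical pooled estimator: coarse below ~1/n_perm
  and anti-conservative for strongly nested collections (above).
- ORA treats genes as exchangeable; annotation biases (well-studied
  genes carry more terms) propagate into enrichment as in any
  hypergeometric framework.
- The dosimetry module compares nominal concentrations; protein binding
  and chemical reactivity in culture media (which lower the effective in
  vitro dose) are out of scope.
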