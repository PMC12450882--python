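"""Quantify exposure-disease linkage by GO BP overlap and find the
cross-chemical signature.

Derives a disease term set from curated AOP events and enriched term sets
for three synthetic exposure conditions, then reports per-condition Venn
counts with Jaccard indices and the terms common to every condition's
disease overlap — the cross-chemical mechanistic signature.
"""

import io

from aoplink import (
    EnrichmentConfig,
    common_signature,
    derive_aop_term_set,
    gsea,
    overlap,
    overlap_matrix,
    parse_obo,
    select_significant,
)
from aoplink.synthetic import SyntheticConfig, generate_annotation, generate_bundle, generate_ontology

bundle = generate_bundle(SyntheticConfig(seed=21, n_terms=120, n_genes=800), n_conditions=3)
graph = parse_obo(io.StringIO(bundle["obo_text"]))
propagated = bundle["annotation"].propagate(graph)
disease = derive_aop_term_set(bundle["events"], graph, source_label="synthetic AA")

enriched_sets = []
overlaps = []
for i, cond in enumerate(bundle["conditions"], start=1):
    records = gsea(cond["ranked"], propagated, EnrichmentConfig(seed=21, n_permutations=500))
    sel = select_significant(records, 0.25, source_label=f"chem {i}")
    enriched_sets.append(sel)
    overlaps.append(overlap(sel, disease, events=bundle["events"]))

print(overlap_matrix(enriched_sets, disease).to_string(index=False))
signature = common_signature(overlaps)
print(f"\ncommon signature across {len(overlaps)} chemicals: {signature.signature_size} terms")
for t in sorted(signature.common_terms):
    print(f"  {t}")
# Each row is one exposure condition vs the disease set: the Jaccard index
# normalises the intersection for set sizes; the signature lists terms
# recurring in every chemical's disease overlap.
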