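"""Curate a disease GO BP term set from AOP event mappings.

Builds a small synthetic GO BP ontology and an AOP event table, expands
each event's mapped terms into parent + descendant ("child") terms, and
deduplicates into the disease mechanism set used for overlap analysis.
"""

import io

from aoplink import derive_aop_term_set, parse_obo, vocabulary_coverage
from aoplink.synthetic import SyntheticConfig, generate_event_mappings, generate_ontology

cfg = SyntheticConfig(seed=7, n_terms=120, n_events=8)
obo_text, ont_manifest = generate_ontology(cfg)
graph = parse_obo(io.StringIO(obo_text))
events_tsv, events, _ = generate_event_mappings(ont_manifest, cfg)

term_set = derive_aop_term_set(events, graph, source_label="synthetic LFD")

print(f"events curated:        {len(events)}")
print(f"parents + children:    {term_set.raw_count}  (pre-dedup expansion size)")
print(f"unique GO BP terms:    {term_set.unique_count}  (after removing duplicates)")
coverage = vocabulary_coverage(term_set, len(graph.terms))
print(f"vocabulary coverage:   {coverage}% of the {len(graph.terms)}-term BP vocabulary")
# The gap between the raw and unique counts shows how strongly AOP events
# converge on shared biology; the coverage says how specific the set is.
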