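"""Curated AOP/disease-gene term-set derivation."""

import io

import pandas as pd
import pytest

from aoplink.curation import (
    AopEvent,
    GoTermSet,
    SchemaError,
    derive_aop_term_set,
    derive_disease_term_set,
    load_event_mappings,
    load_gene_disease_table,
    merge_term_sets,
    vocabulary_coverage,
)
from aoplink.enrichment import EnrichmentConfig
from aoplink.synthetic import SyntheticConfig, generate_annotation, generate_disease_genes, generate_ontology


def _table(rows, columns=("aop_id", "event_id", "event_type", "go_terms")):
    return pd.DataFrame(rows, columns=list(columns))


def test_load_event_mappings_basic():
    events = load_event_mappings(
        _table([["AOP 39", "Event 1", "MIE", "GO:0007165;GO:0006915"]])
    )
    assert len(events) == 1
    assert events[0].mapped_terms == ("GO:0007165", "GO:0006915")


def test_load_event_mappings_deduplicates_rows():
    row = ["AOP 39", "Event 1", "KE", "GO:0007165"]
    events = load_event_mappings(_table([row, row]))
    assert len(events) == 1


def test_load_event_mappings_empty_terms_kept():
    events = load_event_mappings(_table([["AOP 39", "Event 2", "KE", ""]]))
    assert events[0].mapped_terms == ()


def test_load_event_mappings_missing_column():
    with pytest.raises(SchemaError, match="go_terms"):
        load_event_mappings(
            _table([["AOP 39", "E", "KE"]], columns=("aop_id", "event_id", "event_type"))
        )


def test_event_type_validated():
    with pytest.raises(SchemaError):
        AopEvent("AOP 1", "E1", "XX", ("GO:0000001",))


def test_derive_aop_term_set_matches_generator_manifest(bundle, graph):
    """Expansion + dedup reproduces the generator's raw and unique counts."""
    ts = derive_aop_term_set(bundle["events"], graph)
    m = bundle["events_manifest"]
    assert ts.raw_count == m["raw_count"]
    assert ts.unique_count == m["unique_count"]
    assert ts.terms == frozenset(m["union_terms"])
    assert ts.provenance == "aop_curated"


def test_derive_aop_term_set_order_invariant(bundle, graph):
    a = derive_aop_term_set(bundle["events"], graph)
    b = derive_aop_term_set(list(reversed(bundle["events"])), graph)
    assert a.terms == b.terms and a.raw_count == b.raw_count


def test_derive_aop_term_set_disjoint_leaves(graph, bundle):
    leaves = bundle["ontology_manifest"]["leaves"][:2]
    events = [
        AopEvent("A", "E1", "MIE", (leaves[0],)),
        AopEvent("A", "E2", "KE", (leaves[1],)),
    ]
    ts = derive_aop_term_set(events, graph)
    assert ts.raw_count == 2 and ts.unique_count == 2


def test_derive_aop_term_set_duplicate_parent_idempotent(graph):
    root = sorted(graph.roots("biological_process"))[0]
    one = derive_aop_term_set([AopEvent("A", "E1", "MIE", (root,))], graph)
    two = derive_aop_term_set(
        [AopEvent("A", "E1", "MIE", (root,)), AopEvent("A", "E2", "KE", (root,))],
        graph,
    )
    assert two.unique_count == one.unique_count
    assert two.raw_count == 2 * one.raw_count


def test_unknown_term_skipped_or_strict(graph):
    events = [AopEvent("A", "E1", "MIE", ("GO:0099999",))]
    with pytest.raises(Exception):
        derive_aop_term_set(events, graph, strict=True)
    events.append(AopEvent("A", "E2", "KE", (sorted(graph.terms)[0],)))
    ts = derive_aop_term_set(events, graph, strict=False)
    assert ts.unique_count >= 1


def test_merge_term_sets_identity_and_idempotence():
    s = GoTermSet(frozenset({"GO:0000001", "GO:0000002"}), "aop_curated", "AA")
    empty = GoTermSet(frozenset(), "disgenet_derived", "AA")
    self_merge = merge_term_sets(s, s)
    assert self_merge.terms == s.terms
    assert self_merge.raw_count == 2 * s.unique_count
    assert merge_term_sets(empty, s).terms == s.terms
    a = GoTermSet(frozenset({"GO:0000001"}), "aop_curated")
    b = GoTermSet(frozenset({"GO:0000002"}), "disgenet_derived")
    c = GoTermSet(frozenset({"GO:0000003"}), "enrichment_derived")
    left = merge_term_sets(merge_term_sets(a, b), c)
    right = merge_term_sets(a, merge_term_sets(b, c))
    assert left.terms == right.terms


@pytest.mark.parametrize(
    "count,vocab,expected",
    [(2205, 27047, 8.1), (50, 50, 100.0), (1, 1000, 0.1)],
)
def test_vocabulary_coverage(count, vocab, expected):
    assert vocabulary_coverage(count, vocab) == expected


def test_vocabulary_coverage_errors():
    with pytest.raises(ValueError):
        vocabulary_coverage(1, 0)
    with pytest.raises(ValueError):
        vocabulary_coverage(10, 5)


def test_gene_disease_table_loading():
    df = pd.DataFrame(
        {
            "gene_id": ["TP53", "TP53", "IL4"],
            "disease_id": ["D1", "D1", "D1"],
            "score": [0.9, 0.9, 0.2],
        }
    )
    loaded = load_gene_disease_table(df)
    assert len(loaded) == 2
    filtered = load_gene_disease_table(df, min_score=0.5)
    assert list(filtered["gene_id"]) == ["TP53"]
    bad = df.assign(score=[1.5, 0.9, 0.2])
    with pytest.raises(SchemaError):
        load_gene_disease_table(bad)


def test_disease_term_set_recovers_planted_terms():
    """Power property: every planted term is recovered at FDR 0.05 from the
    contaminated disease gene list, across 20 seeds."""
    from aoplink.ontology import parse_obo

    cfg_enr = EnrichmentConfig(fdr_threshold=0.05)
    for seed in range(20):
        # the stated power conditions: 2000-gene universe, 20-50-gene planted
        # terms; a smaller universe dilutes the hypergeometric signal
        cfg = SyntheticConfig(seed=seed)
        obo, om = generate_ontology(cfg)
        ann, am = generate_annotation(om, cfg)
        annp = ann.propagate(parse_obo(io.StringIO(obo)))
        genes, truth = generate_disease_genes(am, cfg)
        ts = derive_disease_term_set(genes, annp, config=cfg_enr, source_label="AA")
        assert set(truth["planted_terms"]) <= set(ts.terms), f"seed {seed}"
        assert ts.provenance == "disgenet_derived"


def test_disease_term_set_null_gene_lists_mostly_empty(annotation):
    """Uniformly sampled gene lists yield zero terms at FDR 0.05 in at least
    19 of 20 seeds (the hypergeometric test is conservative)."""
    import numpy as np

    universe = sorted(annotation.universe)
    cfg_enr = EnrichmentConfig(fdr_threshold=0.05)
    zero = 0
    for seed in range(20):
        rng = np.random.default_rng(seed + 500)
        genes = [universe[i] for i in rng.choice(len(universe), 50, replace=False)]
        ts = derive_disease_term_set(genes, annotation, config=cfg_enr)
        zero += int(ts.unique_count == 0)
    assert zero >= 19


def test_disease_term_set_unmapped_genes_error(annotation):
    with pytest.raises(ValueError, match="id-mapping"):
        derive_disease_term_set(["NOSUCHGENE1", "NOSUCHGENE2"], annotation)
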