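"""GSEA and ORA engines: oracles, determinism, calibration."""

import io
import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from aoplink.enrichment import (
    AnnotationTable,
    EnrichmentConfig,
    RankedGeneList,
    gsea,
    gsea_enrichment_score,
    ora,
    read_gmt,
    select_significant,
    write_gmt,
)
from aoplink.synthetic import SyntheticConfig, generate_annotation, generate_ontology, generate_ranked_list


def brute_force_es(genes, fold_changes, gene_set, weight):
    """Independent step-by-step running-sum loop (the oracle).

    Walks the already-ranked list, accumulating the hit/miss increments one
    position at a time, and returns the running-sum value of maximal
    absolute deviation (positive preferred on exact ties).
    """
    n = len(genes)
    hits = [g in gene_set for g in genes]
    n_hit = sum(hits)
    denom = sum(abs(fc) ** weight for g, fc, h in zip(genes, fold_changes, hits) if h)
    running = 0.0
    best = 0.0
    for g, fc, h in zip(genes, fold_changes, hits):
        if h:
            running += (abs(fc) ** weight) / denom if denom > 0 else 1.0 / n_hit
        else:
            running -= 1.0 / (n - n_hit)
        if abs(running) > abs(best) or (abs(running) == abs(best) and running > best):
            best = running
    return best


def hypergeom_tail_oracle(N, K, n, k_obs):
    """Upper-tail hypergeometric probability via explicit combinatorics."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k_obs, min(K, n) + 1)
    ) / total


def _ranked(seed=0, n=10):
    rng = np.random.default_rng(seed)
    genes = [f"G{i:03d}" for i in range(n)]
    return RankedGeneList("t", genes, rng.normal(0, 1, n))


# ---------------------------------------------------------------------------
# ranked list container
# ---------------------------------------------------------------------------


def test_ranked_list_sorted_desc_with_tiebreak():
    r = RankedGeneList("c", ["b", "a", "c"], [1.0, 1.0, 2.0])
    assert list(r.genes) == ["C", "A", "B"]


def test_ranked_list_duplicate_keeps_max_abs():
    r = RankedGeneList("c", ["a", "a", "b"], [0.5, -3.0, 1.0])
    assert dict(zip(r.genes, r.fold_changes))["A"] == -3.0


def test_ranked_list_from_table_dialect():
    df = pd.DataFrame({"Gene ID": ["g1", "g2"], "Fold Change Value": [2.0, -1.0]})
    r = RankedGeneList.from_table(df, condition_label="UFP 20h")
    assert r.condition_label == "UFP 20h"
    assert list(r.genes) == ["G1", "G2"]
    with pytest.raises(ValueError, match="Fold Change"):
        RankedGeneList.from_table(pd.DataFrame({"x": [1]}))


# ---------------------------------------------------------------------------
# GSEA enrichment score
# ---------------------------------------------------------------------------


def test_es_top_gene_only_is_one():
    r = _ranked(1)
    es, running, leading = gsea_enrichment_score(r, {str(r.genes[0])})
    assert es == pytest.approx(1.0, abs=1e-12)
    assert leading == (str(r.genes[0]),)


def test_es_all_genes_is_one():
    r = _ranked(2)
    es, running, _ = gsea_enrichment_score(r, set(map(str, r.genes)))
    assert es == pytest.approx(1.0, abs=1e-12)
    assert running[-1] == pytest.approx(1.0, abs=1e-12)


def test_es_matches_brute_force_loop():
    rng = np.random.default_rng(11)
    for _ in range(100):
        n = int(rng.integers(5, 30))
        r = _ranked(int(rng.integers(1 << 30)), n)
        k = int(rng.integers(1, n))
        gene_set = {str(g) for g in rng.choice(r.genes, size=k, replace=False)}
        w = float(rng.choice([0.0, 1.0, 2.0]))
        es, _, _ = gsea_enrichment_score(r, gene_set, w)
        oracle = brute_force_es(list(map(str, r.genes)), r.fold_changes, gene_set, w)
        assert es == pytest.approx(oracle, abs=1e-12)


def test_es_bounded_and_no_overlap_sentinel():
    r = _ranked(3, 20)
    assert gsea_enrichment_score(r, {"NOT_PRESENT"}) is None
    rng = np.random.default_rng(5)
    for _ in range(50):
        k = int(rng.integers(1, 20))
        gs = {str(g) for g in rng.choice(r.genes, size=k, replace=False)}
        es, _, _ = gsea_enrichment_score(r, gs)
        assert -1.0 <= es <= 1.0


def test_unweighted_complement_mirrors_running_sum():
    """With weight 0 the complement's running sum is the exact negation, so
    the extrema swap sign."""
    r = _ranked(7, 15)
    gs = {str(g) for g in r.genes[[1, 4, 9]]}
    comp = {str(g) for g in r.genes if str(g) not in gs}
    _, run_a, _ = gsea_enrichment_score(r, gs, 0.0)
    _, run_b, _ = gsea_enrichment_score(r, comp, 0.0)
    np.testing.assert_allclose(run_a, -run_b, atol=1e-12)


def test_gseapy_cross_check():
    """Independent implementation agrees on the weighted enrichment score."""
    gseapy = pytest.importorskip("gseapy")
    rng = np.random.default_rng(7)
    genes = [f"G{i:03d}" for i in range(100)]
    fc = np.sort(rng.normal(0, 1, 100))[::-1] + np.linspace(0.001, 0, 100)
    r = RankedGeneList("x", genes, fc)
    sets = {
        "TOP": {str(g) for g in r.genes[[2, 5, 9, 20, 40]]},
        "BOTTOM": {str(g) for g in r.genes[[60, 70, 80, 90, 95]]},
    }
    res = gseapy.prerank(
        rnk=pd.DataFrame({"gene": r.genes, "score": r.fold_changes}).set_index("gene"),
        gene_sets={k: sorted(v) for k, v in sets.items()},
        permutation_num=10,
        min_size=2,
        max_size=50,
        seed=1,
        outdir=None,
        no_plot=True,
    )
    table = res.res2d.set_index("Term")
    for term, gs in sets.items():
        mine = gsea_enrichment_score(r, gs)[0]
        assert mine == pytest.approx(float(table.loc[term, "ES"]), abs=1e-9)


# ---------------------------------------------------------------------------
# full GSEA
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def planted_run():
    from aoplink.ontology import parse_obo

    cfg = SyntheticConfig(seed=5, n_terms=80, n_genes=400)
    obo, om = generate_ontology(cfg)
    ann, am = generate_annotation(om, cfg)
    graph = parse_obo(io.StringIO(obo))
    prop = ann.propagate(graph)
    ranked, truth = generate_ranked_list(am, cfg)
    return ranked, prop, truth


def test_gsea_detects_planted_terms(planted_run):
    ranked, prop, truth = planted_run
    records = gsea(ranked, prop, EnrichmentConfig(seed=5, n_permutations=200))
    fdr = {r.term_id: r.fdr for r in records}
    for term in truth["planted_terms"]:
        assert fdr[term] < 0.25


def test_gsea_deterministic_and_order_invariant(planted_run):
    ranked, prop, _ = planted_run
    cfg = EnrichmentConfig(seed=9, n_permutations=100)
    a = gsea(ranked, prop, cfg)
    b = gsea(ranked, prop, cfg)
    assert a == b
    # permuted collection insertion order
    items = list(prop.term_to_genes.items())
    shuffled = AnnotationTable([])
    shuffled.term_to_genes = dict(reversed(items))
    c = gsea(ranked, shuffled, cfg)
    assert a == c
    # permuted DE table row order
    rng = np.random.default_rng(0)
    idx = rng.permutation(len(ranked))
    ranked2 = RankedGeneList(
        ranked.condition_label,
        [str(g) for g in ranked.genes[idx]],
        ranked.fold_changes[idx],
    )
    d = gsea(ranked2, prop, cfg)
    assert a == d


def test_gsea_all_tied_fold_changes_deterministic():
    genes = [f"G{i:02d}" for i in range(40)]
    r1 = RankedGeneList("ties", genes, [1.0] * 40)
    sets = {"S": set(genes[:8]), "T": set(genes[8:20])}
    cfg = EnrichmentConfig(seed=4, n_permutations=100, min_set_size=2)
    a = gsea(r1, sets, cfg)
    b = gsea(r1, sets, cfg)
    assert a == b
    assert all(-1 <= rec.statistic <= 1 for rec in a)


def test_gsea_permutation_count_validation(planted_run):
    ranked, prop, _ = planted_run
    with pytest.raises(ValueError):
        gsea(ranked, prop, EnrichmentConfig(n_permutations=0))


def test_select_significant_strictly_below():
    from aoplink.enrichment import EnrichmentRecord

    records = [
        EnrichmentRecord(f"GO:000000{i}", 10, 0.5, 1.5, 0.01, f)
        for i, f in enumerate((0.24, 0.25, 0.26), start=1)
    ]
    chosen = select_significant(records, 0.25, source_label="UFP 20h")
    assert chosen.terms == frozenset({"GO:0000001"})
    assert chosen.provenance == "enrichment_derived"
    assert chosen.source_label == "UFP 20h"
    assert select_significant([], 0.25).unique_count == 0


# ---------------------------------------------------------------------------
# ORA
# ---------------------------------------------------------------------------


def test_ora_exact_small_case_by_enumeration():
    """p for (universe 20, term set 5, query 5, overlap 4) equals exhaustive
    enumeration over all C(20,5) queries."""
    universe = [f"g{i}" for i in range(20)]
    term_genes = set(universe[:5])
    query = set(universe[:4]) | {universe[10]}
    ann = AnnotationTable([(g, "GO:0000001") for g in term_genes])
    cfg = EnrichmentConfig(min_set_size=1)
    [rec] = ora(query, ann, universe=universe, config=cfg)
    hits = sum(
        1
        for draw in combinations(range(20), 5)
        if len(set(draw) & set(range(5))) >= 4
    )
    assert hits / math.comb(20, 5) == pytest.approx(76 / 15504)
    assert rec.p_value == pytest.approx(76 / 15504, abs=1e-12)


def test_ora_matches_combinatorial_oracle_random_instances():
    rng = np.random.default_rng(21)
    for _ in range(100):
        N = int(rng.integers(8, 40))
        K = int(rng.integers(1, N))
        n = int(rng.integers(1, N))
        universe = [f"g{i}" for i in range(N)]
        term_genes = set(universe[:K])
        query = {universe[i] for i in rng.choice(N, size=n, replace=False)}
        ann = AnnotationTable([(g, "GO:0000001") for g in term_genes])
        [rec] = ora(query, ann, universe=universe, config=EnrichmentConfig(min_set_size=1))
        k_obs = len(term_genes & query)
        assert rec.p_value == pytest.approx(
            hypergeom_tail_oracle(N, K, n, k_obs), abs=1e-12
        )
        assert rec.statistic == k_obs


def test_ora_zero_overlap_p_is_one():
    universe = [f"g{i}" for i in range(10)]
    ann = AnnotationTable([(g, "GO:0000001") for g in universe[:3]])
    [rec] = ora(set(universe[5:]), ann, universe=universe, config=EnrichmentConfig(min_set_size=1))
    assert rec.p_value == pytest.approx(1.0)


def test_ora_planted_term_ranks_first():
    """The planted term beats all non-planted terms on p in ≥18/20 seeds."""
    from aoplink.ontology import parse_obo

    wins = 0
    for seed in range(20):
        cfg = SyntheticConfig(seed=seed, n_terms=60, n_genes=300, planted_terms=1)
        obo, om = generate_ontology(cfg)
        ann, am = generate_annotation(om, cfg)
        prop = ann.propagate(parse_obo(io.StringIO(obo)))
        from aoplink.synthetic import generate_disease_genes, pick_planted_terms

        genes, truth = generate_disease_genes(am, cfg)
        records = ora(genes, prop)
        planted = truth["planted_terms"][0]
        best_p = min(r.p_value for r in records)
        planted_rec = next(r for r in records if r.term_id == planted)
        # ancestors of the planted leaf share its genes; require the planted
        # term to be at the very top of the ranking (ties allowed)
        if planted_rec.p_value == best_p:
            wins += 1
    assert wins >= 18


def test_ora_empty_query_errors(annotation):
    with pytest.raises(ValueError, match="id-mapping"):
        ora({"ZZZ_NOT_A_GENE"}, annotation)


def test_ora_bh_fdr_monotone(annotation):
    rng = np.random.default_rng(2)
    universe = sorted(annotation.universe)
    query = {universe[i] for i in rng.choice(len(universe), 40, replace=False)}
    records = ora(query, annotation)
    by_p = sorted(records, key=lambda r: r.p_value)
    fdrs = [r.fdr for r in by_p]
    assert all(a <= b + 1e-12 for a, b in zip(fdrs, fdrs[1:]))
    assert all(0 <= r.fdr <= 1 for r in records)


# ---------------------------------------------------------------------------
# gene-set file formats
# ---------------------------------------------------------------------------


def test_gmt_roundtrip(tmp_path):
    sets = {"GO:0000001": {"A", "B"}, "GO:0000002": {"C"}}
    path = tmp_path / "sets.gmt"
    write_gmt(sets, path)
    assert read_gmt(path) == sets


def test_annotation_from_gaf(tmp_path):
    gaf = tmp_path / "anno.gaf"
    gaf.write_text(
        "!gaf-version: 2.2\n"
        "DB\tP1\tP1SYM\t\tGO:0000001\tREF\tIEA\t\tP\t\t\t\t\t\t\t\t\n"
        "DB\tP2\tP2SYM\t\tGO:0000002\tREF\tEXP\t\tP\t\t\t\t\t\t\t\t\n"
    )
    ann = AnnotationTable.from_gaf(gaf)
    assert ann.term_to_genes == {"GO:0000001": {"P1"}, "GO:0000002": {"P2"}}


def test_true_path_propagation(graph, bundle):
    """After propagation a gene annotated to a term is annotated to every
    is_a ancestor (the generator manifest is the oracle)."""
    prop = bundle["annotation"].propagate(graph)
    m = bundle["annotation_manifest"]["propagated_gene_sets"]
    assert set(prop.term_to_genes) == set(m)
    for term, genes in m.items():
        assert prop.term_to_genes[term] == set(genes)
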