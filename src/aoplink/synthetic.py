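"""Synthetic inputs with planted ground truth for every pipeline stage.

Generates — purely from a seed and stated parameters — a toy GO BP
ontology (OBO text), gene→term annotations, AOP event→GO mapping tables,
disease gene lists and fold-change-ranked differential-expression tables
with planted enrichment.  Each generator returns, next to the artifact in
the exact file dialect the pipeline reads, a *manifest* from which the
expected output of every downstream stage can be computed without running
that stage; manifests are therefore the oracles of the test suite.

Planted enrichment follows an additive Gaussian model: fold change =
Normal(0, noise_sd) + δ·1[gene ∈ any planted term].  Planted terms are
auto-picked among terms with 20–50 member genes after true-path
propagation, so the planted signal sits in gene sets of realistic
pathway size against a 2000-gene universe.

All randomness flows from one seed, stream-split per generator, so adding
a generator call never perturbs another generator's draws.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .curation import AopEvent
from .enrichment import AnnotationTable, RankedGeneList

# fixed stream ids: adding a stream never shifts existing ones
_STREAMS = {
    "ontology": 11,
    "annotation": 13,
    "planted": 17,
    "ranked": 19,
    "disease": 23,
    "events": 29,
}

PLANTED_SIZE_RANGE = (20, 50)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the synthetic benchmark."""

    seed: int = 0
    n_terms: int = 200
    max_children: int = 4
    n_genes: int = 2000
    genes_per_leaf_term: tuple[int, int] = (5, 50)
    planted_terms: int | tuple[str, ...] = 5
    effect_shift: float = 1.5
    noise_sd: float = 1.0
    disease_gene_contamination: float = 0.2
    n_events: int = 10

    def __post_init__(self) -> None:
        if self.n_terms < 2 or self.n_genes < 1 or self.max_children < 1:
            raise ValueError("counts must be positive (n_terms >= 2)")
        if not (0 <= self.disease_gene_contamination < 1):
            raise ValueError("contamination must lie in [0, 1)")
        lo, hi = self.genes_per_leaf_term
        if not (0 < lo <= hi):
            raise ValueError("genes_per_leaf_term must be a positive range")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([_STREAMS[stream], self.seed])


def _term_id(i: int) -> str:
    return f"GO:{i:07d}"


def _gene_id(i: int) -> str:
    return f"SGENE{i:04d}"


def generate_ontology(config: SyntheticConfig) -> tuple[str, dict]:
    """A rooted is_a DAG in the BP namespace, as OBO text plus manifest.

    Term 1 is the root; every later term attaches to one uniformly chosen
    earlier term that still has capacity (< max_children), with a 10%
    chance of a second is_a parent to make the graph a genuine DAG.  The
    manifest lists terms, edges and per-term descendant-closure counts.
    """
    rng = config.rng("ontology")
    n = config.n_terms
    children_count = {1: 0}
    edges: list[tuple[str, str]] = []  # (child, parent)
    parents_of: dict[int, set[int]] = {1: set()}
    for i in range(2, n + 1):
        capacity = [t for t, c in children_count.items() if c < config.max_children]
        parent = int(capacity[rng.integers(len(capacity))])
        parents_of[i] = {parent}
        children_count[parent] += 1
        children_count[i] = 0
        if i > 2 and rng.random() < 0.10:
            extra_pool = [t for t in capacity if t != parent]
            if extra_pool:
                extra = int(extra_pool[rng.integers(len(extra_pool))])
                parents_of[i].add(extra)
                children_count[extra] += 1
        for p in sorted(parents_of[i]):
            edges.append((_term_id(i), _term_id(p)))

    # descendant closure counts, computed here independently of the ontology module
    children_of: dict[int, list[int]] = {i: [] for i in range(1, n + 1)}
    for c, ps in parents_of.items():
        for p in ps:
            children_of[p].append(c)
    desc_counts: dict[str, int] = {}
    desc_sets: dict[int, set[int]] = {}
    for i in range(n, 0, -1):  # children have larger indices than parents
        s = {i}
        for c in children_of[i]:
            s |= desc_sets[c]
        desc_sets[i] = s
        desc_counts[_term_id(i)] = len(s)

    buf = io.StringIO()
    buf.write("format-version: 1.2\nontology: synthetic-go-bp\n")
    for i in range(1, n + 1):
        buf.write("\n[Term]\n")
        buf.write(f"id: {_term_id(i)}\n")
        buf.write(f"name: synthetic process {i}\n")
        buf.write("namespace: biological_process\n")
        for p in sorted(parents_of[i]):
            buf.write(f"is_a: {_term_id(p)} ! synthetic process {p}\n")
    manifest = {
        "n_terms": n,
        "terms": [_term_id(i) for i in range(1, n + 1)],
        "edges": [[c, p] for c, p in edges],
        "descendant_counts": desc_counts,
        "leaves": [_term_id(i) for i in range(1, n + 1) if not children_of[i]],
        "parents_of": {_term_id(i): sorted(_term_id(p) for p in ps) for i, ps in parents_of.items()},
    }
    return buf.getvalue(), manifest


def generate_annotation(
    ontology_manifest: dict, config: SyntheticConfig
) -> tuple[AnnotationTable, dict]:
    """Genes assigned to leaf terms, then true-path propagated.

    Leaf gene-set sizes are uniform over ``genes_per_leaf_term``; every
    gene is guaranteed at least one leaf assignment so the annotation
    universe equals the full gene universe.  The manifest records the final
    (propagated) gene set of every term, computed with the generator's own
    parent map.
    """
    rng = config.rng("annotation")
    genes = [_gene_id(i) for i in range(1, config.n_genes + 1)]
    leaves = list(ontology_manifest["leaves"])
    lo, hi = config.genes_per_leaf_term
    leaf_genes: dict[str, set[str]] = {}
    for leaf in leaves:
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(config.n_genes, size=min(size, config.n_genes), replace=False)
        leaf_genes[leaf] = {genes[j] for j in idx}
    assigned = set().union(*leaf_genes.values()) if leaf_genes else set()
    orphans = [g for g in genes if g not in assigned]
    for g in orphans:
        leaf = leaves[int(rng.integers(len(leaves)))]
        leaf_genes[leaf].add(g)

    parents_of = {t: set(ps) for t, ps in ontology_manifest["parents_of"].items()}

    def ancestors(term: str) -> set[str]:
        seen = {term}
        frontier = [term]
        while frontier:
            t = frontier.pop()
            for p in parents_of.get(t, ()):  # root has no parents
                if p not in seen:
                    seen.add(p)
                    frontier.append(p)
        return seen

    propagated: dict[str, set[str]] = {}
    for leaf, gs in leaf_genes.items():
        for anc in ancestors(leaf):
            propagated.setdefault(anc, set()).update(gs)

    pairs = [(g, leaf) for leaf, gs in sorted(leaf_genes.items()) for g in sorted(gs)]
    table = AnnotationTable(pairs)
    manifest = {
        "leaf_gene_sets": {t: sorted(gs) for t, gs in sorted(leaf_genes.items())},
        "propagated_gene_sets": {t: sorted(gs) for t, gs in sorted(propagated.items())},
        "universe": genes,
    }
    return table, manifest


def pick_planted_terms(annotation_manifest: dict, config: SyntheticConfig) -> list[str]:
    """The planted terms: explicit list, or auto-picked 20–50-gene leaf terms.

    Auto-pick draws without replacement from the *leaf* terms whose gene
    count lies in ``PLANTED_SIZE_RANGE``, using the dedicated ``planted``
    stream so the ranked-list and disease-gene generators agree on the
    truth.  Restricting to leaves keeps the ground truth unambiguous: a
    planted internal term would make every descendant a fully-planted
    "non-planted" term; with leaves, only ancestors receive (diluted)
    planted signal.
    """
    if not isinstance(config.planted_terms, int):
        return list(config.planted_terms)
    rng = config.rng("planted")
    lo, hi = PLANTED_SIZE_RANGE
    leaf_sets = annotation_manifest["leaf_gene_sets"]
    eligible = sorted(t for t, gs in leaf_sets.items() if lo <= len(gs) <= hi)
    k = config.planted_terms
    if len(eligible) < k:
        raise ValueError(
            f"only {len(eligible)} terms with {lo}-{hi} genes; cannot plant {k}"
        )
    idx = rng.choice(len(eligible), size=k, replace=False)
    return [eligible[i] for i in sorted(idx)]


def generate_ranked_list(
    annotation_manifest: dict,
    config: SyntheticConfig,
    condition_label: str = "synthetic condition",
) -> tuple[RankedGeneList, dict]:
    """A fold-change table with planted enrichment, plus the truth manifest.

    fold change = Normal(0, noise_sd) + effect_shift for members of any
    planted term.  Raises when a planted term has fewer genes than the
    default minimum testable set size (5).
    """
    planted = pick_planted_terms(annotation_manifest, config)
    sets = annotation_manifest["propagated_gene_sets"]
    for t in planted:
        if len(sets.get(t, ())) < 5:
            raise ValueError(f"planted term {t} has fewer than 5 genes")
    planted_genes = set().union(*(set(sets[t]) for t in planted)) if planted else set()
    rng = config.rng("ranked")
    genes = annotation_manifest["universe"]
    fc = rng.normal(0.0, config.noise_sd, size=len(genes))
    mask = np.array([g in planted_genes for g in genes])
    fc = fc + config.effect_shift * mask
    ranked = RankedGeneList(condition_label, genes, fc)
    truth = {
        "planted_terms": planted,
        "planted_genes": sorted(planted_genes),
        "effect_shift": config.effect_shift,
        "noise_sd": config.noise_sd,
    }
    return ranked, truth


def generate_disease_genes(
    annotation_manifest: dict, config: SyntheticConfig
) -> tuple[list[str], dict]:
    """A disease gene list: planted-term genes diluted with random genes.

    A fraction (1 − contamination) of the list is subsampled from the union
    of planted-term genes; the rest is padded with uniformly drawn
    non-planted universe genes.  The truth manifest records both parts.
    """
    planted = pick_planted_terms(annotation_manifest, config)
    sets = annotation_manifest["propagated_gene_sets"]
    union = sorted(set().union(*(set(sets[t]) for t in planted))) if planted else []
    rng = config.rng("disease")
    c = config.disease_gene_contamination
    n_true = max(1, int(round(len(union) * (1 - c))))
    true_idx = rng.choice(len(union), size=n_true, replace=False)
    true_genes = [union[i] for i in sorted(true_idx)]
    n_noise = int(round(len(union) * c))
    pool = [g for g in annotation_manifest["universe"] if g not in set(union)]
    noise_idx = rng.choice(len(pool), size=min(n_noise, len(pool)), replace=False)
    noise_genes = [pool[i] for i in sorted(noise_idx)]
    gene_list = true_genes + noise_genes
    truth = {
        "planted_terms": planted,
        "true_genes": true_genes,
        "noise_genes": noise_genes,
    }
    return gene_list, truth


def generate_event_mappings(
    ontology_manifest: dict, config: SyntheticConfig
) -> tuple[str, list[AopEvent], dict]:
    """Synthetic AOP event→GO mapping table (TSV text, events, manifest).

    Each of ``n_events`` events maps to 1–3 parent terms drawn (with
    replacement across events) from the internal, non-root terms, so that
    term duplication across events is controlled and the raw vs unique
    expanded counts are known from the ontology manifest's descendant
    closures.
    """
    rng = config.rng("events")
    desc = ontology_manifest["descendant_counts"]
    leaves = set(ontology_manifest["leaves"])
    internal = sorted(t for t in ontology_manifest["terms"] if t not in leaves and t != ontology_manifest["terms"][0])
    if not internal:
        internal = sorted(leaves)
    events: list[AopEvent] = []
    lines = ["aop_id\tevent_id\tevent_type\tgo_terms\tlabel"]
    raw_count = 0
    union: set[str] = set()

    # descendant closures via the manifest's parent map (oracle-side BFS)
    parents_of = {t: set(ps) for t, ps in ontology_manifest["parents_of"].items()}
    children_of: dict[str, list[str]] = {}
    for t, ps in parents_of.items():
        for p in ps:
            children_of.setdefault(p, []).append(t)

    def closure(term: str) -> set[str]:
        seen = {term}
        frontier = [term]
        while frontier:
            t = frontier.pop()
            for ch in children_of.get(t, ()):  # leaves absent from the map
                if ch not in seen:
                    seen.add(ch)
                    frontier.append(ch)
        return seen

    for e in range(1, config.n_events + 1):
        n_terms = int(rng.integers(1, 4))
        idx = rng.choice(len(internal), size=min(n_terms, len(internal)), replace=False)
        terms = tuple(internal[i] for i in sorted(idx))
        event_type = "MIE" if e == 1 else "KE"
        events.append(
            AopEvent(
                aop_id="AOP 1",
                event_id=f"Event {e}",
                event_type=event_type,
                mapped_terms=terms,
                label=f"synthetic event {e}",
            )
        )
        lines.append(f"AOP 1\tEvent {e}\t{event_type}\t{';'.join(terms)}\tsynthetic event {e}")
        for t in terms:
            cl = closure(t)
            assert len(cl) == desc[t]
            raw_count += len(cl)
            union |= cl
    manifest = {
        "n_events": config.n_events,
        "event_terms": {ev.event_id: list(ev.mapped_terms) for ev in events},
        "raw_count": raw_count,
        "unique_count": len(union),
        "union_terms": sorted(union),
    }
    return "\n".join(lines) + "\n", events, manifest


def generate_bundle(config: SyntheticConfig, n_conditions: int = 1) -> dict:
    """Everything at once, for the orchestrated workflow and the examples.

    All conditions share the same planted terms — they emulate different
    chemicals perturbing one disease mechanism set — but conditions beyond
    the first draw their noise with a shifted seed, so fold changes are
    independent across conditions.
    """
    obo_text, ont_manifest = generate_ontology(config)
    annotation, ann_manifest = generate_annotation(ont_manifest, config)
    events_tsv, events, ev_manifest = generate_event_mappings(ont_manifest, config)
    disease, disease_truth = generate_disease_genes(ann_manifest, config)
    planted = tuple(pick_planted_terms(ann_manifest, config))
    conditions = []
    for i in range(n_conditions):
        cfg_i = replace(
            config,
            seed=config.seed + 1000 * i,
            planted_terms=planted,
        ) if i else config
        label = f"condition {i + 1}"
        ranked, truth = generate_ranked_list(ann_manifest, cfg_i, condition_label=label)
        conditions.append({"ranked": ranked, "truth": truth})
    return {
        "config": config,
        "obo_text": obo_text,
        "ontology_manifest": ont_manifest,
        "annotation": annotation,
        "annotation_manifest": ann_manifest,
        "events_tsv": events_tsv,
        "events": events,
        "events_manifest": ev_manifest,
        "disease_genes": disease,
        "disease_truth": disease_truth,
        "conditions": conditions,
    }


def ranked_list_to_tsv(ranked: RankedGeneList) -> str:
    """The two-column DE dialect the pipeline reads."""
    lines = ["Gene ID\tFold Change Value"]
    for g, v in zip(ranked.genes, ranked.fold_changes):
        lines.append(f"{g}\t{float(v)!r}")
    return "\n".join(lines) + "\n"


def disease_genes_to_tsv(genes: Sequence[str], disease_id: str = "SYN:AA") -> str:
    lines = ["gene_id\tdisease_id\tscore"]
    for g in genes:
        lines.append(f"{g}\t{disease_id}\t0.5")
    return "\n".join(lines) + "\n"
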