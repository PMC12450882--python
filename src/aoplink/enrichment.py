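"""Gene set enrichment engines: weighted running-sum GSEA and hypergeometric ORA.

Two engines turn per-condition transcriptomics into enriched GO BP sets:

* :func:`gsea` — ranked-list Gene Set Enrichment Analysis with the weighted
  Kolmogorov–Smirnov running-sum statistic, a gene-set permutation null,
  normalized enrichment scores (NES) and a pooled-NES empirical FDR.  Input
  is a fold-change-ranked gene list per exposure condition; there are no
  sample-level replicates, so the null permutes gene sets, not phenotypes.
* :func:`ora` — one-sided hypergeometric overrepresentation analysis with
  Benjamini–Hochberg FDR, used for deriving disease term sets from gene
  lists.

Terms with FDR strictly below the configured threshold (default 0.25) are
selected into an ``enrichment_derived`` term set via
:func:`select_significant`.

Gene identifiers are matched case-insensitively (upper-cased internally).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .curation import GoTermSet
from .ontology import OntologyGraph, normalize_term_id

logger = logging.getLogger(__name__)


def _norm_gene(g: str) -> str:
    return str(g).strip().upper()


@dataclass(frozen=True)
class EnrichmentConfig:
    """Knobs of both enrichment engines.

    fdr_threshold:
        Selection rule for significant terms; strictly-below comparison.
    n_permutations:
        Size of the gene-set permutation null for GSEA.
    weight_exponent:
        Exponent on |fold change| in the running sum; 1 is the canonical
        weighted statistic, 0 the classic Kolmogorov–Smirnov variant.
    min_set_size / max_set_size:
        Gene-set size window (computed on the genes present in the ranked
        list / universe) outside which terms are not tested.
    """

    fdr_threshold: float = 0.25
    n_permutations: int = 1000
    weight_exponent: float = 1.0
    min_set_size: int = 5
    max_set_size: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fdr_threshold <= 1):
            raise ValueError("fdr_threshold must lie in (0, 1]")
        if self.min_set_size > self.max_set_size:
            raise ValueError("min_set_size must not exceed max_set_size")
        if self.n_permutations <= 0:
            raise ValueError("n_permutations must be positive")
        if self.n_permutations < 100:
            logger.warning(
                "n_permutations=%d is low; empirical p/FDR will be coarse",
                self.n_permutations,
            )


@dataclass(frozen=True)
class EnrichmentRecord:
    """Per-term enrichment outcome from either engine.

    For GSEA, ``statistic`` is the enrichment score (ES) and
    ``normalized_statistic`` the NES; for ORA, the overlap count and the
    odds ratio.  ``genes`` carries the leading edge (GSEA) or the
    overlapping genes (ORA).
    """

    term_id: str
    set_size: int
    statistic: float
    normalized_statistic: float
    p_value: float
    fdr: float
    genes: tuple[str, ...] = ()


class RankedGeneList:
    """An ordered (gene, fold change) list for one exposure condition.

    Rows are sorted by descending fold change, ties broken by ascending
    gene id so that the ordering is deterministic.  Duplicate gene ids keep
    the record with the largest |fold change| (probe-collapse convention,
    logged).
    """

    def __init__(self, condition_label: str, genes: Sequence[str], fold_changes: Sequence[float]):
        genes = [_norm_gene(g) for g in genes]
        fc = np.asarray(fold_changes, dtype=float)
        if len(genes) != len(fc):
            raise ValueError("genes and fold_changes must have equal length")
        if len(genes) == 0:
            raise ValueError("ranked list is empty")
        best: dict[str, float] = {}
        dup = 0
        for g, v in zip(genes, fc):
            if g in best:
                dup += 1
                if abs(v) > abs(best[g]):
                    best[g] = v
            else:
                best[g] = v
        if dup:
            logger.warning(
                "%s: collapsed %d duplicate gene id(s), keeping max |fold change|",
                condition_label,
                dup,
            )
        order = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))
        self.condition_label = condition_label
        self.genes: np.ndarray = np.array([g for g, _ in order])
        self.fold_changes: np.ndarray = np.array([v for _, v in order], dtype=float)
        self._index = {g: i for i, g in enumerate(self.genes)}

    def __len__(self) -> int:
        return len(self.genes)

    def positions(self, gene_set: Iterable[str]) -> np.ndarray:
        """Sorted rank positions of the gene-set members present in the list."""
        pos = [self._index[_norm_gene(g)] for g in gene_set if _norm_gene(g) in self._index]
        return np.array(sorted(pos), dtype=np.int64)

    @classmethod
    def from_table(cls, source, condition_label: str | None = None) -> "RankedGeneList":
        """Read the two-column DE dialect: headers "Gene ID", "Fold Change Value"."""
        df = (
            source
            if isinstance(source, pd.DataFrame)
            else pd.read_csv(source, sep="\t", float_precision="round_trip")
        )
        cols = {c.strip().lower(): c for c in df.columns}
        try:
            gcol = cols["gene id"]
            fcol = cols["fold change value"]
        except KeyError as exc:
            raise ValueError(
                'DE table must have columns "Gene ID" and "Fold Change Value"'
            ) from exc
        label = condition_label or "condition"
        return cls(label, df[gcol].astype(str).tolist(), df[fcol].astype(float).tolist())


class AnnotationTable:
    """gene→GO BP annotation with true-path propagation.

    Built from (gene, term) pairs; after :meth:`propagate` every gene
    annotated to a term is also annotated to all of that term's is_a
    ancestors within the biological_process namespace.  The universe is the
    set of genes carrying at least one BP annotation.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self.term_to_genes: dict[str, set[str]] = {}
        for gene, term in pairs:
            self.term_to_genes.setdefault(normalize_term_id(term), set()).add(_norm_gene(gene))
        self._propagated = False
        self._matrix_cache: tuple | None = None

    @classmethod
    def from_tsv(cls, source) -> "AnnotationTable":
        """Two-column TSV: gene_id <tab> term_id (header optional)."""
        df = pd.read_csv(source, sep="\t", dtype=str, comment="!")
        if df.shape[1] < 2:
            raise ValueError("annotation TSV needs two columns: gene_id, term_id")
        gcol, tcol = df.columns[:2]
        return cls(zip(df[gcol], df[tcol]))

    @classmethod
    def from_gaf(cls, source) -> "AnnotationTable":
        """GAF 2.x subset: columns 2 (object id), 5 (GO id), 7 (evidence)."""
        pairs: list[tuple[str, str]] = []
        fh = open(source) if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__") else source
        try:
            for line in fh:
                if not line.strip() or line.startswith("!"):
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 7:
                    continue
                pairs.append((cols[1], cols[4]))
        finally:
            if fh is not source:
                fh.close()
        return cls(pairs)

    @classmethod
    def from_gmt(cls, source) -> "AnnotationTable":
        table = cls([])
        table.term_to_genes = {t: set(gs) for t, gs in read_gmt(source).items()}
        return table

    def propagate(self, graph: OntologyGraph) -> "AnnotationTable":
        """Apply the true-path rule over is_a ancestors (BP namespace only)."""
        out: dict[str, set[str]] = {}
        for term, genes in self.term_to_genes.items():
            if term not in graph:
                logger.warning("annotation term %s not in ontology; kept as-is", term)
                out.setdefault(term, set()).update(genes)
                continue
            canon = graph.resolve(term)
            if graph.terms[canon].namespace != "biological_process":
                continue
            for anc in graph.ancestors(canon, ("is_a",)):
                out.setdefault(anc, set()).update(genes)
        new = AnnotationTable([])
        new.term_to_genes = out
        new._propagated = True
        return new

    @property
    def universe(self) -> set[str]:
        u: set[str] = set()
        for genes in self.term_to_genes.values():
            u |= genes
        return u

    def size_filtered(self, min_size: int, max_size: int, within: set[str] | None = None) -> dict[str, set[str]]:
        """Term→gene-set mapping restricted to sets whose effective size
        (intersection with ``within`` when given) lies in [min_size, max_size]."""
        out = {}
        for term, genes in self.term_to_genes.items():
            eff = genes & within if within is not None else genes
            if min_size <= len(eff) <= max_size:
                out[term] = eff
        return out


def read_gmt(source) -> dict[str, set[str]]:
    """Read a GMT gene-set collection (term <tab> description <tab> genes...)."""
    sets: dict[str, set[str]] = {}
    fh = open(source) if not hasattr(source, "read") else source
    try:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0].strip():
                continue
            sets[parts[0].strip()] = {_norm_gene(g) for g in parts[2:] if g.strip()}
    finally:
        if fh is not source:
            fh.close()
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path, description: str = "aoplink") -> None:
    with open(path, "w") as fh:
        for term in sorted(sets):
            genes = "\t".join(sorted(sets[term]))
            fh.write(f"{term}\t{description}\t{genes}\n")


# ---------------------------------------------------------------------------
# ORA — hypergeometric overrepresentation
# ---------------------------------------------------------------------------

def ora(
    query: Iterable[str],
    annotation: AnnotationTable,
    universe: Iterable[str] | None = None,
    config: EnrichmentConfig | None = None,
) -> list[EnrichmentRecord]:
    """One-sided hypergeometric overrepresentation analysis.

    For each term whose effective gene-set size lies within the configured
    window, the upper-tail hypergeometric probability of observing at least
    the observed overlap is computed, followed by Benjamini–Hochberg FDR
    across the tested terms.  The default universe is every gene with at
    least one BP annotation.  Records are sorted by (p, term_id).
    """
    config = config or EnrichmentConfig()
    uni = set(_norm_gene(g) for g in universe) if universe is not None else annotation.universe
    q = {_norm_gene(g) for g in query} & uni
    if not q:
        raise ValueError(
            "no query genes map into the annotation universe "
            "(id-mapping failure: check gene identifier type/casing)"
        )
    term_sets = annotation.size_filtered(config.min_set_size, config.max_set_size, within=uni)
    if not term_sets:
        logger.warning("no term passed the set-size filter; empty ORA result")
        return []
    terms = sorted(term_sets)
    N, n = len(uni), len(q)
    K = np.array([len(term_sets[t]) for t in terms], dtype=np.int64)
    k = np.array([len(term_sets[t] & q) for t in terms], dtype=np.int64)
    pvals = hypergeom.sf(k - 1, N, K, n)
    pvals = np.clip(pvals, 0.0, 1.0)
    fdrs = multipletests(pvals, method="fdr_bh")[1]
    # sample odds ratio of the 2x2 overlap table; inf when a zero cell
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (k * (N - K - n + k)) / np.where((K - k) * (n - k) > 0, (K - k) * (n - k), np.nan)
    records = [
        EnrichmentRecord(
            term_id=t,
            set_size=int(K[i]),
            statistic=float(k[i]),
            normalized_statistic=float(odds[i]) if np.isfinite(odds[i]) else float("inf"),
            p_value=float(pvals[i]),
            fdr=float(fdrs[i]),
            genes=tuple(sorted(term_sets[t] & q)),
        )
        for i, t in enumerate(terms)
    ]
    records.sort(key=lambda r: (r.p_value, r.term_id))
    return records


# ---------------------------------------------------------------------------
# GSEA — weighted Kolmogorov–Smirnov running sum with gene-set permutation
# ---------------------------------------------------------------------------

def gsea_enrichment_score(
    ranked: RankedGeneList,
    gene_set: Iterable[str],
    weight_exponent: float = 1.0,
):
    """Enrichment score of one gene set on one ranked list.

    Walking the ranked list from top to bottom, hits increment the running
    sum by |fold change|^weight normalized by the summed hit weights, misses
    decrement it by 1/(N − N_hits); the ES is the running-sum value of
    maximal absolute deviation (ties broken towards the positive extremum).
    The leading edge contains the hit genes up to (ES ≥ 0) or after
    (ES < 0) the extremum.

    Returns ``(ES, running_sum, leading_edge)`` or ``None`` when the gene
    set shares no gene with the ranked list (logged, never a crash).
    """
    hits_pos = ranked.positions(gene_set)
    n = len(ranked)
    n_hit = len(hits_pos)
    if n_hit == 0:
        logger.warning("%s: gene set has no member in the ranked list; skipped", ranked.condition_label)
        return None
    weights = np.abs(ranked.fold_changes) ** weight_exponent
    hit_w = weights[hits_pos]
    total = hit_w.sum()
    if total == 0:  # degenerate all-zero weights: fall back to equal steps
        hit_w = np.ones(n_hit)
        total = float(n_hit)
    steps = np.zeros(n)
    steps[hits_pos] = hit_w / total
    if n > n_hit:
        miss = np.ones(n, dtype=bool)
        miss[hits_pos] = False
        steps[miss] = -1.0 / (n - n_hit)
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        es = float(running[i_max])
        leading = [str(g) for g in ranked.genes[hits_pos[hits_pos <= i_max]]]
    else:
        es = float(running[i_min])
        leading = [str(g) for g in ranked.genes[hits_pos[hits_pos > i_min]]]
    return es, running, tuple(leading)


def _es_from_positions(pos: np.ndarray, weights: np.ndarray, n: int) -> np.ndarray:
    """Vectorized ES for a batch of hit-position sets.

    ``pos`` is (m, k) of rank positions (any order); evaluation exploits
    that the running-sum extrema occur at, or immediately before, hit
    positions, so only O(k) candidates per row are examined.
    """
    pos = np.sort(pos, axis=1)
    m, k = pos.shape
    w = weights[pos]
    total = w.sum(axis=1, keepdims=True)
    zero = total[:, 0] == 0
    if np.any(zero):  # all-zero weights: equal steps
        w[zero] = 1.0
        total[zero] = k
    gains = np.cumsum(w, axis=1) / total
    if n == k:
        return gains[:, -1]
    idx = np.arange(k, dtype=np.int64)
    miss_before = (pos - idx) / (n - k)
    val_at_hit = gains - miss_before
    val_pre_hit = np.concatenate([np.zeros((m, 1)), gains[:, :-1]], axis=1) - miss_before
    best_pos = val_at_hit.max(axis=1)
    best_neg = np.minimum(val_pre_hit.min(axis=1), 0.0)
    return np.where(best_pos >= -best_neg, best_pos, best_neg)


def gsea(
    ranked: RankedGeneList,
    collection: Mapping[str, Iterable[str]] | AnnotationTable,
    config: EnrichmentConfig | None = None,
) -> list[EnrichmentRecord]:
    """Ranked-list GSEA over a gene-set collection.

    Per term: observed ES; a gene-set permutation null of
    ``config.n_permutations`` same-size random sets drawn (without
    replacement) from the ranked genes; NES = ES divided by the mean |null
    ES| of the same sign; an empirical same-sign p-value; FDR by pooling the
    normalized null distribution across all terms.  Bit-reproducible for a
    fixed seed, and invariant to the input row order of the DE table and of
    the collection.
    """
    config = config or EnrichmentConfig()
    if isinstance(collection, AnnotationTable):
        sets = collection.term_to_genes
    else:
        sets = {t: set(g) for t, g in collection.items()}
    ranked_genes = set(ranked.genes)
    eff = {
        t: {_norm_gene(g) for g in gs} & ranked_genes
        for t, gs in sets.items()
    }
    eff = {
        t: gs
        for t, gs in eff.items()
        if config.min_set_size <= len(gs) <= config.max_set_size
    }
    if not eff:
        logger.warning("%s: no gene set within the size window", ranked.condition_label)
        return []
    terms = sorted(eff)
    n = len(ranked)
    weights = np.abs(ranked.fold_changes) ** config.weight_exponent

    observed: dict[str, tuple[float, tuple[str, ...]]] = {}
    for t in terms:
        res = gsea_enrichment_score(ranked, eff[t], config.weight_exponent)
        assert res is not None  # eff sets intersect the ranked list by construction
        observed[t] = (res[0], res[2])

    # Shared permutation pool: each row is a permutation of all rank
    # positions; the first k entries form a uniform random k-subset, so one
    # pool serves every set size and collection order cannot perturb draws.
    rng = np.random.default_rng(config.seed)
    B = config.n_permutations
    pool = np.argsort(rng.random((B, n)), axis=1)

    es_obs = np.array([observed[t][0] for t in terms])
    nes_obs = np.empty(len(terms))
    pvals = np.empty(len(terms))
    pooled_null: list[np.ndarray] = []
    for i, t in enumerate(terms):
        k = len(eff[t])
        null_es = _es_from_positions(pool[:, :k], weights, n)
        pos_null = null_es[null_es > 0]
        neg_null = -null_es[null_es < 0]
        mean_pos = pos_null.mean() if pos_null.size else np.abs(null_es).mean() or 1.0
        mean_neg = neg_null.mean() if neg_null.size else np.abs(null_es).mean() or 1.0
        es = es_obs[i]
        if es >= 0:
            nes_obs[i] = es / mean_pos
            pvals[i] = (1 + np.sum(pos_null >= es)) / (1 + pos_null.size)
        else:
            nes_obs[i] = es / mean_neg
            pvals[i] = (1 + np.sum(neg_null >= -es)) / (1 + neg_null.size)
        null_nes = np.where(null_es >= 0, null_es / mean_pos, null_es / mean_neg)
        pooled_null.append(null_nes)
    null_all = np.concatenate(pooled_null)
    fdrs = _pooled_nes_fdr(nes_obs, null_all)

    records = [
        EnrichmentRecord(
            term_id=t,
            set_size=len(eff[t]),
            statistic=float(es_obs[i]),
            normalized_statistic=float(nes_obs[i]),
            p_value=float(pvals[i]),
            fdr=float(fdrs[i]),
            genes=observed[t][1],
        )
        for i, t in enumerate(terms)
    ]
    records.sort(key=lambda r: (r.p_value, r.term_id))
    return records


def _pooled_nes_fdr(nes_obs: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """Empirical FDR from the pooled normalized null, per sign.

    q(NES*) = [share of pooled same-sign null NES at least as extreme] /
    [share of observed same-sign NES at least as extreme], clipped to [0, 1]
    and made monotone non-decreasing as significance decreases.
    """
    fdr = np.ones_like(nes_obs)
    for sign in (1, -1):
        mask = nes_obs >= 0 if sign == 1 else nes_obs < 0
        if not mask.any():
            continue
        obs = sign * nes_obs[mask]
        null = sign * null_nes[null_nes >= 0 if sign == 1 else null_nes < 0]
        if null.size == 0:
            fdr[mask] = 0.0
            continue
        null_sorted = np.sort(null)
        obs_sorted = np.sort(obs)
        # fraction of null >= x  /  fraction of observed >= x
        num = 1.0 - np.searchsorted(null_sorted, obs, side="left") / null.size
        den = (obs.size - np.searchsorted(obs_sorted, obs, side="left")) / obs.size
        raw = np.clip(np.where(den > 0, num / np.maximum(den, 1e-300), 1.0), 0.0, 1.0)
        # monotone: a more extreme NES never has a larger q
        order = np.argsort(-obs)  # most significant first
        mono = np.minimum.accumulate(raw[order][::-1])[::-1]
        out = np.empty_like(raw)
        out[order] = mono
        fdr[mask] = out
    return fdr


def select_significant(
    records: Sequence[EnrichmentRecord],
    fdr_threshold: float = 0.25,
    source_label: str = "",
) -> GoTermSet:
    """Terms with FDR strictly below the threshold, as an enrichment-derived set."""
    terms = frozenset(r.term_id for r in records if r.fdr < fdr_threshold)
    return GoTermSet(terms=terms, provenance="enrichment_derived", source_label=source_label)


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in records],
            "set_size": [r.set_size for r in records],
            "statistic": [r.statistic for r in records],
            "normalized_statistic": [r.normalized_statistic for r in records],
            "p_value": [r.p_value for r in records],
            "fdr": [r.fdr for r in records],
            "genes": [";".join(r.genes) for r in records],
        }
    )
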