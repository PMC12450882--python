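"""Curated mechanism sets: AOP event→GO mappings and disease-gene derived terms.

Two routes produce disease-mechanism GO Biological Process sets:

* the AOP route — expert-curated tables mapping Molecular Initiating Events
  and Key Events of Adverse Outcome Pathways to GO terms, expanded with
  descendant ("child") terms and deduplicated;
* the gene-disease route — a DisGeNET-style gene/disease association table
  whose genes are fed into an overrepresentation analysis, keeping terms
  below an FDR threshold.

Both routes yield a provenance-tagged :class:`GoTermSet` that downstream
overlap analysis consumes; the two can be merged (union with dedup).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from .ontology import OntologyGraph, UnknownTermError, expand_terms, normalize_term_id

logger = logging.getLogger(__name__)

EVENT_TYPES = ("MIE", "KE", "AO")
PROVENANCES = ("aop_curated", "disgenet_derived", "enrichment_derived", "merged")

EVENT_COLUMNS = ("aop_id", "event_id", "event_type", "go_terms")


class SchemaError(ValueError):
    """An input table is missing required columns or carries invalid values."""


@dataclass(frozen=True)
class AopEvent:
    """One curated AOP event (MIE/KE/AO) with its mapped GO terms."""

    aop_id: str
    event_id: str
    event_type: str
    mapped_terms: tuple[str, ...]
    label: str = ""
    cascade_position: str | None = None

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise SchemaError(
                f"event {self.event_id}: event_type must be one of {EVENT_TYPES}, "
                f"got {self.event_type!r}"
            )


@dataclass(frozen=True)
class GoTermSet:
    """A deduplicated, provenance-tagged set of GO BP term ids.

    ``raw_count`` is the pre-dedup size (e.g. parent + child list lengths
    summed over events); ``unique_count`` is ``len(terms)``.
    """

    terms: frozenset[str]
    provenance: str
    source_label: str = ""
    raw_count: int | None = None

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.raw_count is None:
            object.__setattr__(self, "raw_count", len(self.terms))
        if self.raw_count < len(self.terms):
            raise ValueError("raw_count cannot be smaller than unique_count")

    @property
    def unique_count(self) -> int:
        return len(self.terms)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def sorted_terms(self) -> list[str]:
        return sorted(self.terms)


def load_event_mappings(source) -> list[AopEvent]:
    """Read an AOP event mapping TSV into a list of :class:`AopEvent`.

    Required columns: ``aop_id``, ``event_id``, ``event_type``, ``go_terms``
    (semicolon-separated GO accessions).  Optional: ``label``,
    ``cascade_position``.  Duplicated rows are collapsed with a warning;
    rows with empty ``go_terms`` are kept (empty mapping) and logged.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t", dtype=str)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"event mapping table missing column(s): {', '.join(missing)}")
    n_before = len(df)
    df = df.drop_duplicates()
    if len(df) < n_before:
        logger.warning("event mappings: collapsed %d duplicated row(s)", n_before - len(df))
    events: list[AopEvent] = []
    for _, row in df.iterrows():
        raw = row["go_terms"]
        if pd.isna(raw) or not str(raw).strip():
            logger.warning("event %s has no mapped GO terms", row["event_id"])
            terms: tuple[str, ...] = ()
        else:
            terms = tuple(
                dict.fromkeys(
                    normalize_term_id(tok)
                    for tok in str(raw).split(";")
                    if tok.strip()
                )
            )
        events.append(
            AopEvent(
                aop_id=str(row["aop_id"]),
                event_id=str(row["event_id"]),
                event_type=str(row["event_type"]),
                mapped_terms=terms,
                label=str(row["label"]) if "label" in df.columns and pd.notna(row.get("label")) else "",
                cascade_position=(
                    str(row["cascade_position"])
                    if "cascade_position" in df.columns and pd.notna(row.get("cascade_position"))
                    else None
                ),
            )
        )
    return events


def derive_aop_term_set(
    events: Sequence[AopEvent],
    graph: OntologyGraph,
    relations: Iterable[str] = ("is_a",),
    mode: str = "descendants",
    source_label: str = "",
    strict: bool = False,
) -> GoTermSet:
    """Expand every event's mapped terms with their child terms and deduplicate.

    ``raw_count`` is the summed size of the per-term expansions before the
    union (the paper-style "parents + linked children" count); the unique
    count is the deduplicated union.  Terms outside the biological_process
    namespace are filtered with a logged count; terms absent from the
    ontology are skipped with a warning unless ``strict``.
    """
    if not events:
        raise ValueError("no events supplied")
    union: set[str] = set()
    raw_count = 0
    n_missing = 0
    n_non_bp = 0
    for event in events:
        for tid in event.mapped_terms:
            try:
                canon = graph.resolve(tid)
            except UnknownTermError:
                if strict:
                    raise
                n_missing += 1
                logger.warning("event %s: term %s not in ontology, skipped", event.event_id, tid)
                continue
            if graph.terms[canon].namespace != "biological_process":
                n_non_bp += 1
                continue
            expansion = expand_terms(graph, [canon], relations, mode)[canon]
            raw_count += len(expansion)
            union |= expansion
    if n_non_bp:
        logger.info("filtered %d non-BP mapped term(s)", n_non_bp)
    return GoTermSet(
        terms=frozenset(union),
        provenance="aop_curated",
        source_label=source_label,
        raw_count=raw_count,
    )


def load_gene_disease_table(source, min_score: float | None = None) -> pd.DataFrame:
    """Read a DisGeNET-like TSV (gene_id, disease_id, optional score).

    Duplicate (gene, disease) pairs are dropped; scores, when present, must
    lie in [0, 1].  ``min_score`` optionally filters rows (the default keeps
    everything: no evidence-score cut-off is applied unless asked for).
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t", dtype={"gene_id": str, "disease_id": str})
    for col in ("gene_id", "disease_id"):
        if col not in df.columns:
            raise SchemaError(f"gene-disease table missing column {col!r}")
    if "score" in df.columns:
        scores = pd.to_numeric(df["score"], errors="coerce")
        bad = scores.dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise SchemaError("gene-disease scores must lie in [0, 1]")
        df = df.assign(score=scores)
        if min_score is not None:
            df = df[df["score"].fillna(0.0) >= min_score]
    df = df.drop_duplicates(subset=["gene_id", "disease_id"])
    return df.reset_index(drop=True)


def disease_genes(table: pd.DataFrame, disease_id: str) -> list[str]:
    """Genes associated with one disease, case preserved, duplicates removed."""
    sel = table[table["disease_id"] == disease_id]
    return list(dict.fromkeys(sel["gene_id"].astype(str)))


def derive_disease_term_set(
    genes: Sequence[str],
    annotation,
    config=None,
    source_label: str = "",
) -> GoTermSet:
    """Overrepresentation analysis of a disease gene list → GO BP term set.

    Runs the hypergeometric ORA engine against the annotation's universe and
    keeps terms with FDR strictly below ``config.fdr_threshold``.  Gene
    symbol matching is case-insensitive.  Raises if none of the supplied
    genes can be mapped into the annotation universe.
    """
    from .enrichment import EnrichmentConfig, ora, select_significant

    if config is None:
        config = EnrichmentConfig()
    if not genes:
        raise ValueError("no disease genes supplied")
    records = ora(set(genes), annotation, config=config)
    selected = select_significant(records, config.fdr_threshold, source_label=source_label)
    return replace(selected, provenance="disgenet_derived")


def merge_term_sets(a: GoTermSet, b: GoTermSet, source_label: str | None = None) -> GoTermSet:
    """Union of two term sets with duplicates removed (provenance ``merged``).

    ``raw_count`` of the result is the summed unique counts of the inputs,
    so the dedup gain remains visible.
    """
    label = source_label if source_label is not None else f"{a.source_label}+{b.source_label}"
    return GoTermSet(
        terms=a.terms | b.terms,
        provenance="merged",
        source_label=label,
        raw_count=a.unique_count + b.unique_count,
    )


def vocabulary_coverage(term_set: GoTermSet | int, vocabulary_size: int, decimals: int = 1) -> float:
    """Share of the GO BP vocabulary covered by a term set, as a percentage.

    The value is truncated (not rounded) to ``decimals`` decimal places so a
    set covering 8.15% of the vocabulary reports 8.1% rather than
    overstating its reach.
    """
    count = term_set if isinstance(term_set, int) else term_set.unique_count
    if vocabulary_size <= 0:
        raise ValueError("vocabulary_size must be positive")
    if count > vocabulary_size:
        raise ValueError("term set larger than the vocabulary it is measured against")
    pct = 100.0 * count / vocabulary_size
    factor = 10 ** decimals
    return int(pct * factor + 1e-9) / factor


def write_term_set(term_set: GoTermSet, path) -> None:
    """One term per line, preceded by a provenance header comment."""
    with open(path, "w") as fh:
        fh.write(f"# provenance: {term_set.provenance}\n")
        fh.write(f"# source: {term_set.source_label}\n")
        fh.write(f"# raw_count: {term_set.raw_count}\tunique_count: {term_set.unique_count}\n")
        for t in term_set.sorted_terms():
            fh.write(t + "\n")


def read_term_set(path, provenance: str = "merged", source_label: str = "") -> GoTermSet:
    terms: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            terms.append(normalize_term_id(line))
    return GoTermSet(frozenset(terms), provenance=provenance, source_label=source_label)
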