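"""End-to-end orchestration: curated sets + enrichment + overlap + dosimetry.

``run_workflow`` wires the stage operations together without adding any
hidden state: every number in the report bundle equals what the public
stage functions return when called individually.  Conditions (chemical ×
time point) are processed independently — no FDR pooling across
conditions.  ``write_report`` emits a deterministic, byte-stable file set.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .curation import (
    GoTermSet,
    derive_aop_term_set,
    derive_disease_term_set,
    disease_genes,
    load_event_mappings,
    load_gene_disease_table,
    merge_term_sets,
)
from .dosimetry import compare_table, comparisons_to_frame, load_concentration_table, load_notes
from .enrichment import (
    AnnotationTable,
    EnrichmentConfig,
    RankedGeneList,
    gsea,
    records_to_frame,
    select_significant,
)
from .ontology import parse_obo
from .overlap import common_signature, overlap, overlap_matrix

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Paths and switches of one workflow run.

    ``disease_source`` chooses between the AOP-curated disease set alone
    (``"aop"``) and the set augmented with gene-disease derived terms
    (``"aop+genes"``).  ``expand_mode`` controls whether "child GO terms"
    means the full descendant closure or direct children only.
    """

    ontology_path: str
    annotation_path: str
    event_table_path: str
    de_table_paths: Mapping[str, str]  # condition label -> path
    output_dir: str
    disease_label: str = "disease"
    disease_gene_table_path: str | None = None
    disease_id: str | None = None
    concentration_table_path: str | None = None
    disease_source: str = "aop"
    expand_mode: str = "descendants"
    relations: tuple[str, ...] = ("is_a",)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)

    def __post_init__(self) -> None:
        if self.disease_source not in ("aop", "aop+genes"):
            raise ValueError("disease_source must be 'aop' or 'aop+genes'")
        if self.disease_source == "aop+genes" and not self.disease_gene_table_path:
            raise ValueError("disease_source 'aop+genes' needs disease_gene_table_path")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        enr = raw.pop("enrichment", {})
        raw["enrichment"] = EnrichmentConfig(**enr)
        if "relations" in raw:
            raw["relations"] = tuple(raw["relations"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["de_table_paths"] = dict(payload["de_table_paths"])
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All stage outputs of one run, ready for writing."""

    disease_set: GoTermSet
    enriched: dict[str, pd.DataFrame]
    enriched_sets: dict[str, GoTermSet]
    overlaps: dict
    matrix: pd.DataFrame
    signature: object | None
    dosimetry: pd.DataFrame | None
    metadata: dict


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


@_stage("ontology")
def _load_ontology(path):
    with open(path) as fh:
        graph = parse_obo(fh)
    logger.info("ontology: %d terms, %d edges", len(graph.terms), len(graph.edges))
    return graph


@_stage("annotation")
def _load_annotation(path, graph):
    table = AnnotationTable.from_tsv(path)
    propagated = table.propagate(graph)
    logger.info(
        "annotation: %d terms, universe %d genes",
        len(propagated.term_to_genes),
        len(propagated.universe),
    )
    return propagated


@_stage("curation")
def _disease_set(config: RunConfig, graph, annotation) -> tuple[GoTermSet, list]:
    events = load_event_mappings(config.event_table_path)
    aop_set = derive_aop_term_set(
        events,
        graph,
        relations=config.relations,
        mode=config.expand_mode,
        source_label=config.disease_label,
    )
    logger.info(
        "curation: %d events -> raw %d, unique %d AOP-derived terms",
        len(events),
        aop_set.raw_count,
        aop_set.unique_count,
    )
    if config.disease_source == "aop":
        return aop_set, events
    table = load_gene_disease_table(config.disease_gene_table_path)
    if config.disease_id:
        genes = disease_genes(table, config.disease_id)
    else:
        genes = list(dict.fromkeys(table["gene_id"].astype(str)))
    gene_set = derive_disease_term_set(
        genes, annotation, config=config.enrichment, source_label=config.disease_label
    )
    merged = merge_term_sets(aop_set, gene_set, source_label=config.disease_label)
    logger.info(
        "curation: +%d gene-derived terms -> merged unique %d",
        gene_set.unique_count,
        merged.unique_count,
    )
    return merged, events


def run_workflow(config: RunConfig) -> ReportBundle:
    """Execute the full workflow for one disease against all conditions.

    Per condition: GSEA on the ranked DE table, FDR-threshold selection,
    overlap against the disease term set.  Across conditions (when ≥ 2):
    the cross-chemical common signature.  Optionally: the dosimetry
    comparison table.  Any stage error aborts with a stage-named message.
    """
    for label, path in config.de_table_paths.items():
        if not Path(path).exists():
            raise StageError(f"stage 'input' failed: DE table for {label!r} missing: {path}")
    graph = _load_ontology(config.ontology_path)
    annotation = _load_annotation(config.annotation_path, graph)
    disease_set, events = _disease_set(config, graph, annotation)

    enriched: dict[str, pd.DataFrame] = {}
    enriched_sets: dict[str, GoTermSet] = {}
    overlaps = {}
    for label in sorted(config.de_table_paths):
        path = config.de_table_paths[label]
        try:
            ranked = RankedGeneList.from_table(path, condition_label=label)
            records = gsea(ranked, annotation, config.enrichment)
            selected = select_significant(
                records, config.enrichment.fdr_threshold, source_label=label
            )
        except Exception as exc:
            raise StageError(f"stage 'enrichment' failed for {label!r}: {exc}") from exc
        enriched[label] = records_to_frame(records)
        enriched_sets[label] = selected
        overlaps[label] = overlap(selected, disease_set, events=events)
        logger.info(
            "%s: %d enriched terms, %d overlap disease set (J=%.4f)",
            label,
            selected.unique_count,
            overlaps[label].intersection_size,
            overlaps[label].jaccard,
        )

    matrix = overlap_matrix(
        [enriched_sets[l] for l in sorted(enriched_sets)], disease_set, events=events
    )
    signature = None
    if len(overlaps) >= 2:
        signature = common_signature([overlaps[l] for l in sorted(overlaps)])
        logger.info("signature: %d common terms across %d conditions", signature.signature_size, len(overlaps))

    dosimetry_frame = None
    if config.concentration_table_path:
        try:
            records = load_concentration_table(config.concentration_table_path)
            notes = load_notes(config.concentration_table_path)
            dosimetry_frame = comparisons_to_frame(compare_table(records, notes=notes))
        except Exception as exc:
            raise StageError(f"stage 'dosimetry' failed: {exc}") from exc

    metadata = {
        "aoplink_version": __version__,
        "seed": config.enrichment.seed,
        "fdr_threshold": config.enrichment.fdr_threshold,
        "disease_source": config.disease_source,
        "expand_mode": config.expand_mode,
        "config_hash": config.config_hash(),
    }
    return ReportBundle(
        disease_set=disease_set,
        enriched=enriched,
        enriched_sets=enriched_sets,
        overlaps=overlaps,
        matrix=matrix,
        signature=signature,
        dosimetry=dosimetry_frame,
        metadata=metadata,
    )


def write_report(bundle: ReportBundle, directory) -> list[Path]:
    """Write the report bundle as a deterministic TSV/JSON file set.

    Files: overlap_matrix.tsv, intersection_terms.tsv, per-condition
    enrichment tables, signature_membership.tsv (when a signature exists),
    dosimetry_comparisons.tsv (when dosimetry ran) and summary.json holding
    every figure-level number plus run metadata.  Re-running with the same
    bundle is byte-identical.  On failure, partially written files are
    removed.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        p = directory / "overlap_matrix.tsv"
        bundle.matrix.to_csv(p, sep="\t", index=False, float_format="%.6g")
        written.append(p)

        rows = []
        for label in sorted(bundle.overlaps):
            o = bundle.overlaps[label]
            for term in o.sorted_intersection():
                rows.append(
                    {
                        "condition": label,
                        "term_id": term,
                        "events": ";".join(o.term_events.get(term, ())),
                    }
                )
        p = directory / "intersection_terms.tsv"
        pd.DataFrame(rows, columns=["condition", "term_id", "events"]).to_csv(
            p, sep="\t", index=False
        )
        written.append(p)

        for label in sorted(bundle.enriched):
            p = directory / f"enrichment_{label.replace(' ', '_').replace('/', '_')}.tsv"
            bundle.enriched[label].to_csv(p, sep="\t", index=False, float_format="%.6g")
            written.append(p)

        if bundle.signature is not None:
            p = directory / "signature_membership.tsv"
            bundle.signature.membership_matrix.to_csv(p, sep="\t")
            written.append(p)

        if bundle.dosimetry is not None:
            p = directory / "dosimetry_comparisons.tsv"
            bundle.dosimetry.to_csv(p, sep="\t", index=False, float_format="%.6g")
            written.append(p)

        summary = {
            "metadata": bundle.metadata,
            "disease_set": {
                "label": bundle.disease_set.source_label,
                "provenance": bundle.disease_set.provenance,
                "raw_count": bundle.disease_set.raw_count,
                "unique_count": bundle.disease_set.unique_count,
            },
            "conditions": {
                label: {
                    "enriched_terms": bundle.overlaps[label].set_a_size,
                    "disease_terms": bundle.overlaps[label].set_b_size,
                    "intersection": bundle.overlaps[label].intersection_size,
                    "union": bundle.overlaps[label].union_size,
                    "jaccard": bundle.overlaps[label].jaccard,
                }
                for label in sorted(bundle.overlaps)
            },
            "signature_size": bundle.signature.signature_size if bundle.signature else None,
            "signature_terms": sorted(bundle.signature.common_terms) if bundle.signature else None,
        }
        p = directory / "summary.json"
        with open(p, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(p)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return written
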