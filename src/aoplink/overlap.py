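"""Exposure↔disease mechanistic linkage by GO BP set overlap.

Each comparison of an exposure-derived term set (enriched GO BPs from one
chemical/time condition) against a disease-derived term set (AOP-curated
and/or gene-disease derived GO BPs) yields Venn counts and a Jaccard index
J(A,B) = |A∩B| / |A∪B|.  Across chemicals, the terms present in every
per-chemical overlap form the cross-chemical common signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .curation import GoTermSet

logger = logging.getLogger(__name__)


def jaccard(a: Iterable, b: Iterable) -> float:
    """Jaccard index |a∩b|/|a∪b| in [0, 1].

    1 means complete overlap, 0 no overlap.  The degenerate case of two
    empty sets is defined as 0 (with a warning) to avoid reporting a
    spurious complete overlap.
    """
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        logger.warning("Jaccard of two empty sets: defined as 0")
        return 0.0
    return len(sa & sb) / len(union)


@dataclass(frozen=True)
class OverlapResult:
    """Venn counts and Jaccard index for one exposure × disease comparison."""

    exposure_label: str
    disease_label: str
    set_a_size: int
    set_b_size: int
    intersection_size: int
    union_size: int
    jaccard: float
    intersection_terms: frozenset[str]
    term_events: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def sorted_intersection(self) -> list[str]:
        return sorted(self.intersection_terms)


@dataclass(frozen=True)
class SignatureResult:
    """Terms common to every chemical's disease overlap, with membership matrix."""

    chemicals: tuple[str, ...]
    common_terms: frozenset[str]
    membership_matrix: pd.DataFrame  # term × chemical booleans

    @property
    def signature_size(self) -> int:
        return len(self.common_terms)


def overlap(
    exposure_set: GoTermSet,
    disease_set: GoTermSet,
    events: Sequence | None = None,
) -> OverlapResult:
    """Full overlap record between one exposure condition and one disease set.

    When curated AOP ``events`` are supplied, each intersecting term is
    back-mapped to the event(s) that contributed it (directly mapped terms
    only; descendant contributions trace to their mapped parent's event).
    """
    a, b = set(exposure_set.terms), set(disease_set.terms)
    if not a or not b:
        logger.warning(
            "overlap %s vs %s: empty input set(s)",
            exposure_set.source_label,
            disease_set.source_label,
        )
    inter = a & b
    union = a | b
    term_events: dict[str, tuple[str, ...]] = {}
    if events is not None:
        for term in inter:
            contributing = tuple(
                sorted(e.event_id for e in events if term in e.mapped_terms)
            )
            if contributing:
                term_events[term] = contributing
    return OverlapResult(
        exposure_label=exposure_set.source_label,
        disease_label=disease_set.source_label,
        set_a_size=len(a),
        set_b_size=len(b),
        intersection_size=len(inter),
        union_size=len(union),
        jaccard=jaccard(a, b),
        intersection_terms=frozenset(inter),
        term_events=term_events,
    )


def common_signature(
    overlaps: Sequence[OverlapResult],
    mode: str = "intersection_terms",
) -> SignatureResult:
    """Cross-chemical common-GO signature.

    ``mode='intersection_terms'`` (default) intersects each chemical's
    disease-overlapping terms — the terms that both overlap the disease set
    and recur in every chemical.  ``mode='exposure_sets'`` would require the
    full exposure sets and is provided by intersecting upstream; here the
    overlaps' term sets are the unit of analysis.
    All overlaps must target the same disease set.
    """
    if len(overlaps) < 2:
        raise ValueError("need at least two overlaps to form a signature")
    labels = {o.disease_label for o in overlaps}
    if len(labels) != 1:
        raise ValueError(f"mismatched disease labels: {sorted(labels)}")
    if mode != "intersection_terms":
        raise ValueError(f"unknown signature mode {mode!r}")
    chemicals = tuple(o.exposure_label for o in overlaps)
    common: set[str] = set(overlaps[0].intersection_terms)
    for o in overlaps[1:]:
        common &= o.intersection_terms
    all_terms = sorted(set().union(*(o.intersection_terms for o in overlaps)))
    matrix = pd.DataFrame(
        {o.exposure_label: [t in o.intersection_terms for t in all_terms] for o in overlaps},
        index=pd.Index(all_terms, name="term_id"),
    )
    return SignatureResult(
        chemicals=chemicals,
        common_terms=frozenset(common),
        membership_matrix=matrix,
    )


def overlap_matrix(
    conditions: Sequence[GoTermSet],
    disease_set: GoTermSet,
    events: Sequence | None = None,
) -> pd.DataFrame:
    """One row per exposure condition: sizes, intersection count, Jaccard.

    Row order follows the input condition order; columns are fixed so the
    table is reproducible byte-for-byte.
    """
    rows = []
    for cond in conditions:
        o = overlap(cond, disease_set, events=events)
        rows.append(
            {
                "condition": o.exposure_label,
                "disease": o.disease_label,
                "enriched_terms": o.set_a_size,
                "disease_terms": o.set_b_size,
                "intersection": o.intersection_size,
                "union": o.union_size,
                "jaccard": o.jaccard,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "condition",
            "disease",
            "enriched_terms",
            "disease_terms",
            "intersection",
            "union",
            "jaccard",
        ],
    )
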