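"""In vitro vs in vivo dosimetry comparison for respiratory sensitisers.

Transcriptomics studies expose cells at nominal medium concentrations
(hundreds to thousands of µM); realistic occupational exposure scenarios,
translated to internal concentrations by PBK modelling or biomonitoring,
are typically far lower.  This module canonicalizes concentration records
to µM, forms in vitro / in vivo fold ratios and their orders of magnitude,
and emits the full pairwise comparison table.  Kinetic (PBK) modelling
itself is out of scope: predicted internal concentrations enter as plain
records.

A packaged fixture (``data/in_vitro_in_vivo_concentrations.tsv``)
reproduces the study-selection concentration table for the five
sensitisers (PA, GLUT, TDI, MA, TMA) verbatim.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

CONTEXTS = (
    "in_vitro_epithelial",
    "in_vitro_dendritic",
    "in_vivo_predicted",
    "in_vivo_biomonitoring",
)
IN_VITRO_CONTEXTS = ("in_vitro_epithelial", "in_vitro_dendritic")
IN_VIVO_CONTEXTS = ("in_vivo_predicted", "in_vivo_biomonitoring")

# unit spellings are normalized before lookup (µ/μ/u all accepted)
UNITS = ("uM", "mM", "ug/m3", "ug/mL", "umol/mmol-creatinine")

_UNIT_ALIASES = {
    "um": "uM",
    "umol/l": "uM",
    "mm": "mM",
    "mmol/l": "mM",
    "ug/m3": "ug/m3",
    "ug/m^3": "ug/m3",
    "ug/ml": "ug/mL",
    "mg/l": "ug/mL",
    "umol/mmol-creatinine": "umol/mmol-creatinine",
    "umol/mmol creatinine": "umol/mmol-creatinine",
}


def _normalize_unit(unit: str) -> str:
    u = unit.strip().replace("µ", "u").replace("μ", "u").lower()
    try:
        return _UNIT_ALIASES[u]
    except KeyError:
        raise ValueError(f"unknown concentration unit {unit!r}") from None


@dataclass(frozen=True)
class ConcentrationRecord:
    """One concentration measurement/prediction for a chemical in a context."""

    chemical: str
    context: str
    value: float
    unit: str
    medium: str = ""
    cas: str = ""
    scenario: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValueError(f"context must be one of {CONTEXTS}, got {self.context!r}")
        if not (self.value > 0):
            raise ValueError(f"{self.chemical}: concentration must be positive")
        object.__setattr__(self, "unit", _normalize_unit(self.unit))


@dataclass(frozen=True)
class ExposureComparison:
    """in vitro vs in vivo pairing with fold and orders-of-magnitude."""

    chemical: str
    in_vitro: ConcentrationRecord | None
    in_vivo: ConcentrationRecord | None
    fold: float | None
    orders_of_magnitude: float | None
    reason: str = ""


def to_micromolar(
    record: ConcentrationRecord,
    molar_mass: float | None = None,
    aux: Mapping[str, float] | None = None,
) -> tuple[float, str]:
    """Convert a concentration record to µM, returning (value, conversion trace).

    ``molar_mass`` (g/mol) is required for mass-per-volume units;
    ``aux['creatinine_mmol_per_l']`` is required for creatinine-normalized
    urinary concentrations.  Air concentrations (µg/m³) describe an external
    exposure scenario, not an internal dose, and are deliberately not
    convertible here (that translation is the kinetic model's job).
    """
    unit = record.unit
    v = record.value
    if unit == "uM":
        return v, f"{v} uM (identity)"
    if unit == "mM":
        return v * 1000.0, f"{v} mM x 1000 = {v * 1000.0} uM"
    if unit == "ug/mL":
        if molar_mass is None:
            raise ValueError(
                f"{record.chemical}: molar mass (g/mol) required to convert {unit}"
            )
        out = v * 1000.0 / molar_mass
        return out, f"{v} ug/mL / {molar_mass} g/mol x 1000 = {out} uM"
    if unit == "umol/mmol-creatinine":
        creat = (aux or {}).get("creatinine_mmol_per_l")
        if creat is None:
            raise ValueError(
                f"{record.chemical}: assumed urinary creatinine concentration "
                "(aux['creatinine_mmol_per_l']) required"
            )
        out = v * creat
        return out, f"{v} umol/mmol-creatinine x {creat} mmol/L = {out} umol/L"
    if unit == "ug/m3":
        raise ValueError(
            f"{record.chemical}: air concentration (ug/m3) is external-exposure "
            "metadata; internal-dose conversion requires kinetic modelling"
        )
    raise ValueError(f"no conversion defined for unit {unit!r}")


def fold_ratio(in_vitro_um: float, in_vivo_um: float) -> float:
    """in vitro / in vivo concentration ratio (both in µM)."""
    if not (in_vitro_um > 0 and in_vivo_um > 0):
        raise ValueError("fold_ratio requires positive concentrations")
    return in_vitro_um / in_vivo_um


def orders_of_magnitude(fold: float) -> float:
    """log10 of a fold ratio."""
    if not fold > 0:
        raise ValueError("fold must be positive")
    return math.log10(fold)


def format_fold(fold: float) -> str:
    """Report style: nearest integer for folds ≥ 100, one decimal below."""
    if fold >= 100:
        return str(int(round(fold)))
    return f"{round(fold, 1):.1f}"


def load_concentration_table(source=None) -> list[ConcentrationRecord]:
    """Read a concentrations TSV; with no argument, the packaged fixture.

    Columns: chemical, cas, context, medium, scenario, value, unit,
    provenance.  Rows whose value is empty (qualitative evidence only, e.g.
    antibody detection without a concentration) are skipped here and
    surfaced by :func:`compare_table` via the notes mapping.
    """
    if source is None:
        source = resources.files("aoplink.data").joinpath(
            "in_vitro_in_vivo_concentrations.tsv"
        )
        with resources.as_file(source) as path:
            df = pd.read_csv(path, sep="\t", dtype=str)
    else:
        df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t", dtype=str)
    records = []
    for _, row in df.iterrows():
        if pd.isna(row.get("value")) or str(row["value"]).strip() == "":
            continue
        records.append(
            ConcentrationRecord(
                chemical=str(row["chemical"]),
                cas=str(row.get("cas", "")) if pd.notna(row.get("cas")) else "",
                context=str(row["context"]),
                medium=str(row.get("medium", "")) if pd.notna(row.get("medium")) else "",
                scenario=str(row.get("scenario", "")) if pd.notna(row.get("scenario")) else "",
                value=float(row["value"]),
                unit=str(row["unit"]),
                provenance=str(row.get("provenance", "")) if pd.notna(row.get("provenance")) else "",
            )
        )
    return records


def load_notes(source=None) -> dict[str, str]:
    """Per-chemical qualitative notes (rows without a quantitative value)."""
    if source is None:
        res = resources.files("aoplink.data").joinpath("in_vitro_in_vivo_concentrations.tsv")
        with resources.as_file(res) as path:
            df = pd.read_csv(path, sep="\t", dtype=str)
    else:
        df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t", dtype=str)
    notes = {}
    for _, row in df.iterrows():
        if pd.isna(row.get("value")) or str(row["value"]).strip() == "":
            notes[str(row["chemical"])] = (
                str(row.get("provenance", "")) if pd.notna(row.get("provenance")) else "no quantitative in vivo estimate"
            )
    return notes


def compare_table(
    records: Sequence[ConcentrationRecord],
    notes: Mapping[str, str] | None = None,
    molar_masses: Mapping[str, float] | None = None,
    aux: Mapping[str, float] | None = None,
) -> list[ExposureComparison]:
    """All pairwise in vitro × in vivo comparisons, per chemical.

    Chemicals with in vitro records but no quantitative in vivo record are
    emitted with an absent fold and a reason (from ``notes`` when given).
    Air-concentration records are scenario metadata and excluded from
    pairing.
    """
    notes = notes or {}
    by_chem: dict[str, dict[str, list[ConcentrationRecord]]] = {}
    for r in records:
        side = (
            "vitro"
            if r.context in IN_VITRO_CONTEXTS
            else "vivo"
            if r.context in IN_VIVO_CONTEXTS and r.unit != "ug/m3"
            else None
        )
        if side is None:
            continue
        by_chem.setdefault(r.chemical, {"vitro": [], "vivo": []})[side].append(r)
    comparisons: list[ExposureComparison] = []
    for chem in sorted(by_chem):
        vitro = by_chem[chem]["vitro"]
        vivo = by_chem[chem]["vivo"]
        if not vivo:
            comparisons.append(
                ExposureComparison(
                    chemical=chem,
                    in_vitro=vitro[0] if vitro else None,
                    in_vivo=None,
                    fold=None,
                    orders_of_magnitude=None,
                    reason=notes.get(chem, "no quantitative in vivo estimate"),
                )
            )
            continue
        mm = (molar_masses or {}).get(chem)
        for a in vitro:
            for b in vivo:
                va, _ = to_micromolar(a, molar_mass=mm, aux=aux)
                vb, _ = to_micromolar(b, molar_mass=mm, aux=aux)
                fold = fold_ratio(va, vb)
                comparisons.append(
                    ExposureComparison(
                        chemical=chem,
                        in_vitro=a,
                        in_vivo=b,
                        fold=fold,
                        orders_of_magnitude=orders_of_magnitude(fold),
                    )
                )
    return comparisons


def comparisons_to_frame(comparisons: Sequence[ExposureComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        rows.append(
            {
                "chemical": c.chemical,
                "in_vitro_context": c.in_vitro.context if c.in_vitro else "",
                "in_vitro_uM": c.in_vitro.value if c.in_vitro else float("nan"),
                "in_vivo_context": c.in_vivo.context if c.in_vivo else "",
                "in_vivo_medium": c.in_vivo.medium if c.in_vivo else "",
                "in_vivo_scenario": c.in_vivo.scenario if c.in_vivo else "",
                "in_vivo_value": c.in_vivo.value if c.in_vivo else float("nan"),
                "in_vivo_unit": c.in_vivo.unit if c.in_vivo else "",
                "fold": c.fold if c.fold is not None else float("nan"),
                "fold_reported": format_fold(c.fold) if c.fold is not None else "",
                "orders_of_magnitude": c.orders_of_magnitude
                if c.orders_of_magnitude is not None
                else float("nan"),
                "reason": c.reason,
            }
        )
    return pd.DataFrame(rows)
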