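"""Five-stage curation cascade for raw bioactivity tables.

Raw activity rows (Kd / Ki / IC50 with heterogeneous units) are turned
into deduplicated, unit-harmonized p-scale measurements by five ordered
stages:

1. group by system (protein, ligand) and remove the bioactivity
   database's 'dummy' verification target;
2. convert activities to the p-scale (−log10 molar) and remove records
   with unclear units or extreme affinities (> 10 mM or < 1 fM, strict);
3. within each (system, publication) group keep only the highest p-value
   — this removes unclear stereoisomer annotations and assay-optimization
   repeats;
4. remove re-citations: among publications reporting an identical value
   for the same system, keep only the earliest;
5. remove author-overlapping reports: among publications on the same
   system that share one or more authors, keep only the earliest per
   connected component, so that surviving measurements are independent.

Every stage logs its drop reasons into a :class:`CurationReport` whose
counts chain (records_out of stage k == records_in of stage k+1).
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import networkx as nx

from .core import (
    AssayConditions,
    DatasetProvider,
    Measurement,
    Metadata,
    Protein,
    canonical_smiles,
    make_ligand,
    make_system,
)

# --- units and p-scale conversion -------------------------------------------

#: Molar conversion factors for recognized concentration units
#: (case-insensitive; both micro signs µ/μ and 'u' are accepted).
UNIT_FACTORS = {
    "fm": 1e-15,
    "pm": 1e-12,
    "nm": 1e-9,
    "um": 1e-6,
    "mm": 1e-3,
    "m": 1.0,
}

#: Raw binding-assay activity types and the p-scale measurement type each maps to.
RAW_TO_P = {"Kd": "pKd", "Ki": "pKi", "IC50": "pIC50"}

#: Default dummy target: a verification pseudo-target used by the source
#: database to flag unchecked analyses; its records carry no real activity.
DEFAULT_DUMMY_TARGETS = frozenset({"CHEMBL612545"})

#: Extreme-affinity window on the p-scale.  Concentrations strictly above
#: 10 mM (p < 2) or strictly below 1 fM (p > 15) are implausible and removed;
#: the boundaries themselves are retained (strict inequalities as stated).
P_EXTREME_LOW = 2.0
P_EXTREME_HIGH = 15.0


class UnclearUnitsError(ValueError):
    """Raised when an activity's units cannot be converted to molar."""


def _normalize_units(units: str) -> str:
    u = units.strip().replace("µ", "u").replace("μ", "u")
    return u.lower()


def standardize_activity(value: float, units: str, rtype: str) -> tuple[str, float]:
    """Convert a raw activity to the p-scale.

    Returns ``(mtype, p)`` where ``p = −log10(value in molar)`` and
    ``mtype`` is the p-scale type for *rtype* (Kd→pKd, Ki→pKi, IC50→pIC50).

    Raises :class:`UnclearUnitsError` for unconvertible units and
    :class:`ValueError` for a non-positive or non-finite value or an
    unknown activity type.
    """
    if rtype not in RAW_TO_P:
        raise ValueError(f"unknown raw activity type {rtype!r}; expected {sorted(RAW_TO_P)}")
    factor = UNIT_FACTORS.get(_normalize_units(units))
    if factor is None:
        raise UnclearUnitsError(f"unclear units: {units!r}")
    if not math.isfinite(value) or value <= 0:
        raise ValueError(f"activity value must be positive and finite, got {value}")
    return RAW_TO_P[rtype], -math.log10(value * factor)


# --- records -----------------------------------------------------------------


@lru_cache(maxsize=16384)
def _canonical(smiles: str) -> str:
    return canonical_smiles(smiles)


_WS = re.compile(r"\s+")


def normalize_author(name: str) -> str:
    """Case-fold and whitespace-collapse an author name for exact matching."""
    return _WS.sub(" ", name.strip()).casefold()


@dataclass(frozen=True)
class ActivityRecord:
    """One raw activity row, as ingested.

    ``index`` is the ingestion order; it is the deterministic tie-break
    everywhere the cascade must choose between otherwise equivalent records.
    ``pvalue``/``mtype`` are filled by the standardization stage.
    """

    record_id: str
    uniprot_id: str
    target_id: str
    smiles: str
    rtype: str
    value: float
    units: str
    document_id: str
    year: Optional[int]
    authors: tuple[str, ...]
    index: int = 0
    mtype: Optional[str] = None
    pvalue: Optional[float] = None

    @property
    def system_key(self) -> tuple[str, str]:
        return (self.uniprot_id, _canonical(self.smiles))

    @property
    def author_set(self) -> frozenset[str]:
        return frozenset(normalize_author(a) for a in self.authors if a.strip())

    def _year_rank(self) -> tuple[float, int]:
        # Missing year sorts last: a record of unknown vintage is never
        # treated as the original publication.
        y = self.year if self.year is not None else math.inf
        return (y, self.index)


# --- report ------------------------------------------------------------------

STAGE_NAMES = (
    "group_and_remove_dummy_targets",
    "standardize_and_filter_extremes",
    "within_document_collapse",
    "citation_deduplication",
    "author_overlap_deduplication",
)


@dataclass
class StageReport:
    stage: str
    records_in: int
    records_out: int
    drop_reasons: dict[str, int] = field(default_factory=dict)


@dataclass
class CurationReport:
    """Per-stage record counts and drop reasons for one cascade run."""

    stages: list[StageReport] = field(default_factory=list)
    surviving_ids: list[str] = field(default_factory=list)

    def add_stage(
        self, stage: str, records_in: int, records_out: int, drop_reasons: dict[str, int]
    ) -> None:
        if records_out > records_in:
            raise ValueError(f"stage {stage}: records_out {records_out} > records_in {records_in}")
        if self.stages and self.stages[-1].records_out != records_in:
            raise ValueError(
                f"stage {stage}: records_in {records_in} does not chain from "
                f"previous records_out {self.stages[-1].records_out}"
            )
        self.stages.append(StageReport(stage, records_in, records_out, dict(drop_reasons)))

    def counts(self) -> list[tuple[int, int]]:
        return [(s.records_in, s.records_out) for s in self.stages]

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "stage": s.stage,
                    "records_in": s.records_in,
                    "records_out": s.records_out,
                    "drop_reasons": dict(sorted(s.drop_reasons.items())),
                }
                for s in self.stages
            ],
            "surviving_ids": list(self.surviving_ids),
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)


# --- stages ------------------------------------------------------------------


def remove_dummy_targets(
    records: Sequence[ActivityRecord],
    dummy_ids: Iterable[str] = DEFAULT_DUMMY_TARGETS,
) -> list[ActivityRecord]:
    """Drop records whose source-database target is a verification dummy."""
    dummy = set(dummy_ids)
    return [r for r in records if r.target_id not in dummy]


def filter_extremes(records: Sequence[ActivityRecord]) -> list[ActivityRecord]:
    """Drop p-scale records outside the plausible affinity window.

    Strict boundaries: a concentration of exactly 10 mM (p = 2) or exactly
    1 fM (p = 15) is retained.
    """
    out = []
    for r in records:
        if r.pvalue is None:
            raise ValueError(f"record {r.record_id} has no p-scale value")
        if P_EXTREME_LOW <= r.pvalue <= P_EXTREME_HIGH:
            out.append(r)
    return out


def collapse_within_document(records: Sequence[ActivityRecord]) -> list[ActivityRecord]:
    """Keep the highest p-value per (system, publication) group.

    Ties are broken toward the lowest ingestion index so the survivor is
    deterministic.
    """
    best: dict[tuple, ActivityRecord] = {}
    for r in records:
        key = (r.system_key, r.document_id)
        cur = best.get(key)
        if cur is None or (r.pvalue, -r.index) > (cur.pvalue, -cur.index):
            best[key] = r
    keep = {id(r) for r in best.values()}
    return [r for r in records if id(r) in keep]


def remove_cited_duplicates(
    records: Sequence[ActivityRecord], tolerance: float = 1e-6
) -> list[ActivityRecord]:
    """Collapse re-citations of previously published values.

    Within each system, records whose p-values are identical (within
    *tolerance*, closed transitively) are assumed to cite a single original
    experiment; only the earliest-year publication's record survives.
    Records with no year are treated as latest and never kept as the
    original.
    """
    by_system: dict[tuple, list[ActivityRecord]] = {}
    for r in records:
        by_system.setdefault(r.system_key, []).append(r)

    keep: set[int] = set()
    for group in by_system.values():
        ordered = sorted(group, key=lambda r: (r.pvalue, r.index))
        # cluster consecutive records whose p-values chain within tolerance
        cluster: list[ActivityRecord] = []
        clusters: list[list[ActivityRecord]] = []
        for r in ordered:
            if cluster and abs(r.pvalue - cluster[-1].pvalue) > tolerance:
                clusters.append(cluster)
                cluster = []
            cluster.append(r)
        if cluster:
            clusters.append(cluster)
        for c in clusters:
            keep.add(id(min(c, key=lambda r: r._year_rank())))
    return [r for r in records if id(r) in keep]


def remove_author_overlap(records: Sequence[ActivityRecord]) -> list[ActivityRecord]:
    """Keep one record per author-connected component of publications.

    Within each system, publications are nodes of a graph with an edge
    wherever their normalized author sets intersect; from every connected
    component only the earliest-year publication's record survives, leaving
    truly independent measurements.  A publication with no authors forms
    its own component.
    """
    by_system: dict[tuple, list[ActivityRecord]] = {}
    for r in records:
        by_system.setdefault(r.system_key, []).append(r)

    keep: set[int] = set()
    for group in by_system.values():
        graph = nx.Graph()
        graph.add_nodes_from(range(len(group)))
        for i in range(len(group)):
            ai = group[i].author_set
            if not ai:
                continue
            for j in range(i + 1, len(group)):
                if ai & group[j].author_set:
                    graph.add_edge(i, j)
        for component in nx.connected_components(graph):
            keep.add(id(min((group[i] for i in component), key=lambda r: r._year_rank())))
    return [r for r in records if id(r) in keep]


# --- cascade -----------------------------------------------------------------


@dataclass(frozen=True)
class CurationConfig:
    """Tunable knobs of the cascade; defaults match the documented pipeline."""

    dummy_targets: frozenset[str] = DEFAULT_DUMMY_TARGETS
    citation_tolerance: float = 1e-6
    source: str = "unknown"


def run_cascade(
    records: Sequence[ActivityRecord],
    config: Optional[CurationConfig] = None,
) -> tuple[list[Measurement], CurationReport]:
    """Run all five stages in order and emit measurements plus a report.

    The returned measurements carry the standardized p-scale value, assay
    conditions (pH 7, 298.15 K) and full provenance metadata.  The report
    records chained per-stage counts, drop reasons, and surviving record ids.
    """
    config = config or CurationConfig()
    report = CurationReport()
    records = [replace(r, index=i) for i, r in enumerate(records)]

    # stage 1: group by system, remove dummy targets
    n_in = len(records)
    stage1 = remove_dummy_targets(records, config.dummy_targets)
    report.add_stage(
        STAGE_NAMES[0],
        n_in,
        len(stage1),
        {"dummy_target": n_in - len(stage1)} if n_in - len(stage1) else {},
    )

    # stage 2: standardize units to p-scale, drop unclear units and extremes
    standardized: list[ActivityRecord] = []
    reasons: dict[str, int] = {}
    for r in stage1:
        try:
            mtype, p = standardize_activity(r.value, r.units, r.rtype)
        except UnclearUnitsError:
            reasons["unclear_units"] = reasons.get("unclear_units", 0) + 1
            continue
        except ValueError:
            reasons["invalid_value"] = reasons.get("invalid_value", 0) + 1
            continue
        standardized.append(replace(r, mtype=mtype, pvalue=p))
    stage2 = filter_extremes(standardized)
    n_extreme = len(standardized) - len(stage2)
    if n_extreme:
        reasons["extreme_value"] = n_extreme
    report.add_stage(STAGE_NAMES[1], len(stage1), len(stage2), reasons)

    # stage 3: within-publication collapse to the highest affinity
    stage3 = collapse_within_document(stage2)
    report.add_stage(
        STAGE_NAMES[2],
        len(stage2),
        len(stage3),
        {"lower_duplicate_in_document": len(stage2) - len(stage3)}
        if len(stage2) - len(stage3)
        else {},
    )

    # stage 4: citation deduplication
    stage4 = remove_cited_duplicates(stage3, config.citation_tolerance)
    report.add_stage(
        STAGE_NAMES[3],
        len(stage3),
        len(stage4),
        {"cited_duplicate": len(stage3) - len(stage4)} if len(stage3) - len(stage4) else {},
    )

    # stage 5: author-overlap deduplication
    stage5 = remove_author_overlap(stage4)
    report.add_stage(
        STAGE_NAMES[4],
        len(stage4),
        len(stage5),
        {"author_overlap": len(stage4) - len(stage5)} if len(stage4) - len(stage5) else {},
    )

    report.surviving_ids = [r.record_id for r in stage5]
    measurements = [_to_measurement(r, config.source) for r in stage5]
    return measurements, report


def _to_measurement(record: ActivityRecord, source: str) -> Measurement:
    protein = Protein(uniprot_id=record.uniprot_id)
    ligand = make_ligand(record.smiles)
    system = make_system([protein, ligand])
    return Measurement(
        system=system,
        mtype=record.mtype,
        values=(record.pvalue,),
        conditions=AssayConditions(pH=7.0, temperature=298.15),
        metadata=Metadata(
            source=source,
            document_id=record.document_id,
            year=record.year,
            authors=record.authors,
            original_value=record.value,
            original_units=record.units,
        ),
    )


def curated_frame(measurements: Sequence[Measurement], report: CurationReport):
    """Tabulate curated measurements for serialization (deterministic order)."""
    import pandas as pd

    rows = []
    for rid, m in zip(report.surviving_ids, measurements):
        rows.append(
            {
                "record_id": rid,
                "uniprot_id": m.system.protein.uniprot_id,
                "smiles": m.system.ligand.smiles,
                "mtype": m.mtype,
                "pvalue": f"{m.values[0]:.6f}",
                "document_id": m.metadata.document_id,
                "year": m.metadata.year,
                "authors": ";".join(m.metadata.authors),
                "original_value": m.metadata.original_value,
                "original_units": m.metadata.original_units,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "record_id",
            "uniprot_id",
            "smiles",
            "mtype",
            "pvalue",
            "document_id",
            "year",
            "authors",
            "original_value",
            "original_units",
        ],
    )
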