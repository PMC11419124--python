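"""Dataset providers: parse activity tables into measurement collections.

Two table dialects are supported:

* an activity CSV in the dialect of large bioactivity databases — one row
  per measurement with a UniProt accession, a source-database target id,
  a compound SMILES, a raw activity type (Kd / Ki / IC50) with value and
  units, and publication provenance;
* a wide percent-displacement panel in the dialect of published kinase
  inhibitor screens — one row per compound, one column per kinase display
  name, plus a separate display-name → UniProt mapping table.

Kinase-definition snapshot tables from several sources can be merged into
a single UniProt-keyed roster; the UniProt accession is the primary join
key because it is the only universal protein identifier across sources.
All randomness (subsampling) uses NumPy's seeded PCG64 generator and the
seed is recorded in the provider's provenance.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    AssayConditions,
    DatasetProvider,
    Measurement,
    Metadata,
    Protein,
    make_ligand,
    make_system,
)
from .curation import ActivityRecord, UnclearUnitsError, standardize_activity

# Default column map for the activity-CSV dialect; override any entry via
# the ``column_map`` argument (config key ``dataset.column_map``).
DEFAULT_CHEMBL_COLUMNS = {
    "uniprot_id": "uniprot_id",
    "target_id": "target_chembl_id",
    "compound_id": "compound_chembl_id",
    "smiles": "smiles",
    "activity_type": "activity_type",
    "value": "value",
    "units": "units",
    "document_id": "document_chembl_id",
    "year": "year",
    "authors": "authors",
}

AUTHOR_SEPARATOR = ";"


class DialectError(ValueError):
    """Raised when an input table lacks required columns of its dialect."""


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DialectError(f"{what} is missing required column(s): {', '.join(missing)}")


def _split_authors(cell) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return ()
    return tuple(a.strip() for a in str(cell).split(AUTHOR_SEPARATOR) if a.strip())


def _parse_year(cell) -> Optional[int]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return None
    return int(cell)


def read_activity_records(
    path,
    column_map: Optional[Mapping[str, str]] = None,
) -> list[ActivityRecord]:
    """Read an activity CSV into raw :class:`ActivityRecord` rows (no filtering).

    This is the entry point for the curation cascade, which expects raw
    (pre-standardization) records.
    """
    cols = dict(DEFAULT_CHEMBL_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, dtype={cols["units"]: str, cols["authors"]: str})
    _require_columns(df, cols.values(), "activity CSV")
    has_record_id = "record_id" in df.columns
    records = []
    for i, row in enumerate(df.to_dict("records")):
        records.append(
            ActivityRecord(
                record_id=str(row["record_id"])
                if has_record_id
                else f"{row[cols['compound_id']]}/{i}",
                uniprot_id=str(row[cols["uniprot_id"]]),
                target_id=str(row[cols["target_id"]]),
                smiles=str(row[cols["smiles"]]),
                rtype=str(row[cols["activity_type"]]),
                value=float(row[cols["value"]]),
                units=str(row[cols["units"]]),
                document_id=str(row[cols["document_id"]]),
                year=_parse_year(row[cols["year"]]),
                authors=_split_authors(row[cols["authors"]]),
                index=i,
            )
        )
    return records


def read_chembl_csv(
    path,
    uniprot_ids: Optional[Iterable[str]] = None,
    mtypes: Optional[Iterable[str]] = None,
    sample_size: Optional[int] = None,
    seed: int = 0,
    column_map: Optional[Mapping[str, str]] = None,
) -> DatasetProvider:
    """Parse an activity CSV into a provider of p-scale measurements.

    Filters are applied in order: target accession, measurement type, then
    a uniform random subsample of exactly ``sample_size`` rows drawn with
    NumPy's PCG64 generator under ``seed`` (recorded in provenance).  Rows
    whose units cannot be converted to molar are collected into
    ``provider.rejects`` rather than silently dropped.
    """
    records = read_activity_records(path, column_map=column_map)

    if uniprot_ids is not None:
        wanted = set(uniprot_ids)
        records = [r for r in records if r.uniprot_id in wanted]

    measurements: list[Measurement] = []
    rejects: list[dict] = []
    mtype_filter = set(mtypes) if mtypes is not None else None
    for r in records:
        try:
            mtype, p = standardize_activity(r.value, r.units, r.rtype)
        except (UnclearUnitsError, ValueError) as exc:
            rejects.append({"record_id": r.record_id, "reason": str(exc)})
            continue
        if mtype_filter is not None and mtype not in mtype_filter:
            continue
        measurements.append(
            Measurement(
                system=make_system([Protein(uniprot_id=r.uniprot_id), make_ligand(r.smiles)]),
                mtype=mtype,
                values=(p,),
                conditions=AssayConditions(pH=7.0),
                metadata=Metadata(
                    source="chembl-dialect csv",
                    document_id=r.document_id,
                    year=r.year,
                    authors=r.authors,
                    original_value=r.value,
                    original_units=r.units,
                ),
            )
        )

    if sample_size is not None:
        if sample_size > len(measurements):
            raise ValueError(
                f"sample_size {sample_size} exceeds available rows ({len(measurements)})"
            )
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(measurements), size=sample_size, replace=False))
        measurements = [measurements[i] for i in idx]

    provenance = {
        "path": str(path),
        "dialect": "chembl",
        "uniprot_ids": sorted(uniprot_ids) if uniprot_ids is not None else None,
        "measurement_types": sorted(mtypes) if mtypes is not None else None,
        "sample_size": sample_size,
        "rng": "numpy.random.default_rng (PCG64)",
        "seed": seed,
    }
    return DatasetProvider(measurements, provenance=provenance, rejects=rejects)


# --- percent-displacement panel ---------------------------------------------

PKIS2_META_COLUMNS = ("smiles", "compound_name")


def read_pkis2_table(
    path,
    name_to_uniprot: Union[pd.DataFrame, Mapping[str, str], None],
    strict: bool = True,
    probe_concentration: Optional[float] = None,
) -> DatasetProvider:
    """Parse a wide percent-displacement panel into a provider.

    The table has one row per compound (``smiles``, ``compound_name``) and
    one column per kinase display name.  ``name_to_uniprot`` maps display
    names to UniProt accessions (a mapping, or a DataFrame with columns
    ``name`` and ``uniprot_id``).  In strict mode an unmapped kinase name
    aborts with an error listing the names; in lenient mode its cells are
    collected into ``provider.rejects``.

    ``probe_concentration`` (molar), when known, is stored in every
    measurement's assay conditions; it is required later by the
    displacement link function but not for ingestion.
    """
    if name_to_uniprot is None:
        raise ValueError("a kinase name → UniProt mapping table is required")
    if isinstance(name_to_uniprot, pd.DataFrame):
        _require_columns(name_to_uniprot, ("name", "uniprot_id"), "name mapping table")
        mapping = dict(zip(name_to_uniprot["name"], name_to_uniprot["uniprot_id"]))
    else:
        mapping = dict(name_to_uniprot)

    df = pd.read_csv(path) if not isinstance(path, pd.DataFrame) else path
    _require_columns(df, PKIS2_META_COLUMNS, "percent-displacement table")
    kinase_cols = [c for c in df.columns if c not in PKIS2_META_COLUMNS]
    unmapped = sorted(c for c in kinase_cols if c not in mapping)
    if unmapped and strict:
        raise ValueError(f"unmapped kinase name(s): {', '.join(unmapped)}")

    conditions = AssayConditions(pH=7.0, probe_concentration=probe_concentration)
    measurements: list[Measurement] = []
    rejects: list[dict] = []
    for _, row in df.iterrows():
        ligand = make_ligand(str(row["smiles"]), name=str(row["compound_name"]))
        for kinase in kinase_cols:
            value = row[kinase]
            if kinase in mapping:
                protein = Protein(uniprot_id=mapping[kinase], name=kinase)
                measurements.append(
                    Measurement(
                        system=make_system([protein, ligand]),
                        mtype="percent_displacement",
                        values=(float(value),),
                        conditions=conditions,
                        metadata=Metadata(
                            source="pkis2-dialect table",
                            document_id="pkis2",
                            original_value=float(value),
                            original_units="%",
                        ),
                    )
                )
            else:
                rejects.append(
                    {
                        "compound_name": str(row["compound_name"]),
                        "kinase_name": kinase,
                        "reason": "unmapped kinase name",
                    }
                )
    provenance = {
        "path": str(path) if not isinstance(path, pd.DataFrame) else "<in-memory>",
        "dialect": "pkis2",
        "probe_concentration": probe_concentration,
        "unmapped_names": unmapped,
    }
    return DatasetProvider(measurements, provenance=provenance, rejects=rejects)


# --- kinase roster -----------------------------------------------------------


class KinaseRoster:
    """A UniProt-keyed union of kinase definitions from several sources.

    ``table`` has one row per accession with boolean membership flags
    ``in_<source>`` and display names ``name_<source>``.
    """

    def __init__(self, table: pd.DataFrame, sources: Sequence[str]) -> None:
        self.table = table
        self.sources = list(sources)

    def __len__(self) -> int:
        return len(self.table)

    def membership_counts(self) -> dict[str, int]:
        return {s: int(self.table[f"in_{s}"].sum()) for s in self.sources}


def merge_kinase_lists(
    tables: Sequence[tuple[str, Union[pd.DataFrame, Mapping[str, str]]]],
) -> KinaseRoster:
    """Merge per-source accession → display-name snapshot tables.

    Each input is ``(source_name, table)`` where the table is a mapping or
    a DataFrame with columns ``uniprot_id`` and ``name``.  A duplicate
    accession within one source marks an ill-formed snapshot and is
    rejected.
    """
    if not tables:
        raise ValueError("at least one source table is required")
    per_source: dict[str, dict[str, str]] = {}
    for source, table in tables:
        if isinstance(table, pd.DataFrame):
            _require_columns(table, ("uniprot_id", "name"), f"snapshot table {source!r}")
            accs = list(table["uniprot_id"])
            if len(accs) != len(set(accs)):
                dupes = sorted({a for a in accs if accs.count(a) > 1})
                raise ValueError(
                    f"duplicate accession(s) in source {source!r}: {', '.join(dupes)}"
                )
            per_source[source] = dict(zip(table["uniprot_id"], table["name"]))
        else:
            per_source[source] = dict(table)

    sources = [s for s, _ in tables]
    accessions = sorted(set().union(*(set(m) for m in per_source.values())))
    rows = []
    for acc in accessions:
        row: dict[str, object] = {"uniprot_id": acc}
        for s in sources:
            row[f"in_{s}"] = acc in per_source[s]
            row[f"name_{s}"] = per_source[s].get(acc, "")
        rows.append(row)
    table = pd.DataFrame(rows).set_index("uniprot_id", drop=False)
    return KinaseRoster(table, sources)


def count_in_all(roster: KinaseRoster) -> int:
    """Size of the intersection across all sources in the roster."""
    flags = roster.table[[f"in_{s}" for s in roster.sources]]
    return int(flags.all(axis=1).sum())
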