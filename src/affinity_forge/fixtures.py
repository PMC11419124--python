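"""Synthetic fixture generators with planted, self-documented ground truth.

Every input dialect the package consumes can be generated here with known
structure, so the whole pipeline is testable without downloading any
external database:

* :func:`generate_curation_fixture` writes an activity table in the
  ChEMBL-style dialect with planted dummy-target rows, unclear units,
  extreme affinities, within-publication duplicates, citation chains and
  author-overlap components — and returns a :class:`GroundTruth` holding
  the exact per-stage record counts and surviving record ids the curation
  cascade must reproduce;
* :func:`generate_pkis2_fixture` builds a wide percent-displacement panel
  plus its kinase-name → UniProt mapping;
* :func:`generate_kinase_snapshots` builds per-source kinase definition
  tables with an engineered all-source intersection;
* :func:`generate_template_table` builds a template-structure table with
  known similarity ranking (the query ligand itself is planted);
* :func:`simulate_recovery_experiment` simulates systems with known ΔG
  emitting mixed-type noisy observations, for validating the observation
  model's parameter recovery.

All generators are deterministic: the same (spec, seed) yields identical
bytes.  Planted duplicate values are copied exactly (never re-noised) so
"identical value" semantics are unambiguous, and every planted group gets
its own protein:ligand system so groups cannot interact across stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .assaymodel import (
    ThermoContext,
    dg_from_pkd,
    displacement_from_dg,
    fit_free_energy,
    pkd_from_dg,
    predict_observable,
)
from .core import AssayConditions, Measurement, Protein, make_ligand, make_system
from .curation import RAW_TO_P

#: Packaged pool of valid, chemically diverse drug-like SMILES (all parse
#: and canonicalize under rdkit; validated in the test suite).
SMILES_POOL: tuple[str, ...] = (
    "CC(=O)Oc1ccccc1C(=O)O", "CC(=O)Nc1ccc(O)cc1", "CC(C)Cc1ccc(C(C)C(=O)O)cc1",
    "CN1CCC[C@H]1c1cccnc1", "Cn1cnc2c1c(=O)n(C)c(=O)n2C", "CC(=O)NCCc1c[nH]c2ccc(OC)cc12",
    "OC(=O)c1ccccc1O", "Nc1ccc(S(N)(=O)=O)cc1", "CC(N)Cc1ccccc1",
    "NC(=O)c1ccc[nH]1", "OCC1OC(O)C(O)C(O)C1O", "CN(C)CCc1c[nH]c2ccccc12",
    "COc1cc2c(cc1OC)C(=O)C(CC1CCN(Cc3ccccc3)CC1)C2", "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1",
    "Clc1ccccc1-c1nc2ccccc2[nH]1", "O=C(O)Cc1ccccc1Nc1c(Cl)cccc1Cl",
    "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1", "CCOC(=O)c1ccccc1N", "COc1ccc2cc(C(C)C(=O)O)ccc2c1",
    "NS(=O)(=O)c1cc2c(cc1Cl)NC(C(Cl)Cl)NS2(=O)=O", "Cc1ccc(C(=O)O)cc1N",
    "O=c1[nH]cnc2[nH]ncc12", "CC(=O)c1ccc(S(N)(=O)=O)cc1", "Nc1nc(N)c2nc(-c3ccccc3)c(N)nc2n1",
    "CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21", "CC(CS)C(=O)N1CCCC1C(=O)O",
    "Clc1ccc2c(c1)C(c1ccccc1)=NCc1nncn1-2", "OC(c1ccccc1)(c1ccccc1)C1CCN(CCc2ccccc2)CC1",
    "CN(C)CCCN1c2ccccc2CCc2ccc(Cl)cc21", "COc1ccc(CCN(C)CCCC(C#N)(C(C)C)c2ccc(OC)c(OC)c2)cc1OC",
    "Cc1oc2ccccc2c1C(=O)c1cc(I)c(OCC(=O)O)c(I)c1", "O=C(Nc1ccc(Cl)cc1)Nc1ccccn1",
    "Oc1ccc(CC2NCCc3cc(O)c(O)cc32)cc1O", "CCN(CC)CCNC(=O)c1ccc(N)cc1",
    "CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(=O)O", "CCCCC1(CC)C(=O)NC(=O)NC1=O",
    "Cc1cccc(C)c1NC(=O)CN(CC)CC", "CC(O)C(O)c1cnc2nc(N)[nH]c(=O)c2n1",
    "Nc1nc2[nH]c(CNc3ccc(C(=O)NC(CCC(=O)O)C(=O)O)cc3)cc2c(=O)[nH]1",
    "CN1CCN(CCCN2c3ccccc3Sc3ccc(Cl)cc32)CC1", "CC(C)NCC(O)COc1cccc2ccccc12",
    "CCC(C)C1(CC)C(=O)NC(=O)NC1=O", "NC(Cc1ccc(O)cc1)C(=O)O",
    "NC(Cc1c[nH]c2ccccc12)C(=O)O", "NC(CCC(=O)O)C(=O)O",
    "OC(=O)C1CCCN1", "NC(CO)C(=O)O", "CSCCC(N)C(=O)O",
    "Oc1ccc2[nH]cc(CCN)c2c1", "NCCc1ccc(O)c(O)c1", "CNCC(O)c1ccc(O)c(O)c1",
    "COc1ccc(Cc2cnc(N)nc2N)cc1OC", "Clc1cccc(Cl)c1N=C1NCCN1",
    "CC(C(=O)O)c1ccc(-c2ccccc2)cc1", "OCCN1CCN(CCCN2c3ccccc3C=Cc3ccccc32)CC1",
    "CC(=O)SC1CC2=CC(=O)CCC2(C)C2CCC3(C)C(CCC3(O)C#C)C12", "CC12CCC3c4ccc(O)cc4CCC3C1CCC2O",
    "CC(=O)OCC(=O)C1(O)CCC2C3CCC4=CC(=O)CCC4(C)C3C(O)CC21C",
    "Nc1ccn(C2OC(CO)C(O)C2O)c(=O)n1", "O=c1cc(-c2ccccc2)oc2cc(O)cc(O)c12",
    "COc1cc(C=CC(=O)CC(=O)C=Cc2ccc(O)c(OC)c2)ccc1O", "O=C(O)c1cc(O)c(O)c(O)c1",
)

_AUTHOR_POOL: tuple[str, ...] = tuple(
    f"{surname} {initial}"
    for surname in (
        "Adler", "Baros", "Chen", "Duarte", "Endo", "Farkas", "Gupta", "Hansen",
        "Iqbal", "Jansen", "Kim", "Lindqvist", "Moreau", "Novak", "Okafor",
        "Petrov", "Quiroga", "Rossi", "Sato", "Tanaka",
    )
    for initial in ("A", "J")
)


class InfeasibleSpecError(ValueError):
    """Raised when a fixture spec's planted structure cannot fit."""


@dataclass(frozen=True)
class FixtureSpec:
    """Requested structure of a curation fixture.

    Group-count fields request *groups* (each consuming ``group_size``
    records); scalar-count fields request single records.  Whatever
    remains of ``n_records`` is filled with clean singleton records.
    """

    n_records: int = 200
    seed: int = 0
    n_dummy_targets: int = 5
    n_extreme_high: int = 5
    n_extreme_low: int = 5
    n_unclear_units: int = 5
    n_within_doc_duplicate_groups: int = 8
    n_citation_chains: int = 6
    n_author_overlap_components: int = 6
    group_size: int = 2
    ligand_pool_size: int = 30
    protein_pool_size: int = 10

    def planted_records(self) -> int:
        singles = (
            self.n_dummy_targets
            + self.n_extreme_high
            + self.n_extreme_low
            + self.n_unclear_units
        )
        groups = (
            self.n_within_doc_duplicate_groups
            + self.n_citation_chains
            + self.n_author_overlap_components
        )
        return singles + groups * self.group_size

    def validate(self) -> None:
        if self.n_records < 0 or self.group_size < 2:
            raise InfeasibleSpecError("n_records must be ≥ 0 and group_size ≥ 2")
        if any(
            getattr(self, f) < 0
            for f in (
                "n_dummy_targets", "n_extreme_high", "n_extreme_low", "n_unclear_units",
                "n_within_doc_duplicate_groups", "n_citation_chains",
                "n_author_overlap_components",
            )
        ):
            raise InfeasibleSpecError("planted counts must be non-negative")
        if self.planted_records() > self.n_records:
            raise InfeasibleSpecError(
                f"planted structure needs {self.planted_records()} records but "
                f"n_records is {self.n_records}"
            )
        if self.ligand_pool_size > len(SMILES_POOL):
            raise InfeasibleSpecError(
                f"ligand_pool_size {self.ligand_pool_size} exceeds packaged pool "
                f"({len(SMILES_POOL)})"
            )
        n_systems = self.n_systems()
        if n_systems > self.ligand_pool_size * self.protein_pool_size:
            raise InfeasibleSpecError(
                f"spec needs {n_systems} distinct systems but the pools provide "
                f"{self.ligand_pool_size * self.protein_pool_size}"
            )

    def n_systems(self) -> int:
        n_clean = self.n_records - self.planted_records()
        return (
            n_clean
            + self.n_dummy_targets
            + self.n_extreme_high
            + self.n_extreme_low
            + self.n_unclear_units
            + self.n_within_doc_duplicate_groups
            + self.n_citation_chains
            + self.n_author_overlap_components
        )


@dataclass
class GroundTruth:
    """The exact cascade outcome a generated fixture is built to produce."""

    stage_counts: list[dict] = field(default_factory=list)
    surviving_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "stage_counts": self.stage_counts,
            "surviving_ids": sorted(self.surviving_ids),
        }


CHEMBL_FIXTURE_COLUMNS = [
    "record_id", "uniprot_id", "target_chembl_id", "compound_chembl_id", "smiles",
    "activity_type", "value", "units", "document_chembl_id", "year", "authors",
]


def generate_curation_fixture(spec: FixtureSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Build a ChEMBL-dialect activity table with planted cascade structure.

    Returns the table (rows shuffled, values preformatted as strings so
    CSV serialization is byte-deterministic) and the ground truth the
    cascade must reproduce: per-stage in/out counts, per-stage drop
    counts, and the surviving record ids.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    ligands = [
        SMILES_POOL[i]
        for i in rng.choice(len(SMILES_POOL), size=spec.ligand_pool_size, replace=False)
    ]
    proteins = [
        (f"P{40000 + i:05d}", f"CHEMBL{3000 + i}") for i in range(spec.protein_pool_size)
    ]
    system_pool = [(p, l) for p in range(spec.protein_pool_size) for l in range(spec.ligand_pool_size)]
    order = rng.permutation(len(system_pool))
    system_iter = iter(order)

    doc_counter = [0]
    rid_counter = [0]
    rows: list[dict] = []

    def next_system() -> tuple[str, str, str, str]:
        p, l = system_pool[next(system_iter)]
        uniprot, target = proteins[p]
        return uniprot, target, f"CHEMBL{100000 + p * 1000 + l}", ligands[l]

    def next_doc() -> str:
        doc_counter[0] += 1
        return f"DOC{doc_counter[0]:05d}"

    def next_rid() -> str:
        rid_counter[0] += 1
        return f"R{rid_counter[0]:05d}"

    def sample_authors(k: int = 3) -> list[str]:
        idx = rng.choice(len(_AUTHOR_POOL), size=k, replace=False)
        return [_AUTHOR_POOL[i] for i in idx]

    def format_value(p: float) -> tuple[str, str]:
        """Express a p-scale affinity as (value string, units)."""
        units = ("nM", "uM", "pM")[int(rng.integers(3))]
        exponent = {"nM": 9, "uM": 6, "pM": 12}[units]
        return f"{10.0 ** (exponent - p):.6g}", units

    def base_row(p: Optional[float] = None, units: Optional[str] = None,
                 value: Optional[str] = None) -> dict:
        uniprot, target, compound, smiles = next_system()
        if value is None:
            value, units = format_value(p)
        return {
            "record_id": next_rid(),
            "uniprot_id": uniprot,
            "target_chembl_id": target,
            "compound_chembl_id": compound,
            "smiles": smiles,
            "activity_type": ("Ki", "Kd", "IC50")[int(rng.integers(3))],
            "value": value,
            "units": units,
            "document_chembl_id": next_doc(),
            "year": int(rng.integers(1995, 2021)),
            "authors": ";".join(sample_authors()),
        }

    def clean_p() -> float:
        return float(rng.uniform(4.0, 10.0))

    surviving: list[str] = []

    # dummy-target rows (dropped in stage 1)
    for _ in range(spec.n_dummy_targets):
        row = base_row(clean_p())
        row["target_chembl_id"] = "CHEMBL612545"
        rows.append(row)

    # unclear units (dropped in stage 2)
    for _ in range(spec.n_unclear_units):
        row = base_row(value=f"{rng.uniform(1, 100):.6g}",
                       units=("mg/mL", "ug/mL", "%", "mol")[int(rng.integers(4))])
        rows.append(row)

    # extreme affinities (dropped in stage 2): weaker than 10 mM / stronger than 1 fM
    for _ in range(spec.n_extreme_high):
        rows.append(base_row(float(rng.uniform(0.3, 1.8))))
    for _ in range(spec.n_extreme_low):
        rows.append(base_row(float(rng.uniform(15.2, 16.5))))

    # within-publication duplicate groups (stage 3 keeps the highest p)
    for _ in range(spec.n_within_doc_duplicate_groups):
        first = base_row(clean_p())
        group = [first]
        ps = [-math.log10(float(first["value"]) * {"nM": 1e-9, "uM": 1e-6, "pM": 1e-12}[first["units"]])]
        for _ in range(spec.group_size - 1):
            # distinct value, same system + document
            p = clean_p()
            while any(abs(p - q) < 0.05 for q in ps):
                p = clean_p()
            ps.append(p)
            row = dict(first)
            row["record_id"] = next_rid()
            value, units = format_value(p)
            row["value"], row["units"] = value, units
            group.append(row)
        winner = group[int(np.argmax(ps))]
        surviving.append(winner["record_id"])
        rows.extend(group)

    # citation chains (stage 4 keeps the earliest year); identical value
    # strings, distinct documents/years, disjoint author sets
    for _ in range(spec.n_citation_chains):
        first = base_row(clean_p())
        years = sorted(
            int(y) for y in rng.choice(np.arange(1995, 2021), size=spec.group_size, replace=False)
        )
        authors = sample_authors(spec.group_size * 2)
        chain = []
        for j in range(spec.group_size):
            row = dict(first)
            if j > 0:
                row["record_id"] = next_rid()
                row["document_chembl_id"] = next_doc()
            row["year"] = years[j]
            row["authors"] = ";".join(authors[2 * j : 2 * j + 2])
            chain.append(row)
        surviving.append(chain[0]["record_id"])
        rows.extend(chain)

    # author-overlap components (stage 5 keeps the earliest year): chained
    # author sharing A∩B≠∅, B∩C≠∅, ..., distinct values so stage 4 is inert
    for _ in range(spec.n_author_overlap_components):
        first = base_row(clean_p())
        ps = [-math.log10(float(first["value"]) * {"nM": 1e-9, "uM": 1e-6, "pM": 1e-12}[first["units"]])]
        years = sorted(
            int(y) for y in rng.choice(np.arange(1995, 2021), size=spec.group_size, replace=False)
        )
        names = sample_authors(spec.group_size + 1)
        component = []
        for j in range(spec.group_size):
            row = dict(first)
            if j > 0:
                row["record_id"] = next_rid()
                row["document_chembl_id"] = next_doc()
                p = clean_p()
                while any(abs(p - q) < 0.05 for q in ps):
                    p = clean_p()
                ps.append(p)
                value, units = format_value(p)
                row["value"], row["units"] = value, units
            row["year"] = years[j]
            row["authors"] = ";".join([names[j], names[j + 1]])
            component.append(row)
        surviving.append(component[0]["record_id"])
        rows.extend(component)

    # clean singleton records (all survive)
    n_clean = spec.n_records - spec.planted_records()
    for _ in range(n_clean):
        row = base_row(clean_p())
        surviving.append(row["record_id"])
        rows.append(row)

    frame = pd.DataFrame(rows, columns=CHEMBL_FIXTURE_COLUMNS)
    frame = frame.iloc[rng.permutation(len(frame))].reset_index(drop=True)

    n = spec.n_records
    s1_out = n - spec.n_dummy_targets
    s2_drop = spec.n_unclear_units + spec.n_extreme_high + spec.n_extreme_low
    s2_out = s1_out - s2_drop
    s3_drop = spec.n_within_doc_duplicate_groups * (spec.group_size - 1)
    s3_out = s2_out - s3_drop
    s4_drop = spec.n_citation_chains * (spec.group_size - 1)
    s4_out = s3_out - s4_drop
    s5_drop = spec.n_author_overlap_components * (spec.group_size - 1)
    s5_out = s4_out - s5_drop
    truth = GroundTruth(
        stage_counts=[
            {"stage": "group_and_remove_dummy_targets", "records_in": n, "records_out": s1_out},
            {"stage": "standardize_and_filter_extremes", "records_in": s1_out, "records_out": s2_out},
            {"stage": "within_document_collapse", "records_in": s2_out, "records_out": s3_out},
            {"stage": "citation_deduplication", "records_in": s3_out, "records_out": s4_out},
            {"stage": "author_overlap_deduplication", "records_in": s4_out, "records_out": s5_out},
        ],
        surviving_ids=sorted(surviving),
    )
    return frame, truth


def random_spec(rng: np.random.Generator, max_records: int = 500) -> FixtureSpec:
    """Draw a feasible random spec (for closure testing at many shapes)."""
    while True:
        spec = FixtureSpec(
            n_records=int(rng.integers(60, max_records + 1)),
            seed=int(rng.integers(0, 2**31 - 1)),
            n_dummy_targets=int(rng.integers(0, 8)),
            n_extreme_high=int(rng.integers(0, 8)),
            n_extreme_low=int(rng.integers(0, 8)),
            n_unclear_units=int(rng.integers(0, 8)),
            n_within_doc_duplicate_groups=int(rng.integers(0, 10)),
            n_citation_chains=int(rng.integers(0, 10)),
            n_author_overlap_components=int(rng.integers(0, 10)),
            group_size=int(rng.integers(2, 4)),
            ligand_pool_size=min(60, len(SMILES_POOL)),
            protein_pool_size=12,
        )
        try:
            spec.validate()
        except InfeasibleSpecError:
            continue
        return spec


def generate_ligand_set(n: int, seed: int = 0, replace: bool = False) -> list[str]:
    """Seeded sample of valid drug-like SMILES from the packaged pool."""
    if n < 1:
        raise ValueError("n must be ≥ 1")
    if not replace and n > len(SMILES_POOL):
        raise ValueError(
            f"n {n} exceeds the pool size {len(SMILES_POOL)} without replacement"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(SMILES_POOL), size=n, replace=replace)
    return [SMILES_POOL[i] for i in idx]


# --- other dialects ----------------------------------------------------------


def generate_pkis2_fixture(
    n_compounds: int = 3,
    kinase_names: Sequence[str] = ("ABL1", "EGFR"),
    seed: int = 0,
    unmapped_names: Sequence[str] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Wide percent-displacement panel plus its name → UniProt mapping.

    Names in ``unmapped_names`` appear as panel columns but are left out
    of the mapping table (to exercise strict/lenient resolution).
    """
    rng = np.random.default_rng(seed)
    smiles = generate_ligand_set(n_compounds, seed=seed)
    all_names = list(kinase_names) + list(unmapped_names)
    rows = []
    for i, s in enumerate(smiles):
        row = {"smiles": s, "compound_name": f"compound-{i + 1:03d}"}
        for name in all_names:
            row[name] = round(float(rng.uniform(0.0, 100.0)), 2)
        rows.append(row)
    table = pd.DataFrame(rows, columns=["smiles", "compound_name"] + all_names)
    mapping = pd.DataFrame(
        {
            "name": list(kinase_names),
            "uniprot_id": [f"P{50000 + i:05d}" for i in range(len(kinase_names))],
        }
    )
    return table, mapping


def generate_kinase_snapshots(
    n_sources: int = 5,
    intersection_size: int = 7,
    extra_per_source: int = 4,
    seed: int = 0,
) -> list[tuple[str, pd.DataFrame]]:
    """Per-source kinase rosters with an engineered all-source intersection.

    Every source contains the same ``intersection_size`` core accessions
    plus ``extra_per_source`` accessions unique to it.
    """
    rng = np.random.default_rng(seed)
    core = [f"P{60000 + i:05d}" for i in range(intersection_size)]
    tables = []
    for s in range(n_sources):
        extras = [f"Q{s:1d}{70000 + i:05d}" for i in range(extra_per_source)]
        accs = core + extras
        perm = rng.permutation(len(accs))
        accs = [accs[i] for i in perm]
        tables.append(
            (
                f"source_{chr(ord('A') + s)}",
                pd.DataFrame({"uniprot_id": accs, "name": [f"K{a}" for a in accs]}),
            )
        )
    return tables


def generate_template_table(
    query_smiles: str,
    n_decoys: int = 5,
    seed: int = 0,
    include_query: bool = True,
) -> pd.DataFrame:
    """Template-structure table (structure_id, co-ligand SMILES).

    With ``include_query`` the query ligand itself is planted under id
    ``"TMPL_SELF"`` so the expected argmax (similarity 1.0) is known.
    """
    decoys = generate_ligand_set(n_decoys, seed=seed)
    rows = [
        {"structure_id": f"TMPL_{i + 1:03d}", "smiles": s} for i, s in enumerate(decoys)
    ]
    if include_query:
        rows.append({"structure_id": "TMPL_SELF", "smiles": query_smiles})
    return pd.DataFrame(rows, columns=["structure_id", "smiles"])


# --- observation-model recovery experiment -----------------------------------


@dataclass
class RecoveryResult:
    true_dg: np.ndarray
    recovered_dg: np.ndarray
    tolerance: np.ndarray

    @property
    def within_tolerance(self) -> np.ndarray:
        return np.abs(self.recovered_dg - self.true_dg) <= self.tolerance

    @property
    def fraction_recovered(self) -> float:
        return float(self.within_tolerance.mean())


def simulate_recovery_experiment(
    n_systems: int = 500,
    seed: int = 0,
    sigma_p: float = 0.2,
    sigma_percent: float = 3.0,
    probe_concentration: float = 1e-6,
    dg_range: tuple[float, float] = (-14.0, -6.0),
    max_replicates: int = 3,
) -> RecoveryResult:
    """Simulate mixed-assay observations and recover ΔG per system.

    True ΔG is uniform on ``dg_range`` (kcal/mol).  Each system emits 1–3
    measurements of random types; p-scale readouts get Gaussian noise
    σ = ``sigma_p``, percent readouts σ = ``sigma_percent`` (clipped to
    the tolerated band).  The per-system recovery tolerance is three
    standard errors of the estimator actually used — unweighted least
    squares on the observation scales — whose linearized sampling
    variance is ``Σ_j f_j′(ΔG)² σ_j² / (Σ_j f_j′(ΔG)²)²``; for m
    replicates of one p-scale type this reduces to the familiar
    3σ·RT·ln10/√m.
    """
    rng = np.random.default_rng(seed)
    ligand = make_ligand(SMILES_POOL[0])
    mtypes = ["pKd", "pKi", "pIC50", "percent_displacement"]

    true = rng.uniform(dg_range[0], dg_range[1], size=n_systems)
    recovered = np.empty(n_systems)
    tolerance = np.empty(n_systems)

    for i, dg in enumerate(true):
        protein = Protein(uniprot_id=f"P{80000 + i:05d}")
        system = make_system([protein, ligand])
        n_meas = int(rng.integers(1, max_replicates + 1))
        measurements = []
        sum_d2 = 0.0  # Σ f'²
        sum_d2s2 = 0.0  # Σ f'² σ²
        for _ in range(n_meas):
            mtype = mtypes[int(rng.integers(len(mtypes)))]
            if mtype == "percent_displacement":
                conditions = AssayConditions(probe_concentration=probe_concentration)
                sigma = sigma_percent
            else:
                conditions = AssayConditions()
                sigma = sigma_p
            ctx = ThermoContext.from_conditions(conditions)
            value, deriv = predict_observable(dg, mtype, ctx)
            noisy = value + rng.normal(0.0, sigma)
            if mtype == "percent_displacement":
                noisy = float(np.clip(noisy, -10.0, 110.0))
            measurements.append(
                Measurement(
                    system=system, mtype=mtype, values=(noisy,), conditions=conditions
                )
            )
            sum_d2 += deriv**2
            sum_d2s2 += deriv**2 * sigma**2
        recovered[i] = fit_free_energy(measurements, bounds=(-30.0, 5.0))
        tolerance[i] = 3.0 * math.sqrt(sum_d2s2) / sum_d2
    return RecoveryResult(true_dg=true, recovered_dg=recovered, tolerance=tolerance)
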