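"""Domain object model for protein:ligand bioactivity data.

The hierarchy mirrors how heterogeneous activity data is organized in
practice: molecular components (:class:`Ligand`, :class:`Protein`) are
composed into a :class:`System`; an observed activity is a
:class:`Measurement` attaching an array of values, the
:class:`AssayConditions` under which they were obtained, and provenance
:class:`Metadata` to a system; a :class:`DatasetProvider` is an ordered,
provenance-stamped collection of measurements.

Systems compare equal when they denote the same physical protein:ligand
pair — the grouping key is ``(protein primary key, ligand canonical
SMILES)``, with the UniProt accession preferred as the protein key since
it is the universal join key across kinase data sources.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence, Union

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # rdkit parse warnings are surfaced as exceptions instead

#: One-letter codes accepted in protein sequences ('X' = unknown residue).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
SEQUENCE_ALPHABET = AMINO_ACIDS + "X"

#: Measurement types on the p-scale (unitless −log10 molar).
P_SCALE_TYPES = ("pIC50", "pKi", "pKd")
PERCENT_DISPLACEMENT = "percent_displacement"
MEASUREMENT_TYPES = P_SCALE_TYPES + (PERCENT_DISPLACEMENT,)

#: Tolerated range for percent-displacement readouts (assay noise can
#: produce values slightly outside [0, 100]).
PERCENT_RANGE = (-10.0, 110.0)


class InvalidMoleculeError(ValueError):
    """Raised when a SMILES string does not parse as a valid molecule."""


def canonical_smiles(smiles: str) -> str:
    """Return the canonical SMILES for *smiles*, raising on parse failure.

    Canonicalization is idempotent: ``canonical(canonical(s)) == canonical(s)``.
    Stereochemistry is preserved as written; racemates are not enumerated.
    """
    if not smiles:
        raise InvalidMoleculeError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidMoleculeError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class Ligand:
    """A small molecule, stored by its canonical SMILES.

    Use :func:`make_ligand` to construct one from a raw SMILES string;
    direct construction assumes ``smiles`` is already canonical.
    """

    smiles: str
    name: str = ""
    identifiers: tuple[tuple[str, str], ...] = ()

    def identifier(self, namespace: str) -> Optional[str]:
        for ns, value in self.identifiers:
            if ns == namespace:
                return value
        return None


def make_ligand(
    smiles: str,
    name: str = "",
    identifiers: Optional[Mapping[str, str]] = None,
) -> Ligand:
    """Build a :class:`Ligand` from any valid SMILES spelling.

    The stored SMILES is the canonical form; the input spelling is retained
    under the ``"input_smiles"`` identifier namespace so provenance survives
    canonicalization.
    """
    canon = canonical_smiles(smiles)
    ids = {"input_smiles": smiles}
    if identifiers:
        ids.update(identifiers)
    return Ligand(smiles=canon, name=name, identifiers=tuple(sorted(ids.items())))


@dataclass(frozen=True)
class Protein:
    """A protein identified by accession and/or sequence.

    At least one of ``uniprot_id``, ``ncbi_id`` or ``sequence`` must be
    present.  The primary key used for system grouping prefers the UniProt
    accession, then the NCBI accession, then a hash of the sequence.
    """

    uniprot_id: Optional[str] = None
    ncbi_id: Optional[str] = None
    name: str = ""
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.uniprot_id or self.ncbi_id or self.sequence):
            raise ValueError(
                "Protein needs at least one of uniprot_id, ncbi_id, sequence"
            )
        if self.sequence is not None:
            bad = set(self.sequence.upper()) - set(SEQUENCE_ALPHABET)
            if bad:
                raise ValueError(
                    f"sequence contains letters outside the amino-acid alphabet: "
                    f"{sorted(bad)}"
                )

    @property
    def primary_key(self) -> str:
        if self.uniprot_id:
            return self.uniprot_id
        if self.ncbi_id:
            return self.ncbi_id
        assert self.sequence is not None
        return "seq:" + hashlib.sha1(self.sequence.upper().encode()).hexdigest()[:12]


class SystemKind(str, Enum):
    LIGAND_ONLY = "ligand_only"
    PROTEIN_ONLY = "protein_only"
    PROTEIN_LIGAND_COMPLEX = "protein_ligand_complex"


@dataclass(frozen=True)
class System:
    """A typed composition of molecular components.

    Equality and hashing are structural on the grouping key
    ``(protein primary key, ligand canonical SMILES)`` so that systems
    built from different spellings of the same molecule, or carrying
    different display names, group together during curation.
    """

    components: tuple[Union[Ligand, Protein], ...]
    kind: SystemKind

    @property
    def ligand(self) -> Optional[Ligand]:
        for c in self.components:
            if isinstance(c, Ligand):
                return c
        return None

    @property
    def protein(self) -> Optional[Protein]:
        for c in self.components:
            if isinstance(c, Protein):
                return c
        return None

    @property
    def key(self) -> tuple[Optional[str], Optional[str]]:
        prot, lig = self.protein, self.ligand
        return (
            prot.primary_key if prot is not None else None,
            lig.smiles if lig is not None else None,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, System):
            return NotImplemented
        return self.kind == other.kind and self.key == other.key

    def __hash__(self) -> int:
        return hash((self.kind, self.key))


def make_system(components: Sequence[Union[Ligand, Protein]]) -> System:
    """Compose 1–2 components into a :class:`System`; kind follows composition."""
    ligands = [c for c in components if isinstance(c, Ligand)]
    proteins = [c for c in components if isinstance(c, Protein)]
    if len(ligands) + len(proteins) != len(components):
        raise TypeError("components must be Ligand or Protein instances")
    if len(ligands) > 1 or len(proteins) > 1:
        raise ValueError(
            f"a system holds at most one ligand and one protein "
            f"(got {len(ligands)} ligands, {len(proteins)} proteins)"
        )
    if ligands and proteins:
        kind = SystemKind.PROTEIN_LIGAND_COMPLEX
    elif ligands:
        kind = SystemKind.LIGAND_ONLY
    elif proteins:
        kind = SystemKind.PROTEIN_ONLY
    else:
        raise ValueError("a system needs at least one component")
    return System(components=tuple(components), kind=kind)


@dataclass(frozen=True)
class AssayConditions:
    """Biochemical context of an assay.

    pH defaults to 7 (the condition under which the supported bioactivity
    panels were run) and temperature to 298.15 K (standard ambient;
    assay temperature is rarely reported).  ``probe_concentration`` (molar)
    is meaningful only for single-concentration competition-binding
    readouts and is therefore optional and never defaulted.
    """

    pH: float = 7.0
    temperature: float = 298.15
    probe_concentration: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pH <= 14.0:
            raise ValueError(f"pH must lie in [0, 14], got {self.pH}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if self.probe_concentration is not None and self.probe_concentration <= 0:
            raise ValueError(
                f"probe_concentration must be positive, got {self.probe_concentration}"
            )


@dataclass(frozen=True)
class Metadata:
    """Provenance of a measurement: where it came from and what was ingested."""

    source: str = ""
    document_id: str = ""
    year: Optional[int] = None
    authors: tuple[str, ...] = ()
    original_value: Optional[float] = None
    original_units: str = ""


@dataclass(frozen=True)
class Measurement:
    """An activity observation: values on a common scale tied to a system.

    ``values`` holds one or more numbers; multiple entries are treated as
    replicates of the same observation.  p-scale values must be finite;
    percent-displacement values must lie within the tolerated noise band.
    """

    system: System
    mtype: str
    values: tuple[float, ...]
    conditions: AssayConditions = AssayConditions()
    metadata: Metadata = Metadata()

    def __post_init__(self) -> None:
        if self.mtype not in MEASUREMENT_TYPES:
            raise ValueError(
                f"unknown measurement type {self.mtype!r}; "
                f"expected one of {MEASUREMENT_TYPES}"
            )
        if not self.values:
            raise ValueError("values must be non-empty")
        for v in self.values:
            if not math.isfinite(v):
                raise ValueError(f"non-finite measurement value: {v}")
            if self.mtype == PERCENT_DISPLACEMENT and not (
                PERCENT_RANGE[0] <= v <= PERCENT_RANGE[1]
            ):
                raise ValueError(
                    f"percent displacement {v} outside tolerated range "
                    f"{PERCENT_RANGE}"
                )


class DatasetProvider:
    """An ordered collection of measurements sharing one provenance record."""

    def __init__(
        self,
        measurements: Sequence[Measurement],
        provenance: Optional[Mapping[str, object]] = None,
        rejects: Optional[Sequence[Mapping[str, object]]] = None,
    ) -> None:
        self.measurements: list[Measurement] = list(measurements)
        self.provenance: dict[str, object] = dict(provenance or {})
        #: Rows that could not be converted into measurements, with reasons.
        self.rejects: list[dict[str, object]] = [dict(r) for r in (rejects or [])]

    def __len__(self) -> int:
        return len(self.measurements)

    def __iter__(self):
        return iter(self.measurements)

    def __getitem__(self, i: int) -> Measurement:
        return self.measurements[i]

    def systems(self) -> list[System]:
        """Unique systems in first-appearance order."""
        seen: dict[System, None] = {}
        for m in self.measurements:
            seen.setdefault(m.system, None)
        return list(seen)
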