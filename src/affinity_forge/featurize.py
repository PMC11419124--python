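"""Featurizers: turn systems into numeric tensors, singly or in pipelines.

Implemented featurizers:

* Morgan (ECFP-style) circular fingerprints for ligands — per-atom
  invariants iteratively hashed over bond neighborhoods up to a radius,
  folded modulo a bit-vector length;
* one-hot encodings of canonical SMILES strings and protein sequences;
* fingerprint-similarity template selection — given a table of structures
  with co-crystallized ligands, pick the structure whose ligand is most
  Tanimoto-similar to the query compound (the standard prelude to
  template docking, which is outside this package's scope).

A :class:`FeaturizationPipeline` runs several featurizers in order on a
batch of systems; per-stage outputs are concatenated (flattened row-major)
into a ``concat`` feature, or only the last stage is retained when memory
matters.  A featurizer that does not apply to a system (e.g. a sequence
encoder on a ligand-only system) fails that system only; the batch
continues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from rdkit.Chem import rdFingerprintGenerator

from rdkit import Chem

from .core import Ligand, Protein, SEQUENCE_ALPHABET, System


@dataclass
class FeatureTensor:
    """A named numeric array produced by one featurizer.

    ``dtype`` is ``"bit"`` (entries in {0, 1}, stored uint8) or
    ``"float"`` (float64).  ``values`` is an ndarray, or — for a ragged
    tensor — a list of 1-D row arrays of varying length.
    """

    name: str
    values: object
    dtype: str = "float"

    def __post_init__(self) -> None:
        if self.dtype not in ("bit", "float"):
            raise ValueError(f"dtype must be 'bit' or 'float', got {self.dtype!r}")
        np_item = np.uint8 if self.dtype == "bit" else np.float64
        try:
            self.values = np.asarray(self.values, dtype=np_item)
        except ValueError:
            # ragged: rows of varying length
            self.values = [np.asarray(row, dtype=np_item).ravel() for row in self.values]
        for chunk in self.values if isinstance(self.values, list) else [self.values]:
            if self.dtype == "bit":
                if chunk.size and not np.isin(chunk, (0, 1)).all():
                    raise ValueError(
                        f"bit tensor {self.name!r} has entries outside {{0,1}}"
                    )
            elif chunk.size and not np.isfinite(chunk).all():
                raise ValueError(f"tensor {self.name!r} has non-finite entries")

    @property
    def is_ragged(self) -> bool:
        return isinstance(self.values, list)


# --- Morgan fingerprints -----------------------------------------------------


def _mol(ligand: Union[Ligand, str]) -> Chem.Mol:
    smiles = ligand.smiles if isinstance(ligand, Ligand) else ligand
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


def morgan_fingerprint(
    ligand: Union[Ligand, str], radius: int = 2, n_bits: int = 2048
) -> FeatureTensor:
    """ECFP-style circular fingerprint as a bit tensor of length ``n_bits``.

    Atom environments (element, degree, charge, attached hydrogens, ring
    membership, iteratively hashed over neighborhoods up to ``radius``)
    are folded modulo ``n_bits``.  Invariant under SMILES respelling of
    the same molecule.  Defaults (radius 2 ≙ ECFP4, 2048 bits) follow
    community convention.
    """
    if n_bits <= 0:
        raise ValueError(f"n_bits must be positive, got {n_bits}")
    if radius < 0:
        raise ValueError(f"radius must be non-negative, got {radius}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    arr = gen.GetFingerprintAsNumPy(_mol(ligand)).astype(np.uint8)
    return FeatureTensor(name=f"morgan_r{radius}_b{n_bits}", values=arr, dtype="bit")


def tanimoto(a: FeatureTensor, b: FeatureTensor) -> float:
    """Tanimoto similarity |a∧b| / |a∨b| of two equal-length bit tensors.

    Defined as 1.0 when both vectors are all-zero (two moleculeless
    fingerprints are indistinguishable, hence maximally similar by
    convention).
    """
    va, vb = np.asarray(a.values).ravel(), np.asarray(b.values).ravel()
    if va.shape != vb.shape:
        raise ValueError(f"fingerprint length mismatch: {va.shape} vs {vb.shape}")
    union = int(np.logical_or(va, vb).sum())
    if union == 0:
        return 1.0
    return float(np.logical_and(va, vb).sum() / union)


# --- one-hot encodings -------------------------------------------------------

#: Characters of canonical organic-subset SMILES: element letters (with
#: 'l'/'r' completing Cl/Br and 'H' for bracket hydrogens), aromatic
#: lowercase forms, ring-bond digits, and structural symbols.
DEFAULT_SMILES_ALPHABET = (
    "BCNOPSFIH" + "bcnops" + "lr" + "0123456789" + "()[]=#+-@/\\:.%"
)


def _one_hot(string: str, alphabet: str, max_length: int, what: str) -> np.ndarray:
    if max_length <= 0:
        raise ValueError(f"max_length must be positive, got {max_length}")
    if len(string) > max_length:
        raise ValueError(
            f"{what} of length {len(string)} exceeds max_length {max_length}"
        )
    index = {ch: i for i, ch in enumerate(alphabet)}
    out = np.zeros((max_length, len(alphabet)), dtype=np.uint8)
    for i, ch in enumerate(string):
        if ch not in index:
            raise ValueError(f"character {ch!r} in {what} is not in the alphabet")
        out[i, index[ch]] = 1
    return out


def one_hot_smiles(
    ligand: Union[Ligand, str],
    max_length: int = 128,
    alphabet: str = DEFAULT_SMILES_ALPHABET,
) -> FeatureTensor:
    """One-hot encode the canonical SMILES: shape (max_length, |alphabet|).

    Row *i* is one-hot at the alphabet index of character *i*; rows past
    the string's end are all-zero padding, so argmax decoding of non-zero
    rows reconstructs the string exactly.
    """
    smiles = ligand.smiles if isinstance(ligand, Ligand) else ligand
    values = _one_hot(smiles, alphabet, max_length, f"SMILES {smiles!r}")
    return FeatureTensor(name="one_hot_smiles", values=values, dtype="bit")


def one_hot_sequence(
    protein: Protein,
    max_length: int = 1024,
    alphabet: str = SEQUENCE_ALPHABET,
    lenient: bool = False,
) -> FeatureTensor:
    """One-hot encode a protein sequence over the 20 amino acids + 'X'.

    With ``lenient=True`` ambiguous or non-canonical residue codes
    (B, Z, J, U, O) map to 'X'; otherwise they are rejected.
    """
    if protein.sequence is None:
        raise ValueError(
            f"protein {protein.name or protein.primary_key!r} has no sequence"
        )
    seq = protein.sequence.upper()
    if lenient:
        seq = "".join(ch if ch in alphabet else "X" for ch in seq)
    values = _one_hot(seq, alphabet, max_length, "sequence")
    return FeatureTensor(name="one_hot_sequence", values=values, dtype="bit")


def decode_one_hot(tensor: FeatureTensor, alphabet: str) -> str:
    """Invert a one-hot encoding (padding rows are all-zero)."""
    values = np.asarray(tensor.values)
    chars = []
    for row in values:
        if not row.any():
            break
        chars.append(alphabet[int(np.argmax(row))])
    return "".join(chars)


# --- template selection ------------------------------------------------------


def select_template(
    ligand: Union[Ligand, str],
    candidates: Union[pd.DataFrame, Sequence[tuple[str, str]]],
    metric: str = "fingerprint",
    radius: int = 2,
    n_bits: int = 2048,
) -> tuple[str, float]:
    """Pick the candidate structure whose co-crystallized ligand is most
    similar to the query compound.

    ``candidates`` is a table of ``(structure_id, smiles)``.  Similarity is
    Tanimoto on Morgan fingerprints; ties break toward the
    lexicographically smallest structure id.  Only the fingerprint metric
    is supported.
    """
    if metric != "fingerprint":
        raise ValueError(f"unsupported similarity metric {metric!r}")
    if isinstance(candidates, pd.DataFrame):
        if not {"structure_id", "smiles"}.issubset(candidates.columns):
            raise ValueError("candidate table needs columns structure_id, smiles")
        pairs = list(zip(candidates["structure_id"], candidates["smiles"]))
    else:
        pairs = list(candidates)
    if not pairs:
        raise ValueError("candidate table is empty")

    query_fp = morgan_fingerprint(ligand, radius=radius, n_bits=n_bits)
    best: Optional[tuple[str, float]] = None
    for structure_id, smiles in sorted(pairs, key=lambda p: str(p[0])):
        sim = tanimoto(query_fp, morgan_fingerprint(str(smiles), radius, n_bits))
        if best is None or sim > best[1]:
            best = (str(structure_id), sim)
    return best


# --- pipelines ---------------------------------------------------------------


@dataclass(frozen=True)
class FeaturizerSpec:
    """A featurizer by name with serializable parameters."""

    name: str
    params: tuple[tuple[str, object], ...] = ()

    @classmethod
    def make(cls, name: str, **params) -> "FeaturizerSpec":
        return cls(name=name, params=tuple(sorted(params.items())))

    def to_dict(self) -> dict:
        return {"name": self.name, "params": dict(self.params)}


@dataclass(frozen=True)
class FeaturizationPipeline:
    """An ordered, serializable list of featurizer specs."""

    steps: tuple[FeaturizerSpec, ...]
    retain_last_only: bool = False

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("a pipeline needs at least one featurizer")

    @classmethod
    def from_config(cls, config: Mapping) -> "FeaturizationPipeline":
        steps = tuple(
            FeaturizerSpec.make(entry["name"], **entry.get("params", {}))
            for entry in config["pipeline"]
        )
        return cls(steps=steps, retain_last_only=bool(config.get("retain_last_only", False)))

    def to_config(self) -> dict:
        return {
            "pipeline": [s.to_dict() for s in self.steps],
            "retain_last_only": self.retain_last_only,
        }


@dataclass
class PipelineResult:
    """Featurization outcome for one system.

    On success ``features`` maps featurizer names (plus ``concat`` unless
    only the last stage is retained) to tensors and ``annotations`` holds
    scalar side products (e.g. the selected template id); on failure
    ``error`` describes why the system was skipped.
    """

    system: System
    features: dict[str, FeatureTensor] = field(default_factory=dict)
    annotations: dict[str, str] = field(default_factory=dict)
    error: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.error is None


def _needs_ligand(system: System, name: str) -> Ligand:
    if system.ligand is None:
        raise ValueError(f"featurizer {name!r} requires a ligand component")
    return system.ligand


def _needs_protein(system: System, name: str) -> Protein:
    if system.protein is None:
        raise ValueError(f"featurizer {name!r} requires a protein component")
    return system.protein


def _run_morgan(system: System, result: PipelineResult, **params) -> FeatureTensor:
    return morgan_fingerprint(_needs_ligand(system, "morgan"), **params)


def _run_one_hot_smiles(system: System, result: PipelineResult, **params) -> FeatureTensor:
    return one_hot_smiles(_needs_ligand(system, "one_hot_smiles"), **params)


def _run_one_hot_sequence(system: System, result: PipelineResult, **params) -> FeatureTensor:
    return one_hot_sequence(_needs_protein(system, "one_hot_sequence"), **params)


def _run_template(system: System, result: PipelineResult, **params) -> FeatureTensor:
    candidates = params.pop("candidates")
    if isinstance(candidates, str):
        candidates = pd.read_csv(candidates)
    structure_id, sim = select_template(
        _needs_ligand(system, "template"), candidates, **params
    )
    result.annotations["template_structure_id"] = structure_id
    return FeatureTensor(name="template_similarity", values=np.array([sim]), dtype="float")


FEATURIZER_REGISTRY: dict[str, Callable] = {
    "morgan": _run_morgan,
    "one_hot_smiles": _run_one_hot_smiles,
    "one_hot_sequence": _run_one_hot_sequence,
    "template": _run_template,
}


def run_pipeline(
    pipeline: FeaturizationPipeline, systems: Sequence[System]
) -> list[PipelineResult]:
    """Run every pipeline stage on every system.

    Stage outputs are flattened row-major and concatenated into a
    ``concat`` feature; with ``retain_last_only`` only the final stage's
    tensor is kept.  A failing featurizer marks that system's result with
    an error and the batch continues.
    """
    results = []
    for system in systems:
        result = PipelineResult(system=system)
        stage_tensors: list[FeatureTensor] = []
        try:
            for spec in pipeline.steps:
                if spec.name not in FEATURIZER_REGISTRY:
                    raise ValueError(f"unknown featurizer {spec.name!r}")
                tensor = FEATURIZER_REGISTRY[spec.name](system, result, **dict(spec.params))
                stage_tensors.append(tensor)
        except ValueError as exc:
            result.error = str(exc)
            results.append(result)
            continue
        if pipeline.retain_last_only:
            last = stage_tensors[-1]
            result.features = {last.name: last}
        else:
            result.features = {t.name: t for t in stage_tensors}
            flat = [np.asarray(t.values, dtype=np.float64).ravel(order="C") for t in stage_tensors]
            result.features["concat"] = FeatureTensor(
                name="concat", values=np.concatenate(flat), dtype="float"
            )
        results.append(result)
    return results
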