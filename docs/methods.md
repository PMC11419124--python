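# Methods

This note documents the models, conventions and numerical choices behind
affinity-forge, and what its synthetic fixtures do and do not establish
about behavior on real data.

## Object model and system identity

A *system* is the unit everything else keys on: a typed composition of at
most one protein and one ligand. Curation and grouping identify a system
by `(protein primary key, ligand canonical SMILES)`. The protein primary
key prefers the UniProt accession — the only universal protein join key
across kinase data sources — then the NCBI accession, then a SHA-1 hash
of the sequence. Ligands are stored as RDKit canonical SMILES with the
input spelling retained under the `input_smiles` identifier namespace, so
two spellings of one molecule always group together while provenance
survives. Stereochemistry is preserved exactly as written; racemates are
not enumerated — unclear stereo-annotations are instead handled
statistically by the within-publication collapse (stage 3).

A measurement's `values` array may hold several numbers; they are
treated as replicates of one observation (the loss averages over them),
not as alternative measurements.

## Curation cascade

Stages run in a fixed order; each only removes records, so counts chain
monotonically and the per-stage report is an audit trail.

- **Dummy target** (stage 1): the default removal set is
  `{CHEMBL612545}`, a verification pseudo-target whose rows carry no real
  activity; the set is configurable.
- **Unit standardization** (stage 2): recognized concentration units are
  fM, pM, nM, µM (micro sign or `u`), mM, M, case-insensitively; p =
  −log10(molar). Anything else ("mg/mL", "%", missing) is dropped with
  reason `unclear_units` — mass-per-volume units are unconvertible
  without molecular weights and assay context. Non-positive values are
  dropped as `invalid_value`.
- **Extreme filter** (stage 2): concentrations strictly weaker than
  10 mM (p < 2) or stronger than 1 fM (p > 15) are implausible for a
  binding assay and removed. The inequalities are deliberately strict:
  a record at exactly 10 mM or 1 fM is retained.
- **Within-publication collapse** (stage 3): per (system, publication)
  the maximum p survives; ties break toward the earliest-ingested row so
  the survivor is deterministic under reruns.
- **Citation dedup** (stage 4): "identical value" means |Δp| ≤ 1e−6
  (configurable), closed transitively — values within tolerance of a
  common member join one group. The earliest publication year survives,
  matching the intent of removing re-citations of previously published
  numbers; a record with no year is ranked last and never kept as the
  original.
- **Author-overlap dedup** (stage 5): author names are compared exactly
  after case-folding and whitespace collapsing; fuzzy matching is out of
  scope. Publications whose author sets intersect are edges of a graph;
  one record (earliest year) survives per connected component. A
  publication with no listed authors forms its own component.

Permuting input rows can change which of two *tied* records survives,
never the stage counts. Re-running the cascade on its own survivors is
the identity.

## Observation model

The gas constant is fixed at R = 1.987204259×10⁻³ kcal·mol⁻¹·K⁻¹;
temperature comes from each measurement's assay conditions (default
298.15 K — standard ambient, chosen because assay temperature is rarely
reported). The standard-state concentration is 1 M.

- pKd link: pKd = −ΔG/(RT ln 10); derivative constant −1/(RT ln 10)
  ≈ −1.366 p-units per kcal/mol at 298.15 K. Exact closed-form inverse.
- Percent displacement: single-site occupancy 100·L/(L + Kd) — the
  standard competitive-binding approximation for single-concentration
  panel readouts; L is a required input with no default, because panels
  run at assay-specific probe concentrations.
- pKi and pIC50 reuse the pKd link. The exact corrections (e.g.
  Cheng–Prusoff) need substrate concentration and K_m, which activity
  tables do not report; a per-assay additive offset hook is the
  extension point for users who have them.

The loss is mean squared error on each measurement's native scale with
analytic chain-rule gradients; it is the simplest loss the differentiable
-link design supports and keeps the gradient contract ("value plus first
derivative") framework-agnostic. ΔG fitting uses bounded scalar
minimization (Brent, bounds −30 to +5 kcal/mol, xatol 1e−8).

### Recovery experiment

The validation experiment simulates 500 systems with true ΔG uniform on
[−14, −6] kcal/mol — spanning millimolar to sub-nanomolar binders — each
emitting 1–3 measurements of random type with Gaussian noise σ = 0.2 on
the p-scale and σ = 3 on the percent scale (clipped to the tolerated
[−10, 110] band). The probe concentration is 1 µM, a typical
single-concentration panel choice. Because the loss is *unweighted*
across scales, the statistically correct per-system tolerance is three
standard errors of the unweighted least-squares estimator,
3·√(Σf′²σ²)/Σf′², which reduces to 3σ·RT·ln10/√m for m replicates of one
p-scale type. A system whose only readout is a saturated displacement
measurement is genuinely uninformative (f′ ≈ 0); its tolerance is
correspondingly wide, which is the honest statement of what such data
can constrain. The acceptance threshold is recovery within tolerance for
≥95% of systems.

## Featurization

- Morgan/ECFP fingerprints are computed with RDKit's Morgan generator
  (defaults radius 2 ≙ ECFP4, 2048 bits — community convention). Folded
  on-bit positions are hash-implementation-defined, so cross-toolkit
  bit-level equality is not a meaningful target; the tests instead verify
  respelling invariance and that folded bits equal sparse environment
  identifiers folded modulo the bit length through an independent API
  route.
- Tanimoto similarity of two all-zero fingerprints is defined as 1.0
  (documented convention: featureless queries are indistinguishable).
- The default SMILES one-hot alphabet covers canonical organic-subset
  SMILES: `BCNOPSFIH bcnops lr 0-9 ()[]=#+-@/\:.%` — including `H`
  because bracket atoms like `[nH]` are ubiquitous in canonical
  aromatic-nitrogen SMILES. The alphabet is a parameter; out-of-alphabet
  characters are rejected by name rather than silently dropped. Sequence
  encoding uses the 20 canonical amino acids plus `X`, with a lenient
  mode mapping ambiguity codes (B, Z, J, U, O) to `X`.
- Template selection supports the fingerprint metric only (MCS and
  shape-based metrics are out of scope); ties break toward the
  lexicographically smallest structure id.
- Pipelines flatten multi-dimensional stage outputs row-major (C order)
  before concatenation. A featurizer inapplicable to a system (sequence
  encoder on a ligand-only system, say) fails that system and records
  the reason; the batch continues — batch featurization of large sets
  must not abort on one bad record.

## Tensor store

Nested Parquet list columns store each feature without padding: 1-D
tensors as `list<item>`, 2-D (possibly ragged-rowed) tensors as
`list<list<item>>`, bit tensors as uint8, floats as float64 — both
round-trip bit-exactly, including zero-length rows. A feature missing
from one record is an explicit null. Per-feature dtype/rank, a schema
version (readers refuse a different major, naming both versions), and
store provenance (tool version, config hash, seed) live in the file
metadata. Writes are deterministic for fixed input and library versions,
so file bytes can serve as a content-addressed provenance hash.
Streaming reads and sharding are out of scope.

## Synthetic fixtures: what they do and do not show

The fixture generator emulates the *structural* failure modes the
cascade exists to remove — dummy targets, unconvertible units, extreme
values, within-publication repeats, exact-value citation chains, and
author-overlap components — each planted in its own system so groups
cannot interact and the expected outcome of every stage is known by
construction. Planted duplicate values are copied exactly, never
re-noised, so "identical value" is unambiguous. Ligands come from a
packaged pool of 62 valid, chemically diverse drug-like SMILES; authors
from a synthetic name pool with controlled overlap; affinities are
uniform on p ∈ [4, 10] with no structure–activity relationship.

Passing the closure property (cascade output ≡ planted ground truth on
100 random fixture shapes, and ≡ an independent exhaustive-pairwise
oracle on small sets) shows the cascade implements its stated semantics
exactly. It does not show robustness to failure modes the generator does
not model: near-identical values from genuinely independent experiments,
misspelled author names, ambiguous stereochemistry, or mixed-construct
assays. Those require curation judgment on real data and are documented
limitations, not covered behavior. Absolute record counts from any
specific public database release are likewise out of scope: they depend
on that external snapshot, while the tests here validate the transformation.

## Problem sizes

The shipped validation runs use 100 random fixtures of up to 500
records, 500 simulated systems for recovery, 12 ligands × 20 respellings
for fingerprint invariance, and 1,000 ragged records for storage — sizes
chosen so the full suite exercises every code path in well under the
patience of a pre-commit run while keeping every check statistically
meaningful.
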