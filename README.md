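# affinity-forge

Tools for taking heterogeneous kinase-inhibitor bioactivity data from raw
activity tables to ML-ready tensors: ingestion of ChEMBL-style and
percent-displacement panel dialects, a five-stage curation cascade,
composable featurization pipelines, differentiable assay-class link
functions from a latent binding free energy, and bit-exact ragged-tensor
Parquet storage. Everything is testable offline: a synthetic fixture
generator plants known structure (duplicates, extreme values, citation
chains, author overlaps) and records the exact ground truth the pipeline
must reproduce.

## Who this is for

Practitioners building binding-affinity models across a protein family
face three recurring chores before any modeling happens: cleaning public
bioactivity data whose rows duplicate, contradict and re-cite each other;
turning protein:ligand pairs into numeric features reproducibly; and
training against assays that measure *different* physical quantities
(K_d, K_i, IC50, single-concentration % displacement). This package
implements each of those steps as a small, deterministic, testable
library with a thin CLI.

## The core procedures

**Curation cascade.** Raw rows (target accession, SMILES, K_d/K_i/IC50
value + units, publication, year, authors) pass through five ordered
stages:

1. group by system — a (protein, ligand) pair keyed by UniProt accession
   and canonical SMILES — and drop the source database's "dummy"
   verification target (`CHEMBL612545`);
2. convert activities to the p-scale, p = −log10(concentration in M),
   dropping unclear units and implausible extremes (strictly beyond
   10 mM or 1 fM, i.e. p < 2 or p > 15; boundaries kept);
3. within each (system, publication), keep only the highest p-value;
4. among publications reporting an identical value for a system
   (|Δp| ≤ 1e−6), keep only the earliest — later ones are citations;
5. among publications on a system sharing one or more authors, keep the
   earliest per connected component, so survivors are independent.

Each run emits a per-stage report (counts and drop reasons) whose
numbers chain exactly.

**Assay-class observation model.** A model predicts one latent
quantity, the binding free energy ΔG (kcal/mol), mapped onto each
measurement's own scale by deterministic, differentiable links:

    Kd  = c0 · exp(ΔG / RT),     c0 = 1 M
    pKd = −ΔG / (RT ln 10)                       (pKi, pIC50 reuse this link)
    D%  = 100 · L / (L + Kd)                     (probe concentration L)

Every link returns its analytic derivative d(value)/dΔG, so a squared
error on the native observation scale backpropagates through the link —
heterogeneous assays train one model without prior unit unification.

**Featurization.** Morgan/ECFP circular fingerprints, one-hot SMILES and
sequence encodings, and fingerprint-similarity template selection (pick
the structure whose co-crystallized ligand is most Tanimoto-similar to a
query), composable into pipelines whose per-stage outputs concatenate.

**Tensor store.** Feature tensors of heterogeneous and ragged shapes are
serialized to Parquet as nested list columns — no padding — with y
values, string metadata, a schema version, and embedded provenance;
writes are byte-deterministic so files can be content-hashed.

## Worked example

```python
import io
from affinity_forge import FixtureSpec, generate_curation_fixture, run_cascade
from affinity_forge.ingest import read_activity_records

spec = FixtureSpec(n_records=200, seed=1)          # plants 5 dummy rows, 5 unclear
frame, truth = generate_curation_fixture(spec)     # units, 10 extremes, 8+6+6 groups
records = read_activity_records(io.StringIO(frame.to_csv(index=False)))
measurements, report = run_cascade(records)
for s in report.stages:
    print(f"{s.stage:35s} {s.records_in:4d} -> {s.records_out:4d}  {dict(s.drop_reasons)}")
```

prints

```
group_and_remove_dummy_targets       200 ->  195  {'dummy_target': 5}
standardize_and_filter_extremes      195 ->  180  {'unclear_units': 5, 'extreme_value': 10}
within_document_collapse             180 ->  172  {'lower_duplicate_in_document': 8}
citation_deduplication               172 ->  166  {'cited_duplicate': 6}
author_overlap_deduplication         166 ->  160  {'author_overlap': 6}
```

— exactly the generator's planted ground truth: 5 dummy-target rows, 5
unclear-unit rows, 10 extremes, and 8/6/6 duplicate groups each
collapsing to one survivor. Fitting a free energy to mixed observations:

```python
from affinity_forge import Measurement, AssayConditions, fit_free_energy

system = measurements[0].system
dg = fit_free_energy([
    Measurement(system=system, mtype="pKi", values=(7.8,)),
    Measurement(system=system, mtype="percent_displacement", values=(91.0,),
                conditions=AssayConditions(probe_concentration=1e-6)),
])
print(f"fitted dG = {dg:.3f} kcal/mol")
```

prints `fitted dG = -9.559 kcal/mol` (pKd-equivalent ≈ 7.0): the latent
ΔG reconciling a p-scale and a percent-displacement readout of the same
system.

The same flows are available from a shell:

```sh
affinity-forge fixtures  --spec spec.yaml --out fixture_dir/
affinity-forge curate    --input fixture_dir/raw.csv --output curated.csv --report report.json
affinity-forge featurize --config feats.yaml --input curated.csv --output features.parquet
```

Reruns with identical inputs and config produce byte-identical outputs.

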