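import numpy as np
import pandas as pd
import pytest
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from affinity_forge.core import Protein, make_ligand, make_system
from affinity_forge.featurize import (
    DEFAULT_SMILES_ALPHABET,
    FeaturizationPipeline,
    FeatureTensor,
    FeaturizerSpec,
    decode_one_hot,
    morgan_fingerprint,
    one_hot_sequence,
    one_hot_smiles,
    run_pipeline,
    select_template,
    tanimoto,
)
from affinity_forge.fixtures import SMILES_POOL, generate_ligand_set, generate_template_table


class TestMorganFingerprint:
    def test_spellings_of_same_molecule_give_identical_bits(self):
        a = morgan_fingerprint(make_ligand("CCO"), radius=2, n_bits=1024)
        b = morgan_fingerprint(make_ligand("OCC"), radius=2, n_bits=1024)
        assert a.dtype == "bit" and a.values.shape == (1024,)
        assert np.array_equal(a.values, b.values)

    @pytest.mark.parametrize("smiles", generate_ligand_set(8, seed=21))
    def test_invariance_under_random_respellings(self, smiles):
        mol = Chem.MolFromSmiles(smiles)
        reference = morgan_fingerprint(make_ligand(smiles)).values
        for respelled in Chem.MolToRandomSmilesVect(mol, 20, randomSeed=7):
            assert np.array_equal(morgan_fingerprint(make_ligand(respelled)).values, reference)

    @pytest.mark.parametrize("smiles", ["CCO", "CC(=O)Oc1ccccc1C(=O)O"])
    @pytest.mark.parametrize("n_bits", [512, 2048])
    def test_on_bits_match_independent_sparse_fold(self, smiles, n_bits):
        """Folded on-bit positions equal sparse environment ids taken modulo
        the bit length through an independent fingerprinting route."""
        fp = morgan_fingerprint(make_ligand(smiles), radius=2, n_bits=n_bits)
        on_bits = set(np.nonzero(fp.values)[0].tolist())
        sparse = rdFingerprintGenerator.GetMorganGenerator(radius=2).GetSparseFingerprint(
            Chem.MolFromSmiles(smiles)
        )
        assert on_bits == {b % n_bits for b in sparse.GetOnBits()}

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            morgan_fingerprint(make_ligand("CCO"), n_bits=0)
        with pytest.raises(ValueError):
            morgan_fingerprint(make_ligand("CCO"), radius=-1)


class TestTanimoto:
    def test_self_similarity_is_one(self):
        fp = morgan_fingerprint(make_ligand("CCO"))
        assert tanimoto(fp, fp) == 1.0

    def test_disjoint_bits_give_zero(self):
        a = FeatureTensor("a", [1, 1, 0, 0], "bit")
        b = FeatureTensor("b", [0, 0, 1, 1], "bit")
        assert tanimoto(a, b) == 0.0

    def test_known_overlap(self):
        a = FeatureTensor("a", [1, 1, 0, 0], "bit")
        b = FeatureTensor("b", [1, 0, 1, 0], "bit")
        assert tanimoto(a, b) == pytest.approx(1 / 3)

    def test_all_zero_convention(self):
        z = FeatureTensor("z", [0, 0, 0], "bit")
        assert tanimoto(z, z) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            tanimoto(FeatureTensor("a", [1], "bit"), FeatureTensor("b", [1, 0], "bit"))


class TestOneHot:
    def test_smiles_rows_and_padding(self):
        t = one_hot_smiles(make_ligand("CCO"), max_length=5)
        assert t.values.shape == (5, len(DEFAULT_SMILES_ALPHABET))
        assert list(t.values[:3].sum(axis=1)) == [1, 1, 1]
        assert t.values[3:].sum() == 0

    @pytest.mark.parametrize("smiles", SMILES_POOL)
    def test_smiles_round_trip_over_pool(self, smiles):
        lig = make_ligand(smiles)
        t = one_hot_smiles(lig, max_length=128)
        assert decode_one_hot(t, DEFAULT_SMILES_ALPHABET) == lig.smiles

    def test_out_of_alphabet_character_named(self):
        with pytest.raises(ValueError, match="§"):
            one_hot_smiles("C§C", max_length=8)

    def test_over_length_rejected(self):
        with pytest.raises(ValueError, match="max_length"):
            one_hot_smiles(make_ligand("CCCCCCCC"), max_length=4)

    def test_sequence_encoding_and_round_trip(self):
        prot = Protein(uniprot_id="P1", sequence="ACD")
        t = one_hot_sequence(prot, max_length=4)
        assert t.values.shape == (4, 21)
        assert list(t.values.sum(axis=1)) == [1, 1, 1, 0]
        assert decode_one_hot(t, "ACDEFGHIKLMNPQRSTVWYX") == "ACD"

    def test_ambiguous_residue_lenient_vs_strict(self):
        prot = Protein(uniprot_id="P1", sequence="ACDX")
        assert one_hot_sequence(prot, max_length=8).values.sum() == 4
        odd = Protein.__new__(Protein)  # bypass validation to carry a 'B'
        object.__setattr__(odd, "uniprot_id", "P1")
        object.__setattr__(odd, "ncbi_id", None)
        object.__setattr__(odd, "name", "")
        object.__setattr__(odd, "sequence", "ABD")
        lenient = one_hot_sequence(odd, max_length=4, lenient=True)
        assert decode_one_hot(lenient, "ACDEFGHIKLMNPQRSTVWYX") == "AXD"
        with pytest.raises(ValueError, match="'B'"):
            one_hot_sequence(odd, max_length=4)

    def test_absent_sequence_rejected(self):
        with pytest.raises(ValueError, match="no sequence"):
            one_hot_sequence(Protein(uniprot_id="P1"), max_length=4)


class TestSelectTemplate:
    def test_verbatim_query_wins_with_similarity_one(self):
        query = SMILES_POOL[3]
        table = generate_template_table(query, n_decoys=5, seed=1)
        structure_id, sim = select_template(make_ligand(query), table)
        assert structure_id == "TMPL_SELF"
        assert sim == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_argmax_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        query = SMILES_POOL[int(rng.integers(len(SMILES_POOL)))]
        decoys = generate_ligand_set(8, seed=seed + 100)
        table = pd.DataFrame(
            {"structure_id": [f"T{i:02d}" for i in range(len(decoys))], "smiles": decoys}
        )
        structure_id, sim = select_template(make_ligand(query), table)
        # oracle: exhaustive pairwise Tanimoto scan
        fps = {
            row.structure_id: morgan_fingerprint(make_ligand(row.smiles))
            for row in table.itertuples()
        }
        qfp = morgan_fingerprint(make_ligand(query))
        sims = {sid: tanimoto(qfp, fp) for sid, fp in fps.items()}
        best = max(sims.values())
        assert sim == pytest.approx(best)
        assert structure_id == min(s for s, v in sims.items() if v == best)

    def test_tie_breaks_lexicographically(self):
        table = [("Z_STRUCT", "CCO"), ("A_STRUCT", "OCC")]
        structure_id, sim = select_template(make_ligand("CCO"), table)
        assert structure_id == "A_STRUCT" and sim == 1.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_template(make_ligand("CCO"), [])

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="metric"):
            select_template(make_ligand("CCO"), [("T", "CCO")], metric="shape")


class TestPipeline:
    def _systems(self, n=3):
        smiles = generate_ligand_set(n, seed=3)
        return [
            make_system([Protein(uniprot_id=f"P{i}", sequence="ACDEFGHIK"), make_ligand(s)])
            for i, s in enumerate(smiles)
        ]

    def test_concat_shape_arithmetic(self):
        pipe = FeaturizationPipeline(
            steps=(
                FeaturizerSpec.make("morgan", radius=2, n_bits=8),
                FeaturizerSpec.make("one_hot_smiles", max_length=4),
            )
        )
        [result] = run_pipeline(pipe, [make_system([make_ligand("CCO")])])
        assert result.ok
        assert result.features["concat"].values.shape == (
            8 + 4 * len(DEFAULT_SMILES_ALPHABET),
        )

    def test_retain_last_only_keeps_final_stage(self):
        pipe = FeaturizationPipeline(
            steps=(
                FeaturizerSpec.make("morgan", radius=2, n_bits=8),
                FeaturizerSpec.make("one_hot_smiles", max_length=4),
            ),
            retain_last_only=True,
        )
        [result] = run_pipeline(pipe, [make_system([make_ligand("CCO")])])
        assert set(result.features) == {"one_hot_smiles"}

    def test_empty_system_list_gives_empty_output(self):
        pipe = FeaturizationPipeline(steps=(FeaturizerSpec.make("morgan"),))
        assert run_pipeline(pipe, []) == []

    def test_inapplicable_featurizer_skips_system_not_batch(self):
        pipe = FeaturizationPipeline(
            steps=(FeaturizerSpec.make("one_hot_sequence", max_length=16),)
        )
        systems = [make_system([make_ligand("CCO")])] + self._systems(2)
        results = run_pipeline(pipe, systems)
        assert [r.ok for r in results] == [False, True, True]
        assert "protein" in results[0].error

    def test_permutation_equivariance(self):
        pipe = FeaturizationPipeline(
            steps=(FeaturizerSpec.make("morgan", radius=2, n_bits=64),)
        )
        systems = self._systems(4)
        forward = run_pipeline(pipe, systems)
        backward = run_pipeline(pipe, systems[::-1])
        for f, b in zip(forward, backward[::-1]):
            assert np.array_equal(
                f.features["concat"].values, b.features["concat"].values
            )

    def test_concatenation_is_associative(self):
        lig = make_ligand("CCO")
        parts = [
            morgan_fingerprint(lig, 2, 16).values.astype(float).ravel(),
            one_hot_smiles(lig, max_length=4).values.astype(float).ravel(),
            morgan_fingerprint(lig, 1, 8).values.astype(float).ravel(),
        ]
        left = np.concatenate([np.concatenate(parts[:2]), parts[2]])
        right = np.concatenate([parts[0], np.concatenate(parts[1:])])
        assert np.array_equal(left, right)
        pipe = FeaturizationPipeline(
            steps=(
                FeaturizerSpec.make("morgan", radius=2, n_bits=16),
                FeaturizerSpec.make("one_hot_smiles", max_length=4),
                FeaturizerSpec.make("morgan", radius=1, n_bits=8),
            )
        )
        [result] = run_pipeline(pipe, [make_system([lig])])
        assert np.array_equal(result.features["concat"].values, left)

    def test_template_stage_annotates_structure_id(self):
        query = SMILES_POOL[0]
        table = generate_template_table(query, n_decoys=3, seed=2)
        pipe = FeaturizationPipeline(
            steps=(
                FeaturizerSpec.make("template", candidates=table),
                FeaturizerSpec.make("morgan", radius=2, n_bits=16),
            )
        )
        [result] = run_pipeline(pipe, [make_system([make_ligand(query)])])
        assert result.annotations["template_structure_id"] == "TMPL_SELF"
        assert result.features["template_similarity"].values[0] == 1.0

    def test_pipeline_config_round_trip(self):
        pipe = FeaturizationPipeline(
            steps=(FeaturizerSpec.make("morgan", radius=2, n_bits=64),),
            retain_last_only=True,
        )
        assert FeaturizationPipeline.from_config(pipe.to_config()) == pipe

    def test_empty_pipeline_rejected(self):
        with pytest.raises(ValueError):
            FeaturizationPipeline(steps=())


class TestFeatureTensorValidation:
    def test_bit_tensor_rejects_non_binary(self):
        with pytest.raises(ValueError, match="outside"):
            FeatureTensor("x", [0, 2], "bit")

    def test_float_tensor_rejects_non_finite(self):
        with pytest.raises(ValueError, match="non-finite"):
            FeatureTensor("x", [1.0, float("inf")], "float")

    def test_ragged_rows_supported(self):
        t = FeatureTensor("x", [[1.0, 2.0], [3.0]], "float")
        assert t.is_ragged
        assert [row.tolist() for row in t.values] == [[1.0, 2.0], [3.0]]
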