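"""Descriptor engine: graph construction, oracles and prefiltering."""
import math

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem
from rdkit.Chem import Descriptors as RDDescriptors, rdMolDescriptors
from rdkit.Chem.EState import EStateIndices

from intrinsol.descriptors import (
    DescriptorMatrix,
    PrefilterConfig,
    RELATIVE_POLARIZABILITY,
    atom_contribution_provider,
    burden_matrix,
    calc_alogp2,
    calc_mollogp,
    calc_shbd,
    calc_sm04_ea_bo,
    calc_spmax1_bhp,
    calc_tpsa,
    compute_descriptors,
    edge_adjacency_matrix,
    estate_indices,
    prefilter,
    xlogs_provider,
)
from intrinsol.errors import DescriptorUndefinedError, EmptyMatrixError


def _renumbered(smiles: str, seed: int) -> Chem.Mol:
    """Same molecule with a seeded random atom ordering."""
    mol = Chem.MolFromSmiles(smiles)
    perm = list(np.random.default_rng(seed).permutation(mol.GetNumAtoms()))
    return Chem.RenumberAtoms(mol, [int(i) for i in perm])


class TestSM04:
    def test_ethane_single_bond_is_zero(self):
        # 1x1 edge adjacency [1], trace(B^4) = 1, ln 1 = 0
        assert calc_sm04_ea_bo("CC") == pytest.approx(0.0, abs=1e-14)

    def test_propane_two_adjacent_bonds(self):
        # B = [[1,1],[1,1]]; eigenvalues {2, 0}; trace(B^4) = 16
        assert calc_sm04_ea_bo("CCC") == pytest.approx(math.log(16.0), abs=1e-12)

    def test_trace_identity_with_eigenvalue_oracle(self, all_fixture_smiles):
        # independent spectral route: trace(B^4) == sum of fourth powers of eigenvalues
        small = [s for s in all_fixture_smiles.values()
                 if Chem.MolFromSmiles(s).GetNumBonds() <= 8]
        assert len(small) >= 5
        for smiles in small:
            B = edge_adjacency_matrix(Chem.MolFromSmiles(smiles))
            oracle = math.log(float((np.linalg.eigvalsh(B) ** 4).sum()))
            assert calc_sm04_ea_bo(smiles) == pytest.approx(oracle, rel=1e-10)

    def test_atom_only_molecule_is_undefined(self):
        with pytest.raises(DescriptorUndefinedError, match="no bonds"):
            calc_sm04_ea_bo("C")

    def test_aromatic_bonds_counted_with_order_1_5(self):
        B = edge_adjacency_matrix(Chem.MolFromSmiles("c1ccccc1"))
        assert np.allclose(np.diag(B), 1.5)


class TestALOGP2:
    @pytest.mark.parametrize("logp,expected", [(-1.5, 2.25), (0.0, 0.0), (2.0, 4.0)])
    def test_squares_the_provider_value(self, logp, expected):
        assert calc_alogp2("CCO", logp_provider=lambda mol: logp) == expected

    def test_atom_contribution_table_provider_hand_summed(self):
        # synthetic per-element table; propane = 3 C + 8 H, summed by hand
        table = {"C": -0.15, "H": 0.023}
        provider = atom_contribution_provider(table)
        hand_sum = 3 * (-0.15) + 8 * 0.023
        assert calc_alogp2("CCC", logp_provider=provider) == pytest.approx(
            hand_sum**2, rel=1e-12
        )

    def test_provider_failure_carries_descriptor_name(self):
        def bad(mol):
            raise RuntimeError("boom")

        with pytest.raises(DescriptorUndefinedError, match="ALOGP2"):
            calc_alogp2("CCO", logp_provider=bad)


class TestTPSAAndMolLogP:
    def test_hydrocarbons_have_zero_tpsa(self):
        assert calc_tpsa("c1ccccc1") == 0.0
        assert calc_tpsa("CCCC") == 0.0

    def test_ethanol_matches_published_hydroxyl_contribution(self):
        # Ertl fragment table: aliphatic O-H contributes 20.23 A^2
        assert calc_tpsa("CCO") == pytest.approx(20.23, abs=1e-9)

    def test_toolkit_agreement_on_fixture_set(self, all_fixture_smiles):
        for smiles in all_fixture_smiles.values():
            mol = Chem.MolFromSmiles(smiles)
            assert calc_tpsa(mol) == pytest.approx(RDDescriptors.TPSA(mol), abs=1e-6)
            assert calc_mollogp(mol) == pytest.approx(
                RDDescriptors.MolLogP(mol), abs=1e-6
            )

    def test_mollogp_is_sum_of_atom_contributions(self, all_fixture_smiles):
        for smiles in list(all_fixture_smiles.values())[:8]:
            mol = Chem.MolFromSmiles(smiles)
            contribs = rdMolDescriptors._CalcCrippenContribs(Chem.AddHs(mol))
            assert calc_mollogp(mol) == pytest.approx(
                sum(c[0] for c in contribs), abs=1e-9
            )

    def test_additivity_over_disconnected_fragments(self):
        one = calc_mollogp(Chem.MolFromSmiles("CCO"))
        two = calc_mollogp(Chem.MolFromSmiles("CCO.CCO"))
        assert two == pytest.approx(2 * one, rel=1e-12)


class TestSpMax1Bhp:
    def test_single_carbon_is_unity(self):
        assert calc_spmax1_bhp("C") == pytest.approx(1.0, abs=1e-14)

    def test_cc_closed_form_eigenvalues(self):
        # [[1, 0.1], [0.1, 1]] has eigenvalues 1 ± 0.1
        assert calc_spmax1_bhp("CC") == pytest.approx(1.1, abs=1e-12)

    def test_brute_force_eigensolver_oracle(self, all_fixture_smiles):
        # oracle: general (non-symmetric) eigensolver on the same matrix
        for smiles in all_fixture_smiles.values():
            M = burden_matrix(Chem.MolFromSmiles(smiles))
            oracle = float(np.max(np.abs(np.linalg.eigvals(M))))
            assert calc_spmax1_bhp(smiles) == pytest.approx(oracle, rel=1e-10)

    def test_carbon_reference_polarizability_is_exactly_one(self):
        assert RELATIVE_POLARIZABILITY["C"] == 1.0

    def test_unknown_element_is_undefined(self):
        with pytest.raises(DescriptorUndefinedError, match="polarizability"):
            calc_spmax1_bhp("[Po](C)C")


class TestSHBd:
    def test_donor_free_molecules_are_exactly_zero(self):
        for smiles in ("CC", "c1ccccc1", "COC", "c1ccncc1", "ClCCl"):
            assert calc_shbd(smiles) == 0.0

    def test_ethane_intrinsic_states(self):
        # symmetric CH3 carbons: delta = delta_v = 1, N = 2 -> I = S = 2
        assert np.allclose(estate_indices(Chem.MolFromSmiles("CC")), [2.0, 2.0])

    def test_ethanol_hydroxyl_estate_hand_oracle(self):
        # 3-atom chain C-C-O: I = (2.0, 1.5, 6.0); perturbations summed by hand
        s_oxygen = 6.0 + (6.0 - 1.5) / 4.0 + (6.0 - 2.0) / 9.0
        assert calc_shbd("CCO") == pytest.approx(s_oxygen, abs=1e-12)

    def test_estate_matches_toolkit_oracle(self, all_fixture_smiles):
        for smiles in all_fixture_smiles.values():
            mol = Chem.MolFromSmiles(smiles)
            assert np.allclose(
                estate_indices(mol), np.asarray(EStateIndices(mol)), atol=1e-8
            )

    def test_multiple_donors_summed(self):
        # aniline NH2 is one donor atom; ethanolamine has N and O donors
        mol = Chem.MolFromSmiles("NCCO")
        donors_sum = calc_shbd(mol)
        states = estate_indices(mol)
        assert donors_sum == pytest.approx(states[0] + states[3], abs=1e-12)


class TestOrderingInvariance:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_all_descriptors_invariant_to_atom_reordering(self, all_fixture_smiles, seed):
        funcs = (calc_sm04_ea_bo, calc_tpsa, calc_mollogp, calc_spmax1_bhp, calc_shbd)
        for smiles in list(all_fixture_smiles.values())[::3]:
            mol = Chem.MolFromSmiles(smiles)
            shuffled = _renumbered(smiles, seed)
            for func in funcs:
                if func is calc_sm04_ea_bo and mol.GetNumBonds() == 0:
                    continue
                assert func(shuffled) == pytest.approx(func(mol), rel=1e-9)


class TestMatrixAssembly:
    def test_xlogs_column_passthrough_and_missing_mask(self, toy_smiles):
        table = xlogs_provider({"ethane": -2.0})
        matrix, failures = compute_descriptors(
            [("ethane", "CC"), ("propane", "CCC")],
            names=("XlogS", "TPSA"),
            xlogs_table=table,
        )
        assert matrix.frame.loc["ethane", "XlogS"] == -2.0
        assert matrix.missing.loc["propane", "XlogS"]
        assert ("propane", "XlogS", "no XlogS value supplied") in failures

    def test_undefined_descriptor_recorded_not_raised(self):
        matrix, failures = compute_descriptors(
            [("methane", "C")], names=("SM04_EA_bo", "TPSA")
        )
        assert matrix.missing.loc["methane", "SM04_EA_bo"]
        assert matrix.frame.loc["methane", "TPSA"] == 0.0
        assert failures[0][:2] == ("methane", "SM04_EA_bo")

    def test_csv_roundtrip_preserves_values_exactly(self, tmp_path, toy_descriptor_matrix):
        path = tmp_path / "m.csv"
        toy_descriptor_matrix.to_csv(path)
        back = DescriptorMatrix.from_csv(path)
        pd.testing.assert_frame_equal(back.frame, toy_descriptor_matrix.frame)


class TestPrefilter:
    def _matrix(self, frame):
        return DescriptorMatrix(frame)

    def test_constant_column_removed_as_zero_variance(self, rng):
        frame = pd.DataFrame({"a": rng.normal(size=30), "const": 1.0})
        out, log = prefilter(self._matrix(frame))
        assert out.names == ["a"]
        assert ("const", "zero variance") in log

    def test_duplicated_column_second_occurrence_removed(self, rng):
        a = rng.normal(size=30)
        frame = pd.DataFrame({"a": a, "b": rng.normal(size=30), "a_copy": a})
        out, log = prefilter(self._matrix(frame))
        assert out.names == ["a", "b"]
        assert any(c == "a_copy" and "|R|" in reason for c, reason in log)

    def test_planted_correlated_pair_reduced_to_one(self, rng):
        n = 200
        base = rng.normal(size=n)
        # pair at R ~= 0.95, everything else independent
        pair = 0.95 * base + math.sqrt(1 - 0.95**2) * rng.normal(size=n)
        frame = pd.DataFrame(
            {
                "c1": rng.normal(size=n),
                "c2": base,
                "c3": rng.normal(size=n),
                "c4": pair,
                "c5": rng.normal(size=n),
            }
        )
        assert abs(np.corrcoef(base, pair)[0, 1]) > 0.9
        out, log = prefilter(self._matrix(frame))
        assert out.names == ["c1", "c2", "c3", "c5"]

    def test_missing_values_and_blacklist(self, rng):
        frame = pd.DataFrame(
            {"a": rng.normal(size=10), "b": rng.normal(size=10), "MLOGP": rng.normal(size=10)}
        )
        frame.loc[frame.index[0], "b"] = np.nan
        out, log = prefilter(
            self._matrix(frame), PrefilterConfig(name_blacklist=("MLOGP",))
        )
        assert out.names == ["a"]
        reasons = dict(log)
        assert reasons["b"] == "missing values"
        assert reasons["MLOGP"] == "blacklisted name"

    def test_idempotent(self, rng):
        a = rng.normal(size=50)
        frame = pd.DataFrame({"a": a, "b": rng.normal(size=50), "dup": a, "const": 0.0})
        once, _ = prefilter(self._matrix(frame))
        twice, log2 = prefilter(once)
        assert twice.names == once.names
        assert log2 == []

    def test_all_columns_removed_is_an_error(self):
        frame = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [2.0, 2.0, 2.0]})
        with pytest.raises(EmptyMatrixError):
            prefilter(self._matrix(frame))
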