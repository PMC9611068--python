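"""Structure standardization, unit conversion and dataset curation."""
import math

import pytest
from hypothesis import given, settings, strategies as st

from intrinsol.chemio import (
    Dataset,
    MoleculeRecord,
    RawSolubilityEntry,
    SolubilityUnit,
    aggregate_duplicates,
    from_log_molar,
    read_dataset,
    read_smiles_file,
    remove_overlap,
    standardize_structure,
    to_log_molar,
    write_dataset,
    write_smiles_file,
)
from intrinsol.errors import SchemaError, SmilesParseError, UnitConversionError


class TestStandardize:
    @pytest.mark.parametrize(
        "a,b",
        [
            ("CC[N+](=O)[O-]", "CCN(=O)=O"),      # nitro dialects
            ("C1=CC=CC=C1", "c1ccccc1"),          # Kekulé vs aromatic benzene
            ("OCC", "CCO"),                        # atom-order variants
            ("c1ccc(cc1)[N+](=O)[O-]", "O=N(=O)c1ccccc1"),
        ],
    )
    def test_equivalent_inputs_share_canonical_form(self, a, b):
        assert standardize_structure(a) == standardize_structure(b)

    def test_unparseable_smiles_raises_named_error(self):
        with pytest.raises(SmilesParseError, match="not_a_smiles"):
            standardize_structure("not_a_smiles")

    def test_idempotent_on_fixture_molecules(self, all_fixture_smiles):
        for smiles in all_fixture_smiles.values():
            once = standardize_structure(smiles)
            assert standardize_structure(once) == once

    def test_multifragment_rejected_by_default(self):
        with pytest.raises(SmilesParseError, match="multi-fragment"):
            standardize_structure("CCO.[Na+]")

    def test_largest_organic_fragment_kept_on_request(self):
        # the carbon-containing fragment wins even against a larger salt ion
        assert standardize_structure("CCO.[Na+]", keep_largest_fragment=True) == "CCO"
        assert (
            standardize_structure("CC(=O)O.OCCO", keep_largest_fragment=True)
            == standardize_structure("OCCO")
        )


class TestUnitConversion:
    @pytest.mark.parametrize(
        "value,unit,mw,expected",
        [
            (1.0, SolubilityUnit.MG_PER_ML, 100.0, -2.0),   # 0.01 M
            (1.0, SolubilityUnit.MOLAR, None, 0.0),
            (-3.5, SolubilityUnit.LOG_MOLAR, None, -3.5),
            (1000.0, SolubilityUnit.UG_PER_ML, 100.0, -2.0),
        ],
    )
    def test_known_conversions(self, value, unit, mw, expected):
        entry = RawSolubilityEntry("c", value, unit, molecular_weight=mw)
        assert to_log_molar(entry) == pytest.approx(expected, abs=1e-12)

    def test_mass_unit_without_mw_errors(self):
        entry = RawSolubilityEntry("c", 1.0, SolubilityUnit.MG_PER_ML)
        with pytest.raises(UnitConversionError, match="molecular weight"):
            to_log_molar(entry)

    def test_nonpositive_solubility_rejected(self):
        with pytest.raises(UnitConversionError):
            RawSolubilityEntry("c", 0.0, SolubilityUnit.MOLAR)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        logs0=st.floats(min_value=-12, max_value=1),
        unit=st.sampled_from(list(SolubilityUnit)),
        mw=st.floats(min_value=20, max_value=1500),
    )
    def test_roundtrip_identity(self, logs0, unit, mw):
        value = from_log_molar(logs0, unit, molecular_weight=mw)
        entry = RawSolubilityEntry("c", value, unit, molecular_weight=mw)
        assert to_log_molar(entry) == pytest.approx(logs0, rel=1e-12, abs=1e-12)


def _records(values, smiles="CCO", prefix="r"):
    return [
        MoleculeRecord(id=f"{prefix}{i}", smiles=smiles, logS0_exp=v)
        for i, v in enumerate(values)
    ]


class TestAggregateDuplicates:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([-3.0, -3.2, -3.4], -3.2),   # odd count: central value
            ([-3.0, -3.4], -3.2),         # even count: midpoint
            ([-5.1], -5.1),               # single value passes through
        ],
    )
    def test_median_aggregation(self, values, expected):
        ds = Dataset(_records(values))
        out = aggregate_duplicates(ds)
        assert len(out) == 1
        assert out.records[0].logS0_exp == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.permutations([-3.0, -3.2, -3.4, -4.1, -2.9]))
    def test_median_is_permutation_invariant(self, values):
        out = aggregate_duplicates(Dataset(_records(values)))
        assert out.records[0].logS0_exp == pytest.approx(-3.2)

    def test_key_multiset_only_changes_by_deduplication(self):
        ds = Dataset(
            _records([-1.0, -2.0], smiles="CCO", prefix="a")
            + _records([-3.0], smiles="c1ccccc1", prefix="b")
            + _records([-4.0], smiles="C1=CC=CC=C1", prefix="c")  # same as benzene
        )
        out = aggregate_duplicates(ds)
        keys = sorted(standardize_structure(r.smiles) for r in out)
        assert keys == sorted({standardize_structure(r.smiles) for r in ds})
        assert len(out) == 2

    def test_provenance_sources_are_merged(self):
        recs = [
            MoleculeRecord(id="a", smiles="CCO", logS0_exp=-1.0, sources=("src1",)),
            MoleculeRecord(id="b", smiles="OCC", logS0_exp=-2.0, sources=("src2",)),
        ]
        out = aggregate_duplicates(Dataset(recs))
        assert out.records[0].sources == ("src1", "src2")


class TestRemoveOverlap:
    def test_overlapping_structures_routed_out(self):
        train = Dataset(
            [
                MoleculeRecord(id="A", smiles="CCO"),
                MoleculeRecord(id="B", smiles="c1ccccc1"),
                MoleculeRecord(id="C", smiles="CCC"),
            ]
        )
        held = Dataset([MoleculeRecord(id="x", smiles="C1=CC=CC=C1")])  # benzene
        kept, removed = remove_overlap(train, held)
        assert kept.ids == ["A", "C"]
        assert removed.ids == ["B"]

    def test_disjoint_sets_unchanged(self):
        train = Dataset([MoleculeRecord(id="A", smiles="CCO")])
        held = Dataset([MoleculeRecord(id="x", smiles="CCC")])
        kept, removed = remove_overlap(train, held)
        assert kept.ids == ["A"] and len(removed) == 0

    def test_curation_bookkeeping_123_to_81(self):
        # 123 distinct linear alkanes; 42 shared with the held-out set
        source = Dataset(
            [MoleculeRecord(id=f"m{n}", smiles="C" * n) for n in range(1, 124)]
        )
        held = Dataset(
            [MoleculeRecord(id=f"t{n}", smiles="C" * n) for n in range(1, 43)]
        )
        kept, removed = remove_overlap(source, held)
        assert (len(source), len(kept), len(removed)) == (123, 81, 42)


class TestTableIO:
    def _dataset(self):
        return Dataset(
            [
                MoleculeRecord(id="a", smiles="CCO", name="ethanol", logS0_exp=-0.25,
                               role="train"),
                MoleculeRecord(id="b", smiles="c1ccccc1", logS0_exp=None, role="test"),
                MoleculeRecord(id="c", smiles="CCC", logS0_exp=-1.5),
            ]
        )

    @pytest.mark.parametrize("suffix", [".csv", ".tsv"])
    def test_roundtrip(self, tmp_path, suffix):
        ds = self._dataset()
        path = tmp_path / f"data{suffix}"
        write_dataset(ds, path)
        back = read_dataset(path)
        assert back.ids == ds.ids
        for orig, new in zip(ds, back):
            assert (new.smiles, new.name or None, new.logS0_exp, new.role) == (
                orig.smiles, orig.name, orig.logS0_exp, orig.role
            )

    def test_blank_logs0_read_as_absent(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("id,smiles,name,logS0,role\nx,CCO,,,train\n", encoding="utf-8")
        ds = read_dataset(path)
        assert ds.records[0].logS0_exp is None

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("id,smiles\nx,CCO\nx,CCC\n", encoding="utf-8")
        with pytest.raises(SchemaError, match="duplicate"):
            read_dataset(path)

    def test_missing_mandatory_column_rejected(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("id,name\nx,foo\n", encoding="utf-8")
        with pytest.raises(SchemaError, match="smiles"):
            read_dataset(path)

    def test_smiles_file_roundtrip(self, tmp_path):
        ds = self._dataset()
        path = tmp_path / "mols.smi"
        write_smiles_file(ds, path)
        back = read_smiles_file(path)
        assert back.ids == ds.ids
        assert [r.smiles for r in back] == [r.smiles for r in ds]

    def test_nonfinite_logs0_rejected(self):
        with pytest.raises(SchemaError, match="finite"):
            MoleculeRecord(id="x", smiles="CCO", logS0_exp=math.nan)
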