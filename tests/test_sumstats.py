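import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrmediate.errors import ConfigurationError, NoSharedInstrumentsError
from mrmediate.sumstats import (
    SummaryStatsTable,
    VariantAssociation,
    harmonize,
    read_sumstats,
    write_sumstats,
)

from conftest import make_table, make_variant


class TestVariantAssociation:
    def test_valid_record(self):
        rec = make_variant()
        assert rec.beta == 0.1

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"se": 0.0},
            {"se": -0.1},
            {"eaf": 1.5},
            {"pos": 0},
            {"pval": 0.0},
            {"pval": 1.5},
            {"effect_allele": "A", "other_allele": "A"},
            {"effect_allele": "AT"},
            {"effect_allele": "N"},
            {"n": 0},
        ],
    )
    def test_invariant_violations(self, kwargs):
        with pytest.raises(ValueError):
            make_variant(**kwargs)

    def test_palindromic_detection(self):
        assert make_variant(effect_allele="A", other_allele="T").is_palindromic()
        assert make_variant(effect_allele="C", other_allele="G").is_palindromic()
        assert not make_variant(effect_allele="A", other_allele="G").is_palindromic()

    def test_duplicate_variant_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_table([make_variant(), make_variant()])


class TestReadWrite:
    HEADER = "variant_id\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn\n"

    def _write(self, tmp_path, body, header=None):
        path = tmp_path / "sumstats.tsv"
        path.write_text((header or self.HEADER) + body)
        return path

    def test_well_formed_file(self, tmp_path):
        body = (
            "rs1\t1\t100\tA\tG\t0.2\t0.1\t0.02\t1e-06\t5000\n"
            "rs2\t1\t200\tC\tT\t0.3\t-0.05\t0.01\t0.5\t5000\n"
            "rs3\t2\t300\tG\tA\t0.4\t0.2\t0.05\t0.001\t5000\n"
        )
        result = read_sumstats(self._write(tmp_path, body))
        assert len(result.table) == 3
        assert result.rejected == []

    def test_column_map(self, tmp_path):
        header = "variant_id\tchrom\tpos\teffect_allele\tother_allele\teaf\tb\tse\tpval\tn\n"
        body = "rs1\t1\t100\tA\tG\t0.2\t0.1\t0.02\t1e-06\t5000\n"
        result = read_sumstats(
            self._write(tmp_path, body, header), column_map={"b": "beta"}
        )
        assert result.table.records[0].beta == 0.1

    def test_zero_se_rejected_row_level(self, tmp_path):
        body = (
            "rs1\t1\t100\tA\tG\t0.2\t0.1\t0.0\t1e-06\t5000\n"
            "rs2\t1\t200\tC\tT\t0.3\t-0.05\t0.01\t0.5\t5000\n"
        )
        result = read_sumstats(self._write(tmp_path, body))
        assert len(result.table) == 1
        assert len(result.rejected) == 1
        row_no, reason = result.rejected[0]
        assert row_no == 1
        assert "se" in reason

    def test_unparseable_numeric_rejected_not_fatal(self, tmp_path):
        body = (
            "rs1\t1\t100\tA\tG\t0.2\tnotanumber\t0.02\t1e-06\t5000\n"
            "rs2\t1\t200\tC\tT\t0.3\t-0.05\t0.01\t0.5\t5000\n"
        )
        result = read_sumstats(self._write(tmp_path, body))
        assert len(result.table) == 1
        assert len(result.rejected) == 1

    def test_missing_mandatory_column(self, tmp_path):
        header = "variant_id\tchrom\tpos\teffect_allele\tother_allele\teaf\tse\tpval\tn\n"
        body = "rs1\t1\t100\tA\tG\t0.2\t0.02\t1e-06\t5000\n"
        with pytest.raises(ConfigurationError, match="beta"):
            read_sumstats(self._write(tmp_path, body, header))

    def test_empty_table_roundtrip(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_sumstats(make_table([], trait_id="t"), path)
        assert path.read_text().count("\n") == 1  # header only
        result = read_sumstats(path, trait_id="t")
        assert len(result.table) == 0

    def test_roundtrip_five_records(self, tmp_path):
        table = make_table(
            [
                make_variant("rs1", beta=0.123456789012345, se=0.02),
                make_variant("rs2", pos=2000, beta=-1e-7, se=1e-9, pval=1e-300),
                make_variant("rs3", pos=3000, eaf=None),
                make_variant("rs4", pos=4000, n=None),
                make_variant("rs5", chrom="X", pos=5000),
            ],
            trait_id="t",
        )
        path = tmp_path / "t.tsv"
        write_sumstats(table, path)
        back = read_sumstats(path, trait_id="t", trait_label="t").table
        assert back.records == table.records

    def test_missing_eaf_serialized_as_na(self, tmp_path):
        table = make_table([make_variant(eaf=None)], trait_id="t")
        path = tmp_path / "t.tsv"
        write_sumstats(table, path)
        assert "\tNA\t" in path.read_text()
        assert read_sumstats(path).table.records[0].eaf is None


class TestHarmonize:
    def test_identical_alleles_kept_unchanged(self):
        exp = make_table([make_variant(beta=0.1)], "X")
        out = make_table([make_variant(beta=0.2, se=0.03)], "Y")
        hset = harmonize(exp, out)
        assert hset.nsnp == 1
        row = hset.rows.iloc[0]
        assert row.beta_exp == 0.1
        assert row.beta_out == 0.2
        assert hset.dropped == []

    def test_swapped_alleles_flip_sign(self):
        exp = make_table([make_variant(effect_allele="A", other_allele="G")], "X")
        out = make_table(
            [make_variant(effect_allele="G", other_allele="A", beta=0.2, eaf=0.7)],
            "Y",
        )
        hset = harmonize(exp, out)
        row = hset.rows.iloc[0]
        assert row.beta_out == -0.2
        assert row.eaf_out == pytest.approx(0.3)

    def test_strand_complement_kept(self):
        exp = make_table([make_variant(effect_allele="A", other_allele="G")], "X")
        out = make_table(
            [make_variant(effect_allele="T", other_allele="C", beta=0.2)], "Y"
        )
        hset = harmonize(exp, out)
        assert hset.rows.iloc[0].beta_out == 0.2

    def test_ambiguous_palindrome_dropped(self):
        exp = make_table(
            [make_variant(effect_allele="A", other_allele="T", eaf=0.50)], "X"
        )
        out = make_table(
            [make_variant(effect_allele="A", other_allele="T", eaf=0.3)], "Y"
        )
        hset = harmonize(exp, out, "infer_by_eaf", 0.08)
        assert hset.nsnp == 0
        assert hset.dropped == [("rs1", "ambiguous palindrome")]

    def test_palindrome_drop_all(self):
        exp = make_table(
            [make_variant(effect_allele="C", other_allele="G", eaf=0.1)], "X"
        )
        out = make_table(
            [make_variant(effect_allele="C", other_allele="G", eaf=0.1)], "Y"
        )
        hset = harmonize(exp, out, "drop_all")
        assert hset.dropped == [("rs1", "palindrome")]

    def test_palindrome_inferred_by_eaf_flip(self):
        # eafs on opposite sides of 0.5: outcome effect allele is the
        # exposure's other allele on the opposite strand.
        exp = make_table(
            [make_variant(effect_allele="A", other_allele="T", eaf=0.2)], "X"
        )
        out = make_table(
            [make_variant(effect_allele="A", other_allele="T", eaf=0.8, beta=0.2)],
            "Y",
        )
        hset = harmonize(exp, out, "infer_by_eaf", 0.08)
        row = hset.rows.iloc[0]
        assert row.beta_out == -0.2
        assert row.eaf_out == pytest.approx(0.2)

    def test_unreconcilable_alleles_dropped_with_reason(self):
        exp = make_table([make_variant(effect_allele="A", other_allele="G")], "X")
        out = make_table(
            [make_variant(effect_allele="A", other_allele="C", beta=0.2)], "Y"
        )
        hset = harmonize(exp, out)
        assert hset.dropped == [("rs1", "allele mismatch")]

    def test_empty_intersection_raises(self):
        exp = make_table([make_variant("rs1")], "X")
        out = make_table([make_variant("rs2")], "Y")
        with pytest.raises(NoSharedInstrumentsError):
            harmonize(exp, out)

    def test_only_shared_variants_kept(self):
        exp = make_table([make_variant("rs1"), make_variant("rs2", pos=2000)], "X")
        out = make_table([make_variant("rs2", pos=2000)], "Y")
        hset = harmonize(exp, out)
        assert hset.rows["variant_id"].tolist() == ["rs2"]

    def test_idempotence(self):
        """Harmonizing an already-aligned pair changes nothing."""
        exp = make_table(
            [
                make_variant("rs1", beta=0.1, eaf=0.2),
                make_variant("rs2", pos=2000, effect_allele="C", other_allele="A", beta=-0.2, eaf=0.7),
            ],
            "X",
        )
        out = make_table(
            [
                make_variant("rs1", beta=0.3, se=0.04, eaf=0.25),
                make_variant("rs2", pos=2000, effect_allele="C", other_allele="A", beta=0.1, se=0.03, eaf=0.6),
            ],
            "Y",
        )
        first = harmonize(exp, out)
        # Rebuild the outcome table on the exposure's alleles from the
        # harmonized rows and harmonize again.
        realigned = make_table(
            [
                VariantAssociation(
                    r.variant_id,
                    exp.get(r.variant_id).chrom,
                    exp.get(r.variant_id).pos,
                    exp.get(r.variant_id).effect_allele,
                    exp.get(r.variant_id).other_allele,
                    r.eaf_out,
                    r.beta_out,
                    r.se_out,
                    0.5,
                    None,
                )
                for r in first.rows.itertuples()
            ],
            "Y",
        )
        second = harmonize(exp, realigned)
        for col in ("beta_exp", "beta_out", "eaf_out"):
            assert second.rows[col].tolist() == first.rows[col].tolist()

    def test_sign_consistency(self):
        """Flipping outcome alleles and negating beta yields the same set."""
        exp = make_table([make_variant(beta=0.1, eaf=0.2)], "X")
        out_direct = make_table([make_variant(beta=0.2, se=0.03, eaf=0.25)], "Y")
        out_flipped = make_table(
            [
                make_variant(
                    effect_allele="G", other_allele="A", beta=-0.2, se=0.03, eaf=0.75
                )
            ],
            "Y",
        )
        h1 = harmonize(exp, out_direct)
        h2 = harmonize(exp, out_flipped)
        assert h1.rows["beta_out"].tolist() == h2.rows["beta_out"].tolist()
        assert h1.rows["eaf_out"].tolist() == pytest.approx(
            h2.rows["eaf_out"].tolist()
        )


@settings(max_examples=50, deadline=None)
@given(
    beta=st.floats(-2, 2, allow_nan=False),
    se=st.floats(1e-6, 1, allow_nan=False),
    pval=st.floats(1e-300, 1.0, exclude_min=False, allow_nan=False),
    eaf=st.one_of(st.none(), st.floats(0, 1, allow_nan=False)),
)
def test_roundtrip_property(tmp_path_factory, beta, se, pval, eaf):
    table = make_table(
        [make_variant(beta=beta, se=se, pval=pval, eaf=eaf)], trait_id="t"
    )
    path = tmp_path_factory.mktemp("rt") / "t.tsv"
    write_sumstats(table, path)
    back = read_sumstats(path, trait_id="t", trait_label="t").table
    assert back.records == table.records
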