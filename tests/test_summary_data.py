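"""Summary-statistics I/O, allele harmonisation, and LD sign alignment."""

import numpy as np
import pytest

from cismr import (
    LDMatrix,
    SummaryDataset,
    align_ld,
    harmonise,
    read_ld,
    read_summary,
    table1_fixture,
    write_ld,
    write_summary,
)
from cismr.summary_data import ColumnMappingError, VariantAssociation

from conftest import make_variant


TSV_HEADER = "rsid\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn\n"


def _table1_tsv(tmp_path, mutate=None):
    ds, _ = table1_fixture()
    lines = [TSV_HEADER]
    for rec in ds:
        row = [rec.rsid, rec.chrom, str(rec.pos), rec.effect_allele, rec.other_allele,
               str(rec.eaf), str(rec.beta), str(rec.se), str(rec.pval), str(rec.n)]
        if mutate:
            row = mutate(rec.rsid, row)
        lines.append("\t".join(row) + "\n")
    path = tmp_path / "exposure.tsv"
    path.write_text("".join(lines))
    return path


class TestReadSummary:
    def test_reads_instrument_table(self, tmp_path):
        path = _table1_tsv(tmp_path)
        ds, errors = read_summary(path, trait="dbp", trait_sd=10.7)
        assert len(ds) == 5 and not errors
        rec = ds.get("rs66887589")
        assert rec.beta == pytest.approx(0.161)
        assert rec.se == pytest.approx(0.017)

    def test_empty_file_gives_empty_dataset(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text(TSV_HEADER)
        ds, errors = read_summary(path)
        assert len(ds) == 0 and not errors

    def test_bad_se_collected_not_dropped_silently(self, tmp_path):
        def mutate(rsid, row):
            if rsid == "rs12646525":
                row[7] = "NA"
            return row

        ds, errors = read_summary(_table1_tsv(tmp_path, mutate), trait="dbp")
        assert len(ds) == 4
        assert len(errors) == 1 and errors[0].rsid == "rs12646525"

    def test_missing_mapped_column_is_configuration_error(self, tmp_path):
        path = _table1_tsv(tmp_path)
        with pytest.raises(ColumnMappingError):
            read_summary(path, column_map={"beta": "BETA_GWAS"})

    def test_column_map_renames(self, tmp_path):
        path = tmp_path / "renamed.tsv"
        path.write_text(
            "SNP\tchrom\tpos\teffect_allele\tother_allele\teaf\tb\tse\tpval\tn\n"
            "rs1\t4\t100\tA\tG\t0.3\t0.1\t0.02\t1e-9\t1000\n"
        )
        ds, _ = read_summary(path, column_map={"rsid": "SNP", "beta": "b"})
        assert ds.rsids == ["rs1"] and ds.get("rs1").beta == 0.1


class TestRoundTrip:
    def test_summary_round_trip(self, tmp_path, table1):
        ds, _ = table1
        write_summary(ds, tmp_path / "t.tsv")
        back, errors = read_summary(tmp_path / "t.tsv", trait=ds.trait, trait_sd=ds.trait_sd)
        assert not errors
        assert [r.beta for r in back] == [r.beta for r in ds]

    def test_ld_round_trip(self, tmp_path):
        ld = LDMatrix(rsids=["rs1", "rs2"], ref_alleles=["A", "C"],
                      r=np.array([[1.0, -0.4], [-0.4, 1.0]]))
        write_ld(ld, tmp_path / "ld.tsv", tmp_path / "al.tsv")
        back = read_ld(tmp_path / "ld.tsv", tmp_path / "al.tsv")
        assert back.rsids == ld.rsids and back.ref_alleles == ld.ref_alleles
        np.testing.assert_allclose(back.r, ld.r)


class TestAlignLd:
    @pytest.fixture
    def ld(self):
        return LDMatrix(rsids=["rs1", "rs2"], ref_alleles=["A", "C"],
                        r=np.array([[1.0, 0.6], [0.6, 1.0]]))

    def test_single_flip_negates_off_diagonal(self, ld):
        out = align_ld(ld, {"rs1": "G", "rs2": "C"})
        assert out.r[0, 1] == pytest.approx(-0.6)
        assert out.r[0, 0] == out.r[1, 1] == 1.0

    def test_double_flip_is_identity_on_r(self, ld):
        out = align_ld(ld, {"rs1": "G", "rs2": "T"})
        np.testing.assert_allclose(out.r, ld.r)

    def test_no_flip_identity(self, ld):
        out = align_ld(ld, {"rs1": "A", "rs2": "C"})
        np.testing.assert_allclose(out.r, ld.r)

    def test_align_is_involution(self, ld):
        targets = {"rs1": "G"}
        twice = align_ld(align_ld(ld, targets), {"rs1": "A"})
        np.testing.assert_allclose(twice.r, ld.r)

    def test_unknown_rsid_named_in_error(self, ld):
        with pytest.raises(KeyError, match="rs99"):
            align_ld(ld, {"rs99": "A"})


def _pair(exposure_kwargs, outcome_kwargs):
    exp = SummaryDataset(trait="exp", records=[make_variant(**exposure_kwargs)])
    out = SummaryDataset(trait="out", records=[make_variant(**outcome_kwargs)])
    ld = LDMatrix(rsids=[exp.records[0].rsid],
                  ref_alleles=[exp.records[0].effect_allele], r=np.eye(1))
    return exp, out, ld


class TestHarmonise:
    def test_swapped_alleles_flip_beta(self):
        exp, out, ld = _pair(
            dict(ea="A", oa="G", beta=0.1),
            dict(ea="G", oa="A", beta=0.02, eaf=0.3),
        )
        h = harmonise(exp, out, ld)
        assert h.Gamma[0] == pytest.approx(-0.02)

    def test_identical_alleles_unchanged(self):
        exp, out, ld = _pair(dict(beta=0.1), dict(beta=0.02))
        h = harmonise(exp, out, ld)
        assert h.Gamma[0] == pytest.approx(0.02)
        assert h.gamma[0] == pytest.approx(0.1)

    def test_strand_complement_resolved(self):
        # exposure T/C vs outcome A/G is 'same' on the other strand
        exp, out, ld = _pair(
            dict(ea="T", oa="C", beta=0.1),
            dict(ea="A", oa="G", beta=0.02),
        )
        h = harmonise(exp, out, ld)
        assert h.Gamma[0] == pytest.approx(0.02)

    def test_ambiguous_palindrome_excluded(self):
        exp = SummaryDataset(trait="exp", records=[
            make_variant(rsid="rs1", ea="A", oa="T", eaf=0.5),
            make_variant(rsid="rs2", pos=120_500_100),
        ])
        out = SummaryDataset(trait="out", records=[
            make_variant(rsid="rs1", ea="A", oa="T", eaf=0.5),
            make_variant(rsid="rs2", pos=120_500_100),
        ])
        ld = LDMatrix(rsids=["rs1", "rs2"], ref_alleles=["A", "A"], r=np.eye(2))
        h = harmonise(exp, out, ld)
        assert h.rsids == ["rs2"]
        (exc,) = h.exclusions
        assert exc.rsid == "rs1" and exc.reason == "ambiguous palindrome"

    def test_nonambiguous_palindrome_kept(self):
        exp, out, ld = _pair(
            dict(ea="A", oa="T", eaf=0.9),
            dict(ea="A", oa="T", eaf=0.9),
        )
        assert harmonise(exp, out, ld).rsids == ["rs1"]

    def test_incompatible_alleles_excluded_with_reason(self):
        exp = SummaryDataset(trait="exp", records=[
            make_variant(rsid="rs1", ea="A", oa="G"),
            make_variant(rsid="rs2", pos=120_500_100),
        ])
        out = SummaryDataset(trait="out", records=[
            make_variant(rsid="rs1", ea="A", oa="C"),
            make_variant(rsid="rs2", pos=120_500_100),
        ])
        ld = LDMatrix(rsids=["rs1", "rs2"], ref_alleles=["A", "A"], r=np.eye(2))
        h = harmonise(exp, out, ld)
        assert h.rsids == ["rs2"]
        assert h.exclusions[0].reason == "incompatible alleles"

    def test_empty_intersection_is_hard_error(self):
        exp = SummaryDataset(trait="exp", records=[make_variant(rsid="rsA")])
        out = SummaryDataset(trait="out", records=[make_variant(rsid="rsB")])
        ld = LDMatrix(rsids=["rsA"], ref_alleles=["A"], r=np.eye(1))
        with pytest.raises(ValueError, match="no rsid common"):
            harmonise(exp, out, ld)

    def test_retained_plus_excluded_equals_input(self, table1):
        exp, ld = table1
        # outcome shares alleles; corrupt one variant's alleles to force exclusion
        out_records = []
        for rec in exp:
            kw = dict(rsid=rec.rsid, pos=rec.pos, ea=rec.effect_allele,
                      oa=rec.other_allele, eaf=rec.eaf, beta=0.01, se=0.005)
            if rec.rsid == "rs80223330":
                kw.update(ea="C", oa="G")
            out_records.append(make_variant(**kw))
        out = SummaryDataset(trait="out", records=out_records)
        h = harmonise(exp, out, ld)
        assert len(h) + len(h.exclusions) == len(exp)

    def test_harmonise_is_idempotent(self, table1):
        exp, ld = table1
        out = SummaryDataset(trait="out", records=[
            make_variant(rsid=r.rsid, pos=r.pos, ea=r.other_allele,
                         oa=r.effect_allele, eaf=1 - r.eaf, beta=0.01, se=0.005)
            for r in exp
        ])
        h1 = harmonise(exp, out, ld)
        # rebuild datasets from harmonised output and run again
        out2 = SummaryDataset(trait="out", records=[
            make_variant(rsid=rs, pos=exp.get(rs).pos, ea=exp.get(rs).effect_allele,
                         oa=exp.get(rs).other_allele, eaf=exp.get(rs).eaf,
                         beta=float(h1.Gamma[i]), se=float(h1.Gamma_se[i]))
            for i, rs in enumerate(h1.rsids)
        ])
        h2 = harmonise(exp.subset(h1.rsids), out2, h1.ld)
        np.testing.assert_allclose(h2.Gamma, h1.Gamma)
        np.testing.assert_allclose(h2.ld.r, h1.ld.r)
        assert h2.rsids == h1.rsids


class TestVariantInvariants:
    @pytest.mark.parametrize("kwargs", [
        dict(se=0.0),
        dict(se=-0.1),
        dict(eaf=1.2),
        dict(pval=0.0),
        dict(ea="A", oa="A"),
    ])
    def test_invalid_records_rejected(self, kwargs):
        with pytest.raises(ValueError):
            make_variant(**kwargs)

    def test_duplicate_rsid_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            SummaryDataset(trait="t", records=[make_variant(), make_variant()])
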