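"""Readers/writers: dialect handling, invariants, round trips."""

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from famseg.formats import (
    ExpressionMatrix,
    FilterParams,
    FormatError,
    GeneModel,
    GeneSetCollection,
    GenotypeCall,
    Individual,
    Pedigree,
    ValidationError,
    Variant,
    read_expression,
    read_gene_models,
    read_gmt,
    read_known_set,
    read_ped,
    read_vcf,
    write_expression,
    write_gene_models,
    write_gmt,
    write_known_set,
    write_ped,
    write_vcf,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadVcf:
    def test_two_sample_het_record(self, tmp_path):
        p = _write(
            tmp_path,
            "a.vcf",
            VCF_HEADER
            + "chr13\t29008268\t.\tA\tT\t.\t.\tMQ=60\tGT:DP:GQ\t0/1:20:99\t0/1:18:95\n",
        )
        (v,) = read_vcf(p)
        assert v.key == ("chr13", 29008268, "A", "T")
        assert v.site_mq == 60
        assert all(g.is_het("A", "T") for g in v.genotypes)
        assert v.genotype("S1").depth == 20 and v.genotype("S2").gq == 95

    def test_empty_body(self, tmp_path):
        assert read_vcf(_write(tmp_path, "e.vcf", VCF_HEADER)) == []

    def test_multiallelic_split_matches_hand_expansion(self, tmp_path):
        # hand-expanded oracle for ALT "T,C" with genotypes 1/2 and 0/2:
        #  alt T: S1 carries one T (other allele -> ref), S2 is hom-ref
        #  alt C: S1 carries one C, S2 is ref/C het
        p = _write(
            tmp_path,
            "m.vcf",
            VCF_HEADER
            + "chr1\t100\t.\tA\tT,C\t.\t.\tMQ=50\tGT:DP:GQ\t1/2:30:99\t0/2:25:80\n",
        )
        v_c, v_t = read_vcf(p)  # output sorted by (chrom, pos, alt)
        assert (v_t.alt, v_c.alt) == ("T", "C")
        assert set(v_t.genotype("S1").alleles) == {"A", "T"}
        assert v_t.genotype("S2").alleles == ("A", "A")
        assert set(v_c.genotype("S1").alleles) == {"A", "C"}
        assert v_c.genotype("S2").is_het("A", "C")

    def test_split_conserves_site_alt_pairs(self, tmp_path):
        p = _write(
            tmp_path,
            "s.vcf",
            VCF_HEADER
            + "chr1\t10\t.\tA\tT,C,G\t.\t.\t.\tGT:DP:GQ\t0/1:9:9\t1/3:9:9\n"
            + "chr1\t20\t.\tG\tA\t.\t.\t.\tGT:DP:GQ\t0/0:9:9\t0/1:9:9\n",
        )
        variants = read_vcf(p)
        assert len(variants) == 4
        assert [v.key for v in variants] == sorted(v.key for v in variants)

    def test_missing_gt_is_format_error(self, tmp_path):
        p = _write(
            tmp_path,
            "g.vcf",
            VCF_HEADER + "chr1\t10\t.\tA\tT\t.\t.\t.\tDP:GQ\t20:99\t20:99\n",
        )
        with pytest.raises(FormatError, match="GT"):
            read_vcf(p)

    def test_ragged_row_names_line(self, tmp_path):
        p = _write(
            tmp_path, "r.vcf", VCF_HEADER + "chr1\t10\t.\tA\tT\t.\t.\t.\n"
        )
        with pytest.raises(FormatError, match=":3"):
            read_vcf(p)

    def test_predictor_info_keys(self, tmp_path):
        p = _write(
            tmp_path,
            "p.vcf",
            VCF_HEADER
            + "chr1\t10\t.\tA\tT\t.\t.\tMQ=60;SIFT=tolerated;POLYPHEN=damaging\t"
            "GT:DP:GQ\t0/1:9:9\t0/0:9:9\n",
        )
        (v,) = read_vcf(p)
        assert v.predictor_calls == {
            "sift": "tolerated",
            "polyphen2": "damaging",
        }


class TestReadPed:
    def test_affected_parent_child_pair(self, tmp_path):
        p = _write(
            tmp_path,
            "f.ped",
            "F1 FA M0 M1 1 0\nF1 M1 0 0 2 2\nF1 M0 0 0 1 0\nF1 C1 M0 M1 1 2\n",
        )
        ped = read_ped(p)
        # only the mother-child pair is affected-affected
        assert ped.affected_parent_child_pairs("F1") == [("M1", "C1")]

    def test_empty_file(self, tmp_path):
        assert len(read_ped(_write(tmp_path, "e.ped", ""))) == 0

    def test_extended_family_affected_count(self, tmp_path):
        rows = [
            "F4 I-1 0 0 1 1",
            "F4 I-2 0 0 2 1",
            "F4 II-3 I-1 I-2 2 2",
            "F4 II-4 0 0 1 1",
            "F4 II-8 I-1 I-2 1 2",
            "F4 II-9 0 0 2 2",
            "F4 III-2 II-4 II-3 1 1",
            "F4 III-3 II-4 II-3 2 2",
            "F4 III-6 II-8 II-9 2 1",
            "F4 III-7 II-8 II-9 1 2",
            "F4 III-8 II-8 II-9 2 2",
            "F4 III-9 II-8 II-9 1 1",
        ]
        ped = read_ped(_write(tmp_path, "x.ped", "\n".join(rows) + "\n"))
        assert len(ped) == 12
        assert len(ped.affected_members("F4")) == 6

    def test_dangling_parent_is_error(self, tmp_path):
        p = _write(tmp_path, "d.ped", "F1 C1 NOPE 0 1 2\n")
        with pytest.raises(ValidationError, match="NOPE"):
            read_ped(p)

    def test_cycle_is_error(self):
        with pytest.raises(ValidationError, match="ancestor"):
            Pedigree(
                individuals=(
                    Individual("A", "F", "B", None, "1", True),
                    Individual("B", "F", "A", None, "1", True),
                )
            )


class TestGeneModels:
    def test_two_exon_cds_spans_both(self):
        # CDS length must stay a positive multiple of 3 for codon lookups
        m = GeneModel(
            gene_symbol="G",
            chrom="chr1",
            strand="+",
            exons=((101, 200), (301, 401)),
            cds_start=101,
            cds_end=401,
            cds_sequence="A" * 200 + "C",
        )
        assert m.cds_length == 201

    def test_cds_not_multiple_of_3_names_gene(self, tmp_path):
        line = "BAD\tchr1\t+\t101-204\t101\t204\t" + "A" * 104 + "\n"
        p = _write(tmp_path, "g.tsv", line)
        with pytest.raises(FormatError, match="BAD"):
            read_gene_models(p)


class TestGmt:
    def test_focal_adhesion_line(self, tmp_path):
        p = _write(tmp_path, "s.gmt", "FOCAL_ADHESION\tna\tITGA2\tFLT1\tVEGFB\n")
        coll = read_gmt(p)
        assert coll.sets["FOCAL_ADHESION"] == ("ITGA2", "FLT1", "VEGFB")

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            GeneSetCollection(sets={"S": ()})


class TestExpression:
    def test_duplicate_gene_rejected(self):
        df = pd.DataFrame(
            [[1.0] * 4] * 2, index=["G1", "G1"], columns=list("abcd")
        )
        groups = {s: ("case" if s in "ab" else "control") for s in "abcd"}
        with pytest.raises(ValidationError, match="duplicate"):
            ExpressionMatrix(values=df, group_labels=groups)

    def test_small_group_rejected(self):
        df = pd.DataFrame([[1.0] * 3], index=["G"], columns=list("abc"))
        groups = {"a": "case", "b": "case", "c": "control"}
        with pytest.raises(ValidationError, match="< 2"):
            ExpressionMatrix(values=df, group_labels=groups)


class TestRoundTrips:
    """write(read(x)) re-read equals the in-memory object field-for-field."""

    def test_vcf(self, tmp_path):
        variants = [
            Variant(
                chrom="chr2",
                pos=50,
                ref="A",
                alt="TG",
                site_mq=45.0,
                predictor_calls={"sift": "damaging"},
                genotypes=(
                    GenotypeCall("S1", ("A", "TG"), 12, 70.0),
                    GenotypeCall("S2", (None, None), None, None),
                ),
            ),
            Variant(
                chrom="chr1",
                pos=10,
                ref="G",
                alt="C",
                site_mq=None,
                genotypes=(
                    GenotypeCall("S1", ("C", "C"), 30, 99.0),
                    GenotypeCall("S2", ("G", "C"), 8, 50.0),
                ),
            ),
        ]
        p = tmp_path / "rt.vcf"
        write_vcf(variants, p, sample_ids=["S1", "S2"])
        back = read_vcf(p)
        assert back == sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt))
        p2 = tmp_path / "rt2.vcf"
        write_vcf(back, p2, sample_ids=["S1", "S2"])
        assert p.read_text() == p2.read_text()

    def test_ped(self, tmp_path):
        ped = Pedigree(
            individuals=(
                Individual("P1", "F9", None, None, "2", True),
                Individual("P2", "F9", None, None, "1", None),
                Individual("K1", "F9", "P2", "P1", "2", False),
            )
        )
        p = tmp_path / "rt.ped"
        write_ped(ped, p)
        assert read_ped(p) == ped

    def test_gene_models(self, tmp_path):
        models = [
            GeneModel(
                gene_symbol="G1",
                chrom="chr3",
                strand="-",
                exons=((100, 159), (500, 619)),
                cds_start=100,
                cds_end=619,
                cds_sequence="ACG" * 59 + "TTT",
            )
        ]
        p = tmp_path / "rt.tsv"
        write_gene_models(models, p)
        assert read_gene_models(p) == models

    def test_gmt(self, tmp_path):
        coll = GeneSetCollection(sets={"A": ("X", "Y"), "B": ("Z",)})
        p = tmp_path / "rt.gmt"
        write_gmt(coll, p)
        assert read_gmt(p).sets == coll.sets

    def test_known_set(self, tmp_path):
        from famseg.formats import KnownVariantSet

        known = KnownVariantSet(
            keys=frozenset({("chr1", 5, "A", "T"), ("chr2", 9, "G", "GA")})
        )
        p = tmp_path / "rt.tsv"
        write_known_set(known, p)
        assert read_known_set(p) == known

    def test_expression(self, tmp_path):
        df = pd.DataFrame(
            [[1.25, 2.5, 3.0, 4.0], [0.5, 0.5, 0.5, 0.5]],
            index=["G1", "G2"],
            columns=["a", "b", "c", "d"],
        )
        groups = {"a": "case", "b": "case", "c": "control", "d": "control"}
        m = ExpressionMatrix(values=df, group_labels=groups)
        write_expression(m, tmp_path / "e.tsv", tmp_path / "g.tsv")
        back = read_expression(tmp_path / "e.tsv", tmp_path / "g.tsv")
        pd.testing.assert_frame_equal(back.values, m.values, check_names=False)
        assert back.group_labels == m.group_labels


@given(
    st.lists(
        st.tuples(
            st.sampled_from(["chr1", "chr2"]),
            st.integers(1, 1000),
            st.sampled_from("ACGT"),
            st.sampled_from("ACGT"),
        ),
        max_size=20,
    )
)
def test_vcf_roundtrip_property(tmp_path_factory, raw):
    """Any valid split variant list survives write -> read intact."""
    seen = set()
    variants = []
    for chrom, pos, ref, alt in raw:
        if ref == alt or (chrom, pos, alt) in seen:
            continue
        seen.add((chrom, pos, alt))
        variants.append(
            Variant(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                site_mq=60.0,
                genotypes=(GenotypeCall("S1", (ref, alt), 10, 50.0),),
            )
        )
    p = tmp_path_factory.mktemp("rt") / "x.vcf"
    write_vcf(variants, p, sample_ids=["S1"])
    back = read_vcf(p)
    assert sorted(v.key for v in back) == sorted(v.key for v in variants)
    assert len(back) == len(variants)


def test_filter_params_validation():
    with pytest.raises(ValidationError):
        FilterParams(cluster_min_count=1)
    with pytest.raises(ValidationError):
        FilterParams(min_depth=0)
    with pytest.raises(ValidationError, match="unknown"):
        FilterParams.from_mapping({"bogus": 1})
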