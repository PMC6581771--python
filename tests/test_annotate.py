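"""Coordinate mapping, codon consequences and splice classification."""

import pytest
from Bio.Seq import Seq, reverse_complement
from hypothesis import given
from hypothesis import strategies as st

from famseg.annotate import (
    CdsCoordinate,
    ReferenceMismatchError,
    annotate_indel,
    annotate_substitution,
    annotate_variant,
    cds_to_genomic,
    classify_splice,
    genomic_to_cds,
    is_nssi,
    predictor_consensus,
    residue_index,
)
from famseg.formats import ContractError, GeneModel, GenotypeCall, Variant

CODONS = [
    "GCT", "GCC", "GTT", "CTT", "ATC", "ACC", "AAC", "GAC",
    "GGT", "TCC", "CCT", "CAC", "CGT", "GAA", "AGC", "AAA",
]


def single_exon_model(n_codons=250, start=1001, codon="GAA", strand="+"):
    seq = codon * n_codons
    return GeneModel(
        gene_symbol="TOY",
        chrom="chr1",
        strand=strand,
        exons=((start, start + 3 * n_codons - 1),),
        cds_start=start,
        cds_end=start + 3 * n_codons - 1,
        cds_sequence=seq,
    )


def two_exon_model(exon1_len=502, total=720, start=1001, intron=500):
    e1 = (start, start + exon1_len - 1)
    s2 = e1[1] + intron + 1
    e2 = (s2, s2 + (total - exon1_len) - 1)
    return GeneModel(
        gene_symbol="TOY2",
        chrom="chr1",
        strand="+",
        exons=(e1, e2),
        cds_start=e1[0],
        cds_end=e2[1],
        cds_sequence="AAC" * (total // 3),
    )


def _sub(pos, ref, alt, chrom="chr1", predictors=None):
    return Variant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        predictor_calls=predictors or {},
        genotypes=(GenotypeCall("S1", (ref, alt), 30, 99.0),),
    )


class TestResidueIndex:
    @pytest.mark.parametrize(
        "cds_pos,expected", [(603, 201), (1, 1), (322, 108), (3, 1), (4, 2)]
    )
    def test_examples(self, cds_pos, expected):
        assert residue_index(cds_pos) == expected

    def test_three_consecutive_positions_share_a_residue(self):
        idx = [residue_index(p) for p in range(1, 301)]
        assert idx == sorted(idx)
        assert all(idx.count(i) == 3 for i in set(idx))


class TestGenomicToCds:
    def test_single_exon_offset_arithmetic(self):
        model = single_exon_model(start=1001)
        assert genomic_to_cds(model, 1603) == CdsCoordinate(603)

    def test_first_intronic_base_after_donor(self):
        model = two_exon_model(exon1_len=502)
        pos = model.exons[0][1] + 1
        coord = genomic_to_cds(model, pos)
        assert coord == CdsCoordinate(502, +1)
        assert coord.render() == "502+1"

    def test_last_intronic_base_before_acceptor(self):
        model = two_exon_model(exon1_len=502)
        pos = model.exons[1][0] - 1
        assert genomic_to_cds(model, pos) == CdsCoordinate(503, -1)

    def test_outside_gene_is_none(self):
        model = single_exon_model()
        assert genomic_to_cds(model, 5) is None
        assert genomic_to_cds(model, 10**6) is None

    def test_minus_strand_agrees_with_mirrored_plus_model(self):
        # strand-flip oracle: a minus-strand gene maps like the
        # coordinate-flipped, reverse-complemented plus-strand construction
        n = 60
        seq = ("GAC" * n)[: 3 * n]
        L = 10_000
        start_minus, end_minus = 2001, 2001 + 3 * n - 1
        minus = GeneModel(
            gene_symbol="M",
            chrom="chr1",
            strand="-",
            exons=((start_minus, end_minus),),
            cds_start=start_minus,
            cds_end=end_minus,
            cds_sequence=seq,
        )
        start_plus = L - end_minus + 1
        plus = GeneModel(
            gene_symbol="P",
            chrom="chr1",
            strand="+",
            exons=((start_plus, start_plus + 3 * n - 1),),
            cds_start=start_plus,
            cds_end=start_plus + 3 * n - 1,
            cds_sequence=seq,
        )
        for pos in range(start_minus, end_minus + 1):
            mirrored = L - pos + 1
            assert genomic_to_cds(minus, pos) == genomic_to_cds(plus, mirrored)

    @given(st.integers(1, 240))
    def test_inverse_composition_identity(self, cds_pos):
        for strand in "+-":
            model = single_exon_model(n_codons=80, strand=strand)
            assert genomic_to_cds(model, cds_to_genomic(model, cds_pos)) == (
                CdsCoordinate(cds_pos)
            )


class TestAnnotateSubstitution:
    def test_e201d(self):
        model = single_exon_model(codon="GAA", start=1001)
        c = annotate_substitution(model, _sub(1001 + 602, "A", "T"))
        assert c.category == "nonsynonymous"
        assert c.hgvs_c == "c.603A>T"
        assert c.hgvs_p == "p.E201D"
        assert c.residue_index == 201

    def test_synonymous_third_base(self):
        model = single_exon_model(codon="GAA")
        c = annotate_substitution(model, _sub(1001 + 602, "A", "G"))
        assert c.category == "synonymous"
        assert c.hgvs_p == "p.E201E"

    def test_s108r(self):
        model = single_exon_model(codon="AGC", n_codons=140)
        c = annotate_substitution(model, _sub(1001 + 321, "A", "C"))
        assert c.category == "nonsynonymous"
        assert c.hgvs_c == "c.322A>C"
        assert c.hgvs_p == "p.S108R"
        assert c.residue_index == 108

    def test_stop_gained(self):
        model = single_exon_model(codon="TCA")  # S; TCA -> TGA is a stop
        c = annotate_substitution(model, _sub(1001 + 1, "C", "G"))
        assert c.category == "stop_gained"
        assert c.hgvs_p == "p.S1*"

    def test_reference_mismatch_is_error(self):
        model = single_exon_model(codon="GAA")
        with pytest.raises(ReferenceMismatchError):
            annotate_substitution(model, _sub(1001, "C", "T"))

    @given(st.data())
    def test_matches_full_translation_oracle(self, data):
        """Category agrees with translating the whole CDS before/after."""
        n = 40
        codons = data.draw(
            st.lists(st.sampled_from(CODONS), min_size=n, max_size=n)
        )
        seq = "".join(codons)
        strand = data.draw(st.sampled_from("+-"))
        model = GeneModel(
            gene_symbol="R",
            chrom="chr1",
            strand=strand,
            exons=((501, 500 + 3 * n),),
            cds_start=501,
            cds_end=500 + 3 * n,
            cds_sequence=seq,
        )
        cds_pos = data.draw(st.integers(1, 3 * n))
        coding_ref = seq[cds_pos - 1]
        coding_alt = data.draw(
            st.sampled_from([b for b in "ACGT" if b != coding_ref])
        )
        pos = cds_to_genomic(model, cds_pos)
        if strand == "+":
            ref, alt = coding_ref, coding_alt
        else:
            ref, alt = reverse_complement(coding_ref), reverse_complement(coding_alt)
        c = annotate_substitution(model, _sub(pos, ref, alt))
        mutated = seq[: cds_pos - 1] + coding_alt + seq[cds_pos:]
        before = str(Seq(seq).translate())
        after = str(Seq(mutated).translate())
        if before == after:
            assert c.category == "synonymous"
        elif "*" in after and "*" not in before:
            assert c.category == "stop_gained"
        else:
            assert c.category == "nonsynonymous"
        # protein-level rendering agrees with the oracle's residue
        i = c.residue_index - 1
        assert c.hgvs_p == f"p.{before[i]}{c.residue_index}{after[i]}"


class TestClassifySplice:
    def test_donor_plus_one(self):
        model = two_exon_model(exon1_len=502)
        v = _sub(model.exons[0][1] + 1, "G", "A")
        c = classify_splice(model, v)
        assert c.category == "splice_donor"
        assert c.hgvs_c == "c.502+1G>A"
        assert c.hgvs_p is None

    def test_acceptor_minus_one(self):
        model = two_exon_model(exon1_len=502)
        v = _sub(model.exons[1][0] - 1, "A", "G")
        assert classify_splice(model, v).category == "splice_acceptor"

    @pytest.mark.parametrize("offset", range(1, 11))
    def test_offset_sweep_donor_and_acceptor(self, offset):
        model = two_exon_model(exon1_len=502, intron=500)
        donor = classify_splice(model, _sub(model.exons[0][1] + offset, "G", "A"))
        acceptor = classify_splice(
            model, _sub(model.exons[1][0] - offset, "A", "G")
        )
        if offset <= 2:
            assert donor.category == "splice_donor"
            assert acceptor.category == "splice_acceptor"
        else:
            assert donor.category == "intronic"
            assert acceptor.category == "intronic"

    def test_exonic_position_is_contract_error(self):
        model = two_exon_model()
        with pytest.raises(ContractError):
            classify_splice(model, _sub(model.exons[0][0], "A", "G"))


class TestAnnotateIndel:
    def test_one_bp_deletion_is_frameshift(self):
        model = single_exon_model(codon="AAC")
        v = Variant(chrom="chr1", pos=1010, ref="CA", alt="C")
        assert annotate_indel(model, v).category == "frameshift_indel"

    def test_three_bp_deletion_is_inframe(self):
        model = single_exon_model(codon="AAC")
        v = Variant(chrom="chr1", pos=1010, ref="CAAC", alt="C")
        assert annotate_indel(model, v).category == "inframe_indel"

    @given(st.integers(1, 12), st.booleans())
    def test_matches_length_arithmetic_oracle(self, length, is_insertion):
        model = single_exon_model(codon="AAC")
        if is_insertion:
            v = Variant(chrom="chr1", pos=1010, ref="C", alt="C" + "A" * length)
        else:
            v = Variant(chrom="chr1", pos=1010, ref="C" + "A" * length, alt="C")
        c = annotate_indel(model, v)
        delta = len(v.alt) - len(v.ref)
        expected = "inframe_indel" if delta % 3 == 0 else "frameshift_indel"
        assert c.category == expected


class TestNssiAndConsensus:
    @pytest.mark.parametrize(
        "category,expected",
        [
            ("nonsynonymous", True),
            ("stop_gained", True),
            ("splice_donor", True),
            ("splice_acceptor", True),
            ("frameshift_indel", True),
            ("inframe_indel", True),
            ("synonymous", False),
            ("intronic", False),
            ("intergenic", False),
        ],
    )
    def test_nssi_membership(self, category, expected):
        from famseg.annotate import Consequence

        hgvs_p = "p.K1Q" if category in (
            "nonsynonymous", "synonymous", "stop_gained", "stop_lost"
        ) else None
        c = Consequence(
            gene_symbol="G", category=category, hgvs_c="c.1A>C", hgvs_p=hgvs_p
        )
        assert is_nssi(c) is expected

    def test_consensus_vote_counting(self):
        v = _sub(
            100,
            "A",
            "T",
            predictors={
                "sift": "tolerated",
                "polyphen2": "damaging",
                "phylop": "conserved",
                "mutation_taster": "disease_causing",
            },
        )
        assert predictor_consensus(v, 2) is True
        assert predictor_consensus(v, 3) is True
        assert predictor_consensus(v, 4) is False  # only 3 deleterious calls

    def test_absent_predictors_never_vote(self):
        assert predictor_consensus(_sub(100, "A", "T"), 1) is False

    def test_min_votes_above_predictor_count_always_false(self):
        v = _sub(
            100,
            "A",
            "T",
            predictors={
                "sift": "damaging",
                "polyphen2": "damaging",
                "phylop": "conserved",
                "mutation_taster": "disease_causing",
            },
        )
        assert predictor_consensus(v, 5) is False


def test_annotate_variant_dispatch():
    exonic = two_exon_model(exon1_len=502)
    donor = _sub(exonic.exons[0][1] + 1, "G", "A")
    assert annotate_variant([exonic], donor).category == "splice_donor"
    sub = _sub(exonic.exons[0][0], "A", "C")
    assert annotate_variant([exonic], sub).category == "nonsynonymous"
    far = _sub(999_999, "A", "C")
    assert annotate_variant([exonic], far).category == "intergenic"
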