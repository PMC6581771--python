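"""Consequence annotation on minimal transcript models.

Maps genomic positions to spliced-CDS coordinates (strand-aware, with
HGVS-style intronic offsets), calls codon-level effects of substitutions
with the standard genetic code, classifies canonical splice-site disruption
(the +/-1 and +/-2 intronic dinucleotides), annotates coding indels as
frameshift/in-frame, renders HGVS c. and p. strings, and evaluates the
NS/SS/I class and the pathogenicity-predictor consensus vote.

Only canonical splice-site positions are computed here; external
splice-strength predictors are consumed, not re-implemented.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import reverse_complement

from .formats import DELETERIOUS_CALLS, ContractError, GeneModel, Variant

#: categories that count as NS/SS/I (the retained functional classes:
#: nonsynonymous substitutions, splice acceptor/donor, coding indels)
NSSI_CATEGORIES = frozenset(
    {
        "nonsynonymous",
        "stop_gained",
        "stop_lost",
        "splice_donor",
        "splice_acceptor",
        "frameshift_indel",
        "inframe_indel",
    }
)

_CODON_CATEGORIES = frozenset(
    {"nonsynonymous", "synonymous", "stop_gained", "stop_lost"}
)


class ReferenceMismatchError(ValueError):
    """The variant's REF allele disagrees with the model's CDS base."""


@dataclass(frozen=True)
class CdsCoordinate:
    """Position within the spliced CDS, or an exon-boundary anchor.

    ``intron_offset`` is 0 for exonic coding positions, +k for the k-th base
    after a splice donor, -k for the k-th base before a splice acceptor;
    rendered "502+1"-style in HGVS c. notation.
    """

    cds_pos: int
    intron_offset: int = 0

    def render(self) -> str:
        if self.intron_offset > 0:
            return f"{self.cds_pos}+{self.intron_offset}"
        if self.intron_offset < 0:
            return f"{self.cds_pos}{self.intron_offset}"
        return str(self.cds_pos)


@dataclass(frozen=True)
class Consequence:
    """Functional consequence of one variant on one transcript."""

    gene_symbol: str
    category: str
    hgvs_c: str
    hgvs_p: str | None = None
    residue_index: int | None = None

    def __post_init__(self) -> None:
        has_p = self.hgvs_p is not None
        if has_p != (self.category in _CODON_CATEGORIES):
            raise ValueError(
                f"hgvs_p must be present iff the category affects a codon "
                f"(category={self.category!r}, hgvs_p={self.hgvs_p!r})"
            )


def is_nssi(consequence: Consequence) -> bool:
    """True iff the consequence is in the retained NS/SS/I class."""
    return consequence.category in NSSI_CATEGORIES


def residue_index(cds_pos: int) -> int:
    """1-based protein residue index for a CDS position: ceil(cds_pos/3)."""
    if cds_pos < 1:
        raise ValueError(f"cds_pos must be >= 1, got {cds_pos}")
    return -(-cds_pos // 3)


def genomic_to_cds(model: GeneModel, pos: int) -> CdsCoordinate | None:
    """Map a genomic position to a spliced-CDS coordinate.

    Exonic coding positions map to cds_pos in translation order. Intronic
    positions inside the gene anchor to the nearest exon boundary with a
    signed offset (donor side +, acceptor side -, in transcription
    orientation; ties go to the donor). Positions outside the gene span, or
    exonic but non-coding, map to None.
    """
    coding = model.coding_positions()
    index = {p: i + 1 for i, p in enumerate(coding)}
    if pos in index:
        return CdsCoordinate(cds_pos=index[pos])
    span_lo, span_hi = model.span
    if pos < span_lo or pos > span_hi:
        return None
    # intronic iff between consecutive exons
    for (s1, e1), (s2, e2) in zip(model.exons, model.exons[1:]):
        if e1 < pos < s2:
            if model.strand == "+":
                donor_anchor, donor_dist = e1, pos - e1
                accept_anchor, accept_dist = s2, s2 - pos
            else:
                donor_anchor, donor_dist = s2, s2 - pos
                accept_anchor, accept_dist = e1, pos - e1
            if donor_anchor not in index or accept_anchor not in index:
                return None  # flanking exon base is non-coding
            if donor_dist <= accept_dist:
                return CdsCoordinate(index[donor_anchor], +donor_dist)
            return CdsCoordinate(index[accept_anchor], -accept_dist)
    return None  # exonic but outside the CDS (UTR)


def cds_to_genomic(model: GeneModel, cds_pos: int) -> int:
    """Inverse of :func:`genomic_to_cds` on exonic coding positions."""
    coding = model.coding_positions()
    if not 1 <= cds_pos <= len(coding):
        raise ValueError(f"cds_pos {cds_pos} outside CDS of {model.gene_symbol}")
    return coding[cds_pos - 1]


def _complement(base: str) -> str:
    return reverse_complement(base)


def _translate_codon(codon: str) -> str:
    """One-letter amino acid, '*' for stop (standard nuclear code)."""
    if codon in standard_dna_table.stop_codons:
        return "*"
    return standard_dna_table.forward_table[codon]


def annotate_substitution(model: GeneModel, variant: Variant) -> Consequence:
    """Codon-level consequence of a single-base substitution in the CDS.

    The reference and mutated codons are translated with the standard
    genetic code; alleles in hgvs_c are given on the coding strand.
    Raises :class:`ReferenceMismatchError` when the VCF REF base disagrees
    with the model's CDS sequence, and :class:`ContractError` when the
    position is not a coding position of the model.
    """
    if not variant.is_snv:
        raise ContractError("annotate_substitution requires a single-base SNV")
    coord = genomic_to_cds(model, variant.pos)
    if coord is None or coord.intron_offset != 0:
        raise ContractError(
            f"{variant.chrom}:{variant.pos} is not in the CDS of "
            f"{model.gene_symbol}"
        )
    cds_pos = coord.cds_pos
    if model.strand == "+":
        ref_c, alt_c = variant.ref, variant.alt
    else:
        ref_c, alt_c = _complement(variant.ref), _complement(variant.alt)
    if model.cds_sequence[cds_pos - 1] != ref_c:
        raise ReferenceMismatchError(
            f"{model.gene_symbol} CDS position {cds_pos}: model base "
            f"{model.cds_sequence[cds_pos - 1]!r} != variant ref {ref_c!r} "
            "(coding strand)"
        )
    idx = residue_index(cds_pos)
    codon = model.cds_sequence[3 * (idx - 1) : 3 * idx]
    within = (cds_pos - 1) % 3
    mutated = codon[:within] + alt_c + codon[within + 1 :]
    aa_ref = _translate_codon(codon)
    aa_alt = _translate_codon(mutated)
    if aa_ref == aa_alt:
        category = "synonymous"
    elif aa_alt == "*":
        category = "stop_gained"
    elif aa_ref == "*":
        category = "stop_lost"
    else:
        category = "nonsynonymous"
    return Consequence(
        gene_symbol=model.gene_symbol,
        category=category,
        hgvs_c=f"c.{cds_pos}{ref_c}>{alt_c}",
        hgvs_p=f"p.{aa_ref}{idx}{aa_alt}",
        residue_index=idx,
    )


def classify_splice(model: GeneModel, variant: Variant) -> Consequence:
    """Classify an intronic variant: canonical splice site or plain intronic.

    Intron offsets +1/+2 hit the donor dinucleotide, -1/-2 the acceptor;
    anything deeper is intronic. hgvs_c uses offset notation with
    coding-strand alleles.
    """
    coord = genomic_to_cds(model, variant.pos)
    if coord is None or coord.intron_offset == 0:
        raise ContractError(
            f"{variant.chrom}:{variant.pos} is not intronic in {model.gene_symbol}"
        )
    off = coord.intron_offset
    if off in (1, 2):
        category = "splice_donor"
    elif off in (-1, -2):
        category = "splice_acceptor"
    else:
        category = "intronic"
    if model.strand == "+":
        ref_c, alt_c = variant.ref, variant.alt
    else:
        ref_c, alt_c = _complement(variant.ref), _complement(variant.alt)
    return Consequence(
        gene_symbol=model.gene_symbol,
        category=category,
        hgvs_c=f"c.{coord.render()}{ref_c}>{alt_c}",
    )


def annotate_indel(model: GeneModel, variant: Variant) -> Consequence:
    """Frameshift/in-frame call for an insertion or deletion in the CDS."""
    if variant.is_snv:
        raise ContractError("annotate_indel requires an insertion or deletion")
    coord = genomic_to_cds(model, variant.pos)
    if coord is None:
        raise ContractError(
            f"{variant.chrom}:{variant.pos} does not touch {model.gene_symbol}"
        )
    delta = len(variant.alt) - len(variant.ref)
    category = "inframe_indel" if delta % 3 == 0 else "frameshift_indel"
    anchor = coord.render()
    if delta < 0:  # deletion of -delta bases after the anchor base
        if -delta == 1:
            hgvs_c = f"c.{anchor}del"
        else:
            hgvs_c = f"c.{anchor}del{-delta}"
    else:
        hgvs_c = f"c.{anchor}ins{variant.alt[len(variant.ref):]}"
    return Consequence(
        gene_symbol=model.gene_symbol, category=category, hgvs_c=hgvs_c
    )


def annotate_variant(
    models: list[GeneModel], variant: Variant
) -> Consequence:
    """Dispatch to the right annotator for the model overlapping the variant.

    One model per gene is assumed; the first model on the variant's
    chromosome whose span contains the position wins. Variants outside
    every gene are intergenic.
    """
    for model in models:
        if model.chrom != variant.chrom:
            continue
        lo, hi = model.span
        if not lo <= variant.pos <= hi:
            continue
        coord = genomic_to_cds(model, variant.pos)
        if coord is None:
            continue
        if not variant.is_snv:
            return annotate_indel(model, variant)
        if coord.intron_offset == 0:
            return annotate_substitution(model, variant)
        return classify_splice(model, variant)
    return Consequence(
        gene_symbol="", category="intergenic", hgvs_c=f"g.{variant.pos}{variant.ref}>{variant.alt}"
    )


def predictor_consensus(variant: Variant, min_votes: int = 2) -> bool:
    """True iff >= ``min_votes`` predictors call the variant deleterious.

    Deleterious-class calls are ``damaging`` (SIFT/PolyPhen2), ``conserved``
    (PhyloP) and ``disease_causing`` (MutationTaster); a missing predictor
    contributes no vote.
    """
    votes = sum(
        1 for call in variant.predictor_calls.values() if call in DELETERIOUS_CALLS
    )
    return votes >= min_votes
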