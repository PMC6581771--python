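"""Deterministic, seedable generator of complete pipeline inputs.

Emits a file bundle (per-family VCFs, PED, gene models, known-variant list,
expression matrix + group map, GMT gene sets, background universe, serology
table, run config) together with a :class:`GroundTruth` ledger of everything
that was planted, so recovery can be asserted exactly.

The packaged "paper scenario" preset mirrors the structure of a four-family
house-dust-mite allergic-rhinitis study: four pedigrees with affected
parent-child pairs (family 4 a 12-member extended pedigree), three causal
variants (a FLT1 missense at CDS 603, a VEGFB missense at CDS 322 and an
ITGA2 canonical splice-donor variant at c.502+1) planted heterozygously in
their carriers, cross-family decoy genes segregating in two families each,
a 20,000-gene expression matrix (7 cases vs 5 controls) with 1117 planted
DE genes of which 22 overlap the WGS candidate genes, and a focal-adhesion
gene set containing the three causal genes.

Toy genomes are a few ~1 Mb chromosomes; VCF REF alleles are kept
self-consistent with the gene models' CDS sequences, so no reference FASTA
is needed. Background variation is deliberately neutral (intergenic or
synonymous), keeping every NS/SS/I tally attributable to planted variants.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .annotate import cds_to_genomic
from .cohort import SerologyRecord, write_serology
from .formats import (
    ExpressionMatrix,
    GeneModel,
    GeneSetCollection,
    GenotypeCall,
    Individual,
    KnownVariantSet,
    Pedigree,
    ValidationError,
    Variant,
    write_expression,
    write_gene_models,
    write_gmt,
    write_known_set,
    write_ped,
    write_vcf,
)

import pandas as pd

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_SAFE_CODONS = (  # no stop codons, no accidental stops after planted edits
    "GCT", "GCC", "GTT", "GTC", "CTT", "CTC", "ATC", "ACC",
    "AAC", "GAC", "GGT", "GGC", "TCC", "CCT", "CAC", "CGT",
)


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named, independent stream: adding a stream never perturbs others."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(zlib.crc32(name.encode()),))
    )


# ---------------------------------------------------------------------------
# Config types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MemberSpec:
    individual_id: str
    father_id: str | None
    mother_id: str | None
    sex: str
    affected: bool | None


@dataclass(frozen=True)
class PedigreeSpec:
    family_id: str
    members: tuple[MemberSpec, ...]


@dataclass(frozen=True)
class GeneSpec:
    """Structural plan for one toy gene model."""

    symbol: str
    chrom: str
    tx_start: int
    n_codons: int
    strand: str = "+"
    exon1_cds_len: int | None = None  # split CDS after this many bases
    intron_len: int = 500


@dataclass(frozen=True)
class PlantSpec:
    """One planted variant: where, in whom, and with what role.

    ``kind`` is "sub" (CDS substitution given coding-strand alt with the
    reference codon pinned) or "splice" (intronic offset from a CDS anchor).
    ``genotypes`` maps carrier id -> "het" | "hom". ``role`` drives the
    ground-truth bookkeeping; quality overrides make a variant fail a
    specific filter on purpose.
    """

    family_id: str
    gene: str
    kind: str  # "sub" | "splice"
    cds_pos: int  # substitution position, or splice anchor
    coding_ref_codon: str | None  # pinned codon (sub only)
    coding_alt: str  # coding-strand alt base
    genotypes: Mapping[str, str]
    role: str  # causal|decoy_crossfam|filler|extra|cluster|lowqual_dp|...
    splice_offset: int = 0
    predictor_calls: Mapping[str, str] = field(default_factory=dict)
    in_known_set: bool = False
    depth_override: int | None = None
    gq_override: float | None = None
    mq_override: float | None = None


@dataclass(frozen=True)
class ScenarioConfig:
    seed: int
    pedigrees: tuple[PedigreeSpec, ...]
    genes: tuple[GeneSpec, ...]
    planted: tuple[PlantSpec, ...]
    deg_extra_genes: tuple[str, ...]  # DE genes beyond the planted candidates
    gene_sets: Mapping[str, tuple[str, ...]]
    n_background_variants: int = 200
    known_db_coverage: float = 0.95
    n_genes_expression: int = 20_000
    deg_shift: float = 100.0
    within_group_sd: float = 0.1
    n_cases: int = 7
    n_controls: int = 5
    candidate_deg_overlap: int | None = None
    chrom_length: int = 1_000_000

    def __post_init__(self) -> None:
        gene_syms = {g.symbol for g in self.genes}
        for p in self.planted:
            if p.gene not in gene_syms:
                raise ValidationError(
                    f"planted gene {p.gene!r} has no gene model"
                )


@dataclass
class GroundTruth:
    """What the generator planted, keyed the way the pipeline reports it."""

    per_individual_nssi: dict[str, dict[str, int]]
    parent_child_shared: dict[str, list[str]]
    family_shared_genes: dict[str, list[str]]
    cross_family_genes: list[str]
    candidate_genes: list[str]
    deg_genes: list[str]
    intersection_genes: list[str]
    expected_final: list[str]
    expected_compound_het: dict[str, list[list[str]]]
    planted_decoys: list[dict[str, str]]
    carriers: dict[str, list[str]]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def variant_key_str(key: tuple[str, int, str, str]) -> str:
    return f"{key[0]}:{key[1]}:{key[2]}:{key[3]}"


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def mendelian_transmit(
    father: tuple[str, str], mother: tuple[str, str], rng: np.random.Generator
) -> tuple[str, str]:
    """Child genotype: one allele drawn uniformly from each parent."""
    return (
        father[int(rng.integers(2))],
        mother[int(rng.integers(2))],
    )


def build_gene_model(spec: GeneSpec, rng: np.random.Generator) -> GeneModel:
    """Random-codon gene model following the structural plan."""
    n = spec.n_codons
    seq = "".join(rng.choice(_SAFE_CODONS) for _ in range(n))
    cds_len = 3 * n
    if spec.exon1_cds_len is None:
        exons = ((spec.tx_start, spec.tx_start + cds_len - 1),)
    else:
        l1 = spec.exon1_cds_len
        if not 0 < l1 < cds_len:
            raise ValidationError(
                f"{spec.symbol}: exon1_cds_len must split the CDS"
            )
        e1 = (spec.tx_start, spec.tx_start + l1 - 1)
        s2 = e1[1] + spec.intron_len + 1
        e2 = (s2, s2 + (cds_len - l1) - 1)
        exons = (e1, e2)
    return GeneModel(
        gene_symbol=spec.symbol,
        chrom=spec.chrom,
        strand=spec.strand,
        exons=exons,
        cds_start=exons[0][0],
        cds_end=exons[-1][1],
        cds_sequence=seq,
    )


def _pin_codon(model: GeneModel, residue: int, codon: str) -> GeneModel:
    seq = model.cds_sequence
    i = 3 * (residue - 1)
    new = seq[:i] + codon + seq[i + 3 :]
    return GeneModel(
        gene_symbol=model.gene_symbol,
        chrom=model.chrom,
        strand=model.strand,
        exons=model.exons,
        cds_start=model.cds_start,
        cds_end=model.cds_end,
        cds_sequence=new,
    )


@dataclass
class _PlantedVariant:
    spec: PlantSpec
    chrom: str
    pos: int
    ref: str
    alt: str
    is_nssi: bool

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def _materialize_plant(
    spec: PlantSpec, models: dict[str, GeneModel]
) -> tuple[_PlantedVariant, dict[str, GeneModel]]:
    """Pin the reference codon and compute the genomic (ref, alt) alleles."""
    model = models[spec.gene]
    if spec.kind == "sub":
        residue = -(-spec.cds_pos // 3)
        if spec.coding_ref_codon is not None:
            model = _pin_codon(model, residue, spec.coding_ref_codon)
            models = {**models, spec.gene: model}
        within = (spec.cds_pos - 1) % 3
        coding_ref = model.cds_sequence[spec.cds_pos - 1]
        coding_alt = spec.coding_alt
        if coding_ref == coding_alt:
            raise ValidationError(f"{spec.gene}: alt equals pinned ref base")
        pos = cds_to_genomic(model, spec.cds_pos)
        if model.strand == "+":
            ref, alt = coding_ref, coding_alt
        else:
            ref, alt = _COMPLEMENT[coding_ref], _COMPLEMENT[coding_alt]
        codon = model.cds_sequence[3 * (residue - 1) : 3 * residue]
        mutated = codon[:within] + coding_alt + codon[within + 1 :]
        nssi = _translate(codon) != _translate(mutated)
    elif spec.kind == "splice":
        # genomic position of the anchor's neighbour in the intron
        anchor_genomic = cds_to_genomic(model, spec.cds_pos)
        step = 1 if model.strand == "+" else -1
        pos = anchor_genomic + step * spec.splice_offset
        if model.strand == "+":
            ref = "G" if spec.splice_offset > 0 else "A"
            alt = spec.coding_alt
        else:
            ref = _COMPLEMENT["G" if spec.splice_offset > 0 else "A"]
            alt = _COMPLEMENT[spec.coding_alt]
        if ref == alt:
            raise ValidationError(f"{spec.gene}: splice alt equals ref")
        nssi = abs(spec.splice_offset) <= 2
    else:
        raise ValidationError(f"unknown plant kind {spec.kind!r}")
    return (
        _PlantedVariant(
            spec=spec, chrom=model.chrom, pos=pos, ref=ref, alt=alt, is_nssi=nssi
        ),
        models,
    )


_CODON_TABLE: dict[str, str] = {}


def _translate(codon: str) -> str:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE[codon]


def _mendelian_check(
    pedigree_members: Sequence[MemberSpec],
    genotypes: Mapping[str, tuple[str, str]],
) -> None:
    for m in pedigree_members:
        if m.father_id is None or m.mother_id is None:
            continue
        a, b = genotypes[m.individual_id]
        father = set(genotypes[m.father_id])
        mother = set(genotypes[m.mother_id])
        # one allele from each parent (obligate transmission included)
        if not ((a in father and b in mother) or (a in mother and b in father)):
            raise ValidationError(
                f"non-Mendelian genotype for {m.individual_id}"
            )


def _family_genotypes_for_plant(
    spec: PlantSpec,
    members: Sequence[MemberSpec],
    ref: str,
    alt: str,
) -> dict[str, tuple[str, str]]:
    gts: dict[str, tuple[str, str]] = {}
    for m in members:
        state = spec.genotypes.get(m.individual_id, "ref")
        if state == "het":
            gts[m.individual_id] = (ref, alt)
        elif state == "hom":
            gts[m.individual_id] = (alt, alt)
        else:
            gts[m.individual_id] = (ref, ref)
    _mendelian_check(members, gts)
    return gts


# ---------------------------------------------------------------------------
# Scenario generation
# ---------------------------------------------------------------------------

def generate_scenario(
    config: ScenarioConfig, out_dir: str | Path
) -> tuple[dict[str, Path], GroundTruth]:
    """Emit the full input bundle and its ground truth.

    Identical config (including seed) produces a byte-identical bundle.
    Returns (file map, GroundTruth); ground truth and a ready-to-run
    pipeline config are also written into ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- gene models ------------------------------------------------------
    models: dict[str, GeneModel] = {}
    rng_genes = _rng(config.seed, "genes")
    for spec in config.genes:
        models[spec.symbol] = build_gene_model(spec, rng_genes)

    planted: list[_PlantedVariant] = []
    for pspec in config.planted:
        pv, models = _materialize_plant(pspec, models)
        planted.append(pv)
    # same key may recur across families (a shared mutation), never within one
    fam_keys = [(pv.spec.family_id, pv.key) for pv in planted]
    if len(fam_keys) != len(set(fam_keys)):
        raise ValidationError("planted variants collide within a family")

    # --- per-family variant tables ---------------------------------------
    vcf_paths: dict[str, Path] = {}
    known_keys: set[tuple[str, int, str, str]] = set()
    per_individual_nssi: dict[str, dict[str, int]] = {}
    parent_child_shared: dict[str, list[str]] = {}
    family_shared_genes: dict[str, list[str]] = {}
    decoys: list[dict[str, str]] = []
    carriers_out: dict[str, list[str]] = {}

    gene_spans = [
        (m.chrom, m.span[0], m.span[1]) for m in models.values()
    ]

    for ped in config.pedigrees:
        fam = ped.family_id
        rng_fam = _rng(config.seed, f"family:{fam}")
        member_ids = [m.individual_id for m in ped.members]
        used_positions: dict[str, list[int]] = {}
        variants: list[Variant] = []

        def _occupied(chrom: str, pos: int, min_gap: int = 11) -> bool:
            return any(
                abs(pos - p) < min_gap for p in used_positions.get(chrom, ())
            )

        def _claim(chrom: str, pos: int) -> None:
            used_positions.setdefault(chrom, []).append(pos)

        # planted variants for this family
        fam_planted = [pv for pv in planted if pv.spec.family_id == fam]
        cluster_roles = {"cluster"}
        for pv in fam_planted:
            _claim(pv.chrom, pv.pos)
        for pv in fam_planted:
            gts = _family_genotypes_for_plant(pv.spec, ped.members, pv.ref, pv.alt)
            genotypes = tuple(
                GenotypeCall(
                    sample_id=iid,
                    alleles=gts[iid],
                    depth=pv.spec.depth_override
                    if pv.spec.depth_override is not None
                    else int(rng_fam.integers(20, 41)),
                    gq=pv.spec.gq_override
                    if pv.spec.gq_override is not None
                    else float(rng_fam.integers(60, 100)),
                )
                for iid in member_ids
            )
            variants.append(
                Variant(
                    chrom=pv.chrom,
                    pos=pv.pos,
                    ref=pv.ref,
                    alt=pv.alt,
                    site_mq=pv.spec.mq_override
                    if pv.spec.mq_override is not None
                    else 60.0,
                    predictor_calls=dict(pv.spec.predictor_calls),
                    genotypes=genotypes,
                )
            )
            if pv.spec.in_known_set:
                known_keys.add(pv.key)

        # neutral background: intergenic or synonymous third-base edits
        chroms = sorted({g.chrom for g in config.genes})
        model_list = sorted(models.values(), key=lambda m: m.gene_symbol)
        rng_bg = _rng(config.seed, f"background:{fam}")
        founders = [
            m.individual_id
            for m in ped.members
            if m.father_id is None and m.mother_id is None
        ]
        n_bg = 0
        guard = 0
        while n_bg < config.n_background_variants and guard < 100_000:
            guard += 1
            if rng_bg.random() < 0.5:
                # intergenic SNV
                chrom = chroms[int(rng_bg.integers(len(chroms)))]
                pos = int(rng_bg.integers(1, config.chrom_length + 1))
                if any(
                    c == chrom and s - 10 <= pos <= e + 10
                    for c, s, e in gene_spans
                ) or _occupied(chrom, pos):
                    continue
                ref = "ACGT"[int(rng_bg.integers(4))]
                alt = "ACGT"[int(rng_bg.integers(4))]
                if ref == alt:
                    continue
            else:
                # synonymous: pin nothing, use CTG codons' 4-fold third base
                model = model_list[int(rng_bg.integers(len(model_list)))]
                n_cod = len(model.cds_sequence) // 3
                residue = int(rng_bg.integers(1, n_cod + 1))
                codon = model.cds_sequence[3 * (residue - 1) : 3 * residue]
                cds_pos = 3 * residue  # third base
                coding_ref = codon[2]
                choices = [
                    b
                    for b in "ACGT"
                    if b != coding_ref
                    and _translate(codon[:2] + b) == _translate(codon)
                ]
                if not choices:
                    continue
                coding_alt = choices[int(rng_bg.integers(len(choices)))]
                pos = cds_to_genomic(model, cds_pos)
                chrom = model.chrom
                if _occupied(chrom, pos):
                    continue
                if model.strand == "+":
                    ref, alt = coding_ref, coding_alt
                else:
                    ref, alt = _COMPLEMENT[coding_ref], _COMPLEMENT[coding_alt]
            _claim(chrom, pos)
            gts: dict[str, tuple[str, str]] = {}
            for m in ped.members:
                if m.individual_id in founders:
                    gts[m.individual_id] = (
                        (ref, alt) if rng_bg.random() < 0.3 else (ref, ref)
                    )
            for m in ped.members:  # members are listed parents-first
                if m.individual_id in gts:
                    continue
                gts[m.individual_id] = mendelian_transmit(
                    gts[m.father_id], gts[m.mother_id], rng_bg
                )
            genotypes = tuple(
                GenotypeCall(
                    sample_id=iid,
                    alleles=gts[iid],
                    depth=int(rng_bg.integers(10, 61)),
                    gq=float(rng_bg.integers(45, 100)),
                )
                for iid in member_ids
            )
            variants.append(
                Variant(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    site_mq=60.0,
                    genotypes=genotypes,
                )
            )
            if rng_bg.random() < config.known_db_coverage:
                known_keys.add((chrom, pos, ref, alt))
            n_bg += 1
        if n_bg < config.n_background_variants:
            raise ValidationError("could not place background variants")

        variants.sort(key=lambda v: (v.chrom, v.pos, v.alt))
        vcf_path = out / f"fam_{fam}.vcf"
        write_vcf(variants, vcf_path, sample_ids=member_ids)
        vcf_paths[fam] = vcf_path

        # --- bookkeeping for this family ---------------------------------
        surviving = [
            pv
            for pv in fam_planted
            if pv.spec.role not in cluster_roles
            and pv.spec.depth_override is None
            and pv.spec.gq_override is None
            and pv.spec.mq_override is None
            and not pv.spec.in_known_set
        ]
        counts = {iid: 0 for iid in member_ids}
        for pv in surviving:
            if not pv.is_nssi:
                continue
            for iid, state in pv.spec.genotypes.items():
                if state in ("het", "hom"):
                    counts[iid] += 1
        per_individual_nssi[fam] = counts

        affected = {
            m.individual_id for m in ped.members if m.affected is True
        }
        pairs = [
            (pid, m.individual_id)
            for m in ped.members
            if m.affected is True
            for pid in (m.father_id, m.mother_id)
            if pid in affected
        ]
        shared: list[str] = []
        shared_genes: list[str] = []
        for pv in surviving:
            if not pv.is_nssi:
                continue
            if any(
                pv.spec.genotypes.get(p) == "het"
                and pv.spec.genotypes.get(c) == "het"
                for p, c in pairs
            ):
                shared.append(variant_key_str(pv.key))
                if pv.spec.gene not in shared_genes:
                    shared_genes.append(pv.spec.gene)
        parent_child_shared[fam] = shared
        family_shared_genes[fam] = sorted(shared_genes)
        for pv in fam_planted:
            if pv not in surviving or not any(
                pv.spec.genotypes.get(p) == "het"
                and pv.spec.genotypes.get(c) == "het"
                for p, c in pairs
            ):
                decoys.append(
                    {"key": variant_key_str(pv.key), "role": pv.spec.role}
                )
        for pv in fam_planted:
            key = variant_key_str(pv.key)
            new = {
                iid
                for iid, st in pv.spec.genotypes.items()
                if st in ("het", "hom")
            }
            carriers_out[key] = sorted(set(carriers_out.get(key, [])) | new)

    # --- cross-family / candidate genes ----------------------------------
    gene_to_fams: dict[str, set[str]] = {}
    for fam, genes in family_shared_genes.items():
        for g in genes:
            gene_to_fams.setdefault(g, set()).add(fam)
    cross_family = sorted(g for g, fs in gene_to_fams.items() if len(fs) >= 2)
    candidate_genes = sorted(gene_to_fams)

    # --- expression matrix ------------------------------------------------
    rng_expr = _rng(config.seed, "expression")
    model_genes = [g.symbol for g in config.genes]
    deg_planted = sorted(
        {
            pv.spec.gene
            for pv in planted
            if pv.spec.role in ("causal", "filler")
        }
    )
    gene_list = list(model_genes)
    gene_list += [g for g in config.deg_extra_genes if g not in gene_list]
    for name, members in config.gene_sets.items():
        gene_list += [g for g in members if g not in gene_list]
    seen = set(gene_list)
    i = 0
    while len(gene_list) < config.n_genes_expression:
        name = f"GENE{i:05d}"
        i += 1
        if name in seen:
            continue
        gene_list.append(name)
        seen.add(name)
    gene_list = gene_list[: config.n_genes_expression]
    deg_genes = sorted(set(deg_planted) | set(config.deg_extra_genes))
    missing = set(deg_genes) - set(gene_list)
    if missing:
        raise ValidationError(f"DE genes not in expression universe: {missing}")

    n_samples = config.n_cases + config.n_controls
    sample_ids = [f"CASE{i+1}" for i in range(config.n_cases)] + [
        f"CTRL{i+1}" for i in range(config.n_controls)
    ]
    groups = {
        s: ("case" if s.startswith("CASE") else "control") for s in sample_ids
    }
    baseline = rng_expr.normal(8.0, 1.0, size=len(gene_list))
    values = (
        baseline[:, None]
        + rng_expr.normal(0.0, config.within_group_sd, size=(len(gene_list), n_samples))
    )
    deg_index = {g: i for i, g in enumerate(gene_list)}
    shift = config.deg_shift * config.within_group_sd
    for j, g in enumerate(deg_genes):
        sign = 1.0 if rng_expr.random() < 0.5 else -1.0
        values[deg_index[g], : config.n_cases] += sign * shift
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_list, columns=sample_ids),
        group_labels=groups,
    )

    intersection = sorted(set(candidate_genes) & set(deg_genes))
    if (
        config.candidate_deg_overlap is not None
        and len(intersection) != config.candidate_deg_overlap
    ):
        raise ValidationError(
            f"candidate/DEG overlap is {len(intersection)}, configured "
            f"{config.candidate_deg_overlap}"
        )

    # --- expected final report -------------------------------------------
    sets = GeneSetCollection(
        sets={k: tuple(v) for k, v in config.gene_sets.items()},
        background=None,
    )
    enriched_member_genes = set()
    for members in config.gene_sets.values():
        enriched_member_genes.update(members)
    expected_final: list[str] = []
    compound: dict[str, list[list[str]]] = {}
    final_variants: list[_PlantedVariant] = []
    for pv in planted:
        if pv.spec.role != "causal":
            continue
        k = variant_key_str(pv.key)
        if k in parent_child_shared[pv.spec.family_id]:
            if pv.spec.gene in intersection:
                final_variants.append(pv)
                expected_final.append(k)
    # compound hets among final variants
    het_by_ind: dict[str, list[str]] = {}
    for pv in final_variants:
        for iid, st in pv.spec.genotypes.items():
            if st == "het":
                het_by_ind.setdefault(iid, []).append(variant_key_str(pv.key))
    for iid in sorted(het_by_ind):
        ks = sorted(het_by_ind[iid])
        if len(ks) >= 2:
            compound[iid] = [
                [a, b]
                for i, a in enumerate(ks)
                for b in ks[i + 1 :]
            ]

    truth = GroundTruth(
        per_individual_nssi=per_individual_nssi,
        parent_child_shared=parent_child_shared,
        family_shared_genes=family_shared_genes,
        cross_family_genes=cross_family,
        candidate_genes=candidate_genes,
        deg_genes=deg_genes,
        intersection_genes=intersection,
        expected_final=sorted(expected_final),
        expected_compound_het=compound,
        planted_decoys=decoys,
        carriers=carriers_out,
    )

    # --- emit files -------------------------------------------------------
    files: dict[str, Path] = dict(vcf_paths)
    ped_individuals = tuple(
        Individual(
            individual_id=m.individual_id,
            family_id=ped.family_id,
            father_id=m.father_id,
            mother_id=m.mother_id,
            sex=m.sex,
            affected=m.affected,
        )
        for ped in config.pedigrees
        for m in ped.members
    )
    write_ped(Pedigree(individuals=ped_individuals), out / "families.ped")
    write_gene_models(
        sorted(models.values(), key=lambda m: m.gene_symbol), out / "genes.tsv"
    )
    write_known_set(KnownVariantSet(keys=frozenset(known_keys)), out / "known.tsv")
    write_expression(matrix, out / "expr.tsv", out / "groups.tsv")
    write_gmt(sets, out / "sets.gmt")
    (out / "universe.txt").write_text("\n".join(gene_list) + "\n")
    _write_serology(config, out / "serology.tsv")
    truth.to_json(out / "ground_truth.json")
    files.update(
        ped=out / "families.ped",
        gene_models=out / "genes.tsv",
        known=out / "known.tsv",
        expression=out / "expr.tsv",
        groups=out / "groups.tsv",
        gmt=out / "sets.gmt",
        universe=out / "universe.txt",
        serology=out / "serology.tsv",
        ground_truth=out / "ground_truth.json",
    )
    run_config = {
        "vcf": {fam: str(p.name) for fam, p in vcf_paths.items()},
        "ped": "families.ped",
        "gene_models": "genes.tsv",
        "known": "known.tsv",
        "expression": "expr.tsv",
        "groups": "groups.tsv",
        "gmt": "sets.gmt",
        "universe": "universe.txt",
        "params": {},
        "seed": config.seed,
    }
    (out / "run.yaml").write_text(yaml.safe_dump(run_config, sort_keys=True))
    files["run_config"] = out / "run.yaml"
    return files, truth


def _write_serology(config: ScenarioConfig, path: Path) -> None:
    records = []
    for ped in config.pedigrees:
        for m in ped.members:
            if m.affected is True:
                sige = {"Der f": 5.2, "Der p": 4.1}
                total = 180.0
            else:
                sige = {"Der f": 0.12, "Der p": 0.2}
                total = 40.0
            records.append(
                SerologyRecord(
                    subject_id=m.individual_id,
                    specific_ige=sige,
                    total_ige=total,
                )
            )
    write_serology(records, path)


# ---------------------------------------------------------------------------
# The packaged paper-style scenario
# ---------------------------------------------------------------------------

def _nuclear_family(fam: str) -> PedigreeSpec:
    return PedigreeSpec(
        family_id=fam,
        members=(
            MemberSpec(f"{fam}_FATHER", None, None, "1", False),
            MemberSpec(f"{fam}_MOTHER", None, None, "2", True),
            MemberSpec(
                f"{fam}_CHILD", f"{fam}_FATHER", f"{fam}_MOTHER", "1", True
            ),
        ),
    )


def _extended_family4() -> PedigreeSpec:
    """12-member extended pedigree with 6 affected members."""
    return PedigreeSpec(
        family_id="F4",
        members=(
            MemberSpec("I-1", None, None, "1", False),
            MemberSpec("I-2", None, None, "2", False),
            MemberSpec("II-3", "I-1", "I-2", "2", True),
            MemberSpec("II-4", None, None, "1", False),
            MemberSpec("II-8", "I-1", "I-2", "1", True),
            MemberSpec("II-9", None, None, "2", True),
            MemberSpec("III-2", "II-4", "II-3", "1", False),
            MemberSpec("III-3", "II-4", "II-3", "2", True),
            MemberSpec("III-6", "II-8", "II-9", "2", False),
            MemberSpec("III-7", "II-8", "II-9", "1", True),
            MemberSpec("III-8", "II-8", "II-9", "2", True),
            MemberSpec("III-9", "II-8", "II-9", "1", False),
        ),
    )


_TOLERATED = {"sift": "tolerated", "polyphen2": "benign"}
_DAMAGING3 = {
    "sift": "tolerated",
    "polyphen2": "damaging",
    "phylop": "conserved",
    "mutation_taster": "disease_causing",
}
_FLT1_CALLS = {
    "sift": "tolerated",
    "polyphen2": "damaging",
    "phylop": "conserved",
    "mutation_taster": "polymorphism",
}


def paper_scenario_config(seed: int = 42) -> ScenarioConfig:
    """The packaged four-family preset with planted causal variants.

    Three causal variants (FLT1 CDS-603 A>T in family 1; VEGFB CDS-322 A>C
    and ITGA2 c.502+1G>A in family 4), three cross-family decoy genes
    (KCNG4 and NCOA6 in families 1+4, KIAA1217 in families 2+3, five
    missense variants in all), 19 DE filler candidate genes and 3 non-DE
    extra candidates (so candidate genes ∩ DE genes has exactly 22 genes),
    1117 planted DE genes, and assorted quality/novelty/segregation decoys.
    """
    pedigrees = (
        _nuclear_family("F1"),
        _nuclear_family("F2"),
        _nuclear_family("F3"),
        _extended_family4(),
    )
    genes: list[GeneSpec] = [
        GeneSpec("FLT1", "chr13", 29_000_001, 260),
        GeneSpec("VEGFB", "chr11", 64_000_001, 140),
        GeneSpec("ITGA2", "chr5", 52_300_001, 240, exon1_cds_len=502),
        GeneSpec("KCNG4", "chr16", 84_000_001, 180),
        GeneSpec("NCOA6", "chr20", 33_200_001, 300, exon1_cds_len=601),
        GeneSpec("KIAA1217", "chr10", 23_900_001, 220),
        GeneSpec("SPARE01", "chr2", 110_001, 150),
        GeneSpec("SPARE02", "chr2", 410_001, 150, strand="-"),
    ]
    fillers = [f"CAND{i:02d}" for i in range(1, 20)]
    extras = [f"EXTRA{i:02d}" for i in range(1, 4)]
    pos = 100_001
    for i, symbol in enumerate(fillers + extras):
        chrom = f"chr{(i % 4) + 1}"
        strand = "-" if i % 5 == 0 else "+"
        genes.append(
            GeneSpec(symbol, chrom, pos + 40_000 * (i // 4), 120, strand=strand)
        )
        if i % 4 == 3:
            pos += 3_000
    gene_specs = tuple(genes)

    planted: list[PlantSpec] = []

    def sub(
        fam: str,
        gene: str,
        residue: int,
        carriers: Mapping[str, str],
        role: str,
        predictor_calls: Mapping[str, str] = _TOLERATED,
        **overrides,
    ) -> PlantSpec:
        # pinned AAA codon, first base A>C: K -> Q, always nonsynonymous
        return PlantSpec(
            family_id=fam,
            gene=gene,
            kind="sub",
            cds_pos=3 * residue - 2,
            coding_ref_codon="AAA",
            coding_alt="C",
            genotypes=carriers,
            role=role,
            predictor_calls=predictor_calls,
            **overrides,
        )

    def pair(fam: str) -> dict[str, str]:
        return {f"{fam}_MOTHER": "het", f"{fam}_CHILD": "het"}

    # causal variants (Table-2-style carriers)
    planted.append(
        PlantSpec(
            family_id="F1",
            gene="FLT1",
            kind="sub",
            cds_pos=603,
            coding_ref_codon="GAA",
            coding_alt="T",
            genotypes=pair("F1"),
            role="causal",
            predictor_calls=_FLT1_CALLS,
        )
    )
    planted.append(
        PlantSpec(
            family_id="F4",
            gene="VEGFB",
            kind="sub",
            cds_pos=322,
            coding_ref_codon="AGC",
            coding_alt="C",
            genotypes={"II-9": "het", "III-7": "het"},
            role="causal",
            predictor_calls=_DAMAGING3,
        )
    )
    planted.append(
        PlantSpec(
            family_id="F4",
            gene="ITGA2",
            kind="splice",
            cds_pos=502,
            coding_ref_codon=None,
            splice_offset=1,
            coding_alt="A",
            genotypes={
                "I-2": "het",
                "II-3": "het",
                "II-8": "het",
                "III-3": "het",
                "III-7": "het",
                "III-8": "het",
            },
            role="causal",
            predictor_calls={"mutation_taster": "disease_causing"},
        )
    )

    # cross-family decoy genes: five missense variants in three genes
    planted.append(sub("F1", "KCNG4", 40, pair("F1"), "decoy_crossfam"))
    planted.append(
        sub("F4", "KCNG4", 77, {"II-9": "het", "III-8": "het"}, "decoy_crossfam")
    )
    planted.append(sub("F1", "NCOA6", 120, pair("F1"), "decoy_crossfam"))
    planted.append(
        sub("F4", "NCOA6", 33, {"II-9": "het", "III-7": "het"}, "decoy_crossfam")
    )
    planted.append(sub("F2", "KIAA1217", 90, pair("F2"), "decoy_crossfam"))
    planted.append(sub("F3", "KIAA1217", 90, pair("F3"), "decoy_crossfam"))

    # DE filler candidates: one family each, fail the consensus vote
    fam_cycle = ["F1", "F2", "F3", "F4"]
    for i, gene in enumerate(fillers):
        fam = fam_cycle[i % 4]
        carriers = (
            pair(fam) if fam != "F4" else {"II-9": "het", "III-7": "het"}
        )
        planted.append(sub(fam, gene, 30 + i, carriers, "filler"))
    # candidates outside the DE list
    planted.append(sub("F2", "EXTRA01", 25, pair("F2"), "extra"))
    planted.append(sub("F3", "EXTRA02", 26, pair("F3"), "extra"))
    planted.append(
        sub("F4", "EXTRA03", 27, {"II-9": "het", "III-8": "het"}, "extra")
    )

    # decoys removed by specific stages
    for residue in (50, 51, 52):  # 3 variants inside 10 bp
        planted.append(sub("F1", "SPARE01", residue, pair("F1"), "cluster"))
    planted.append(
        sub("F2", "SPARE02", 60, pair("F2"), "lowqual_dp", depth_override=4)
    )
    planted.append(
        sub("F3", "SPARE01", 70, pair("F3"), "lowqual_gq", gq_override=20.0)
    )
    planted.append(
        sub(
            "F4",
            "SPARE02",
            80,
            {"II-9": "het", "III-7": "het"},
            "lowqual_mq",
            mq_override=20.0,
        )
    )
    planted.append(sub("F3", "SPARE02", 90, pair("F3"), "known", in_known_set=True))
    planted.append(
        sub(
            "F4",
            "SPARE02",
            95,
            {"II-9": "het", "III-7": "het"},
            "known",
            in_known_set=True,
        )
    )
    # transmitted but not shared by any affected pair
    planted.append(sub("F1", "SPARE01", 100, {"F1_FATHER": "het"}, "nonseg"))
    planted.append(sub("F2", "SPARE01", 105, {"F2_MOTHER": "het"}, "nonseg"))
    # hom-alt parent fails the strict heterozygous sharing rule
    # (children of a hom-alt mother are obligate carriers)
    planted.append(
        sub(
            "F4",
            "SPARE01",
            110,
            {
                "II-9": "hom",
                "III-6": "het",
                "III-7": "het",
                "III-8": "het",
                "III-9": "het",
            },
            "homalt_parent",
        )
    )

    # expression: 1117 DE genes = 3 causal + 19 fillers + 1095 extras
    deg_extra = tuple(f"DEGN{i:04d}" for i in range(1, 1096))
    padding = tuple(f"PAD{i:02d}" for i in range(1, 23))
    gene_sets = {
        "FOCAL_ADHESION": ("ITGA2", "FLT1", "VEGFB") + padding,
        "CHANNEL_PATHWAY": ("KCNG4", "NCOA6", "KIAA1217", "SPARE01", "SPARE02")
        + tuple(f"GENE{i:05d}" for i in range(40, 55)),
        "HOUSEKEEPING": tuple(f"GENE{i:05d}" for i in range(100, 140)),
    }
    return ScenarioConfig(
        seed=seed,
        pedigrees=pedigrees,
        genes=gene_specs,
        planted=tuple(planted),
        deg_extra_genes=deg_extra,
        gene_sets=gene_sets,
        n_background_variants=200,
        known_db_coverage=0.95,
        n_genes_expression=20_000,
        deg_shift=100.0,
        within_group_sd=0.1,
        n_cases=7,
        n_controls=5,
        candidate_deg_overlap=22,
    )


def bundle_digests(files: Mapping[str, Path]) -> dict[str, str]:
    """SHA-256 digest per emitted file (determinism checks)."""
    return {
        name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
        for name, p in sorted(files.items())
    }
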