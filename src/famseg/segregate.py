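"""Pedigree-aware filtering: novelty, co-segregation, cross-family sharing.

The family-study cascade retains heterozygous NS/SS/I variants that are
absent from the known-variant databases and shared by at least one affected
parent-child pair, then asks which genes carry qualifying variants in two
or more families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .annotate import Consequence, is_nssi
from .formats import ContractError, KnownVariantSet, Pedigree, Variant


@dataclass(frozen=True)
class FamilyCandidates:
    """Per-family cascade output: counts, co-segregating variants, genes."""

    family_id: str
    per_individual_nssi_counts: Mapping[str, int]
    shared_variants: tuple[tuple[Variant, Consequence], ...]
    shared_genes: frozenset[str]

    def __post_init__(self) -> None:
        genes = {c.gene_symbol for _, c in self.shared_variants}
        if not genes <= set(self.shared_genes):
            raise ValueError("shared variant gene missing from shared_genes")
        if any(n < 0 for n in self.per_individual_nssi_counts.values()):
            raise ValueError("negative NS/SS/I count")


@dataclass(frozen=True)
class CrossFamilyResult:
    """Gene -> families carrying a qualifying variant; genes in >= 2 families."""

    gene_families: Mapping[str, frozenset[str]]
    selected_genes: frozenset[str]

    def __post_init__(self) -> None:
        for gene in self.selected_genes:
            if len(self.gene_families.get(gene, frozenset())) < 2:
                raise ValueError(f"selected gene {gene} seen in < 2 families")


def filter_known(
    variants: Sequence[Variant], known: KnownVariantSet
) -> tuple[list[Variant], list[Variant]]:
    """Partition variants into (novel, known_hits) by exact-key membership."""
    novel = [v for v in variants if v.key not in known.keys]
    hits = [v for v in variants if v.key in known.keys]
    return novel, hits


def affected_pair_shared(
    variants: Sequence[Variant],
    pedigree: Pedigree,
    family_id: str,
    allow_hom: bool = False,
) -> list[Variant]:
    """Variants heterozygous in both members of >= 1 affected parent-child pair.

    Unaffected carriers elsewhere in the family do not disqualify a variant
    at this stage. With ``allow_hom`` the carrier test relaxes to "carries
    at least one alt allele" instead of strictly heterozygous.
    """
    pairs = pedigree.affected_parent_child_pairs(family_id)
    if not pairs:
        raise ContractError(
            f"family {family_id!r} has no affected parent-child pair"
        )
    out = []
    for v in variants:
        by_sample = {g.sample_id: g for g in v.genotypes}
        for parent_id, child_id in pairs:
            gp = by_sample.get(parent_id)
            gc = by_sample.get(child_id)
            if gp is None or gc is None:
                continue
            if allow_hom:
                ok = gp.carries(v.alt) and gc.carries(v.alt)
            else:
                ok = gp.is_het(v.ref, v.alt) and gc.is_het(v.ref, v.alt)
            if ok:
                out.append(v)
                break
    return out


def count_nssi(
    variants: Sequence[Variant],
    consequences: Mapping[tuple[str, int, str, str], Consequence],
    individual_id: str,
) -> int:
    """NS/SS/I variants carried (>= 1 alt allele) by one individual."""
    found = False
    count = 0
    for v in variants:
        try:
            g = v.genotype(individual_id)
        except KeyError:
            continue
        found = True
        if g.carries(v.alt) and is_nssi(consequences[v.key]):
            count += 1
    if not found:
        raise KeyError(f"individual {individual_id!r} absent from all variants")
    return count


def cross_family_genes(
    per_family: Sequence[FamilyCandidates], min_families: int = 2
) -> CrossFamilyResult:
    """Genes whose qualifying variants occur in >= ``min_families`` families."""
    gene_families: dict[str, set[str]] = {}
    for fam in per_family:
        for gene in fam.shared_genes:
            gene_families.setdefault(gene, set()).add(fam.family_id)
    frozen = {g: frozenset(fams) for g, fams in gene_families.items()}
    selected = frozenset(
        g for g, fams in frozen.items() if len(fams) >= min_families
    )
    return CrossFamilyResult(gene_families=frozen, selected_genes=selected)


def family_candidates(
    variants: Sequence[Variant],
    consequences: Mapping[tuple[str, int, str, str], Consequence],
    pedigree: Pedigree,
    family_id: str,
    allow_hom: bool = False,
) -> FamilyCandidates:
    """Assemble the per-family cascade product.

    ``variants`` must already be quality-filtered and novelty-filtered;
    NS/SS/I selection and affected-pair sharing are applied here, and
    per-individual NS/SS/I tallies are computed over the NS/SS/I variants.
    """
    nssi = [v for v in variants if is_nssi(consequences[v.key])]
    counts = {}
    for ind in pedigree.members(family_id):
        try:
            counts[ind.individual_id] = count_nssi(
                nssi, consequences, ind.individual_id
            )
        except KeyError:
            counts[ind.individual_id] = 0  # not a sequenced sample
    shared = affected_pair_shared(nssi, pedigree, family_id, allow_hom=allow_hom)
    pairs = tuple((v, consequences[v.key]) for v in shared)
    genes = frozenset(c.gene_symbol for _, c in pairs)
    return FamilyCandidates(
        family_id=family_id,
        per_individual_nssi_counts=counts,
        shared_variants=pairs,
        shared_genes=genes,
    )
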