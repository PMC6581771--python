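"""Conjoint prioritization: DEG intersection, gene-set enrichment,
predictor consensus, compound-heterozygote flagging and the final report.

The final candidate set is the conjunction of independent evidence lines:
a variant must co-segregate in an affected parent-child pair, its gene must
be differentially expressed and sit in a significantly enriched gene set,
and it must carry functional support (predictor consensus for missense
substitutions; splice-site, frameshift and stop-gain variants qualify by
category). Each conjunct is independently switchable for ablation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .annotate import Consequence, predictor_consensus
from .expression import bh_adjust
from .formats import (
    FilterParams,
    GeneSetCollection,
    ValidationError,
    Variant,
)
from .segregate import FamilyCandidates

#: categories with intrinsic functional support, exempt from the
#: missense-predictor consensus vote
_LOF_CATEGORIES = frozenset(
    {"splice_donor", "splice_acceptor", "frameshift_indel", "stop_gained"}
)


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene set's over-representation test."""

    set_name: str
    k: int  # hits in query
    n: int  # query size
    K: int  # set size within background
    N: int  # background size
    p_value: float
    q_value: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K) and self.n <= self.N and self.K <= self.N):
            raise ValidationError(
                f"inconsistent counts for {self.set_name}: "
                f"k={self.k} n={self.n} K={self.K} N={self.N}"
            )


@dataclass(frozen=True)
class ReportEntry:
    family_id: str
    variant: Variant
    gene_symbol: str
    consequence: Consequence
    consensus_damaging: bool
    in_deg_set: bool
    enriched_sets: tuple[str, ...]


@dataclass(frozen=True)
class CandidateReport:
    """Final prioritized variants with carriers and compound-het flags."""

    entries: tuple[ReportEntry, ...]
    carriers: Mapping[tuple[str, int, str, str], tuple[tuple[str, str], ...]]
    compound_het_carriers: tuple[
        tuple[str, tuple[tuple[tuple[str, int, str, str], tuple[str, int, str, str]], ...]],
        ...,
    ]

    def variant_keys(self) -> list[tuple[str, int, str, str]]:
        seen: list[tuple[str, int, str, str]] = []
        for e in self.entries:
            if e.variant.key not in seen:
                seen.append(e.variant.key)
        return seen


def intersect_genes(candidate_genes: set[str], deg_genes: set[str]) -> set[str]:
    """Exact intersection of the WGS candidate genes with the DEG list."""
    return set(candidate_genes) & set(deg_genes)


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: Iterable[str],
    sets: GeneSetCollection,
    background: Iterable[str] | None = None,
    ease: bool = True,
) -> list[EnrichmentResult]:
    """One-tailed over-representation test per gene set, BH-adjusted.

    The plain statistic is the hypergeometric tail P(X >= k) over a
    background universe of N genes with K set members and an n-gene query.
    With ``ease`` the conservative EASE variant discounts one hit:
    p = P(X >= k-1), and p = 1 whenever k <= 1. Every set is intersected
    with the background before testing; results sorted by p then name.
    """
    if background is None:
        background = sets.background
    if background is None:
        raise ValidationError("no background universe given")
    bg = set(background)
    if not bg:
        raise ValidationError("empty background universe")
    query_set = set(query)
    offenders = sorted(query_set - bg)
    if offenders:
        raise ValidationError(
            f"query genes outside the background: {offenders[:10]}"
        )
    N = len(bg)
    n = len(query_set)
    results = []
    for name, genes in sets.sets.items():
        members = set(genes) & bg
        K = len(members)
        k = len(query_set & members)
        if ease:
            p = 1.0 if k <= 1 else hypergeom_tail(k - 1, N, K, n)
        else:
            p = hypergeom_tail(k, N, K, n)
        results.append(
            EnrichmentResult(set_name=name, k=k, n=n, K=K, N=N, p_value=p)
        )
    qs = bh_adjust([r.p_value for r in results])
    results = [
        EnrichmentResult(
            set_name=r.set_name,
            k=r.k,
            n=r.n,
            K=r.K,
            N=r.N,
            p_value=r.p_value,
            q_value=q,
        )
        for r, q in zip(results, qs)
    ]
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results


def compound_het(
    report_variants: Sequence[Variant],
) -> list[tuple[str, list[tuple[tuple[str, int, str, str], tuple[str, int, str, str]]]]]:
    """Individuals heterozygous for >= 2 distinct report variants.

    Phase is ignored (any gene pair counts); all carried pairs are listed
    in (chrom, pos) order.
    """
    carried: dict[str, list[Variant]] = {}
    seen_keys: set[tuple[str, int, str, str]] = set()
    for v in sorted(report_variants, key=lambda v: (v.chrom, v.pos, v.alt)):
        if v.key in seen_keys:
            continue
        seen_keys.add(v.key)
        for g in v.genotypes:
            if g.is_het(v.ref, v.alt):
                carried.setdefault(g.sample_id, []).append(v)
    out = []
    for sample_id in sorted(carried):
        variants = carried[sample_id]
        if len(variants) >= 2:
            pairs = [
                (a.key, b.key) for a, b in itertools.combinations(variants, 2)
            ]
            out.append((sample_id, pairs))
    return out


def _qualifies_consensus(
    variant: Variant, consequence: Consequence, min_votes: int
) -> bool:
    if consequence.category in _LOF_CATEGORIES:
        return True
    return predictor_consensus(variant, min_votes)


def build_report(
    per_family: Sequence[FamilyCandidates],
    deg_genes: set[str],
    enrichments: Sequence[EnrichmentResult],
    gene_sets: GeneSetCollection,
    params: FilterParams,
    require_deg: bool = True,
    require_enriched: bool = True,
    require_consensus: bool = True,
) -> CandidateReport:
    """Final report: segregation candidates surviving every evidence line.

    A candidate variant is reported iff its gene is in the DEG set, its
    gene belongs to >= 1 enriched gene set (q <= enrich_alpha), and it
    passes the functional-support rule. Entries are ordered by
    (family, chrom, pos); carriers and compound heterozygotes attached.
    """
    sig_sets = {
        e.set_name for e in enrichments if e.q_value <= params.enrich_alpha
    }
    entries = []
    for fam in sorted(per_family, key=lambda f: f.family_id):
        for variant, consequence in sorted(
            fam.shared_variants,
            key=lambda vc: (vc[0].chrom, vc[0].pos, vc[0].alt),
        ):
            gene = consequence.gene_symbol
            in_deg = gene in deg_genes
            member_sets = tuple(
                sorted(
                    name
                    for name in sig_sets
                    if gene in gene_sets.sets.get(name, ())
                )
            )
            consensus = _qualifies_consensus(
                variant, consequence, params.damaging_min_votes
            )
            if require_deg and not in_deg:
                continue
            if require_enriched and not member_sets:
                continue
            if require_consensus and not consensus:
                continue
            entries.append(
                ReportEntry(
                    family_id=fam.family_id,
                    variant=variant,
                    gene_symbol=gene,
                    consequence=consequence,
                    consensus_damaging=consensus,
                    in_deg_set=in_deg,
                    enriched_sets=member_sets,
                )
            )
    carriers = {}
    report_variants = []
    for e in entries:
        if e.variant.key in carriers:
            continue
        report_variants.append(e.variant)
        carriers[e.variant.key] = tuple(
            (g.sample_id, "/".join(sorted("0" if a == e.variant.ref else "1" for a in g.alleles)))
            for g in e.variant.genotypes
            if g.carries(e.variant.alt)
        )
    chets = tuple(
        (sid, tuple(pairs)) for sid, pairs in compound_het(report_variants)
    )
    return CandidateReport(
        entries=tuple(entries), carriers=carriers, compound_het_carriers=chets
    )
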