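"""Typed containers and plain-text readers/writers for the pipeline's formats.

Covers the restricted VCF v4.2 dialect used by family studies (GT:DP:GQ
genotype fields, site-level MQ, optional pathogenicity-predictor INFO keys),
6-column PED pedigrees, tab-separated gene models with spliced CDS sequence,
GMT gene sets, a gene-by-sample expression matrix with a two-group sidecar,
and a known-variant exclusion list standing in for dbSNP/1000 Genomes.

Coordinates are 1-based and fully closed throughout (VCF/HGVS convention).
Genotype phase is ignored: ``0|1`` and ``0/1`` are the same call.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

MISSING = None

#: INFO key on disk -> canonical predictor name
PREDICTOR_KEYS = {
    "SIFT": "sift",
    "POLYPHEN": "polyphen2",
    "PHYLOP": "phylop",
    "MTASTER": "mutation_taster",
}
_PREDICTOR_KEYS_INV = {v: k for k, v in PREDICTOR_KEYS.items()}

#: categorical calls counted as deleterious by the consensus vote
DELETERIOUS_CALLS = frozenset({"damaging", "conserved", "disease_causing"})

_ALLELE_RE = re.compile(r"^[ACGT]+$")


class FormatError(ValueError):
    """Malformed input file (names the offending line where possible)."""


class ValidationError(ValueError):
    """An object violates a domain invariant."""


class ContractError(ValueError):
    """An operation was called outside its stated precondition."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeCall:
    """One sample's unphased diploid call at a site.

    ``alleles`` holds the two allele strings (ref or alt sequence), or
    ``(None, None)`` for a missing genotype. ``depth``/``gq`` are the
    per-genotype DP and GQ fields; ``None`` when the caller omitted them.
    """

    sample_id: str
    alleles: tuple[str | None, str | None]
    depth: int | None = None
    gq: float | None = None

    @property
    def is_missing(self) -> bool:
        return self.alleles[0] is None and self.alleles[1] is None

    def is_het(self, ref: str, alt: str) -> bool:
        return set(self.alleles) == {ref, alt}

    def is_hom(self, allele: str) -> bool:
        return self.alleles == (allele, allele)

    def carries(self, alt: str) -> bool:
        return alt in self.alleles


@dataclass(frozen=True)
class Variant:
    """One site+allele with per-sample genotypes; the atom of the cascade.

    Multi-allelic source records are split upstream so every Variant has
    exactly one alt. ``site_mq`` is the site-level mapping quality (INFO MQ);
    ``predictor_calls`` maps predictor name (``sift``, ``polyphen2``,
    ``phylop``, ``mutation_taster``) to its categorical call.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    site_mq: float | None = None
    predictor_calls: Mapping[str, str] = field(default_factory=dict)
    genotypes: tuple[GenotypeCall, ...] = ()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        for allele, label in ((self.ref, "ref"), (self.alt, "alt")):
            if not allele or not _ALLELE_RE.match(allele):
                raise ValidationError(
                    f"{label} allele {allele!r} at {self.chrom}:{self.pos} "
                    "is not a nonempty A/C/G/T string"
                )
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt at {self.chrom}:{self.pos}")
        ids = [g.sample_id for g in self.genotypes]
        if len(ids) != len(set(ids)):
            raise ValidationError(
                f"duplicate sample ids in genotypes at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def genotype(self, sample_id: str) -> GenotypeCall:
        for g in self.genotypes:
            if g.sample_id == sample_id:
                return g
        raise KeyError(sample_id)

    def sample_ids(self) -> list[str]:
        return [g.sample_id for g in self.genotypes]


@dataclass(frozen=True)
class Individual:
    individual_id: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "1" male, "2" female, "0" unknown
    affected: bool | None  # None = unknown phenotype


@dataclass(frozen=True)
class Pedigree:
    """Family graph; affection status drives the segregation logic."""

    individuals: tuple[Individual, ...] = ()

    def __post_init__(self) -> None:
        by_id: dict[str, Individual] = {}
        for ind in self.individuals:
            if ind.individual_id in by_id:
                raise ValidationError(f"duplicate individual {ind.individual_id}")
            by_id[ind.individual_id] = ind
        for ind in self.individuals:
            for pid in (ind.father_id, ind.mother_id):
                if pid is None:
                    continue
                if pid not in by_id:
                    raise ValidationError(
                        f"dangling parent id {pid!r} for {ind.individual_id}"
                    )
                if by_id[pid].family_id != ind.family_id:
                    raise ValidationError(
                        f"parent {pid} of {ind.individual_id} is in a "
                        "different family"
                    )
        # acyclicity: no individual may appear among its own ancestors
        for ind in self.individuals:
            seen: set[str] = set()
            stack = [p for p in (ind.father_id, ind.mother_id) if p]
            while stack:
                cur = stack.pop()
                if cur == ind.individual_id:
                    raise ValidationError(
                        f"{ind.individual_id} is its own ancestor"
                    )
                if cur in seen:
                    continue
                seen.add(cur)
                node = by_id[cur]
                stack.extend(p for p in (node.father_id, node.mother_id) if p)

    def __len__(self) -> int:
        return len(self.individuals)

    def by_id(self) -> dict[str, Individual]:
        return {i.individual_id: i for i in self.individuals}

    def family_ids(self) -> list[str]:
        seen: list[str] = []
        for i in self.individuals:
            if i.family_id not in seen:
                seen.append(i.family_id)
        return seen

    def members(self, family_id: str) -> list[Individual]:
        return [i for i in self.individuals if i.family_id == family_id]

    def affected_members(self, family_id: str) -> list[Individual]:
        return [i for i in self.members(family_id) if i.affected is True]

    def affected_parent_child_pairs(
        self, family_id: str
    ) -> list[tuple[str, str]]:
        """(parent_id, child_id) pairs with both members affected."""
        pairs = []
        for child in self.members(family_id):
            if child.affected is not True:
                continue
            by = self.by_id()
            for pid in (child.father_id, child.mother_id):
                if pid and by[pid].affected is True:
                    pairs.append((pid, child.individual_id))
        return pairs


@dataclass(frozen=True)
class GeneModel:
    """Minimal transcript: exons + CDS bounds + spliced CDS sequence.

    ``exons`` are 1-based closed genomic intervals sorted by coordinate.
    ``cds_sequence`` is the coding-strand spliced CDS (translation order),
    which anchors codon lookups and reference-allele checks.
    """

    gene_symbol: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    cds_sequence: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_symbol}: bad strand {self.strand!r}")
        prev_end = 0
        for start, end in self.exons:
            if start <= prev_end:
                raise ValidationError(
                    f"{self.gene_symbol}: exons overlap or are unsorted"
                )
            if end < start:
                raise ValidationError(f"{self.gene_symbol}: exon end < start")
            prev_end = end
        if self.cds_start > self.cds_end:
            raise ValidationError(f"{self.gene_symbol}: cds_start > cds_end")
        n = self.cds_length
        if n <= 0 or n % 3 != 0:
            raise ValidationError(
                f"{self.gene_symbol}: CDS length {n} is not a positive "
                "multiple of 3"
            )
        if len(self.cds_sequence) != n:
            raise ValidationError(
                f"{self.gene_symbol}: cds_sequence length "
                f"{len(self.cds_sequence)} != CDS length {n}"
            )
        if not _ALLELE_RE.match(self.cds_sequence):
            raise ValidationError(f"{self.gene_symbol}: cds_sequence not ACGT")

    @property
    def cds_length(self) -> int:
        return sum(
            max(0, min(end, self.cds_end) - max(start, self.cds_start) + 1)
            for start, end in self.exons
        )

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    def coding_positions(self) -> list[int]:
        """Genomic positions of CDS bases in translation order."""
        pos = [
            p
            for start, end in self.exons
            for p in range(max(start, self.cds_start), min(end, self.cds_end) + 1)
        ]
        return pos if self.strand == "+" else pos[::-1]


@dataclass(frozen=True)
class KnownVariantSet:
    """Exact-key membership set for (chrom, pos, ref, alt)."""

    keys: frozenset[tuple[str, int, str, str]] = frozenset()

    def __contains__(self, item: Variant | tuple[str, int, str, str]) -> bool:
        key = item.key if isinstance(item, Variant) else item
        return key in self.keys

    def __len__(self) -> int:
        return len(self.keys)


@dataclass
class ExpressionMatrix:
    """Genes x samples log2-scale intensities with two-group labels."""

    values: pd.DataFrame  # index = gene symbols, columns = sample ids
    group_labels: dict[str, str]  # sample_id -> "case" | "control"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate gene in matrix: {dup}")
        if set(self.values.columns) != set(self.group_labels):
            raise ValidationError("sample ids and group labels disagree")
        bad = set(self.group_labels.values()) - {"case", "control"}
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        for grp in ("case", "control"):
            if len(self.samples_in(grp)) < 2:
                raise ValidationError(f"group {grp!r} has < 2 samples")

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group_labels[s] == group]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (GMT) with an optional explicit background universe."""

    sets: Mapping[str, tuple[str, ...]]
    background: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"empty gene set {name!r}")
            if len(genes) != len(set(genes)):
                raise ValidationError(f"duplicate genes in set {name!r}")


@dataclass
class FilterParams:
    """Thresholds of the filtering cascade; defaults follow the study design.

    Quality exclusions: >= ``cluster_min_count`` variants within
    ``cluster_window_bp``; depth < ``min_depth``; site mapping quality
    < ``min_site_mq``; genotype quality < ``min_gq`` (all strict "less than"
    exclusions, so a value at the threshold is retained).
    """

    cluster_window_bp: int = 10
    cluster_min_count: int = 3
    min_depth: int = 5
    min_site_mq: float = 30.0
    min_gq: float = 30.0
    deg_fdr: float = 0.05
    deg_min_abs_log2fc: float = 1.0
    enrich_alpha: float = 0.05
    ease_mode: bool = True
    damaging_min_votes: int = 2
    allow_hom: bool = False

    def __post_init__(self) -> None:
        for name in (
            "cluster_window_bp",
            "cluster_min_count",
            "min_depth",
            "min_site_mq",
            "min_gq",
            "deg_fdr",
            "deg_min_abs_log2fc",
            "enrich_alpha",
            "damaging_min_votes",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.cluster_min_count < 2:
            raise ValidationError("cluster_min_count must be >= 2")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "FilterParams":
        known = {k: v for k, v in mapping.items() if k in cls.__dataclass_fields__}
        unknown = set(mapping) - set(known)
        if unknown:
            raise ValidationError(f"unknown parameters: {sorted(unknown)}")
        return cls(**known)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_COLUMNS = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]


def _parse_info(text: str) -> dict[str, str]:
    if text in (".", ""):
        return {}
    out = {}
    for item in text.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
        else:
            out[item] = ""
    return out


def read_vcf(path: str | Path) -> list[Variant]:
    """Read a VCF v4.2 text file into split, sorted :class:`Variant` records.

    Multi-allelic records are split one alt per Variant; genotype allele
    indices are remapped per split (the matching alt keeps its allele, any
    other non-reference allele is treated as reference for that split).
    Output is sorted by (chrom, pos, alt).
    """
    path = Path(path)
    samples: list[str] | None = None
    variants: list[Variant] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if cols[:8] != _VCF_COLUMNS:
                    raise FormatError(
                        f"{path}:{lineno}: malformed #CHROM header"
                    )
                if len(cols) > 8 and cols[8] != "FORMAT":
                    raise FormatError(f"{path}:{lineno}: expected FORMAT column")
                samples = cols[9:]
                continue
            if samples is None:
                raise FormatError(f"{path}:{lineno}: data before #CHROM header")
            fields = line.split("\t")
            expected = 8 if not samples else 9 + len(samples)
            if len(fields) != expected:
                raise FormatError(
                    f"{path}:{lineno}: ragged row ({len(fields)} fields, "
                    f"expected {expected})"
                )
            chrom, pos_s, _id, ref, alt_s = fields[:5]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad POS {pos_s!r}") from exc
            info = _parse_info(fields[7])
            site_mq = float(info["MQ"]) if "MQ" in info else None
            predictor_calls = {
                canon: info[key]
                for key, canon in PREDICTOR_KEYS.items()
                if key in info
            }
            alts = alt_s.split(",")
            gt_parts: list[dict[str, str]] = []
            if samples:
                fmt = fields[8].split(":")
                if "GT" not in fmt:
                    raise FormatError(
                        f"{path}:{lineno}: FORMAT is missing the GT field"
                    )
                for cell in fields[9:]:
                    vals = cell.split(":")
                    gt_parts.append(
                        {k: v for k, v in zip(fmt, vals)}
                    )
            for alt_index, alt in enumerate(alts, start=1):
                genotypes = []
                for sample_id, part in zip(samples, gt_parts):
                    gt = part.get("GT", ".")
                    allele_idx = re.split(r"[/|]", gt)
                    alleles: list[str | None] = []
                    for a in allele_idx:
                        if a == "." or a == "":
                            alleles.append(None)
                        elif int(a) == alt_index:
                            alleles.append(alt)
                        else:
                            alleles.append(ref)
                    if len(alleles) == 1:  # haploid call; duplicate
                        alleles = alleles * 2
                    dp_s = part.get("DP", ".")
                    gq_s = part.get("GQ", ".")
                    genotypes.append(
                        GenotypeCall(
                            sample_id=sample_id,
                            alleles=(alleles[0], alleles[1]),
                            depth=int(dp_s) if dp_s not in (".", "") else None,
                            gq=float(gq_s) if gq_s not in (".", "") else None,
                        )
                    )
                try:
                    variants.append(
                        Variant(
                            chrom=chrom,
                            pos=pos,
                            ref=ref,
                            alt=alt,
                            site_mq=site_mq,
                            predictor_calls=predictor_calls,
                            genotypes=tuple(genotypes),
                        )
                    )
                except ValidationError as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from exc
    variants.sort(key=lambda v: (v.chrom, v.pos, v.alt))
    return variants


def write_vcf(
    variants: Sequence[Variant], path: str | Path, sample_ids: Sequence[str] | None = None
) -> None:
    """Write split Variants as VCF v4.2 text (GT:DP:GQ, MQ + predictor INFO)."""
    path = Path(path)
    if sample_ids is None:
        sample_ids = variants[0].sample_ids() if variants else []
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    ]
    for key in PREDICTOR_KEYS:
        lines.append(
            f'##INFO=<ID={key},Number=1,Type=String,Description="Predictor call">'
        )
    header = _VCF_COLUMNS + (["FORMAT"] + list(sample_ids) if sample_ids else [])
    lines.append("\t".join(header))
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt)):
        info_items = []
        if v.site_mq is not None:
            info_items.append(f"MQ={_fmt_num(v.site_mq)}")
        for canon, call in sorted(v.predictor_calls.items()):
            info_items.append(f"{_PREDICTOR_KEYS_INV[canon]}={call}")
        info = ";".join(info_items) if info_items else "."
        row = [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", ".", info]
        if sample_ids:
            row.append("GT:DP:GQ")
            by_sample = {g.sample_id: g for g in v.genotypes}
            for sid in sample_ids:
                g = by_sample.get(sid)
                if g is None or g.is_missing:
                    gt = "./."
                else:
                    idx = sorted(0 if a == v.ref else 1 for a in g.alleles)
                    gt = f"{idx[0]}/{idx[1]}"
                dp = "." if g is None or g.depth is None else str(g.depth)
                gq = "." if g is None or g.gq is None else _fmt_num(g.gq)
                row.append(f"{gt}:{dp}:{gq}")
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

def read_ped(path: str | Path) -> Pedigree:
    """Read a 6-column PED file (2=affected, 1=unaffected, 0/-9=unknown)."""
    path = Path(path)
    individuals = []
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) != 6:
            raise FormatError(f"{path}:{lineno}: expected 6 columns, got {len(cols)}")
        fam, iid, fat, mot, sex, pheno = cols
        affected: bool | None
        if pheno == "2":
            affected = True
        elif pheno == "1":
            affected = False
        elif pheno in ("0", "-9"):
            affected = None
        else:
            raise FormatError(f"{path}:{lineno}: bad phenotype code {pheno!r}")
        individuals.append(
            Individual(
                individual_id=iid,
                family_id=fam,
                father_id=None if fat == "0" else fat,
                mother_id=None if mot == "0" else mot,
                sex=sex,
                affected=affected,
            )
        )
    return Pedigree(individuals=tuple(individuals))


def write_ped(pedigree: Pedigree, path: str | Path) -> None:
    lines = []
    for i in pedigree.individuals:
        pheno = "2" if i.affected is True else "1" if i.affected is False else "0"
        lines.append(
            "\t".join(
                [
                    i.family_id,
                    i.individual_id,
                    i.father_id or "0",
                    i.mother_id or "0",
                    i.sex,
                    pheno,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read tab-separated gene models.

    Columns: symbol, chrom, strand, exons ("start-end,start-end"),
    cds_start, cds_end, cds_sequence.
    """
    path = Path(path)
    models = []
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 7:
            raise FormatError(f"{path}:{lineno}: expected 7 columns, got {len(cols)}")
        symbol, chrom, strand, exons_s, cds_start, cds_end, seq = cols
        exons = []
        for part in exons_s.split(","):
            try:
                start_s, end_s = part.split("-")
                exons.append((int(start_s), int(end_s)))
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: bad exon interval {part!r}"
                ) from exc
        try:
            models.append(
                GeneModel(
                    gene_symbol=symbol,
                    chrom=chrom,
                    strand=strand,
                    exons=tuple(exons),
                    cds_start=int(cds_start),
                    cds_end=int(cds_end),
                    cds_sequence=seq,
                )
            )
        except ValidationError as exc:
            raise FormatError(f"{path}:{lineno}: gene {symbol}: {exc}") from exc
    return models


def write_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    lines = []
    for m in models:
        exons = ",".join(f"{s}-{e}" for s, e in m.exons)
        lines.append(
            "\t".join(
                [
                    m.gene_symbol,
                    m.chrom,
                    m.strand,
                    exons,
                    str(m.cds_start),
                    str(m.cds_end),
                    m.cds_sequence,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, background: Iterable[str] | None = None) -> GeneSetCollection:
    """Read the standard GMT dialect: name<TAB>description<TAB>genes..."""
    path = Path(path)
    sets: dict[str, tuple[str, ...]] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.rstrip()
        if not line:
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
            )
        name, _desc, *genes = cols
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set {name!r}")
        sets[name] = tuple(genes)
    return GeneSetCollection(
        sets=sets,
        background=frozenset(background) if background is not None else None,
    )


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, "na", *genes]) for name, genes in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample TSV plus a sample->group sidecar TSV."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    groups: dict[str, str] = {}
    for lineno, raw in enumerate(Path(groups_path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 2:
            raise FormatError(f"{groups_path}:{lineno}: expected 2 columns")
        groups[cols[0]] = cols[1]
    return ExpressionMatrix(values=values, group_labels=groups)


def write_expression(
    matrix: ExpressionMatrix, path: str | Path, groups_path: str | Path
) -> None:
    matrix.values.to_csv(path, sep="\t", float_format="%.6f", index_label="gene")
    lines = [f"{sid}\t{matrix.group_labels[sid]}" for sid in matrix.sample_ids]
    Path(groups_path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Known-variant list
# ---------------------------------------------------------------------------

def read_known_set(path: str | Path) -> KnownVariantSet:
    """Read a TSV of (chrom, pos, ref, alt) keys."""
    path = Path(path)
    keys = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 4:
            raise FormatError(f"{path}:{lineno}: expected 4 columns")
        chrom, pos_s, ref, alt = cols
        keys.add((chrom, int(pos_s), ref, alt))
    return KnownVariantSet(keys=frozenset(keys))


def write_known_set(known: KnownVariantSet, path: str | Path) -> None:
    lines = [
        "\t".join([c, str(p), r, a]) for c, p, r, a in sorted(known.keys)
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
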