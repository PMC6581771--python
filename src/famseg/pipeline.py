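"""End-to-end orchestration: one config file in, report + run summary out.

Stage order: read formats -> cluster filter -> site/genotype quality filter
-> consequence annotation -> known-variant exclusion -> NS/SS/I selection
and affected-pair co-segregation (per family) -> cross-family shared genes
-> differential expression -> DEG intersection -> gene-set enrichment ->
conjoint report. Deterministic given inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .annotate import annotate_variant, is_nssi
from .conjoint import (
    CandidateReport,
    EnrichmentResult,
    build_report,
    intersect_genes,
)
from .expression import deg_genes, deg_test
from .formats import (
    FilterParams,
    ValidationError,
    read_expression,
    read_gene_models,
    read_gmt,
    read_known_set,
    read_ped,
    read_vcf,
)
from .segregate import cross_family_genes, family_candidates, filter_known
from .varfilter import filter_cluster, filter_quality

logger = logging.getLogger("famseg")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunSummary:
    """Cascade counts per family/individual plus provenance."""

    parameters: dict
    input_digests: dict[str, str]
    seed: int | None
    per_family: dict[str, dict] = field(default_factory=dict)
    n_deg: int = 0
    n_candidate_genes: int = 0
    n_intersection: int = 0
    n_enriched_sets: int = 0
    n_final_variants: int = 0
    cross_family_genes: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path) -> dict:
    path = Path(path)
    cfg = yaml.safe_load(path.read_text())
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    required = {"vcf", "ped", "gene_models", "known", "expression", "groups", "gmt"}
    missing = required - set(cfg)
    if missing:
        raise ValidationError(f"{path}: missing config keys {sorted(missing)}")
    base = path.parent
    cfg = dict(cfg)
    cfg["vcf"] = {fam: base / p for fam, p in cfg["vcf"].items()}
    for key in ("ped", "gene_models", "known", "expression", "groups", "gmt", "universe"):
        if cfg.get(key):
            cfg[key] = base / cfg[key]
    return cfg


def run_all(
    config_path: str | Path, out_dir: str | Path | None = None
) -> tuple[CandidateReport, RunSummary]:
    """Execute the full cascade described by a YAML config file.

    The config names the per-family VCFs, PED, gene models, known-variant
    list, expression matrix + groups, GMT file, an optional explicit
    background universe, and parameter overrides. When ``out_dir`` is given,
    report.tsv, summary.json, removed.tsv, deg.tsv and enrichment.tsv are
    written there.
    """
    cfg = load_config(config_path)
    params = FilterParams.from_mapping(cfg.get("params") or {})
    digests = {}
    for key in ("ped", "gene_models", "known", "expression", "groups", "gmt", "universe"):
        if cfg.get(key):
            digests[key] = _sha256(Path(cfg[key]))
    for fam, p in cfg["vcf"].items():
        digests[f"vcf:{fam}"] = _sha256(Path(p))

    summary = RunSummary(
        parameters=asdict(params), input_digests=digests, seed=cfg.get("seed")
    )

    try:
        pedigree = read_ped(cfg["ped"])
        models = read_gene_models(cfg["gene_models"])
        known = read_known_set(cfg["known"])
        gene_sets = read_gmt(cfg["gmt"])
        matrix = read_expression(cfg["expression"], cfg["groups"])
        universe: set[str] | None = None
        if cfg.get("universe"):
            universe = {
                line.strip()
                for line in Path(cfg["universe"]).read_text().splitlines()
                if line.strip()
            }
    except (OSError, ValueError) as exc:
        raise StageError("formats", str(exc)) from exc

    per_family = []
    removed_rows: list[tuple[str, str, str]] = []
    for fam in sorted(cfg["vcf"]):
        try:
            variants = read_vcf(cfg["vcf"][fam])
        except ValueError as exc:
            raise StageError("formats", f"family {fam}: {exc}") from exc
        member_ids = [i.individual_id for i in pedigree.members(fam)]
        n_input = len(variants)
        try:
            kept, removed_cluster = filter_cluster(
                variants, params.cluster_window_bp, params.cluster_min_count
            )
            kept, removed_quality = filter_quality(kept, params, member_ids)
        except ValueError as exc:
            raise StageError("varfilter", f"family {fam}: {exc}") from exc
        for r in removed_cluster + removed_quality:
            removed_rows.append(
                (fam, f"{r.variant.chrom}:{r.variant.pos}:{r.variant.ref}:{r.variant.alt}", r.reason)
            )
        try:
            consequences = {v.key: annotate_variant(models, v) for v in kept}
        except ValueError as exc:
            raise StageError("annotate", f"family {fam}: {exc}") from exc
        novel, _known_hits = filter_known(kept, known)
        try:
            fc = family_candidates(
                novel, consequences, pedigree, fam, allow_hom=params.allow_hom
            )
        except ValueError as exc:
            raise StageError("segregate", f"family {fam}: {exc}") from exc
        per_family.append(fc)
        n_nssi_variants = sum(
            1 for v in novel if is_nssi(consequences[v.key])
        )
        summary.per_family[fam] = {
            "n_input": n_input,
            "n_after_cluster": n_input - len(removed_cluster),
            "n_after_quality": n_input - len(removed_cluster) - len(removed_quality),
            "n_novel": len(novel),
            "n_nssi_novel": n_nssi_variants,
            "n_pair_shared": len(fc.shared_variants),
            "per_individual_nssi": dict(fc.per_individual_nssi_counts),
            "shared_genes": sorted(fc.shared_genes),
        }
        logger.info(
            "family %s: %d variants -> %d after filters -> %d novel NS/SS/I "
            "-> %d pair-shared",
            fam,
            n_input,
            summary.per_family[fam]["n_after_quality"],
            n_nssi_variants,
            len(fc.shared_variants),
        )

    cross = cross_family_genes(per_family, min_families=2)
    summary.cross_family_genes = sorted(cross.selected_genes)

    try:
        deg_results = deg_test(matrix, params)
    except ValueError as exc:
        raise StageError("expression", str(exc)) from exc
    degs = deg_genes(deg_results)
    summary.n_deg = len(degs)

    candidate_genes = set().union(*(fc.shared_genes for fc in per_family))
    summary.n_candidate_genes = len(candidate_genes)
    intersection = intersect_genes(candidate_genes, degs)
    summary.n_intersection = len(intersection)

    background = universe if universe is not None else {m.gene_symbol for m in models}
    try:
        from .conjoint import enrich

        enrichments = enrich(
            intersection, gene_sets, background=background, ease=params.ease_mode
        )
    except ValueError as exc:
        raise StageError("conjoint", str(exc)) from exc
    summary.n_enriched_sets = sum(
        1 for e in enrichments if e.q_value <= params.enrich_alpha
    )

    report = build_report(
        per_family, degs, enrichments, gene_sets, params
    )
    summary.n_final_variants = len(report.variant_keys())
    logger.info(
        "cascade: %d candidate genes, %d DEGs, %d in intersection, "
        "%d enriched sets, %d final variants",
        summary.n_candidate_genes,
        summary.n_deg,
        summary.n_intersection,
        summary.n_enriched_sets,
        summary.n_final_variants,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_report_tsv(report, out / "report.tsv")
        summary.to_json(out / "summary.json")
        _write_removed_tsv(removed_rows, out / "removed.tsv")
        _write_deg_tsv(deg_results, out / "deg.tsv")
        _write_enrichment_tsv(enrichments, out / "enrichment.tsv")
    return report, summary


def _write_report_tsv(report: CandidateReport, path: Path) -> None:
    lines = [
        "family\tchrom\tpos\tref\talt\tgene\tcategory\thgvs_c\thgvs_p\t"
        "consensus_damaging\tin_deg_set\tenriched_sets\tcarriers\tcompound_het_carriers"
    ]
    chet_by_variant: dict[tuple, set[str]] = {}
    for sid, pairs in report.compound_het_carriers:
        for a, b in pairs:
            chet_by_variant.setdefault(tuple(a), set()).add(sid)
            chet_by_variant.setdefault(tuple(b), set()).add(sid)
    for e in report.entries:
        v = e.variant
        carriers = ",".join(
            f"{sid}({gt})" for sid, gt in report.carriers.get(v.key, ())
        )
        chet = ",".join(sorted(chet_by_variant.get(v.key, ()))) or "-"
        lines.append(
            "\t".join(
                [
                    e.family_id,
                    v.chrom,
                    str(v.pos),
                    v.ref,
                    v.alt,
                    e.gene_symbol,
                    e.consequence.category,
                    e.consequence.hgvs_c,
                    e.consequence.hgvs_p or "-",
                    str(e.consensus_damaging).lower(),
                    str(e.in_deg_set).lower(),
                    ",".join(e.enriched_sets) or "-",
                    carriers or "-",
                    chet,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def _write_removed_tsv(rows: list[tuple[str, str, str]], path: Path) -> None:
    lines = ["family\tvariant\treason"]
    lines += ["\t".join(r) for r in rows]
    path.write_text("\n".join(lines) + "\n")


def _write_deg_tsv(results, path: Path) -> None:
    lines = ["gene\tlog2fc\tp_value\tq_value\tis_deg"]
    for r in results:
        lines.append(
            f"{r.gene_symbol}\t{r.log2_fold_change:.6f}\t{r.p_value:.6g}\t"
            f"{r.q_value:.6g}\t{str(r.is_deg).lower()}"
        )
    path.write_text("\n".join(lines) + "\n")


def _write_enrichment_tsv(results: list[EnrichmentResult], path: Path) -> None:
    lines = ["set_name\tk\tn\tK\tN\tp_value\tq_value"]
    for e in results:
        lines.append(
            f"{e.set_name}\t{e.k}\t{e.n}\t{e.K}\t{e.N}\t{e.p_value:.6g}\t{e.q_value:.6g}"
        )
    path.write_text("\n".join(lines) + "\n")
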