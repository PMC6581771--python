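"""Two-group differential expression: Welch t-test with BH FDR control.

Values are assumed gene-level log2 intensities. A gene is called DE when
its BH-adjusted p-value is at or below ``deg_fdr`` and its absolute
case-minus-control mean difference (log2 fold change) is at least
``deg_min_abs_log2fc``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .formats import ExpressionMatrix, FilterParams, ValidationError


@dataclass(frozen=True)
class DEGResult:
    gene_symbol: str
    log2_fold_change: float
    p_value: float
    q_value: float
    is_deg: bool


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    q_i = min_{j: p_j >= p_i} ( p_j * m / rank_j ), capped at 1 — the
    standard min-over-suffix formulation with monotonicity enforcement.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


def deg_test(matrix: ExpressionMatrix, params: FilterParams) -> list[DEGResult]:
    """Per-gene Welch two-sample t-test (two-sided) with BH adjustment.

    Genes with zero variance in both groups and equal means get p = 1;
    zero variance with unequal means is treated as an arbitrarily strong
    signal (p = 0).
    """
    cases = matrix.samples_in("case")
    controls = matrix.samples_in("control")
    if len(cases) < 2 or len(controls) < 2:
        raise ValidationError("each group needs >= 2 samples")
    x = matrix.values[cases].to_numpy(dtype=float)
    y = matrix.values[controls].to_numpy(dtype=float)
    log2fc = x.mean(axis=1) - y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(x, y, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        same_mean = np.isclose(log2fc, 0.0)
        p[degenerate & same_mean] = 1.0
        p[degenerate & ~same_mean] = 0.0
    q = np.asarray(bh_adjust(p.tolist()))
    is_deg = (q <= params.deg_fdr) & (
        np.abs(log2fc) >= params.deg_min_abs_log2fc
    )
    return [
        DEGResult(
            gene_symbol=gene,
            log2_fold_change=float(log2fc[i]),
            p_value=float(p[i]),
            q_value=float(q[i]),
            is_deg=bool(is_deg[i]),
        )
        for i, gene in enumerate(matrix.gene_symbols)
    ]


def deg_genes(results: Sequence[DEGResult]) -> set[str]:
    """Gene symbols flagged as differentially expressed."""
    return {r.gene_symbol for r in results if r.is_deg}
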