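"""Per-gene log2 fold changes and gene-set response statistics.

Between two growth conditions, each gene's LFC is the log2 ratio of
condition means (with a pseudocount); a gene set's response is the mean
and sample standard deviation of its members' LFCs, and its enrichment
is a Kruskal-Wallis test of set LFCs against the non-set background,
Benjamini-Hochberg corrected across all sets tested together.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .stats import bh_fdr, kruskal_wallis

logger = logging.getLogger("exoflux")


def gene_lfc(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2((mean_b + eps) / (mean_a + eps)).

    ``expr`` is genes x samples; ``meta`` maps sample_id -> condition.
    Each condition needs >= 2 replicate samples present in ``expr``.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    cols = {}
    for cond in (condition_a, condition_b):
        ids = meta.loc[meta["condition"] == cond, "sample_id"]
        ids = [s for s in ids if s in expr.columns]
        if len(ids) < 2:
            raise ValueError(f"condition {cond!r} has {len(ids)} sample(s) in the matrix")
        cols[cond] = ids
    mean_a = expr[cols[condition_a]].mean(axis=1)
    mean_b = expr[cols[condition_b]].mean(axis=1)
    return np.log2((mean_b + pseudocount) / (mean_a + pseudocount)).rename("lfc")


def set_response(lfcs: pd.Series, gene_set: list[str], set_name: str = "") -> dict:
    """Mean and sample sd (n-1 denominator) of a set's LFCs.

    Genes absent from ``lfcs`` are counted and reported; an empty
    intersection is an error naming the set.
    """
    present = [g for g in gene_set if g in lfcs.index]
    if not present:
        raise ValueError(f"gene set {set_name or '<unnamed>'!r}: no member gene has an LFC")
    vals = lfcs.loc[present].to_numpy(dtype=float)
    return {
        "set_name": set_name,
        "n_genes": len(present),
        "n_missing": len(gene_set) - len(present),
        "mean_lfc": float(vals.mean()),
        "sd_lfc": float(vals.std(ddof=1)) if len(vals) > 1 else None,
    }


def set_enrichment_test(
    lfcs: pd.Series, gene_set: list[str], mode: str = "asymptotic"
) -> float:
    """Kruskal-Wallis p-value for set LFCs vs non-set (background) LFCs.

    A set equal to the whole background is degenerate: p = 1 with a
    warning.
    """
    set_idx = [g for g in gene_set if g in lfcs.index]
    if not set_idx:
        raise ValueError("gene set has no member in the LFC vector")
    bg_idx = lfcs.index.difference(set_idx)
    if len(bg_idx) == 0:
        logger.warning("gene set equals the background; enrichment test degenerate")
        return 1.0
    if len(set_idx) < 2 or len(bg_idx) < 2:
        return 1.0  # too few observations on one side for a rank test
    return kruskal_wallis(
        lfcs.loc[set_idx].to_numpy(), lfcs.loc[bg_idx].to_numpy(), mode=mode
    )


def geneset_response_table(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    sets: dict[str, list[str]],
    condition_a: str,
    condition_b: str,
    pseudocount: float = 1.0,
    alpha: float = 0.05,
    mode: str = "asymptotic",
) -> pd.DataFrame:
    """Full gene-set response report: mean/sd LFC, KW p, BH q, enriched flag."""
    if not sets:
        raise ValueError("no gene sets supplied")
    lfcs = gene_lfc(expr, meta, condition_a, condition_b, pseudocount)
    rows = []
    for name in sorted(sets):
        resp = set_response(lfcs, sets[name], name)
        resp["p_value"] = set_enrichment_test(lfcs, sets[name], mode=mode)
        rows.append(resp)
    out = pd.DataFrame(rows)
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    out["enriched"] = out["q_value"] <= alpha
    return out
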