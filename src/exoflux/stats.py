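"""Start-vs-end differential abundance for cross-feeding experiments.

Each metabolite's ion counts in the donor's spent medium ("start") are
compared with the counts after incubation with the recipient ("end")
by a two-group Kruskal-Wallis test, Benjamini-Hochberg corrected across
the metabolites of one feeding direction. Effect size is the log2 fold
change of group means with a pseudocount; significant negative LFCs are
"depleted", significant positive LFCs "exuded".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .model import Call, ChemClass, Direction

EXACT_MAX_N = 12  # enumeration of C(n, n1) assignments beyond this is refused


@dataclass
class ExchangeResult:
    metabolite: str
    chem_class: ChemClass
    direction: Direction
    lfc: float
    p_value: float
    q_value: float
    call: Call


def log2_fold_change(start, end, pseudocount: float = 1.0) -> float:
    """log2((mean(end) + eps) / (mean(start) + eps)); eps guards zeros."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    return float(np.log2((end.mean() + pseudocount) / (start.mean() + pseudocount)))


def _h_statistic(start: np.ndarray, end: np.ndarray) -> float:
    """Tie-corrected two-group Kruskal-Wallis H."""
    combined = np.concatenate([start, end])
    ranks = sps.rankdata(combined)
    n1, n = len(start), len(combined)
    r1, r2 = ranks[:n1], ranks[n1:]
    h = 12.0 / (n * (n + 1)) * (r1.sum() ** 2 / n1 + r2.sum() ** 2 / (n - n1)) - 3 * (n + 1)
    _, counts = np.unique(combined, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if correction == 0:  # all values tied
        return 0.0
    return h / correction


def kruskal_wallis(start, end, mode: str = "asymptotic") -> float:
    """Two-group Kruskal-Wallis p-value.

    ``asymptotic``: tie-corrected H referred to chi-square with 1 df
    (two groups). ``exact``: permutation null, enumerating all
    C(n1+n2, n1) group assignments (combined n <= 12). Inputs with all
    values tied return p = 1.
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    if len(start) < 2 or len(end) < 2 or len(start) + len(end) < 4:
        raise ValueError("each group needs >= 2 observations (combined n >= 4)")
    combined = np.concatenate([start, end])
    if np.all(combined == combined[0]):
        return 1.0
    if mode == "asymptotic":
        try:
            p = float(sps.kruskal(start, end).pvalue)
        except ValueError:  # scipy refuses all-identical input
            return 1.0
        # guard chi-square tail underflow at extreme H; p stays in (0, 1]
        return max(p, float(np.finfo(float).tiny))
    if mode == "exact":
        n = len(combined)
        if n > EXACT_MAX_N:
            raise ValueError(
                f"exact mode supports combined n <= {EXACT_MAX_N}, got {n}"
            )
        h_obs = _h_statistic(start, end)
        n1 = len(start)
        idx_all = frozenset(range(n))
        count = total = 0
        for chosen in combinations(range(n), n1):
            g1 = combined[list(chosen)]
            g2 = combined[list(idx_all - set(chosen))]
            total += 1
            if _h_statistic(g1, g2) >= h_obs - 1e-12:
                count += 1
        return count / total
    raise ValueError(f"unknown mode {mode!r}")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_exchange(lfc: float, q_value: float, alpha: float = 0.05) -> Call:
    if q_value <= alpha:
        if lfc < 0:
            return Call.depleted
        if lfc > 0:
            return Call.exuded
    return Call.unchanged


def depletion_percent_from_lfc(lfc: float) -> float:
    """Percent of the starting pool consumed, implied by a negative LFC."""
    if lfc > 0:
        raise ValueError("LFC must be <= 0 (use 2**lfc as an exudation fold instead)")
    return 100.0 * (1.0 - 2.0**lfc)


def differential_abundance(
    pairs: pd.DataFrame,
    direction: Direction,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    mode: str = "asymptotic",
) -> pd.DataFrame:
    """Run the full start-vs-end analysis for one feeding direction.

    ``pairs`` needs columns metabolite, chem_class, start, end where
    start/end hold replicate ion-count vectors. BH-FDR is applied across
    all metabolites of the direction (one family per direction).
    """
    if pairs.empty:
        raise ValueError("no metabolites to test")
    rows = []
    for _, row in pairs.iterrows():
        start = np.asarray(row["start"], dtype=float)
        end = np.asarray(row["end"], dtype=float)
        if (start < 0).any() or (end < 0).any():
            raise ValueError(f"{row['metabolite']}: negative ion counts")
        rows.append(
            {
                "metabolite": row["metabolite"],
                "chem_class": ChemClass(row["chem_class"]).value,
                "direction": direction.value,
                "lfc": log2_fold_change(start, end, pseudocount),
                "p_value": kruskal_wallis(start, end, mode=mode),
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    out["call"] = [
        classify_exchange(l, q, alpha).value for l, q in zip(out["lfc"], out["q_value"])
    ]
    return out


def class_summary(results: pd.DataFrame, direction: Direction | None = None) -> pd.DataFrame:
    """Per chemical class: detected, depleted, percent depleted.

    Classes with zero detected metabolites are omitted (noted via the
    absence of the row; totals preserved in the returned frame).
    """
    if results.empty:
        raise ValueError("no exchange results")
    df = results
    if direction is not None:
        df = df[df["direction"] == direction.value]
    rows = []
    for cls, grp in df.groupby("chem_class", sort=True):
        n_detected = len(grp)
        if n_detected == 0:
            continue
        n_depleted = int((grp["call"] == Call.depleted.value).sum())
        rows.append(
            {
                "chem_class": cls,
                "n_detected": n_detected,
                "n_depleted": n_depleted,
                "percent_depleted": 100.0 * n_depleted / n_detected,
            }
        )
    return pd.DataFrame(rows)


def overall_depletion_fraction(
    results: pd.DataFrame, exuded_names: list[str] | None = None
) -> tuple[float | None, int, int]:
    """Percent of donor-exuded metabolites called depleted.

    ``exuded_names`` restricts the denominator to metabolites established
    as exuded by the donor; None uses every metabolite in ``results``.
    Returns (percent or None when the denominator is zero, n_depleted,
    n_denominator).
    """
    df = results
    if exuded_names is not None:
        df = df[df["metabolite"].isin(set(exuded_names))]
    n_denom = len(df)
    n_depleted = int((df["call"] == Call.depleted.value).sum())
    if n_denom == 0:
        return None, n_depleted, 0
    return 100.0 * n_depleted / n_denom, n_depleted, n_denom


def growth_synergy_test(
    weights_a, weights_b, weights_ab, mode: str = "asymptotic"
) -> float:
    """Co-culture dry weight vs the replicate-paired sum of individual growth.

    Replicates of A and B are paired by index to form sums A_i + B_i,
    which are compared with the co-culture weights by Kruskal-Wallis.
    """
    weights_a = np.asarray(weights_a, dtype=float)
    weights_b = np.asarray(weights_b, dtype=float)
    weights_ab = np.asarray(weights_ab, dtype=float)
    if len(weights_a) != len(weights_b):
        raise ValueError(
            f"cannot pair replicates: A has {len(weights_a)}, B has {len(weights_b)}"
        )
    sums = weights_a + weights_b
    return kruskal_wallis(sums, weights_ab, mode=mode)


def growth_synergy_panel(
    conditions: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    mode: str = "asymptotic",
) -> pd.DataFrame:
    """Synergy test per condition (e.g. pH level), BH-FDR across conditions."""
    rows = [
        {"condition": name, "p_value": growth_synergy_test(a, b, ab, mode=mode)}
        for name, (a, b, ab) in conditions.items()
    ]
    out = pd.DataFrame(rows)
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    return out
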