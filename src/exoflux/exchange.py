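"""Exudation calls and the bidirectional metabolite exchange map.

A metabolite is established as exuded by an organism when its mean ion
count in that organism's spent medium exceeds a fold threshold over the
medium blank and it is detected in enough replicates. An exchange edge
donor -> recipient exists when the metabolite is exuded by the donor and
called depleted in that feeding direction; reciprocal edges are allowed
and flagged, and MSI induction calls can corroborate edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import Call, Condition, Direction, FeatureTable, Organism

logger = logging.getLogger("exoflux")


@dataclass
class ExudationParams:
    fold_threshold: float = 3.0  # k: mean_spent >= k x max(mean_blank, eps)
    min_reps_detected: int = 3
    eps: float = 1.0  # ion-count floor for blank means


def define_exuded(
    spent: FeatureTable,
    blank: FeatureTable,
    donor: Organism,
    params: ExudationParams | None = None,
) -> pd.DataFrame:
    """Exudation calls for one donor from its spent medium vs the blank.

    ``spent`` must carry start-condition samples for the direction in
    which ``donor`` is the donor (recipient = partner); the blank table
    supplies medium-only replicates. A metabolite missing from the blank
    table is treated as blank 0 with a warning.
    """
    params = params or ExudationParams()
    direction = (
        Direction.A_fed_to_B if donor == Organism.A_host else Direction.B_fed_to_A
    )
    spent_samples = spent.samples_for(organism=direction.recipient, condition=Condition.start)
    if len(spent_samples) < 2:
        raise ValueError(
            f"spent table lacks start samples for direction {direction.value}"
        )
    blank_samples = blank.samples_for(condition=Condition.blank)
    if len(blank_samples) < 2:
        raise ValueError("blank table lacks blank-condition samples")
    blank_map = {fid: blank.intensities(fid, blank_samples) for fid in blank.feature_ids}
    rows = []
    n_missing_blank = 0
    for fid in spent.feature_ids:
        vals = spent.intensities(fid, spent_samples)
        if fid in blank_map:
            mean_blank = float(blank_map[fid].mean())
        else:
            mean_blank = 0.0
            n_missing_blank += 1
        mean_spent = float(vals.mean())
        n_detected = int((vals > 0).sum())
        fold = mean_spent / max(mean_blank, params.eps)
        exuded = (
            fold >= params.fold_threshold and n_detected >= params.min_reps_detected
        )
        rows.append(
            {
                "metabolite": fid,
                "donor": donor.value,
                "mean_spent": mean_spent,
                "mean_blank": mean_blank,
                "fold_over_blank": fold,
                "n_reps_detected": n_detected,
                "exuded": exuded,
            }
        )
    if n_missing_blank:
        logger.warning(
            "%d metabolite(s) absent from blank table treated as blank 0", n_missing_blank
        )
    return pd.DataFrame(rows)


def build_exchange_map(
    exudations: dict[Organism, pd.DataFrame],
    results: dict[Direction, pd.DataFrame],
    msi_calls: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Directed exchange edges from exudation calls and depletion results.

    One edge per (metabolite, direction) where the metabolite is exuded
    by the direction's donor and called depleted in that direction.
    Reciprocal exchanges (edges both ways for one metabolite) are
    flagged. ``msi_calls`` (columns metabolite/channel, induced) sets
    the msi_corroborated flag.
    """
    edges = []
    for direction, res in results.items():
        dup = res.duplicated(subset=["metabolite"])
        if dup.any():
            raise ValueError(
                f"conflicting duplicate results for {res.loc[dup, 'metabolite'].iloc[0]!r} "
                f"in direction {direction.value}"
            )
        donor = direction.donor
        exuded_set = set(
            exudations[donor].loc[exudations[donor]["exuded"], "metabolite"]
        )
        for _, row in res.iterrows():
            if row["call"] != Call.depleted.value:
                continue
            if row["metabolite"] not in exuded_set:
                continue
            edges.append(
                {
                    "metabolite": row["metabolite"],
                    "chem_class": row["chem_class"],
                    "from_organism": donor.value,
                    "to_organism": direction.recipient.value,
                    "direction": direction.value,
                    "lfc": row["lfc"],
                    "q_value": row["q_value"],
                }
            )
    edge_df = pd.DataFrame(
        edges,
        columns=[
            "metabolite", "chem_class", "from_organism", "to_organism",
            "direction", "lfc", "q_value",
        ],
    )
    counts = edge_df["metabolite"].value_counts()
    edge_df["reciprocal"] = edge_df["metabolite"].map(counts).fillna(0).astype(int) > 1
    if msi_calls is not None and not msi_calls.empty:
        key = "metabolite" if "metabolite" in msi_calls.columns else "channel"
        induced = set(msi_calls.loc[msi_calls["induced"].astype(bool), key])
        edge_df["msi_corroborated"] = edge_df["metabolite"].isin(induced)
    else:
        edge_df["msi_corroborated"] = pd.NA
    return edge_df.sort_values(["direction", "metabolite"]).reset_index(drop=True)


def summarize_exchange(edge_df: pd.DataFrame) -> dict:
    """Per-direction and per-class edge counts, reciprocal list, corroboration."""
    per_direction = {d.value: int((edge_df["direction"] == d.value).sum()) for d in Direction}
    per_class = (
        edge_df.groupby(["direction", "chem_class"]).size().rename("n_edges").reset_index()
        if not edge_df.empty
        else pd.DataFrame(columns=["direction", "chem_class", "n_edges"])
    )
    reciprocal = sorted(edge_df.loc[edge_df["reciprocal"], "metabolite"].unique())
    corroborated = (
        int(edge_df["msi_corroborated"].eq(True).sum())
        if "msi_corroborated" in edge_df
        else 0
    )
    return {
        "n_edges": int(len(edge_df)),
        "per_direction": per_direction,
        "per_class": per_class,
        "reciprocal_metabolites": reciprocal,
        "n_msi_corroborated": corroborated,
    }
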