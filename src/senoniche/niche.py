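"""Senescent-niche analysis: roles, composition, and positivity rates.

A cell's niche role is one of three mutually exclusive values:
``p21_positive`` (reporter-positive), ``neighbor`` (its segment boundary
directly contacts at least one p21-positive segment, and it is not itself
p21-positive), or ``other``. Composition tables and per-type positivity
ratios summarize how senescence distributes across lineages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .segmentation import NeighborGraph

__all__ = ["ROLES", "assign_roles", "composition_table", "p21_rate_by_type"]

ROLES = ("p21_positive", "neighbor", "other")


def assign_roles(g: NeighborGraph, p21_ids: set[int]) -> pd.Series:
    """Partition graph nodes into p21_positive / neighbor / other.

    ``neighbor`` = adjacent to >= 1 p21-positive cell and not itself
    p21-positive (p21 positivity takes precedence; two touching
    p21-positive cells are both ``p21_positive``, not neighbors).
    """
    p21_ids = {int(i) for i in p21_ids}
    unknown = p21_ids - g.nodes
    if unknown:
        raise ValueError(f"p21 ids not present in the graph: {sorted(unknown)[:10]}")
    neighbors = g.neighbors_of(p21_ids)
    roles = {}
    for node in g.nodes:
        if node in p21_ids:
            roles[node] = "p21_positive"
        elif node in neighbors:
            roles[node] = "neighbor"
        else:
            roles[node] = "other"
    s = pd.Series(roles, name="niche_role").sort_index()
    s.index.name = "segment_id"
    return s


def composition_table(roles: pd.Series, types: pd.Series) -> pd.DataFrame:
    """Counts and within-role fractions per (role, type).

    The counts partition the cells exactly; fractions sum to 1 within each
    role present.
    """
    df = pd.DataFrame({"niche_role": roles, "cell_type": types})
    if df.isna().any().any():
        raise ValueError("every cell needs both a role and a type")
    counts = (
        df.groupby(["niche_role", "cell_type"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    totals = counts.groupby("niche_role")["count"].transform("sum")
    counts["fraction"] = counts["count"] / totals
    return counts


def p21_rate_by_type(
    roles: pd.Series,
    types: pd.Series,
    replicate: pd.Series | None = None,
) -> pd.DataFrame:
    """p21-positivity ratio per cell type, per replicate and pooled.

    ratio = (# p21_positive of the type) / (# cells of the type). Types with
    zero cells in a replicate are emitted as missing (NaN).
    """
    df = pd.DataFrame({"role": roles, "cell_type": types})
    if replicate is None:
        replicate = pd.Series("pooled", index=roles.index)
    df["replicate"] = replicate
    if df.isna().any().any():
        raise ValueError("every cell needs a role, a type and a replicate")
    df["is_p21"] = df["role"] == "p21_positive"

    def _rates(sub: pd.DataFrame, rep_label) -> pd.DataFrame:
        g = sub.groupby("cell_type", observed=True)["is_p21"].agg(["sum", "count"])
        g["ratio"] = g["sum"] / g["count"].where(g["count"] > 0)
        g = g.rename(columns={"sum": "n_p21", "count": "n_cells"}).reset_index()
        g.insert(0, "replicate", rep_label)
        return g

    parts = [_rates(df, "pooled")]
    for rep, sub in df.groupby("replicate", observed=True):
        if rep != "pooled":
            parts.append(_rates(sub, rep))
    return pd.concat(parts, ignore_index=True)
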