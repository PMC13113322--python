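"""Statistical layer: rank-sum contrasts, FDR, ISG scoring, exact overlap tests.

Within each annotated cell type, two two-group contrasts are evaluated with
the nonparametric Wilcoxon rank-sum (Mann-Whitney) test on normalized
expression: p21-positive cells versus the remaining cells of the type, and
neighboring cells versus the remaining cells of the type. P-values are
adjusted per (type, contrast) with Benjamini-Hochberg, and a gene is called
significant when its adjusted p < 0.05 with positive log2 fold change.

The interferon-stimulated-gene (ISG) program is summarized by a cumulative
per-cell score (mean normalized expression over the ISG panel), thresholded
into an ISG status, and the overlap between p21 and ISG status is tested
per biological replicate with Fisher's exact test on the 2x2 table.

The rank-sum and Fisher tests are implemented here from first principles
(exact enumeration on small problems, standard approximations otherwise) so
their behavior is fully specified and oracle-testable.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, norm, rankdata

from .annotation import NormalizedMatrix

__all__ = [
    "ContrastResult",
    "IsgPanel",
    "OverlapTable",
    "rank_sum_test",
    "bh_adjust",
    "run_contrasts",
    "isg_score",
    "isg_call",
    "isg_call_from_clusters",
    "fisher_exact_2x2",
    "overlap_analysis",
]

log = logging.getLogger(__name__)

CONTRASTS = ("p21_vs_rest", "neighbor_vs_rest")
DEFAULT_ISG_GENES = ("Rsad2", "Ifit1", "Cmpk2", "Ifit3")
LOG2FC_EPS = 1e-9
EXACT_N_MAX = 12


@dataclass
class IsgPanel:
    genes: tuple[str, ...] = DEFAULT_ISG_GENES

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("ISG panel must be non-empty")


@dataclass
class ContrastResult:
    """Per-gene differential expression for one (cell type, contrast)."""

    cell_type: str
    contrast: str
    table: pd.DataFrame  # columns: gene, log2fc, pval, qval, significant
    n_group_a: int
    n_group_b: int


@dataclass
class OverlapTable:
    """Replicate-specific 2x2 table over (p21 status) x (ISG status)."""

    replicate: object
    a: int  # p21+ ISG+
    b: int  # p21+ ISG-
    c: int  # p21- ISG+
    d: int  # p21- ISG-
    fisher_p: float
    odds_ratio: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be >= 0")
        if not 0.0 <= self.fisher_p <= 1.0:
            raise ValueError("p must be in [0, 1]")


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def rank_sum_test(a, b, method: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    With ``method="auto"`` (default): exact null enumeration over all rank
    assignments when ``len(a) + len(b) <= 12`` and there are no ties
    (two-sided p doubles the smaller tail, capped at 1); otherwise the
    normal approximation with midranks, tie correction and a 0.5 continuity
    correction. ``method="exact"`` / ``"approx"`` force a path (exact
    requires no ties). Identical constant samples give p = 1.
    """
    if method not in ("auto", "exact", "approx"):
        raise ValueError("method must be auto, exact or approx")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)
    N = n + m
    has_ties = len(np.unique(pooled)) < N
    if method == "exact" and has_ties:
        raise ValueError("exact enumeration requires tie-free data")
    use_exact = (method == "exact") or (
        method == "auto" and N <= EXACT_N_MAX and not has_ties
    )
    if use_exact:
        ranks = rankdata(pooled)
        w_obs = ranks[:n].sum()
        lo = eq = hi = 0
        for combo in itertools.combinations(range(1, N + 1), n):
            w = sum(combo)
            if w < w_obs:
                lo += 1
            elif w > w_obs:
                hi += 1
            else:
                eq += 1
        total = lo + eq + hi
        p = 2.0 * min(lo + eq, hi + eq) / total
        return min(p, 1.0)
    # normal approximation with midranks
    ranks = rankdata(pooled)
    w = ranks[:n].sum()
    mean_w = n * (N + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (N * (N - 1))
    var_w = n * m / 12.0 * ((N + 1) - tie_term)
    if var_w <= 0:
        return 1.0  # all values identical across both groups
    diff = w - mean_w
    z = (diff - 0.5 * np.sign(diff)) / math.sqrt(var_w)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_adjust(pvals) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values, returned in input order.

    q_(i) = min over j >= i of p_(j) * m / j over the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1 or np.isnan(p).any()):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Contrast engine


def run_contrasts(
    nm: NormalizedMatrix,
    roles: pd.Series,
    types: pd.Series,
    min_cells: int = 3,
    alpha: float = 0.05,
    skip_types: tuple[str, ...] = ("unassigned",),
) -> list[ContrastResult]:
    """Within-type two-group contrasts on normalized expression.

    For each cell type: group A = p21-positive cells (contrast
    ``p21_vs_rest``) against all remaining cells of the type, and group A =
    neighbor cells (``neighbor_vs_rest``) against the type's remaining
    non-p21 cells. Pairs with fewer than ``min_cells`` in either group are
    skipped with a logged reason. log2FC uses means of normalized values
    with a small pseudocount; adjustment is within each (type, contrast).
    """
    roles = roles.reindex(nm.cell_ids)
    types = types.reindex(nm.cell_ids)
    if roles.isna().any() or types.isna().any():
        raise ValueError("roles/types missing for some cells in the matrix")
    bad = set(roles.unique()) - {"p21_positive", "neighbor", "other"}
    if bad:
        raise ValueError(f"unknown role label(s): {bad}")

    role_arr = roles.to_numpy()
    type_arr = types.to_numpy(dtype=object)
    results: list[ContrastResult] = []
    for ctype in pd.unique(type_arr):
        if ctype in skip_types:
            continue
        in_type = type_arr == ctype
        for contrast in CONTRASTS:
            if contrast == "p21_vs_rest":
                mask_a = in_type & (role_arr == "p21_positive")
                mask_b = in_type & (role_arr != "p21_positive")
            else:
                mask_a = in_type & (role_arr == "neighbor")
                mask_b = in_type & (role_arr == "other")
            na, nb = int(mask_a.sum()), int(mask_b.sum())
            if na < min_cells or nb < min_cells:
                log.info(
                    "skipping %s/%s: group sizes %d vs %d below min_cells=%d",
                    ctype, contrast, na, nb, min_cells,
                )
                continue
            A = nm.values[mask_a]
            B = nm.values[mask_b]
            mean_a = A.mean(axis=0)
            mean_b = B.mean(axis=0)
            log2fc = np.log2((mean_a + LOG2FC_EPS) / (mean_b + LOG2FC_EPS))
            pvals = np.array(
                [rank_sum_test(A[:, j], B[:, j]) for j in range(A.shape[1])]
            )
            qvals = bh_adjust(pvals)
            table = pd.DataFrame(
                {
                    "gene": nm.gene_ids,
                    "log2fc": log2fc,
                    "pval": pvals,
                    "qval": qvals,
                    "significant": (qvals < alpha) & (log2fc > 0),
                }
            )
            results.append(
                ContrastResult(cell_type=str(ctype), contrast=contrast,
                               table=table, n_group_a=na, n_group_b=nb)
            )
    return results


def contrasts_frame(results: list[ContrastResult]) -> pd.DataFrame:
    """Flat table of all contrast results."""
    if not results:
        return pd.DataFrame(
            columns=["cell_type", "contrast", "gene", "log2fc", "pval", "qval",
                     "significant"]
        )
    parts = []
    for r in results:
        t = r.table.copy()
        t.insert(0, "contrast", r.contrast)
        t.insert(0, "cell_type", r.cell_type)
        parts.append(t)
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# ISG scoring


def isg_score(
    nm: NormalizedMatrix,
    panel: IsgPanel = IsgPanel(),
    mode: str = "mean",
) -> pd.Series:
    """Cumulative ISG score per cell: mean (default) or sum of normalized
    expression over the panel genes present in the matrix."""
    if mode not in ("mean", "sum"):
        raise ValueError("mode must be 'mean' or 'sum'")
    pos = [nm.gene_ids.index(g) for g in panel.genes if g in nm.gene_ids]
    if not pos:
        raise ValueError("no ISG panel genes present in the matrix")
    vals = nm.values[:, pos]
    score = vals.mean(axis=1) if mode == "mean" else vals.sum(axis=1)
    return pd.Series(score, index=pd.Index(nm.cell_ids, name="segment_id"),
                     name="isg_score")


def isg_call(scores: pd.Series, threshold_quantile: float = 0.98) -> pd.Series:
    """ISG-positive iff score strictly exceeds the given quantile of all scores."""
    if not 0.0 < threshold_quantile < 1.0:
        raise ValueError("threshold_quantile must be in (0, 1)")
    thr = float(np.quantile(scores.to_numpy(dtype=float), threshold_quantile))
    return (scores > thr).rename("is_isg_positive")


def isg_call_from_clusters(clusters: pd.Series, isg_cluster) -> pd.Series:
    """Cluster-membership route: ISG-positive iff the cell's cluster id matches."""
    return (clusters.astype(str) == str(isg_cluster)).rename("is_isg_positive")


# ---------------------------------------------------------------------------
# Fisher's exact test


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on the 2x2 table [[a, b], [c, d]].

    p = sum of hypergeometric probabilities of every table with the same
    margins whose probability is <= the observed one (probability-mass rule,
    within relative tolerance 1e-7). Odds ratio = (a*d)/(b*c); infinity when
    b*c = 0 and a*d > 0. A zero margin gives p = 1 and an undefined (NaN)
    odds ratio.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be >= 0")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    N = r1 + r2
    if min(r1, r2, c1, c2) == 0:
        return 1.0, float("nan")
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    dist = hypergeom(N, r1, c1)
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(a)
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return min(p, 1.0), odds


def overlap_analysis(
    p21: pd.Series,
    isg: pd.Series,
    replicate: pd.Series,
) -> tuple[list[OverlapTable], pd.DataFrame]:
    """Replicate-wise exact tests of the p21 x ISG overlap, plus pooled summary.

    Returns one :class:`OverlapTable` per replicate (with at least one cell)
    and a pooled table reporting, for each of the four categories, the raw
    count and the percentage of all cells.
    """
    df = pd.DataFrame({"p21": p21.astype(bool), "isg": isg.astype(bool),
                       "replicate": replicate})
    if df.isna().any().any():
        raise ValueError("p21/ISG status and replicate required for every cell")
    tables: list[OverlapTable] = []
    for rep, sub in df.groupby("replicate", observed=True):
        if len(sub) < 1:
            log.info("skipping replicate %r: no cells", rep)
            continue
        a = int((sub.p21 & sub.isg).sum())
        b = int((sub.p21 & ~sub.isg).sum())
        c = int((~sub.p21 & sub.isg).sum())
        d = int((~sub.p21 & ~sub.isg).sum())
        p, odds = fisher_exact_2x2(a, b, c, d)
        tables.append(OverlapTable(replicate=rep, a=a, b=b, c=c, d=d,
                                   fisher_p=p, odds_ratio=odds))
    total = len(df)
    cats = {
        "p21+/ISG+": (df.p21 & df.isg).sum(),
        "p21+/ISG-": (df.p21 & ~df.isg).sum(),
        "p21-/ISG+": (~df.p21 & df.isg).sum(),
        "p21-/ISG-": (~df.p21 & ~df.isg).sum(),
    }
    pooled = pd.DataFrame(
        {
            "category": list(cats),
            "count": [int(v) for v in cats.values()],
            "percent": [100.0 * int(v) / total if total else 0.0 for v in cats.values()],
        }
    )
    return tables, pooled


def overlap_frame(tables: list[OverlapTable]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "replicate": [t.replicate for t in tables],
            "p21_pos_isg_pos": [t.a for t in tables],
            "p21_pos_isg_neg": [t.b for t in tables],
            "p21_neg_isg_pos": [t.c for t in tables],
            "p21_neg_isg_neg": [t.d for t in tables],
            "fisher_p": [t.fisher_p for t in tables],
            "odds_ratio": [t.odds_ratio for t in tables],
        }
    )
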