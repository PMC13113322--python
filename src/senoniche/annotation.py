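"""Normalization, marker-panel cell typing, and delegated clustering.

Depth differences between cells are removed with the standard library-size
log transform: value(c, g) = ln(1 + count(c, g) * target_sum / total(c)),
with ``target_sum`` defaulting to the median per-cell total. Cell types are
assigned by scoring canonical marker panels (mean normalized expression over
the panel's genes) and taking the argmax with a minimum margin; unsupervised
clustering (PCA -> kNN graph -> Leiden community detection) is also provided
as the cluster-then-annotate route and is delegated to scanpy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CellMatrix

__all__ = ["MarkerPanels", "NormalizedMatrix", "normalize", "score_panels",
           "assign_types", "cluster_cells"]

UNASSIGNED = "unassigned"


@dataclass
class MarkerPanels:
    """Map of cell-type name -> list of marker gene ids."""

    panels: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, genes in self.panels.items():
            if not genes:
                raise ValueError(f"panel {name!r} is empty")
            if any(not g for g in genes):
                raise ValueError(f"panel {name!r} contains an empty gene id")

    @classmethod
    def default(cls) -> "MarkerPanels":
        from .synthetic import default_marker_panels

        return cls(panels=default_marker_panels())

    @classmethod
    def from_yaml(cls, path) -> "MarkerPanels":
        import yaml

        with open(path) as fh:
            return cls(panels={k: list(v) for k, v in yaml.safe_load(fh).items()})


@dataclass
class NormalizedMatrix:
    """Dense cells x genes matrix of depth-normalized log expression."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: np.ndarray  # segment ids, aligned with rows
    target_sum: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if not np.isfinite(self.values).all():
            raise ValueError("normalized values must be finite")
        if self.values.shape[1] != len(self.gene_ids):
            raise ValueError("gene_ids length mismatch")
        if self.values.shape[0] != len(self.cell_ids):
            raise ValueError("cell_ids length mismatch")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def gene_column(self, gene: str) -> np.ndarray:
        return self.values[:, self.gene_ids.index(gene)]


def normalize(m: CellMatrix, target_sum: float | None = None) -> NormalizedMatrix:
    """Library-size normalization followed by log1p.

    value(c, g) = ln(1 + count(c, g) * target_sum / total(c)). The result is
    exactly invariant to scaling any single cell's counts. ``target_sum``
    defaults to the median per-cell total count.
    """
    totals = np.asarray(m.counts.sum(axis=1), dtype=float).ravel()
    if (totals <= 0).any():
        raise ValueError(
            "cells with zero total counts present; apply qc_filter before normalize"
        )
    if target_sum is None:
        target_sum = float(np.median(totals))
    dense = np.asarray(m.counts.todense(), dtype=float)
    values = np.log1p(dense * (target_sum / totals[:, None]))
    return NormalizedMatrix(
        values=values,
        gene_ids=list(m.gene_ids),
        cell_ids=m.cell_meta["segment_id"].to_numpy(),
        target_sum=target_sum,
    )


def score_panels(nm: NormalizedMatrix, panels: MarkerPanels) -> pd.DataFrame:
    """Per-cell panel scores: mean normalized value over each panel's genes.

    Panel genes absent from the matrix are ignored with a warning; a panel
    with no present genes is an error.
    """
    gene_pos = {g: i for i, g in enumerate(nm.gene_ids)}
    scores = {}
    for name, genes in panels.panels.items():
        present = [gene_pos[g] for g in genes if g in gene_pos]
        absent = [g for g in genes if g not in gene_pos]
        if not present:
            raise ValueError(f"no genes of panel {name!r} are present in the matrix")
        if absent:
            warnings.warn(f"panel {name!r}: ignoring absent gene(s) {absent}")
        scores[name] = nm.values[:, present].mean(axis=1)
    return pd.DataFrame(scores, index=pd.Index(nm.cell_ids, name="segment_id"))


def assign_types(scores: pd.DataFrame, min_margin: float = 0.25) -> pd.Series:
    """Argmax type per cell; ties or margin < ``min_margin`` -> "unassigned"."""
    vals = scores.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("scores must be finite")
    order = np.argsort(vals, axis=1)
    top = vals[np.arange(len(vals)), order[:, -1]]
    second = vals[np.arange(len(vals)), order[:, -2]] if vals.shape[1] > 1 else np.full(len(vals), -np.inf)
    labels = scores.columns.to_numpy(dtype=object)[order[:, -1]]
    labels = np.where(top - second < min_margin, UNASSIGNED, labels)
    return pd.Series(labels, index=scores.index, name="cell_type")


def cluster_cells(
    nm: NormalizedMatrix,
    n_components: int = 30,
    resolution: float = 0.1,
    seed: int = 0,
    n_neighbors: int = 30,
) -> pd.Series:
    """Unsupervised clustering: PCA -> kNN graph -> Leiden (via scanpy).

    Deterministic for a fixed ``seed``; every cell receives a cluster id.
    The conservative default resolution targets major-lineage granularity:
    transcript spillover between adjacent segments (inherent to
    radius-capped nuclear segmentation) blurs fine substructure, so higher
    resolutions tend to cut the zonation continuum rather than find types.
    """
    import anndata as ad
    import scanpy as sc

    if nm.n_cells < 2:
        raise ValueError("clustering needs at least 2 cells")
    n_comps = min(n_components, nm.n_cells - 1, len(nm.gene_ids) - 1)
    if n_comps < 1:
        raise ValueError("fewer usable dimensions than requested components")
    adata = ad.AnnData(X=nm.values.astype(np.float32))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.pca(adata, n_comps=n_comps, svd_solver="arpack", random_state=seed)
        sc.pp.neighbors(adata, n_neighbors=min(n_neighbors, nm.n_cells - 1),
                        random_state=seed)
        sc.tl.leiden(
            adata, resolution=resolution, random_state=seed,
            flavor="igraph", n_iterations=2, directed=False,
        )
    return pd.Series(
        adata.obs["leiden"].astype(str).to_numpy(),
        index=pd.Index(nm.cell_ids, name="segment_id"),
        name="cluster",
    )
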