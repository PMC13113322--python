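"""Readers and writers for the pipeline's on-disk formats.

Formats are deliberately plain-text and standard: TSV for point tables and
metadata, Matrix Market triplets for the sparse cell-by-gene matrix, TIFF for
intensity and label images. Every reader/writer pair round-trips exactly.

Coordinate convention throughout the package: 0-based pixel indices, origin
at the top-left, ``x`` = column, ``y`` = row. Transcripts carry fractional
pixel coordinates and are binned by truncation to the containing pixel.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import tifffile

__all__ = [
    "SdgeTable",
    "FluorescenceStack",
    "CellMatrix",
    "SdgeFormatError",
    "read_sdge",
    "write_sdge",
    "read_fluorescence",
    "write_fluorescence",
    "read_cell_matrix",
    "write_cell_matrix",
    "read_label_map",
    "write_label_map",
    "render_label_png",
]

SDGE_COLUMNS = ("x", "y", "gene", "count")


class SdgeFormatError(ValueError):
    """Raised when a spatial expression table violates the expected schema."""


@dataclass
class SdgeTable:
    """Point cloud of spatially located transcript counts.

    ``records`` holds one row per captured molecule (or per aggregated
    pixel/gene entry) with columns ``x``, ``y`` (fractional pixel
    coordinates), ``gene`` and ``count``.
    """

    records: pd.DataFrame
    pixel_size_um: float
    rejected: pd.DataFrame | None = None  # malformed input rows, with line numbers

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in SDGE_COLUMNS if c not in df.columns]
        if missing:
            raise SdgeFormatError(f"sDGE table missing column(s): {missing}")
        self.records = df = df.loc[:, list(SDGE_COLUMNS)].reset_index(drop=True)
        if len(df):
            xy = df[["x", "y"]].to_numpy(dtype=float)
            if not np.isfinite(xy).all():
                raise SdgeFormatError("sDGE coordinates must be finite")
            counts = df["count"].to_numpy()
            if (counts < 1).any():
                raise SdgeFormatError("sDGE counts must be >= 1")
            if (df["gene"].astype(str).str.len() == 0).any():
                raise SdgeFormatError("sDGE gene identifiers must be non-empty")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def total_count(self) -> int:
        return int(self.records["count"].sum()) if len(self.records) else 0


@dataclass
class FluorescenceStack:
    """Co-registered multi-channel fluorescence image (DAPI/GFP/tdTomato)."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self) -> None:
        shapes = {ch: a.shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for ch, a in self.channels.items():
            if a.ndim != 2:
                raise ValueError(f"channel {ch!r} is not 2-D")
            if np.nanmin(a) < 0:
                raise ValueError(f"channel {ch!r} has negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.channels[channel]


@dataclass
class CellMatrix:
    """Cells x genes count matrix plus per-cell metadata.

    Rows of ``counts`` align with rows of ``cell_meta`` (indexed by
    ``segment_id``); columns align with ``gene_ids``. Metadata columns are
    added progressively by downstream stages (reporter class, cell type,
    niche role, replicate).
    """

    counts: sp.csr_matrix
    cell_meta: pd.DataFrame
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape[0] != len(self.cell_meta):
            raise ValueError("counts rows do not match cell_meta length")
        if self.counts.shape[1] != len(self.gene_ids):
            raise ValueError("counts columns do not match gene_ids length")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if "segment_id" not in self.cell_meta.columns:
            raise ValueError("cell_meta requires a segment_id column")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def unique_features(self) -> np.ndarray:
        """Number of genes with nonzero count per cell (nFeature)."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel().astype(int)


# ---------------------------------------------------------------------------
# sDGE tables


def read_sdge(
    path: str | os.PathLike,
    pixel_size_um: float,
    strict: bool = True,
) -> SdgeTable:
    """Read a tab-delimited sDGE table (columns x, y, gene, count; header required).

    Malformed rows (non-numeric coordinates, count < 1, empty gene) are
    reported with their 1-based line numbers: with ``strict=True`` (default)
    a :class:`SdgeFormatError` is raised; otherwise offending rows are
    dropped and returned in ``SdgeTable.rejected`` so that
    ``input rows == len(records) + len(rejected)``.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SDGE_COLUMNS if c not in raw.columns]
    if missing:
        raise SdgeFormatError(f"{path}: missing required column(s) {missing}")
    raw = raw.loc[:, list(SDGE_COLUMNS)]
    x = pd.to_numeric(raw["x"], errors="coerce")
    y = pd.to_numeric(raw["y"], errors="coerce")
    count = pd.to_numeric(raw["count"], errors="coerce")
    int_count = count.round()
    bad = (
        x.isna()
        | y.isna()
        | ~np.isfinite(x.fillna(np.inf))
        | ~np.isfinite(y.fillna(np.inf))
        | count.isna()
        | (count < 1)
        | (count != int_count)
        | (raw["gene"].str.len() == 0)
    )
    if bad.any():
        lines = (raw.index[bad] + 2).tolist()  # +1 header, +1 to 1-based
        if strict:
            raise SdgeFormatError(
                f"{path}: {int(bad.sum())} malformed row(s) at line(s) {lines[:20]}"
            )
    good = ~bad
    records = pd.DataFrame(
        {
            "x": x[good].astype(float),
            "y": y[good].astype(float),
            "gene": raw.loc[good, "gene"],
            "count": int_count[good].astype(int),
        }
    ).reset_index(drop=True)
    rejected = raw.loc[bad].assign(line=raw.index[bad] + 2).reset_index(drop=True)
    return SdgeTable(records=records, pixel_size_um=pixel_size_um, rejected=rejected)


def write_sdge(table: SdgeTable, path: str | os.PathLike) -> None:
    table.records.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Fluorescence images


def write_fluorescence(stack: FluorescenceStack, directory: str | os.PathLike) -> None:
    """Write each channel as a single-channel float32 TIFF named ``<channel>.tif``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for ch, arr in stack.channels.items():
        tifffile.imwrite(directory / f"{ch}.tif", arr.astype(np.float32))


def read_fluorescence(
    directory: str | os.PathLike,
    channels: tuple[str, ...] = ("dapi", "gfp", "tdtomato"),
    pixel_size_um: float = 1.0,
) -> FluorescenceStack:
    directory = Path(directory)
    loaded = {ch: tifffile.imread(directory / f"{ch}.tif") for ch in channels}
    return FluorescenceStack(channels=loaded, pixel_size_um=pixel_size_um)


# ---------------------------------------------------------------------------
# Cell matrices (Matrix Market triplets + TSV sidecars)


def write_cell_matrix(m: CellMatrix, directory: str | os.PathLike) -> None:
    """Write a CellMatrix as ``matrix.mtx`` + ``cells.tsv`` + ``genes.tsv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(directory / "matrix.mtx", sp.coo_matrix(m.counts), field="integer")
    m.cell_meta.to_csv(directory / "cells.tsv", sep="\t", index=False, float_format="%.10g")
    pd.Series(m.gene_ids, name="gene").to_csv(directory / "genes.tsv", sep="\t", index=False)


def read_cell_matrix(directory: str | os.PathLike) -> CellMatrix:
    directory = Path(directory)
    counts = sp.csr_matrix(scipy.io.mmread(directory / "matrix.mtx")).astype(np.int64)
    cell_meta = pd.read_csv(directory / "cells.tsv", sep="\t")
    gene_ids = pd.read_csv(directory / "genes.tsv", sep="\t")["gene"].astype(str).tolist()
    return CellMatrix(counts=counts, cell_meta=cell_meta, gene_ids=gene_ids)


# ---------------------------------------------------------------------------
# Label maps


def write_label_map(labels: np.ndarray, path: str | os.PathLike) -> None:
    tifffile.imwrite(path, np.asarray(labels, dtype=np.int32))


def read_label_map(path: str | os.PathLike) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def render_label_png(labels: np.ndarray, path: str | os.PathLike, seed: int = 0) -> None:
    """Render a label map as an RGB PNG with randomized (but seeded) colors."""
    import imageio.v3 as iio

    labels = np.asarray(labels)
    n = int(labels.max()) + 1
    rng = np.random.default_rng(seed)
    lut = rng.integers(40, 255, size=(max(n, 1), 3), dtype=np.uint8)
    lut[0] = 0  # background black
    iio.imwrite(path, lut[labels])
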