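"""Transcript aggregation, QC, fluorescence quantification and reporter calling.

Transcripts falling inside a segment are aggregated into a single datapoint
treated as one cell (keyed by segment id). Cells with fewer than a minimum
number of unique detected genes (default 100) are removed. Per-segment mean
fluorescence in the GFP and tdTomato channels is thresholded to call the
reporter class of each cell: double-positive (ongoing p21 activity),
tdTomato-only (prior activation history), GFP-only, or none.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import scipy.sparse as sp

from .io import CellMatrix, FluorescenceStack, SdgeTable
from .segmentation import SegmentMap

__all__ = [
    "QcConfig",
    "ReporterCall",
    "assign_transcripts",
    "qc_filter",
    "quantify_fluorescence",
    "background_thresholds",
    "call_reporter",
]

log = logging.getLogger(__name__)

REPORTER_CHANNELS = ("gfp", "tdtomato")


@dataclass
class QcConfig:
    """Cell-level QC: retain cells with >= min_unique_features detected genes."""

    min_unique_features: int = 100

    def __post_init__(self) -> None:
        if self.min_unique_features < 0:
            raise ValueError("min_unique_features must be >= 0")


@dataclass
class ReporterCall:
    segment_id: int
    reporter_class: str  # none | gfp_only | tdtomato_only | double
    channel_means: dict[str, float]
    thresholds: dict[str, float]
    is_p21_positive: bool


def assign_transcripts(
    sdge: SdgeTable,
    seg: SegmentMap,
    on_out_of_bounds: str = "raise",
) -> tuple[CellMatrix, int]:
    """Aggregate transcripts into per-segment cells.

    Each record contributes its count to (segment at its truncated pixel,
    gene); records landing on background (label 0) are tallied as
    ``unassigned``. Total counts are conserved exactly:
    ``matrix.sum() + unassigned == sdge.total_count``.

    Records with coordinates outside the label image are rejected: an error
    by default, or dropped (and logged) with ``on_out_of_bounds="skip"``.
    The matrix has one row per seed id 1..max(label), including segments
    that received no transcripts.
    """
    if on_out_of_bounds not in ("raise", "skip"):
        raise ValueError("on_out_of_bounds must be 'raise' or 'skip'")
    h, w = seg.labels.shape
    rec = sdge.records
    px = np.floor(rec["x"].to_numpy(dtype=float)).astype(int)
    py = np.floor(rec["y"].to_numpy(dtype=float)).astype(int)
    oob = (px < 0) | (px >= w) | (py < 0) | (py >= h)
    if oob.any():
        if on_out_of_bounds == "raise":
            raise ValueError(
                f"{int(oob.sum())} record(s) fall outside the {h}x{w} label image "
                f"(first offending row index: {int(np.flatnonzero(oob)[0])})"
            )
        log.warning("dropping %d out-of-bounds transcript record(s)", int(oob.sum()))
        rec = rec.loc[~oob]
        px, py = px[~oob], py[~oob]

    counts = rec["count"].to_numpy(dtype=np.int64)
    seg_of = seg.labels[py, px] if len(rec) else np.empty(0, dtype=np.int32)
    unassigned = int(counts[seg_of == 0].sum()) if len(rec) else 0

    n_cells = int(seg.labels.max())
    genes = pd.Index(pd.unique(rec["gene"])) if len(rec) else pd.Index([], dtype=object)
    keep = seg_of > 0
    gi = genes.get_indexer(rec.loc[keep, "gene"]) if keep.any() else np.empty(0, dtype=int)
    mat = sp.coo_matrix(
        (counts[keep], (seg_of[keep] - 1, gi)),
        shape=(n_cells, len(genes)),
        dtype=np.int64,
    ).tocsr()
    mat.sum_duplicates()

    seed_y, seed_x = _segment_centroids(seg, n_cells)
    meta = pd.DataFrame(
        {
            "segment_id": np.arange(1, n_cells + 1),
            "centroid_x": seed_x,
            "centroid_y": seed_y,
            "area_px": seg.areas(n_cells),
        }
    )
    return CellMatrix(counts=mat, cell_meta=meta, gene_ids=list(genes)), unassigned


def _segment_centroids(seg: SegmentMap, n: int) -> tuple[np.ndarray, np.ndarray]:
    if n == 0:
        return np.empty(0), np.empty(0)
    idx = np.arange(1, n + 1)
    com = ndi.center_of_mass(np.ones_like(seg.labels), labels=seg.labels, index=idx)
    com = np.asarray(com, dtype=float)  # rows of (y, x); NaN for absent labels
    return com[:, 0], com[:, 1]


def qc_filter(m: CellMatrix, qc: QcConfig = QcConfig()) -> CellMatrix:
    """Retain exactly the cells with unique detected genes >= the cutoff.

    The rule is inclusive at the cutoff and idempotent; cell order is
    preserved.
    """
    keep = m.unique_features() >= qc.min_unique_features
    return CellMatrix(
        counts=m.counts[keep],
        cell_meta=m.cell_meta.loc[keep].reset_index(drop=True),
        gene_ids=list(m.gene_ids),
    )


def quantify_fluorescence(
    seg: SegmentMap,
    stack: FluorescenceStack,
    statistic: str = "mean",
) -> pd.DataFrame:
    """Per-segment per-channel intensity summary (mean by default, max by flag).

    Returns a DataFrame indexed by segment_id with one column per channel.
    """
    if stack.shape != seg.labels.shape:
        raise ValueError(
            f"fluorescence shape {stack.shape} != label map shape {seg.labels.shape}"
        )
    if statistic not in ("mean", "max"):
        raise ValueError("statistic must be 'mean' or 'max'")
    n = int(seg.labels.max())
    idx = np.arange(1, n + 1)
    fn = ndi.mean if statistic == "mean" else ndi.maximum
    out = {ch: fn(arr, labels=seg.labels, index=idx) for ch, arr in stack.channels.items()}
    return pd.DataFrame(out, index=pd.Index(idx, name="segment_id"))


def background_thresholds(
    stack: FluorescenceStack,
    seg: SegmentMap,
    quantile_pct: float = 99.9,
    channels: tuple[str, ...] = REPORTER_CHANNELS,
) -> dict[str, float]:
    """Per-channel positivity threshold: a high percentile of background pixels.

    Background = pixels outside every segment. The default 99.9th percentile
    makes a spurious positive pixel a 1-in-1000 event per channel.
    """
    bg = seg.labels == 0
    if not bg.any():
        raise ValueError("no background pixels to estimate thresholds from")
    return {ch: float(np.percentile(stack[ch][bg], quantile_pct)) for ch in channels}


def call_reporter(
    means: pd.DataFrame,
    thresholds: dict[str, float],
    p21_rule: str = "or",
) -> list[ReporterCall]:
    """Call the reporter class of each segment from mean channel intensities.

    A channel is positive iff its mean strictly exceeds its threshold. The
    class follows the (GFP, tdTomato) positivity pair. With ``p21_rule="or"``
    (default) any reporter fluorescence marks the cell p21-positive; with
    ``p21_rule="tdtomato"`` only tdTomato-involved classes (double or
    tdTomato-only, the two classes observed in the reporter system) count.
    """
    if p21_rule not in ("or", "tdtomato"):
        raise ValueError("p21_rule must be 'or' or 'tdtomato'")
    for ch in REPORTER_CHANNELS:
        if ch not in means.columns:
            raise ValueError(f"means lacks channel {ch!r}")
        if thresholds.get(ch, -1.0) < 0:
            raise ValueError(f"threshold for {ch!r} missing or negative")
    calls = []
    for seg_id, row in means.iterrows():
        gfp = bool(row["gfp"] > thresholds["gfp"])
        tdt = bool(row["tdtomato"] > thresholds["tdtomato"])
        cls = {(False, False): "none", (True, False): "gfp_only",
               (False, True): "tdtomato_only", (True, True): "double"}[(gfp, tdt)]
        positive = (gfp or tdt) if p21_rule == "or" else tdt
        calls.append(
            ReporterCall(
                segment_id=int(seg_id),
                reporter_class=cls,
                channel_means={ch: float(row[ch]) for ch in REPORTER_CHANNELS},
                thresholds={ch: float(thresholds[ch]) for ch in REPORTER_CHANNELS},
                is_p21_positive=positive,
            )
        )
    return calls


def reporter_calls_frame(calls: list[ReporterCall]) -> pd.DataFrame:
    """Tabular view of reporter calls (one row per segment)."""
    return pd.DataFrame(
        {
            "segment_id": [c.segment_id for c in calls],
            "reporter_class": [c.reporter_class for c in calls],
            "gfp_mean": [c.channel_means["gfp"] for c in calls],
            "tdtomato_mean": [c.channel_means["tdtomato"] for c in calls],
            "gfp_threshold": [c.thresholds["gfp"] for c in calls],
            "tdtomato_threshold": [c.thresholds["tdtomato"] for c in calls],
            "is_p21_positive": [c.is_p21_positive for c in calls],
        }
    )
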