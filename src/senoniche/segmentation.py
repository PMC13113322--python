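"""Nuclear-seeded, radius-capped cell segmentation.

The core spatial computation: DAPI intensity peaks become segment centers
(one seed per nucleus), and each seed grows isotropically into a mutually
exclusive territory until it either reaches the radius cap (default 6 px,
~15 um at 2.5 um/px, chosen because hepatocytes are 20-30 um across) or
meets a neighboring territory. The result is exactly the distance-capped
Voronoi partition of the pixel grid: a pixel takes the label of its nearest
seed by Euclidean distance between pixel centers, provided that distance is
<= the cap; ties go to the smaller seed id; pixels farther than the cap from
every seed stay background (0).

The approach deliberately reduces nuclei to points and all cells to equal
maximal radii — it does not capture cell-size variability, and accuracy
degrades in densely packed regions; that trade-off is inherent to the
method, not an implementation shortcut.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu

__all__ = ["SeedSet", "SegmentMap", "NeighborGraph",
           "detect_nuclei", "grow_segments", "contact_graph"]


@dataclass
class SeedSet:
    """Detected nuclear seeds: ids consecutive from 1, integer pixel coords."""

    ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    dapi_intensity: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.x = np.asarray(self.x, dtype=int)
        self.y = np.asarray(self.y, dtype=int)
        self.dapi_intensity = np.asarray(self.dapi_intensity, dtype=float)
        n = len(self.ids)
        if not (len(self.x) == len(self.y) == len(self.dapi_intensity) == n):
            raise ValueError("seed arrays have mismatched lengths")
        if n and not np.array_equal(self.ids, np.arange(1, n + 1)):
            raise ValueError("seed ids must be consecutive from 1")

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"seed_id": self.ids, "x": self.x, "y": self.y,
             "dapi_intensity": self.dapi_intensity}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SeedSet":
        return cls(ids=df["seed_id"].to_numpy(), x=df["x"].to_numpy(),
                   y=df["y"].to_numpy(), dapi_intensity=df["dapi_intensity"].to_numpy())


@dataclass
class SegmentMap:
    """Integer label image: 0 = background, k >= 1 = territory of seed k."""

    labels: np.ndarray
    radius_px: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D")
        if self.radius_px <= 0:
            raise ValueError("radius_px must be positive")

    @property
    def segment_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def areas(self, n_segments: int | None = None) -> np.ndarray:
        """Pixel area per segment id 1..n (0 for seeds that got no pixels)."""
        n = n_segments or (int(self.labels.max()) if self.labels.size else 0)
        return np.bincount(self.labels.ravel(), minlength=n + 1)[1: n + 1]


@dataclass
class NeighborGraph:
    """Boundary-contact adjacency among segments (undirected, no self-edges)."""

    nodes: set[int]
    edges: set[tuple[int, int]]  # stored as (min, max) pairs

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError("self-edges are not allowed")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a},{b}) references unknown node")

    def neighbors_of(self, ids: set[int]) -> set[int]:
        out: set[int] = set()
        for a, b in self.edges:
            if a in ids:
                out.add(b)
            if b in ids:
                out.add(a)
        return out - set(ids)


def detect_nuclei(
    dapi: np.ndarray,
    smooth_sigma: float = 1.0,
    min_distance_px: int = 3,
    min_intensity: float | None = None,
) -> SeedSet:
    """Find nuclear seeds as local maxima of the Gaussian-smoothed DAPI image.

    Maxima must be separated by >= ``min_distance_px`` and have smoothed
    intensity >= ``min_intensity`` (default: Otsu threshold of the smoothed
    image). Ids are assigned in descending-intensity order, ties broken by
    (y, x) lexicographic order.

    The default smoothing (sigma 1 px) and separation (3 px) are sized for
    nuclei a few pixels across at center spacings down to ~6 px: heavier
    smoothing merges adjacent nuclei into a single peak.
    """
    dapi = np.asarray(dapi, dtype=float)
    if dapi.size == 0:
        raise ValueError("empty DAPI image")
    if smooth_sigma < 0:
        raise ValueError("smooth_sigma must be >= 0")
    smoothed = gaussian(dapi, sigma=smooth_sigma, preserve_range=True) if smooth_sigma > 0 else dapi
    if np.ptp(smoothed) == 0:  # flat image: no strict maxima
        empty = np.empty(0)
        return SeedSet(ids=empty, x=empty, y=empty, dapi_intensity=empty)
    if min_intensity is None:
        min_intensity = float(threshold_otsu(smoothed))
    coords = peak_local_max(
        smoothed,
        min_distance=int(min_distance_px),
        threshold_abs=float(min_intensity),
        exclude_border=False,
    )
    if len(coords) == 0:
        empty = np.empty(0)
        return SeedSet(ids=empty, x=empty, y=empty, dapi_intensity=empty)
    yy, xx = coords[:, 0], coords[:, 1]
    inten = smoothed[yy, xx]
    order = np.lexsort((xx, yy, -inten))  # primary: intensity desc; ties: (y, x)
    yy, xx, inten = yy[order], xx[order], inten[order]
    return SeedSet(ids=np.arange(1, len(xx) + 1), x=xx, y=yy, dapi_intensity=inten)


def grow_segments(
    seeds: SeedSet,
    shape: tuple[int, int],
    radius_px: float = 6.0,
) -> SegmentMap:
    """Grow the distance-capped Voronoi partition around the seeds.

    Pixel (x, y) is labeled with the id of its nearest seed (Euclidean
    distance between pixel centers, inclusive at exactly ``radius_px``);
    equidistant pixels go to the smaller seed id; pixels beyond the cap from
    every seed stay 0.
    """
    h, w = shape
    if radius_px <= 0:
        raise ValueError("radius_px must be positive")
    xs, ys = seeds.x, seeds.y
    if len(xs):
        if xs.min() < 0 or ys.min() < 0 or xs.max() >= w or ys.max() >= h:
            raise ValueError("seed coordinates outside the grid")
        if len(np.unique(np.stack([xs, ys], axis=1), axis=0)) != len(xs):
            raise ValueError("duplicate seed coordinates")
    labels = np.zeros(shape, dtype=np.int32)
    best_d2 = np.full(shape, np.inf)
    r = int(np.floor(radius_px))
    r2 = radius_px * radius_px
    # process seeds in increasing id order; strict improvement required, so
    # at exact ties the earlier (smaller) id keeps the pixel
    for sid, sx, sy in zip(seeds.ids, xs, ys):
        x0, x1 = max(0, sx - r), min(w, sx + r + 1)
        y0, y1 = max(0, sy - r), min(h, sy + r + 1)
        dx = np.arange(x0, x1) - sx
        dy = np.arange(y0, y1) - sy
        d2 = dy[:, None] ** 2 + dx[None, :] ** 2
        win = (d2 <= r2) & (d2 < best_d2[y0:y1, x0:x1])
        labels[y0:y1, x0:x1][win] = sid
        best_d2[y0:y1, x0:x1] = np.where(win, d2, best_d2[y0:y1, x0:x1])
    return SegmentMap(labels=labels, radius_px=float(radius_px))


def contact_graph(seg: SegmentMap, connectivity: int = 8) -> NeighborGraph:
    """Adjacency between segments whose territories directly touch.

    Edge (a, b) exists iff some pixel labeled a has a pixel labeled b in its
    4- or 8-neighborhood. Background (0) creates no edges. Connectivity 8
    (the default) counts corner contact as touching.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    L = seg.labels
    shifts = [((slice(None), slice(None, -1)), (slice(None), slice(1, None))),  # right
              ((slice(None, -1), slice(None)), (slice(1, None), slice(None)))]  # down
    if connectivity == 8:
        shifts += [
            ((slice(None, -1), slice(None, -1)), (slice(1, None), slice(1, None))),  # down-right
            ((slice(None, -1), slice(1, None)), (slice(1, None), slice(None, -1))),  # down-left
        ]
    pairs = []
    for sa, sb in shifts:
        a, b = L[sa], L[sb]
        m = (a != b) & (a > 0) & (b > 0)
        if m.any():
            pairs.append(np.stack([a[m], b[m]], axis=1))
    nodes = {int(i) for i in np.unique(L) if i > 0}
    edges: set[tuple[int, int]] = set()
    if pairs:
        p = np.concatenate(pairs)
        p = np.stack([p.min(axis=1), p.max(axis=1)], axis=1)
        edges = {(int(a), int(b)) for a, b in np.unique(p, axis=0)}
    return NeighborGraph(nodes=nodes, edges=edges)
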