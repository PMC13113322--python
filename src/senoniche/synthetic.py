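"""Synthetic aged-liver section generator with full ground truth.

Emulates the structure of a zonated liver section profiled by a
micrometer-resolution spatial platform with co-registered DAPI/GFP/tdTomato
imaging of a p21-Cre dual-reporter animal:

* nuclei placed by Poisson-disc sampling (minimum spacing 2x nuclear radius);
* a DAPI channel of isotropic Gaussian nuclear blobs plus background noise;
* rare reporter-positive cells (either GFP+tdTomato double-positive, ongoing
  p21 activity, or tdTomato-only, prior activation history) lighting up the
  GFP/tdTomato channels;
* per-cell transcript point clouds with Poisson totals, placed in a
  cytoplasmic annulus around the nucleus, gene identities drawn from
  cell-type expression profiles with a monotone periportal->pericentral
  mixing gradient along x;
* an ISG-expressing focus (interferon-stimulated program: Rsad2, Ifit1,
  Cmpk2, Ifit3) planted as a compact group of cells;
* p21-positive macrophages with boosted SASP chemokines (Gpnmb, Cxcl9,
  Cxcl10).

Everything is reproducible from ``TissueConfig.rng_seed`` and the per-cell /
per-transcript ground truth is returned alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .io import FluorescenceStack, SdgeTable

__all__ = [
    "TissueConfig",
    "GroundTruth",
    "PlacementError",
    "generate_tissue",
    "default_expression_profiles",
    "default_marker_panels",
    "PERIPORTAL_MARKERS",
    "PERICENTRAL_MARKERS",
    "SASP_GENES",
    "ISG_GENES",
]

REPORTER_CLASSES = ("none", "gfp_only", "tdtomato_only", "double")

PERIPORTAL_MARKERS = ("Cyp2f2", "Hal", "Sds")
PERICENTRAL_MARKERS = ("Glul", "Cyp2e1", "Oat")
SASP_GENES = ("Gpnmb", "Cxcl9", "Cxcl10", "Ccl8", "Mmp3")
ISG_GENES = ("Rsad2", "Ifit1", "Cmpk2", "Ifit3")

N_BACKGROUND_GENES = 250


class PlacementError(RuntimeError):
    """Poisson-disc sampling could not place the requested number of cells."""


def _background_genes() -> list[str]:
    return [f"Gm{1000 + i}" for i in range(1, N_BACKGROUND_GENES + 1)]


def default_expression_profiles() -> dict[str, dict[str, float]]:
    """Per-type gene weight vectors (unnormalized sampling weights).

    Marker weights are strong (10-60x a background gene), as canonical
    markers are in real liver data. Zonation genes carry a placeholder
    weight here; at sampling time their weight is split between the
    periportal and pericentral sets according to the cell's x position.
    """
    common = {g: 1.0 for g in _background_genes()}
    common.update({"Actb": 8.0, "B2m": 4.0, "Cdkn1a": 0.5})

    hep = dict(common)
    hep.update({"Alb": 60.0, "Ttr": 20.0, "Apoa1": 15.0})
    # total zonation mass 36, split by gradient at sampling time
    for g in PERIPORTAL_MARKERS + PERICENTRAL_MARKERS:
        hep[g] = 0.0

    injured = dict(common)
    injured.update({"Alb": 25.0, "Ttr": 8.0, "Saa1": 50.0, "Saa2": 40.0})

    mac = dict(common)
    mac.update(
        {
            "Vcam1": 25.0, "Cd74": 30.0, "H2-Ab1": 20.0, "Clec4f": 15.0,
            "Cxcl13": 10.0,
            "Gpnmb": 4.0, "Cxcl9": 4.0, "Cxcl10": 4.0, "Ccl8": 3.0, "Mmp3": 3.0,
        }
    )

    neut = dict(common)
    neut.update({"S100a8": 40.0, "S100a9": 40.0, "Ngp": 20.0, "Il1b": 8.0})

    plasma = dict(common)
    plasma.update({"Igkc": 50.0, "Jchain": 40.0, "Mzb1": 25.0})

    hsc = dict(common)
    hsc.update({"Col1a1": 35.0, "Col3a1": 30.0, "Dcn": 20.0})

    isg = dict(common)
    isg.update(
        {
            "Alb": 15.0,
            "Rsad2": 35.0, "Ifit1": 25.0, "Cmpk2": 20.0, "Ifit3": 20.0,
            "Cxcl10": 10.0, "Cxcl9": 6.0,
        }
    )

    return {
        "hepatocyte": hep,
        "injured_hep": injured,
        "macrophage": mac,
        "neutrophil": neut,
        "plasma_cell": plasma,
        "hsc": hsc,
        "isg": isg,  # override profile for the planted ISG focus
    }


def default_marker_panels() -> dict[str, list[str]]:
    """Canonical marker panels used for type annotation."""
    return {
        "hepatocyte": ["Alb", "Ttr", "Apoa1", "Cyp2f2", "Glul"],
        "injured_hep": ["Saa1", "Saa2"],
        "macrophage": ["Vcam1", "Cd74", "H2-Ab1", "Clec4f"],
        "neutrophil": ["S100a8", "S100a9", "Ngp"],
        "plasma_cell": ["Igkc", "Jchain", "Mzb1"],
        "hsc": ["Col1a1", "Col3a1", "Dcn"],
        "isg": list(ISG_GENES),
    }


@dataclass
class TissueConfig:
    """Study conditions for the synthetic section.

    Defaults emulate a 1.28 mm square of aged mouse liver at 2.5 um/px
    (so the 6 px segmentation radius is ~15 um): 2000 cells dominated by
    hepatocytes, reporter-positive cells a ~1.6% minority concentrated in
    macrophages, one compact ISG focus, and ~500 captured transcripts per
    cell (same order as the per-cell depth of the real platform).
    """

    width_px: int = 512
    height_px: int = 512
    pixel_size_um: float = 2.5
    n_cells: int = 2000
    n_replicates: int = 3
    type_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "hepatocyte": 0.70,
            "macrophage": 0.12,
            "neutrophil": 0.05,
            "plasma_cell": 0.04,
            "hsc": 0.05,
            "injured_hep": 0.04,
        }
    )
    p21_fraction_by_type: dict[str, float] = field(
        default_factory=lambda: {
            "hepatocyte": 0.012,
            "macrophage": 0.04,
            "neutrophil": 0.015,
            "plasma_cell": 0.015,
            "hsc": 0.02,
            "injured_hep": 0.015,
        }
    )
    double_positive_fraction: float = 0.6  # remainder is tdTomato-only
    isg_focus: tuple[tuple[float, float], float, int] = ((400.0, 130.0), 45.0, 40)
    mean_counts_per_cell: float = 500.0
    nuclear_radius_px: float = 3.0
    cytoplasm_annulus_px: tuple[float, float] = (3.0, 6.0)
    zonation_mass: float = 36.0
    sasp_boost_genes: tuple[str, ...] = ("Gpnmb", "Cxcl9", "Cxcl10")
    sasp_boost_factor: float = 4.0
    sasp_boost_type: str = "macrophage"
    cdkn1a_boost_factor: float = 8.0
    reporter_transcript_weight: float = 6.0
    fluor_snr: float = 10.0
    rng_seed: int = 0
    expression_profiles: dict[str, dict[str, float]] | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        total = sum(self.type_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"type_proportions must sum to 1 (got {total})")
        for name, frac in {**self.type_proportions, **self.p21_fraction_by_type}.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction for {name!r} outside [0, 1]")
        if not 0.0 <= self.double_positive_fraction <= 1.0:
            raise ValueError("double_positive_fraction outside [0, 1]")

    def profiles(self) -> dict[str, dict[str, float]]:
        return self.expression_profiles or default_expression_profiles()

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["isg_focus"] = {
            "center": list(self.isg_focus[0]),
            "radius": float(self.isg_focus[1]),
            "n_cells": int(self.isg_focus[2]),
        }
        d["cytoplasm_annulus_px"] = list(self.cytoplasm_annulus_px)
        d["sasp_boost_genes"] = list(self.sasp_boost_genes)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TissueConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "isg_focus" in d and isinstance(d["isg_focus"], dict):
            f = d["isg_focus"]
            d["isg_focus"] = (tuple(f["center"]), float(f["radius"]), int(f["n_cells"]))
        if "cytoplasm_annulus_px" in d:
            d["cytoplasm_annulus_px"] = tuple(d["cytoplasm_annulus_px"])
        if "sasp_boost_genes" in d:
            d["sasp_boost_genes"] = tuple(d["sasp_boost_genes"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted truth: per-cell table and per-transcript source cell ids.

    ``cells`` columns: cell_id (1-based), x, y (true centroid), cell_type,
    reporter_class, is_isg, replicate. ``transcript_cell`` aligns with the
    rows of the generated :class:`SdgeTable`.
    """

    cells: pd.DataFrame
    transcript_cell: np.ndarray

    def __post_init__(self) -> None:
        bad = set(self.cells["reporter_class"]) - set(REPORTER_CLASSES)
        if bad:
            raise ValueError(f"unknown reporter classes: {bad}")
        if len(self.transcript_cell):
            known = set(self.cells["cell_id"])
            if not set(np.unique(self.transcript_cell)).issubset(known):
                raise ValueError("transcript source cell id does not exist")


# ---------------------------------------------------------------------------


def _poisson_disc(
    rng: np.random.Generator,
    n: int,
    width: float,
    height: float,
    min_dist: float,
    margin: float,
    max_attempts_per_point: int = 200,
) -> np.ndarray:
    """Dart-throwing Poisson-disc sampler on [margin, width-margin) x [...)."""
    lo_x, hi_x = margin, width - margin
    lo_y, hi_y = margin, height - margin
    if hi_x <= lo_x or hi_y <= lo_y:
        raise PlacementError("domain smaller than the required margin")
    cell = min_dist / np.sqrt(2.0)
    nx = int(np.ceil((hi_x - lo_x) / cell))
    ny = int(np.ceil((hi_y - lo_y) / cell))
    grid: dict[tuple[int, int], int] = {}
    pts = np.empty((n, 2))
    d2 = min_dist * min_dist
    placed = 0
    attempts = 0
    budget = max_attempts_per_point * n
    while placed < n:
        if attempts >= budget:
            raise PlacementError(
                f"could only place {placed} of {n} cells at spacing {min_dist:g}px; "
                "reduce n_cells or enlarge the section"
            )
        attempts += 1
        px = rng.uniform(lo_x, hi_x)
        py = rng.uniform(lo_y, hi_y)
        gx = int((px - lo_x) / cell)
        gy = int((py - lo_y) / cell)
        ok = True
        for ix in range(max(0, gx - 2), min(nx, gx + 3)):
            for iy in range(max(0, gy - 2), min(ny, gy + 3)):
                j = grid.get((ix, iy))
                if j is not None:
                    q = pts[j]
                    if (q[0] - px) ** 2 + (q[1] - py) ** 2 < d2:
                        ok = False
                        break
            if not ok:
                break
        if ok:
            pts[placed] = (px, py)
            grid[(gx, gy)] = placed
            placed += 1
    return pts


def _render_blobs(
    shape: tuple[int, int],
    centers: np.ndarray,
    sigma: float,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Sum of isotropic Gaussian blobs, each rendered on a local window."""
    img = np.zeros(shape, dtype=np.float64)
    if len(centers) == 0:
        return img
    h, w = shape
    half = int(np.ceil(4 * sigma))
    for cx, cy in centers:
        x0, x1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
        y0, y1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
        xs = np.arange(x0, x1) - cx
        ys = np.arange(y0, y1) - cy
        img[y0:y1, x0:x1] += amplitude * np.exp(
            -(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * sigma * sigma)
        )
    return img


def _render_disks(
    shape: tuple[int, int],
    centers: np.ndarray,
    radius: float,
    edge_sigma: float = 1.0,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Soft-edged filled disks: flat top inside ``radius``, Gaussian rolloff.

    Models cytoplasm-filling reporter fluorescence, which is roughly uniform
    over the cell body and falls off quickly at the membrane (unlike the
    peaked nuclear DAPI signal).
    """
    img = np.zeros(shape, dtype=np.float64)
    if len(centers) == 0:
        return img
    h, w = shape
    half = int(np.ceil(radius + 4 * edge_sigma))
    for cx, cy in centers:
        x0, x1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
        y0, y1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
        xs = np.arange(x0, x1) - cx
        ys = np.arange(y0, y1) - cy
        r = np.sqrt(ys[:, None] ** 2 + xs[None, :] ** 2)
        excess = np.maximum(r - radius, 0.0)
        img[y0:y1, x0:x1] += amplitude * np.exp(-(excess**2) / (2 * edge_sigma**2))
    return img


def _replicate_of(y: np.ndarray, height: int, n_replicates: int) -> np.ndarray:
    """Replicate blocks along y (each block stands in for one section)."""
    rep = np.floor(np.asarray(y, dtype=float) * n_replicates / height).astype(int)
    return np.clip(rep, 0, n_replicates - 1) + 1


def generate_tissue(
    cfg: TissueConfig,
) -> tuple[SdgeTable, FluorescenceStack, GroundTruth]:
    """Generate (sDGE table, fluorescence stack, ground truth) from ``cfg``."""
    rng = np.random.default_rng(cfg.rng_seed)
    profiles = cfg.profiles()
    margin = cfg.cytoplasm_annulus_px[1]

    centers = _poisson_disc(
        rng,
        cfg.n_cells,
        cfg.width_px,
        cfg.height_px,
        min_dist=2.0 * cfg.nuclear_radius_px,
        margin=margin,
    )

    # --- per-cell truth -----------------------------------------------------
    types = list(cfg.type_proportions)
    type_p = np.array([cfg.type_proportions[t] for t in types])
    cell_type = rng.choice(len(types), size=cfg.n_cells, p=type_p)
    cell_type = np.array([types[i] for i in cell_type])

    p21_frac = np.array([cfg.p21_fraction_by_type.get(t, 0.0) for t in cell_type])
    is_p21 = rng.random(cfg.n_cells) < p21_frac
    reporter = np.full(cfg.n_cells, "none", dtype=object)
    dbl = rng.random(cfg.n_cells) < cfg.double_positive_fraction
    reporter[is_p21 & dbl] = "double"
    reporter[is_p21 & ~dbl] = "tdtomato_only"

    (fx, fy), fr, fn = cfg.isg_focus
    dist_focus = np.hypot(centers[:, 0] - fx, centers[:, 1] - fy)
    in_radius = np.where(dist_focus <= fr)[0]
    focus_idx = in_radius[np.argsort(dist_focus[in_radius])][:fn]
    is_isg = np.zeros(cfg.n_cells, dtype=bool)
    is_isg[focus_idx] = True

    replicate = _replicate_of(centers[:, 1], cfg.height_px, cfg.n_replicates)

    # --- gene universe ------------------------------------------------------
    gene_set: dict[str, None] = {}
    for prof in profiles.values():
        for g in prof:
            gene_set[g] = None
    for g in PERIPORTAL_MARKERS + PERICENTRAL_MARKERS + ("EGFP", "tdTomato"):
        gene_set[g] = None
    genes = list(gene_set)
    gene_index = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    base_w = {
        t: np.array([prof.get(g, 0.0) for g in genes])
        for t, prof in profiles.items()
    }
    pp_idx = [gene_index[g] for g in PERIPORTAL_MARKERS]
    pc_idx = [gene_index[g] for g in PERICENTRAL_MARKERS]
    sasp_idx = [gene_index[g] for g in cfg.sasp_boost_genes if g in gene_index]
    cdkn1a_idx = gene_index.get("Cdkn1a")
    egfp_idx = gene_index["EGFP"]
    tdt_idx = gene_index["tdTomato"]

    # --- transcripts --------------------------------------------------------
    r_in2, r_out2 = cfg.cytoplasm_annulus_px[0] ** 2, cfg.cytoplasm_annulus_px[1] ** 2
    n_per_cell = rng.poisson(cfg.mean_counts_per_cell, size=cfg.n_cells)
    xs_all, ys_all, gene_all, src_all = [], [], [], []
    for i in range(cfg.n_cells):
        w = base_w["isg" if is_isg[i] else cell_type[i]].copy()
        if not is_isg[i] and cell_type[i] == "hepatocyte":
            t = centers[i, 0] / max(cfg.width_px - 1, 1)
            w[pp_idx] = cfg.zonation_mass * (1.0 - t) / len(pp_idx)
            w[pc_idx] = cfg.zonation_mass * t / len(pc_idx)
        if is_p21[i]:
            if cdkn1a_idx is not None:
                w[cdkn1a_idx] *= cfg.cdkn1a_boost_factor
            if reporter[i] == "double":
                w[egfp_idx] = cfg.reporter_transcript_weight
            w[tdt_idx] = cfg.reporter_transcript_weight
            if cell_type[i] == cfg.sasp_boost_type:
                w[sasp_idx] *= cfg.sasp_boost_factor
        n_i = int(n_per_cell[i])
        if n_i == 0:
            continue
        counts = rng.multinomial(n_i, w / w.sum())
        gidx = np.repeat(np.arange(n_genes), counts)
        r = np.sqrt(rng.uniform(r_in2, r_out2, size=n_i))
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n_i)
        xs_all.append(centers[i, 0] + r * np.cos(theta))
        ys_all.append(centers[i, 1] + r * np.sin(theta))
        gene_all.append(gidx)
        src_all.append(np.full(n_i, i + 1, dtype=np.int64))

    if xs_all:
        x = np.clip(np.concatenate(xs_all), 0.0, cfg.width_px - 1e-6)
        y = np.clip(np.concatenate(ys_all), 0.0, cfg.height_px - 1e-6)
        gidx = np.concatenate(gene_all)
        src = np.concatenate(src_all)
    else:
        x = y = np.empty(0)
        gidx = src = np.empty(0, dtype=np.int64)

    records = pd.DataFrame(
        {
            "x": x,
            "y": y,
            "gene": pd.Categorical.from_codes(gidx, categories=genes).astype(str),
            "count": np.ones(len(x), dtype=int),
        }
    )
    sdge = SdgeTable(records=records, pixel_size_um=cfg.pixel_size_um)

    # --- fluorescence -------------------------------------------------------
    shape = (cfg.height_px, cfg.width_px)
    noise_scale = 1.0 / cfg.fluor_snr if cfg.fluor_snr > 0 else 0.0
    dapi_sigma = cfg.nuclear_radius_px / 1.5
    # reporter protein fills the cytoplasm: flat disk slightly inside the
    # cell territory, sharp rolloff at the membrane
    reporter_radius = cfg.cytoplasm_annulus_px[1] - 1.5

    dapi = _render_blobs(shape, centers, dapi_sigma)
    gfp_centers = centers[reporter == "double"]
    tdt_centers = centers[(reporter == "double") | (reporter == "tdtomato_only")]
    gfp = _render_disks(shape, gfp_centers, reporter_radius)
    tdt = _render_disks(shape, tdt_centers, reporter_radius)
    for img in (dapi, gfp, tdt):
        img += np.abs(rng.normal(0.0, noise_scale, size=shape))
    stack = FluorescenceStack(
        channels={"dapi": dapi, "gfp": gfp, "tdtomato": tdt},
        pixel_size_um=cfg.pixel_size_um,
    )

    truth = GroundTruth(
        cells=pd.DataFrame(
            {
                "cell_id": np.arange(1, cfg.n_cells + 1),
                "x": centers[:, 0],
                "y": centers[:, 1],
                "cell_type": cell_type,
                "reporter_class": reporter,
                "is_isg": is_isg,
                "replicate": replicate,
            }
        ),
        transcript_cell=src,
    )
    return sdge, stack, truth
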