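"""End-to-end orchestration: simulate/ingest -> segment -> quantify ->
annotate -> niche -> statistics, with deterministic on-disk artifacts and a
run manifest.

Every stage writes its result in the package's plain-text formats (TSV, MTX,
TIFF) under the output directory; the manifest records the configuration,
seeds, and per-stage counts so a run is fully reproducible: identical config
and seeds give byte-identical result tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .annotation import MarkerPanels, assign_types, normalize, score_panels
from .niche import assign_roles, composition_table, p21_rate_by_type
from .quantification import (
    QcConfig,
    assign_transcripts,
    background_thresholds,
    call_reporter,
    qc_filter,
    quantify_fluorescence,
    reporter_calls_frame,
)
from .segmentation import contact_graph, detect_nuclei, grow_segments
from .stats import (
    IsgPanel,
    contrasts_frame,
    isg_call,
    isg_score,
    overlap_analysis,
    overlap_frame,
    run_contrasts,
)
from .synthetic import TissueConfig, generate_tissue, _replicate_of

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``synthetic`` (a :class:`TissueConfig`) or ``sdge_path``
    + ``image_dir`` must be supplied.
    """

    synthetic: TissueConfig | None = None
    sdge_path: str | None = None
    image_dir: str | None = None
    pixel_size_um: float = 2.5
    radius_px: float = 6.0
    connectivity: int = 8
    min_unique_features: int = 100
    threshold_quantile_pct: float = 99.9
    p21_rule: str = "or"
    panels: MarkerPanels = field(default_factory=MarkerPanels.default)
    min_margin: float = 0.25
    isg_panel: IsgPanel = field(default_factory=IsgPanel)
    isg_threshold_quantile: float = 0.98
    min_cells_per_group: int = 3
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.sdge_path is not None and self.image_dir is not None
        if (self.synthetic is None) == (not has_files):
            raise ValueError(
                "supply exactly one of: a synthetic TissueConfig, or "
                "sdge_path + image_dir"
            )
        if has_files:
            for p in (self.sdge_path, self.image_dir):
                if not Path(p).exists():
                    raise FileNotFoundError(p)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages in order and write every intermediate artifact.

    Returns the run manifest (also written to ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings: dict[str, float] = {}
    counts: dict[str, int] = {}

    def stage_done(name: str) -> None:
        timings[name] = round(time.time() - t0 - sum(timings.values()), 3)
        log.info("stage %s done (%.2fs)", name, timings[name])

    # --- inputs -------------------------------------------------------------
    if cfg.synthetic is not None:
        sdge, stack, truth = generate_tissue(cfg.synthetic)
        sio.write_sdge(sdge, outdir / "sdge.tsv")
        sio.write_fluorescence(stack, outdir / "images")
        _write_tsv(truth.cells, outdir / "ground_truth_cells.tsv")
        height = cfg.synthetic.height_px
        n_replicates = cfg.synthetic.n_replicates
    else:
        sdge = sio.read_sdge(cfg.sdge_path, pixel_size_um=cfg.pixel_size_um)
        stack = sio.read_fluorescence(cfg.image_dir, pixel_size_um=cfg.pixel_size_um)
        height = stack.shape[0]
        n_replicates = cfg.n_replicates
    counts["transcript_records"] = len(sdge)
    stage_done("input")

    # --- segmentation -------------------------------------------------------
    seeds = detect_nuclei(stack["dapi"])
    seg = grow_segments(seeds, shape=stack.shape, radius_px=cfg.radius_px)
    seeds.to_frame().to_csv(outdir / "seeds.tsv", sep="\t", index=False,
                            float_format=_FLOAT_FMT)
    sio.write_label_map(seg.labels, outdir / "segments.tif")
    counts["seeds_detected"] = len(seeds)
    counts["cells_segmented"] = len(seeds)
    stage_done("segmentation")

    # --- quantification -----------------------------------------------------
    matrix, unassigned = assign_transcripts(sdge, seg)
    counts["transcripts_unassigned"] = unassigned
    means = quantify_fluorescence(seg, stack)
    thresholds = background_thresholds(stack, seg,
                                       quantile_pct=cfg.threshold_quantile_pct)
    calls = call_reporter(means, thresholds, p21_rule=cfg.p21_rule)
    calls_df = reporter_calls_frame(calls)
    _write_tsv(calls_df, outdir / "reporter_calls.tsv")

    matrix.cell_meta["reporter_class"] = calls_df["reporter_class"].to_numpy()
    matrix.cell_meta["is_p21_positive"] = calls_df["is_p21_positive"].to_numpy()
    matrix.cell_meta["replicate"] = _replicate_of(
        matrix.cell_meta["centroid_y"].to_numpy(), height, n_replicates
    )
    qc = QcConfig(min_unique_features=cfg.min_unique_features)
    matrix = qc_filter(matrix, qc)
    counts["cells_qc_passing"] = matrix.n_cells
    counts["p21_positive_cells"] = int(matrix.cell_meta["is_p21_positive"].sum())
    sio.write_cell_matrix(matrix, outdir / "cell_matrix")
    stage_done("quantification")

    # --- annotation ---------------------------------------------------------
    if matrix.n_cells == 0:
        raise RuntimeError("no cells passed QC; aborting after quantification")
    nm = normalize(matrix)
    scores = score_panels(nm, cfg.panels)
    types = assign_types(scores, min_margin=cfg.min_margin)
    matrix.cell_meta["cell_type"] = types.to_numpy()
    _write_tsv(
        types.rename("cell_type").reset_index(), outdir / "cell_types.tsv"
    )
    stage_done("annotation")

    # --- niche --------------------------------------------------------------
    graph = contact_graph(seg, connectivity=cfg.connectivity)
    qc_ids = set(int(i) for i in matrix.cell_meta["segment_id"])
    # neighbors computed among QC-passing cells only
    sub_nodes = graph.nodes & qc_ids
    sub_edges = {(a, b) for a, b in graph.edges if a in qc_ids and b in qc_ids}
    from .segmentation import NeighborGraph

    sub_graph = NeighborGraph(nodes=sub_nodes, edges=sub_edges)
    p21_ids = set(
        int(i)
        for i in matrix.cell_meta.loc[matrix.cell_meta["is_p21_positive"], "segment_id"]
    )
    roles = assign_roles(sub_graph, p21_ids & sub_nodes)
    roles = roles.reindex(matrix.cell_meta["segment_id"]).fillna("other")
    matrix.cell_meta["niche_role"] = roles.to_numpy()
    counts["neighbor_cells"] = int((roles == "neighbor").sum())

    types_s = pd.Series(
        matrix.cell_meta["cell_type"].to_numpy(),
        index=matrix.cell_meta["segment_id"], name="cell_type",
    )
    rep_s = pd.Series(
        matrix.cell_meta["replicate"].to_numpy(),
        index=matrix.cell_meta["segment_id"], name="replicate",
    )
    roles_s = pd.Series(
        matrix.cell_meta["niche_role"].to_numpy(),
        index=matrix.cell_meta["segment_id"], name="niche_role",
    )
    _write_tsv(roles_s.reset_index(), outdir / "niche_roles.tsv")
    _write_tsv(composition_table(roles_s, types_s), outdir / "niche_composition.tsv")
    _write_tsv(p21_rate_by_type(roles_s, types_s, rep_s), outdir / "p21_rates.tsv")
    stage_done("niche")

    # --- statistics ---------------------------------------------------------
    results = run_contrasts(nm, roles_s, types_s,
                            min_cells=cfg.min_cells_per_group)
    _write_tsv(contrasts_frame(results), outdir / "contrasts.tsv")

    scores_isg = isg_score(nm, cfg.isg_panel)
    isg_status = isg_call(scores_isg, cfg.isg_threshold_quantile)
    _write_tsv(
        pd.DataFrame(
            {"segment_id": scores_isg.index, "isg_score": scores_isg.to_numpy(),
             "is_isg_positive": isg_status.to_numpy()}
        ),
        outdir / "isg_scores.tsv",
    )
    p21_s = pd.Series(
        matrix.cell_meta["is_p21_positive"].to_numpy(),
        index=matrix.cell_meta["segment_id"],
    )
    tables, pooled = overlap_analysis(p21_s, isg_status, rep_s)
    _write_tsv(overlap_frame(tables), outdir / "overlap_tables.tsv")
    _write_tsv(pooled, outdir / "overlap_pooled.tsv")
    counts["isg_positive_cells"] = int(isg_status.sum())
    counts["contrasts_evaluated"] = len(results)
    stage_done("stats")

    # --- manifest -----------------------------------------------------------
    cfg_desc = {
        "synthetic": (cfg.synthetic.__dict__ if cfg.synthetic else None),
        "sdge_path": cfg.sdge_path,
        "image_dir": cfg.image_dir,
        "radius_px": cfg.radius_px,
        "connectivity": cfg.connectivity,
        "min_unique_features": cfg.min_unique_features,
        "threshold_quantile_pct": cfg.threshold_quantile_pct,
        "p21_rule": cfg.p21_rule,
        "min_margin": cfg.min_margin,
        "isg_threshold_quantile": cfg.isg_threshold_quantile,
        "min_cells_per_group": cfg.min_cells_per_group,
        "seed": cfg.seed,
    }
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_desc, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest = {
        "config_hash": cfg_hash,
        "seed": cfg.seed,
        "counts": counts,
        "timings_s": timings,
        "outputs": sorted(p.name for p in outdir.iterdir()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
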