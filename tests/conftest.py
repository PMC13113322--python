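"""Shared fixtures: the default synthetic section and a fully analyzed run.

The heavy objects are session-scoped so the generator and the analysis
chain run once; individual tests only read from them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from senoniche.annotation import MarkerPanels, assign_types, normalize, score_panels
from senoniche.niche import assign_roles
from senoniche.quantification import (
    QcConfig,
    assign_transcripts,
    background_thresholds,
    call_reporter,
    qc_filter,
    quantify_fluorescence,
    reporter_calls_frame,
)
from senoniche.segmentation import SeedSet, contact_graph, detect_nuclei, grow_segments
from senoniche.synthetic import TissueConfig, generate_tissue, _replicate_of
from senoniche.evaluate import match_points


def brute_force_capped_voronoi(
    seeds: SeedSet, shape: tuple[int, int], radius_px: float
) -> np.ndarray:
    """Independent oracle: per-pixel nearest seed within the radius cap.

    Every pixel is compared against every seed; ties in squared distance go
    to the smaller seed id (ids are ordered, so argmin on a stable first-hit
    basis implements the rule).
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    pix = np.stack([xx.ravel(), yy.ravel()], axis=1)
    if len(seeds) == 0:
        return np.zeros(shape, dtype=np.int32)
    sxy = np.stack([seeds.x, seeds.y], axis=1)
    d2 = ((pix[:, None, :] - sxy[None, :, :]) ** 2).sum(axis=2)
    best = np.argmin(d2, axis=1)  # np.argmin returns the FIRST minimum: smaller id
    best_d2 = d2[np.arange(len(pix)), best]
    labels = np.where(best_d2 <= radius_px**2, seeds.ids[best], 0)
    return labels.reshape(shape).astype(np.int32)


@pytest.fixture(scope="session")
def default_tissue():
    """The default synthetic section (fixed seed) with ground truth."""
    return generate_tissue(TissueConfig())


@pytest.fixture(scope="session")
def default_analysis(default_tissue):
    """Full analysis of the default section, all stages applied in order."""
    sdge, stack, truth = default_tissue
    cfg = TissueConfig()

    seeds = detect_nuclei(stack["dapi"])
    seg = grow_segments(seeds, stack.shape, radius_px=6.0)
    matrix, unassigned = assign_transcripts(sdge, seg)

    means = quantify_fluorescence(seg, stack)
    thresholds = background_thresholds(stack, seg)
    calls = reporter_calls_frame(call_reporter(means, thresholds))
    matrix.cell_meta["reporter_class"] = calls["reporter_class"].to_numpy()
    matrix.cell_meta["is_p21_positive"] = calls["is_p21_positive"].to_numpy()
    matrix.cell_meta["replicate"] = _replicate_of(
        matrix.cell_meta["centroid_y"].to_numpy(), cfg.height_px, cfg.n_replicates
    )
    matrix = qc_filter(matrix, QcConfig())

    nm = normalize(matrix)
    types = assign_types(score_panels(nm, MarkerPanels.default()))

    graph = contact_graph(seg)
    qc_ids = set(int(i) for i in matrix.cell_meta["segment_id"])
    from senoniche.segmentation import NeighborGraph

    sub = NeighborGraph(
        nodes=graph.nodes & qc_ids,
        edges={(a, b) for a, b in graph.edges if a in qc_ids and b in qc_ids},
    )
    p21_ids = {
        int(i)
        for i in matrix.cell_meta.loc[matrix.cell_meta["is_p21_positive"], "segment_id"]
    }
    roles = assign_roles(sub, p21_ids).reindex(matrix.cell_meta["segment_id"]).fillna("other")
    roles.name = "niche_role"

    # one-to-one match of detected segments to planted cells (3 px)
    matches = match_points(
        np.stack([seeds.x, seeds.y], axis=1),
        truth.cells[["x", "y"]].to_numpy(),
        max_dist=3.0,
    )
    seg_to_truth = {
        int(d) + 1: int(t) for d, t in zip(matches.detected_idx, matches.truth_idx)
    }

    types_s = pd.Series(types.to_numpy(), index=matrix.cell_meta["segment_id"], name="cell_type")
    rep_s = pd.Series(
        matrix.cell_meta["replicate"].to_numpy(),
        index=matrix.cell_meta["segment_id"], name="replicate",
    )
    return {
        "config": cfg,
        "sdge": sdge,
        "stack": stack,
        "truth": truth,
        "seeds": seeds,
        "seg": seg,
        "matrix": matrix,
        "unassigned": unassigned,
        "calls": calls,
        "nm": nm,
        "types": types_s,
        "roles": roles,
        "replicate": rep_s,
        "seg_to_truth": seg_to_truth,
    }


def effective_truth_types(truth) -> pd.Series:
    """Planted type labels with the ISG focus treated as its own annotation."""
    return truth.cells["cell_type"].where(~truth.cells["is_isg"], "isg")
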