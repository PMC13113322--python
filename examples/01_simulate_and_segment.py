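"""Simulate a small reporter-tissue section and segment it from DAPI.

Generates a 256-px synthetic liver section with known ground truth, detects
nuclear seeds on the DAPI channel, grows radius-capped territories, and
reports how well the detected seeds recover the planted nuclei.
"""

import numpy as np

from senoniche.evaluate import seed_precision_recall
from senoniche.segmentation import detect_nuclei, grow_segments
from senoniche.synthetic import TissueConfig, generate_tissue

cfg = TissueConfig(width_px=256, height_px=256, n_cells=400,
                   mean_counts_per_cell=300.0, rng_seed=1,
                   isg_focus=((190.0, 70.0), 35.0, 10))
sdge, stack, truth = generate_tissue(cfg)
print(f"simulated {len(truth.cells)} cells emitting {len(sdge)} transcripts")

seeds = detect_nuclei(stack["dapi"])
seg = grow_segments(seeds, stack.shape, radius_px=6.0)
precision, recall, _ = seed_precision_recall(
    np.stack([seeds.x, seeds.y], axis=1),
    truth.cells[["x", "y"]].to_numpy(),
    max_dist=3.0,
)
areas = seg.areas(len(seeds))
print(f"detected {len(seeds)} seeds: precision {precision:.3f}, recall {recall:.3f}")
print(f"median territory {int(np.median(areas))} px (isolated cap = 113 px at radius 6)")
# precision/recall near 1 mean nearly every planted nucleus maps one-to-one
# to a detected seed within 3 px; territories shrink below 113 px wherever
# neighboring cells meet before the radius cap.
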