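# senoniche

Fluorescence-guided spatial single-cell analysis of senescent cells, for
micrometer-resolution spatial transcriptomics of reporter tissue.

Senescent cells are rare (roughly 1–2% of an aged tissue), span many
lineages, and reshape their local neighborhood through secreted signals
(the SASP). `senoniche` implements the analysis layer for experiments that
co-register a spatial digital gene expression (sDGE) table — one record per
captured transcript with (x, y) pixel coordinates — with DAPI/GFP/tdTomato
fluorescence of a p21-Cre dual-reporter section (GFP+tdTomato = ongoing p21
activity; tdTomato-only = prior activation history):

1. **Nuclear-anchored segmentation.** DAPI intensity peaks become segment
   centers; each seed grows isotropically until it meets a neighbor or a
   6-pixel radius cap (~15 µm at 2.5 µm/px). Formally, pixel *p* receives
   label *k* iff seed *k* is its nearest seed and ‖p − s_k‖ ≤ r — the
   distance-capped Voronoi partition (ties to the smaller seed id).
2. **Quantification.** Transcripts are binned to the segment containing
   them; cells with < 100 unique detected genes are removed; per-segment
   mean GFP/tdTomato intensity, thresholded at the 99.9th percentile of
   background pixels, calls each cell's reporter class.
3. **Annotation.** Depth-normalized log expression
   (ln(1 + c·t/total)) is scored against canonical marker panels;
   cluster-then-annotate via PCA → kNN → Leiden is also provided.
4. **Niche analysis.** The boundary-contact graph of segments defines
   neighbors: cells whose territory directly touches a p21⁺ segment.
5. **Statistics.** Within each cell type, two Wilcoxon rank-sum contrasts
   (p21⁺ vs rest, neighbor vs rest) with Benjamini–Hochberg correction;
   significant = adjusted p < 0.05 and log₂FC > 0. A cumulative ISG score
   (panel mean over Rsad2/Ifit1/Cmpk2/Ifit3) is thresholded into an ISG
   status, and p21 × ISG overlap is tested per biological replicate with
   Fisher's exact test on the 2×2 table. Rank-sum (exact enumeration for
   n ≤ 12 without ties) and Fisher (hypergeometric probability-mass rule)
   are implemented from first principles and oracle-tested.

Because real reporter sections are not required for development, the
package ships a **synthetic tissue generator** (`senoniche.synthetic`) that
emulates a zonated aged-liver section with full ground truth: Poisson-disc
nuclei, cytoplasmic transcript point clouds, a periportal→pericentral
gradient, rare multi-lineage reporter cells with SASP-boosted macrophages,
and a compact ISG focus.

## Worked example

```bash
python examples/02_reporter_calling.py
```

```
thresholds: gfp 0.359, tdtomato 0.410
reporter_class
none             1973
tdtomato_only      14
double             13
class agreement with planted truth: 2000/2000 cells
```

All 27 planted reporter cells (1.35% of the section) are recovered with
their exact class — the background-percentile thresholds sit well below
the reporter-filled segments (mean intensity ≈ 0.8) and well above
unlabeled ones (≈ 0.08). Continuing with the niche statistics
(`examples/04_contrasts_and_isg.py`):

```
significant genes, p21+ macrophages vs other macrophages:
    gene   log2fc         qval
  Cdkn1a 1.841579 6.517428e-05
   Cxcl9 0.887552 1.189232e-05
  Cxcl10 0.799250 4.506794e-05
   Gpnmb 0.779859 2.720338e-05
    EGFP 6.506928 5.422166e-18
tdTomato 7.062735 3.175772e-38
```

The three SASP genes planted at 4× in p21⁺ macrophages (Gpnmb, Cxcl9,
Cxcl10) are exactly the biological hits; Cdkn1a (p21 itself) and the two
reporter transcripts act as positive controls. The replicate-wise Fisher
tests on p21 × ISG status all return p = 1, reflecting the planted
independence of the two programs.

A thin CLI mirrors the library
(`senoniche simulate|segment|quantify|annotate|niche|de|isg|overlap|run`);
`senoniche run out/ --seed 1` executes the whole synthetic workflow and
writes every intermediate as TSV/TIFF/MTX plus a JSON manifest.

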