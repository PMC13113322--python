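"""Transcript aggregation, QC filtering, fluorescence summaries, reporter calls."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from senoniche.io import CellMatrix, FluorescenceStack, SdgeTable
from senoniche.quantification import (
    QcConfig,
    assign_transcripts,
    call_reporter,
    qc_filter,
    quantify_fluorescence,
)
from senoniche.segmentation import SegmentMap


def sdge_from_rows(rows):
    df = pd.DataFrame(rows, columns=["x", "y", "gene", "count"])
    return SdgeTable(records=df, pixel_size_um=2.5)


def seg_two_cells():
    lab = np.zeros((10, 10), dtype=int)
    lab[1:4, 1:4] = 1
    lab[6:9, 6:9] = 2
    return SegmentMap(labels=lab, radius_px=6.0)


class TestAssignTranscripts:
    def test_record_inside_segment_counts_toward_it(self):
        m, unassigned = assign_transcripts(
            sdge_from_rows([(2.7, 2.2, "Alb", 3)]), seg_two_cells()
        )
        assert unassigned == 0
        assert m.counts[0, m.gene_ids.index("Alb")] == 3
        assert m.counts.sum() == 3

    def test_background_record_is_unassigned(self):
        m, unassigned = assign_transcripts(
            sdge_from_rows([(0.0, 0.0, "Alb", 2)]), seg_two_cells()
        )
        assert unassigned == 2
        assert m.counts.sum() == 0

    def test_out_of_bounds_rejected_or_skipped(self):
        t = sdge_from_rows([(50.0, 2.0, "Alb", 1)])
        with pytest.raises(ValueError, match="outside"):
            assign_transcripts(t, seg_two_cells())
        m, unassigned = assign_transcripts(t, seg_two_cells(), on_out_of_bounds="skip")
        assert m.counts.sum() == 0 and unassigned == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_against_per_record_retally(self, seed):
        rng = np.random.default_rng(seed)
        lab = rng.integers(0, 6, size=(20, 20))
        seg = SegmentMap(labels=lab, radius_px=6.0)
        n = 500
        rows = pd.DataFrame(
            {
                "x": rng.uniform(0, 20, n),
                "y": rng.uniform(0, 20, n),
                "gene": rng.choice([f"g{i}" for i in range(12)], n),
                "count": rng.integers(1, 5, n),
            }
        )
        table = SdgeTable(records=rows, pixel_size_um=1.0)
        m, unassigned = assign_transcripts(table, seg)
        assert m.counts.sum() + unassigned == table.total_count
        # independent per-record re-tally
        expect = np.zeros((int(lab.max()), len(m.gene_ids)), dtype=int)
        gidx = {g: i for i, g in enumerate(m.gene_ids)}
        for _, r in rows.iterrows():
            s = lab[int(np.floor(r.y)), int(np.floor(r.x))]
            if s > 0:
                expect[s - 1, gidx[r.gene]] += r["count"]
        np.testing.assert_array_equal(m.counts.toarray(), expect)


class TestQcFilter:
    @staticmethod
    def matrix_with_features(n_features_per_cell, n_genes=300):
        rows = []
        for nf in n_features_per_cell:
            row = np.zeros(n_genes, dtype=int)
            row[:nf] = 1
            rows.append(row)
        counts = sp.csr_matrix(np.array(rows))
        meta = pd.DataFrame({"segment_id": np.arange(1, len(rows) + 1)})
        return CellMatrix(counts=counts, cell_meta=meta,
                          gene_ids=[f"g{i}" for i in range(n_genes)])

    def test_cutoff_is_inclusive_at_100(self):
        m = self.matrix_with_features([50, 100, 250])
        out = qc_filter(m, QcConfig(min_unique_features=100))
        assert list(out.cell_meta["segment_id"]) == [2, 3]

    def test_zero_cutoff_keeps_everything(self):
        m = self.matrix_with_features([0, 5, 10])
        assert qc_filter(m, QcConfig(min_unique_features=0)).n_cells == 3

    def test_all_zero_matrix_fully_removed(self):
        m = self.matrix_with_features([0, 0])
        assert qc_filter(m, QcConfig(min_unique_features=100)).n_cells == 0

    def test_idempotent(self):
        m = self.matrix_with_features([50, 150, 220])
        once = qc_filter(m, QcConfig(min_unique_features=100))
        twice = qc_filter(once, QcConfig(min_unique_features=100))
        assert (once.counts != twice.counts).nnz == 0
        pd.testing.assert_frame_equal(once.cell_meta, twice.cell_meta)


class TestQuantifyFluorescence:
    @staticmethod
    def stack(chans):
        return FluorescenceStack(channels=chans, pixel_size_um=1.0)

    def test_constant_channel_gives_constant_means(self):
        seg = seg_two_cells()
        means = quantify_fluorescence(seg, self.stack({"gfp": np.full((10, 10), 5.0)}))
        assert (means["gfp"] == 5.0).all()

    def test_signal_localized_to_one_segment(self):
        seg = seg_two_cells()
        gfp = np.zeros((10, 10))
        gfp[6:9, 6:9] = 2.0
        means = quantify_fluorescence(seg, self.stack({"gfp": gfp}))
        assert means.loc[1, "gfp"] == 0.0
        assert means.loc[2, "gfp"] == 2.0

    def test_random_field_matches_per_pixel_average(self):
        rng = np.random.default_rng(0)
        seg = seg_two_cells()
        img = rng.random((10, 10))
        means = quantify_fluorescence(seg, self.stack({"gfp": img}))
        for sid in (1, 2):
            assert means.loc[sid, "gfp"] == pytest.approx(img[seg.labels == sid].mean())

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            quantify_fluorescence(seg_two_cells(), self.stack({"gfp": np.zeros((4, 4))}))


class TestCallReporter:
    @staticmethod
    def means(gfp, tdt):
        return pd.DataFrame({"gfp": [gfp], "tdtomato": [tdt]},
                            index=pd.Index([1], name="segment_id"))

    THRESHOLDS = {"gfp": 1.0, "tdtomato": 1.0}

    @pytest.mark.parametrize(
        "gfp,tdt,cls,positive",
        [
            (2.0, 0.5, "gfp_only", True),
            (0.5, 2.0, "tdtomato_only", True),
            (2.0, 2.0, "double", True),
            (0.5, 0.5, "none", False),
            (1.0, 1.0, "none", False),  # strictly-greater rule
        ],
    )
    def test_truth_table(self, gfp, tdt, cls, positive):
        (call,) = call_reporter(self.means(gfp, tdt), self.THRESHOLDS)
        assert call.reporter_class == cls
        assert call.is_p21_positive is positive

    def test_tdtomato_rule_excludes_gfp_only(self):
        (call,) = call_reporter(self.means(2.0, 0.5), self.THRESHOLDS, p21_rule="tdtomato")
        assert call.reporter_class == "gfp_only"
        assert call.is_p21_positive is False

    def test_raising_threshold_is_monotone(self):
        low = call_reporter(self.means(2.0, 2.0), {"gfp": 1.0, "tdtomato": 1.0})[0]
        high = call_reporter(self.means(2.0, 2.0), {"gfp": 3.0, "tdtomato": 3.0})[0]
        assert low.is_p21_positive and not high.is_p21_positive
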