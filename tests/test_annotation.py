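"""Normalization math, marker scoring, type assignment, delegated clustering."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from senoniche.annotation import (
    MarkerPanels,
    assign_types,
    cluster_cells,
    normalize,
    score_panels,
)
from senoniche.io import CellMatrix
from conftest import effective_truth_types


def matrix_from_dense(arr, genes):
    arr = np.asarray(arr)
    meta = pd.DataFrame({"segment_id": np.arange(1, arr.shape[0] + 1)})
    return CellMatrix(counts=sp.csr_matrix(arr), cell_meta=meta, gene_ids=list(genes))


class TestNormalize:
    def test_closed_form_value(self):
        m = matrix_from_dense([[5, 495]], ["a", "b"])
        nm = normalize(m, target_sum=500.0)
        assert nm.values[0, 0] == pytest.approx(np.log(6.0))

    def test_zero_count_maps_to_zero(self):
        m = matrix_from_dense([[0, 10]], ["a", "b"])
        assert normalize(m, target_sum=100.0).values[0, 0] == 0.0

    def test_invariant_to_cell_depth_scaling(self):
        m1 = matrix_from_dense([[3, 7, 10]], list("abc"))
        m2 = matrix_from_dense([[6, 14, 20]], list("abc"))
        np.testing.assert_allclose(
            normalize(m1, target_sum=100.0).values,
            normalize(m2, target_sum=100.0).values,
        )

    def test_target_sum_defaults_to_median_total(self):
        m = matrix_from_dense([[10, 0], [0, 30], [50, 0]], ["a", "b"])
        assert normalize(m).target_sum == 30.0

    def test_zero_total_cell_rejected(self):
        m = matrix_from_dense([[0, 0], [1, 1]], ["a", "b"])
        with pytest.raises(ValueError, match="qc_filter"):
            normalize(m)


class TestScorePanels:
    def test_disjoint_panels_score_only_their_type(self):
        m = matrix_from_dense([[5, 5, 0, 0]], ["Alb", "Ttr", "Cd74", "Vcam1"])
        nm = normalize(m, target_sum=10.0)
        panels = MarkerPanels(panels={"hep": ["Alb", "Ttr"], "mac": ["Cd74", "Vcam1"]})
        s = score_panels(nm, panels)
        assert s.loc[1, "hep"] > 0
        assert s.loc[1, "mac"] == 0.0

    def test_all_zero_cell_scores_zero(self):
        m = matrix_from_dense([[0, 0], [1, 1]], ["Alb", "Cd74"])
        nm = normalize(qc_keep_nonzero(m), target_sum=10.0)
        s = score_panels(nm, MarkerPanels(panels={"hep": ["Alb"]}))
        assert (s >= 0).all().all()

    def test_scores_equal_brute_force_panel_means(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(10)]
        m = matrix_from_dense(rng.integers(1, 9, size=(6, 10)), genes)
        nm = normalize(m, target_sum=50.0)
        panels = MarkerPanels(panels={"p1": genes[:4], "p2": genes[4:9]})
        s = score_panels(nm, panels)
        np.testing.assert_allclose(s["p1"], nm.values[:, :4].mean(axis=1))
        np.testing.assert_allclose(s["p2"], nm.values[:, 4:9].mean(axis=1))

    def test_absent_panel_gene_warns_and_fully_absent_panel_errors(self):
        m = matrix_from_dense([[3, 2]], ["Alb", "Ttr"])
        nm = normalize(m, target_sum=5.0)
        with pytest.warns(UserWarning, match="Missing1"):
            score_panels(nm, MarkerPanels(panels={"hep": ["Alb", "Missing1"]}))
        with pytest.raises(ValueError, match="ghost"):
            score_panels(nm, MarkerPanels(panels={"ghost": ["NotThere"]}))


def qc_keep_nonzero(m):
    from senoniche.quantification import QcConfig, qc_filter

    return qc_filter(m, QcConfig(min_unique_features=1))


class TestAssignTypes:
    def test_clear_winner_assigned(self):
        s = pd.DataFrame({"hep": [2.0], "mac": [0.1]}, index=[1])
        assert assign_types(s, min_margin=0.5).loc[1] == "hep"

    def test_exact_tie_is_unassigned(self):
        s = pd.DataFrame({"hep": [1.0], "mac": [1.0]}, index=[1])
        assert assign_types(s, min_margin=0.01).loc[1] == "unassigned"

    def test_margin_below_threshold_is_unassigned(self):
        s = pd.DataFrame({"hep": [1.0], "mac": [0.9]}, index=[1])
        assert assign_types(s, min_margin=0.25).loc[1] == "unassigned"

    def test_planted_types_recovered_on_default_tissue(self, default_analysis):
        a = default_analysis
        eff = effective_truth_types(a["truth"])
        hits = total = 0
        for sid, pred in a["types"].items():
            tix = a["seg_to_truth"].get(int(sid))
            if tix is None:
                continue
            total += 1
            hits += pred == eff.iloc[tix]
        assert total > 0
        assert hits / total >= 0.90


class TestClusterCells:
    def test_two_separated_populations_split_cleanly(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(8.0, size=(60, 5))
        b = rng.poisson(8.0, size=(60, 5))
        arr = np.zeros((120, 10), dtype=int)
        arr[:60, :5] = a
        arr[60:, 5:] = b
        m = matrix_from_dense(arr, [f"g{i}" for i in range(10)])
        cl = cluster_cells(normalize(m, target_sum=40.0), resolution=0.5, seed=0)
        assert cl.nunique() == 2
        assert cl.iloc[:60].nunique() == 1 and cl.iloc[60:].nunique() == 1

    def test_homogeneous_population_stays_one_cluster(self):
        rng = np.random.default_rng(1)
        m = matrix_from_dense(rng.poisson(6.0, size=(80, 8)) + 1, [f"g{i}" for i in range(8)])
        cl = cluster_cells(normalize(m, target_sum=48.0), resolution=0.01, seed=0)
        assert cl.nunique() == 1

    def test_too_few_cells_rejected(self):
        m = matrix_from_dense([[1, 2]], ["a", "b"])
        with pytest.raises(ValueError):
            cluster_cells(normalize(m, target_sum=3.0))

    def test_clusters_concord_with_planted_types(self, default_analysis):
        from sklearn.metrics import adjusted_rand_score

        a = default_analysis
        cl = cluster_cells(a["nm"], seed=0)
        eff = effective_truth_types(a["truth"])
        pairs = [
            (cl.loc[sid], eff.iloc[a["seg_to_truth"][int(sid)]])
            for sid in cl.index
            if int(sid) in a["seg_to_truth"]
        ]
        got, want = zip(*pairs)
        assert adjusted_rand_score(got, want) >= 0.7
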