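"""Greedy ground-truth matching, the four metrics, and grid search."""

import numpy as np
import pytest

from pelvidet import (
    DetectionBox,
    NodeInstance,
    evaluate,
    grid_search,
    image_auc,
    match,
    node_sensitivity,
    slice_precision,
)
from pelvidet.evaluation import slice_scores
from conftest import make_mask, make_volume
from oracles import all_pairs_auc


def node(node_id, slice_boxes):
    voxels = frozenset(
        (z, y, x)
        for z, (x0, y0, x1, y1) in slice_boxes.items()
        for y in range(int(y0), int(y1))
        for x in range(int(x0), int(x1))
    )
    return NodeInstance(node_id=node_id, voxel_set=voxels, slice_boxes=slice_boxes)


def pred(z, box, score, voter="v"):
    return DetectionBox(z=z, box=box, score=score, voter_id=voter)


class TestMatch:
    gt = [node(0, {2: (10, 10, 20, 20), 3: (10, 10, 20, 20)}),
          node(1, {2: (40, 40, 48, 48)})]

    def test_exact_prediction_is_tp(self):
        res = match([pred(2, (10, 10, 20, 20), 0.9)], self.gt, 0.5)
        assert res.tp == 1 and res.fp == 0
        assert res.matched_gt_slices == {(0, 2)}

    def test_two_preds_one_gt_box(self):
        lo = pred(2, (10, 10, 20, 20), 0.5)
        hi = pred(2, (11, 10, 21, 20), 0.8)
        res = match([lo, hi], self.gt, 0.5)
        assert res.tp_boxes == [hi] and res.fp_boxes == [lo]

    def test_below_threshold_is_fp(self):
        # IoU 0.4 < tau3=0.5
        p = pred(2, (10, 16, 20, 26), 0.9)
        from pelvidet import iou

        assert iou(p.box, (10, 10, 20, 20)) == pytest.approx(0.25)
        res = match([p], self.gt, 0.5)
        assert res.fp == 1 and res.tp == 0

    def test_order_invariance(self):
        preds = [pred(2, (10, 10, 20, 20), 0.7), pred(2, (40, 40, 48, 48), 0.9),
                 pred(3, (11, 11, 21, 21), 0.4), pred(2, (9, 9, 19, 19), 0.6)]
        a = match(preds, self.gt, 0.3)
        b = match(preds[::-1], self.gt, 0.3)
        assert {id(x) for x in a.tp_boxes} == {id(x) for x in b.tp_boxes}

    def test_bad_tau3(self):
        with pytest.raises(ValueError):
            match([], self.gt, 0.0)


class TestSensitivityPrecision:
    def test_all_nodes_hit(self):
        gt = [node(0, {1: (0, 0, 5, 5)}), node(1, {1: (10, 10, 15, 15)})]
        res = match([pred(1, (0, 0, 5, 5), 0.9), pred(1, (10, 10, 15, 15), 0.8)], gt, 0.5)
        assert node_sensitivity(res, gt) == 100.0

    def test_one_of_three_nodes(self):
        gt = [node(i, {1: (10 * i, 0, 10 * i + 5, 5)}) for i in range(3)]
        res = match([pred(1, (0, 0, 5, 5), 0.9)], gt, 0.5)
        assert node_sensitivity(res, gt) == pytest.approx(100 / 3)

    def test_multi_slice_node_counts_once(self):
        gt = [node(0, {z: (0, 0, 5, 5) for z in range(5)})]
        preds = [pred(z, (0, 0, 5, 5), 0.9) for z in range(4)]  # 4 of 5 slices
        res = match(preds, gt, 0.5)
        assert node_sensitivity(res, gt) == 100.0
        assert res.tp == 4

    def test_empty_gt_rejected(self):
        res = match([], [node(0, {0: (0, 0, 1, 1)})], 0.5)
        with pytest.raises(ValueError):
            node_sensitivity(res, [])

    @pytest.mark.parametrize("tp, fp, expected", [(4, 0, 100.0), (3, 1, 75.0)])
    def test_precision_counts(self, tp, fp, expected):
        gt = [node(0, {z: (0, 0, 5, 5) for z in range(tp)})]
        preds = [pred(z, (0, 0, 5, 5), 0.9) for z in range(tp)]
        preds += [pred(10 + i, (50, 50, 55, 55), 0.3) for i in range(fp)]
        gt_far = gt + [node(1, {10 + i: (0, 0, 2, 2) for i in range(fp)})] if fp else gt
        res = match(preds, gt_far, 0.5)
        value, degenerate = slice_precision(res)
        assert value == expected and not degenerate

    def test_zero_predictions_flagged(self):
        res = match([], [node(0, {0: (0, 0, 1, 1)})], 0.5)
        value, degenerate = slice_precision(res)
        assert value == 0.0 and degenerate

    def test_extra_fp_never_raises_precision(self):
        gt = [node(0, {1: (0, 0, 5, 5)})]
        base = [pred(1, (0, 0, 5, 5), 0.9)]
        p0, _ = slice_precision(match(base, gt, 0.5))
        p1, _ = slice_precision(match(base + [pred(1, (20, 20, 25, 25), 0.5)], gt, 0.5))
        assert p1 <= p0


class TestImageAuc:
    def test_perfect_separation(self):
        assert image_auc([(True, 0.9), (False, 0.0)]) == 100.0
        assert image_auc([(True, 0.8), (False, 0.3), (False, 0.0)]) == 100.0

    def test_tie_counts_half(self):
        assert image_auc([(True, 0.5), (False, 0.5)]) == 50.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            image_auc([(True, 0.5)])
        with pytest.raises(ValueError, match="positive"):
            image_auc([(False, 0.5)])

    def test_matches_all_pairs_oracle_and_sklearn(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = int(rng.integers(4, 40))
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            got = image_auc(list(zip(labels, scores)))
            assert got == pytest.approx(100 * all_pairs_auc(labels, scores), abs=1e-12)
            from sklearn.metrics import roc_auc_score

            assert got == pytest.approx(100 * roc_auc_score(labels, scores), abs=1e-9)

    def test_slice_scores_max_and_zero_fill(self):
        gt = [node(0, {2: (0, 0, 5, 5)})]
        preds = [pred(2, (0, 0, 5, 5), 0.4), pred(2, (0, 0, 5, 5), 0.9),
                 pred(3, (0, 0, 5, 5), 0.2)]
        rows = slice_scores(preds, gt, eval_slices=[1, 2, 3])
        assert rows == [(False, 0.0), (True, 0.9), (False, 0.2)]


class TestEvaluate:
    def test_harmonic_mean_fixture(self):
        # 5 nodes, 4 hit once each -> S=80; 4 TP + 4 FP -> P=50
        gt = [node(i, {1: (12 * i, 0, 12 * i + 6, 6)}) for i in range(5)]
        preds = [pred(1, (12 * i, 0, 12 * i + 6, 6), 0.9) for i in range(4)]
        preds += [pred(1, (12 * i, 40, 12 * i + 6, 46), 0.3) for i in range(4)]
        m = evaluate(preds, gt, 0.5, eval_slices=[0, 1])
        assert m.sensitivity == 80.0 and m.precision == 50.0
        assert m.f1 == pytest.approx(2 * 80 * 50 / 130)

    def test_empty_predictions(self):
        gt = [node(0, {1: (0, 0, 5, 5)})]
        m = evaluate([], gt, 0.5, eval_slices=[0, 1, 2])
        assert (m.sensitivity, m.precision, m.f1) == (0.0, 0.0, 0.0)
        assert "no_predictions" in m.flags
        assert m.auc == 50.0  # all-zero scores tie everywhere


class TestGridSearch:
    def _setup(self):
        vox = np.full((1, 64, 64), 40.0)
        vol = make_volume(vox)
        m = np.zeros((1, 64, 64))
        m[0, 10:54, 10:54] = 1
        ctv = make_mask(m, "ctv", vol)
        gt = [node(0, {0: (20, 20, 28, 28)})]
        voters = {"A": [pred(0, (20, 20, 28, 28), 0.9, "A")],
                  "B": [pred(0, (20, 20, 28, 28), 0.8, "B")]}
        return voters, gt, vol, ctv

    def test_single_cell(self):
        voters, gt, vol, ctv = self._setup()
        grid = {k: [v] for k, v in
                dict(tau1=0.5, tau2=2, tau3=0.5, tau4=2, tau5=160, tau6=0.8).items()}
        best, table = grid_search(voters, gt, vol, ctv, grid=grid)
        assert best == dict(tau1=0.5, tau2=2, tau3=0.5, tau4=2, tau5=160, tau6=0.8)
        assert len(table) == 1 and table.iloc[0].f1 == 100.0

    def test_tie_breaks_lexicographically(self):
        voters, gt, vol, ctv = self._setup()
        grid = dict(tau1=[0.4, 0.5], tau2=[2], tau3=[0.5], tau4=[2], tau5=[160], tau6=[0.8])
        best, table = grid_search(voters, gt, vol, ctv, grid=grid)
        assert best["tau1"] == 0.4  # equal criterion everywhere
        assert len(table) == 2

    def test_empty_grid_rejected(self):
        voters, gt, vol, ctv = self._setup()
        with pytest.raises(ValueError, match="tau5"):
            grid_search(voters, gt, vol, ctv,
                        grid=dict(tau1=[0.5], tau2=[1], tau3=[0.5], tau4=[2],
                                  tau5=[], tau6=[0.8]))

    def test_tau6_dominance_fixture(self):
        # TP boxes contain a bright sliver: max HU > tau5 but the 0.8
        # quantile is soft tissue, so tau6=1.0 kills the TPs and loses
        vox = np.full((1, 64, 64), 40.0)
        vox[0, 20, 20:28] = 300.0  # bright top row: 12.5% of the node box
        vol = make_volume(vox)
        m = np.zeros((1, 64, 64))
        m[0, 5:60, 5:60] = 1
        ctv = make_mask(m, "ctv", vol)
        gt = [node(0, {0: (20, 20, 28, 28)})]
        voters = {"A": [pred(0, (20, 20, 28, 28), 0.9, "A")]}
        grid = dict(tau1=[0.5], tau2=[1], tau3=[0.5], tau4=[3], tau5=[160],
                    tau6=[0.8, 1.0])
        best, table = grid_search(voters, gt, vol, ctv, grid=grid, criterion="f1")
        assert best["tau6"] == 0.8
        f1 = {row.tau6: row.f1 for row in table.itertuples()}
        assert f1[0.8] > f1[1.0]

    def test_best_cell_dominates_manual_cells(self):
        voters, gt, vol, ctv = self._setup()
        grid = dict(tau1=[0.3, 0.6], tau2=[1, 2], tau3=[0.5], tau4=[2, 5],
                    tau5=[120, 160], tau6=[0.5, 1.0])
        best, table = grid_search(voters, gt, vol, ctv, grid=grid, criterion="f1")
        best_f1 = table[(table[list(best)] == list(best.values())).all(axis=1)].f1.iloc[0]
        assert best_f1 >= table.f1.max() - 1e-12
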