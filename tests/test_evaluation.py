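"""Evaluation protocol vs. independent brute-force oracles."""

import numpy as np
import pytest

from ildseg.evaluation import (
    SingleClassError,
    compare_models,
    count_lesion_fp,
    label_components,
    roc_auc,
    summarize_cohort,
    voxel_metrics,
    youden_threshold,
    CaseMetrics,
    RocCurve,
)

from _oracles import (
    oracle_count_fp,
    oracle_flood_fill_components,
    oracle_rank_sum_p,
    oracle_voxel_metrics,
    oracle_youden,
)


class TestRocAuc:
    def test_perfect_separation_gives_auc_one(self, rng):
        gt = rng.uniform(size=(10, 10, 10)) > 0.8
        mask = np.ones_like(gt)
        area, _ = roc_auc(gt.astype(float), gt, mask)
        assert area == 1.0

    def test_label_independent_noise_gives_half(self, rng):
        gt = np.zeros((50, 50, 40), dtype=bool)
        gt[rng.uniform(size=gt.shape) > 0.5] = True
        probs = rng.uniform(size=gt.shape)
        area, _ = roc_auc(probs, gt, np.ones_like(gt))
        assert area == pytest.approx(0.5, abs=0.02)

    def test_invariant_under_strictly_monotone_transform(self, rng):
        gt = rng.uniform(size=(8, 8, 8)) > 0.7
        probs = rng.uniform(size=gt.shape)
        mask = np.ones_like(gt)
        a1, _ = roc_auc(probs, gt, mask)
        a2, _ = roc_auc(probs**3 * 0.5 + 0.1, gt, mask)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        arr = np.zeros((4, 4, 4))
        with pytest.raises(SingleClassError):
            roc_auc(arr, np.zeros_like(arr, dtype=bool), np.ones_like(arr, dtype=bool))

    def test_curve_on_grid_of_identical_cases_averages_to_itself(self, rng):
        gt = rng.uniform(size=(8, 8, 8)) > 0.7
        probs = rng.uniform(size=gt.shape)
        _, curve = roc_auc(probs, gt, np.ones_like(gt))
        cases = [
            CaseMetrics(auc=1, dice=1, iou=1, precision=1, recall=1, fpr=0,
                        fp_all=0, fp_10mm3=0, threshold_used=0.5,
                        roc=RocCurve(curve.fpr_grid, curve.tpr.copy()))
            for _ in range(3)
        ]
        summary = summarize_cohort(cases)
        assert np.allclose(summary.tpr_mean, curve.tpr)
        assert np.allclose(summary.tpr_lo, np.clip(curve.tpr, 0, 1))


class TestYouden:
    def test_matches_exhaustive_oracle_on_random_maps(self, rng):
        for _ in range(50):
            shape = (5, 5, 4)
            probs = np.round(rng.uniform(size=shape), 2)  # ties are likely
            gt = rng.uniform(size=shape) > 0.7
            mask = rng.uniform(size=shape) > 0.1
            if not (gt & mask).any() or not (~gt & mask).any():
                continue
            t_oracle, j_oracle = oracle_youden(probs, gt, mask)
            t = youden_threshold([probs], [gt], [mask])
            assert t == pytest.approx(t_oracle, abs=1e-12)

    def test_separated_classes_pick_largest_optimal_threshold(self):
        probs = np.array([[[0.1, 0.1, 0.9, 0.9]]])
        gt = np.array([[[False, False, True, True]]])
        mask = np.ones_like(gt)
        assert youden_threshold([probs], [gt], [mask]) == pytest.approx(0.9)

    def test_single_positive_forces_its_value(self):
        probs = np.array([[[0.1, 0.2, 0.76, 0.3]]])
        gt = np.array([[[False, False, True, False]]])
        mask = np.ones_like(gt)
        assert youden_threshold([probs], [gt], [mask]) == pytest.approx(0.76)

    def test_pooled_across_cases(self, rng):
        """Pooling two cases must equal one case holding both volumes."""
        a, b = rng.uniform(size=(4, 4, 4)), rng.uniform(size=(4, 4, 4))
        ga = rng.uniform(size=a.shape) > 0.6
        gb = rng.uniform(size=b.shape) > 0.6
        mask = np.ones_like(ga)
        pooled = youden_threshold([a, b], [ga, gb], [mask, mask])
        merged = youden_threshold(
            [np.concatenate([a, b])], [np.concatenate([ga, gb])],
            [np.concatenate([mask, mask])])
        assert pooled == merged


class TestVoxelMetrics:
    def test_identity_prediction(self, small_phantom):
        vm = voxel_metrics(small_phantom.ground_truth, small_phantom.ground_truth,
                           small_phantom.brain_mask)
        assert (vm["dice"], vm["iou"], vm["precision"], vm["recall"]) == (1, 1, 1, 1)
        assert vm["fpr"] == 0

    def test_hand_counted_overlap(self):
        gt = np.zeros((4, 4, 1), dtype=bool)
        pred = np.zeros_like(gt)
        gt[0, 0:4, 0] = True        # |gt| = 4
        pred[0:4, 0, 0] = True      # |pred| = 4, overlap at (0,0) only
        pred[0, 1, 0] = True        # second overlap; drop one non-overlap
        pred[3, 0, 0] = False
        mask = np.ones_like(gt)
        vm = voxel_metrics(pred, gt, mask)
        assert vm["tp"] == 2 and vm["fp"] == 2 and vm["fn"] == 2
        assert vm["dice"] == pytest.approx(0.5)
        assert vm["iou"] == pytest.approx(1 / 3)
        assert vm["precision"] == pytest.approx(0.5)
        assert vm["recall"] == pytest.approx(0.5)

    def test_matches_loop_oracle_on_random_volumes(self, rng):
        for _ in range(100):
            shape = tuple(rng.integers(3, 7, size=3))
            pred = rng.uniform(size=shape) > 0.6
            gt = rng.uniform(size=shape) > 0.6
            mask = rng.uniform(size=shape) > 0.2
            got = voxel_metrics(pred, gt, mask)
            want = oracle_voxel_metrics(pred, gt, mask)
            for key, val in want.items():
                assert got[key] == pytest.approx(val, abs=1e-12), key

    def test_empty_conventions(self):
        shape = (3, 3, 3)
        empty = np.zeros(shape, dtype=bool)
        full_mask = np.ones(shape, dtype=bool)
        both_empty = voxel_metrics(empty, empty, full_mask)
        assert both_empty["dice"] == both_empty["iou"] == 1.0
        assert both_empty["precision"] == both_empty["recall"] == 1.0
        one = empty.copy()
        one[1, 1, 1] = True
        assert voxel_metrics(one, empty, full_mask)["dice"] == 0.0
        assert voxel_metrics(empty, one, full_mask)["dice"] == 0.0
        assert voxel_metrics(empty, one, full_mask)["precision"] == 0.0


class TestComponents:
    def test_corner_touching_voxels_are_one_component(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True  # touch only at a corner
        comps = label_components(mask, (1, 1, 1))
        assert comps.n_components == 1

    def test_gap_separates_components(self):
        mask = np.zeros((5, 1, 1), dtype=bool)
        mask[0] = mask[2] = True  # one background voxel between
        assert label_components(mask, (1, 1, 1)).n_components == 2

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(100):
            mask = rng.uniform(size=(6, 6, 6)) > 0.7
            got = label_components(mask, (1, 1, 1))
            want = oracle_flood_fill_components(mask)
            assert got.n_components == len(want)
            # memberships: every oracle component maps to exactly one label
            for comp in want:
                labels = {got.labels[v] for v in comp}
                assert len(labels) == 1 and 0 not in labels

    def test_component_volume_uses_voxel_volume(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[0, 0, :2] = True
        comps = label_components(mask, (2.0, 1.0, 0.5))
        assert comps.volumes_mm3 == pytest.approx([2.0])


class TestLesionFp:
    def test_perfect_prediction_has_no_fp(self, small_phantom):
        comps = label_components(small_phantom.ground_truth, small_phantom.voxel_spacing)
        assert count_lesion_fp(comps, small_phantom.ground_truth, 0.0) == 0
        assert count_lesion_fp(comps, small_phantom.ground_truth, 10.0) == 0

    def test_small_component_excluded_by_size_limit(self):
        pred = np.zeros((6, 6, 6), dtype=bool)
        pred[0:2, 0:2, 0:2] = True  # 8 voxels = 8 mm^3, no overlap
        gt = np.zeros_like(pred)
        gt[5, 5, 5] = True
        comps = label_components(pred, (1, 1, 1))
        assert count_lesion_fp(comps, gt, 0.0) == 1
        assert count_lesion_fp(comps, gt, 10.0) == 0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(100):
            pred = rng.uniform(size=(6, 6, 6)) > 0.75
            gt = rng.uniform(size=(6, 6, 6)) > 0.85
            spacing = rng.uniform(0.5, 2.0, size=3)
            comps = label_components(pred, spacing)
            for limit in (0.0, 10.0):
                assert count_lesion_fp(comps, gt, limit) == \
                    oracle_count_fp(pred, gt, spacing, limit)

    def test_fp_monotone_in_size_limit(self, rng):
        pred = rng.uniform(size=(8, 8, 8)) > 0.7
        gt = rng.uniform(size=(8, 8, 8)) > 0.9
        comps = label_components(pred, (1, 1, 1))
        counts = [count_lesion_fp(comps, gt, v) for v in (0, 5, 10, 20, 50)]
        assert counts == sorted(counts, reverse=True)


class TestCompareModels:
    def test_identical_samples_not_significant(self):
        res = compare_models([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.p_value == 1.0 and not res.significant

    def test_exact_small_sample_value(self):
        res = compare_models([1, 2, 3], [10, 11, 12])
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        assert not res.significant

    def test_matches_permutation_oracle(self, rng):
        for _ in range(30):
            n, m = rng.integers(3, 8, size=2)
            a = rng.normal(size=n)
            b = rng.normal(loc=rng.uniform(0, 2), size=m)
            res = compare_models(a, b)
            assert res.p_value == pytest.approx(oracle_rank_sum_p(a, b), abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_models([], [1.0])


class TestEvaluateCase:
    def _random_map(self, study, rng):
        from ildseg.inference import ProbabilityMap
        from ildseg.ild import AvailabilityPattern

        noisy = np.clip(study.ground_truth + 0.4 * rng.uniform(-1, 1, study.grid_shape),
                        0, 1)
        return ProbabilityMap(values=noisy, voxel_spacing=study.voxel_spacing,
                              pattern=AvailabilityPattern.all_available(4), model_id="m")

    def test_perfect_map_is_all_ones_and_no_fp(self, small_phantom):
        from ildseg.inference import ProbabilityMap
        from ildseg.ild import AvailabilityPattern
        from ildseg.evaluation import evaluate_case

        pmap = ProbabilityMap(values=small_phantom.ground_truth.astype(np.float32),
                              voxel_spacing=small_phantom.voxel_spacing,
                              pattern=AvailabilityPattern.all_available(4), model_id="m")
        case = evaluate_case(pmap, small_phantom, threshold=0.5)
        assert case.auc == 1.0
        assert case.dice == case.iou == case.precision == case.recall == 1.0
        assert case.fp_all == case.fp_10mm3 == 0

    def test_composition_equals_individual_operations(self, small_phantom, rng):
        from ildseg.evaluation import evaluate_case
        from ildseg.inference import binarize

        pmap = self._random_map(small_phantom, rng)
        case = evaluate_case(pmap, small_phantom, threshold=0.6)
        area, _ = roc_auc(pmap, small_phantom.ground_truth, small_phantom.brain_mask)
        pred = binarize(pmap, 0.6)
        vm = voxel_metrics(pred, small_phantom.ground_truth, small_phantom.brain_mask)
        comps = label_components(pred, small_phantom.voxel_spacing)
        assert case.auc == area
        assert case.dice == vm["dice"] and case.iou == vm["iou"]
        assert case.fp_all == count_lesion_fp(comps, small_phantom.ground_truth, 0.0)
        assert case.fp_10mm3 == count_lesion_fp(comps, small_phantom.ground_truth, 10.0)
        assert case.fp_10mm3 <= case.fp_all

    def test_dice_iou_identity_per_case(self, small_phantom, rng):
        from ildseg.evaluation import evaluate_case

        for _ in range(50):
            case = evaluate_case(self._random_map(small_phantom, rng), small_phantom,
                                 threshold=float(rng.uniform(0.2, 0.9)))
            assert case.dice == pytest.approx(2 * case.iou / (1 + case.iou), abs=1e-12)


class TestSummaries:
    def _case(self, dice, iou=0.5, **kw):
        base = dict(auc=0.9, dice=dice, iou=iou, precision=0.8, recall=0.7,
                    fpr=0.01, fp_all=3, fp_10mm3=1, threshold_used=0.5)
        base.update(kw)
        return CaseMetrics(**base)

    def test_identical_cases_have_zero_sd(self):
        summary = summarize_cohort([self._case(0.8), self._case(0.8)])
        assert summary.table.loc["dice", "mean"] == pytest.approx(0.8)
        assert summary.table.loc["dice", "sd"] == 0.0

    def test_means_match_hand_computation(self):
        cases = [self._case(0.6, iou=0.4), self._case(0.8, iou=0.5),
                 self._case(0.7, iou=0.6)]
        summary = summarize_cohort(cases)
        assert summary.table.loc["dice", "mean"] == pytest.approx(0.7)
        assert summary.table.loc["iou", "mean"] == pytest.approx(0.5)
        assert summary.table.loc["dice", "sd"] == pytest.approx(np.std(
            [0.6, 0.8, 0.7], ddof=1))

    def test_single_case_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort([self._case(0.5)])
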