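"""Segmentation metric correctness against brute-force pixel-loop oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from conftest import make_mask, random_mask_pair
from temporalis.imaging_io import BinaryMask
from temporalis.metrics import (
    agreement_stats,
    csa_error,
    evaluate_pair,
    hausdorff_distance,
    overlap_metrics,
    summarize,
)


def _mask_pair_strategy():
    bits = st.lists(st.booleans(), min_size=64, max_size=64)
    return st.tuples(bits, bits).map(
        lambda ab: (
            BinaryMask(labels=np.array(ab[0], dtype=np.uint8).reshape(8, 8), spacing=(1.0, 1.0)),
            BinaryMask(labels=np.array(ab[1], dtype=np.uint8).reshape(8, 8), spacing=(1.0, 1.0)),
        )
    )


class TestOverlapMetrics:
    def test_identity(self, mask_factory):
        m = mask_factory([(1, 1), (1, 2)])
        assert overlap_metrics(m, m) == (1.0, 1.0, 1.0, 1.0)

    def test_disjoint(self, mask_factory):
        a = mask_factory([(0, 0)])
        b = mask_factory([(5, 5)])
        assert overlap_metrics(a, b) == (0.0, 0.0, 0.0, 0.0)

    def test_half_overlap_confusion_counts(self, mask_factory):
        pred = mask_factory([(0, 0), (0, 1)])
        gt = mask_factory([(0, 1), (0, 2)])
        dsc, ji, precision, recall = overlap_metrics(pred, gt)
        assert dsc == pytest.approx(0.5)
        assert ji == pytest.approx(1 / 3)
        assert precision == pytest.approx(0.5)
        assert recall == pytest.approx(0.5)

    def test_empty_conventions(self, mask_factory):
        empty = mask_factory([])
        full = mask_factory([(2, 2)])
        assert overlap_metrics(empty, empty) == (1.0, 1.0, 1.0, 1.0)
        dsc, ji, precision, recall = overlap_metrics(empty, full)
        assert (dsc, ji, precision) == (0.0, 0.0, 0.0)
        assert recall == 0.0

    def test_matches_pixel_loop_oracle_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a, b = random_mask_pair(rng)
            got = overlap_metrics(a, b)
            want = oracles.overlap_metrics_loop(a.labels.tolist(), b.labels.tolist())
            assert got == pytest.approx(want, abs=1e-9)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(_mask_pair_strategy())
    def test_dsc_jaccard_identity(self, pair):
        a, b = pair
        dsc, ji, _, _ = overlap_metrics(a, b)
        assert dsc == pytest.approx(2 * ji / (1 + ji), abs=1e-12)
        assert ji <= dsc + 1e-12


class TestHausdorff:
    def test_identical_masks_give_zero(self, mask_factory):
        m = mask_factory([(1, 1), (3, 4)])
        assert hausdorff_distance(m, m) == 0.0

    def test_single_point_pair(self, mask_factory):
        a = mask_factory([(0, 0)])
        b = mask_factory([(0, 3)])
        assert hausdorff_distance(a, b) == pytest.approx(3.0)

    def test_directed_max_dominates(self, mask_factory):
        a = mask_factory([(0, 0), (0, 10)], shape=(12, 12))
        b = mask_factory([(0, 0)], shape=(12, 12))
        assert hausdorff_distance(a, b) == pytest.approx(10.0)

    def test_physical_spacing_scales_distance(self, mask_factory):
        a = make_mask([(0, 0)], spacing=(0.5, 0.5))
        b = make_mask([(0, 3)], spacing=(0.5, 0.5))
        assert hausdorff_distance(a, b) == pytest.approx(1.5)

    def test_empty_mask_raises(self, mask_factory):
        with pytest.raises(ValueError):
            hausdorff_distance(mask_factory([]), mask_factory([(0, 0)]))

    def test_matches_brute_force_and_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b = random_mask_pair(rng, shape=(10, 10), spacing=(1.3, 0.8))
            if a.labels.sum() == 0 or b.labels.sum() == 0:
                continue
            want = oracles.hausdorff_loop(a.labels.tolist(), b.labels.tolist(), (1.3, 0.8))
            assert hausdorff_distance(a, b) == pytest.approx(want, abs=1e-9)
            assert hausdorff_distance(a, b) == hausdorff_distance(b, a)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            a, b = random_mask_pair(rng, shape=(9, 9))
            c, _ = random_mask_pair(rng, shape=(9, 9))
            if min(a.labels.sum(), b.labels.sum(), c.labels.sum()) == 0:
                continue
            assert hausdorff_distance(a, c) <= (
                hausdorff_distance(a, b) + hausdorff_distance(b, c) + 1e-9
            )


class TestCSAError:
    def test_identity_is_zero(self, mask_factory):
        m = mask_factory([(0, 0), (1, 1)])
        assert csa_error(m, m) == 0.0

    def test_ten_percent_overcall(self):
        gt = np.zeros((20, 20), dtype=np.uint8)
        gt[:10, :10] = 1  # 100 px
        pred = gt.copy()
        pred[10, :10] = 1  # 110 px
        assert csa_error(
            BinaryMask(labels=pred, spacing=(1, 1)), BinaryMask(labels=gt, spacing=(1, 1))
        ) == pytest.approx(10.0)

    def test_total_miss_is_100_percent(self, mask_factory):
        assert csa_error(mask_factory([]), mask_factory([(0, 0)])) == pytest.approx(100.0)

    def test_empty_ground_truth_raises(self, mask_factory):
        with pytest.raises(ValueError):
            csa_error(mask_factory([(0, 0)]), mask_factory([]))

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            a, b = random_mask_pair(rng, spacing=(2.0, 1.5))
            if b.labels.sum() == 0:
                continue
            want = oracles.csa_error_loop(a.labels.tolist(), b.labels.tolist(), (2.0, 1.5))
            assert csa_error(a, b) == pytest.approx(want, abs=1e-9)


class TestAgreement:
    def test_identical_lists(self):
        areas = [500.0, 600.0, 550.0, 620.0, 480.0]
        r, p, ba = agreement_stats(areas, areas)
        assert r == pytest.approx(1.0)
        assert ba.mean_difference == 0.0

    def test_perfect_linearity(self):
        x = np.arange(1.0, 11.0)
        r, _, _ = agreement_stats(2 * x, x)
        assert r == pytest.approx(1.0)

    def test_fixed_table_matches_textbook_formula(self):
        pred = [510.0, 620.0, 480.0, 555.0, 700.0]
        gt = [500.0, 640.0, 470.0, 560.0, 680.0]
        r, _, ba = agreement_stats(pred, gt)
        assert r == pytest.approx(oracles.pearson_loop(pred, gt), abs=1e-9)
        diffs = np.array(pred) - np.array(gt)
        assert ba.mean_difference == pytest.approx(diffs.mean())
        assert ba.loa_high == pytest.approx(diffs.mean() + 1.96 * diffs.std(ddof=1))

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            agreement_stats([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSummary:
    def test_mean_sd_over_pairs(self, mask_factory):
        rng = np.random.default_rng(4)
        recs = []
        for _ in range(5):
            a, b = random_mask_pair(rng)
            if a.labels.sum() and b.labels.sum():
                recs.append(evaluate_pair(a, b))
        summ = summarize(recs)
        assert summ.n == len(recs)
        assert summ.mean["dsc"] == pytest.approx(np.mean([r.dsc for r in recs]))
        assert summ.sd["hd_mm"] == pytest.approx(np.std([r.hd_mm for r in recs], ddof=1))
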