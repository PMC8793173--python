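"""Loss algebra and metric formulas against hand values and brute force."""
import numpy as np
import pytest

from iresunet3p import autodiff as ad
from iresunet3p.losses_metrics import (ContingencyCounts, LossWeights,
                                       MetricError, bce_loss,
                                       counts_from_masks, dice_coefficient,
                                       generalized_dice_loss,
                                       hausdorff_distance, metric_report,
                                       mixed_loss, region_metrics,
                                       sensitivity, summarize)
from iresunet3p.preprocessing import RegionMask


def nested_random_target(rng, shape=(2, 3, 6, 6)):
    y = (rng.random(shape) < 0.3).astype(np.float32)
    y[:, 0] = np.maximum(y[:, 0], np.maximum(y[:, 1], y[:, 2]))
    y[:, 1] = np.maximum(y[:, 1], y[:, 2])
    return y


class TestMixedLoss:
    def test_perfect_prediction_near_zero(self, rng):
        y = nested_random_target(rng)
        pred = np.clip(y, 1e-6, 1 - 1e-6)
        loss = mixed_loss(pred, y, LossWeights(0.5, 1.0))
        assert loss.item() == pytest.approx(0.0, abs=1e-3)

    def test_weighted_combination_algebra(self, rng):
        """L_all = alpha * L_bce + beta * L_dice for the actual terms."""
        y = nested_random_target(rng)
        pred = ad.Tensor(rng.uniform(0.05, 0.95, size=y.shape)
                         .astype(np.float32))
        b = bce_loss(pred, y).item()
        d = generalized_dice_loss(pred, y).item()
        total = mixed_loss(pred, y, LossWeights(0.5, 1.0)).item()
        assert total == pytest.approx(0.5 * b + 1.0 * d, rel=1e-5)
        # the plug-in example: L_bce=0.2, L_dice=0.4 -> 0.5*0.2 + 1.0*0.4
        assert 0.5 * 0.2 + 1.0 * 0.4 == pytest.approx(0.5)

    def test_alpha_zero_is_pure_dice(self, rng):
        y = nested_random_target(rng)
        pred = ad.Tensor(rng.uniform(0.1, 0.9, size=y.shape)
                         .astype(np.float32))
        total = mixed_loss(pred, y, LossWeights(0.0, 2.0)).item()
        assert total == pytest.approx(
            2.0 * generalized_dice_loss(pred, y).item(), rel=1e-6)

    def test_dice_loss_bounded_and_loss_nonnegative(self, rng):
        for _ in range(5):
            y = nested_random_target(rng)
            pred = ad.Tensor(rng.uniform(0, 1, size=y.shape)
                             .astype(np.float32))
            d = generalized_dice_loss(pred, y).item()
            assert -1e-6 <= d <= 1.0 + 1e-6
            assert mixed_loss(pred, y).item() >= -1e-6

    def test_hard_prediction_dice_loss_matches_one_minus_dice(self, rng):
        """Single channel: 1 - Dice of a hard prediction equals the Dice
        loss within the smoothing constant's tolerance."""
        p = (rng.random((1, 1, 8, 8)) < 0.4).astype(np.float32)
        t = (rng.random((1, 1, 8, 8)) < 0.4).astype(np.float32)
        c = counts_from_masks(p[0, 0], t[0, 0])
        loss = generalized_dice_loss(ad.Tensor(p), t).item()
        assert loss == pytest.approx(1.0 - dice_coefficient(c), abs=1e-3)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(MetricError):
            mixed_loss(np.zeros((1, 3, 4, 4)), np.zeros((1, 3, 4, 5)))

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(0.0, 0.0)
        with pytest.raises(ValueError):
            LossWeights(-1.0, 1.0)

    def test_gradient_is_finite(self, rng):
        y = nested_random_target(rng, (1, 3, 4, 4))
        pred = ad.Tensor(rng.uniform(0.01, 0.99, (1, 3, 4, 4))
                         .astype(np.float32), requires_grad=True)
        mixed_loss(pred, y).backward()
        assert np.all(np.isfinite(pred.grad))


class TestHardMetrics:
    def test_dice_hand_tables(self):
        assert dice_coefficient(ContingencyCounts(2, 1, 1)) == pytest.approx(4 / 6)
        assert dice_coefficient(ContingencyCounts(5, 0, 0)) == 1.0
        assert dice_coefficient(ContingencyCounts(0, 3, 4)) == 0.0
        assert dice_coefficient(ContingencyCounts(0, 0, 0)) == 1.0

    def test_sensitivity_hand_tables(self):
        assert sensitivity(ContingencyCounts(3, 0, 1)) == pytest.approx(0.75)
        assert sensitivity(ContingencyCounts(4, 2, 0)) == 1.0
        assert sensitivity(ContingencyCounts(0, 1, 5)) == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(MetricError):
            ContingencyCounts(-1, 0, 0)

    def test_counts_vs_voxel_loop_oracle(self, rng):
        p = rng.random((4, 5, 6)) < 0.5
        r = rng.random((4, 5, 6)) < 0.5
        c = counts_from_masks(p, r)
        tp = fp = fn = 0
        for i in range(4):
            for j in range(5):
                for k in range(6):
                    if p[i, j, k] and r[i, j, k]:
                        tp += 1
                    elif p[i, j, k]:
                        fp += 1
                    elif r[i, j, k]:
                        fn += 1
        assert (c.tp, c.fp, c.fn) == (tp, fp, fn)
        tn = p.size - tp - fp - fn
        assert tp + fp + fn + tn == p.size

    def test_counts_symmetry_swaps_fp_fn(self, rng):
        p = rng.random((5, 5, 5)) < 0.4
        r = rng.random((5, 5, 5)) < 0.4
        a = counts_from_masks(p, r)
        b = counts_from_masks(r, p)
        assert (a.tp, a.fp, a.fn) == (b.tp, b.fn, b.fp)
        assert dice_coefficient(a) == dice_coefficient(b)

    def test_non_binary_rejected(self):
        with pytest.raises(MetricError):
            counts_from_masks(np.array([0, 2]), np.array([0, 1]))


def surface_oracle(mask):
    """Independent boundary extraction: a mask voxel is surface if any
    face-neighbour (array edge counts as background) is outside the mask."""
    pts = []
    idx = np.argwhere(mask)
    for p in idx:
        on_surface = False
        for ax in range(mask.ndim):
            for d in (-1, 1):
                q = p.copy()
                q[ax] += d
                if (q[ax] < 0 or q[ax] >= mask.shape[ax]
                        or not mask[tuple(q)]):
                    on_surface = True
        if on_surface:
            pts.append(p)
    return np.array(pts)


def hausdorff_oracle(a, b, percentile=None):
    pa, pb = surface_oracle(a), surface_oracle(b)
    dmat = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    d_ab = dmat.min(axis=1)
    d_ba = dmat.min(axis=0)
    if percentile is None:
        return max(d_ab.max(), d_ba.max())
    return max(np.percentile(d_ab, percentile),
               np.percentile(d_ba, percentile))


class TestHausdorff:
    def test_identical_masks_zero(self, rng):
        m = rng.random((6, 6, 6)) < 0.4
        m[3, 3, 3] = True
        assert hausdorff_distance(m, m) == 0.0

    def test_two_points_three_apart(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[2, 4, 4] = True
        b[5, 4, 4] = True
        assert hausdorff_distance(a, b) == pytest.approx(3.0)

    def test_spacing_scales_distance(self):
        a = np.zeros((8, 4, 4), bool)
        b = np.zeros((8, 4, 4), bool)
        a[2, 2, 2] = True
        b[4, 2, 2] = True
        assert hausdorff_distance(a, b, spacing=(2.5, 1, 1)) == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((7, 7, 7)) < 0.25
        b = rng.random((7, 7, 7)) < 0.25
        a[3, 3, 3] = b[3, 3, 3] = True  # nonempty
        assert a.sum() <= 500 and b.sum() <= 500
        assert hausdorff_distance(a, b) == pytest.approx(
            hausdorff_oracle(a, b))

    def test_hd95_matches_oracle_and_bounded_by_hd(self):
        rng = np.random.default_rng(9)
        a = rng.random((8, 8, 8)) < 0.3
        b = rng.random((8, 8, 8)) < 0.3
        a[4, 4, 4] = b[4, 4, 4] = True
        hd = hausdorff_distance(a, b)
        hd95 = hausdorff_distance(a, b, percentile=95)
        assert hd95 <= hd + 1e-12
        assert hd95 == pytest.approx(hausdorff_oracle(a, b, percentile=95))

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(4)
        masks = []
        for _ in range(3):
            m = rng.random((6, 6, 6)) < 0.3
            m[3, 3, 3] = True
            masks.append(m)
        a, b, c = masks
        assert hausdorff_distance(a, b) == hausdorff_distance(b, a)
        assert hausdorff_distance(a, c) <= (hausdorff_distance(a, b)
                                            + hausdorff_distance(b, c) + 1e-9)

    def test_empty_mask_error_names_side(self):
        m = np.zeros((4, 4, 4), bool)
        n = m.copy()
        n[1, 1, 1] = True
        with pytest.raises(MetricError, match="first"):
            hausdorff_distance(m, n)
        with pytest.raises(MetricError, match="second"):
            hausdorff_distance(n, m)


class TestSummaries:
    def test_median_of_four(self):
        s = summarize([1, 2, 3, 4])
        assert s["median"] == pytest.approx(2.5)

    def test_constant_scores_zero_sd(self):
        s = summarize([0.7] * 6)
        assert s["sd"] == pytest.approx(0.0, abs=1e-12)
        assert s["q25"] == s["median"] == s["q75"] == pytest.approx(0.7)

    def test_quartiles_vs_sort_and_interpolate_oracle(self):
        scores = np.arange(101) / 100.0
        s = summarize(scores)

        def interp_quantile(sorted_vals, q):
            pos = q * (len(sorted_vals) - 1)
            lo = int(np.floor(pos))
            hi = int(np.ceil(pos))
            frac = pos - lo
            return sorted_vals[lo] * (1 - frac) + sorted_vals[hi] * frac

        sv = np.sort(scores)
        for key, q in (("q25", 0.25), ("median", 0.5), ("q75", 0.75)):
            assert s[key] == pytest.approx(interp_quantile(sv, q))
        assert s["q25"] <= s["median"] <= s["q75"]

    def test_empty_rejected(self):
        with pytest.raises(MetricError):
            summarize([])


class TestRegionReports:
    def test_perfect_prediction_report(self, rng):
        wt = rng.random((6, 6, 6)) < 0.5
        tc = wt & (rng.random((6, 6, 6)) < 0.6)
        et = tc & (rng.random((6, 6, 6)) < 0.6)
        wt[3, 3, 3] = tc[3, 3, 3] = et[3, 3, 3] = True
        m = RegionMask(wt=wt, tc=tc, et=et)
        res = region_metrics(m, m)
        for region in ("wt", "tc", "et"):
            assert res[region]["dice"] == 1.0
            assert res[region]["sensitivity"] == 1.0
            assert res[region]["hausdorff"] == 0.0

    def test_empty_conventions(self):
        empty = RegionMask(*(np.zeros((4, 4, 4), bool),) * 3)
        one = np.zeros((4, 4, 4), bool)
        one[1, 1, 1] = True
        nonempty = RegionMask(wt=one, tc=one, et=one)
        both = region_metrics(empty, empty)
        assert both["wt"]["dice"] == 1.0 and both["wt"]["sensitivity"] == 1.0
        miss = region_metrics(empty, nonempty)
        assert miss["wt"]["dice"] == 0.0 and miss["wt"]["sensitivity"] == 0.0
        assert np.isnan(miss["wt"]["hausdorff"])

    def test_report_excludes_empty_hd_with_count(self):
        empty = RegionMask(*(np.zeros((4, 4, 4), bool),) * 3)
        per_case = {"a": region_metrics(empty, empty)}
        rep = metric_report(per_case)
        assert rep["regions"]["wt"]["hd_excluded"] == 1
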