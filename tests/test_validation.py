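import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lodosim.cli_io import OBSERVER_TABLES
from lodosim.phantom import RoiSpec
from lodosim.recon import ReconImage
from lodosim.validation import (
    ObserverTable,
    RoiMeasurement,
    build_discrepancy_report,
    chance_level_test,
    cohen_kappa,
    ctdi_scale,
    mean_difference_ci,
    observer_summary,
    paired_t_test,
    percent_discrepancy,
    roi_stats,
)


def make_image(grid, mas=100.0, provenance="original"):
    return ReconImage(grid, 1.0, "ramp-hann", mas, provenance)


class TestRoiStats:
    def test_constant_region(self):
        img = make_image(np.full((64, 64), 42.0))
        m = roi_stats(img, RoiSpec(center=(32, 32), area_mm2=50.0, tissue_name="muscle"))
        assert m.mean_hu == 42.0 and m.sd_hu == 0.0

    def test_two_pixel_roi_hand_computation(self):
        grid = np.zeros((8, 8))
        grid[3, 4] = 2.0  # ROI covers exactly pixels (3,4) and (4,4)
        roi = RoiSpec(center=(3.5, 4.0), area_mm2=np.pi * 0.6**2)
        mask = roi.mask((8, 8), 1.0)
        assert mask.sum() == 2
        m = roi_stats(make_image(grid), roi)
        assert m.mean_hu == pytest.approx(1.0)
        assert m.sd_hu == pytest.approx(np.sqrt(2.0))

    def test_sd_of_iid_normal_pixels(self):
        # sampling-distribution oracle: sd over ~1e4 iid N(50, 30^2) pixels
        rng = np.random.default_rng(11)
        grid = rng.normal(50.0, 30.0, size=(160, 160))
        roi = RoiSpec(center=(79.5, 79.5), area_mm2=np.pi * 56.4**2)
        mask = roi.mask((160, 160), 1.0)
        assert mask.sum() > 9500
        m = roi_stats(make_image(grid), roi)
        assert m.sd_hu == pytest.approx(30.0, rel=0.03)


class TestPercentDiscrepancy:
    @pytest.mark.parametrize(
        "orig,sim,expected",
        [
            (5.0, 5.0, 0.0),
            (68.4, 68.7, 0.4386),  # printed 10 mAs noise pair
            (21.0, 20.8, -0.9524),  # printed 80 mAs noise pair
        ],
    )
    def test_values(self, orig, sim, expected):
        assert percent_discrepancy(sim, orig) == pytest.approx(expected, abs=1e-4)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_discrepancy(1.0, 0.0)

    @given(st.floats(min_value=0.1, max_value=1e3))
    @settings(max_examples=30, deadline=None)
    def test_self_discrepancy_is_zero(self, x):
        assert percent_discrepancy(x, x) == 0.0


class TestMeanDifferenceCi:
    def test_identical_pairs_collapse_to_zero(self):
        assert mean_difference_ci([(3.0, 3.0)] * 5) == (0.0, 0.0, 0.0)

    def test_symmetric_differences_center_on_zero(self):
        mean, lo, hi = mean_difference_ci([(0.0, -1.0), (0.0, 0.0), (0.0, 1.0)])
        assert mean == 0.0
        assert lo == pytest.approx(-hi)

    def test_against_textbook_t_interval(self):
        # 10 pairs with differences 1..10: mean 5.5, s = 3.02765, n = 10,
        # t_{0.975, 9} = 2.2621571628 -> 5.5 +/- 2.26216 * 3.02765/sqrt(10)
        pairs = [(0.0, float(d)) for d in range(1, 11)]
        mean, lo, hi = mean_difference_ci(pairs)
        s = np.std(np.arange(1, 11), ddof=1)
        half = 2.2621571628 * s / np.sqrt(10)
        assert mean == pytest.approx(5.5)
        assert lo == pytest.approx(5.5 - half, abs=1e-6)
        assert hi == pytest.approx(5.5 + half, abs=1e-6)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            mean_difference_ci([(1.0, 2.0)])


def t_sf_numeric(t, df):
    """Independent oracle: upper tail of Student t by numerical integration."""
    from scipy.integrate import quad

    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    pdf = lambda u: c * (1 + u * u / df) ** (-(df + 1) / 2)
    val, _ = quad(pdf, t, np.inf)
    return val


class TestPairedTTest:
    def test_identical_samples(self):
        t, p = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_swapping_negates_t_preserves_p(self):
        x, y = [1.0, 2.5, 3.0, 4.0], [1.5, 2.0, 2.0, 5.0]
        t1, p1 = paired_t_test(x, y)
        t2, p2 = paired_t_test(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_against_numerical_t_cdf(self):
        # fixed 6-pair example; p = 2 * SF(|t|) with SF integrated numerically
        x = [10.0, 12.0, 9.0, 11.0, 13.0, 10.5]
        y = [9.0, 11.5, 9.5, 10.0, 12.0, 10.0]
        t, p = paired_t_test(x, y)
        d = np.array(x) - np.array(y)
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert t == pytest.approx(t_manual)
        assert p == pytest.approx(2 * t_sf_numeric(abs(t_manual), len(d) - 1), abs=1e-9)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0, 2.0], [1.0])


class TestObserverSummary:
    def test_published_tables_totals(self):
        s = observer_summary(OBSERVER_TABLES)
        assert s["n_total"] == 640
        assert s["n_correct"] == 323
        assert s["n_orig_correct"] == 160
        assert s["n_sim_correct"] == 163
        assert s["n_incorrect"] == 317
        assert s["n_sim_rated_orig"] == 157
        assert s["n_orig_rated_sim"] == 160
        assert s["proportions"]["correct"] == pytest.approx(323 / 640)

    def test_all_zero_table(self):
        s = observer_summary([ObserverTable("z", 0, 0, 0, 0)])
        assert s["n_correct"] == 0 and s["n_total"] == 0

    def test_permutation_invariance_and_additivity(self):
        s1 = observer_summary(OBSERVER_TABLES)
        s2 = observer_summary(OBSERVER_TABLES[::-1])
        assert s1["n_correct"] == s2["n_correct"]
        part = observer_summary(OBSERVER_TABLES[:2])
        rest = observer_summary(OBSERVER_TABLES[2:])
        assert part["n_correct"] + rest["n_correct"] == s1["n_correct"]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ObserverTable("bad", -1, 0, 0, 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            observer_summary([])


def kappa_bruteforce(a, b):
    a, b = np.asarray(a), np.asarray(b)
    p_o = (a == b).mean()
    p_e = sum((a == c).mean() * (b == c).mean() for c in np.union1d(a, b))
    return (p_o - p_e) / (1 - p_e)


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa([1, 2, 1, 2], [1, 2, 1, 2]) == 1.0

    def test_constant_rater_vs_balanced(self):
        # rater b always says 1 while a is balanced: agreement equals chance
        assert cohen_kappa([1, 2, 1, 2], [1, 1, 1, 1]) == pytest.approx(
            kappa_bruteforce([1, 2, 1, 2], [1, 1, 1, 1]), abs=1e-12
        )
        assert cohen_kappa([1, 2, 1, 2], [1, 1, 1, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_2x2_table_40_10_10_40(self):
        # hand computation: p_o = 0.8, p_e = 0.5 -> kappa = 0.6
        a = [1] * 50 + [2] * 50
        b = [1] * 40 + [2] * 10 + [1] * 10 + [2] * 40
        assert cohen_kappa(a, b) == pytest.approx(0.6)
        assert kappa_bruteforce(a, b) == pytest.approx(0.6)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa([1, 2], [1])

    @given(st.lists(st.sampled_from([1, 2]), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_relabel_invariant(self, a):
        rng = np.random.default_rng(len(a))
        b = list(rng.choice([1, 2], size=len(a)))
        k = cohen_kappa(a, b)
        assert -1.0 - 1e-12 <= k <= 1.0 + 1e-12
        relabel = {1: 2, 2: 1}
        k2 = cohen_kappa([relabel[v] for v in a], [relabel[v] for v in b])
        assert k2 == pytest.approx(k, abs=1e-12)


class TestChanceLevelTest:
    def test_exactly_chance(self):
        assert chance_level_test(5, 10) == pytest.approx(1.0)

    def test_published_detection_count_not_above_chance(self):
        # exact binomial sum oracle for 323 of 640 at p=0.5
        p = chance_level_test(323, 640)
        tail = sum(math.comb(640, k) for k in range(323, 641)) / 2**640
        assert p == pytest.approx(2 * tail, rel=1e-9)
        assert p > 0.05

    def test_perfect_discrimination(self):
        assert chance_level_test(640, 640) < 1e-9

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            chance_level_test(11, 10)


class TestCtdiScale:
    @pytest.mark.parametrize(
        "ref,mas_ref,mas_t,expected",
        [(4.4, 100.0, 10.0, 0.44), (4.4, 100.0, 100.0, 4.4), (4.4, 100.0, 50.0, 2.2)],
    )
    def test_linear_scaling(self, ref, mas_ref, mas_t, expected):
        assert ctdi_scale(ref, mas_ref, mas_t) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ctdi_scale(4.4, 0.0, 10.0)


class TestDiscrepancyReport:
    @staticmethod
    def measurements():
        out = []
        rng = np.random.default_rng(0)
        for tissue, base in [("muscle", 20.0), ("fat", 15.0)]:
            for dose in (10.0, 80.0):
                for i in range(4):
                    for prov in ("original", "simulated"):
                        out.append(
                            RoiMeasurement(
                                tissue, dose, prov,
                                mean_hu=200.0 + rng.normal(0, 1),
                                sd_hu=base + rng.normal(0, 0.5),
                            )
                        )
        return out

    def test_mean_lies_within_range(self):
        rep = build_discrepancy_report(self.measurements())
        lo, hi = rep.range_noise_pct
        assert lo <= rep.mean_noise_pct <= hi
        assert set(rep.cells.tissue) == {"muscle", "fat"}
        assert len(rep.t_p) == 4  # 2 doses x (noise, hu)

    def test_unpaired_measurements_rejected(self):
        ms = self.measurements()[:-1]
        with pytest.raises(ValueError, match="unpaired"):
            build_discrepancy_report(ms)
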