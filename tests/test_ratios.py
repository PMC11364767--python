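"""Harm classification and content-ratio machinery."""

import numpy as np
import pytest

from chronospread import DiurnalCurve
from chronospread.activity import CATEGORIES, N_BINS, UserProfile
from chronospread.ratios import (
    activity_ratio_correlation,
    circular_interpolate,
    classify_harm,
    cluster_ratio_curve,
    posts_vs_ratio_correlation,
    smooth_ratio,
    susceptibility_times,
    user_overall_ratio,
    user_ratio_curve,
)


def profile(uid, **cat_bins):
    """Build a profile from category -> {bin: count} mappings; category
    names use underscores for spaces."""
    counts = np.zeros((N_BINS, len(CATEGORIES)))
    for cat_key, bins in cat_bins.items():
        cat = cat_key.replace("_", " ")
        ci = CATEGORIES.index(cat)
        for b, c in bins.items():
            counts[b, ci] = c
    return UserProfile(uid, counts)


class TestClassifyHarm:
    @pytest.mark.parametrize("cat,score,flag", [
        ("Political", 7, True),
        ("Fake and Hoax", 8, True),
        ("Conspiracy and Junk Science", 9, True),
        ("Mainstream Media", 2, False),
        ("Satire", 3, False),
        ("Shadow", 6, False),
    ])
    def test_threshold_rule(self, cat, score, flag):
        assert classify_harm(cat) == (score, flag)

    def test_scores_increase_in_listed_order(self):
        scores = [classify_harm(c)[0] for c in
                  ("Scientific", "Mainstream Media", "Satire", "Clickbait",
                   "Other", "Shadow", "Political", "Fake and Hoax",
                   "Conspiracy and Junk Science")]
        assert scores == sorted(scores) and len(set(scores)) == 9

    def test_unknown_category(self):
        with pytest.raises(ValueError):
            classify_harm("Opinion")


class TestUserRatio:
    def test_direct_division(self):
        prof = profile("u", Political={5: 3}, Mainstream_Media={5: 7})
        r = user_ratio_curve(prof)
        assert r[5] == pytest.approx(0.3)

    def test_other_excluded_from_denominator(self):
        prof = profile("u", Political={5: 2}, Other={5: 2},
                       Mainstream_Media={5: 6})
        r = user_ratio_curve(prof)
        assert r[5] == pytest.approx(2 / 8)

    def test_empty_denominator_undefined(self):
        prof = profile("u", Other={5: 10})
        r = user_ratio_curve(prof)
        assert np.isnan(r[5])

    def test_target_must_be_classified(self):
        prof = profile("u", Political={5: 1})
        with pytest.raises(ValueError):
            user_ratio_curve(prof, target=("Other",))

    def test_ratios_stay_in_unit_interval(self, rng):
        counts = rng.integers(0, 5, size=(N_BINS, len(CATEGORIES))).astype(float)
        prof = UserProfile("u", counts)
        r = user_ratio_curve(prof)
        finite = r[np.isfinite(r)]
        assert np.all((finite >= 0) & (finite <= 1))


class TestClusterRatio:
    def test_singleton_identity(self):
        prof = profile("u", Political={3: 1}, Mainstream_Media={3: 3})
        out = cluster_ratio_curve({"u": prof}, ["u"])
        assert out.values[3] == pytest.approx(0.25)

    def test_mean_of_defined_members(self):
        a = profile("a", Political={3: 1}, Mainstream_Media={3: 4})   # 0.2
        b = profile("b", Political={3: 2}, Mainstream_Media={3: 3})   # 0.4
        out = cluster_ratio_curve({"a": a, "b": b}, ["a", "b"])
        assert out.values[3] == pytest.approx(0.3)

    def test_undefined_member_masked_not_zero_filled(self):
        a = profile("a", Political={3: 1}, Mainstream_Media={3: 1})   # 0.5
        b = profile("b", Mainstream_Media={7: 5})                     # undefined at 3
        out = cluster_ratio_curve({"a": a, "b": b}, ["a", "b"])
        assert out.values[3] == pytest.approx(0.5)

    def test_convex_combination_property(self, rng):
        profs = {}
        for uid in "abcd":
            counts = rng.integers(0, 4, size=(N_BINS, len(CATEGORIES))).astype(float)
            profs[uid] = UserProfile(uid, counts)
        out = cluster_ratio_curve(profs, list("abcd")).values
        per_user = np.vstack([user_ratio_curve(profs[u]) for u in "abcd"])
        lo = np.nanmin(per_user, axis=0)
        hi = np.nanmax(per_user, axis=0)
        finite = np.isfinite(out)
        assert np.all(out[finite] >= lo[finite] - 1e-12)
        assert np.all(out[finite] <= hi[finite] + 1e-12)


class TestSmoothRatio:
    def test_constant_ratios_stay_constant(self):
        profs = {"u": profile("u",
                              Political={b: 1 for b in range(N_BINS)},
                              Mainstream_Media={b: 3 for b in range(N_BINS)})}
        coarse, smooth, m, n_interp = smooth_ratio(profs, ["u"])
        assert np.allclose(coarse.values, 0.25)
        assert np.allclose(smooth.values, 0.25, atol=1e-9)
        assert n_interp == 0

    def test_planted_night_elevation_peak_recovered(self):
        # ratio follows a sinusoid peaking at 3:00; the smoothed curve's
        # peak must come back within 2 bins
        profs = {}
        hours = np.arange(N_BINS) * 0.25
        level = 0.25 + 0.15 * np.cos(2 * np.pi * (hours - 3.0) / 24)
        pol = {b: round(40 * level[b]) for b in range(N_BINS)}
        msm = {b: 40 - pol[b] for b in range(N_BINS)}
        profs["u"] = profile("u", Political=pol, Mainstream_Media=msm)
        _, smooth, _, _ = smooth_ratio(profs, ["u"])
        peak_bin = int(np.argmax(smooth.values))
        assert min(abs(peak_bin - 12) % 96, abs(12 - peak_bin) % 96) <= 2

    def test_all_undefined_rejected(self):
        profs = {"u": profile("u", Other={3: 5})}
        with pytest.raises(ValueError):
            smooth_ratio(profs, ["u"])

    def test_interpolation_before_dft_is_flagged(self):
        pol = {b: 1 for b in range(0, 48)}
        msm = {b: 3 for b in range(0, 48)}
        profs = {"u": profile("u", Political=pol, Mainstream_Media=msm)}
        coarse, smooth, m, n_interp = smooth_ratio(profs, ["u"])
        assert n_interp > 0
        assert np.all(np.isfinite(smooth.values))


class TestCircularInterpolation:
    def test_gap_across_midnight(self):
        v = np.full(N_BINS, np.nan)
        v[90] = 1.0
        v[6] = 1.0
        out = circular_interpolate(v)
        assert np.all(np.isfinite(out))
        assert out[94] == pytest.approx(1.0)
        assert out[0] == pytest.approx(1.0)

    def test_linear_across_the_seam(self):
        v = np.full(N_BINS, np.nan)
        v[94] = 0.0
        v[2] = 4.0
        out = circular_interpolate(v)
        assert out[95] == pytest.approx(1.0)
        assert out[0] == pytest.approx(2.0)
        assert out[1] == pytest.approx(3.0)


class TestSusceptibility:
    def test_constant_curve_empty(self):
        curve = DiurnalCurve(np.full(N_BINS, 0.2), kind="ratio")
        assert susceptibility_times(curve).size == 0

    def test_distinct_values_give_top_quartile(self):
        curve = DiurnalCurve(np.linspace(0, 1, N_BINS), kind="ratio")
        bins = susceptibility_times(curve)
        assert bins.size == 24
        assert bins.min() == 72

    def test_single_outlier(self):
        v = np.full(N_BINS, 0.2)
        v[40] = 0.9
        bins = susceptibility_times(DiurnalCurve(v, kind="ratio"))
        assert list(bins) == [40]


class TestCorrelations:
    def test_monotone_users(self):
        profs = {}
        for i, (total, pol) in enumerate([(10, 1), (20, 4), (40, 12),
                                          (80, 40)]):
            profs[f"u{i}"] = profile(
                f"u{i}", Political={0: pol},
                Mainstream_Media={0: total - pol})
        res = posts_vs_ratio_correlation(profs)
        assert res.statistic == pytest.approx(1.0)

    def test_antimonotone_users(self):
        profs = {}
        for i, (total, pol) in enumerate([(10, 8), (20, 10), (40, 12),
                                          (80, 10)]):
            profs[f"u{i}"] = profile(
                f"u{i}", Political={0: pol},
                Mainstream_Media={0: total - pol})
        res = posts_vs_ratio_correlation(profs)
        assert res.statistic == pytest.approx(-1.0)

    def test_too_few_users(self):
        profs = {"a": profile("a", Political={0: 1})}
        with pytest.raises(ValueError):
            posts_vs_ratio_correlation(profs)

    def test_activity_ratio_perfect_monotone(self, rng):
        a = rng.random(N_BINS)
        res = activity_ratio_correlation(a, a ** 3)  # monotone transform
        assert res.statistic == pytest.approx(1.0)

    def test_independent_curves_near_zero(self):
        hits = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            res = activity_ratio_correlation(r.random(N_BINS),
                                             r.random(N_BINS))
            hits += abs(res.statistic) < 0.3
        assert hits >= 38  # ~95%

    def test_constant_activity_flagged(self):
        res = activity_ratio_correlation(np.ones(N_BINS),
                                         np.linspace(0, 1, N_BINS))
        assert np.isnan(res.statistic) and res.note == "constant-input"

    def test_undefined_bins_pairwise_deleted(self, rng):
        a = rng.random(N_BINS)
        r = a.copy()
        r[10:20] = np.nan
        res = activity_ratio_correlation(a, r)
        assert res.extra["bins_used"] == 86
        assert res.statistic == pytest.approx(1.0)
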