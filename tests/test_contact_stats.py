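"""Invasion ratio, directionality score, proportions, and the tests on them."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from tz4c.contact_stats import (
    anova_tukey,
    directionality_score,
    interval_proportions,
    invasion_ratio,
    permutation_test_one_sided,
)
from tz4c.fourc_processing import ContactProfile, exclude_near_viewpoint
from tz4c.locus_model import GenomicInterval, Viewpoint

from conftest import make_map, make_profile

GI = GenomicInterval


class TestInvasionRatio:
    def _profile(self):
        counts = np.zeros(40, dtype=int)
        counts[0:10] = 100  # control zone [0,1000)
        counts[30:33] = [4, 3, 3]  # invasion zone [3000,3300)
        return make_profile(counts, vp_pos=1500)

    def test_simple_division(self):
        res = invasion_ratio(
            self._profile(), GI("chrT", 3000, 3500), GI("chrT", 0, 1000)
        )
        assert res.invasion_count == 10 and res.control_count == 1000
        assert res.ratio == pytest.approx(0.01)

    def test_zero_invasion_gives_zero(self):
        res = invasion_ratio(
            self._profile(), GI("chrT", 3500, 4000), GI("chrT", 0, 1000)
        )
        assert res.ratio == 0.0

    def test_zero_control_rejected(self):
        with pytest.raises(ZeroDivisionError):
            invasion_ratio(
                self._profile(), GI("chrT", 3000, 3500), GI("chrT", 1200, 1400)
            )

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError):
            invasion_ratio(self._profile(), GI("chrT", 0, 500), GI("chrT", 400, 900))

    def test_doubling_counts_leaves_ratio_unchanged(self, rng):
        counts = rng.integers(1, 50, size=40)
        a = make_profile(counts, vp_pos=1500)
        b = make_profile(counts * 2, vp_pos=1500)
        inv, ctl = GI("chrT", 3000, 4000), GI("chrT", 0, 1000)
        assert invasion_ratio(a, inv, ctl).ratio == pytest.approx(
            invasion_ratio(b, inv, ctl).ratio
        )


class TestDirectionalityScore:
    def _profile(self, left_total, right_total, n=20):
        counts = np.zeros(2 * n + 1, dtype=int)
        counts[:n] = np.full(n, left_total // n)
        counts[n + 1 :] = np.full(n, right_total // n)
        counts[0] += left_total - counts[:n].sum()
        counts[-1] += right_total - counts[n + 1 :].sum()
        return make_profile(counts, vp_pos=100 * n + 50, exclusion=1)

    @pytest.mark.parametrize(
        "left,right,expected", [(100, 100, 0.0), (0, 80, 1.0), (150, 50, -0.5)]
    )
    def test_worked_values(self, left, right, expected):
        res = directionality_score(self._profile(left, right), window=10_000)
        assert res.score == pytest.approx(expected)
        assert res.left_count == left and res.right_count == right

    def test_bounds(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 30, size=41)
            p = make_profile(counts, vp_pos=2050, exclusion=1)
            s = directionality_score(p, window=10_000).score
            assert -1.0 <= s <= 1.0

    def test_antisymmetry_under_mirroring(self, rng):
        counts = rng.integers(0, 30, size=41)
        p = exclude_near_viewpoint(make_profile(counts, vp_pos=2050, exclusion=1))
        q = exclude_near_viewpoint(
            make_profile(counts[::-1], vp_pos=2050, exclusion=1)
        )
        a = directionality_score(p, window=10_000).score
        b = directionality_score(q, window=10_000).score
        assert a == pytest.approx(-b)

    def test_empty_window_rejected(self):
        p = make_profile([0] * 21, vp_pos=1050)
        with pytest.raises(ZeroDivisionError):
            directionality_score(p, window=500)

    def test_masked_fragments_excluded(self):
        p = self._profile(100, 100)
        p = exclude_near_viewpoint(p, radius=150)  # masks one fragment per side
        res = directionality_score(p, window=10_000)
        assert res.left_count < 100 and res.right_count < 100


class TestIntervalProportions:
    AREAS = [
        GI("chrT", 0, 1000, "Tfap2c-cen"),
        GI("chrT", 1000, 2000, "Tfap2c-tel"),
        GI("chrT", 2000, 3000, "TZ"),
        GI("chrT", 3000, 4000, "Bmp7-domain"),
    ]

    def test_worked_percentages_and_ratio(self):
        counts = np.zeros(40, dtype=int)
        for block, total in zip(range(4), (25, 50, 12, 13)):
            counts[block * 10] = total
        p = make_profile(counts, vp_pos=3999, exclusion=1)
        res = interval_proportions(p, self.AREAS)
        assert res.percentages == pytest.approx(
            {"Tfap2c-cen": 25, "Tfap2c-tel": 50, "TZ": 12, "Bmp7-domain": 13}
        )
        assert res.tel_cen_ratio == pytest.approx(2.0)

    def test_single_area_totality(self):
        counts = np.zeros(40, dtype=int)
        counts[5] = 7
        p = make_profile(counts, vp_pos=3999, exclusion=1)
        res = interval_proportions(p, self.AREAS)
        assert res.percentages["Tfap2c-cen"] == 100.0
        assert sum(res.percentages.values()) == pytest.approx(100.0)

    def test_matches_bruteforce_recount(self, rng):
        counts = rng.integers(0, 40, size=40)
        p = make_profile(counts, vp_pos=2050, exclusion=120)
        p = exclude_near_viewpoint(p)
        res = interval_proportions(p, self.AREAS)
        for area in self.AREAS:
            expected = sum(
                int(c)
                for i, c in enumerate(counts)
                if area.start <= (p.fragment_map.midpoints[i]) < area.end
                and not p.mask[i]
            )
            assert res.counts[area.name] == expected

    def test_no_reads_rejected(self):
        p = make_profile([0] * 40, vp_pos=2050)
        with pytest.raises(ZeroDivisionError):
            interval_proportions(p, self.AREAS)


class TestPermutationTest:
    def test_exact_enumeration_quarter_case(self):
        res = permutation_test_one_sided([1, 2], [10, 11], "greater")
        assert res.p_value == pytest.approx(1 / 6)
        assert res.min_p == pytest.approx(1 / 6)
        assert res.statistic == pytest.approx(9.0)

    def test_identical_multisets_not_significant(self):
        res = permutation_test_one_sided([1, 2, 3], [1, 2, 3], "greater")
        assert res.p_value >= 0.5

    def test_singleton_tie_gives_p_one(self):
        res = permutation_test_one_sided([5], [5], "greater")
        assert res.p_value == 1.0

    def test_less_alternative_mirrors_greater(self, rng):
        a = rng.normal(size=4).tolist()
        b = rng.normal(size=3).tolist()
        g = permutation_test_one_sided(a, b, "greater")
        l = permutation_test_one_sided([-x for x in a], [-x for x in b], "less")
        assert g.p_value == pytest.approx(l.p_value)

    def test_matches_scipy_exact_enumeration(self, rng):
        for _ in range(25):
            a = rng.integers(0, 40, size=int(rng.integers(2, 5))).tolist()
            b = rng.integers(0, 40, size=int(rng.integers(2, 5))).tolist()
            mine = permutation_test_one_sided(a, b, "greater")
            ref = sps.permutation_test(
                (a, b),
                lambda x, y, axis=-1: np.mean(y, axis=axis) - np.mean(x, axis=axis),
                permutation_type="independent",
                alternative="greater",
                n_resamples=np.inf,
            )
            assert mine.p_value == pytest.approx(ref.pvalue)

    def test_monte_carlo_path_is_deterministic(self, rng):
        a = rng.normal(size=9).tolist()
        b = rng.normal(size=9).tolist()  # C(18,9) = 48620 > 20000 -> MC
        r1 = permutation_test_one_sided(a, b, "greater", seed=11)
        r2 = permutation_test_one_sided(a, b, "greater", seed=11)
        assert r1.p_value == r2.p_value
        assert r1.min_p == pytest.approx(1 / 10_001)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_test_one_sided([], [1.0], "greater")

    def test_null_calibration_is_conservative(self):
        """i.i.d. groups, n=3+3: rejection rate at 0.05 stays <= 0.07."""
        rng = np.random.default_rng(2026)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            a = rng.normal(size=3)
            b = rng.normal(size=3)
            p = permutation_test_one_sided(a, b, "greater").p_value
            rejections += p <= 0.05
        assert rejections / n_sim <= 0.07


class TestAnovaTukey:
    def test_identical_constant_groups(self):
        res = anova_tukey({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert res[0].method == "anova"
        assert res[0].statistic == 0.0 and res[0].p_value == 1.0
        assert all(r.p_value == 1.0 for r in res[1:])

    def test_two_groups_f_equals_t_squared(self, rng):
        a = rng.normal(size=5).tolist()
        b = rng.normal(1.0, size=6).tolist()
        res = anova_tukey({"a": a, "b": b})
        t = sps.ttest_ind(a, b).statistic
        assert res[0].statistic == pytest.approx(t**2, rel=1e-9)

    def test_matches_statsmodels_tukey(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        groups = {
            "g1": rng.normal(0, 1, 5),
            "g2": rng.normal(0.5, 1, 5),
            "g3": rng.normal(2.0, 1, 5),
        }
        res = anova_tukey(groups)
        mine = {tuple(r.groups): r.p_value for r in res if r.method == "tukey"}
        values = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), [5, 5, 5])
        sm = pairwise_tukeyhsd(values, labels)
        for (g1, g2), p_adj in zip(
            [tuple(row[:2]) for row in sm.summary().data[1:]], sm.pvalues
        ):
            assert mine[(g1, g2)] == pytest.approx(p_adj, abs=1e-6)

    def test_reference_pairs_reported_first(self, rng):
        groups = {n: rng.normal(size=3) for n in ("Hap", "x", "y", "z")}
        res = anova_tukey(groups, reference="Hap")
        tukey = [r for r in res if r.method == "tukey"]
        assert all(t.groups[0] == "Hap" for t in tukey[:3])

    def test_shifted_group_flagged_against_reference(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            groups = {
                "Hap": rng.normal(2.0, 0.1, 3),
                "shifted": rng.normal(3.5, 0.1, 3),
                "same": rng.normal(2.0, 0.1, 3),
            }
            res = anova_tukey(groups, reference="Hap")
            by_pair = {r.groups: r for r in res if r.method == "tukey"}
            hits += by_pair[("Hap", "shifted")].p_value < 0.05
        assert hits == 20

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey({"a": [1.0], "b": [1.0, 2.0]})
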