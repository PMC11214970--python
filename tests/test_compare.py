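"""Method ranges, plausibility flags, reference deltas, seasonal contrasts."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from trophicpos import (
    TEFScheme,
    TPEstimate,
    compare_to_reference,
    flag_implausible,
    kruskal_2group,
    method_range,
    packaged_baseline,
    seasonal_contrast,
)
from conftest import make_sample


def est(mean, label, species="Acanthurus lineatus", n=5, sd=0.1):
    return TPEstimate(species=species, method_label=label, mean_tp=mean, sd_tp=sd, n=n)


class TestMethodRange:
    def test_spread_across_methods(self):
        estimates = [
            est(1.36, "TP_phyto-va"),
            est(2.56, "TP_Pima"),
            est(2.16, "TP_algae-va"),
            est(1.45, "TP_phyto"),
        ]
        r = method_range(estimates)
        assert r.min_method == "TP_phyto-va" and r.min_tp == 1.36
        assert r.max_method == "TP_Pima" and r.max_tp == 2.56
        assert r.spread == pytest.approx(1.20)

    def test_repeated_value_gives_zero_spread(self):
        r = method_range([est(2.5, "TP_algae"), est(2.5, "TP_phyto")])
        assert r.spread == 0.0

    def test_ties_broken_by_canonical_method_order(self):
        estimates = [est(2.0, "TP_Pima"), est(3.0, "TP_AA-Sr"), est(3.0, "TP_algae")]
        r = method_range(estimates)
        assert r.max_method == "TP_algae"  # first in canonical order among the tied maxima

    def test_fewer_than_two_estimates_rejected(self):
        with pytest.raises(ValueError):
            method_range([est(2.5, "TP_algae")])


class TestFlagImplausible:
    def test_consumer_below_two_flagged(self):
        flags = flag_implausible([est(1.45, "TP_phyto")])
        assert len(flags) == 1 and "TP < 2" in flags[0].reason

    def test_boundary_value_not_flagged(self):
        assert flag_implausible([est(2.0, "TP_algae")]) == []

    def test_below_producer_floor_double_flagged(self):
        flags = flag_implausible([est(0.9, "TP_phyto")])
        assert len(flags) == 2
        assert {f.reason for f in flags} == {"below consumer floor (TP < 2)", "below producer floor (TP < 1)"}


class TestCompareToReference:
    REF = {"Acanthurus nigricans": (2.0, 0.0)}

    def test_delta_against_reference(self):
        df = compare_to_reference([est(2.45, "TP_algae", species="Acanthurus nigricans")], self.REF)
        assert df.loc[0, "delta"] == pytest.approx(0.45)

    def test_species_without_reference_marked_nd(self):
        df = compare_to_reference([est(2.45, "TP_algae", species="Ctenochaetus flavicauda")], self.REF)
        assert df.loc[0, "delta"] == "nd" and df.loc[0, "tp_ref"] == "nd"

    def test_zero_delta_when_equal(self):
        df = compare_to_reference([est(2.0, "TP_algae", species="Acanthurus nigricans")], self.REF)
        assert df.loc[0, "delta"] == pytest.approx(0.0)


class TestKruskal2Group:
    def test_identical_groups_not_significant(self):
        h, p = kruskal_2group([2.1, 2.2, 2.3], [2.1, 2.2, 2.3], method="exact")
        assert p >= 0.99

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_exact_p_matches_brute_force_enumeration(self, seed):
        """Independent oracle: scipy's H on every one of the 20 assignments."""
        rng = np.random.default_rng(seed)
        pooled = list(rng.normal(0, 1, 6).round(2))  # rounding induces occasional ties
        x, y = pooled[:3], pooled[3:]
        h_obs, p_exact = kruskal_2group(x, y, method="exact")
        hits = total = 0
        for chosen in combinations(range(6), 3):
            xs = [pooled[i] for i in chosen]
            ys = [pooled[i] for i in range(6) if i not in chosen]
            if len(set(pooled)) == 1:
                h = 0.0
            else:
                h = stats.kruskal(xs, ys).statistic
            total += 1
            hits += h >= h_obs - 1e-12
        assert total == 20
        assert p_exact == pytest.approx(hits / total, abs=1e-12)
        assert h_obs == pytest.approx(stats.kruskal(x, y).statistic, abs=1e-9)

    def test_asymptotic_matches_scipy(self):
        x, y = [2.1, 2.5, 2.8, 3.0, 2.2, 2.6], [3.1, 3.3, 2.9, 3.4, 3.2, 3.0]
        h, p = kruskal_2group(x, y, method="asymptotic")
        ref = stats.kruskal(x, y)
        assert (h, p) == (pytest.approx(ref.statistic), pytest.approx(ref.pvalue))

    def test_statistic_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        x, y = list(rng.normal(2, 1, 8)), list(rng.normal(3, 1, 9))
        h1, p1 = kruskal_2group(x, y)
        h2, p2 = kruskal_2group([np.exp(v) for v in x], [np.exp(v) for v in y])
        assert h1 == pytest.approx(h2, abs=1e-9) and p1 == pytest.approx(p2, abs=1e-12)


def two_season_samples(species="Acanthurus synthetica", winter=(), summer=(), guild="herbivore-detritivore"):
    out = []
    for i, v in enumerate(winter):
        out.append(make_sample(v, species=species, guild=guild, season="winter", sample_id=f"{species}w{i}"))
    for i, v in enumerate(summer):
        out.append(make_sample(v, species=species, guild=guild, season="summer", sample_id=f"{species}s{i}"))
    return out


class TestSeasonalContrast:
    BW = packaged_baseline("macroalgae", "winter")
    BS = packaged_baseline("macroalgae", "summer")

    def test_identical_tp_lists_give_zero_difference(self):
        # same δ¹⁵N values in both seasons against a shared baseline
        # → identical per-individual TP lists, exactly
        values = (16.0, 16.5, 17.0)
        samples = two_season_samples(winter=values, summer=values)
        (c,) = seasonal_contrast(samples, self.BW, self.BW, TEFScheme.constant())
        assert c.difference == pytest.approx(0.0, abs=1e-12)
        assert c.p_value >= 0.99

    def test_season_invariant_d15n_gives_higher_winter_tp(self):
        # winter baseline (10.2‰) below summer (11.9‰): same consumer δ¹⁵N
        # sits more enrichment steps above the winter baseline
        values = (16.0, 16.5, 17.0, 15.8)
        for guild, scheme in [("herbivore-detritivore", TEFScheme.constant()),
                              ("carnivore", TEFScheme.by_guild())]:
            samples = two_season_samples(winter=values, summer=values, guild=guild)
            (c,) = seasonal_contrast(samples, self.BW, self.BS, scheme)
            assert c.difference > 0

    def test_species_below_min_n_excluded(self):
        samples = two_season_samples(winter=(16.0, 16.5), summer=(15.0, 15.5, 16.0))
        samples += two_season_samples(species="Lutjanus synthetica", guild="carnivore",
                                      winter=(20.0, 20.5, 21.0), summer=(19.0, 19.5, 20.0))
        contrasts = seasonal_contrast(samples, self.BW, self.BS, TEFScheme.constant())
        assert [c.species for c in contrasts] == ["Lutjanus synthetica"]
        assert contrasts[0].n_winter == 3 and contrasts[0].n_summer == 3

    def test_shared_baseline_p_equals_raw_d15n_p(self):
        """TP is affine in δ¹⁵N, so ranks — and the test — are unchanged."""
        rng = np.random.default_rng(11)
        winter = tuple(rng.normal(17, 0.5, 8).round(3))
        summer = tuple(rng.normal(16.2, 0.5, 8).round(3))
        samples = two_season_samples(winter=winter, summer=summer)
        shared = self.BW
        (c,) = seasonal_contrast(samples, shared, shared, TEFScheme.constant(), p_method="asymptotic")
        _, p_raw = kruskal_2group(list(winter), list(summer), method="asymptotic")
        assert c.p_value == pytest.approx(p_raw, abs=1e-12)

    def test_bh_adjustment_only_increases_p(self):
        rng = np.random.default_rng(3)
        samples = []
        for i in range(4):
            samples += two_season_samples(
                species=f"Sp {i}",
                winter=tuple(rng.normal(17, 0.4, 5)),
                summer=tuple(rng.normal(16, 0.4, 5)),
            )
        plain = seasonal_contrast(samples, self.BW, self.BS, TEFScheme.constant(), p_method="asymptotic")
        adjusted = seasonal_contrast(samples, self.BW, self.BS, TEFScheme.constant(),
                                     p_method="asymptotic", bh_correct=True)
        for c0, c1 in zip(plain, adjusted):
            assert c1.p_value >= c0.p_value - 1e-15
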