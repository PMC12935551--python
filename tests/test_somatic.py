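"""Somatic-expansion fractions, age trends, long-allele metrics, calibration."""

import math

import numpy as np
import pandas as pd
import pytest

from strmosaic.harvest import GermlineGenotype
from strmosaic.simulate import SimConfig, simulate_reads, truth_frame
from strmosaic.somatic import (
    age_trend,
    attributable_counts,
    calibrate_by_group,
    expansion_fraction,
    expected_irr_pairs,
    fragment_score,
    long_allele_length,
    midlength_score,
    pool_by_allele_age,
    screen_instability,
)

from test_harvest import _spanning_stub


def wilson(k, n, z=1.959963984540054):
    """Closed-form Wilson score interval, the independent oracle."""
    p = k / n
    centre = (p + z**2 / (2 * n)) / (1 + z**2 / n)
    half = z / (1 + z**2 / n) * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2))
    return centre - half, centre + half


class TestExpansionFraction:
    def test_basic_ratio_and_wilson_ci(self):
        est = expansion_fraction(20, 1)
        assert est.fraction == pytest.approx(1 / 21)
        lo, hi = wilson(1, 21)
        assert est.ci_low == pytest.approx(lo, abs=1e-9)
        assert est.ci_high == pytest.approx(hi, abs=1e-9)

    def test_zero_shifted_reads(self):
        est = expansion_fraction(20, 0)
        assert est.fraction == 0.0
        assert est.ci_low == 0.0

    def test_homozygote_per_allele_copy(self):
        assert expansion_fraction(40, 2).fraction == pytest.approx(2 / 42)

    def test_no_reads_raises(self):
        with pytest.raises(ValueError):
            expansion_fraction(0, 0)


class TestAttribution:
    def _gt(self, *alleles):
        return GermlineGenotype("S1", "L1", tuple(sorted(alleles)), {})

    def test_adjacent_other_allele_ineligible(self):
        calls = [_spanning_stub(10, f"r{i}") for i in range(5)]
        assert attributable_counts(calls, self._gt(10, 11), 10) is None
        assert attributable_counts(calls, self._gt(10, 12), 10) is None  # gap 2 < 3

    def test_distant_other_allele_counted(self):
        calls = [_spanning_stub(u, f"r{i}") for i, u in enumerate([10, 10, 11, 17])]
        assert attributable_counts(calls, self._gt(10, 17), 10) == (2, 1)

    def test_exact_homozygote_allowed(self):
        calls = [_spanning_stub(u, f"r{i}") for i, u in enumerate([10] * 4 + [11])]
        assert attributable_counts(calls, self._gt(10, 10), 10) == (4, 1)

    def test_germline_allele_at_shifted_length_ineligible(self):
        assert attributable_counts([], self._gt(10, 11), 10, direction=1) is None


class TestPooling:
    def test_counts_summed_before_ratio(self):
        parts = [expansion_fraction(20, 1, locus_id="L1", allele=18, age_bin="40-50")
                 for _ in range(2)]
        pooled = pool_by_allele_age(parts)
        assert len(pooled) == 1
        assert pooled[0].fraction == pytest.approx(2 / 42)
        assert pooled[0].n_base_reads == 40

    def test_single_individual_unchanged(self):
        part = expansion_fraction(20, 1, locus_id="L1", allele=18, age_bin="40-50")
        assert pool_by_allele_age([part])[0].fraction == part.fraction


class TestAgeTrend:
    def test_three_point_closed_form(self):
        trend = age_trend([0.004, 0.005, 0.006], [40, 50, 60])
        assert trend.slope == pytest.approx(1.0e-4)

    def test_constant_metric_zero_slope(self):
        trend = age_trend([0.004] * 6, [40, 45, 50, 55, 60, 65])
        assert trend.slope == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_design_raises(self):
        with pytest.raises(ValueError):
            age_trend([1, 2, 3], [50, 50, 50])


class TestLongAllele:
    def test_censored_when_no_irrs(self):
        m = long_allele_length(0, 0.2)
        assert m.censored and m.est_length_bp is None

    def test_inversion_arithmetic(self):
        # c=0.2, 10 IRRs, R=151 -> 150 + 50 = 200 bp = 66.67 CAG units
        m = long_allele_length(10, 0.2)
        assert m.est_length_bp == pytest.approx(200.0)
        assert m.est_length_units == pytest.approx(200 / 3)
        assert m.est_length_bp >= 151 - 1

    def test_invalid_density(self):
        with pytest.raises(ValueError):
            long_allele_length(5, 0.0)


class TestFragmentMetric:
    def test_zero_pairs_zero_score(self):
        assert fragment_score(0, 0.1) == 0.0

    def test_fixed_fragment_length_enumeration(self):
        # L >= F: eligible starts L - F + 1
        assert expected_irr_pairs(450, 400, 0.0, 0.1) == pytest.approx(
            0.1 * (450 - 400 + 1)
        )
        assert expected_irr_pairs(300, 400, 0.0, 0.1) == 0.0

    def test_expected_pairs_monotone_in_length(self):
        vals = [expected_irr_pairs(L, 400, 60, 0.1) for L in (300, 450, 600, 900)]
        assert vals == sorted(vals)
        assert vals[-1] > vals[0]

    def test_longer_allele_scores_higher_in_simulation(self, rng):
        cfg = SimConfig(error_rate=0.0, stutter_prob=0.0)
        wins = 0
        n_rep = 20
        for _ in range(n_rep):
            counts = []
            for units in (150, 300):  # 450 vs 900 bp
                reads = simulate_reads("S", [[(units, 1.0)]], cfg, rng)
                tf = truth_frame(reads)
                pair_frags = (
                    tf[tf["class"] == "irr"]
                    .groupby(tf["read_id"].str.split("/").str[0])
                    .size()
                )
                counts.append(int((pair_frags == 2).sum()))
            if fragment_score(counts[1], cfg.fragment_start_density) > fragment_score(
                counts[0], cfg.fragment_start_density
            ):
                wins += 1
        assert wins >= 17  # 450 vs 900 bp separated in nearly all replicates


class TestCalibration:
    def _frame(self, values, group="g", start=0):
        return pd.DataFrame(
            {
                "sample_id": [f"S{start + i}" for i in range(len(values))],
                "group_id": group,
                "raw_metric": values,
            }
        )

    def test_z_score_example(self):
        out = calibrate_by_group(self._frame([1.0, 2.0, 3.0]), min_group=3)
        assert out.loc[out.raw_metric == 3.0, "z_value"].iloc[0] == pytest.approx(1.0)

    def test_middle_rank_int_zero(self):
        out = calibrate_by_group(self._frame([1.0, 2.0, 3.0]), min_group=3)
        assert out.loc[out.raw_metric == 2.0, "int_value"].iloc[0] == pytest.approx(0.0)

    def test_zero_variance_group_dropped(self):
        out = calibrate_by_group(self._frame([5.0, 5.0, 5.0]), min_group=3)
        assert out.empty

    def test_small_group_dropped(self):
        out = calibrate_by_group(self._frame([1.0, 2.0]), min_group=10)
        assert out.empty

    def test_within_group_moments_and_monotonicity(self, rng):
        df = pd.concat(
            [
                self._frame(rng.normal(size=40), group="g1"),
                self._frame(rng.normal(2, 3, size=25), group="g2", start=100),
            ]
        )
        out = calibrate_by_group(df, min_group=10)
        for _, sub in out.groupby("group_id"):
            assert sub.z_value.mean() == pytest.approx(0.0, abs=1e-12)
            assert sub.z_value.std(ddof=1) == pytest.approx(1.0)
            ordered = sub.sort_values("raw_metric")
            assert ordered.int_value.is_monotonic_increasing


class TestMidlengthScore:
    def _gt(self, *alleles):
        return GermlineGenotype("S1", "L1", tuple(sorted(alleles)), {})

    def test_mean_shift(self):
        calls = [_spanning_stub(u, f"r{i}") for i, u in enumerate([20, 20, 20, 21])]
        assert midlength_score(calls, self._gt(20, 25), 20) == pytest.approx(0.25)

    def test_all_at_allele_zero(self):
        calls = [_spanning_stub(20, f"r{i}") for i in range(4)]
        assert midlength_score(calls, self._gt(20, 25), 20) == 0.0

    def test_no_attributable_reads(self):
        assert midlength_score([], self._gt(20, 25), 20) is None

    def test_mosaic_fraction_recovered(self, rng):
        f = 0.2
        shifts = rng.random(400) < f
        calls = [_spanning_stub(20 + int(s), f"r{i}") for i, s in enumerate(shifts)]
        score = midlength_score(calls, self._gt(20, 25), 20)
        se = math.sqrt(f * (1 - f) / 400)
        assert abs(score - f) < 3 * se


class TestContractionNull:
    def test_expansion_only_world_gives_zero_contraction_fraction(self, rng):
        """With the simulator configured expansion-only, the -1 direction
        estimate is consistent with zero (mirror-direction estimator check)."""
        from strmosaic.harvest import harvest
        from strmosaic.simulate import simulate_mosaic, simulate_reads, to_read_records

        cfg = SimConfig(
            error_rate=0.0, stutter_prob=0.0, somatic_rate_per_year=1e-3,
            allele_dist={20: 1.0}, age_range=(50, 50),
            fragment_mean=250, fragment_sd=30, flank_len=340,
        )
        reads = []
        for i in range(20):
            mix = simulate_mosaic((20, 20), 50, cfg)
            reads += simulate_reads(f"S{i}", mix, cfg, rng, keep="overlap")
        result = harvest(to_read_records(reads, cfg), [cfg.catalog_entry()])
        gt = GermlineGenotype("S0", "locus1", (20, 20), {})
        calls = result.spanning_calls
        n_base = sum(1 for c in calls if c.unit_count == 20)
        n_down = sum(1 for c in calls if c.unit_count == 19)
        est = expansion_fraction(n_base, n_down, direction=-1)
        assert est.fraction == 0.0
        assert est.ci_high < 0.02


class TestScreen:
    def test_constant_covariate_raises(self):
        with pytest.raises(ValueError):
            screen_instability([1.0, 2.0, 3.0], [1, 1, 1])

    def test_dosage_effect_detected(self):
        """0.1 sd-per-sd-of-dosage effect at n=5000 is detected at P < 1e-4."""
        detected = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            dosage = rng.binomial(2, 0.5, size=5000)
            x = (dosage - dosage.mean()) / dosage.std()
            y = 0.1 * x + rng.normal(size=5000)
            _, p = screen_instability(y, dosage)
            detected += p < 1e-4
        assert detected >= 9

    def test_null_z_moderate(self, rng):
        y = rng.normal(size=2000)
        dosage = rng.binomial(2, 0.3, size=2000)
        z, p = screen_instability(y, dosage)
        assert abs(z) < 4
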