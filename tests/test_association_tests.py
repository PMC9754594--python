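import math

import numpy as np
import pytest
from scipy.special import comb

from regionsig import (
    FeatureInterval,
    GenomeLayout,
    flank_segments,
    flank_test,
    overlap_test,
    run_profile,
    simulate_sample,
)
from regionsig.association_tests import (
    admissible_boundaries,
    boundary_interval,
    sample_nonadjacent_boundaries,
)
from regionsig.simulate import PlantedSegment, SimulationConfig


@pytest.fixture(scope="module")
def two_switch_profile(catalog2_orthogonal):
    """30 bins on one 90 Mb chromosome with planted switches at bins 10 and 20."""
    layout = GenomeLayout(chroms=("1",), lengths=(90_000_000,))
    cfg = SimulationConfig(
        layout=layout,
        catalog=catalog2_orthogonal,
        segments=(
            PlantedSegment("1", 0, 30_000_000, (1.0, 0.0), n_mutations=1000),
            PlantedSegment("1", 30_000_000, 60_000_000, (0.0, 1.0), n_mutations=1000),
            PlantedSegment("1", 60_000_000, 90_000_000, (1.0, 0.0), n_mutations=1000),
        ),
        seed=6,
    )
    muts, _ = simulate_sample(cfg)
    prof = run_profile(muts, catalog2_orthogonal, bin_size=100, mode="genome_wise")
    assert [cp.boundary for cp in prof.changepoints] == [10, 20]
    return prof, layout


class TestNonAdjacentSampling:
    def test_uniform_over_admissible_sets(self):
        adm = np.arange(1, 7)  # B = 7
        rng = np.random.default_rng(0)
        draws = sample_nonadjacent_boundaries(adm, 2, 20_000, rng)
        seen = {tuple(row) for row in draws}
        valid = {
            (a, b) for a in adm for b in adm if b - a >= 2
        }
        assert seen == valid
        # uniformity: each of the 10 sets near 1/10
        counts = {}
        for row in draws:
            counts[tuple(row)] = counts.get(tuple(row), 0) + 1
        for v in counts.values():
            assert abs(v / 20_000 - 1 / len(valid)) < 0.01

    def test_too_many_changepoints_rejected(self):
        with pytest.raises(ValueError):
            sample_nonadjacent_boundaries(np.arange(1, 5), 3, 1, np.random.default_rng(0))


class TestOverlapTest:
    def test_genome_wide_feature_saturates(self, two_switch_profile, catalog2_orthogonal):
        prof, layout = two_switch_profile
        feature = [FeatureInterval("1", 0, layout.lengths[0])]
        res = overlap_test(prof.changepoints, feature, prof.series, n_null=199, seed=1)
        assert res.observed_proportion == 1.0
        assert res.p_value == 1.0
        assert not res.significant

    def test_feature_absent_from_changepoint_chromosomes(self, two_switch_profile):
        prof, _ = two_switch_profile
        feature = [FeatureInterval("22", 0, 1000)]
        res = overlap_test(prof.changepoints, feature, prof.series, n_null=199, seed=1)
        assert res.observed_proportion == 0.0
        assert res.p_value == 1.0

    def test_deterministic_given_seed(self, two_switch_profile):
        prof, _ = two_switch_profile
        feature = [FeatureInterval("1", 25_000_000, 35_000_000)]
        r1 = overlap_test(prof.changepoints, feature, prof.series, n_null=499, seed=7)
        r2 = overlap_test(prof.changepoints, feature, prof.series, n_null=499, seed=7)
        assert r1 == r2

    def test_add_one_pvalue_never_zero(self, two_switch_profile):
        prof, _ = two_switch_profile
        feature = [FeatureInterval("1", 29_000_000, 31_000_000)]
        res = overlap_test(prof.changepoints, feature, prof.series, n_null=199, seed=3)
        assert res.p_value > 0

    def test_enlarging_features_never_decreases_observed_proportion(self, two_switch_profile):
        prof, _ = two_switch_profile
        rng = np.random.default_rng(11)
        for _ in range(10):
            s = int(rng.integers(0, 80_000_000))
            small = [FeatureInterval("1", s, s + 1_000_000)]
            big = [FeatureInterval("1", max(0, s - 5_000_000), s + 6_000_000)]
            p_small = overlap_test(prof.changepoints, small, prof.series, n_null=9, seed=0).observed_proportion
            p_big = overlap_test(prof.changepoints, big, prof.series, n_null=9, seed=0).observed_proportion
            assert p_big >= p_small

    def test_tiny_profile_matches_exact_enumeration(self, catalog2_orthogonal):
        """Empirical p-value agrees with the exact combinatorial probability."""
        layout = GenomeLayout(chroms=("1",), lengths=(60_000_000,))
        cfg = SimulationConfig(
            layout=layout,
            catalog=catalog2_orthogonal,
            segments=(
                PlantedSegment("1", 0, 30_000_000, (1.0, 0.0), n_mutations=300),
                PlantedSegment("1", 30_000_000, 60_000_000, (0.0, 1.0), n_mutations=300),
            ),
            seed=2,
        )
        muts, _ = simulate_sample(cfg)
        prof = run_profile(muts, catalog2_orthogonal, bin_size=100, mode="genome_wise")
        assert [cp.boundary for cp in prof.changepoints] == [3]
        series = prof.series
        adm = admissible_boundaries(series)
        [cp] = prof.changepoints
        feature = [FeatureInterval("1", cp.start, cp.end)]  # overlaps exactly the observed boundary
        overlapping = [
            b
            for b in adm
            if (lambda iv: iv[1] < cp.end and cp.start < iv[2])(boundary_interval(series, int(b)))
        ]
        q = len(overlapping) / len(adm)  # exact P(null proportion >= 1)
        n_null = 2000
        res = overlap_test(prof.changepoints, feature, prof.series, n_null=n_null, seed=5)
        exact = (1 + n_null * q) / (n_null + 1)
        se = math.sqrt(q * (1 - q) / n_null)
        assert abs(res.p_value - exact) <= 3 * se


class TestFlankSegments:
    def test_forced_construction(self):
        cp_seg, fl_seg = flank_segments(100e6, 140e6)
        assert cp_seg == (90e6, 110e6)
        assert fl_seg == (130e6, 150e6)

    def test_upstream_mirrors_downstream(self):
        L = 200e6
        down_cp, down_fl = flank_segments(100e6, 140e6)
        up_cp, up_fl = flank_segments(L - 100e6, L - 140e6)
        assert up_cp == (L - down_cp[1], L - down_cp[0])
        assert up_fl == (L - down_fl[1], L - down_fl[0])

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            flank_segments(50.0, 50.0)

    def test_clipping_to_chromosome(self):
        cp_seg, fl_seg = flank_segments(10e6, 50e6, chrom_length=55_000_000)
        assert fl_seg[1] == 55_000_000


def exact_fisher_two_sided(table):
    """Oracle: full hypergeometric enumeration with fixed margins."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if prob(x) <= p_obs * (1 + 1e-9):
            total += prob(x)
    return total


class TestFlankTest:
    def _feature(self, rng, layout, shift_window=None, shift=0.0):
        """Continuous track: one value per 1 Mb window, N(0,1), optionally shifted."""
        out = []
        L = layout.lengths[0]
        for start in range(0, L, 1_000_000):
            v = float(rng.normal())
            if shift_window and shift_window[0] <= start < shift_window[1]:
                v += shift
            out.append(FeatureInterval("1", start, min(L, start + 1_000_000), v))
        return out

    def test_fisher_inner_matches_hypergeometric_enumeration(self):
        from scipy.stats import fisher_exact

        for table in ([[3, 2], [1, 4]], [[5, 0], [2, 7]], [[1, 1], [1, 1]]):
            assert fisher_exact(table, alternative="two-sided")[1] == pytest.approx(
                exact_fisher_two_sided(table), rel=1e-9
            )

    def test_strong_shift_is_detected(self, two_switch_profile, catalog2_orthogonal):
        prof, layout = two_switch_profile
        cp = prof.changepoints[0]
        rng = np.random.default_rng(21)
        # shift the windows around the first changepoint by 3 SD
        feature = self._feature(rng, layout, shift_window=(cp.start - 5_000_000, cp.end + 5_000_000), shift=3.0)
        res = flank_test(
            cp, prof.changepoints, feature, "continuous", prof.series, layout,
            n_null=199, seed=3,
        )
        assert res.significant_any

    def test_null_feature_usually_not_significant_and_deterministic(self, two_switch_profile):
        prof, layout = two_switch_profile
        cp = prof.changepoints[1]
        rng = np.random.default_rng(4)
        feature = self._feature(rng, layout)
        r1 = flank_test(cp, prof.changepoints, feature, "continuous", prof.series, layout, n_null=199, seed=9)
        r2 = flank_test(cp, prof.changepoints, feature, "continuous", prof.series, layout, n_null=199, seed=9)
        assert r1 == r2
        assert r1.p_cd is not None and r1.p_cu is not None
        assert r1.significant_any == (r1.significant_downstream or r1.significant_upstream)

    def test_counts_feature_runs_end_to_end(self, two_switch_profile):
        prof, layout = two_switch_profile
        cp = prof.changepoints[0]
        rng = np.random.default_rng(17)
        events = [
            FeatureInterval("1", int(s := rng.integers(0, 89_000_000)), int(s) + 10_000)
            for _ in range(40)
        ]
        res = flank_test(cp, prof.changepoints, events, "counts", prof.series, layout, n_null=99, seed=2)
        assert res.p_cd is None or 0 < res.p_cd <= 1
        assert res.emp_p_down is None or res.emp_p_down > 0

    def test_segment_without_feature_windows_is_skipped(self, two_switch_profile, caplog):
        prof, layout = two_switch_profile
        cp = prof.changepoints[0]
        feature = [FeatureInterval("1", 88_000_000, 89_000_000, 1.0)]  # far from cp segment
        with caplog.at_level("WARNING", logger="regionsig"):
            res = flank_test(cp, prof.changepoints, feature, "continuous", prof.series, layout, n_null=49, seed=0)
        assert res.p_cd is None and res.p_cu is None
        assert not res.significant_any
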