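import itertools
import math

import numpy as np
import pytest

from regionsig import (
    SignatureCatalog,
    default_penalty,
    em_fit,
    pelt_segment,
    run_profile,
    segment_cost,
    simulate_sample,
    synthetic_catalog,
)
from regionsig.simulate import GenomeLayout, PlantedSegment, SimulationConfig

from conftest import random_series, series_from_counts


def brute_force_dp(series, catalog, penalty):
    """Independent oracle: enumerate every admissible changepoint set."""
    B = len(series)
    counts = series.count_matrix
    cost = {}
    for i in range(B):
        for j in range(i, B):
            cost[(i, j)] = -2.0 * em_fit(counts[i : j + 1].sum(axis=0), catalog).log_likelihood
    best = (math.inf, ())
    for m in range(0, (B + 1) // 2 + 1):
        for bounds in itertools.combinations(range(1, B), m):
            if any(b2 - b1 < 2 for b1, b2 in zip(bounds, bounds[1:])):
                continue
            edges = [0, *bounds, B]
            total = sum(cost[(a, b - 1)] for a, b in zip(edges[:-1], edges[1:]))
            total += penalty * m
            if total < best[0] - 1e-12:
                best = (total, bounds)
    return best


class TestSegmentCost:
    def test_single_bin_single_signature_closed_form(self):
        mu = np.zeros(96)
        mu[:3] = [0.5, 0.25, 0.25]
        cat = SignatureCatalog(("s",), mu[None, :])
        counts = np.zeros((1, 96))
        counts[0, :3] = [8, 4, 4]
        series = series_from_counts(counts)
        cost, act = segment_cost(series, 0, 0, cat)
        expected = -2 * float(counts[0, :3] @ np.log(mu[:3]))
        assert cost == pytest.approx(expected)
        np.testing.assert_allclose(act.activities, [1.0])

    def test_superadditivity(self, catalog4):
        """Pooled fit never beats the sum of separately maximized sub-fits."""
        rng = np.random.default_rng(17)
        series = random_series(rng, 6, catalog4)
        for i in range(6):
            for j in range(i + 1, 6):
                cj, _ = segment_cost(series, i, j, catalog4)
                for m in range(i, j):
                    c1, _ = segment_cost(series, i, m, catalog4)
                    c2, _ = segment_cost(series, m + 1, j, catalog4)
                    assert cj >= c1 + c2 - 1e-6

    def test_pooling_identical_bins_matches_single_bin(self, catalog4):
        # the maximizer is unchanged when counts are doubled; compare the
        # EM fixed points at tight convergence
        rng = np.random.default_rng(2)
        row = rng.multinomial(200, np.full(4, 0.25) @ catalog4.emissions).astype(float)
        act1 = em_fit(row, catalog4, tol=1e-13, max_iter=100_000).activity
        act2 = em_fit(2 * row, catalog4, tol=1e-13, max_iter=100_000).activity
        np.testing.assert_allclose(act1.activities, act2.activities, atol=1e-6)


class TestDefaultPenalty:
    def test_bic_formula(self, catalog2_orthogonal):
        counts = np.zeros((100, 96), dtype=int)
        counts[:, 0] = 100  # 10,000 mutations total
        series = series_from_counts(counts)
        assert default_penalty(series, catalog2_orthogonal) == pytest.approx(
            math.log(10_000)
        )

    def test_single_signature_gives_infinity(self):
        mu = np.zeros(96)
        mu[0] = 1.0
        cat = SignatureCatalog(("s",), mu[None, :])
        counts = np.zeros((2, 96), dtype=int)
        counts[:, 0] = 10
        assert default_penalty(series_from_counts(counts), cat) == math.inf

    def test_doubling_n_adds_log2_per_free_parameter(self, catalog4):
        c1 = np.zeros((10, 96), dtype=int)
        c1[:, 0] = 50
        c2 = np.zeros((10, 96), dtype=int)
        c2[:, 0] = 100
        p1 = default_penalty(series_from_counts(c1), catalog4)
        p2 = default_penalty(series_from_counts(c2), catalog4)
        assert p2 - p1 == pytest.approx(3 * math.log(2))


class TestPELT:
    def test_infinite_penalty_gives_one_segment(self, catalog4):
        rng = np.random.default_rng(1)
        series = random_series(rng, 8, catalog4)
        res = pelt_segment(series, catalog4, penalty=math.inf)
        assert len(res.segments) == 1
        assert res.changepoints == ()

    @pytest.mark.parametrize("seed", range(12))
    def test_equals_exhaustive_dp_on_small_series(self, seed, catalog4):
        rng = np.random.default_rng(seed)
        B = int(rng.integers(4, 13))
        series = random_series(rng, B, catalog4, muts_per_bin=60)
        penalty = float(rng.uniform(2.0, 30.0))
        res = pelt_segment(series, catalog4, penalty=penalty)
        opt_cost, opt_bounds = brute_force_dp(series, catalog4, penalty)
        assert res.total_penalized_cost == pytest.approx(opt_cost, abs=1e-6)
        got = tuple(cp.boundary for cp in res.changepoints)
        # PELT's solution must itself attain the optimum and be admissible
        assert all(b2 - b1 >= 2 for b1, b2 in zip(got, got[1:]))

    def test_penalty_never_increases_changepoints(self, catalog4):
        rng = np.random.default_rng(77)
        series = random_series(rng, 10, catalog4)
        free = pelt_segment(series, catalog4, penalty=0.0)
        pen = pelt_segment(series, catalog4)
        assert len(pen.changepoints) <= len(free.changepoints)

    def test_planted_switch_recovered(self, catalog2_orthogonal):
        """A strong mid-series activity switch yields exactly one changepoint there."""
        from regionsig import planted_switch_config

        hits = 0
        n_rep = 15
        for seed in range(n_rep):
            cfg = planted_switch_config(
                catalog2_orthogonal, (1.0, 0.0), (0.0, 1.0), 2000, 2000, seed=seed
            )
            muts, _ = simulate_sample(cfg)
            prof = run_profile(muts, catalog2_orthogonal, bin_size=200, mode="genome_wise")
            bounds = [cp.boundary for cp in prof.changepoints]
            if bounds == [10]:
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_relabeling_invariance(self, catalog4):
        """Consistently permuting channels leaves the penalized cost unchanged."""
        rng = np.random.default_rng(5)
        series = random_series(rng, 8, catalog4)
        perm = rng.permutation(96)
        series_p = series_from_counts(series.count_matrix[:, perm])
        cat_p = SignatureCatalog(catalog4.names, catalog4.emissions[:, perm])
        r1 = pelt_segment(series, catalog4, penalty=10.0)
        r2 = pelt_segment(series_p, cat_p, penalty=10.0)
        assert r1.total_penalized_cost == pytest.approx(r2.total_penalized_cost, abs=1e-6)
        assert [cp.boundary for cp in r1.changepoints] == [
            cp.boundary for cp in r2.changepoints
        ]


class TestRunProfile:
    def test_constant_chromosomes_have_no_changepoints(self, catalog4):
        from regionsig import constant_config

        layout = GenomeLayout(chroms=("1", "2"), lengths=(50_000_000, 50_000_000))
        cfg = SimulationConfig(
            layout=layout,
            catalog=catalog4,
            segments=(
                PlantedSegment("1", 0, 50_000_000, (0.4, 0.3, 0.2, 0.1), n_mutations=1000),
                PlantedSegment("2", 0, 50_000_000, (0.4, 0.3, 0.2, 0.1), n_mutations=1000),
            ),
            seed=4,
        )
        muts, _ = simulate_sample(cfg)
        prof = run_profile(muts, catalog4, bin_size=100, mode="chromosome_wise")
        assert prof.changepoints == ()

    def test_modes_agree_on_within_chromosome_switch(self, catalog2_orthogonal):
        layout = GenomeLayout(chroms=("1", "2"), lengths=(60_000_000, 60_000_000))
        cfg = SimulationConfig(
            layout=layout,
            catalog=catalog2_orthogonal,
            segments=(
                PlantedSegment("1", 0, 30_000_000, (1.0, 0.0), n_mutations=1500),
                PlantedSegment("1", 30_000_000, 60_000_000, (0.0, 1.0), n_mutations=1500),
                PlantedSegment("2", 0, 60_000_000, (0.5, 0.5), n_mutations=1500),
            ),
            seed=8,
        )
        muts, _ = simulate_sample(cfg)
        g = run_profile(muts, catalog2_orthogonal, bin_size=150, mode="genome_wise")
        c = run_profile(muts, catalog2_orthogonal, bin_size=150, mode="chromosome_wise")
        gi = [(cp.chrom, cp.start, cp.end) for cp in g.changepoints]
        ci = [(cp.chrom, cp.start, cp.end) for cp in c.changepoints]
        assert len(gi) >= 1 and len(ci) >= 1
        # both modes place a changepoint whose interval covers the planted locus
        assert any(s <= 30_000_000 <= e and ch == "1" for ch, s, e in gi)
        assert any(s <= 30_000_000 <= e and ch == "1" for ch, s, e in ci)

    def test_chromosome_results_are_independent(self, catalog4):
        rng = np.random.default_rng(10)
        from regionsig import Mutation, make_bins
        from regionsig.catalog96 import channel_to_mutation_parts
        from regionsig.segmentation import segment_series

        muts = []
        for chrom in ("1", "2"):
            pi = rng.dirichlet(np.ones(4))
            mix = pi @ catalog4.emissions
            for pos in np.sort(rng.integers(1, 10**7, size=400)):
                ctx, ref, alt = channel_to_mutation_parts(int(rng.choice(96, p=mix)))
                muts.append(Mutation("s", chrom, int(pos), ref, alt, ctx))
        series = make_bins(muts, bin_size=100, mode="chromosome_wise")
        full = segment_series(series, catalog4)
        only2 = make_bins([m for m in muts if m.chrom == "2"], bin_size=100, mode="chromosome_wise")
        alone = segment_series(only2, catalog4)
        full_chr2 = [cp.boundary - 4 for cp in full.changepoints if cp.chrom == "2"]
        assert full_chr2 == [cp.boundary for cp in alone.changepoints]
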