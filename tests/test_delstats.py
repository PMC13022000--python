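"""Docking-score statistics: Z-scores, enrichment factors, Mann–Whitney."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import norm

from erepoc.delstats import (
    enrichment_factor,
    mann_whitney_one_sided,
    monte_carlo_ef,
    top_fraction,
    top_fraction_per_target,
    zscores,
)
from erepoc.fixtures import make_docking_scores


class TestZscores:
    def test_score_at_mean_is_zero(self):
        z = zscores([-5.0, -6.0, -7.0])
        assert z[1] == pytest.approx(0.0)

    def test_closed_form_population_sd(self):
        z = zscores([-1.0, 0.0, 1.0])
        np.testing.assert_allclose(z, [-math.sqrt(3 / 2), 0.0, math.sqrt(3 / 2)],
                                   atol=1e-12)

    def test_normalization_identity(self):
        rng = np.random.default_rng(0)
        z = zscores(rng.normal(-6, 2, size=500))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            zscores([1.0, 1.0, 1.0])


class TestEnrichmentFactor:
    def test_identical_pools_give_unity(self):
        pool = [-9.0, -8.5, -7.0, -6.0]
        for c in (-8.6, -7.5, -6.0):
            assert enrichment_factor(pool, pool, c) == pytest.approx(1.0)

    def test_undefined_below_all_scores(self):
        assert math.isnan(enrichment_factor([-5.0], [-5.0], -20.0))

    def test_counting_oracle_on_shifted_pools(self):
        rng = np.random.default_rng(1)
        neg = rng.normal(-6, 1, size=300)
        pos = neg - 1.0
        for c in (-8.0, -7.0, -6.0):
            expected = ((pos <= c).mean()) / ((neg <= c).mean())
            assert enrichment_factor(pos, neg, c) == pytest.approx(expected)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        pos = rng.normal(-7, 1, size=100)
        neg = rng.normal(-6, 1, size=100)
        c = -6.5
        ef1 = enrichment_factor(pos, neg, c)
        ef2 = enrichment_factor(pos * 3.0, neg * 3.0, c * 3.0)
        assert ef1 == pytest.approx(ef2)


class TestMonteCarloEF:
    def test_null_symmetry(self):
        rng = np.random.default_rng(3)
        pool = rng.normal(-6, 1, size=2000)
        curve = monte_carlo_ef(pool, pool, cutoffs=[-6.5, -6.0, -5.5],
                               sample_size=200, iterations=400, seed=9)
        for mean, sd in zip(curve.ef_mean, curve.ef_sd):
            assert abs(mean - 1.0) <= 3 * sd / math.sqrt(curve.n_iterations) + 0.05

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        pos, neg = rng.normal(-7, 1, 500), rng.normal(-6, 1, 500)
        c1 = monte_carlo_ef(pos, neg, sample_size=100, iterations=50, seed=5)
        c2 = monte_carlo_ef(pos, neg, sample_size=100, iterations=50, seed=5)
        np.testing.assert_array_equal(c1.ef_mean, c2.ef_mean)

    def test_converges_to_full_pool_ef(self):
        rng = np.random.default_rng(5)
        pos = rng.normal(-7.5, 1.5, size=4000)
        neg = rng.normal(-6.0, 1.5, size=4000)
        # interior cutoffs: both tail fractions are large enough that the
        # finite-sample ratio bias of EF is well below the MC tolerance
        cutoffs = [-7.0, -6.5]
        curve = monte_carlo_ef(pos, neg, cutoffs=cutoffs, sample_size=200,
                               iterations=1000, seed=6)
        for j, c in enumerate(cutoffs):
            full = enrichment_factor(pos, neg, c)
            tol = 3 * curve.ef_sd[j] / math.sqrt(curve.n_iterations) + 0.02 * full
            assert abs(curve.ef_mean[j] - full) < tol

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError):
            monte_carlo_ef(np.zeros(10), np.zeros(10), sample_size=20)


class TestTopFraction:
    def test_one_percent_of_hundred_is_the_minimum(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(-6, 1, size=100)
        idx = top_fraction(scores, 0.01)
        assert len(idx) == 1
        assert scores[idx[0]] == scores.min()

    def test_full_fraction_returns_all(self):
        assert len(top_fraction(np.arange(10.0), 1.0)) == 10

    def test_tie_break_matches_sort_oracle(self):
        scores = np.array([-5.0, -7.0, -7.0, -6.0, -7.0] * 50)
        ids = [f"c{i:03d}" for i in range(250)]
        idx = top_fraction(scores, 0.012, compound_ids=ids)  # ceil(3) = 3
        ranked = sorted(range(250), key=lambda i: (scores[i], ids[i]))
        assert list(idx) == ranked[:3]

    def test_per_target_extraction(self):
        import pandas as pd

        df = pd.DataFrame({
            "compound_id": [f"c{i}" for i in range(200)],
            "target_id": ["t1"] * 100 + ["t2"] * 100,
            "score": np.concatenate([np.linspace(-10, -1, 100),
                                     np.linspace(-8, -2, 100)]),
        })
        top = top_fraction_per_target(df, 0.02)
        assert len(top) == 4  # ceil(2) per target
        assert set(top["target_id"]) == {"t1", "t2"}

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            top_fraction([1.0], 0.0)


def _u_stat(xs, ys):
    """Rank-sum U of x: the number of (x, y) pairs with x > y (midrank ties)."""
    return sum(1 for xi in xs for yi in ys if xi > yi) \
        + 0.5 * sum(1 for xi in xs for yi in ys if xi == yi)


def _exact_p_by_enumeration(x, y):
    """P(U_X <= observed) over all equally likely rank assignments."""
    x, y = list(x), list(y)
    nx = len(x)
    combined = sorted(x + y)
    u_obs = _u_stat(x, y)
    count = 0
    total = 0
    for positions in itertools.combinations(range(len(combined)), nx):
        xs = [combined[i] for i in positions]
        ys = [combined[i] for i in range(len(combined)) if i not in positions]
        total += 1
        if _u_stat(xs, ys) <= u_obs + 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_identical_samples_near_half(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        res = mann_whitney_one_sided(x, x)
        assert 0.4 < res.p_value < 0.6
        assert abs(res.effect_r) < 0.05

    def test_tiny_example_matches_enumeration(self):
        x, y = [1.0, 2.0], [3.0, 4.0]
        res = mann_whitney_one_sided(x, y)
        assert res.U == 0.0
        assert res.p_value == pytest.approx(_exact_p_by_enumeration(x, y))
        assert res.p_value == pytest.approx(1 / 6)  # C(4,2)=6 assignments, 1 extreme

    def test_complete_separation_minimum_p(self):
        x = list(range(10))
        y = [v + 100 for v in range(10)]
        res = mann_whitney_one_sided(x, y)
        assert res.U == 0.0
        assert res.p_value == pytest.approx(1 / math.comb(20, 10))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_on_small_samples(self, seed):
        rng = np.random.default_rng(seed)
        nx = int(rng.integers(2, 6))
        ny = int(rng.integers(2, 13 - nx))
        x = rng.normal(size=nx)
        y = rng.normal(loc=rng.uniform(-1, 1), size=ny)
        res = mann_whitney_one_sided(x, y)
        assert res.p_value == pytest.approx(_exact_p_by_enumeration(x, y), rel=1e-9)

    def test_effect_size_sign_and_magnitude(self):
        rng = np.random.default_rng(8)
        x = rng.normal(-1.0, 1, size=200)
        y = rng.normal(0.0, 1, size=200)
        res = mann_whitney_one_sided(x, y)
        assert res.effect_r < -0.2  # x stochastically smaller -> negative r
        assert res.p_value < 1e-6
        # r = z / sqrt(N) by construction
        assert res.effect_r == pytest.approx(res.z / math.sqrt(400))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_one_sided([], [1.0])


class TestGaussianFixtureClosedForm:
    def test_ef_matches_phi_ratio(self):
        """EF at cutoff mu0 - 2 sigma against the Gaussian-tail closed form."""
        sigma, mu0, shift = 1.0, -6.0, 1.5
        df = make_docking_scores(n_per_group=5000, shift=shift, sigma=sigma,
                                 mu0=mu0, seed=13)
        pos = df.loc[df.group == "enriched", "score"].to_numpy()
        neg = df.loc[df.group == "neutral", "score"].to_numpy()
        c = mu0 - 2 * sigma
        expected = norm.cdf((-2 * sigma + shift) / sigma) / norm.cdf(-2.0)
        ef = enrichment_factor(pos, neg, c)
        # Monte-Carlo error of the tail counts at n=5000
        assert ef == pytest.approx(expected, rel=0.25)

    def test_null_shift_is_symmetric(self):
        df = make_docking_scores(n_per_group=4000, shift=0.0, seed=14)
        pos = df.loc[df.group == "enriched", "score"].to_numpy()
        neg = df.loc[df.group == "neutral", "score"].to_numpy()
        res = mann_whitney_one_sided(pos, neg)
        assert 0.01 < res.p_value < 0.99
        ef = enrichment_factor(pos, neg, np.quantile(neg, 0.1))
        assert ef == pytest.approx(1.0, abs=0.25)
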