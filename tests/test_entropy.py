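"""Cross-ApEn / Cross-SampEn: analytic cases, invariances, error handling."""

import numpy as np
import pytest

from neuroxent.entropy import (
    DegenerateSeriesError,
    EntropyParams,
    MatchCounts,
    SeriesPair,
    SeriesTooShortError,
    chebyshev_distance,
    cross_apen,
    cross_entropy,
    cross_sampen,
    sampen_value,
    template_match_counts,
    znormalize,
)
from neuroxent.oracle import entropy_oracle

RNG = np.random.default_rng(20240)


def random_pair(n=200):
    return RNG.standard_normal(n), RNG.standard_normal(n)


class TestZnormalize:
    def test_mean_zero_unit_population_sd(self):
        z = znormalize(RNG.standard_normal(100) * 5 + 3)
        assert abs(z.mean()) < 1e-12
        assert abs(z.std()) - 1 < 1e-12  # population (divide-by-N) SD

    def test_constant_raises(self):
        with pytest.raises(DegenerateSeriesError):
            znormalize(np.ones(50))

    def test_nonfinite_raises(self):
        with pytest.raises(DegenerateSeriesError):
            znormalize(np.array([1.0, np.nan, 2.0]))


class TestChebyshev:
    def test_example(self):
        assert chebyshev_distance([1.0, 5.0], [2.0, 3.0]) == 2.0

    def test_mismatch(self):
        with pytest.raises(ValueError):
            chebyshev_distance([1.0], [1.0, 2.0])


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"metric": "nope"},
            {"m": 0},
            {"m": 1.5},
            {"r": 0.0},
            {"r": 1.0},
            {"correction": "nope"},
            {"variant": "nope"},
            {"on_no_matches": "nope"},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            EntropyParams(**kwargs)

    def test_series_pair_validation(self):
        with pytest.raises(ValueError):
            SeriesPair(np.zeros((2, 2)), np.zeros(4))
        with pytest.raises(ValueError):
            SeriesPair(np.arange(5.0), np.arange(6.0))
        with pytest.raises(DegenerateSeriesError):
            SeriesPair(np.ones(5), np.arange(5.0))


class TestAnalyticCases:
    """Analytic cases, also recomputed by scripts/acceptance.py."""

    def test_periodic_identical_sampen_zero(self):
        u = np.array([1.0, 2.0] * 4)
        assert cross_sampen(u, u, m=1, r=0.2) == 0.0

    def test_periodic_identical_apen_near_zero(self):
        # Not exactly 0: the length-m and length-(m+1) passes normalize over
        # N-m+1 vs N-m templates, so the phis differ slightly even for a
        # perfectly matching periodic pair.  Frozen against the brute-force
        # oracle and bounded near zero.
        u = np.array([1.0, 2.0] * 4)
        val = cross_apen(u, u, m=1, r=0.2)
        ref = entropy_oracle(u, u, EntropyParams(metric="cross_apen", m=1, r=0.2))
        assert val == pytest.approx(ref, abs=1e-12)
        assert abs(val) < 0.05

    def test_sampen_symmetric(self):
        for _ in range(5):
            u, v = random_pair()
            for m in (1, 2):
                assert abs(
                    cross_sampen(u, v, m=m, r=0.2) - cross_sampen(v, u, m=m, r=0.2)
                ) <= 1e-12

    def test_sampen_nonnegative(self):
        for _ in range(10):
            u, v = random_pair(150)
            for m, r in ((1, 0.1), (2, 0.2), (2, 0.25)):
                assert cross_sampen(u, v, m=m, r=r) >= 0.0

    def test_apen_asymmetric_on_generic_inputs(self):
        u, v = random_pair()
        assert abs(cross_apen(u, v, 2, 0.2) - cross_apen(v, u, 2, 0.2)) > 1e-6


class TestInvariances:
    def test_scale_and_offset_invariance(self):
        u, v = random_pair()
        base = cross_sampen(u, v, m=1, r=0.2)
        assert cross_sampen(3.7 * u - 11.0, v, m=1, r=0.2) == pytest.approx(base, abs=1e-12)
        base_a = cross_apen(u, v, m=1, r=0.2)
        assert cross_apen(u, 0.01 * v + 5, m=1, r=0.2) == pytest.approx(base_a, abs=1e-12)

    def test_coupling_trend(self):
        # v = alpha*u + (1-alpha)*noise: Cross-SampEn is nearly flat at low
        # alpha for Gaussian inputs (the metric tracks shared pattern
        # recurrence, not linear correlation) and clearly decreasing once the
        # shared component dominates — assert the upper-half trend and the
        # endpoint drop.
        rng = np.random.default_rng(99)
        medians = {}
        for alpha in (0.0, 0.5, 0.75, 1.0):
            vals = []
            for _ in range(25):
                u = rng.standard_normal(300)
                w = rng.standard_normal(300)
                vals.append(cross_sampen(u, alpha * u + (1 - alpha) * w, m=1, r=0.2))
            medians[alpha] = float(np.median(vals))
        assert medians[1.0] < medians[0.75] < medians[0.5] + 1e-6
        assert medians[0.0] - medians[1.0] > 0.02


class TestDegenerateHandling:
    def test_too_short_raises(self):
        with pytest.raises(SeriesTooShortError):
            cross_sampen(np.arange(3.0), np.arange(3.0), m=2, r=0.2)

    def test_sampen_no_short_matches_resolution_bound(self):
        counts = MatchCounts(
            short=np.zeros(10, dtype=np.int64),
            long=np.zeros(10, dtype=np.int64),
            short_denom=10,
            long_denom=10,
        )
        assert sampen_value(counts) == pytest.approx(2 * np.log(10))
        assert sampen_value(counts, on_no_matches="inf") == np.inf

    def test_sampen_no_long_matches_surrogate(self):
        short = np.full(10, 3, dtype=np.int64)
        counts = MatchCounts(
            short=short, long=np.zeros(10, dtype=np.int64), short_denom=10, long_denom=10
        )
        # surrogate: one fictitious match out of (N-m)^2 comparisons
        assert sampen_value(counts) == pytest.approx(-np.log((1 / 100) / (30 / 100)))
        assert sampen_value(counts, on_no_matches="inf") == np.inf

    def test_count_subset_property_enforced(self):
        with pytest.raises(AssertionError):
            MatchCounts(
                short=np.zeros(5, dtype=np.int64),
                long=np.ones(5, dtype=np.int64),
                short_denom=5,
                long_denom=5,
            )


class TestVariantsAndDispatch:
    def test_literal_variant_runs_and_differs(self):
        u, v = random_pair(300)
        lit = cross_sampen(u, v, m=1, r=0.25, variant="literal")
        can = cross_sampen(u, v, m=1, r=0.25)
        assert np.isfinite(lit) and lit != can

    def test_self_match_exclusion_changes_counts(self):
        u = RNG.standard_normal(100)
        with_self = cross_sampen(u, u.copy(), m=1, r=0.2)
        without = cross_sampen(u, u.copy(), m=1, r=0.2, self_match_exclusion=True)
        assert without >= with_self

    def test_apen_corrections(self):
        u, v = random_pair(80)
        for correction in ("bias_max", "bias_zero"):
            val = cross_apen(u, v, m=2, r=0.1, correction=correction)
            assert np.isfinite(val)
        # "none" is NaN when any template has zero matches
        u2 = np.concatenate([np.zeros(20) + RNG.normal(0, 0.01, 20), [50.0]])
        v2 = RNG.standard_normal(21)
        with pytest.warns(RuntimeWarning):
            assert np.isnan(cross_apen(u2, v2, m=1, r=0.1, correction="none"))

    def test_cross_entropy_dispatch(self):
        u, v = random_pair(120)
        p_s = EntropyParams(metric="cross_sampen", m=1, r=0.2)
        p_a = EntropyParams(metric="cross_apen", m=1, r=0.2)
        assert cross_entropy(u, v, p_s) == cross_sampen(u, v, 1, 0.2)
        assert cross_entropy(u, v, p_a) == cross_apen(u, v, 1, 0.2)


class TestMatchCountsHelper:
    def test_template_match_counts_subset(self):
        u, v = random_pair(100)
        for metric in ("cross_sampen", "cross_apen"):
            c = template_match_counts(u, v, EntropyParams(metric=metric, m=2, r=0.2))
            assert np.all(c.long <= c.short[: c.long.shape[0]])

    def test_oracle_agreement_spot(self):
        u, v = random_pair(150)
        for params in (
            EntropyParams(metric="cross_sampen", m=1, r=0.15),
            EntropyParams(metric="cross_sampen", m=2, r=0.2, variant="literal"),
            EntropyParams(metric="cross_sampen", m=1, r=0.2, self_match_exclusion=True),
            EntropyParams(metric="cross_apen", m=2, r=0.25),
            EntropyParams(metric="cross_apen", m=1, r=0.1, correction="bias_zero"),
        ):
            assert cross_entropy(u, v, params) == pytest.approx(
                entropy_oracle(u, v, params), abs=1e-12
            )
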