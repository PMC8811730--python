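"""Rate-vector computation: interpolation, slopes, growth fit, trimming."""

import numpy as np
import pytest

import phenoclust as pc
from phenoclust.rates import growth_rate, interpolate_concentration, specific_rate


# --------------------------------------------------------------------------
# independent shape-preserving Hermite oracle (Fritsch-Carlson derivatives)

def _fritsch_carlson_eval(x, y, xq):
    """Evaluate the monotone cubic Hermite interpolant at one point.

    Knot derivatives follow the Fritsch-Carlson weighted harmonic mean of
    adjacent secants (zero at local extrema); written independently of any
    interpolation library.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    h = np.diff(x)
    delta = np.diff(y) / h
    n = len(x)
    d = np.zeros(n)
    for i in range(1, n - 1):
        if delta[i - 1] * delta[i] > 0:
            w1 = 2 * h[i] + h[i - 1]
            w2 = h[i] + 2 * h[i - 1]
            d[i] = (w1 + w2) / (w1 / delta[i - 1] + w2 / delta[i])
    # one-sided endpoint formula with monotonicity clamping
    for i, (ha, hb, da, db) in ((0, (h[0], h[1], delta[0], delta[1])),
                                (n - 1, (h[-1], h[-2], delta[-1], delta[-2]))):
        dd = ((2 * ha + hb) * da - ha * db) / (ha + hb)
        if dd * da <= 0:
            dd = 0.0
        elif da * db < 0 and abs(dd) > 3 * abs(da):
            dd = 3 * da
        d[i] = dd
    k = int(np.searchsorted(x, xq, side="right") - 1)
    k = min(max(k, 0), n - 2)
    t = (xq - x[k]) / h[k]
    h00 = 2 * t**3 - 3 * t**2 + 1
    h10 = t**3 - 2 * t**2 + t
    h01 = -2 * t**3 + 3 * t**2
    h11 = t**3 - t**2
    return (h00 * y[k] + h10 * h[k] * d[k] + h01 * y[k + 1] + h11 * h[k] * d[k + 1])


class TestInterpolation:
    def test_passes_through_knots(self):
        out = interpolate_concentration([0, 1, 2], [1, 2, 3], [0, 1, 2])
        assert np.allclose(out, [1, 2, 3])

    def test_preserves_monotonicity(self):
        t = np.array([0.0, 1.0, 2.5, 4.0, 6.0])
        v = np.array([10.0, 8.0, 3.0, 2.5, 0.1])
        dense = interpolate_concentration(t, v, np.linspace(0, 6, 400))
        assert np.all(np.diff(dense) <= 1e-12)

    def test_matches_independent_hermite_oracle(self):
        x = [0.0, 1.0, 2.0, 3.0]
        y = [0.0, 1.0, 8.0, 27.0]
        got = interpolate_concentration(x, y, [1.5])[0]
        expected = _fritsch_carlson_eval(x, y, 1.5)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_query_outside_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            interpolate_concentration([0, 1], [1, 2], [1.5])

    def test_too_few_knots_rejected(self):
        with pytest.raises(ValueError, match="2 knots"):
            interpolate_concentration([0], [1], [0])


class TestSpecificRate:
    def test_direct_division_and_sign(self):
        assert specific_rate(2.0, 4.0) == pytest.approx(2.0)
        assert specific_rate(1.0, -3.0) == pytest.approx(-3.0)

    def test_zero_biomass_undefined(self):
        with pytest.raises(ValueError, match="biomass"):
            specific_rate(0.0, 1.0)


class TestGrowthRate:
    def test_exact_exponential(self):
        t = np.linspace(0, 4, 5)
        bm = 0.1 * np.exp(0.2 * t)
        for tq in (1.0, 2.0, 3.0):
            assert growth_rate(t, bm, tq, window=4.0) == pytest.approx(0.2, abs=1e-9)

    def test_constant_biomass_gives_zero(self):
        t = np.linspace(0, 4, 5)
        assert growth_rate(t, np.full(5, 0.7), 2.0, 4.0) == pytest.approx(0.0, abs=1e-12)

    def test_ramped_growth_matches_finite_difference_oracle(self):
        # mu(t) = 0.1 + 0.02 t  ->  ln c1 = 0.1 t + 0.01 t^2
        t = np.linspace(0, 10, 101)
        bm = 0.1 * np.exp(0.1 * t + 0.01 * t**2)
        for tq in (3.0, 5.0, 7.0):
            got = growth_rate(t, bm, tq, window=2.0)
            # centered finite difference of ln c1 on the dense grid
            i = int(round(tq / 0.1))
            oracle = (np.log(bm[i + 1]) - np.log(bm[i - 1])) / 0.2
            assert got == pytest.approx(oracle, rel=0.02)

    def test_no_positive_points_rejected(self):
        with pytest.raises(ValueError):
            growth_rate([0, 1, 2], [0.0, 0.0, 0.0], 1.0, 2.0)


class TestComputeRateVectors:
    def test_recovers_constant_planted_rates(self, library, registry):
        cfg = pc.SimulationConfig(
            experiment_id="const",
            schedule=[(0.0, 10.0, {"pdo_acetate": 1.0})],
            initial_concentrations={"BM": 0.1, "Gly": 400.0},
            sampling_times=list(np.arange(0.0, 10.5, 1.0)),
            noise_sigma=0.0,
            seed=0,
        )
        exp, truth = pc.simulate_experiment(cfg, library, registry)
        vectors = pc.compute_rate_vectors(exp, registry=registry)
        assert len(vectors) == exp.n_samples - 2
        arch = library[0]
        pdo = next(c for c in registry if c.abbreviation == "PDO").dimension_index
        for v in vectors:
            assert v.mu == pytest.approx(arch.mu, rel=0.03)
            assert v.rates[pdo] == pytest.approx(arch.rates["PDO"], rel=0.03)

    def test_error_shrinks_with_sampling_density(self, library, registry):
        """Recovered-rate error at least halves when sampling is twice as dense."""
        errs = []
        for dt in (1.0, 0.5):
            cfg = pc.SimulationConfig(
                experiment_id=f"dense_{dt}",
                schedule=[(0.0, 6.0, {"acidogenic": 1.0})],
                initial_concentrations={"BM": 0.2, "Gly": 500.0},
                sampling_times=list(np.arange(0.0, 6.0 + dt / 2, dt)),
                noise_sigma=0.0,
                seed=0,
            )
            exp, truth = pc.simulate_experiment(cfg, library, registry)
            vectors = pc.compute_rate_vectors(exp, registry=registry)
            df = pc.synth.truth_rate_errors(vectors, truth, registry)
            errs.append(df[df.dimension != "mu"].rel_err.median())
        assert errs[1] <= errs[0] / 2

    def test_monotone_decreasing_compound_gives_negative_rates(self, registry):
        t = list(np.arange(0.0, 8.0, 1.0))
        gly = next(c for c in registry if c.abbreviation == "Gly").dimension_index
        exp = pc.CultivationExperiment(
            experiment_id="down",
            times=t,
            concentrations=[
                {1: 0.1 * np.exp(0.1 * tt), gly: 500.0 * np.exp(-0.2 * tt)} for tt in t
            ],
        )
        for v in pc.compute_rate_vectors(exp, registry=registry):
            assert v.rates[gly] < 0

    def test_short_or_dead_experiments_give_no_vectors(self, registry):
        two = pc.CultivationExperiment("short", [0.0, 1.0], [{1: 0.1}, {1: 0.2}])
        assert pc.compute_rate_vectors(two, registry=registry) == []
        dead = pc.CultivationExperiment(
            "dead", [0.0, 1.0, 2.0], [{1: 0.0}, {1: 0.0}, {1: 0.0}]
        )
        assert pc.compute_rate_vectors(dead, registry=registry) == []

    def test_cumulative_column_yields_consumption_rate(self, registry):
        # fed-batch book-keeping: cumulative consumed glycerol increases,
        # the derived rate must be negative (consumption) and flagged
        t = list(np.arange(0.0, 6.0, 1.0))
        gly = 3
        exp = pc.CultivationExperiment(
            experiment_id="fb",
            times=t,
            concentrations=[{1: 0.2 * np.exp(0.1 * tt), gly: 30.0 * tt} for tt in t],
            fed_batch_cumulative={gly},
        )
        vectors = pc.compute_rate_vectors(exp, registry=registry)
        assert vectors
        for v in vectors:
            assert v.rates[gly] < 0
            assert gly in v.cumulative_dims


class TestRemoveOutliers:
    def test_full_band_is_identity(self, noisy_vectors):
        kept, removed = pc.remove_outliers(noisy_vectors, 0.0, 100.0)
        assert removed == []
        assert kept == list(noisy_vectors)

    def test_matches_brute_force_double_loop(self, noisy_vectors, registry):
        kept, removed = pc.remove_outliers(noisy_vectors, 3.0, 97.0)
        X = pc.vectors_to_matrix(noisy_vectors, registry)
        flags = []
        for i in range(X.shape[0]):
            bad = False
            for dcol in range(X.shape[1]):
                lo = np.percentile(X[:, dcol], 3.0)
                hi = np.percentile(X[:, dcol], 97.0)
                if X[i, dcol] < lo or X[i, dcol] > hi:
                    bad = True
            flags.append(bad)
        assert sum(flags) == len(removed)
        assert len(kept) + len(removed) == len(noisy_vectors)

    def test_identical_vectors_not_removed(self, registry):
        v = pc.RateVector("e", 1.0, 0.1, {2: 0.0, 3: -1.0}, {1: 0.5})
        kept, removed = pc.remove_outliers([v] * 10, registry=registry)
        assert len(kept) == 10 and removed == []

    def test_wider_band_never_removes_more(self, noisy_vectors):
        removed_counts = []
        for lo, hi in ((10, 90), (5, 95), (3, 97), (1, 99)):
            _, removed = pc.remove_outliers(noisy_vectors, lo, hi)
            removed_counts.append(len(removed))
        assert removed_counts == sorted(removed_counts, reverse=True)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pc.remove_outliers([])
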