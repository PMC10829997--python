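from fractions import Fraction

import numpy as np
import pytest

from helpers import render_bursts

from meavocab.bursts import Burst
from meavocab.plasticity import (DEFAULT_ALPHA_GRID, basin_analysis, delta_cdf,
                                 evoked_variability, group_compare,
                                 pattern_existence_change, z_score_within_network)


def oracle_delta_cdf(before, after, alpha):
    """Exact rational-arithmetic oracle: type-1 quantile + <= counting."""
    s = sorted(Fraction(x).limit_denominator(10 ** 9) for x in before)
    n = len(s)
    # inverse-CDF (type 1) quantile: smallest x with CDF(x) >= alpha
    k = int(np.ceil(alpha * n)) - 1
    x_a = s[max(k, 0)]
    count = sum(1 for y in after if Fraction(y).limit_denominator(10 ** 9) <= x_a)
    return alpha - Fraction(count, len(after))


class TestDeltaCDF:
    def test_identical_samples_zero_within_step(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(size=200)
        r = delta_cdf(s, s)
        assert np.all(np.abs(r.delta_cdf) <= 1.0 / len(s) + 1e-12)

    def test_uniform_truncated_converges_to_minus_point_two(self):
        """before ~ U(0,1), after ~ U(0,0.8): at alpha=0.8 the statistic
        converges to 0.8 - 1 = -0.2."""
        rng = np.random.default_rng(1)
        r = delta_cdf(rng.uniform(0, 1, 10 ** 4), rng.uniform(0, 0.8, 10 ** 4),
                      alphas=np.array([0.8]))
        assert r.delta_cdf[0] == pytest.approx(-0.2, abs=0.02)

    def test_uniform_shifted_up_converges_to_plus_five_percent(self):
        """before ~ U(0,1), after ~ U(0.2,1): CDF_after(0.8) = 0.75, so
        the statistic converges to +0.05."""
        rng = np.random.default_rng(2)
        r = delta_cdf(rng.uniform(0, 1, 10 ** 4), rng.uniform(0.2, 1, 10 ** 4),
                      alphas=np.array([0.8]))
        assert r.delta_cdf[0] == pytest.approx(0.05, abs=0.02)

    def test_matches_exact_counting_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            nb, na = rng.integers(5, 40, 2)
            before = rng.uniform(size=nb)
            after = rng.uniform(size=na)
            alpha = float(rng.choice(DEFAULT_ALPHA_GRID))
            r = delta_cdf(before, after, alphas=np.array([alpha]))
            expected = oracle_delta_cdf(before, after, Fraction(alpha).limit_denominator(1000))
            assert r.delta_cdf[0] == pytest.approx(float(expected), abs=1e-12)

    def test_bounds_invariant(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            r = delta_cdf(rng.uniform(size=30), rng.uniform(size=25))
            assert np.all(r.delta_cdf <= r.alphas + 1e-12)
            assert np.all(r.delta_cdf >= r.alphas - 1 - 1e-12)

    def test_monotone_in_location_shift(self):
        """Shifting the after sample further down never shrinks the
        negative shift, at any alpha."""
        rng = np.random.default_rng(5)
        before = rng.normal(0.7, 0.1, 2000)
        after = rng.normal(0.7, 0.1, 2000)
        prev = delta_cdf(before, after).delta_cdf
        for delta in (0.05, 0.1, 0.2):
            cur = delta_cdf(before, after - delta).delta_cdf
            assert np.all(cur <= prev + 1e-12)
            prev = cur

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            delta_cdf(np.array([]), np.array([0.5]))


class TestPatternExistenceChange:
    def test_duplicate_population_yields_unit_correlations(self):
        rng = np.random.default_rng(6)
        m = rng.uniform(size=(120, 20))
        ref = Burst(matrix=m, initial_state=m[:, 0].copy(), start_ms=0.0)
        dup = Burst(matrix=m.copy(), initial_state=m[:, 0].copy(), start_ms=1.0)
        other = Burst(matrix=rng.uniform(size=(120, 20)),
                      initial_state=rng.uniform(size=120), start_ms=2.0)
        r = pattern_existence_change([ref], [ref, dup, other], [dup, other])
        assert np.isclose(r.before_samples, 1.0).any()
        # the reference itself was excluded from its own epoch's population
        assert len(r.before_samples) == 2

    def test_empty_epoch_rejected(self):
        rng = np.random.default_rng(7)
        m = rng.uniform(size=(120, 20))
        b = Burst(matrix=m, initial_state=m[:, 0].copy(), start_ms=0.0)
        with pytest.raises(ValueError):
            pattern_existence_change([b], [], [b])


class TestGroupCompare:
    def make_results(self, rng, n, shift=0.0, network_prefix="n"):
        out = []
        for i in range(n):
            r = delta_cdf(rng.uniform(0, 1, 300), rng.uniform(0 - shift, 1 - shift, 300))
            r.network = f"{network_prefix}{i}"
            out.append(r)
        return out

    def test_z_scoring_normalizes_within_network(self):
        rng = np.random.default_rng(8)
        results = self.make_results(rng, 1) + self.make_results(rng, 1, network_prefix="m")
        z_score_within_network(results)
        for r in results:
            assert r.z_scored.mean() == pytest.approx(0.0, abs=1e-9)
            assert r.z_scored.std() == pytest.approx(1.0, abs=1e-9)

    def test_planted_effect_detected(self):
        rng = np.random.default_rng(9)
        stim = self.make_results(rng, 11, shift=0.15, network_prefix="s")
        ctrl = self.make_results(rng, 5, shift=0.0, network_prefix="c")
        cmp = group_compare(stim, ctrl)
        assert (cmp.p_values < 0.05).any()

    def test_minimum_group_size(self):
        rng = np.random.default_rng(10)
        with pytest.raises(ValueError):
            group_compare(self.make_results(rng, 1), self.make_results(rng, 3))


class TestEvokedVariability:
    def make_responses(self, rng, n, jitter=0.0):
        base = rng.uniform(size=(120, 20))
        out = []
        for i in range(n):
            m = base + jitter * rng.normal(size=(120, 20))
            out.append(Burst(matrix=m, initial_state=m[:, 0].copy(), start_ms=0.0))
        return out

    def test_identical_responses_degenerate_ones(self):
        rng = np.random.default_rng(11)
        resp = self.make_responses(rng, 8)
        times = np.arange(8) * 10 * 60e3   # 10 min apart
        ev = evoked_variability(resp, times, window_min=30.0)
        assert ev.degenerate
        assert np.allclose(ev.normalized[np.isfinite(ev.normalized)], 1.0)

    def test_first_window_normalized_to_one(self):
        rng = np.random.default_rng(12)
        resp = self.make_responses(rng, 12, jitter=0.3)
        times = np.arange(12) * 10 * 60e3
        ev = evoked_variability(resp, times, window_min=30.0)
        assert ev.normalized[0] == pytest.approx(1.0)

    def test_empty_window_is_gap(self):
        rng = np.random.default_rng(13)
        resp = self.make_responses(rng, 6, jitter=0.3)
        times = np.array([0, 1, 2, 65, 66, 67]) * 60e3  # nothing in window 2
        ev = evoked_variability(resp, times, window_min=30.0)
        assert np.isnan(ev.deviations[1])
        assert np.isfinite(ev.deviations[0]) and np.isfinite(ev.deviations[2])

    def test_shrinking_noise_non_increasing(self, geometry, templates3):
        rng = np.random.default_rng(14)
        resp, times = [], []
        for w, scale in enumerate((1.0, 0.7, 0.45, 0.3)):
            for i in range(15):
                [b] = render_bursts(templates3[0], geometry, rng, 1, noise_scale=scale)
                resp.append(b)
                times.append((w * 30 + i) * 60e3)
        ev = evoked_variability(resp, np.asarray(times), window_min=30.0)
        assert ev.normalized[-1] < 1.0
        assert np.all(np.diff(ev.normalized) < 0.05)  # non-increasing within MC noise

    def test_single_window_rejected(self):
        rng = np.random.default_rng(15)
        resp = self.make_responses(rng, 3)
        with pytest.raises(ValueError):
            evoked_variability(resp, np.array([0.0, 1.0, 2.0]), window_min=30.0)


class TestBasinAnalysis:
    def test_before_vs_itself_zero(self, geometry, templates3):
        rng = np.random.default_rng(16)
        bursts = render_bursts(templates3[0], geometry, rng, 30)
        r = basin_analysis(bursts, bursts, bursts[:10], initial_threshold=0.3)
        assert np.all(np.abs(r.delta_cdf) <= 0.05)

    def test_insufficient_candidates_flagged(self, geometry, templates3):
        rng = np.random.default_rng(17)
        ref = render_bursts(templates3[0], geometry, rng, 5)
        far = render_bursts(templates3[1], geometry, rng, 10)
        r = basin_analysis(far, far, ref, initial_threshold=0.999)
        assert r.insufficient
        assert np.isnan(r.delta_cdf).all()

    def test_divergent_after_epoch_negative(self, geometry, templates3):
        """Bursts from the same initial region that no longer converge give
        a negative shift at every alpha."""
        rng = np.random.default_rng(18)
        before = render_bursts(templates3[0], geometry, rng, 30)
        after = render_bursts(templates3[0], geometry, rng, 30, noise_scale=4.0)
        r = basin_analysis(before, after, before[:10], initial_threshold=0.2)
        assert not r.insufficient
        assert np.all(r.delta_cdf < 0)
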