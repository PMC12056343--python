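"""Two-block Gaussian change-point search and the broken-stick validator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dielscope import broken_stick_changepoint, detect_changepoint, split_loglik
from dielscope.changepoint import MIN_SEGMENT, VARIANCE_FLOOR


def oracle_split_loglik(x, k):
    """Independent naive oracle: per-block Gaussian log-likelihood at the MLE,
    computed with an explicit two-pass mean/variance and floored variance."""
    x = np.asarray(x, float)
    total = 0.0
    for block in (x[:k], x[k:]):
        m = len(block)
        mean = sum(block) / m
        var = sum((v - mean) ** 2 for v in block) / m
        var_f = max(var, VARIANCE_FLOOR)
        total += -0.5 * m * (np.log(2 * np.pi * var_f) + var / var_f)
    return total


def oracle_best_split(x):
    n = len(x)
    best_k, best_ll = None, -np.inf
    for k in range(MIN_SEGMENT, n - MIN_SEGMENT + 1):
        ll = oracle_split_loglik(x, k)
        if ll > best_ll:  # strict: keeps the earliest maximiser
            best_k, best_ll = k, ll
    return best_k


class TestSplitLoglik:
    def test_perfect_step_maximised_at_break(self):
        x = np.array([0.0] * 8 + [10.0] * 8)
        lls = [split_loglik(x, k) for k in range(MIN_SEGMENT, len(x) - MIN_SEGMENT + 1)]
        ks = list(range(MIN_SEGMENT, len(x) - MIN_SEGMENT + 1))
        assert ks[int(np.argmax(lls))] == 8
        assert all(split_loglik(x, 8) > split_loglik(x, k) for k in ks if k != 8)

    def test_constant_series_flat_profile(self):
        x = np.full(20, 3.7)
        lls = {k: split_loglik(x, k) for k in range(MIN_SEGMENT, 16)}
        vals = list(lls.values())
        assert np.allclose(vals, vals[0])

    def test_out_of_range_split_rejected(self):
        with pytest.raises(ValueError):
            split_loglik(np.zeros(20), MIN_SEGMENT - 1)

    @given(st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2 * MIN_SEGMENT, 60))
        x = rng.normal(size=n)
        k = int(rng.integers(MIN_SEGMENT, n - MIN_SEGMENT + 1))
        assert split_loglik(x, k) == pytest.approx(oracle_split_loglik(x, k), abs=1e-10)


class TestDetectChangepoint:
    def test_perfect_step_any_position(self):
        for j in range(MIN_SEGMENT, 40 - MIN_SEGMENT + 1):
            x = np.array([0.0] * j + [12.0] * (40 - j))
            assert detect_changepoint(x).split_index == j

    def test_noisy_step_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        x = np.concatenate([rng.normal(0, 0.5, 20), rng.normal(12, 3, 20)])
        res = detect_changepoint(x)
        assert res.split_index == 20
        assert res.split_index == oracle_best_split(x)

    def test_exhaustive_oracle_equivalence_random_series(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(2 * MIN_SEGMENT, 80))
            x = rng.normal(0, 1, n)
            if rng.random() < 0.7:  # inject a shift at a random location
                j = int(rng.integers(MIN_SEGMENT, n - MIN_SEGMENT + 1))
                x[j:] += rng.uniform(0.5, 8)
            assert detect_changepoint(x).split_index == oracle_best_split(x)

    def test_pure_noise_has_low_support(self):
        """On stationary noise the support statistic stays far below a real step's."""
        rng = np.random.default_rng(3)
        noise_support = [detect_changepoint(rng.normal(0, 1, 100)).support for _ in range(50)]
        step = np.concatenate([rng.normal(0, 1, 50), rng.normal(10, 1, 50)])
        assert np.median(noise_support) < 0.1 * detect_changepoint(step).support

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            detect_changepoint(np.zeros(2 * MIN_SEGMENT - 1))

    def test_tie_breaks_to_earliest_split(self):
        x = np.full(24, 1.0)  # fully exchangeable: every split ties
        assert detect_changepoint(x).split_index == MIN_SEGMENT

    @given(
        shift=st.floats(min_value=-100, max_value=100),
        scale=st.floats(min_value=0.01, max_value=50),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_translation_and_scale_invariance(self, shift, scale):
        rng = np.random.default_rng(11)
        x = np.concatenate([rng.normal(0, 0.4, 15), rng.normal(5, 2, 17)])
        k0 = detect_changepoint(x).split_index
        assert detect_changepoint(x + shift).split_index == k0
        assert detect_changepoint(x * scale).split_index == k0

    def test_split_time_maps_to_grid(self):
        x = np.array([0.0] * 10 + [9.0] * 10)
        times = pd.date_range("2020-03-10 05:00", periods=20, freq="180s", tz="UTC")
        res = detect_changepoint(x, times)
        assert res.split_time == times[10]


class TestBrokenStick:
    def test_perfect_step_recovered_within_one_slot(self):
        x = np.array([0.0] * 20 + [15.0] * 20)
        res = broken_stick_changepoint(x)
        assert abs(res.split_index - 20) <= 1
        assert res.method == "broken_stick"

    def test_flat_series_flagged_wide_posterior(self):
        rng = np.random.default_rng(5)
        res = broken_stick_changepoint(rng.normal(0, 1, 80))
        assert res.extra["flat"]

    def test_agrees_with_changepoint_on_ramped_steps(self):
        """Across noisy step fixtures the two estimators track each other."""
        rng = np.random.default_rng(9)
        cp, bs = [], []
        for _ in range(60):
            j = int(rng.integers(15, 45))
            x = np.concatenate([rng.normal(0, 1, j), rng.normal(14, 4, 60 - j)])
            cp.append(detect_changepoint(x).split_index)
            bs.append(broken_stick_changepoint(x).split_index)
        r = np.corrcoef(cp, bs)[0, 1]
        assert r > 0.9
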