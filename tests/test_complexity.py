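"""Entropies, Lempel-Ziv complexity and phase-rectified signal averaging,
each checked against an explicit brute-force oracle."""

import math

import numpy as np
import pytest

from ctgscreen.complexity import (
    PRSACurve,
    apen,
    capacity,
    lz76_complexity,
    lzc,
    prsa_anchors,
    prsa_curve,
    prsa_features,
    sampen,
    symbolize,
)


# ----------------------------------------------------------------- oracles
def apen_bruteforce(x, m, r_abs):
    """Template counting straight from the definition, self-matches included."""
    n = len(x)

    def phi(mm):
        nt = n - mm + 1
        total = 0.0
        for i in range(nt):
            c = 0
            for j in range(nt):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r_abs:
                    c += 1
            total += math.log(c / nt)
        return total / nt

    return phi(m) - phi(m + 1)


def sampen_bruteforce(x, m, r_abs):
    """Pairwise template counting, self-matches excluded, -ln(A/B)."""
    n = len(x)
    nt = n - m
    A = B = 0
    for i in range(nt):
        for j in range(nt):
            if i == j:
                continue
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r_abs:
                B += 1
                if abs(x[i + m] - x[j + m]) <= r_abs:
                    A += 1
    if A == 0 or B == 0:
        return float("nan")
    return -math.log(A / B)


def lz76_bruteforce(symbols):
    """Phrase count by the exhaustive-history definition: the next phrase is
    the shortest prefix of the remainder that does not occur in the string
    up to (but not including) the phrase's last symbol."""
    s = "".join(str(int(v)) for v in symbols)
    n = len(s)
    c = 0
    i = 0
    while i < n:
        k = 1
        while i + k < n:
            phrase = s[i : i + k]
            history = s[: i + k - 1]
            found = any(
                history[t : t + k] == phrase for t in range(len(history) - k + 1)
            )
            if not found:
                break
            k += 1
        c += 1
        i += k
    return c


def prsa_anchor_bruteforce(x, T, direction):
    out = []
    for i in range(T, len(x) - T + 1):
        after = sum(x[i : i + T]) / T
        before = sum(x[i - T : i]) / T
        if direction == "acceleration" and after > before:
            out.append(i)
        if direction == "deceleration" and after < before:
            out.append(i)
    return out


# ------------------------------------------------------------------ tests
class TestApEn:
    def test_constant_signal_zero(self):
        assert apen(np.full(200, 5.0)) == 0.0

    def test_alternating_signal_low(self, rng):
        x = np.tile([0.0, 10.0], 100)
        assert apen(x) < 0.2

    def test_noise_exceeds_alternating(self, rng):
        x_alt = np.tile([0.0, 10.0], 100)
        x_noise = rng.standard_normal(200)
        assert apen(x_noise) > apen(x_alt)

    def test_matches_bruteforce(self, rng):
        for _ in range(5):
            x = rng.standard_normal(60)
            r_abs = 0.1 * x.std()
            assert apen(x) == pytest.approx(
                apen_bruteforce(x, 1, r_abs), abs=1e-12
            )


class TestSampEn:
    def test_constant_signal_zero(self):
        assert sampen(np.full(200, 5.0)) == 0.0

    def test_matches_bruteforce_on_sine(self, rng):
        t = np.arange(100)
        x = np.sin(2 * np.pi * t / 20.0) + 0.01 * rng.standard_normal(100)
        r_abs = 0.1 * x.std()
        assert sampen(x) == pytest.approx(
            sampen_bruteforce(x, 1, r_abs), abs=1e-12
        )

    def test_matches_bruteforce_random(self, rng):
        for _ in range(5):
            x = rng.standard_normal(80)
            assert sampen(x) == pytest.approx(
                sampen_bruteforce(x, 1, 0.1 * x.std()), abs=1e-12
            )

    def test_reversal_invariance(self, rng):
        x = rng.standard_normal(150)
        assert sampen(x) == pytest.approx(sampen(x[::-1]), abs=1e-12)

    def test_undefined_cases_agree_with_bruteforce(self, rng):
        # tiny signals often have no template matches: both routes must
        # then report NaN (undefined), never infinity
        for _ in range(20):
            x = rng.standard_normal(6)
            got = sampen(x)
            exp = sampen_bruteforce(x, 1, 0.1 * x.std())
            if np.isnan(exp):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(exp, abs=1e-12)
            assert not np.isinf(got)


class TestLZC:
    def test_canonical_16_symbol_string(self):
        s = np.array([int(c) for c in "0001101001000101"])
        assert lz76_complexity(s) == 6
        assert lz76_bruteforce(s) == 6

    def test_matches_bruteforce_parser(self, rng):
        for alphabet in (2, 3):
            for _ in range(30):
                s = rng.integers(0, alphabet, size=int(rng.integers(2, 200)))
                assert lz76_complexity(s) == lz76_bruteforce(s), s

    def test_constant_signal_minimal(self):
        x = np.full(200, 7.0)
        sym = symbolize(x, "ternary")
        # all-zero difference string parses as "0" + reproducible remainder
        assert lz76_complexity(sym) == 2 == lz76_bruteforce(sym)
        n = len(sym)
        assert lzc(x, "ternary") == pytest.approx(2 * np.log(n) / np.log(3) / n)

    def test_periodic_string_low_complexity(self):
        x = np.tile([0.0, 1.0], 300)  # differences alternate +1/-1
        assert lzc(x, "binary") < 0.1

    def test_monotone_rescaling_invariance(self, rng):
        x = rng.standard_normal(300)
        for alphabet in ("binary", "ternary"):
            assert lzc(x, alphabet) == lzc(3.7 * x + 11.0, alphabet)
            assert lzc(x, alphabet) == lzc(np.exp(x), alphabet)

    def test_ternary_keeps_zero_differences(self):
        x = np.array([1.0, 1.0, 2.0, 1.5, 1.5, 3.0])
        np.testing.assert_array_equal(
            symbolize(x, "ternary"), [0, 1, -1, 0, 1]
        )
        np.testing.assert_array_equal(symbolize(x, "binary"), [0, 1, 0, 0, 1])


class TestPRSA:
    def test_constant_signal_has_no_anchors(self):
        assert len(prsa_anchors(np.full(500, 140.0), T=5, direction="acceleration")) == 0
        curve = prsa_curve(np.full(500, 140.0), T=5, direction="acceleration", L=100)
        assert curve.empty
        assert np.isnan(capacity(curve, s=5))

    def test_ramp_every_index_is_anchor(self):
        x = np.arange(600, dtype=float)
        anchors = prsa_anchors(x, T=5, direction="acceleration")
        assert np.array_equal(anchors, np.arange(5, 596))
        assert len(prsa_anchors(x, T=5, direction="deceleration")) == 0
        curve = prsa_curve(x, T=5, direction="acceleration", L=100)
        # average of aligned ramps is a ramp with unit slope
        np.testing.assert_allclose(np.diff(curve.x), 1.0, atol=1e-8)

    def test_anchor_sets_match_bruteforce(self, rng):
        for T in (1, 5, 9, 40):
            x = rng.standard_normal(400)
            for direction in ("acceleration", "deceleration"):
                got = prsa_anchors(x, T, direction)
                exp = prsa_anchor_bruteforce(x, T, direction)
                assert list(got) == exp, (T, direction)

    def test_single_impulse_anchor_enumeration(self):
        x = np.zeros(300)
        x[150] = 10.0
        # T=1: mean after > mean before exactly where the impulse enters
        got = list(prsa_anchors(x, T=1, direction="acceleration"))
        exp = prsa_anchor_bruteforce(x, 1, "acceleration")
        assert got == exp == [150]

    def test_step_curve_capacity_is_half_height(self):
        L, h = 100, 6.0
        curve_x = np.concatenate([np.zeros(L), np.full(L, h)])
        curve = PRSACurve(curve_x, n_anchors=5, direction="acceleration", L=L)
        for s in (1, 2, 5, 9):
            assert capacity(curve, s) == pytest.approx(h / 2.0)

    def test_constant_curve_capacity_zero(self):
        curve = PRSACurve(np.full(200, 3.3), 4, "acceleration", L=100)
        assert capacity(curve, 5) == pytest.approx(0.0)

    def test_deceleration_reserve_vanishes_by_symmetry(self, rng):
        # a time-reversal-symmetric signal has AC = -DC, so DR = 0
        half = rng.standard_normal(1500)
        x = np.concatenate([half, half[::-1]])
        feats = prsa_features(x)
        for ts in ("T1_s2", "T5_s5", "T9_s9"):
            ac, dc = feats[f"AC_{ts}"], feats[f"DC_{ts}"]
            assert ac == pytest.approx(-dc, abs=1e-9)
            assert feats[f"DR_{ts}"] == pytest.approx(0.0, abs=1e-9)

    def test_capacity_signs_on_noise(self, rng):
        x = 140 + rng.standard_normal(3000)
        feats = prsa_features(x)
        for ts in ("T1_s2", "T5_s5", "T9_s9", "T40_s1"):
            assert feats[f"AC_{ts}"] > 0
            assert feats[f"DC_{ts}"] < 0
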