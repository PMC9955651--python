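import itertools
import math

import numpy as np
import pytest

from hrvcomplexity import pentropy as pe
from hrvcomplexity.pentropy import OrdinalDistribution


def brute_force_patterns(x, m, tau):
    """Naive reference: count each window's stable-argsort permutation."""
    perms = list(itertools.permutations(range(m)))
    counts = {p: 0 for p in perms}
    for start in range(len(x) - (m - 1) * tau):
        window = [x[start + j * tau] for j in range(m)]
        order = tuple(sorted(range(m), key=lambda i: (window[i], i)))
        counts[order] += 1
    return np.array([counts[p] for p in perms])


class TestOrdinalPatterns:
    def test_monotone_ramp_single_pattern(self):
        d = pe.ordinal_patterns([1, 2, 3, 4, 5], m=2, tau=1)
        np.testing.assert_array_equal(d.counts, [4, 0])

    def test_simple_mixed(self):
        d = pe.ordinal_patterns([3, 1, 2], m=2, tau=1)
        np.testing.assert_array_equal(d.counts, [1, 1])

    def test_exhaustive_small_series_oracle(self):
        # all series of length <= 7 over alphabet {1..4} (with repeats,
        # exercising the tie rule), m in {2, 3}, tau in {1, 2}
        for length in range(4, 8):
            for vals in itertools.product([1, 2, 3, 4], repeat=length):
                x = np.array(vals, dtype=float)
                for m, tau in ((2, 1), (3, 1), (3, 2)):
                    if len(x) < (m - 1) * tau + 1:
                        continue
                    got = pe.ordinal_patterns(x, m, tau).counts
                    want = brute_force_patterns(x, m, tau)
                    np.testing.assert_array_equal(got, want)

    def test_random_longer_series_oracle(self, rng):
        for _ in range(30):
            x = rng.integers(1, 5, size=12).astype(float)
            got = pe.ordinal_patterns(x, 3, 1).counts
            np.testing.assert_array_equal(got, brute_force_patterns(x, 3, 1))

    def test_counts_sum_to_windows(self, rng):
        x = rng.standard_normal(100)
        d = pe.ordinal_patterns(x, 4, 2)
        assert d.n_windows == 100 - 3 * 2

    def test_period2_concentrates_on_two_patterns(self):
        x = np.resize([1.0, 2.0], 100)
        d = pe.ordinal_patterns(x, 3, 1)
        assert np.count_nonzero(d.counts) == 2

    def test_order_guard(self):
        with pytest.raises(ValueError):
            pe.ordinal_patterns(np.arange(100.0), m=8)


class TestEntropyFunctional:
    FAMILIES = [("shannon", {}), ("renyi", {"alpha": 2.0}),
                ("tsallis", {"q": 2.0}), ("min", {})]

    @pytest.mark.parametrize("family,kw", FAMILIES)
    def test_single_pattern_zero(self, family, kw):
        d = pe.ordinal_patterns(np.arange(50.0), 3, 1)
        assert pe.entropy_functional(d, family, **kw) == pytest.approx(0.0)

    @pytest.mark.parametrize("family,kw", FAMILIES)
    def test_uniform_is_one(self, family, kw):
        d = OrdinalDistribution(3, 1, np.full(6, 10))
        assert pe.entropy_functional(d, family, **kw) == pytest.approx(1.0)

    def test_iid_noise_near_one(self):
        vals = [pe.permutation_entropy(
            np.random.default_rng(s).standard_normal(2 ** 14), 3, 1)
            for s in range(20)]
        assert min(vals) >= 0.995

    def test_monotone_transform_invariance(self, rng):
        x = rng.standard_normal(500)
        a = pe.permutation_entropy(x, 3, 1)
        b = pe.permutation_entropy(np.exp(2 * x), 3, 1)
        assert a == pytest.approx(b, rel=1e-12)

    def test_outputs_in_unit_interval(self, rng):
        x = rng.standard_normal(300)
        for fam, kw in self.FAMILIES:
            d = pe.ordinal_patterns(x, 3, 1)
            assert 0.0 <= pe.entropy_functional(d, fam, **kw) <= 1.0


class TestAAPE:
    def test_equal_amplitude_reduces_to_pe(self):
        # +/-1 alternation: every window has the same mean |value| and
        # mean |difference|, so all weights coincide
        x = np.resize([-1.0, 1.0], 60)
        assert pe.aape(x, 3, 1, a=0.5) == pytest.approx(
            pe.permutation_entropy(x, 3, 1), rel=1e-12)

    def test_monotone_ramp_zero(self):
        assert pe.aape(np.arange(50.0), 3, 1) == pytest.approx(0.0)

    def test_matches_hand_weighting(self, rng):
        x = rng.standard_normal(10)
        m, tau, a = 3, 1, 0.5
        got = pe.aape(x, m, tau, a)
        z = x / np.std(x)
        weights = {}
        for s in range(len(z) - 2):
            w = (a * np.mean(np.abs(z[s:s + 3]))
                 + (1 - a) * np.mean(np.abs(np.diff(z[s:s + 3]))))
            order = tuple(sorted(range(3), key=lambda i: (z[s + i], i)))
            weights[order] = weights.get(order, 0.0) + w
        p = np.array(list(weights.values()))
        p = p / p.sum()
        want = -(p * np.log(p)).sum() / np.log(6)
        assert got == pytest.approx(want, rel=1e-12)

    def test_not_invariant_under_amplitude_rescaling_of_part(self, rng):
        x = rng.standard_normal(200)
        y = x.copy()
        y[100:] *= 10.0  # amplitude structure changes the weighting
        assert pe.aape(x, 3, 1) != pytest.approx(pe.aape(y, 3, 1), abs=1e-6)


class TestEdgePE:
    def test_constant_increment_ramp_zero(self):
        assert pe.edge_pe(np.arange(60.0), 3, 1) == pytest.approx(0.0)

    def test_equal_weights_equals_plain_pe(self):
        x = np.resize([1.0, 2.0], 60)  # every window has edge sum 2
        assert pe.edge_pe(x, 3, 1) == pytest.approx(
            pe.permutation_entropy(x, 3, 1), rel=1e-9)

    def test_large_edge_window_upweighted(self):
        # one huge downward edge among gentle rises
        x = np.concatenate([np.arange(0, 20.0), [0.0],
                            np.arange(0.0, 20.0)])
        win = np.lib.stride_tricks.sliding_window_view(x, 3)
        w = np.sum(np.abs(np.diff(win, axis=1)), axis=1)
        # brute-force weighted entropy
        probs = {}
        for row, wt in zip(win, w):
            order = tuple(np.argsort(row, kind="stable"))
            probs[order] = probs.get(order, 0.0) + wt
        p = np.array(list(probs.values()))
        p /= p.sum()
        want = -(p * np.log(p)).sum() / np.log(6)
        assert pe.edge_pe(x, 3, 1) == pytest.approx(want, rel=1e-12)
        assert pe.edge_pe(x, 3, 1) > pe.permutation_entropy(x, 3, 1)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            pe.edge_pe(np.ones(60), 3, 1)


class TestCPEI:
    def test_monotone_ramp_zero(self):
        assert pe.cpei(np.arange(60.0), 0.0) == pytest.approx(0.0)

    def test_iid_noise_high(self):
        vals = [pe.cpei(np.random.default_rng(s).standard_normal(2 ** 13))
                for s in range(5)]
        assert min(vals) >= 0.9

    def test_huge_threshold_all_tied(self, rng):
        x = rng.standard_normal(100)
        assert pe.cpei(x, tie_threshold=1e6) == pytest.approx(0.0)


class TestPJSC:
    def test_uniform_zero(self):
        d = OrdinalDistribution(3, 1, np.full(6, 5))
        assert pe.pjsc(d) == pytest.approx(0.0, abs=1e-12)

    def test_single_pattern_zero(self):
        d = OrdinalDistribution(3, 1, np.array([10, 0, 0, 0, 0, 0]))
        assert pe.pjsc(d) == pytest.approx(0.0, abs=1e-12)

    def test_golden_value_two_patterns(self):
        # hand evaluation of the JSD pipeline for p = [0.75, 0.25], m = 2
        p = np.array([0.75, 0.25])
        u = np.array([0.5, 0.5])
        h = lambda q: -(q[q > 0] * np.log(q[q > 0])).sum()
        jsd = h(0.5 * (p + u)) - 0.5 * (h(p) + h(u))
        qmax = -0.5 * (1.5 * np.log(3) - 2 * np.log(4) + np.log(2))
        want = jsd / qmax * h(p) / np.log(2)
        d = OrdinalDistribution(2, 1, np.array([75, 25]))
        assert pe.pjsc(d) == pytest.approx(want, rel=1e-12)
        assert want == pytest.approx(0.1272, abs=2e-4)


class TestMultiscale:
    def test_coarse_grain_examples(self):
        np.testing.assert_array_equal(pe.coarse_grain([1, 3, 5, 7], 2), [2, 6])
        x = np.arange(10.0)
        np.testing.assert_array_equal(pe.coarse_grain(x, 1), x)

    def test_coarse_grain_preserves_mean(self, rng):
        x = rng.standard_normal(30)
        cg = pe.coarse_grain(x, 3)
        assert cg.mean() == pytest.approx(x[:30].mean(), rel=1e-12)

    def test_scale_one_matches_plain(self, rng):
        x = rng.standard_normal(300)
        out = pe.multiscale_pe(x, 3, 1, scales=[1], variant="mPE")
        assert out[1] == pytest.approx(pe.permutation_entropy(x, 3, 1))
        outm = pe.multiscale_pe(x, 3, 1, scales=[1], variant="mPM_E")
        d = pe.ordinal_patterns(x, 3, 1)
        assert outm[1] == pytest.approx(pe.entropy_functional(d, "min"))

    def test_white_noise_flat_across_scales(self):
        x = np.random.default_rng(3).standard_normal(2 ** 14)
        out = pe.multiscale_pe(x, 3, 1, scales=[1, 2, 3, 4, 5])
        assert all(v > 0.99 for v in out.values())

    def test_impe_equals_offset_average_brute_force(self, rng):
        x = rng.standard_normal(60)
        s = 3
        got = pe.multiscale_pe(x, 3, 1, scales=[s], variant="ImPE")[s]
        counts = np.zeros(6)
        for off in range(s):
            cg = pe.coarse_grain(x[off:], s)
            counts += brute_force_patterns(cg, 3, 1)
        p = counts / counts.sum()
        want = -(p[p > 0] * np.log(p[p > 0])).sum() / np.log(6)
        assert got == pytest.approx(want, rel=1e-12)

    def test_too_short_scale_raises(self, rng):
        with pytest.raises(ValueError):
            pe.multiscale_pe(rng.standard_normal(30), 3, 1, scales=[10])
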