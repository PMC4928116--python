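"""Synchronization likelihood: embedding, cutoffs, pairwise SL, matrices."""
import math

import numpy as np
import pytest

from fafnet import erp as E
from fafnet import sl as S
from fafnet.config import EmbeddingParams

TOY = EmbeddingParams(lag=2, dim=3, w1=5, w2=200, p_ref=0.05)


def naive_sl(x, y, p):
    """Plain-loop reference SL, independent of the vectorized path."""
    ex, ey = S.embed(x, p), S.embed(y, p)
    nv = len(ex)
    n_min = math.ceil(1.0 / p.p_ref)
    sx = sy = 0.0
    n_ref = 0
    for i in range(nv):
        cand = [j for j in range(nv) if p.w1 < abs(i - j) < p.w2]
        if len(cand) < n_min:
            continue
        dx = sorted(float(np.linalg.norm(ex[j] - ex[i])) for j in cand)
        dy = sorted(float(np.linalg.norm(ey[j] - ey[i])) for j in cand)
        k = math.ceil(p.p_ref * len(cand))
        rx, ry = dx[k - 1], dy[k - 1]
        hx = hy = hxy = 0
        for j in cand:
            in_x = np.linalg.norm(ex[j] - ex[i]) <= rx
            in_y = np.linalg.norm(ey[j] - ey[i]) <= ry
            hx += in_x
            hy += in_y
            hxy += in_x and in_y
        sx += hxy / hx
        sy += hxy / hy
        n_ref += 1
    return 0.5 * (sx + sy) / n_ref


class TestEmbedding:
    def test_basic_example(self):
        p = EmbeddingParams(lag=1, dim=2, w1=1, w2=3)
        out = S.embed(np.array([1.0, 2, 3, 4]), p)
        np.testing.assert_array_equal(out, [[1, 2], [2, 3], [3, 4]])

    def test_dim_one_returns_scalars(self):
        p = EmbeddingParams(lag=1, dim=1, w1=1, w2=3)
        out = S.embed(np.array([5.0, 6, 7]), p)
        np.testing.assert_array_equal(out[:, 0], [5, 6, 7])

    @pytest.mark.parametrize("n,dim,lag", [(20, 3, 2), (50, 5, 4), (11, 2, 5)])
    def test_count_formula_against_enumeration(self, n, dim, lag):
        p = EmbeddingParams(lag=lag, dim=dim, w1=1, w2=5)
        x = np.arange(n, dtype=float)
        out = S.embed(x, p)
        brute = [[x[i + k * lag] for k in range(dim)]
                 for i in range(n) if i + (dim - 1) * lag < n]
        assert len(out) == n - (dim - 1) * lag == len(brute)
        np.testing.assert_array_equal(out, brute)

    def test_too_short_series_errors(self):
        p = EmbeddingParams(lag=10, dim=9, w1=1, w2=5)
        with pytest.raises(ValueError, match="too short"):
            S.embed(np.zeros(80), p)


class TestCriticalDistance:
    def test_matches_sort_oracle(self, rng):
        vecs = rng.standard_normal((300, 3))
        p = EmbeddingParams(lag=1, dim=3, w1=2, w2=250, p_ref=0.03)
        i = 100
        cand = S.candidate_indices(len(vecs), i, p)
        d = np.sort(np.linalg.norm(vecs[cand] - vecs[i], axis=1))
        k = math.ceil(p.p_ref * len(cand))
        assert S.critical_distance(vecs, i, p) == pytest.approx(d[k - 1])

    def test_identical_vectors_epsilon_zero(self):
        vecs = np.ones((200, 2))
        p = EmbeddingParams(lag=1, dim=2, w1=1, w2=150, p_ref=0.05)
        eps = S.critical_distance(vecs, 50, p)
        assert eps == 0.0
        cand = S.candidate_indices(len(vecs), 50, p)
        assert (np.linalg.norm(vecs[cand] - vecs[50], axis=1) <= eps).all()

    def test_p_ref_fixes_recurrence_count(self, rng):
        """500 distinct-distance candidates at P_ref = 0.01 -> 5 recurrences."""
        vecs = rng.standard_normal((502, 4))
        p = EmbeddingParams(lag=1, dim=4, w1=1, w2=10_000, p_ref=0.01)
        i = 0
        cand = S.candidate_indices(len(vecs), i, p)
        assert len(cand) == 500
        eps = S.critical_distance(vecs, i, p)
        assert (np.linalg.norm(vecs[cand] - vecs[i], axis=1) <= eps).sum() == 5

    def test_insufficient_candidates_error(self, rng):
        vecs = rng.standard_normal((30, 2))
        p = EmbeddingParams(lag=1, dim=2, w1=1, w2=30, p_ref=0.01)
        with pytest.raises(ValueError, match="longer epochs"):
            S.critical_distance(vecs, 15, p)


class TestPairwiseSL:
    def test_self_synchronization_is_one(self, rng):
        x = S.theta_filter(rng.standard_normal(600), 250.0)
        assert S.synchronization_likelihood(x, x, TOY) == pytest.approx(1.0)

    def test_symmetric_in_arguments(self, rng):
        x, y = rng.standard_normal((2, 500))
        assert (S.synchronization_likelihood(x, y, TOY)
                == pytest.approx(S.synchronization_likelihood(y, x, TOY)))

    def test_invariant_under_linear_rescaling(self, rng):
        x, y = rng.standard_normal((2, 500))
        a = S.synchronization_likelihood(x, y, TOY)
        b = S.synchronization_likelihood(3.0 * x - 7.0, 3.0 * y - 7.0, TOY)
        assert b == pytest.approx(a, abs=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            S.synchronization_likelihood(np.ones(400), np.arange(400.0), TOY)

    def test_matches_naive_reference(self, rng):
        """Vectorized SL equals the plain-loop recurrence counter."""
        for _ in range(3):
            x, y = rng.standard_normal((2, 220))
            p = EmbeddingParams(lag=2, dim=2, w1=4, w2=220, p_ref=0.06)
            assert (S.synchronization_likelihood(x, y, p)
                    == pytest.approx(naive_sl(x, y, p), abs=1e-12))

    def test_coupled_exceeds_uncoupled(self, rng):
        common = S.theta_filter(rng.standard_normal(800), 250.0)
        nx = S.theta_filter(rng.standard_normal(800), 250.0)
        ny = S.theta_filter(rng.standard_normal(800), 250.0)
        c = 0.8
        x = math.sqrt(c) * common + math.sqrt(1 - c) * nx
        y = math.sqrt(c) * common + math.sqrt(1 - c) * ny
        coupled = S.synchronization_likelihood(x, y, TOY)
        uncoupled = S.synchronization_likelihood(nx, ny, TOY)
        assert coupled > uncoupled + 0.1

    def test_monotone_in_coupling_strength(self, rng):
        common = S.theta_filter(rng.standard_normal(1500), 250.0)
        vals = []
        for c in (0.0, 0.25, 0.5, 0.75, 1.0):
            nx = S.theta_filter(rng.standard_normal(1500), 250.0)
            ny = S.theta_filter(rng.standard_normal(1500), 250.0)
            x = math.sqrt(c) * common + math.sqrt(1 - c) * nx
            y = math.sqrt(c) * common + math.sqrt(1 - c) * ny
            p = EmbeddingParams.for_band(3, 8, 250, n_samples=1500)
            vals.append(S.synchronization_likelihood(x, y, p, max_refs=128))
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(1.0)


class TestThetaFilter:
    def test_band_edges(self):
        fs = 1000.0
        t = np.arange(0, 8, 1 / fs)
        tone5 = np.sin(2 * np.pi * 5 * t)
        tone20 = np.sin(2 * np.pi * 20 * t)
        mid = slice(2000, 6000)
        assert np.abs(S.theta_filter(tone5, fs)[mid]).max() == pytest.approx(1.0, rel=0.05)
        assert np.abs(S.theta_filter(tone20, fs)[mid]).max() < 0.1
        assert np.allclose(S.theta_filter(np.zeros(4000), fs), 0.0)


class TestEmbeddingRecipe:
    def test_band_recipe_long_series(self):
        p = EmbeddingParams.for_band(3, 8, 250, n_samples=2048)
        assert p.lag == 10          # 250 / (3 * 8)
        assert p.dim == 9           # 1 + ceil(3 * 8 / 3)
        assert p.w1 == 2 * p.span
        assert p.p_ref == 0.01

    def test_recipe_shrinks_for_short_epochs(self):
        p = EmbeddingParams.for_band(3, 8, 250, n_samples=175)
        assert p.dim < 9
        nv = 175 - p.span
        assert min(p.w2 - 1, nv - 1) - p.w1 >= p.min_candidates

    def test_infeasible_length_errors(self):
        with pytest.raises(ValueError, match="feasible"):
            EmbeddingParams.for_band(3, 8, 250, n_samples=40)


def _epoch_set(data, names=None):
    n_ep, n_ch, n_s = data.shape
    names = names or [f"ch{i}" for i in range(n_ch)]
    return E.EpochSet(data=data, times_ms=np.arange(n_s, dtype=float), fs=250.0,
                      channel_names=names, magnitudes_cents=np.full(n_ep, 50.0))


class TestSLMatrix:
    def test_shape_symmetry_diagonal(self, rng):
        data = rng.standard_normal((3, 5, 400))
        m = S.sl_matrix(_epoch_set(data), params=TOY)
        assert m.values.shape == (5, 5)
        np.testing.assert_allclose(m.values, m.values.T)
        np.testing.assert_allclose(np.diag(m.values), 1.0)
        off = m.values[np.triu_indices(5, 1)]
        assert ((off >= 0) & (off <= 1)).all()

    def test_duplicated_channel_pair_is_one(self, rng):
        data = rng.standard_normal((2, 3, 400))
        data[:, 1] = data[:, 0]
        m = S.sl_matrix(_epoch_set(data), params=TOY)
        assert m.values[0, 1] == pytest.approx(1.0)

    def test_mean_over_epochs_matches_direct_average(self, rng):
        data = rng.standard_normal((3, 4, 400))
        full = S.sl_matrix(_epoch_set(data), params=TOY).values
        singles = [S.sl_matrix(_epoch_set(data[i:i + 1]), params=TOY).values
                   for i in range(3)]
        np.testing.assert_allclose(full, np.mean(singles, axis=0), atol=1e-12)

    def test_pair_entries_match_pairwise_function(self, rng):
        data = rng.standard_normal((1, 3, 400))
        m = S.sl_matrix(_epoch_set(data), params=TOY, max_refs=None)
        for i in range(3):
            for j in range(i + 1, 3):
                direct = S.synchronization_likelihood(data[0, i], data[0, j], TOY)
                assert m.values[i, j] == pytest.approx(direct, abs=1e-12)

    def test_bad_channel_excluded_with_nan(self, rng):
        data = rng.standard_normal((2, 4, 400))
        eps = _epoch_set(data)
        eps.bad_channels = ["ch2"]
        m = S.sl_matrix(eps, params=TOY)
        assert np.isnan(m.values[2, :]).all()
        assert np.isnan(m.values[:, 2]).all()
        assert np.isfinite(m.values[0, 1])


def test_decimate_epochs_halves_rate(rng):
    data = rng.standard_normal((2, 3, 1000))
    eps = _epoch_set(data)
    eps.fs = 1000.0
    out = S.decimate_epochs(eps, 250.0)
    assert out.fs == 250.0
    assert out.data.shape[-1] == 250
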