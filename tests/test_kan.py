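"""KAN layers: B-spline basis against an independent Cox–de Boor oracle,
partition of unity, forward-pass equivalence, gradients, activation profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scafkan import KANLayer, ResKANBlock, SplineGrid, activation_profile
from scafkan.kan import bspline_basis, bspline_design
from scafkan.nn import Parameter, Tensor, no_grad


def cox_de_boor(x: float, i: int, k: int, t: np.ndarray) -> float:
    """Textbook recursive B-spline evaluation (independent oracle)."""
    if k == 0:
        return 1.0 if t[i] <= x < t[i + 1] else 0.0
    left = 0.0
    if t[i + k] != t[i]:
        left = (x - t[i]) / (t[i + k] - t[i]) * cox_de_boor(x, i, k - 1, t)
    right = 0.0
    if t[i + k + 1] != t[i + 1]:
        right = (t[i + k + 1] - x) / (t[i + k + 1] - t[i + 1]) * \
            cox_de_boor(x, i + 1, k - 1, t)
    return left + right


class TestBasis:
    def test_matches_recursive_oracle_on_random_probes(self, rng):
        for _ in range(40):
            G = int(rng.integers(1, 8))
            k = int(rng.integers(1, 4))
            lo = float(rng.uniform(-5, 0))
            hi = lo + float(rng.uniform(0.5, 6))
            grid = SplineGrid(lo, hi, G, k)
            t = grid.knots
            xs = rng.uniform(lo - 1, hi + 1, size=25)
            B = bspline_design(xs, grid)
            oracle = np.array([[cox_de_boor(x, i, k, t)
                                for i in range(grid.n_basis)] for x in xs])
            assert np.abs(B - oracle).max() < 1e-10

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_partition_of_unity_inside_grid(self, k, rng):
        grid = SplineGrid(-3, 3, 5, k)
        xs = rng.uniform(-3, 3, size=200)
        B = bspline_design(xs, grid)
        assert np.abs(B.sum(axis=-1) - 1.0).max() < 1e-12
        assert B.min() >= 0.0

    def test_order_zero_is_interval_indicator(self):
        grid = SplineGrid(0.0, 1.0, 4, 0)
        b = bspline_basis(0.3, grid)
        assert b.tolist() == [0, 1, 0, 0]

    def test_degenerate_grid_refused(self):
        with pytest.raises(ValueError):
            SplineGrid(0, 1, G=0, k=3)

    def test_out_of_range_evaluated_on_extended_knots(self):
        grid = SplineGrid(-1, 1, 3, 3)
        b = bspline_design(np.array([1.5]), grid)[0]   # inside the extension
        assert b.sum() > 0
        far = bspline_design(np.array([100.0]), grid)[0]
        assert np.all(far == 0.0)

    def test_derivative_matches_finite_differences(self, rng):
        grid = SplineGrid(-2, 2, 5, 3)
        xs = rng.uniform(-2, 2, 30)
        _, dB = bspline_design(xs, grid, with_derivative=True)
        eps = 1e-6
        num = (bspline_design(xs + eps, grid) - bspline_design(xs - eps, grid)) / (2 * eps)
        assert np.abs(dB - num).max() < 1e-6


class TestLayer:
    def naive_forward(self, layer: KANLayer, X: np.ndarray) -> np.ndarray:
        """Per-edge loop implementation (independent of the vectorised path)."""
        n = X.shape[0]
        out = np.zeros((n, layer.out_dim))
        for r in range(n):
            for j in range(layer.out_dim):
                acc = 0.0
                for i in range(layer.in_dim):
                    x = X[r, i]
                    silu = x / (1 + np.exp(-x))
                    spline = float(bspline_basis(x, layer.grid)
                                   @ layer.coef.data[i, j])
                    acc += layer.base_weight.data[i, j] * silu \
                        + layer.spline_weight.data[i, j] * spline
                out[r, j] = acc
        return out

    def test_forward_equals_naive_per_edge_loop(self, rng):
        for _ in range(5):
            layer = KANLayer(int(rng.integers(1, 6)), int(rng.integers(1, 6)),
                             rng=np.random.default_rng(rng.integers(1000)))
            X = rng.normal(size=(8, layer.in_dim))
            with no_grad():
                fast = layer(Tensor(X)).data
            assert np.abs(fast - self.naive_forward(layer, X)).max() < 1e-10

    def test_zero_spline_coefficients_reduce_to_silu_sum(self, rng):
        layer = KANLayer(4, 3, rng=rng)
        layer.coef.data[:] = 0.0
        layer.base_weight.data[:] = 1.0
        X = rng.normal(size=(6, 4))
        with no_grad():
            out = layer(Tensor(X)).data
        silu_sum = (X / (1 + np.exp(-X))).sum(axis=1)
        assert np.allclose(out, silu_sum[:, None], atol=1e-12)

    def test_linear_spline_reproduces_identity(self):
        # Greville abscissae as coefficients give exact linear reproduction
        grid = SplineGrid(-3, 3, 5, 3)
        layer = KANLayer(1, 1, grid, rng=np.random.default_rng(0))
        t = grid.knots
        greville = np.array([t[i + 1:i + 1 + grid.k].mean()
                             for i in range(grid.n_basis)])
        layer.coef.data[0, 0] = greville
        layer.base_weight.data[:] = 0.0
        layer.spline_weight.data[:] = 1.0
        xs = np.linspace(-3, 3, 41)
        with no_grad():
            out = layer(Tensor(xs[:, None])).data[:, 0]
        assert np.abs(out - xs).max() < 1e-10

    def test_row_permutation_equivariance(self, rng):
        layer = KANLayer(3, 2, rng=rng)
        X = rng.normal(size=(10, 3))
        perm = rng.permutation(10)
        with no_grad():
            assert np.allclose(layer(Tensor(X[perm])).data,
                               layer(Tensor(X)).data[perm])

    def test_dimension_mismatch_refused(self, rng):
        layer = KANLayer(3, 2, rng=rng)
        with pytest.raises(ValueError):
            layer(Tensor(rng.normal(size=(4, 5))))

    def test_gradients_match_finite_differences(self, rng):
        layer = KANLayer(3, 2, rng=rng)
        X = rng.normal(size=(5, 3))
        xt = Parameter(X.copy())
        (layer(xt) ** 2).sum().backward()

        def value():
            with no_grad():
                return float((layer(Tensor(layer_x)) ** 2).sum().data)

        eps = 1e-6
        # spline coefficient gradient
        layer_x = X
        i, j, b = 1, 0, 2
        c0 = layer.coef.data[i, j, b]
        layer.coef.data[i, j, b] = c0 + eps
        fp = value()
        layer.coef.data[i, j, b] = c0 - eps
        fm = value()
        layer.coef.data[i, j, b] = c0
        assert layer.coef.grad[i, j, b] == pytest.approx((fp - fm) / (2 * eps),
                                                         abs=1e-4)
        # input gradient
        Xp, Xm = X.copy(), X.copy()
        Xp[2, 1] += eps
        Xm[2, 1] -= eps
        layer_x = Xp
        fp = value()
        layer_x = Xm
        fm = value()
        assert xt.grad[2, 1] == pytest.approx((fp - fm) / (2 * eps), abs=1e-4)


class TestActivationProfile:
    def test_zero_parameter_edge_is_flat_zero(self, rng):
        layer = KANLayer(2, 2, rng=rng)
        layer.coef.data[0, 1] = 0.0
        layer.base_weight.data[0, 1] = 0.0
        xs = np.linspace(-3, 3, 50)
        assert np.all(activation_profile(layer, (0, 1), xs) == 0.0)

    def test_profile_consistent_with_forward(self, rng):
        layer = KANLayer(1, 1, rng=rng)
        xs = np.linspace(-2.5, 2.5, 17)
        with no_grad():
            fwd = layer(Tensor(xs[:, None])).data[:, 0]
        assert np.allclose(activation_profile(layer, (0, 0), xs), fwd, atol=1e-12)

    def test_profile_is_continuous(self, rng):
        layer = KANLayer(2, 3, rng=rng)
        xs = np.linspace(-3, 3, 2000)
        prof = activation_profile(layer, (1, 2), xs)
        assert np.abs(np.diff(prof)).max() < 0.05

    def test_edge_out_of_range_refused(self, rng):
        layer = KANLayer(2, 2, rng=rng)
        with pytest.raises(IndexError):
            activation_profile(layer, (2, 0), np.zeros(3))


def test_reskan_block_projects_skip_when_dims_differ(rng):
    block = ResKANBlock(4, 7, rng=rng)
    with no_grad():
        out = block(Tensor(rng.normal(size=(3, 4))))
    assert out.shape == (3, 7)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.floats(-6, 6), st.integers(1, 3), st.integers(1, 6))
def test_basis_nonnegative_everywhere(x, k, G):
    grid = SplineGrid(-3, 3, G, k)
    b = bspline_design(np.array([x]), grid)[0]
    assert b.min() >= 0.0
    assert b.sum() <= 1.0 + 1e-12
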