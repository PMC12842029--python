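"""Kolmogorov–Arnold network layers.

A KAN layer replaces the usual weight-matrix-plus-fixed-nonlinearity with a
learnable univariate activation on every directed edge (input i → output j):

    phi_ij(x) = w_b[i,j] · silu(x) + w_s[i,j] · Σ_b c[i,j,b] · B_b(x)

where the B_b are B-spline basis functions of degree ``k`` on a uniform
grid shared across edges, and each output unit sums its incoming edge
activations.  The spline part is evaluated with an iterative (vectorised)
Cox–de Boor recurrence; its derivative is analytic, so the layer
back-propagates through both the coefficients and its inputs.

Inputs outside the nominal grid range are evaluated on the extended knot
vector (the grid is extended by ``k`` intervals on each side) rather than
clamped; far outside the extension the spline part decays to zero and only
the silu base path remains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import LayerNorm, Linear, Module, Parameter, Tensor

__all__ = ["SplineGrid", "bspline_basis", "bspline_design", "KANLayer",
           "ResKANBlock", "activation_profile"]


@dataclass(frozen=True)
class SplineGrid:
    """Uniform B-spline grid: range, interior interval count G, degree k."""

    g_lo: float = -3.0
    g_hi: float = 3.0
    G: int = 5
    k: int = 3

    def __post_init__(self) -> None:
        if not self.g_lo < self.g_hi:
            raise ValueError("grid range must satisfy g_lo < g_hi")
        if self.G < 1:
            raise ValueError("degenerate grid: need at least one interior interval")
        if self.k < 0:
            raise ValueError("spline order must be non-negative")

    @property
    def n_basis(self) -> int:
        return self.G + self.k

    @property
    def knots(self) -> np.ndarray:
        """Uniform knot vector extended by k intervals on each side (G+2k+1 knots)."""
        h = (self.g_hi - self.g_lo) / self.G
        return self.g_lo + h * np.arange(-self.k, self.G + self.k + 1)


def bspline_design(x: np.ndarray, grid: SplineGrid,
                   with_derivative: bool = False):
    """Evaluate all degree-k basis functions (and optionally d/dx) at ``x``.

    Returns an array of shape ``x.shape + (G+k,)``; columns are
    non-negative and sum to 1 for x inside [g_lo, g_hi].
    """
    x = np.asarray(x, dtype=float)
    flat = x.reshape(-1)
    t = grid.knots
    k = grid.k
    # degree-0: half-open interval indicators on the extended knots
    B = ((t[:-1][None, :] <= flat[:, None]) & (flat[:, None] < t[1:][None, :])
         ).astype(float)
    B_prev = None
    for d in range(1, k + 1):
        B_prev = B
        left = (flat[:, None] - t[None, :-(d + 1)]) / (t[d:-1] - t[:-(d + 1)])[None, :]
        right = (t[None, d + 1:] - flat[:, None]) / (t[d + 1:] - t[1:-d])[None, :]
        B = left * B[:, :-1] + right * B[:, 1:]
    if k == 0:
        basis = B.reshape(*x.shape, grid.n_basis)
        if with_derivative:
            return basis, np.zeros_like(basis)
        return basis
    basis = B.reshape(*x.shape, grid.n_basis)
    if not with_derivative:
        return basis
    # d/dx B_{i,k} = k ( B_{i,k-1}/(t_{i+k}-t_i) − B_{i+1,k-1}/(t_{i+k+1}-t_{i+1}) )
    denom_l = (t[k:-1] - t[:-(k + 1)])
    denom_r = (t[k + 1:] - t[1:-k])
    dB = k * (B_prev[:, :-1] / denom_l[None, :] - B_prev[:, 1:] / denom_r[None, :])
    return basis, dB.reshape(*x.shape, grid.n_basis)


def bspline_basis(x: float, grid: SplineGrid) -> np.ndarray:
    """Basis vector (length G+k) at a single scalar x."""
    if not np.isfinite(x):
        raise ValueError("x must be finite")
    return bspline_design(np.array([x]), grid)[0]


def _bspline_tensor(x: Tensor, grid: SplineGrid) -> Tensor:
    """Autodiff-aware design matrix: (n, in) -> (n, in, G+k)."""
    basis, deriv = bspline_design(x.data, grid, with_derivative=True)

    def backward(grad_out):
        return [(grad_out * deriv).sum(axis=-1)]

    return Tensor.custom(basis, (x,), backward)


class KANLayer(Module):
    """One KAN layer: per-edge spline activations summed into output units."""

    def __init__(self, in_dim: int, out_dim: int, grid: SplineGrid = SplineGrid(),
                 rng: np.random.Generator | None = None, coef_sigma: float = 0.1):
        if in_dim < 1 or out_dim < 1:
            raise ValueError("dimensions must be positive")
        rng = rng or np.random.default_rng(0)
        self.in_dim = in_dim
        self.out_dim = out_dim
        self.grid = grid
        self.coef = Parameter(rng.normal(0.0, coef_sigma,
                                         (in_dim, out_dim, grid.n_basis)))
        self.base_weight = Parameter(
            rng.normal(0.0, np.sqrt(2.0 / (in_dim + out_dim)), (in_dim, out_dim)))
        self.spline_weight = Parameter(np.ones((in_dim, out_dim)))

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.in_dim:
            raise ValueError(f"expected {self.in_dim} input columns, got {x.shape[-1]}")
        base = x.silu() @ self.base_weight
        B = _bspline_tensor(x, self.grid)                       # (n, in, nb)
        nb = self.grid.n_basis
        # fold spline weights into the coefficient tensor, then one matmul
        w = self.spline_weight.reshape(self.in_dim, self.out_dim, 1)
        Cw = (w * self.coef).transpose(0, 2, 1).reshape(self.in_dim * nb, self.out_dim)
        spline = B.reshape(-1, self.in_dim * nb) @ Cw
        return base + spline


def activation_profile(layer: KANLayer, edge: tuple[int, int],
                       xs: np.ndarray) -> np.ndarray:
    """Sample the learned edge activation phi_ij over ``xs`` (plot-ready)."""
    i, j = edge
    if not (0 <= i < layer.in_dim and 0 <= j < layer.out_dim):
        raise IndexError(f"edge {edge} out of range for "
                         f"{layer.in_dim}x{layer.out_dim} layer")
    xs = np.asarray(xs, float)
    silu = xs / (1.0 + np.exp(-xs))
    B = bspline_design(xs, layer.grid)
    spline = B @ layer.coef.data[i, j]
    return layer.base_weight.data[i, j] * silu + layer.spline_weight.data[i, j] * spline


class ResKANBlock(Module):
    """Pre-norm residual KAN block with a projection skip when dims differ."""

    def __init__(self, in_dim: int, out_dim: int, grid: SplineGrid = SplineGrid(),
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.norm = LayerNorm(in_dim)
        self.layer = KANLayer(in_dim, out_dim, grid, rng)
        self.skip = None if in_dim == out_dim else Linear(in_dim, out_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        shortcut = x if self.skip is None else self.skip(x)
        return shortcut + self.layer(self.norm(x))
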