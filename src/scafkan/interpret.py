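"""Model interpretation: Shapley attribution, local surrogates, activations.

Global attribution follows the kernel-weighted coalition-sampling view of
Shapley values: a coalition S is scored as the model's mean output when
the features in S take the patient's values and the rest are drawn from a
background set; coalitions are sampled from the Shapley kernel
distribution (antithetically, with their complements) and a constrained
least-squares fit recovers per-feature contributions.  The sum constraint
is built into the solve, so local accuracy — contributions summing to
prediction minus background mean — holds exactly for every patient.

``exact_shapley`` enumerates all 2^m coalitions and is practical for small
m; it doubles as an independent check on the sampled estimator.

Local explanations fit a distance-kernel-weighted sparse linear surrogate
to model outputs on Gaussian perturbations around one patient (the LIME
recipe).  Activation reports sample the learned input-layer KAN edge
activations over each feature's observed range.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Callable, Optional, Sequence

import numpy as np

from .kan import activation_profile

__all__ = ["AttributionReport", "LocalExplanation", "global_attribution",
           "exact_shapley", "local_explanation", "select_top_features",
           "activation_report"]

PredictFn = Callable[[np.ndarray], np.ndarray]


@dataclass
class AttributionReport:
    """Per-patient Shapley attributions plus the global ranking."""

    feature_names: list[str]
    attributions: np.ndarray        # (n_patients, m)
    predictions: np.ndarray         # model output per patient
    base_value: float               # mean model output over the background
    budget: int
    seed: int

    @property
    def global_importance(self) -> np.ndarray:
        """Mean |attribution| per feature across patients."""
        return np.abs(self.attributions).mean(axis=0)

    def ranking(self) -> list[tuple[str, float]]:
        imp = self.global_importance
        order = np.argsort(-imp, kind="stable")    # ties: canonical order
        return [(self.feature_names[j], float(imp[j])) for j in order]

    def local_accuracy_error(self) -> np.ndarray:
        return np.abs(self.attributions.sum(axis=1)
                      - (self.predictions - self.base_value))


def _coalition_values(predict: PredictFn, x: np.ndarray,
                      background: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """v(S) for each coalition row of Z: mean prediction with features in S
    set to the patient's values and the rest to background rows."""
    n_bg = len(background)
    vals = np.empty(len(Z))
    for i, z in enumerate(Z):
        hybrid = background.copy()
        hybrid[:, z.astype(bool)] = x[z.astype(bool)]
        vals[i] = predict(hybrid).mean()
    return vals


def _solve_constrained(Z: np.ndarray, v: np.ndarray, v0: float,
                       fx: float) -> np.ndarray:
    """Least squares for phi with sum(phi) = fx - v0 enforced exactly."""
    m = Z.shape[1]
    total = fx - v0
    y = (v - v0) - Z[:, -1] * total
    A = Z[:, :-1] - Z[:, -1:]
    phi_head, *_ = np.linalg.lstsq(A, y, rcond=None)
    return np.append(phi_head, total - phi_head.sum())


def _sample_coalitions(m: int, budget: int, rng: np.random.Generator) -> np.ndarray:
    """Draw coalitions (excluding empty/full) from the Shapley kernel
    distribution over sizes, pairing each with its complement."""
    sizes = np.arange(1, m)
    size_w = (m - 1) / (sizes * (m - sizes))      # kernel weight aggregated per size
    size_p = size_w / size_w.sum()
    n_pairs = max(budget // 2, m)
    Z = np.zeros((2 * n_pairs, m))
    for i in range(n_pairs):
        s = rng.choice(sizes, p=size_p)
        idx = rng.choice(m, size=s, replace=False)
        Z[2 * i, idx] = 1.0
        Z[2 * i + 1] = 1.0 - Z[2 * i]
    return Z


def shapley_sample(predict: PredictFn, x: np.ndarray, background: np.ndarray,
                   budget: int, rng: np.random.Generator) -> tuple[np.ndarray, float, float]:
    """Sampled Shapley attribution for one patient.

    Returns (phi, base_value, prediction).
    """
    m = len(x)
    v0 = float(predict(background).mean())
    fx = float(predict(x[None, :])[0])
    Z = _sample_coalitions(m, budget, rng)
    v = _coalition_values(predict, x, background, Z)
    return _solve_constrained(Z, v, v0, fx), v0, fx


def exact_shapley(predict: PredictFn, x: np.ndarray,
                  background: np.ndarray) -> np.ndarray:
    """Shapley values by full coalition enumeration (feasible for small m)."""
    m = len(x)
    if m > 16:
        raise ValueError("exact enumeration is exponential; m > 16 refused")
    # cache v(S) for all subsets
    v = np.empty(2 ** m)
    for code in range(2 ** m):
        z = np.array([(code >> j) & 1 for j in range(m)], float)
        v[code] = _coalition_values(predict, x, background, z[None, :])[0]
    phi = np.zeros(m)
    for j in range(m):
        for code in range(2 ** m):
            if (code >> j) & 1:
                continue
            s = bin(code).count("1")
            w = 1.0 / (m * comb(m - 1, s))
            phi[j] += w * (v[code | (1 << j)] - v[code])
    return phi


def global_attribution(predict: PredictFn, data: np.ndarray,
                       background: np.ndarray,
                       feature_names: Optional[Sequence[str]] = None,
                       budget: int = 2048, seed: int = 0,
                       max_background: int = 100) -> AttributionReport:
    """Shapley attribution for every row of ``data``; global importance is
    the mean absolute attribution per feature."""
    data = np.atleast_2d(np.asarray(data, float))
    background = np.atleast_2d(np.asarray(background, float))
    if len(background) == 0:
        raise ValueError("background set must be non-empty")
    m = data.shape[1]
    if budget < m + 2:
        raise ValueError(f"budget {budget} too small for {m} features")
    if len(background) > max_background:
        sub = np.random.default_rng(seed).choice(len(background),
                                                 max_background, replace=False)
        background = background[sub]
    rng = np.random.default_rng(seed)
    attr = np.empty_like(data)
    preds = np.empty(len(data))
    base = float(predict(background).mean())
    for i, x in enumerate(data):
        phi, _, fx = shapley_sample(predict, x, background, budget, rng)
        attr[i] = phi
        preds[i] = fx
    names = list(feature_names) if feature_names is not None else \
        [f"x{j}" for j in range(m)]
    return AttributionReport(names, attr, preds, base, budget, seed)


def select_top_features(report: AttributionReport, k: int) -> list[str]:
    """Top-k features by global importance; ties break by canonical order."""
    if not 1 <= k <= len(report.feature_names):
        raise ValueError("k out of range")
    return [name for name, _ in report.ranking()[:k]]


@dataclass
class LocalExplanation:
    """Sparse linear surrogate around one patient."""

    patient_index: int
    feature_names: list[str]
    weights: np.ndarray            # dense vector, at most k nonzeros
    intercept: float
    r_squared: float               # kernel-weighted fit quality
    kernel_width: float
    n_perturb: int
    seed: int

    def top_terms(self) -> list[tuple[str, float]]:
        nz = np.flatnonzero(self.weights)
        order = nz[np.argsort(-np.abs(self.weights[nz]), kind="stable")]
        return [(self.feature_names[j], float(self.weights[j])) for j in order]


def local_explanation(predict: PredictFn, x: np.ndarray,
                      feature_names: Optional[Sequence[str]] = None,
                      n_perturb: int = 1000,
                      kernel_width: Optional[float] = None,
                      n_features: int = 10, seed: int = 0,
                      scales: Optional[np.ndarray] = None,
                      patient_index: int = 0) -> LocalExplanation:
    """LIME-style explanation: weighted sparse linear fit on perturbations."""
    x = np.asarray(x, float)
    m = len(x)
    if n_perturb < m + 2:
        raise ValueError("need more perturbations than features")
    scales = np.ones(m) if scales is None else np.asarray(scales, float)
    if not np.any(scales > 0):
        raise ValueError("zero-variance perturbations: all scales are zero")
    rng = np.random.default_rng(seed)
    P = x + rng.standard_normal((n_perturb, m)) * scales
    yp = predict(P)
    d = np.sqrt((((P - x) / np.where(scales > 0, scales, 1.0)) ** 2).sum(axis=1))
    width = kernel_width if kernel_width is not None else np.sqrt(m) * 0.75
    w = np.exp(-(d ** 2) / (width ** 2))

    def weighted_fit(cols: np.ndarray) -> tuple[np.ndarray, float]:
        A = np.column_stack([np.ones(n_perturb), P[:, cols]])
        Aw = A * np.sqrt(w)[:, None]
        yw = yp * np.sqrt(w)
        # tiny ridge keeps the solve stable when perturbations are collinear
        coef = np.linalg.solve(Aw.T @ Aw + 1e-8 * np.eye(A.shape[1]), Aw.T @ yw)
        return coef[0], coef[1:]

    # rank all features by a full weighted ridge fit, keep the top k, refit
    _, full_beta = weighted_fit(np.arange(m))
    keep = np.argsort(-np.abs(full_beta), kind="stable")[:min(n_features, m)]
    intercept, beta = weighted_fit(np.sort(keep))
    weights = np.zeros(m)
    weights[np.sort(keep)] = beta
    fitted = intercept + P @ weights
    ss_res = float((w * (yp - fitted) ** 2).sum())
    ybar = float((w * yp).sum() / w.sum())
    ss_tot = float((w * (yp - ybar) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    names = list(feature_names) if feature_names is not None else \
        [f"x{j}" for j in range(m)]
    return LocalExplanation(patient_index, names, weights, float(intercept),
                            r2, width, n_perturb, seed)


def activation_report(fusion_net, data: np.ndarray,
                      feature_names: Sequence[str],
                      top_features: Sequence[str],
                      n_samples: int = 100) -> dict[str, dict]:
    """Input-layer KAN edge activations across each feature's observed range.

    Returns plot-ready tables: per listed feature, the sample grid and one
    activation curve per output unit of the first KAN layer.
    """
    layer = fusion_net.kan_path.blocks[0].layer
    data = np.asarray(data, float)
    names = list(feature_names)
    out = {}
    for feat in top_features:
        i = names.index(feat)
        lo, hi = data[:, i].min(), data[:, i].max()
        xs = np.linspace(lo, hi, n_samples)
        profiles = np.stack([activation_profile(layer, (i, j), xs)
                             for j in range(layer.out_dim)])
        out[feat] = {"x": xs, "profiles": profiles}
    return out
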