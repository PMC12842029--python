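"""Leakage-safe preprocessing for clinical tables.

Pipeline (fitted on a training split only, then frozen):

1. ``log1p`` of the right-skewed markers (default NT-proBNP, CRP).
2. Chained-equations imputation: iterated per-feature ridge regressions on
   all other features, initialised from training means, run until the
   imputed values stabilise or a maximum iteration count is reached.
3. Binary features are imputed on the continuous scale then rounded to
   {0, 1}; by default they are left 0/1 rather than z-scored so attribution
   signs stay interpretable.
4. z-standardisation of continuous features with training center/scale.

The fitted state carries a fingerprint of the training rows so an
evaluation harness can assert that no held-out row leaked into the fit.
Minority oversampling (SMOTE-style segment interpolation) is provided for
training folds only.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.linear_model import Ridge
from sklearn.neighbors import NearestNeighbors

from .cohort import CohortTable
from .schema import SKEWED_FEATURES

__all__ = ["PreprocessState", "ResampleConfig", "fit_preprocessor",
           "apply_preprocessor", "oversample_minority"]

_MAX_ITER = 10
_TOL = 1e-3


def _rows_fingerprint(values: np.ndarray, labels: np.ndarray, fold_id: str) -> str:
    h = hashlib.sha256()
    h.update(fold_id.encode())
    h.update(np.ascontiguousarray(np.nan_to_num(values, nan=-1e30)).tobytes())
    h.update(np.ascontiguousarray(labels).tobytes())
    return h.hexdigest()[:16]


@dataclass
class PreprocessState:
    """Frozen preprocessing parameters fitted on one training split."""

    feature_names: list[str]
    binary_mask: np.ndarray          # per-feature, True for 0/1 flags
    log1p_features: list[str]
    center: np.ndarray               # per-feature center on transformed scale
    scale: np.ndarray                # per-feature scale (1.0 for binaries unless configured)
    imputation_coefs: list[Optional[dict]]   # per-feature {"coef": [...], "intercept": f} or None
    imputation_iters: int
    column_means: np.ndarray         # transformed-scale means used to seed imputation
    standardize_binary: bool
    fingerprint: str

    def __post_init__(self) -> None:
        if np.any(self.scale <= 0):
            raise ValueError("all scales must be positive")

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        def ser(c):
            return None if c is None else {"coef": list(map(float, c["coef"])),
                                           "intercept": float(c["intercept"])}
        return json.dumps({
            "feature_names": self.feature_names,
            "binary_mask": self.binary_mask.astype(int).tolist(),
            "log1p_features": self.log1p_features,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "imputation_coefs": [ser(c) for c in self.imputation_coefs],
            "imputation_iters": self.imputation_iters,
            "column_means": self.column_means.tolist(),
            "standardize_binary": self.standardize_binary,
            "fingerprint": self.fingerprint,
        })

    @classmethod
    def from_json(cls, text: str) -> "PreprocessState":
        d = json.loads(text)
        return cls(
            feature_names=d["feature_names"],
            binary_mask=np.array(d["binary_mask"], bool),
            log1p_features=d["log1p_features"],
            center=np.array(d["center"], float),
            scale=np.array(d["scale"], float),
            imputation_coefs=d["imputation_coefs"],
            imputation_iters=d["imputation_iters"],
            column_means=np.array(d["column_means"], float),
            standardize_binary=d["standardize_binary"],
            fingerprint=d["fingerprint"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "PreprocessState":
        return cls.from_json(Path(path).read_text())


def _log_transform(values: np.ndarray, names: Sequence[str],
                   log1p_features: Sequence[str]) -> np.ndarray:
    out = values.copy()
    for f in log1p_features:
        j = list(names).index(f)
        out[:, j] = np.log1p(out[:, j])
    return out


def _chained_impute(X: np.ndarray, coefs: list[Optional[dict]],
                    col_means: np.ndarray, n_iter: int) -> np.ndarray:
    """Apply frozen per-feature ridge equations to fill NaNs."""
    mask = np.isnan(X)
    if not mask.any():
        return X.copy()
    filled = np.where(mask, col_means, X)
    for _ in range(max(n_iter, 1)):
        prev = filled.copy()
        for j in range(X.shape[1]):
            if not mask[:, j].any():
                continue
            c = coefs[j]
            if c is None:       # feature was fully observed at fit time but is
                continue        # missing now: keep the training-mean fill
            others = np.delete(filled, j, axis=1)
            pred = others @ np.asarray(c["coef"]) + c["intercept"]
            filled[mask[:, j], j] = pred[mask[:, j]]
        if np.max(np.abs(filled - prev)) < _TOL:
            break
    return filled


def fit_preprocessor(train: CohortTable,
                     log1p_features: Sequence[str] = SKEWED_FEATURES,
                     standardize_binary: bool = False,
                     fold_id: str = "train") -> PreprocessState:
    """Fit imputation, transforms, and standardisation on a training split."""
    y = train.labels
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("training split needs >= 2 rows per class")
    names = train.feature_names
    raw = train.values
    fully_missing = np.isnan(raw).all(axis=0)
    if fully_missing.any():
        bad = [names[j] for j in np.flatnonzero(fully_missing)]
        raise ValueError(f"feature(s) fully missing in training split: {bad}")

    X = _log_transform(raw, names, log1p_features)
    mask = np.isnan(X)
    col_means = np.nanmean(X, axis=0)

    # chained-equations fit: iterate ridge regressions feature-by-feature
    filled = np.where(mask, col_means, X)
    coefs: list[Optional[dict]] = [None] * X.shape[1]
    iters_used = 0
    if mask.any():
        for it in range(_MAX_ITER):
            prev = filled.copy()
            for j in range(X.shape[1]):
                if not mask[:, j].any():
                    continue
                obs = ~mask[:, j]
                others = np.delete(filled, j, axis=1)
                model = Ridge(alpha=1.0)
                model.fit(others[obs], X[obs, j])
                coefs[j] = {"coef": model.coef_.tolist(),
                            "intercept": float(model.intercept_)}
                filled[mask[:, j], j] = model.predict(others[mask[:, j]])
            iters_used = it + 1
            if np.max(np.abs(filled - prev)) < _TOL:
                break
        # canonical fill: replay the frozen equations so that apply() on the
        # training split reproduces the fitted matrix exactly
        filled = _chained_impute(X, coefs, col_means, iters_used)

    binary_mask = np.array([s.kind == "binary" for s in train.schema])
    filled[:, binary_mask] = np.clip(np.round(filled[:, binary_mask]), 0, 1)

    center = filled.mean(axis=0)
    sd = filled.std(axis=0, ddof=0)
    scale = np.where(sd > 0, sd, 1.0)
    if not standardize_binary:
        center = np.where(binary_mask, 0.0, center)
        scale = np.where(binary_mask, 1.0, scale)

    return PreprocessState(
        feature_names=list(names),
        binary_mask=binary_mask,
        log1p_features=list(log1p_features),
        center=center,
        scale=scale,
        imputation_coefs=coefs,
        imputation_iters=iters_used,
        column_means=col_means,
        standardize_binary=standardize_binary,
        fingerprint=_rows_fingerprint(raw, y, fold_id),
    )


def apply_preprocessor(state: PreprocessState, table: CohortTable) -> np.ndarray:
    """Transform a table with frozen parameters; output has no missing cells."""
    if table.feature_names != state.feature_names:
        raise ValueError("table schema does not match preprocessor state")
    X = _log_transform(table.values, state.feature_names, state.log1p_features)
    X = _chained_impute(X, state.imputation_coefs, state.column_means,
                        state.imputation_iters)
    X[:, state.binary_mask] = np.clip(np.round(X[:, state.binary_mask]), 0, 1)
    return (X - state.center) / state.scale


@dataclass(frozen=True)
class ResampleConfig:
    """Settings for minority oversampling (segment interpolation)."""

    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def oversample_minority(X: np.ndarray, y: np.ndarray,
                        cfg: ResampleConfig = ResampleConfig()) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by interpolating synthetic minority rows.

    Each synthetic row lies on the segment between a minority row and one of
    its ``k`` nearest minority neighbours; originals are preserved verbatim.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("oversampling requires exactly two classes")
    if counts[0] == counts[1]:
        return X, y
    minority = classes[np.argmin(counts)]
    n_needed = int(abs(counts[0] - counts[1]))
    Xm = X[y == minority]
    if cfg.k_neighbors >= len(Xm):
        raise ValueError("k_neighbors must be smaller than the minority class size")
    nn = NearestNeighbors(n_neighbors=cfg.k_neighbors + 1).fit(Xm)
    _, idx = nn.kneighbors(Xm)          # idx[:, 0] is the point itself
    rng = np.random.default_rng(cfg.seed)
    base = rng.integers(len(Xm), size=n_needed)
    pick = rng.integers(1, cfg.k_neighbors + 1, size=n_needed)
    t = rng.random((n_needed, 1))
    neighbors = Xm[idx[base, pick]]
    synthetic = Xm[base] + t * (neighbors - Xm[base])
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_needed, minority)])
    return X_out, y_out
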