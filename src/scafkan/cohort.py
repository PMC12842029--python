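"""Synthetic CIED cohort generation.

Draws patient tables whose marginal statistics match the development
cohort's published arm summaries: labels at a configured SCAF prevalence,
continuous features per arm from truncated Gaussians (log-normal for the
right-skewed markers NT-proBNP and CRP, parameterized so the back-transformed
mean/SD match the configured values), and binary flags per arm at the
configured event probabilities.  Missing-at-random gaps can be injected
afterwards.  Everything is reproducible from a single integer seed.

Joint structure is identity by default (the source summaries are marginal);
an optional latent-Gaussian correlation hook exists for sensitivity work.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .schema import (CANONICAL_SCHEMA, FEATURE_NAMES, LABEL_NAME, FeatureSpec,
                     null_schema)

__all__ = ["CohortConfig", "CohortTable", "generate_cohort",
           "generate_planted_cohort", "inject_missingness"]

#: development cohort SCAF prevalence (39 of 124 patients)
DEV_PREVALENCE = 39 / 124
#: external validation cohort SCAF prevalence (10 of 35 patients)
EXTERNAL_PREVALENCE = 10 / 35


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort draw."""

    n_patients: int = 124
    prevalence: float = DEV_PREVALENCE
    missing_rate: float = 0.0
    seed: int = 0
    schema: tuple[FeatureSpec, ...] = CANONICAL_SCHEMA
    #: optional latent correlation matrix over continuous features (identity = independent)
    correlation: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.n_patients < 10:
            raise ValueError("n_patients < 10 gives degenerate folds; refusing")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.prevalence * self.n_patients < 2:
            raise ValueError("expected positive count < 2; refusing")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")

    def fingerprint(self) -> str:
        payload = {
            "n": self.n_patients,
            "prev": self.prevalence,
            "missing": self.missing_rate,
            "seed": self.seed,
            "features": [s.name for s in self.schema],
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class CohortTable:
    """Patients × features with labels, missingness mask, and provenance.

    ``values`` holds the observed matrix with NaN at masked cells; ``mask``
    is True where a cell is missing.  Column order always matches ``schema``.
    """

    values: np.ndarray
    labels: np.ndarray
    schema: tuple[FeatureSpec, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.shape != (len(self.labels), len(self.schema)):
            raise ValueError("values shape inconsistent with labels/schema")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def feature_names(self) -> list[str]:
        return [s.name for s in self.schema]

    @property
    def mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df[LABEL_NAME] = self.labels
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       schema: tuple[FeatureSpec, ...] = CANONICAL_SCHEMA,
                       provenance: dict | None = None) -> "CohortTable":
        names = [s.name for s in schema]
        missing_cols = [c for c in names + [LABEL_NAME] if c not in df.columns]
        if missing_cols:
            raise ValueError(f"dataframe lacks columns: {missing_cols}")
        return cls(df[names].to_numpy(dtype=float),
                   df[LABEL_NAME].to_numpy(dtype=int),
                   schema, provenance or {})

    def write_csv(self, path: str | Path) -> None:
        """CSV with empty cells for masked values plus a sidecar JSON schema."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False, na_rep="")
        sidecar = {
            "label": LABEL_NAME,
            "mask_encoding": "empty cell",
            "provenance": self.provenance,
            "features": [
                {"name": s.name, "unit": s.unit, "kind": s.kind, "group": s.group,
                 "skewed": s.skewed, "bounds": list(s.bounds)}
                for s in self.schema
            ],
        }
        path.with_suffix(path.suffix + ".schema.json").write_text(
            json.dumps(sidecar, indent=2))

    @classmethod
    def read_csv(cls, path: str | Path,
                 schema: tuple[FeatureSpec, ...] = CANONICAL_SCHEMA) -> "CohortTable":
        df = pd.read_csv(path)
        sidecar = Path(path).with_suffix(Path(path).suffix + ".schema.json")
        provenance = {}
        if sidecar.exists():
            provenance = json.loads(sidecar.read_text()).get("provenance", {})
        return cls.from_dataframe(df, schema, provenance)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Underlying normal (mu, sigma) so the log-normal has the given mean/SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def generate_cohort(config: CohortConfig) -> CohortTable:
    """Draw one synthetic cohort.

    Labels are iid Bernoulli at the configured prevalence.  Continuous
    features are drawn per arm from a Gaussian (log-normal for skewed
    markers) and clipped to physiologic bounds; binary flags per arm at the
    configured probabilities.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    y = (rng.random(n) < config.prevalence).astype(int)

    p = len(config.schema)
    X = np.empty((n, p))
    cont_idx = [j for j, s in enumerate(config.schema) if s.kind == "continuous"]

    # latent standard-normal draws, optionally correlated across continuous features
    z = rng.standard_normal((n, len(cont_idx)))
    if config.correlation is not None:
        C = np.asarray(config.correlation, float)
        if C.shape != (len(cont_idx), len(cont_idx)):
            raise ValueError("correlation matrix must be square over continuous features")
        z = z @ np.linalg.cholesky(C).T

    zcol = {j: k for k, j in enumerate(cont_idx)}
    for j, spec in enumerate(config.schema):
        if spec.kind == "binary":
            prob = np.where(y == 1, spec.scaf_loc, spec.nonscaf_loc)
            X[:, j] = (rng.random(n) < prob).astype(float)
            continue
        zj = z[:, zcol[j]]
        col = np.empty(n)
        for arm, (m, s) in ((1, (spec.scaf_loc, spec.scaf_scale)),
                            (0, (spec.nonscaf_loc, spec.nonscaf_scale))):
            sel = y == arm
            if spec.skewed:
                mu, sigma = _lognormal_params(m, s)
                col[sel] = np.exp(mu + sigma * zj[sel])
            else:
                col[sel] = m + s * zj[sel]
        X[:, j] = np.clip(col, *spec.bounds)

    table = CohortTable(X, y, config.schema,
                        provenance={"seed": config.seed,
                                    "config_hash": config.fingerprint()})
    if config.missing_rate > 0:
        # derived stream keeps the masking independent of the value draws
        table = inject_missingness(table, config.missing_rate,
                                   seed=int(rng.integers(2**31)))
    return table


def generate_planted_cohort(n_patients: int = 124,
                            prevalence: float = DEV_PREVALENCE,
                            seed: int = 0,
                            lad_weight: float = 2.2,
                            threshold_weight: float = 1.5,
                            interaction_weight: float = 1.0) -> CohortTable:
    """Cohort with a known LAD-dominant nonlinear decision rule.

    Features come from the pooled-cohort marginals with *identical* arms, so
    they carry no intrinsic label signal; labels are then drawn from

        logit(risk) = b0 + w1·z_LAD + w2·max(z_LAD − 0.5, 0)
                      + w3·z_LAD·z_{septal E/e'}

    (a smooth increasing left-atrial-diameter effect with a threshold kink
    plus a diastolic-function interaction), with b0 calibrated so the
    realised prevalence matches the target.  Used for planted-signal
    recovery and capacity checks.
    """
    base_cfg = CohortConfig(n_patients=n_patients, prevalence=0.5, seed=seed,
                            schema=null_schema())
    table = generate_cohort(base_cfg)
    names = table.feature_names
    z_lad = (table.values[:, names.index("lad")] - 41.5) / 4.7
    z_see = (table.values[:, names.index("septal_e_over_e_prime")] - 12.4) / 6.5
    raw = (lad_weight * z_lad + threshold_weight * np.maximum(z_lad - 0.5, 0.0)
           + interaction_weight * z_lad * z_see)

    def realised(b0):
        return float((1.0 / (1.0 + np.exp(-(b0 + raw)))).mean())

    lo, hi = -20.0, 20.0
    for _ in range(60):          # bisection on the intercept
        mid = (lo + hi) / 2
        if realised(mid) < prevalence:
            lo = mid
        else:
            hi = mid
    prob = 1.0 / (1.0 + np.exp(-((lo + hi) / 2 + raw)))
    rng = np.random.default_rng(seed + 10_000)
    y = (rng.random(n_patients) < prob).astype(int)
    if y.sum() < 2 or y.sum() > n_patients - 2:
        raise RuntimeError("planted labels degenerate; adjust weights")
    prov = dict(table.provenance)
    prov["planted"] = {"lad_weight": lad_weight,
                       "threshold_weight": threshold_weight,
                       "interaction_weight": interaction_weight}
    return CohortTable(table.values, y, table.schema, prov)


def inject_missingness(table: CohortTable, rate: float, seed: int) -> CohortTable:
    """Mask each feature cell independently with probability ``rate`` (MCAR).

    Labels are never masked.  Original values at masked cells are discarded
    (set to NaN).
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("missing rate must lie in [0, 1)")
    if rate == 0.0:
        return table
    rng = np.random.default_rng(seed)
    mask = rng.random(table.values.shape) < rate
    values = table.values.copy()
    values[mask] = np.nan
    prov = dict(table.provenance)
    prov["missing_rate"] = rate
    prov["missing_seed"] = seed
    return CohortTable(values, table.labels.copy(), table.schema, prov)
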