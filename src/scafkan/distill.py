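"""Knowledge distillation to a 10-feature clinical logistic risk score.

The teacher is any model producing SCAF probabilities on a cohort; the
student is a logistic regression on raw clinical units (LDH enters as
ln(LDH+1)) so its fitted coefficients export directly as a bedside
formula.  The student minimises

    alpha * T^2 * CE(teacher probs softened at temperature T, student)
      + (1 - alpha) * CE(true labels, student)

with both cross-entropies evaluated on temperature-scaled logits.  At
alpha=0 this reduces to a plain label fit; at alpha=1, T=1, distilling a
logistic teacher on the same features recovers its coefficients exactly
(the soft cross-entropy is minimised pointwise).

A frozen, read-only fixture of the published 10-feature score ships with
the package (``RiskScoreModel.published()``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import pearsonr

from .cohort import CohortTable
from .metrics import roc_auc

__all__ = ["RiskScoreModel", "DistillConfig", "FidelityReport",
           "distill_student", "fidelity"]

_TRANSFORMS = {
    "identity": lambda v: v,
    "log1p": np.log1p,
}

#: schema features treated as 0/1 indicators when scoring raw inputs
_BINARY_FEATURES = {"male_gender", "hypertension", "diabetes",
                    "coronary_heart_disease", "aortic_valve_disease",
                    "mitral_valve_disease", "tricuspid_valve_disease"}


@dataclass(frozen=True)
class RiskScoreModel:
    """Linear risk score: ordered features, transforms, coefficients."""

    features: tuple[str, ...]
    transforms: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    threshold: float = 0.5
    version: str = "fitted"

    def __post_init__(self) -> None:
        if not (len(self.features) == len(self.transforms)
                == len(self.coefficients)):
            raise ValueError("features, transforms, coefficients must align")
        for t in self.transforms:
            if t not in _TRANSFORMS:
                raise ValueError(f"unknown transform {t!r}")

    @classmethod
    def published(cls) -> "RiskScoreModel":
        """The frozen published 10-feature SCAF risk score."""
        text = resources.files("scafkan").joinpath(
            "data/published_risk_score.json").read_text()
        return cls.from_json(text, version="published")

    # -- scoring -----------------------------------------------------------
    def _validate_row(self, row: dict[str, float]) -> np.ndarray:
        vals = np.empty(len(self.features))
        for i, (name, transform) in enumerate(zip(self.features, self.transforms)):
            if name not in row or row[name] is None or \
                    (isinstance(row[name], float) and np.isnan(row[name])):
                raise ValueError(f"missing feature: {name}")
            v = float(row[name])
            if name in _BINARY_FEATURES and v not in (0.0, 1.0):
                raise ValueError(f"non-binary indicator value for {name}: {v}")
            if transform == "log1p" and v <= -1.0:
                raise ValueError(f"{name} must exceed -1 for the log transform")
            vals[i] = _TRANSFORMS[transform](v)
        return vals

    def score(self, patient: dict[str, float]) -> tuple[float, float, bool]:
        """(linear score, probability, high-risk flag) for one raw-unit patient."""
        x = self._validate_row(patient)
        s = float(np.dot(self.coefficients, x) + self.intercept)
        p = float(expit(s))
        return s, p, p > self.threshold

    def design_matrix(self, table: CohortTable | np.ndarray,
                      feature_names: Optional[Sequence[str]] = None) -> np.ndarray:
        """Transformed raw-unit design matrix for the score's features."""
        if isinstance(table, CohortTable):
            values, names = table.values, table.feature_names
        else:
            values = np.asarray(table, float)
            names = list(feature_names)
        cols = []
        for name, transform in zip(self.features, self.transforms):
            j = names.index(name)
            cols.append(_TRANSFORMS[transform](values[:, j]))
        return np.column_stack(cols)

    def predict_proba(self, table: CohortTable | np.ndarray,
                      feature_names: Optional[Sequence[str]] = None) -> np.ndarray:
        Xt = self.design_matrix(table, feature_names)
        return expit(Xt @ np.asarray(self.coefficients) + self.intercept)

    def formula(self) -> str:
        parts = []
        for c, name, t in zip(self.coefficients, self.features, self.transforms):
            term = f"ln({name}+1)" if t == "log1p" else name
            parts.append(f"{c:+.6f}×{term}")
        return "score = " + " ".join(parts) + f" {self.intercept:+.6f}"

    # -- serialisation (round-trips bit-identically) -----------------------
    def to_json(self) -> str:
        return json.dumps({
            "version": self.version,
            "threshold": self.threshold,
            "intercept": self.intercept,
            "terms": [{"feature": f, "transform": t, "coef": c}
                      for f, t, c in zip(self.features, self.transforms,
                                         self.coefficients)],
        }, indent=2)

    @classmethod
    def from_json(cls, text: str, version: Optional[str] = None) -> "RiskScoreModel":
        d = json.loads(text)
        return cls(
            features=tuple(t["feature"] for t in d["terms"]),
            transforms=tuple(t["transform"] for t in d["terms"]),
            coefficients=tuple(float(t["coef"]) for t in d["terms"]),
            intercept=float(d["intercept"]),
            threshold=float(d.get("threshold", 0.5)),
            version=version or d.get("version", "fitted"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "RiskScoreModel":
        return cls.from_json(Path(path).read_text())


@dataclass(frozen=True)
class DistillConfig:
    """Soft/hard loss mixing for student training."""

    temperature: float = 2.0
    alpha: float = 0.7
    max_iter: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature < 1.0:
            raise ValueError("temperature must be >= 1")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


def distill_student(teacher_probs: np.ndarray, cohort: CohortTable,
                    features: Sequence[str],
                    cfg: DistillConfig = DistillConfig(),
                    transforms: Optional[Sequence[str]] = None) -> RiskScoreModel:
    """Fit the logistic student against teacher probabilities + true labels.

    ``teacher_probs`` must align with the cohort rows.  ``features`` is
    typically the top-10 global-attribution list; LDH defaults to the
    ln(value+1) transform, everything else to identity.
    """
    p_t = np.asarray(teacher_probs, float)
    y = cohort.labels.astype(float)
    if len(p_t) != cohort.n_patients:
        raise ValueError("teacher probabilities must align with cohort rows")
    if np.ptp(p_t) < 1e-12:
        warnings.warn("degenerate teacher (constant output); student reduces "
                      "to a label-only fit")
        cfg = DistillConfig(temperature=cfg.temperature, alpha=0.0,
                            max_iter=cfg.max_iter, seed=cfg.seed)
    if transforms is None:
        transforms = ["log1p" if f == "ldh" else "identity" for f in features]
    proto = RiskScoreModel(tuple(features), tuple(transforms),
                           tuple(0.0 for _ in features), 0.0)
    Xt = proto.design_matrix(cohort)
    if np.isnan(Xt).any():
        raise ValueError("cohort has missing values in the score features; "
                        "impute before distilling")

    # internal standardisation for conditioning; mapped back afterwards
    mu, sd = Xt.mean(axis=0), Xt.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (Xt - mu) / sd
    T, alpha = cfg.temperature, cfg.alpha
    eps = 1e-12
    p_clip = np.clip(p_t, eps, 1 - eps)
    q_soft = expit(logit(p_clip) / T)          # teacher softened at T

    def loss_grad(theta):
        b0, beta = theta[0], theta[1:]
        z = b0 + Z @ beta
        s_soft = expit(z / T)
        s_hard = expit(z)
        ce_soft = -(q_soft * np.log(s_soft + eps)
                    + (1 - q_soft) * np.log(1 - s_soft + eps)).mean()
        ce_hard = -(y * np.log(s_hard + eps)
                    + (1 - y) * np.log(1 - s_hard + eps)).mean()
        L = alpha * T * T * ce_soft + (1 - alpha) * ce_hard
        dz = (alpha * T * (s_soft - q_soft)
              + (1 - alpha) * (s_hard - y)) / len(y)
        g = np.concatenate([[dz.sum()], Z.T @ dz])
        return L, g

    theta0 = np.zeros(1 + Z.shape[1])
    res = minimize(loss_grad, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": cfg.max_iter, "ftol": 1e-14,
                            "gtol": 1e-10})
    b0, beta_z = res.x[0], res.x[1:]
    beta_raw = beta_z / sd
    intercept = float(b0 - np.dot(beta_z, mu / sd))
    return RiskScoreModel(tuple(features), tuple(transforms),
                          tuple(float(b) for b in beta_raw), intercept)


@dataclass(frozen=True)
class FidelityReport:
    """Teacher/student agreement on one evaluation split."""

    correlation: float
    mae: float
    teacher_auc: float
    student_auc: float
    auc_retention: float

    def summary(self) -> str:
        return ("teacher vs student fidelity\n"
                f"  Pearson r        {self.correlation: .4f}\n"
                f"  MAE              {self.mae: .4f}\n"
                f"  teacher AUC      {self.teacher_auc: .4f}\n"
                f"  student AUC      {self.student_auc: .4f}\n"
                f"  AUC retention    {self.auc_retention: .4f}")


def fidelity(teacher_probs: np.ndarray, student_probs: np.ndarray,
             labels: np.ndarray) -> FidelityReport:
    p_t = np.asarray(teacher_probs, float)
    p_s = np.asarray(student_probs, float)
    if p_t.shape != p_s.shape:
        raise ValueError("probability vectors must align")
    if np.ptp(p_t) < 1e-15 or np.ptp(p_s) < 1e-15:
        corr = 1.0 if np.allclose(p_t, p_s) else 0.0
    else:
        corr = float(pearsonr(p_t, p_s)[0])
    t_auc = roc_auc(labels, p_t)
    s_auc = roc_auc(labels, p_s)
    return FidelityReport(
        correlation=corr,
        mae=float(np.abs(p_t - p_s).mean()),
        teacher_auc=t_auc,
        student_auc=s_auc,
        auc_retention=s_auc / t_auc,
    )
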