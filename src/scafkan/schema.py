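"""Canonical clinical feature schema for the SCAF cohort.

The panel covers 27 routinely collected parameters in CIED (cardiac
implantable electronic device) patients: demographics, comorbidity flags,
biochemical markers, and transthoracic / tissue-Doppler echocardiographic
measures, plus a binary subclinical-AF (SCAF) outcome label.

Each :class:`FeatureSpec` carries the per-arm marginal statistics of the
development cohort (SCAF arm n=39, non-SCAF arm n=85): mean and SD for
continuous features, event probability for binary flags.  These are the
default parameters of the synthetic cohort generator.

Physiologic clip bounds are maintainer-chosen plausibility limits, not
cohort observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

__all__ = [
    "FeatureSpec",
    "CANONICAL_SCHEMA",
    "FEATURE_NAMES",
    "LABEL_NAME",
    "feature_by_name",
    "continuous_features",
    "binary_features",
    "SKEWED_FEATURES",
]

LABEL_NAME = "scaf"


@dataclass(frozen=True)
class FeatureSpec:
    """One clinical feature: identity, units, kind, and arm statistics.

    Parameters
    ----------
    name : str
        Canonical identifier (snake_case).
    unit : str
        Clinical unit; "" for dimensionless / binary flags.
    kind : {"continuous", "binary"}
    group : {"demographic", "comorbidity", "biochemical", "echocardiographic"}
    skewed : bool
        True for strongly right-skewed markers generated log-normally and
        log1p-transformed during preprocessing.
    bounds : (float, float)
        Physiologic clip range applied to generated values.
    scaf_loc, scaf_scale : float
        Mean and SD (continuous) in the SCAF arm; for binary features
        ``scaf_loc`` is the event probability and ``scaf_scale`` is None.
    nonscaf_loc, nonscaf_scale : float
        Same for the non-SCAF arm.
    """

    name: str
    unit: str
    kind: str
    group: str
    scaf_loc: float
    nonscaf_loc: float
    scaf_scale: Optional[float] = None
    nonscaf_scale: Optional[float] = None
    skewed: bool = False
    bounds: Tuple[float, float] = (-float("inf"), float("inf"))

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.skewed and self.kind != "continuous":
            raise ValueError(f"{self.name}: skewed implies continuous")
        lo, hi = self.bounds
        if not lo < hi:
            raise ValueError(f"{self.name}: bounds.lower must be < bounds.upper")
        if self.kind == "continuous":
            if self.scaf_scale is None or self.nonscaf_scale is None:
                raise ValueError(f"{self.name}: continuous feature needs scales")
            if self.scaf_scale <= 0 or self.nonscaf_scale <= 0:
                raise ValueError(f"{self.name}: scales must be positive")
        else:
            for p in (self.scaf_loc, self.nonscaf_loc):
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{self.name}: binary probability outside [0,1]")


def _cont(name, unit, group, scaf, nonscaf, bounds, skewed=False):
    return FeatureSpec(
        name=name, unit=unit, kind="continuous", group=group,
        scaf_loc=scaf[0], scaf_scale=scaf[1],
        nonscaf_loc=nonscaf[0], nonscaf_scale=nonscaf[1],
        skewed=skewed, bounds=bounds,
    )


def _flag(name, group, p_scaf, p_nonscaf):
    return FeatureSpec(
        name=name, unit="", kind="binary", group=group,
        scaf_loc=p_scaf, nonscaf_loc=p_nonscaf, bounds=(-0.5, 1.5),
    )


# Development cohort arm statistics: SCAF arm (n=39) vs non-SCAF arm (n=85).
CANONICAL_SCHEMA: tuple[FeatureSpec, ...] = (
    # demographics
    _cont("age", "years", "demographic", (72.9, 7.8), (71.5, 12.0), (18.0, 105.0)),
    _flag("male_gender", "demographic", 0.359, 0.635),
    _cont("bmi", "kg/m²", "demographic", (23.6, 4.2), (24.1, 3.4), (12.0, 60.0)),
    # comorbidities
    _flag("hypertension", "comorbidity", 0.615, 0.706),
    _flag("diabetes", "comorbidity", 0.256, 0.329),
    _flag("coronary_heart_disease", "comorbidity", 0.154, 0.318),
    _flag("aortic_valve_disease", "comorbidity", 0.051, 0.047),
    _flag("mitral_valve_disease", "comorbidity", 0.128, 0.012),
    _flag("tricuspid_valve_disease", "comorbidity", 0.128, 0.047),
    # biochemical markers
    _cont("nt_probnp", "pg/mL", "biochemical", (926.2, 1271.3), (393.8, 620.0),
          (1.0, 35000.0), skewed=True),
    _cont("hs_tni", "pg/mL", "biochemical", (25.9, 56.3), (183.3, 1465.3), (0.1, 50000.0)),
    _cont("crp", "mg/L", "biochemical", (4.0, 6.2), (13.1, 27.3), (0.1, 300.0),
          skewed=True),
    _cont("myoglobin", "ng/mL", "biochemical", (29.3, 14.6), (32.9, 23.3), (1.0, 500.0)),
    _cont("ck_mb", "ng/mL", "biochemical", (1.8, 1.5), (1.8, 1.3), (0.1, 50.0)),
    _cont("ldh", "IU/L", "biochemical", (224.1, 50.5), (215.6, 81.3), (50.0, 1500.0)),
    _cont("lp_a", "g/L", "biochemical", (0.3, 0.2), (0.2, 0.2), (0.005, 3.0)),
    _cont("ldl_c", "mmol/L", "biochemical", (2.4, 0.9), (2.2, 0.9), (0.3, 10.0)),
    _cont("serum_creatinine", "µmol/L", "biochemical", (83.5, 29.8), (82.9, 23.6),
          (20.0, 600.0)),
    _cont("egfr", "mL/min/1.73 m²", "biochemical", (71.7, 19.1), (76.4, 17.1),
          (5.0, 150.0)),
    # echocardiographic
    _cont("lad", "mm", "echocardiographic", (43.9, 5.0), (40.3, 4.1), (20.0, 70.0)),
    _cont("lvef", "%", "echocardiographic", (65.2, 5.0), (65.3, 7.8), (10.0, 90.0)),
    _cont("lvedd", "mm", "echocardiographic", (48.2, 5.2), (50.1, 6.2), (30.0, 80.0)),
    _cont("lvedv", "mL", "echocardiographic", (112.4, 28.6), (120.7, 33.4), (40.0, 300.0)),
    _cont("ivs_thickness", "mm", "echocardiographic", (10.0, 1.9), (10.1, 1.7), (5.0, 25.0)),
    _cont("lvpw_thickness", "mm", "echocardiographic", (8.9, 1.3), (9.2, 1.1), (5.0, 20.0)),
    _cont("septal_e_over_e_prime", "", "echocardiographic", (13.8, 6.5), (11.8, 6.5),
          (2.0, 50.0)),
    _cont("lateral_e_over_e_prime", "", "echocardiographic", (9.9, 4.4), (8.5, 3.1),
          (2.0, 50.0)),
)

FEATURE_NAMES: tuple[str, ...] = tuple(s.name for s in CANONICAL_SCHEMA)
SKEWED_FEATURES: tuple[str, ...] = tuple(s.name for s in CANONICAL_SCHEMA if s.skewed)

if len(CANONICAL_SCHEMA) != 27:  # pragma: no cover - schema integrity
    raise AssertionError("canonical schema must have exactly 27 features")
if len(set(FEATURE_NAMES)) != 27:  # pragma: no cover
    raise AssertionError("feature names must be unique")

#: overall-cohort column (both arms pooled): mean/SD or proportion
OVERALL_STATS: dict[str, tuple[float, ...]] = {
    "age": (72.0, 10.8), "male_gender": (0.548,), "bmi": (24.0, 3.7),
    "hypertension": (0.677,), "diabetes": (0.306,),
    "coronary_heart_disease": (0.266,), "aortic_valve_disease": (0.048,),
    "mitral_valve_disease": (0.048,), "tricuspid_valve_disease": (0.073,),
    "nt_probnp": (564.0, 911.1), "hs_tni": (135.7, 1224.1),
    "crp": (10.2, 23.2), "myoglobin": (31.8, 21.1), "ck_mb": (1.8, 1.3),
    "ldh": (218.3, 73.0), "lp_a": (0.2, 0.2), "ldl_c": (2.3, 0.9),
    "serum_creatinine": (83.1, 25.6), "egfr": (74.9, 17.8),
    "lad": (41.5, 4.7), "lvef": (65.2, 7.0), "lvedd": (49.5, 6.0),
    "lvedv": (118.2, 32.1), "ivs_thickness": (10.1, 1.7),
    "lvpw_thickness": (9.1, 1.1), "septal_e_over_e_prime": (12.4, 6.5),
    "lateral_e_over_e_prime": (9.0, 3.6),
}


def null_schema() -> tuple[FeatureSpec, ...]:
    """Schema variant with identical arms (overall-cohort statistics).

    Cohorts generated from it carry no label signal in the features; label
    rules can then be planted explicitly.
    """
    out = []
    for s in CANONICAL_SCHEMA:
        stats = OVERALL_STATS[s.name]
        if s.kind == "binary":
            out.append(FeatureSpec(s.name, s.unit, s.kind, s.group,
                                   stats[0], stats[0], bounds=s.bounds))
        else:
            out.append(FeatureSpec(s.name, s.unit, s.kind, s.group,
                                   stats[0], stats[0], stats[1], stats[1],
                                   skewed=s.skewed, bounds=s.bounds))
    return tuple(out)


_BY_NAME = {s.name: s for s in CANONICAL_SCHEMA}


def feature_by_name(name: str) -> FeatureSpec:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown feature {name!r}") from None


def continuous_features() -> list[FeatureSpec]:
    return [s for s in CANONICAL_SCHEMA if s.kind == "continuous"]


def binary_features() -> list[FeatureSpec]:
    return [s for s in CANONICAL_SCHEMA if s.kind == "binary"]
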