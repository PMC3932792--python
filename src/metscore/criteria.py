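"""Harmonized dichotomous metabolic-syndrome classification.

An individual is classified by five dichotomous features — abdominal
obesity, low HDL, elevated triglycerides, elevated blood pressure,
hyperglycemia — under the harmonized criteria: waist >= 94 cm (men) /
80 cm (women); HDL < 40 (men) / < 50 mg/dL (women); TG >= 150 mg/dL;
SBP >= 130 **or** DBP >= 85 mmHg; glucose >= 100 mg/dL.  Medication for a
feature counts as an alternative indicator of that feature.  MetS is
present when >= 3 of the 5 features are.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, SchemaError

FEATURES = ("abdominal_obesity", "low_hdl", "high_tg", "elevated_bp", "hyperglycemia")


@dataclass(frozen=True)
class CriteriaThresholds:
    """Harmonized cut-offs.  Boundary handling follows the printed
    criteria: waist/TG/BP/glucose are inclusive (>=), HDL is strict (<).

    ``med_chol_features`` maps lipid-lowering medication to both lipid
    features by default; the mapping is configurable because criteria
    texts leave it open.
    """

    waist_cm_male: float = 94.0
    waist_cm_female: float = 80.0
    hdl_mg_dl_male: float = 40.0
    hdl_mg_dl_female: float = 50.0
    tg_mg_dl: float = 150.0
    sbp_mmHg: float = 130.0
    dbp_mmHg: float = 85.0
    glucose_mg_dl: float = 100.0
    med_chol_features: tuple[str, ...] = ("low_hdl", "high_tg")

    def __post_init__(self):
        for name in (
            "waist_cm_male", "waist_cm_female", "hdl_mg_dl_male", "hdl_mg_dl_female",
            "tg_mg_dl", "sbp_mmHg", "dbp_mmHg", "glucose_mg_dl",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"threshold {name} must be positive")
        bad = set(self.med_chol_features) - set(FEATURES)
        if bad:
            raise ParameterError(f"unknown feature(s) in med_chol_features: {bad}")


@dataclass(frozen=True)
class MetsStatus:
    abdominal_obesity: bool
    low_hdl: bool
    high_tg: bool
    elevated_bp: bool
    hyperglycemia: bool

    @property
    def risk_count(self) -> int:
        return sum(
            (self.abdominal_obesity, self.low_hdl, self.high_tg,
             self.elevated_bp, self.hyperglycemia)
        )

    @property
    def mets(self) -> bool:
        return self.risk_count >= 3


def _get(record, key):
    try:
        v = record[key]
    except (KeyError, IndexError):
        return None
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return v


def evaluate_features(record, thresholds: CriteriaThresholds | None = None) -> MetsStatus:
    """Evaluate the five harmonized features for one individual.

    ``record`` is any mapping (dict, pandas row) with the trait columns,
    ``sex`` and the medication flags.  A feature is true when its
    threshold is met **or** the corresponding medication flag is set; a
    missing trait without a medication override raises
    :class:`SchemaError` (the caller excludes and logs the record).
    """
    th = thresholds or CriteriaThresholds()
    sex = _get(record, "sex")
    if sex not in ("male", "female"):
        raise SchemaError(f"sex must be 'male' or 'female', got {sex!r}")
    med_htn = bool(_get(record, "med_htn") or False)
    med_chol = bool(_get(record, "med_chol") or False)
    med_diab = bool(_get(record, "med_diab") or False)

    def feature(value_keys, predicate, medicated):
        vals = [_get(record, k) for k in value_keys]
        if any(v is None for v in vals):
            if medicated:
                return True
            raise SchemaError(
                f"missing {value_keys} with no medication override"
            )
        return bool(predicate(*vals)) or medicated

    waist_th = th.waist_cm_male if sex == "male" else th.waist_cm_female
    hdl_th = th.hdl_mg_dl_male if sex == "male" else th.hdl_mg_dl_female
    return MetsStatus(
        abdominal_obesity=feature(("waist_cm",), lambda w: w >= waist_th, False),
        low_hdl=feature(
            ("hdl_mg_dl",), lambda h: h < hdl_th,
            med_chol and "low_hdl" in th.med_chol_features,
        ),
        high_tg=feature(
            ("tg_mg_dl",), lambda t: t >= th.tg_mg_dl,
            med_chol and "high_tg" in th.med_chol_features,
        ),
        elevated_bp=feature(
            ("sbp_mmHg", "dbp_mmHg"),
            lambda s, d: s >= th.sbp_mmHg or d >= th.dbp_mmHg,
            med_htn,
        ),
        hyperglycemia=feature(
            ("glucose_mg_dl",), lambda g: g >= th.glucose_mg_dl, med_diab
        ),
    )


def classify_table(
    table: pd.DataFrame, thresholds: CriteriaThresholds | None = None
) -> tuple[pd.DataFrame, list]:
    """Classify every record; returns (status table, excluded ids).

    Records with missing features and no medication override are excluded
    (listed, not fatal), mirroring a survey analysis that drops incomplete
    records.
    """
    rows, excluded = {}, []
    for idx, record in table.iterrows():
        try:
            st = evaluate_features(record, thresholds)
        except SchemaError:
            excluded.append(idx)
            continue
        rows[idx] = {
            **{f: getattr(st, f) for f in FEATURES},
            "risk_count": st.risk_count,
            "mets": st.mets,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = table.index.name
    return out, excluded


def prevalence_ci(
    p_hat: float, n: int, level: float = 0.95, method: str = "wald"
) -> tuple[float, float]:
    """Confidence interval for a prevalence.

    ``wald`` (default): p ± z * sqrt(p(1−p)/n), truncated to [0, 1];
    ``wilson``: the Wilson score interval.
    """
    if not (0.0 <= p_hat <= 1.0):
        raise ParameterError("p_hat must lie in [0, 1]")
    if n < 1:
        raise ParameterError("n must be >= 1")
    if method == "wald":
        z = stats.norm.ppf((1.0 + level) / 2.0)
        half = z * math.sqrt(p_hat * (1.0 - p_hat) / n)
        return max(0.0, p_hat - half), min(1.0, p_hat + half)
    if method == "wilson":
        from statsmodels.stats.proportion import proportion_confint

        lo, hi = proportion_confint(round(p_hat * n), n, alpha=1 - level, method="wilson")
        return float(lo), float(hi)
    raise ParameterError(f"unknown CI method {method!r}")
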