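"""Covariate-adjusted genotype effects on the continuous score.

An ordinary least-squares linear model ``score ~ genotype group +
covariates`` estimates the adjusted between-genotype mean difference.
Covariates are screened first: only those explaining more than a
threshold share (default 5%) of the score's variance — measured as the
incremental R² of the covariate alone against an intercept-only model —
enter the model.  The genotype group is always retained regardless of
screening.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateDataError, InsufficientDataError, ParameterError


@dataclass
class ScreenResult:
    """Per-covariate variance contributions and the included set."""

    contributions: dict[str, float]
    included: list[str]
    threshold: float
    notes: dict[str, str] = field(default_factory=dict)


def covariate_screen(
    score, covariates: pd.DataFrame, threshold: float = 0.05
) -> ScreenResult:
    """Marginal variance-contribution screen.

    Contribution of covariate x = R² of the simple regression score ~ x
    (equivalently the squared Pearson correlation for a single
    regressor).  A covariate is included iff its contribution exceeds
    ``threshold``; constant covariates contribute 0 and are excluded with
    a note.
    """
    y = np.asarray(score, dtype=float)
    contributions: dict[str, float] = {}
    notes: dict[str, str] = {}
    for name in covariates.columns:
        x = _encode(covariates[name])
        keep = ~(np.isnan(x) | np.isnan(y))
        if keep.sum() < 3 or np.ptp(x[keep]) == 0.0:
            contributions[name] = 0.0
            notes[name] = "constant or insufficient data; excluded"
            continue
        r = np.corrcoef(x[keep], y[keep])[0, 1]
        contributions[name] = float(r * r)
    included = [c for c, v in contributions.items() if v > threshold]
    return ScreenResult(contributions, included, threshold, notes)


def _encode(col: pd.Series) -> np.ndarray:
    """Binary/boolean columns to 0/1 (sex: female=1), numerics passed through."""
    if col.dtype == bool:
        return col.to_numpy(dtype=float)
    if col.dtype == object:
        vals = set(col.dropna().unique())
        if vals <= {"male", "female"}:
            return col.map({"male": 0.0, "female": 1.0}).to_numpy(dtype=float)
        raise ParameterError(f"cannot encode covariate {col.name!r} with values {vals}")
    return col.to_numpy(dtype=float)


@dataclass
class AdjustedResult:
    """Adjusted between-genotype mean difference.

    ``mean_diff`` is reference − carrier, matching the unadjusted
    association orientation, with its CI and the coefficient's t-based
    p-value.
    """

    snp_id: str
    covariates: list[str]
    mean_diff: float
    ci_level: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    contributions: dict[str, float] = field(default_factory=dict)


def fit_adjusted_model(
    score,
    carrier,
    covariates: pd.DataFrame | None = None,
    level: float = 0.95,
    snp_id: str = "",
    contributions: dict[str, float] | None = None,
) -> AdjustedResult:
    """OLS fit of score ~ carrier + covariates (treatment coding).

    ``carrier`` is the 0/1 dominance-group indicator (1 = carries >= 1
    minor allele).  With no covariates the estimate, CI and p reduce
    exactly to the pooled two-sample t-test.  A rank-deficient design
    raises :class:`DegenerateDataError` naming the offending columns.
    """
    y = np.asarray(score, dtype=float)
    g = np.asarray(carrier, dtype=float)
    if set(np.unique(g[~np.isnan(g)])) - {0.0, 1.0}:
        raise ParameterError("carrier must be a 0/1 indicator")
    cols = {"carrier": g}
    names = []
    if covariates is not None:
        for name in covariates.columns:
            cols[name] = _encode(covariates[name])
            names.append(name)
    X = pd.DataFrame(cols)
    keep = ~(X.isna().any(axis=1) | np.isnan(y))
    X, y = X.loc[keep], y[keep.to_numpy()]
    if (X["carrier"] == 1).sum() < 2 or (X["carrier"] == 0).sum() < 2:
        raise InsufficientDataError("need >= 2 individuals per genotype group")
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # identify columns that add no rank
        offenders = []
        base = design[["const"]].to_numpy()
        for c in design.columns[1:]:
            cand = np.column_stack([base, design[c].to_numpy()])
            if np.linalg.matrix_rank(cand) == np.linalg.matrix_rank(base):
                offenders.append(c)
            else:
                base = cand
        raise DegenerateDataError(f"collinear design; offending column(s): {offenders}")
    fit = sm.OLS(y, design).fit()
    coef = fit.params["carrier"]
    ci = fit.conf_int(alpha=1.0 - level).loc["carrier"]
    return AdjustedResult(
        snp_id=snp_id,
        covariates=names,
        mean_diff=float(-coef),  # reference − carrier
        ci_level=level,
        ci_low=float(-ci[1]),
        ci_high=float(-ci[0]),
        p=float(fit.pvalues["carrier"]),
        n=int(len(y)),
        contributions=dict(contributions or {}),
    )
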