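"""Normality screening and trait normalization ahead of the score PCA.

Six quantitative metabolic-syndrome traits enter the continuous score:
waist circumference (cm), diastolic and systolic blood pressure (mmHg),
fasting glucose, HDL cholesterol and triglycerides (mg/dL).  Waist and DBP
are used as measured; the other four are mapped toward normality with
fixed monotone transforms before standardization:

======== =========================== ===========
trait    transform                   direction
======== =========================== ===========
SBP      log10(log10 x)              increasing
glucose  1 / (log10 x)**10           decreasing
HDL      (ln x)**2                   increasing (x > 1)
TG       log10(log10 x)              increasing
======== =========================== ===========

The glucose transform is *decreasing*, so a negative loading of the
transformed trait on a principal component still means that higher raw
glucose pushes the component (and the score) up.  The doubled-log
transforms require log10(x) > 0, i.e. raw values strictly above 1; all
four clinical traits sit far above that bound in any plausible cohort.

Missing values (NaN) propagate through transforms; listwise exclusion of
incomplete records happens once, just before PCA.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, DomainError, InsufficientDataError, ParameterError

#: canonical trait order used throughout the package
TRAITS: tuple[str, ...] = (
    "waist_cm",
    "dbp_mmHg",
    "sbp_mmHg",
    "glucose_mg_dl",
    "hdl_mg_dl",
    "tg_mg_dl",
)

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class Transform:
    """One elementwise monotone transform with its inverse and derivative.

    ``raw_min`` is the open lower bound of the valid raw domain;
    ``transformed_min`` the open lower bound of the attainable transformed
    range (``-inf`` when unbounded) — the synthetic generator uses it to
    reject latent draws whose inverse image would be undefined.
    """

    name: str
    func: Callable[[np.ndarray], np.ndarray]
    inverse: Callable[[np.ndarray], np.ndarray]
    deriv: Callable[[np.ndarray], np.ndarray]
    raw_min: float
    transformed_min: float
    increasing: bool


TRANSFORMS: dict[str, Transform] = {
    "identity": Transform(
        "identity",
        func=lambda x: np.asarray(x, dtype=float),
        inverse=lambda y: np.asarray(y, dtype=float),
        deriv=lambda x: np.ones_like(np.asarray(x, dtype=float)),
        raw_min=0.0,
        transformed_min=-np.inf,
        increasing=True,
    ),
    "log10log10": Transform(
        "log10log10",
        func=lambda x: np.log10(np.log10(x)),
        inverse=lambda y: 10.0 ** (10.0 ** np.asarray(y, dtype=float)),
        deriv=lambda x: 1.0 / (np.asarray(x, dtype=float) * _LN10**2 * np.log10(x)),
        raw_min=1.0,
        transformed_min=-np.inf,
        increasing=True,
    ),
    "inv_log10_pow10": Transform(
        "inv_log10_pow10",
        func=lambda x: np.log10(x) ** -10.0,
        inverse=lambda y: 10.0 ** (np.asarray(y, dtype=float) ** -0.1),
        deriv=lambda x: -10.0 * np.log10(x) ** -11.0 / (np.asarray(x, dtype=float) * _LN10),
        raw_min=1.0,
        transformed_min=0.0,
        increasing=False,
    ),
    "sq_ln": Transform(
        "sq_ln",
        func=lambda x: np.log(x) ** 2.0,
        inverse=lambda y: np.exp(np.sqrt(np.asarray(y, dtype=float))),
        deriv=lambda x: 2.0 * np.log(x) / np.asarray(x, dtype=float),
        raw_min=1.0,  # restrict to ln(x) > 0 so the square is invertible
        transformed_min=0.0,
        increasing=True,
    ),
}

#: fixed trait -> transform assignment used by the default ("fixed") pipeline mode
DEFAULT_TRAIT_TRANSFORMS: dict[str, str] = {
    "waist_cm": "identity",
    "dbp_mmHg": "identity",
    "sbp_mmHg": "log10log10",
    "glucose_mg_dl": "inv_log10_pow10",
    "hdl_mg_dl": "sq_ln",
    "tg_mg_dl": "log10log10",
}

#: transforms a trait receives when it fails the normality screen
DESIGNATED_TRANSFORMS: dict[str, str] = {
    "sbp_mmHg": "log10log10",
    "glucose_mg_dl": "inv_log10_pow10",
    "hdl_mg_dl": "sq_ln",
    "tg_mg_dl": "log10log10",
}


def shapiro_normality(values) -> tuple[float, float]:
    """Shapiro–Wilk normality test on the non-missing values.

    Returns (W, p).  Raises :class:`InsufficientDataError` for fewer than
    3 non-missing values and :class:`DegenerateDataError` for a constant
    vector (W is undefined at zero variance).
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise InsufficientDataError(
            f"Shapiro-Wilk needs >= 3 non-missing values, got {x.size}"
        )
    if np.ptp(x) == 0.0:
        raise DegenerateDataError("Shapiro-Wilk is undefined for a constant vector")
    with warnings.catch_warnings():
        # scipy warns that p may be inaccurate for n > 5000; we accept that
        warnings.simplefilter("ignore")
        w, p = stats.shapiro(x)
    return float(w), float(p)


def transform_trait(trait: str, values, transform: str | None = None) -> np.ndarray:
    """Apply a trait's transform elementwise, propagating NaN.

    ``transform`` overrides the default assignment for ``trait``.  Values
    at or below the transform's raw domain bound raise :class:`DomainError`
    listing the offending positions (index labels for pandas input).
    """
    name = transform if transform is not None else DEFAULT_TRAIT_TRANSFORMS.get(trait)
    if name is None or name not in TRANSFORMS:
        raise ParameterError(f"unknown transform {name!r} for trait {trait!r}")
    tr = TRANSFORMS[name]
    index = values.index if isinstance(values, pd.Series) else None
    x = np.asarray(values, dtype=float)
    finite = ~np.isnan(x)
    bad = finite & (x <= tr.raw_min)
    if bad.any():
        ids = list(index[bad]) if index is not None else list(np.nonzero(bad)[0])
        raise DomainError(
            f"{trait}: {bad.sum()} value(s) <= {tr.raw_min} outside the domain of "
            f"{name}",
            offending_ids=ids,
        )
    out = np.full_like(x, np.nan)
    out[finite] = tr.func(x[finite])
    return out


def inverse_transform_trait(trait: str, values, transform: str | None = None) -> np.ndarray:
    """Invert :func:`transform_trait` (NaN propagates)."""
    name = transform if transform is not None else DEFAULT_TRAIT_TRANSFORMS.get(trait)
    if name is None or name not in TRANSFORMS:
        raise ParameterError(f"unknown transform {name!r} for trait {trait!r}")
    tr = TRANSFORMS[name]
    x = np.asarray(values, dtype=float)
    finite = ~np.isnan(x)
    if np.any(finite & (x <= tr.transformed_min)):
        raise DomainError(
            f"{trait}: transformed values <= {tr.transformed_min} have no inverse "
            f"under {name}"
        )
    out = np.full_like(x, np.nan)
    out[finite] = tr.inverse(x[finite])
    return out


@dataclass(frozen=True)
class TraitTransformInfo:
    trait: str
    shapiro_w: float
    shapiro_p: float
    transform: str
    mean: float  # post-transform mean used for standardization
    sd: float    # post-transform SD (ddof=1), > 0


@dataclass(frozen=True)
class TransformSpec:
    """Per-trait transform assignment plus standardization constants."""

    entries: dict[str, TraitTransformInfo]
    mode: str  # "fixed" or "screen"
    alpha: float = 0.05

    def transform_for(self, trait: str) -> str:
        return self.entries[trait].transform

    def to_text(self) -> str:
        lines = [f"# metscore transform spec v1", f"mode\t{self.mode}", f"alpha\t{self.alpha}"]
        for t, e in self.entries.items():
            lines.append(
                f"{t}\t{e.transform}\t{e.mean!r}\t{e.sd!r}\t{e.shapiro_w!r}\t{e.shapiro_p!r}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "TransformSpec":
        mode, alpha, entries = "fixed", 0.05, {}
        for line in text.splitlines():
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "mode":
                mode = parts[1]
            elif parts[0] == "alpha":
                alpha = float(parts[1])
            else:
                t, tr, mean, sd, w, p = parts
                entries[t] = TraitTransformInfo(t, float(w), float(p), tr, float(mean), float(sd))
        return cls(entries=entries, mode=mode, alpha=alpha)


def build_transform_spec(
    table: pd.DataFrame,
    alpha: float = 0.05,
    mode: str = "fixed",
    strict: bool = True,
) -> TransformSpec:
    """Decide each trait's transform and record standardization constants.

    ``mode="fixed"`` (default) applies the four canonical transforms
    unconditionally — reproducible regardless of which traits a particular
    sample happens to flag.  ``mode="screen"`` runs a Shapiro–Wilk screen
    at ``alpha`` and transforms only the traits that fail it; a failing
    trait without a designated transform raises in strict mode and falls
    back to identity (with a warning) otherwise.
    """
    if mode not in ("fixed", "screen"):
        raise ParameterError(f"unknown transform mode {mode!r}")
    missing = [t for t in TRAITS if t not in table.columns]
    if missing:
        raise ParameterError(f"phenotype table lacks trait column(s): {missing}")
    entries: dict[str, TraitTransformInfo] = {}
    for trait in TRAITS:
        w, p = shapiro_normality(table[trait])
        if mode == "fixed":
            name = DEFAULT_TRAIT_TRANSFORMS[trait]
        else:
            if p >= alpha:
                name = "identity"
            elif trait in DESIGNATED_TRANSFORMS:
                name = DESIGNATED_TRANSFORMS[trait]
            elif strict:
                raise ParameterError(
                    f"{trait} fails the normality screen (p={p:.3g}) but has no "
                    "designated transform; rerun with strict=False to keep identity"
                )
            else:
                warnings.warn(
                    f"{trait} fails the normality screen but has no designated "
                    "transform; keeping identity",
                    stacklevel=2,
                )
                name = "identity"
        tv = transform_trait(trait, table[trait], transform=name)
        mean = float(np.nanmean(tv))
        sd = float(np.nanstd(tv, ddof=1))
        if sd <= 0.0:
            raise DegenerateDataError(f"{trait}: zero variance after transform {name}")
        entries[trait] = TraitTransformInfo(trait, w, p, name, mean, sd)
    return TransformSpec(entries=entries, mode=mode, alpha=alpha)


def apply_transform_spec(table: pd.DataFrame, spec: TransformSpec) -> pd.DataFrame:
    """Transform (but do not standardize) the six trait columns."""
    out = {}
    for trait in TRAITS:
        out[trait] = transform_trait(trait, table[trait], transform=spec.transform_for(trait))
    return pd.DataFrame(out, index=table.index)


def standardize(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Column-wise z-scoring (ddof=1): returns (z, means, SDs).

    Each output column has sample mean 0 and sample SD 1.  A zero-variance
    column raises :class:`DegenerateDataError` naming the trait.
    """
    means = table.mean()
    sds = table.std(ddof=1)
    dead = sds[~(sds > 0.0)]
    if len(dead):
        raise DegenerateDataError(f"zero-variance column(s): {list(dead.index)}")
    z = (table - means) / sds
    return z, means, sds
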