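"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a small cross-sectional survey cohort: six
metabolic-syndrome traits whose *transformed* (near-normal) forms are
driven by two latent standard-normal factors — a blood-pressure /
waist / glucose axis and a lipid (TG/HDL) axis — plus independent unique
noise; candidate-SNP genotypes drawn under Hardy–Weinberg equilibrium at
configured minor-allele frequencies; and lifestyle/medication covariates
drawn at configured prevalences.  Optional dominance-model genetic
effects shift carriers' latent factor before the traits are generated, so
every downstream stage (transforms, PCA score, association, adjustment)
can be tested against a known truth.

Traits are generated on the transformed scale — the scale on which the
score PCA operates and on which the factor loadings are defined — then
mapped to raw clinical units by inverting the trait transforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DomainError, ParameterError
from .genetics import GenotypeMatrix
from .trait_prep import DEFAULT_TRAIT_TRANSFORMS, TRAITS, TRANSFORMS

# Two-factor loading matrix of the transformed traits (rows follow TRAITS:
# waist, DBP, SBP, glucose, HDL, TG).  Factor 1 is the blood-pressure /
# adiposity / glycemia axis, factor 2 the lipid axis.  The glucose row is
# negative because its transform (1/(log10 x)^10) is decreasing.
DEFAULT_FACTOR_LOADINGS = np.array(
    [
        [0.650, 0.255],
        [0.771, 0.320],
        [0.826, 0.057],
        [-0.598, 0.147],
        [0.079, -0.885],
        [0.305, 0.818],
    ]
)

#: unique variance per trait; communality + uniqueness = 1 on the
#: standardized transformed scale
DEFAULT_UNIQUENESS = 1.0 - (DEFAULT_FACTOR_LOADINGS**2).sum(axis=1)

#: raw-scale location/dispersion targets used to derive the transformed-scale
#: affine constants (mean, SD in clinical units)
RAW_TRAIT_MOMENTS: dict[str, tuple[float, float]] = {
    "waist_cm": (95.50, 12.56),
    "dbp_mmHg": (80.67, 9.96),
    "sbp_mmHg": (131.72, 20.02),
    "glucose_mg_dl": (103.29, 33.91),
    "hdl_mg_dl": (53.51, 13.33),
    "tg_mg_dl": (107.71, 60.29),
}

DEFAULT_COVARIATE_PREVALENCES: dict[str, float] = {
    "female": 0.578,
    "smoker": 0.180,
    "excess_alcohol": 0.087,
    "inactive": 0.597,
    "unhealthy_diet": 0.359,
    "med_htn": 0.262,
    "med_chol": 0.126,
    "med_diab": 0.073,
}


@dataclass(frozen=True)
class SnpDef:
    snp_id: str
    gene: str
    maf: float

    def __post_init__(self):
        if not (0.0 <= self.maf <= 0.5):
            raise ParameterError(f"{self.snp_id}: MAF must lie in [0, 0.5], got {self.maf}")


@dataclass(frozen=True)
class GeneticEffect:
    """Dominance-model shift: carriers of >= 1 minor allele at ``snp_id``
    have their latent factor moved by ``beta`` (latent SD units)."""

    snp_id: str
    beta: float
    model: str = "dominant"

    def __post_init__(self):
        if self.model != "dominant":
            raise ParameterError(f"unknown genetic model {self.model!r}")


#: a small candidate panel at realistic minor-allele frequencies
DEFAULT_SNP_PANEL: tuple[SnpDef, ...] = (
    SnpDef("rs4244285", "CYP2C19", 0.129),
    SnpDef("rs279871", "GABRA2", 0.434),
    SnpDef("rs16147", "NPY", 0.450),
    SnpDef("rs1142345", "TPMT", 0.032),
)


def default_location_scale() -> dict[str, tuple[float, float]]:
    """Transformed-scale affine constants (mean, SD) per trait.

    Derived from the raw-scale targets by the delta method:
    mean_t = T(mean_raw), sd_t = |T'(mean_raw)| * sd_raw.  For transforms
    whose transformed-scale domain is bounded below (glucose), sd_t is
    capped at (mean_t − bound)/4 so that invalid draws are ~Phi(−4) rare
    and row resampling stays a fallback rather than a systematic
    truncation that would bias the latent structure.
    """
    out = {}
    for trait, (m, s) in RAW_TRAIT_MOMENTS.items():
        tr = TRANSFORMS[DEFAULT_TRAIT_TRANSFORMS[trait]]
        mu = float(tr.func(np.array([m]))[0])
        sd = float(abs(tr.deriv(np.array([m]))[0]) * s)
        if math.isfinite(tr.transformed_min):
            sd = min(sd, (mu - tr.transformed_min) / 4.0)
        out[trait] = (mu, sd)
    return out


@dataclass
class SyntheticConfig:
    """All generator knobs; the defaults define the study conditions.

    ``age_slope`` adds an age -> latent-factor linear term (units: latent
    SD per SD of age), making covariate adjustment testable;
    ``carrier_age_shift_sd`` additionally shifts carriers' age (in age
    SDs) at the SNPs that carry genetic effects, inducing genuine
    age confounding of the genotype effect.
    """

    n_individuals: int = 206
    seed: int = 0
    factor_loadings: np.ndarray = field(
        default_factory=lambda: DEFAULT_FACTOR_LOADINGS.copy()
    )
    uniqueness: np.ndarray | None = None  # default: 1 - communality
    snp_panel: tuple[SnpDef, ...] = DEFAULT_SNP_PANEL
    genetic_effects: tuple[GeneticEffect, ...] = ()
    effect_factor: int = 0  # which latent factor genetic/age effects act on
    covariate_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PREVALENCES)
    )
    age_mean: float = 56.43
    age_sd: float = 16.23
    age_slope: float = 0.0
    carrier_age_shift_sd: float = 0.0
    trait_location_scale: dict[str, tuple[float, float]] = field(
        default_factory=default_location_scale
    )
    max_retries: int = 100

    def __post_init__(self):
        self.factor_loadings = np.asarray(self.factor_loadings, dtype=float)
        if self.factor_loadings.shape != (6, 2):
            raise ParameterError("factor_loadings must be a 6x2 matrix")
        communality = (self.factor_loadings**2).sum(axis=1)
        if self.uniqueness is None:
            self.uniqueness = 1.0 - communality
        self.uniqueness = np.asarray(self.uniqueness, dtype=float)
        if self.uniqueness.shape != (6,) or (self.uniqueness <= 0.0).any():
            raise ParameterError("uniqueness must be 6 positive reals")
        if not np.allclose(communality + self.uniqueness, 1.0, atol=1e-6):
            raise ParameterError(
                "communality + uniqueness must equal 1 per trait on the "
                "standardized transformed scale"
            )
        if self.n_individuals < 1:
            raise ParameterError("n_individuals must be positive")
        panel_ids = {s.snp_id for s in self.snp_panel}
        for eff in self.genetic_effects:
            if eff.snp_id not in panel_ids:
                raise ParameterError(f"effect on unknown SNP {eff.snp_id!r}")
        for name, p in self.covariate_prevalences.items():
            if not (0.0 <= p <= 1.0):
                raise ParameterError(f"prevalence {name}={p} outside [0, 1]")
        if self.effect_factor not in (0, 1):
            raise ParameterError("effect_factor must be 0 or 1")
        for trait in TRAITS:
            if trait not in self.trait_location_scale:
                raise ParameterError(f"trait_location_scale missing {trait}")


def generate_genotypes(n: int, maf: float, rng) -> np.ndarray:
    """Draw n minor-allele dosages under Hardy–Weinberg equilibrium:
    P(0)=(1−q)^2, P(1)=2q(1−q), P(2)=q^2, i.e. Binomial(2, q).

    ``rng`` may be a seed or a numpy Generator.
    """
    if not (0.0 <= maf <= 0.5):
        raise ParameterError(f"maf must lie in [0, 0.5], got {maf}")
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return rng.binomial(2, maf, size=n).astype(float)


def apply_genetic_effect(latent, dosages, beta: float, model: str = "dominant") -> np.ndarray:
    """Shift carriers' latent values by ``beta`` under a dominance model
    (carrier = dosage >= 1); non-carriers are unchanged."""
    if model != "dominant":
        raise ParameterError(f"unknown genetic model {model!r}")
    lat = np.asarray(latent, dtype=float).copy()
    d = np.asarray(dosages, dtype=float)
    if lat.shape != d.shape:
        raise ParameterError("latent and dosages must have equal length")
    lat[d >= 1] += beta
    return lat


def expected_correlation_matrix(config: SyntheticConfig) -> np.ndarray:
    """Population correlation matrix of the transformed traits implied by
    the two-factor generative model: L L' + diag(uniqueness)."""
    L = config.factor_loadings
    return L @ L.T + np.diag(config.uniqueness)


def expected_explained_variance(config: SyntheticConfig, k: int = 2) -> float:
    """Population share of variance carried by the top-``k`` principal
    components of the generative correlation matrix.

    Note this exceeds the factor-model communality share whenever the
    unique variances are positive: the leading components absorb part of
    the unique noise as well as the common factors.
    """
    ev = np.sort(np.linalg.eigvalsh(expected_correlation_matrix(config)))[::-1]
    return float(ev[:k].sum() / ev.sum())


def _draw_traits(config: SyntheticConfig, rng, shift: np.ndarray):
    """Draw factors + unique noise, returning (factors, transformed-scale
    trait matrix) with the per-row latent shift applied to the effect
    factor.  Rows whose transformed values would have no inverse image are
    redrawn up to ``max_retries`` times."""
    n = config.n_individuals
    L = config.factor_loadings
    sqrt_u = np.sqrt(config.uniqueness)
    mus = np.array([config.trait_location_scale[t][0] for t in TRAITS])
    sds = np.array([config.trait_location_scale[t][1] for t in TRAITS])
    t_min = np.array(
        [TRANSFORMS[DEFAULT_TRAIT_TRANSFORMS[t]].transformed_min for t in TRAITS]
    )
    raw_min = np.array(
        [max(TRANSFORMS[DEFAULT_TRAIT_TRANSFORMS[t]].raw_min, 10.0)
         if t in ("sbp_mmHg", "glucose_mg_dl", "tg_mg_dl")
         else TRANSFORMS[DEFAULT_TRAIT_TRANSFORMS[t]].raw_min
         for t in TRAITS]
    )

    factors = rng.standard_normal((n, 2))
    noise = rng.standard_normal((n, 6))
    active = np.arange(n)
    for attempt in range(config.max_retries + 1):
        fa = factors.copy()
        fa[:, config.effect_factor] += shift
        z = fa @ L.T + noise * sqrt_u
        tvals = mus + sds * z
        bad_t = (tvals <= t_min).any(axis=1)
        # raw-scale validity: positive traits, doubled-log traits > 10
        raw = np.empty_like(tvals)
        for j, trait in enumerate(TRAITS):
            tr = TRANSFORMS[DEFAULT_TRAIT_TRANSFORMS[trait]]
            col = tvals[:, j]
            raw[:, j] = np.where(col > tr.transformed_min, tr.inverse(np.maximum(col, tr.transformed_min + 1e-12)), np.nan)
        bad_raw = ~(raw > raw_min).all(axis=1) | ~np.isfinite(raw).all(axis=1)
        bad = np.nonzero(bad_t | bad_raw)[0]
        if bad.size == 0:
            return fa, tvals, raw
        if attempt == config.max_retries:
            raise DomainError(
                f"{bad.size} row(s) still outside the transform domain after "
                f"{config.max_retries} redraws",
                offending_ids=bad.tolist(),
            )
        factors[bad] = rng.standard_normal((bad.size, 2))
        noise[bad] = rng.standard_normal((bad.size, 6))
    raise AssertionError("unreachable")


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, GenotypeMatrix, pd.DataFrame]:
    """Generate one cohort.

    Returns (phenotype table, genotypes, truth table).  The truth table
    carries the post-effect latent factors and the latent score (the
    factor the genetic/age effects act on), for recovery tests.  All
    randomness derives from one generator seeded with ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    ids = [f"S{i + 1:05d}" for i in range(n)]

    # genotypes first: effects and confounding depend on carrier status
    dosage_cols = {
        s.snp_id: generate_genotypes(n, s.maf, rng) for s in config.snp_panel
    }
    dosages = pd.DataFrame(dosage_cols, index=pd.Index(ids, name="id"))
    snps = pd.DataFrame(
        {
            "gene": [s.gene for s in config.snp_panel],
            "ref_maf": [s.maf for s in config.snp_panel],
        },
        index=pd.Index([s.snp_id for s in config.snp_panel], name="snp_id"),
    )
    genotypes = GenotypeMatrix(dosages=dosages, snps=snps)

    # age, with optional carrier shift (the confounding switch)
    age_z = rng.standard_normal(n)
    effect_carrier = np.zeros(n, dtype=bool)
    for eff in config.genetic_effects:
        effect_carrier |= dosages[eff.snp_id].to_numpy() >= 1
    if config.carrier_age_shift_sd:
        age_z = age_z + config.carrier_age_shift_sd * effect_carrier
    age = np.clip(config.age_mean + config.age_sd * age_z, 18.0, 100.0)

    # latent shift: dominance effects + age term, applied to one factor
    shift = np.zeros(n)
    for eff in config.genetic_effects:
        shift = apply_genetic_effect(shift, dosages[eff.snp_id], eff.beta, eff.model)
    if config.age_slope:
        shift = shift + config.age_slope * (age - config.age_mean) / config.age_sd

    factors, _tvals, raw = _draw_traits(config, rng, shift)

    prev = config.covariate_prevalences
    sex = np.where(rng.random(n) < prev["female"], "female", "male")
    flags = {
        name: rng.random(n) < prev[name]
        for name in (
            "smoker", "excess_alcohol", "inactive", "unhealthy_diet",
            "med_htn", "med_chol", "med_diab",
        )
    }

    pheno = pd.DataFrame({"id": ids})
    for j, trait in enumerate(TRAITS):
        pheno[trait] = raw[:, j]
    pheno["sex"] = sex
    pheno["age_years"] = age
    for name, vals in flags.items():
        pheno[name] = vals
    pheno = pheno.set_index("id")

    truth = pd.DataFrame(
        {
            "factor1": factors[:, 0],
            "factor2": factors[:, 1],
            "latent_score": factors[:, config.effect_factor],
        },
        index=pd.Index(ids, name="id"),
    )
    for eff in config.genetic_effects:
        truth[f"carrier_{eff.snp_id}"] = (dosages[eff.snp_id] >= 1).astype(int)
        truth[f"beta_{eff.snp_id}"] = eff.beta
    return pheno, genotypes, truth
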