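"""SNP descriptive statistics, association tests and power arithmetic.

Genotypes are held as minor-allele dosages (0/1/2, NaN for missing).  The
association machinery follows the candidate-gene workflow for a
quantitative outcome: a dominance grouping (major-allele homozygotes vs
carriers of >= 1 minor allele), a pooled-variance two-sample t-test on the
continuous score, Bonferroni family-wise correction, plus a chi-square
Hardy–Weinberg check per SNP and a normal-approximation
minimum-detectable-difference power calculation.

All tests accept either raw value vectors or the (n, mean, SD) summaries a
published table prints; the two entry points agree exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, InsufficientDataError, ParameterError
from .trait_prep import shapiro_normality


# ---------------------------------------------------------------------------
# containers


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs minor-allele dosage matrix with SNP metadata.

    ``dosages``: DataFrame indexed by sample id, one column per snp_id,
    float entries in {0, 1, 2} or NaN.  ``snps``: DataFrame indexed by
    snp_id with at least a ``gene`` column; optional ``ref_maf`` (reference
    population minor-allele frequency) and allele labels.
    """

    dosages: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self):
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ParameterError("dosages must be 0, 1, 2 or missing")
        unknown = [s for s in self.dosages.columns if s not in self.snps.index]
        if unknown:
            raise ParameterError(f"snp metadata missing for: {unknown}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.columns)

    def genotype_counts(self, snp_id: str) -> tuple[int, int, int]:
        d = self.dosages[snp_id].dropna()
        return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


@dataclass(frozen=True)
class HweResult:
    snp_id: str
    n_hom_major: int
    n_het: int
    n_hom_minor: int
    maf: float
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class AssociationResult:
    """Two-group comparison of a quantitative outcome.

    ``mean_diff`` is mean(group 1) − mean(group 2); with the dominance
    grouping, group 1 is the major-allele homozygote (reference) group.
    ``p_corrected`` is filled by :func:`bonferroni` when a family size is
    known, else equals NaN.
    """

    snp_id: str
    grouping: str
    n1: int
    mean1: float
    sd1: float
    n2: int
    mean2: float
    sd2: float
    mean_diff: float
    ci_level: float
    ci_low: float
    ci_high: float
    t: float
    df: float
    p: float
    p_corrected: float = math.nan
    n_tests: int = 0
    test_used: str = "pooled_t"

    def corrected(self, m: int) -> "AssociationResult":
        from dataclasses import replace

        return replace(self, p_corrected=bonferroni(self.p, m), n_tests=m)


@dataclass(frozen=True)
class PowerSpec:
    """Inputs for the minimum-detectable-difference calculation.

    ``sigma`` is the common SD of the outcome (typically the sample SD of
    the continuous score), ``n1``/``n2`` the two genotype-group sizes.
    """

    n1: int
    n2: int
    sigma: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.power < 1.0):
            raise ParameterError("alpha and power must lie in (0, 1)")
        if self.sigma <= 0.0:
            raise ParameterError("sigma must be positive")
        if self.n1 < 2 or self.n2 < 2:
            raise ParameterError("group sizes must be >= 2")


# ---------------------------------------------------------------------------
# descriptive statistics


def maf(dosages) -> float:
    """Observed minor-allele frequency: sum(dosages) / (2 * n non-missing)."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise InsufficientDataError("all dosages missing")
    return float(d.sum() / (2.0 * d.size))


def hwe_test(n_hom_major: int, n_het: int, n_hom_minor: int, snp_id: str = "") -> HweResult:
    """Chi-square (1 df) goodness-of-fit test against Hardy–Weinberg
    proportions, no continuity correction.

    Expected counts are n(1−q)^2, 2nq(1−q), nq^2 from the observed allele
    frequency q.  A monomorphic SNP (q in {0, 1}) has no test and raises
    :class:`DegenerateDataError`.
    """
    counts = np.array([n_hom_major, n_het, n_hom_minor], dtype=float)
    if (counts < 0).any():
        raise ParameterError("genotype counts must be non-negative")
    n = counts.sum()
    if n < 1:
        raise InsufficientDataError("no genotypes")
    q = (counts[1] + 2.0 * counts[2]) / (2.0 * n)
    if q == 0.0 or q == 1.0:
        raise DegenerateDataError("monomorphic SNP: HWE test undefined")
    expected = n * np.array([(1.0 - q) ** 2, 2.0 * q * (1.0 - q), q**2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return HweResult(snp_id, int(n_hom_major), int(n_het), int(n_hom_minor), float(q), chi2, 1, p)


def group_dominant(dosages) -> tuple[np.ndarray, np.ndarray]:
    """Dominance-model split: positions with dosage 0 (reference
    homozygotes) vs dosage >= 1 (minor-allele carriers); missing excluded.

    Returns (reference indices, carrier indices).  Empty groups are the
    caller's problem — downstream tests raise on them.
    """
    d = np.asarray(dosages, dtype=float)
    obs = ~np.isnan(d)
    return np.nonzero(obs & (d == 0))[0], np.nonzero(obs & (d >= 1))[0]


# ---------------------------------------------------------------------------
# two-group tests


def t_test_summary(
    n1: int,
    mean1: float,
    sd1: float,
    n2: int,
    mean2: float,
    sd2: float,
    level: float = 0.95,
    snp_id: str = "",
    grouping: str = "",
) -> AssociationResult:
    """Pooled-variance (Student) two-sample t-test from group summaries.

    s_p^2 = ((n1−1)s1^2 + (n2−1)s2^2)/(n1+n2−2); t = (mean1−mean2)/SE with
    SE = s_p sqrt(1/n1 + 1/n2); two-sided p on n1+n2−2 df; CI at ``level``.
    """
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ParameterError("SDs must be non-negative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 <= 0.0:
        raise DegenerateDataError("zero pooled variance")
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = mean1 - mean2
    t = diff / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    tcrit = float(stats.t.ppf((1.0 + level) / 2.0, df))
    return AssociationResult(
        snp_id=snp_id,
        grouping=grouping,
        n1=int(n1), mean1=float(mean1), sd1=float(sd1),
        n2=int(n2), mean2=float(mean2), sd2=float(sd2),
        mean_diff=float(diff), ci_level=level,
        ci_low=diff - tcrit * se, ci_high=diff + tcrit * se,
        t=float(t), df=float(df), p=min(p, 1.0),
    )


def t_test_raw(values1, values2, level: float = 0.95, **kw) -> AssociationResult:
    """Pooled t-test on raw group values; agrees exactly with
    :func:`t_test_summary` applied to the groups' own n/mean/SD."""
    x = np.asarray(values1, dtype=float)
    y = np.asarray(values2, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("each group needs >= 2 non-missing values")
    return t_test_summary(
        x.size, float(x.mean()), float(x.std(ddof=1)),
        y.size, float(y.mean()), float(y.std(ddof=1)),
        level=level, **kw,
    )


def mann_whitney(values1, values2) -> tuple[float, float]:
    """Two-sided Mann–Whitney rank-sum test.

    Uses the exact null distribution when both groups have <= 8
    observations and there are no ties; otherwise the normal approximation
    with midranks and tie correction.
    """
    x = np.asarray(values1, dtype=float)
    y = np.asarray(values2, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise InsufficientDataError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and max(x.size, y.size) <= 8) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_raw: float, m: int = 37) -> float:
    """Family-wise corrected p-value min(1, m * p_raw).

    The default family size of 37 matches a typical candidate-SNP panel;
    pass the actual number of tests performed.
    """
    if not (0.0 <= p_raw <= 1.0):
        raise ParameterError("p_raw must lie in [0, 1]")
    if m < 1:
        raise ParameterError("m must be >= 1")
    return min(1.0, m * p_raw)


def per_trait_association(
    values1, values2, alpha: float = 0.05
) -> tuple[str, float, float]:
    """Two-group comparison of a single quantitative trait, dispatching on
    normality: pooled t-test when both groups pass Shapiro–Wilk at
    ``alpha``, Mann–Whitney otherwise.

    Returns (test_used, statistic, p).
    """
    x = np.asarray(values1, dtype=float)
    y = np.asarray(values2, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    try:
        normal = (
            shapiro_normality(x)[1] >= alpha and shapiro_normality(y)[1] >= alpha
        )
    except (InsufficientDataError, DegenerateDataError):
        normal = False
    if normal:
        res = t_test_raw(x, y)
        return "t", res.t, res.p
    u, p = mann_whitney(x, y)
    return "mann_whitney", u, p


def chi2_association(group_labels, binary_status, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square test of independence on the 2x2 table of a
    binary grouping against a binary status (df = 1, no continuity
    correction unless ``correction=True``).

    Raises :class:`DegenerateDataError` when any table margin is zero
    (an exact test would be needed there).
    """
    table = pd.crosstab(pd.Series(group_labels), pd.Series(binary_status))
    if min(table.shape) < 2:
        # a variable observed at a single level is a zero-margin table
        raise DegenerateDataError("zero margin in 2x2 table; use an exact test")
    if table.shape != (2, 2):
        raise ParameterError("both variables must take exactly two values")
    arr = table.to_numpy(dtype=float)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateDataError("zero margin in 2x2 table; use an exact test")
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=correction)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# additive risk count and power


def risk_genotype_count(
    genotypes: GenotypeMatrix, risk_orientation: dict[str, bool]
) -> pd.Series:
    """Per-individual count of risk genotypes across a SNP panel.

    ``risk_orientation`` maps snp_id -> True when *carrying* >= 1 minor
    allele is the risk state, False when the risk state is the
    major-allele homozygote (a protective minor allele).  One missing
    dosage at any panel SNP makes the individual's count missing.
    """
    unknown = [s for s in risk_orientation if s not in genotypes.dosages.columns]
    if unknown:
        raise ParameterError(f"unknown snp id(s): {unknown}")
    total = pd.Series(0.0, index=genotypes.sample_ids)
    for snp_id, carrier_is_risk in risk_orientation.items():
        d = genotypes.dosages[snp_id]
        carrier = (d >= 1).astype(float)
        carrier[d.isna()] = np.nan
        total = total + (carrier if carrier_is_risk else 1.0 - carrier)
    return total


def min_detectable_diff(spec: PowerSpec, exact: bool = False) -> float:
    """Smallest two-group mean difference detectable at the spec's alpha
    and power.

    Normal approximation (default):
    delta = (z_{1-alpha/2} + z_{power}) * sigma * sqrt(1/n1 + 1/n2).
    With ``exact=True`` the noncentral-t power function of the pooled
    t-test is inverted instead.
    """
    se = spec.sigma * math.sqrt(1.0 / spec.n1 + 1.0 / spec.n2)
    z = stats.norm.ppf(1.0 - spec.alpha / 2.0) + stats.norm.ppf(spec.power)
    delta = float(z * se)
    if not exact:
        return delta
    from scipy.optimize import brentq

    df = spec.n1 + spec.n2 - 2
    tcrit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)

    def pw(d: float) -> float:
        nc = d / se
        return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))

    return float(brentq(lambda d: pw(d) - spec.power, delta * 0.5, delta * 2.0, xtol=1e-10))


def power_for_diff(diff: float, spec: PowerSpec) -> float:
    """Normal-approximation power of the two-sided test at mean difference
    ``diff`` — the inverse companion of :func:`min_detectable_diff`."""
    se = spec.sigma * math.sqrt(1.0 / spec.n1 + 1.0 / spec.n2)
    nc = abs(diff) / se
    zc = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    return float(stats.norm.cdf(nc - zc) + stats.norm.cdf(-nc - zc))


def hwe_report(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP genotype counts, observed MAF and HWE chi-square p-value.

    Monomorphic SNPs are kept in the table with NaN statistics and a note.
    """
    rows = []
    for snp_id in genotypes.snp_ids:
        n0, n1, n2 = genotypes.genotype_counts(snp_id)
        gene = genotypes.snps.loc[snp_id].get("gene", "")
        row = {
            "snp_id": snp_id, "gene": gene,
            "n": n0 + n1 + n2, "n_hom_major": n0, "n_het": n1, "n_hom_minor": n2,
        }
        try:
            res = hwe_test(n0, n1, n2, snp_id=snp_id)
            row.update(maf=res.maf, chi2=res.chi2, hwe_p=res.p, note="")
        except (DegenerateDataError, InsufficientDataError) as exc:
            d = genotypes.dosages[snp_id].dropna()
            row.update(
                maf=maf(d) if len(d) else math.nan,
                chi2=math.nan, hwe_p=math.nan, note=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("snp_id")
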