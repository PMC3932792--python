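"""End-to-end analysis pipeline: normalize -> score -> classify ->
HWE/MAF -> associate -> correct -> trend -> adjust -> power.

Each stage writes a full-precision TSV; rounding to the 3-decimal style
of a publication table happens only in the human-readable summary.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adjustment import covariate_screen, fit_adjusted_model
from .criteria import CriteriaThresholds, classify_table, prevalence_ci
from .errors import DegenerateDataError, InsufficientDataError, MetscoreError
from .genetics import (
    GenotypeMatrix,
    PowerSpec,
    bonferroni,
    group_dominant,
    hwe_report,
    min_detectable_diff,
    t_test_raw,
)
from .io import read_genotypes, read_phenotypes, write_scores
from .score import compute_scores, fit_score_model, validate_score
from .trait_prep import TRAITS, apply_transform_spec, build_transform_spec, standardize

COVARIATES = ("age_years", "sex", "smoker", "excess_alcohol", "inactive", "unhealthy_diet")


@dataclass
class RunConfig:
    """Pipeline configuration (CLI flags map onto these fields)."""

    pheno_path: str | Path
    geno_path: str | Path
    out_dir: str | Path
    geno_format: str = "csv"
    transforms: str = "fixed"          # or "screen"
    weighting: str = "proportional"    # or "equal"
    n_tests: int | None = None         # None: number of SNPs actually tested
    ci_level: float = 0.95
    alpha: float = 0.05
    power: float = 0.80
    seed: int = 0
    risk_orientation: dict[str, bool] | None = None  # None: carrier = risk
    screen_threshold: float = 0.05
    counted_alleles: dict[str, str] | None = None


@dataclass
class PipelineResult:
    scores: pd.Series
    score_model: object
    status: pd.DataFrame
    prevalence: tuple[float, float, float]  # p_hat, ci_low, ci_high
    hwe: pd.DataFrame
    association: pd.DataFrame
    adjusted: pd.DataFrame
    screening: pd.DataFrame
    power: pd.DataFrame
    validation: object
    log_lines: list[str]


def _associate(scores: pd.Series, genotypes: GenotypeMatrix, level: float,
               m: int | None) -> pd.DataFrame:
    rows = []
    s = scores.to_numpy(dtype=float)
    for snp_id in genotypes.snp_ids:
        d = genotypes.dosages[snp_id].to_numpy(dtype=float)
        ref_idx, car_idx = group_dominant(d)
        gene = genotypes.snps.loc[snp_id].get("gene", "")
        base = {"snp_id": snp_id, "gene": gene,
                "n_ref": ref_idx.size, "n_carrier": car_idx.size}
        if ref_idx.size < 2 or car_idx.size < 2:
            rows.append({**base, "note": "insufficient group size; skipped"})
            continue
        try:
            res = t_test_raw(s[ref_idx], s[car_idx], level=level,
                             snp_id=snp_id, grouping="ref(0) vs carrier(1+)")
        except (DegenerateDataError, InsufficientDataError) as exc:
            rows.append({**base, "note": str(exc)})
            continue
        rows.append({
            **base,
            "mean_ref": res.mean1, "sd_ref": res.sd1,
            "mean_carrier": res.mean2, "sd_carrier": res.sd2,
            "mean_diff": res.mean_diff,
            "ci_low": res.ci_low, "ci_high": res.ci_high,
            "t": res.t, "df": res.df, "p_raw": res.p,
            "test_used": res.test_used, "note": "",
        })
    table = pd.DataFrame(rows).set_index("snp_id")
    tested = table["p_raw"].notna() if "p_raw" in table else pd.Series(False, index=table.index)
    n_tested = int(tested.sum())
    m_eff = m if m is not None else n_tested
    if "p_raw" in table:
        table["n_tests"] = m_eff
        table["p_bonferroni"] = [
            bonferroni(p, m_eff) if np.isfinite(p) else np.nan for p in table["p_raw"].fillna(np.nan)
        ]
    return table


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the whole analysis and write all artifacts to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = [f"metscore {__version__}",
           f"numpy {np.__version__} pandas {pd.__version__}",
           f"config: {dataclasses.asdict(config)}"]

    pheno = read_phenotypes(config.pheno_path)
    genotypes, notes = read_genotypes(
        config.geno_path, format=config.geno_format,
        sample_ids=pheno.index, counted_alleles=config.counted_alleles,
    )
    log.extend(notes)

    # --- normalize: listwise-complete records on the six traits
    complete = pheno[list(TRAITS)].dropna().index
    if len(complete) < len(pheno):
        log.append(f"excluded {len(pheno) - len(complete)} record(s) with missing traits")
    traits = pheno.loc[complete, list(TRAITS)]
    spec = build_transform_spec(traits, mode=config.transforms)
    (out / "transform_spec.txt").write_text(spec.to_text())
    z, _, _ = standardize(apply_transform_spec(traits, spec))

    # --- score
    model = fit_score_model(z)
    (out / "score_model.txt").write_text(model.to_text())
    sv = compute_scores(model, z, weighting=config.weighting)
    scores = sv.scores
    write_scores(scores, out / "scores.tsv")
    log.append(f"score: K={model.n_components}, "
               f"explained={model.explained.round(4).tolist()}, "
               f"weighting={config.weighting}, sd={sv.sd:.4f}")

    # --- classify
    status, excluded = classify_table(pheno.loc[complete])
    if excluded:
        log.append(f"classification excluded id(s): {excluded}")
    status.to_csv(out / "status.tsv", sep="\t")
    p_hat = float(status["mets"].mean())
    ci = prevalence_ci(p_hat, len(status), level=config.ci_level)
    prevalence = (p_hat, ci[0], ci[1])

    # --- HWE / MAF
    gsub = GenotypeMatrix(dosages=genotypes.dosages.loc[complete], snps=genotypes.snps)
    hwe = hwe_report(gsub)
    hwe.to_csv(out / "hwe_maf.tsv", sep="\t")

    # --- association + Bonferroni
    association = _associate(scores, gsub, config.ci_level, config.n_tests)
    association.to_csv(out / "association.tsv", sep="\t")

    # --- score validity: trend across risk-factor counts + group contrast
    aligned = status.loc[scores.index]
    validation = validate_score(scores, aligned["mets"], aligned["risk_count"])

    # --- adjusted models
    covs = pheno.loc[scores.index, list(COVARIATES)]
    screen = covariate_screen(scores, covs, threshold=config.screen_threshold)
    screening = pd.DataFrame({
        "covariate": list(screen.contributions),
        "contribution": list(screen.contributions.values()),
        "included": [c in screen.included for c in screen.contributions],
    }).set_index("covariate")
    screening.to_csv(out / "screening.tsv", sep="\t")
    adj_rows = []
    for snp_id in gsub.snp_ids:
        d = gsub.dosages[snp_id]
        carrier = (d >= 1).astype(float).where(d.notna())
        try:
            res = fit_adjusted_model(
                scores, carrier.loc[scores.index],
                covs[screen.included] if screen.included else None,
                level=config.ci_level, snp_id=snp_id,
                contributions=screen.contributions,
            )
        except MetscoreError as exc:
            adj_rows.append({"snp_id": snp_id, "note": str(exc)})
            continue
        adj_rows.append({
            "snp_id": snp_id, "covariates": ",".join(res.covariates),
            "mean_diff": res.mean_diff, "ci_low": res.ci_low,
            "ci_high": res.ci_high, "p": res.p, "n": res.n, "note": "",
        })
    adjusted = pd.DataFrame(adj_rows).set_index("snp_id")
    adjusted.to_csv(out / "adjusted.tsv", sep="\t")

    # --- power block
    sigma = sv.sd
    pw_rows = []
    for snp_id in gsub.snp_ids:
        row = association.loc[snp_id]
        n1, n2 = int(row["n_ref"]), int(row["n_carrier"])
        if n1 >= 2 and n2 >= 2:
            mdd = min_detectable_diff(
                PowerSpec(n1=n1, n2=n2, sigma=sigma,
                          alpha=config.alpha, power=config.power)
            )
        else:
            mdd = np.nan
        pw_rows.append({"snp_id": snp_id, "n_ref": n1, "n_carrier": n2,
                        "sigma": sigma, "alpha": config.alpha,
                        "power": config.power, "min_detectable_diff": mdd})
    power = pd.DataFrame(pw_rows).set_index("snp_id")
    power.to_csv(out / "power.tsv", sep="\t")

    # --- human-readable summary (3-decimal style)
    summary = [
        f"n = {len(scores)} complete records",
        f"MetS prevalence: {100 * p_hat:.2f}% "
        f"({100 * ci[0]:.2f}-{100 * ci[1]:.2f}%)",
        f"score mean +/- SD: {sv.mean:.2f} +/- {sv.sd:.2f} ({config.weighting} weights)",
        f"trend across risk counts: F={validation.trend.statistic:.3f}, "
        f"p={validation.trend.p:.3g}",
    ]
    if validation.t_p is not None:
        summary.append(
            f"MetS vs non-MetS score: {validation.mean_affected:.2f} vs "
            f"{validation.mean_unaffected:.2f} (t p={validation.t_p:.3g})"
        )
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    log.append("pipeline complete")
    (out / "run.log").write_text("\n".join(log) + "\n")

    return PipelineResult(
        scores=scores, score_model=model, status=status, prevalence=prevalence,
        hwe=hwe, association=association, adjusted=adjusted,
        screening=screening, power=power, validation=validation, log_lines=log,
    )
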