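"""Continuous metabolic-syndrome score: PCA fit, scoring and validation.

The score condenses the six standardized (transformed) traits into one
severity index: principal components are extracted from the correlation
matrix, components with eigenvalue > 1 are retained, a varimax rotation
is applied to the retained loadings, and each individual's score is the
weighted sum of their (unit-variance) component scores.  Two weighting
conventions are exposed:

* ``proportional`` — w_k = v_k / sum(v_k) with v_k the explained-variance
  shares of the retained components;
* ``equal`` — w_k = 1, which with two uncorrelated unit-variance
  component scores gives the score a sample SD of sqrt(2) ~ 1.41.

A higher score means a less favorable metabolic profile (the glucose
trait enters through a decreasing transform, so its negative loading
preserves that direction).
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    ParameterError,
    SchemaError,
)
from .trait_prep import TRAITS

#: direction of "less favorable" on the *transformed* scale per trait:
#: glucose is −1 because its transform is decreasing, HDL is −1 because
#: higher HDL is protective.  Used to orient components so that a higher
#: score always means a worse metabolic profile.
SEVERITY_DIRECTIONS: dict[str, float] = {
    "waist_cm": 1.0,
    "dbp_mmHg": 1.0,
    "sbp_mmHg": 1.0,
    "glucose_mg_dl": -1.0,
    "hdl_mg_dl": -1.0,
    "tg_mg_dl": 1.0,
}


def _varimax(loadings: np.ndarray, max_iter: int = 500, tol: float = 1e-10) -> np.ndarray:
    """Orthogonal varimax rotation (gamma = 1) of a p x k loading matrix."""
    p, k = loadings.shape
    rotation = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        rotated = loadings @ rotation
        u, s, vt = np.linalg.svd(
            loadings.T
            @ (rotated**3 - rotated @ np.diag((rotated**2).sum(axis=0)) / p)
        )
        rotation = u @ vt
        new_var = s.sum()
        if new_var <= var * (1.0 + tol):
            break
        var = new_var
    return loadings @ rotation


@dataclass
class ScoreModel:
    """Fitted PCA score model.

    ``loadings`` are trait–component correlations (p x K, entries in
    [−1, 1]); ``eigenvalues`` the retained components' pre-rotation
    eigenvalues; ``explained`` their explained-variance shares (recomputed
    after rotation when rotation is applied); ``all_explained`` the shares
    of all p components (summing to 1); ``score_weights`` maps a
    standardized trait row to unit-variance component scores by the
    regression method.
    """

    traits: tuple[str, ...]
    n_components: int
    loadings: np.ndarray
    eigenvalues: np.ndarray
    explained: np.ndarray
    all_explained: np.ndarray
    rotated: bool
    score_weights: np.ndarray
    score_scales: np.ndarray
    eigen_threshold: float = 1.0

    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write("# metscore score model v1\n")
        buf.write(f"traits\t{','.join(self.traits)}\n")
        buf.write(f"n_components\t{self.n_components}\n")
        buf.write(f"rotated\t{int(self.rotated)}\n")
        buf.write(f"eigen_threshold\t{self.eigen_threshold!r}\n")
        for name, arr in (
            ("eigenvalues", self.eigenvalues),
            ("explained", self.explained),
            ("all_explained", self.all_explained),
            ("score_scales", self.score_scales),
        ):
            buf.write(name + "\t" + ",".join(repr(float(v)) for v in arr) + "\n")
        for name, mat in (("loadings", self.loadings), ("score_weights", self.score_weights)):
            for row in mat:
                buf.write(name + "\t" + ",".join(repr(float(v)) for v in row) + "\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "ScoreModel":
        fields: dict[str, list] = {"loadings": [], "score_weights": []}
        for line in text.splitlines():
            if not line or line.startswith("#"):
                continue
            key, val = line.split("\t", 1)
            if key in ("loadings", "score_weights"):
                fields[key].append([float(v) for v in val.split(",")])
            elif key == "traits":
                fields[key] = val.split(",")
            else:
                fields[key] = val
        return cls(
            traits=tuple(fields["traits"]),
            n_components=int(fields["n_components"]),
            loadings=np.array(fields["loadings"]),
            eigenvalues=np.array([float(v) for v in fields["eigenvalues"].split(",")]),
            explained=np.array([float(v) for v in fields["explained"].split(",")]),
            all_explained=np.array([float(v) for v in fields["all_explained"].split(",")]),
            rotated=bool(int(fields["rotated"])),
            score_weights=np.array(fields["score_weights"]),
            score_scales=np.array([float(v) for v in fields["score_scales"].split(",")]),
            eigen_threshold=float(fields["eigen_threshold"]),
        )


@dataclass
class ScoreVector:
    """Per-individual continuous scores with their sample moments."""

    scores: pd.Series
    weighting: str
    weights: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.scores.mean())

    @property
    def sd(self) -> float:
        return float(self.scores.std(ddof=1))


def _as_frame(zmatrix, traits=None) -> pd.DataFrame:
    if isinstance(zmatrix, pd.DataFrame):
        return zmatrix
    arr = np.asarray(zmatrix, dtype=float)
    cols = traits if traits is not None else [f"x{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=cols)


def fit_score_model(
    zmatrix,
    eigen_threshold: float = 1.0,
    rotate: bool = True,
    risk_directions=None,
) -> ScoreModel:
    """Fit the PCA score model on a standardized trait matrix.

    Components are extracted from the correlation matrix, ordered by
    decreasing explained variance; those with eigenvalue strictly above
    ``eigen_threshold`` are retained.  With ``rotate=True`` a varimax
    rotation is applied to the retained loadings and explained shares are
    recomputed from the rotated loadings.

    PCA component signs are arbitrary, so each component is oriented
    deterministically.  When the columns are the six canonical traits (or
    ``risk_directions``, a ±1 vector per column, is given) a component is
    flipped so that its loadings point toward metabolic severity — this
    is what makes the score increase for a less favorable profile.  For
    generic columns the component's largest-magnitude loading is made
    positive instead.
    """
    z = _as_frame(zmatrix).dropna()
    if len(z) < 10:
        raise InsufficientDataError("need >= 10 complete rows to fit the score model")
    p = z.shape[1]
    # standardize defensively so the regression-score algebra is exact
    sds = z.std(ddof=1)
    if not (sds > 0).all():
        raise DegenerateDataError(
            f"zero-variance column(s): {list(sds.index[~(sds > 0)])}"
        )
    zs = (z - z.mean()) / sds
    n = len(zs)
    corr = zs.to_numpy().T @ zs.to_numpy() / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    if eigvals[-1] < 1e-10:
        raise DegenerateDataError("rank-deficient trait matrix: collinear traits")
    all_explained = eigvals / eigvals.sum()
    retained = eigvals > eigen_threshold  # strict ">"
    k = int(retained.sum())
    if k == 0:
        raise ParameterError(
            f"no eigenvalue above {eigen_threshold}; lower the threshold"
        )
    loadings = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    rotated = bool(rotate and k >= 2)
    if rotated:
        loadings = _varimax(loadings)
    explained = (loadings**2).sum(axis=0) / p
    # order by decreasing explained variance, then orient each component
    order_k = np.argsort(explained)[::-1]
    loadings, explained = loadings[:, order_k], explained[order_k]
    if risk_directions is None and tuple(z.columns) == TRAITS:
        risk_directions = [SEVERITY_DIRECTIONS[t] for t in TRAITS]
    for j in range(k):
        if risk_directions is not None:
            flip = float(np.dot(np.asarray(risk_directions, dtype=float), loadings[:, j])) < 0
        else:
            flip = loadings[np.argmax(np.abs(loadings[:, j])), j] < 0
        if flip:
            loadings[:, j] = -loadings[:, j]
    # regression-method score weights on standardized traits
    weights = np.linalg.solve(corr, loadings)
    s_fit = zs.to_numpy() @ weights
    scales = s_fit.std(axis=0, ddof=1)
    return ScoreModel(
        traits=tuple(z.columns),
        n_components=k,
        loadings=loadings,
        eigenvalues=eigvals[:k],
        explained=explained,
        all_explained=all_explained,
        rotated=rotated,
        score_weights=weights / scales,
        score_scales=scales,
        eigen_threshold=eigen_threshold,
    )


def component_scores(model: ScoreModel, zmatrix) -> pd.DataFrame:
    """Unit-variance component scores for a standardized trait matrix."""
    z = _as_frame(zmatrix, traits=model.traits)
    if tuple(z.columns) != model.traits:
        raise SchemaError(
            f"columns {tuple(z.columns)} do not match the fitted traits {model.traits}"
        )
    s = z.to_numpy(dtype=float) @ model.score_weights
    return pd.DataFrame(s, index=z.index, columns=[f"PC{i+1}" for i in range(model.n_components)])


def compute_scores(model: ScoreModel, zmatrix, weighting: str = "proportional") -> ScoreVector:
    """Combine component scores into the continuous score.

    ``proportional``: w_k = v_k / sum(v_k); ``equal``: w_k = 1.  On the
    fitting sample the score has mean 0; under equal weighting with two
    (uncorrelated) components its SD is sqrt(2).
    """
    if weighting == "proportional":
        w = model.explained / model.explained.sum()
    elif weighting == "equal":
        w = np.ones(model.n_components)
    else:
        raise ParameterError(f"unknown weighting {weighting!r}")
    s = component_scores(model, zmatrix)
    scores = pd.Series(s.to_numpy() @ w, index=s.index, name="mets_score")
    return ScoreVector(scores=scores, weighting=weighting, weights=w)


@dataclass(frozen=True)
class TrendResult:
    statistic: float  # linear-contrast F (1, N - G) df
    p: float
    df_error: int
    group_means: dict[int, float]
    contrast_estimate: float


def anova_trend(values, ordinal_group) -> TrendResult:
    """ANOVA linear-trend test across ordered groups.

    The linear contrast uses centered group codes as coefficients; the
    error term is the pooled within-group mean square (df = N − G).
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(ordinal_group)
    keep = ~np.isnan(y)
    y, g = y[keep], g[keep]
    levels = np.unique(g)
    if levels.size < 2:
        raise DegenerateDataError("trend test needs >= 2 ordinal levels")
    ns = np.array([(g == lv).sum() for lv in levels], dtype=float)
    means = np.array([y[g == lv].mean() for lv in levels])
    sse = sum(((y[g == lv] - m) ** 2).sum() for lv, m in zip(levels, means))
    df_err = int(y.size - levels.size)
    if df_err <= 0:
        raise InsufficientDataError("no within-group degrees of freedom")
    mse = sse / df_err
    codes = levels.astype(float)
    c = codes - codes.mean()
    estimate = float((c * means).sum())
    if mse <= 0.0:
        p = 0.0 if abs(estimate) > 0 else 1.0
        return TrendResult(math.inf if abs(estimate) > 0 else 0.0, p, df_err,
                           dict(zip(levels.tolist(), means.tolist())), estimate)
    f = estimate**2 / (mse * (c**2 / ns).sum())
    p = float(stats.f.sf(f, 1, df_err))
    return TrendResult(float(f), p, df_err, dict(zip(levels.tolist(), means.tolist())), estimate)


@dataclass
class ScoreValidation:
    """Score-validity report: trend across risk-factor counts and the
    affected-vs-unaffected comparison."""

    trend: TrendResult
    mean_affected: float | None
    mean_unaffected: float | None
    t: float | None
    t_p: float | None

    @property
    def trend_p(self) -> float:
        return self.trend.p


def validate_score(scores, mets_status, risk_counts) -> ScoreValidation:
    """Check the score behaves like a severity index: it should rise with
    the number of dichotomous risk factors (linear trend) and separate
    affected from unaffected individuals (pooled t-test)."""
    s = np.asarray(scores, dtype=float)
    status = np.asarray(mets_status, dtype=bool)
    counts = np.asarray(risk_counts)
    if not (s.size == status.size == counts.size):
        raise SchemaError("scores, status and risk counts must align")
    trend = anova_trend(s, counts)
    if status.all() or (~status).all():
        warnings.warn("all individuals share one status; comparison skipped", stacklevel=2)
        return ScoreValidation(trend, None, None, None, None)
    from .genetics import t_test_raw

    res = t_test_raw(s[status], s[~status])
    return ScoreValidation(
        trend,
        mean_affected=res.mean1,
        mean_unaffected=res.mean2,
        t=res.t,
        t_p=res.p,
    )
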