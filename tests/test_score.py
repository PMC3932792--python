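"""PCA score model: retention, rotation, weighting, trend and validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import metscore as m
from metscore.score import SEVERITY_DIRECTIONS, _varimax, anova_trend
from metscore.trait_prep import TRAITS


def test_two_factor_structure_recovered(cohort5k, model5k):
    config, _, _, _ = cohort5k
    assert model5k.n_components == 2
    assert (model5k.eigenvalues > 1.0).all()
    expected = m.expected_explained_variance(config)
    assert model5k.explained.sum() == pytest.approx(expected, abs=0.05)
    assert model5k.all_explained.sum() == pytest.approx(1.0, abs=1e-9)
    assert (np.abs(model5k.loadings) <= 1.0 + 1e-9).all()


def test_components_oriented_toward_severity(model5k):
    direction = np.array([SEVERITY_DIRECTIONS[t] for t in TRAITS])
    for j in range(model5k.n_components):
        assert direction @ model5k.loadings[:, j] > 0


def test_equal_weight_score_sd_is_sqrt2(zmatrix5k, model5k):
    sv = m.compute_scores(model5k, zmatrix5k, weighting="equal")
    assert sv.mean == pytest.approx(0.0, abs=1e-9)
    assert sv.sd == pytest.approx(np.sqrt(2.0), abs=1e-8)


def test_proportional_weights_sum_to_one(zmatrix5k, model5k):
    sv = m.compute_scores(model5k, zmatrix5k, weighting="proportional")
    assert sv.weights.sum() == pytest.approx(1.0)
    manual = m.component_scores(model5k, zmatrix5k).to_numpy() @ sv.weights
    assert np.allclose(sv.scores, manual)


def test_component_scores_uncorrelated(zmatrix5k):
    for rotate in (False, True):
        model = m.fit_score_model(zmatrix5k, rotate=rotate)
        s = m.component_scores(model, zmatrix5k)
        r = np.corrcoef(s.to_numpy().T)
        assert abs(r[0, 1]) < 0.05
        assert np.allclose(s.std(ddof=1), 1.0, atol=1e-9)


def test_single_component_score_is_that_component():
    rng = np.random.default_rng(0)
    f = rng.standard_normal(800)
    z = pd.DataFrame({f"x{i}": 0.8 * f + 0.6 * rng.standard_normal(800) for i in range(4)})
    z = (z - z.mean()) / z.std(ddof=1)
    model = m.fit_score_model(z)
    assert model.n_components == 1
    sv = m.compute_scores(model, z, weighting="equal")
    assert np.allclose(sv.scores, m.component_scores(model, z)["PC1"])


def test_isotropic_data_handled_by_strict_threshold():
    rng = np.random.default_rng(1)
    z = pd.DataFrame(rng.standard_normal((10000, 6)), columns=[f"x{i}" for i in range(6)])
    model = m.fit_score_model(z)
    assert model.n_components >= 1
    assert np.allclose(model.eigenvalues, 1.0, atol=0.2)


def test_generic_columns_use_largest_loading_positive():
    rng = np.random.default_rng(2)
    f = rng.standard_normal(2000)
    z = pd.DataFrame({
        "a": -0.9 * f + 0.44 * rng.standard_normal(2000),
        "b": -0.8 * f + 0.6 * rng.standard_normal(2000),
        "c": 0.3 * f + 0.95 * rng.standard_normal(2000),
    })
    model = m.fit_score_model(z)
    for j in range(model.n_components):
        col = model.loadings[:, j]
        assert col[np.argmax(np.abs(col))] > 0


def test_no_component_above_threshold_errors():
    rng = np.random.default_rng(3)
    z = pd.DataFrame(rng.standard_normal((500, 4)), columns=list("abcd"))
    with pytest.raises(m.ParameterError, match="threshold"):
        m.fit_score_model(z, eigen_threshold=10.0)


def test_collinear_traits_rejected():
    rng = np.random.default_rng(4)
    x = rng.standard_normal(100)
    z = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.standard_normal(100)})
    with pytest.raises(m.DegenerateDataError):
        m.fit_score_model(z)


def test_raising_tg_raises_score(cohort5k, zmatrix5k, model5k):
    """Monotone severity: more triglycerides -> higher score, both weightings."""
    for weighting in ("proportional", "equal"):
        base = m.compute_scores(model5k, zmatrix5k, weighting=weighting).scores
        bumped = zmatrix5k.copy()
        bumped["tg_mg_dl"] = bumped["tg_mg_dl"] + 0.5  # higher transformed TG
        new = m.compute_scores(model5k, bumped, weighting=weighting).scores
        assert (new > base).all()


def test_score_invariant_to_affine_trait_rescaling(zmatrix5k, model5k):
    rescaled = zmatrix5k.copy()
    rescaled["waist_cm"] = 3.0 * rescaled["waist_cm"] + 7.0
    z2 = (rescaled - rescaled.mean()) / rescaled.std(ddof=1)
    model2 = m.fit_score_model(z2)
    s1 = m.compute_scores(model5k, zmatrix5k).scores
    s2 = m.compute_scores(model2, z2).scores
    assert np.allclose(s1, s2, atol=1e-9)


def test_varimax_preserves_communalities():
    rng = np.random.default_rng(5)
    L = rng.normal(size=(6, 2)) * 0.5
    R = _varimax(L)
    assert np.allclose((L**2).sum(axis=1), (R**2).sum(axis=1), atol=1e-8)


def test_model_text_round_trip(model5k, zmatrix5k):
    back = m.ScoreModel.from_text(model5k.to_text())
    assert back.traits == model5k.traits
    assert np.allclose(back.loadings, model5k.loadings)
    s1 = m.compute_scores(model5k, zmatrix5k).scores
    s2 = m.compute_scores(back, zmatrix5k).scores
    assert np.allclose(s1, s2)


# --- ANOVA linear trend ------------------------------------------------------


def test_trend_flat_means_gives_p_near_one():
    rng = np.random.default_rng(6)
    g = np.repeat([0, 1, 2, 3], 40)
    y = rng.standard_normal(160)
    y = y - np.concatenate([np.full(40, y[g == k].mean()) for k in range(4)])
    res = anova_trend(y, g)
    assert res.contrast_estimate == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0, abs=1e-9)


def test_trend_detects_constructed_linear_signal():
    rng = np.random.default_rng(7)
    g = np.repeat(np.arange(5), 50)
    y = g.astype(float) + rng.normal(0, 0.1, 250)
    assert anova_trend(y, g).p < 1e-6


def test_trend_two_level_equals_regression_slope_test():
    """With two levels the linear contrast and the OLS slope test share
    error df, so their p-values coincide exactly."""
    rng = np.random.default_rng(8)
    g = np.repeat([0, 1], 30)
    y = 0.4 * g + rng.standard_normal(60)
    res = anova_trend(y, g)
    lr = stats.linregress(g.astype(float), y)
    assert res.p == pytest.approx(lr.pvalue, abs=1e-6)


def test_trend_multi_level_close_to_regression_when_linear():
    rng = np.random.default_rng(9)
    g = np.repeat(np.arange(5), 50)
    y = 0.1 * g + rng.normal(0, 1.0, 250)
    res = anova_trend(y, g)
    lr = stats.linregress(g.astype(float), y)
    # error terms differ by the (tiny) lack-of-fit component only
    assert np.log10(res.p) == pytest.approx(np.log10(lr.pvalue), abs=0.05)


def test_trend_single_level_errors():
    with pytest.raises(m.DegenerateDataError):
        anova_trend([1.0, 2.0, 3.0], [1, 1, 1])


# --- score validation --------------------------------------------------------


def test_validate_score_on_default_cohort(cohort5k, zmatrix5k, model5k):
    _, pheno, _, _ = cohort5k
    scores = m.compute_scores(model5k, zmatrix5k).scores
    status, excluded = m.classify_table(pheno.loc[scores.index])
    assert not excluded
    report = m.validate_score(scores, status["mets"], status["risk_count"])
    assert report.trend_p < 0.001
    assert report.mean_affected > report.mean_unaffected
    assert report.t_p < 0.001


def test_validate_score_permuted_labels_null():
    rng = np.random.default_rng(10)
    scores = rng.standard_normal(400)
    counts = rng.integers(0, 5, 400)
    hits = 0
    for _ in range(200):
        status = rng.permutation(np.repeat([True, False], 200))
        rep = m.validate_score(scores, status, counts)
        if rep.t_p < 0.05:
            hits += 1
    assert 0.05 * 200 * 0.2 <= hits <= 0.05 * 200 * 3  # ~5% rejections


def test_validate_score_degenerate_status_warns():
    with pytest.warns(UserWarning):
        rep = m.validate_score(
            np.arange(10.0), np.ones(10, dtype=bool), np.repeat([0, 1], 5)
        )
    assert rep.t_p is None
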