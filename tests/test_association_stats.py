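import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from egmst.association_stats import (
    Normalizer,
    bonferroni_alpha,
    compute_vif,
    correlation_heatmap,
    fit_mixed_logit,
    fit_multivariable,
    fit_single_mixed,
    normalize_features,
    screen_features,
    vif_prune,
)
from egmst.synthetic_data import simulate_logistic_clusters


# ---------------------------------------------------------------- normalization


def test_normalizer_zscore_on_training_rows(rng):
    df = pd.DataFrame({"a": rng.normal(5, 2, 400), "b": rng.normal(-3, 0.5, 400)})
    mask = np.zeros(400, dtype=bool)
    mask[:300] = True
    out, norm = normalize_features(df, ["a", "b"], train_mask=mask)
    for col in ("a", "b"):
        assert out.loc[mask, col].mean() == pytest.approx(0.0, abs=1e-9)
        assert out.loc[mask, col].std(ddof=0) == pytest.approx(1.0, abs=1e-9)
    assert not norm.log_cols and not norm.constant_columns


def test_normalizer_log_transforms_skewed(rng):
    df = pd.DataFrame({"sk": rng.lognormal(0, 1.5, 2000), "sym": rng.normal(size=2000)})
    _, norm = normalize_features(df, ["sk", "sym"])
    assert "sk" in norm.log_cols
    assert "sym" not in norm.log_cols


def test_normalizer_constant_column_flagged():
    df = pd.DataFrame({"c": np.ones(50), "x": np.arange(50.0)})
    out, norm = normalize_features(df, ["c", "x"])
    assert norm.constant_columns == ["c"]
    assert (out["c"] == 0).all()


def test_normalizer_no_test_leakage(rng):
    """Transform statistics must come from the fit rows only."""
    df = pd.DataFrame({"a": rng.normal(size=100)})
    norm = Normalizer.fit(df.iloc[:50], ["a"])
    shifted = pd.DataFrame({"a": df["a"] + 100.0})
    out = norm.transform(shifted)
    assert out["a"].mean() > 50  # test rows are NOT re-centred on themselves


def test_correlation_heatmap_properties(rng):
    df = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
    pear, spear = correlation_heatmap(df, list("abc"))
    for m in (pear, spear):
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)


# ---------------------------------------------------------------- mixed logit


def test_mixed_logit_reduces_to_pooled_glm_when_sigma_zero():
    import statsmodels.api as sm

    df = simulate_logistic_clusters(20, 200, beta=[0.8, -0.5], sigma=0.0, seed=5)
    fit = fit_mixed_logit(df[["x0", "x1"]].to_numpy(), df["y"].to_numpy(),
                          df["map_id"].to_numpy(), feature_names=["x0", "x1"])
    glm = sm.GLM(df["y"], sm.add_constant(df[["x0", "x1"]]),
                 family=sm.families.Binomial()).fit()
    assert fit.sigma < 0.15  # variance shrinks toward zero
    for name, ref in zip(["intercept", "x0", "x1"], glm.params):
        b, _ = fit.coef(name)
        assert b == pytest.approx(ref, rel=0.02, abs=0.02)


def test_mixed_logit_recovers_odds_ratio():
    df = simulate_logistic_clusters(20, 300, beta=[np.log(2.0)], sigma=0.5, seed=9)
    fit = fit_mixed_logit(df[["x0"]].to_numpy(), df["y"].to_numpy(),
                          df["map_id"].to_numpy(), feature_names=["x0"])
    b, se = fit.coef("x0")
    assert np.exp(b) == pytest.approx(2.0, rel=0.25)
    assert 0 < se < 0.5
    assert 0.1 < fit.sigma < 1.2


def test_mixed_logit_matches_lme4():
    """Cross-check the Gauss-Hermite fit against R's glmer on one dataset."""
    rscript = shutil.which("Rscript")
    assert rscript, "Rscript with lme4 is part of the supported toolchain"
    df = simulate_logistic_clusters(15, 200, beta=[0.7], sigma=0.6, seed=21)
    fit = fit_mixed_logit(df[["x0"]].to_numpy(), df["y"].to_numpy(),
                          df["map_id"].to_numpy(), feature_names=["x0"])
    with tempfile.TemporaryDirectory() as td:
        csv = Path(td) / "d.csv"
        df.to_csv(csv, index=False)
        r_code = f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- glmer(y ~ x0 + (1 | map_id), data=d, family=binomial, nAGQ=15)
        cat(fixef(m)[1], fixef(m)[2],
            sqrt(as.numeric(VarCorr(m)$map_id)), sep="\\n")
        """
        out = subprocess.run([rscript, "-e", r_code], capture_output=True,
                             text=True, check=True)
    ref_int, ref_b, ref_sigma = (float(v) for v in out.stdout.split())
    assert fit.coef("intercept")[0] == pytest.approx(ref_int, abs=0.02)
    assert fit.coef("x0")[0] == pytest.approx(ref_b, abs=0.02)
    assert fit.sigma == pytest.approx(ref_sigma, abs=0.05)


def test_mixed_logit_needs_two_groups():
    df = simulate_logistic_clusters(1, 100, beta=[0.5], sigma=0.0, seed=0)
    with pytest.raises(ValueError):
        fit_mixed_logit(df[["x0"]].to_numpy(), df["y"].to_numpy(),
                        df["map_id"].to_numpy())


def test_summary_frame_consistency():
    df = simulate_logistic_clusters(10, 150, beta=[0.6], sigma=0.3, seed=2)
    fit = fit_mixed_logit(df[["x0"]].to_numpy(), df["y"].to_numpy(),
                          df["map_id"].to_numpy(), feature_names=["x0"])
    sf = fit.summary_frame()
    assert np.allclose(sf["odds_ratio"], np.exp(sf["coef"]))
    assert ((sf["p_value"] >= 0) & (sf["p_value"] <= 1)).all()
    assert (sf["ci_low"] <= sf["odds_ratio"]).all()
    assert (sf["odds_ratio"] <= sf["ci_high"]).all()


# ---------------------------------------------------------------- screening


def test_bonferroni_alpha():
    assert bonferroni_alpha(46) == pytest.approx(0.05 / 46)
    assert bonferroni_alpha(1) == 0.05
    with pytest.raises(ValueError):
        bonferroni_alpha(0)


def test_screen_features_separates_signal_from_noise(rng):
    df = simulate_logistic_clusters(12, 250, beta=[1.2], sigma=0.3, seed=3)
    df = df.rename(columns={"x0": "signal"})
    df["noise"] = rng.normal(size=len(df))
    df = df.rename(columns={"y": "label"})
    results, significant = screen_features(df, ["signal", "noise"])
    assert "signal" in significant
    assert "noise" not in significant
    by_name = {r.feature: r for r in results}
    assert by_name["signal"].odds_ratio > 1.5
    assert by_name["signal"].ci_low > 1.0


# ---------------------------------------------------------------- VIF


def test_vif_matches_closed_form(rng):
    import statsmodels.api as sm

    n = 300
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    x3 = x1 + x2 + 0.3 * rng.normal(size=n)
    df = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
    vifs = compute_vif(df, ["x1", "x2", "x3"])
    for j, name in enumerate(["x1", "x2", "x3"]):
        others = df.drop(columns=name)
        r2 = sm.OLS(df[name], sm.add_constant(others)).fit().rsquared
        assert vifs[name] == pytest.approx(1.0 / (1.0 - r2), rel=1e-8)


def test_vif_perfect_collinearity_inf(rng):
    x = rng.normal(size=100)
    df = pd.DataFrame({"a": x, "b": 2.0 * x, "c": rng.normal(size=100)})
    vifs = compute_vif(df, ["a", "b", "c"])
    assert np.isinf(vifs["a"]) and np.isinf(vifs["b"])
    assert np.isfinite(vifs["c"])


def test_vif_prune_drops_collinear(rng):
    n = 400
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    df = pd.DataFrame({"x1": x1, "x2": x2,
                       "dup": x1 + 0.05 * rng.normal(size=n)})
    kept = vif_prune(df, ["x1", "x2", "dup"], threshold=10.0)
    assert "x2" in kept
    assert len(kept) == 2  # one of the near-duplicates is gone
    assert max(compute_vif(df, kept).values()) <= 10.0


# ---------------------------------------------------------------- multivariable


def test_fit_multivariable_empty_and_covariates(rng):
    df = simulate_logistic_clusters(10, 150, beta=[0.8], sigma=0.3, seed=6)
    df = df.rename(columns={"y": "label"})
    assert fit_multivariable(df, []) == []
    df["const_cov"] = 1.0
    df["cov"] = rng.normal(size=len(df))
    res = fit_multivariable(df, ["x0"], covariates=["cov", "const_cov"])
    assert [r.feature for r in res] == ["x0"]  # covariates not reported
    assert res[0].model == "multi"
    assert res[0].odds_ratio > 1.0


def test_fit_single_mixed_on_feature_table(small_table):
    res = fit_single_mixed(small_table.dropna(subset=["A_B"]), "A_B")
    assert res.model == "single"
    assert 0 <= res.p_value <= 1
    assert res.ci_low <= res.odds_ratio <= res.ci_high
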