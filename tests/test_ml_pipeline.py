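import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from egmst.ml_pipeline import (
    enumerate_model_configs,
    grouped_split,
    make_folds,
    metrics_at_threshold,
    pca_baseline,
    ppv_from_rates,
    rf_importance,
    roc_operating_point,
    run_model_suite,
    sequential_addition,
    single_feature_benchmark,
    train_eval,
    undersample,
)


def _toy_table(n_groups=12, rows_per_group=6, n_neg=400, n_maps=5, seed=0,
               n_features=3, informative=True):
    """Labeled table with VT-site positive groups and map-scoped negatives."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        for i in range(rows_per_group):
            rows.append({"label": 1, "group_id": f"site{g}",
                         "map_id": f"m{g % n_maps}"})
    for i in range(n_neg):
        rows.append({"label": 0, "group_id": f"neg:m{i % n_maps}",
                     "map_id": f"m{i % n_maps}"})
    df = pd.DataFrame(rows)
    for j in range(n_features):
        shift = (2.5 if (informative and j == 0) else 0.0) * df["label"]
        df[f"f{j}"] = rng.normal(size=len(df)) + shift
    df["rhythm"] = "SR"
    df["point_id"] = [f"p{i}" for i in range(len(df))]
    return df


# ---------------------------------------------------------------- splitting


@settings(max_examples=30, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_grouped_split_leakage_invariant(seed):
    df = _toy_table(seed=seed % 7)
    plan = grouped_split(df, seed=seed)
    # exact partition
    both = np.concatenate([plan.train_idx, plan.test_idx])
    assert np.array_equal(np.sort(both), np.arange(len(df)))
    # no positive group on both sides
    g = df["group_id"].to_numpy()
    lab = df["label"].to_numpy()
    tr = {g[i] for i in plan.train_idx if lab[i] == 1}
    te = {g[i] for i in plan.test_idx if lab[i] == 1}
    assert not (tr & te)
    assert tr and te  # both sides keep positives


def test_grouped_split_fraction():
    df = _toy_table(n_groups=10, rows_per_group=5, n_neg=1000)
    plan = grouped_split(df, frac=0.8, seed=1)
    neg_train = (df.iloc[plan.train_idx]["label"] == 0).sum()
    assert neg_train == 800  # negatives split at row level, exactly 80%
    pos_train = (df.iloc[plan.train_idx]["label"] == 1).sum()
    assert 0.6 * 50 <= pos_train <= 0.95 * 50  # group granularity around 80%


def test_grouped_split_needs_two_groups():
    df = _toy_table(n_groups=1)
    with pytest.raises(ValueError):
        grouped_split(df)


def test_make_folds_partition_and_group_integrity():
    df = _toy_table(n_groups=12)
    folds = make_folds(df, k=10, repeats=3, seed=0)
    assert folds.shape == (3, len(df))
    g = df["group_id"].to_numpy()
    lab = df["label"].to_numpy()
    for r in range(3):
        assert set(np.unique(folds[r])) == set(range(10))
        for grp in np.unique(g[lab == 1]):
            assert len(np.unique(folds[r][(g == grp) & (lab == 1)])) == 1
    # negatives are re-randomized between repeats
    neg = lab == 0
    assert not np.array_equal(folds[0][neg], folds[1][neg])


def test_make_folds_too_few_groups():
    df = _toy_table(n_groups=5)
    with pytest.raises(ValueError):
        make_folds(df, k=10)


# ---------------------------------------------------------------- undersampling


def test_undersample_exact_counts():
    df = _toy_table(n_groups=20, rows_per_group=5, n_neg=900)  # 100 pos
    for ratio, want in (("1:1", 100), ("1:5", 500)):
        out = undersample(df, ratio, seed=0)
        assert (out["label"] == 1).sum() == 100  # all positives kept
        assert (out["label"] == 0).sum() == want
    assert undersample(df, "none", seed=0) is df


def test_undersample_stratified_by_map():
    df = _toy_table(n_groups=4, rows_per_group=5, n_neg=1000, n_maps=4)
    out = undersample(df, "1:1", seed=3)
    neg = out[out["label"] == 0]["map_id"].value_counts()
    assert neg.sum() == 20
    assert neg.max() - neg.min() <= 1  # proportional allocation of equal pools


def test_undersample_keeps_all_when_short():
    df = _toy_table(n_groups=20, rows_per_group=5, n_neg=50)
    out = undersample(df, "1:5", seed=0)  # wants 500, only 50 exist
    assert len(out) == len(df)


# ---------------------------------------------------------------- metrics


def test_roc_operating_point_closest_to_corner():
    # ROC vertices (0,0) -> (0.2, 0.9) -> (1,1); the middle vertex wins
    y = np.array([1] * 10 + [0] * 10)
    scores = np.array([0.9] * 9 + [0.2] + [0.9] * 2 + [0.2] * 8)
    thr, sens, spec = roc_operating_point(y, scores)
    assert sens == pytest.approx(0.9)
    assert spec == pytest.approx(0.8)
    m = metrics_at_threshold(y, scores, thr)
    assert m["sensitivity_pct"] == pytest.approx(90.0)
    assert m["specificity_pct"] == pytest.approx(80.0)


def test_metrics_against_confusion_oracle(rng):
    from sklearn.metrics import confusion_matrix, f1_score, roc_auc_score

    y = rng.integers(0, 2, 200)
    scores = rng.uniform(size=200) + 0.3 * y
    thr = 0.6
    m = metrics_at_threshold(y, scores, thr)
    pred = (scores >= thr).astype(int)
    tn, fp, fn, tp = confusion_matrix(y, pred).ravel()
    assert m["sensitivity_pct"] == pytest.approx(100 * tp / (tp + fn))
    assert m["specificity_pct"] == pytest.approx(100 * tn / (tn + fp))
    assert m["ppv_pct"] == pytest.approx(100 * tp / (tp + fp))
    assert m["f1_pct"] == pytest.approx(100 * f1_score(y, pred))
    assert m["auc"] == pytest.approx(roc_auc_score(y, scores))


def test_ppv_closed_form_and_prevalence_monotonicity():
    # PPV = sens*pi / (sens*pi + (1-spec)(1-pi))
    sens, spec = 0.814, 0.714
    for pi in (0.0731, 0.2, 0.5):
        want = sens * pi / (sens * pi + (1 - spec) * (1 - pi))
        assert ppv_from_rates(sens, spec, pi) == pytest.approx(want)
    curve = [ppv_from_rates(sens, spec, pi) for pi in (0.3, 0.15, 0.0731, 0.03)]
    assert all(b < a for a, b in zip(curve, curve[1:]))  # drops with prevalence


# ---------------------------------------------------------------- importance / PCA


def test_rf_importance_recovers_informative_feature():
    hits = 0
    for seed in range(20):
        df = _toy_table(seed=seed, n_features=5)
        rank = rf_importance(df, [f"f{j}" for j in range(5)], seed=seed)
        assert len(rank) == 5
        hits += rank["feature"].iloc[0] == "f0"
    assert hits >= 18  # informative feature ranks first in >= 90% of seeds


def test_rf_importance_null_scores_near_zero():
    df = _toy_table(seed=1, n_features=4, informative=False)
    rank = rf_importance(df, [f"f{j}" for j in range(4)], seed=1)
    assert np.all(np.abs(rank["score"]) < 0.15)


def test_rf_importance_deterministic():
    df = _toy_table(seed=2, n_features=4)
    a = rf_importance(df, [f"f{j}" for j in range(4)], seed=5)
    b = rf_importance(df, [f"f{j}" for j in range(4)], seed=5)
    pd.testing.assert_frame_equal(a, b)


def test_sequential_addition_curve():
    df = _toy_table(n_groups=12, n_features=4)
    ranking = [f"f{j}" for j in range(4)]
    curve = sequential_addition(df, ranking, k_folds=5, repeats=1, seed=0,
                                select_top=2)
    assert curve["n_features"].tolist() == [1, 2, 3, 4]
    assert ((curve["cv_auc"] >= 0) & (curve["cv_auc"] <= 1)).all()
    assert curve.attrs["selected"] == ranking[:2]


def test_pca_baseline_variance_and_orthogonality(rng):
    df = _toy_table(n_groups=8, n_neg=300, n_features=6, seed=4)
    proj, pca, n_comp = pca_baseline(df, [f"f{j}" for j in range(6)],
                                     variance_target=0.90)
    assert np.cumsum(pca.explained_variance_ratio_)[n_comp - 1] >= 0.90
    C = pca.components_[:n_comp]
    assert np.allclose(C @ C.T, np.eye(n_comp), atol=1e-10)
    assert {"label", "group_id"} <= set(proj.columns)


def test_pca_rank_two_needs_two_components(rng):
    base = rng.normal(size=(500, 2))
    X = base @ rng.normal(size=(2, 6))
    df = pd.DataFrame(X, columns=[f"f{j}" for j in range(6)])
    df["label"] = 0
    _, _, n_comp = pca_baseline(df, [f"f{j}" for j in range(6)],
                                variance_target=0.99)
    assert n_comp == 2


# ---------------------------------------------------------------- train/eval


def test_train_eval_perfectly_separable():
    df = _toy_table(n_groups=12, rows_per_group=6, n_neg=300, seed=0)
    df["f0"] = df["label"] * 10.0  # separably informative
    plan = grouped_split(df, seed=0)
    rep = train_eval(df, plan, "logistic", ["f0", "f1", "f2"],
                     k_folds=5, repeats=2, seed=0)
    assert rep.cv_auc_mean == pytest.approx(1.0)
    assert rep.test_metrics["auc"] == pytest.approx(1.0)
    assert rep.test_metrics["sensitivity_pct"] == pytest.approx(100.0)
    assert rep.test_metrics["specificity_pct"] == pytest.approx(100.0)


def test_train_eval_shuffled_labels_chance_level():
    """Permutation null: over independent shuffles the CV AUC is centred on
    0.5 (a single fixed permutation keeps a realized chance association)."""
    means = []
    for sh in range(4):
        df = _toy_table(n_groups=16, rows_per_group=6, n_neg=500, seed=8)
        rng = np.random.default_rng(sh)
        df["label"] = rng.permutation(df["label"].to_numpy())
        # shuffling breaks site structure; every positive row is its own group
        df["group_id"] = np.where(df["label"] == 1,
                                  [f"g{i}" for i in range(len(df))],
                                  "neg:" + df["map_id"])
        plan = grouped_split(df, seed=0)
        rep = train_eval(df, plan, "RF", ["f0", "f1", "f2"],
                         k_folds=5, repeats=2, seed=0)
        means.append(rep.cv_auc_mean)
    assert abs(np.mean(means) - 0.5) < 0.05


def test_train_eval_undersampled_ratios_run():
    df = _toy_table(n_groups=12, n_neg=600, seed=3)
    plan = grouped_split(df, seed=1)
    for ratio in ("1:1", "1:5"):
        rep = train_eval(df, plan, "RF", ["f0", "f1", "f2"],
                         undersample_ratio=ratio, k_folds=5, repeats=1, seed=1)
        assert rep.test_metrics["auc"] > 0.8  # informative f0 still found


@pytest.mark.parametrize("algorithm", ["RF", "SVM", "KNN"])
def test_algorithms_supported(algorithm):
    df = _toy_table(n_groups=12, n_neg=300, seed=2)
    plan = grouped_split(df, seed=2)
    rep = train_eval(df, plan, algorithm, ["f0", "f1", "f2"],
                     k_folds=5, repeats=1, seed=2)
    assert 0.5 <= rep.test_metrics["auc"] <= 1.0


# ---------------------------------------------------------------- suite


def test_enumerate_model_configs_is_the_stated_cross():
    cfgs = enumerate_model_configs()
    assert len(cfgs) == 10
    assert {(c.signal, c.maps) for c in cfgs} == {
        ("both", "all"), ("both", "SR"), ("both", "LV"), ("both", "RV"),
        ("unipolar", "SR"), ("unipolar", "LV"), ("unipolar", "RV"),
        ("bipolar", "SR"), ("bipolar", "LV"), ("bipolar", "RV"),
    }
    assert not any(c.maps == "BIV" for c in cfgs)  # BIV never modelled alone


def test_config_feature_scoping():
    from egmst.core_model import MAP_TYPE_COLUMNS, Channel, build_registry
    from egmst.ml_pipeline import _config_features

    reg = build_registry()
    cfgs = {c.name: c for c in enumerate_model_configs()}
    uni_feats = _config_features(cfgs["unipolar_SR"])
    assert set(uni_feats) == set(reg.names_for_model(Channel.UNIPOLAR))
    all_feats = _config_features(cfgs["both_all"])
    assert set(MAP_TYPE_COLUMNS) <= set(all_feats)  # indicators only for "all"
    assert not set(MAP_TYPE_COLUMNS) & set(uni_feats)


def test_run_model_suite_produces_all_reports(feature_table):
    reports = run_model_suite(feature_table, seed=0, k_folds=2, repeats=1,
                              select_top=None)
    assert len(reports) == 10
    for name, rep in reports.items():
        assert rep.config_name == name
        assert 0.0 <= rep.test_metrics["auc"] <= 1.0


def test_single_feature_benchmark_oracles(rng):
    df = _toy_table(n_groups=12, n_neg=400, seed=5)
    df["perfect"] = df["label"].astype(float)
    df["noise"] = rng.normal(size=len(df))
    df["flat"] = 1.0
    plan = grouped_split(df, seed=0)
    out = single_feature_benchmark(df, plan, features=("perfect", "noise", "flat"))
    assert out["perfect"] == pytest.approx(1.0)
    assert abs(out["noise"] - 0.5) < 0.15
    assert np.isnan(out["flat"])
    assert out["noise"] >= 0.5  # orientation guarantees AUC >= 0.5


def test_distance_sensitivity_prevalence_monotone(small_table):
    from egmst.ml_pipeline import distance_sensitivity

    sens = distance_sensitivity(small_table, radii=tuple(range(3, 11)),
                                seed=0, k_folds=3, repeats=1)
    assert len(sens) == 8
    prev = sens["prevalence"].to_numpy()
    assert np.all(np.diff(prev) >= 0)  # nested labels
    aucs = sens["test_auc"].to_numpy()
    ok = ~np.isnan(aucs)
    assert ok.any()
    assert np.all((aucs[ok] >= 0) & (aucs[ok] <= 1))


def test_unipolar_outperforms_bipolar_on_average():
    """Signal-type ordering under the default simulated study conditions:
    averaged over 10 seeds, the unipolar SR model's held-out AUC is at least
    the bipolar-only SR model's (the unipolar channel carries the
    repolarization effects the bipolar channel cannot see)."""
    from egmst import SimConfig, build_feature_table, generate_study
    from egmst.ml_pipeline import _config_features, _config_rows

    cfgs = {c.name: c for c in enumerate_model_configs()}
    uni, bip = [], []
    for seed in range(10):
        table = build_feature_table(generate_study(SimConfig(seed=seed)))
        for name, store in (("unipolar_SR", uni), ("bipolar_SR", bip)):
            cfg = cfgs[name]
            rows = _config_rows(table, cfg).reset_index(drop=True)
            plan = grouped_split(rows, seed=seed)
            rep = train_eval(rows, plan, "RF", _config_features(cfg),
                             config_name=name, k_folds=10, repeats=2, seed=seed)
            store.append(rep.test_metrics["auc"])
    assert np.mean(uni) > np.mean(bip)
    assert np.mean(uni) >= 0.9 and np.mean(bip) >= 0.9  # both models work
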