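"""Leakage-aware classification protocol for ablation-target localization.

Implements the full training/evaluation protocol: an 80/20 split grouped so
that all points labelling the same VT critical site stay on one side; 10x
repeated 10-fold cross-validation with group-safe positive folds and freshly
randomized negatives per repeat; stratified undersampling (1:1, 1:5 or none);
random-forest permutation-importance feature ranking with sequential feature
addition (top-20 default); a PCA baseline at 90% explained variance; RF /
SVM / KNN / logistic classifiers with the published hyperparameters; ROC
operating point closest to the top-left corner; distance-sensitivity sweeps
(3-10 mm); and single-feature benchmarks (GradAT, GradARI, voltage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .core_model import MAP_TYPE_COLUMNS, Channel, build_registry
from .association_stats import Normalizer

__all__ = [
    "SplitPlan", "ModelConfig", "EvalReport",
    "grouped_split", "make_folds", "undersample",
    "rf_importance", "sequential_addition", "pca_baseline",
    "train_eval", "enumerate_model_configs", "run_model_suite",
    "distance_sensitivity", "single_feature_benchmark",
    "roc_operating_point", "metrics_at_threshold", "ppv_from_rates",
]

logger = logging.getLogger(__name__)

ALGORITHMS = ("RF", "SVM", "KNN", "logistic")


def _make_estimator(algorithm: str, seed: int):
    """Published hyperparameters: RF 100 trees / min leaf 1; SVM Gaussian
    kernel, box constraint 1; KNN k=10 Euclidean."""
    if algorithm == "RF":
        return RandomForestClassifier(n_estimators=100, min_samples_leaf=1,
                                      random_state=seed, n_jobs=1)
    if algorithm == "SVM":
        return SVC(kernel="rbf", C=1.0, random_state=seed)
    if algorithm == "KNN":
        return KNeighborsClassifier(n_neighbors=10, metric="euclidean")
    if algorithm == "logistic":
        return LogisticRegression(max_iter=2000)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _scores(est, X: np.ndarray) -> np.ndarray:
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    return est.decision_function(X)  # monotone in any probability calibration


# ---------------------------------------------------------------------------
# Splits, folds, undersampling
# ---------------------------------------------------------------------------


@dataclass
class SplitPlan:
    train_idx: np.ndarray  # positional row indices into the table
    test_idx: np.ndarray
    seed: int


def grouped_split(table: pd.DataFrame, frac: float = 0.8,
                  seed: int = 0) -> SplitPlan:
    """80/20 split; positive VT-site groups are kept whole, negatives split
    at row level.  Reproducible under the seed."""
    rng = np.random.default_rng(seed)
    labels = table["label"].to_numpy()
    groups = table["group_id"].to_numpy()
    pos_rows = np.nonzero(labels == 1)[0]
    neg_rows = np.nonzero(labels == 0)[0]
    pos_groups = pd.unique(groups[pos_rows])
    if len(pos_groups) < 2:
        raise ValueError("need at least 2 positive VT-site groups to split")
    perm = rng.permutation(len(pos_groups))
    sizes = pd.Series(groups[pos_rows]).value_counts()
    target = frac * len(pos_rows)
    train_groups, acc = [], 0
    for g in np.asarray(pos_groups, dtype=object)[perm]:
        if acc >= target and train_groups:
            break
        train_groups.append(g)
        acc += int(sizes[g])
    if len(train_groups) == len(pos_groups):  # keep at least one test group
        train_groups = train_groups[:-1]
    train_set = set(train_groups)
    pos_train = pos_rows[[groups[i] in train_set for i in pos_rows]]
    pos_test = pos_rows[[groups[i] not in train_set for i in pos_rows]]
    neg_perm = rng.permutation(neg_rows)
    n_neg_train = int(round(frac * len(neg_rows)))
    train = np.sort(np.concatenate([pos_train, neg_perm[:n_neg_train]]))
    test = np.sort(np.concatenate([pos_test, neg_perm[n_neg_train:]]))
    return SplitPlan(train_idx=train, test_idx=test, seed=seed)


def make_folds(train_table: pd.DataFrame, k: int = 10, repeats: int = 10,
               seed: int = 0) -> np.ndarray:
    """(repeats, n_train) fold ids; positives assigned fold-wise by VT-site
    group, negatives randomized afresh each repeat."""
    rng = np.random.default_rng(seed)
    labels = train_table["label"].to_numpy()
    groups = train_table["group_id"].to_numpy()
    n = len(train_table)
    pos_rows = np.nonzero(labels == 1)[0]
    neg_rows = np.nonzero(labels == 0)[0]
    pos_groups = pd.unique(groups[pos_rows])
    if len(pos_groups) < k:
        raise ValueError(f"need >= {k} positive groups for {k}-fold CV, "
                         f"have {len(pos_groups)}")
    out = np.zeros((repeats, n), dtype=int)
    for r in range(repeats):
        gperm = np.asarray(pos_groups, dtype=object)[rng.permutation(len(pos_groups))]
        gfold = {g: i % k for i, g in enumerate(gperm)}
        for i in pos_rows:
            out[r, i] = gfold[groups[i]]
        nperm = rng.permutation(neg_rows)
        out[r, nperm] = np.arange(len(neg_rows)) % k
    return out


def undersample(table: pd.DataFrame, ratio: str, seed: int = 0,
                rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Keep all positives; sample negatives without replacement to the ratio,
    stratified by map (proportional allocation)."""
    if ratio in (None, "none"):
        return table
    mult = {"1:1": 1, "1:5": 5}[ratio]
    rng = rng if rng is not None else np.random.default_rng(seed)
    pos = table[table["label"] == 1]
    neg = table[table["label"] == 0]
    n_want = mult * len(pos)
    if n_want >= len(neg):
        logger.warning("undersample: only %d negatives for target %d; keeping all",
                       len(neg), n_want)
        return table
    # proportional per-map allocation (largest remainder), then sample
    counts = neg.groupby("map_id").size()
    quota = counts / counts.sum() * n_want
    take = np.floor(quota).astype(int)
    remainder = n_want - int(take.sum())
    order = (quota - take).sort_values(ascending=False).index
    for mid in order[:remainder]:
        take[mid] += 1
    parts = [pos]
    for mid, cnt in take.items():
        sub = neg[neg["map_id"] == mid]
        cnt = min(int(cnt), len(sub))
        if cnt:
            sel = rng.choice(len(sub), size=cnt, replace=False)
            parts.append(sub.iloc[np.sort(sel)])
    return pd.concat(parts).sort_index()


# ---------------------------------------------------------------------------
# Metrics and operating point
# ---------------------------------------------------------------------------


def roc_operating_point(y: np.ndarray, scores: np.ndarray) -> tuple[float, float, float]:
    """Threshold on the ROC curve closest to the top-left corner (0, 1).

    Returns (threshold, sensitivity, specificity) at that point.
    """
    fpr, tpr, thr = roc_curve(y, scores)
    d = np.hypot(fpr, 1.0 - tpr)
    i = int(np.argmin(d))
    return float(thr[i]), float(tpr[i]), float(1.0 - fpr[i])


def metrics_at_threshold(y: np.ndarray, scores: np.ndarray,
                         threshold: float) -> dict[str, float]:
    """AUC plus rates (%) from the single confusion matrix at the threshold."""
    y = np.asarray(y)
    pred = (np.asarray(scores) >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    ppv = tp / (tp + fp) if tp + fp else np.nan
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else np.nan
    auc = roc_auc_score(y, scores) if len(np.unique(y)) == 2 else np.nan
    return {"auc": float(auc), "f1_pct": 100 * f1, "ppv_pct": 100 * ppv,
            "sensitivity_pct": 100 * sens, "specificity_pct": 100 * spec}


def ppv_from_rates(sensitivity: float, specificity: float,
                   prevalence: float) -> float:
    """Closed-form positive predictive value at the given class prevalence."""
    num = sensitivity * prevalence
    return num / (num + (1.0 - specificity) * (1.0 - prevalence))


# ---------------------------------------------------------------------------
# Feature ranking / reduction
# ---------------------------------------------------------------------------


def _impute_median(train: pd.DataFrame, apply_to: list[pd.DataFrame],
                   features: list[str]) -> tuple[pd.Series, list[pd.DataFrame]]:
    med = train[features].median(numeric_only=True)
    med = med.fillna(0.0)
    out = [df.assign(**{c: df[c].fillna(med[c]) for c in features})
           for df in apply_to]
    return med, out


def rf_importance(table: pd.DataFrame, features: list[str],
                  seed: int = 0, holdout_frac: float = 0.25) -> pd.DataFrame:
    """Permutation-importance ranking from an RF on a held-out quarter.

    Returns a frame (feature, score) sorted by descending importance;
    deterministic under the seed.
    """
    rng = np.random.default_rng(seed)
    _, [tbl] = _impute_median(table, [table], features)
    # stratified holdout so the AUC scorer always sees both classes
    lab = tbl["label"].to_numpy()
    hold_parts, fit_parts = [], []
    for cls in np.unique(lab):
        rows = rng.permutation(np.nonzero(lab == cls)[0])
        n_hold = max(1, int(holdout_frac * rows.size))
        hold_parts.append(rows[:n_hold])
        fit_parts.append(rows[n_hold:])
    hold = np.sort(np.concatenate(hold_parts))
    fit = np.sort(np.concatenate(fit_parts))
    est = _make_estimator("RF", seed)
    est.fit(tbl.iloc[fit][features], tbl.iloc[fit]["label"])
    imp = permutation_importance(est, tbl.iloc[hold][features],
                                 tbl.iloc[hold]["label"], scoring="roc_auc",
                                 n_repeats=5, random_state=seed)
    out = pd.DataFrame({"feature": features, "score": imp.importances_mean})
    return out.sort_values("score", ascending=False, ignore_index=True)


def sequential_addition(table: pd.DataFrame, ranking: list[str],
                        algorithm: str = "RF", seed: int = 0,
                        k_folds: int = 10, repeats: int = 1,
                        select_top: int = 20,
                        k_grid: list[int] | None = None) -> pd.DataFrame:
    """CV AUC as features are added from most to least important.

    Returns a frame (n_features, cv_auc); attrs['selected'] holds the default
    selection (top ``select_top`` of the ranking).
    """
    ks = k_grid or list(range(1, len(ranking) + 1))
    folds = make_folds(table, k=k_folds, repeats=repeats, seed=seed)
    rows = []
    for k in ks:
        feats = ranking[:k]
        aucs = _cv_aucs(table, feats, algorithm, folds, "none", seed)
        rows.append({"n_features": k, "cv_auc": float(np.mean(aucs))})
    out = pd.DataFrame(rows)
    out.attrs["selected"] = ranking[:min(select_top, len(ranking))]
    return out


def pca_baseline(table: pd.DataFrame, features: list[str],
                 variance_target: float = 0.90,
                 train_mask: np.ndarray | None = None,
                 seed: int = 0) -> tuple[pd.DataFrame, PCA, int]:
    """Project onto the smallest PC set explaining >= the variance target.

    Loadings are fit on training rows only; the whole table is projected.
    """
    mask = np.ones(len(table), dtype=bool) if train_mask is None else train_mask
    _, [tbl] = _impute_median(table.loc[mask], [table], features)
    pca = PCA(random_state=seed)
    pca.fit(tbl.loc[mask, features])
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, variance_target) + 1)
    Z = pca.transform(tbl[features])[:, :n_comp]
    cols = [f"PC{i + 1}" for i in range(n_comp)]
    proj = pd.DataFrame(Z, columns=cols, index=table.index)
    for c in ("map_id", "point_id", "label", "group_id"):
        if c in table.columns:
            proj[c] = table[c]
    return proj, pca, n_comp


# ---------------------------------------------------------------------------
# Training and evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    config_name: str
    algorithm: str
    features: list[str]
    cv_auc_mean: float
    cv_auc_ci: tuple[float, float]
    cv_metrics_mean: dict[str, float]
    cv_metrics_sd: dict[str, float]
    operating_threshold: float
    test_metrics: dict[str, float]
    n_train: int
    n_test: int

    def to_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {
            "config": self.config_name, "algorithm": self.algorithm,
            "cv_auc": self.cv_auc_mean,
            "cv_auc_ci_low": self.cv_auc_ci[0], "cv_auc_ci_high": self.cv_auc_ci[1],
        }
        row.update({f"test_{k}": v for k, v in self.test_metrics.items()})
        return row


def _cv_aucs(train_tbl: pd.DataFrame, features: list[str], algorithm: str,
             folds: np.ndarray, ratio: str, seed: int) -> list[float]:
    aucs = []
    rng = np.random.default_rng(seed)
    for r in range(folds.shape[0]):
        for f in np.unique(folds[r]):
            val = train_tbl.iloc[folds[r] == f]
            fit_tbl = train_tbl.iloc[folds[r] != f]
            if val["label"].nunique() < 2 or fit_tbl["label"].nunique() < 2:
                continue
            fit_tbl = undersample(fit_tbl, ratio, rng=rng)
            _, [fit_i, val_i] = _impute_median(fit_tbl, [fit_tbl, val], features)
            est = _make_estimator(algorithm, seed)
            est.fit(fit_i[features], fit_i["label"])
            aucs.append(float(roc_auc_score(val["label"],
                                            _scores(est, val_i[features]))))
    return aucs


def _bootstrap_ci(values: np.ndarray, seed: int, n_boot: int = 1000,
                  level: float = 0.95) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return (np.nan, np.nan)
    boots = rng.choice(values, size=(n_boot, values.size), replace=True).mean(axis=1)
    a = (1 - level) / 2
    return (float(np.quantile(boots, a)), float(np.quantile(boots, 1 - a)))


def train_eval(table: pd.DataFrame, split: SplitPlan, algorithm: str,
               features: list[str], config_name: str = "model",
               undersample_ratio: str = "none",
               k_folds: int = 10, repeats: int = 10, seed: int = 0,
               normalize: bool = True) -> EvalReport:
    """Cross-validated training and held-out evaluation of one configuration.

    Per CV iteration: undersample the fitting part, impute by its medians,
    fit, and take ROC metrics on the validation fold at the operating point
    closest to (0, 1).  The iteration with the highest validation AUC
    supplies the model and threshold applied to the held-out test rows.
    Degenerate single-class folds are skipped and logged.
    """
    train_tbl = table.iloc[split.train_idx].reset_index(drop=True)
    test_tbl = table.iloc[split.test_idx].reset_index(drop=True)
    if normalize:
        norm = Normalizer.fit(train_tbl, features)
        train_tbl = norm.transform(train_tbl)
        test_tbl = norm.transform(test_tbl)
    folds = make_folds(train_tbl, k=k_folds, repeats=repeats, seed=seed)
    rng = np.random.default_rng(seed)

    per_iter: list[dict[str, float]] = []
    best = {"auc": -np.inf, "est": None, "thr": np.nan, "medians": None}
    skipped = 0
    for r in range(folds.shape[0]):
        for f in np.unique(folds[r]):
            val = train_tbl.iloc[folds[r] == f]
            fit_tbl = train_tbl.iloc[folds[r] != f]
            if val["label"].nunique() < 2 or fit_tbl["label"].nunique() < 2:
                skipped += 1
                continue
            fit_s = undersample(fit_tbl, undersample_ratio, rng=rng)
            med, [fit_i, val_i] = _impute_median(fit_s, [fit_s, val], features)
            est = _make_estimator(algorithm, seed)
            est.fit(fit_i[features], fit_i["label"])
            scores = _scores(est, val_i[features])
            thr, _, _ = roc_operating_point(val["label"], scores)
            m = metrics_at_threshold(val["label"].to_numpy(), scores, thr)
            per_iter.append(m)
            if m["auc"] > best["auc"]:
                best = {"auc": m["auc"], "est": est, "thr": thr, "medians": med}
    if skipped:
        logger.info("train_eval[%s]: skipped %d degenerate folds",
                    config_name, skipped)
    if not per_iter or best["est"] is None:
        raise ValueError(f"{config_name}: no valid CV iteration")

    keys = list(per_iter[0])
    cv_mean = {k: float(np.nanmean([m[k] for m in per_iter])) for k in keys}
    cv_sd = {k: float(np.nanstd([m[k] for m in per_iter])) for k in keys}
    aucs = np.array([m["auc"] for m in per_iter])
    ci = _bootstrap_ci(aucs, seed=seed + 1)

    test_i = test_tbl.assign(**{c: test_tbl[c].fillna(best["medians"][c])
                                for c in features})
    test_scores = _scores(best["est"], test_i[features])
    test_m = metrics_at_threshold(test_tbl["label"].to_numpy(), test_scores,
                                  best["thr"])
    return EvalReport(
        config_name=config_name, algorithm=algorithm, features=list(features),
        cv_auc_mean=float(np.mean(aucs)), cv_auc_ci=ci,
        cv_metrics_mean=cv_mean, cv_metrics_sd=cv_sd,
        operating_threshold=float(best["thr"]), test_metrics=test_m,
        n_train=len(train_tbl), n_test=len(test_tbl),
    )


# ---------------------------------------------------------------------------
# Model suite / sensitivity / benchmarks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelConfig:
    name: str
    signal: str   # "both" | "unipolar" | "bipolar"
    maps: str     # "all" | "SR" | "LV" | "RV"
    algorithm: str = "RF"
    undersample_ratio: str = "none"


def enumerate_model_configs(algorithm: str = "RF") -> list[ModelConfig]:
    """The 10 signal-type x map-source configurations (BIV never alone)."""
    cfgs = [ModelConfig(f"both_{m}", "both", m, algorithm)
            for m in ("all", "SR", "LV", "RV")]
    cfgs += [ModelConfig(f"unipolar_{m}", "unipolar", m, algorithm)
             for m in ("SR", "LV", "RV")]
    cfgs += [ModelConfig(f"bipolar_{m}", "bipolar", m, algorithm)
             for m in ("SR", "LV", "RV")]
    return cfgs


def _config_features(cfg: ModelConfig) -> list[str]:
    registry = build_registry()
    if cfg.signal == "both":
        feats = list(registry.names)
    else:
        feats = registry.names_for_model(Channel(cfg.signal))
    if cfg.maps == "all":
        feats = feats + MAP_TYPE_COLUMNS
    return feats


def _config_rows(table: pd.DataFrame, cfg: ModelConfig) -> pd.DataFrame:
    if cfg.maps == "all":
        return table
    return table[table["rhythm"] == cfg.maps]


def run_model_suite(table: pd.DataFrame,
                    configs: list[ModelConfig] | None = None,
                    seed: int = 0, k_folds: int = 10, repeats: int = 10,
                    select_top: int | None = 20,
                    frac: float = 0.8) -> dict[str, EvalReport]:
    """One EvalReport per configuration; configurations without enough rows or
    positive groups are skipped with a warning."""
    configs = configs or enumerate_model_configs()
    reports: dict[str, EvalReport] = {}
    for i, cfg in enumerate(configs):
        rows = _config_rows(table, cfg).reset_index(drop=True)
        feats = _config_features(cfg)
        try:
            split = grouped_split(rows, frac=frac, seed=seed + i)
            if select_top:
                train_rows = rows.iloc[split.train_idx]
                ranking = rf_importance(train_rows, feats, seed=seed + i)
                feats = [f for f in ranking["feature"].head(select_top)]
            reports[cfg.name] = train_eval(
                rows, split, cfg.algorithm, feats, config_name=cfg.name,
                undersample_ratio=cfg.undersample_ratio,
                k_folds=k_folds, repeats=repeats, seed=seed + i)
        except ValueError as exc:
            logger.warning("suite: skipping %s (%s)", cfg.name, exc)
    return reports


def distance_sensitivity(table: pd.DataFrame,
                         radii: tuple[float, ...] = tuple(range(3, 11)),
                         algorithm: str = "RF",
                         features: list[str] | None = None,
                         seed: int = 0, k_folds: int = 10,
                         repeats: int = 2) -> pd.DataFrame:
    """Held-out AUC and prevalence as the target-region radius grows.

    ``table`` must carry ``site_distance_mm`` and ``group_id``; labels are
    re-derived per radius (nested positive sets).  Radii whose test rows lack
    positives are reported with NaN AUC.
    """
    features = features or build_registry().names
    rows = []
    for r in radii:
        tbl = table.copy()
        tbl["label"] = (tbl["site_distance_mm"] <= r).astype(int)
        if "nearest_site_id" in tbl.columns:
            tbl["group_id"] = np.where(tbl["label"] == 1,
                                       tbl["nearest_site_id"],
                                       "neg:" + tbl["map_id"].astype(str))
        prev = float(tbl["label"].mean())
        try:
            split = grouped_split(tbl, seed=seed)
            rep = train_eval(tbl, split, algorithm, features,
                             config_name=f"radius_{r}mm",
                             k_folds=k_folds, repeats=repeats, seed=seed)
            auc = rep.test_metrics["auc"]
        except ValueError as exc:
            logger.warning("distance_sensitivity: radius %s mm skipped (%s)", r, exc)
            auc = np.nan
        rows.append({"radius_mm": float(r), "test_auc": auc, "prevalence": prev})
    return pd.DataFrame(rows)


def single_feature_benchmark(table: pd.DataFrame, split: SplitPlan,
                             features: tuple[str, ...] = ("Grad_AT", "Grad_ARI", "A_B"),
                             ) -> dict[str, float]:
    """Test AUC of each raw feature alone, oriented so AUC >= 0.5.

    The defaults are the conduction-gradient, repolarization-gradient and
    voltage (bipolar peak-to-peak amplitude) benchmarks.  Constant features
    yield NaN.
    """
    test = table.iloc[split.test_idx]
    out = {}
    for f in features:
        sub = test[[f, "label"]].dropna()
        if sub[f].nunique() < 2 or sub["label"].nunique() < 2:
            out[f] = float("nan")
            continue
        auc = roc_auc_score(sub["label"], sub[f])
        out[f] = float(max(auc, 1.0 - auc))
    return out
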