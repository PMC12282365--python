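"""Feature normalization, correlations, and mixed-effects logistic screening.

The association analysis regresses the potential-ablation-target label on
each signal feature with a random intercept per substrate map (to absorb
pseudo-replication across the many points of one map), then fits a joint
multivariable model on the Bonferroni-significant features after removing
collinear ones (variance inflation factor above 10).

The random-intercept logistic marginal likelihood is integrated by adaptive
Gauss-Hermite quadrature (the integrand factorizes over maps; nodes are
re-centred at each map's posterior mode), maximized by quasi-Newton with
finite-difference gradients; Wald standard errors come from the numerical
Hessian at the optimum.  Odds ratios are per 1-SD of the (z-scored) feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit
from statsmodels.tools.numdiff import approx_hess1

__all__ = [
    "Normalizer",
    "normalize_features",
    "correlation_heatmap",
    "MixedLogitFit",
    "fit_mixed_logit",
    "AssociationResult",
    "fit_single_mixed",
    "bonferroni_alpha",
    "screen_features",
    "vif_prune",
    "compute_vif",
    "fit_multivariable",
]

logger = logging.getLogger(__name__)

SKEW_THRESHOLD = 2.0  # |skewness| above which a feature is log-transformed


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


@dataclass
class Normalizer:
    """Log-transform skewed features, then z-score; statistics from training rows.

    Features with |skewness| > 2 on the training rows get ``log1p`` after a
    shift to positive support.  Zero-variance columns are left at 0 and
    flagged in ``constant_columns``.
    """

    feature_cols: list[str]
    log_cols: dict[str, float] = field(default_factory=dict)  # col -> shift
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    constant_columns: list[str] = field(default_factory=list)

    @classmethod
    def fit(cls, table: pd.DataFrame, feature_cols: list[str],
            train_mask: np.ndarray | None = None) -> "Normalizer":
        norm = cls(feature_cols=list(feature_cols))
        rows = table if train_mask is None else table.loc[train_mask]
        for col in feature_cols:
            x = rows[col].to_numpy(dtype=float)
            x = x[np.isfinite(x)]
            if x.size == 0 or float(np.std(x)) == 0.0:
                norm.constant_columns.append(col)
                norm.means[col], norm.sds[col] = 0.0, 1.0
                continue
            if abs(float(stats.skew(x))) > SKEW_THRESHOLD:
                shift = float(np.min(x))
                norm.log_cols[col] = shift
                x = np.log1p(x - shift)
            norm.means[col] = float(np.mean(x))
            sd = float(np.std(x, ddof=0))
            norm.sds[col] = sd if sd > 0 else 1.0
            if sd == 0:
                norm.constant_columns.append(col)
        if norm.constant_columns:
            logger.warning("normalize: constant columns left at 0: %s",
                           norm.constant_columns)
        return norm

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for col in self.feature_cols:
            x = out[col].to_numpy(dtype=float)
            if col in self.constant_columns:
                out[col] = 0.0
                continue
            if col in self.log_cols:
                x = np.log1p(np.maximum(x - self.log_cols[col], 0.0))
            out[col] = (x - self.means[col]) / self.sds[col]
        return out


def normalize_features(table: pd.DataFrame, feature_cols: list[str],
                       train_mask: np.ndarray | None = None
                       ) -> tuple[pd.DataFrame, Normalizer]:
    """Fit on training rows (all rows if no mask), transform the whole table."""
    norm = Normalizer.fit(table, feature_cols, train_mask)
    return norm.transform(table), norm


def correlation_heatmap(table: pd.DataFrame, feature_cols: list[str]
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson and Spearman correlation matrices of the features."""
    if len(feature_cols) < 2:
        raise ValueError("need at least 2 features for a correlation matrix")
    sub = table[feature_cols]
    return sub.corr(method="pearson"), sub.corr(method="spearman")


# ---------------------------------------------------------------------------
# Random-intercept logistic regression (Gauss-Hermite marginal likelihood)
# ---------------------------------------------------------------------------


def _cluster_codes(groups: np.ndarray) -> tuple[np.ndarray, int]:
    _, codes = np.unique(np.asarray(groups), return_inverse=True)
    return codes, int(codes.max()) + 1


def _adaptive_loglik(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                     codes: np.ndarray, n_groups: int,
                     nodes: np.ndarray, log_w: np.ndarray,
                     penalty: float = 0.0) -> float:
    """Adaptive Gauss-Hermite marginal log-likelihood.

    The per-cluster integrand is sharply peaked relative to the N(0, sigma)
    prior once clusters have many observations, so a fixed node grid
    under-resolves it; nodes are therefore re-centred at each cluster's
    posterior mode and scaled by its Laplace curvature (the glmer nAGQ
    scheme).
    """
    p = X.shape[1]
    beta, log_sigma = theta[:p], theta[p]
    sigma = np.exp(log_sigma)
    sig2 = sigma * sigma
    xb = X @ beta

    # posterior mode of the random intercept, Newton vectorized over clusters
    b = np.zeros(n_groups)
    for _ in range(50):
        mu = expit(xb + b[codes])
        g = np.bincount(codes, weights=y - mu, minlength=n_groups) - b / sig2
        h = np.bincount(codes, weights=mu * (1 - mu), minlength=n_groups)
        step = g / (h + 1.0 / sig2)
        b += step
        if np.max(np.abs(step)) < 1e-10:
            break
    mu = expit(xb + b[codes])
    info = np.bincount(codes, weights=mu * (1 - mu), minlength=n_groups)
    tau = 1.0 / np.sqrt(info + 1.0 / sig2)

    # int h(b) db ~= sqrt(2) tau sum_k w_k exp(t_k^2) h(b + sqrt(2) tau t_k)
    bk = b[:, None] + np.sqrt(2.0) * tau[:, None] * nodes[None, :]  # (G, K)
    eta = xb[:, None] + bk[codes]                                   # (n, K)
    ll = y[:, None] * eta - np.logaddexp(0.0, eta)
    L = np.zeros((n_groups, nodes.size))
    for k in range(nodes.size):
        L[:, k] = np.bincount(codes, weights=ll[:, k], minlength=n_groups)
    log_prior = (-0.5 * (bk / sigma) ** 2
                 - 0.5 * np.log(2.0 * np.pi) - log_sigma)
    A = (L + log_prior + log_w[None, :] + nodes[None, :] ** 2
         + 0.5 * np.log(2.0) + np.log(tau)[:, None])
    m = A.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(A - m).sum(axis=1))
    loglik = float(lse.sum())
    if penalty > 0:  # ridge on sigma^2 (regularizes a drifting variance)
        loglik -= penalty * sig2
    return loglik


@dataclass
class MixedLogitFit:
    feature_names: list[str]
    beta: np.ndarray            # includes intercept first
    se: np.ndarray
    sigma: float
    sigma_se: float
    loglik: float
    converged: bool
    n_obs: int
    n_groups: int

    def coef(self, name: str) -> tuple[float, float]:
        i = self.feature_names.index(name)
        return float(self.beta[i]), float(self.se[i])

    def summary_frame(self) -> pd.DataFrame:
        z = self.beta / self.se
        pvals = 2 * stats.norm.sf(np.abs(z))
        with np.errstate(over="ignore"):
            return pd.DataFrame({
                "coef": self.beta, "se": self.se,
                "odds_ratio": np.exp(self.beta),
                "ci_low": np.exp(self.beta - 1.96 * self.se),
                "ci_high": np.exp(self.beta + 1.96 * self.se),
                "p_value": pvals,
            }, index=self.feature_names)


def fit_mixed_logit(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                    feature_names: list[str] | None = None,
                    n_quad: int = 15) -> MixedLogitFit:
    """Random-intercept logistic fit; X gets an intercept column prepended.

    Non-convergence triggers one retry with a variance-ridge penalty; the
    result is flagged (``converged``) rather than raised.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    codes, n_groups = _cluster_codes(groups)
    if n_groups < 2:
        raise ValueError("need at least 2 maps (groups) for a random intercept")
    Xd = np.column_stack([np.ones(len(y)), X])
    names = ["intercept"] + (feature_names or [f"x{i}" for i in range(X.shape[1])])

    gh_nodes, gh_w = np.polynomial.hermite.hermgauss(n_quad)
    log_w = np.log(gh_w)

    def neg(theta, penalty=0.0):
        return -_adaptive_loglik(theta, Xd, y, codes, n_groups,
                                 gh_nodes, log_w, penalty)

    theta0 = np.zeros(Xd.shape[1] + 1)
    theta0[-1] = np.log(0.3)
    bounds = [(None, None)] * Xd.shape[1] + [(-8.0, 5.0)]
    res = optimize.minimize(neg, theta0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-11})
    penalty = 0.0
    if not res.success:
        logger.warning("mixed logit did not converge (%s); retrying with "
                       "variance regularization", res.message)
        penalty = 1.0
        res = optimize.minimize(lambda t: neg(t, penalty), theta0,
                                method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 500})
    theta = res.x
    H = approx_hess1(theta, lambda t: neg(t, penalty))
    try:
        cov = np.linalg.inv(H)
        se_all = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se_all = np.full(theta.size, np.nan)
    p = Xd.shape[1]
    sigma = float(np.exp(theta[p]))
    return MixedLogitFit(
        feature_names=names, beta=theta[:p], se=se_all[:p],
        sigma=sigma, sigma_se=float(se_all[p] * sigma),  # delta method
        loglik=float(-res.fun), converged=bool(res.success),
        n_obs=len(y), n_groups=n_groups,
    )


# ---------------------------------------------------------------------------
# Association screening
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssociationResult:
    feature: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    model: str  # "single" | "multi"
    converged: bool = True


def _result_for(fit: MixedLogitFit, feature: str, model: str) -> AssociationResult:
    b, se = fit.coef(feature)
    z = b / se if se > 0 else np.nan
    # inf bounds are a legitimate representation of a separated/degenerate fit
    with np.errstate(over="ignore"):
        or_, lo, hi = np.exp(b), np.exp(b - 1.96 * se), np.exp(b + 1.96 * se)
    return AssociationResult(
        feature=feature,
        odds_ratio=float(or_),
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 1.0,
        model=model,
        converged=fit.converged,
    )


def fit_single_mixed(table: pd.DataFrame, feature: str,
                     label_col: str = "label", group_col: str = "map_id",
                     n_quad: int = 15) -> AssociationResult:
    """Single-variable random-intercept logistic association for one feature."""
    sub = table[[feature, label_col, group_col]].dropna()
    fit = fit_mixed_logit(sub[feature].to_numpy(), sub[label_col].to_numpy(),
                          sub[group_col].to_numpy(), feature_names=[feature],
                          n_quad=n_quad)
    return _result_for(fit, feature, "single")


def bonferroni_alpha(n_features: int, family_alpha: float = 0.05) -> float:
    """Per-test significance threshold after Bonferroni correction."""
    if n_features < 1:
        raise ValueError("need at least one tested feature")
    return family_alpha / n_features


def screen_features(table: pd.DataFrame, features: list[str],
                    label_col: str = "label", group_col: str = "map_id",
                    n_quad: int = 15) -> tuple[list[AssociationResult], list[str]]:
    """Single-variable fits for all features; returns (results, significant).

    Significance uses the Bonferroni-corrected threshold 0.05 / n_tested.
    """
    results = [fit_single_mixed(table, f, label_col, group_col, n_quad)
               for f in features]
    alpha = bonferroni_alpha(len(features))
    significant = [r.feature for r in results if r.p_value < alpha]
    return results, significant


# ---------------------------------------------------------------------------
# Collinearity pruning
# ---------------------------------------------------------------------------


def compute_vif(table: pd.DataFrame, features: list[str]) -> dict[str, float]:
    """VIF_j = 1 / (1 - R^2) of feature j regressed (with intercept) on the rest."""
    X = table[features].dropna().to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more rows than features for VIF")
    out = {}
    for j, name in enumerate(features):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        if ss_tot <= 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_prune(table: pd.DataFrame, features: list[str],
              threshold: float = 10.0) -> list[str]:
    """Iteratively drop the worst-VIF feature until all VIFs <= threshold."""
    keep = list(features)
    while len(keep) > 1:
        vifs = compute_vif(table, keep)
        worst = max(keep, key=lambda f: vifs[f])
        if vifs[worst] <= threshold:
            break
        logger.info("vif_prune: dropping %s (VIF=%.2f)", worst, vifs[worst])
        keep.remove(worst)
    return keep


def fit_multivariable(table: pd.DataFrame, features: list[str],
                      label_col: str = "label", group_col: str = "map_id",
                      covariates: list[str] | None = None,
                      n_quad: int = 15) -> list[AssociationResult]:
    """Joint random-intercept logistic fit of the retained features.

    ``covariates`` (e.g. map-type indicators) enter as fixed effects but are
    not reported.  An empty feature set returns an empty list with a warning.
    """
    if not features:
        logger.warning("fit_multivariable: empty retained feature set")
        return []
    covariates = [c for c in (covariates or [])
                  if table[c].nunique(dropna=True) > 1]
    cols = list(features) + covariates
    sub = table[cols + [label_col, group_col]].dropna()
    fit = fit_mixed_logit(sub[cols].to_numpy(), sub[label_col].to_numpy(),
                          sub[group_col].to_numpy(), feature_names=cols,
                          n_quad=n_quad)
    return [_result_for(fit, f, "multi") for f in features]
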