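"""Statistical battery for pattern-record tables.

Covers: range normalisation, Kruskal–Wallis with Dunn/Bonferroni post hoc
tests, random-intercept linear mixed models (square-root transformed
response, Satterthwaite-style or residual denominator df), ordered
quantile normalisation, and the distance-dependent correlation analysis
(per-distance Pearson R between species-median metrics and unpalatability,
followed by an OLS regression of R on viewing distance).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize_scalar
from scipy.special import ndtri

__all__ = [
    "DegenerateDataError",
    "range_normalize",
    "kruskal_wallis",
    "dunn_posthoc",
    "ordered_quantile_normalize",
    "KruskalResult",
    "FTestResult",
    "RandomInterceptFit",
    "fit_random_intercept",
    "wald_f_test",
    "lmm_class_distance",
    "species_median_correlations",
    "distance_correlation_regression",
    "permutation_r_band",
    "METRIC_COLUMNS",
]

log = logging.getLogger(__name__)

METRIC_COLUMNS = (
    "lum_detectability",
    "col_detectability",
    "lum_boldness",
    "col_boldness",
)


class DegenerateDataError(ValueError):
    """The data admit no meaningful value for the requested statistic."""


# ---------------------------------------------------------------------------
# normalisations


def range_normalize(values) -> np.ndarray:
    """Map values linearly onto [0, 1]: ``(x - min) / (max - min)``."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DegenerateDataError("need at least two values to range-normalize")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateDataError("constant input cannot be range-normalized")
    return (x - lo) / (hi - lo)


def ordered_quantile_normalize(values) -> np.ndarray:
    """Rank-based inverse-normal transform, ``Φ⁻¹((rank − 0.5)/n)``.

    Ties share averaged ranks; the transform is monotone in the input.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise DegenerateDataError("need at least three values")
    ranks = sps.rankdata(x, method="average")
    return ndtri((ranks - 0.5) / x.size)


# ---------------------------------------------------------------------------
# rank tests


@dataclass(frozen=True)
class KruskalResult:
    h: float
    df: int
    p: float


def _pooled_ranks(groups):
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise DegenerateDataError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise DegenerateDataError("every group must be non-empty")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        raise DegenerateDataError("all values identical")
    ranks = sps.rankdata(pooled, method="average")
    sizes = [g.size for g in groups]
    split = np.split(ranks, np.cumsum(sizes)[:-1])
    _, tie_counts = np.unique(pooled, return_counts=True)
    return split, sizes, pooled.size, tie_counts


def kruskal_wallis(groups) -> KruskalResult:
    """Kruskal–Wallis H with tie correction and chi-square reference."""
    split, sizes, n, ties = _pooled_ranks(groups)
    h = 12.0 / (n * (n + 1)) * sum(
        sz * r.mean() ** 2 for sz, r in zip(sizes, split)
    ) - 3.0 * (n + 1)
    h /= 1.0 - (ties**3 - ties).sum() / (n**3 - n)
    df = len(sizes) - 1
    return KruskalResult(h=float(h), df=df, p=float(sps.chi2.sf(h, df)))


def dunn_posthoc(groups, labels=None, adjust: str = "bonferroni") -> pd.DataFrame:
    """Pairwise Dunn z tests on mean ranks, Bonferroni-adjusted.

    Returns one row per unordered pair with columns
    ``group_a, group_b, z, p, p_adj``; ``p_adj = min(1, p · n_pairs)``.
    """
    if adjust not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    split, sizes, n, ties = _pooled_ranks(groups)
    k = len(sizes)
    if labels is None:
        labels = [str(i) for i in range(k)]
    tie_term = (ties**3 - ties).sum() / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_term
    rows = []
    n_pairs = k * (k - 1) // 2
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (split[i].mean() - split[j].mean()) / se
            p = 2.0 * sps.norm.sf(abs(z))
            p_adj = min(1.0, p * n_pairs) if adjust == "bonferroni" else p
            rows.append(
                {"group_a": labels[i], "group_b": labels[j], "z": float(z),
                 "p": float(p), "p_adj": float(p_adj)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# random-intercept linear mixed model


@dataclass(frozen=True)
class FTestResult:
    f: float
    df_num: int
    df_den: float
    p: float
    method: str


@dataclass
class RandomInterceptFit:
    """REML fit of ``y = Xβ + b_group + ε`` with one random intercept."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2_group: float
    sigma2_resid: float
    n: int
    p: int
    singular: bool
    _X: np.ndarray
    _y: np.ndarray
    _group_slices: list


def _group_indices(groups) -> list:
    groups = np.asarray(groups)
    return [np.flatnonzero(groups == g) for g in pd.unique(groups)]


def _gls_pieces(X, y, idx_list, ratio):
    """X'V0⁻¹X, X'V0⁻¹y, y'V0⁻¹y and Σ log|V0g| for V0 = I + ratio·J."""
    p = X.shape[1]
    xtx = np.zeros((p, p))
    xty = np.zeros(p)
    yty = 0.0
    logdet = 0.0
    for idx in idx_list:
        Xg, yg = X[idx], y[idx]
        ng = idx.size
        c = ratio / (1.0 + ratio * ng)
        sx, sy = Xg.sum(axis=0), yg.sum()
        xtx += Xg.T @ Xg - c * np.outer(sx, sx)
        xty += Xg.T @ yg - c * sx * sy
        yty += yg @ yg - c * sy * sy
        logdet += np.log1p(ratio * ng)
    return xtx, xty, yty, logdet


def _profiled_neg2reml(ratio, X, y, idx_list):
    n, p = X.shape
    xtx, xty, yty, logdet = _gls_pieces(X, y, idx_list, ratio)
    beta = np.linalg.solve(xtx, xty)
    rss = max(yty - beta @ xty, 1e-300)
    sigma2 = rss / (n - p)
    _, ld_xtx = np.linalg.slogdet(xtx)
    # REML criterion up to an additive constant
    return (n - p) * np.log(sigma2) + logdet + ld_xtx, beta, sigma2, xtx


def fit_random_intercept(y, X, groups) -> RandomInterceptFit:
    """REML estimation via 1-D profiling of the variance ratio.

    A boundary estimate (group variance ≈ 0) is flagged ``singular``;
    callers should then fall back to a fixed-effects analysis.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise DegenerateDataError("too few observations for the design")
    idx_list = _group_indices(groups)

    def objective(t):
        return _profiled_neg2reml(np.exp(t), X, y, idx_list)[0]

    res = minimize_scalar(objective, bounds=(-14.0, 8.0), method="bounded",
                          options={"xatol": 1e-7})
    t_hat = res.x
    crit0, *_ = _profiled_neg2reml(0.0, X, y, idx_list)
    singular = crit0 <= res.fun + 1e-8 or t_hat < -12.0
    ratio = 0.0 if singular else float(np.exp(t_hat))
    _, beta, sigma2, xtx = _profiled_neg2reml(ratio, X, y, idx_list)
    return RandomInterceptFit(
        beta=beta,
        cov_beta=sigma2 * np.linalg.inv(xtx),
        sigma2_group=ratio * sigma2,
        sigma2_resid=sigma2,
        n=n,
        p=p,
        singular=singular,
        _X=X,
        _y=y,
        _group_slices=idx_list,
    )


def _cov_beta_at(theta, fit: RandomInterceptFit) -> np.ndarray:
    s2b, s2e = theta
    ratio = max(s2b, 0.0) / s2e
    xtx, *_ = _gls_pieces(fit._X, fit._y, fit._group_slices, ratio)
    return s2e * np.linalg.inv(xtx)


def _neg2reml_at(theta, fit: RandomInterceptFit) -> float:
    s2b, s2e = theta
    if s2e <= 0 or s2b < 0:
        return np.inf
    ratio = s2b / s2e
    n, p = fit.n, fit.p
    xtx, xty, yty, logdet = _gls_pieces(fit._X, fit._y, fit._group_slices, ratio)
    beta = np.linalg.solve(xtx, xty)
    rss = max(yty - beta @ xty, 1e-300)
    _, ld_xtx = np.linalg.slogdet(xtx)
    return (
        n * np.log(s2e)
        + logdet
        + rss / s2e
        + ld_xtx
        - p * np.log(s2e)
    )


def _satterthwaite_df(fit: RandomInterceptFit, L: np.ndarray) -> float:
    """Satterthwaite-style denominator df for the multi-df Wald F on L.

    Uses the eigencontrast pooling of per-contrast Satterthwaite df: each
    1-df contrast gets ``ν = 2·φ² / (∇φ' A ∇φ)`` where ``φ = l'C(θ)l`` and
    ``A`` is the (finite-difference) REML covariance of the variance
    components ``θ = (σ²_group, σ²_resid)``.
    """
    theta = np.array([max(fit.sigma2_group, 1e-10), fit.sigma2_resid])
    h = np.maximum(1e-5 * theta, 1e-10)

    # observed information of -2·REML log-likelihood -> Var(θ̂) ≈ 2 H⁻¹
    H = np.zeros((2, 2))
    f0 = _neg2reml_at(theta, fit)
    for a in range(2):
        for b in range(a, 2):
            ea = np.eye(2)[a] * h[a]
            eb = np.eye(2)[b] * h[b]
            fpp = _neg2reml_at(theta + ea + eb, fit)
            fpm = _neg2reml_at(theta + ea - eb, fit)
            fmp = _neg2reml_at(theta - ea + eb, fit)
            fmm = _neg2reml_at(theta - ea - eb, fit)
            H[a, b] = H[b, a] = (fpp - fpm - fmp + fmm) / (4 * h[a] * h[b])
    try:
        A = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return float(fit.n - fit.p)
    if not np.all(np.isfinite(A)):
        return float(fit.n - fit.p)

    C = _cov_beta_at(theta, fit)
    lcl = L @ C @ L.T
    eigvals, eigvecs = np.linalg.eigh(lcl)
    q = L.shape[0]
    nus = []
    for d in range(q):
        b_d = eigvecs[:, d] @ L
        grad = np.zeros(2)
        for a in range(2):
            ea = np.eye(2)[a] * h[a]
            phi_p = b_d @ _cov_beta_at(theta + ea, fit) @ b_d
            phi_m = b_d @ _cov_beta_at(theta - ea, fit) @ b_d
            grad[a] = (phi_p - phi_m) / (2 * h[a])
        denom = grad @ A @ grad
        phi = b_d @ C @ b_d
        nu = 2.0 * phi**2 / denom if denom > 0 else float(fit.n - fit.p)
        nus.append(nu)
    e_sum = sum(nu / (nu - 2.0) for nu in nus if nu > 2.0)
    if e_sum <= q:
        return float(fit.n - fit.p)
    return float(2.0 * e_sum / (e_sum - q))


def wald_f_test(
    fit: RandomInterceptFit, L: np.ndarray, ddf_method: str = "satterthwaite"
) -> FTestResult:
    """Wald F test of ``Lβ = 0`` with a configurable denominator df."""
    L = np.atleast_2d(np.asarray(L, dtype=float))
    q = L.shape[0]
    lb = L @ fit.beta
    lcl = L @ fit.cov_beta @ L.T
    f = float(lb @ np.linalg.solve(lcl, lb) / q)
    if ddf_method == "satterthwaite" and not fit.singular:
        ddf = _satterthwaite_df(fit, L)
        method = "satterthwaite"
    elif ddf_method in ("satterthwaite", "residual"):
        ddf = float(fit.n - fit.p)
        method = "residual" if not fit.singular else "residual(singular)"
    else:
        raise ValueError(f"unknown ddf_method {ddf_method!r}")
    return FTestResult(f=f, df_num=q, df_den=ddf, p=float(sps.f.sf(f, q, ddf)), method=method)


def _categorical_design(df: pd.DataFrame, term: str):
    """Intercept + treatment-coded dummies (first sorted level dropped)."""
    levels = sorted(df[term].unique())
    X = [np.ones(len(df))]
    for lev in levels[1:]:
        X.append((df[term] == lev).to_numpy(dtype=float))
    X = np.column_stack(X)
    L = np.zeros((len(levels) - 1, X.shape[1]))
    for i in range(len(levels) - 1):
        L[i, i + 1] = 1.0
    return X, L, levels


def _ols_f(y, X, L) -> FTestResult:
    """Fixed-effects fallback when the random intercept is singular."""
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = resid @ resid / (n - p)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    lb = L @ beta
    f = float(lb @ np.linalg.solve(L @ cov @ L.T, lb) / L.shape[0])
    ddf = float(n - p)
    return FTestResult(f=f, df_num=L.shape[0], df_den=ddf,
                       p=float(sps.f.sf(f, L.shape[0], ddf)), method="ols_fallback")


def _fit_term_test(df, response, term, transform, ddf_method) -> tuple[FTestResult, bool]:
    y = df[response].to_numpy(dtype=float)
    if transform is not None:
        y = transform(y)
    X, L, _ = _categorical_design(df, term)
    fit = fit_random_intercept(y, X, df["species"].to_numpy())
    if fit.singular:
        log.info("singular random intercept for %s ~ %s; OLS fallback", response, term)
        return _ols_f(y, X, L), True
    return wald_f_test(fit, L, ddf_method=ddf_method), False


def lmm_class_distance(
    records: pd.DataFrame,
    response: str,
    transform=np.sqrt,
    ddf_method: str = "satterthwaite",
) -> pd.DataFrame:
    """Mixed-model F tables for one response metric.

    Fits ``transform(response) ~ distance`` (categorical, random intercept
    per species) within each defence class, and ``transform(response) ~
    defence_class`` at each fixed viewing distance.  Singular fits fall
    back to fixed-effects ANOVA with a logged note.  Returns a tidy table
    with columns ``scope, term, f, df_num, df_den, p, method, n``.
    """
    required = {"species", "defence_class", "distance_cm", response}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records table lacks columns: {sorted(missing)}")
    rows = []
    for cls, sub in records.groupby("defence_class", sort=True):
        if sub["species"].nunique() < 2 or sub["distance_cm"].nunique() < 2:
            log.warning("skipping class %s: not enough species/distances", cls)
            continue
        res, _ = _fit_term_test(sub, response, "distance_cm", transform, ddf_method)
        rows.append({"scope": f"class:{cls}", "term": "distance_cm", **res.__dict__,
                     "n": len(sub)})
    for dist, sub in records.groupby("distance_cm", sort=True):
        if sub["defence_class"].nunique() < 2:
            continue
        res, _ = _fit_term_test(sub, response, "defence_class", transform, ddf_method)
        rows.append({"scope": f"distance:{dist:g}", "term": "defence_class",
                     **res.__dict__, "n": len(sub)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# distance-dependent correlation analysis


def species_median_correlations(
    records: pd.DataFrame, metrics=METRIC_COLUMNS
) -> pd.DataFrame:
    """Per-distance Pearson R between species-median metrics and u.

    Species medians of each metric are ordered-quantile normalised and
    correlated against range-normalised unpalatability at every viewing
    distance.  Distances with constant medians are dropped with a warning.
    """
    rows = []
    for metric in metrics:
        for dist, sub in records.groupby("distance_cm", sort=True):
            med = sub.groupby("species").agg(
                value=(metric, "median"), u=("unpalatability", "first")
            )
            if len(med) < 4:
                raise DegenerateDataError("need at least 4 species")
            if med["value"].nunique() < 2 or med["u"].nunique() < 2:
                warnings.warn(
                    f"constant species medians for {metric} at {dist} cm; dropped"
                )
                continue
            v = ordered_quantile_normalize(med["value"].to_numpy())
            u = range_normalize(med["u"].to_numpy())
            r, p = sps.pearsonr(v, u)
            rows.append(
                {"metric": metric, "distance_cm": float(dist),
                 "n_species": len(med), "r": float(r), "p": float(p)}
            )
    return pd.DataFrame(rows)


def distance_correlation_regression(
    records: pd.DataFrame, metrics=METRIC_COLUMNS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fig-3-style summary: R per distance plus an OLS line of R on distance.

    Returns ``(per_distance, regression)`` tables; the regression reports
    slope, intercept, r², F(1, n−2) and p per metric and refuses fits with
    fewer than 3 retained distances.
    """
    per_distance = species_median_correlations(records, metrics)
    reg_rows = []
    for metric in metrics:
        sub = per_distance[per_distance["metric"] == metric]
        if len(sub) < 3:
            warnings.warn(f"fewer than 3 distances with defined R for {metric}")
            continue
        res = sps.linregress(sub["distance_cm"], sub["r"])
        df_den = len(sub) - 2
        f = res.rvalue**2 * df_den / max(1.0 - res.rvalue**2, 1e-300)
        reg_rows.append(
            {"metric": metric, "slope": float(res.slope),
             "intercept": float(res.intercept), "r_squared": float(res.rvalue**2),
             "f": float(f), "df_num": 1, "df_den": df_den,
             "p": float(res.pvalue)}
        )
    return per_distance, pd.DataFrame(reg_rows)


def permutation_r_band(
    x, y, n_perm: int = 999, seed: int = 0, alpha: float = 0.05
) -> tuple[float, float]:
    """Two-sided permutation band for Pearson R under the null.

    Permutes ``y`` relative to ``x`` ``n_perm`` times and returns the
    (alpha/2, 1−alpha/2) quantiles of the resulting R distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    rs = np.empty(n_perm)
    for i in range(n_perm):
        rs[i] = sps.pearsonr(x, rng.permutation(y))[0]
    lo, hi = np.quantile(rs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)
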