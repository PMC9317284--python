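"""Haseman-Elston variance components, heritability CIs, FDR control.

For each standardized trait the fixed effects (intercept, disease status,
sex) are removed by ordinary least squares and the residual products
``e_i * e_j`` over all pairs ``i <= j`` are regressed, without intercept, on

    1(i = j),  a_ij,  h_ij

where A is the additive relationship matrix and H the shared-household
matrix.  The least-squares coefficients are the moment estimates of
(sigma2_I, sigma2_G, sigma2_C); heritability is the ratio
``h2 = sigma2_G / sigma2_T`` and the shared-environment fraction
``c2 = sigma2_C / sigma2_T``.

Each component estimate is a quadratic form ``e' B_k e``, so tail
probabilities of the variance-fraction estimators are tail probabilities of
``e' (B_num - t * B_tot) e`` — a weighted sum of chi-squares under a
plug-in Gaussian law for the residuals.  These tails are computed with a
Lugannani-Rice saddlepoint approximation (numerical characteristic-function
inversion as fallback), and confidence limits come from a binary search on
the fraction scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats
from statsmodels.stats.multitest import multipletests

from .pedigree import CovarianceStructure

__all__ = [
    "UnidentifiableError",
    "VarianceComponents",
    "HEDesign",
    "HeritabilityEstimate",
    "standardize",
    "residualize",
    "hat_matrix",
    "he_fit",
    "weighted_chi2_cdf",
    "ratio_tail_probability",
    "confidence_interval",
    "bh_adjust",
    "heritability_analysis",
]

logger = logging.getLogger(__name__)

_RIDGE = 1e-8


class UnidentifiableError(ValueError):
    """Raised when variance components are aliased in the pair design."""


@dataclass
class VarianceComponents:
    sigma2_G: float
    sigma2_C: float
    sigma2_I: float

    @property
    def sigma2_T(self) -> float:
        return self.sigma2_G + self.sigma2_C + self.sigma2_I

    @property
    def h2(self) -> float:
        return self.sigma2_G / self.sigma2_T if self.sigma2_T > 0 else 0.0

    @property
    def c2(self) -> float:
        return self.sigma2_C / self.sigma2_T if self.sigma2_T > 0 else 0.0


@dataclass
class HEDesign:
    """Quadratic-form representation of the pair regression.

    ``B[k]`` satisfies ``sigma2_k_raw = e' B[k] e`` for k in "I", "G", "C"
    (a zero matrix for components excluded from the design).  ``raw`` holds
    the untruncated least-squares solution; ``n_pairs`` counts the pairs
    (diagonal included when ``include_diagonal``).  ``projection`` is the
    fixed-effects hat matrix when the predictors were projection-adjusted
    (None for the plain design).
    """

    B: dict[str, np.ndarray]
    raw: dict[str, float]
    n_pairs: int
    include_diagonal: bool
    components: tuple[str, ...]
    projection: np.ndarray | None = None

    def B_total(self) -> np.ndarray:
        return self.B["I"] + self.B["G"] + self.B["C"]


def standardize(values) -> np.ndarray:
    """Center and scale to sample mean 0, SD 1 (ddof=1 over the full sample)."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("degenerate trait: constant or non-finite values")
    return (x - x.mean()) / sd


def residualize(y, covariates: pd.DataFrame | np.ndarray):
    """OLS residuals of y on an intercept plus covariate columns.

    Rank-deficient columns (e.g. a constant sex column) are dropped with a
    warning.  Returns ``(residuals, beta, columns_used)`` where ``beta`` is
    indexed intercept-first.
    """
    y = np.asarray(y, dtype=float)
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        W = covariates.to_numpy(dtype=float)
    else:
        W = np.asarray(covariates, dtype=float)
        if W.ndim == 1:
            W = W[:, None]
        names = [f"x{k}" for k in range(W.shape[1])]
    X = np.column_stack([np.ones(len(y)), W])
    cols = ["intercept"] + names
    keep = [0]
    for j in range(1, X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            logger.warning("dropping rank-deficient covariate %r", cols[j])
    X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    e = y - X @ beta
    return e, beta, [cols[j] for j in keep]


def hat_matrix(covariates: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Hat (projection) matrix of the intercept-plus-covariates design.

    Rank-deficient covariate columns are dropped exactly as in
    ``residualize``, so the projection matches the residuals it produced.
    """
    if isinstance(covariates, pd.DataFrame):
        W = covariates.to_numpy(dtype=float)
    else:
        W = np.asarray(covariates, dtype=float)
        if W.ndim == 1:
            W = W[:, None]
    X = np.column_stack([np.ones(len(W)), W])
    keep = [0]
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, keep + [j]]) == len(keep) + 1:
            keep.append(j)
    X = X[:, keep]
    return X @ np.linalg.solve(X.T @ X, X.T)


def _pair_sum(M: np.ndarray, N: np.ndarray, include_diagonal: bool) -> float:
    """sum over pairs i<=j (or i<j) of M_ij * N_ij."""
    total = float(np.sum(M * N))
    diag = float(np.sum(np.diag(M) * np.diag(N)))
    return (total + diag) / 2.0 if include_diagonal else (total - diag) / 2.0


def he_fit(e, structure: CovarianceStructure, include_diagonal: bool = True,
           use_household: bool = True,
           components: tuple[str, ...] | None = None,
           projection: np.ndarray | None = None) -> tuple[VarianceComponents, HEDesign]:
    """Haseman-Elston pair regression for (sigma2_I, sigma2_G, sigma2_C).

    Solves the no-intercept least squares of residual products on
    (1(i=j), a_ij, h_ij) over all pairs i <= j, in closed form via the
    3x3 normal equations; negative estimates are truncated at zero.
    ``use_household=False`` drops the H column (sigma2_C fixed at 0);
    ``components`` selects an arbitrary predictor subset (e.g. ("I", "C")
    for the null fit with no additive component).

    When ``projection`` (the fixed-effects hat matrix P) is given, the
    predictor matrices are replaced by (I-P) M (I-P): since
    E[ee'] = (I-P) Sigma (I-P) for OLS residuals, this removes the
    downward bias that fixed-effect estimation otherwise induces in the
    genetic and household components.
    """
    e = np.asarray(e, dtype=float)
    n = structure.n
    if len(e) != n:
        raise ValueError("residual vector length does not match structure")
    I = np.eye(n)
    all_mats = {"I": I, "G": structure.A, "C": structure.H}
    if projection is not None:
        IP = I - projection
        all_mats = {k: IP @ M @ IP for k, M in all_mats.items()}
    if components is None:
        components = ("I", "G", "C") if use_household else ("I", "G")
    if include_diagonal and "I" not in components:
        raise ValueError("the identity component is part of the diagonal-inclusive design")
    if not include_diagonal:
        # 1(i=j) vanishes off the diagonal; sigma2_I is recovered afterwards
        # from the mean squared residual.
        components = tuple(m for m in components if m != "I")
    mats = {m: all_mats[m] for m in components}
    comps = tuple(mats)
    k = len(comps)
    G = np.empty((k, k))
    for a, ka in enumerate(comps):
        for b, kb in enumerate(comps):
            G[a, b] = _pair_sum(mats[ka], mats[kb], include_diagonal)
    # aliasing check on the pair-space Gram matrix
    d = np.sqrt(np.diag(G))
    corr = G / np.outer(d, d)
    for a in range(k):
        for b in range(a + 1, k):
            if abs(corr[a, b]) > 1.0 - 1e-10:
                raise UnidentifiableError(
                    f"components {comps[a]} and {comps[b]} are aliased in the pair design")
    if np.linalg.cond(G) > 1e12:
        raise UnidentifiableError(f"pair design is singular (components {comps})")
    Ginv = np.linalg.inv(G)
    # rhs_m = sum_{i<=j} (D_m)_ij e_i e_j = e' ((D_m + diag(D_m)) / 2) e
    half = {m: (mats[m] + np.diag(np.diag(mats[m]))) / 2.0 if include_diagonal
            else (mats[m] - np.diag(np.diag(mats[m]))) / 2.0 for m in comps}
    rhs = np.array([e @ half[m] @ e for m in comps])
    theta = Ginv @ rhs
    B = {m: np.zeros((n, n)) for m in ("I", "G", "C")}
    for a, ka in enumerate(comps):
        B[ka] = sum(Ginv[a, b] * half[kb] for b, kb in enumerate(comps))
    raw = {m: 0.0 for m in ("I", "G", "C")}
    raw.update(dict(zip(comps, theta)))
    if not include_diagonal:
        # E[e_i^2] = sigma2_I + sigma2_G a_ii + sigma2_C h_ii
        mean_sq = float(np.mean(e ** 2))
        mean_a = float(np.mean(np.diag(all_mats["G"])))
        mean_h = float(np.mean(np.diag(all_mats["C"])))
        raw["I"] = mean_sq - raw["G"] * mean_a - raw["C"] * mean_h
        B["I"] = np.eye(n) / n - mean_a * B["G"] - mean_h * B["C"]
    n_pairs = n * (n + 1) // 2 if include_diagonal else n * (n - 1) // 2
    vc = VarianceComponents(
        sigma2_G=max(raw["G"], 0.0),
        sigma2_C=max(raw["C"], 0.0),
        sigma2_I=max(raw["I"], 0.0),
    )
    design = HEDesign(B=B, raw=raw, n_pairs=n_pairs,
                      include_diagonal=include_diagonal, components=comps,
                      projection=projection)
    return vc, design


# ---------------------------------------------------------------------------
# weighted chi-square tails


def _imhof_cdf(lam: np.ndarray, q: float) -> float | None:
    """P(sum lam_i X_i <= q), X_i iid chi2_1, by Imhof's inversion integral.

    Returns None when the quadrature's own error estimate is too large to
    trust (callers then fall back to the saddlepoint approximation).
    """

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
        log_rho = 0.25 * np.sum(np.log1p((lam * u) ** 2))
        if log_rho > 600.0:  # integrand numerically zero
            return 0.0
        return np.sin(theta) / (u * np.exp(log_rho))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        try:
            val, abserr = integrate.quad(integrand, 0.0, np.inf, limit=400)
        except Exception:  # pragma: no cover - defensive
            return None
    if not np.isfinite(val) or abserr > 1e-4:
        return None
    return float(np.clip(0.5 - val / np.pi, 0.0, 1.0))


def _saddlepoint_cdf(lam: np.ndarray, q: float) -> float | None:
    """Lugannani-Rice saddlepoint approximation to the weighted-chi-square CDF.

    Fast (no quadrature) but first-order: absolute error can reach a few
    thousandths.  Returns None when the saddlepoint equation cannot be
    solved or degenerates (q at the distribution mean).
    """
    lmin, lmax = lam.min(), lam.max()

    def Kp(s):
        return np.sum(lam / (1.0 - 2.0 * s * lam))

    lo = 1.0 / (2.0 * lmin) if lmin < 0 else -1e8
    hi = 1.0 / (2.0 * lmax) if lmax > 0 else 1e8
    eps = 1e-10 * (hi - lo)
    a, b = lo + eps, hi - eps
    try:
        if (Kp(a) - q) * (Kp(b) - q) > 0:
            return None
        s_hat = optimize.brentq(lambda s: Kp(s) - q, a, b, xtol=1e-14, rtol=1e-14)
    except (ValueError, RuntimeError):
        return None
    if abs(s_hat) < 1e-8 / max(min(abs(lo), abs(hi)), 1e-8):
        return None
    K = -0.5 * np.sum(np.log1p(-2.0 * s_hat * lam))
    Kpp = 2.0 * np.sum(lam ** 2 / (1.0 - 2.0 * s_hat * lam) ** 2)
    w = np.sign(s_hat) * np.sqrt(max(2.0 * (s_hat * q - K), 0.0))
    v = s_hat * np.sqrt(Kpp)
    if w == 0.0 or v == 0.0:
        return None
    return float(np.clip(stats.norm.cdf(w + np.log(v / w) / w), 0.0, 1.0))


def weighted_chi2_cdf(lam, q: float = 0.0, method: str = "auto") -> float:
    """P(sum lam_i X_i <= q) for X_i iid chi-square(1).

    ``method="auto"`` (default) uses characteristic-function inversion
    (Imhof), accurate to quadrature precision, and falls back to the
    Lugannani-Rice saddlepoint when the quadrature is unreliable;
    ``"saddlepoint"`` forces the fast approximation (with inversion as its
    own fallback for degenerate saddlepoints), ``"inversion"`` forces Imhof.
    """
    lam = np.asarray(lam, dtype=float)
    lam = lam[np.abs(lam) > 1e-12 * max(1.0, np.abs(lam).max(initial=0.0))]
    if lam.size == 0:
        return 1.0 if q >= 0 else 0.0
    if lam.min() >= 0 and q <= 0:
        return 0.0
    if lam.max() <= 0 and q >= 0:
        return 1.0
    order = (("saddlepoint", "inversion") if method == "saddlepoint"
             else ("inversion", "saddlepoint"))
    for meth in order:
        p = _saddlepoint_cdf(lam, q) if meth == "saddlepoint" else _imhof_cdf(lam, q)
        if p is not None:
            return p
        logger.info("%s tail computation unreliable; trying alternative", meth)
    # both failed: q sits at the mean of a near-degenerate distribution
    return 0.5


def _psd_sqrt(mat: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(mat)
    return (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T


def _ratio_cdf_factory(design: HEDesign, structure: CovarianceStructure,
                       vc: VarianceComponents, component: str):
    """Build t -> P(fraction estimator <= t) under the plug-in Gaussian law.

    For the plain design the quadratic forms and the plug-in covariance are
    block diagonal by family, so eigenvalues are gathered block by block.
    The projection-adjusted design couples individuals across families and
    uses the dense path with the projected plug-in covariance
    (I-P) Sigma (I-P).
    """
    Bn, Bt = design.B[component], design.B_total()
    n = structure.n
    if design.projection is None:
        roots = []
        for idx in structure.family_blocks():
            sig = (vc.sigma2_G * structure.A[np.ix_(idx, idx)]
                   + vc.sigma2_C * structure.H[np.ix_(idx, idx)]
                   + (vc.sigma2_I + _RIDGE) * np.eye(len(idx)))
            roots.append((idx, _psd_sqrt(sig)))
        Bn_blocks = [Bn[np.ix_(idx, idx)] for idx, _ in roots]
        Bt_blocks = [Bt[np.ix_(idx, idx)] for idx, _ in roots]

        def F(t: float) -> float:
            lams = [np.linalg.eigvalsh(S @ (bn - t * bt) @ S)
                    for (idx, S), bn, bt in zip(roots, Bn_blocks, Bt_blocks)]
            return weighted_chi2_cdf(np.concatenate(lams), 0.0)

        return F
    sigma = (vc.sigma2_G * structure.A + vc.sigma2_C * structure.H
             + (vc.sigma2_I + _RIDGE) * np.eye(n))
    IP = np.eye(n) - design.projection
    S = _psd_sqrt(IP @ sigma @ IP + _RIDGE * np.eye(n))
    Un = S @ Bn @ S
    Ut = S @ Bt @ S

    def F(t: float) -> float:
        return weighted_chi2_cdf(np.linalg.eigvalsh(Un - t * Ut), 0.0)

    return F


def ratio_tail_probability(design: HEDesign, structure: CovarianceStructure,
                           vc: VarianceComponents, t: float,
                           component: str = "G") -> float:
    """P(variance-fraction estimator <= t) under e ~ N(0, plug-in Sigma).

    The fraction ``sigma2_k / sigma2_T`` is below ``t`` exactly when the
    quadratic form ``e' (B_k - t * B_total) e`` is negative (the total being
    positive), whose law is a weighted sum of chi-squares with weights the
    eigenvalues of ``Sigma^1/2 (B_k - t B_total) Sigma^1/2``.
    """
    return _ratio_cdf_factory(design, structure, vc, component)(t)


def confidence_interval(design: HEDesign, structure: CovarianceStructure,
                        vc: VarianceComponents, component: str = "G",
                        level: float = 0.95, tol: float = 1e-4) -> tuple[float, float]:
    """Confidence limits for a variance fraction by binary search on [0, 1].

    Finds t where the plug-in tail probability equals (1-level)/2 and
    1-(1-level)/2; endpoints are truncated to [0, 1].
    """
    alpha = 1.0 - level
    F = _ratio_cdf_factory(design, structure, vc, component)

    def solve(target):
        lo_t, hi_t = 0.0, 1.0
        f_lo, f_hi = F(0.0), F(1.0)
        if f_lo >= target:
            return 0.0
        if f_hi <= target:
            return 1.0
        while hi_t - lo_t > tol:
            mid = 0.5 * (lo_t + hi_t)
            if F(mid) < target:
                lo_t = mid
            else:
                hi_t = mid
        return 0.5 * (lo_t + hi_t)

    low = solve(alpha / 2.0)
    high = solve(1.0 - alpha / 2.0)
    if low > high:  # tail function non-monotone beyond tolerance
        logger.warning("CI endpoints crossed; returning widest bracket")
        low, high = min(low, high), max(low, high)
    return float(np.clip(low, 0.0, 1.0)), float(np.clip(high, 0.0, 1.0))


def component_p_value(e, structure: CovarianceStructure, design: HEDesign,
                      component: str = "G") -> float:
    """One-sided p-value for H0: the component's variance fraction is zero.

    The null plug-in covariance refits the pair regression with the tested
    component removed; the observed (untruncated) fraction is then referred
    to the upper tail of its null law.
    """
    e = np.asarray(e, dtype=float)
    null_comps = tuple(c for c in design.components if c != component)
    null_vc, _ = he_fit(e, structure, include_diagonal=design.include_diagonal,
                        components=null_comps, projection=design.projection)
    raw_tot = design.raw["I"] + design.raw["G"] + design.raw["C"]
    if raw_tot <= 0:
        return 1.0
    t_obs = design.raw[component] / raw_tot
    cdf = ratio_tail_probability(design, structure, null_vc, t_obs, component=component)
    return float(np.clip(1.0 - cdf, 0.0, 1.0))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class HeritabilityEstimate:
    trait: str
    h2: float
    c2: float
    h2_ci: tuple[float, float]
    c2_ci: tuple[float, float]
    p_h2: float
    p_c2: float
    fixed_effects: dict[str, float] = field(default_factory=dict)
    components: VarianceComponents | None = None
    p_h2_adj: float = np.nan
    p_c2_adj: float = np.nan


def heritability_analysis(traits: pd.DataFrame, covariates: pd.DataFrame,
                          structure: CovarianceStructure,
                          level: float = 0.95, fdr: float = 0.05,
                          compute_ci: bool = True,
                          adjust_for_fixed_effects: bool = True) -> pd.DataFrame:
    """Per-trait HE heritability with tail-probability CIs and BH adjustment.

    ``traits``: one column per trait, rows aligned with ``structure.ids``.
    ``covariates``: columns ``status`` (0/1 case) and ``sex`` (0/1 female),
    same row order.  Returns a tidy results table; p-values are one-sided
    for a positive variance fraction and BH-adjusted across traits.

    ``adjust_for_fixed_effects`` (default) regresses residual products on
    projection-adjusted covariance entries, removing the small-sample
    downward bias that OLS residualization induces in h2.
    """
    P = hat_matrix(covariates) if adjust_for_fixed_effects else None
    records = []
    for trait in traits.columns:
        y = standardize(traits[trait].to_numpy(dtype=float))
        e, beta, cols = residualize(y, covariates)
        vc, design = he_fit(e, structure, projection=P)
        est = HeritabilityEstimate(
            trait=trait, h2=vc.h2, c2=vc.c2,
            h2_ci=(np.nan, np.nan), c2_ci=(np.nan, np.nan),
            p_h2=component_p_value(e, structure, design, "G"),
            p_c2=component_p_value(e, structure, design, "C"),
            fixed_effects=dict(zip(cols, beta)), components=vc,
        )
        if compute_ci:
            est.h2_ci = confidence_interval(design, structure, vc, "G", level=level)
            est.c2_ci = confidence_interval(design, structure, vc, "C", level=level)
        records.append(est)
    p_h2_adj = bh_adjust([r.p_h2 for r in records])
    p_c2_adj = bh_adjust([r.p_c2 for r in records])
    rows = []
    for r, pa, pc in zip(records, p_h2_adj, p_c2_adj):
        r.p_h2_adj, r.p_c2_adj = pa, pc
        rows.append({
            "trait": r.trait,
            "h2": r.h2, "h2_ci_low": r.h2_ci[0], "h2_ci_high": r.h2_ci[1],
            "p_h2": r.p_h2, "p_h2_adj": pa,
            "c2": r.c2, "c2_ci_low": r.c2_ci[0], "c2_ci_high": r.c2_ci[1],
            "p_c2": r.p_c2, "p_c2_adj": pc,
            "significant_h2": pa <= fdr,
        })
    return pd.DataFrame(rows)
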