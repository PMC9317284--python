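"""pQTL stage: genotype QC, mixed-model scan, stepwise selection, marginal R2.

The scan regresses each standardized trait on sex plus one SNP dosage under
a linear mixed model whose random structure is the pedigree covariance

    V = s2G * A + s2C * H + s2I * I,

fitted by REML.  The best multi-SNP set is chosen by forward-backward
stepwise selection at a single alpha among the top univariate hits, and the
variance jointly explained by the selected SNPs is summarized by the
marginal R2 of the multivariable fit, with a bias-corrected accelerated
(BCA) confidence interval from a block bootstrap that resamples whole
families.

QC filters (minor allele frequency, exact Hardy-Weinberg test, greedy
windowed LD pruning) run in the order MAF -> HWE -> LD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .pedigree import CovarianceStructure
from .simulate import GenotypeTable

__all__ = [
    "LMMFit",
    "StepwiseConvergenceError",
    "maf_filter",
    "hwe_exact_test",
    "hwe_filter",
    "ld_prune",
    "qc_pipeline",
    "reml_fit",
    "univariate_scan",
    "select_candidates",
    "stepwise_select",
    "marginal_r2",
    "bca_block_bootstrap",
    "explained_variance",
]

logger = logging.getLogger(__name__)


class StepwiseConvergenceError(RuntimeError):
    """Raised when a mixed-model fit inside the stepwise path fails to converge."""


# ---------------------------------------------------------------------------
# genotype QC


def maf_filter(gt: GenotypeTable, threshold: float = 0.05) -> GenotypeTable:
    """Drop SNPs with minor allele frequency strictly below ``threshold``.

    MAF is computed on non-missing dosages of the analyzed individuals; SNPs
    whose effect allele is the major one are re-oriented (dosage -> 2 -
    dosage, alleles swapped) so the effect allele is always the minor allele.
    """
    gt = _orient_to_minor(gt)
    maf = gt.maf()
    keep = maf >= threshold
    out = gt.subset_snps(keep)
    if out.n_snps == 0:
        logger.warning("MAF filter removed every SNP")
    return out


def _orient_to_minor(gt: GenotypeTable) -> GenotypeTable:
    freq = gt.maf()
    flip = freq > 0.5
    if not flip.any():
        return gt
    dos = gt.dosages.copy()
    dos[:, flip] = 2.0 - dos[:, flip]
    snps = gt.snps.copy()
    ea = snps.loc[flip, "effect_allele"].copy()
    snps.loc[flip, "effect_allele"] = snps.loc[flip, "reference_allele"].to_numpy()
    snps.loc[flip, "reference_allele"] = ea.to_numpy()
    return GenotypeTable(gt.ids, snps, dos)


def hwe_exact_test(dosages) -> float:
    """Exact conditional Hardy-Weinberg test p-value for one SNP.

    Conditions on the allele counts and sums the probabilities of all
    heterozygote counts no more probable than the observed one.
    Monomorphic SNPs return p = 1.
    """
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    n0 = int(np.sum(d == 0))
    n1 = int(np.sum(d == 1))
    n2 = int(np.sum(d == 2))
    n = n0 + n1 + n2
    if n == 0:
        return 1.0
    rare = 2 * n2 + n1 if (2 * n2 + n1) <= n else 2 * n0 + n1
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    hom_r = (rare - hets) // 2
    hom_c = n - hets - hom_r
    from scipy.special import gammaln
    logp = (hets * np.log(2.0) - gammaln(hets + 1) - gammaln(hom_r + 1)
            - gammaln(hom_c + 1))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = np.where(hets == n1)[0][0]
    return float(min(1.0, p[p <= p[obs] * (1 + 1e-12)].sum()))


def hwe_filter(gt: GenotypeTable, threshold: float = 1e-4) -> GenotypeTable:
    """Drop SNPs whose exact HWE p-value is below ``threshold``."""
    pvals = np.array([hwe_exact_test(gt.dosages[:, j]) for j in range(gt.n_snps)])
    return gt.subset_snps(pvals >= threshold)


def ld_prune(gt: GenotypeTable, r2_max: float = 0.2, window: int = 50,
             step: int = 5) -> GenotypeTable:
    """Greedy windowed LD pruning on dosage correlations.

    Within each window of ``window`` SNPs (advancing by ``step``), while any
    surviving pair has squared Pearson correlation above ``r2_max``, the
    member with the lower MAF is dropped (tie: the later position).  Input
    must be sorted by (chromosome, position).
    """
    snps = gt.snps
    order = snps.sort_values(["chromosome", "position"], kind="stable").index
    if not np.array_equal(order.to_numpy(), np.arange(len(snps))):
        raise ValueError("SNPs must be sorted by chromosome and position")
    m = gt.n_snps
    dos = gt.dosages.copy()
    col_mean = np.nanmean(dos, axis=0)
    nanmask = np.isnan(dos)
    if nanmask.any():
        dos[nanmask] = np.take(col_mean, np.where(nanmask)[1])
    maf = gt.maf()
    pos = snps["position"].to_numpy()
    keep = np.ones(m, dtype=bool)
    for start in range(0, m, step):
        idx = np.where(keep[start:start + window])[0] + start
        if len(idx) < 2:
            continue
        sub = dos[:, idx]
        sd = sub.std(axis=0)
        ok = sd > 0
        idx = idx[ok]
        if len(idx) < 2:
            continue
        while True:
            sub = dos[:, idx]
            r = np.corrcoef(sub, rowvar=False)
            r2 = r ** 2
            np.fill_diagonal(r2, 0.0)
            i, j = np.unravel_index(np.argmax(r2), r2.shape)
            if r2[i, j] <= r2_max:
                break
            a, b = idx[i], idx[j]
            if maf[a] < maf[b] or (maf[a] == maf[b] and pos[a] > pos[b]):
                drop = a
            else:
                drop = b
            keep[drop] = False
            idx = idx[idx != drop]
            if len(idx) < 2:
                break
    return gt.subset_snps(keep)


def qc_pipeline(gt: GenotypeTable, maf: float = 0.05, hwe: float = 1e-4,
                r2_max: float = 0.2, window: int = 50, step: int = 5):
    """MAF -> HWE -> LD filters; returns the surviving panel and a QC report."""
    n0 = gt.n_snps
    gt1 = maf_filter(gt, maf)
    gt2 = hwe_filter(gt1, hwe)
    gt3 = ld_prune(gt2, r2_max=r2_max, window=window, step=step)
    report = {"input": n0, "removed_maf": n0 - gt1.n_snps,
              "removed_hwe": gt1.n_snps - gt2.n_snps,
              "removed_ld": gt2.n_snps - gt3.n_snps, "output": gt3.n_snps}
    return gt3, report


# ---------------------------------------------------------------------------
# REML linear mixed model


@dataclass
class LMMFit:
    beta: np.ndarray
    se: np.ndarray
    names: list[str]
    sigma2_G: float
    sigma2_C: float
    sigma2_I: float
    loglik: float
    converged: bool
    sigma2_F: float = 0.0
    sigma2_SNPs: float = 0.0
    n: int = 0
    _extra: dict = field(default_factory=dict, repr=False)

    def wald_p(self) -> np.ndarray:
        z = self.beta / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def coef(self, name: str) -> tuple[float, float, float]:
        """(beta, SE, p) for a named fixed effect."""
        k = self.names.index(name)
        return float(self.beta[k]), float(self.se[k]), float(self.wald_p()[k])


class _REMLWorkspace:
    """Pre-sliced family blocks for fast REML evaluations.

    V = s2G*A + s2C*H + s2I*I is block diagonal by family.  Singleton
    families form one vectorized diagonal group; multi-member families are
    grouped by size and evaluated with batched numpy linear algebra.  With
    nonnegative components and a positive residual variance V is positive
    definite by construction (A and H are PSD).
    """

    def __init__(self, y, X, structure: CovarianceStructure):
        blocks = structure.family_blocks()
        self.n, self.p = X.shape
        singles = [b for b in blocks if len(b) == 1]
        s_idx = np.concatenate(singles) if singles else np.empty(0, dtype=int)
        self.s_idx = s_idx.astype(int)
        self.a_s = structure.A[self.s_idx, self.s_idx] if len(self.s_idx) else np.empty(0)
        self.ys = y[self.s_idx]
        self.Xs = X[self.s_idx]
        by_size: dict[int, list[np.ndarray]] = {}
        for b in blocks:
            if len(b) > 1:
                by_size.setdefault(len(b), []).append(b)
        self.groups = []
        for size, blist in by_size.items():
            Ab = np.stack([structure.A[np.ix_(b, b)] for b in blist])
            Hb = np.stack([structure.H[np.ix_(b, b)] for b in blist])
            Xb = np.stack([X[b] for b in blist])
            yb = np.stack([y[b] for b in blist])
            self.groups.append((Ab, Hb, Xb, yb, np.eye(size)))

    def neg_loglik_grad(self, theta):
        sG, sC, sI = theta
        p = self.p
        bad = (1e12, np.zeros(3))
        logdetV = 0.0
        XtViX = np.zeros((p, p))
        Xtu = np.zeros(p)
        ytu = 0.0
        v_s = sG * self.a_s + sC + sI
        if len(self.s_idx):
            if np.any(v_s <= 0):
                return bad
            logdetV += float(np.sum(np.log(v_s)))
            Ws = self.Xs / v_s[:, None]
            us = self.ys / v_s
            XtViX += self.Xs.T @ Ws
            Xtu += self.Xs.T @ us
            ytu += float(self.ys @ us)
        parts = []
        for Ab, Hb, Xb, yb, I in self.groups:
            V = sG * Ab + sC * Hb + sI * I
            sign, ld = np.linalg.slogdet(V)
            if np.any(sign <= 0):
                return bad
            logdetV += float(np.sum(ld))
            Vi = np.linalg.inv(V)
            W = Vi @ Xb                       # batched (k, s, p)
            u = np.einsum("kst,kt->ks", Vi, yb)
            XtViX += np.einsum("ksp,ksq->pq", Xb, W)
            Xtu += np.einsum("ksp,ks->p", Xb, u)
            ytu += float(np.einsum("ks,ks->", yb, u))
            parts.append((Ab, Hb, Vi, W, u))
        sign, logdetXtViX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return bad
        XtViX_inv = np.linalg.inv(XtViX)
        beta = XtViX_inv @ Xtu
        quad = ytu - float(Xtu @ beta)
        f = 0.5 * (logdetV + logdetXtViX + quad)
        # gradient: 0.5 * (tr(P Vk) - Py' Vk Py), P = Vi - ViX (X'ViX)^-1 X'Vi
        trVi = np.zeros(3)       # tr(Vi Vk) for k in (G, C, I)
        M = np.zeros((3, p, p))  # (ViX)' Vk (ViX)
        qf = np.zeros(3)         # Py' Vk Py
        if len(self.s_idx):
            Py_s = us - Ws @ beta
            inv2 = 1.0 / v_s ** 2
            trVi += [np.sum(self.a_s / v_s), np.sum(1.0 / v_s), np.sum(1.0 / v_s)]
            M[0] += self.Xs.T @ (self.Xs * (self.a_s * inv2)[:, None])
            M[1] += self.Xs.T @ (self.Xs * inv2[:, None])
            M[2] = M[1].copy()
            qf += [float(Py_s @ (self.a_s * Py_s)), float(Py_s @ Py_s), float(Py_s @ Py_s)]
        for Ab, Hb, Vi, W, u in parts:
            Py = u - np.einsum("ksp,p->ks", W, beta)
            VkW_A = np.einsum("kst,ktp->ksp", Ab, W)
            VkW_H = np.einsum("kst,ktp->ksp", Hb, W)
            trVi[0] += float(np.einsum("kst,kst->", Vi, Ab))
            trVi[1] += float(np.einsum("kst,kst->", Vi, Hb))
            trVi[2] += float(np.einsum("kss->", Vi))
            M[0] += np.einsum("ksp,ksq->pq", W, VkW_A)
            M[1] += np.einsum("ksp,ksq->pq", W, VkW_H)
            M[2] += np.einsum("ksp,ksq->pq", W, W)
            qf[0] += float(np.einsum("ks,kst,kt->", Py, Ab, Py))
            qf[1] += float(np.einsum("ks,kst,kt->", Py, Hb, Py))
            qf[2] += float(np.einsum("ks,ks->", Py, Py))
        grad = np.array([
            0.5 * (trVi[k] - float(np.einsum("ij,ij->", XtViX_inv, M[k])) - qf[k])
            for k in range(3)
        ])
        return f, grad


def reml_fit(y, X, structure: CovarianceStructure,
             snp_cols: list[str] | None = None,
             start: tuple[float, float, float] | None = None,
             use_household: bool = True) -> LMMFit:
    """REML fit of the three-component mixed model.

    ``X`` is a DataFrame of fixed-effect columns (an intercept is added);
    ``snp_cols`` names the columns whose joint linear predictor defines
    ``sigma2_SNPs`` (the remaining non-intercept columns define
    ``sigma2_F``).  Variance components are bounded below at zero
    (residual at 1e-8); generalized-least-squares fixed effects and Wald
    standard errors are evaluated at the optimum.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        names = [f"x{k}" for k in range(Xm.shape[1])]
    y = np.asarray(y, dtype=float)
    n = len(y)
    Xm = np.column_stack([np.ones(n), Xm])
    names = ["intercept"] + names
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise ValueError("fixed-effects design is rank deficient")
    vary = float(np.var(y, ddof=1))
    if start is None:
        start = (0.3 * vary, 0.1 * vary if use_household else 0.0, 0.6 * vary)
    bounds = [(0.0, None), (0.0, None) if use_household else (0.0, 0.0), (1e-8, None)]
    ws = _REMLWorkspace(y, Xm, structure)
    res = optimize.minimize(
        lambda th: ws.neg_loglik_grad(th), x0=np.asarray(start, dtype=float),
        method="L-BFGS-B", bounds=bounds, jac=True,
        options={"maxiter": 200, "ftol": 1e-13, "gtol": 1e-7},
    )
    if not res.success:
        # line searches can stall at machine precision; restart from the
        # current point with a realistic tolerance
        res = optimize.minimize(
            lambda th: ws.neg_loglik_grad(th), x0=res.x,
            method="L-BFGS-B", bounds=bounds, jac=True,
            options={"maxiter": 200, "ftol": 1e-10, "gtol": 1e-6},
        )
    # converged when the projected gradient vanishes: components pinned at a
    # lower bound may keep a positive (outward) gradient
    _, grad = ws.neg_loglik_grad(res.x)
    at_bound = np.array([res.x[k] <= bounds[k][0] + 1e-12 for k in range(3)])
    fixed = np.array([bounds[k][1] is not None and bounds[k][0] == bounds[k][1]
                      for k in range(3)])
    proj = np.where(fixed | (at_bound & (grad > 0)), 0.0, grad)
    grad_ok = bool(np.max(np.abs(proj)) < 1e-3)
    sG, sC, sI = res.x
    V = sG * structure.A + sC * structure.H + sI * np.eye(n)
    c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    Vi_X = linalg.cho_solve((c, low), Xm, check_finite=False)
    XtViX = Xm.T @ Vi_X
    cov_beta = np.linalg.inv(XtViX)
    beta = cov_beta @ (Vi_X.T @ y)
    se = np.sqrt(np.diag(cov_beta))
    snp_cols = snp_cols or []
    snp_idx = [names.index(s) for s in snp_cols]
    other_idx = [k for k in range(1, len(names)) if k not in snp_idx]
    s2_snps = float(np.var(Xm[:, snp_idx] @ beta[snp_idx], ddof=1)) if snp_idx else 0.0
    s2_f = float(np.var(Xm[:, other_idx] @ beta[other_idx], ddof=1)) if other_idx else 0.0
    converged = (bool(res.success) or grad_ok) and np.all(np.isfinite(se)) and np.all(se > 0)
    return LMMFit(beta=beta, se=se, names=names, sigma2_G=float(sG),
                  sigma2_C=float(sC), sigma2_I=float(sI),
                  loglik=-float(res.fun), converged=converged,
                  sigma2_F=s2_f, sigma2_SNPs=s2_snps, n=n)


# ---------------------------------------------------------------------------
# scan, selection, explained variance


def _mean_impute(col: np.ndarray) -> np.ndarray:
    out = col.astype(float).copy()
    bad = np.isnan(out)
    if bad.any():
        out[bad] = np.nanmean(out)
    return out


def univariate_scan(y, gt: GenotypeTable, structure: CovarianceStructure,
                    covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """One mixed-model fit per SNP (covariate: sex); Wald test on the dosage.

    Returns a tidy table ordered by (chromosome, position) with columns
    snp_id, effect_allele, maf, beta, se, p_value.  SNPs whose fit does not
    converge get a missing p-value.
    """
    rows = []
    maf = gt.maf()
    start = None
    for j in range(gt.n_snps):
        dose = _mean_impute(gt.dosages[:, j])
        X = pd.DataFrame({"snp": dose})
        if covariates is not None:
            X = pd.concat([covariates.reset_index(drop=True), X], axis=1)
        try:
            fit = reml_fit(y, X, structure, snp_cols=["snp"], start=start)
        except (ValueError, linalg.LinAlgError):
            fit = None
        rec = gt.snps.iloc[j]
        if fit is not None and fit.converged:
            b, se, p = fit.coef("snp")
            start = (fit.sigma2_G, fit.sigma2_C, fit.sigma2_I)
        else:
            b = se = p = np.nan
            logger.warning("scan fit did not converge for %s", rec["snp_id"])
        rows.append({"snp_id": rec["snp_id"], "chromosome": rec["chromosome"],
                     "position": rec["position"],
                     "effect_allele": rec["effect_allele"], "maf": maf[j],
                     "beta": b, "se": se, "p_value": p})
    out = pd.DataFrame(rows)
    return out.sort_values(["chromosome", "position"], kind="stable").reset_index(drop=True)


def select_candidates(scan: pd.DataFrame, k: int = 50) -> list[str]:
    """Top-k SNP ids by univariate p (ties: |z| descending, then position)."""
    valid = scan.dropna(subset=["p_value"]).copy()
    if len(valid) < k:
        logger.warning("only %d valid scan results for k=%d", len(valid), k)
    valid["absz"] = np.abs(valid["beta"] / valid["se"])
    valid = valid.sort_values(["p_value", "absz", "position"],
                              ascending=[True, False, True], kind="stable")
    return list(valid["snp_id"].head(k))


def stepwise_select(y, gt: GenotypeTable, candidates: list[str],
                    structure: CovarianceStructure,
                    covariates: pd.DataFrame | None = None,
                    alpha: float = 1e-4) -> list[str]:
    """Forward-backward stepwise SNP selection on the mixed model.

    Forward: add the candidate with the smallest Wald p among models
    extending the current set, if that p < alpha.  Backward: drop the worst
    included SNP with p >= alpha.  Repeats until stable; deterministic given
    the candidate order.  Raises StepwiseConvergenceError if a required fit
    fails, which callers translate into a candidate-pool reduction.
    """
    snp_pos = {s: k for k, s in enumerate(gt.snps["snp_id"])}
    dose = {s: _mean_impute(gt.dosages[:, snp_pos[s]]) for s in candidates}
    base = covariates.reset_index(drop=True) if covariates is not None else pd.DataFrame(index=range(len(y)))

    def fit_set(snps: list[str]) -> LMMFit:
        X = base.copy()
        for s in snps:
            X[s] = dose[s]
        fit = reml_fit(y, X, structure, snp_cols=list(snps))
        if not fit.converged:
            raise StepwiseConvergenceError(f"fit failed for set {snps}")
        return fit

    selected: list[str] = []
    while True:
        changed = False
        best_p, best_s = np.inf, None
        for s in candidates:
            if s in selected:
                continue
            cols = selected + [s]
            if np.linalg.matrix_rank(np.column_stack([dose[c] for c in cols])) < len(cols):
                continue  # collinear with current set
            try:
                fit = fit_set(cols)
            except StepwiseConvergenceError:
                raise
            _, _, p = fit.coef(s)
            if p < best_p:
                best_p, best_s = p, s
        if best_s is not None and best_p < alpha:
            selected.append(best_s)
            changed = True
        # backward pass
        while len(selected) > 0:
            fit = fit_set(selected)
            ps = [fit.coef(s)[2] for s in selected]
            worst = int(np.argmax(ps))
            if ps[worst] >= alpha:
                selected.pop(worst)
                changed = True
            else:
                break
        if not changed:
            break
    return selected


def marginal_r2(fit: LMMFit, include_snp_variance_in_denominator: bool = True) -> float:
    """Proportion of modeled variance explained by the selected SNPs.

    Numerator: sample variance of the joint SNP linear predictor.
    Denominator: sigma2_G + sigma2_C + sigma2_F + sigma2_I, plus the SNP
    predictor variance itself under the (default) marginal-R2 convention;
    the variant omitting it is available for comparison.  Clipped to [0, 1].
    """
    denom = fit.sigma2_G + fit.sigma2_C + fit.sigma2_F + fit.sigma2_I
    if include_snp_variance_in_denominator:
        denom += fit.sigma2_SNPs
    if denom <= 0:
        return 0.0
    return float(np.clip(fit.sigma2_SNPs / denom, 0.0, 1.0))


def bca_block_bootstrap(statistic, families: list[np.ndarray], B: int = 1000,
                        level: float = 0.95, seed: int = 0) -> tuple[float, float]:
    """BCA confidence interval for a statistic of family-clustered data.

    ``statistic`` maps a list of family index arrays to a scalar; families
    are resampled whole, with replacement.  Bias correction z0 comes from
    the fraction of bootstrap replicates below the point estimate and the
    acceleration from a leave-one-family-out jackknife.  The returned
    interval is clipped to [0, 1].
    """
    if len(families) < 2:
        raise ValueError("need at least 2 families to bootstrap")
    rng = np.random.default_rng(seed)
    m = len(families)
    theta_hat = statistic(families)
    boot = np.empty(B)
    for b in range(B):
        draw = rng.integers(m, size=m)
        boot[b] = statistic([families[i] for i in draw])
    if np.allclose(boot, boot[0]):
        logger.warning("degenerate bootstrap distribution; zero-width interval")
        return float(theta_hat), float(theta_hat)
    prop = np.mean(boot < theta_hat)
    z0 = stats.norm.ppf(np.clip(prop, 1.0 / (B + 1), 1.0 - 1.0 / (B + 1)))
    jack = np.array([statistic(families[:i] + families[i + 1:]) for i in range(m)])
    jmean = jack.mean()
    num = np.sum((jmean - jack) ** 3)
    den = 6.0 * np.sum((jmean - jack) ** 2) ** 1.5
    a = num / den if den > 0 else 0.0
    alpha = 1.0 - level
    out = []
    for q in (alpha / 2.0, 1.0 - alpha / 2.0):
        z = stats.norm.ppf(q)
        adj = stats.norm.cdf(z0 + (z0 + z) / (1.0 - a * (z0 + z)))
        out.append(np.quantile(boot, np.clip(adj, 0.0, 1.0)))
    low, high = sorted(out)
    return float(np.clip(low, 0.0, 1.0)), float(np.clip(high, 0.0, 1.0))


def _resampled_arrays(y, X: pd.DataFrame, structure: CovarianceStructure,
                      blocks: list[np.ndarray]):
    """Assemble y, X and a block-diagonal structure from resampled family blocks.

    Each drawn block becomes an independent family in the resampled data,
    so duplicated families contribute independent blocks (no cross-copy
    covariance)."""
    idx = np.concatenate(blocks)
    n = len(idx)
    A = np.zeros((n, n))
    Hm = np.zeros((n, n))
    fam = {}
    offset = 0
    ids = []
    for b, blk in enumerate(blocks):
        k = len(blk)
        sl = slice(offset, offset + k)
        A[sl, sl] = structure.A[np.ix_(blk, blk)]
        Hm[sl, sl] = structure.H[np.ix_(blk, blk)]
        for t in range(k):
            iid = f"b{b}_{t}"
            ids.append(iid)
            fam[iid] = f"fam{b}"
        offset += k
    st = CovarianceStructure(ids=ids, A=A, H=Hm, family_incidence=fam)
    yb = np.asarray(y, dtype=float)[idx]
    Xb = X.iloc[idx].reset_index(drop=True)
    return yb, Xb, st


def explained_variance(y, gt: GenotypeTable, structure: CovarianceStructure,
                       covariates: pd.DataFrame | None = None,
                       topk: int = 50, alpha: float = 1e-4, B: int = 1000,
                       level: float = 0.95, seed: int = 0,
                       scan: pd.DataFrame | None = None,
                       include_snp_variance_in_denominator: bool = True,
                       resample_selection: bool = False) -> dict:
    """Full per-trait pipeline: scan -> top-k -> stepwise -> R2 with BCA CI.

    On stepwise non-convergence the candidate pool shrinks by 5 (floor 10)
    and selection is retried.  By default the bootstrap refits the
    multivariable model with the selected SNP set held fixed;
    ``resample_selection`` repeats the stepwise search in each replicate.
    Returns a dict with the scan, selected SNPs, per-SNP effects, R2 and CI.
    """
    if scan is None:
        scan = univariate_scan(y, gt, structure, covariates)
    k = topk
    selected: list[str] = []
    pool_history = []
    while True:
        pool_history.append(k)
        candidates = select_candidates(scan, k)
        try:
            selected = stepwise_select(y, gt, candidates, structure, covariates, alpha)
            break
        except StepwiseConvergenceError:
            if k - 5 < 10:
                logger.warning("stepwise failed even at pool size %d", k)
                selected = []
                break
            logger.warning("stepwise non-convergence at pool %d; reducing to %d", k, k - 5)
            k -= 5
    base = covariates.reset_index(drop=True) if covariates is not None else pd.DataFrame(index=range(len(y)))
    snp_pos = {s: j for j, s in enumerate(gt.snps["snp_id"])}

    def build_X(snps):
        X = base.copy()
        for s in snps:
            X[s] = _mean_impute(gt.dosages[:, snp_pos[s]])
        return X

    result = {"scan": scan, "selected": selected, "candidate_pool_size": k,
              "pool_history": pool_history, "B": B}
    if not selected:
        result.update({"r2_snps": 0.0, "ci": (0.0, 0.0), "effects": pd.DataFrame()})
        return result
    X = build_X(selected)
    fit = reml_fit(np.asarray(y, float), X, structure, snp_cols=selected)
    eff = pd.DataFrame([{
        "snp_id": s,
        "effect_allele": gt.snps.loc[snp_pos[s], "effect_allele"],
        "chromosome": gt.snps.loc[snp_pos[s], "chromosome"],
        "position": gt.snps.loc[snp_pos[s], "position"],
        "maf": gt.maf()[snp_pos[s]],
        "beta": fit.coef(s)[0], "se": fit.coef(s)[1], "p_value": fit.coef(s)[2],
    } for s in selected])
    r2 = marginal_r2(fit, include_snp_variance_in_denominator)
    warm = (fit.sigma2_G, fit.sigma2_C, fit.sigma2_I)

    def stat(blocks):
        yb, Xb, st = _resampled_arrays(np.asarray(y, float), X, structure, blocks)
        try:
            fb = reml_fit(yb, Xb, st, snp_cols=selected, start=warm)
        except (ValueError, linalg.LinAlgError):
            return np.nan
        return marginal_r2(fb, include_snp_variance_in_denominator)

    if resample_selection:
        cov_cols = list(base.columns)

        def stat(blocks):  # noqa: F811 - opt-in honest variant
            yb, Xb, st = _resampled_arrays(np.asarray(y, float), build_X(list(snp_pos)), structure, blocks)
            gtb = GenotypeTable(st.ids, gt.snps.copy(),
                                Xb[[s for s in snp_pos]].to_numpy())
            covb = Xb[cov_cols] if cov_cols else None
            res = explained_variance(yb, gtb, st, covb, topk=k, alpha=alpha,
                                     B=0, seed=seed)
            return res["r2_snps"]

    blocks = structure.family_blocks()
    if B > 0:
        ci = bca_block_bootstrap(stat, blocks, B=B, level=level, seed=seed)
    else:
        ci = (np.nan, np.nan)
    result.update({"r2_snps": r2, "ci": ci, "effects": eff, "fit": fit})
    return result
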