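"""REML estimation of the G+K+F+C+S linear mixed model.

The model is  y = Xb + g + k + f + c + s + e  with each random term having
covariance sigma^2_i * A_i for a known relationship matrix A_i and the
residual covariance sigma^2_e * I.  Estimation is restricted maximum
likelihood by average-information (AI) updates with an EM first step and EM
fallback; components are constrained non-negative by default (pinned at a
small floor), with an unconstrained refit when a constrained fit fails to
converge.  Estimates are reported as fractions of the total phenotypic
variance, the convention used for published variance decompositions.

Also here: likelihood-ratio and Wald tests for single components (boundary
null handled with the 1/2 chi2_0 + 1/2 chi2_1 mixture), backward stepwise
model selection, observed-to-liability-scale conversion and the GREML power
calculation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg, stats

from .relmat import RelationshipMatrix


@dataclass
class LiabilityParams:
    """Population prevalence K and sample case proportion P for the
    observed-to-liability scale conversion of a thresholded binary trait."""

    prevalence_K: float
    case_proportion_P: float

    def __post_init__(self) -> None:
        for v in (self.prevalence_K, self.case_proportion_P):
            if not (0.0 < v < 1.0):
                raise ValueError("prevalence and case proportion must be in (0, 1)")


@dataclass
class VarianceFit:
    """Result of a REML fit.

    ``estimates`` are per-component fractions of phenotypic variance
    (``resid`` included, so they sum to 1); ``variances`` the absolute
    variance components on the trait scale.
    """

    components: list[str]
    estimates: dict[str, float]
    se: dict[str, float]
    variances: dict[str, float] = field(repr=False)
    loglik: float = np.nan
    wald_p: dict[str, float] = field(default_factory=dict)
    lrt_p: dict[str, float] = field(default_factory=dict)
    converged: bool = False
    constrained: bool = True
    n_iter: int = 0
    n: int = 0

    def total_variance(self) -> float:
        return float(sum(self.variances.values()))

    def narrow_sense(self) -> float:
        """Narrow-sense heritability: SNP (G) plus pedigree (K) fractions —
        in a family sample their sum is the additive genetic variance when
        shared environment is modelled alongside."""
        return float(sum(self.estimates.get(c, 0.0) for c in ("G", "K")))

    def unexplained(self) -> float:
        """Residual fraction of phenotypic variance."""
        return float(self.estimates.get("resid", np.nan))


class RemlError(RuntimeError):
    pass


def _check_design(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] < X.shape[1]:
        X = X.T
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    bad = np.where(diag < 1e-10 * max(diag.max(), 1.0))[0]
    if len(bad):
        raise RemlError(f"collinear covariate columns: {bad.tolist()}")
    return X


def _pd_inv(V: np.ndarray) -> tuple[np.ndarray, float]:
    """Inverse and log-determinant of a symmetric positive-definite matrix."""
    c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    inv = linalg.lapack.dpotri(c, lower=True)[0]
    inv = np.tril(inv) + np.tril(inv, -1).T
    return inv, logdet


def _reml_quantities(theta, mats, X, y):
    n = len(y)
    V = theta[-1] * np.eye(n)
    for t, A in zip(theta[:-1], mats):
        V += t * A
    try:
        Vi, logdetV = _pd_inv(V)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise RemlError("total covariance matrix is not positive definite") from exc
    ViX = Vi @ X
    XtViX = X.T @ ViX
    cf = linalg.cho_factor(XtViX, check_finite=False)
    logdetX = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    P = Vi - ViX @ linalg.cho_solve(cf, ViX.T, check_finite=False)
    Py = P @ y
    loglik = -0.5 * (logdetV + logdetX + float(y @ Py))
    return P, Py, loglik


def reml_fit(y: np.ndarray, X: np.ndarray | None,
             matrices: list[RelationshipMatrix],
             constrain_nonnegative: bool = True, max_iter: int = 100,
             tol: float = 1e-6, init: np.ndarray | None = None,
             _allow_refit: bool = True) -> VarianceFit:
    """Fit variance components by AI-REML.

    Parameters
    ----------
    y : phenotype vector (rows with missing values are dropped, along with
        the matching rows of ``X`` and the matrices).
    X : fixed-effect design; an intercept column is added if absent.
    matrices : relationship matrices, one per non-residual component; their
        ``component`` labels name the estimates.
    constrain_nonnegative : pin components at a small positive floor instead
        of letting them go negative.  If a pinned fit fails to converge an
        unconstrained refit is performed and flagged.
    """
    y = np.asarray(y, float).ravel()
    keep = ~np.isnan(y)
    if X is None:
        X = np.ones((len(y), 1))
    X = _check_design(X)
    if not keep.all():
        y, X = y[keep], X[keep]
    n = len(y)
    labels = [m.component for m in matrices]
    if len(set(labels)) != len(labels):
        raise RemlError("duplicate component labels")
    mats = []
    for m in matrices:
        if m.n != len(keep):
            raise RemlError("matrix dimension does not match phenotype length")
        mats.append(m.values[np.ix_(keep, keep)] if not keep.all() else m.values)

    vary = float(np.var(y, ddof=1))
    k = len(mats)
    floor = 1e-8 * vary
    theta = np.full(k + 1, vary / (k + 1)) if init is None else np.asarray(init, float)
    pinned = np.zeros(k + 1, dtype=bool)

    P, Py, loglik = _reml_quantities(theta, mats, X, y)
    converged = False
    n_iter = 0
    AI = np.eye(k + 1)
    for n_iter in range(1, max_iter + 1):
        APy = [A @ Py for A in mats] + [Py]
        trPA = [float(np.sum(P * A)) for A in mats] + [float(np.trace(P))]
        yPAPy = [float(Py @ a) for a in APy]
        score = np.array([-0.5 * (trPA[i] - yPAPy[i]) for i in range(k + 1)])
        PAPy = [P @ a for a in APy]
        AI = 0.5 * np.array([[float(APy[i] @ PAPy[j]) for j in range(k + 1)]
                             for i in range(k + 1)])

        if constrain_nonnegative:
            pinned &= ~(score > 0)  # release a pinned component if helpful
        free = ~pinned
        delta = np.zeros(k + 1)
        em_delta = theta ** 2 * np.array(
            [yPAPy[i] - trPA[i] for i in range(k + 1)]) / n
        AI_free = AI[np.ix_(free, free)]
        if n_iter == 1:
            delta[free] = em_delta[free]
        else:
            # minimum-norm Newton step: singular-value truncation keeps the
            # step benign along flat (ridge) directions of the AI matrix
            delta[free] = np.linalg.lstsq(AI_free, score[free],
                                          rcond=1e-8)[0]

        accepted = False
        for _ in range(6):  # step halving
            new_theta = theta + delta
            if constrain_nonnegative:
                newly = new_theta < 0
                new_theta[newly] = floor
            if new_theta[-1] <= 0:  # residual must stay positive
                new_theta[-1] = floor
            try:
                P_new, Py_new, ll_new = _reml_quantities(new_theta, mats, X, y)
            except RemlError:
                delta *= 0.5
                continue
            if ll_new >= loglik - 1e-8 or np.max(np.abs(delta)) < tol * vary:
                accepted = True
                break
            delta *= 0.5
        if not accepted:
            # EM fallback step (guaranteed ascent direction)
            delta = em_delta.copy()
            delta[pinned] = 0.0
            new_theta = np.maximum(theta + delta, floor if constrain_nonnegative else -np.inf)
            new_theta[-1] = max(new_theta[-1], floor)
            P_new, Py_new, ll_new = _reml_quantities(new_theta, mats, X, y)

        if constrain_nonnegative:
            pinned[:-1] = new_theta[:-1] <= floor * (1 + 1e-9)
        change = ll_new - loglik
        theta, P, Py, loglik = new_theta, P_new, Py_new, ll_new
        if abs(change) < tol:
            converged = True
            break

    if not converged and constrain_nonnegative and pinned.any() and _allow_refit:
        # mirror the published convention: non-convergence of a constrained
        # fit triggers an unconstrained REML refit, flagged in the output
        fit = reml_fit(y, X, matrices, constrain_nonnegative=False,
                       max_iter=max_iter, tol=tol, _allow_refit=False)
        fit.constrained = False
        return fit

    # SEs on the fraction scale by the delta method from the inverse AI
    try:
        cov_theta = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov_theta = np.linalg.pinv(AI)
    total = theta.sum()
    J = (np.eye(k + 1) * total - theta[:, None]) / total ** 2  # d(frac)/d(theta)
    cov_frac = J @ cov_theta @ J.T
    se_frac = np.sqrt(np.clip(np.diag(cov_frac), 0.0, None))

    names = labels + ["resid"]
    estimates = {nm: float(theta[i] / total) for i, nm in enumerate(names)}
    se = {nm: float(se_frac[i]) for i, nm in enumerate(names)}
    variances = {nm: float(theta[i]) for i, nm in enumerate(names)}
    wald_p = {}
    for nm in labels:
        z2 = (estimates[nm] / se[nm]) ** 2 if se[nm] > 0 else np.inf
        wald_p[nm] = float(stats.chi2.sf(z2, 1))
    return VarianceFit(components=list(labels), estimates=estimates, se=se,
                       variances=variances, loglik=float(loglik),
                       wald_p=wald_p, converged=converged,
                       constrained=constrain_nonnegative, n_iter=n_iter, n=n)


# ------------------------------------------------------------------- testing
def lrt(full: VarianceFit, reduced: VarianceFit) -> float:
    """Likelihood-ratio p-value for dropping one variance component.

    The null (sigma^2 = 0) lies on the boundary of the parameter space, so
    the statistic 2*(lnL_full - lnL_reduced) is referred to the mixture
    1/2 chi2_0 + 1/2 chi2_1.  A non-positive statistic gives p = 1 (the
    point mass at zero contributes its full 1/2 alongside chi2_1's tail at 0).
    """
    if not set(reduced.components) < set(full.components):
        raise ValueError("reduced model is not nested in the full model")
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat <= 0:
        return 1.0
    return float(0.5 * stats.chi2.sf(stat, 1))


def stepwise_select(y: np.ndarray, X: np.ndarray | None,
                    matrices: list[RelationshipMatrix], alpha: float = 0.05,
                    **reml_kwargs) -> tuple[list[str], list[VarianceFit]]:
    """Backward stepwise selection over variance components.

    Starting from the full model, each round refits the model without each
    remaining component to get LRT p-values, takes Wald p-values from the
    full fit, and removes the component that is non-significant in BOTH
    tests and has the largest Wald p.  Stops when every remaining component
    is significant in at least one test (an empty final model is legal).
    Returns the final component labels and the trace of fits (each annotated
    with its ``lrt_p``).
    """
    current = list(matrices)
    trace: list[VarianceFit] = []
    while current:
        fit = reml_fit(y, X, current, **reml_kwargs)
        for m in current:
            reduced_mats = [o for o in current if o.component != m.component]
            reduced = reml_fit(y, X, reduced_mats, **reml_kwargs)
            fit.lrt_p[m.component] = lrt(fit, reduced)
        trace.append(fit)
        removable = [m.component for m in current
                     if fit.wald_p[m.component] > alpha
                     and fit.lrt_p[m.component] > alpha]
        if not removable:
            break
        worst = max(removable, key=lambda c: fit.wald_p[c])
        current = [m for m in current if m.component != worst]
    if not current:
        trace.append(reml_fit(y, X, [], **reml_kwargs))
    return [m.component for m in current], trace


# ------------------------------------------------------- liability & power
def liability_multiplier(params: LiabilityParams) -> float:
    """Variance-scale factor c converting observed-scale heritability of a
    thresholded binary trait to the liability scale:

        c = K^2 (1-K)^2 / (P (1-P) z^2),   z = phi(Phi^-1(1-K)).
    """
    K, P = params.prevalence_K, params.case_proportion_P
    z = stats.norm.pdf(stats.norm.ppf(1.0 - K))
    return float(K ** 2 * (1.0 - K) ** 2 / (P * (1.0 - P) * z ** 2))


def liability_transform(h2_obs: float, se_obs: float,
                        params: LiabilityParams) -> tuple[float, float]:
    """Observed-scale heritability and SE to the liability scale."""
    c = liability_multiplier(params)
    return h2_obs * c, se_obs * c


def liability_transform_inverse(h2_liab: float, se_liab: float,
                                params: LiabilityParams) -> tuple[float, float]:
    c = liability_multiplier(params)
    return h2_liab / c, se_liab / c


def greml_power(n: int | tuple[int, int], h2: float, var_pi: float = 2e-5,
                alpha: float = 0.05,
                liability: LiabilityParams | None = None,
                n_genotyped: int | None = None) -> float:
    """Power of GREML to detect SNP heritability ``h2``.

    Quantitative design: SE(h2) = sqrt(2 / (n^2 var_pi)), non-centrality
    (h2/SE)^2, power the noncentral chi2_1 tail beyond the alpha critical
    value.  Case-control design (``n`` a (cases, controls) tuple or
    ``liability`` given): h2 is first converted from the liability to the
    observed scale; ``n_genotyped`` overrides the analysis sample size when
    fewer individuals have genotypes than phenotypes.
    """
    if not (0.0 <= h2 <= 1.0):
        raise ValueError("h2 must be in [0, 1]")
    if isinstance(n, tuple):
        n_cases, n_controls = n
        total = n_cases + n_controls
        if liability is None:
            raise ValueError("case-control design requires liability parameters")
        liability = replace(liability,
                            case_proportion_P=n_cases / total)
        n_eff = n_genotyped if n_genotyped is not None else total
    else:
        n_eff = n_genotyped if n_genotyped is not None else n
    h2_use = h2
    if liability is not None:
        h2_use = h2 / liability_multiplier(liability)
    se = np.sqrt(2.0 / (n_eff ** 2 * var_pi))
    ncp = (h2_use / se) ** 2
    crit = stats.chi2.ppf(1.0 - alpha, 1)
    return float(stats.ncx2.sf(crit, 1, ncp)) if ncp > 0 else float(alpha)
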