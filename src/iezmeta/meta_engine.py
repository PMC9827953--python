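"""Multilevel random-effects meta-analysis with a known sampling vcov.

The marginal model for the effect-size vector y is

    y ~ N(X beta,  M),    M = V + sum_k sigma_k^2 Z_k Z_k',

where V is the known sampling variance-covariance matrix (including
shared-control covariances) and each Z_k Z_k' is the block indicator of one
grouping factor (observation, clade, species-in-clade, source,
study-in-source). Variance components are estimated by REML; fixed effects
are generalized least squares at the estimated M, with Wald (normal)
confidence intervals.

Fit statistics follow standard meta-analytic practice: Cochran's Q_E for
residual heterogeneity from the V-weighted fixed-effects fit, Wald-type
omnibus Q_M tests for moderators (main effects tested after dropping their
interactions), AICc from the full likelihood evaluated at the REML
estimates with k counting fixed effects plus free variance components, and
marginal/conditional R2 with the Higgins-Thompson typical sampling
variance. Profile likelihoods over single components diagnose
identifiability, and the Egger regression of residuals on precision screens
for funnel-plot asymmetry.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

from .meta_design import ModeratorSpec, RandomEffectsSpec, build_design

#: Floor applied to zero diagonal entries of V (should not occur after
#: SD imputation; kept as a numerical guard).
_V_FLOOR = 1e-8

#: Relative convergence tolerance of the REML optimizer.
_TOL = 1e-8


class ConvergenceWarning(UserWarning):
    pass


@dataclasses.dataclass
class FittedMetaModel:
    """REML fit of a multilevel meta-analytic model."""

    beta: np.ndarray
    beta_labels: list[str]
    beta_cov: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pvalues: np.ndarray
    sigma2: np.ndarray
    sigma2_labels: tuple[str, ...]
    loglik_restricted: float
    loglik_full: float
    converged: bool
    n_obs: int
    n_params: int                      # fixed effects + free variance comps
    qe: tuple[float, int, float] | None = None
    qm: tuple[float, int, float] | None = None
    r2_marginal: float | None = None
    r2_conditional: float | None = None
    # fit context, kept for refits (Q_M with dropped interactions, profiles)
    spec: ModeratorSpec | None = None
    re_spec: RandomEffectsSpec | None = None
    taxon_group: str | None = None
    y: np.ndarray | None = None
    V: np.ndarray | None = None
    X: np.ndarray | None = None
    groups: list[np.ndarray] | None = None
    data: pd.DataFrame | None = None
    fixed_sigma2: np.ndarray | None = None

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.beta_cov))

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.beta_labels,
            "estimate": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.pvalues,
        })

    def summary_dict(self) -> dict:
        out = {
            "coefficients": self.coefficient_table().to_dict("records"),
            "sigma2": dict(zip(self.sigma2_labels, self.sigma2.tolist())),
            "loglik_restricted": self.loglik_restricted,
            "loglik_full": self.loglik_full,
            "aicc": aicc(self),
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
        }
        for name in ("qe", "qm"):
            val = getattr(self, name)
            if val is not None:
                out[name] = {"statistic": val[0], "df": val[1], "p": val[2]}
        if self.r2_marginal is not None:
            out["r2_marginal"] = self.r2_marginal
            out["r2_conditional"] = self.r2_conditional
        return out


def _group_matrices(groups: Sequence[np.ndarray], n: int) -> list[np.ndarray]:
    mats = []
    for g in groups:
        g = np.asarray(g)
        if g.shape != (n,):
            raise ValueError("each grouping must label every observation")
        mats.append((g[:, None] == g[None, :]).astype(float))
    return mats


def _reml_pieces(sigma2, V, X, y, gmats):
    """Cholesky-based pieces shared by the objective and the gradient."""
    M = V.copy()
    for s2, G in zip(sigma2, gmats):
        if s2 != 0.0:
            M += s2 * G
    try:
        c, low = sla.cho_factor(M, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("marginal covariance not PD") from exc
    logdet_m = 2.0 * np.log(np.diag(c)).sum()
    Minv = sla.cho_solve((c, low), np.eye(len(y)))
    A = X.T @ Minv @ X
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'M^-1X not positive definite")
    Ainv = np.linalg.inv(A)
    WX = Minv @ X
    P = Minv - WX @ Ainv @ WX.T
    Py = P @ y
    return M, Minv, Ainv, P, Py, logdet_m, logdet_a


def _restricted_nll_grad(u, free, fixed_vals, V, X, y, gmats):
    """-2 restricted log-likelihood (up to no constants dropped) + gradient
    w.r.t. u = log sigma2 of the free components."""
    n, p = X.shape
    sigma2 = fixed_vals.copy()
    sigma2[free] = np.exp(u)
    _, _, _, P, Py, logdet_m, logdet_a = _reml_pieces(sigma2, V, X, y, gmats)
    nll = ((n - p) * np.log(2 * np.pi) + logdet_m + logdet_a + y @ Py)
    grad = []
    for k in np.flatnonzero(free):
        G = gmats[k]
        d = np.sum(P * G) - Py @ G @ Py       # d(-2ll)/d sigma2_k
        grad.append(d * sigma2[k])            # chain rule to log scale
    return nll, np.asarray(grad)


def reml_fit(
    y: np.ndarray,
    V: np.ndarray,
    X: np.ndarray,
    groups: Sequence[np.ndarray],
    *,
    fixed_sigma2: np.ndarray | None = None,
    multistart: bool = True,
    component_labels: Sequence[str] | None = None,
    beta_labels: Sequence[str] | None = None,
) -> FittedMetaModel:
    """REML fit of the marginal model M = V + sum_k sigma_k^2 Z_k Z_k'.

    Parameters
    ----------
    y, V, X
        Effect sizes, their known sampling vcov (PSD), and the full-rank
        fixed-effects design.
    groups
        One integer label array per variance component.
    fixed_sigma2
        Optional array (len = number of components) with NaN for free
        components and a fixed value otherwise; used by profile likelihoods
        and for closed-form checks with all components pinned at zero.
    multistart
        Start the bounded quasi-Newton optimizer from three points (near
        zero, a method-of-moments heuristic, large) and keep the best;
        disable for speed inside simulation loops.
    """
    y = np.asarray(y, dtype=float)
    V = np.asarray(V, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(y)
    if V.shape != (n, n):
        raise ValueError("V must be n x n")
    if np.linalg.eigvalsh(V).min() < -1e-8:
        raise ValueError("V must be positive semidefinite")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    zero_rows = np.diag(V) <= 0
    if zero_rows.any():
        warnings.warn(
            f"{zero_rows.sum()} zero sampling variance(s) floored at {_V_FLOOR}",
            UserWarning, stacklevel=2)
        V = V.copy()
        V[zero_rows, zero_rows] = _V_FLOOR

    K = len(groups)
    gmats = _group_matrices(groups, n)
    fixed = np.full(K, np.nan) if fixed_sigma2 is None else np.asarray(
        fixed_sigma2, dtype=float).copy()
    free = np.isnan(fixed)
    fixed_vals = np.where(free, 0.0, fixed)

    # Effect sizes are log response ratios, so heterogeneity variances live
    # on an O(1) scale; absolute bounds keep the search robust to the
    # heavy-tailed sampling variances of near-zero-mean records.
    lo, hi = np.log(1e-10), np.log(1e4)

    converged = True
    if free.any():
        # method-of-moments start: leftover variance of WLS residuals
        try:
            Vi = np.linalg.inv(V)
            bw = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
            resid = y - X @ bw
            mom = float(np.var(resid, ddof=1)) - float(np.median(np.diag(V)))
        except np.linalg.LinAlgError:
            mom = 0.1
        mom = float(np.clip(mom, 1e-4, 1e3))
        nfree = int(free.sum())
        starts = [np.full(nfree, np.log(mom / nfree))]
        if multistart:
            starts = [np.full(nfree, np.log(1e-8)),
                      starts[0],
                      np.full(nfree, np.log(10.0))]
        best = None
        for u0 in starts:
            res = scipy.optimize.minimize(
                _restricted_nll_grad, u0,
                args=(free, fixed_vals, V, X, y, gmats),
                jac=True, method="L-BFGS-B",
                bounds=[(lo, hi)] * nfree,
                options={"ftol": _TOL, "gtol": 1e-8, "maxiter": 500})
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        sigma2 = fixed_vals.copy()
        sigma2[free] = np.exp(best.x)
        converged = bool(best.success)
        if not converged:
            warnings.warn(
                f"REML optimizer did not converge: {best.message}",
                ConvergenceWarning, stacklevel=2)
    else:
        sigma2 = fixed_vals

    # snap components at the lower bound to exactly zero
    sigma2 = np.where(sigma2 <= 2e-10, 0.0, sigma2)

    _, Minv, Ainv, P, Py, logdet_m, logdet_a = _reml_pieces(
        sigma2, V, X, y, gmats)
    p = X.shape[1]
    beta = Ainv @ X.T @ (Minv @ y)
    beta_cov = Ainv
    se = np.sqrt(np.diag(beta_cov))
    z = scipy.stats.norm.ppf(0.975)
    yPy = float(y @ Py)
    ll_r = -0.5 * ((n - p) * np.log(2 * np.pi) + logdet_m + logdet_a + yPy)
    ll_f = -0.5 * (n * np.log(2 * np.pi) + logdet_m + yPy)

    labels = tuple(component_labels) if component_labels is not None else \
        tuple(f"sigma2_{k + 1}" for k in range(K))
    blabels = list(beta_labels) if beta_labels is not None else \
        [f"b{j}" for j in range(p)]
    with np.errstate(divide="ignore", invalid="ignore"):
        pvals = 2 * scipy.stats.norm.sf(np.abs(beta / se))
    return FittedMetaModel(
        beta=beta, beta_labels=blabels, beta_cov=beta_cov,
        ci_low=beta - z * se, ci_high=beta + z * se, pvalues=pvals,
        sigma2=sigma2, sigma2_labels=labels,
        loglik_restricted=ll_r, loglik_full=ll_f,
        converged=converged, n_obs=n,
        n_params=p + int(free.sum()),
        y=y, V=V, X=X, groups=[np.asarray(g) for g in groups],
        fixed_sigma2=fixed if fixed_sigma2 is not None else None,
    )


def fit_model(
    effect_set,
    spec: ModeratorSpec,
    re_spec: RandomEffectsSpec,
    taxon_group: str,
    *,
    fixed_sigma2: np.ndarray | None = None,
    multistart: bool = True,
    with_stats: bool = True,
) -> FittedMetaModel:
    """Fit a moderator specification to an :class:`EffectSizeSet`.

    Convenience wrapper: builds the design and groupings, runs
    :func:`reml_fit`, and (optionally) attaches Q_E, the omnibus Q_M over
    all non-intercept coefficients, and marginal/conditional R2.
    """
    df = effect_set.table
    X, labels = build_design(df, spec, taxon_group)
    groups = re_spec.build_groups(df)
    model = reml_fit(
        effect_set.y, effect_set.vcov, X, groups,
        fixed_sigma2=fixed_sigma2, multistart=multistart,
        component_labels=re_spec.components, beta_labels=labels)
    model.spec = spec
    model.re_spec = re_spec
    model.taxon_group = taxon_group
    model.data = df
    if with_stats:
        model.qe = q_e(model.y, model.V, model.X)
        if X.shape[1] > 1:
            model.qm = q_m(model, [t for t in spec.terms if t != "intercept"],
                           drop_interactions=False)
        model.r2_marginal, model.r2_conditional = r2_nakagawa(model)
    return model


# ---------------------------------------------------------------------------
# Fit statistics

def q_e(y: np.ndarray, V: np.ndarray, X: np.ndarray) -> tuple[float, int, float]:
    """Cochran's Q_E: residual heterogeneity of the V-weighted fixed-effects
    fit, chi-square with n - p degrees of freedom under homogeneity."""
    y = np.asarray(y, dtype=float)
    V = np.asarray(V, dtype=float)
    X = np.asarray(X, dtype=float)
    try:
        c, low = sla.cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("V is singular; Q_E undefined") from exc
    Viy = sla.cho_solve((c, low), y)
    ViX = sla.cho_solve((c, low), X)
    beta = np.linalg.solve(X.T @ ViX, X.T @ Viy)
    r = y - X @ beta
    stat = float(r @ sla.cho_solve((c, low), r))
    df = len(y) - X.shape[1]
    return stat, df, float(scipy.stats.chi2.sf(stat, df))


def q_m(
    model: FittedMetaModel,
    tested_terms: Sequence[str],
    *,
    drop_interactions: bool = True,
) -> tuple[float, int, float]:
    """Wald-type omnibus test of a subset of moderators.

    ``tested_terms`` are term names (an ``infratype`` entry tests all its
    dummies jointly; ``distance`` tests the linear and quadratic distance
    columns jointly). When a tested main effect participates in
    interactions that are not themselves tested, the model is refit without
    those interactions before testing (set ``drop_interactions=False`` to
    test coefficients in the full model, as for the model-wide omnibus).
    """
    tested = list(tested_terms)
    if not tested:
        raise ValueError("tested_terms must be non-empty")
    if "intercept" in tested:
        raise ValueError("the intercept is not a testable moderator")
    target = model
    if drop_interactions:
        to_drop: list[str] = []
        for t in tested:
            if ":" not in t:
                to_drop += [i for i in model.spec.interactions_of(t)
                            if i not in tested]
        if to_drop:
            if model.data is None:
                raise ValueError("model lacks fit context for refitting")
            from .effect_sizes import EffectSizeSet  # local to avoid cycle
            eset = EffectSizeSet.__new__(EffectSizeSet)
            eset.table = model.data
            eset.vcov = model.V
            target = fit_model(
                eset, model.spec.drop(to_drop), model.re_spec,
                model.taxon_group, multistart=False, with_stats=False)

    cols: list[int] = []
    for t in tested:
        expand = [t]
        if t == "distance" and "distance2" in (target.spec.terms
                                               if target.spec else ()):
            expand.append("distance2")
        for name in expand:
            matched = [j for j, lab in enumerate(target.beta_labels)
                       if lab == name or lab.startswith(f"{name}[")]
            cols += matched
    cols = sorted(set(cols))
    if not cols:
        raise ValueError(f"no coefficients matched {tested!r}")
    b = target.beta[cols]
    cov = target.beta_cov[np.ix_(cols, cols)]
    stat = float(b @ np.linalg.solve(cov, b))
    df = len(cols)
    return stat, df, float(scipy.stats.chi2.sf(stat, df))


def aicc(model: FittedMetaModel) -> float:
    """Small-sample AIC from the full likelihood at the REML estimates.

    k counts fixed effects plus free variance components.
    """
    k = model.n_params
    n = model.n_obs
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * model.loglik_full + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def typical_sampling_variance(V: np.ndarray) -> float:
    """Higgins-Thompson 'typical' within-study variance s^2 from diag(V)."""
    w = 1.0 / np.diag(np.asarray(V, dtype=float))
    n = len(w)
    denom = w.sum() ** 2 - (w**2).sum()
    if denom <= 0:
        raise ValueError("degenerate weights; typical variance undefined")
    return float((n - 1) * w.sum() / denom)


def r2_nakagawa(model: FittedMetaModel,
                V: np.ndarray | None = None) -> tuple[float, float]:
    """Marginal and conditional R2 for a meta-analytic mixed model.

    The total variance is the fixed-effect variance var(X beta-hat) plus all
    random-effect components plus the typical sampling variance s^2.
    """
    V = model.V if V is None else V
    fitted = model.X @ model.beta
    sf2 = float(np.var(fitted, ddof=1)) if len(fitted) > 1 else 0.0
    ssum = float(model.sigma2.sum())
    s2 = typical_sampling_variance(V)
    total = sf2 + ssum + s2
    if total <= 0:
        raise ValueError("degenerate total variance")
    return sf2 / total, (sf2 + ssum) / total


def variance_proportions(model: FittedMetaModel) -> dict[str, float]:
    """Each variance component as a percentage of total heterogeneity plus
    the typical sampling variance."""
    s2 = typical_sampling_variance(model.V)
    denom = float(model.sigma2.sum()) + s2
    if denom == 0:
        return {lab: 0.0 for lab in model.sigma2_labels}
    return {lab: 100.0 * float(v) / denom
            for lab, v in zip(model.sigma2_labels, model.sigma2)}


# ---------------------------------------------------------------------------
# Profile likelihood

@dataclasses.dataclass
class ProfileResult:
    component: str
    grid: np.ndarray
    loglik: np.ndarray
    identifiable: bool
    reason: str


def profile_component(
    model: FittedMetaModel, component_index: int, grid: Sequence[float]
) -> ProfileResult:
    """Profile the restricted likelihood over one variance component.

    Each grid value pins the component while the others are re-optimized.
    The component is deemed identifiable when the profile has a unique
    interior maximum and drops by at least 1.92 units (the 95% chi-square
    half-width) towards both grid ends.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0):
        raise ValueError("variance grid must be non-negative")
    K = len(model.groups)
    lls = np.empty(len(grid))
    for i, val in enumerate(grid):
        fixed = np.full(K, np.nan)
        fixed[component_index] = val
        sub = reml_fit(model.y, model.V, model.X, model.groups,
                       fixed_sigma2=fixed, multistart=False)
        lls[i] = sub.loglik_restricted
    imax = int(np.argmax(lls))
    top = lls[imax]
    interior = 0 < imax < len(grid) - 1
    local_maxima = [i for i in range(1, len(grid) - 1)
                    if lls[i] > lls[i - 1] and lls[i] >= lls[i + 1]
                    and lls[i] > top - 1.92]
    drops = top - lls[0] >= 1.92 and top - lls[-1] >= 1.92
    if not interior:
        verdict, reason = False, "maximum at grid boundary"
    elif len(local_maxima) > 1:
        verdict, reason = False, "multimodal profile"
    elif not drops:
        verdict, reason = False, "flat profile (drop < 1.92 within grid)"
    else:
        verdict, reason = True, "unique interior maximum with adequate drop"
    return ProfileResult(
        component=model.sigma2_labels[component_index],
        grid=grid, loglik=lls, identifiable=verdict, reason=reason)


# ---------------------------------------------------------------------------
# Publication-bias diagnostic

@dataclasses.dataclass
class EggerResult:
    intercept: float
    se: float
    p: float

    @property
    def biased(self) -> bool:
        return self.p < 0.05


def egger_test(model: FittedMetaModel,
               V: np.ndarray | None = None) -> EggerResult:
    """Egger regression of meta-analytic residuals on precision (1/SE).

    A non-zero intercept indicates funnel-plot asymmetry consistent with
    publication bias; p >= 0.05 is read as no evidence of bias.
    """
    V = model.V if V is None else np.asarray(V, dtype=float)
    resid = model.y - model.X @ model.beta
    if len(resid) < 3:
        raise ValueError("Egger test needs at least 3 observations")
    precision = 1.0 / np.sqrt(np.diag(V))
    ols = sm.OLS(resid, sm.add_constant(precision)).fit()
    return EggerResult(intercept=float(ols.params[0]),
                       se=float(ols.bse[0]),
                       p=float(ols.pvalues[0]))
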