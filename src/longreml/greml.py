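"""Restricted maximum likelihood estimation of genomic variance components.

The model is ``y = X beta + sum_c g_c + e`` with ``Var(g_c) = A_c sigma2_g[c]``
for one or more genetic relationship matrices A_c (genome-wide, or one per
chromosome) and ``Var(e) = I sigma2_e``.  The restricted log-likelihood

    l_R = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ],
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1

(constant terms omitted consistently between nested models) is maximized by
average-information REML with a single EM burn-in step.  Components proposed
negative are clamped to a small positive floor (1e-6 of the phenotypic
variance), mirroring the behaviour of mainstream GREML software near the
boundary.  SNP heritability is ``h2 = sum sigma2_g / (sum sigma2_g + sigma2_e)``;
standard errors come from the inverse average-information matrix with the
delta method for h2.

Because the null value of a variance component lies on the boundary of its
parameter space, the likelihood-ratio statistic is referred to a 50:50
mixture of a point mass at zero and chi-square with 1 df.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .exceptions import DegenerateDataError, ParameterError
from .grm import GRM

_RIDGE = 1e-6


@dataclass
class VarianceComponentFit:
    """Result of one REML fit (single- or multi-GRM)."""

    sigma2_g: np.ndarray            # genetic variance per component
    sigma2_e: float
    h2: float                       # total SNP heritability
    h2_per_component: np.ndarray
    se_sigma2: np.ndarray           # SEs of [sigma2_g..., sigma2_e]
    se_h2: float
    loglik: float                   # restricted log-likelihood, full model
    loglik_null: float              # no genetic components
    lrt: float
    pvalue: float
    status: str                     # "converged" | "failed" | "flat"
    n_iter: int
    n: int
    component_labels: list[str] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return self.status == "converged"

    @property
    def total_variance(self) -> float:
        return float(self.sigma2_g.sum() + self.sigma2_e)


def _as_matrices(grms) -> list[np.ndarray]:
    out = []
    for g in grms:
        out.append(g.values if isinstance(g, GRM) else np.asarray(g, dtype=float))
    return out


def _reml_pieces(y: np.ndarray, X: np.ndarray, A: list[np.ndarray], theta: np.ndarray):
    """Log-likelihood and projection quantities at the current components.

    theta = [sigma2_g..., sigma2_e].  Returns (ll, P, Py).
    """
    n = y.size
    V = theta[-1] * np.eye(n)
    for Ac, s in zip(A, theta[:-1]):
        V += s * Ac
    c, low = linalg.cho_factor(V, check_finite=False)
    logdet_V = 2.0 * np.sum(np.log(np.diag(c)))
    Vi = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
    ViX = Vi @ X
    XtViX = X.T @ ViX
    sign, logdet_X = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise DegenerateDataError("X' V^-1 X is singular: fixed-effect design X is rank deficient")
    P = Vi - ViX @ np.linalg.solve(XtViX, ViX.T)
    Py = P @ y
    ll = -0.5 * (logdet_V + logdet_X + float(y @ Py))
    return ll, P, Py


def _ll_only(y: np.ndarray, X: np.ndarray, A: list[np.ndarray], theta: np.ndarray) -> float:
    """Restricted log-likelihood without forming P (one Cholesky, two solves)."""
    n = y.size
    V = theta[-1] * np.eye(n)
    for Ac, s in zip(A, theta[:-1]):
        V += s * Ac
    c, low = linalg.cho_factor(V, check_finite=False)
    logdet_V = 2.0 * np.sum(np.log(np.diag(c)))
    ViX = linalg.cho_solve((c, low), X, check_finite=False)
    XtViX = X.T @ ViX
    sign, logdet_X = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise DegenerateDataError("X' V^-1 X is singular: fixed-effect design X is rank deficient")
    Viy = linalg.cho_solve((c, low), y, check_finite=False)
    t = X.T @ Viy
    yPy = float(y @ Viy) - float(t @ np.linalg.solve(XtViX, t))
    return -0.5 * (logdet_V + logdet_X + yPy)


def _coordinate_polish(
    y: np.ndarray,
    X: np.ndarray,
    A: list[np.ndarray],
    theta: np.ndarray,
    floor: float,
    varp: float,
) -> tuple[np.ndarray, float]:
    """Safeguarded derivative-free refinement on the log-variance scale,
    for likelihood ridges that run close to the positive-definiteness
    boundary where the average-information step cannot move."""
    from scipy.optimize import minimize

    lo, hi = np.log(floor), np.log(5.0 * varp + floor)

    def neg(logtheta: np.ndarray) -> float:
        if (logtheta < lo - 1e-12).any() or (logtheta > hi).any():
            return np.inf
        try:
            return -_ll_only(y, X, A, np.exp(logtheta))
        except (linalg.LinAlgError, DegenerateDataError):
            return np.inf

    x0 = np.log(np.maximum(theta, floor))
    res = minimize(
        neg,
        x0,
        method="Nelder-Mead",
        options={
            "xatol": 1e-13,
            "fatol": 1e-13,
            "maxiter": 4000 * theta.size,
            "maxfev": 4000 * theta.size,
        },
    )
    if np.isfinite(res.fun) and -res.fun >= -neg(x0):
        return np.exp(res.x), -res.fun
    return theta, -neg(x0)


def restricted_log_likelihood(y, X, grms, variances) -> float:
    """Restricted log-likelihood of y given component variances.

    ``grms`` is a list of GRMs (possibly empty for the residual-only model);
    ``variances`` lists the genetic components in the same order followed by
    the residual variance.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    A = _as_matrices(grms)
    theta = np.asarray(variances, dtype=float)
    if theta.size != len(A) + 1:
        raise ParameterError(
            f"{len(A)} GRMs require {len(A) + 1} variances, got {theta.size}"
        )
    try:
        ll, _, _ = _reml_pieces(y, X, A, theta)
    except linalg.LinAlgError as exc:
        raise DegenerateDataError(
            "V = sum_c sigma2_c A_c + sigma2_e I is not positive definite at the "
            "requested variances"
        ) from exc
    return ll


def fit_null(y, X) -> tuple[float, float]:
    """Closed-form residual-only REML: sigma2_e = RSS/(n-p) and its restricted
    log-likelihood on the same constant convention as the full model."""
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise DegenerateDataError("fixed-effect design X is rank deficient")
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (y.size - rank)
    return sigma2, restricted_log_likelihood(y, X, [], [sigma2])


def lrt_pvalue(loglik_full: float, loglik_null: float, tol: float = 1e-6) -> float:
    """P-value of the variance-component LRT under the 50:50 chi2_0 : chi2_1
    boundary mixture; an observed statistic of 0 gives p = 0.5."""
    lrt = 2.0 * (loglik_full - loglik_null)
    if lrt < -tol:
        warnings.warn(
            f"full-model log-likelihood below null by {-lrt / 2:.3g}; clamping LRT to 0",
            stacklevel=2,
        )
    lrt = max(lrt, 0.0)
    return float(0.5 * stats.chi2.sf(lrt, df=1))


def fit_greml(
    y,
    X,
    grms,
    component_labels: list[str] | None = None,
    max_iter: int = 100,
    tol_loglik: float = 1e-4,
    tol_param: float = 1e-8,
    polish: bool = False,
    ids=None,
) -> VarianceComponentFit:
    """Average-information REML with one EM burn-in iteration.

    ``grms`` is a single GRM/array or a list of them.  If ``ids`` (a sequence
    of subject ids aligned with y) is given, each :class:`~longreml.grm.GRM`'s
    id list is checked against it.  Convergence requires the successive
    log-likelihood change below ``tol_loglik`` and relative component changes
    below ``tol_param``.  A flat likelihood (e.g. a GRM indistinguishable from
    the identity, leaving total variance unidentifiable) is detected from a
    singular average-information matrix and reported via ``status='flat'``.
    """
    if isinstance(grms, (GRM, np.ndarray)):
        grms = [grms]
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n = y.size

    if ids is not None:
        ids = list(ids)
        if len(ids) != n:
            raise ParameterError("ids length does not match y")
        for g in grms:
            if isinstance(g, GRM) and list(g.ids["iid"]) != ids:
                raise ParameterError(
                    f"GRM component {g.component!r} subject ids are not aligned with y"
                )

    A = _as_matrices(grms)
    for Ac in A:
        if Ac.shape != (n, n):
            raise ParameterError(f"GRM shape {Ac.shape} does not match n={n}")
    if component_labels is None:
        component_labels = [
            g.component if isinstance(g, GRM) else f"g{i + 1}" for i, g in enumerate(grms)
        ]

    n_comp = len(A) + 1
    if n < X.shape[1] + n_comp + 1:
        raise ParameterError("too few subjects for the number of fixed effects and components")

    varp = float(np.var(y, ddof=1))
    if varp <= 0:
        raise DegenerateDataError("response has zero variance")
    floor = _RIDGE * varp

    theta = np.full(n_comp, varp / n_comp)
    try:
        ll, P, Py = _reml_pieces(y, X, A, theta)
    except linalg.LinAlgError:
        # severely non-PSD GRM: ridge its diagonal and retry
        warnings.warn(
            "a GRM is far from positive semidefinite; adding 1e-6 to its diagonal",
            stacklevel=2,
        )
        A = [Ac + _RIDGE * np.eye(n) for Ac in A]
        ll, P, Py = _reml_pieces(y, X, A, theta)

    status = "failed"
    it = 0
    for it in range(1, max_iter + 1):
        # per-component quantities; the residual component has A = I
        T = np.empty((n, n_comp))
        trPA = np.empty(n_comp)
        for c, Ac in enumerate(A):
            T[:, c] = Ac @ Py
            trPA[c] = float(np.sum(P * Ac))
        T[:, -1] = Py
        trPA[-1] = float(np.trace(P))
        yPAPy = Py @ T
        grad = -0.5 * (trPA - yPAPy)

        if it == 1:
            # EM burn-in: theta_c += theta_c^2 (y'PA_cPy - tr(PA_c)) / n
            proposal = theta + theta**2 * (yPAPy - trPA) / n
        else:
            S = P @ T
            AI = 0.5 * (T.T @ S)
            # active-set Newton step: components pinned at the floor whose
            # gradient points further down are frozen and the AI system is
            # re-solved for the free components
            free = np.ones(n_comp, dtype=bool)
            flat = False
            delta = np.zeros(n_comp)
            for _ in range(n_comp):
                sub = AI[np.ix_(free, free)]
                cond = np.linalg.cond(sub)
                if not np.isfinite(cond) or cond > 1e9:
                    flat = True
                    break
                delta[:] = 0.0
                delta[free] = np.linalg.solve(sub, grad[free])
                viol = free & (theta + delta < floor) & (theta <= floor * (1 + 1e-9))
                if not viol.any():
                    break
                free &= ~viol
                if not free.any():
                    break
            if flat:
                status = "flat"
                warnings.warn(
                    "average-information matrix is singular: likelihood is flat in "
                    "some component direction (components not separately identifiable)",
                    stacklevel=2,
                )
                break
            proposal = theta + delta

        # clamp negative proposals to the floor, then backtrack on the AI/EM
        # step until the restricted likelihood does not decrease
        step = 1.0
        accepted = None
        evaluated = False
        for _ in range(30):
            cand = np.maximum(theta + step * (proposal - theta), floor)
            if np.array_equal(cand, theta):
                break
            try:
                cand_ll = _ll_only(y, X, A, cand)
            except linalg.LinAlgError:
                step *= 0.5
                continue
            evaluated = True
            if cand_ll >= ll - 1e-10:
                accepted = (cand, cand_ll)
                break
            step *= 0.5
        if accepted is None:
            # no move improves the likelihood: at a (possibly constrained)
            # optimum if we could evaluate candidates, otherwise stuck at the
            # positive-definiteness boundary
            if evaluated or np.array_equal(np.maximum(proposal, floor), theta):
                if it > 1:
                    status = "converged"
            break
        new_theta, new_ll = accepted
        _, P, Py = _reml_pieces(y, X, A, new_theta)

        d_ll = abs(new_ll - ll)
        d_par = float(np.max(np.abs(new_theta - theta) / np.maximum(np.abs(theta), floor)))
        theta, ll = new_theta, new_ll
        if it > 1 and d_ll < tol_loglik and d_par < tol_param:
            status = "converged"
            break

    if polish and status != "flat":
        theta, polished_ll = _coordinate_polish(y, X, A, theta.copy(), floor, varp)
        if polished_ll > ll:
            if polished_ll - ll < 10 * tol_loglik:
                status = "converged"
            ll = polished_ll
        _, P, Py = _reml_pieces(y, X, A, theta)

    # standard errors from the AI matrix at the final estimate
    T = np.empty((n, n_comp))
    for c, Ac in enumerate(A):
        T[:, c] = Ac @ Py
    T[:, -1] = Py
    AI = 0.5 * (T.T @ (P @ T))
    try:
        ai_inv = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        ai_inv = np.linalg.pinv(AI)
        if status == "converged":
            status = "flat"
    se_sigma2 = np.sqrt(np.clip(np.diag(ai_inv), 0.0, None))

    sigma2_g = theta[:-1].copy()
    sigma2_e = float(theta[-1])
    total = float(theta.sum())
    h2 = float(sigma2_g.sum() / total)
    h2_per = sigma2_g / total

    # delta method for total h2: d h2 / d sigma2_gc = sigma2_e-ish terms
    grad_h2 = np.empty(n_comp)
    grad_h2[:-1] = (total - sigma2_g.sum()) / total**2
    grad_h2[-1] = -sigma2_g.sum() / total**2
    se_h2 = float(np.sqrt(max(grad_h2 @ ai_inv @ grad_h2, 0.0)))

    _, loglik_null = fit_null(y, X)
    lrt = max(2.0 * (ll - loglik_null), 0.0)
    p = lrt_pvalue(ll, loglik_null)

    return VarianceComponentFit(
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        h2=h2,
        h2_per_component=h2_per,
        se_sigma2=se_sigma2,
        se_h2=se_h2,
        loglik=ll,
        loglik_null=loglik_null,
        lrt=lrt,
        pvalue=p,
        status=status,
        n_iter=it,
        n=n,
        component_labels=list(component_labels) + ["residual"],
    )


def fit_chromosomal(y, X, grms: list, joint: bool = True, **kwargs) -> VarianceComponentFit:
    """Per-chromosome variance partition.

    ``joint=True`` (default) fits one REML model with all chromosome GRMs plus
    a residual; ``joint=False`` runs an independent single-GRM fit per
    chromosome and assembles the per-component table from those.
    """
    if joint:
        return fit_greml(y, X, grms, **kwargs)

    fits = [fit_greml(y, X, [g], **kwargs) for g in grms]
    sigma2_g = np.array([f.sigma2_g[0] for f in fits])
    h2_per = np.array([f.h2 for f in fits])
    labels = [
        g.component if isinstance(g, GRM) else f"g{i + 1}" for i, g in enumerate(grms)
    ]
    se = np.append(np.array([f.se_sigma2[0] for f in fits]), np.nan)
    ref = fits[0]
    return VarianceComponentFit(
        sigma2_g=sigma2_g,
        sigma2_e=float(np.mean([f.sigma2_e for f in fits])),
        h2=float(h2_per.sum()),
        h2_per_component=h2_per,
        se_sigma2=se,
        se_h2=float(np.sqrt(np.sum([f.se_h2**2 for f in fits]))),
        loglik=np.nan,
        loglik_null=ref.loglik_null,
        lrt=np.nan,
        pvalue=np.nan,
        status="separate",
        n_iter=sum(f.n_iter for f in fits),
        n=ref.n,
        component_labels=labels + ["residual"],
    )


def chromosome_length_correlation(
    h2_per_component: np.ndarray, lengths: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation between per-chromosome heritability and chromosome
    length (SNP count or physical length), with a two-sided t-test p-value.

    Returns (nan, nan) with a warning when either vector is constant.
    """
    h2c = np.asarray(h2_per_component, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if h2c.size != lengths.size:
        raise ParameterError("length vector does not match the number of components")
    if np.all(h2c == h2c[0]) or np.all(lengths == lengths[0]):
        warnings.warn("correlation undefined: constant per-chromosome values", stacklevel=2)
        return float("nan"), float("nan")
    r, p = stats.pearsonr(h2c, lengths)
    return float(r), float(p)
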