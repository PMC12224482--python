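"""Two-timepoint intra-class effect decomposition (ICED) by maximum likelihood.

The model is a covariance-structure SEM with two observed occasions loading
(fixed loadings of 1) on a single between-subjects factor with variance
``sigma_b2``, plus occasion-specific error variances.  In the default
("constrained") specification the two error variances are equal, giving the
compound-symmetric implied covariance

    Sigma = [[sigma_b2 + sigma_e2, sigma_b2],
             [sigma_b2, sigma_b2 + sigma_e2]]

Fitting minimizes the normal-theory ML discrepancy

    F_ML = log|Sigma| + tr(S Sigma^-1) - log|S| - p

over the free variance components, with chi-square = (n - 1) * F_ML at the
minimum (Wishart likelihood of the sample covariance S).  Means are saturated
and play no role in the fit.

Stability is summarized as the intraclass correlation

    ICC  = sigma_b2 / (sigma_b2 + sigma_e2)

and its construct-level counterpart over N repeated measures, which replaces
the error term with the effective error ``sigma_e2 / N``:

    ICC2 = sigma_b2 / (sigma_b2 + sigma_e2 / N)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    InsufficientDataError,
    NotPositiveSemiDefiniteError,
)

__all__ = [
    "CovarianceSummary",
    "ModelSpec",
    "VarianceComponents",
    "FitIndices",
    "ConfidenceInterval",
    "ICEDFit",
    "ErrorConstraintComparison",
    "summarize_two_timepoint",
    "fit_iced",
    "fit_baseline",
    "compute_cfi",
    "icc_from_components",
    "icc2_from_components",
    "icc_confint",
    "compare_error_constraints",
]

_PSD_TOL = 1e-10


@dataclass(frozen=True)
class CovarianceSummary:
    """Sufficient statistics for the two-timepoint model: 2x2 covariance, n, means."""

    s11: float
    s22: float
    s12: float
    n: int
    means: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n < 3:
            raise InsufficientDataError(
                f"need at least 3 complete cases, got n={self.n}"
            )
        if self.s11 < 0 or self.s22 < 0:
            raise NotPositiveSemiDefiniteError("negative sample variance")
        scale = max(self.s11, self.s22, 1.0)
        if self.s11 * self.s22 - self.s12**2 < -_PSD_TOL * scale**2:
            raise NotPositiveSemiDefiniteError(
                "sample covariance matrix is not positive semi-definite"
            )

    def matrix(self) -> np.ndarray:
        return np.array([[self.s11, self.s12], [self.s12, self.s22]], dtype=float)

    @property
    def mean_variance(self) -> float:
        return 0.5 * (self.s11 + self.s22)

    @property
    def correlation(self) -> float:
        denom = math.sqrt(self.s11 * self.s22)
        return self.s12 / denom if denom > 0 else float("nan")


@dataclass(frozen=True)
class ModelSpec:
    """Model variant: equal error variances across occasions, or free.

    Loadings are fixed to 1 and are not configurable.  ``nonnegative`` switches
    the optimizer to box constraints at zero; by default variances are
    unbounded during optimization (common SEM practice) and negative estimates
    are reported with a warning.
    """

    constrained_error: bool = True
    nonnegative: bool = False


@dataclass
class VarianceComponents:
    """Between-subjects and error variance estimates (measure units squared)."""

    sigma_b2: float
    sigma_e2: float
    sigma_e1_2: Optional[float] = None
    sigma_e2_2: Optional[float] = None

    def effective_error(self, n_measures: int) -> float:
        """Effective error sigma_e2 / N for the average of N repeated measures."""
        if n_measures < 1:
            raise ValueError("n_measures must be >= 1")
        return self.sigma_e2 / n_measures


@dataclass
class FitIndices:
    loglik: float
    chisq: float
    df: int
    cfi: float = float("nan")


@dataclass
class ConfidenceInterval:
    low: float
    high: float
    level: float
    one_sided: bool = False


@dataclass
class ICEDFit:
    """Fitted components, fit indices, and ICC/ICC2 for a single data slice."""

    components: VarianceComponents
    indices: FitIndices
    icc: float
    icc2: float
    icc_ci: Optional[ConfidenceInterval]
    status: str  # "ok" | "non_converged" | "degenerate"
    summary: Optional[CovarianceSummary] = None
    spec: ModelSpec = field(default_factory=ModelSpec)


def summarize_two_timepoint(dataset_slice: pd.DataFrame) -> CovarianceSummary:
    """Unbiased (n-1) sample covariance of (T1, T2) for one measure x region x group.

    The slice must contain ``value_t1`` and ``value_t2`` columns with no
    missing values (complete-case contract) and at least 3 rows.
    """
    x = np.asarray(dataset_slice["value_t1"], dtype=float)
    y = np.asarray(dataset_slice["value_t2"], dtype=float)
    if np.isnan(x).any() or np.isnan(y).any():
        raise InsufficientDataError("missing values in two-timepoint slice")
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"need at least 3 complete cases, got n={n}")
    cov = np.cov(x, y, ddof=1)
    return CovarianceSummary(
        s11=float(cov[0, 0]),
        s22=float(cov[1, 1]),
        s12=float(cov[0, 1]),
        n=n,
        means=(float(x.mean()), float(y.mean())),
    )


# ---------------------------------------------------------------------------
# ML discrepancy machinery


def _fml(S: np.ndarray, sigma: np.ndarray, logdet_s: float) -> float:
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return float("inf")
    inv = np.linalg.inv(sigma)
    return float(logdet + (S * inv).sum() - logdet_s - 2.0)


def _implied_constrained(theta: np.ndarray) -> np.ndarray:
    b, e = theta
    return np.array([[b + e, b], [b, b + e]])


_DERIV_DIRS = (np.ones((2, 2)), np.eye(2))  # dSigma/d(sigma_b2), dSigma/d(sigma_e2)


def _fml_grad_hess(S: np.ndarray, theta: np.ndarray):
    sigma = _implied_constrained(theta)
    sign, _ = np.linalg.slogdet(sigma)
    if sign <= 0:
        return None, None
    inv = np.linalg.inv(sigma)
    m = inv - inv @ S @ inv
    grad = np.array([(m * d).sum() for d in _DERIV_DIRS])
    hess = np.zeros((2, 2))
    for j, dj in enumerate(_DERIV_DIRS):
        a = inv @ dj @ inv
        for k, dk in enumerate(_DERIV_DIRS):
            hess[j, k] = np.trace(
                a @ (S @ inv @ dk - dk) + inv @ S @ a @ dk
            )
    return grad, hess


def _newton_polish(S: np.ndarray, theta: np.ndarray, logdet_s: float,
                   max_iter: int = 30) -> np.ndarray:
    """Damped Newton refinement near the optimum (quadratic convergence)."""
    f_cur = _fml(S, _implied_constrained(theta), logdet_s)
    for _ in range(max_iter):
        grad, hess = _fml_grad_hess(S, theta)
        if grad is None or np.linalg.norm(grad) < 1e-14:
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        improved = False
        for _ in range(20):
            cand = theta - scale * step
            f_new = _fml(S, _implied_constrained(cand), logdet_s)
            if math.isfinite(f_new) and f_new <= f_cur + 1e-15:
                theta, f_cur, improved = cand, f_new, True
                break
            scale *= 0.5
        if not improved:
            break
    return theta


def _minimize_constrained(
    summary: CovarianceSummary,
    start: Optional[Sequence[float]] = None,
    nonnegative: bool = False,
    gtol: float = 1e-12,
):
    """Numerically minimize F_ML for the equal-error model over (sigma_b2, sigma_e2).

    Returns (theta_hat, fmin, converged).  The analytic gradient uses
    dF/dtheta_k = tr((Sigma^-1 - Sigma^-1 S Sigma^-1) dSigma/dtheta_k).
    """
    S = summary.matrix()
    sign_s, logdet_s = np.linalg.slogdet(S)
    if sign_s <= 0:
        raise NotPositiveSemiDefiniteError("singular sample covariance")
    big = 1e12

    def fun(theta):
        val = _fml(S, _implied_constrained(theta), logdet_s)
        return big if not math.isfinite(val) else val

    def jac(theta):
        sigma = _implied_constrained(theta)
        sign, _ = np.linalg.slogdet(sigma)
        if sign <= 0:
            return np.zeros(2)
        inv = np.linalg.inv(sigma)
        m = inv - inv @ S @ inv
        return np.array([m.sum(), np.trace(m)])

    if start is None:
        # moment estimates (these coincide with the interior closed-form MLE)
        start = (summary.s12, summary.mean_variance - summary.s12)
    x0 = np.asarray(start, dtype=float)
    if nonnegative:
        x0 = np.maximum(x0, 1e-8)
        res = optimize.minimize(
            fun, x0, jac=jac, method="L-BFGS-B",
            bounds=[(0.0, None), (1e-12, None)],
            options={"ftol": 1e-15, "gtol": gtol, "maxiter": 500},
        )
    else:
        res = optimize.minimize(
            fun, x0, jac=jac, method="BFGS",
            options={"gtol": gtol, "maxiter": 500},
        )
    theta = res.x
    if not nonnegative:
        theta = _newton_polish(S, theta, logdet_s)
    fmin = fun(theta)
    converged = bool(np.linalg.norm(jac(theta)) < 1e-6 or res.success)
    if not converged:
        # derivative-free polish from the best point seen
        res2 = optimize.minimize(
            fun, theta, method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 2000},
        )
        if res2.fun <= fmin:
            theta, fmin = res2.x, float(res2.fun)
        converged = bool(np.linalg.norm(jac(theta)) < 1e-5)
    return theta, fmin, converged


def _loglik(summary: CovarianceSummary, fmin_excess: float) -> float:
    # up to an additive constant shared by all models on the same data
    w = summary.n - 1
    S = summary.matrix()
    _, logdet_s = np.linalg.slogdet(S)
    return -0.5 * w * (fmin_excess + logdet_s + 2.0 + 2.0 * math.log(2 * math.pi))


def fit_baseline(summary: CovarianceSummary) -> FitIndices:
    """Independence baseline: zero covariance, two free variances (df = 1).

    Its ML solution keeps the sample variances, so F = -log(1 - r^2) and
    chi-square = (n-1) * F, growing without bound as |r| -> 1.
    """
    r2 = summary.correlation**2
    w = summary.n - 1
    if r2 >= 1.0:
        f = float("inf")
    else:
        f = -math.log1p(-r2)
    chisq = w * f
    return FitIndices(loglik=_loglik(summary, f) if math.isfinite(f) else -math.inf,
                      chisq=chisq, df=1)


def compute_cfi(model: FitIndices, baseline: FitIndices) -> float:
    """Comparative fit index: 1 - max(0, X2m - dfm) / max(0, X2m - dfm, X2b - dfb).

    Both excesses zero returns 1 by convention (a saturated model against
    perfectly independent data).
    """
    num = max(0.0, model.chisq - model.df)
    den = max(num, baseline.chisq - baseline.df)
    if den == 0.0:
        return 1.0
    return 1.0 - num / den


def icc_from_components(vc: VarianceComponents, clip: bool = True) -> float:
    """ICC = sigma_b2 / (sigma_b2 + sigma_e2), the stability of one measurement.

    Zero total variance yields NaN with a warning; out-of-[0,1] ratios (possible
    with unbounded negative-variance estimates) are clipped for reporting.
    """
    total = vc.sigma_b2 + vc.sigma_e2
    if total <= 0:
        warnings.warn("zero or negative total variance; ICC undefined", stacklevel=2)
        return float("nan")
    icc = vc.sigma_b2 / total
    if clip:
        icc = min(1.0, max(0.0, icc))
    return icc


def icc2_from_components(vc: VarianceComponents, n_measures: int) -> float:
    """Construct-level ICC2 = sigma_b2 / (sigma_b2 + sigma_e2 / N).

    Equals ICC at N = 1 and increases toward 1 with more independent
    measurement occasions (effective error shrinks as sigma_e2 / N).
    """
    if n_measures < 1:
        raise ValueError("n_measures must be >= 1")
    total = vc.sigma_b2 + vc.effective_error(n_measures)
    if total <= 0:
        warnings.warn("zero or negative total variance; ICC2 undefined", stacklevel=2)
        return float("nan")
    return min(1.0, max(0.0, vc.sigma_b2 / total))


def _degenerate_fit(summary: CovarianceSummary, spec: ModelSpec) -> ICEDFit:
    b = summary.s12
    e = summary.mean_variance - summary.s12
    vc = VarianceComponents(sigma_b2=b, sigma_e2=e)
    symmetric = math.isclose(summary.s11, summary.s22,
                             rel_tol=1e-9, abs_tol=1e-12)
    chisq = 0.0 if symmetric else float("nan")
    indices = FitIndices(loglik=float("nan"), chisq=chisq,
                         df=1 if spec.constrained_error else 0,
                         cfi=1.0 if symmetric else float("nan"))
    total = b + e
    if total <= 0:
        icc = float("nan")
        icc2 = float("nan")
        ci = None
    else:
        icc = icc_from_components(vc)
        icc2 = icc2_from_components(vc, 2)
        ci = (ConfidenceInterval(1.0, 1.0, 0.95, one_sided=True)
              if icc >= 1.0 else None)
    return ICEDFit(components=vc, indices=indices, icc=icc, icc2=icc2,
                   icc_ci=ci, status="degenerate", summary=summary, spec=spec)


def fit_iced(
    summary: CovarianceSummary,
    spec: ModelSpec = ModelSpec(),
    ci: bool = True,
    ci_level: float = 0.95,
    n_measures: int = 2,
    start: Optional[Sequence[float]] = None,
) -> ICEDFit:
    """Fit the two-timepoint ICED model to a covariance summary.

    Constrained spec (equal errors): 2 free parameters against 3 observed
    moments, df = 1, chi-square tests the equal-error restriction.
    Unconstrained spec: saturated (3 parameters), chi-square = 0, df = 0,
    CFI = 1 identically.
    """
    scale = max(summary.s11, summary.s22)
    if scale <= 0:
        return _degenerate_fit(summary, spec)
    det_s = summary.s11 * summary.s22 - summary.s12**2
    if det_s <= _PSD_TOL * scale**2:
        return _degenerate_fit(summary, spec)

    w = summary.n - 1
    if spec.constrained_error:
        theta, fmin, converged = _minimize_constrained(
            summary, start=start, nonnegative=spec.nonnegative
        )
        b, e = float(theta[0]), float(theta[1])
        vc = VarianceComponents(sigma_b2=b, sigma_e2=e)
        chisq = max(0.0, w * fmin)
        indices = FitIndices(loglik=_loglik(summary, max(fmin, 0.0)),
                             chisq=chisq, df=1)
        status = "ok" if converged else "non_converged"
    else:
        b = summary.s12
        e1 = summary.s11 - summary.s12
        e2 = summary.s22 - summary.s12
        vc = VarianceComponents(sigma_b2=b, sigma_e2=0.5 * (e1 + e2),
                                sigma_e1_2=e1, sigma_e2_2=e2)
        indices = FitIndices(loglik=_loglik(summary, 0.0), chisq=0.0, df=0)
        status = "ok"
        converged = True

    if vc.sigma_b2 < 0 or vc.sigma_e2 < 0:
        warnings.warn(
            "negative variance estimate "
            f"(sigma_b2={vc.sigma_b2:.4g}, sigma_e2={vc.sigma_e2:.4g}); "
            "ICC clipped to [0, 1]",
            stacklevel=2,
        )
    indices.cfi = compute_cfi(indices, fit_baseline(summary))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        icc = icc_from_components(vc)
        icc2 = icc2_from_components(vc, n_measures) if not math.isnan(icc) else float("nan")

    fit = ICEDFit(components=vc, indices=indices, icc=icc, icc2=icc2,
                  icc_ci=None, status=status, summary=summary, spec=spec)
    if ci and converged:
        try:
            fit.icc_ci = icc_confint(fit, level=ci_level)
        except (ValueError, ArithmeticError):
            fit.icc_ci = None
    return fit


def icc_confint(fit: ICEDFit, level: float = 0.95) -> ConfidenceInterval:
    """Profile-likelihood confidence interval for the ICC.

    Reparameterizes the constrained model as (total variance, ICC); for fixed
    ICC = rho the total variance profiles out in closed form, leaving a
    one-dimensional likelihood-ratio function inverted with the chi-square(1)
    cutoff.  Boundary estimates yield a flagged one-sided interval.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    summary = fit.summary
    if summary is None:
        raise ValueError("fit carries no covariance summary")
    s11, s22, s12 = summary.s11, summary.s22, summary.s12
    mbar = summary.mean_variance
    if mbar <= 0:
        raise ValueError("zero total variance; interval undefined")
    det_s = s11 * s22 - s12**2
    scale = max(s11, s22)
    if det_s <= _PSD_TOL * scale**2:
        # perfectly correlated data: sigma_e2 = 0, ICC pinned at 1
        return ConfidenceInterval(1.0, 1.0, level, one_sided=True)
    w = summary.n - 1
    logdet_s = math.log(det_s)
    rho_hat = s12 / mbar

    def profile_f(rho: float) -> float:
        q = mbar - rho * s12
        if q <= 0 or not -1 < rho < 1:
            return float("inf")
        return 2.0 * math.log(q) - math.log1p(-rho * rho) - logdet_s

    f_min = profile_f(rho_hat)
    cut = stats.chi2.ppf(level, 1)

    def g(rho: float) -> float:
        return w * (profile_f(rho) - f_min) - cut

    eps = 1e-9
    lo_edge, hi_edge = -1 + eps, 1 - eps
    one_sided = False
    if g(lo_edge) > 0 and rho_hat > lo_edge:
        low = optimize.brentq(g, lo_edge, rho_hat, xtol=1e-10)
    else:
        low, one_sided = lo_edge, True
    if g(hi_edge) > 0 and rho_hat < hi_edge:
        high = optimize.brentq(g, rho_hat, hi_edge, xtol=1e-10)
    else:
        high, one_sided = hi_edge, True
    low_c, high_c = min(1.0, max(0.0, low)), min(1.0, max(0.0, high))
    if low <= 0.0 or high >= 1.0:
        one_sided = True
    return ConfidenceInterval(low_c, high_c, level, one_sided=one_sided)


@dataclass
class ErrorConstraintComparison:
    """CFI comparison of equal-error vs free-error (saturated) occasion models."""

    cfi_constrained: float
    cfi_unconstrained: float
    delta_cfi: float
    flag: bool
    threshold: float


def compare_error_constraints(
    data: "pd.DataFrame | CovarianceSummary",
    threshold: float = 0.02,
) -> ErrorConstraintComparison:
    """Compare equal-error and free-error models on one slice via delta-CFI.

    The free-error model is saturated (CFI = 1), so delta-CFI reduces to
    1 - CFI_constrained; values above ``threshold`` (default .02) flag a
    meaningful violation of equal error variances across occasions.
    """
    summary = data if isinstance(data, CovarianceSummary) else summarize_two_timepoint(data)
    constrained = fit_iced(summary, ModelSpec(constrained_error=True), ci=False)
    unconstrained = fit_iced(summary, ModelSpec(constrained_error=False), ci=False)
    delta = unconstrained.indices.cfi - constrained.indices.cfi
    return ErrorConstraintComparison(
        cfi_constrained=constrained.indices.cfi,
        cfi_unconstrained=unconstrained.indices.cfi,
        delta_cfi=delta,
        flag=delta > threshold,
        threshold=threshold,
    )
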