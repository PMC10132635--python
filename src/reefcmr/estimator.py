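"""Maximum-likelihood fitting of Robust Design models.

`RobustDesignModel` is a scikit-learn style estimator: structure choices are
constructor parameters, `fit` accepts a `CaptureMatrix` (or a binary array
plus a design) and exposes fitted attributes with trailing underscores.
Estimation maximizes the conditional (Huggins-style) likelihood on the logit
scale with a quasi-Newton optimizer from a deterministic start (all
probabilities 0.5); abundance per primary period is derived afterwards as
N_t = n_t / p*_t with delta-method uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm
from sklearn.base import BaseEstimator
from statsmodels.tools.numdiff import approx_hess1

from .design import StudyDesign
from .likelihood import _pstar_per_primary, _primary_slices, rd_log_likelihood
from .matrix import CaptureMatrix
from .specs import ParameterLayout, RDModelSpec, RDParameters

#: |logit| beyond which an estimate is considered to sit on the boundary
_BOUNDARY_LOGIT = 12.0


def _jacobian(f, x, eps: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian, shape (len(f(x)), len(x))."""
    x = np.asarray(x, dtype=float)
    f0 = np.atleast_1d(f(x))
    J = np.empty((f0.size, x.size))
    for j in range(x.size):
        step = np.zeros_like(x)
        step[j] = eps
        J[:, j] = (np.atleast_1d(f(x + step)) - np.atleast_1d(f(x - step))) \
            / (2 * eps)
    return J


@dataclass
class FitResult:
    """Summary of one maximized model (serializable view of the estimator)."""

    spec: RDModelSpec
    log_likelihood: float
    n_par: int
    aic: float
    converged: bool
    boundary: bool
    estimates: RDParameters
    theta: np.ndarray                 # free parameters, logit scale
    covariance: np.ndarray            # logit scale
    conf_int: pd.DataFrame            # natural scale, per free parameter
    message: str = ""

    def qaic(self, c_hat: float = 1.0) -> float:
        return information_criterion(self, c_hat)[1]


def information_criterion(fit, c_hat: float = 1.0) -> tuple[float, float]:
    """(AIC, QAIC) of a fit: AIC = -2lnL + 2K, QAIC = -2lnL/c_hat + 2K.

    A variance-inflation factor below 1 signals underdispersion and is
    clamped to 1 (with a warning) so model complexity is never rewarded.
    """
    if c_hat < 1.0:
        warnings.warn(f"c_hat = {c_hat:.3f} < 1 clamped to 1", stacklevel=2)
        c_hat = 1.0
    lnl, k = fit.log_likelihood, fit.n_par
    aic = -2.0 * lnl + 2.0 * k
    qaic = -2.0 * lnl / c_hat + 2.0 * k
    return aic, qaic


class RobustDesignModel(BaseEstimator):
    """Pollock's Robust Design capture-recapture model.

    Parameters
    ----------
    survival : {'constant', 'seasonal'}
        Apparent-survival structure over between-primary intervals.
    emigration : {'none', 'random', 'markovian'}
        Temporary-emigration structure (gamma' = gamma'' = 0, gamma' =
        gamma'', or both free).
    detection : {'constant', 'seasonal', 'monthly', 'seasonal_by_month', 'mixture2'}
        Within-primary detection structure; 'mixture2' is a two-class finite
        mixture capturing individual heterogeneity.
    design : StudyDesign, optional
        Required only when `fit` receives a bare array instead of a
        CaptureMatrix.
    n_restarts : int
        Additional random restarts around the deterministic default start
        (useful for mixture models, whose likelihood can be multimodal).
    random_state : int, optional
        Seed for the restart perturbations only; the default start is
        deterministic.

    Attributes
    ----------
    params_ : RDParameters
        Expanded natural-scale estimates.
    loglik_, n_par_, aic_, converged_, boundary_ : fit diagnostics.
    covariance_ : ndarray, logit-scale covariance (Hessian inverse).
    conf_int_ : DataFrame, 95% Wald intervals back-transformed to [0, 1].
    result_ : FitResult
    """

    def __init__(self, survival: str = "constant", emigration: str = "none",
                 detection: str = "constant", design: StudyDesign | None = None,
                 maxiter: int = 1000, n_restarts: int = 0,
                 random_state: int | None = None):
        self.survival = survival
        self.emigration = emigration
        self.detection = detection
        self.design = design
        self.maxiter = maxiter
        self.n_restarts = n_restarts
        self.random_state = random_state

    # ------------------------------------------------------------------

    @property
    def spec(self) -> RDModelSpec:
        return RDModelSpec(self.survival, self.emigration, self.detection)

    def _coerce(self, X) -> tuple[np.ndarray, StudyDesign]:
        if isinstance(X, CaptureMatrix):
            return X.data, X.design
        if self.design is None:
            raise ValueError("design must be given when X is a bare array")
        X = np.asarray(X, dtype=np.int8)
        if X.ndim != 2 or X.shape[1] != self.design.n_occasions:
            raise ValueError("X must be (individuals x occasions) binary")
        if not np.isin(X, (0, 1)).all():
            raise ValueError("X must be binary")
        if np.any(X.sum(axis=1) == 0):
            raise ValueError("every history needs at least one detection")
        return X, self.design

    def fit(self, X, y=None):
        """Maximize the conditional likelihood on a capture matrix."""
        data, design = self._coerce(X)
        spec = self.spec
        layout = ParameterLayout(spec, design)
        uniq, counts = np.unique(data, axis=0, return_counts=True)

        from .likelihood import conditional_history_probabilities

        def negloglik(theta):
            params = layout.expand(theta)
            with np.errstate(divide="ignore", invalid="ignore"):
                probs = conditional_history_probabilities(uniq, params, design)
            if np.any(probs <= 0) or np.any(~np.isfinite(probs)):
                return 1e12
            return -float(np.dot(counts, np.log(probs)))

        starts = [layout.default_start()]
        if self.n_restarts:
            rng = np.random.default_rng(self.random_state)
            starts += [layout.default_start() + rng.normal(0, 1.0, layout.n_par)
                       for _ in range(self.n_restarts)]
        if spec.detection == "mixture2":
            # break the label symmetry of the default start
            s = layout.default_start()
            s[-3], s[-2] = -1.5, 1.5
            starts[0] = s

        best = None
        for theta0 in starts:
            res = optimize.minimize(
                negloglik, theta0, method="L-BFGS-B",
                options={"maxiter": self.maxiter, "ftol": 1e-12, "gtol": 1e-8},
            )
            if best is None or res.fun < best.fun:
                best = res

        theta = np.asarray(best.x, dtype=float)
        loglik = -float(best.fun)
        boundary = bool(np.any(np.abs(theta) > _BOUNDARY_LOGIT))
        converged = bool(best.success) and loglik > -1e11

        cov = self._covariance(negloglik, theta)
        se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        z = norm.ppf(0.975)
        from scipy.special import expit
        ci = pd.DataFrame({
            "estimate": expit(theta),
            "lo": expit(theta - z * se),
            "hi": expit(theta + z * se),
            "se_logit": se,
        }, index=layout.names)

        self.layout_ = layout
        self.design_ = design
        self.theta_ = theta
        self.params_ = layout.expand(theta)
        self.loglik_ = loglik
        self.n_par_ = layout.n_par
        self.aic_ = -2.0 * loglik + 2.0 * layout.n_par
        self.converged_ = converged
        self.boundary_ = boundary
        self.covariance_ = cov
        self.conf_int_ = ci
        self.n_t_ = self._counts_per_primary(data, design)
        self.result_ = FitResult(
            spec=spec, log_likelihood=loglik, n_par=layout.n_par,
            aic=self.aic_, converged=converged, boundary=boundary,
            estimates=self.params_, theta=theta, covariance=cov,
            conf_int=ci, message=str(best.message),
        )
        return self

    @staticmethod
    def _counts_per_primary(data: np.ndarray, design: StudyDesign) -> np.ndarray:
        pooled = np.zeros((data.shape[0], design.n_primary), dtype=np.int8)
        for j, o in enumerate(design.occasions):
            pooled[:, o.primary - 1] |= data[:, j]
        return pooled.sum(axis=0)

    @staticmethod
    def _covariance(negloglik, theta) -> np.ndarray:
        k = len(theta)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                hess = approx_hess1(theta, negloglik)
            cov = np.linalg.pinv(hess)
            # symmetrize; pinv of a noisy FD Hessian can drift slightly
            cov = (cov + cov.T) / 2.0
        except Exception:
            cov = np.full((k, k), np.nan)
        return cov

    # ------------------------------------------------------------------

    def score(self, X, y=None) -> float:
        """Conditional log-likelihood of X under the fitted parameters."""
        data, design = self._coerce(X)
        return rd_log_likelihood(data, self.params_, design)

    def pstar(self) -> np.ndarray:
        """Mixture-pooled P(>=1 detection | available) per primary period."""
        slices = _primary_slices(self.design_)
        return self._pstar_of_theta(self.theta_, slices)

    def _pstar_of_theta(self, theta, slices) -> np.ndarray:
        params = self.layout_.expand(theta)
        ps = np.zeros(len(slices))
        for c, w in enumerate(params.pi):
            ps += w * _pstar_per_primary(params.p[:, c], slices)
        return ps

    def abundance(self, alpha: float = 0.05,
                  pstar_floor: float = 1e-6) -> pd.DataFrame:
        """Derived abundance series N_t = n_t / p*_t with uncertainty.

        The standard error combines the binomial sampling component
        n_t (1 - p*) / p*^2 with the delta-method propagation of the fitted
        parameter covariance through p*.  Primaries whose pooled p* falls
        below ``pstar_floor`` get an undefined (NaN) abundance.
        """
        slices = _primary_slices(self.design_)
        pstar = self.pstar()
        n_t = self.n_t_.astype(float)
        grad = _jacobian(lambda th: self._pstar_of_theta(th, slices),
                         self.theta_)
        # d N_t / d theta = -n_t / p*^2 * d p* / d theta
        T = len(pstar)
        var = np.empty(T)
        N = np.empty(T)
        for t in range(T):
            if pstar[t] < pstar_floor:
                N[t] = np.nan
                var[t] = np.nan
                continue
            N[t] = n_t[t] / pstar[t]
            g = -n_t[t] / pstar[t] ** 2 * grad[t]
            v_par = float(g @ self.covariance_ @ g)
            v_bin = n_t[t] * (1.0 - pstar[t]) / pstar[t] ** 2
            var[t] = max(v_par, 0.0) + v_bin
        se = np.sqrt(var)
        z = norm.ppf(1 - alpha / 2)
        lo = np.maximum(N - z * se, n_t)
        hi = N + z * se
        return pd.DataFrame({
            "primary": np.arange(1, T + 1),
            "season": [self.design_.primary_season(t + 1) for t in range(T)],
            "n": self.n_t_,
            "p_star": pstar,
            "N_hat": N,
            "se": se,
            "lo": lo,
            "hi": hi,
        })


# -- functional wrappers ----------------------------------------------------

def fit_model(matrix: CaptureMatrix, spec: RDModelSpec,
              **options) -> FitResult:
    """Fit one model structure to a capture matrix (thin estimator wrapper)."""
    est = RobustDesignModel(spec.survival, spec.emigration, spec.detection,
                            **options)
    est.fit(matrix)
    return est.result_


def derive_abundance(matrix: CaptureMatrix, spec: RDModelSpec,
                     **options) -> pd.DataFrame:
    """Fit a structure and return its derived abundance series."""
    est = RobustDesignModel(spec.survival, spec.emigration, spec.detection,
                            **options)
    est.fit(matrix)
    return est.abundance()
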