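"""Variable-error-rate (VER) joint model and the generalized 4PL marginal.

The VER model relaxes the conditional-independence assumption of the
constant-rate model: classifier error probabilities may depend on the
latent trait through logit-linear models

    eps_fp(theta) = logistic(fp_intercept + fp_slope * theta)
    eps_fn(theta) = logistic(fn_intercept + fn_slope * theta)

With person abilities fixed to point estimates from the manual-score
calibration (fixed-parameter linking), these become ordinary manifest
logistic regressions of the error indicator on the ability estimate,
fitted per item and per error type: the false-positive regression among
manually-incorrect responses, the false-negative regression among
manually-correct ones.  With both slopes at zero the model collapses to
the constant-rate model (the intercept-only MLE equals the sample
log-odds of the error rate, exactly).

The marginal automatic-score model is the generalized 4PL (G4PL),

    P(V=1 | theta) = eps_fp(theta) (1 - P_U(theta)) + (1 - eps_fn(theta)) P_U(theta),

whose asymptotes vary with theta.  Unlike the 4PL it need not be
monotone, and its item information can locally exceed the manual 2PL's:
when error rates change with ability, disagreement between scoring
methods itself carries information.

Sparse extremes of the ability range can produce complete separation in
the per-item logistic fits; the fitter then falls back to a weakly
L2-penalized refit (lambda = 1e-4 on the slope) and flags it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

from .cer import ConstantErrorRates
from .eap import QuadratureGrid, eap_estimates

__all__ = [
    "LogitErrorModel",
    "JointModelVER",
    "eps_fp",
    "eps_fn",
    "fit_ver_item",
    "g4pl_prob",
    "loglik_ver",
    "VERModel",
]

#: Minimum conditioning-cell size for fitting a slope; below this the
#: error type falls back to an intercept-only (constant-rate) fit.
MIN_CASES = 10

#: Ridge penalty on the slope used by the separation fallback.
SLOPE_PENALTY = 1e-4


@dataclass(frozen=True)
class LogitErrorModel:
    """Per-item logit-linear classifier error rates.

    ``*_fitted`` records whether the slope of that error type was
    estimated; a slope of 0 reduces the error type to a constant rate
    logistic(intercept).  ``*_penalized`` flags a separation fallback.
    """

    fp_intercept: float
    fn_intercept: float
    fp_slope: float = 0.0
    fn_slope: float = 0.0
    fp_fitted: bool = False
    fn_fitted: bool = False
    fp_penalized: bool = False
    fn_penalized: bool = False

    def __post_init__(self) -> None:
        for name in ("fp_intercept", "fn_intercept", "fp_slope", "fn_slope"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @classmethod
    def from_constant_rates(cls, rates: ConstantErrorRates) -> "LogitErrorModel":
        """Constant-rate model on the logit scale (rates clipped off 0/1)."""
        fp = float(np.clip(rates.eps_fp, 1e-12, 1 - 1e-12))
        fn = float(np.clip(rates.eps_fn, 1e-12, 1 - 1e-12))
        return cls(fp_intercept=float(logit(fp)), fn_intercept=float(logit(fn)))


def eps_fp(theta, m: LogitErrorModel):
    """P(V=1 | U=0, theta) = logistic(fp_intercept + fp_slope * theta)."""
    return expit(m.fp_intercept + m.fp_slope * np.asarray(theta, dtype=float))


def eps_fn(theta, m: LogitErrorModel):
    """P(V=0 | U=1, theta) = logistic(fn_intercept + fn_slope * theta)."""
    return expit(m.fn_intercept + m.fn_slope * np.asarray(theta, dtype=float))


@dataclass(frozen=True)
class JointModelVER:
    """Dichotomous manual-score model paired with logit-linear error rates."""

    manual_model: object
    error_model: LogitErrorModel

    n_categories = 2

    def __post_init__(self) -> None:
        if self.manual_model.n_categories != 2:
            raise ValueError("VER model is defined for dichotomous items only")

    def icc(self, theta, D: float = 1.0):
        return g4pl_prob(theta, self, D=D)

    def prob(self, theta, v: int, D: float = 1.0):
        p = g4pl_prob(theta, self, D=D)
        if v == 1:
            return p
        if v == 0:
            return 1.0 - p
        raise ValueError(f"dichotomous model has categories {{0, 1}}, got {v}")


def g4pl_prob(theta, model: JointModelVER, D: float = 1.0):
    """Generalized-4PL marginal probability of an automatic score of 1.

    Total probability over the manual score with theta-dependent rates:
    eps_fp(theta) (1 - P_U) + (1 - eps_fn(theta)) P_U.  With both slopes
    zero this is exactly the constant-rate marginal 4PL.
    """
    p_u = np.asarray(model.manual_model.icc(theta, D=D), dtype=float)
    e_fp = eps_fp(theta, model.error_model)
    e_fn = eps_fn(theta, model.error_model)
    return e_fp * (1.0 - p_u) + (1.0 - e_fn) * p_u


def _neg_loglik_logistic(beta, x, y, penalty=0.0):
    eta = beta[0] + beta[1] * x
    # log(1 + exp(.)) evaluated stably
    ll = np.sum(y * eta - np.logaddexp(0.0, eta))
    return -ll + penalty * beta[1] ** 2


def _fit_logistic(x: np.ndarray, y: np.ndarray):
    """MLE logistic regression of y on x with a penalized fallback.

    Returns (intercept, slope, penalized_flag).
    """
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False))
            params = np.asarray(res.params, dtype=float)
            separated = not np.all(np.abs(params) < 30.0)
        except Exception:
            converged, separated, params = False, True, None
    if converged and not separated:
        return float(params[0]), float(params[1]), False
    # separation / nonconvergence: weak ridge on the slope restores a
    # finite, near-ML solution
    start = np.array([float(logit(np.clip(y.mean(), 1e-6, 1 - 1e-6))), 0.0])
    opt = minimize(
        _neg_loglik_logistic,
        start,
        args=(x, y, SLOPE_PENALTY),
        method="BFGS",
    )
    warnings.warn(
        "separation or nonconvergence in error-rate logistic regression; "
        "refit with weak L2 penalty on the slope",
        UserWarning,
        stacklevel=3,
    )
    return float(opt.x[0]), float(opt.x[1]), True


def _intercept_only(err: np.ndarray) -> float:
    rate = float(np.clip(err.mean(), 1e-12, 1 - 1e-12))
    return float(logit(rate))


def fit_ver_item(
    u,
    v,
    theta_hat,
    which: str = "both",
    min_cases: int = MIN_CASES,
) -> LogitErrorModel:
    """Fit the per-item logit error-rate regressions at fixed abilities.

    The false-negative regression models 1{V=0} among manually-correct
    responses (U=1) as a function of theta_hat; the false-positive
    regression models 1{V=1} among manually-incorrect ones (U=0).
    ``which`` selects the error types that receive a slope ('fp', 'fn',
    'both', or 'none'); unrequested types are fitted intercept-only,
    which equals the sample log-odds of the constant rate.  A requested
    type with fewer than ``min_cases`` conditioning observations falls
    back to intercept-only with a warning.  Inputs are never modified.
    """
    if which not in {"fp", "fn", "both", "none"}:
        raise ValueError(f"which must be one of fp/fn/both/none, got {which!r}")
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    theta_hat = np.asarray(theta_hat, dtype=float).ravel()
    if not (u.shape == v.shape == theta_hat.shape):
        raise ValueError("u, v and theta_hat must have equal length")
    keep = ~(np.isnan(u) | np.isnan(v) | np.isnan(theta_hat))
    u, v, theta_hat = u[keep].astype(int), v[keep].astype(int), theta_hat[keep]
    if u.size == 0:
        raise ValueError("no complete (u, v, theta_hat) triples")

    out = {}
    for err_type, cond, indicator in (
        ("fp", u == 0, lambda vv: (vv == 1).astype(float)),
        ("fn", u == 1, lambda vv: (vv == 0).astype(float)),
    ):
        x = theta_hat[cond]
        y = indicator(v[cond])
        want_slope = which in {err_type, "both"}
        if x.size == 0:
            raise ValueError(
                f"cannot fit {err_type} error model: no conditioning observations"
            )
        if want_slope and x.size < min_cases:
            warnings.warn(
                f"{err_type}: only {x.size} conditioning cases (< {min_cases}); "
                "falling back to intercept-only fit",
                UserWarning,
                stacklevel=2,
            )
            want_slope = False
        if want_slope:
            b0, b1, penalized = _fit_logistic(x, y)
            out[err_type] = (b0, b1, True, penalized)
        else:
            out[err_type] = (_intercept_only(y), 0.0, False, False)

    return LogitErrorModel(
        fp_intercept=out["fp"][0],
        fp_slope=out["fp"][1],
        fp_fitted=out["fp"][2],
        fp_penalized=out["fp"][3],
        fn_intercept=out["fn"][0],
        fn_slope=out["fn"][1],
        fn_fitted=out["fn"][2],
        fn_penalized=out["fn"][3],
    )


def loglik_ver(U, V, theta_hat, items, error_models) -> float:
    """Classifier-term log-likelihood of the VER model at fixed abilities.

    With abilities and item parameters held at point estimates, only the
    classifier factor varies with the error-model coefficients; it
    decomposes over items and is maximized by :func:`fit_ver_item`.
    Zero-probability events give -inf with a warning.
    """
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    theta_hat = np.asarray(theta_hat, dtype=float)
    if U.shape != V.shape or U.shape[0] != theta_hat.size:
        raise ValueError("U, V and theta_hat must align (persons x items)")
    total = 0.0
    for i, em in enumerate(error_models):
        obs = ~(np.isnan(U[:, i]) | np.isnan(V[:, i]))
        if not obs.any():
            continue
        u = U[obs, i].astype(int)
        v = V[obs, i].astype(int)
        th = theta_hat[obs]
        e_fp = eps_fp(th, em)
        e_fn = eps_fn(th, em)
        # P(V=v | U=u, theta)
        p = np.where(
            u == 1,
            np.where(v == 0, e_fn, 1.0 - e_fn),
            np.where(v == 1, e_fp, 1.0 - e_fp),
        )
        if np.any(p <= 0):
            warnings.warn(
                f"item {i}: zero-probability classification event",
                RuntimeWarning,
                stacklevel=2,
            )
            return -np.inf
        total += float(np.sum(np.log(p)))
    return total


class VERModel(BaseEstimator):
    """Variable-error-rate joint model with G4PL ability estimation.

    Parameters
    ----------
    items : list of Item2PL or Item4PL
        Manual-score models per item, fixed from prior calibration.
    which : str or list of str
        Error types receiving a slope per item ('fp', 'fn', 'both',
        'none'); a list gives one choice per item, e.g. driven by
        conditional-independence test decisions.
    min_cases : int
        Minimum conditioning-cell size for a slope fit.
    n_nodes, lower, upper, prior_mean, prior_sd, scaling_d
        EAP quadrature configuration.

    Attributes
    ----------
    error_models_ : list of LogitErrorModel
    marginal_models_ : list of JointModelVER (G4PL measurement models)
    """

    def __init__(
        self,
        items=None,
        which="both",
        min_cases: int = MIN_CASES,
        n_nodes: int = 100,
        lower: float = -6.0,
        upper: float = 6.0,
        prior_mean: float = 0.0,
        prior_sd: float = 1.0,
        scaling_d: float = 1.0,
    ):
        self.items = items
        self.which = which
        self.min_cases = min_cases
        self.n_nodes = n_nodes
        self.lower = lower
        self.upper = upper
        self.prior_mean = prior_mean
        self.prior_sd = prior_sd
        self.scaling_d = scaling_d

    def fit(self, U, V, theta_hat):
        """Fit per-item error regressions at fixed ability point estimates.

        ``theta_hat`` is typically the EAP estimate from the manual-score
        model; neither it nor the item parameters are altered
        (fixed-parameter linking).
        """
        if not self.items:
            raise ValueError("items must be a non-empty list of item models")
        U = np.asarray(U, dtype=float)
        V = np.asarray(V, dtype=float)
        if U.shape != V.shape or U.shape[1] != len(self.items):
            raise ValueError("score matrices and item list must align")
        which = self.which
        if isinstance(which, str):
            which = [which] * len(self.items)
        if len(which) != len(self.items):
            raise ValueError("per-item 'which' list must match the item count")
        self.error_models_ = [
            fit_ver_item(U[:, i], V[:, i], theta_hat, which=w, min_cases=self.min_cases)
            for i, w in enumerate(which)
        ]
        self.marginal_models_ = [
            JointModelVER(item, em)
            for item, em in zip(self.items, self.error_models_)
        ]
        self.grid_ = QuadratureGrid.from_normal_prior(
            n_nodes=self.n_nodes,
            lower=self.lower,
            upper=self.upper,
            prior_mean=self.prior_mean,
            prior_sd=self.prior_sd,
        )
        return self

    def predict(self, V):
        """EAP abilities from automatic scores under the G4PL marginals."""
        return self.estimate(V)[0]

    def estimate(self, V):
        if not hasattr(self, "marginal_models_"):
            raise RuntimeError("VERModel must be fitted before estimating abilities")
        return eap_estimates(V, self.marginal_models_, self.grid_, D=self.scaling_d)

    def score(self, U, V, theta_hat) -> float:
        """Classifier-term log-likelihood at the fitted coefficients."""
        return loglik_ver(U, V, theta_hat, self.items, self.error_models_)
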