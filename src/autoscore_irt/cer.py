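"""Constant-error-rate (CER) joint model for manual and automatic scores.

The joint probability of a manual score U and an automatic score V
factorizes as P(U, V | theta) = P(U | theta) * P(V | U): an item response
model for the human ("ground truth") score times a classifier-error
component that, under the CER assumption, does not depend on the latent
trait.  For dichotomous items the error component is summarized by the
false-positive rate eps_fp = P(V=1 | U=0) and false-negative rate
eps_fn = P(V=0 | U=1); for polytomous items it is a full confusion
matrix P(V=v | U=u).

Because the log-likelihood splits additively into a manual-score term
and a classifier term, the classifier parameters are estimated by simple
conditional proportions from paired scores, independently of the item
response model.

Marginalizing the manual score out via the law of total probability
yields a measurement model for the automatic score alone.  For a 2PL
manual model it is exactly a 4PL with lower asymptote eps_fp and upper
asymptote 1 - eps_fn; for a 4PL manual model the asymptotes compose as
c* = eps_fp + (1 - eps_fp - eps_fn) c and d* likewise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .eap import QuadratureGrid, eap_estimates
from .items import Item2PL, Item4PL

__all__ = [
    "ConfusionMatrix",
    "ConstantErrorRates",
    "JointModelCER",
    "estimate_confusion",
    "estimate_error_rates",
    "joint_prob_cer",
    "marginal_cer_prob",
    "marginal_4pl_from_2pl",
    "marginal_4pl_from_4pl",
    "loglik_cer",
    "CERLogLik",
    "CERModel",
]

#: Clamp for error rates entering a marginal 4PL, keeping asymptotes off
#: exact 0/1 so downstream log-likelihoods stay finite.  Raw estimates are
#: reported unclamped.
RATE_CLAMP = 1e-6


@dataclass(frozen=True)
class ConfusionMatrix:
    """Row-stochastic classifier error matrix, entry (u, v) = P(V=v | U=u)."""

    p_v_given_u: np.ndarray
    degenerate_rows: np.ndarray = None  # rows estimated from zero observations

    def __post_init__(self) -> None:
        P = np.asarray(self.p_v_given_u, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(P < 0) or np.any(P > 1):
            raise ValueError("confusion entries must lie in [0, 1]")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("confusion rows must each sum to 1")
        object.__setattr__(self, "p_v_given_u", P)
        if self.degenerate_rows is None:
            object.__setattr__(self, "degenerate_rows", np.zeros(P.shape[0], dtype=bool))
        else:
            object.__setattr__(
                self, "degenerate_rows", np.asarray(self.degenerate_rows, dtype=bool)
            )

    @property
    def K(self) -> int:
        return self.p_v_given_u.shape[0]

    @classmethod
    def identity(cls, K: int) -> "ConfusionMatrix":
        return cls(p_v_given_u=np.eye(K))

    @classmethod
    def from_rates(cls, rates: "ConstantErrorRates") -> "ConfusionMatrix":
        return cls(
            p_v_given_u=np.array(
                [
                    [1.0 - rates.eps_fp, rates.eps_fp],
                    [rates.eps_fn, 1.0 - rates.eps_fn],
                ]
            )
        )


@dataclass(frozen=True)
class ConstantErrorRates:
    """Dichotomous classifier error rates.

    ``eps_fp`` is P(V=1 | U=0) — an incorrect response scored as correct;
    ``eps_fn`` is P(V=0 | U=1).  Their complements are the classifier's
    specificity and sensitivity.  An informative classifier satisfies
    eps_fp + eps_fn < 1; violations are warned about, since the implied
    marginal ICC would decrease in ability.
    """

    eps_fp: float
    eps_fn: float
    degenerate_fp: bool = False
    degenerate_fn: bool = False

    def __post_init__(self) -> None:
        for name, r in (("eps_fp", self.eps_fp), ("eps_fn", self.eps_fn)):
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {r}")
        if self.eps_fp + self.eps_fn >= 1.0:
            warnings.warn(
                f"eps_fp + eps_fn = {self.eps_fp + self.eps_fn:.3f} >= 1: "
                "classifier is not informative about the manual score",
                UserWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class JointModelCER:
    """Manual-score response model paired with a constant classifier-error model."""

    manual_model: object
    confusion: ConfusionMatrix

    def __post_init__(self) -> None:
        if self.manual_model.n_categories != self.confusion.K:
            raise ValueError(
                "manual model and confusion matrix disagree on category count"
            )

    @property
    def n_categories(self) -> int:
        return self.confusion.K

    def prob(self, theta, v: int, D: float = 1.0):
        """Marginal P(V=v | theta); makes the joint model usable for EAP."""
        return marginal_cer_prob(theta, self, v, D=D)

    def icc(self, theta, D: float = 1.0):
        if self.n_categories != 2:
            raise ValueError("icc defined for dichotomous models only")
        return marginal_cer_prob(theta, self, 1, D=D)


def _paired(u, v):
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError("paired score vectors must have equal length")
    keep = ~(np.isnan(u) | np.isnan(v))
    u, v = u[keep].astype(int), v[keep].astype(int)
    if u.size == 0:
        raise ValueError("no complete score pairs")
    return u, v


def estimate_confusion(
    u, v, K: int, smoothing: float = 0.0, strict: bool = False
) -> ConfusionMatrix:
    """MLE of the confusion matrix: row-wise conditional proportions.

    Entry (u, v) is the count of pairs with manual score u and automatic
    score v divided by the count of manual score u.  Rows with no
    observations default to uniform and are flagged degenerate (pass
    ``strict=True`` to error instead); ``smoothing`` adds alpha
    pseudo-counts (Laplace style) to every cell before normalizing.
    """
    u, v = _paired(u, v)
    if u.min() < 0 or u.max() >= K or v.min() < 0 or v.max() >= K:
        raise ValueError(f"scores must lie in [0, {K})")
    counts = np.zeros((K, K))
    np.add.at(counts, (u, v), 1.0)
    counts += smoothing
    row_tot = counts.sum(axis=1)
    degenerate = row_tot == 0
    if degenerate.any() and strict:
        raise ValueError(
            f"manual categories {np.flatnonzero(degenerate).tolist()} unobserved"
        )
    P = np.empty_like(counts)
    P[~degenerate] = counts[~degenerate] / row_tot[~degenerate, None]
    P[degenerate] = 1.0 / K
    return ConfusionMatrix(p_v_given_u=P, degenerate_rows=degenerate)


def estimate_error_rates(u, v) -> ConstantErrorRates:
    """MLE of dichotomous error rates: empirical conditional proportions.

    The dichotomous specialization of :func:`estimate_confusion`:
    eps_fp = #(U=0, V=1) / #(U=0) and eps_fn = #(U=1, V=0) / #(U=1).
    A side with no manual scores is flagged degenerate with rate 0.
    """
    u, v = _paired(u, v)
    if u.max() > 1 or v.max() > 1 or u.min() < 0 or v.min() < 0:
        raise ValueError("estimate_error_rates expects dichotomous 0/1 scores")
    n0 = int(np.sum(u == 0))
    n1 = int(np.sum(u == 1))
    eps_fp = float(np.sum((u == 0) & (v == 1)) / n0) if n0 else 0.0
    eps_fn = float(np.sum((u == 1) & (v == 0)) / n1) if n1 else 0.0
    return ConstantErrorRates(
        eps_fp=eps_fp, eps_fn=eps_fn, degenerate_fp=n0 == 0, degenerate_fn=n1 == 0
    )


def joint_prob_cer(theta, model: JointModelCER, u: int, v: int, D: float = 1.0):
    """Joint probability P(U=u, V=v | theta) = P(U=u | theta) P(V=v | U=u)."""
    K = model.n_categories
    if not (0 <= u < K and 0 <= v < K):
        raise ValueError(f"categories must lie in [0, {K}), got u={u}, v={v}")
    return model.manual_model.prob(theta, u, D=D) * model.confusion.p_v_given_u[u, v]


def marginal_cer_prob(theta, model: JointModelCER, v: int, D: float = 1.0):
    """Marginal P(V=v | theta) by total probability over the manual score."""
    K = model.n_categories
    if not (0 <= v < K):
        raise ValueError(f"category must lie in [0, {K}), got {v}")
    total = 0.0
    for u in range(K):
        total = total + model.manual_model.prob(theta, u, D=D) * model.confusion.p_v_given_u[u, v]
    return total


def _clamped(rates: ConstantErrorRates, clamp: bool):
    if not clamp:
        return rates.eps_fp, rates.eps_fn
    fp = float(np.clip(rates.eps_fp, RATE_CLAMP, 1.0 - RATE_CLAMP))
    fn = float(np.clip(rates.eps_fn, RATE_CLAMP, 1.0 - RATE_CLAMP))
    return fp, fn


def marginal_4pl_from_2pl(
    item: Item2PL, rates: ConstantErrorRates, clamp: bool = True
) -> Item4PL:
    """Marginal automatic-score model of a 2PL item under constant error rates.

    P(V=1|theta) = eps_fp (1-p) + (1-eps_fn) p is a 4PL with the 2PL's
    discrimination and difficulty, lower asymptote c = eps_fp and upper
    asymptote d = 1 - eps_fn.
    """
    fp, fn = _clamped(rates, clamp)
    if fp >= 1.0 - fn:
        raise ValueError(
            f"eps_fp + eps_fn >= 1 (fp={rates.eps_fp}, fn={rates.eps_fn}): "
            "marginal asymptotes would violate c < d"
        )
    return Item4PL(a=item.a, b=item.b, c=fp, d=1.0 - fn)


def marginal_4pl_from_4pl(
    item: Item4PL, rates: ConstantErrorRates, clamp: bool = True
) -> Item4PL:
    """Marginal automatic-score model of a 4PL manual model: asymptotes compose.

    c* = eps_fp + (1 - eps_fp - eps_fn) c, d* = eps_fp + (1 - eps_fp - eps_fn) d.
    Reduces to :func:`marginal_4pl_from_2pl` when c = 0, d = 1.
    """
    fp, fn = _clamped(rates, clamp)
    shrink = 1.0 - fp - fn
    c_star = fp + shrink * item.c
    d_star = fp + shrink * item.d
    if c_star >= d_star:
        raise ValueError(
            f"composed asymptotes violate c* < d* (c*={c_star}, d*={d_star}); "
            "classifier is not informative"
        )
    return Item4PL(a=item.a, b=item.b, c=c_star, d=d_star)


@dataclass(frozen=True)
class CERLogLik:
    """Additive decomposition of the CER joint log-likelihood."""

    total: float
    manual_term: float
    classifier_term: float


def loglik_cer(U, V, thetas, models, D: float = 1.0) -> CERLogLik:
    """Joint CER log-likelihood over a persons x items paired-score design.

    Decomposes exactly as (manual-score IRT term) + (classifier term);
    missing entries are dropped pairwise per item.  A zero-probability
    observation yields -inf with a diagnostic warning.
    """
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    thetas = np.asarray(thetas, dtype=float)
    if U.shape != V.shape or U.shape[0] != thetas.size:
        raise ValueError("U, V and thetas must align (persons x items)")
    manual_term = 0.0
    classifier_term = 0.0
    for i, model in enumerate(models):
        obs = ~(np.isnan(U[:, i]) | np.isnan(V[:, i]))
        if not obs.any():
            continue
        u = U[obs, i].astype(int)
        v = V[obs, i].astype(int)
        th = thetas[obs]
        K = model.n_categories
        P_u = np.stack(
            [np.asarray(model.manual_model.prob(th, k, D=D), float) for k in range(K)]
        )  # (K, n_obs)
        p_manual = P_u[u, np.arange(u.size)]
        p_class = model.confusion.p_v_given_u[u, v]
        if np.any(p_manual <= 0) or np.any(p_class <= 0):
            warnings.warn(
                f"item {i}: zero-probability observation; log-likelihood is -inf",
                RuntimeWarning,
                stacklevel=2,
            )
            bad_m = p_manual <= 0
            bad_c = p_class <= 0
            manual_term += float(np.sum(np.log(p_manual[~bad_m]))) + (
                -np.inf if bad_m.any() else 0.0
            )
            classifier_term += float(np.sum(np.log(p_class[~bad_c]))) + (
                -np.inf if bad_c.any() else 0.0
            )
            continue
        manual_term += float(np.sum(np.log(p_manual)))
        classifier_term += float(np.sum(np.log(p_class)))
    return CERLogLik(
        total=manual_term + classifier_term,
        manual_term=manual_term,
        classifier_term=classifier_term,
    )


class CERModel(BaseEstimator):
    """Constant-error-rate joint model, fitted from paired manual/automatic scores.

    Parameters
    ----------
    items : list of Item2PL or Item4PL
        Manual-score measurement models, one per item column, known from
        prior calibration (they are never re-estimated here).
    smoothing : float
        Pseudo-count added to confusion cells for polytomous items.
    n_nodes, lower, upper, prior_mean, prior_sd, scaling_d
        EAP quadrature configuration used by :meth:`predict`.

    Attributes
    ----------
    error_rates_ : list of ConstantErrorRates (dichotomous items)
    confusion_ : list of ConfusionMatrix
    marginal_items_ : list of Item4PL
        Automatic-score measurement models implied by the fitted rates.
    """

    def __init__(
        self,
        items=None,
        smoothing: float = 0.0,
        n_nodes: int = 100,
        lower: float = -6.0,
        upper: float = 6.0,
        prior_mean: float = 0.0,
        prior_sd: float = 1.0,
        scaling_d: float = 1.0,
    ):
        self.items = items
        self.smoothing = smoothing
        self.n_nodes = n_nodes
        self.lower = lower
        self.upper = upper
        self.prior_mean = prior_mean
        self.prior_sd = prior_sd
        self.scaling_d = scaling_d

    def fit(self, U, V):
        """Estimate per-item classifier error parameters from paired scores."""
        if not self.items:
            raise ValueError("items must be a non-empty list of item models")
        U = np.asarray(U, dtype=float)
        V = np.asarray(V, dtype=float)
        if U.shape != V.shape:
            raise ValueError("manual and automatic score matrices must align")
        if U.shape[1] != len(self.items):
            raise ValueError("score matrices and item list disagree on item count")
        self.error_rates_ = []
        self.confusion_ = []
        self.marginal_items_ = []
        for i, item in enumerate(self.items):
            K = item.n_categories
            if K == 2:
                rates = estimate_error_rates(U[:, i], V[:, i])
                self.error_rates_.append(rates)
                self.confusion_.append(ConfusionMatrix.from_rates(rates))
                if isinstance(item, Item4PL):
                    self.marginal_items_.append(marginal_4pl_from_4pl(item, rates))
                else:
                    self.marginal_items_.append(marginal_4pl_from_2pl(item, rates))
            else:
                conf = estimate_confusion(U[:, i], V[:, i], K, smoothing=self.smoothing)
                self.error_rates_.append(None)
                self.confusion_.append(conf)
                self.marginal_items_.append(JointModelCER(item, conf))
        self.grid_ = QuadratureGrid.from_normal_prior(
            n_nodes=self.n_nodes,
            lower=self.lower,
            upper=self.upper,
            prior_mean=self.prior_mean,
            prior_sd=self.prior_sd,
        )
        return self

    def predict(self, V):
        """EAP abilities from automatic scores under the marginal models."""
        return self.estimate(V)[0]

    def estimate(self, V):
        if not hasattr(self, "marginal_items_"):
            raise RuntimeError("CERModel must be fitted before estimating abilities")
        return eap_estimates(V, self.marginal_items_, self.grid_, D=self.scaling_d)

    def joint_models_(self):
        return [
            JointModelCER(item, conf)
            for item, conf in zip(self.items, self.confusion_)
        ]

    def score(self, U, V, thetas) -> float:
        """Joint CER log-likelihood of paired scores at fixed abilities."""
        return loglik_cer(U, V, thetas, self.joint_models_(), D=self.scaling_d).total
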