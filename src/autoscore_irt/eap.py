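"""Expected a posteriori (EAP) ability estimation by rectangle-rule quadrature.

The posterior over the latent trait theta given a person's item responses
is evaluated on a fixed, equally spaced grid of nodes under a normal
prior; the EAP estimate is the posterior mean and its posterior standard
deviation (PSD) quantifies remaining uncertainty.  Defaults follow common
operational practice: 100 nodes on [-6, 6].  The prior is configurable —
N(0, 1) is appropriate when it matches the generating/population
distribution (simulation work), a wider N(0, 4) when a deliberately
non-informative prior is wanted for empirical scoring.

Missing responses (coded as NaN) are simply skipped in the likelihood;
a person with no observed responses receives the prior mean and prior
standard deviation, flagged as degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.base import BaseEstimator

__all__ = [
    "QuadratureGrid",
    "AbilityEstimate",
    "eap_estimate",
    "eap_estimates",
    "eap_reliability",
    "EAPAbilityEstimator",
]


@dataclass(frozen=True)
class QuadratureGrid:
    """Equally spaced quadrature nodes with (normalized) prior weights."""

    nodes: np.ndarray
    prior_weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.prior_weights, dtype=float)
        if nodes.ndim != 1 or nodes.size < 2:
            raise ValueError("grid needs at least two nodes")
        if weights.shape != nodes.shape:
            raise ValueError("nodes and prior_weights must have the same length")
        step = np.diff(nodes)
        if np.any(step <= 0) or not np.allclose(step, step[0], rtol=1e-8):
            raise ValueError("nodes must be strictly increasing and equally spaced")
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ValueError("prior weights must be nonnegative with positive sum")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "prior_weights", weights / weights.sum())

    @classmethod
    def from_normal_prior(
        cls,
        n_nodes: int = 100,
        lower: float = -6.0,
        upper: float = 6.0,
        prior_mean: float = 0.0,
        prior_sd: float = 1.0,
    ) -> "QuadratureGrid":
        """Rectangle-rule grid with N(prior_mean, prior_sd^2) prior mass."""
        if n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if not (lower < upper):
            raise ValueError("lower must be < upper")
        if prior_sd <= 0:
            raise ValueError("prior_sd must be > 0")
        nodes = np.linspace(lower, upper, n_nodes)
        weights = norm.pdf(nodes, loc=prior_mean, scale=prior_sd)
        return cls(nodes=nodes, prior_weights=weights)

    @property
    def prior_mean(self) -> float:
        return float(np.sum(self.nodes * self.prior_weights))

    @property
    def prior_sd(self) -> float:
        m = self.prior_mean
        return float(np.sqrt(np.sum(self.nodes**2 * self.prior_weights) - m**2))


@dataclass(frozen=True)
class AbilityEstimate:
    """EAP point estimate with posterior standard deviation."""

    eap: float
    psd: float
    degenerate: bool = False  # True when no responses were observed


def _log_likelihood_grid(V: np.ndarray, models, nodes: np.ndarray, D: float) -> np.ndarray:
    """Log-likelihood of each person's responses at each grid node.

    V is (n_persons, n_items) float with NaN for missing; returns
    (n_persons, n_nodes).
    """
    n_persons = V.shape[0]
    ll = np.zeros((n_persons, nodes.size))
    for i, model in enumerate(models):
        v = V[:, i]
        observed = ~np.isnan(v)
        if not observed.any():
            continue
        K = model.n_categories
        vi = v[observed].astype(int)
        if vi.min() < 0 or vi.max() >= K:
            raise ValueError(
                f"item {i}: responses must lie in [0, {K}), got range "
                f"[{vi.min()}, {vi.max()}]"
            )
        try:
            P = np.stack([np.asarray(model.prob(nodes, k, D=D), float) for k in range(K)])
        except TypeError:  # response model without a scaling constant
            P = np.stack([np.asarray(model.prob(nodes, k), float) for k in range(K)])
        logP = np.log(np.clip(P, 1e-300, None))  # (K, n_nodes)
        ll[observed] += logP[vi]
    return ll


def eap_estimates(V, models, grid: QuadratureGrid, D: float = 1.0):
    """Vectorized EAP for a persons x items score matrix (NaN = missing).

    Returns arrays ``(eap, psd, degenerate)`` of length n_persons.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("score matrix must be 2-d (persons x items)")
    models = list(models)
    if V.shape[1] != len(models):
        raise ValueError(
            f"score matrix has {V.shape[1]} items but {len(models)} models given"
        )
    nodes, w = grid.nodes, grid.prior_weights
    ll = _log_likelihood_grid(V, models, nodes, D)
    ll -= ll.max(axis=1, keepdims=True)
    post = np.exp(ll) * w
    post /= post.sum(axis=1, keepdims=True)
    eap = post @ nodes
    second = post @ nodes**2
    psd = np.sqrt(np.maximum(second - eap**2, 0.0))
    degenerate = ~np.any(~np.isnan(V), axis=1)
    return eap, psd, degenerate


def eap_estimate(responses, models, grid: QuadratureGrid, D: float = 1.0) -> AbilityEstimate:
    """EAP estimate for one person's responses (NaN = missing item)."""
    responses = np.asarray(responses, dtype=float).reshape(1, -1)
    eap, psd, degenerate = eap_estimates(responses, models, grid, D=D)
    return AbilityEstimate(eap=float(eap[0]), psd=float(psd[0]), degenerate=bool(degenerate[0]))


def eap_reliability(eap, psd=None) -> float:
    """EAP reliability: Var(EAP) / (Var(EAP) + mean(PSD^2)).

    Accepts either parallel arrays of EAPs and PSDs or an iterable of
    :class:`AbilityEstimate`.
    """
    if psd is None:
        estimates = list(eap)
        eap = np.array([e.eap for e in estimates])
        psd = np.array([e.psd for e in estimates])
    eap = np.asarray(eap, dtype=float)
    psd = np.asarray(psd, dtype=float)
    if eap.size < 2:
        raise ValueError("reliability needs at least two persons")
    var_eap = float(np.var(eap, ddof=1))
    mean_err = float(np.mean(psd**2))
    if var_eap + mean_err <= 0:
        return 0.0
    return var_eap / (var_eap + mean_err)


class EAPAbilityEstimator(BaseEstimator):
    """Score abilities from a persons x items response matrix by EAP.

    Parameters
    ----------
    models : list of response models
        One per item column, each exposing ``n_categories`` and
        ``prob(theta, category)`` (e.g. :class:`~autoscore_irt.items.Item2PL`,
        :class:`~autoscore_irt.items.Item4PL`, or a fitted joint model's
        marginal).  Item parameters are taken as known from prior
        calibration; ``fit`` validates configuration and builds the grid.
    n_nodes, lower, upper : quadrature grid (default 100 nodes on [-6, 6]).
    prior_mean, prior_sd : normal prior moments (default standard normal).
    scaling_d : logistic scaling constant D (default 1.0).
    """

    def __init__(
        self,
        models=None,
        n_nodes: int = 100,
        lower: float = -6.0,
        upper: float = 6.0,
        prior_mean: float = 0.0,
        prior_sd: float = 1.0,
        scaling_d: float = 1.0,
    ):
        self.models = models
        self.n_nodes = n_nodes
        self.lower = lower
        self.upper = upper
        self.prior_mean = prior_mean
        self.prior_sd = prior_sd
        self.scaling_d = scaling_d

    def fit(self, X=None, y=None):
        if not self.models:
            raise ValueError("models must be a non-empty list of response models")
        self.models_ = list(self.models)
        self.grid_ = QuadratureGrid.from_normal_prior(
            n_nodes=self.n_nodes,
            lower=self.lower,
            upper=self.upper,
            prior_mean=self.prior_mean,
            prior_sd=self.prior_sd,
        )
        self.n_items_ = len(self.models_)
        return self

    def estimate(self, X):
        """Return ``(eap, psd, degenerate)`` arrays for the score matrix X."""
        if not hasattr(self, "grid_"):
            self.fit()
        return eap_estimates(X, self.models_, self.grid_, D=self.scaling_d)

    def predict(self, X):
        """EAP point estimates for the score matrix X (NaN = missing)."""
        return self.estimate(X)[0]

    def reliability(self, X) -> float:
        eap, psd, _ = self.estimate(X)
        return eap_reliability(eap, psd)
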