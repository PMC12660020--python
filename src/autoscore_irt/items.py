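"""Item characteristic curves, item information, and test-level SEM.

Dichotomous logistic item response models: the two-parameter logistic
(2PL) model with discrimination ``a`` and difficulty ``b``, and the
four-parameter logistic (4PL) model which adds a lower asymptote ``c``
("guessing") and an upper asymptote ``d`` ("slipping"):

    P_2PL(theta) = 1 / (1 + exp(-D a (theta - b)))
    P_4PL(theta) = c + (d - c) * P_2PL(theta)

The logistic scaling constant ``D`` defaults to 1.0 (pure logit metric);
``D = 1.7`` approximates the normal-ogive metric and may be passed
explicitly everywhere a curve is evaluated.

Any object exposing ``n_categories`` and ``prob(theta, category)`` (with
category probabilities summing to one at every ability value) can act as
a response model for ability estimation; the classes here implement that
contract for dichotomous items.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Item2PL",
    "Item4PL",
    "icc_2pl",
    "icc_4pl",
    "item_information",
    "test_sem",
]

#: Step for central-difference derivatives of arbitrary response models.
_FD_STEP = 1e-4


def _check_theta(theta) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("ability values must be finite")
    return theta


@dataclass(frozen=True)
class Item2PL:
    """2PL item: discrimination ``a`` (> 0) and difficulty ``b`` (logits)."""

    a: float
    b: float

    n_categories = 2

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a) and self.a > 0):
            raise ValueError(f"discrimination must be finite and > 0, got {self.a}")
        if not math.isfinite(self.b):
            raise ValueError(f"difficulty must be finite, got {self.b}")

    def icc(self, theta, D: float = 1.0):
        """P(correct | theta)."""
        theta = _check_theta(theta)
        # expit via tanh is numerically stable at extreme logits
        z = D * self.a * (theta - self.b)
        return 0.5 * (1.0 + np.tanh(0.5 * z))

    def icc_deriv(self, theta, D: float = 1.0):
        """Analytic dP/dtheta."""
        p = self.icc(theta, D=D)
        return D * self.a * p * (1.0 - p)

    def prob(self, theta, category: int, D: float = 1.0):
        p = self.icc(theta, D=D)
        if category == 1:
            return p
        if category == 0:
            return 1.0 - p
        raise ValueError(f"dichotomous item has categories {{0, 1}}, got {category}")


@dataclass(frozen=True)
class Item4PL:
    """4PL item: adds lower asymptote ``c`` and upper asymptote ``d`` to a 2PL.

    Requires ``0 <= c < d <= 1``; with ``c = 0, d = 1`` the model reduces
    exactly to the 2PL.
    """

    a: float
    b: float
    c: float = 0.0
    d: float = 1.0

    n_categories = 2

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a) and self.a > 0):
            raise ValueError(f"discrimination must be finite and > 0, got {self.a}")
        if not math.isfinite(self.b):
            raise ValueError(f"difficulty must be finite, got {self.b}")
        if not (0.0 <= self.c < self.d <= 1.0):
            raise ValueError(
                f"asymptotes must satisfy 0 <= c < d <= 1, got c={self.c}, d={self.d}"
            )

    def icc(self, theta, D: float = 1.0):
        theta = _check_theta(theta)
        z = D * self.a * (theta - self.b)
        p2 = 0.5 * (1.0 + np.tanh(0.5 * z))
        return self.c + (self.d - self.c) * p2

    def icc_deriv(self, theta, D: float = 1.0):
        theta = _check_theta(theta)
        z = D * self.a * (theta - self.b)
        p2 = 0.5 * (1.0 + np.tanh(0.5 * z))
        return (self.d - self.c) * D * self.a * p2 * (1.0 - p2)

    def prob(self, theta, category: int, D: float = 1.0):
        p = self.icc(theta, D=D)
        if category == 1:
            return p
        if category == 0:
            return 1.0 - p
        raise ValueError(f"dichotomous item has categories {{0, 1}}, got {category}")


def icc_2pl(theta, item: Item2PL, D: float = 1.0):
    """2PL item characteristic curve P(correct | theta)."""
    return item.icc(theta, D=D)


def icc_4pl(theta, item: Item4PL, D: float = 1.0):
    """4PL item characteristic curve ``c + (d - c) * logistic(D a (theta - b))``."""
    return item.icc(theta, D=D)


def item_information(theta, model, D: float = 1.0):
    """Fisher information of a dichotomous item, I(theta) = P'(theta)^2 / (P (1-P)).

    Uses the analytic derivative when the model provides ``icc_deriv``
    (2PL/4PL); otherwise a central difference with step 1e-4, which covers
    arbitrary dichotomous response models such as the generalized 4PL.
    Where P reaches machine 0 or 1 the information is returned as 0 with
    a warning (the Fisher ratio is indeterminate there).
    """
    theta = _check_theta(theta)
    if getattr(model, "n_categories", 2) != 2:
        raise ValueError("item information is defined here for dichotomous models only")
    if hasattr(model, "icc"):
        p = np.asarray(model.icc(theta, D=D), dtype=float)
    else:
        p = np.asarray(model.prob(theta, 1), dtype=float)
    if hasattr(model, "icc_deriv"):
        dp = np.asarray(model.icc_deriv(theta, D=D), dtype=float)
    else:
        h = _FD_STEP
        if hasattr(model, "icc"):
            dp = (model.icc(theta + h, D=D) - model.icc(theta - h, D=D)) / (2 * h)
        else:
            dp = (model.prob(theta + h, 1) - model.prob(theta - h, 1)) / (2 * h)
        dp = np.asarray(dp, dtype=float)
    denom = p * (1.0 - p)
    bad = denom <= 0.0
    if np.any(bad):
        warnings.warn(
            "ICC reached machine 0/1; item information set to 0 there",
            RuntimeWarning,
            stacklevel=2,
        )
    info = np.zeros_like(denom)
    ok = ~bad
    info[ok] = dp[ok] ** 2 / denom[ok]
    if np.ndim(theta) == 0:
        return float(info)
    return info


def test_sem(theta, models, D: float = 1.0):
    """Standard error of measurement, 1 / sqrt(sum of item informations).

    Returns ``inf`` where the total information is zero.
    """
    models = list(models)
    if not models:
        raise ValueError("test_sem requires at least one item")
    theta = _check_theta(theta)
    total = np.zeros_like(np.atleast_1d(theta).astype(float))
    for m in models:
        total = total + np.atleast_1d(item_information(theta, m, D=D))
    with np.errstate(divide="ignore"):
        sem = np.where(total > 0.0, 1.0 / np.sqrt(np.maximum(total, 1e-300)), np.inf)
    if np.ndim(theta) == 0:
        return float(sem[0])
    return sem
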