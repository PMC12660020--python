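"""Conditional-independence testing, agreement statistics, and estimate comparison.

Whether a classifier's error rates depend on the latent trait is tested
nonparametrically: if the false-negative probability is constant in
ability, splitting the manually-correct responses by the automatic score
is a purely random split, so the ability distributions of the two cells
coincide.  A two-sample Kolmogorov–Smirnov test compares the cells per
item and error type, with a Bonferroni correction holding the cumulative
type-I error at the item level (two tests per item, each at alpha/2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score

__all__ = [
    "CellSplit",
    "IndependenceTestResult",
    "split_cells",
    "ks_independence_test",
    "agreement_stats",
    "compare_estimates",
    "train_test_split_scores",
]


@dataclass(frozen=True)
class CellSplit:
    """Ability subsamples by (manual, automatic) score cell for one item.

    ``theta_uv`` holds the ability estimates of persons with manual score
    u and automatic score v; the four cells partition the item's
    pairwise-complete sample.
    """

    theta_00: np.ndarray
    theta_01: np.ndarray
    theta_10: np.ndarray
    theta_11: np.ndarray

    @property
    def n(self) -> int:
        return sum(
            cell.size for cell in (self.theta_00, self.theta_01, self.theta_10, self.theta_11)
        )


@dataclass(frozen=True)
class IndependenceTestResult:
    """Per-item KS tests of constant error rates, with Bonferroni decisions."""

    fp_statistic: Optional[float]
    fp_pvalue: Optional[float]
    fn_statistic: Optional[float]
    fn_pvalue: Optional[float]
    n_00: int
    n_01: int
    n_10: int
    n_11: int
    alpha: float
    reject_fp: bool
    reject_fn: bool
    fp_testable: bool
    fn_testable: bool


def _complete(theta_hat, u, v):
    theta_hat = np.asarray(theta_hat, dtype=float).ravel()
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if not (theta_hat.shape == u.shape == v.shape):
        raise ValueError("theta_hat, u and v must have equal length")
    keep = ~(np.isnan(theta_hat) | np.isnan(u) | np.isnan(v))
    return theta_hat[keep], u[keep].astype(int), v[keep].astype(int)


def split_cells(theta_hat, u, v) -> CellSplit:
    """Partition abilities into the four (manual, automatic) score cells."""
    th, u, v = _complete(theta_hat, u, v)
    return CellSplit(
        theta_00=th[(u == 0) & (v == 0)],
        theta_01=th[(u == 0) & (v == 1)],
        theta_10=th[(u == 1) & (v == 0)],
        theta_11=th[(u == 1) & (v == 1)],
    )


def ks_independence_test(
    theta_hat, u, v, alpha: float = 0.05, method: str = "asymp"
) -> IndependenceTestResult:
    """Two-sample KS tests of constant false-positive and false-negative rates.

    The false-positive test compares the ability distributions of cells
    (U=0, V=0) and (U=0, V=1); the false-negative test compares
    (U=1, V=1) and (U=1, V=0).  Each test is evaluated at alpha/2 so the
    item-level probability of a false rejection stays at alpha.  An
    error type with an empty cell is reported untestable (not rejected).
    The asymptotic KS distribution is the default; ``method='exact'``
    switches to the exact small-sample computation.
    """
    cells = split_cells(theta_hat, u, v)
    alpha_adj = alpha / 2.0

    def _ks(x, y):
        if x.size == 0 or y.size == 0:
            return None, None, False
        res = stats.ks_2samp(x, y, method=method)
        return float(res.statistic), float(res.pvalue), True

    fp_stat, fp_p, fp_testable = _ks(cells.theta_00, cells.theta_01)
    fn_stat, fn_p, fn_testable = _ks(cells.theta_11, cells.theta_10)
    return IndependenceTestResult(
        fp_statistic=fp_stat,
        fp_pvalue=fp_p,
        fn_statistic=fn_stat,
        fn_pvalue=fn_p,
        n_00=cells.theta_00.size,
        n_01=cells.theta_01.size,
        n_10=cells.theta_10.size,
        n_11=cells.theta_11.size,
        alpha=alpha,
        reject_fp=fp_testable and fp_p < alpha_adj,
        reject_fn=fn_testable and fn_p < alpha_adj,
        fp_testable=fp_testable,
        fn_testable=fn_testable,
    )


def agreement_stats(u, v) -> dict:
    """Classifier agreement summary for paired dichotomous scores.

    Returns Cohen's kappa, the false-positive and false-negative rates,
    sensitivity, specificity, and raw accuracy.  Kappa is undefined (NaN)
    when either rater uses a single category.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    keep = ~(np.isnan(u) | np.isnan(v))
    u, v = u[keep].astype(int), v[keep].astype(int)
    if u.size == 0:
        raise ValueError("no complete score pairs")
    if set(np.unique(u)) - {0, 1} or set(np.unique(v)) - {0, 1}:
        raise ValueError("agreement_stats expects dichotomous 0/1 scores")
    n0 = int(np.sum(u == 0))
    n1 = int(np.sum(u == 1))
    fp_rate = float(np.sum((u == 0) & (v == 1)) / n0) if n0 else np.nan
    fn_rate = float(np.sum((u == 1) & (v == 0)) / n1) if n1 else np.nan
    if len(np.unique(u)) < 2 or len(np.unique(v)) < 2:
        kappa = np.nan
    else:
        kappa = float(cohen_kappa_score(u, v))
    return {
        "kappa": kappa,
        "fp_rate": fp_rate,
        "fn_rate": fn_rate,
        "sensitivity": 1.0 - fn_rate if n1 else np.nan,
        "specificity": 1.0 - fp_rate if n0 else np.nan,
        "accuracy": float(np.mean(u == v)),
    }


def compare_estimates(ref, alt) -> dict:
    """Compare an alternative ability estimate against a reference.

    Returns the Pearson correlation, the mean bias (alt - ref), and a
    95% normal-approximation confidence interval for the bias.
    """
    ref = np.asarray(ref, dtype=float).ravel()
    alt = np.asarray(alt, dtype=float).ravel()
    if ref.shape != alt.shape:
        raise ValueError("estimate vectors must have equal length")
    keep = ~(np.isnan(ref) | np.isnan(alt))
    ref, alt = ref[keep], alt[keep]
    if ref.size < 3:
        raise ValueError("need at least 3 complete pairs")
    diff = alt - ref
    bias = float(diff.mean())
    se = float(diff.std(ddof=1) / np.sqrt(diff.size))
    if np.std(ref) == 0 or np.std(alt) == 0:
        r = np.nan
    else:
        r = float(stats.pearsonr(ref, alt).statistic)
    return {
        "pearson_r": r,
        "mean_bias": bias,
        "bias_ci95": (bias - 1.96 * se, bias + 1.96 * se),
        "n": int(diff.size),
    }


def train_test_split_scores(
    table: pd.DataFrame, fraction: float = 0.9, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a long-format score table into train/test sets per item.

    Each item's records are split independently at the given fraction
    (matching designs where classifier evaluation is done item-wise),
    reproducibly under the seed.  The two parts are disjoint and their
    union is the input.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    if "item_id" not in table.columns:
        raise ValueError("table must have an 'item_id' column")
    rng = np.random.default_rng(seed)
    train_idx = []
    for _, group in table.groupby("item_id", sort=True):
        idx = group.index.to_numpy()
        n_train = int(round(fraction * idx.size))
        picked = rng.permutation(idx.size)[:n_train]
        train_idx.append(idx[picked])
    train_idx = np.concatenate(train_idx) if train_idx else np.array([], dtype=int)
    mask = table.index.isin(train_idx)
    return table.loc[mask], table.loc[~mask]
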