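"""Monte-Carlo study of parameter recovery under classifier error.

Generating process per dataset: abilities and item difficulties are
standard normal, discriminations log-normal(0, 0.25); manual scores are
Bernoulli draws from the 2PL; automatic scores are derived from the
manual scores by injecting classification errors under either the
constant-rate (CER) or variable-rate (VER) process.

Error-rate calibration: doubled error rates are drawn from a Beta
distribution (so rates are capped at 0.5) whose parameters are solved
numerically such that the 2.5th/97.5th percentiles of the halved draws
hit the targets — (0.05, 0.25) in the balanced condition, (0.10, 0.40)
for the increased error type of an unbalanced condition.  Under the VER
process the intercepts are the logits of rates drawn the same way and
the slopes are N(0, 0.5^2).

The study driver crosses items x persons x error balance for both
processes and, per replicate, scores abilities four ways: the 2PL on
manual scores (reference), the 2PL on automatic scores (naive baseline
that ignores classification error), the marginal 4PL with rates
estimated by the CER model, and — under the VER process — the G4PL with
logit error models fitted at the manual-score EAP.  Bias, RMSE and
Pearson correlation are averaged across replicates with Monte-Carlo
standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logit

from .cer import CERModel, ConstantErrorRates
from .eap import QuadratureGrid, eap_estimates
from .items import Item2PL
from .ver import LogitErrorModel, VERModel, eps_fn, eps_fp

__all__ = [
    "SimulationCondition",
    "SimulatedDataset",
    "BALANCED_TARGETS",
    "INCREASED_TARGETS",
    "calibrate_beta",
    "draw_error_rates",
    "generate_dataset",
    "performance_measures",
    "run_study",
    "full_design",
]

#: 2.5th/97.5th percentile targets for classifier error rates.
BALANCED_TARGETS = (0.05, 0.25)
INCREASED_TARGETS = (0.10, 0.40)

#: Default design grids (4 x 4 x 3 per generating process).
N_ITEMS_GRID = (10, 20, 30, 40)
N_PERSONS_GRID = (500, 1000, 2000, 4000)
ERROR_BALANCES = ("balanced", "fp_increased", "fn_increased")

#: Standard deviation of generated VER error-rate slopes.
VER_SLOPE_SD = 0.5

#: Log-scale sd of generated item discriminations.
DISCRIMINATION_LOG_SD = 0.25


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of the simulation design."""

    n_items: int
    n_persons: int
    error_balance: str = "balanced"
    model_kind: str = "CER"

    def __post_init__(self) -> None:
        if self.n_items < 1 or self.n_persons < 1:
            raise ValueError("n_items and n_persons must be positive")
        if self.error_balance not in ERROR_BALANCES:
            raise ValueError(f"error_balance must be one of {ERROR_BALANCES}")
        if self.model_kind not in ("CER", "VER"):
            raise ValueError("model_kind must be 'CER' or 'VER'")


@dataclass(frozen=True)
class SimulatedDataset:
    """True parameters plus manual (U) and automatic (V) score matrices."""

    condition: SimulationCondition
    theta: np.ndarray
    items: list
    error_params: list  # ConstantErrorRates or LogitErrorModel per item
    U: np.ndarray
    V: np.ndarray


def calibrate_beta(
    pct_lo: float,
    pct_hi: float,
    q_lo: float = 0.025,
    q_hi: float = 0.975,
) -> tuple[float, float]:
    """Solve for Beta parameters of the doubled-rate distribution.

    Finds (alpha, beta) such that the halved Beta(alpha, beta) draws have
    their ``q_lo``/``q_hi`` quantiles at ``pct_lo``/``pct_hi`` (i.e. the
    Beta quantiles are the doubled targets), to within 1e-6.
    """
    if not (0.0 < pct_lo < pct_hi):
        raise ValueError("need 0 < pct_lo < pct_hi")
    if 2.0 * pct_hi > 1.0:
        raise ValueError("doubled upper target exceeds 1; infeasible for a Beta")
    target = np.array([2.0 * pct_lo, 2.0 * pct_hi])

    def residual(log_ab):
        a, b = np.exp(log_ab)
        return stats.beta.ppf([q_lo, q_hi], a, b) - target

    sol = optimize.root(residual, x0=np.log([2.0, 6.0]), method="hybr")
    res = residual(sol.x)
    if not sol.success or np.max(np.abs(res)) > 2e-6:
        raise ValueError(
            f"Beta calibration failed for targets ({pct_lo}, {pct_hi}): "
            f"residual {res}"
        )
    a, b = np.exp(sol.x)
    return float(a), float(b)


def draw_error_rates(
    n: int, targets: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Draw n error rates as halved variates of the calibrated Beta."""
    a, b = calibrate_beta(*targets)
    return rng.beta(a, b, size=n) / 2.0


def _condition_targets(error_balance: str) -> tuple[tuple, tuple]:
    """(fp_targets, fn_targets) for a design cell."""
    fp = INCREASED_TARGETS if error_balance == "fp_increased" else BALANCED_TARGETS
    fn = INCREASED_TARGETS if error_balance == "fn_increased" else BALANCED_TARGETS
    return fp, fn


def generate_dataset(
    cond: SimulationCondition, seed=None, rng: Optional[np.random.Generator] = None
) -> SimulatedDataset:
    """Generate one dataset under the condition's generating process."""
    if rng is None:
        rng = np.random.default_rng(seed)
    n_i, n_p = cond.n_items, cond.n_persons
    theta = rng.standard_normal(n_p)
    b = rng.standard_normal(n_i)
    a = rng.lognormal(mean=0.0, sigma=DISCRIMINATION_LOG_SD, size=n_i)
    items = [Item2PL(a=float(ai), b=float(bi)) for ai, bi in zip(a, b)]

    fp_targets, fn_targets = _condition_targets(cond.error_balance)
    fp_rates = draw_error_rates(n_i, fp_targets, rng)
    fn_rates = draw_error_rates(n_i, fn_targets, rng)

    error_params: list = []
    if cond.model_kind == "CER":
        for fp, fn in zip(fp_rates, fn_rates):
            error_params.append(ConstantErrorRates(eps_fp=float(fp), eps_fn=float(fn)))
    else:
        fp_slopes = rng.normal(0.0, VER_SLOPE_SD, size=n_i)
        fn_slopes = rng.normal(0.0, VER_SLOPE_SD, size=n_i)
        for fp, fn, sfp, sfn in zip(fp_rates, fn_rates, fp_slopes, fn_slopes):
            error_params.append(
                LogitErrorModel(
                    fp_intercept=float(logit(fp)),
                    fn_intercept=float(logit(fn)),
                    fp_slope=float(sfp),
                    fn_slope=float(sfn),
                    fp_fitted=True,
                    fn_fitted=True,
                )
            )

    U = np.empty((n_p, n_i))
    V = np.empty((n_p, n_i))
    for i, item in enumerate(items):
        p_u = item.icc(theta)
        u = (rng.random(n_p) < p_u).astype(float)
        ep = error_params[i]
        if cond.model_kind == "CER":
            e_fp = np.full(n_p, ep.eps_fp)
            e_fn = np.full(n_p, ep.eps_fn)
        else:
            e_fp = eps_fp(theta, ep)
            e_fn = eps_fn(theta, ep)
        # V=1 with prob 1-eps_fn if U=1, with prob eps_fp if U=0
        p_v1 = np.where(u == 1, 1.0 - e_fn, e_fp)
        v = (rng.random(n_p) < p_v1).astype(float)
        U[:, i] = u
        V[:, i] = v
    return SimulatedDataset(
        condition=cond, theta=theta, items=items, error_params=error_params, U=U, V=V
    )


def performance_measures(true_values, estimates) -> dict:
    """Bias, RMSE and Pearson correlation of estimates against truth."""
    t = np.asarray(true_values, dtype=float).ravel()
    e = np.asarray(estimates, dtype=float).ravel()
    if t.shape != e.shape:
        raise ValueError("true values and estimates must align")
    keep = np.isfinite(t) & np.isfinite(e)
    t, e = t[keep], e[keep]
    if t.size == 0:
        raise ValueError("no finite (true, estimate) pairs")
    diff = e - t
    bias = float(diff.mean())
    rmse = float(np.sqrt(np.mean(diff**2)))
    if t.size < 2 or np.std(t) == 0 or np.std(e) == 0:
        r = np.nan
    else:
        r = float(stats.pearsonr(t, e).statistic)
    return {"bias": bias, "rmse": rmse, "r": r}


def full_design(model_kinds: Sequence[str] = ("CER", "VER")) -> list[SimulationCondition]:
    """The complete items x persons x error-balance grid per process."""
    return [
        SimulationCondition(ni, np_, bal, kind)
        for kind in model_kinds
        for ni in N_ITEMS_GRID
        for np_ in N_PERSONS_GRID
        for bal in ERROR_BALANCES
    ]


def _replicate_measures(ds: SimulatedDataset, grid: QuadratureGrid) -> dict:
    """All estimator/parameter-group performance measures for one dataset."""
    cond = ds.condition
    out: dict[tuple[str, str], dict] = {}

    eap_manual, _, _ = eap_estimates(ds.U, ds.items, grid)
    out[("2pl_manual", "ability")] = performance_measures(ds.theta, eap_manual)

    eap_naive, _, _ = eap_estimates(ds.V, ds.items, grid)
    out[("2pl_auto_naive", "ability")] = performance_measures(ds.theta, eap_naive)

    cer = CERModel(items=ds.items, prior_sd=grid.prior_sd).fit(ds.U, ds.V)
    out[("cer_4pl", "ability")] = performance_measures(ds.theta, cer.predict(ds.V))

    if cond.model_kind == "CER":
        true_int = np.array(
            [logit(ep.eps_fp) for ep in ds.error_params]
            + [logit(ep.eps_fn) for ep in ds.error_params]
        )
        est_rates = np.array(
            [r.eps_fp for r in cer.error_rates_] + [r.eps_fn for r in cer.error_rates_]
        )
        with np.errstate(divide="ignore"):
            est_int = logit(est_rates)
        finite = np.isfinite(est_int)
        out[("cer", "error_intercept")] = performance_measures(
            true_int[finite], est_int[finite]
        )
        out[("cer", "error_intercept")]["n_dropped"] = int((~finite).sum())
    else:
        ver = VERModel(items=ds.items, prior_sd=grid.prior_sd).fit(
            ds.U, ds.V, eap_manual
        )
        out[("ver_g4pl", "ability")] = performance_measures(
            ds.theta, ver.predict(ds.V)
        )
        true_int = np.array(
            [ep.fp_intercept for ep in ds.error_params]
            + [ep.fn_intercept for ep in ds.error_params]
        )
        est_int = np.array(
            [m.fp_intercept for m in ver.error_models_]
            + [m.fn_intercept for m in ver.error_models_]
        )
        true_slope = np.array(
            [ep.fp_slope for ep in ds.error_params]
            + [ep.fn_slope for ep in ds.error_params]
        )
        est_slope = np.array(
            [m.fp_slope for m in ver.error_models_]
            + [m.fn_slope for m in ver.error_models_]
        )
        out[("ver", "error_intercept")] = performance_measures(true_int, est_int)
        out[("ver", "error_slope")] = performance_measures(true_slope, est_slope)
    return out


def run_study(
    conditions: Sequence[SimulationCondition],
    replicates: int = 100,
    seed: int = 0,
    n_nodes: int = 100,
    lower: float = -6.0,
    upper: float = 6.0,
    prior_sd: float = 1.0,
) -> pd.DataFrame:
    """Run the Monte-Carlo study and summarize performance per condition.

    Returns a tidy table with one row per (condition, estimator,
    parameter group): bias/RMSE/correlation averaged across replicates
    plus Monte-Carlo standard errors.  Replicates in which an estimator
    fails (e.g. a degenerate classifier) are excluded for that estimator
    with a count in ``n_failed``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    grid = QuadratureGrid.from_normal_prior(
        n_nodes=n_nodes, lower=lower, upper=upper, prior_mean=0.0, prior_sd=prior_sd
    )
    rows = []
    for ci, cond in enumerate(conditions):
        collected: dict[tuple[str, str], list[dict]] = {}
        failures: dict[tuple[str, str], int] = {}
        for rep in range(replicates):
            ss = np.random.SeedSequence([int(seed), ci, rep])
            rng = np.random.default_rng(ss)
            ds = generate_dataset(cond, rng=rng)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    measures = _replicate_measures(ds, grid)
            except Exception:
                failures[("all", "all")] = failures.get(("all", "all"), 0) + 1
                continue
            for key, m in measures.items():
                collected.setdefault(key, []).append(m)
        for (estimator, group), ms in sorted(collected.items()):
            arr = {k: np.array([m[k] for m in ms]) for k in ("bias", "rmse", "r")}
            n_rep = len(ms)
            row = {
                "n_items": cond.n_items,
                "n_persons": cond.n_persons,
                "error_balance": cond.error_balance,
                "model_kind": cond.model_kind,
                "estimator": estimator,
                "parameter_group": group,
                "n_replicates": n_rep,
                "n_failed": failures.get(("all", "all"), 0),
            }
            for k, vals in arr.items():
                vals = vals[np.isfinite(vals)]
                row[k] = float(vals.mean()) if vals.size else np.nan
                row[f"mc_se_{k}"] = (
                    float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan
                )
            rows.append(row)
    return pd.DataFrame(rows)
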