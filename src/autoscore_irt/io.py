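"""Delimited-table input/output and model-bundle serialization.

Score data travel as long-format delimited text with columns
``person_id, item_id, manual, automatic`` (plus an optional
``theta_hat``); long format handles incomplete designs naturally, and a
wide persons x items matrix is derived on demand.  Fitted models are
bundled — manual-score item parameters, per-item classifier error
models, and the estimation configuration — into a single JSON document
that round-trips losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cer import ConfusionMatrix, ConstantErrorRates, JointModelCER, marginal_4pl_from_2pl, marginal_4pl_from_4pl
from .items import Item2PL, Item4PL
from .ver import JointModelVER, LogitErrorModel

__all__ = [
    "read_score_table",
    "write_score_table",
    "score_matrices",
    "read_item_table",
    "write_item_table",
    "ModelBundle",
    "make_fixtures",
]

SCORE_COLUMNS = ("person_id", "item_id", "manual", "automatic")


def read_score_table(
    path,
    delimiter: str = "\t",
    missing: str = "NA",
) -> pd.DataFrame:
    """Read a long-format paired-score table.

    Requires columns ``person_id, item_id, manual, automatic``; the
    ``missing`` code maps to NaN.  Duplicate (person, item) keys and
    non-integer scores are rejected.
    """
    df = pd.read_csv(
        path,
        sep=delimiter,
        comment="#",
        na_values=[missing],
        keep_default_na=False,
        dtype={"person_id": str, "item_id": str},
    )
    for col in SCORE_COLUMNS[:2]:
        if col not in df.columns:
            raise ValueError(f"score table missing required column {col!r}")
    if "manual" not in df.columns and "automatic" not in df.columns:
        raise ValueError("score table needs a 'manual' and/or 'automatic' column")
    dup = df.duplicated(subset=["person_id", "item_id"], keep=False)
    if dup.any():
        keys = (
            df.loc[dup, ["person_id", "item_id"]]
            .drop_duplicates()
            .itertuples(index=False, name=None)
        )
        raise ValueError(f"duplicate (person_id, item_id) keys: {sorted(keys)[:10]}")
    for col in ("manual", "automatic", "theta_hat"):
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        newly_bad = vals.isna() & df[col].notna()
        if newly_bad.any():
            raise ValueError(f"non-numeric values in column {col!r}")
        if col != "theta_hat":
            finite = vals.dropna()
            if not np.allclose(finite, finite.round()) or (finite < 0).any():
                raise ValueError(f"column {col!r} must contain integer scores >= 0")
        df[col] = vals
    return df


def write_score_table(
    table: pd.DataFrame, path, delimiter: str = "\t", missing: str = "NA", header_lines=()
) -> None:
    """Write a long-format score table; ``header_lines`` become '#' comments."""
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep=delimiter, index=False, na_rep=missing)


def score_matrices(table: pd.DataFrame, item_order=None):
    """Pivot a long score table to wide matrices.

    Returns ``(U, V, person_ids, item_ids)`` with NaN for entries missing
    by design; columns absent in the table yield all-NaN matrices.
    """
    person_ids = sorted(table["person_id"].unique())
    if item_order is None:
        item_order = sorted(table["item_id"].unique())
    shape = (len(person_ids), len(item_order))

    def pivot(col):
        if col not in table.columns:
            return np.full(shape, np.nan)
        wide = table.pivot(index="person_id", columns="item_id", values=col)
        wide = wide.reindex(index=person_ids, columns=item_order)
        return wide.to_numpy(dtype=float)

    return pivot("manual"), pivot("automatic"), list(person_ids), list(item_order)


def read_item_table(path, delimiter: str = "\t") -> dict:
    """Read item parameters (item_id, a, b[, c, d]) into item models.

    Missing or all-default asymptote columns give 2PL items; rows with
    c/d present give 4PL items.
    """
    df = pd.read_csv(path, sep=delimiter, comment="#", dtype={"item_id": str})
    for col in ("item_id", "a", "b"):
        if col not in df.columns:
            raise ValueError(f"item table missing required column {col!r}")
    items = {}
    for row in df.itertuples(index=False):
        c = getattr(row, "c", 0.0)
        d = getattr(row, "d", 1.0)
        c = 0.0 if pd.isna(c) else float(c)
        d = 1.0 if pd.isna(d) else float(d)
        if c == 0.0 and d == 1.0:
            items[row.item_id] = Item2PL(a=float(row.a), b=float(row.b))
        else:
            items[row.item_id] = Item4PL(a=float(row.a), b=float(row.b), c=c, d=d)
    return items


def write_item_table(items: dict, path, delimiter: str = "\t") -> None:
    rows = []
    for item_id, it in items.items():
        rows.append(
            {
                "item_id": item_id,
                "a": it.a,
                "b": it.b,
                "c": getattr(it, "c", 0.0),
                "d": getattr(it, "d", 1.0),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


def _item_to_dict(item) -> dict:
    if isinstance(item, Item4PL):
        return {"type": "4pl", "a": item.a, "b": item.b, "c": item.c, "d": item.d}
    return {"type": "2pl", "a": item.a, "b": item.b}


def _item_from_dict(d: dict):
    if d["type"] == "4pl":
        return Item4PL(a=d["a"], b=d["b"], c=d["c"], d=d["d"])
    if d["type"] == "2pl":
        return Item2PL(a=d["a"], b=d["b"])
    raise ValueError(f"unknown item type {d['type']!r}")


def _error_to_dict(em) -> dict:
    if isinstance(em, ConstantErrorRates):
        return {"type": "constant", "eps_fp": em.eps_fp, "eps_fn": em.eps_fn}
    if isinstance(em, LogitErrorModel):
        return {
            "type": "logit",
            "fp": {"intercept": em.fp_intercept, "slope": em.fp_slope, "fitted": em.fp_fitted},
            "fn": {"intercept": em.fn_intercept, "slope": em.fn_slope, "fitted": em.fn_fitted},
        }
    if isinstance(em, ConfusionMatrix):
        return {"type": "confusion", "matrix": em.p_v_given_u.tolist()}
    raise ValueError(f"unknown error model {type(em).__name__}")


def _error_from_dict(d: dict):
    if d["type"] == "constant":
        return ConstantErrorRates(eps_fp=d["eps_fp"], eps_fn=d["eps_fn"])
    if d["type"] == "logit":
        return LogitErrorModel(
            fp_intercept=d["fp"]["intercept"],
            fp_slope=d["fp"]["slope"],
            fp_fitted=d["fp"]["fitted"],
            fn_intercept=d["fn"]["intercept"],
            fn_slope=d["fn"]["slope"],
            fn_fitted=d["fn"]["fitted"],
        )
    if d["type"] == "confusion":
        return ConfusionMatrix(p_v_given_u=np.asarray(d["matrix"], dtype=float))
    raise ValueError(f"unknown error model type {d['type']!r}")


DEFAULT_CONFIG = {
    "n_nodes": 100,
    "lower": -6.0,
    "upper": 6.0,
    "prior_mean": 0.0,
    "prior_sd": 1.0,
    "scaling_d": 1.0,
}


@dataclass
class ModelBundle:
    """Item models + per-item classifier error models + estimation config."""

    items: dict
    error_models: dict = field(default_factory=dict)
    config: dict = field(default_factory=lambda: dict(DEFAULT_CONFIG))

    def marginal_model(self, item_id: str):
        """Automatic-score measurement model implied for one item."""
        item = self.items[item_id]
        em = self.error_models.get(item_id)
        if em is None:
            return item
        if isinstance(em, ConstantErrorRates):
            if isinstance(item, Item4PL):
                return marginal_4pl_from_4pl(item, em)
            return marginal_4pl_from_2pl(item, em)
        if isinstance(em, LogitErrorModel):
            return JointModelVER(manual_model=item, error_model=em)
        if isinstance(em, ConfusionMatrix):
            return JointModelCER(manual_model=item, confusion=em)
        raise ValueError(f"unknown error model for item {item_id!r}")

    def to_json(self, path) -> None:
        doc = {
            "items": {k: _item_to_dict(v) for k, v in self.items.items()},
            "error_models": {k: _error_to_dict(v) for k, v in self.error_models.items()},
            "config": self.config,
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "ModelBundle":
        doc = json.loads(Path(path).read_text())
        return cls(
            items={k: _item_from_dict(v) for k, v in doc["items"].items()},
            error_models={k: _error_from_dict(v) for k, v in doc["error_models"].items()},
            config=doc.get("config", dict(DEFAULT_CONFIG)),
        )


def make_fixtures(outdir, seed: int = 20240901) -> dict:
    """Write small deterministic paired-score fixtures for each condition type.

    Generates one <= 200-person, <= 8-item dataset per generating process
    and error balance, plus the corresponding item-parameter table; all
    files regenerate bit-identically under the same seed.  Returns the
    mapping of fixture names to paths.
    """
    from .simulation import SimulationCondition, generate_dataset

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for kind in ("CER", "VER"):
        for balance in ("balanced", "fp_increased", "fn_increased"):
            cond = SimulationCondition(
                n_items=8, n_persons=200, error_balance=balance, model_kind=kind
            )
            sub_seed = abs(hash((kind, balance))) % 10_000
            ds = generate_dataset(cond, seed=np.random.SeedSequence([seed, sub_seed]))
            name = f"{kind.lower()}_{balance}"
            rows = []
            for p in range(cond.n_persons):
                for i in range(cond.n_items):
                    rows.append(
                        {
                            "person_id": f"p{p:03d}",
                            "item_id": f"i{i}",
                            "manual": int(ds.U[p, i]),
                            "automatic": int(ds.V[p, i]),
                        }
                    )
            table = pd.DataFrame(rows)
            score_path = outdir / f"{name}_scores.tsv"
            write_score_table(
                table, score_path, header_lines=[f"fixture {name}", f"seed {seed}"]
            )
            item_path = outdir / f"{name}_items.tsv"
            write_item_table(
                {f"i{i}": it for i, it in enumerate(ds.items)}, item_path
            )
            paths[name] = {"scores": score_path, "items": item_path}
    return paths
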