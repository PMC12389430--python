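"""Accuracy evaluation of scanner-derived DBH and height against field data.

Metrics follow the 1:1-line convention: residuals are field minus estimate,
R-squared is computed about the identity line (not a refitted regression),
RMSE divides by n, and a positive bias means the scanner underestimates.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


@dataclass
class EvaluationReport:
    """R2, RMSE, rRMSE (%), MAE, bias and bias (%) for one variable."""

    n: int
    r2: float
    rmse: float
    rrmse_pct: float
    mae: float
    bias: float
    bias_pct: float

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate(y_field, y_est) -> EvaluationReport:
    """Compare field measurements ``y_field`` with estimates ``y_est``.

    * R2    = 1 - SSE / SST, SSE about the 1:1 line
    * RMSE  = sqrt(SSE / n)
    * rRMSE = 100 * RMSE / mean(y_field)
    * MAE   = mean |y - y_hat|
    * bias  = mean (y - y_hat)   (positive => estimate underestimates)
    * bias% = 100 * bias / mean(y_field)
    """
    y = np.asarray(y_field, dtype=float)
    yhat = np.asarray(y_est, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("paired series must have equal length")
    n = y.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    ybar = y.mean()
    if ybar == 0:
        raise ValueError("zero mean field value: relative metrics undefined")
    resid = y - yhat
    sse = float((resid**2).sum())
    sst = float(((y - ybar) ** 2).sum())
    rmse = float(np.sqrt(sse / n))
    bias = float(resid.mean())
    return EvaluationReport(
        n=n,
        r2=float(1.0 - sse / sst) if sst > 0 else float("nan"),
        rmse=rmse,
        rrmse_pct=float(100.0 * rmse / ybar),
        mae=float(np.abs(resid).mean()),
        bias=bias,
        bias_pct=float(100.0 * bias / ybar),
    )


def evaluate_paired_table(pairs: pd.DataFrame) -> dict[str, EvaluationReport]:
    """Evaluate both DBH and height from a paired-measurement table
    (columns dbh_field_cm / dbh_bls_cm and th_field_m / th_bls_m)."""
    out = {}
    if {"dbh_field_cm", "dbh_bls_cm"} <= set(pairs.columns):
        out["dbh"] = evaluate(pairs["dbh_field_cm"], pairs["dbh_bls_cm"])
    if {"th_field_m", "th_bls_m"} <= set(pairs.columns):
        out["th"] = evaluate(pairs["th_field_m"], pairs["th_bls_m"])
    if not out:
        raise ValueError("no paired DBH or height columns found")
    return out


def match_by_position(
    field: pd.DataFrame, bls: pd.DataFrame, max_dist: float = 1.0
) -> pd.DataFrame:
    """Join field and scanner tree tables by nearest stem position.

    Each field tree takes the closest scanner stem within ``max_dist`` m;
    unmatched trees are dropped.  Use only when shared tags are missing.
    """
    tree = cKDTree(bls[["x_m", "y_m"]].to_numpy(float))
    d, j = tree.query(field[["x_m", "y_m"]].to_numpy(float))
    ok = d <= max_dist
    matched = field.loc[ok, ["tree_id", "dbh_cm", "height_m"]].rename(
        columns={"dbh_cm": "dbh_field_cm", "height_m": "th_field_m"}
    )
    matched["dbh_bls_cm"] = bls["dbh_cm"].to_numpy(float)[j[ok]]
    matched["th_bls_m"] = bls["height_m"].to_numpy(float)[j[ok]]
    matched["match_dist_m"] = d[ok]
    return matched.reset_index(drop=True)


def scatter_figure(pairs: pd.DataFrame, path) -> None:
    """Basic 1:1 scatter of field vs estimated DBH and height."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, (fcol, bcol, label) in zip(
        axes,
        [
            ("dbh_field_cm", "dbh_bls_cm", "DBH (cm)"),
            ("th_field_m", "th_bls_m", "TH (m)"),
        ],
    ):
        if fcol not in pairs.columns:
            continue
        ax.scatter(pairs[fcol], pairs[bcol], s=12, alpha=0.6)
        lim = [
            min(pairs[fcol].min(), pairs[bcol].min()),
            max(pairs[fcol].max(), pairs[bcol].max()),
        ]
        ax.plot(lim, lim, "k--", lw=1)
        ax.set_xlabel(f"field {label}")
        ax.set_ylabel(f"estimated {label}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
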