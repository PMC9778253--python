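"""Prediction-accuracy metrics: NRMSE at all aggregation levels and the
relative efficiencies between tuning strategies.

NRMSE for a trait in a fold is RMSE divided by the mean of the observed
values (its absolute value, so the metric is nonnegative for traits measured
on a negative scale; the two coincide for the positive-valued traits this
model targets).  Trait-level values average the 7 folds, the across-trait
summary averages traits, and "Global" rows pool every test cell across
environments before normalizing (default; a mean-of-environment alternative
is available).

Relative efficiency RE = NRMSE_ref / NRMSE_alt; RE > 1 means the alternative
strategy predicts better.  The three reported comparisons are
re_grs = NT/GrS, re_bo = NT/BO and re_grs_bo = GrS/BO.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

GLOBAL = "Global"
ALL_TRAITS = "ALL"

_RE_PAIRS = {
    "re_grs": ("NT", "GrS"),
    "re_bo": ("NT", "BO"),
    "re_grs_bo": ("GrS", "BO"),
}


def nrmse(observed, predicted) -> float:
    """Root mean square error scaled by |mean(observed)|."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size < 1:
        raise ValueError("need at least one observation")
    mean = obs.mean()
    if abs(mean) < 1e-12:
        raise ValueError("mean of observed values is zero; NRMSE is undefined")
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    return rmse / abs(mean)


def relative_efficiency(nrmse_ref: float, nrmse_alt: float) -> float:
    """Ratio reference/alternative; > 1 means the alternative is better."""
    if nrmse_alt <= 0.0:
        raise ValueError("alternative NRMSE must be positive")
    return float(nrmse_ref) / float(nrmse_alt)


def per_fold_rows(
    predictions: pd.DataFrame,
    strategy: str,
    dataset: str = "synthetic",
    global_mode: str = "pooled",
) -> pd.DataFrame:
    """Per-fold NRMSE rows from a raw prediction log.

    ``predictions`` needs columns fold, trait, env, observed, predicted (cells
    with missing observed values must already be excluded).  Emits one row per
    (trait, env, fold) plus trait-level Global rows per fold.
    """
    if global_mode not in ("pooled", "mean_of_env"):
        raise ValueError(f"unknown global_mode {global_mode!r}")
    rows = []
    for (fold, trait), grp in predictions.groupby(["fold", "trait"], sort=True):
        env_vals = {}
        for env, sub in grp.groupby("env", sort=True):
            env_vals[env] = nrmse(sub["observed"], sub["predicted"])
            rows.append((dataset, strategy, trait, env, fold, "nrmse", env_vals[env]))
        if global_mode == "pooled":
            g = nrmse(grp["observed"], grp["predicted"])
        else:
            g = float(np.mean(list(env_vals.values())))
        rows.append((dataset, strategy, trait, GLOBAL, fold, "nrmse", g))
    return pd.DataFrame(
        rows, columns=["dataset", "strategy", "trait", "environment", "fold", "metric", "value"]
    )


def aggregate(per_fold: pd.DataFrame) -> pd.DataFrame:
    """Fold means, fold standard errors and across-trait summaries.

    Trait-level NRMSE is the unweighted mean over folds (fold="mean"); the
    standard error is sd/sqrt(n_folds) (metric="se").  Across-trait rows
    (trait="ALL") average the trait-level means per (strategy, environment).
    """
    nr = per_fold[per_fold["metric"] == "nrmse"]
    out = []
    keys = ["dataset", "strategy", "trait", "environment"]
    for key, grp in nr.groupby(keys, sort=True):
        vals = grp["value"].to_numpy(dtype=float)
        out.append((*key, "mean", "nrmse", float(vals.mean())))
        se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        out.append((*key, "mean", "se", se))
    agg = pd.DataFrame(out, columns=[*keys, "fold", "metric", "value"])
    trait_means = agg[(agg["metric"] == "nrmse")]
    extra = []
    for key, grp in trait_means.groupby(["dataset", "strategy", "environment"], sort=True):
        extra.append((key[0], key[1], ALL_TRAITS, key[2], "mean", "nrmse", float(grp["value"].mean())))
    return pd.concat([agg, pd.DataFrame(extra, columns=agg.columns)], ignore_index=True)


def re_table(aggregated: pd.DataFrame) -> pd.DataFrame:
    """Relative-efficiency rows from aggregated NRMSE rows.

    An RE row is emitted only where both operand strategies have an NRMSE for
    the same (trait, environment).
    """
    nr = aggregated[(aggregated["metric"] == "nrmse") & (aggregated["fold"] == "mean")]
    pivot = nr.pivot_table(
        index=["dataset", "trait", "environment"], columns="strategy", values="value"
    )
    rows = []
    for (dataset, trait, env), row in pivot.iterrows():
        for name, (ref, alt) in _RE_PAIRS.items():
            if ref in row.index and alt in row.index:
                a, b = row[ref], row[alt]
                if np.isfinite(a) and np.isfinite(b) and b > 0:
                    rows.append((dataset, "", trait, env, "mean", name, relative_efficiency(a, b)))
    return pd.DataFrame(
        rows, columns=["dataset", "strategy", "trait", "environment", "fold", "metric", "value"]
    )


def compact_report(aggregated: pd.DataFrame, res: pd.DataFrame) -> dict:
    """Per-strategy Global NRMSE plus the RE matrix, JSON-serializable."""
    nr = aggregated[
        (aggregated["metric"] == "nrmse")
        & (aggregated["fold"] == "mean")
        & (aggregated["environment"] == GLOBAL)
        & (aggregated["trait"] == ALL_TRAITS)
    ]
    global_nrmse = {r["strategy"]: float(r["value"]) for _, r in nr.iterrows()}
    re_global = {
        r["metric"]: float(r["value"])
        for _, r in res.iterrows()
        if r["environment"] == GLOBAL and r["trait"] == ALL_TRAITS
    }
    return {"global_nrmse": global_nrmse, "re_global": re_global}


def plot_re_bars(res: pd.DataFrame, path) -> None:
    """Bar chart of Global relative efficiencies per trait (matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = res[res["environment"] == GLOBAL]
    if sub.empty:
        raise ValueError("no Global RE rows to plot")
    pivot = sub.pivot_table(index="trait", columns="metric", values="value")
    ax = pivot.plot.bar(rot=0)
    ax.axhline(1.0, color="k", lw=0.8)
    ax.set_ylabel("relative efficiency")
    ax.figure.tight_layout()
    ax.figure.savefig(path, dpi=120)
    plt.close(ax.figure)
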