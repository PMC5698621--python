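"""Interval recombination rates (cM/Mb), neighbour LOESS smoothing, and
brood aggregation.

Rates are simple recombinant fractions per adjacent-marker interval:
r = n_recombinant / n_total, cM = 100 r, cM/Mb = 100 r / physical length.
No map-function (Haldane/Kosambi) correction is applied by default: at
~1.2 Mb spacing and ~4 cM/Mb the intervals are a few cM, where r is linear
in map distance to well below sampling error.  A Haldane correction is
available behind ``map_function="haldane"``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def estimate_rates(counts: pd.DataFrame, map_function: str = "none") -> pd.DataFrame:
    """Convert interval counts to a long-format rate table.

    Rows with ``n_total`` 0 are kept with r / cM_per_Mb missing (NaN).
    Recombination fractions above 0.5 are flagged with a warning but kept:
    they indicate marker or calling problems, not valid fine-scale rates.
    """
    if map_function not in ("none", "haldane"):
        raise ValueError(f"unknown map_function {map_function!r}")
    out = counts.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = out["n_recombinant"] / out["n_total"]
    r = r.where(out["n_total"] > 0, np.nan)
    out["r"] = r
    if map_function == "haldane":
        # d = -ln(1-2r)/2 Morgans; undefined at r >= 0.5
        with np.errstate(invalid="ignore", divide="ignore"):
            cm = -50.0 * np.log1p(-2.0 * r)
    else:
        cm = 100.0 * r
    out["cM_per_Mb"] = cm / out["length_mb"]
    n_hot = int((r > 0.5).sum())
    if n_hot:
        warnings.warn(
            f"{n_hot} interval estimates have recombinant fraction > 0.5; "
            "flagged but retained"
        )
    return out


def _tricube(u: np.ndarray) -> np.ndarray:
    a = np.clip(np.abs(u), 0.0, 1.0)
    return (1.0 - a**3) ** 3


# tricube half-width as a multiple of the max in-window distance; >1 so the
# farthest neighbour keeps positive weight even with equal marker spacing
_HALFWIDTH_FACTOR = 1.5


def _local_linear(x: np.ndarray, y: np.ndarray, x0: float, h: float) -> float:
    """Weighted degree-1 fit at x0 with tricube weights of half-width h."""
    w = _tricube((x - x0) / h)
    X = np.column_stack([np.ones_like(x), x - x0])
    WX = X * w[:, None]
    beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ y, rcond=None)
    return float(beta[0])


def loess_neighbours(
    rates: pd.DataFrame,
    value_col: str = "cM_per_Mb",
    pool_females: bool = False,
) -> pd.DataFrame:
    """Three-point neighbour LOESS per treatment x brood.

    At each interval midpoint a local degree-1 (linear) fit is taken over the
    window consisting of that position and its two flanking positions, with
    tricube weights; endpoints use their two available neighbours.  By
    default the fit pools the replicate females' point estimates at each
    position; ``pool_females=True`` smooths the per-position mean instead.

    The standard error reported with the smoother is the between-female
    variability at each position (SD across female point estimates divided
    by sqrt(number of females)), i.e. the replicate variability band, not a
    LOESS residual error.

    Returns a DataFrame with columns treatment, brood, midpoint_mb,
    smoothed, se.
    """
    needed = {"treatment", "brood", "midpoint_mb", value_col}
    missing = needed - set(rates.columns)
    if missing:
        raise ValueError(f"rate table missing columns: {sorted(missing)}")
    out_rows = []
    for (trt, brood), sub in rates.groupby(["treatment", "brood"], sort=True, observed=True):
        sub = sub.dropna(subset=[value_col])
        positions = np.sort(sub["midpoint_mb"].unique())
        by_pos = sub.groupby("midpoint_mb")[value_col]
        means = by_pos.mean()
        sds = by_pos.std(ddof=1)
        ns = by_pos.count()
        se = (sds / np.sqrt(ns)).fillna(0.0)
        if len(positions) < 3:
            warnings.warn(
                f"treatment {trt!r} brood {brood}: fewer than 3 positions; "
                "smoother is an identity pass-through"
            )
            for p in positions:
                out_rows.append((trt, brood, p, means[p], se[p]))
            continue
        for k, p in enumerate(positions):
            lo, hi = max(0, k - 1), min(len(positions), k + 2)
            window = positions[lo:hi]
            if pool_females:
                x = window
                y = means.loc[window].to_numpy()
            else:
                mask = sub["midpoint_mb"].isin(window)
                x = sub.loc[mask, "midpoint_mb"].to_numpy()
                y = sub.loc[mask, value_col].to_numpy()
            h = _HALFWIDTH_FACTOR * np.max(np.abs(window - p))
            smoothed = _local_linear(x, y, p, h)
            out_rows.append((trt, brood, p, smoothed, se[p]))
    return pd.DataFrame(out_rows, columns=["treatment", "brood", "midpoint_mb", "smoothed", "se"])


def aggregate_broods(rates: pd.DataFrame, scheme: dict) -> pd.DataFrame:
    """Pool counts across broods into periods, then recompute rates.

    ``scheme`` maps each brood index to a period label (e.g. broods 1-2 ->
    "early", 3-5 -> "late").  Counts (n_recombinant, n_total) are pooled
    within period *before* recomputing r and cM/Mb — pooling the underlying
    progeny, not averaging rates.  Every brood present in the table must be
    covered by the scheme.

    The returned table has the same columns with ``brood`` replaced by the
    period label.
    """
    broods = set(int(b) for b in rates["brood"].unique())
    uncovered = sorted(broods - set(int(k) for k in scheme))
    if uncovered:
        raise ValueError(f"aggregation scheme missing broods: {uncovered}")
    df = rates.copy()
    df["brood"] = df["brood"].map(lambda b: scheme[int(b)])
    group_cols = ["female_id", "replicate_id", "treatment", "brood", "midpoint_mb", "length_mb"]
    if "interval" in df.columns:
        group_cols.append("interval")
    pooled = (
        df.groupby(group_cols, sort=True, observed=True)[["n_recombinant", "n_total"]]
        .sum()
        .reset_index()
    )
    return estimate_rates(pooled)
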