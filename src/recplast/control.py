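"""Crossover-control statistics: interference and assurance.

Interference is quantified by the coefficient of coincidence
``c = observed joint recombinants / expected under independence`` for pairs
of marker intervals, binned by the genetic distance between them; the
interference coefficient is ``I = 1 - c``.  Assurance (the obligate
crossover rule) is the proportion of progeny chromatids carrying at least
one detected crossover, compared between treatments with a two-proportion
test.

Both statistics are computed from single-chromatid (progeny) data, not
tetrads, so coincidence here conflates chromatid and chiasma interference —
this is what backcross progeny data permit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .crossovers import CrossoverSet, interval_status
from .io import IntervalIndex


@dataclass
class CoincidenceCurve:
    """Coefficient of coincidence per genetic-distance bin, one treatment."""

    treatment: str
    bin_edges_cM: np.ndarray
    coincidence: np.ndarray  # c per bin (NaN for empty bins)
    interference: np.ndarray  # 1 - c
    observed_joint: np.ndarray  # summed joint recombinant counts per bin
    expected_joint: np.ndarray  # summed n_ij * r_i * r_j per bin
    n_pairs: np.ndarray  # interval pairs contributing per bin
    low_confidence: np.ndarray  # expected joint count below threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "treatment": self.treatment,
                "bin_left_cM": self.bin_edges_cM[:-1],
                "bin_right_cM": self.bin_edges_cM[1:],
                "coincidence": self.coincidence,
                "interference": self.interference,
                "observed_joint": self.observed_joint,
                "expected_joint": self.expected_joint,
                "n_pairs": self.n_pairs,
                "low_confidence": self.low_confidence,
            }
        )


@dataclass
class AssuranceResult:
    """Obligate-crossover adherence per treatment, with optional test."""

    treatments: tuple
    n_with_co: tuple
    n_total: tuple
    proportions: tuple
    statistic: float | None = None
    p_value: float | None = None
    test: str | None = None
    degenerate: bool = False

    def to_dict(self) -> dict:
        d = {
            trt: {"n_with_co": int(w), "n_total": int(n), "proportion": float(p)}
            for trt, w, n, p in zip(self.treatments, self.n_with_co, self.n_total, self.proportions)
        }
        if self.test is not None:
            d["test"] = {
                "method": self.test,
                "statistic": None if self.statistic is None else float(self.statistic),
                "p_value": float(self.p_value),
                "degenerate": self.degenerate,
            }
        return d


DEFAULT_BINS_CM = np.arange(0.0, 35.0, 5.0)  # 5 cM bins to 30 cM


def coincidence_curve(
    recombinant: np.ndarray,
    informative: np.ndarray,
    interval_cM: np.ndarray,
    bins_cM: np.ndarray | None = None,
    treatment: str = "",
    min_expected: float = 5.0,
) -> CoincidenceCurve:
    """Coefficient-of-coincidence curve over genetic distance bins.

    Parameters
    ----------
    recombinant, informative : bool arrays (n_progeny, n_intervals)
        Per-progeny per-interval recombinant status and whether both
        flanking markers were informative (see
        :func:`recplast.crossovers.interval_status`).
    interval_cM : array (n_intervals,)
        Pooled genetic length of each interval; supplies both the expected
        recombination fraction r_i = cM_i / 100 and the inter-interval
        distances (midpoint to midpoint).
    bins_cM : bin edges in cM (default 0-30 by 5).

    Notes
    -----
    For every ordered interval pair (i < j), the observed joint recombinant
    count is summed over progeny informative in both intervals, and the
    expected count under independence is n_ij * r_i * r_j.  Each bin's c is
    the ratio of summed observed to summed expected over the pairs whose
    midpoint-to-midpoint distance falls in the bin; empty bins give NaN.
    """
    rec = np.asarray(recombinant, bool)
    inf = np.asarray(informative, bool)
    cm = np.asarray(interval_cM, float)
    K = cm.shape[0]
    if rec.shape[1] != K or inf.shape[1] != K:
        raise ValueError("status matrices and interval_cM disagree on interval count")
    if K < 2:
        raise ValueError("need at least 2 intervals for a coincidence curve")
    edges = DEFAULT_BINS_CM if bins_cM is None else np.asarray(bins_cM, float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be increasing")

    r = cm / 100.0
    # genetic midpoint of interval i on the cumulative cM axis
    cum = np.concatenate([[0.0], np.cumsum(cm)])
    mid = (cum[:-1] + cum[1:]) / 2.0

    nb = len(edges) - 1
    obs = np.zeros(nb)
    exp = np.zeros(nb)
    npairs = np.zeros(nb, dtype=int)
    for i in range(K):
        for j in range(i + 1, K):
            d = mid[j] - mid[i]
            b = np.searchsorted(edges, d, side="right") - 1
            if b < 0 or b >= nb:
                continue
            both_inf = inf[:, i] & inf[:, j]
            n_ij = int(both_inf.sum())
            if n_ij == 0:
                continue
            obs[b] += int((rec[:, i] & rec[:, j] & both_inf).sum())
            exp[b] += n_ij * r[i] * r[j]
            npairs[b] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(exp > 0, obs / exp, np.nan)
    return CoincidenceCurve(
        treatment=treatment,
        bin_edges_cM=edges,
        coincidence=c,
        interference=1.0 - c,
        observed_joint=obs,
        expected_joint=exp,
        n_pairs=npairs,
        low_confidence=exp < min_expected,
    )


def assurance_proportion(calls: list[CrossoverSet], treatment: str = "") -> AssuranceResult:
    """Proportion of progeny chromatids with at least one detected CO.

    Uninformative progeny (flagged in calling) are excluded from the
    denominator.
    """
    usable = [xo for xo in calls if not xo.uninformative]
    if not usable:
        raise ValueError(f"no informative progeny in group {treatment!r}")
    n_with = sum(1 for xo in usable if xo.n_co >= 1)
    n = len(usable)
    return AssuranceResult(
        treatments=(treatment,),
        n_with_co=(n_with,),
        n_total=(n,),
        proportions=(n_with / n,),
    )


def assurance_test(a: AssuranceResult, b: AssuranceResult) -> AssuranceResult:
    """Two-sided test of equal obligate-crossover proportions.

    Chi-square with continuity correction by default; Fisher's exact test
    when any expected cell count is below 5.  When both groups share a
    single outcome (all with or all without a CO) the comparison is
    degenerate and p = 1 by convention, flagged.
    """
    (wa,), (na,) = a.n_with_co, a.n_total
    (wb,), (nb,) = b.n_with_co, b.n_total
    if na == 0 or nb == 0:
        raise ValueError("both groups need totals > 0")
    table = np.array([[wa, na - wa], [wb, nb - wb]], dtype=float)
    merged = dict(
        treatments=(a.treatments[0], b.treatments[0]),
        n_with_co=(wa, wb),
        n_total=(na, nb),
        proportions=(wa / na, wb / nb),
    )
    col_sums = table.sum(axis=0)
    if (col_sums == 0).any():
        return AssuranceResult(**merged, statistic=0.0, p_value=1.0, test="degenerate", degenerate=True)
    expected = np.outer(table.sum(axis=1), col_sums) / table.sum()
    if (expected < 5).any():
        _, p = stats.fisher_exact(table.astype(int), alternative="two-sided")
        return AssuranceResult(**merged, statistic=None, p_value=float(p), test="fisher_exact")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return AssuranceResult(**merged, statistic=float(chi2), p_value=float(p), test="chi2_cc")


def control_report(
    table,
    calls: list[CrossoverSet],
    intervals: IntervalIndex,
    pooled_interval_cM: np.ndarray,
    bins_cM: np.ndarray | None = None,
) -> dict:
    """Interference curves per treatment and the assurance comparison.

    ``pooled_interval_cM`` should come from the treatment-pooled rate table
    (pooling stabilises the distance bins).  Returns a JSON-ready dict.
    """
    rec, inf = interval_status(table.genotypes)
    treatments = sorted(table.meta["treatment"].unique())
    curves = {}
    assurances = {}
    for trt in treatments:
        mask = (table.meta["treatment"] == trt).to_numpy()
        curves[trt] = coincidence_curve(
            rec[mask], inf[mask], pooled_interval_cM, bins_cM, treatment=str(trt)
        )
        trt_calls = [xo for xo, m in zip(calls, mask) if m]
        assurances[trt] = assurance_proportion(trt_calls, treatment=str(trt))
    report = {
        "coincidence": {
            trt: curves[trt].to_frame().drop(columns="treatment").to_dict(orient="list")
            for trt in treatments
        },
        "assurance": {trt: assurances[trt].to_dict()[str(trt)] for trt in treatments},
    }
    if len(treatments) == 2:
        tested = assurance_test(assurances[treatments[0]], assurances[treatments[1]])
        report["assurance"]["test"] = tested.to_dict()["test"]
    return report
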