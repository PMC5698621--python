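"""Crossover calling from backcross genotype vectors.

In a backcross, each progeny inherits one recombinant (or non-recombinant)
chromatid from the F1 mother, so a crossover is observed wherever the
genotype state (HET vs HOM-recurrent) switches between consecutive
*informative* (non-missing) markers.  Missing markers are skipped, so a
called breakpoint may span several physical intervals ("wide" events).

Because crossover interference makes two crossovers within a few cM of each
other extremely unlikely, an apparent double crossover isolating a single
marker is far more plausibly a genotyping error; ``flag_tight_double_crossovers``
implements that filter (mask-and-recall by default, configurable to keep).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, MarkerMap, ProgenyTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CrossoverSet:
    """Called crossover breakpoints for one progeny chromatid.

    ``breakpoints`` holds (left, right) marker indices of consecutive
    informative markers whose states differ; ``n_co`` is the number of such
    switches.  ``informative`` marks the valid marker calls used.
    """

    progeny_id: str
    breakpoints: tuple  # of (left_marker_index, right_marker_index)
    n_co: int
    informative: np.ndarray  # bool mask over markers
    uninformative: bool = False  # <2 informative markers

    def __post_init__(self):
        if self.n_co != len(self.breakpoints):
            raise ValueError("n_co must equal the number of breakpoints")
        for (a, b), (c, d) in zip(self.breakpoints[:-1], self.breakpoints[1:]):
            if not (a < b <= c < d):
                raise ValueError("breakpoints must be ordered and non-overlapping")

    def is_wide(self) -> np.ndarray:
        """True per breakpoint when its flanks are not adjacent markers."""
        return np.array([right - left > 1 for left, right in self.breakpoints], dtype=bool)


def call_crossovers(genotypes: np.ndarray, mmap: MarkerMap, progeny_id: str = "") -> CrossoverSet:
    """Call crossovers on one progeny genotype vector.

    Parameters
    ----------
    genotypes : array of int8
        Codes over the ordered markers of ``mmap`` (HOM / HET / MISSING).

    Returns
    -------
    CrossoverSet
        A breakpoint between each pair of consecutive informative markers
        whose states differ.  Progeny with fewer than 2 informative markers
        are flagged ``uninformative`` (n_co = 0) and logged.
    """
    g = np.asarray(genotypes, dtype=np.int8)
    if g.shape != (mmap.n_markers,):
        raise ValueError(
            f"genotype vector length {g.shape} does not match {mmap.n_markers} markers"
        )
    informative = g != MISSING
    idx = np.flatnonzero(informative)
    if len(idx) < 2:
        logger.info("progeny %s has <2 informative markers; excluded", progeny_id)
        return CrossoverSet(progeny_id, (), 0, informative, uninformative=True)
    states = g[idx]
    switches = np.flatnonzero(states[:-1] != states[1:])
    breakpoints = tuple((int(idx[k]), int(idx[k + 1])) for k in switches)
    return CrossoverSet(progeny_id, breakpoints, len(breakpoints), informative)


def call_all(table: ProgenyTable) -> list:
    """Call crossovers for every progeny in a table."""
    return [
        call_crossovers(table.genotypes[i], table.marker_map, str(table.meta["progeny_id"].iloc[i]))
        for i in range(table.n_progeny)
    ]


def flag_tight_double_crossovers(
    xo: CrossoverSet,
    genotypes: np.ndarray,
    mmap: MarkerMap,
    min_cM_gap: float | None = None,
    interval_cM: np.ndarray | None = None,
    action: str = "mask",
):
    """Flag apparent double crossovers that isolate a single marker.

    A pair of consecutive breakpoints sharing one informative marker between
    them (pattern ...HET, HOM, HET...) implies two crossovers within one
    marker spacing — implausible under strong interference and most likely a
    genotyping error at the isolated marker.

    Parameters
    ----------
    min_cM_gap : float, optional
        When given together with ``interval_cM`` (a provisional genetic
        length per physical interval), only singleton-isolating doubles whose
        total genetic span is below this gap are flagged.  Default flags
        every singleton-isolating double.
    action : {"mask", "keep"}
        "mask" sets the isolated marker MISSING and re-calls; "keep" returns
        the original call with flags only.

    Returns
    -------
    (CrossoverSet, flagged_marker_indices, masked_genotypes)
    """
    if action not in ("mask", "keep"):
        raise ValueError(f"unknown action {action!r}")
    g = np.asarray(genotypes, dtype=np.int8).copy()
    flagged = []
    for (l1, r1), (l2, r2) in zip(xo.breakpoints[:-1], xo.breakpoints[1:]):
        if r1 == l2 and r1 - l1 == 1 and r2 - l2 == 1:
            # single informative marker isolated by two adjacent-marker breakpoints
            if min_cM_gap is not None and interval_cM is not None:
                span_cM = float(interval_cM[l1]) + float(interval_cM[l2])
                if span_cM >= min_cM_gap:
                    continue
            flagged.append(r1)
    if action == "keep" or not flagged:
        return xo, flagged, g
    g[flagged] = MISSING
    recalled = call_crossovers(g, mmap, xo.progeny_id)
    return recalled, flagged, g


def apply_tight_double_filter(
    table: ProgenyTable,
    min_cM_gap: float | None = None,
    interval_cM: np.ndarray | None = None,
    action: str = "mask",
) -> tuple:
    """Run calling with the tight-double filter over a whole table.

    Returns (list of CrossoverSet, masked genotype matrix, flag count).
    """
    geno = table.genotypes.copy()
    calls = []
    n_flagged = 0
    for i in range(table.n_progeny):
        pid = str(table.meta["progeny_id"].iloc[i])
        xo = call_crossovers(geno[i], table.marker_map, pid)
        xo, flagged, g = flag_tight_double_crossovers(
            xo, geno[i], table.marker_map, min_cM_gap, interval_cM, action
        )
        geno[i] = g
        n_flagged += len(flagged)
        calls.append(xo)
    if n_flagged:
        logger.info("tight-double filter flagged %d marker calls", n_flagged)
    return calls, geno, n_flagged


def interval_status(genotypes: np.ndarray) -> tuple:
    """Per-adjacent-interval recombinant status from flanking markers.

    Returns (recombinant, informative) boolean arrays of length
    n_markers - 1; an interval is informative only when both flanking
    markers are non-missing (classical two-point scoring).
    """
    g = np.asarray(genotypes, dtype=np.int8)
    left, right = g[..., :-1], g[..., 1:]
    informative = (left != MISSING) & (right != MISSING)
    recombinant = informative & (left != right)
    return recombinant, informative


def count_recombinants(
    table: ProgenyTable,
    genotypes: np.ndarray | None = None,
    min_informative_fraction: float = 0.5,
) -> pd.DataFrame:
    """Tabulate recombinants per female x treatment x brood x interval.

    For each adjacent-marker interval, ``n_recombinant`` counts progeny whose
    two flanking markers are informative and differ in state; ``n_total``
    counts progeny with both flanks informative.  Groups with no progeny in
    an interval keep a zero-count row.

    Progeny with fewer than ``min_informative_fraction`` informative markers
    are excluded (logged); set to 0 to keep all.

    Parameters
    ----------
    genotypes : optional matrix overriding ``table.genotypes`` — used to
        count on error-filtered (masked) genotypes.
    """
    geno = table.genotypes if genotypes is None else np.asarray(genotypes, dtype=np.int8)
    informative_frac = (geno != MISSING).mean(axis=1)
    keep = informative_frac >= min_informative_fraction
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "excluding %d progeny with <%.0f%% informative markers",
            n_dropped,
            100 * min_informative_fraction,
        )
    rec, inf = interval_status(geno[keep])
    meta = table.meta.loc[keep].reset_index(drop=True)
    intervals = table.marker_map.intervals()

    n_int = intervals.n_intervals
    frames = []
    group_cols = ["female_id", "replicate_id", "treatment", "brood"]
    groups = meta.groupby(group_cols, sort=True, observed=True).indices
    # every observed group gets a row for every interval (zero counts retained)
    for key in sorted(groups):
        rows = groups[key]
        frames.append(
            pd.DataFrame(
                {
                    "female_id": key[0],
                    "replicate_id": key[1],
                    "treatment": key[2],
                    "brood": key[3],
                    "interval": np.arange(n_int),
                    "midpoint_mb": intervals.midpoints_mb,
                    "length_mb": intervals.lengths_mb,
                    "n_recombinant": rec[rows].sum(axis=0).astype(int),
                    "n_total": inf[rows].sum(axis=0).astype(int),
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=group_cols
            + ["interval", "midpoint_mb", "length_mb", "n_recombinant", "n_total"]
        )
    out = pd.concat(frames, ignore_index=True)
    assert (out["n_recombinant"] <= out["n_total"]).all()
    return out


def crossover_table(calls: list) -> pd.DataFrame:
    """Flatten CrossoverSets to a long table (one row per breakpoint)."""
    rows = []
    for xo in calls:
        for left, right in xo.breakpoints:
            rows.append((xo.progeny_id, left, right))
    return pd.DataFrame(rows, columns=["progeny_id", "breakpoint_left_marker", "breakpoint_right_marker"])
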