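"""Tabular input/output and validation for backcross genotype data.

Two delimited-text formats are read: a marker map (marker_id, chromosome,
position_bp) and a progeny table (progeny_id, female_id, replicate_id,
treatment, brood, one genotype column per marker).  Genotype codes are
configurable; the defaults are ``H`` = heterozygous, ``A`` = homozygous for
the recurrent parent, ``.`` = missing.  In a backcross only these two
informative classes occur, so any unexpected code is demoted to missing with
a warning rather than rejected.

Coordinates are 1-based base pairs; intervals between adjacent markers are
half-open ``[left, right)`` and Mb = bp / 1e6 exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# genotype codes used internally
HOM = 0
HET = 1
MISSING = 2

DEFAULT_GENOTYPE_CODES = {"H": HET, "A": HOM, ".": MISSING}

_CODE_NAMES = {HOM: "HOM", HET: "HET", MISSING: "MISSING"}


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class MarkerMap:
    """Ordered physical positions of genotyped markers on one chromosome.

    Parameters
    ----------
    chromosome : str
        Chromosome label (a single chromosome per map).
    marker_ids : tuple of str
        Marker identifiers, sorted by physical position.
    positions_bp : numpy.ndarray
        1-based physical positions in bp, strictly increasing.
    """

    chromosome: str
    marker_ids: tuple
    positions_bp: np.ndarray
    # permutation taking original input row order to sorted order
    input_order: tuple = field(default=(), compare=False)

    def __post_init__(self):
        pos = np.asarray(self.positions_bp, dtype=np.int64)
        object.__setattr__(self, "positions_bp", pos)
        if len(self.marker_ids) != len(pos):
            raise ValidationError("marker_ids and positions_bp length mismatch")
        if len(pos) < 2:
            raise ValidationError("a marker map needs at least 2 markers")
        if np.any(pos <= 0):
            raise ValidationError("marker positions must be positive (1-based bp)")
        if np.any(np.diff(pos) <= 0):
            raise ValidationError("marker positions must be strictly increasing")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            dupes = sorted({m for m in self.marker_ids if list(self.marker_ids).count(m) > 1})
            raise ValidationError(f"duplicate marker ids: {dupes}")

    @property
    def n_markers(self) -> int:
        return len(self.positions_bp)

    @property
    def positions_mb(self) -> np.ndarray:
        return self.positions_bp / 1e6

    def intervals(self) -> "IntervalIndex":
        return IntervalIndex.from_marker_map(self)


@dataclass(frozen=True)
class IntervalIndex:
    """Adjacent-marker intervals: the denominators of cM/Mb.

    One row per adjacent marker pair: left/right marker ids, physical length
    in Mb (exactly ``(right_bp - left_bp) / 1e6``) and the interval midpoint
    in Mb.
    """

    left_markers: tuple
    right_markers: tuple
    lengths_mb: np.ndarray
    midpoints_mb: np.ndarray

    @classmethod
    def from_marker_map(cls, mmap: MarkerMap) -> "IntervalIndex":
        pos = mmap.positions_bp
        lengths = np.diff(pos) / 1e6
        mids = (pos[:-1] + pos[1:]) / 2e6
        return cls(
            left_markers=tuple(mmap.marker_ids[:-1]),
            right_markers=tuple(mmap.marker_ids[1:]),
            lengths_mb=lengths,
            midpoints_mb=mids,
        )

    def __post_init__(self):
        lengths = np.asarray(self.lengths_mb, dtype=float)
        object.__setattr__(self, "lengths_mb", lengths)
        object.__setattr__(self, "midpoints_mb", np.asarray(self.midpoints_mb, dtype=float))
        if np.any(lengths <= 0):
            raise ValidationError("interval physical lengths must be > 0")

    @property
    def n_intervals(self) -> int:
        return len(self.lengths_mb)


@dataclass
class ProgenyTable:
    """Per-progeny genotype vectors with cross metadata.

    ``meta`` is a DataFrame with columns progeny_id, female_id, replicate_id,
    treatment, brood (one row per progeny); ``genotypes`` is an int8 array of
    shape (n_progeny, n_markers) holding HOM / HET / MISSING codes aligned
    to ``marker_map``.
    """

    meta: pd.DataFrame
    genotypes: np.ndarray
    marker_map: MarkerMap

    META_COLUMNS = ("progeny_id", "female_id", "replicate_id", "treatment", "brood")

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.meta = self.meta.reset_index(drop=True)
        missing_cols = [c for c in self.META_COLUMNS if c not in self.meta.columns]
        if missing_cols:
            raise ValidationError(f"progeny table missing metadata columns: {missing_cols}")
        if self.genotypes.shape != (len(self.meta), self.marker_map.n_markers):
            raise ValidationError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.meta)} progeny x {self.marker_map.n_markers} markers"
            )
        if self.meta["progeny_id"].duplicated().any():
            dupes = self.meta.loc[self.meta["progeny_id"].duplicated(), "progeny_id"].tolist()
            raise ValidationError(f"duplicate progeny ids: {dupes}")
        bad = ~np.isin(self.genotypes, [HOM, HET, MISSING])
        if bad.any():
            raise ValidationError("genotype matrix contains codes outside {HOM, HET, MISSING}")
        # each female maps to exactly one replicate and one treatment
        fem = self.meta.groupby("female_id")[["replicate_id", "treatment"]].nunique()
        offenders = fem[(fem > 1).any(axis=1)].index.tolist()
        if offenders:
            raise ValidationError(
                f"females mapped to multiple replicates/treatments: {offenders}"
            )
        broods = self.meta["brood"].to_numpy()
        if not np.issubdtype(np.asarray(broods).dtype, np.integer):
            raise ValidationError("brood indices must be integers")
        if (broods < 1).any():
            raise ValidationError("brood indices must be >= 1")
        for trt, sub in self.meta.groupby("treatment"):
            levels = np.sort(sub["brood"].unique())
            if not np.array_equal(levels, np.arange(levels[0], levels[-1] + 1)):
                raise ValidationError(
                    f"brood indices for treatment {trt!r} are not contiguous: {levels.tolist()}"
                )

    @property
    def n_progeny(self) -> int:
        return len(self.meta)

    def missingness_by_marker(self) -> pd.Series:
        frac = (self.genotypes == MISSING).mean(axis=0)
        return pd.Series(frac, index=list(self.marker_map.marker_ids), name="missing_fraction")

    def all_missing_progeny(self) -> list:
        mask = (self.genotypes == MISSING).all(axis=1)
        return self.meta.loc[mask, "progeny_id"].tolist()


def _sniff_delimiter(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_marker_map(path) -> MarkerMap:
    """Read and validate a marker map from delimited text.

    The file must have a header with columns marker_id, chromosome,
    position_bp.  Rows may be in any physical order; the returned map is
    sorted by position and records the original->sorted permutation.
    """
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype={"marker_id": str, "chromosome": str})
    required = {"marker_id", "chromosome", "position_bp"}
    if not required.issubset(df.columns):
        raise ValidationError(f"marker map must have columns {sorted(required)}, got {list(df.columns)}")
    try:
        positions = df["position_bp"].astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-integer position_bp in marker map: {exc}") from exc
    if not (df["position_bp"].astype(float) == positions.astype(float)).all():
        bad = df.loc[df["position_bp"].astype(float) != positions.astype(float)].index.tolist()
        raise ValidationError(f"non-integer position_bp at rows {bad}")
    if df["chromosome"].nunique() > 1:
        raise ValidationError(
            f"marker map spans multiple chromosomes: {sorted(df['chromosome'].unique())}"
        )
    if df["marker_id"].duplicated().any():
        dupes = df.loc[df["marker_id"].duplicated(), "marker_id"].tolist()
        raise ValidationError(f"duplicate marker ids: {dupes}")
    if positions.duplicated().any():
        rows = df.index[positions.duplicated(keep=False)].tolist()
        raise ValidationError(f"duplicate positions at rows {rows}")
    order = np.argsort(positions.to_numpy(), kind="stable")
    return MarkerMap(
        chromosome=str(df["chromosome"].iloc[0]),
        marker_ids=tuple(df["marker_id"].to_numpy()[order]),
        positions_bp=positions.to_numpy()[order],
        input_order=tuple(int(i) for i in order),
    )


def write_marker_map(mmap: MarkerMap, path, sep: str = ",") -> None:
    df = pd.DataFrame(
        {
            "marker_id": list(mmap.marker_ids),
            "chromosome": mmap.chromosome,
            "position_bp": mmap.positions_bp,
        }
    )
    df.to_csv(path, sep=sep, index=False)


def read_progeny_table(path, mmap: MarkerMap, genotype_codes=None) -> ProgenyTable:
    """Read and validate a progeny genotype table against a marker map.

    Genotype columns are located by marker id, so column order in the file
    need not match map order.  Unknown genotype codes raise with the row and
    column; progeny with all-missing genotypes are retained but logged.
    """
    codes = dict(DEFAULT_GENOTYPE_CODES if genotype_codes is None else genotype_codes)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    meta_cols = list(ProgenyTable.META_COLUMNS)
    missing_meta = [c for c in meta_cols if c not in df.columns]
    if missing_meta:
        raise ValidationError(f"progeny table missing columns: {missing_meta}")
    geno_cols = [c for c in df.columns if c not in meta_cols]
    missing_markers = [m for m in mmap.marker_ids if m not in geno_cols]
    if missing_markers:
        raise ValidationError(
            f"progeny table lacks genotype columns for markers: {missing_markers}"
        )
    extra = [c for c in geno_cols if c not in mmap.marker_ids]
    if extra:
        raise ValidationError(f"genotype columns not in marker map: {extra}")

    geno = np.full((len(df), mmap.n_markers), MISSING, dtype=np.int8)
    for j, marker in enumerate(mmap.marker_ids):
        col = df[marker].str.strip()
        for code, value in codes.items():
            geno[(col == code).to_numpy(), j] = value
        known = col.isin(codes.keys())
        if not known.all():
            bad = df.index[~known]
            unknown = sorted(col[~known].unique())
            raise ValidationError(
                f"unknown genotype code(s) {unknown} in column {marker!r} at rows {bad.tolist()}"
            )

    meta = df[meta_cols].copy()
    try:
        meta["brood"] = meta["brood"].astype(np.int64)
    except ValueError as exc:
        raise ValidationError(f"non-integer brood index: {exc}") from exc
    table = ProgenyTable(meta=meta, genotypes=geno, marker_map=mmap)
    allmiss = table.all_missing_progeny()
    if allmiss:
        warnings.warn(f"{len(allmiss)} progeny have all-missing genotypes: {allmiss[:10]}")
    logger.info("per-marker missingness:\n%s", table.missingness_by_marker().to_string())
    return table


def write_progeny_table(table: ProgenyTable, path, genotype_codes=None, sep: str = ",") -> None:
    codes = dict(DEFAULT_GENOTYPE_CODES if genotype_codes is None else genotype_codes)
    inverse = {v: k for k, v in codes.items()}
    out = table.meta.copy()
    for j, marker in enumerate(table.marker_map.marker_ids):
        out[marker] = [inverse[int(g)] for g in table.genotypes[:, j]]
    out.to_csv(path, sep=sep, index=False)


RATE_COLUMNS = [
    "female_id",
    "replicate_id",
    "treatment",
    "brood",
    "midpoint_mb",
    "length_mb",
    "n_recombinant",
    "n_total",
    "r",
    "cM_per_Mb",
]


def write_rate_table(rates: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a long-format rate table with a deterministic row order.

    Values round-trip through text at 17 significant digits (IEEE double
    exact).
    """
    df = rates.copy()
    missing = [c for c in RATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"rate table missing columns: {missing}")
    df = df[RATE_COLUMNS].sort_values(
        ["treatment", "replicate_id", "female_id", "brood", "midpoint_mb"],
        kind="stable",
    )
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_rate_table(path) -> pd.DataFrame:
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in RATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"rate table missing columns: {missing}")
    return df


def validation_report(mmap: MarkerMap, table: ProgenyTable) -> str:
    """Human-readable validation summary used by ``recplast validate``."""
    lines = [
        f"chromosome: {mmap.chromosome}",
        f"markers: {mmap.n_markers} spanning "
        f"{mmap.positions_bp[0]:,}-{mmap.positions_bp[-1]:,} bp "
        f"(mean spacing {np.diff(mmap.positions_bp).mean() / 1e6:.3f} Mb)",
        f"progeny: {table.n_progeny}",
        f"females: {table.meta['female_id'].nunique()}  "
        f"replicates: {table.meta['replicate_id'].nunique()}  "
        f"treatments: {sorted(table.meta['treatment'].unique())}",
        f"broods: {sorted(table.meta['brood'].unique())}",
        f"overall missingness: {(table.genotypes == MISSING).mean():.4f}",
    ]
    allmiss = table.all_missing_progeny()
    if allmiss:
        lines.append(f"all-missing progeny ({len(allmiss)}): {allmiss[:10]}")
    counts = table.meta.groupby(["treatment", "brood"]).size()
    lines.append("progeny per treatment x brood:")
    lines.append(counts.to_string())
    return "\n".join(lines)
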