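"""Meiosis and brood time-course simulator.

Generates backcross progeny genotype data with the statistical structure the
pipeline assumes, plus a per-progeny truth table for oracle checks:

* Chiasmata are placed on the four-chromatid bivalent by a *stationary gamma
  renewal process*: inter-chiasma distances are Gamma(shape nu, mean 50 cM)
  on the bundle scale, so the expected chromatid map length equals the input
  genetic map.  nu = 1 is a Poisson process (no interference); nu > 1 gives
  underdispersed, interfering placements.  Stationarity is achieved by
  starting the renewal sequence far upstream of the chromosome and keeping
  the points that land on it.  Obligate crossing-over is imposed by
  rejection (condition on >= 1 chiasma per bivalent).
* Each chiasma involves one chromatid of each homolog, chosen uniformly and
  independently (no chromatid interference); a single meiotic product is
  transmitted.  Biased pronucleus selection (transmission distortion) is
  modelled by sampling the transmitted product with weight ``delta`` for
  recombinant products and 1 otherwise; delta = 1 is fair meiosis.
* Treatment effects multiply per-interval genetic map lengths in the
  treated arm, switched on per brood according to a temporal mechanism:
  ``early`` (effect delayed by the oogenesis pipeline, visible only in
  later broods), ``late`` (immediate, lasting while the treatment lasts)
  or ``permanent`` (all broods).
* Genotyping noise: each marker call independently missing with
  probability mu, otherwise flipped with probability epsilon.

The simulated chromosome spans the marker panel; crossover positions are
converted between the genetic and physical scales piecewise-linearly per
marker interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import HET, HOM, MISSING, MarkerMap, ProgenyTable

__all__ = [
    "SimConfig",
    "SimResult",
    "simulate_bivalent",
    "thin_to_chromatid",
    "apply_mechanism",
    "apply_distortion",
    "genotype_progeny",
    "simulate_experiment",
]

# mean inter-chiasma distance on the 4-chromatid bundle, cM: two chiasmata
# per Morgan so that 1/2-thinning reproduces the chromatid map length
_MEAN_SPACING_CM = 50.0
# upstream burn-in (in mean spacings) to reach the stationary renewal state
_BURNIN_SPACINGS = 20.0

_MECHANISMS = ("early", "late", "permanent")


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the meiosis/brood simulator.

    Defaults mirror the temperature time-course design the pipeline targets:
    24 markers at 1.23 Mb spacing on one chromosome, a uniform background
    map of 3.8 cM/Mb, strong interference (nu = 10) with obligate
    crossing-over, two treatment arms (18C control, 23C treated) followed
    over five 48 h broods, with 2 replicate vials x 4 F1 females per arm
    and 14 progeny per female per brood (~224 progeny per brood per
    time point).

    ``effect_map`` (per-interval fold-change for the treated arm) defaults
    to ``fold_change`` at ``effect_intervals`` (all intervals when None).
    ``effect_onset_brood`` / ``effect_duration_broods`` override the
    mechanism's temporal window.
    """

    n_markers: int = 24
    spacing_mb: float = 1.23
    chromosome: str = "2"
    marker_map: MarkerMap | None = None
    base_cM_per_Mb: float = 3.8
    base_interval_cM: tuple | None = None  # overrides the uniform map
    nu: float = 10.0
    obligate: bool = True
    fold_change: float = 1.0
    effect_intervals: tuple | None = None
    effect_map: tuple | None = None
    mechanism: str = "permanent"
    effect_onset_brood: int | None = None
    effect_duration_broods: int | None = None
    treatment_end_brood: int | None = None  # for "late": effect while treated
    delta: float = 1.0
    epsilon: float = 0.001
    mu: float = 0.02
    treatments: tuple = ("18C", "23C")
    treated_arm: str = "23C"
    n_replicates: int = 2
    females_per_replicate: int = 4
    progeny_per_female_per_brood: int = 14
    n_broods: int = 5
    replicate_effect_sd: float = 0.1  # lognormal SD of a per-vial map scaling
    seed: int = 0

    def __post_init__(self):
        if self.nu < 1:
            raise ValueError("interference shape nu must be >= 1")
        if self.mechanism not in _MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}; choose from {_MECHANISMS}")
        if not (0 <= self.epsilon <= 1 and 0 <= self.mu <= 1):
            raise ValueError("epsilon and mu must be probabilities")
        if self.delta < 0:
            raise ValueError("distortion weight delta must be >= 0")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")
        for name in ("n_markers", "n_replicates", "females_per_replicate",
                     "progeny_per_female_per_brood", "n_broods"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.treated_arm not in self.treatments:
            raise ValueError("treated_arm must be one of treatments")
        if len(self.treatments) != 2:
            raise ValueError("exactly two treatment arms are supported")

    # --- derived pieces ---------------------------------------------------

    def build_marker_map(self) -> MarkerMap:
        if self.marker_map is not None:
            return self.marker_map
        spacing_bp = int(round(self.spacing_mb * 1e6))
        positions = 1_000_000 + spacing_bp * np.arange(self.n_markers)
        ids = tuple(f"M{i + 1:02d}" for i in range(self.n_markers))
        return MarkerMap(chromosome=self.chromosome, marker_ids=ids, positions_bp=positions)

    def base_map_cM(self) -> np.ndarray:
        mmap = self.build_marker_map()
        lengths_mb = np.diff(mmap.positions_bp) / 1e6
        if self.base_interval_cM is not None:
            arr = np.asarray(self.base_interval_cM, float)
            if arr.shape != lengths_mb.shape:
                raise ValueError("base_interval_cM length must equal n_markers - 1")
            return arr
        return self.base_cM_per_Mb * lengths_mb

    def fold_map(self) -> np.ndarray:
        n_int = self.build_marker_map().n_markers - 1
        if self.effect_map is not None:
            arr = np.asarray(self.effect_map, float)
            if arr.shape != (n_int,):
                raise ValueError("effect_map length must equal n_markers - 1")
            if np.any(arr <= 0):
                raise ValueError("effect_map fold-changes must be > 0")
            return arr
        folds = np.ones(n_int)
        idx = np.arange(n_int) if self.effect_intervals is None else np.asarray(self.effect_intervals, int)
        folds[idx] = self.fold_change
        return folds

    def effect_window(self) -> tuple:
        """(onset brood, duration in broods) resolved from the mechanism."""
        if self.mechanism == "early":
            onset = 2 if self.effect_onset_brood is None else self.effect_onset_brood
            duration = 3 if self.effect_duration_broods is None else self.effect_duration_broods
        elif self.mechanism == "late":
            onset = 1 if self.effect_onset_brood is None else self.effect_onset_brood
            end = self.n_broods if self.treatment_end_brood is None else self.treatment_end_brood
            duration = end - onset + 1 if self.effect_duration_broods is None else self.effect_duration_broods
        else:  # permanent
            onset = 1 if self.effect_onset_brood is None else self.effect_onset_brood
            duration = self.n_broods if self.effect_duration_broods is None else self.effect_duration_broods
        return onset, duration


def apply_mechanism(config: SimConfig, brood: int, treatment: str) -> np.ndarray:
    """Effective per-interval genetic map (cM) for one brood and arm.

    The control arm always gets the base map.  In the treated arm the
    per-interval fold-change applies to broods inside the mechanism's
    temporal window: immediately for ``late`` and ``permanent``, after a
    one-brood oogenesis delay (default) for ``early``.
    """
    base = config.base_map_cM()
    if treatment != config.treated_arm:
        return base
    onset, duration = config.effect_window()
    if onset <= brood < onset + duration:
        return base * config.fold_map()
    return base


# ---------------------------------------------------------------------------
# meiosis primitives
# ---------------------------------------------------------------------------


def _simulate_bivalents(map_length_cM: float, nu: float, obligate: bool,
                        rng: np.random.Generator, n: int) -> list:
    """n independent stationary gamma-renewal chiasma draws on [0, L)."""
    L = float(map_length_cM)
    if L <= 0:
        raise ValueError("map_length_cM must be > 0")
    burn = _BURNIN_SPACINGS * _MEAN_SPACING_CM
    total = burn + L
    scale = _MEAN_SPACING_CM / nu

    def draw(m: int) -> list:
        k = int(np.ceil(total / _MEAN_SPACING_CM * 1.5)) + 10
        inter = rng.gamma(nu, scale, size=(m, k))
        pos = np.cumsum(inter, axis=1)
        # extend the rare rows whose renewal sequence ends before L
        while True:
            short = pos[:, -1] < total
            if not short.any():
                break
            extra = rng.gamma(nu, scale, size=(int(short.sum()), k))
            tail = pos[short, -1][:, None] + np.cumsum(extra, axis=1)
            pos = np.concatenate([pos, np.full((m, k), np.inf)], axis=1)
            pos[short, -k:] = tail
        shifted = pos - burn
        return [row[(row >= 0) & (row < L)] for row in shifted]

    out = draw(n)
    if obligate:
        while True:
            empty = [i for i, ch in enumerate(out) if len(ch) == 0]
            if not empty:
                break
            redrawn = draw(len(empty))
            for i, ch in zip(empty, redrawn):
                out[i] = ch
    return out


def simulate_bivalent(map_length_cM: float, nu: float, obligate: bool,
                      rng: np.random.Generator) -> np.ndarray:
    """One bivalent's chiasma positions (cM, bundle scale).

    Points follow a stationary gamma renewal process with shape ``nu`` and
    mean inter-event distance 50 cM (two chiasmata per Morgan, so that
    1/2-thinning to a chromatid reproduces the input map length).  With
    ``obligate`` the draw is conditioned on >= 1 chiasma by rejection.
    """
    return _simulate_bivalents(map_length_cM, nu, obligate, rng, 1)[0]


def thin_to_chromatid(chiasmata: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Crossovers on one chromatid: each chiasma retained with prob 1/2.

    This is the marginal of the no-chromatid-interference model in which
    each chiasma involves one uniformly chosen chromatid of each homolog.
    """
    ch = np.asarray(chiasmata, float)
    return ch[rng.random(ch.shape) < 0.5]


def _four_products(chiasmata: np.ndarray, rng: np.random.Generator):
    """Involvement of the 4 meiotic products in each chiasma.

    Returns a (4, m) boolean matrix; products 0/1 are the two chromatids of
    one homolog, 2/3 of the other.  Each chiasma involves exactly one
    chromatid of each homolog, drawn uniformly and independently.
    """
    m = len(chiasmata)
    a = rng.integers(0, 2, size=m)
    b = rng.integers(0, 2, size=m)
    return np.array([a == 0, a == 1, b == 0, b == 1])


def apply_distortion(involvement: np.ndarray, delta: float, rng: np.random.Generator) -> int:
    """Select the transmitted product among the 4, weighting recombinants.

    ``involvement`` is the (4, m) chiasma-involvement matrix; a product is
    recombinant when it carries >= 1 crossover.  Selection probability is
    proportional to ``delta`` for recombinant products and 1 otherwise;
    delta = 1 is uniform (fair) selection.
    """
    recombinant = involvement.any(axis=1) if involvement.size else np.zeros(4, bool)
    weights = np.where(recombinant, delta, 1.0)
    total = weights.sum()
    if total <= 0:
        raise ValueError("all selection weights are 0 (delta = 0 with all products recombinant)")
    return int(np.searchsorted(np.cumsum(weights) / total, rng.random(), side="right"))


def genotype_progeny(crossovers_cM: np.ndarray, marker_cM: np.ndarray,
                     epsilon: float, mu: float, rng: np.random.Generator) -> np.ndarray:
    """Genotype a chromatid at markers from its crossover positions.

    The state at each marker is HET flipped once per crossover to its left
    (HET at the left telomere by convention).  Each marker call is then
    independently missing with probability mu, else flipped with
    probability epsilon.
    """
    xo = np.sort(np.asarray(crossovers_cM, float))
    parity = np.searchsorted(xo, np.asarray(marker_cM, float), side="right") % 2
    states = np.where(parity == 0, HET, HOM).astype(np.int8)
    k = len(states)
    u = rng.random(k)
    flip = (u >= mu) & (rng.random(k) < epsilon)
    states[flip] = np.int8(HET + HOM) - states[flip]
    states[u < mu] = MISSING
    return states


# ---------------------------------------------------------------------------
# experiment composition
# ---------------------------------------------------------------------------


@dataclass
class SimResult:
    """Simulated experiment: inputs for the pipeline plus the truth table."""

    config: SimConfig
    marker_map: MarkerMap
    progeny_table: ProgenyTable
    truth: pd.DataFrame  # one row per progeny

    def write(self, out_dir) -> dict:
        """Write marker map, progeny table and truth CSVs; returns paths."""
        from pathlib import Path

        from .io import write_marker_map, write_progeny_table

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "marker_map": out / "marker_map.csv",
            "progeny": out / "progeny.csv",
            "truth": out / "truth.csv",
        }
        write_marker_map(self.marker_map, paths["marker_map"])
        write_progeny_table(self.progeny_table, paths["progeny"])
        self.truth.to_csv(paths["truth"], index=False, float_format="%.17g")
        return paths


def _rng(seed: int, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def simulate_experiment(config: SimConfig) -> SimResult:
    """Simulate the full brood time-course experiment.

    Deterministic given ``config.seed``.  Random streams are split by
    (arm, replicate, brood) with separate substreams for chiasma placement
    and for product selection + genotyping, so chiasma-level truth is
    invariant to the distortion parameter delta.
    """
    mmap = config.build_marker_map()
    n_int = mmap.n_markers - 1
    meta_rows = []
    geno_rows = []
    truth_rows = []
    for arm_idx, arm in enumerate(config.treatments):
        for rep in range(config.n_replicates):
            replicate_id = f"{arm}_R{rep + 1}"
            rep_scale = 1.0
            if config.replicate_effect_sd > 0:
                rng_rep = _rng(config.seed, arm_idx, rep, 3)
                rep_scale = float(np.exp(rng_rep.normal(0.0, config.replicate_effect_sd)))
            for brood in range(1, config.n_broods + 1):
                interval_cM = apply_mechanism(config, brood, arm) * rep_scale
                cum_cM = np.concatenate([[0.0], np.cumsum(interval_cM)])
                L = cum_cM[-1]
                n_per_female = config.progeny_per_female_per_brood
                n_block = config.females_per_replicate * n_per_female
                rng_ch = _rng(config.seed, arm_idx, rep, brood, 0)
                rng_sel = _rng(config.seed, arm_idx, rep, brood, 1)
                chiasmata = _simulate_bivalents(L, config.nu, config.obligate, rng_ch, n_block)
                for i in range(n_block):
                    fem = i // n_per_female + 1
                    female_id = f"{replicate_id}_F{fem}"
                    progeny_id = f"{female_id}_B{brood}_P{i % n_per_female + 1}"
                    ch = chiasmata[i]
                    involvement = _four_products(ch, rng_sel)
                    j = apply_distortion(involvement, config.delta, rng_sel)
                    xo = np.sort(ch[involvement[j]])
                    geno = genotype_progeny(xo, cum_cM, config.epsilon, config.mu, rng_sel)
                    meta_rows.append((progeny_id, female_id, replicate_id, arm, brood))
                    geno_rows.append(geno)
                    # interval recombinant truth: odd crossover count inside
                    counts = np.diff(np.searchsorted(xo, cum_cM, side="right"))
                    rec = counts % 2 == 1
                    truth_rows.append(
                        (
                            progeny_id,
                            arm,
                            brood,
                            len(ch),
                            ";".join(f"{p:.6f}" for p in ch),
                            len(xo),
                            ";".join(f"{p:.6f}" for p in xo),
                            ";".join(str(k) for k in np.flatnonzero(rec)),
                            bool(involvement[j].any()),
                        )
                    )
    meta = pd.DataFrame(
        meta_rows, columns=["progeny_id", "female_id", "replicate_id", "treatment", "brood"]
    )
    table = ProgenyTable(meta=meta, genotypes=np.vstack(geno_rows), marker_map=mmap)
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "progeny_id",
            "treatment",
            "brood",
            "n_chiasmata",
            "chiasma_pos_cM",
            "n_co",
            "co_pos_cM",
            "recombinant_intervals",
            "selected_recombinant",
        ],
    )
    assert truth["n_co"].le(truth["n_chiasmata"]).all()
    return SimResult(config=config, marker_map=mmap, progeny_table=table, truth=truth)


def truth_interval_matrix(result: SimResult) -> np.ndarray:
    """Boolean (n_progeny, n_intervals) true recombinant-status matrix."""
    n_int = result.marker_map.n_markers - 1
    mat = np.zeros((len(result.truth), n_int), dtype=bool)
    for i, s in enumerate(result.truth["recombinant_intervals"]):
        if isinstance(s, str) and s:
            mat[i, [int(k) for k in s.split(";")]] = True
    return mat
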