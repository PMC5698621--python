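import numpy as np
import pandas as pd
import pytest

from recplast.io import HET, HOM, MISSING, MarkerMap, ProgenyTable


@pytest.fixture
def small_map():
    """Four markers at 1, 2.5, 4, 5 Mb (intervals 1.5, 1.5, 1.0 Mb)."""
    return MarkerMap(
        chromosome="2",
        marker_ids=("m1", "m2", "m3", "m4"),
        positions_bp=np.array([1_000_000, 2_500_000, 4_000_000, 5_000_000]),
    )


def make_progeny_table(mmap, genotypes, treatments=None, broods=None,
                       females=None, replicates=None):
    """Assemble a ProgenyTable from a genotype matrix and optional metadata."""
    geno = np.asarray(genotypes, dtype=np.int8)
    n = len(geno)
    meta = pd.DataFrame(
        {
            "progeny_id": [f"p{i}" for i in range(n)],
            "female_id": females if females is not None else ["f1"] * n,
            "replicate_id": replicates if replicates is not None else ["r1"] * n,
            "treatment": treatments if treatments is not None else ["18C"] * n,
            "brood": broods if broods is not None else [1] * n,
        }
    )
    return ProgenyTable(meta=meta, genotypes=geno, marker_map=mmap)


@pytest.fixture
def make_table(small_map):
    def _make(genotypes, **kwargs):
        return make_progeny_table(small_map, genotypes, **kwargs)

    return _make


def brute_force_n_co(genotypes):
    """Independent crossover-count oracle: drop missing, count adjacent
    state changes."""
    states = [g for g in genotypes if g != MISSING]
    return sum(1 for a, b in zip(states[:-1], states[1:]) if a != b)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
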