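import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recplast import crossovers as xod
from recplast import rates as rt
from recplast.rates import _HALFWIDTH_FACTOR, _tricube
from recplast.simulate import SimConfig, simulate_experiment


def counts_frame(rows):
    """rows: (n_recombinant, n_total, length_mb) triples for one group."""
    return pd.DataFrame(
        {
            "female_id": "f1",
            "replicate_id": "r1",
            "treatment": "18C",
            "brood": 1,
            "interval": np.arange(len(rows)),
            "midpoint_mb": np.arange(len(rows)) + 1.0,
            "length_mb": [r[2] for r in rows],
            "n_recombinant": [r[0] for r in rows],
            "n_total": [r[1] for r in rows],
        }
    )


class TestEstimateRates:
    def test_basic_arithmetic(self):
        out = rt.estimate_rates(counts_frame([(5, 100, 1.0)]))
        assert out["r"].iloc[0] == 0.05
        assert out["cM_per_Mb"].iloc[0] == pytest.approx(5.0)

    def test_zero_recombinants(self):
        out = rt.estimate_rates(counts_frame([(0, 37, 2.0)]))
        assert out["cM_per_Mb"].iloc[0] == 0.0

    def test_zero_total_is_missing(self):
        out = rt.estimate_rates(counts_frame([(0, 0, 1.0)]))
        assert np.isnan(out["r"].iloc[0]) and np.isnan(out["cM_per_Mb"].iloc[0])

    def test_length_scale_consistency(self):
        a = rt.estimate_rates(counts_frame([(5, 100, 1.0)]))["cM_per_Mb"].iloc[0]
        b = rt.estimate_rates(counts_frame([(5, 100, 2.0)]))["cM_per_Mb"].iloc[0]
        assert b == pytest.approx(a / 2)

    def test_excess_fraction_flagged_not_dropped(self):
        with pytest.warns(UserWarning, match="> 0.5"):
            out = rt.estimate_rates(counts_frame([(80, 100, 1.0)]))
        assert len(out) == 1

    def test_haldane_option(self):
        out = rt.estimate_rates(counts_frame([(10, 100, 1.0)]), map_function="haldane")
        assert out["cM_per_Mb"].iloc[0] == pytest.approx(-50 * np.log1p(-0.2))

    def test_simulator_recovers_background_rate(self):
        """Constant true map, strong interference, noise-free genotypes:
        mean estimated cM/Mb within 2 MC SEs of the configured 3.8.

        Interference matters here: without it, double crossovers inside
        ~4.7 cM intervals shrink the observed fraction below the map
        distance (Haldane), which is exactly why no map-function correction
        is applied at this marker spacing in the interfering organism.
        """
        cfg = SimConfig(
            seed=11, nu=10.0, obligate=True, epsilon=0.0, mu=0.0,
            n_replicates=1, females_per_replicate=1,
            progeny_per_female_per_brood=10_000, n_broods=1,
            replicate_effect_sd=0.0,
        )
        res = simulate_experiment(cfg)
        counts = xod.count_recombinants(res.progeny_table)
        out = rt.estimate_rates(counts)
        r = cfg.base_cM_per_Mb * cfg.spacing_mb / 100
        mc_se = 100 * np.sqrt(r * (1 - r) / 10_000) / cfg.spacing_mb / np.sqrt(out.shape[0] / 2)
        assert abs(out["cM_per_Mb"].mean() - cfg.base_cM_per_Mb) < 2 * mc_se


def rates_frame(values, females=None, treatment="18C", brood=1):
    """Long rate table at given positions; values per (female, position)."""
    values = np.atleast_2d(values)
    n_f, n_pos = values.shape
    rows = []
    for f in range(n_f):
        for k in range(n_pos):
            rows.append(
                {
                    "female_id": f"f{f}" if females is None else females[f],
                    "replicate_id": "r1",
                    "treatment": treatment,
                    "brood": brood,
                    "midpoint_mb": float(k + 1),
                    "length_mb": 1.0,
                    "n_recombinant": 0,
                    "n_total": 10,
                    "r": 0.0,
                    "cM_per_Mb": values[f, k],
                }
            )
    return pd.DataFrame(rows)


class TestLoessNeighbours:
    def test_constant_reproduced_with_zero_se(self):
        out = rt.loess_neighbours(rates_frame([[4.0] * 6, [4.0] * 6]))
        np.testing.assert_allclose(out["smoothed"], 4.0)
        np.testing.assert_allclose(out["se"], 0.0)

    def test_linear_reproduced_exactly(self):
        x = np.arange(1, 7, dtype=float)
        out = rt.loess_neighbours(rates_frame(2.0 * x + 1.0))
        np.testing.assert_allclose(out["smoothed"], 2.0 * x + 1.0, atol=1e-10)

    def test_interior_point_matches_wls_oracle(self, rng):
        vals = rng.uniform(0, 10, size=(3, 7))
        out = rt.loess_neighbours(rates_frame(vals)).set_index("midpoint_mb")
        # brute-force weighted linear regression on the 3-point window at x0=4
        x0 = 4.0
        xs, ys = [], []
        for f in range(3):
            for k, x in enumerate([3.0, 4.0, 5.0]):
                xs.append(x)
                ys.append(vals[f, k + 2])
        xs, ys = np.array(xs), np.array(ys)
        w = _tricube((xs - x0) / (_HALFWIDTH_FACTOR * 1.0))
        X = np.column_stack([np.ones_like(xs), xs - x0])
        beta = np.linalg.solve((X * w[:, None]).T @ X, (X * w[:, None]).T @ ys)
        assert out.loc[x0, "smoothed"] == pytest.approx(beta[0], rel=1e-10)

    @settings(max_examples=30, derandomize=True)
    @given(
        vals=st.lists(
            st.floats(min_value=0, max_value=20, allow_nan=False),
            min_size=4,
            max_size=10,
        )
    )
    def test_smoother_stays_in_window_range(self, vals):
        out = rt.loess_neighbours(rates_frame(vals)).sort_values("midpoint_mb")
        sm = out["smoothed"].to_numpy()
        v = np.asarray(vals)
        for k in range(len(v)):
            lo, hi = max(0, k - 1), min(len(v), k + 2)
            assert v[lo:hi].min() - 1e-9 <= sm[k] <= v[lo:hi].max() + 1e-9

    def test_fewer_than_three_positions_passthrough(self):
        df = rates_frame([[3.0, 5.0]])
        with pytest.warns(UserWarning, match="fewer than 3"):
            out = rt.loess_neighbours(df)
        np.testing.assert_allclose(out["smoothed"], [3.0, 5.0])


class TestAggregateBroods:
    def _two_brood_counts(self):
        rows = []
        for brood, (nrec, ntot) in [(1, (1, 10)), (2, (3, 10))]:
            rows.append(
                {
                    "female_id": "f1",
                    "replicate_id": "r1",
                    "treatment": "18C",
                    "brood": brood,
                    "interval": 0,
                    "midpoint_mb": 1.0,
                    "length_mb": 1.0,
                    "n_recombinant": nrec,
                    "n_total": ntot,
                }
            )
        return rt.estimate_rates(pd.DataFrame(rows))

    def test_pooling_arithmetic(self):
        out = rt.aggregate_broods(self._two_brood_counts(), {1: "early", 2: "early"})
        assert len(out) == 1
        assert out["n_recombinant"].iloc[0] == 4
        assert out["n_total"].iloc[0] == 20
        assert out["r"].iloc[0] == pytest.approx(0.2)

    def test_single_brood_identity(self):
        rates = self._two_brood_counts()
        out = rt.aggregate_broods(rates, {1: 1, 2: 2})
        merged = out.set_index("brood")["r"]
        assert merged.loc[1] == pytest.approx(0.1)
        assert merged.loc[2] == pytest.approx(0.3)

    def test_missing_brood_rejected(self):
        with pytest.raises(ValueError, match="missing broods"):
            rt.aggregate_broods(self._two_brood_counts(), {1: "early"})

    def test_pooled_equals_progeny_level_recount(self, rng):
        """Aggregating brood counts equals recounting on progeny relabelled
        into one brood."""
        cfg = SimConfig(seed=3, n_broods=3, progeny_per_female_per_brood=4)
        res = simulate_experiment(cfg)
        counts = xod.count_recombinants(res.progeny_table)
        pooled = rt.aggregate_broods(
            rt.estimate_rates(counts), {1: 1, 2: 1, 3: 1}
        )
        table = res.progeny_table
        table.meta["brood"] = 1
        recount = rt.estimate_rates(xod.count_recombinants(table))
        key = ["female_id", "interval"]
        a = pooled.sort_values(key).reset_index(drop=True)
        b = recount.sort_values(key).reset_index(drop=True)
        np.testing.assert_array_equal(a["n_recombinant"], b["n_recombinant"])
        np.testing.assert_array_equal(a["n_total"], b["n_total"])


def test_haldane_limit_no_interference():
    """nu=1 over one 10 cM interval: recombinant fraction matches
    (1 - exp(-2d))/2 within Monte-Carlo error."""
    cfg = SimConfig(
        seed=9, n_markers=2, base_interval_cM=(10.0,), nu=1.0, obligate=False,
        epsilon=0.0, mu=0.0, delta=1.0, n_replicates=1, females_per_replicate=1,
        progeny_per_female_per_brood=10_000, n_broods=1, replicate_effect_sd=0.0,
    )
    res = simulate_experiment(cfg)
    counts = xod.count_recombinants(res.progeny_table)
    pooled = counts.groupby("interval")[["n_recombinant", "n_total"]].sum()
    frac = pooled["n_recombinant"].sum() / pooled["n_total"].sum()
    expected = (1 - np.exp(-0.2)) / 2
    mc_se = np.sqrt(expected * (1 - expected) / pooled["n_total"].sum())
    assert abs(frac - expected) < 2 * mc_se
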