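"""Growth inference: doublings, expected synthesis, reductive division,
cell sizes, fold comparisons and t-tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sipcoculture import (
    CocultureScenario,
    assess_synthesis,
    doublings,
    expected_xnet,
    length_stats,
    max_density_fold,
    percent_reduction,
    simulate_coculture,
    t_test_two_tailed,
)


class TestDoublings:
    @pytest.mark.parametrize(
        "n0, nt, expected",
        [(1e6, 2e6, 1.0), (1e6, 8e6, 3.0), (1e6, 1e6, 0.0)],
    )
    def test_examples(self, n0, nt, expected):
        assert doublings(n0, nt) == pytest.approx(expected)

    def test_decline_allowed(self):
        assert doublings(2e6, 1e6) == pytest.approx(-1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            doublings(0.0, 1e6)


class TestExpectedXnet:
    def test_five_doublings(self):
        # pre-existing biomass fraction halves each balanced doubling
        assert expected_xnet(5) == pytest.approx(0.96875)
        assert round(expected_xnet(5), 2) == 0.97

    def test_zero(self):
        assert expected_xnet(0) == 0.0

    def test_eight_to_thirteen_doublings_exceed_99_percent(self):
        assert expected_xnet(8) == pytest.approx(0.99609375)
        for d in np.linspace(8, 13, 11):
            assert expected_xnet(d) >= 0.99

    @given(st.floats(min_value=0.0, max_value=40.0))
    def test_monotone_bounded(self, d):
        v = expected_xnet(d)
        assert 0.0 <= v < 1.0
        assert expected_xnet(d + 0.5) > v

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            expected_xnet(-1.0)


def _series(times, densities, replicate=1):
    return pd.DataFrame(
        {
            "time_h": times,
            "density": densities,
            "unit": "CFU/ml",
            "condition": "x",
            "partner": "bacterium",
            "replicate": replicate,
        }
    )


class TestAssessSynthesis:
    def test_starved_culture_flags_reductive_division(self):
        # CFUs rise 3- to 20-fold but tracer-measured synthesis stays low
        series = _series([0, 24, 48], [1e6, 5e6, 2e7])
        measured = pd.DataFrame(
            {"timepoint_h": [24.0, 48.0], "xnet": [0.18, 0.34]}
        )
        out = assess_synthesis(series, measured)
        assert out["reductive_division_flag"].all()
        assert (out["expected_xnet"] > 0.6).all()

    def test_balanced_growth_not_flagged(self):
        series = _series([0, 24], [1e6, 8e6])
        measured = pd.DataFrame(
            {"timepoint_h": [24.0], "xnet": [expected_xnet(3.0)]}
        )
        out = assess_synthesis(series, measured)
        assert not out["reductive_division_flag"].any()
        assert out.loc[0, "gap"] == pytest.approx(0.0, abs=1e-12)

    def test_missing_timepoint_raises(self):
        series = _series([0, 24], [1e6, 8e6])
        measured = pd.DataFrame({"timepoint_h": [72.0], "xnet": [0.5]})
        with pytest.raises(ValueError):
            assess_synthesis(series, measured)

    def test_sucrose_fixture_no_flag_during_log_phase(self):
        """Balanced log-phase growth on sucrose matches the expectation;
        reductive division is never flagged before carbon runs out."""
        sim = simulate_coculture(CocultureScenario.sucrose_monoculture(seed=4))
        led = sim.ledger
        depletion_h = float(
            led.loc[led["doc_pool_ug_per_ml"] < 0.5, "time_h"].iloc[0]
        )
        truth = sim.truth
        F_un, F_sub = 0.0036566, 0.4968283
        measured = (
            truth[truth["partner"] == "bacterium"]
            .groupby("timepoint_h")["true_p15N"].median()
            .sub(F_un).div(F_sub - F_un)
            .rename("xnet").reset_index()
        )
        bact = sim.growth[sim.growth["partner"] == "bacterium"]
        out = assess_synthesis(bact, measured)
        pre = out[out["timepoint_h"] < depletion_h]
        assert not pre["reductive_division_flag"].any()

    def test_coculture_fixture_flags_by_24h(self, continuous_sim):
        truth = continuous_sim.truth
        F_un, F_sub = 0.0036566, 0.4968283
        measured = (
            truth[truth["partner"] == "bacterium"]
            .groupby("timepoint_h")["true_p15N"].median()
            .sub(F_un).div(F_sub - F_un)
            .rename("xnet").reset_index()
        )
        bact = continuous_sim.growth[continuous_sim.growth["partner"] == "bacterium"]
        out = assess_synthesis(bact, measured).set_index("timepoint_h")
        assert out.loc[24.0, "reductive_division_flag"]


class TestCellSize:
    def test_percent_reduction_endpoints(self):
        assert percent_reduction(2.3, 1.45) == pytest.approx(36.96, abs=0.01)
        assert percent_reduction(2.0, 2.0) == 0.0

    def test_stats(self):
        s = length_stats([2.0, 2.0, 2.0])
        assert s == {"mean": 2.0, "sd": 0.0, "n": 3}
        with pytest.raises(ValueError):
            length_stats([])

    @given(st.floats(min_value=0.01, max_value=100.0),
           st.floats(min_value=0.01, max_value=100.0))
    def test_reduction_bounded_above(self, l_ref, l_t):
        assert percent_reduction(l_ref, l_t) < 100.0

    def test_simulated_coculture_length_reduction_in_observed_band(
        self, continuous_sim
    ):
        truth = continuous_sim.truth
        b48 = truth[(truth["partner"] == "bacterium")
                    & (truth["timepoint_h"] == 48.0)]
        sc = continuous_sim.scenario
        red = percent_reduction(sc.cell_length_start_um,
                                length_stats(b48["true_length_um"])["mean"])
        assert 30.0 < red < 55.0


class TestMaxDensityFold:
    def test_identity_and_arithmetic(self):
        a = _series([0, 24], [1e6, 6e7])
        b = _series([0, 24], [1e6, 2e7])
        fold, detail = max_density_fold(a, b)
        assert fold == pytest.approx(3.0)
        assert max_density_fold(a, a)[0] == pytest.approx(1.0)
        assert detail["per_replicate_max_a"] == {1: 6e7}

    def test_unit_mismatch_raises(self):
        a = _series([0], [1e6])
        b = a.copy()
        b["unit"] = "cells/ml"
        with pytest.raises(ValueError, match="unit"):
            max_density_fold(a, b)

    def test_packaged_scenarios_give_threefold(self, continuous_sim, diurnal_sim):
        fold, _ = max_density_fold(
            continuous_sim.growth.query("partner == 'bacterium'"),
            diurnal_sim.growth.query("partner == 'bacterium'"),
        )
        assert 2.4 < fold < 3.6


def _brute_force_t_unpaired(x, y):
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    sx2 = sum((v - mx) ** 2 for v in x) / (nx - 1)
    sy2 = sum((v - my) ** 2 for v in y) / (ny - 1)
    sp2 = ((nx - 1) * sx2 + (ny - 1) * sy2) / (nx + ny - 2)
    return (mx - my) / math.sqrt(sp2 * (1 / nx + 1 / ny))


def _brute_force_t_paired(x, y):
    d = [a - b for a, b in zip(x, y)]
    n = len(d)
    md = sum(d) / n
    sd = math.sqrt(sum((v - md) ** 2 for v in d) / (n - 1))
    return md / (sd / math.sqrt(n))


class TestTTest:
    def test_matches_textbook_formula(self):
        x, y = [1.1, 2.9, 3.4], [2.0, 4.1, 5.2]
        res = t_test_two_tailed(x, y)
        assert res["t"] == pytest.approx(_brute_force_t_unpaired(x, y), abs=1e-12)
        res_p = t_test_two_tailed(x, y, paired=True)
        assert res_p["t"] == pytest.approx(_brute_force_t_paired(x, y), abs=1e-12)

    def test_identical_groups_convention(self):
        res = t_test_two_tailed([1, 2, 3], [1, 2, 3])
        assert res["t"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)
        assert not res["significant"]
        res_p = t_test_two_tailed([2, 2, 2], [2, 2, 2], paired=True)
        assert res_p["p"] == 1.0

    def test_insufficient_n(self):
        with pytest.raises(ValueError):
            t_test_two_tailed([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            t_test_two_tailed([1.0, 2.0], [2.0, 3.0, 4.0], paired=True)

    def test_type_one_error_calibrated(self):
        # simulated null: both groups from the same normal distribution
        rng = np.random.default_rng(123)
        n_rep, n = 2000, 5
        hits = sum(
            t_test_two_tailed(rng.normal(size=n), rng.normal(size=n))["significant"]
            for _ in range(n_rep)
        )
        rate = hits / n_rep
        # 3 sigma Monte-Carlo band around 0.05
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / n_rep)
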