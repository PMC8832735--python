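"""Grid enumeration, E/N-stage elimination and the VENT/SiVENT runs."""

import numpy as np
import pandas as pd
import pytest

from sivent import (
    GridSpec,
    RespiratoryMechanics,
    SafetyThresholds,
    VCSettings,
    compute_outcomes,
    e_stage,
    enumerate_grid,
    evaluate_performance,
    fit_transition_model,
    forecast_percentiles,
    grid_outcomes,
    n_stage,
    run_sivent,
    run_vent,
)
from sivent.protocol import DEFAULT_THRESHOLDS, UNRESTRICTED

# reduced grid for brute-force comparisons: 8*3*8*5*2 = 1920 combinations
SMALL = GridSpec(RR=(6, 34, 4), VT=(4, 8, 2), flow=(10, 150, 20), T_plat=(0.0, 2.0, 0.5))


def survivor_settings(result) -> set:
    cols = ["RR", "waveform", "VT_mL_per_kg", "peak_flow_Lpm", "T_plat_s"]
    return set(map(tuple, result.survivors[cols].itertuples(index=False)))


class TestEnumeration:
    def test_default_grid_size(self):
        assert enumerate_grid().n == 189_000

    def test_single_valued_axes(self):
        g = GridSpec(RR=(15, 15, 1), VT=(6, 6, 1), flow=(40, 40, 5),
                     T_plat=(0.3, 0.3, 0.1), waveforms=("square",))
        assert enumerate_grid(g).n == 1

    def test_rr_axis_has_thirty_values(self):
        assert len(GridSpec().axes()["RR"]) == 30

    def test_empty_axis_raises(self):
        with pytest.raises(ValueError):
            enumerate_grid(GridSpec(waveforms=()))
        with pytest.raises(ValueError):
            GridSpec(RR=(6, 35, 4)).axes()  # range not a multiple of the step


class TestEliminate:
    def test_plateau_exactly_at_limit_is_eliminated(self):
        # E*V_T + PEEP = 50*0.4 + 10 = 30.0: "< 30" is strict
        g = enumerate_grid(GridSpec(RR=(25, 25, 1), VT=(8, 8, 1), flow=(30, 30, 5),
                                    T_plat=(0.0, 0.0, 0.1), waveforms=("square",)))
        out = grid_outcomes(50.0, 0.0, 10.0, 50.0, g)
        assert out["Pplat"][0] == pytest.approx(30.0)
        assert out["IE"][0] == pytest.approx(2.0)
        assert e_stage(out, g).sum() == 0

    def test_disabled_thresholds_keep_everything(self):
        r = run_vent((43.5, 26.2, 13.0), 65.0, thresholds=UNRESTRICTED,
                     objective=None, audit=False)
        assert r.stage_counts["N"] == 189_000
        assert r.pct_reduction == 0.0

    def test_doubling_elastance_cannot_add_survivors(self):
        g = enumerate_grid(SMALL)
        lo = e_stage(grid_outcomes(25.0, 12.0, 8.0, 65.0, g), g)
        hi = e_stage(grid_outcomes(50.0, 12.0, 8.0, 65.0, g), g)
        assert not np.any(hi & ~lo)
        assert hi.sum() <= lo.sum()

    def test_range_elimination_requires_both_percentiles_safe(self):
        g = enumerate_grid(SMALL)
        o_lo = grid_outcomes(30.0, 12.0, 8.0, 65.0, g)
        o_hi = grid_outcomes(55.0, 12.0, 8.0, 65.0, g)
        both = e_stage([o_lo, o_hi], g)
        assert np.array_equal(both, e_stage(o_lo, g) & e_stage(o_hi, g))


class TestNarrow:
    def test_minimum_tier_kept_with_ties(self):
        mask = np.array([True, True, True, False])
        dP = np.array([11.31, 14.14, 11.31, 5.0])
        out = n_stage(mask, dP)
        assert out.tolist() == [True, False, True, False]

    def test_single_survivor_passes_through(self):
        assert n_stage(np.array([True]), np.array([9.9])).tolist() == [True]

    def test_empty_mask_passes_through_empty(self):
        assert n_stage(np.zeros(4, dtype=bool), np.arange(4.0)).sum() == 0

    def test_unknown_objective_raises(self):
        with pytest.raises(ValueError):
            n_stage(np.array([True]), np.array([1.0]), objective="max_comfort")

    def test_narrowing_keeps_only_lowest_tidal_volume_tier(self):
        r = run_vent((26.0, 7.2, 3.0), 52.0, audit=False)
        assert set(r.survivors["VT_mL_per_kg"]) == {4.0}


class TestBruteForce:
    def test_vectorised_engine_matches_per_combination_loop(self):
        E, R, PEEP, weight = 43.5, 26.2, 13.0, 65.0
        g = enumerate_grid(SMALL)
        out = grid_outcomes(E, R, PEEP, weight, g)
        mask = e_stage(out, g)
        final = n_stage(mask, out["dP"])
        mech = RespiratoryMechanics(E, R, PEEP)
        thr = DEFAULT_THRESHOLDS
        brute = []
        for i in range(g.n):
            s = VCSettings(RR=g.RR[i], VT_perkg=g.VT[i], peak_flow=g.flow[i],
                           T_plat=g.T_plat[i],
                           waveform="ramp" if g.is_ramp[i] else "square")
            o = compute_outcomes(mech, s, weight)
            ok = (
                o.P_MAX < thr.Pmax_limit
                and o.P_PLAT < thr.Pplat_limit
                and thr.IE_range[0] - 1e-9 <= o.IE_denom <= thr.IE_range[1] + 1e-9
            )
            brute.append((ok, o.dP))
        brute_mask = np.array([b[0] for b in brute])
        assert np.array_equal(mask, brute_mask)
        dps = np.array([b[1] for b in brute])
        best = dps[brute_mask].min()
        brute_final = brute_mask & (np.abs(dps - best) < 1e-9)
        assert np.array_equal(final, brute_final)

    def test_counts_independent_of_enumeration_order(self):
        from sivent.protocol import SettingGrid

        g = enumerate_grid(SMALL)
        perm = np.random.default_rng(4).permutation(g.n)
        gp = SettingGrid(RR=g.RR[perm], VT=g.VT[perm], flow=g.flow[perm],
                         T_plat=g.T_plat[perm], is_ramp=g.is_ramp[perm])
        o1 = grid_outcomes(43.5, 26.2, 13.0, 65.0, g)
        o2 = grid_outcomes(43.5, 26.2, 13.0, 65.0, gp)
        assert e_stage(o1, g).sum() == e_stage(o2, gp).sum()
        assert n_stage(e_stage(o1, g), o1["dP"]).sum() == n_stage(e_stage(o2, gp), o2["dP"]).sum()


class TestRuns:
    def test_stage_counts_nonincreasing(self):
        r = run_vent((43.5, 26.2, 13.0), 65.0, audit=False)
        c = list(r.stage_counts.values())
        assert all(a >= b for a, b in zip(c, c[1:]))
        assert r.pct_reduction == pytest.approx(
            100.0 * (1 - r.stage_counts["N"] / r.stage_counts["initial"])
        )

    def test_degenerate_forecast_reduces_to_vent(self):
        # forecast band collapses onto the current elastance: SiVENT must
        # reproduce the deterministic run (pressures here are far from the
        # limits, so the +/-0.002 band cannot flip anything)
        model = fit_transition_model([[26.0, 26.0]], bandwidth_rule=0.001)
        vent = run_vent((26.0, 7.2, 3.0), 52.0, audit=False)
        siv = run_sivent((26.0, 7.2, 3.0), model, 52.0, audit=False)
        assert siv.stage_counts == vent.stage_counts
        assert survivor_settings(siv) == survivor_settings(vent)

    def test_sivent_survivors_subset_of_vent(self):
        rng = np.random.default_rng(8)
        y = rng.uniform(20.0, 40.0, 300)
        x = y * np.exp(rng.normal(0.0, 0.05, 300))
        model = fit_transition_model(np.column_stack([y, x]))
        E = 30.0
        lo, hi = forecast_percentiles(model, E, levels=(5, 95)).values
        assert lo <= E <= hi  # forecast band brackets the current value
        vent = run_vent((E, 15.0, 8.0), 65.0, audit=False)
        siv = run_sivent((E, 15.0, 8.0), model, 65.0, audit=False)
        assert siv.stage_counts["N"] <= vent.stage_counts["N"]
        assert survivor_settings(siv) <= survivor_settings(vent)

    def test_high_forecast_elastance_empties_the_set(self):
        # if even the minimum tidal volume forecasts P_PLAT >= 30 at the 95th
        # percentile, nothing survives: E95 > (30 - PEEP)/(0.004*weight)
        model = fit_transition_model([[72.8, 85.0]], bandwidth_rule=0.5)
        weight, peep = 70.2, 7.0
        e95 = forecast_percentiles(model, 72.8, levels=(95.0,)).values[0]
        assert e95 > (30.0 - peep) / (0.004 * weight)
        siv = run_sivent((72.8, 2.2, peep), model, weight, audit=False)
        assert siv.stage_counts["N"] == 0
        assert siv.survivors.empty

    def test_boundary_audit_reports_flip_count(self):
        r = run_vent((43.5, 26.2, 13.0), 65.0, audit=True)
        assert isinstance(r.boundary_flips, int) and r.boundary_flips >= 0
        # timing-only regime: elastance perturbation cannot flip anything
        r1 = run_vent((26.0, 7.2, 3.0), 52.0, audit=True)
        assert r1.boundary_flips == 0

    def test_survivor_table_has_recommendation_columns(self):
        r = run_vent((43.5, 26.2, 13.0), 65.0, audit=False)
        expected = {"RR", "waveform", "VT_mL_per_kg", "peak_flow_Lpm", "T_plat_s",
                    "Pmax_lo", "Pmax_hi", "Pplat_lo", "Pplat_hi", "dP_lo", "dP_hi", "IE"}
        assert expected <= set(r.survivors.columns)
        assert len(r.survivors) == r.stage_counts["N"]
        assert (r.survivors["Pmax_lo"] == r.survivors["Pmax_hi"]).all()


class TestEvaluation:
    def test_three_hour_patient_yields_eighteen_rows(self):
        model = fit_transition_model([[33.8, 33.8]], bandwidth_rule=1.0)
        summaries = [(33.8, 9.8, 10.0)] * 18
        table, agg = evaluate_performance(summaries, model, 65.0)
        assert len(table) == 18
        assert table["vent_count"].nunique() == 1  # constant inputs, constant counts
        assert table["sivent_count"].nunique() == 1
        assert (table["sivent_count"] <= table["vent_count"]).all()

    def test_aggregates_match_quantile_oracle(self):
        model = fit_transition_model([[30.0, 30.0]], bandwidth_rule=1.0)
        summaries = [(e, 10.0, 8.0) for e in (25.0, 30.0, 35.0, 40.0)]
        table, agg = evaluate_performance(summaries, model, 65.0)
        for col in ("vent_count", "sivent_count"):
            assert agg[col]["median"] == np.median(table[col])
            assert agg[col]["iqr"] == tuple(np.percentile(table[col], [25, 75]))

    def test_no_intervals_raises(self):
        model = fit_transition_model([[30.0, 30.0]], bandwidth_rule=1.0)
        with pytest.raises(ValueError):
            evaluate_performance([], model, 65.0)
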