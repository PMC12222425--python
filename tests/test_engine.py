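"""Trajectory-engine tests: schedules, closed-form limits, invariants."""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pytest

from rptparpi.engine import (
    build_phase_schedule,
    ensemble_simulate,
    phase_death_rates,
    simulate_trajectory,
)
from rptparpi.params import CellCycleConfig, PARPiModel, Protocol, SolverOptions


class TestPhaseSchedule:
    CC = CellCycleConfig()  # 24-h cycle

    def test_start_zero_begins_in_g1_with_proportional_durations(self):
        segs = build_phase_schedule(self.CC, 0, 48.0)
        assert segs[0].phase == "G1"
        durations = {}
        for s in segs:
            if s.completed:
                durations.setdefault(s.phase, s.t_end - s.t_start)
        assert durations["G1"] == pytest.approx(11.0)
        assert durations["S"] == pytest.approx(8.0)
        assert durations["G2"] == pytest.approx(4.0)
        assert durations["M"] == pytest.approx(1.0)

    def test_start_offsets_evenly_spaced(self):
        for k in (1, 7, 23):
            segs = build_phase_schedule(self.CC, k, 24.0)
            # remaining time in the current cycle equals cycle - offset
            offset = k / 24 * self.CC.cycle_length
            boundary = next(s.t_end for s in segs if s.phase == "M")
            assert boundary == pytest.approx(self.CC.cycle_length - offset)

    def test_mid_s_start_records_entry_progression(self):
        # offset 14 h = 3 h into S (G1 is 11 h)
        segs = build_phase_schedule(self.CC, 14, 24.0)
        assert segs[0].phase == "S"
        assert segs[0].s_entry == pytest.approx(3.0 / 8.0)
        assert not segs[0].completed

    def test_one_genome_predominance_fraction(self):
        assert self.CC.one_genome_fraction == pytest.approx(0.625)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_phase_schedule(self.CC, 24, 24.0)
        with pytest.raises(ValueError):
            build_phase_schedule(self.CC, 0, -1.0)


STRICT = SolverOptions(rtol=1e-10, atol=1e-12, grid_points=49)


class TestClosedFormLimits:
    def test_untreated_growth_is_malthusian(self, base_params):
        proto = Protocol(a0_bq=0.0, delivery="none")
        tr = simulate_trajectory(0, proto, base_params, STRICT)
        cc = base_params.cellcycle
        n0 = proto.n_seeded * math.exp(cc.mu_gr * proto.seeding_offset_h)
        expected = n0 * np.exp(cc.mu_gr * tr.t)
        np.testing.assert_allclose(tr.columns["n_alive"], expected, rtol=1e-6)
        np.testing.assert_allclose(tr.columns["survival"], 1.0, rtol=1e-9)

    def test_constant_parpi_monotherapy_exponent(self, base_params):
        """PARPi alone: N(t) = N(0) exp((mu_gr + mu_parpi - 1) t)."""
        mu_parpi = 0.9
        params = base_params.with_(parpi=PARPiModel(mode="constant_only",
                                                    mu_parpi=mu_parpi))
        proto = Protocol(a0_bq=0.0, delivery="none")
        tr = simulate_trajectory(5, proto, params, STRICT)
        cc = base_params.cellcycle
        n0 = proto.n_seeded * math.exp(cc.mu_gr * proto.seeding_offset_h)
        rate = cc.mu_gr + mu_parpi - 1.0
        np.testing.assert_allclose(tr.columns["n_alive"],
                                   n0 * np.exp(rate * tr.t), rtol=1e-6)
        np.testing.assert_allclose(tr.columns["survival"],
                                   np.exp(-(1.0 - mu_parpi) * tr.t), rtol=1e-6)


class TestTrajectoryInvariants:
    def test_dose_monotone_and_decay_consistent(self, base_params, fast_opts,
                                                protocol_100kbq):
        tr = simulate_trajectory(3, protocol_100kbq, base_params, fast_opts)
        d = tr.columns["d_gy"]
        assert np.all(np.diff(d) >= -1e-9)
        pre = tr.t < protocol_100kbq.rpt_exposure_h
        a0 = protocol_100kbq.a0_bq
        mu = base_params.kinetics.mu_dec
        np.testing.assert_allclose(tr.columns["a_bq"][pre],
                                   a0 * np.exp(-mu * tr.t[pre]), rtol=1e-12)

    def test_occupancy_bound_holds_along_trajectory(self, base_params, fast_opts,
                                                    protocol_100kbq):
        tr = simulate_trajectory(0, protocol_100kbq, base_params, fast_opts)
        r_alive = base_params.receptors.r_cell * tr.columns["n_alive"]
        assert np.all(tr.columns["c_acs"] <= r_alive * (1.0 + 1e-6) + 1e-9)

    def test_dose_stops_after_washout_without_cell_binding(self, base_params,
                                                           fast_opts):
        """With no binding, washout removes all activity and D freezes."""
        kin = replace(base_params.kinetics, k_on=0.0)
        params = base_params.with_(kinetics=kin)
        tr = simulate_trajectory(0, Protocol(a0_bq=1e5), params, fast_opts)
        after = tr.t > 24.0 + 1e-9
        assert np.all(tr.columns["a_bq"][after] == 0.0)
        d = tr.columns["d_gy"]
        assert d[after].max() == pytest.approx(d[after].min(), rel=1e-12)

    def test_population_bookkeeping(self, base_params, fast_opts, protocol_100kbq):
        """Between events, total cells grow only by division of living cells."""
        tr = simulate_trajectory(2, protocol_100kbq, base_params, fast_opts)
        total = tr.columns["n_alive"] + tr.columns["n_dead"]
        pre = tr.t < 24.0 - 1e-9  # washout resets the dead pool at 24 h
        assert np.all(np.diff(total[pre]) >= -1e-6 * total[0])

    def test_ebrt_impulse_induces_damage_at_start(self, base_params, fast_opts):
        proto = Protocol(a0_bq=0.0, delivery="none", ebrt_dose_gy=5.0)
        tr = simulate_trajectory(0, proto, base_params, fast_opts)
        assert tr.columns["d_gy"][0] == pytest.approx(5.0)
        # start 0 is G1: one genome, p_m = 0
        rp = base_params.repair
        assert tr.columns["n_dsb"][0] == pytest.approx(rp.k_dsb * 5.0)
        assert tr.endpoint_survival < 1.0

    def test_tolerance_refinement_stability(self, base_params, protocol_100kbq):
        """Halving solver tolerances barely moves the endpoint survival."""
        s = []
        for rtol, atol in ((1e-8, 1e-10), (5e-9, 5e-11)):
            opts = SolverOptions(rtol=rtol, atol=atol, grid_points=25)
            s.append(simulate_trajectory(4, protocol_100kbq, base_params,
                                         opts).endpoint_survival)
        assert abs(s[1] - s[0]) / s[0] < 1e-3


class TestEnsemble:
    def test_single_start_matches_trajectory(self, base_params, fast_opts,
                                             protocol_100kbq):
        res = ensemble_simulate(protocol_100kbq, base_params, fast_opts, n_starts=1)
        tr = simulate_trajectory(0, protocol_100kbq,
                                 base_params.with_(cellcycle=replace(
                                     base_params.cellcycle, n_starts=1)),
                                 fast_opts)
        np.testing.assert_allclose(
            res.columns["survival"],
            np.interp(res.t, tr.t, tr.columns["survival"]), rtol=1e-12)

    def test_untreated_self_normalizes(self, base_params, fast_opts):
        res = ensemble_simulate(Protocol(a0_bq=0.0, delivery="none"),
                                base_params, fast_opts, n_starts=4)
        np.testing.assert_allclose(res.relative_n_alive, 1.0)

    def test_start_point_convergence(self, base_params, fast_opts):
        """Doubling the number of start points changes the endpoint < 1%."""
        proto = Protocol(a0_bq=3e4)
        s24 = ensemble_simulate(proto, base_params, fast_opts,
                                n_starts=24).endpoint_relative_survival
        s48 = ensemble_simulate(proto, base_params, fast_opts,
                                n_starts=48).endpoint_relative_survival
        assert abs(s48 - s24) / s24 < 0.01


class TestPhaseDeathRates:
    def test_zero_dose_all_reductions_zero(self, base_params, fast_opts):
        res = ensemble_simulate(Protocol(a0_bq=0.0, delivery="none"),
                                base_params, fast_opts, n_starts=4)
        df = phase_death_rates(res)
        assert np.allclose(df["reduction"], 0.0, atol=1e-10)

    def test_reductions_reassemble_log_survival(self, base_params, fast_opts,
                                                protocol_100kbq):
        res = ensemble_simulate(protocol_100kbq, base_params, fast_opts,
                                n_starts=4, include_control=False)
        df = phase_death_rates(res)
        for tr in res.trajectories:
            total = df[df["start_index"] == tr.start_index]["reduction"].sum()
            assert total == pytest.approx(-math.log(tr.endpoint_survival),
                                          rel=1e-9)

    def test_g2m_deadlier_than_g1_under_rpt(self, base_params, fast_opts,
                                            protocol_100kbq):
        """Radiosensitivity peaks in G2/M (mitotic catastrophe checkpoint)."""
        res = ensemble_simulate(protocol_100kbq, base_params, fast_opts,
                                n_starts=6, include_control=False)
        df = phase_death_rates(res, completed_only=True)
        rate = {}
        for ph in ("G1", "G2", "M"):
            sub = df[df["phase"] == ph]
            rate[ph] = (sub["reduction"] / (sub["t_end"] - sub["t_start"])).mean()
        assert rate["G2"] > rate["G1"]
        assert rate["M"] > rate["G1"]
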