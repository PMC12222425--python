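"""DNA damage-repair and survival-rate unit tests.

The S-phase replication bookkeeping is checked against a discrete
per-lesion brute-force simulator that draws an explicit replication
position for every lesion.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from rptparpi.damage import (
    DamageState,
    PhaseContext,
    effective_ssb_repair,
    genomic_loss_factor,
    interphase_damage_rates,
    repair_probabilities,
    s_phase_damage_rates,
    survival_rate,
)
from rptparpi.params import PARPiModel, RepairParams, SurvivalParams

G1 = PhaseContext("G1")
G2 = PhaseContext("G2")
S_CTX = PhaseContext("S", mu_inter=0.125)


def _repair(**kw) -> RepairParams:
    base = dict(k_ssb=700.0, lambda_ssb=2.0, k_dsb=35.0, lambda_f=2.77,
                lambda_s=0.26, lambda_m=0.02, p_c=0.3, p_hr=1.0)
    base.update(kw)
    return RepairParams(**base)


class TestRepairProbabilities:
    @pytest.mark.parametrize("ctx", [G1, G2, S_CTX])
    def test_full_hr_identity(self, ctx):
        assert repair_probabilities(0.3, 1.0, ctx) == (0.7, 0.3, 0.0)

    def test_complete_hrd_in_g2(self):
        assert repair_probabilities(0.3, 0.0, G2) == (0.7, 0.0, 0.3)

    def test_partial_hrd_substitution(self):
        p_f, p_s, p_m = repair_probabilities(0.4, 0.5, G2)
        assert (p_f, p_s, p_m) == (0.6, pytest.approx(0.2), pytest.approx(0.2))
        assert p_f + p_s + p_m == pytest.approx(1.0)

    def test_g1_ignores_hrd(self):
        assert repair_probabilities(0.4, 0.2, G1) == (0.6, 0.4, 0.0)

    @given(p_c=st.floats(0, 1), p_hr=st.floats(0, 1),
           phase=st.sampled_from(["G1", "S", "G2", "M"]))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_probability_closure(self, p_c, p_hr, phase):
        ctx = PhaseContext(phase, mu_inter=0.125)
        p_f, p_s, p_m = repair_probabilities(p_c, p_hr, ctx)
        assert p_f + p_s + p_m == pytest.approx(1.0, abs=1e-12)
        assert min(p_f, p_s, p_m) >= 0.0


class TestEffectiveSsbRepair:
    def test_passthrough_modes(self):
        assert effective_ssb_repair(1.2, PARPiModel(mode="none"), 50.0) == 1.2
        assert effective_ssb_repair(1.2, PARPiModel(mode="constant_only", mu_parpi=0.9), 50.0) == 1.2

    def test_override_mode(self):
        p = PARPiModel(mode="reduced_ssb_repair", mu_parpi=0.9, lambda_ssb_override=0.3)
        assert effective_ssb_repair(1.2, p, 1e4) == 0.3

    def test_decaying_mode_closed_form(self):
        p = PARPiModel(mode="decaying_ssb_repair", mu_parpi=0.9, lambda_red=0.01)
        assert effective_ssb_repair(1.0, p, 0.0) == 1.0
        assert effective_ssb_repair(1.0, p, 100.0) == pytest.approx(math.exp(-1.0))

    def test_rational_form(self):
        p = PARPiModel(mode="decaying_ssb_repair", mu_parpi=0.9, lambda_red=0.01,
                       decay_form="rational")
        assert effective_ssb_repair(1.0, p, 100.0) == pytest.approx(0.5)

    def test_missing_mode_field_rejected(self):
        with pytest.raises(ValueError):
            PARPiModel(mode="decaying_ssb_repair", mu_parpi=0.9)


class TestInterphaseRates:
    def test_quiescent_fixed_point(self):
        d = interphase_damage_rates(DamageState(), 0.0, _repair(), G1)
        assert np.all(d == 0.0)

    def test_pure_exponential_repair(self):
        d = interphase_damage_rates(DamageState(n_dsb_f=10.0), 0.0,
                                    _repair(lambda_f=2.0), G1)
        np.testing.assert_allclose(d, [0.0, -20.0, 0.0, 0.0])

    def test_s_phase_context_rejected(self):
        with pytest.raises(ValueError):
            interphase_damage_rates(DamageState(), 0.0, _repair(), S_CTX)

    @pytest.mark.parametrize("ctx,doserate", [(G1, 0.2), (G2, 0.35)])
    def test_fast_dsb_steady_state(self, ctx, doserate):
        """Constant dose rate drives N_f to p_f * N_gen * k_dsb * rate / lambda_f."""
        rp = _repair()

        def rhs(t, y):
            dmg = DamageState(n_ssb=y[0], n_dsb_f=y[1], n_dsb_s=y[2], n_dsb_m=y[3])
            return interphase_damage_rates(dmg, doserate, rp, ctx)

        sol = solve_ivp(rhs, (0.0, 80.0), [0.0] * 4, rtol=1e-10, atol=1e-12)
        expected = (1.0 - rp.p_c) * ctx.n_gen * rp.k_dsb * doserate / rp.lambda_f
        assert sol.y[1, -1] == pytest.approx(expected, rel=1e-3)


def _discrete_replication_oracle(rng, n_ssb, n_fast, n_slow, s0, w_s):
    """Per-lesion brute-force replication with explicit fork positions.

    Every unreplicated lesion replicates at a position uniform in
    (s0, 1).  Fast DSBs duplicate onto the replicated copy; slow DSBs
    duplicate and are routed (both copies) to the replicated-slow pool
    with probability w_s, otherwise to the MMEJ pool; SSBs convert into
    a single DSB routed the same way.  With zero repair and dose the
    endpoint totals are exact counts.
    """
    f_rl = 2 * n_fast
    to_slow_dsb = rng.random(n_slow) < w_s
    s_rl = 2 * int(np.sum(to_slow_dsb))
    m = 2 * (n_slow - int(np.sum(to_slow_dsb)))
    to_slow_ssb = rng.random(n_ssb) < w_s
    s_rl += int(np.sum(to_slow_ssb))
    m += n_ssb - int(np.sum(to_slow_ssb))
    return f_rl, s_rl, m


class TestSPhaseRates:
    def test_quiescent_progression_only(self):
        d = s_phase_damage_rates(DamageState(s_prog=0.3), 0.0, _repair(), S_CTX)
        np.testing.assert_allclose(d, [0, 0, 0, 0, 0, 0, 0, S_CTX.mu_inter])

    def test_full_hr_routes_everything_to_slow(self):
        dmg = DamageState(n_ssb_url=10.0, n_dsb_s_url=5.0, s_prog=0.5)
        rp = _repair(lambda_ssb=0, lambda_s=0, lambda_m=0)
        d = s_phase_damage_rates(dmg, 0.0, rp, S_CTX)
        assert d[6] == 0.0  # MMEJ pool untouched
        transfer = S_CTX.mu_inter / 0.5
        assert d[5] == pytest.approx(transfer * (2 * 5.0 + 10.0))

    def test_invalid_s_prog_rejected(self):
        with pytest.raises(ValueError):
            s_phase_damage_rates(DamageState(s_prog=1.5), 0.0, _repair(), S_CTX)

    def test_replication_bookkeeping_matches_discrete_oracle(self):
        """Endpoint replicated totals agree with the per-lesion simulator."""
        rng = np.random.default_rng(11)
        rp_zero = dict(lambda_ssb=0.0, lambda_f=0.0, lambda_s=0.0, lambda_m=0.0)
        eps = 1e-6
        for trial in range(10):
            # >= 1e5 lesions per pool and routing weights away from the
            # extremes keep the oracle's binomial noise well below the
            # 1% comparison tolerance
            n_ssb = int(rng.integers(1e5, 3e5))
            n_fast = int(rng.integers(1e5, 3e5))
            n_slow = int(rng.integers(1e5, 3e5))
            s0 = float(rng.uniform(0.0, 0.8))
            p_hr = float(rng.uniform(0.2, 0.85))
            rp = _repair(p_hr=p_hr, **rp_zero)
            # continuous model
            y0 = [n_ssb, 0.0, n_fast, 0.0, n_slow, 0.0, 0.0, s0]

            def rhs(t, y):
                dmg = DamageState(n_ssb_url=y[0], n_ssb_rl=y[1], n_dsb_f_url=y[2],
                                  n_dsb_f_rl=y[3], n_dsb_s_url=y[4], n_dsb_s_rl=y[5],
                                  n_dsb_m=y[6], s_prog=min(y[7], 1.0))
                return s_phase_damage_rates(dmg, 0.0, rp, S_CTX, s_prog_eps=eps)

            t_end = (1.0 - eps - s0) / S_CTX.mu_inter
            sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA",
                            rtol=1e-10, atol=1e-8)
            f_rl, s_rl, m = sol.y[2, -1] + sol.y[3, -1], sol.y[4, -1] + sol.y[5, -1], sol.y[6, -1]
            of, os_, om = _discrete_replication_oracle(
                rng, n_ssb, n_fast, n_slow, s0, w_s=p_hr)
            assert f_rl == pytest.approx(of, rel=0.01)
            assert s_rl == pytest.approx(os_, rel=0.01)
            assert m == pytest.approx(om, rel=0.01)

    def test_completing_s_doubles_dsb_content(self):
        """With zero repair and dose, replication doubles total DSB mass."""
        rp = _repair(lambda_ssb=0.0, lambda_f=0.0, lambda_s=0.0, lambda_m=0.0,
                     p_hr=0.4)
        y0 = [0.0, 0.0, 50.0, 0.0, 30.0, 0.0, 0.0, 0.0]

        def rhs(t, y):
            dmg = DamageState(n_ssb_url=y[0], n_ssb_rl=y[1], n_dsb_f_url=y[2],
                              n_dsb_f_rl=y[3], n_dsb_s_url=y[4], n_dsb_s_rl=y[5],
                              n_dsb_m=y[6], s_prog=min(y[7], 1.0))
            return s_phase_damage_rates(dmg, 0.0, rp, S_CTX)

        t_end = (1.0 - 1e-6) / S_CTX.mu_inter
        sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA", rtol=1e-10, atol=1e-10)
        total = sol.y[2:7, -1].sum()
        assert total == pytest.approx(2 * (50.0 + 30.0), rel=1e-4)


class TestSurvival:
    SP = SurvivalParams()

    def test_intercepts(self):
        assert genomic_loss_factor(DamageState(), self.SP, G1) == 1.0
        assert genomic_loss_factor(DamageState(s_prog=0.2), self.SP, S_CTX) == 1.0

    def test_quadratic_substitution(self):
        sp = SurvivalParams(ab_by_phase={"G1": (-0.001, -0.01), "G2": (-0.001, -0.01),
                                         "M": (-0.001, -0.01)})
        got = genomic_loss_factor(DamageState(n_dsb_f=10.0), sp, G1)
        assert got == pytest.approx((-0.001 * 10 - 0.01) * 10 + 1)  # 0.8

    def test_loss_clamped_to_unit_interval(self):
        sp = SurvivalParams(ab_by_phase={"G1": (-0.01, -0.1), "G2": (-0.01, -0.1),
                                         "M": (-0.01, -0.1)})
        assert genomic_loss_factor(DamageState(n_dsb_f=1000.0), sp, G1) == 0.0

    def test_quiescent_rate_is_zero(self):
        mu = survival_rate(DamageState(), 0.0, _repair(), self.SP,
                           PARPiModel(mode="none"), G1)
        assert mu == 0.0

    def test_parpi_monotherapy_rate(self):
        mu = survival_rate(DamageState(), 0.0, _repair(), self.SP,
                           PARPiModel(mode="constant_only", mu_parpi=0.9), G1)
        assert mu == pytest.approx(0.1)

    def test_checkpoint_clamp(self):
        """The mitotic term caps the DSB count at the G2/M checkpoint (20)."""
        sp = SurvivalParams(phi=0.05)
        dmg = DamageState(n_dsb_f=100.0)
        mu = survival_rate(dmg, 0.0, _repair(), sp, PARPiModel(mode="none"), G2)
        a, b = sp.ab("G2")
        mu_loss = max((a * 100.0 + b) * 100.0 + 1.0, 0.0)
        want = 1.0 - mu_loss * math.exp(-0.05 * 20.0)
        assert mu == pytest.approx(want, rel=1e-12)

    def test_apoptosis_acts_in_interphase_only(self):
        rp = _repair()
        mu_g1 = survival_rate(DamageState(), 1.0, rp, self.SP, PARPiModel(), G1)
        mu_g2 = survival_rate(DamageState(), 1.0, rp, self.SP, PARPiModel(), G2)
        assert mu_g1 == pytest.approx(1.0 - math.exp(-self.SP.psi * rp.k_dsb * 1.0))
        assert mu_g2 == 0.0
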