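"""Shared brute-force oracles used by unit and acceptance tests."""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from rptparpi.damage import DamageState, PhaseContext, s_phase_damage_rates
from rptparpi.params import RepairParams

S_CTX = PhaseContext("S", mu_inter=0.125)


def discrete_replication_oracle(rng, n_ssb, n_fast, n_slow, w_s):
    """Per-lesion brute-force replication with explicit routing draws.

    Every unreplicated lesion replicates once.  Fast DSBs duplicate onto
    the replicated copy; slow DSBs duplicate and are routed (both
    copies) to the replicated-slow pool with probability w_s, otherwise
    to the MMEJ pool; SSBs convert into a single DSB routed the same
    way.  With zero repair and dose the endpoint totals are exact counts.
    Returns (fast_rl, slow_rl, mmej).
    """
    f_rl = 2 * n_fast
    to_slow_dsb = int(np.sum(rng.random(n_slow) < w_s))
    s_rl = 2 * to_slow_dsb
    m = 2 * (n_slow - to_slow_dsb)
    to_slow_ssb = int(np.sum(rng.random(n_ssb) < w_s))
    s_rl += to_slow_ssb
    m += n_ssb - to_slow_ssb
    return f_rl, s_rl, m


def integrate_s_phase_replication(n_ssb, n_fast, n_slow, s0, p_hr, eps=1e-6):
    """Continuous-model endpoint pools with zero repair and dose.

    Returns (fast_total, slow_total, mmej) after completing S phase.
    """
    rp = RepairParams(k_ssb=700.0, lambda_ssb=0.0, k_dsb=35.0, lambda_f=0.0,
                      lambda_s=0.0, lambda_m=0.0, p_c=0.3, p_hr=p_hr)
    y0 = [n_ssb, 0.0, n_fast, 0.0, n_slow, 0.0, 0.0, s0]

    def rhs(t, y):
        dmg = DamageState(n_ssb_url=y[0], n_ssb_rl=y[1], n_dsb_f_url=y[2],
                          n_dsb_f_rl=y[3], n_dsb_s_url=y[4], n_dsb_s_rl=y[5],
                          n_dsb_m=y[6], s_prog=min(y[7], 1.0))
        return s_phase_damage_rates(dmg, 0.0, rp, S_CTX, s_prog_eps=eps)

    t_end = (1.0 - eps - s0) / S_CTX.mu_inter
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA", rtol=1e-10, atol=1e-8)
    return (sol.y[2, -1] + sol.y[3, -1],
            sol.y[4, -1] + sol.y[5, -1],
            sol.y[6, -1])


def replication_bookkeeping_max_deviation(seed=11, n_trials=10):
    """Worst relative deviation (fraction) between the continuous model
    and the discrete per-lesion oracle over random lesion configurations."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_trials):
        n_ssb = int(rng.integers(1e5, 3e5))
        n_fast = int(rng.integers(1e5, 3e5))
        n_slow = int(rng.integers(1e5, 3e5))
        s0 = float(rng.uniform(0.0, 0.8))
        p_hr = float(rng.uniform(0.2, 0.85))
        f, s, m = integrate_s_phase_replication(n_ssb, n_fast, n_slow, s0, p_hr)
        of, os_, om = discrete_replication_oracle(rng, n_ssb, n_fast, n_slow, p_hr)
        worst = max(worst, abs(f - of) / of, abs(s - os_) / os_, abs(m - om) / om)
    return worst
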