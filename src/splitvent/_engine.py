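"""Fixed-step integrator for the two-patient shared-ventilator lumped circuit.

State vector: (v1, v2, pn)
    v1, v2 : branch volumes above the PEEP-equilibrated baseline [L]
    pn     : pressure at the common (wye) node [cmH2O]

The system is piecewise smooth: the ventilator phase (inspiration /
expiration), the one-way valves of circuit-2 and the inspiratory pressure
cap all switch the right-hand side.  Integration is classical RK4 on a
fixed grid with exact sub-stepping at phase-switch times, so no step ever
straddles a discontinuity of the drive.  Cumulative volumes are
accumulated trapezoidally at the internal step and decimated together
with the other channels.

All pressures cmH2O, flows L/s, volumes L, times s.
"""

from __future__ import annotations

import numpy as np

MODE_PCV = 0
MODE_VCV = 1
TOPO_C1 = 0
TOPO_C2 = 1


def _rhs(y, tc, insp, mode, t_insp, peep, dp_insp, rise, rel, pn_rel,
         q_set, p_max, c1, c2, r1, r2, k2, r_exp1, r_exp2, c_ckt, r_vent,
         topo):
    """Instantaneous flows and node-pressure derivative.

    ``tc`` is the time since the start of the current cycle (used for the
    PCV pressurisation ramp and the expiratory release ramp); ``pn_rel``
    is the node pressure captured at the last insp->exp switch, from which
    the machine releases to PEEP over ``rel`` seconds.  Returns
    (q1, q2, dpn, qv) where q1/q2 are the branch (lung-port) flows,
    inspiratory positive, and qv is the machine-side flow into the node.
    """
    v1, v2, pn = y[0], y[1], y[2]
    palv1 = peep + v1 / c1
    palv2 = peep + v2 / c2

    if insp:
        if mode == MODE_PCV:
            frac = tc / rise if rise > 0.0 else 1.0
            if frac > 1.0:
                frac = 1.0
            ps = peep + dp_insp * frac
            if ps > p_max:
                ps = p_max
            qv = (ps - pn) / r_vent
        else:
            # VCV: constant flow with a linear rise ramp; the pressure cap
            # acts as a continuous relief (flow tapers to zero as the node
            # approaches p_max through the source impedance)
            q_nom = q_set
            if rise > 0.0 and tc < rise:
                q_nom = q_set * tc / rise
            q_lim = (p_max - pn) / r_vent
            if q_lim < 0.0:
                q_lim = 0.0
            qv = q_nom if q_nom < q_lim else q_lim
        if topo == TOPO_C1:
            q1 = (pn - palv1) / r1
            q2 = (pn - palv2) / r2
        else:
            # one-way valves block reverse flow through the inspiratory limb
            dp1 = pn - palv1
            q1 = dp1 / r1 if dp1 > 0.0 else 0.0
            dp2 = pn - palv2
            if dp2 > 0.0:
                if k2 > 0.0:
                    q2 = (-r2 + np.sqrt(r2 * r2 + 4.0 * k2 * dp2)) / (2.0 * k2)
                else:
                    q2 = dp2 / r2
            else:
                q2 = 0.0
        dpn = (qv - q1 - q2) / c_ckt
    else:
        # exhalation-valve release: machine pressure ramps from the
        # end-inspiratory node pressure down to PEEP over ``rel`` seconds
        tc_exp = tc - t_insp
        ps = peep
        if rel > 0.0 and tc_exp < rel and pn_rel > peep:
            ps = peep + (pn_rel - peep) * (1.0 - tc_exp / rel)
        qv = (ps - pn) / r_vent
        if topo == TOPO_C1:
            q1 = (pn - palv1) / r1
            q2 = (pn - palv2) / r2
            dpn = (qv - q1 - q2) / c_ckt
        else:
            # lungs empty through their dedicated expiratory limbs toward
            # the machine pressure; the node drains through the machine
            q1 = -(palv1 - ps) / r_exp1
            if q1 > 0.0:
                q1 = 0.0
            q2 = -(palv2 - ps) / r_exp2
            if q2 > 0.0:
                q2 = 0.0
            dpn = qv / c_ckt
    return q1, q2, dpn, qv


def _rk4_span(y, t0, t1, tcyc_start, insp, mode, t_insp, peep, dp_insp,
              rise, rel, pn_rel, q_set, p_max, c1, c2, r1, r2, k2, r_exp1,
              r_exp2, c_ckt, r_vent, topo):
    """One RK4 step over [t0, t1] with a fixed phase.

    ``tcyc_start`` is the cycle-relative time at t0 (continuous within the
    span since no switch occurs inside it)."""
    h = t1 - t0
    a1, a2, a3, _ = _rhs(y, tcyc_start, insp, mode, t_insp, peep, dp_insp,
                         rise, rel, pn_rel, q_set, p_max, c1, c2, r1, r2,
                         k2, r_exp1, r_exp2, c_ckt, r_vent, topo)
    ym = np.empty(3)
    ym[0] = y[0] + 0.5 * h * a1
    ym[1] = y[1] + 0.5 * h * a2
    ym[2] = y[2] + 0.5 * h * a3
    tcm = tcyc_start + 0.5 * h
    b1, b2, b3, _ = _rhs(ym, tcm, insp, mode, t_insp, peep, dp_insp, rise,
                         rel, pn_rel, q_set, p_max, c1, c2, r1, r2, k2,
                         r_exp1, r_exp2, c_ckt, r_vent, topo)
    ym[0] = y[0] + 0.5 * h * b1
    ym[1] = y[1] + 0.5 * h * b2
    ym[2] = y[2] + 0.5 * h * b3
    c1_, c2_, c3_, _ = _rhs(ym, tcm, insp, mode, t_insp, peep, dp_insp,
                            rise, rel, pn_rel, q_set, p_max, c1, c2, r1,
                            r2, k2, r_exp1, r_exp2, c_ckt, r_vent, topo)
    ym[0] = y[0] + h * c1_
    ym[1] = y[1] + h * c2_
    ym[2] = y[2] + h * c3_
    tce = tcyc_start + h
    d1, d2, d3, _ = _rhs(ym, tce, insp, mode, t_insp, peep, dp_insp, rise,
                         rel, pn_rel, q_set, p_max, c1, c2, r1, r2, k2,
                         r_exp1, r_exp2, c_ckt, r_vent, topo)
    out = np.empty(3)
    out[0] = y[0] + h / 6.0 * (a1 + 2.0 * b1 + 2.0 * c1_ + d1)
    out[1] = y[1] + h / 6.0 * (a2 + 2.0 * b2 + 2.0 * c2_ + d2)
    out[2] = y[2] + h / 6.0 * (a3 + 2.0 * b3 + 2.0 * c3_ + d3)
    return out


def _integrate(n_samples, dt_out, n_sub, mode, rr, insp_frac, peep, dp_insp,
               rise, rel, q_set, p_max, c1, c2, raw1, raw2, r1, r2, k2,
               r_exp1, r_exp2, c_ckt, r_vent, topo):
    """Run the simulation and return decimated channels.

    ``r1``/``r2`` are total inspiratory branch resistances (tube + one-way
    valve + lung airway), ``raw1``/``raw2`` the lung airway shares used to
    reconstruct the port pressures, ``r_exp*`` the expiratory limb totals
    (circuit-2 only).  Returns (p_vent, q_vent, p_sim1, q_sim1, p_sim2,
    q_sim2, v_vent, v_sim1, v_sim2, capped).
    """
    t_cyc = 60.0 / rr
    t_insp = t_cyc * insp_frac
    h = dt_out / n_sub

    p_vent = np.empty(n_samples)
    q_vent = np.empty(n_samples)
    p_sim1 = np.empty(n_samples)
    q_sim1 = np.empty(n_samples)
    p_sim2 = np.empty(n_samples)
    q_sim2 = np.empty(n_samples)
    v_vent = np.empty(n_samples)
    v_sim1 = np.empty(n_samples)
    v_sim2 = np.empty(n_samples)

    y = np.zeros(3)
    y[2] = peep
    vv = 0.0
    vl1 = 0.0
    vl2 = 0.0
    pn_rel = peep
    capped = False

    for i in range(n_samples):
        t = i * dt_out
        n_cyc = int(t / t_cyc + 1e-9)
        tc = t - n_cyc * t_cyc
        if tc >= t_cyc - 1e-9:
            tc = 0.0
        insp = tc < t_insp - 1e-9
        q1, q2, _dpn, qv = _rhs(y, tc, insp, mode, t_insp, peep, dp_insp,
                                rise, rel, pn_rel, q_set, p_max, c1, c2,
                                r1, r2, k2, r_exp1, r_exp2, c_ckt, r_vent,
                                topo)
        p_vent[i] = y[2]
        q_vent[i] = qv
        q_sim1[i] = q1
        q_sim2[i] = q2
        # port (pneumotachograph) pressure sits between tube and simulator
        p_sim1[i] = peep + y[0] / c1 + q1 * raw1
        p_sim2[i] = peep + y[1] / c2 + q2 * raw2
        v_vent[i] = vv
        v_sim1[i] = vl1
        v_sim2[i] = vl2
        if i == n_samples - 1:
            break

        # advance one output interval with sub-steps split at phase switches
        for k in range(n_sub):
            t0 = t + k * h
            t1 = t0 + h
            while t0 < t1 - 1e-12:
                n_cyc = int(t0 / t_cyc + 1e-9)
                tc0 = t0 - n_cyc * t_cyc
                if tc0 >= t_cyc - 1e-9:
                    tc0 = 0.0
                    n_cyc += 1
                if tc0 < t_insp - 1e-9:
                    insp0 = True
                    t_sw = n_cyc * t_cyc + t_insp
                else:
                    insp0 = False
                    t_sw = (n_cyc + 1) * t_cyc
                t_end = t1 if t1 < t_sw else t_sw
                qa1, qa2, _d, qav = _rhs(y, tc0, insp0, mode, t_insp, peep,
                                         dp_insp, rise, rel, pn_rel, q_set,
                                         p_max, c1, c2, r1, r2, k2, r_exp1,
                                         r_exp2, c_ckt, r_vent, topo)
                if insp0 and mode == MODE_VCV:
                    q_nom = q_set
                    if rise > 0.0 and tc0 < rise:
                        q_nom = q_set * tc0 / rise
                    if (p_max - y[2]) / r_vent < q_nom - 1e-9:
                        capped = True
                y = _rk4_span(y, t0, t_end, tc0, insp0, mode, t_insp, peep,
                              dp_insp, rise, rel, pn_rel, q_set, p_max, c1,
                              c2, r1, r2, k2, r_exp1, r_exp2, c_ckt,
                              r_vent, topo)
                if insp0 and t_end == t_sw:
                    # insp -> exp switch: anchor the release ramp
                    pn_rel = y[2]
                qb1, qb2, _d, qbv = _rhs(y, tc0 + (t_end - t0), insp0, mode,
                                         t_insp, peep, dp_insp, rise, rel,
                                         pn_rel, q_set, p_max, c1, c2, r1,
                                         r2, k2, r_exp1, r_exp2, c_ckt,
                                         r_vent, topo)
                dt = t_end - t0
                vv += 0.5 * (qav + qbv) * dt
                vl1 += 0.5 * (qa1 + qb1) * dt
                vl2 += 0.5 * (qa2 + qb2) * dt
                t0 = t_end
    return (p_vent, q_vent, p_sim1, q_sim1, p_sim2, q_sim2,
            v_vent, v_sim1, v_sim2, capped)


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _rhs = njit(cache=True)(_rhs)
    _rk4_span = njit(cache=True)(_rk4_span)
    integrate = njit(cache=True)(_integrate)
except ImportError:  # pure-Python fallback, same code path
    integrate = _integrate
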