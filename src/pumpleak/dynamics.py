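"""Time integration of the flux ODEs with event protocols.

The cell is advanced by explicit Euler steps (default dt = 0.01 min).  Each
step (i) solves the membrane potential algebraically so that the net charge
flux is zero, (ii) advances the ion contents by dt * V * (net flux), and
(iii) re-equilibrates water instantaneously, V = (contents + A) / Osm_o —
water crosses the membrane much faster than ions, so no osmotic water
permeability enters the model.  Electroneutrality and osmotic balance
therefore hold at every output point by construction.

Protocols are ordered lists of timed events (pump block, medium replacement,
parameter steps) that reproduce the computational experiments of pump-block
and anisoosmotic (RVD/RVI) studies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .core import (
    CellState,
    InfeasibleStateError,
    Medium,
    MembraneParams,
    NoSolutionError,
    RT_F_MV,
)
from .equilibrium import solve_membrane_potential
from .fluxes import FluxBreakdown, electrochemical_potentials, total_fluxes

__all__ = ["Event", "Protocol", "Trajectory", "step", "simulate",
           "flux_table", "reverse_transition"]

logger = logging.getLogger(__name__)

_ACTIONS = ("set_beta", "set_kb", "set_medium", "scale_osmolarity", "set_param")
#: parameter changes apply before medium changes at coincident times
_ACTION_ORDER = {"set_beta": 0, "set_kb": 0, "set_param": 0,
                 "set_medium": 1, "scale_osmolarity": 1}


@dataclass(frozen=True)
class Event:
    """A timed protocol action.

    ``action`` is one of set_beta, set_kb, set_medium, scale_osmolarity or
    set_param; ``value`` is the new beta/kb, a Medium, the osmolarity ratio
    kv, or a (name, value) pair for set_param.
    """

    time: float
    action: str
    value: Any = None

    def __post_init__(self) -> None:
        if self.action not in _ACTIONS:
            raise ValueError(f"unknown protocol action {self.action!r}")


@dataclass(frozen=True)
class Protocol:
    """Ordered events plus the run duration and output grid.

    ``out_dt`` is the output grid step in minutes and ``hp`` an additional
    output thinning factor (every hp-th grid point is kept).
    """

    events: tuple[Event, ...] = ()
    duration: float = 240.0
    out_dt: float = 1.0
    hp: int = 1

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be non-decreasing")
        if times and self.duration < times[-1]:
            raise ValueError("duration must cover the last event time")
        if self.out_dt <= 0 or self.hp < 1:
            raise ValueError("out_dt must be > 0 and hp >= 1")


@dataclass
class Trajectory:
    """Simulation output on the decimated time grid.

    Arrays are aligned with ``t``; ``params`` and ``media`` hold the regime
    in force at each output point (events may change them mid-run), with
    ``params[i].beta`` already the effective pump coefficient (kb folded in).
    """

    t: np.ndarray
    na_i: np.ndarray
    k_i: np.ndarray
    cl_i: np.ndarray
    v: np.ndarray
    u: np.ndarray
    states: list[CellState]
    params: list[MembraneParams]
    media: list[Medium]
    balanced: bool = False
    balanced_time: float | None = None

    @property
    def U(self) -> np.ndarray:
        """Membrane potential in mV."""
        return RT_F_MV * self.u

    @property
    def v_over_a(self) -> np.ndarray:
        """Cell water per unit impermeant osmolyte, ml/mmol."""
        a = np.array([s.osmolytes.a for s in self.states])
        return 1000.0 * self.v / a

    def water(self, a_mmol_per_g_protein: float | None = None) -> np.ndarray:
        """Cell water per g protein (ml/g) when the A content per g protein
        is known; otherwise the relative volume V/A (ml/mmol) itself."""
        if a_mmol_per_g_protein is None:
            return self.v_over_a
        return self.v_over_a * a_mmol_per_g_protein

    def mu(self) -> np.ndarray:
        """(n, 3) array of electrochemical potential differences, mV."""
        out = np.empty((len(self.t), 3))
        for i, (s, m) in enumerate(zip(self.states, self.media)):
            out[i] = electrochemical_potentials(
                s.concentrations(), m, RT_F_MV * self.u[i]
            )
        return out

    def to_frame(self, a_mmol_per_g_protein: float | None = None) -> pd.DataFrame:
        mu = self.mu()
        return pd.DataFrame(
            {
                "time_min": self.t,
                "V_over_A_ml_per_mmol": self.v_over_a,
                "water_ml_per_g_protein": self.water(a_mmol_per_g_protein),
                "U_mV": self.U,
                "na_i_mM": self.na_i,
                "k_i_mM": self.k_i,
                "cl_i_mM": self.cl_i,
                "mu_na_mV": mu[:, 0],
                "mu_k_mV": mu[:, 1],
                "mu_cl_mV": mu[:, 2],
            }
        )


def _solve_u_warm(f, u0: float) -> float:
    """Safeguarded Newton on the (monotone) charge flux, warm-started at u0.

    Falls back to bisection-quality brentq over [-10, 10] whenever the
    Newton iterates stall or leave the physical bracket.
    """
    u = u0
    for _ in range(30):
        fu = f(u)
        h = 1e-7
        d = (f(u + h) - fu) / h
        if d == 0.0:
            break
        u_new = u - fu / d
        if not (-10.0 < u_new < 10.0):
            break
        if abs(u_new - u) < 1e-13:
            return u_new
        u = u_new
    from scipy.optimize import brentq

    f_lo, f_hi = f(-10.0), f(10.0)
    if f_lo * f_hi > 0:
        raise NoSolutionError(
            f"charge flux has no root in u [-10, 10]: f(-10)={f_lo:g}, f(10)={f_hi:g}"
        )
    return float(brentq(f, -10.0, 10.0, xtol=1e-14, rtol=8.9e-16))


def step(
    state: CellState,
    params: MembraneParams,
    medium: Medium,
    dt: float,
    t: float = 0.0,
) -> CellState:
    """One explicit Euler step of length dt, returning the new state.

    Potential solve -> content advance -> instantaneous water
    re-equilibration, exactly as inside :func:`simulate`.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt!r}")
    u = solve_membrane_potential(state, params, medium, t)
    fb = total_fluxes(state, params, medium, u, t)
    na_c = state.na_content + dt * state.v * fb.ion_total("Na")
    k_c = state.k_content + dt * state.v * fb.ion_total("K")
    cl_c = state.cl_content + dt * state.v * fb.ion_total("Cl")
    a = state.osmolytes.a
    v = (na_c + k_c + cl_c + a) / medium.osmolarity()
    if v <= 0:
        raise InfeasibleStateError(f"integration failure: V = {v:g} at t = {t:g}")
    return CellState(na_content=na_c, k_content=k_c, cl_content=cl_c, v=v,
                     osmolytes=state.osmolytes)


def _apply_event(
    ev: Event, params: MembraneParams, medium: Medium, t: float
) -> tuple[MembraneParams, Medium, float | None]:
    """Returns (params, medium, kb_ref_time or None)."""
    kb_ref = None
    if ev.action == "set_beta":
        params = replace(params, beta=float(ev.value))
        kb_ref = t  # pump decay restarts from the new beta
    elif ev.action == "set_kb":
        params = replace(params, kb=float(ev.value))
        kb_ref = t
    elif ev.action == "set_param":
        name, value = ev.value
        params = replace(params, **{name: float(value)})
    elif ev.action == "set_medium":
        medium = ev.value
    elif ev.action == "scale_osmolarity":
        kv = float(ev.value)
        medium = Medium(medium.na_o * kv, medium.k_o * kv,
                        medium.cl_o * kv, medium.b_o * kv)
    logger.info("t=%.4g min: applied %s", t, ev.action)
    return params, medium, kb_ref


def simulate(
    initial_state: CellState,
    params: MembraneParams,
    medium: Medium,
    protocol: Protocol,
    dt: float = 0.01,
    balance_tol: float = 1e-6,
    stop_when_balanced: bool = False,
) -> Trajectory:
    """Integrate the flux ODEs under a protocol of timed events.

    The terminal ``balanced`` flag is set once every per-ion total net flux
    falls below ``balance_tol`` (umol min^-1 ml^-1) at an output point; with
    ``stop_when_balanced`` the run then ends early.  The inner loop works on
    plain floats for speed; events are applied on the step grid (their times
    should be multiples of dt) with parameter changes before medium changes
    at coincident times.
    """
    events = sorted(
        protocol.events, key=lambda e: (e.time, _ACTION_ORDER[e.action])
    )
    a = initial_state.osmolytes.a
    z = initial_state.osmolytes.z
    osmolytes = initial_state.osmolytes

    na_c = initial_state.na_content
    k_c = initial_state.k_content
    cl_c = initial_state.cl_content

    ev_idx = 0
    t = 0.0
    kb_ref = 0.0

    def due_events(now: float):
        nonlocal ev_idx, params, medium, kb_ref
        changed = False
        while ev_idx < len(events) and events[ev_idx].time <= now + 0.5 * dt:
            params, medium, new_ref = _apply_event(events[ev_idx], params, medium, now)
            if new_ref is not None:
                kb_ref = new_ref
            ev_idx += 1
            changed = True
        return changed

    # The t = 0 output point records the *initial* regime; events stamped
    # at t = 0 take effect for t > 0 (a pump blocked "at t = 0" leaves the
    # t = 0 table row balanced).
    osm = medium.osmolarity()
    v = (na_c + k_c + cl_c + a) / osm

    # unpack the regime into locals; refreshed after every event
    def regime():
        return (params.p_na, params.p_k, params.p_cl, params.beta, params.gamma,
                params.inc, params.ikc, params.inkcc, params.kb,
                medium.na_o, medium.k_o, medium.cl_o, medium.osmolarity())

    (p_na, p_k, p_cl, beta, gamma, inc, ikc, inkcc, kb,
     na_o, k_o, cl_o, osm) = regime()

    def charge(u: float, na_i: float, k_i: float, cl_i: float,
               pump_charge: float) -> float:
        if u == 0.0:
            w = -1.0
            eu = 1.0
        else:
            eu = math.exp(u)
            w = u / -math.expm1(u)
        return (-p_na * w * (na_o - na_i * eu)
                - p_k * w * (k_o - k_i * eu)
                + p_cl * w * (cl_o * eu - cl_i)
                + pump_charge)

    state0 = CellState(na_content=na_c, k_content=k_c, cl_content=cl_c, v=v,
                       osmolytes=osmolytes)
    u = solve_membrane_potential(state0, params, medium, 0.0)
    logger.info("initial potential U = %.3f mV, V/A = %.4g ml/mmol",
                RT_F_MV * u, 1000.0 * v / a)

    n_steps = int(round(protocol.duration / dt))
    out_every = max(1, int(round(protocol.out_dt * protocol.hp / dt)))

    rec_t = [0.0]
    rec_conc = [(na_c / v, k_c / v, cl_c / v)]
    rec_v = [v]
    rec_u = [u]
    rec_params = [replace(params, beta=max(0.0, beta - kb * (0.0 - kb_ref)), kb=0.0)]
    rec_media = [medium]
    balanced = False
    balanced_time: float | None = None

    if due_events(0.0):
        (p_na, p_k, p_cl, beta, gamma, inc, ikc, inkcc, kb,
         na_o, k_o, cl_o, osm) = regime()
        v = (na_c + k_c + cl_c + a) / osm

    gamma_inv = 1.0 / gamma
    for i in range(1, n_steps + 1):
        na_i = na_c / v
        k_i = k_c / v
        cl_i = cl_c / v
        beta_eff = beta - kb * (t - kb_ref)
        if beta_eff < 0.0:
            beta_eff = 0.0
        pump_charge = beta_eff * na_i * (gamma_inv - 1.0)

        # membrane potential: warm-started Newton on the monotone charge flux
        uu = u
        for _ in range(30):
            fu = charge(uu, na_i, k_i, cl_i, pump_charge)
            d = (charge(uu + 1e-7, na_i, k_i, cl_i, pump_charge) - fu) * 1e7
            if d == 0.0:
                break
            u_new = uu - fu / d
            if not (-10.0 < u_new < 10.0) or not math.isfinite(u_new):
                uu = _solve_u_warm(
                    lambda x: charge(x, na_i, k_i, cl_i, pump_charge), u)
                break
            if abs(u_new - uu) < 1e-13:
                uu = u_new
                break
            uu = u_new
        u = uu

        eu = math.exp(u)
        w = u / -math.expm1(u) if u != 0.0 else -1.0
        ch_na = -p_na * w * (na_o - na_i * eu)
        ch_k = -p_k * w * (k_o - k_i * eu)
        ch_cl = -p_cl * w * (cl_o * eu - cl_i)
        j_nc = inc * (na_o * cl_o - na_i * cl_i)
        j_kc = ikc * (k_o * cl_o - k_i * cl_i)
        j_nkcc = inkcc * (na_o * k_o * cl_o * cl_o - na_i * k_i * cl_i * cl_i)

        net_na = ch_na - beta_eff * na_i + j_nc + j_nkcc
        net_k = ch_k + beta_eff * na_i * gamma_inv + j_kc + j_nkcc
        net_cl = ch_cl + j_nc + j_kc + 2.0 * j_nkcc

        na_c += dt * v * net_na
        k_c += dt * v * net_k
        cl_c += dt * v * net_cl
        t = i * dt
        v = (na_c + k_c + cl_c + a) / osm
        if v <= 0 or not math.isfinite(v):
            raise InfeasibleStateError(
                f"integration failure at t = {t:g} min: V = {v:g}")

        if i % out_every == 0 or i == n_steps:
            # re-solve u at the advanced state so every recorded point is
            # self-consistent (the loop variable u lags by one step)
            na_i = na_c / v
            k_i = k_c / v
            cl_i = cl_c / v
            beta_eff = max(0.0, beta - kb * (t - kb_ref))
            pump_charge = beta_eff * na_i * (gamma_inv - 1.0)
            u = _solve_u_warm(
                lambda x: charge(x, na_i, k_i, cl_i, pump_charge), u)
            rec_t.append(t)
            rec_conc.append((na_i, k_i, cl_i))
            rec_v.append(v)
            rec_u.append(u)
            rec_params.append(replace(params, beta=beta_eff, kb=0.0))
            rec_media.append(medium)
            if (not balanced and abs(net_na) < balance_tol
                    and abs(net_k) < balance_tol and abs(net_cl) < balance_tol):
                balanced = True
                balanced_time = t
                logger.info("balanced state reached at t = %.4g min", t)
                if stop_when_balanced:
                    break

        # events stamped at t apply for times > t (the record above shows
        # the pre-event state)
        if due_events(t):
            (p_na, p_k, p_cl, beta, gamma, inc, ikc, inkcc, kb,
             na_o, k_o, cl_o, osm) = regime()
            gamma_inv = 1.0 / gamma
            v = (na_c + k_c + cl_c + a) / osm

    conc = np.asarray(rec_conc)
    states = [
        CellState.from_concentrations(c[0], c[1], c[2],
                                      a / vv, z, v=vv)
        for c, vv in zip(rec_conc, rec_v)
    ]
    return Trajectory(
        t=np.asarray(rec_t),
        na_i=conc[:, 0],
        k_i=conc[:, 1],
        cl_i=conc[:, 2],
        v=np.asarray(rec_v),
        u=np.asarray(rec_u),
        states=states,
        params=rec_params,
        media=rec_media,
        balanced=balanced,
        balanced_time=balanced_time,
    )


def flux_table(trajectory: Trajectory, times: Sequence[float]) -> pd.DataFrame:
    """Net and unidirectional fluxes by pathway and ion at requested times.

    Rows are (time_min, pathway, ion, influx, efflux, net) in
    umol min^-1 (ml cell water)^-1, with per-ion Total rows, recomputed from
    the stored states at the nearest output grid point.
    """
    frames = []
    t_grid = trajectory.t
    half = 0.5 * (t_grid[1] - t_grid[0]) if len(t_grid) > 1 else 0.0
    for t_req in times:
        i = int(np.argmin(np.abs(t_grid - t_req)))
        if abs(t_grid[i] - t_req) > max(half, 1e-9):
            raise ValueError(
                f"time {t_req} min outside the trajectory span / output grid"
            )
        fb = total_fluxes(
            trajectory.states[i], trajectory.params[i], trajectory.media[i],
            trajectory.u[i],
        )
        frames.append(fb.to_frame(time=float(t_grid[i])))
    return pd.concat(frames, ignore_index=True)


def reverse_transition(
    end_state: CellState,
    params: MembraneParams,
    original_medium: Medium,
    duration: float,
    dt: float = 0.01,
    **kwargs,
) -> Trajectory:
    """Return a cell to its original medium (the RVI-like recovery leg).

    Convenience wrapper: simulates from ``end_state`` in ``original_medium``
    with no further events.
    """
    proto = Protocol(events=(), duration=duration)
    return simulate(end_state, params, original_medium, proto, dt=dt, **kwargs)
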