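"""Algebraic solvers for the balanced state and its inverse problems.

These operations close the model against measured data without any time
integration: inferring the impermeant-osmolyte pool from measured
concentrations, solving the membrane potential from electroneutrality,
recovering channel permeabilities that balance every ion's fluxes
(the inverse problem behind the parameter tables), an OSOR-based closure,
the analytic volume limits of regulatory volume decrease, and the
buoyant-density -> cell-water conversion used to measure water content.
"""

from __future__ import annotations

import math

from scipy.optimize import brentq

from .core import (
    CellState,
    ImpermeantOsmolytes,
    InfeasibleParameterError,
    InfeasibleStateError,
    Medium,
    MembraneParams,
    NoSolutionError,
    RT_F_MV,
)
from .fluxes import _w, charge_flux, cotransporter_fluxes, osor, pump_fluxes

__all__ = [
    "impermeant_from_state",
    "solve_membrane_potential",
    "fit_permeabilities",
    "solve_U_from_osor",
    "balanced_state",
    "density_to_water",
    "rvd_limit",
]


def impermeant_from_state(
    conc_i: tuple[float, float, float], medium: Medium
) -> tuple[float, float]:
    """Infer (A/V, z) of the impermeant osmolytes from measured concentrations.

    Osmotic balance gives A/V = Osm_o - ([Na]i + [K]i + [Cl]i); cytoplasmic
    electroneutrality then gives z = ([Cl]i - [Na]i - [K]i) / (A/V).
    """
    na_i, k_i, cl_i = conc_i
    a_over_v = medium.osmolarity() - (na_i + k_i + cl_i)
    if a_over_v <= 0:
        raise InfeasibleStateError(
            "intracellular ions alone meet or exceed the bath osmolarity; "
            f"A/V = {a_over_v} is not positive"
        )
    z = (cl_i - na_i - k_i) / a_over_v
    return a_over_v, z


def solve_membrane_potential(
    state: CellState,
    params: MembraneParams,
    medium: Medium,
    t: float = 0.0,
) -> float:
    """Dimensionless potential u at which the net charge flux vanishes.

    Enforces that electroneutrality is preserved over time (the membrane
    capacitance is neglected, so u is an algebraic variable).  The charge
    flux is strictly monotone in u for any conductive membrane, so the root
    in the bracket u in [-10, 10] (about +/-267 mV) is unique.
    """
    if params.p_na == 0 and params.p_k == 0 and params.p_cl == 0:
        raise NoSolutionError("no conductive pathway: all channel coefficients are 0")

    def f(u: float) -> float:
        return charge_flux(state, params, medium, u, t)

    lo, hi = -10.0, 10.0
    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0:
        raise NoSolutionError(
            "charge flux does not change sign on u in [-10, 10]: "
            f"f(-10) = {f_lo:g}, f(10) = {f_hi:g}"
        )
    return float(brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16))


def fit_permeabilities(
    conc_i: tuple[float, float, float],
    medium: Medium,
    beta: float,
    gamma: float,
    inc: float,
    ikc: float,
    inkcc: float,
    U: float,
) -> tuple[float, float, float]:
    """Channel permeabilities that balance every ion at the given state and U.

    At a balanced state each ion's channel net flux must cancel the summed
    net flux of its other pathways.  The channel flux is linear in its rate
    coefficient, so the three balances decouple into three scalar equations:

        p_Na: channel Na = -(-beta [Na]i + J_NC + J_NKCC)
        p_K:  channel K  = -( beta [Na]i / gamma + J_KC + J_NKCC)
        p_Cl: channel Cl = -( J_NC + J_KC + 2 J_NKCC)

    A non-positive solution means that cotransporter/closure combination
    cannot balance and raises InfeasibleParameterError.
    """
    na_i, k_i, cl_i = conc_i
    u = U / RT_F_MV
    w = _w(u)
    eu = math.exp(u)

    carrier = MembraneParams(
        p_na=0.0, p_k=0.0, p_cl=0.0, beta=beta, gamma=gamma,
        inc=inc, ikc=ikc, inkcc=inkcc,
    )
    j_nc, j_kc, j_nkcc = cotransporter_fluxes(carrier, conc_i, medium)
    pump_na, pump_k = pump_fluxes(beta, na_i, gamma)

    # Channel net flux per unit rate coefficient.
    n_na = -w * (medium.na_o - na_i * eu)
    n_k = -w * (medium.k_o - k_i * eu)
    n_cl = -w * (medium.cl_o * eu - cl_i)

    p_na = -(-pump_na + j_nc + j_nkcc) / n_na
    p_k = -(pump_k + j_kc + j_nkcc) / n_k
    p_cl = -(j_nc + j_kc + 2.0 * j_nkcc) / n_cl

    for name, p in (("p_na", p_na), ("p_k", p_k), ("p_cl", p_cl)):
        if p <= 0:
            raise InfeasibleParameterError(
                f"inverse problem infeasible: required {name} = {p:g} is not positive"
            )
    return p_na, p_k, p_cl


def solve_U_from_osor(
    conc_i: tuple[float, float, float],
    medium: Medium,
    beta: float,
    gamma: float,
    inc: float,
    ikc: float,
    inkcc: float,
    osor_target: float,
) -> float:
    """Membrane potential (mV) at which the balanced state matches a measured OSOR.

    With the inverse problem closed by fit_permeabilities, U remains free;
    a measured ouabain-sensitive/resistant K influx ratio pins it.  When NC
    is the only cotransporter no other pathway carries K, the K balance
    collapses, and the closed form  exp(u) = [K]o (OSOR + 1) / [K]i  applies.
    Otherwise U is found by a bracketed 1-D root search on the assembled
    osor(U) function.
    """
    if osor_target <= 0:
        raise InfeasibleParameterError(f"OSOR target must be > 0, got {osor_target!r}")
    na_i, k_i, cl_i = conc_i

    if ikc == 0.0 and inkcc == 0.0:
        eu = medium.k_o * (osor_target + 1.0) / k_i
        if eu > 1.0:
            raise InfeasibleParameterError(
                f"OSOR {osor_target} requires exp(u) = {eu:g} > 1 "
                "(a depolarized K-influx regime the closed form excludes)"
            )
        return RT_F_MV * math.log(eu)

    a_over_v, z = impermeant_from_state(conc_i, medium)
    state = CellState.from_concentrations(na_i, k_i, cl_i, a_over_v, z)

    def osor_minus_target(U: float) -> float:
        p_na, p_k, p_cl = fit_permeabilities(
            conc_i, medium, beta, gamma, inc, ikc, inkcc, U
        )
        params = MembraneParams(
            p_na=p_na, p_k=p_k, p_cl=p_cl, beta=beta, gamma=gamma,
            inc=inc, ikc=ikc, inkcc=inkcc,
        )
        return osor(state, params, medium, U) - osor_target

    # Scan for a feasible bracket; permeability fits fail outside a window.
    grid = [-150.0 + 2.5 * i for i in range(60)]  # -150 .. -2.5 mV
    prev: tuple[float, float] | None = None
    for U in grid:
        try:
            val = osor_minus_target(U)
        except InfeasibleParameterError:
            prev = None
            continue
        if val == 0.0:
            return U
        if prev is not None and prev[1] * val < 0:
            return float(brentq(osor_minus_target, prev[0], U, xtol=1e-10))
        prev = (U, val)
    raise NoSolutionError(
        f"no membrane potential in [-150, -2.5] mV yields OSOR = {osor_target}"
    )


def balanced_state(
    params: MembraneParams,
    medium: Medium,
    osmolytes: ImpermeantOsmolytes,
    guess: CellState,
    tol: float = 1e-12,
) -> tuple[CellState, float]:
    """Algebraic fixed point of the flux ODEs under fixed params and medium.

    Solves net Na = net K = net Cl = 0 together with cytoplasmic
    electroneutrality for ([Na]i, [K]i, [Cl]i, u); the water volume follows
    from osmotic balance, V = (contents + A)/Osm_o.  Damped Newton iteration
    from ``guess``; independent of (and cross-checked against) the time
    integrator's long-time limit.

    Returns (state, u).  Raises NoSolutionError when the iteration fails,
    e.g. for the unbounded-swelling regime (no pump, no external impermeant
    osmolyte) where no fixed point exists.
    """
    from scipy.optimize import fsolve

    from .fluxes import total_fluxes

    a, z = osmolytes.a, osmolytes.z
    osm = medium.osmolarity()

    def unpack(x) -> tuple[CellState, float]:
        # log contents keep every amount positive; V follows from osmotic
        # balance, so the concentrations stay admissible throughout.
        na_c, k_c, cl_c = (math.exp(xi) for xi in x[:3])
        v = (na_c + k_c + cl_c + a) / osm
        st = CellState(na_content=na_c, k_content=k_c, cl_content=cl_c,
                       v=v, osmolytes=osmolytes)
        return st, x[3]

    def residuals(x):
        st, u = unpack(x)
        fb = total_fluxes(st, params, medium, u)
        return [
            fb.ion_total("Na"),
            fb.ion_total("K"),
            fb.ion_total("Cl"),
            st.electroneutrality_residual(),
        ]

    x0 = [
        math.log(guess.na_content),
        math.log(guess.k_content),
        math.log(guess.cl_content),
        solve_membrane_potential(guess, params, medium),
    ]
    sol, info, ier, msg = fsolve(residuals, x0, full_output=True, xtol=tol)
    # ier may flag "no progress" when the guess already sits on the root;
    # the residuals are the authoritative acceptance check.
    if max(abs(r) for r in residuals(sol)) > 1e-8:
        raise NoSolutionError(f"no balanced state found: {msg}")
    state, u = unpack(sol)
    if state.v > 1e6 * guess.v:
        # all fluxes vanish as the cell dilutes toward the bath composition:
        # the Donnan "fixed point at infinity" of unbounded swelling
        raise NoSolutionError(
            "no finite balanced state: the cell swells without bound "
            f"(solver diverged to V = {state.v:g})"
        )
    return state, float(u)


def density_to_water(
    rho: float, rho_dry: float = 1.38, protein_share: float = 0.72
) -> float:
    """Cell water per g protein (ml/g) from buoyant density (g/ml).

    v_prot = (1 - rho/rho_dry) / (protein_share * (rho - 1)); rho_dry is the
    cell dry-mass density and protein_share the protein fraction of dry mass.
    """
    if rho <= 1.0:
        raise InfeasibleStateError(
            f"density must exceed 1 g/ml (pure water), got {rho!r}"
        )
    if rho > rho_dry:
        raise InfeasibleStateError(
            f"density {rho} above the dry-mass density {rho_dry} implies "
            "negative water content"
        )
    return (1.0 - rho / rho_dry) / (protein_share * (rho - 1.0))


def rvd_limit(
    osm_iso: float, osm_hypo: float, cl_i_iso: float, cl_i_hypo: float
) -> float:
    """Hypo/iso volume ratio from the osmotic and electroneutrality balances.

    V_hypo / V_iso = (Osm_iso - 2 [Cl]i,iso) / (Osm_hypo - 2 [Cl]i,hypo).
    With [Cl]i,hypo = 0 (intracellular Cl fully exhausted) this is the
    maximal regulatory volume decrease achievable by losing KCl/NaCl alone;
    with both [Cl]i terms zero it reduces to the pure-osmometer ratio
    Osm_iso / Osm_hypo.
    """
    num = osm_iso - 2.0 * cl_i_iso
    den = osm_hypo - 2.0 * cl_i_hypo
    if den <= 0 or num <= 0:
        raise InfeasibleStateError(
            f"non-positive osmotic term in the volume ratio ({num} / {den})"
        )
    return num / den
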