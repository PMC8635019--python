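"""Per-pathway flux kernels: channels, Na/K pump, cotransporters, OSOR.

Every kernel returns unidirectional influx and efflux (both >= 0 under
physiological potentials) whose difference is the net flux, in
umol min^-1 (ml cell water)^-1.

Channel fluxes follow the Goldman constant-field form written with the
dimensionless potential u and g = 1 - exp(u):

    cation:  net = p * u * ([X]i * e^u - [X]o) / g
    anion:   net = p * u * ([Cl]i - [Cl]o * e^u) / g      (valence -1)

so that net flux always runs down the ion's electrochemical gradient and
vanishes exactly at its Nernst potential.  The Na/K pump is first order in
[Na]i with Na:K stoichiometry gamma (3:2 -> gamma = 1.5); the cotransporters
follow mass-action product laws in the participating concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .core import (
    CellState,
    InfeasibleParameterError,
    Medium,
    MembraneParams,
    UndefinedPotentialError,
    RT_F_MV,
)

__all__ = [
    "IONS",
    "PATHWAYS",
    "FluxBreakdown",
    "channel_flux",
    "cotransporter_fluxes",
    "cotransporter_unidirectional",
    "pump_fluxes",
    "electrochemical_potentials",
    "osor",
    "total_fluxes",
    "charge_flux",
]

IONS = ("Na", "K", "Cl")
PATHWAYS = ("Channel", "Pump", "NC", "KC", "NKCC")


def _w(u: float) -> float:
    """u / g with g = 1 - exp(u); analytic limit -1 at u = 0.

    expm1 keeps the ratio accurate for |u| down to machine precision, so only
    u == 0 exactly needs the limit.
    """
    if u == 0.0:
        return -1.0
    return u / (-math.expm1(u))


def channel_flux(
    ion_kind: str, p: float, u: float, c_in: float, c_out: float
) -> tuple[float, float, float]:
    """Goldman-type channel flux for one ion species.

    Parameters
    ----------
    ion_kind
        ``"cation"`` (valence +1) or ``"anion"`` (valence -1).
    p
        Channel rate coefficient, min^-1.
    u
        Dimensionless membrane potential.
    c_in, c_out
        Intra- and extracellular concentrations, mM.

    Returns
    -------
    (influx, efflux, net) with net = influx - efflux.
    """
    w = _w(u)
    eu = math.exp(u)
    if ion_kind == "cation":
        influx = -p * w * c_out
        efflux = -p * w * c_in * eu
    elif ion_kind == "anion":
        influx = -p * w * c_out * eu
        efflux = -p * w * c_in
    else:
        raise ValueError(f"ion_kind must be 'cation' or 'anion', got {ion_kind!r}")
    return influx, efflux, influx - efflux


def cotransporter_unidirectional(
    params: MembraneParams,
    conc_i: tuple[float, float, float],
    medium: Medium,
) -> dict[str, tuple[float, float]]:
    """(influx, efflux) per cotransporter event, from the product laws.

    Influx is the rate coefficient times the product of the outside partner
    concentrations, efflux the same with the inside concentrations:

        NC:   inc   * [Na][Cl]              KC: ikc * [K][Cl]
        NKCC: inkcc * [Na][K][Cl]^2

    Each returned pair is per transport *event*; NKCC moves 2 Cl per event.
    """
    na_i, k_i, cl_i = conc_i
    return {
        "NC": (params.inc * medium.na_o * medium.cl_o, params.inc * na_i * cl_i),
        "KC": (params.ikc * medium.k_o * medium.cl_o, params.ikc * k_i * cl_i),
        "NKCC": (
            params.inkcc * medium.na_o * medium.k_o * medium.cl_o**2,
            params.inkcc * na_i * k_i * cl_i**2,
        ),
    }


def cotransporter_fluxes(
    params: MembraneParams,
    conc_i: tuple[float, float, float],
    medium: Medium,
) -> tuple[float, float, float]:
    """Net cotransporter fluxes (J_NC, J_KC, J_NKCC); positive = influx."""
    uni = cotransporter_unidirectional(params, conc_i, medium)
    return tuple(inf - eff for inf, eff in (uni["NC"], uni["KC"], uni["NKCC"]))


def pump_fluxes(
    beta: float, na_i: float, gamma: float, t: float = 0.0, kb: float = 0.0
) -> tuple[float, float]:
    """Na/K pump fluxes: (Na efflux, K influx) = (b [Na]i, b [Na]i / gamma).

    ``b = max(0, beta - kb*t)`` is the effective pump rate coefficient; kb > 0
    models a linear run-down of the pump with time.
    """
    if na_i < 0:
        raise InfeasibleParameterError(f"na_i must be >= 0, got {na_i!r}")
    b = max(0.0, beta - kb * t)
    na_efflux = b * na_i
    return na_efflux, na_efflux / gamma


def electrochemical_potentials(
    conc_i: tuple[float, float, float], medium: Medium, U: float
) -> tuple[float, float, float]:
    """Transmembrane electrochemical potential differences in mV.

    mu_Na = 26.7 ln([Na]i/[Na]o) + U, likewise for K; Cl carries valence -1
    so mu_Cl = 26.7 ln([Cl]i/[Cl]o) - U.  Positive mu means the passive net
    flux of that ion is outward.
    """
    na_i, k_i, cl_i = conc_i
    pairs = (
        (na_i, medium.na_o),
        (k_i, medium.k_o),
        (cl_i, medium.cl_o),
    )
    for c_in, c_out in pairs:
        if c_in <= 0 or c_out <= 0:
            raise UndefinedPotentialError(
                "electrochemical potential undefined for a zero concentration"
            )
    mu_na = RT_F_MV * math.log(na_i / medium.na_o) + U
    mu_k = RT_F_MV * math.log(k_i / medium.k_o) + U
    mu_cl = RT_F_MV * math.log(cl_i / medium.cl_o) - U
    return mu_na, mu_k, mu_cl


@dataclass(frozen=True)
class FluxBreakdown:
    """All unidirectional and net fluxes, by (pathway, ion).

    ``entries[(pathway, ion)] = (influx, efflux)``; pathways not carrying an
    ion hold (0, 0).  Net is always influx - efflux.  NKCC entries already
    include its 2 Cl per event.
    """

    entries: Mapping[tuple[str, str], tuple[float, float]]

    def influx(self, pathway: str, ion: str) -> float:
        return self.entries[(pathway, ion)][0]

    def efflux(self, pathway: str, ion: str) -> float:
        return self.entries[(pathway, ion)][1]

    def net(self, pathway: str, ion: str) -> float:
        inf, eff = self.entries[(pathway, ion)]
        return inf - eff

    def ion_total(self, ion: str) -> float:
        """Total net flux of one ion over all pathways (an ODE right side)."""
        return sum(self.net(p, ion) for p in PATHWAYS)

    def totals(self) -> dict[str, float]:
        return {ion: self.ion_total(ion) for ion in IONS}

    @property
    def charge_flux(self) -> float:
        """Net charge carried across the membrane: netNa + netK - netCl."""
        return self.ion_total("Na") + self.ion_total("K") - self.ion_total("Cl")

    def max_unidirectional(self) -> float:
        """Largest single unidirectional flux; the natural residual scale."""
        return max(max(pair) for pair in self.entries.values())

    def to_frame(self, time: float | None = None) -> pd.DataFrame:
        """Tabular layout: one row per (pathway, ion) plus per-ion totals."""
        rows = []
        for ion in IONS:
            for pathway in PATHWAYS:
                inf, eff = self.entries[(pathway, ion)]
                rows.append((pathway, ion, inf, eff, inf - eff))
            rows.append(("Total", ion, float("nan"), float("nan"), self.ion_total(ion)))
        frame = pd.DataFrame(rows, columns=["pathway", "ion", "influx", "efflux", "net"])
        if time is not None:
            frame.insert(0, "time_min", time)
        return frame


def total_fluxes(
    state: CellState,
    params: MembraneParams,
    medium: Medium,
    u: float,
    t: float = 0.0,
) -> FluxBreakdown:
    """Assemble every pathway kernel into one FluxBreakdown.

    Pathway-to-ion wiring (per the flux ODEs): Na moves through Channel,
    Pump, NC and NKCC; K through Channel, Pump, KC and NKCC; Cl through
    Channel, NC, KC and NKCC (x2).
    """
    conc = state.concentrations()
    na_i, k_i, cl_i = conc
    zero = (0.0, 0.0)
    entries: dict[tuple[str, str], tuple[float, float]] = {
        (p, ion): zero for p in PATHWAYS for ion in IONS
    }

    for ion, kind, p, c_in, c_out in (
        ("Na", "cation", params.p_na, na_i, medium.na_o),
        ("K", "cation", params.p_k, k_i, medium.k_o),
        ("Cl", "anion", params.p_cl, cl_i, medium.cl_o),
    ):
        inf, eff, _ = channel_flux(kind, p, u, c_in, c_out)
        entries[("Channel", ion)] = (inf, eff)

    na_efflux, k_influx = pump_fluxes(params.beta, na_i, params.gamma, t, params.kb)
    entries[("Pump", "Na")] = (0.0, na_efflux)
    entries[("Pump", "K")] = (k_influx, 0.0)

    uni = cotransporter_unidirectional(params, conc, medium)
    nc_in, nc_out = uni["NC"]
    kc_in, kc_out = uni["KC"]
    nkcc_in, nkcc_out = uni["NKCC"]
    entries[("NC", "Na")] = (nc_in, nc_out)
    entries[("NC", "Cl")] = (nc_in, nc_out)
    entries[("KC", "K")] = (kc_in, kc_out)
    entries[("KC", "Cl")] = (kc_in, kc_out)
    entries[("NKCC", "Na")] = (nkcc_in, nkcc_out)
    entries[("NKCC", "K")] = (nkcc_in, nkcc_out)
    entries[("NKCC", "Cl")] = (2.0 * nkcc_in, 2.0 * nkcc_out)

    return FluxBreakdown(entries=entries)


def charge_flux(
    state: CellState,
    params: MembraneParams,
    medium: Medium,
    u: float,
    t: float = 0.0,
) -> float:
    """Net charge flux netNa + netK - netCl at potential ``u``.

    The electroneutral cotransporters contribute exactly zero by
    construction; only the channels and the pump (beta [Na]i (1/gamma - 1))
    remain.  The membrane potential is the root of this function.
    """
    na_i, k_i, cl_i = state.concentrations()
    w = _w(u)
    eu = math.exp(u)
    net_na = -params.p_na * w * (medium.na_o - na_i * eu)
    net_k = -params.p_k * w * (medium.k_o - k_i * eu)
    net_cl = -params.p_cl * w * (medium.cl_o * eu - cl_i)
    b = max(0.0, params.beta - params.kb * t)
    pump_charge = b * na_i * (1.0 / params.gamma - 1.0)
    return net_na + net_k - net_cl + pump_charge


def osor(
    state: CellState,
    params: MembraneParams,
    medium: Medium,
    U: float,
) -> float:
    """Ratio of ouabain-sensitive to ouabain-resistant K+(Rb+) influx.

    The ouabain-sensitive influx is the pump's K influx beta [Na]i / gamma;
    the resistant denominator sums every other unidirectional K influx:
    channel, KC and NKCC.  Directly comparable with Rb+ uptake measurements.
    """
    if params.beta <= 0:
        raise InfeasibleParameterError("OSOR undefined with a blocked pump (beta = 0)")
    conc = state.concentrations()
    u = U / RT_F_MV
    _, pump_k = pump_fluxes(params.beta, conc[0], params.gamma)
    ch_in, _, _ = channel_flux("cation", params.p_k, u, conc[1], medium.k_o)
    uni = cotransporter_unidirectional(params, conc, medium)
    denom = ch_in + uni["KC"][0] + uni["NKCC"][0]
    if denom <= 0:
        raise InfeasibleParameterError(
            "OSOR undefined: no ouabain-resistant K influx pathway open"
        )
    return pump_k / denom
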