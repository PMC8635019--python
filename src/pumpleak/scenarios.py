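"""Shipped presets and protocol builders for the reference computational experiments.

Two reference U937 cell states are bundled: cell ``A`` (used for pump-block
experiments) and cell ``B`` (used for the regulatory-volume-decrease
studies), each with four cotransporter variants (NC+KC+NKCC, NC+NKCC,
NC+KC, NC) and the channel permeabilities and membrane potential that
balance every ion flux at the measured concentrations.  The preset loader
re-derives the impermeant-osmolyte pool and checks flux-balance closure on
load, so a transcription error fails loudly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .core import (
    CellState,
    Medium,
    MembraneParams,
    hypo_medium_by_nacl_removal,
    standard_rpmi_medium,
    sucrose_substituted_media,
)
from .dynamics import Event, Protocol, simulate
from .equilibrium import fit_permeabilities, impermeant_from_state
from .fluxes import total_fluxes

__all__ = [
    "CELLS",
    "VARIANTS",
    "Preset",
    "preset",
    "reference_column",
    "protocol",
    "fig4_setup",
    "fig9_runs",
    "MEDIUM_STANDARD",
    "MEDIUM_NO_B",
    "MEDIUM_HYPO_160",
]

logger = logging.getLogger(__name__)

CELLS = ("A", "B")
VARIANTS = ("NC+KC+NKCC", "NC+NKCC", "NC+KC", "NC")

#: standard 310 mOsm bath
MEDIUM_STANDARD = standard_rpmi_medium()
#: 310 mOsm bath with no impermeant osmolyte (charge-balanced NaCl/KCl bath)
MEDIUM_NO_B = Medium(na_o=149.2, k_o=5.8, cl_o=155.0, b_o=0.0)
#: 160 mOsm bath obtained by removing 75 mM NaCl from the standard bath
MEDIUM_HYPO_160 = hypo_medium_by_nacl_removal(MEDIUM_STANDARD, 75.0)

# Measured resting characteristics (concentrations mM; beta min^-1).
_MEASURED = {
    "A": dict(k_i=156.0, na_i=35.0, cl_i=70.0, beta=0.039, osor=3.06),
    "B": dict(k_i=147.0, na_i=38.0, cl_i=45.0, beta=0.039, osor=3.89),
}

# Cotransporter sets with the channel parameters and potential that balance
# them (verbatim printed values; closure is verified on load).
_VARIANTS = {
    ("A", "NC+KC+NKCC"): dict(inc=7e-5, ikc=3e-5, inkcc=8e-9,
                              p_na=0.0019, p_k=0.01, p_cl=0.004, U=-45.2,
                              mu_cl=31.7, mu_na=-82.2, mu_k=42.7),
    ("A", "NC+NKCC"): dict(inc=4.7e-5, ikc=0.0, inkcc=8e-9,
                           p_na=0.0032, p_k=0.0149, p_cl=0.00433, U=-42.0,
                           mu_cl=28.6, mu_na=-79.1, mu_k=45.8),
    ("A", "NC+KC"): dict(inc=5e-5, ikc=3e-5, inkcc=0.0,
                         p_na=0.0021, p_k=0.0185, p_cl=0.0029, U=-55.5,
                         mu_cl=42.0, mu_na=-92.5, mu_k=32.4),
    ("A", "NC"): dict(inc=3e-5, ikc=0.0, inkcc=0.0,
                      p_na=0.00317, p_k=0.023, p_cl=0.00354, U=-50.5,
                      mu_cl=37.0, mu_na=-87.5, mu_k=37.4),
    ("B", "NC+KC+NKCC"): dict(inc=7e-5, ikc=8e-5, inkcc=8e-9,
                              p_na=0.0017, p_k=0.0115, p_cl=0.011, U=-45.0,
                              mu_cl=19.8, mu_na=-79.9, mu_k=41.3),
    ("B", "NC+NKCC"): dict(inc=3e-5, ikc=0.0, inkcc=7e-9,
                           p_na=0.0043, p_k=0.0175, p_cl=0.0139, U=-37.6,
                           mu_cl=12.3, mu_na=-72.4, mu_k=48.7),
    ("B", "NC+KC"): dict(inc=4.87e-5, ikc=6e-5, inkcc=0.0,
                         p_na=0.00263, p_k=0.0165, p_cl=0.006, U=-49.3,
                         mu_cl=24.0, mu_na=-84.1, mu_k=37.0),
    ("B", "NC"): dict(inc=3e-5, ikc=0.0, inkcc=0.0,
                      p_na=0.00382, p_k=0.022, p_cl=0.0091, U=-44.7,
                      mu_cl=19.4, mu_na=-79.5, mu_k=41.6),
}

_GAMMA = 1.5  # 3Na:2K pump stoichiometry; closes the K balance of every column


@dataclass(frozen=True)
class Preset:
    """One reference parameter column: measured state plus balancing parameters."""

    cell: str
    variant: str
    na_i: float
    k_i: float
    cl_i: float
    beta: float
    osor_measured: float
    inc: float
    ikc: float
    inkcc: float
    p_na: float
    p_k: float
    p_cl: float
    U: float
    mu_na: float
    mu_k: float
    mu_cl: float
    a_over_v: float
    z: float

    def membrane_params(self, refit: bool = False) -> MembraneParams:
        """Printed channel permeabilities, or exactly re-fitted ones.

        ``refit=True`` recomputes (p_na, p_k, p_cl) by the inverse solver at
        the preset's U, so the returned triple is an exact flux fixed point
        (the printed values are rounded to 2-3 significant figures).
        """
        if refit:
            p_na, p_k, p_cl = fit_permeabilities(
                (self.na_i, self.k_i, self.cl_i), MEDIUM_STANDARD,
                self.beta, _GAMMA, self.inc, self.ikc, self.inkcc, self.U,
            )
        else:
            p_na, p_k, p_cl = self.p_na, self.p_k, self.p_cl
        return MembraneParams(
            p_na=p_na, p_k=p_k, p_cl=p_cl, beta=self.beta, gamma=_GAMMA,
            inc=self.inc, ikc=self.ikc, inkcc=self.inkcc,
        )

    def cell_state(self) -> CellState:
        """Measured state normalized to V = 1 ml of initial cell water."""
        return CellState.from_concentrations(
            self.na_i, self.k_i, self.cl_i, self.a_over_v, self.z, v=1.0
        )


def reference_column(cell: str, variant: str) -> Preset:
    """The full preset record for one (cell, variant) parameter column."""
    if cell not in CELLS or variant not in VARIANTS:
        raise KeyError(f"unknown preset ({cell!r}, {variant!r})")
    meas = _MEASURED[cell]
    var = _VARIANTS[(cell, variant)]
    a_over_v, z = impermeant_from_state(
        (meas["na_i"], meas["k_i"], meas["cl_i"]), MEDIUM_STANDARD
    )
    return Preset(
        cell=cell, variant=variant,
        na_i=meas["na_i"], k_i=meas["k_i"], cl_i=meas["cl_i"],
        beta=meas["beta"], osor_measured=meas["osor"],
        inc=var["inc"], ikc=var["ikc"], inkcc=var["inkcc"],
        p_na=var["p_na"], p_k=var["p_k"], p_cl=var["p_cl"], U=var["U"],
        mu_na=var["mu_na"], mu_k=var["mu_k"], mu_cl=var["mu_cl"],
        a_over_v=a_over_v, z=z,
    )


def preset(
    cell: str, variant: str, refit: bool = False
) -> tuple[CellState, MembraneParams, Medium]:
    """Balanced (state, params, medium) triple for one parameter column.

    The printed parameters are verified on load: each ion's total net flux
    must stay below 1% of the largest unidirectional flux, which catches
    transcription errors while tolerating the table's rounding.
    """
    row = reference_column(cell, variant)
    state = row.cell_state()
    params = row.membrane_params(refit=refit)
    check = row.membrane_params(refit=False)
    fb = total_fluxes(state, check, MEDIUM_STANDARD, row.U / 26.7)
    scale = fb.max_unidirectional()
    worst = max(abs(fb.ion_total(ion)) for ion in ("Na", "K", "Cl"))
    if worst > 0.01 * scale:
        raise AssertionError(
            f"preset ({cell}, {variant}) fails flux-balance closure: "
            f"residual {worst:g} vs scale {scale:g}"
        )
    return state, params, MEDIUM_STANDARD


def protocol(figure: str, **options) -> Protocol:
    """Event protocol for one of the computational experiments.

    fig1/fig2 : pump block (beta -> 0 at t = 0) in the standard bath
                (fig2 is run against both the standard and the B=0 bath).
    fig3      : medium -> 160 mOsm (75 mM NaCl removed) at t = 0.
    fig4      : variant 1|2|3 media substitutions (see :func:`fig4_setup`).
    fig6      : iso -> hypo at t = 0, back to the standard bath at 48 min.
    fig7      : NC rate-coefficient step, with or without the osmotic
                transition (options ``inc``, ``with_transition``,
                ``change_at``, ``return_at``).
    fig8      : single parameter step simultaneous with the hypo transition
                (options ``param``, ``value``).

    ``duration``, ``out_dt`` and ``hp`` may be overridden for any figure.
    """
    duration = options.pop("duration", None)
    out_dt = options.pop("out_dt", 1.0)
    hp = options.pop("hp", 1)

    if figure in ("fig1", "fig2"):
        events = (Event(0.0, "set_beta", 0.0),)
        default_dur = 240.0 if figure == "fig1" else 4000.0
    elif figure in ("fig3", "fig5"):
        events = (Event(0.0, "set_medium", MEDIUM_HYPO_160),)
        default_dur = 120.0
    elif figure == "fig4":
        variant = options.pop("variant", 1)
        iso_sucrose, hypo_no_sucrose = sucrose_substituted_media(MEDIUM_STANDARD)
        target = {1: MEDIUM_HYPO_160, 2: iso_sucrose, 3: hypo_no_sucrose}[variant]
        events = (Event(0.0, "set_medium", target),)
        default_dur = 120.0
    elif figure == "fig6":
        return_at = options.pop("return_at", 48.0)
        events = (
            Event(0.0, "set_medium", MEDIUM_HYPO_160),
            Event(return_at, "set_medium", MEDIUM_STANDARD),
        )
        default_dur = 120.0
    elif figure == "fig7":
        inc = options.pop("inc")
        with_transition = options.pop("with_transition", True)
        change_at = options.pop("change_at", 0.0)
        return_at = options.pop("return_at", None)
        evs = []
        if with_transition:
            evs.append(Event(0.0, "set_medium", MEDIUM_HYPO_160))
            if return_at is not None:
                evs.append(Event(return_at, "set_medium", MEDIUM_STANDARD))
        evs.append(Event(change_at, "set_param", ("inc", inc)))
        events = tuple(sorted(evs, key=lambda e: e.time))
        default_dur = 120.0
    elif figure == "fig8":
        name = options.pop("param")
        value = options.pop("value")
        events = (
            Event(0.0, "set_param", (name, value)),
            Event(0.0, "set_medium", MEDIUM_HYPO_160),
        )
        default_dur = 120.0
    else:
        raise KeyError(f"unknown figure protocol {figure!r}")

    if options:
        raise TypeError(f"unknown options for {figure}: {sorted(options)}")
    return Protocol(events=events, duration=duration or default_dur,
                    out_dt=out_dt, hp=hp)


def fig4_setup(
    variant: int, cell: str = "B", dt: float = 0.02
) -> tuple[CellState, MembraneParams, Medium, Protocol]:
    """Initial conditions and protocol for the NaCl-vs-osmolarity experiment.

    Variants 1 and 2 start from the cell balanced with the standard bath and
    switch at t = 0 to the low-NaCl hypoosmolar bath (1) or the isoosmolar
    sucrose-substituted bath (2).  Variant 3 removes 150 mM sucrose without
    any NaCl change, which requires the cell to start balanced in the
    sucrose-containing 310 mOsm bath: that state is produced here by
    pre-equilibrating to flux balance in that bath.
    """
    state, params, medium = preset(cell, "NC+KC+NKCC", refit=True)
    iso_sucrose, hypo_no_sucrose = sucrose_substituted_media(MEDIUM_STANDARD)
    if variant in (1, 2):
        return state, params, medium, protocol("fig4", variant=variant)
    if variant != 3:
        raise KeyError(f"fig4 variant must be 1, 2 or 3, got {variant!r}")
    pre = simulate(
        state, params, iso_sucrose,
        Protocol(events=(), duration=3000.0, out_dt=5.0),
        dt=dt, stop_when_balanced=True,
    )
    start = pre.states[-1]
    proto = Protocol(events=(Event(0.0, "set_medium", hypo_no_sucrose),),
                     duration=120.0)
    return start, params, iso_sucrose, proto


def fig9_runs(cell: str = "B") -> list[dict]:
    """The 24-run scan: each membrane parameter x10 and x0.1, iso and hypo.

    Returns run specifications (initial state, params, medium, protocol);
    each run is meant to be integrated to the balanced-state flag and its
    final volume compared against the unperturbed balanced volume.
    """
    state, params, _ = preset(cell, "NC+KC+NKCC", refit=True)
    runs = []
    for name in ("p_na", "p_k", "p_cl", "inc", "ikc", "inkcc"):
        for factor in (10.0, 0.1):
            value = getattr(params, name) * factor
            for bath, label in ((MEDIUM_STANDARD, "iso"), (MEDIUM_HYPO_160, "hypo")):
                events = [Event(0.0, "set_param", (name, value))]
                if label == "hypo":
                    events.append(Event(0.0, "set_medium", MEDIUM_HYPO_160))
                runs.append(dict(
                    param=name, factor=factor, bath=label,
                    state=state, params=params, medium=MEDIUM_STANDARD,
                    protocol=Protocol(events=tuple(events), duration=6000.0,
                                      out_dt=5.0),
                ))
    return runs
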