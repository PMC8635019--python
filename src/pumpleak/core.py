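"""Domain types, physical constants and standard media for the pump-leak model.

The model treats an animal cell as an electrochemical system: intracellular
Na+, K+ and Cl- exchange with a bath through electroconductive channels, the
Na/K pump and the electroneutral cation-chloride cotransporters NC (1Na:1Cl),
KC (1K:1Cl) and NKCC (1Na:1K:2Cl), while a fixed amount ``A`` of impermeant
intracellular osmolytes of mean charge ``z`` anchors the Donnan effect.

Units used throughout the package
---------------------------------
concentrations        mM  (= umol per ml water)
ion / osmolyte amounts umol per reference unit (e.g. per g cell protein)
cell water volume V   ml per the same reference unit
channel and pump rate coefficients          min^-1
NC / KC cotransport rate coefficients       ml umol^-1 min^-1
NKCC cotransport rate coefficient           ml^3 umol^-3 min^-1
fluxes                umol min^-1 (ml cell water)^-1
membrane potential    dimensionless u; in mV, U = 26.7 * u at 37 C
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "RT_F_MV",
    "PumpLeakError",
    "InvalidMediumError",
    "InfeasibleStateError",
    "InfeasibleParameterError",
    "NoSolutionError",
    "UndefinedPotentialError",
    "ConfigError",
    "Medium",
    "ImpermeantOsmolytes",
    "MembraneParams",
    "CellState",
    "MembranePotential",
    "u_from_mV",
    "mV_from_u",
    "standard_rpmi_medium",
    "hypo_medium_by_nacl_removal",
    "sucrose_substituted_media",
]

#: RT/F at 37 C in mV.  Kept verbatim at the value used to derive every
#: printed potential and electrochemical gradient; never recomputed.
RT_F_MV: float = 26.7


class PumpLeakError(Exception):
    """Base class for all domain errors raised by this package."""


class InvalidMediumError(PumpLeakError, ValueError):
    """A bath composition with a negative concentration."""


class InfeasibleStateError(PumpLeakError, ValueError):
    """A cell state incompatible with osmotic balance or electroneutrality."""


class InfeasibleParameterError(PumpLeakError, ValueError):
    """The inverse problem has no physically admissible (positive) solution."""


class NoSolutionError(PumpLeakError, RuntimeError):
    """A root search failed to bracket or converge."""


class UndefinedPotentialError(PumpLeakError, ValueError):
    """An electrochemical potential requested with a zero concentration."""


class ConfigError(PumpLeakError, ValueError):
    """A configuration file violating the schema."""


def u_from_mV(U: float) -> float:
    """Convert a membrane potential in mV to the dimensionless ``u``."""
    return U / RT_F_MV


def mV_from_u(u: float) -> float:
    """Convert the dimensionless potential ``u`` to mV (``U = 26.7 u``)."""
    return RT_F_MV * u


@dataclass(frozen=True)
class MembranePotential:
    """Membrane potential carried in both forms, ``U = 26.7 * u`` exactly."""

    u: float

    @property
    def U(self) -> float:
        return mV_from_u(self.u)

    @classmethod
    def from_mV(cls, U: float) -> "MembranePotential":
        return cls(u_from_mV(U))


@dataclass(frozen=True)
class Medium:
    """Extracellular bath composition in mM.

    ``b_o`` lumps all membrane-impermeant non-electrolytes (mannitol, sucrose,
    the non-ionic fraction of a culture medium ...).  It enters the osmotic
    balance only; external electroneutrality is not modelled.
    """

    na_o: float
    k_o: float
    cl_o: float
    b_o: float = 0.0

    def __post_init__(self) -> None:
        for name in ("na_o", "k_o", "cl_o", "b_o"):
            if getattr(self, name) < 0:
                raise InvalidMediumError(
                    f"medium concentration {name} must be >= 0, "
                    f"got {getattr(self, name)!r}"
                )

    def osmolarity(self) -> float:
        """Total bath osmolarity, mM (sum of the four constituents)."""
        return self.na_o + self.k_o + self.cl_o + self.b_o


def standard_rpmi_medium() -> Medium:
    """The standard 310 mOsm RPMI-like bath: Na 140, K 5.8, Cl 116, B 48.2."""
    return Medium(na_o=140.0, k_o=5.8, cl_o=116.0, b_o=48.2)


def hypo_medium_by_nacl_removal(base: Medium, delta_nacl: float) -> Medium:
    """Bath with ``delta_nacl`` mM NaCl removed (Na and Cl each reduced).

    The usual way a hypoosmolar experimental medium is prepared; removing
    75 mM NaCl from the standard 310 mOsm bath gives 160 mOsm.
    """
    if delta_nacl > min(base.na_o, base.cl_o):
        raise InvalidMediumError(
            f"cannot remove {delta_nacl} mM NaCl from "
            f"(Na {base.na_o}, Cl {base.cl_o}) mM"
        )
    return Medium(
        na_o=base.na_o - delta_nacl,
        k_o=base.k_o,
        cl_o=base.cl_o - delta_nacl,
        b_o=base.b_o,
    )


def sucrose_substituted_media(base: Medium) -> tuple[Medium, Medium]:
    """The two sucrose-substitution baths derived from the standard medium.

    Returns ``(iso_sucrose, hypo_no_sucrose)``: 75 mM NaCl is replaced by
    150 mM sucrose (isoosmolar, 310 mOsm), and the second bath is the first
    minus the 150 mM sucrose (hypoosmolar, 160 mOsm).  Together with plain
    NaCl removal these separate the response to reduced NaCl from the
    response to reduced osmolarity.
    """
    low_nacl = hypo_medium_by_nacl_removal(base, 75.0)
    iso_sucrose = replace(low_nacl, b_o=low_nacl.b_o + 150.0)
    return iso_sucrose, low_nacl


@dataclass(frozen=True)
class ImpermeantOsmolytes:
    """Intracellular impermeant osmolytes: amount ``a`` and mean charge ``z``.

    ``a`` is in umol per reference unit; ``z`` is dimensionless and negative
    in all physiological cases considered here.  Both are constant over any
    simulation — the model never transports A.
    """

    a: float
    z: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise InfeasibleStateError(f"impermeant amount a must be > 0, got {self.a!r}")


@dataclass(frozen=True)
class MembraneParams:
    """Rate coefficients of the membrane pathways.

    A cotransporter absent from a model variant is encoded by a zero
    coefficient.  ``kb`` describes an optional linear decay of the pump rate
    coefficient with time: effective beta(t) = max(0, beta - kb*t).
    """

    p_na: float
    p_k: float
    p_cl: float
    beta: float
    gamma: float = 1.5
    inc: float = 0.0
    ikc: float = 0.0
    inkcc: float = 0.0
    kb: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_na", "p_k", "p_cl", "beta", "inc", "ikc", "inkcc", "kb"):
            if getattr(self, name) < 0:
                raise InfeasibleParameterError(
                    f"rate coefficient {name} must be >= 0, got {getattr(self, name)!r}"
                )
        if self.gamma <= 1:
            raise InfeasibleParameterError(
                f"pump stoichiometry gamma must be > 1, got {self.gamma!r}"
            )


@dataclass(frozen=True)
class CellState:
    """Intracellular state: ion amounts, water volume and impermeant osmolytes.

    Amounts are per the same abstract reference unit as ``osmolytes.a``
    (presets use 1 ml of initial cell water so that contents equal the
    measured concentrations).  Concentrations are derived: [X]i = X/V.
    """

    na_content: float
    k_content: float
    cl_content: float
    v: float
    osmolytes: ImpermeantOsmolytes

    def __post_init__(self) -> None:
        if self.v <= 0:
            raise InfeasibleStateError(f"cell water volume must be > 0, got {self.v!r}")
        for name in ("na_content", "k_content", "cl_content"):
            if getattr(self, name) < 0:
                raise InfeasibleStateError(
                    f"ion content {name} must be >= 0, got {getattr(self, name)!r}"
                )

    @classmethod
    def from_concentrations(
        cls,
        na_i: float,
        k_i: float,
        cl_i: float,
        a_over_v: float,
        z: float,
        v: float = 1.0,
    ) -> "CellState":
        """Build a state from concentrations (mM) and A/V (mM) at volume ``v``."""
        return cls(
            na_content=na_i * v,
            k_content=k_i * v,
            cl_content=cl_i * v,
            v=v,
            osmolytes=ImpermeantOsmolytes(a=a_over_v * v, z=z),
        )

    @property
    def na_i(self) -> float:
        return self.na_content / self.v

    @property
    def k_i(self) -> float:
        return self.k_content / self.v

    @property
    def cl_i(self) -> float:
        return self.cl_content / self.v

    @property
    def a_over_v(self) -> float:
        """Concentration of impermeant osmolytes in cell water, mM."""
        return self.osmolytes.a / self.v

    def concentrations(self) -> tuple[float, float, float]:
        """(Na, K, Cl) intracellular concentrations, mM."""
        return (self.na_i, self.k_i, self.cl_i)

    def electroneutrality_residual(self) -> float:
        """[Na]i + [K]i - [Cl]i + z*A/V; zero for an electroneutral cytoplasm."""
        return self.na_i + self.k_i - self.cl_i + self.osmolytes.z * self.a_over_v

    def osmolarity(self) -> float:
        """Total intracellular osmolarity [Na]i + [K]i + [Cl]i + A/V, mM."""
        return self.na_i + self.k_i + self.cl_i + self.a_over_v
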