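"""Config parsing/serialisation and tabular writers.

Configs are single TOML files with sections ``medium``, ``cell``, ``params``
and optionally ``closure`` (for the inverse solver: either ``U`` in mV or
``osor``) and ``protocol`` (duration/out_dt/hp plus ``[[protocol.events]]``
tables).  Unknown keys are rejected.  All trajectory/flux output is TSV with
units spelled out in the headers.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import pandas as pd

from .core import CellState, ConfigError, Medium, MembraneParams, PumpLeakError
from .dynamics import Event, Protocol, Trajectory
from .equilibrium import impermeant_from_state

__all__ = ["ParsedConfig", "parse_config", "write_config",
           "write_trajectory", "write_flux_table"]

_MEDIUM_KEYS = {"na_o", "k_o", "cl_o", "b_o"}
_CELL_KEYS = {"na_i", "k_i", "cl_i", "v", "a_over_v", "z"}
_PARAM_KEYS = {"p_na", "p_k", "p_cl", "beta", "gamma", "inc", "ikc", "inkcc", "kb"}
_CLOSURE_KEYS = {"U", "osor"}
_PROTOCOL_KEYS = {"duration", "out_dt", "hp", "events"}
_EVENT_KEYS = {"time", "action", "value", "param"}


@dataclass(frozen=True)
class ParsedConfig:
    """Typed objects read from one config file."""

    medium: Medium
    state: CellState
    params: MembraneParams | None
    closure: dict[str, float]
    protocol: Protocol | None
    raw_params: dict[str, float]


def _check_keys(section: dict, allowed: set[str], name: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in [{name}]; allowed: {sorted(allowed)}"
        )


def _event_from_table(tbl: dict, media_ok: bool = True) -> Event:
    _check_keys(tbl, _EVENT_KEYS, "protocol.events")
    action = tbl.get("action")
    value: Any = tbl.get("value")
    if action == "set_medium":
        if not isinstance(value, dict):
            raise ConfigError("set_medium event needs a table value {na_o=..,...}")
        _check_keys(value, _MEDIUM_KEYS, "event.value")
        value = Medium(**value)
    elif action == "set_param":
        if "param" not in tbl:
            raise ConfigError("set_param event needs a 'param' name")
        if tbl["param"] not in _PARAM_KEYS:
            raise ConfigError(f"unknown parameter {tbl['param']!r} in set_param event")
        value = (tbl["param"], float(value))
    elif action in ("set_beta", "set_kb", "scale_osmolarity"):
        value = float(value)
    else:
        raise ConfigError(f"unknown event action {action!r}")
    try:
        return Event(time=float(tbl["time"]), action=action, value=value)
    except KeyError as exc:
        raise ConfigError(f"event missing required key {exc}") from exc


def parse_config(path: str | Path) -> ParsedConfig:
    """Read and validate one TOML config into typed model objects.

    ``[cell]`` may give ``a_over_v``/``z`` explicitly; otherwise they are
    inferred from the concentrations and the medium.  ``[params]`` may omit
    the channel permeabilities when the file is meant for the inverse solver
    (``balance``); then ``params`` is None and ``raw_params`` carries the
    pump/cotransporter coefficients.
    """
    path = Path(path)
    with path.open("rb") as fh:
        try:
            doc = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"{path}: invalid TOML: {exc}") from exc

    _check_keys(doc, {"medium", "cell", "params", "closure", "protocol"}, "root")
    for required in ("medium", "cell"):
        if required not in doc:
            raise ConfigError(f"{path}: missing required section [{required}]")

    _check_keys(doc["medium"], _MEDIUM_KEYS, "medium")
    try:
        medium = Medium(**doc["medium"])
    except (TypeError, PumpLeakError) as exc:
        raise ConfigError(f"[medium]: {exc}") from exc

    cell = dict(doc["cell"])
    _check_keys(cell, _CELL_KEYS, "cell")
    try:
        conc = (float(cell["na_i"]), float(cell["k_i"]), float(cell["cl_i"]))
    except KeyError as exc:
        raise ConfigError(f"[cell] missing concentration {exc}") from exc
    if "a_over_v" in cell and "z" in cell:
        a_over_v, z = float(cell["a_over_v"]), float(cell["z"])
    else:
        a_over_v, z = impermeant_from_state(conc, medium)
    try:
        state = CellState.from_concentrations(
            *conc, a_over_v, z, v=float(cell.get("v", 1.0))
        )
    except PumpLeakError as exc:
        raise ConfigError(f"[cell]: {exc}") from exc

    raw_params = dict(doc.get("params", {}))
    _check_keys(raw_params, _PARAM_KEYS, "params")
    params: MembraneParams | None = None
    if {"p_na", "p_k", "p_cl"} <= set(raw_params):
        try:
            params = MembraneParams(**raw_params)
        except (TypeError, PumpLeakError) as exc:
            raise ConfigError(f"[params]: {exc}") from exc

    closure = dict(doc.get("closure", {}))
    _check_keys(closure, _CLOSURE_KEYS, "closure")
    closure = {k: float(v) for k, v in closure.items()}

    protocol = None
    if "protocol" in doc:
        proto = dict(doc["protocol"])
        _check_keys(proto, _PROTOCOL_KEYS, "protocol")
        events = tuple(_event_from_table(t) for t in proto.get("events", []))
        try:
            protocol = Protocol(
                events=events,
                duration=float(proto.get("duration", 240.0)),
                out_dt=float(proto.get("out_dt", 1.0)),
                hp=int(proto.get("hp", 1)),
            )
        except ValueError as exc:
            raise ConfigError(f"[protocol]: {exc}") from exc

    return ParsedConfig(medium=medium, state=state, params=params,
                        closure=closure, protocol=protocol,
                        raw_params={k: float(v) for k, v in raw_params.items()})


def _toml_value(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int,)):
        return str(v)
    if isinstance(v, float):
        return repr(v)
    if isinstance(v, str):
        return f'"{v}"'
    raise TypeError(f"cannot serialise {v!r}")


def write_config(cfg: ParsedConfig, path: str | Path) -> None:
    """Serialise a ParsedConfig back to TOML (lossless round trip)."""
    lines: list[str] = ["[medium]"]
    m = cfg.medium
    for k in ("na_o", "k_o", "cl_o", "b_o"):
        lines.append(f"{k} = {_toml_value(getattr(m, k))}")
    s = cfg.state
    lines += ["", "[cell]"]
    for k, v in (("na_i", s.na_i), ("k_i", s.k_i), ("cl_i", s.cl_i),
                 ("v", s.v), ("a_over_v", s.a_over_v), ("z", s.osmolytes.z)):
        lines.append(f"{k} = {_toml_value(float(v))}")
    if cfg.raw_params:
        lines += ["", "[params]"]
        for k in sorted(cfg.raw_params):
            lines.append(f"{k} = {_toml_value(cfg.raw_params[k])}")
    if cfg.closure:
        lines += ["", "[closure]"]
        for k in sorted(cfg.closure):
            lines.append(f"{k} = {_toml_value(cfg.closure[k])}")
    if cfg.protocol is not None:
        p = cfg.protocol
        lines += ["", "[protocol]",
                  f"duration = {_toml_value(float(p.duration))}",
                  f"out_dt = {_toml_value(float(p.out_dt))}",
                  f"hp = {_toml_value(int(p.hp))}"]
        for ev in p.events:
            lines += ["", "[[protocol.events]]",
                      f"time = {_toml_value(float(ev.time))}",
                      f'action = "{ev.action}"']
            if ev.action == "set_medium":
                vals = ", ".join(
                    f"{k} = {_toml_value(getattr(ev.value, k))}"
                    for k in ("na_o", "k_o", "cl_o", "b_o"))
                lines.append(f"value = {{ {vals} }}")
            elif ev.action == "set_param":
                lines.append(f'param = "{ev.value[0]}"')
                lines.append(f"value = {_toml_value(float(ev.value[1]))}")
            else:
                lines.append(f"value = {_toml_value(float(ev.value))}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_trajectory(
    trajectory: Trajectory,
    path: str | Path,
    a_mmol_per_g_protein: float | None = None,
) -> None:
    """TSV time course: V/A, water, U and concentrations with explicit units."""
    frame = trajectory.to_frame(a_mmol_per_g_protein)
    frame.to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_flux_table(table: pd.DataFrame, path: str | Path) -> None:
    """TSV flux table in the (time, pathway, ion, influx, efflux, net) layout."""
    table.to_csv(path, sep="\t", index=False, float_format="%.8g")
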