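"""File formats and run configuration.

CSV conventions: UTF-8, '.' decimal separator, '#'-prefixed comment lines.
Every file written here embeds the package version, a configuration hash
and the seed in its comment header (CSV) or top-level fields (JSON), so
any artifact can be traced back to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import deb
from .efficiency import Indicators, MassBalanceLedger
from .observations import ObservationSeries

__all__ = [
    "RunConfig",
    "read_observations",
    "write_observations",
    "read_ledger",
    "write_ledger",
    "write_indicators",
    "write_trajectory",
    "write_json",
    "config_hash",
    "load_config",
    "ParseError",
]

OBS_REQUIRED = ("t_d", "x_dw_mg")
OBS_OPTIONAL = ("rco2_mgco2_d", "ltot_mg", "delta_lipid", "delta_dw")


class ParseError(ValueError):
    """Input file violates the documented schema."""


class ParamsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    a_max: float = 1.2
    Y: float = 0.44
    m: float = 0.08
    s_max: float = 0.8
    x5: float = 0.6
    k_B: float = 12.0
    x_A: float = 0.78
    k_A: float = 10.0
    Y_L: float = 0.38
    f_C: float = 0.49
    h: float = 2.33


class ScenarioConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    Xmax: float = 30.0
    X0: float = 0.06
    t0: float = 0.0
    t_end: float = 40.0
    harvest_rule: str = "at-prepupation"
    L0: float = 0.0


class NoiseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cv_weight: float = 0.0
    sd_co2: float = 0.0


class RearingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_larvae: int = 100
    W_DW0: float = 40000.0
    AD: float = 0.8
    mu_mic: float = 0.02


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    model: str = Field(default="deb", pattern="^(deb|logistic)$")
    params: ParamsConfig = Field(default_factory=ParamsConfig)
    scenario: ScenarioConfig = Field(default_factory=ScenarioConfig)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    rearing: RearingConfig = Field(default_factory=RearingConfig)
    seed: int = 0
    verbosity: int = 1

    def deb_params(self) -> deb.DebParams:
        return deb.DebParams(**self.params.model_dump())

    def deb_scenario(self) -> deb.Scenario:
        return deb.Scenario(**self.scenario.model_dump())


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from YAML or JSON, validating against the schema."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") \
        else json.loads(text)
    return RunConfig.model_validate(data)


def config_hash(obj) -> str:
    """Short stable hash of a config / params object for provenance."""
    if isinstance(obj, BaseModel):
        payload = obj.model_dump()
    elif is_dataclass(obj) and not isinstance(obj, type):
        payload = asdict(obj)
    else:
        payload = obj
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(seed=None, cfg_hash=None) -> str:
    from . import __version__
    lines = [f"# bsfdeb v{__version__}"]
    if cfg_hash is not None:
        lines.append(f"# config_hash: {cfg_hash}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    return "\n".join(lines) + "\n"


def read_observations(path: str | Path) -> ObservationSeries:
    """Read an observation-series CSV.

    Required columns: ``t_d`` (age, days) and ``x_dw_mg`` (dry weight per
    larva, mg).  Optional: ``rco2_mgco2_d``, ``ltot_mg``, ``delta_lipid``,
    ``delta_dw``.  Time must be strictly increasing and masses
    non-negative; violations raise :class:`ParseError` naming the row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse CSV: {exc}") from exc
    for col in OBS_REQUIRED:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    t = df["t_d"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if len(bad):
        raise ParseError(f"{path}: time not strictly increasing at data "
                         f"row {bad[0] + 2} (t_d={t[bad[0] + 1]})")
    for col in ("x_dw_mg", "ltot_mg"):
        if col in df.columns:
            v = df[col].to_numpy(dtype=float)
            neg = np.nonzero(v < 0)[0]
            if len(neg):
                raise ParseError(f"{path}: negative {col} at data row "
                                 f"{neg[0] + 2}")
    return ObservationSeries(
        t=t,
        X_DW=df["x_dw_mg"].to_numpy(dtype=float),
        r_CO2=df["rco2_mgco2_d"].to_numpy(dtype=float)
        if "rco2_mgco2_d" in df.columns else None,
        L_tot=df["ltot_mg"].to_numpy(dtype=float)
        if "ltot_mg" in df.columns else None,
        delta_lipid=df["delta_lipid"].to_numpy(dtype=float)
        if "delta_lipid" in df.columns else None,
        delta_DW=df["delta_dw"].to_numpy(dtype=float)
        if "delta_dw" in df.columns else None,
        meta={"path": str(path)})


def write_observations(obs: ObservationSeries, path: str | Path, *,
                       seed=None, cfg_hash=None) -> None:
    cols = {"t_d": obs.t, "x_dw_mg": obs.X_DW}
    for col, attr in (("rco2_mgco2_d", "r_CO2"), ("ltot_mg", "L_tot"),
                      ("delta_lipid", "delta_lipid"),
                      ("delta_dw", "delta_DW")):
        v = getattr(obs, attr)
        if v is not None:
            cols[col] = v
    _write_csv(pd.DataFrame(cols), path, seed=seed, cfg_hash=cfg_hash)


def read_ledger(path: str | Path) -> list[MassBalanceLedger]:
    """Read mass-balance ledgers (columns x_dw0, x_dw, w_dw0, w_dw_res)."""
    df = pd.read_csv(Path(path), comment="#")
    req = ("x_dw0", "x_dw", "w_dw0", "w_dw_res")
    for col in req:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    return [MassBalanceLedger(X_DW0=r.x_dw0, X_DW=r.x_dw, W_DW0=r.w_dw0,
                              W_DW_res=r.w_dw_res)
            for r in df.itertuples()]


def write_ledger(ledgers, path: str | Path, *, seed=None,
                 cfg_hash=None) -> None:
    if isinstance(ledgers, MassBalanceLedger):
        ledgers = [ledgers]
    df = pd.DataFrame([{"x_dw0": l.X_DW0, "x_dw": l.X_DW,
                        "w_dw0": l.W_DW0, "w_dw_res": l.W_DW_res}
                       for l in ledgers])
    _write_csv(df, path, seed=seed, cfg_hash=cfg_hash)


def write_indicators(rows: list[Indicators], path: str | Path, *,
                     seed=None, cfg_hash=None) -> None:
    df = pd.DataFrame([{"br": r.BR, "sce": r.SCE, "scr": r.SCR,
                        "srr": r.SRR,
                        "inconsistent": r.inconsistent} for r in rows])
    _write_csv(df, path, seed=seed, cfg_hash=cfg_hash)


def write_trajectory(traj: deb.Trajectory, path: str | Path, *,
                     seed=None, cfg_hash=None) -> None:
    obs = deb.predict_observables(traj)
    df = pd.DataFrame({
        "t_d": traj.t, "B_mgC": traj.B, "L_mgC": traj.L,
        "X_DW_mg": obs["X_DW"], "rCO2_mgCO2_per_d": obs["r_CO2"],
        "L_tot_mg": obs["L_tot"], "delta_lipid": obs["delta_lipid"],
        "delta_DW": obs["delta_DW"],
        "stage": [s.value for s in traj.stage]})
    _write_csv(df, path, seed=seed, cfg_hash=cfg_hash)


def _write_csv(df: pd.DataFrame, path: str | Path, *, seed=None,
               cfg_hash=None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header_lines(seed=seed, cfg_hash=cfg_hash))
        df.to_csv(fh, index=False, float_format="%.17g")


def write_json(payload: dict, path: str | Path, *, seed=None,
               cfg_hash=None) -> None:
    from . import __version__
    out = {"bsfdeb_version": __version__}
    if cfg_hash is not None:
        out["config_hash"] = cfg_hash
    if seed is not None:
        out["seed"] = seed
    out.update(payload)
    Path(path).write_text(json.dumps(out, indent=2, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if is_dataclass(obj) and not isinstance(obj, type):
        return asdict(obj)
    return str(obj)
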