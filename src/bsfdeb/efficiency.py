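"""Net growth efficiency and mass-balance performance indicators.

Two families of feed-efficiency measures are computed here.

*Net growth efficiency* (NGE) is a metabolic measure: the instantaneous
ratio of carbon built into larval biomass to carbon assimilated,
``NGE = r_X / r_A``, and its lifetime average
``NGE_avg = (X - X0) / A`` where ``A`` is the cumulative assimilated
carbon.  It depends only on larval metabolism, not on what happens in the
substrate, and in a variable-composition (structure + lipid) model it is
written NGE* to flag that carbon and energy need not be conserved with the
same efficiency.

*Mass-balance indicators* are process measures obtained by weighing larvae
and substrate before and after rearing: bioconversion rate
``BR = dX_DW / W_DW0``, substrate conversion efficiency
``SCE = dX_DW / (-dW_DW)``, its inverse the substrate conversion ratio
``SCR``, and the substrate reduction rate ``SRR = -dW_DW / W_DW0``.  They
satisfy ``BR = SCE * SRR`` and ``SCR = 1 / SCE`` identically.  Because
substrate is also removed by microbes and lost as frass, SCE is bounded
above by the larval NGE_avg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .deb import Trajectory

__all__ = [
    "MassBalanceLedger",
    "Indicators",
    "EfficiencyResult",
    "UndefinedRatioError",
    "nge_instantaneous",
    "nge_average",
    "indicators_from_ledger",
    "complete_indicators",
    "table_summary",
    "load_reference_indicators",
]

#: absolute tolerance when cross-checking 2-decimal literature indicators
IDENTITY_TOL = 0.02

INDICATOR_NAMES = ("BR", "SCE", "SCR", "SRR")


class UndefinedRatioError(ZeroDivisionError):
    """A performance ratio was requested with a zero denominator."""


@dataclass(frozen=True)
class MassBalanceLedger:
    """Dry-weight bookkeeping of one rearing experiment.

    ``X_DW0`` / ``X_DW``: total larval dry weight at start and harvest;
    ``W_DW0``: supplied substrate dry weight; ``W_DW_res``: residual
    substrate plus frass at harvest.  Any single mass unit may be used, but
    it must be consistent within the ledger.
    """

    X_DW0: float
    X_DW: float
    W_DW0: float
    W_DW_res: float

    def __post_init__(self) -> None:
        for name in ("X_DW0", "X_DW", "W_DW0", "W_DW_res"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def dX_DW(self) -> float:
        """Larval dry-weight gain."""
        return self.X_DW - self.X_DW0

    @property
    def dW_DW(self) -> float:
        """Substrate dry-weight change (negative when substrate is removed)."""
        return self.W_DW_res - self.W_DW0


@dataclass
class Indicators:
    """The four performance indicators; ``None`` marks an absent value.

    ``provenance`` records per field whether the value was measured (taken
    from a ledger or a study) or derived from the algebraic identities.
    ``inconsistent`` is set when independent routes to the same indicator
    disagree by more than ``IDENTITY_TOL``.
    """

    BR: float | None = None
    SCE: float | None = None
    SCR: float | None = None
    SRR: float | None = None
    provenance: dict = field(default_factory=dict)
    inconsistent: bool = False

    def present(self) -> dict:
        return {k: getattr(self, k) for k in INDICATOR_NAMES
                if getattr(self, k) is not None}


@dataclass
class EfficiencyResult:
    """Average net growth efficiency over [t0, t_harvest] plus the
    instantaneous NGE series on the trajectory grid."""

    nge_avg: float
    nge_series: np.ndarray  # NaN where r_A = 0 (prepupal phase)
    t: np.ndarray
    t0: float
    t_harvest: float


def nge_instantaneous(r_X: float, r_A: float) -> float:
    """Instantaneous net growth efficiency r_X / r_A.

    For the two-compartment model r_X means r_B + r_L.  A zero assimilation
    rate makes the ratio undefined and raises rather than returning 0.
    """
    if r_A == 0:
        raise UndefinedRatioError("NGE undefined at zero assimilation rate")
    return r_X / r_A


def nge_average(traj: Trajectory, t0: float | None = None,
                t_harvest: float | None = None) -> EfficiencyResult:
    """Lifetime-average net growth efficiency of a simulated trajectory.

    ``nge_avg = (X(t_harvest) - X(t0)) / (A(t_harvest) - A(t0))`` in carbon
    equivalents.  Defaults: t0 is the scenario start, t_harvest follows the
    scenario's harvest rule (prepupation time when available).  Values
    outside (0, 1) are possible (e.g. harvest deep in the prepupal phase)
    and are reported with a warning, not clamped.
    """
    t0 = traj.scenario.t0 if t0 is None else t0
    t_harvest = traj.t_harvest if t_harvest is None else t_harvest
    if not t0 < t_harvest:
        raise ValueError("require t0 < t_harvest")
    B0, L0, A0, _ = traj.interp(t0)
    Bh, Lh, Ah, _ = traj.interp(t_harvest)
    if Ah - A0 <= 0:
        raise UndefinedRatioError("no assimilation in the averaging window")
    nge_avg = ((Bh + Lh) - (B0 + L0)) / (Ah - A0)
    if not 0 < nge_avg < 1:
        warnings.warn(f"NGE*_avg = {nge_avg:.3f} outside (0, 1); "
                      "check the harvest window", stacklevel=2)
    series = np.array([f.r_X / f.r_A if f.r_A > 0 else np.nan
                       for f in traj.fluxes])
    return EfficiencyResult(nge_avg=float(nge_avg), nge_series=series,
                            t=traj.t.copy(), t0=t0, t_harvest=t_harvest)


def indicators_from_ledger(ledger: MassBalanceLedger) -> Indicators:
    """Compute BR, SCE, SCR, SRR from a mass-balance ledger.

    Indicators whose denominator vanishes (no growth, or no substrate
    removed) are left absent and marked 'undefined' in the provenance.
    """
    if ledger.W_DW0 <= 0:
        raise UndefinedRatioError("W_DW0 must be positive")
    dX = ledger.dX_DW
    removed = -ledger.dW_DW
    ind = Indicators()
    ind.BR = dX / ledger.W_DW0
    ind.SRR = removed / ledger.W_DW0
    ind.provenance = {"BR": "measured", "SRR": "measured"}
    if removed > 0:
        ind.SCE = dX / removed
        ind.provenance["SCE"] = "measured"
        if dX > 0:
            ind.SCR = removed / dX
            ind.provenance["SCR"] = "measured"
        else:
            ind.provenance["SCR"] = "undefined"
    else:
        ind.provenance["SCE"] = "undefined"
        ind.provenance["SCR"] = "undefined"
    return ind


class CannotCompleteError(ValueError):
    """Not enough indicator fields to apply the completion identities."""


def complete_indicators(partial: Indicators) -> Indicators:
    """Fill missing indicators using SCE = 1/SCR and SCE = BR/SRR.

    Newly filled fields are marked 'derived-from-identity'.  When several
    routes yield the same indicator, disagreement beyond ``IDENTITY_TOL``
    sets the ``inconsistent`` flag.  Idempotent: completing a completed
    record changes nothing.
    """
    vals = {k: getattr(partial, k) for k in INDICATOR_NAMES}
    prov = dict(partial.provenance)
    for k, v in vals.items():
        if v is not None and k not in prov:
            prov[k] = "measured"
    inconsistent = partial.inconsistent

    def candidates(target, v):
        """All routes to `target` from currently known values."""
        out = []
        if target == "SCE":
            if v["SCR"] not in (None, 0):
                out.append(1.0 / v["SCR"])
            if v["BR"] is not None and v["SRR"] not in (None, 0):
                out.append(v["BR"] / v["SRR"])
        elif target == "SCR":
            if v["SCE"] not in (None, 0):
                out.append(1.0 / v["SCE"])
            if v["BR"] not in (None, 0) and v["SRR"] is not None:
                out.append(v["SRR"] / v["BR"])
        elif target == "BR":
            if v["SCE"] is not None and v["SRR"] is not None:
                out.append(v["SCE"] * v["SRR"])
        elif target == "SRR":
            if v["SCE"] not in (None, 0) and v["BR"] is not None:
                out.append(v["BR"] / v["SCE"])
        return out

    if all(v is None for v in vals.values()) or (
            vals["SCE"] is None and vals["SCR"] is None
            and not (vals["BR"] is not None and vals["SRR"] is not None)):
        raise CannotCompleteError(
            "need SCE, SCR, or the pair (BR, SRR) to complete indicators")

    changed = True
    while changed:
        changed = False
        for k in INDICATOR_NAMES:
            cands = candidates(k, vals)
            if vals[k] is not None:
                # cross-check measured/previously derived values
                scale = 1.0 if k != "SCR" else max(abs(vals[k]), 1.0)
                if any(abs(c - vals[k]) > IDENTITY_TOL * scale
                       for c in cands):
                    inconsistent = True
                continue
            if cands:
                if (max(cands) - min(cands)) > IDENTITY_TOL:
                    inconsistent = True
                vals[k] = float(np.mean(cands))
                prov[k] = "derived-from-identity"
                changed = True

    return Indicators(**vals, provenance=prov, inconsistent=inconsistent)


def table_summary(rows: list[Indicators]) -> dict:
    """Per-indicator min / max / count over a list of records, ignoring
    absent fields.  Indicators absent everywhere are marked absent."""
    if not rows:
        raise ValueError("empty indicator list")
    out = {}
    for k in INDICATOR_NAMES:
        vals = [getattr(r, k) for r in rows if getattr(r, k) is not None]
        if vals:
            out[k] = {"min": min(vals), "max": max(vals), "n": len(vals)}
        else:
            out[k] = {"min": None, "max": None, "n": 0}
    return out


def load_reference_indicators(as_frame: bool = False):
    """Packaged literature compilation of chicken-feed performance
    indicators (12 studies).  Returns a list of :class:`Indicators`, or the
    raw :class:`pandas.DataFrame` when ``as_frame`` is true."""
    with resources.files("bsfdeb.data").joinpath(
            "chicken_feed_indicators.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    if as_frame:
        return df
    rows = []
    for _, r in df.iterrows():
        kwargs = {}
        prov = {}
        derived = set(str(r.get("derived", "")).split(";")) \
            if pd.notna(r.get("derived")) else set()
        for col, key in (("br", "BR"), ("sce", "SCE"),
                         ("scr", "SCR"), ("srr", "SRR")):
            if pd.notna(r[col]):
                kwargs[key] = float(r[col])
                prov[key] = ("derived-from-identity" if col in derived
                             else "measured")
        rows.append(Indicators(**kwargs, provenance=prov))
    return rows
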