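"""Two-compartment dynamic energy-budget model of black soldier fly larvae.

The larva is resolved into structural biomass ``B`` (tissue except storage
fat) and storage lipid ``L``, both in mg carbon.  Two rate-limiting flows
drive the budget:

* feed assimilation, with a specific rate that starts at ``a_max`` in newly
  hatched larvae and declines logistically to ~0 as the larva approaches its
  maximal weight, and
* structural growth, whose specific rate stays near-constant through the
  first half of the lifespan and declines logistically only once the larva
  reaches its final instar.

Assimilated carbon pays maintenance first, then structural synthesis (with a
growth cost ``Y``: mg C respired per mg C incorporated), and any excess
overflows into storage lipid.  Because lipid is more reduced than feed,
lipid synthesis releases CO2 at a cost ``Y_L`` to keep the redox balance
neutral.  When assimilation effectively stops, the larva becomes a prepupa:
feeding and growth cease and maintenance is paid by remobilising lipid, so
the animal loses weight.

All masses are carbon equivalents (mg C); feed, tissue and lipid are assumed
to share a common elemental composition, so efficiency ratios are invariant
to the carbon fraction used for the dry-weight observables.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "DebParams",
    "Scenario",
    "Stage",
    "LarvalState",
    "FluxRecord",
    "Trajectory",
    "specific_assimilation",
    "structural_demand",
    "partition_fluxes",
    "prepupal_step",
    "simulate_deb",
    "predict_observables",
    "SimulationError",
]

CO2_PER_C = 44.0 / 12.0  # mg CO2 per mg C


class SimulationError(RuntimeError):
    """Integrator failure; carries the last valid state when available."""

    def __init__(self, message: str, last_state: "LarvalState | None" = None):
        super().__init__(message)
        self.last_state = last_state


@dataclass(frozen=True)
class DebParams:
    """Parameters of the dynamic energy-budget model.

    The three fitted constants are ``a_max`` (maximal specific feed
    assimilation rate, 1/day), ``Y`` (cost of growth: mg C respired per mg C
    built into structure) and ``m`` (maintenance coefficient, mg C respired
    per mg C larva per day).  The remaining fields are reconstruction
    constants fixing the shapes of the two logistic rate declines, the lipid
    synthesis cost and the observable conversions; they are held fixed
    during fitting by default.
    """

    a_max: float = 1.2
    Y: float = 0.44
    m: float = 0.08
    s_max: float = 0.8  # maximal specific structural growth rate, 1/day
    x5: float = 0.6     # X/Xmax midpoint of the instar-5 growth decline
    k_B: float = 12.0   # steepness of the structural decline
    x_A: float = 0.78   # X/Xmax midpoint of the assimilation decline
    k_A: float = 10.0   # steepness of the assimilation decline
    Y_L: float = 0.38   # cost of lipid synthesis (redox balancing CO2)
    f_C: float = 0.49   # carbon fraction of dry weight
    h: float = 2.33     # water mass bound per unit structural dry mass

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a_max) and self.a_max > 0):
            raise ValueError("a_max must be positive and finite")
        if self.Y < 0 or self.Y_L < 0:
            raise ValueError("growth and lipid costs must be >= 0")
        if self.m < 0:
            raise ValueError("maintenance coefficient m must be >= 0")
        if self.s_max <= 0:
            raise ValueError("s_max must be positive")
        if not (0 < self.x5 <= 1 and 0 < self.x_A <= 1.2):
            raise ValueError("logistic midpoints x5, x_A out of range")
        if self.k_A <= 0 or self.k_B <= 0:
            raise ValueError("logistic steepness k_A, k_B must be positive")
        if not 0 < self.f_C < 1:
            raise ValueError("carbon fraction f_C must be in (0, 1)")
        if self.h < 0:
            raise ValueError("hydration ratio h must be >= 0")


@dataclass(frozen=True)
class Scenario:
    """Rearing scenario: size scale, start state and harvest rule.

    ``X0``/``Xmax`` are in mg C.  ``harvest_rule`` is either
    ``"at-prepupation"`` (harvest when feeding stops) or ``"fixed-time"``
    (harvest at ``t_end``).
    """

    Xmax: float = 30.0
    X0: float = 0.06
    t0: float = 0.0
    t_end: float = 40.0
    harvest_rule: str = "at-prepupation"
    L0: float = 0.0  # young larvae treated as lean by default

    def __post_init__(self) -> None:
        if not 0 < self.X0 < self.Xmax:
            raise ValueError("require 0 < X0 < Xmax")
        if not self.t0 < self.t_end:
            raise ValueError("require t0 < t_end")
        if self.harvest_rule not in ("at-prepupation", "fixed-time"):
            raise ValueError(f"unknown harvest rule {self.harvest_rule!r}")
        if self.L0 < 0 or self.L0 >= self.X0:
            raise ValueError("require 0 <= L0 < X0")


class Stage(str, Enum):
    LARVA = "larva"
    PREPUPA = "prepupa"


@dataclass(frozen=True)
class LarvalState:
    """Instantaneous state: age t (days), compartments B, L (mg C)."""

    t: float
    B: float
    L: float
    stage: Stage = Stage.LARVA

    @property
    def X(self) -> float:
        """Total larval mass, mg C."""
        return self.B + self.L


@dataclass(frozen=True)
class FluxRecord:
    """The six metabolic flows, mg C/day.

    ``r_L`` is negative during lipid catabolism (starvation or prepupa);
    the respiration components are always non-negative and carbon closes
    exactly: r_A = r_B + r_L + r_CO2_B + r_CO2_L + r_CO2_m.
    """

    r_A: float
    r_B: float
    r_L: float
    r_CO2_B: float
    r_CO2_L: float
    r_CO2_m: float
    starving: bool = False

    @property
    def r_CO2(self) -> float:
        return self.r_CO2_B + self.r_CO2_L + self.r_CO2_m

    @property
    def r_X(self) -> float:
        """Net biomass production rate (structure + lipid), mg C/day."""
        return self.r_B + self.r_L


@dataclass
class Trajectory:
    """Time-resolved solution of :func:`simulate_deb`.

    Arrays share one strictly increasing time grid.  ``A_cum`` and
    ``CO2_cum`` are integrated as additional ODE states so the cumulative
    carbon balance closes to integrator precision.  ``t_pp`` is the
    prepupation time (NaN if the larva never stopped feeding before
    ``t_end``).
    """

    t: np.ndarray
    B: np.ndarray
    L: np.ndarray
    A_cum: np.ndarray
    CO2_cum: np.ndarray
    stage: np.ndarray  # array of Stage values
    fluxes: list[FluxRecord]
    t_pp: float
    params: DebParams
    scenario: Scenario
    starved: bool = False
    lipid_depleted: bool = False

    @property
    def X(self) -> np.ndarray:
        return self.B + self.L

    def interp(self, t: float) -> tuple[float, float, float, float]:
        """Linear interpolation of (B, L, A_cum, CO2_cum) at time t."""
        if not (self.t[0] <= t <= self.t[-1]):
            raise ValueError(f"t={t} outside trajectory span "
                             f"[{self.t[0]}, {self.t[-1]}]")
        return tuple(np.interp(t, self.t, a)
                     for a in (self.B, self.L, self.A_cum, self.CO2_cum))

    @property
    def t_harvest(self) -> float:
        """Harvest time implied by the scenario's harvest rule."""
        if (self.scenario.harvest_rule == "at-prepupation"
                and np.isfinite(self.t_pp)):
            return self.t_pp
        return float(self.t[-1])


def specific_assimilation(x: float | np.ndarray, p: DebParams):
    """Specific feed assimilation rate a(x) (1/day) at relative weight x.

    Logistic decline from ~a_max in hatchlings to ~0 at the maximal weight:
    a(x) = a_max / (1 + exp(k_A (x - x_A))).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1.05):
        raise ValueError("relative weight x must lie in [0, 1.05]")
    out = p.a_max / (1.0 + np.exp(p.k_A * (x - p.x_A)))
    return float(out) if out.ndim == 0 else out


def structural_demand(x: float, B: float, p: DebParams) -> float:
    """Demand-side structural growth rate (mg C/day).

    Specific rate is near-constant (s_max) through the first half of the
    lifespan and declines logistically after the final-instar midpoint x5:
    demand = s_max B / (1 + exp(k_B (x - x5))).
    """
    if not 0 <= x <= 1.05:
        raise ValueError("relative weight x must lie in [0, 1.05]")
    if B <= 0:
        raise ValueError("structural biomass B must be positive")
    return p.s_max * B / (1.0 + np.exp(p.k_B * (x - p.x5)))


def _larval_fluxes(B: float, L: float, Xmax: float,
                   p: DebParams) -> FluxRecord:
    """Unchecked flux partition; used by the ODE right-hand side, which may
    probe slightly beyond the nominal weight cap during step control."""
    X = B + L
    x = X / Xmax
    r_A = p.a_max / (1.0 + np.exp(p.k_A * (x - p.x_A))) * X
    maint = p.m * X
    if r_A < maint:
        # below-maintenance supply: growth stops, lipid covers the deficit
        return FluxRecord(r_A=r_A, r_B=0.0, r_L=r_A - maint,
                          r_CO2_B=0.0, r_CO2_L=0.0, r_CO2_m=maint,
                          starving=True)
    demand = p.s_max * B / (1.0 + np.exp(p.k_B * (x - p.x5)))
    r_B = min(demand, (r_A - maint) / (1.0 + p.Y))
    r_CO2_B = p.Y * r_B
    # zero in exact arithmetic when supply-limited; clamp rounding residue
    excess = max(r_A - maint - (1.0 + p.Y) * r_B, 0.0)
    r_L = excess / (1.0 + p.Y_L)
    r_CO2_L = p.Y_L * r_L
    return FluxRecord(r_A=r_A, r_B=r_B, r_L=r_L, r_CO2_B=r_CO2_B,
                      r_CO2_L=r_CO2_L, r_CO2_m=maint)


def partition_fluxes(state: LarvalState, p: DebParams,
                     scenario: Scenario) -> FluxRecord:
    """Partition assimilated carbon during the larval (feeding) phase.

    Priority: maintenance first, then structural synthesis up to the
    structural demand (cost Y), then overflow to lipid (cost Y_L).  If
    supply does not cover maintenance, the deficit is drawn from lipid and
    the record is flagged as starving.
    """
    if state.stage is not Stage.LARVA:
        raise ValueError("partition_fluxes applies to the larval stage only")
    x = state.X / scenario.Xmax
    if not 0 <= x <= X_CAP + 1e-9:
        raise ValueError("larval weight must lie in [0, 1.05 Xmax]")
    if state.B <= 0:
        raise ValueError("structural biomass B must be positive")
    return _larval_fluxes(state.B, state.L, scenario.Xmax, p)


def prepupal_step(state: LarvalState, p: DebParams) -> FluxRecord:
    """Post-feeding fluxes: maintenance paid entirely from storage lipid."""
    if state.stage is not Stage.PREPUPA:
        raise ValueError("prepupal_step applies to the prepupal stage only")
    maint = p.m * state.X
    return FluxRecord(r_A=0.0, r_B=0.0, r_L=-maint,
                      r_CO2_B=0.0, r_CO2_L=0.0, r_CO2_m=maint)


# Prepupation fires when the specific assimilation rate has effectively
# collapsed to the maintenance level: a(x) <= m + PP_MARGIN * a_max.  A pure
# a(x) <= 0.01 a_max trigger is unreachable whenever m > 0.01 a_max, because
# weight gain stalls exactly where a(x) = m and x approaches that point only
# asymptotically; the margin keeps the event finite-time for all parameters.
PP_MARGIN = 0.01
# Hard weight cap: prepupation also fires at X = 1.05 Xmax (relevant only in
# the maintenance-free limit, where a(x) = m never happens).
X_CAP = 1.05


def _rhs_larval(t, y, p: DebParams, scenario: Scenario):
    f = _larval_fluxes(y[0], max(y[1], 0.0), scenario.Xmax, p)
    return [f.r_B, f.r_L, f.r_A, f.r_CO2]


class _PrepupalSolution:
    """Exact prepupal-phase solution: B constant, dX/dt = -m X.

    X(t) = X_pp exp(-m (t - t_pp)); lipid L = X - B is depleted at
    t_pp + ln(X_pp / B) / m.  A_cum is frozen; CO2_cum grows by the weight
    lost.  Mirrors the dense-output interface of solve_ivp.
    """

    def __init__(self, t_pp: float, y_pp: np.ndarray, p: DebParams,
                 t_end: float):
        self.t_pp = t_pp
        self.B = float(y_pp[0])
        self.L_pp = max(float(y_pp[1]), 0.0)
        self.A_pp = float(y_pp[2])
        self.CO2_pp = float(y_pp[3])
        self.X_pp = self.B + self.L_pp
        self.m = p.m
        if p.m > 0 and self.L_pp > 0:
            t_dep = t_pp + np.log(self.X_pp / self.B) / p.m
        elif p.m > 0:
            t_dep = t_pp  # lean prepupa: lipid exhausted immediately
        else:
            t_dep = np.inf
        self.depleted = t_dep <= t_end
        self.t_final = min(t_dep, t_end)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        X = self.X_pp * np.exp(-self.m * (t - self.t_pp))
        L = np.maximum(X - self.B, 0.0)
        B = np.full_like(t, self.B)
        A = np.full_like(t, self.A_pp)
        CO2 = self.CO2_pp + (self.X_pp - (self.B + L))
        return np.stack([B, L, A, CO2])


def simulate_deb(p: DebParams, scenario: Scenario, *,
                 rtol: float = 1e-8, atol: float = 1e-10,
                 grid_dt: float = 0.02,
                 t_eval: Sequence[float] | None = None) -> Trajectory:
    """Integrate the energy budget from t0 to t_end.

    States are [B, L, A_cum, CO2_cum]; cumulative assimilation and CO2 are
    co-integrated so the carbon balance closes to integrator precision.
    Prepupation is detected by event location; after it the model switches
    to lipid catabolism and stops early if lipid runs out.

    ``t_eval`` overrides the default uniform output grid (event times are
    always inserted); use a coarse grid plus looser tolerances when calling
    from a fitting loop.
    """
    y0 = [scenario.X0 - scenario.L0, scenario.L0, 0.0, 0.0]

    def ev_prepupation(t, y, *_args):
        x = (y[0] + y[1]) / scenario.Xmax
        a = p.a_max / (1.0 + np.exp(p.k_A * (x - p.x_A)))
        return a - (p.m + PP_MARGIN * p.a_max)

    def ev_cap(t, y, *_args):
        return (y[0] + y[1]) - X_CAP * scenario.Xmax

    def ev_lipid_exhausted(t, y, *_args):
        # fires only if larval-phase starvation has drawn lipid below zero
        return y[1] + 1e-9

    ev_prepupation.terminal = True
    ev_prepupation.direction = -1
    ev_cap.terminal = True
    ev_cap.direction = 1
    ev_lipid_exhausted.terminal = True
    ev_lipid_exhausted.direction = -1

    sol1 = solve_ivp(_rhs_larval, (scenario.t0, scenario.t_end), y0,
                     args=(p, scenario), method="LSODA",
                     rtol=rtol, atol=atol, dense_output=True,
                     events=[ev_prepupation, ev_cap, ev_lipid_exhausted])
    if not sol1.success:
        last = LarvalState(t=float(sol1.t[-1]), B=float(sol1.y[0, -1]),
                           L=float(sol1.y[1, -1]))
        raise SimulationError(f"larval-phase integration failed: "
                              f"{sol1.message}", last)

    t1_end = float(sol1.t[-1])
    hit_pp = len(sol1.t_events[0]) > 0 or len(sol1.t_events[1]) > 0
    lipid_depleted = len(sol1.t_events[2]) > 0
    t_pp = t1_end if hit_pp else float("nan")

    sol2 = None
    if hit_pp and t1_end < scenario.t_end:
        sol2 = _PrepupalSolution(t1_end, sol1.y[:, -1], p, scenario.t_end)
        lipid_depleted = sol2.depleted

    # assemble the output grid, always containing t0, t_pp and the end time
    def phase_grid(a, b):
        n = max(int(np.ceil((b - a) / grid_dt)), 2)
        return np.linspace(a, b, n + 1)

    end = sol2.t_final if sol2 is not None else t1_end
    if t_eval is not None:
        t_eval = np.asarray(t_eval, dtype=float)
        tgrid = np.unique(np.concatenate(
            [t_eval[(t_eval >= scenario.t0) & (t_eval <= end)],
             [scenario.t0, t1_end, end]]))
    else:
        tgrid = phase_grid(scenario.t0, t1_end)
        if sol2 is not None and end > t1_end:
            tgrid = np.unique(np.concatenate(
                [tgrid, phase_grid(t1_end, end)]))

    mask1 = tgrid <= t1_end
    parts = [sol1.sol(tgrid[mask1])]
    if sol2 is not None and np.any(~mask1):
        parts.append(sol2(tgrid[~mask1]))
    y = np.hstack(parts)
    B, L, A_cum, CO2_cum = (np.asarray(row) for row in y)
    # scrub integrator-scale negative lipid without disturbing the balance
    L = np.where((L < 0) & (L > -1e-8), 0.0, L)
    # the phase seam can leave an interpolation-scale dip in the
    # cumulative states; both are non-decreasing by construction
    A_cum = np.maximum.accumulate(A_cum)
    CO2_cum = np.maximum.accumulate(CO2_cum)

    stages = np.array([Stage.PREPUPA if (hit_pp and t > t1_end) else
                       Stage.LARVA for t in tgrid], dtype=object)
    fluxes: list[FluxRecord] = []
    starved = False
    for ti, Bi, Li, st in zip(tgrid, B, L, stages):
        state = LarvalState(t=float(ti), B=float(Bi), L=float(Li), stage=st)
        f = (prepupal_step(state, p) if st is Stage.PREPUPA
             else partition_fluxes(state, p, scenario))
        starved = starved or f.starving
        fluxes.append(f)

    return Trajectory(t=tgrid, B=B, L=L, A_cum=A_cum, CO2_cum=CO2_cum,
                      stage=stages, fluxes=fluxes, t_pp=t_pp, params=p,
                      scenario=scenario, starved=starved,
                      lipid_depleted=lipid_depleted)


def predict_observables(traj: Trajectory, p: DebParams | None = None):
    """Noise-free measurable series from a trajectory.

    Returns a dict of arrays: dry weight ``X_DW`` (mg), CO2 production rate
    ``r_CO2`` (mg CO2/day), total lipid ``L_tot`` (mg DW), relative lipid
    content ``delta_lipid`` and dry-matter content ``delta_DW``.  Water is
    assumed bound to structural mass only (h mg water per mg structural dry
    mass), so fattening larvae have rising dry-matter content.
    """
    if len(traj.t) == 0:
        raise ValueError("empty trajectory")
    p = traj.params if p is None else p
    B_dw = traj.B / p.f_C
    L_dw = traj.L / p.f_C
    X_DW = B_dw + L_dw
    r_CO2 = np.array([f.r_CO2 for f in traj.fluxes]) * CO2_PER_C
    delta_lipid = L_dw / X_DW
    delta_DW = X_DW / (X_DW + p.h * B_dw)
    return {
        "t": traj.t.copy(),
        "X_DW": X_DW,
        "r_CO2": r_CO2,
        "L_tot": L_dw,
        "delta_lipid": delta_lipid,
        "delta_DW": delta_DW,
    }
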