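"""Synthetic larval observation series and whole rearing experiments.

Real rearing studies report noisy per-larva time series (dry weight, CO2
production, lipid content) plus an end-point mass balance of the substrate.
This module generates both from known ground truth so that fitting and the
performance indicators can be validated end to end.

A rearing experiment couples a cohort of ``n_larvae`` average larvae to a
substrate pool.  Larvae ingest ``assimilation / AD`` of substrate dry
weight (``AD`` = digestion efficiency), the undigested fraction returning
to the residue as frass, while co-occurring microbes consume remaining
substrate at a first-order rate ``mu_mic``.  The resulting ledger
reproduces the structural fact that substrate removal exceeds larval
assimilation, so the measured substrate conversion efficiency (SCE) sits
below the larval net growth efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .deb import DebParams, Scenario, Trajectory, predict_observables, \
    simulate_deb
from .efficiency import MassBalanceLedger, nge_average
from .observations import ObservationSeries

__all__ = [
    "NoiseModel",
    "RearingScenario",
    "generate_observations",
    "generate_rearing_experiment",
]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: multiplicative lognormal with coefficient of
    variation ``cv_weight`` on dry weight and lipid, additive Gaussian
    ``sd_co2`` (mg CO2/day) on the CO2 rate."""

    cv_weight: float = 0.0
    sd_co2: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_weight < 0 or self.sd_co2 < 0:
            raise ValueError("noise magnitudes must be >= 0")


@dataclass(frozen=True)
class RearingScenario:
    """A cohort-level rearing experiment.

    ``W_DW0`` supplied substrate dry weight (mg); ``AD`` larval digestion
    efficiency (assimilated / ingested); ``mu_mic`` first-order microbial
    substrate consumption (1/day of remaining substrate).  Undigested
    ingesta (frass) is routed to the residue.
    """

    params: DebParams = field(default_factory=DebParams)
    scenario: Scenario = field(default_factory=Scenario)
    n_larvae: int = 100
    W_DW0: float = 40000.0
    AD: float = 0.8
    mu_mic: float = 0.02

    def __post_init__(self) -> None:
        if not 0 < self.AD <= 1:
            raise ValueError("digestion efficiency AD must be in (0, 1]")
        if self.mu_mic < 0:
            raise ValueError("mu_mic must be >= 0")
        if self.n_larvae <= 0 or self.W_DW0 <= 0:
            raise ValueError("n_larvae and W_DW0 must be positive")


def _lognormal_factors(rng, cv, size):
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=size)


def generate_observations(p: DebParams, scenario: Scenario, times,
                          noise: NoiseModel,
                          traj: Trajectory | None = None) -> ObservationSeries:
    """Simulate, predict observables at ``times`` and apply noise.

    Deterministic given ``noise.seed``; with zero noise the output equals
    :func:`~bsfdeb.deb.predict_observables` exactly.  A pre-computed
    trajectory may be passed to avoid re-simulation.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < scenario.t0) or np.any(times > scenario.t_end):
        raise ValueError("observation times outside the scenario span")
    if traj is None:
        traj = simulate_deb(p, scenario, t_eval=times)
    if times[-1] > traj.t[-1] + 1e-9:
        raise ValueError(
            f"trajectory ends at t={traj.t[-1]:.3f} (lipid depleted) "
            f"before the last observation time {times[-1]:.3f}")
    obs = predict_observables(traj, p)
    at = {k: np.interp(times, obs["t"], obs[k])
          for k in ("X_DW", "r_CO2", "L_tot", "delta_DW")}

    rng = np.random.default_rng(noise.seed)
    x_dw = at["X_DW"] * _lognormal_factors(rng, noise.cv_weight, len(times))
    l_tot = at["L_tot"] * _lognormal_factors(rng, noise.cv_weight,
                                             len(times))
    r_co2 = at["r_CO2"] + rng.normal(0.0, noise.sd_co2, len(times)) \
        if noise.sd_co2 > 0 else at["r_CO2"]
    return ObservationSeries(
        t=times, X_DW=x_dw, r_CO2=r_co2, L_tot=l_tot,
        delta_lipid=l_tot / x_dw, delta_DW=at["delta_DW"],
        meta={"cv_weight": noise.cv_weight, "sd_co2": noise.sd_co2,
              "seed": noise.seed, "synthetic": True})


def default_sampling_times(traj: Trajectory, step: float = 2.0,
                           past_pp: float = 4.0) -> np.ndarray:
    """Every ``step`` days from t0 until ``past_pp`` days after
    prepupation (clipped to the trajectory end), emulating typical study
    designs."""
    t0 = traj.scenario.t0
    t_last = min((traj.t_pp if np.isfinite(traj.t_pp) else traj.t[-1])
                 + past_pp, traj.t[-1])
    return np.arange(t0, t_last + 1e-9, step)


def generate_rearing_experiment(rs: RearingScenario, noise: NoiseModel,
                                times=None):
    """Run a cohort rearing experiment and return
    ``(ledger, observations, truth)``.

    The substrate pool obeys ``dW/dt = -n i(t) - mu_mic W`` with per-capita
    ingestion ``i = r_A / (AD f_C)`` in dry weight.  The ledger closes
    exactly: supplied = remaining + ingested + microbially consumed, and
    the residue is remaining substrate plus frass.  The ledger itself is
    noise-free (end-point weighings); noise applies to the observation
    series.  If the substrate runs out before the nominal harvest, the
    experiment is truncated at exhaustion and flagged in ``truth``.
    """
    p, sc = rs.params, rs.scenario
    traj = simulate_deb(p, sc)
    t_harvest = traj.t_harvest

    # substrate pool on the trajectory grid
    t = traj.t
    r_A = np.array([f.r_A for f in traj.fluxes])
    ingest_rate = rs.n_larvae * r_A / (rs.AD * p.f_C)  # mg DW/day
    # cumulative ingestion from the integrated assimilation (exact)
    ingest_cum = rs.n_larvae * (traj.A_cum - traj.A_cum[0]) / (rs.AD * p.f_C)
    mu = rs.mu_mic
    if mu == 0:
        W = rs.W_DW0 - ingest_cum
    else:
        ef = np.exp(mu * (t - t[0]))
        W = (rs.W_DW0
             - cumulative_trapezoid(ef * ingest_rate, t, initial=0.0)) / ef

    truncated = False
    if np.any(W <= 0):
        i_ex = int(np.argmax(W <= 0))
        t_exhaust = t[max(i_ex - 1, 0)]
        if t_exhaust <= sc.t0:
            raise ValueError("substrate insufficient for the cohort at start")
        truncated = True
        t_harvest = min(t_harvest, t_exhaust)

    ih = int(np.argmin(np.abs(t - t_harvest)))
    t_harvest = float(t[ih])
    ingested = float(ingest_cum[ih])
    W_rem = float(W[ih])
    # enforce exact ledger closure: microbial removal by difference
    microbial = rs.W_DW0 - W_rem - ingested
    frass = (1.0 - rs.AD) * ingested
    residue = W_rem + frass

    Bh, Lh, _, _ = traj.interp(t_harvest)
    ledger = MassBalanceLedger(
        X_DW0=rs.n_larvae * sc.X0 / p.f_C,
        X_DW=rs.n_larvae * (Bh + Lh) / p.f_C,
        W_DW0=rs.W_DW0, W_DW_res=residue)

    if times is None:
        times = default_sampling_times(traj)
    times = np.asarray(times, dtype=float)
    times = times[times <= traj.t[-1] + 1e-9]
    obs = generate_observations(p, sc, times, noise, traj=traj)

    eff = nge_average(traj, sc.t0, t_harvest)
    removed = rs.W_DW0 - residue
    truth = {
        "nge_avg": eff.nge_avg,
        "t_harvest": t_harvest,
        "t_pp": traj.t_pp,
        "ingested_dw": ingested,
        "assimilated_dw": rs.AD * ingested,
        "microbial_dw": microbial,
        "frass_dw": frass,
        "remaining_dw": W_rem,
        "sce": ledger.dX_DW / removed if removed > 0 else float("nan"),
        "truncated": truncated,
        "params": p,
        "scenario": sc,
    }
    return ledger, obs, truth
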