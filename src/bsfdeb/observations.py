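"""Container for measured or synthetic larval observation series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ObservationSeries"]


@dataclass
class ObservationSeries:
    """Time series of larval observables.

    ``t`` in days (strictly increasing); ``X_DW`` dry weight per larva in
    mg; optional ``r_CO2`` in mg CO2 per larva per day, ``L_tot`` total
    lipid in mg, and the derived contents ``delta_lipid`` (lipid / dry
    weight) and ``delta_DW`` (dry weight / wet weight).  ``meta`` carries
    provenance such as the noise model and seed for synthetic series.
    """

    t: np.ndarray
    X_DW: np.ndarray
    r_CO2: np.ndarray | None = None
    L_tot: np.ndarray | None = None
    delta_lipid: np.ndarray | None = None
    delta_DW: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.X_DW = np.asarray(self.X_DW, dtype=float)
        for name in ("r_CO2", "L_tot", "delta_lipid", "delta_DW"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                setattr(self, name, v)
                if v.shape != self.t.shape:
                    raise ValueError(f"{name} length mismatch with t")
        if self.X_DW.shape != self.t.shape:
            raise ValueError("X_DW length mismatch with t")
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.X_DW < 0):
            raise ValueError("dry weights must be >= 0")
        if self.L_tot is not None and np.any(self.L_tot < 0):
            raise ValueError("lipid masses must be >= 0")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def r_CO2_carbon(self) -> np.ndarray | None:
        """CO2 production as a carbon rate (mg C/day): 12/44 x r_CO2."""
        if self.r_CO2 is None:
            return None
        return self.r_CO2 * (12.0 / 44.0)
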