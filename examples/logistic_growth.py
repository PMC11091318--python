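"""Fit the Verhulst logistic curve to a larval dry-weight series.

Builds a noisy synthetic growth curve, fits the three logistic constants
back, and prints them next to the truth.
"""

import numpy as np

from bsfdeb import LogisticParams, fit_verhulst, verhulst_weight

truth = LogisticParams(mu=0.5, X0=1.0, Xmax=100.0)
t = np.arange(0.0, 21.0, 1.0)
rng = np.random.default_rng(1)
X = verhulst_weight(t, truth) * rng.lognormal(0, 0.05, len(t))

fit = fit_verhulst(t, X, seed=1)
p = fit.params
print(f"true:   mu={truth.mu:.3f}/d  X0={truth.X0:.2f}  Xmax={truth.Xmax:.1f} mg C")
print(f"fitted: mu={p.mu:.3f}/d  X0={p.X0:.2f}  Xmax={p.Xmax:.1f} mg C  (rss={fit.rss:.3g})")
print("mu is the early specific growth rate; Xmax the weight at which "
      "growth stops and larvae turn prepupal.")
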