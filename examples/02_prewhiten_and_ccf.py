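"""Prewhitened cross-correlation synchrony for one coupled dyad-block.

Generates a 5-minute dyad whose heart rhythms share a slow latent driver,
prewhitens each 4 Hz IBI series with the exhaustive seasonal-ARIMA search,
and computes the 25-lag cross-correlation synchrony index.
"""

import warnings

import numpy as np

from cardiosync import (CouplingConfig, SynchronyConfig, dyad_block_synchrony,
                        generate_dyad_ibi, ljung_box)

warnings.filterwarnings("ignore")

cfg = CouplingConfig(coupling_gain=1.0, block_duration_s=300.0, seed=11)
ibi1, ibi2, truth = generate_dyad_ibi(cfg)

# full ARIMA search with a 4 s (16-sample) respiratory-like seasonal period
sync_cfg = SynchronyConfig(prewhiten_method="auto_arima",
                           prewhiten_kwargs=dict(p_max=2, q_max=1, P_max=1,
                                                 Q_max=1, m=16))
sv = dyad_block_synchrony(ibi1, ibi2, sync_cfg)

_, p1 = ljung_box(sv.fit1.residuals)
print(f"subject 1 model: ARIMA({sv.fit1.spec.p},1,{sv.fit1.spec.q})"
      f"({sv.fit1.spec.P},1,{sv.fit1.spec.Q})_16, "
      f"lambda={sv.fit1.spec.lam:.2f}, residual Ljung-Box p={p1:.3f}")
print(f"25-lag CCF: peak {sv.ccf.values.max():.3f} at lag "
      f"{sv.ccf.lags[np.argmax(sv.ccf.values)]}")
print("lag-group means:", {k: round(v, 4) for k, v in sv.ccf.lag_group_means.items()})
print(f"averaged CCF = {sv.average_ccf:.4f}, Fisher Z = {sv.fisher_z:.4f}, "
      f"scaled (x100) = {sv.scaled:.2f}")
# With a strong planted driver the zero-lag group dominates and the averaged
# CCF is clearly positive; an uncoupled dyad would scatter around zero.
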