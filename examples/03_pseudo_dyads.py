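"""REAL versus PSEUDO dyads: is synchrony more than shared task context?

Builds a coupled multi-dyad study, computes real-dyad synchrony, enumerates
the participant-shuffling surrogate pairings, and compares the two
distributions with Welch's unequal-variance t-test.
"""

import warnings

from cardiosync import (SynchronyConfig, compare_real_pseudo, enumerate_pseudo_pairs,
                        generate_simulation_study, pseudo_pair_count,
                        pseudo_synchrony_distribution, real_synchrony_table,
                        residual_cache)

warnings.filterwarnings("ignore")

study = generate_simulation_study(n_dyads=10, n_blocks=8, block_duration_s=120.0,
                                  gain=0.5, include_baseline=True, seed=3)
cfg = SynchronyConfig(prewhiten_method="ar_diff")

cache = residual_cache(study, cfg)              # one ARIMA fit per subject-block
real = real_synchrony_table(study, cfg, cache)
pairs = enumerate_pseudo_pairs(study)           # exhaustive within condition cells
pairs = pseudo_synchrony_distribution(study, pairs, cfg, cache)

print(f"condition cells: {pairs.n_c}, surrogate pairs: {pairs.n_pairs} "
      f"(closed form {pseudo_pair_count(pairs.n_b, pairs.n_c)})")
report = compare_real_pseudo(real, pairs.synchrony)
for name, res in report.items():
    print(f"{name}: t = {res.t:.2f}, df = {res.df:.1f}, p = {res.p:.2g}, "
          f"means {res.mean_a:.5f} vs {res.mean_b:.5f}")
# Task-block REAL synchrony exceeds the surrogate null (positive t, small p)
# while the baseline comparison stays null: the coupling is specific to the
# interacting pair, not to doing the same task at the same session position.
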