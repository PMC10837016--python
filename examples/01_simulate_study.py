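"""Generate a synthetic phenotyping study and look at its ground truth.

A study consists of a SNP dosage panel, per-line light-response slopes
(Fq'/Fm' change per µmol photons m^-2 s^-1), season-long fluorescence
measurement streams, and a partially replicated yield trial.
"""

import numpy as np

import chlfpred as cp

cfg = cp.SimulationConfig(
    n_lines=60,
    n_markers=500,
    n_environments=2,
    obs_per_line_per_env=120,
    violation_fractions=(0.05, 0.02, 0.01),
    seed=42,
)
snp = cp.generate_population(cfg)
truth = cp.generate_true_effects(snp, cfg)
records, planted = cp.simulate_chlf_series(truth, cfg)
traits = cp.simulate_yield(truth, cfg)

print(f"SNP panel: {snp.n_lines} lines x {snp.n_markers} markers")
print(f"fluorescence records: {len(records)} across {cfg.n_environments} trials")
print(f"yield plots: {len(traits)} (check lines replicated {cfg.check_replicates}x)")
print(f"mean slope: {truth.true_slope.mean():.2e} Fq'/Fm' per µmol m^-2 s^-1")
print(f"slope sd across lines: {truth.true_slope.mean(axis=1).std():.2e}")
r = np.corrcoef(truth.true_slope.mean(axis=1), truth.true_yield.mean(axis=1))[0, 1]
print(f"planted slope-yield correlation: {r:.2f}")
print("A less negative (shallower) slope means the line keeps PSII efficiency")
print("high under bright light, i.e. higher light-use efficiency and yield.")
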