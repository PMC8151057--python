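"""Score all selection criteria on a small simulated benchmark.

Builds 12 simulated walks (4 augmented sets per true synergy number in
{4, 5, 6}) under the no-additive-noise condition and scores every
criterion with the fraction of correct classifications, the mean error
and the root-mean-square error of the selected synergy number.

This is a miniature of the full 75-set benchmark that
scripts/acceptance.py reproduces.
"""

from choosyn import DatasetConfig, build_simulated_dataset, desk_preset, run_benchmark

dataset = build_simulated_dataset(DatasetConfig(
    true_n_levels=(4, 5, 6), subjects_per_level=2,      # 4 sets per level
    snr_conditions=(None,), n_cycles=30, master_seed=5))
print(f"benchmarking {len(dataset)} simulated walks ...")

report = run_benchmark(dataset, config=desk_preset(), seed=5)
print(report.to_text_table())
# fraction correct counts exact recoveries of the true synergy number;
# ME < 0 means a criterion under-estimates (typical for VAF thresholds),
# RMSE summarizes how far wrong selections stray.
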