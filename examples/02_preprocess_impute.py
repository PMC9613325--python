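"""Filter, log-transform and impute a left-censored dataset, then compare
the truncated-Gibbs imputer with naive constant-minimum imputation against
the known truth."""

import numpy as np

import milknet as mn

config = mn.SyntheticConfig(
    n_per_group=25,
    n_proteins=40,
    censor_quantile=0.3,
    block_spec=(
        mn.BlockSpec(0, 8, 0.8, ("M-C-", "M+C-", "M-C+", "M+C+")),
        mn.BlockSpec(8, 8, 0.7, ("M-C-", "M+C-", "M-C+", "M+C+")),
    ),
    seed=2,
)
table, design, _, truth = mn.generate_lfq_dataset(config)

filtered = mn.filter_by_group_validity(table, design, min_valid=5)
print(f"proteins retained by the >=5-valid-in-one-group filter: "
      f"{filtered.n_proteins} of {table.n_proteins}")

logged = mn.log10_transform(filtered)
result = mn.impute_left_censored(logged, sweeps=10, seed=3)
print(f"Gibbs sweeps run: {result.n_sweeps}; "
      f"final mean relative change: {result.convergence_trace[-1]:.2e}")

missing = logged.data.isna().to_numpy()
truth_vals = truth.true_log10[logged.protein_ids].to_numpy()
baseline = mn.constant_minimum_impute(logged)

for name, completed in (("truncated Gibbs", result.table), ("constant minimum", baseline)):
    err = completed.data.to_numpy()[missing] - truth_vals[missing]
    print(f"RMSE over {missing.sum()} censored cells, {name}: "
          f"{np.sqrt(np.mean(err**2)):.4f} log10 units")
# The regression-based imputer exploits protein-protein correlation and the
# below-minimum truncation, so its RMSE is lower than plugging in the minimum.
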