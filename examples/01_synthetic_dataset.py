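"""Generate a synthetic LFQ milk-proteome dataset with planted ground truth.

Builds a 4-group (mother x child allergy) dataset with a correlated protein
block, a differential hub, a shifted keyword set, and left-censored MNAR
missingness, then prints what was planted.
"""

import milknet as mn

config = mn.SyntheticConfig(
    n_per_group=30,
    n_proteins=60,
    censor_quantile=0.3,
    block_spec=(mn.BlockSpec(start=0, size=8, rho=0.85, active_groups=("M+C+",)),),
    hub_spec=(mn.HubSpec(index=20, neighbors={"M+C+": 6, "M-C-": 2}),),
    shifted_set=mn.ShiftSpec(
        indices=tuple(range(40, 48)), keyword="Ig", group="M-C+", log10_shift=0.5
    ),
    seed=1,
)
table, design, annotation, truth = mn.generate_lfq_dataset(config)

print(f"samples x proteins: {table.data.shape}")
print(f"group sizes: {design.group_sizes().to_dict()}")
missing = table.missing_mask().to_numpy().mean()
print(f"missing fraction: {missing:.3f}  (left-censored, MNAR)")
print(f"shifted proteins (keyword 'Ig'): {truth.differential_proteins}")

# the missingness is informative: low true values go missing far more often
import numpy as np

true = truth.true_log10.to_numpy().ravel()
miss = table.missing_mask().to_numpy().ravel()
lo, hi = np.quantile(true, [0.1, 0.9])
print(
    f"missing rate, bottom decile of true values: {miss[true <= lo].mean():.2f}; "
    f"top decile: {miss[true >= hi].mean():.2f}"
)
# Expect ~0.3 overall missingness concentrated in the bottom decile: values
# below the per-protein detection limit are the ones that vanish.
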