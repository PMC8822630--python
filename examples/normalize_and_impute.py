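"""Run one preprocessing pipeline and score its zero classification.

A pipeline is a normalization (optional) followed by a zero-imputation step
(optional).  Against the simulator's ground truth, every raw zero is either
biological (species truly absent) or technical (lost by sequencing);
sensitivity is the share of technical zeros recovered, specificity the share
of biological zeros correctly left at zero.
"""

from otubench import parse_pipeline, random_preset, run_pipeline, simulate_dataset, zero_confusion

preset = random_preset(
    n_conditions=4, n_features=300, structural_zero_frac=0.40,
    variability=0.25, depth_range=(5_000, 20_000),
    replicates_per_condition=5, intensity_sigma=2.5, seed=7,
)
ds = simulate_dataset(preset)

for key in ("gmpr", "gmpr+scimpute", "gmpr+zcomp_sq"):
    spec = parse_pipeline(key)
    out = run_pipeline(ds.raw, spec, seed=1)
    conf = zero_confusion(ds.ground_truth, ds.raw, out)
    print(f"{spec.name:24s} sparsity {out.sparsity():6.2f} %  "
          f"sensitivity {conf.sensitivity:6.1f} %  "
          f"specificity {conf.specificity:6.1f} %")

print()
print("Normalization alone recovers nothing (sensitivity 0); the dropout-aware")
print("imputer recovers technical zeros while keeping biological ones; the")
print("compositional replacement imputes everything, sacrificing specificity.")
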