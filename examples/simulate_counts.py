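"""Simulate a paired ground-truth/raw 16S count dataset.

The simulator draws per-replicate abundances from a gamma law (biological
variability around each condition's intensity profile) and then sequences
each sample by drawing reads without replacement from a discretized community
pool.  Sequencing can only lose species, so the raw table is sparser than the
ground truth; the extra zeros are the "technical" zeros the benchmark's
imputation methods try to recover.
"""

from otubench import builtin_presets, simulate_dataset

preset = builtin_presets()["scenario1"]
ds = simulate_dataset(preset, seed=0)

print(f"features x samples : {ds.raw.shape[0]} x {ds.raw.shape[1]}")
print(f"conditions         : {ds.raw.groups.nunique()} x "
      f"{preset.replicates_per_condition} replicates")
print(f"depth range        : {ds.depths.min()}-{ds.depths.max()} reads")
print(f"ground-truth sparsity : {ds.ground_truth.sparsity():.2f} %")
print(f"raw sparsity          : {ds.raw.sparsity():.2f} %")
n_tech = int(ds.technical_zero_mask().to_numpy().sum())
print(f"technical zeros       : {n_tech} entries "
      "(present in the ground truth, lost by sequencing)")
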