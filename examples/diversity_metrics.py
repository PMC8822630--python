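"""Alpha and beta diversity of a count table.

Observed richness counts detected features per sample; Pielou evenness is
Shannon entropy over the log of richness (1 = perfectly even community).
Whittaker beta diversity compares presence/absence between samples (1 =
identical feature sets, 2 = disjoint); Bray-Curtis adds abundance
information (0 = identical, 1 = no shared counts).  NMDS embeds the
Bray-Curtis matrix in 2-D while preserving rank order of dissimilarities.
"""

from otubench import CountMatrix, alpha_indices, bray_curtis_matrix, builtin_presets, nmds_embed, simulate_dataset, whittaker_matrix

ds = simulate_dataset(builtin_presets()["scenario1"], seed=0)
samples = ds.raw.samples[:6]  # first six samples for a compact display
cm = CountMatrix(ds.raw.values[samples], groups=ds.raw.groups[samples], layer="raw")

alpha = alpha_indices(cm)
print(alpha.round(3).to_string())
print()
print("Whittaker (presence/absence):")
print(whittaker_matrix(cm).round(2).to_string())
print()
bc = bray_curtis_matrix(cm)
coords, stress = nmds_embed(bc, seed=0)
print(f"NMDS stress {stress:.4f} (values < 0.1 indicate a faithful 2-D layout)")
print(coords.round(3).to_string())
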