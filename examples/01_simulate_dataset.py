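"""Generate a synthetic crop-content FTIR dataset.

Builds the eight taxon-part class profiles (fructose bands only in berries,
oxalate dominated by Salix stems, cutin peaking in catkins, ...), then draws a
small dataset: per sample one set of jittered band heights, per replicate its
own baseline drift and noise.
"""

from spectradiet import SyntheticConfig, default_class_profiles, generate_dataset

profiles = default_class_profiles()
stem, leaf = profiles["Sh-stem"], profiles["D-leaf"]
print("planted oxalate-1620 heights (unit-norm scale):")
print(f"  Sh-stem {stem.height(1620):.4f} > D-leaf {leaf.height(1620):.4f}")

config = SyntheticConfig(n_samples_per_class=3, n_replicates=5, seed=0)
spectra, metas = generate_dataset(config)
print(f"\n{len(metas)} samples x {config.n_replicates} replicates "
      f"= {len(spectra)} spectra on a {len(spectra[0])}-point grid "
      f"({config.grid_max:.0f} -> {config.grid_min:.0f} cm-1, "
      f"step {config.grid_step:.0f})")
print("first sample:", metas[0].sample_id, "|", metas[0].taxon, "/", metas[0].part)
# The planted heights are conventions: only their orderings across classes
# carry meaning, mirroring how band intensities are compared in practice.
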