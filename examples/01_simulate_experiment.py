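"""Generate a synthetic field-vs-chamber diurnal experiment.

Builds the 5-condition × 13-timepoint × 4-replicate design (260 samples)
with known per-gene rhythm phases, amplitudes and environmental-driver
classes, and prints what was injected.
"""

from chronofield import preset_field_vs_chamber

matrix, truth = preset_field_vs_chamber(seed=7, n_genes=1000)

print(f"count matrix: {matrix.n_genes} genes × {matrix.n_samples} samples")
print(f"conditions:   {sorted(set(matrix.samples['condition']))}")
print(f"timepoints:   {len(matrix.timepoints())} (2-h grid over 24 h)")

rhythmic = int(truth.genes["is_rhythmic"].sum())
print(f"\nrhythmic genes: {rhythmic} (24-h cosine profiles, amplitude 0.2-0.9)")
print("environmental-driver classes injected (2^2-fold shifts at their")
print("affected timepoints in the conditions holding that factor constant):")
print(truth.genes["class_label"].value_counts().to_string())
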