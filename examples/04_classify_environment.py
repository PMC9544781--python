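"""Classify genes by their environmental driver via DEG set logic.

Runs per-timepoint DEG calling of FIELD against all four chamber
conditions, applies the truth table (LIGHT = differs exactly in the
constant-light chambers, TH = in the constant-temperature/humidity
chambers, LTH = in all partially constant chambers, UNREP = differs even
from the full simulation), and compares the labels with the generator's
ground truth.
"""

from chronofield.classify import EXP1_SCHEME, class_counts_over_time, classify_conditions, set_overlap
from chronofield.matrix import timepoint_labels
from chronofield.simulate import preset_field_vs_chamber

matrix, truth = preset_field_vs_chamber(seed=7, n_genes=300)
labels, _ = classify_conditions(matrix, EXP1_SCHEME)

counts = class_counts_over_time(labels)
names = timepoint_labels(counts.index)
counts.index = [names[tp] for tp in counts.index]
print("genes per class and timepoint:")
print(counts.to_string())

morning, evening = truth.affected_timepoints["LIGHT"][0], truth.affected_timepoints["LIGHT"][-1]
light_morning = set(labels.query("timepoint == @morning and label == 'LIGHT'")["gene_id"])
light_evening = set(labels.query("timepoint == @evening and label == 'LIGHT'")["gene_id"])
ov = set_overlap(light_morning, light_evening)
print(
    f"\nLIGHT genes at {names[morning]} vs {names[evening]}: "
    f"{ov['intersection']} shared "
    f"({100 * ov['overlap_min_fraction']:.0f}% of the smaller set)"
)

truth_light = set(truth.genes.index[truth.genes["class_label"] == "LIGHT"])
recovered = len(light_morning & truth_light)
print(f"injected LIGHT genes recovered at {names[morning]}: "
      f"{recovered}/{len(truth_light)}")
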