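# chronofield

Diurnal transcriptome analysis under field and controlled conditions.

Growth chambers that replay a field's irradiance, temperature and humidity
trajectories ("field simulators") make it possible to ask which parts of a
plant's diurnal transcriptome are driven by which environmental factor —
and which parts of field expression no chamber reproduces. `chronofield`
implements the statistical chain for that comparison as a reusable,
tested Python library:

* **Expression handling** — gene × sample count matrices with unit-tagged
  transforms: mean-count gene filtering, reads-per-million (rpm) with an
  rRNA exclusion list, log2(rpm + 1).
* **Molecular timetable method** — select *time-indicating genes* whose
  time course is strongly cosine-periodic (best-fit Pearson *r* over 1440
  one-minute peak-time candidates, period fixed at 24 h) and high-amplitude
  (a = SD/mean); estimate any sample's *internal time* as the peak time of
  the cosine best fitting its z-scored marker profile
  (φ_g, z_g) ↦ cos(2π(φ_g − T)/1440).
* **Differential expression** — trimmed mean of M-values (TMM)
  normalization, multi-step DEG-elimination normalization (TMM → liberal
  exact-test pass → TMM on non-DEGs), and a negative-binomial conditional
  exact test with common dispersion by conditional maximum likelihood,
  run independently at every shared timepoint, with Benjamini–Hochberg
  control.
* **Environmental-driver classification** — truth-table set logic over
  per-comparison DEG flags: LIGHT (driven by fluctuating irradiance), TH
  (temperature/humidity), LTH (both), UNREP (field-specific, not
  reproduced even by the full simulation); plus field-specific gene
  extraction (≥ 2-fold mean difference and DEG somewhere) and set-overlap
  summaries.
* **Similarity summaries** — per-timepoint between-condition correlations
  with rank-sum comparisons, per-gene time-course correlations
  (r > 0.7, q < 0.05 counts), gene-centred PCA, correlation-distance
  hierarchical clustering with Newick export.
* **Term enrichment** — two-sided Fisher exact test (exact integer
  tie-handling) over the annotated-gene universe, BH-controlled.
* **Synthetic experiments** — a generator producing both built-in designs
  (5 conditions × 13 timepoints × 4 replicates, 260 samples; and
  4 × 17 × 3, 204 samples) with known per-gene phases, amplitudes, and
  driver classes, so every stage is testable against ground truth.

## Worked example

`examples/` contains one short script per capability. For instance,
classifying genes by environmental driver on a synthetic experiment
(`python examples/04_classify_environment.py`):

```
genes per class and timepoint:
label    LIGHT  TH  LTH  UNREP
19:00        0   0    0      1
...
7:00         9  16   18      0
9:00         9  16   18      0
...
13:00        0   0    0     14
...
17:00        9   0   17      0
19:00_2      9   0   17      0

LIGHT genes at 7:00 vs 19:00_2: 9 shared (100% of the smaller set)
injected LIGHT genes recovered at 7:00: 9/9
```

The generator injected LIGHT/TH/LTH effects at morning (and, for light,
evening) timepoints; the per-timepoint DEG calls plus the truth table
recover exactly those genes at exactly those timepoints, and the
temperature signal (TH, LTH) peaks in the morning while the light signal
persists into the evening — the pattern this kind of factorial chamber
design is built to expose.

Internal-time inference (`python examples/02_internal_time.py`):

```
time-indicating genes selected: 150
peak-time coverage: 5-1434 min
median |estimated - true| over 50 noisy samples: 4.6 min
```

A sample's subjective time is read off a single snapshot to a few minutes
despite z-scale noise of SD 0.3.

## Command line

A thin CLI wraps the library for shell pipelines:

```bash
chronofield simulate --preset exp1 --seed 7 --out-dir sim/
chronofield prep --counts sim/counts.tsv --meta sim/meta.tsv --min-mean 10 --out filtered.tsv
chronofield timetable fit --in sim/counts.tsv --meta sim/meta.tsv --condition FIELD --out model.tsv
chronofield deg --in sim/counts.tsv --meta sim/meta.tsv --a FIELD --b CL_CTH --out deg.tsv
chronofield run --config config.yaml   # full pipeline, deterministic outputs
```

All file formats are plain TSV (documented in the module docstrings);
pipeline outputs carry provenance headers and re-running an identical
config reproduces byte-identical files.

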