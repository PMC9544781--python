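"""Synthetic diurnal count experiments with known ground truth.

The generator emulates the two experimental designs used throughout the
package: a field-vs-chamber comparison sampled every 2 h for 24 h
(5 conditions × 13 timepoints × 4 replicates = 260 samples, ``exp1``) and a
dawn/dusk-focused chamber comparison (4 conditions × 17 timepoints × 3
replicates = 204 samples, ``exp2``).

Each gene g in condition c at clock time t has negative-binomial counts with
mean

    mu = L_s · mu_g · (1 + A_g · cos(2π (t + δ_c − φ_g) / 1440)) · e_{g,c,t}

where L_s is a per-sample library-size factor, mu_g a log-normal baseline,
A_g ∈ [0,1) the relative rhythm amplitude (0 for arrhythmic genes), φ_g the
peak phase in minutes, δ_c an optional per-condition internal-time offset,
and e_{g,c,t} a multiplicative class effect. Class effects encode which
environmental factor drives a gene:

* LIGHT genes are shifted in the constant-light conditions (CL/CTH, CL/FTH),
* TH genes in the constant-temperature/humidity conditions (CL/CTH, FL/CTH),
* LTH genes in every condition with at least one constant factor,
* UNREP genes are shifted in FIELD only (a field-specific signal that no
  chamber simulation reproduces),

each at a class-specific set of affected timepoints (temperature effects in
the morning, light effects in the morning and evening, field-specific
effects at midday). The per-gene generative parameters are returned as a
:class:`SyntheticTruth` for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from chronofield.matrix import ExpressionMatrix, timepoint_key

# Sampling grids as (day, minutes-since-midnight) pairs.
# exp1: every 2 h for 24 h starting 19:00 (the final point is 19:00 again,
# 24 h after the start, written 19:00_2).
EXP1_TIMEPOINTS: tuple[tuple[int, int], ...] = tuple(
    divmod(1140 + 120 * i, 1440) for i in range(13)
)

# exp2: 17 points from 5:00 to 19:00, densified around dawn and dusk.
EXP2_TIMEPOINTS: tuple[tuple[int, int], ...] = tuple(
    (0, m)
    for m in (300, 330, 360, 390, 420, 480, 540, 600, 660, 780, 900, 960, 1020, 1050, 1080, 1110, 1140)
)

EXP1_CONDITIONS = ("FIELD", "FL_FTH", "CL_CTH", "FL_CTH", "CL_FTH")
EXP2_CONDITIONS = ("FL_FTH", "CL_CTH", "FL_CTH", "CL_FTH")

CLASS_LABELS = ("LIGHT", "TH", "LTH", "UNREP")

# Conditions whose deviation from the fluctuating baseline defines each class.
AFFECTED_CONDITIONS: dict[str, tuple[str, ...]] = {
    "LIGHT": ("CL_CTH", "CL_FTH"),
    "TH": ("CL_CTH", "FL_CTH"),
    "LTH": ("CL_CTH", "FL_CTH", "CL_FTH"),
    "UNREP": ("FIELD",),
}


def default_affected_timepoints(design: str) -> dict[str, list[int]]:
    """Class → affected timepoint keys; morning for TH, morning+evening for
    LIGHT and LTH, midday for UNREP."""
    if design == "exp1":
        morning = [timepoint_key(1, 420), timepoint_key(1, 540)]           # 7:00, 9:00
        evening = [timepoint_key(1, 1020), timepoint_key(1, 1140)]         # 17:00, 19:00_2
        midday = [timepoint_key(1, 780)]                                   # 13:00
    elif design == "exp2":
        morning = [timepoint_key(0, m) for m in (360, 390, 420)]           # 6:00-7:00
        evening = [timepoint_key(0, m) for m in (1020, 1050, 1080)]        # 17:00-18:00
        midday = [timepoint_key(0, 780)]
    else:
        raise ValueError(f"unknown design {design!r}")
    return {
        "LIGHT": morning + evening,
        "TH": list(morning),
        "LTH": morning + evening,
        "UNREP": list(midday),
    }


@dataclass
class SimConfig:
    """Parameters of one synthetic diurnal experiment.

    ``class_fractions`` are fractions of all genes assigned to each
    environmental-driver class (they must sum to ≤ 1; remaining genes are
    class 'none'). Rhythmicity is drawn independently at
    ``fraction_rhythmic``. ``effect_log2fc`` is the magnitude of the class
    effect in log2 units, applied with a random per-gene sign at the
    class's affected timepoints in its affected conditions.
    """

    n_genes: int = 1000
    fraction_rhythmic: float = 0.3
    class_fractions: dict = field(
        default_factory=lambda: {"LIGHT": 0.05, "TH": 0.05, "LTH": 0.05, "UNREP": 0.05}
    )
    effect_log2fc: float = 2.0
    affected_timepoints: dict | None = None  # class → list of timepoint keys
    baseline_logmean_mu: float = float(np.log(100.0))
    baseline_logmean_sigma: float = 1.2
    rhythm_amplitude_range: tuple[float, float] = (0.2, 0.9)
    nb_dispersion: float = 0.1
    library_size_range: tuple[float, float] = (0.7, 1.3)
    design: str = "exp1"
    n_replicates: int | None = None  # default: 4 for exp1, 3 for exp2
    internal_time_offsets: dict = field(default_factory=dict)  # condition → minutes
    seed: int = 0

    def validate(self) -> None:
        if self.design not in ("exp1", "exp2"):
            raise ValueError(f"unknown design {self.design!r}")
        if not 0.0 <= self.fraction_rhythmic <= 1.0:
            raise ValueError("fraction_rhythmic must lie in [0, 1]")
        fracs = dict(self.class_fractions)
        unknown = sorted(set(fracs) - set(CLASS_LABELS))
        if unknown:
            raise ValueError(f"unknown class labels in class_fractions: {unknown}")
        if any(f < 0 or f > 1 for f in fracs.values()):
            raise ValueError("class fractions must lie in [0, 1]")
        if sum(fracs.values()) > 1.0 + 1e-12:
            raise ValueError("class fractions sum to more than 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be ≥ 0")
        lo, hi = self.rhythm_amplitude_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("rhythm_amplitude_range must satisfy 0 ≤ lo ≤ hi < 1")

    @property
    def conditions(self) -> tuple[str, ...]:
        return EXP1_CONDITIONS if self.design == "exp1" else EXP2_CONDITIONS

    @property
    def grid(self) -> tuple[tuple[int, int], ...]:
        return EXP1_TIMEPOINTS if self.design == "exp1" else EXP2_TIMEPOINTS

    @property
    def replicates(self) -> int:
        if self.n_replicates is not None:
            return self.n_replicates
        return 4 if self.design == "exp1" else 3


@dataclass
class SyntheticTruth:
    """Per-gene generative parameters plus the noise-free mean profiles.

    ``genes`` has one row per gene: is_rhythmic, phase (NaN for arrhythmic
    genes), amplitude, class_label ('none' for unaffected genes),
    effect_sign, effect_log2fc. ``condition_time_means`` holds the expected
    expression (before library-size scaling) for every (condition,
    timepoint) cell, genes × MultiIndex columns. ``affected_timepoints``
    and ``affected_conditions`` record where each class effect acts.
    """

    genes: pd.DataFrame
    condition_time_means: pd.DataFrame
    affected_timepoints: dict
    affected_conditions: dict
    library_sizes: pd.Series

    def expected_labels(self, tp: int) -> pd.Series:
        """Class label each gene should receive at timepoint key ``tp``
        ('none' where the gene's class effect is not active)."""
        labels = pd.Series("none", index=self.genes.index)
        for cls, tps in self.affected_timepoints.items():
            if tp in tps:
                mask = self.genes["class_label"] == cls
                labels[mask] = cls
        return labels


def simulate_experiment(cfg: SimConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw one synthetic experiment; deterministic given ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    gene_ids = pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id")

    # --- per-gene generative parameters ---
    baseline = np.exp(rng.normal(cfg.baseline_logmean_mu, cfg.baseline_logmean_sigma, n))
    is_rhythmic = rng.random(n) < cfg.fraction_rhythmic
    phase = np.where(is_rhythmic, rng.uniform(0, 1440, n), np.nan)
    lo, hi = cfg.rhythm_amplitude_range
    amplitude = np.where(is_rhythmic, rng.uniform(lo, hi, n), 0.0)

    labels = np.array(["none"] * n, dtype=object)
    fracs = {c: cfg.class_fractions.get(c, 0.0) for c in CLASS_LABELS}
    u = rng.random(n)
    edges = np.cumsum([fracs[c] for c in CLASS_LABELS])
    starts = np.concatenate([[0.0], edges[:-1]])
    for cls, a, b in zip(CLASS_LABELS, starts, edges):
        labels[(u >= a) & (u < b)] = cls
    effect_sign = rng.choice([-1.0, 1.0], size=n)

    affected_tps = cfg.affected_timepoints or default_affected_timepoints(cfg.design)

    # --- expected means per (condition, timepoint), before library scaling ---
    conditions = cfg.conditions
    grid = cfg.grid
    tp_keys = [timepoint_key(d, c) for d, c in grid]
    cols = pd.MultiIndex.from_product([conditions, tp_keys], names=["condition", "timepoint"])
    means = np.empty((n, len(cols)))
    phase0 = np.where(is_rhythmic, phase, 0.0)
    for j, (cond, tp) in enumerate(cols):
        clock = tp % 1440
        delta = cfg.internal_time_offsets.get(cond, 0.0)
        osc = 1.0 + amplitude * np.cos(2 * np.pi * (clock + delta - phase0) / 1440.0)
        eff = np.ones(n)
        for cls in CLASS_LABELS:
            if cond in AFFECTED_CONDITIONS[cls] and tp in affected_tps.get(cls, ()):
                mask = labels == cls
                eff[mask] = 2.0 ** (effect_sign[mask] * cfg.effect_log2fc)
        means[:, j] = baseline * osc * eff
    mean_df = pd.DataFrame(means, index=gene_ids, columns=cols)

    # --- samples and counts ---
    reps = cfg.replicates
    sample_ids, meta_rows, count_cols = [], [], []
    lib_lo, lib_hi = cfg.library_size_range
    lib_sizes = {}
    for cond in conditions:
        for (day, clock) in grid:
            tp = timepoint_key(day, clock)
            mu_ct = mean_df[(cond, tp)].to_numpy()
            for rep in range(1, reps + 1):
                sid = f"{cond}_d{day}t{clock:04d}_r{rep}"
                L = rng.uniform(lib_lo, lib_hi)
                lib_sizes[sid] = L
                mu = L * mu_ct
                if cfg.nb_dispersion <= 1e-12:
                    counts = rng.poisson(mu)
                else:
                    r = 1.0 / cfg.nb_dispersion
                    p = r / (r + mu)
                    counts = rng.negative_binomial(r, p)
                sample_ids.append(sid)
                meta_rows.append((cond, clock, day, rep, cfg.design))
                count_cols.append(counts)
    values = pd.DataFrame(
        np.column_stack(count_cols).astype(float), index=gene_ids, columns=sample_ids
    )
    samples = pd.DataFrame(
        meta_rows,
        index=pd.Index(sample_ids, name="sample_id"),
        columns=["condition", "clock_time", "day", "replicate", "experiment"],
    )
    matrix = ExpressionMatrix(values, samples, "counts")

    genes = pd.DataFrame(
        {
            "is_rhythmic": is_rhythmic,
            "phase": phase,
            "amplitude": amplitude,
            "class_label": labels,
            "effect_sign": effect_sign,
            "effect_log2fc": np.where(labels == "none", 0.0, cfg.effect_log2fc),
        },
        index=gene_ids,
    )
    truth = SyntheticTruth(
        genes=genes,
        condition_time_means=mean_df,
        affected_timepoints={k: list(v) for k, v in affected_tps.items()},
        affected_conditions={k: tuple(v) for k, v in AFFECTED_CONDITIONS.items()},
        library_sizes=pd.Series(lib_sizes, name="library_size_factor"),
    )
    return matrix, truth


def preset_field_vs_chamber(seed: int, n_genes: int = 1000, **overrides):
    """The exp1 design (5 conditions × 13 timepoints × 4 replicates, 260
    samples) with the default class structure."""
    cfg = SimConfig(n_genes=n_genes, design="exp1", seed=seed, **overrides)
    return simulate_experiment(cfg)


def preset_dawn_dusk(seed: int, n_genes: int = 1000, **overrides):
    """The exp2 design (4 conditions × 17 timepoints × 3 replicates, 204
    samples)."""
    cfg = SimConfig(n_genes=n_genes, design="exp2", seed=seed, **overrides)
    return simulate_experiment(cfg)


def write_truth(truth: SyntheticTruth, path) -> None:
    out = truth.genes.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", lineterminator="\n")
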