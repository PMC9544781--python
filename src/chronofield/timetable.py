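"""Molecular timetable method: internal-time inference from one expression snapshot.

The method selects *time-indicating genes* — genes whose time course under
the training condition is strongly cosine-periodic (high best-fit Pearson
correlation r) and high-amplitude (a = SD/mean) — records each one's
*molecular peak time* φ, and then estimates the *internal time* of any
sample by fitting a unit cosine to the sample's (φ_g, z_g) profile, where
z_g is the z-scored expression of marker gene g against its training mean
and SD.

Both fits scan 1440 candidate peak times on a 1-minute grid over the fixed
24-h period and return the grid argmax of the Pearson correlation, ties
broken toward the smallest candidate. (For the continuous problem this
argmax coincides with the closed-form harmonic-regression phase, so the
grid answer is within half a grid step of it.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from chronofield.matrix import ExpressionMatrix

PERIOD = 1440.0  # minutes; the period is fixed at 24 h, only the peak varies
GRID = np.arange(1440.0)  # candidate peak times, 1-minute steps

_TWO_PI = 2.0 * np.pi


@dataclass
class TimetableModel:
    """Selected time-indicating genes with their training statistics.

    ``table`` has one row per marker gene: phi (molecular peak time,
    minutes in [0, 1440)), r (best-fit cosine Pearson correlation),
    a (SD/mean amplitude index), mean and sd of training expression.
    """

    table: pd.DataFrame
    r_cut: float
    a_cut: float
    training_condition: str

    def __post_init__(self) -> None:
        required = {"phi", "r", "a", "mean", "sd"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"model table missing columns: {sorted(missing)}")
        if (self.table["sd"] <= 0).any():
            raise ValueError("model SDs must be positive")
        phi = self.table["phi"].to_numpy()
        if ((phi < 0) | (phi >= PERIOD)).any():
            raise ValueError("phi must lie in [0, 1440)")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def write(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out = out.rename(columns={"phi": "phi_min"})
        out.to_csv(path, sep="\t", lineterminator="\n")

    @classmethod
    def read(cls, path, r_cut=float("nan"), a_cut=float("nan"), training_condition="") -> "TimetableModel":
        table = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        table = table.rename(columns={"phi_min": "phi"})
        return cls(table, r_cut, a_cut, training_condition)


def circular_distance(a, b, period: float = PERIOD):
    """Shortest distance on a circle of the given period: min(|Δ|, period − |Δ|)."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % period
    return np.minimum(d, period - d)


def _grid_correlations(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Pearson correlation of series x(t) with cos(2π(t−φ)/1440) for every
    grid φ; returns the length-1440 correlation vector."""
    xc = x - x.mean()
    nx = np.sqrt((xc**2).sum())
    if nx == 0:
        raise ValueError("zero variance: series is constant")
    # cos(2π(t−φ)/P) = cosφ'·cos(ωt) + sinφ'·sin(ωt); precompute the two bases
    wt = _TWO_PI * t / PERIOD
    c, s = np.cos(wt), np.sin(wt)
    phi = _TWO_PI * GRID / PERIOD
    curves = np.outer(np.cos(phi), c) + np.outer(np.sin(phi), s)  # 1440 × n
    curves -= curves.mean(axis=1, keepdims=True)
    denom = np.sqrt((curves**2).sum(axis=1)) * nx
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = curves @ xc / denom
    return np.where(np.isfinite(corr), corr, -np.inf)


def cosine_fit(x, t) -> tuple[float, float]:
    """Best-fitting 24-h cosine peak time for a series.

    Scans the 1440 one-minute candidate peak times and returns
    ``(phi, r)``: the argmax peak time in minutes and its Pearson
    correlation. Ties break toward the smallest φ.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if x.shape != t.shape:
        raise ValueError("x and t must have the same length")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    corr = _grid_correlations(x, t)
    best = int(np.argmax(corr))  # argmax returns the first (smallest φ) on ties
    return float(GRID[best]), float(corr[best])


def amplitude_index(x) -> float:
    """Amplitude index a = SD/mean (sample SD, n−1 denominator)."""
    x = np.asarray(x, dtype=float)
    mean = x.mean()
    if mean <= 0:
        raise ValueError(f"amplitude index requires positive mean, got {mean}")
    return float(x.std(ddof=1) / mean)


def select_time_indicating(
    m: ExpressionMatrix,
    r_cut: float = 0.935,
    a_cut: float = 0.15,
    training_condition: str = "FIELD",
) -> TimetableModel:
    """Select time-indicating genes from the training condition's time course.

    Every replicate enters the cosine fit as an independent observation at
    its clock time. Genes pass if their best-fit cosine correlation
    r ≥ r_cut and amplitude index a ≥ a_cut; constant or non-positive-mean
    genes can never pass and are skipped. Defaults r=0.935, a=0.15.
    """
    train = m.subset_condition(training_condition)
    if train.n_samples == 0:
        raise ValueError(f"no samples for training condition {training_condition!r}")
    t = train.samples["clock_time"].to_numpy(dtype=float)
    span = (train.samples["day"] * 1440 + train.samples["clock_time"]).agg(["min", "max"])
    if span["max"] - span["min"] < 1320:  # need ≈ a full day of coverage
        raise ValueError("training samples must span at least one full day")

    X = train.values.to_numpy(dtype=float)
    means = X.mean(axis=1)
    sds = X.std(axis=1, ddof=1)
    ok = (sds > 0) & (means > 0)

    # vectorized grid correlation for all candidate genes at once
    wt = _TWO_PI * t / PERIOD
    c, s = np.cos(wt), np.sin(wt)
    phi = _TWO_PI * GRID / PERIOD
    curves = np.outer(np.cos(phi), c) + np.outer(np.sin(phi), s)
    curves -= curves.mean(axis=1, keepdims=True)
    curve_norm = np.sqrt((curves**2).sum(axis=1))

    Xc = X[ok] - X[ok].mean(axis=1, keepdims=True)
    xnorm = np.sqrt((Xc**2).sum(axis=1))
    corr = (Xc @ curves.T) / np.outer(xnorm, curve_norm)  # genes × 1440
    best_idx = np.argmax(corr, axis=1)
    best_r = corr[np.arange(corr.shape[0]), best_idx]
    a_vals = sds[ok] / means[ok]

    passing = (best_r >= r_cut) & (a_vals >= a_cut)
    if not passing.any():
        raise ValueError(
            f"no genes pass r ≥ {r_cut} and a ≥ {a_cut}; lower the cutoffs"
        )
    idx = m.gene_ids[ok][passing]
    table = pd.DataFrame(
        {
            "phi": GRID[best_idx[passing]],
            "r": best_r[passing],
            "a": a_vals[passing],
            "mean": means[ok][passing],
            "sd": sds[ok][passing],
        },
        index=idx,
    )
    return TimetableModel(table, r_cut, a_cut, training_condition)


def estimate_internal_time(model: TimetableModel, sample_expr) -> tuple[float, float]:
    """Internal time of one sample from its marker-gene expression.

    ``sample_expr`` maps gene id → expression (Series or dict). Expression
    is z-scored against the model's training mean/SD, and the candidate
    internal time T maximizing the Pearson correlation between z_g and
    cos(2π(φ_g − T)/1440) over the 1-minute grid is returned with its
    correlation. Ties break toward the smallest T.
    """
    expr = pd.Series(sample_expr)
    missing = [g for g in model.gene_ids if g not in expr.index]
    if missing:
        raise ValueError(f"sample missing model genes: {missing[:10]}")
    x = expr.loc[model.gene_ids].to_numpy(dtype=float)
    z = (x - model.table["mean"].to_numpy()) / model.table["sd"].to_numpy()
    corr = _profile_correlations(z, model.table["phi"].to_numpy())
    best = int(np.argmax(corr))
    return float(GRID[best]), float(corr[best])


def _profile_correlations(z: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Correlation of a (φ_g, z_g) profile with cos(2π(φ_g − T)/1440) for
    every candidate T on the grid."""
    zc = z - z.mean()
    nz = np.sqrt((zc**2).sum())
    if nz == 0:
        raise ValueError("zero variance: z-score profile is constant")
    wphi = _TWO_PI * phi / PERIOD
    c, s = np.cos(wphi), np.sin(wphi)
    wT = _TWO_PI * GRID / PERIOD
    curves = np.outer(np.cos(wT), c) + np.outer(np.sin(wT), s)  # 1440 × genes
    curves -= curves.mean(axis=1, keepdims=True)
    denom = np.sqrt((curves**2).sum(axis=1)) * nz
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = curves @ zc / denom
    return np.where(np.isfinite(corr), corr, -np.inf)


def estimate_internal_times(model: TimetableModel, m: ExpressionMatrix) -> pd.DataFrame:
    """Internal-time estimates for every sample of a matrix.

    Returns a DataFrame indexed by sample_id with columns
    internal_time (minutes), fit_r, clock_time, and the signed circular
    deviation internal − clock in minutes.
    """
    rows = {}
    for sid in m.values.columns:
        T, r = estimate_internal_time(model, m.values[sid])
        rows[sid] = (T, r)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["internal_time", "fit_r"])
    out["clock_time"] = m.samples["clock_time"].astype(float)
    delta = (out["internal_time"] - out["clock_time"] + PERIOD / 2) % PERIOD - PERIOD / 2
    out["deviation_min"] = delta
    return out


def measurement_noise(
    model: TimetableModel, m: ExpressionMatrix, amplitude: str = "fit"
) -> pd.DataFrame:
    """Per-gene measurement noise of the marker set over a sample matrix.

    For every sample the internal time is estimated; the residual of gene g
    in sample s is its observed z-score minus the gene's expected cosine
    value β_g·cos(2π(φ_g − T̂_s)/1440). With ``amplitude="fit"`` (default)
    β_g is the per-gene least-squares amplitude across samples, so a
    noise-free sinusoidal gene has zero residuals (the z-score of an ideal
    sinusoid is a √2-amplitude cosine, not a unit one);
    ``amplitude="unit"`` forces β_g = 1. Noise is the SD (n−1) of the
    residuals, reported both on the z scale and ×100 as a percentage (the
    percent convention is a package assumption, recorded because the
    normalization baseline of published percentage figures is ambiguous).
    """
    est = estimate_internal_times(model, m)
    X = m.values.loc[model.gene_ids].to_numpy(dtype=float)
    Z = (X - model.table["mean"].to_numpy()[:, None]) / model.table["sd"].to_numpy()[:, None]
    phi = model.table["phi"].to_numpy()[:, None]
    T = est["internal_time"].to_numpy()[None, :]
    cosine = np.cos(_TWO_PI * (phi - T) / PERIOD)
    if amplitude == "fit":
        beta = (Z * cosine).sum(axis=1) / (cosine**2).sum(axis=1)
    elif amplitude == "unit":
        beta = np.ones(Z.shape[0])
    else:
        raise ValueError(f"amplitude must be 'fit' or 'unit', got {amplitude!r}")
    resid = Z - beta[:, None] * cosine
    sd = resid.std(axis=1, ddof=1)
    return pd.DataFrame(
        {"noise_sd": sd, "noise_percent": 100.0 * sd, "fitted_amplitude": beta},
        index=model.gene_ids,
    )
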