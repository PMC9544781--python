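"""Shared fixtures: small deterministic expression matrices and presets."""

import numpy as np
import pandas as pd
import pytest

from chronofield.matrix import ExpressionMatrix
from chronofield.simulate import EXP1_TIMEPOINTS


#: balanced 12-point 2-h grid covering one day with no repeated clock time
EVEN_TIMEPOINTS = tuple((0, 120 * i) for i in range(12))


def field_sample_frame(reps: int = 4, grid=EXP1_TIMEPOINTS) -> pd.DataFrame:
    """Metadata for FIELD replicates on the given (day, clock) grid."""
    rows, ids = [], []
    for (day, clock) in grid:
        for rep in range(1, reps + 1):
            ids.append(f"FIELD_d{day}t{clock:04d}_r{rep}")
            rows.append(("FIELD", clock, day, rep, "exp1"))
    return pd.DataFrame(
        rows,
        index=pd.Index(ids, name="sample_id"),
        columns=["condition", "clock_time", "day", "replicate", "experiment"],
    )


def cosine_field_matrix(
    n_cosine: int = 50,
    n_flat: int = 50,
    seed: int = 0,
    noise_sd: float = 0.0,
    amplitude_range=(0.3, 0.9),
    mean: float = 100.0,
    reps: int = 4,
    on_grid_phases: bool = False,
    grid=EXP1_TIMEPOINTS,
):
    """FIELD-only matrix of noiseless-or-noisy cosine genes plus flat genes.

    Returns (ExpressionMatrix(rpm-tagged), phases, amplitudes); phases are
    NaN for flat genes. ``noise_sd`` is additive Gaussian noise expressed as
    a fraction of each gene's mean. ``grid=EVEN_TIMEPOINTS`` gives a
    balanced circular design (no repeated clock time), on which the
    z-score of a noise-free sinusoid is exactly a √2-amplitude cosine.
    """
    rng = np.random.default_rng(seed)
    samples = field_sample_frame(reps, grid)
    clocks = samples["clock_time"].to_numpy(dtype=float)
    phases = rng.uniform(0, 1440, n_cosine)
    if on_grid_phases:
        phases = np.round(phases)
    amps = rng.uniform(*amplitude_range, n_cosine)
    rows = [
        mean * (1 + amps[i] * np.cos(2 * np.pi * (clocks - phases[i]) / 1440.0))
        for i in range(n_cosine)
    ]
    rows += [np.full(len(clocks), mean) for _ in range(n_flat)]
    X = np.asarray(rows)
    if noise_sd > 0:
        X = X + rng.normal(0, noise_sd * mean, X.shape)
    X = np.clip(X, 0, None)
    values = pd.DataFrame(
        X, index=[f"g{i:03d}" for i in range(n_cosine + n_flat)], columns=samples.index
    )
    m = ExpressionMatrix(values, samples, "rpm")
    phi = np.concatenate([phases, np.full(n_flat, np.nan)])
    amp = np.concatenate([amps, np.zeros(n_flat)])
    return m, phi, amp


@pytest.fixture(scope="session")
def cosine_field():
    return cosine_field_matrix()


@pytest.fixture()
def tiny_counts_files(tmp_path):
    """A 3-gene × 2-sample count TSV plus matching metadata TSV on disk."""
    counts = tmp_path / "counts.tsv"
    counts.write_text(
        "gene_id\ts1\ts2\n"
        "gA\t10\t5\n"
        "gB\t90\t45\n"
        "gC\t0\t50\n"
    )
    meta = tmp_path / "meta.tsv"
    meta.write_text(
        "sample_id\tcondition\tclock_time\tday\treplicate\texperiment\n"
        "s1\tFIELD\t7:00\t0\t1\texp1\n"
        "s2\tFL_FTH\t7:00\t0\t1\texp1\n"
    )
    return counts, meta
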