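"""Expression-matrix container, TSV I/O and the core expression transforms.

The central object is :class:`ExpressionMatrix`: a gene × sample table of
non-negative numbers together with per-sample metadata and a unit tag that
records where the values sit in the counts → rpm → log2(rpm+1) chain.
Operations that are only meaningful on one unit (e.g. rpm normalization on
raw counts) enforce the tag and fail loudly otherwise.

Time is stored as minutes since midnight plus an integer day index, so that
a 24-h time course starting at 19:00 can distinguish the first 19:00 sample
from the one taken 24 h later (written "19:00_2" in labels).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

CONDITIONS = ("FIELD", "FL_FTH", "CL_CTH", "FL_CTH", "CL_FTH")
EXPERIMENTS = ("exp1", "exp2")
UNITS = ("counts", "rpm", "log2rpm")

META_COLUMNS = ["sample_id", "condition", "clock_time", "day", "replicate", "experiment"]


def parse_clock(text: str) -> int:
    """Parse "HH:MM" into minutes since midnight in [0, 1440)."""
    try:
        hh, mm = str(text).split(":")
        minutes = int(hh) * 60 + int(mm)
    except (ValueError, AttributeError) as exc:
        raise ValueError(f"cannot parse clock time {text!r}, expected HH:MM") from exc
    if not 0 <= minutes < 1440:
        raise ValueError(f"clock time {text!r} outside [0:00, 24:00)")
    return minutes


def format_clock(minutes: int) -> str:
    return f"{minutes // 60}:{minutes % 60:02d}"


def timepoint_key(day: int, clock: int) -> int:
    """Sortable unique key for a sampling timepoint: minutes since day 0 midnight."""
    return int(day) * 1440 + int(clock)


def timepoint_label(key: int) -> str:
    """Human label for a timepoint key; day ≥ 1 gets a "_2"-style suffix."""
    day, clock = divmod(int(key), 1440)
    base = format_clock(clock)
    return base if day == 0 else f"{base}_{day + 1}"


def timepoint_labels(keys) -> dict[int, str]:
    """Context-aware labels for a set of timepoint keys: only a clock time
    that recurs on a later day gets a suffix, so a course starting 19:00
    ends at "19:00_2" while 7:00 on day 1 stays "7:00"."""
    labels: dict[int, str] = {}
    seen: dict[int, int] = {}
    for key in sorted({int(k) for k in keys}):
        clock = key % 1440
        n = seen.get(clock, 0)
        labels[key] = format_clock(clock) if n == 0 else f"{format_clock(clock)}_{n + 1}"
        seen[clock] = n + 1
    return labels


@dataclass
class ExpressionMatrix:
    """Gene × sample expression table with metadata and a unit tag.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample_id.
    samples
        DataFrame with columns condition, clock_time (minutes), day,
        replicate, experiment; indexed by sample_id, in column order
        of ``values``.
    unit
        One of ``counts``, ``rpm``, ``log2rpm``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if list(self.values.columns) != list(self.samples.index):
            missing = [c for c in self.values.columns if c not in self.samples.index]
            if missing:
                raise ValueError(f"samples missing from metadata: {missing[:5]}")
            # same set, different order: align metadata to the matrix
            self.samples = self.samples.loc[list(self.values.columns)]
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite value at gene {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )
        if self.unit in ("counts", "rpm") and (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative value at gene {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )
        key = self.samples[["condition", "clock_time", "day", "replicate", "experiment"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValueError(f"duplicate sample key: {dup.to_dict()}")

    # -- conveniences --------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def timepoints(self) -> np.ndarray:
        """Sorted unique timepoint keys (day*1440 + clock)."""
        keys = self.samples["day"].to_numpy() * 1440 + self.samples["clock_time"].to_numpy()
        return np.unique(keys)

    def sample_timepoints(self) -> pd.Series:
        """Per-sample timepoint key, indexed by sample_id."""
        return self.samples["day"] * 1440 + self.samples["clock_time"]

    def subset_samples(self, mask: pd.Series | np.ndarray) -> "ExpressionMatrix":
        ids = self.samples.index[np.asarray(mask, dtype=bool)]
        return ExpressionMatrix(self.values[ids].copy(), self.samples.loc[ids].copy(), self.unit)

    def subset_condition(self, condition: str) -> "ExpressionMatrix":
        return self.subset_samples((self.samples["condition"] == condition).to_numpy())

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)].copy(), self.samples.copy(), self.unit)


# ---------------------------------------------------------------------------
# TSV I/O (tab-separated, UTF-8, '.' decimal, no quoting; header cell gene_id)
# ---------------------------------------------------------------------------

def read_metadata(meta_path) -> pd.DataFrame:
    meta = pd.read_csv(meta_path, sep="\t", dtype=str, comment="#")
    missing_cols = [c for c in META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata missing required columns: {missing_cols}")
    meta = meta.set_index("sample_id")
    if meta.index.duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    out = pd.DataFrame(index=meta.index)
    out["condition"] = meta["condition"]
    bad_cond = sorted(set(out["condition"]) - set(CONDITIONS))
    if bad_cond:
        raise ValueError(f"unknown conditions in metadata: {bad_cond}")
    out["clock_time"] = meta["clock_time"].map(parse_clock)
    out["day"] = meta["day"].astype(int)
    out["replicate"] = meta["replicate"].astype(int)
    if (out["replicate"] < 1).any():
        raise ValueError("replicate indices must be positive")
    out["experiment"] = meta["experiment"]
    bad_exp = sorted(set(out["experiment"]) - set(EXPERIMENTS))
    if bad_exp:
        raise ValueError(f"unknown experiment labels: {bad_exp}")
    return out


def read_counts(counts_path, meta_path) -> ExpressionMatrix:
    """Read a gene × sample count TSV plus its sample-metadata TSV.

    The counts file has a header row of sample ids (first cell ``gene_id``)
    and one row per gene. Every column must have a metadata row; extra
    metadata rows are ignored so one metadata file can serve several
    sub-matrices.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
    counts.index = counts.index.astype(str)
    meta = read_metadata(meta_path)
    missing = [c for c in counts.columns if c not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        for j, col in enumerate(counts.columns):
            colvals = pd.to_numeric(counts[col], errors="coerce")
            if colvals.isna().any():
                gene = counts.index[colvals.isna().to_numpy().argmax()]
                raise ValueError(f"non-numeric count at gene {gene!r}, sample {col!r}")
        counts = counts.astype(float)
        arr = counts.to_numpy()
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ValueError(f"negative count at gene {counts.index[i]!r}, sample {counts.columns[j]!r}")
    return ExpressionMatrix(counts.astype(float), meta.loc[list(counts.columns)].copy(), "counts")


def write_counts(m: ExpressionMatrix, path, header_lines: list[str] | None = None) -> None:
    """Write the value matrix as TSV; optional '#'-prefixed provenance header."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        buf = io.StringIO()
        out = m.values.copy()
        out.index.name = "gene_id"
        out.to_csv(buf, sep="\t", lineterminator="\n")
        fh.write(buf.getvalue())


def write_metadata(samples: pd.DataFrame, path) -> None:
    out = samples.copy()
    out.insert(1, "clock_hhmm", out["clock_time"].map(format_clock))
    out = out.drop(columns=["clock_time"]).rename(columns={"clock_hhmm": "clock_time"})
    out = out[["condition", "clock_time", "day", "replicate", "experiment"]]
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def compute_rpm(m: ExpressionMatrix, exclude_ids=()) -> ExpressionMatrix:
    """Reads-per-million normalization after dropping an exclusion list.

    Typical use is excluding rRNA genes before scaling: each retained gene's
    count is divided by the per-sample total over retained genes and
    multiplied by 1e6, so every output column sums to exactly one million.
    """
    if m.unit != "counts":
        raise ValueError(f"compute_rpm requires unit='counts', got {m.unit!r}")
    excl = set(exclude_ids)
    keep = [g for g in m.gene_ids if g not in excl]
    vals = m.values.loc[keep]
    totals = vals.sum(axis=0)
    zero = totals.index[totals.to_numpy() <= 0].tolist()
    if zero:
        raise ValueError(f"samples with zero retained total counts: {zero}")
    rpm = vals.div(totals, axis=1) * 1e6
    return ExpressionMatrix(rpm, m.samples.copy(), "rpm")


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(rpm + 1) transform."""
    if m.unit != "rpm":
        raise ValueError(f"log_transform requires unit='rpm', got {m.unit!r}")
    return ExpressionMatrix(np.log2(m.values + 1.0), m.samples.copy(), "log2rpm")


def filter_min_mean(m: ExpressionMatrix, threshold: float = 10.0) -> ExpressionMatrix:
    """Keep genes whose mean raw count across all samples is strictly > threshold."""
    if m.unit != "counts":
        raise ValueError(f"filter_min_mean requires unit='counts', got {m.unit!r}")
    keep = m.values.mean(axis=1) > threshold
    return ExpressionMatrix(m.values.loc[keep].copy(), m.samples.copy(), "counts")
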