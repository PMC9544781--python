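"""Two-group differential expression for count data.

Three layers, matching how multi-step normalization pipelines are built:

1. :func:`tmm_factors` — trimmed mean of M-values between-sample
   normalization (composition-robust scale factors with geometric mean 1).
2. :func:`nb_exact_test` — negative-binomial conditional exact test with a
   common dispersion estimated by conditional maximum likelihood; two-sided
   p-values sum all group-split outcomes no more probable than the one
   observed, conditional on the two group totals.
3. :func:`ideges_normalize` — DEG-elimination normalization: TMM, a liberal
   exact-test pass to flag putative DEGs, then TMM recomputed on the
   non-DEG genes only, which removes the bias that asymmetric differential
   expression induces in the scale factors.

:func:`call_degs_per_timepoint` applies the full chain independently at
every shared sampling timepoint of two conditions.

Counts are rounded to the nearest integer before exact testing (fractional
expected counts from upstream quantifiers are accepted), and libraries are
adjusted to the geometric-mean effective size by scaling means rather than
resampling pseudo-counts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from chronofield.matrix import ExpressionMatrix

_DEG_COLUMNS = ["log2fc", "pvalue", "qvalue", "is_deg"]


def _as_frame(counts) -> pd.DataFrame:
    if isinstance(counts, ExpressionMatrix):
        return counts.values
    return pd.DataFrame(counts)


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def tmm_factors(
    counts,
    lib_sizes=None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.DataFrame:
    """Trimmed-mean-of-M-values normalization factors.

    The reference sample is the one whose upper quartile of nonzero
    relative counts is closest to the mean upper quartile. For every other
    sample, gene-wise log2 abundance ratios M and average log2 abundances A
    are computed over genes nonzero in both; the most extreme ``trim_m`` of
    M and ``trim_a`` of A are trimmed (half per tail) and the factor is two
    to the precision-weighted mean of the retained M, weights the inverse
    asymptotic binomial variance. Factors are rescaled to geometric mean 1.

    Returns a DataFrame indexed by sample with columns ``library_size``
    and ``norm_factor``.
    """
    table = _as_frame(counts)
    X = table.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = np.asarray(lib_sizes, dtype=float) if lib_sizes is not None else X.sum(axis=0)
    if (lib <= 0).any():
        bad = table.columns[lib <= 0].tolist()
        raise ValueError(f"samples with non-positive library size: {bad}")
    if n_genes == 0:
        return pd.DataFrame(
            {"library_size": lib, "norm_factor": np.ones(n_samples)}, index=table.columns
        )

    rel = X / lib
    uq = np.array([
        np.quantile(col[col > 0], 0.75) if (col > 0).any() else 0.0 for col in rel.T
    ])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(n_samples)
    yr, Nr = X[:, ref], lib[ref]
    for i in range(n_samples):
        if i == ref:
            continue
        yi, Ni = X[:, i], lib[i]
        mask = (yi > 0) & (yr > 0)
        if not mask.any():
            raise ValueError(
                f"sample {table.columns[i]!r} shares no nonzero genes with the reference"
            )
        pi, pr = yi[mask] / Ni, yr[mask] / Nr
        M = np.log2(pi / pr)
        A = 0.5 * np.log2(pi * pr)
        w = (Ni - yi[mask]) / (Ni * yi[mask]) + (Nr - yr[mask]) / (Nr * yr[mask])
        keep = _double_trim(M, A, trim_m, trim_a)
        if not keep.any():  # pathological tiny inputs: fall back to no trimming
            keep = np.ones(M.size, dtype=bool)
        with np.errstate(divide="ignore"):
            inv_w = 1.0 / w[keep]
        inv_w[~np.isfinite(inv_w)] = 0.0
        if inv_w.sum() == 0:
            factors[i] = 2.0 ** np.mean(M[keep])
        else:
            factors[i] = 2.0 ** (np.sum(M[keep] * inv_w) / inv_w.sum())
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.DataFrame({"library_size": lib, "norm_factor": factors}, index=table.columns)


def _double_trim(M: np.ndarray, A: np.ndarray, trim_m: float, trim_a: float) -> np.ndarray:
    """Boolean mask keeping genes inside both the M and the A trim bands."""
    n = M.size
    lo_m, hi_m = _trim_bounds(n, trim_m)
    lo_a, hi_a = _trim_bounds(n, trim_a)
    rank_m = np.empty(n, dtype=int)
    rank_m[np.argsort(M, kind="stable")] = np.arange(n)
    rank_a = np.empty(n, dtype=int)
    rank_a[np.argsort(A, kind="stable")] = np.arange(n)
    return (rank_m >= lo_m) & (rank_m < hi_m) & (rank_a >= lo_a) & (rank_a < hi_a)


def _trim_bounds(n: int, trim: float) -> tuple[int, int]:
    cut = int(np.floor(n * trim / 2.0))
    return cut, n - cut


# ---------------------------------------------------------------------------
# NB conditional exact test
# ---------------------------------------------------------------------------

def _split_groups(columns, groups):
    groups = np.asarray(groups)
    if groups.size != len(columns):
        raise ValueError("groups must have one label per sample")
    levels = pd.unique(groups)
    if levels.size != 2:
        raise ValueError(f"exactly two groups required, got {list(levels)}")
    idx1 = np.flatnonzero(groups == levels[0])
    idx2 = np.flatnonzero(groups == levels[1])
    if idx1.size < 2 or idx2.size < 2:
        raise ValueError("each group needs at least 2 replicates")
    return levels, idx1, idx2


def _conditional_loglik(y: np.ndarray, group_slices, r: float) -> float:
    """Summed NB conditional log-likelihood (conditional on group totals)
    over all genes and groups, as a function of the size parameter r=1/φ."""
    total = 0.0
    for idx in group_slices:
        yk = y[:, idx]
        n_k = idx.size
        z = yk.sum(axis=1)
        total += float(
            np.sum(gammaln(yk + r))
            - np.sum(gammaln(z + n_k * r))
            + z.size * gammaln(n_k * r)
            - z.size * n_k * gammaln(r)
        )
    return total


def estimate_common_dispersion(y: np.ndarray, group_slices) -> float:
    """Common NB dispersion φ maximizing the conditional log-likelihood.

    Falls back to a pooled method-of-moments estimate (with a warning) if
    the likelihood optimization fails.
    """
    informative = y.sum(axis=1) > 0
    y = y[informative]
    if y.shape[0] == 0:
        return 0.1

    def neg_ll(log_phi: float) -> float:
        r = 1.0 / np.exp(log_phi)
        return -_conditional_loglik(y, group_slices, r)

    try:
        res = minimize_scalar(neg_ll, bounds=(np.log(1e-6), np.log(30.0)), method="bounded")
        if not res.success or not np.isfinite(res.fun):
            raise RuntimeError(res.message)
        return float(np.exp(res.x))
    except Exception as exc:  # pragma: no cover - defensive fallback
        warnings.warn(f"dispersion fit failed ({exc}); using method-of-moments")
        phis = []
        for idx in group_slices:
            mu = y[:, idx].mean(axis=1)
            var = y[:, idx].var(axis=1, ddof=1)
            ok = mu > 0
            phis.append(np.clip((var[ok] - mu[ok]) / mu[ok] ** 2, 0, None))
        pooled = np.concatenate(phis)
        return float(max(np.mean(pooled), 1e-6)) if pooled.size else 0.1


def _exact_pvalue(z1: int, z2: int, n1: int, n2: int, r: float) -> float:
    """Two-sided conditional exact p for a group split (z1, z2) of z = z1+z2
    reads between n1 and n2 equal-size NB libraries with size parameter r.

    Conditional on z, the group-1 total follows a negative hypergeometric
    law; the p-value sums the probabilities of all splits no more probable
    than the observed one.
    """
    z = z1 + z2
    if z == 0:
        return 1.0
    k = np.arange(z + 1.0)
    logw = (
        gammaln(k + n1 * r)
        - gammaln(k + 1.0)
        + gammaln(z - k + n2 * r)
        - gammaln(z - k + 1.0)
    )
    logw -= logsumexp(logw)
    cutoff = logw[z1] + 1e-10  # tolerate float ties (e.g. symmetric splits)
    return float(min(1.0, np.exp(logsumexp(logw[logw <= cutoff]))))


def nb_exact_test(
    counts,
    groups,
    factors=None,
    dispersion="common",
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-gene NB conditional exact test between two groups.

    ``groups`` gives one label per sample (two levels, ≥ 2 replicates
    each); the reported log2 fold-change is level2 vs level1 in order of
    first appearance. ``factors`` may be the output of
    :func:`tmm_factors` (or a plain Series of factors); effective library
    sizes are scaled to their geometric mean before testing.
    ``dispersion`` is ``"common"`` (estimated by conditional maximum
    likelihood) or a float.

    Returns a DataFrame with columns log2fc, pvalue, qvalue (BH) and
    is_deg (qvalue < ``fdr``); the fitted dispersion and group order are
    stored in ``.attrs``.
    """
    table = _as_frame(counts)
    levels, idx1, idx2 = _split_groups(table.columns, groups)
    if table.shape[0] == 0:
        out = pd.DataFrame(columns=_DEG_COLUMNS, index=table.index)
        out.attrs["dispersion"] = np.nan
        out.attrs["groups"] = tuple(levels)
        return out

    y = np.rint(table.to_numpy(dtype=float))
    if y[:, idx1].sum() == 0 or y[:, idx2].sum() == 0:
        raise ValueError("one group has zero counts for every gene")

    lib = y.sum(axis=0)
    if factors is None:
        f = np.ones(y.shape[1])
    elif isinstance(factors, pd.DataFrame):
        f = factors.loc[list(table.columns), "norm_factor"].to_numpy(dtype=float)
    else:
        f = pd.Series(factors).loc[list(table.columns)].to_numpy(dtype=float)
    eff = lib * f
    common_size = np.exp(np.mean(np.log(eff)))
    y_adj = np.rint(y * (common_size / eff))

    if dispersion == "common":
        phi = estimate_common_dispersion(y_adj, (idx1, idx2))
    else:
        phi = float(dispersion)
        if phi < 0:
            raise ValueError("dispersion must be ≥ 0")
    r = 1.0 / max(phi, 1e-8)

    z1 = y_adj[:, idx1].sum(axis=1).astype(np.int64)
    z2 = y_adj[:, idx2].sum(axis=1).astype(np.int64)
    n1, n2 = idx1.size, idx2.size

    pvals = np.ones(y.shape[0])
    cache: dict[tuple[int, int], float] = {}
    for g in range(y.shape[0]):
        key = (int(z1[g]), int(z2[g]))
        if key not in cache:
            cache[key] = _exact_pvalue(key[0], key[1], n1, n2, r)
        pvals[g] = cache[key]

    log2fc = np.log2((z2 / n2 + 0.5) / (z1 / n1 + 0.5))
    qvals = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvals,
            "qvalue": qvals,
            "is_deg": qvals < fdr,
        },
        index=table.index,
    )
    out.attrs["dispersion"] = phi
    out.attrs["groups"] = tuple(levels)
    return out


# ---------------------------------------------------------------------------
# DEG-elimination normalization
# ---------------------------------------------------------------------------

def ideges_normalize(
    counts,
    groups,
    elim_fdr: float = 0.1,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.DataFrame:
    """Multi-step DEG-elimination normalization (TMM → exact test → TMM).

    Step 1 computes TMM factors; step 2 runs the exact test with them and
    flags genes at q < ``elim_fdr``; step 3 recomputes TMM on the unflagged
    genes only and converts the subset factors back to full-library-size
    scale. If every gene is flagged, step-1 factors are returned with a
    warning.
    """
    table = _as_frame(counts)
    step1 = tmm_factors(table, trim_m=trim_m, trim_a=trim_a)
    if table.shape[0] == 0:
        return step1
    result = nb_exact_test(table, groups, factors=step1)
    keep = ~(result["qvalue"] < elim_fdr)
    if not keep.any():
        warnings.warn("all genes flagged as DEGs; falling back to step-1 TMM factors")
        return step1
    sub = table.loc[keep.to_numpy()]
    sub_lib = sub.to_numpy(dtype=float).sum(axis=0)
    if (sub_lib <= 0).any():
        warnings.warn("a sample has zero counts over non-DEG genes; using step-1 factors")
        return step1
    sub_f = tmm_factors(sub, trim_m=trim_m, trim_a=trim_a)
    full_lib = step1["library_size"].to_numpy()
    eff = sub_lib * sub_f["norm_factor"].to_numpy()
    factors = eff / full_lib
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.DataFrame({"library_size": full_lib, "norm_factor": factors}, index=table.columns)


# ---------------------------------------------------------------------------
# Per-timepoint DEG calling
# ---------------------------------------------------------------------------

def call_degs_per_timepoint(
    m: ExpressionMatrix,
    cond_a: str,
    cond_b: str,
    fdr: float = 0.05,
    elim_fdr: float = 0.1,
) -> dict[int, pd.DataFrame]:
    """DEG tests between two conditions, run independently per timepoint.

    At each timepoint shared by both conditions with ≥ 2 replicates each,
    DEG-elimination normalization is followed by the exact test on that
    timepoint's replicates; genes are flagged at q < ``fdr``. Timepoints
    missing from either condition are skipped with a warning. Returns a
    map timepoint key → result table (log2fc is ``cond_b`` vs ``cond_a``).
    """
    if m.unit != "counts":
        raise ValueError(f"DEG calling requires unit='counts', got {m.unit!r}")
    tp = m.sample_timepoints()
    cond = m.samples["condition"]
    results: dict[int, pd.DataFrame] = {}
    for key in np.unique(tp):
        ids_a = m.samples.index[(cond == cond_a) & (tp == key)]
        ids_b = m.samples.index[(cond == cond_b) & (tp == key)]
        if len(ids_a) < 2 or len(ids_b) < 2:
            warnings.warn(
                f"timepoint {key}: fewer than 2 replicates in "
                f"{cond_a if len(ids_a) < 2 else cond_b}; skipped"
            )
            continue
        sub = m.values[list(ids_a) + list(ids_b)]
        groups = [cond_a] * len(ids_a) + [cond_b] * len(ids_b)
        if m.n_genes == 0:
            results[int(key)] = pd.DataFrame(columns=_DEG_COLUMNS)
            continue
        factors = ideges_normalize(sub, groups, elim_fdr=elim_fdr)
        results[int(key)] = nb_exact_test(sub, groups, factors=factors, fdr=fdr)
    return results


def deg_gene_sets(results: dict[int, pd.DataFrame]) -> dict[int, set]:
    """Timepoint → set of flagged gene ids."""
    return {tp: set(res.index[res["is_deg"].astype(bool)]) for tp, res in results.items()}
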