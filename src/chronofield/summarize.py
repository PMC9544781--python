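"""Transcriptome-similarity summaries between conditions.

Works on log2(rpm+1) matrices: per-timepoint between-condition sample
correlations with rank-sum comparisons, per-gene time-course correlations
with multiplicity control, PCA score summaries, and correlation-distance
hierarchical clustering with Newick export.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from chronofield.matrix import ExpressionMatrix


def _require_log(m: ExpressionMatrix, op: str) -> None:
    if m.unit != "log2rpm":
        raise ValueError(f"{op} expects unit='log2rpm', got {m.unit!r}")


def timepoint_condition_correlation(
    m: ExpressionMatrix,
    baseline: str,
    others,
    method: str = "pairs",
) -> pd.DataFrame:
    """Pearson correlation of whole transcriptomes between conditions,
    per timepoint.

    With ``method="pairs"`` (default) every baseline replicate is
    correlated with every other-condition replicate at the same timepoint,
    preserving within-timepoint variability (a 4×4 design yields 16 r
    values per timepoint); ``method="mean_profile"`` correlates the two
    replicate-mean profiles instead. Returns a long DataFrame
    (timepoint, condition, rep_baseline, rep_other, r).
    """
    _require_log(m, "timepoint_condition_correlation")
    if m.n_genes < 2:
        raise ValueError("need at least 2 genes to correlate transcriptomes")
    tp = m.sample_timepoints()
    cond = m.samples["condition"]
    rows = []
    for other in others:
        shared = sorted(
            set(tp[cond == baseline].unique()) & set(tp[cond == other].unique())
        )
        for key in shared:
            ids_a = m.samples.index[(cond == baseline) & (tp == key)]
            ids_b = m.samples.index[(cond == other) & (tp == key)]
            if method == "mean_profile":
                prof_a = m.values[list(ids_a)].mean(axis=1)
                prof_b = m.values[list(ids_b)].mean(axis=1)
                r = float(np.corrcoef(prof_a, prof_b)[0, 1])
                rows.append((key, other, "mean", "mean", r))
            elif method == "pairs":
                A = m.values[list(ids_a)].to_numpy()
                B = m.values[list(ids_b)].to_numpy()
                Ac = A - A.mean(axis=0)
                Bc = B - B.mean(axis=0)
                denom = np.outer(
                    np.sqrt((Ac**2).sum(axis=0)), np.sqrt((Bc**2).sum(axis=0))
                )
                R = (Ac.T @ Bc) / denom
                for i, sa in enumerate(ids_a):
                    for j, sb in enumerate(ids_b):
                        rows.append((key, other, sa, sb, float(R[i, j])))
            else:
                raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(
        rows, columns=["timepoint", "condition", "rep_baseline", "rep_other", "r"]
    )


def rank_sum_compare(groups: dict, pairs=None) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum tests between groups of values, with BH
    adjustment across the tested pairs.

    ``groups`` maps name → list of values (each ≥ 3); ``pairs`` restricts
    testing to the given (name, name) tuples, defaulting to all unordered
    pairs. Uses the tie-corrected normal approximation; a pair with every
    value identical across both groups gets p = 1.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for name, vals in groups.items():
        if len(vals) < 3:
            raise ValueError(f"group {name!r} has fewer than 3 values")
    if pairs is None:
        pairs = list(itertools.combinations(names, 2))
    rows = []
    for a, b in pairs:
        x = np.asarray(groups[a], dtype=float)
        y = np.asarray(groups[b], dtype=float)
        if np.unique(np.concatenate([x, y])).size == 1:
            stat, p = float(x.size * y.size / 2.0), 1.0
        else:
            res = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=False
            )
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append((a, b, stat, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "U", "pvalue"])
    out["qvalue"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out


def per_gene_correlation(
    m: ExpressionMatrix,
    baseline: str,
    other: str,
    r_cut: float = 0.7,
    q_cut: float = 0.05,
) -> tuple[pd.DataFrame, int]:
    """Per-gene correlation of two conditions' time courses.

    For every gene, Pearson r between the replicate-mean time courses of
    the two conditions over their shared timepoints; p from the
    t-distributed statistic r·√((n−2)/(1−r²)) with n−2 df; BH q across
    tested genes. Genes constant in either condition are skipped with a
    warning. Returns the table and the count of genes with r > ``r_cut``
    and q < ``q_cut``.
    """
    _require_log(m, "per_gene_correlation")
    tp = m.sample_timepoints()
    cond = m.samples["condition"]
    shared = sorted(set(tp[cond == baseline].unique()) & set(tp[cond == other].unique()))
    if len(shared) < 4:
        raise ValueError("need at least 4 shared timepoints")

    def mean_profiles(c: str) -> pd.DataFrame:
        sub = m.subset_condition(c)
        keys = sub.sample_timepoints()
        prof = sub.values.T.groupby(keys.to_numpy()).mean().T
        return prof[shared]

    A = mean_profiles(baseline).to_numpy()
    B = mean_profiles(other).to_numpy()
    n = len(shared)
    sa = A.std(axis=1)
    sb = B.std(axis=1)
    ok = (sa > 0) & (sb > 0)
    skipped = int((~ok).sum())
    if skipped:
        warnings.warn(f"{skipped} genes with a constant time course skipped")
    Ac = A[ok] - A[ok].mean(axis=1, keepdims=True)
    Bc = B[ok] - B[ok].mean(axis=1, keepdims=True)
    r = (Ac * Bc).sum(axis=1) / np.sqrt((Ac**2).sum(axis=1) * (Bc**2).sum(axis=1))
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        tstat = r * np.sqrt((n - 2) / np.clip(1 - r**2, 1e-300, None))
    p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    q = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {"r": r, "pvalue": p, "qvalue": q}, index=m.gene_ids[ok]
    )
    count = int(((table["r"] > r_cut) & (table["qvalue"] < q_cut)).sum())
    return table, count


def pca_scores(m: ExpressionMatrix, n_components: int | None = None):
    """Gene-centred PCA over all samples.

    Genes are features (centred, not scaled). Returns
    ``(scores, summary, variance_ratio)``: per-sample scores on all
    components, per-(condition, timepoint) mean ± standard error on PC1 and
    PC2, and the variance fraction per component.
    """
    X = m.values.to_numpy(dtype=float).T  # samples × genes
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples for PCA")
    k = min(X.shape) if n_components is None else n_components
    pca = PCA(n_components=k, svd_solver="full")
    S = pca.fit_transform(X)
    scores = pd.DataFrame(
        S, index=m.samples.index, columns=[f"PC{i+1}" for i in range(S.shape[1])]
    )
    meta = scores[["PC1", "PC2"]].copy()
    meta["condition"] = m.samples["condition"]
    meta["timepoint"] = m.sample_timepoints()
    grouped = meta.groupby(["condition", "timepoint"], observed=True)[["PC1", "PC2"]]
    summary = grouped.agg(["mean", "sem"])
    summary.columns = ["_".join(c) for c in summary.columns]
    return scores, summary, pca.explained_variance_ratio_


def correlation_hclust(m: ExpressionMatrix, linkage: str = "average"):
    """Hierarchical clustering of samples on correlation distance.

    Distance = 1 − Pearson r between sample expression profiles;
    agglomeration with the configured linkage. Returns
    ``(linkage_matrix, newick)`` where the Newick string carries branch
    lengths and sample ids as tip labels.
    """
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples to cluster")
    X = m.values.to_numpy(dtype=float).T
    dist = pdist(X, metric="correlation")
    Z = hierarchy.linkage(dist, method=linkage)
    newick = linkage_to_newick(Z, list(m.samples.index))
    return Z, newick


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a SciPy linkage matrix as a Newick string with branch
    lengths (via scikit-bio's tree container)."""
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(Z, labels)
    return str(tree)


def cut_to_clusters(Z: np.ndarray, n_clusters: int) -> np.ndarray:
    """Flat cluster labels from cutting the dendrogram into n clusters."""
    return hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
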