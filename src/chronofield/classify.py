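"""Truth-table classification of environmental drivers from DEG flags.

At each timepoint a gene carries one DEG flag per condition comparison
against a baseline. A :class:`ClassificationScheme` maps each flag tuple to
one of the driver classes:

* ``LIGHT`` — differs from the baseline exactly in the constant-light
  conditions: driven by fluctuating irradiance,
* ``TH`` — differs exactly in the constant-temperature/humidity
  conditions: driven by fluctuating temperature/humidity,
* ``LTH`` — differs in every condition where either factor is held
  constant: driven by both,
* ``UNREP`` — differs even from the full environmental simulation: driven
  by field-specific factor(s) no chamber reproduces,
* ``none`` — everything else.

The default schemes cover the field experiment (baseline FIELD, four
comparisons) and the chamber-only experiment (baseline FL/FTH, three
comparisons); any alternative table can be supplied, e.g. from a YAML
config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from chronofield.matrix import ExpressionMatrix

LABELS = ("LIGHT", "TH", "LTH", "UNREP", "none")


@dataclass
class ClassificationScheme:
    """Ordered truth-table rules over per-comparison DEG flags.

    ``comparisons`` names the conditions compared against ``baseline``, in
    flag-tuple order. ``rules`` is an ordered list of (label, pattern)
    pairs; a pattern entry is True/False to require that flag, or None as
    a wildcard. The first matching rule wins; unmatched tuples are 'none',
    so every possible flag tuple maps to exactly one label.
    """

    baseline: str
    comparisons: tuple[str, ...]
    rules: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for label, pattern in self.rules:
            if len(pattern) != len(self.comparisons):
                raise ValueError(
                    f"rule {label!r} pattern length {len(pattern)} != "
                    f"{len(self.comparisons)} comparisons"
                )

    def label_for(self, flags: tuple[bool, ...]) -> str:
        for label, pattern in self.rules:
            if all(p is None or p == f for p, f in zip(pattern, flags)):
                return label
        return "none"


# Field experiment: baseline FIELD, comparisons vs the four chamber
# conditions. A gene not distinguishable from the full simulation (first
# flag False) is classified by which constant-factor conditions it differs
# in; a gene that differs even from the full simulation is UNREP regardless
# of the other flags.
EXP1_SCHEME = ClassificationScheme(
    baseline="FIELD",
    comparisons=("FL_FTH", "CL_CTH", "FL_CTH", "CL_FTH"),
    rules=(
        ("UNREP", (True, None, None, None)),
        ("LIGHT", (False, True, False, True)),
        ("TH", (False, True, True, False)),
        ("LTH", (False, True, True, True)),
    ),
)

# Chamber-only experiment: baseline is the full simulation itself, so no
# UNREP class exists.
EXP2_SCHEME = ClassificationScheme(
    baseline="FL_FTH",
    comparisons=("CL_CTH", "FL_CTH", "CL_FTH"),
    rules=(
        ("LIGHT", (True, False, True)),
        ("TH", (True, True, False)),
        ("LTH", (True, True, True)),
    ),
)


def scheme_from_dict(spec: dict) -> ClassificationScheme:
    """Build a scheme from a plain mapping (e.g. parsed YAML) with keys
    ``baseline``, ``comparisons`` and ``rules`` (label → list of
    true/false/null)."""
    rules = tuple(
        (label, tuple(None if v is None else bool(v) for v in pattern))
        for label, pattern in spec["rules"].items()
    )
    return ClassificationScheme(
        baseline=spec["baseline"], comparisons=tuple(spec["comparisons"]), rules=rules
    )


def classify(
    flags: dict[str, dict[int, pd.DataFrame]],
    scheme: ClassificationScheme,
) -> pd.DataFrame:
    """Apply the scheme's truth table per gene per timepoint.

    ``flags`` maps comparison name → (timepoint → DEG result table with an
    ``is_deg`` column), as produced by
    :func:`chronofield.deg.call_degs_per_timepoint`. Only timepoints
    present for every comparison are classified. Returns a long-format
    DataFrame (timepoint, gene_id, label).
    """
    missing = [c for c in scheme.comparisons if c not in flags]
    if missing:
        raise ValueError(f"missing comparisons: {missing}")
    per_comp = [flags[c] for c in scheme.comparisons]
    shared_tps = sorted(set.intersection(*(set(d) for d in per_comp)))
    rows = []
    for tp in shared_tps:
        tables = [d[tp] for d in per_comp]
        genes = tables[0].index
        flag_matrix = np.column_stack(
            [t.loc[genes, "is_deg"].to_numpy(dtype=bool) for t in tables]
        )
        labels = np.full(len(genes), "none", dtype=object)
        unassigned = np.ones(len(genes), dtype=bool)
        for label, pattern in scheme.rules:
            match = unassigned.copy()
            for j, p in enumerate(pattern):
                if p is not None:
                    match &= flag_matrix[:, j] == p
            labels[match] = label
            unassigned &= ~match
        rows.append(pd.DataFrame({"timepoint": tp, "gene_id": genes, "label": labels}))
    if not rows:
        return pd.DataFrame(columns=["timepoint", "gene_id", "label"])
    return pd.concat(rows, ignore_index=True)


def class_counts_over_time(table: pd.DataFrame, include_none: bool = False) -> pd.DataFrame:
    """Timepoint × label count matrix ('none' excluded by default)."""
    if table.empty:
        labels = [l for l in LABELS if include_none or l != "none"]
        return pd.DataFrame(columns=labels, dtype=int)
    counts = (
        table.groupby(["timepoint", "label"], observed=True).size().unstack(fill_value=0)
    )
    for l in LABELS:
        if l not in counts.columns:
            counts[l] = 0
    cols = [l for l in LABELS if include_none or l != "none"]
    return counts[cols].astype(int)


def set_overlap(set_a, set_b) -> dict:
    """Exact overlap arithmetic between two gene sets.

    Returns only_a, intersection and only_b sizes plus two overlap
    fractions: |A∩B|/min(|A|,|B|) and the Jaccard index |A∩B|/|A∪B|.
    """
    a, b = set(set_a), set(set_b)
    inter = a & b
    union = a | b
    min_size = min(len(a), len(b))
    return {
        "only_a": len(a - b),
        "intersection": len(inter),
        "only_b": len(b - a),
        "overlap_min_fraction": len(inter) / min_size if min_size else float("nan"),
        "jaccard": len(inter) / len(union) if union else float("nan"),
    }


def field_specific_genes(
    m: ExpressionMatrix,
    deg: dict[int, pd.DataFrame],
    baseline: str = "FIELD",
    other: str = "FL_FTH",
    fold: float = 2.0,
) -> tuple[list, list]:
    """Genes expressed ≥ fold higher (or lower) in the baseline condition.

    Per gene and condition, replicate means per timepoint are averaged over
    all timepoints; a gene goes on the up list if its baseline mean is at
    least ``fold`` times the other condition's mean AND it is a DEG at one
    or more timepoints (``deg`` is the per-timepoint result map for
    baseline vs other). The down list is symmetric.
    """
    means = {}
    tp = m.sample_timepoints()
    for cond in (baseline, other):
        sub = m.subset_condition(cond)
        sub_tp = tp.loc[sub.samples.index]
        per_tp = sub.values.T.groupby(sub_tp.to_numpy()).mean()
        means[cond] = per_tp.mean(axis=0)
    floor = 1e-9
    base_mean = means[baseline].clip(lower=floor)
    other_mean = means[other].clip(lower=floor)
    ever_deg = set()
    for res in deg.values():
        ever_deg |= set(res.index[res["is_deg"].astype(bool)])
    up = [
        g for g in m.gene_ids
        if base_mean[g] >= fold * other_mean[g] and g in ever_deg
    ]
    down = [
        g for g in m.gene_ids
        if other_mean[g] >= fold * base_mean[g] and g in ever_deg
    ]
    return up, down


def fold_change_concordance(
    diff_a: pd.Series,
    diff_b: pd.Series,
    min_abs: float = 0.0,
) -> tuple[pd.DataFrame, float]:
    """Cross-study concordance of per-gene expression differences.

    Joins two per-gene mean log-difference vectors on their shared genes
    and reports the paired table plus the fraction of genes with matching
    sign among those whose difference exceeds ``min_abs`` in magnitude in
    both studies.
    """
    shared = diff_a.index.intersection(diff_b.index)
    if shared.empty:
        raise ValueError("no shared gene ids between the two difference vectors")
    table = pd.DataFrame({"diff_a": diff_a.loc[shared], "diff_b": diff_b.loc[shared]})
    mask = (table["diff_a"].abs() > min_abs) & (table["diff_b"].abs() > min_abs)
    sel = table[mask]
    if sel.empty:
        return table, float("nan")
    agreement = float((np.sign(sel["diff_a"]) == np.sign(sel["diff_b"])).mean())
    return table, agreement


def classify_conditions(
    m: ExpressionMatrix,
    scheme: ClassificationScheme,
    fdr: float = 0.05,
    elim_fdr: float = 0.1,
) -> tuple[pd.DataFrame, dict[str, dict[int, pd.DataFrame]]]:
    """Convenience wrapper: run per-timepoint DEG calling for every scheme
    comparison against the baseline, then classify. Returns the label
    table and the raw DEG results."""
    from chronofield.deg import call_degs_per_timepoint

    flags = {
        other: call_degs_per_timepoint(m, scheme.baseline, other, fdr=fdr, elim_fdr=elim_fdr)
        for other in scheme.comparisons
    }
    return classify(flags, scheme), flags
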