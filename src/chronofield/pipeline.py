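"""Single-config orchestration of the full analysis chain.

``run_pipeline`` executes the enabled stages in dependency order —
prep → timetable → deg → classify → summarize → enrich — reading and
writing only documented TSV formats, so any stage can be re-run on its own
from files. Every output carries a provenance header (package version,
config hash, seed) and re-running with an identical config reproduces
byte-identical files.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

import chronofield
from chronofield import matrix as cmx
from chronofield.classify import (
    EXP1_SCHEME,
    EXP2_SCHEME,
    ClassificationScheme,
    class_counts_over_time,
    classify,
    field_specific_genes,
    scheme_from_dict,
)
from chronofield.deg import call_degs_per_timepoint
from chronofield.enrichment import AnnotationTable, fisher_enrichment
from chronofield.summarize import (
    correlation_hclust,
    pca_scores,
    per_gene_correlation,
    timepoint_condition_correlation,
)
from chronofield.timetable import (
    estimate_internal_times,
    measurement_noise,
    select_time_indicating,
)

logger = logging.getLogger("chronofield")

ALL_STAGES = ("prep", "timetable", "deg", "classify", "summarize", "enrich")


@dataclass
class PipelineConfig:
    """Everything one run needs: input paths, per-stage parameters, stage
    toggles and the seed recorded in output headers."""

    counts: str = ""
    metadata: str = ""
    annotations: str | None = None
    exclude: str | None = None
    out_dir: str = "chronofield_out"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    min_mean: float = 10.0
    timetable_condition: str = "FIELD"
    r_cut: float = 0.935
    a_cut: float = 0.15
    scheme: str | dict = "exp1"
    fdr: float = 0.05
    elim_fdr: float = 0.1
    field_fold: float = 2.0
    r_cut_gene_corr: float = 0.7
    linkage: str = "average"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(d["stages"])
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def validate(self) -> None:
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        for name, path in (("counts", self.counts), ("metadata", self.metadata)):
            if not path or not Path(path).exists():
                raise FileNotFoundError(f"{name} path does not exist: {path!r}")
        for name, path in (("annotations", self.annotations), ("exclude", self.exclude)):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} path does not exist: {path!r}")
        if not 0 < self.fdr < 1 or not 0 <= self.elim_fdr < 1:
            raise ValueError("FDR thresholds must lie in (0, 1)")

    def resolve_scheme(self) -> ClassificationScheme:
        if isinstance(self.scheme, dict):
            return scheme_from_dict(self.scheme)
        if self.scheme == "exp1":
            return EXP1_SCHEME
        if self.scheme == "exp2":
            return EXP2_SCHEME
        raise ValueError(f"unknown scheme {self.scheme!r}")


def _write_table(df: pd.DataFrame, path: Path, header: list[str], index_label=None) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        buf = io.StringIO()
        df.to_csv(buf, sep="\t", lineterminator="\n", index_label=index_label)
        fh.write(buf.getvalue())


def run_pipeline(cfg: PipelineConfig) -> dict[str, list[str]]:
    """Execute the enabled stages; returns a manifest stage → output files.

    Any stage error aborts the run with the stage name attached.
    """
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = [
        f"chronofield {chronofield.__version__}",
        f"config {cfg.config_hash()}",
        f"seed {cfg.seed}",
    ]
    with open(out_dir / "config_used.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    manifest: dict[str, list[str]] = {"config": [str(out_dir / "config_used.yaml")]}

    state: dict = {}
    stage = "prep"  # prep always runs: everything downstream needs the matrix
    try:
        raw = cmx.read_counts(cfg.counts, cfg.metadata)
        exclude = []
        if cfg.exclude:
            exclude = [
                l.strip() for l in Path(cfg.exclude).read_text().splitlines() if l.strip()
            ]
        filtered = cmx.filter_min_mean(raw, cfg.min_mean)
        logger.info("prep: %d/%d genes pass mean > %s", filtered.n_genes, raw.n_genes, cfg.min_mean)
        rpm = cmx.compute_rpm(filtered, exclude)
        log2 = cmx.log_transform(rpm)
        state.update(filtered=filtered, rpm=rpm, log2=log2)
        if "prep" in cfg.stages:
            files = []
            for name, mat in (("filtered_counts", filtered), ("rpm", rpm), ("log2rpm", log2)):
                path = out_dir / f"{name}.tsv"
                cmx.write_counts(mat, path, header)
                files.append(str(path))
            meta_path = out_dir / "metadata_used.tsv"
            cmx.write_metadata(filtered.samples, meta_path)
            files.append(str(meta_path))
            manifest["prep"] = files

        scheme = cfg.resolve_scheme()

        if "timetable" in cfg.stages:
            stage = "timetable"
            model = select_time_indicating(
                state["rpm"], cfg.r_cut, cfg.a_cut, cfg.timetable_condition
            )
            times = estimate_internal_times(model, state["rpm"])
            noise = measurement_noise(model, state["rpm"])
            model_path = out_dir / "timetable_model.tsv"
            model.write(model_path)
            times_path = out_dir / "internal_times.tsv"
            _write_table(times, times_path, header, index_label="sample_id")
            noise_path = out_dir / "measurement_noise.tsv"
            _write_table(noise, noise_path, header, index_label="gene_id")
            manifest["timetable"] = [str(model_path), str(times_path), str(noise_path)]
            state["model"] = model

        if "deg" in cfg.stages or "classify" in cfg.stages or "enrich" in cfg.stages:
            stage = "deg"
            flags = {}
            files = []
            for other in scheme.comparisons:
                res = call_degs_per_timepoint(
                    state["filtered"], scheme.baseline, other,
                    fdr=cfg.fdr, elim_fdr=cfg.elim_fdr,
                )
                flags[other] = res
                rows = []
                for tp, table in sorted(res.items()):
                    t = table.reset_index(names="gene_id")
                    t.insert(0, "timepoint", tp)
                    rows.append(t)
                long = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
                    columns=["timepoint", "gene_id", "log2fc", "pvalue", "qvalue", "is_deg"]
                )
                path = out_dir / f"deg_{scheme.baseline}_vs_{other}.tsv"
                _write_table(long, path, header, index_label=None)
                files.append(str(path))
            if "deg" in cfg.stages:
                manifest["deg"] = files
            state["flags"] = flags

        if "classify" in cfg.stages:
            stage = "classify"
            labels = classify(state["flags"], scheme)
            labels_path = out_dir / "class_labels.tsv"
            _write_table(labels, labels_path, header)
            counts_path = out_dir / "class_counts.tsv"
            _write_table(
                class_counts_over_time(labels), counts_path, header, index_label="timepoint"
            )
            manifest["classify"] = [str(labels_path), str(counts_path)]
            state["labels"] = labels
            if scheme.baseline == "FIELD" and "FL_FTH" in scheme.comparisons:
                up, down = field_specific_genes(
                    state["rpm"], state["flags"]["FL_FTH"], fold=cfg.field_fold
                )
                for name, genes in (("up", up), ("down", down)):
                    path = out_dir / f"field_specific_{name}.txt"
                    path.write_text("".join(f"{g}\n" for g in genes))
                    manifest["classify"].append(str(path))

        if "summarize" in cfg.stages:
            stage = "summarize"
            corr = timepoint_condition_correlation(
                state["log2"], scheme.baseline, scheme.comparisons
            )
            corr_path = out_dir / "timepoint_correlations.tsv"
            _write_table(corr, corr_path, header)
            gene_counts = []
            for other in scheme.comparisons:
                _, count = per_gene_correlation(
                    state["log2"], scheme.baseline, other, r_cut=cfg.r_cut_gene_corr
                )
                gene_counts.append((other, count))
            gc_path = out_dir / "gene_correlation_counts.tsv"
            _write_table(
                pd.DataFrame(gene_counts, columns=["condition", "n_pass"]), gc_path, header
            )
            scores, summary, var = pca_scores(state["log2"])
            pca_path = out_dir / "pca_scores.tsv"
            score_out = scores.copy()
            score_out.insert(0, "condition", state["log2"].samples["condition"])
            score_out.insert(1, "timepoint", state["log2"].sample_timepoints())
            _write_table(score_out, pca_path, header, index_label="sample_id")
            pca_group_path = out_dir / "pca_group_summary.tsv"
            _write_table(summary, pca_group_path, header, index_label=["condition", "timepoint"])
            _, newick = correlation_hclust(state["log2"], cfg.linkage)
            nwk_path = out_dir / "dendrogram.nwk"
            nwk_path.write_text(newick if newick.endswith("\n") else newick + "\n")
            manifest["summarize"] = [
                str(corr_path), str(gc_path), str(pca_path), str(pca_group_path), str(nwk_path)
            ]

        if "enrich" in cfg.stages:
            stage = "enrich"
            if not cfg.annotations:
                logger.warning("enrich stage enabled but no annotations provided; skipped")
            elif "labels" not in state:
                logger.warning("enrich stage needs classify output; skipped")
            else:
                ann = AnnotationTable.read(cfg.annotations)
                manifest["enrich"] = []
                labels = state["labels"]
                for label in sorted(set(labels["label"]) - {"none"}):
                    genes = set(labels.loc[labels["label"] == label, "gene_id"])
                    try:
                        res = fisher_enrichment(
                            genes, ann, background=set(state["filtered"].gene_ids)
                        )
                    except ValueError as exc:
                        logger.warning("enrichment for %s skipped: %s", label, exc)
                        continue
                    path = out_dir / f"enrichment_{label}.tsv"
                    _write_table(res, path, header, index_label="term_id")
                    manifest["enrich"].append(str(path))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = out_dir / "manifest.tsv"
    rows = [(s, f) for s, fl in manifest.items() for f in fl]
    _write_table(pd.DataFrame(rows, columns=["stage", "file"]), manifest_path, header)
    manifest["manifest"] = [str(manifest_path)]
    return manifest
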