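"""Orchestration of the three analyses plus simulation.

Each ``run_*`` entry point reads its inputs through :mod:`hemoconcord.io`,
executes the corresponding stages, writes every intermediate table as
TSV, and emits a JSON run manifest recording the package version, seed,
thresholds actually applied, and SHA-256 hashes of the input files.
Re-running with the same config and seed reproduces the primary outputs
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .concordance import consensus_map, overlap_matrix, paired_enrichment
from .io import (
    ClusterLabeling,
    CountMatrix,
    MarkerTable,
    ValidationError,
    read_counts,
    read_gmt,
    read_labels,
    read_marker_table,
    write_counts,
    write_labels,
    write_marker_table,
)
from .markers import find_all_markers, lognormalize
from .pseudobulk import (
    DEFAULT_HEMOCYTE_MARKERS,
    annotate_best_match,
    correlate,
    detection_fractions,
    identify_hemocyte_cluster,
    marker_dotplot_table,
    pseudo_transcriptome,
    specific_signature,
)
from .regulons import aucell_score, differential_activity, rank_genes_per_cell
from .simulate import StudyConfig, generate_study, generate_study_pair

logger = logging.getLogger(__name__)

_THRESHOLD_RANGES = {
    "log2fc_min": (0.0, 10.0),
    "p_adj_max": (0.0, 1.0),
    "min_pct": (0.0, 1.0),
    "tie_band": (0.0, 1.0),
    "top_fraction": (0.0, 1.0),
    "z_threshold": (0.0, 100.0),
    "fold_min": (1.0, 1000.0),
    "detect_min": (0.0, 1.0),
    "scale_factor": (0.0, 1e9),
}


@dataclass
class PipelineConfig:
    """All paths and thresholds of a pipeline run; YAML round-trippable."""

    inputs: dict[str, str] = field(default_factory=dict)
    out_dir: str = "results"
    seed: int = 0
    log2fc_min: float = 0.25
    p_adj_max: float = 0.01
    min_pct: float = 0.1
    tie_band: float = 0.8
    top_fraction: float = 0.05
    z_threshold: float = 2.0
    fold_min: float = 2.0
    detect_min: float = 0.5
    scale_factor: float = 1e4
    exclude_subgroups_a: list[str] = field(default_factory=list)
    exclude_subgroups_b: list[str] = field(default_factory=list)

    def validate(self) -> None:
        for name, (lo, hi) in _THRESHOLD_RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValidationError(f"{name}={v} outside [{lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(cfg: PipelineConfig, stage: str, outputs: list[str]) -> Path:
    out_dir = Path(cfg.out_dir)
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "seed": cfg.seed,
        "thresholds": {k: getattr(cfg, k) for k in _THRESHOLD_RANGES},
        "excluded_subgroups": {
            "a": cfg.exclude_subgroups_a,
            "b": cfg.exclude_subgroups_b,
        },
        "inputs": {
            k: {"path": v, "sha256": _sha256(v)}
            for k, v in cfg.inputs.items()
            if Path(v).is_file()
        },
        "outputs": outputs,
    }
    path = out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _require(cfg: PipelineConfig, keys: list[str]) -> None:
    missing = [k for k in keys if k not in cfg.inputs or not Path(cfg.inputs[k]).is_file()]
    if missing:
        raise ValidationError(f"missing input file(s): {missing}")


def _load_markers(cfg: PipelineConfig, side: str) -> MarkerTable:
    """Marker table for one side: precomputed TSV or computed from raw data."""
    if f"markers_{side}" in cfg.inputs:
        _require(cfg, [f"markers_{side}"])
        return read_marker_table(cfg.inputs[f"markers_{side}"])
    _require(cfg, [f"counts_{side}", f"labels_{side}"])
    cm = read_counts(cfg.inputs[f"counts_{side}"])
    labels = read_labels(cfg.inputs[f"labels_{side}"])
    norm = lognormalize(cm, cfg.scale_factor)
    return find_all_markers(norm, labels, cfg.log2fc_min, cfg.p_adj_max, cfg.min_pct)


def run_simulate(cfg: PipelineConfig, pair: bool = True) -> dict[str, Path]:
    """Generate a synthetic study (or study pair) and write it to disk."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def dump(tag: str, cm: CountMatrix, labeling: ClusterLabeling, truth_markers: pd.DataFrame):
        write_counts(cm, out / f"counts_{tag}.tsv")
        write_labels(labeling, out / f"labels_{tag}.tsv")
        truth_markers.to_csv(out / f"planted_markers_{tag}.tsv", sep="\t", index=False)
        written[f"counts_{tag}"] = out / f"counts_{tag}.tsv"
        written[f"labels_{tag}"] = out / f"labels_{tag}.tsv"

    if pair:
        (cm_a, gt_a), (cm_b, gt_b) = generate_study_pair(
            StudyConfig(seed=cfg.seed), shared_truth_seed=cfg.seed + 1
        )
        dump("a", cm_a, gt_a.labeling, gt_a.markers)
        dump("b", cm_b, gt_b.labeling, gt_b.markers)
        pd.DataFrame(
            sorted(gt_a.correspondence.items()), columns=["subgroup_a", "subgroup_b"]
        ).to_csv(out / "planted_correspondence.tsv", sep="\t", index=False)
    else:
        cm, gt = generate_study(StudyConfig(seed=cfg.seed))
        dump("a", cm, gt.labeling, gt.markers)
    _write_manifest(cfg, "simulate", sorted(str(p) for p in written.values()))
    return written


def run_concordance(cfg: PipelineConfig) -> dict[str, Path]:
    """Markers (if needed) -> overlap, paired enrichments, consensus map."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    markers_a = _load_markers(cfg, "a")
    markers_b = _load_markers(cfg, "b")
    for sub in cfg.exclude_subgroups_a:
        markers_a = markers_a.drop_subgroup(sub)
    for sub in cfg.exclude_subgroups_b:
        markers_b = markers_b.drop_subgroup(sub)

    write_marker_table(markers_a, out / "markers_a.tsv")
    write_marker_table(markers_b, out / "markers_b.tsv")
    ov = overlap_matrix(markers_a, markers_b)
    ov.counts.to_csv(out / "overlap_matrix.tsv", sep="\t")
    cmap = consensus_map(markers_a, markers_b, tie_band=cfg.tie_band)
    cmap.pairs.to_csv(out / "consensus_map.tsv", sep="\t", index=False)
    cmap.scores.to_csv(out / "match_scores.tsv", sep="\t")

    pair_frames = []
    for _, row in cmap.pairs.iterrows():
        pe = paired_enrichment(markers_a, markers_b, row["subgroup_a"], row["subgroup_b"])
        pair_frames.append(
            pe.df.assign(subgroup_a=pe.subgroup_a, subgroup_b=pe.subgroup_b)
        )
    if pair_frames:
        pd.concat(pair_frames, ignore_index=True).to_csv(
            out / "paired_enrichment.tsv", sep="\t", index=False
        )
    outputs = [
        "markers_a.tsv",
        "markers_b.tsv",
        "overlap_matrix.tsv",
        "consensus_map.tsv",
        "match_scores.tsv",
        "paired_enrichment.tsv",
    ]
    manifest = _write_manifest(cfg, "concordance", outputs)
    return {"consensus_map": out / "consensus_map.tsv", "manifest": manifest}


def run_annotation(cfg: PipelineConfig) -> dict[str, Path]:
    """Pseudo-bulk correlation annotation of a query dataset vs a reference."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _require(cfg, ["counts_query", "labels_query", "counts_ref", "labels_ref"])
    cm_q = read_counts(cfg.inputs["counts_query"])
    lb_q = read_labels(cfg.inputs["labels_query"])
    cm_r = read_counts(cfg.inputs["counts_ref"])
    lb_r = read_labels(cfg.inputs["labels_ref"])
    norm_q = lognormalize(cm_q, cfg.scale_factor)
    norm_r = lognormalize(cm_r, cfg.scale_factor)
    pt_q = pseudo_transcriptome(norm_q, lb_q)
    pt_r = pseudo_transcriptome(norm_r, lb_r)

    canonical = cfg.inputs.get("canonical_markers")
    marker_list = (
        [l.strip() for l in open(canonical) if l.strip()]
        if canonical
        else DEFAULT_HEMOCYTE_MARKERS
    )
    hemo, evidence = identify_hemocyte_cluster(pt_q, marker_list)
    evidence.to_csv(out / "hemocyte_evidence.tsv", sep="\t", index=False)
    pd.DataFrame({"hemocyte_cluster": hemo}).to_csv(
        out / "hemocyte_clusters.tsv", sep="\t", index=False
    )

    ct = correlate(pt_q, pt_r)
    ct.r.to_csv(out / "correlation_table.tsv", sep="\t")
    annotate_best_match(ct).to_csv(out / "best_matches.tsv", sep="\t", index=False)

    sig_frames = []
    for q in pt_q.subgroups:
        pct = detection_fractions(norm_q, lb_q, q)
        sig = specific_signature(
            pt_q.column(q), pt_r.values, pct, cfg.fold_min, cfg.detect_min
        )
        sig_frames.append(sig.assign(query=q))
    pd.concat(sig_frames, ignore_index=True).to_csv(
        out / "specific_signatures.tsv", sep="\t", index=False
    )
    marker_dotplot_table(norm_q, lb_q, marker_list).to_csv(
        out / "marker_dotplot.tsv", sep="\t", index=False
    )
    outputs = [
        "hemocyte_evidence.tsv",
        "hemocyte_clusters.tsv",
        "correlation_table.tsv",
        "best_matches.tsv",
        "specific_signatures.tsv",
        "marker_dotplot.tsv",
    ]
    manifest = _write_manifest(cfg, "annotation", outputs)
    return {"correlation_table": out / "correlation_table.tsv", "manifest": manifest}


def run_regulon(cfg: PipelineConfig) -> dict[str, Path]:
    """AUC activity scoring plus Mann-Whitney differential activity."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _require(cfg, ["counts_a", "labels_a", "regulons"])
    cm = read_counts(cfg.inputs["counts_a"])
    labels = read_labels(cfg.inputs["labels_a"])
    regulons = read_gmt(cfg.inputs["regulons"])
    norm = lognormalize(cm, cfg.scale_factor)
    ranking = rank_genes_per_cell(norm, seed=cfg.seed)
    activity = aucell_score(ranking, regulons, cfg.top_fraction)
    diff = differential_activity(activity, labels, cfg.z_threshold)

    with open(out / "activity.tsv", "w") as fh:
        fh.write(f"# tie_break_seed={cfg.seed}\ttop_fraction={cfg.top_fraction}\n")
        activity.values.to_csv(fh, sep="\t")
    diff.table.to_csv(out / "differential_activity.tsv", sep="\t", index=False)
    with open(out / "zscores.tsv", "w") as fh:
        fh.write(f"# row_order=hierarchical\tlinkage={diff.linkage_method}\n")
        diff.z_matrix.to_csv(fh, sep="\t")
    sel = diff.table[diff.table["selected"]][["regulon", "cluster", "z"]]
    sel.to_csv(out / "selected_regulons.tsv", sep="\t", index=False)
    outputs = ["activity.tsv", "differential_activity.tsv", "zscores.tsv", "selected_regulons.tsv"]
    manifest = _write_manifest(cfg, "regulon", outputs)
    return {"zscores": out / "zscores.tsv", "manifest": manifest}
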