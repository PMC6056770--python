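"""Pipeline orchestration: the compare and time-course runs.

The two normalization modes follow the pre-processing contract:

* ``cnv-raw`` (default): the coverage-filtered matrix is quantile-normalized
  only for the moderated-t comparator branch; the CNV branch averages the
  raw replicates with no prior normalization (the compartment models absorb
  scale differences themselves).
* ``comparison-quantile``: the matrix is quantile-normalized once, up front,
  and both branches consume the normalized values — used when benchmarking
  the two approaches on equal footing.

Every output TSV starts with a ``# config_hash=...`` comment so a table can
be traced to the exact configuration that produced it; re-running with the
same configuration and inputs reproduces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from cnvar import annotation as ann_mod
from cnvar import cnv_core, diffexp, shift_analysis, simulate, timecourse
from cnvar.errors import ConfigurationError
from cnvar.io_preprocess import (
    average_replicates,
    filter_by_replicate_coverage,
    quantile_normalize,
    read_abundance_table,
)

logger = logging.getLogger(__name__)

COMPARTMENT_SETS = {
    "four": list(ann_mod.FOUR_MAJOR_COMPARTMENTS),
    "ten": list(ann_mod.TEN_COMPARTMENTS),
}


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    mode: str  # compare | timecourse | simulate
    outdir: str
    matrix: str | None = None
    design: str | None = None
    obo: str | None = None
    gaf: str | None = None
    groups: str | None = None
    conditions: tuple[str, str] | None = None
    timepoints: list[str] | None = None
    baseline: str | None = None
    complexes: str | None = None
    compartments: str | list[str] = "four"
    value_scale: str = "log2"
    is_ratio: bool = False
    normalization: str = "cnv-raw"
    model_p: float = 0.05
    q_thresholds: tuple[float, ...] = (0.05, 0.1, 0.25)
    alpha: float = 0.01
    background: str = "whole-proteome"
    min_fit_size: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("compare", "timecourse", "simulate"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        has_go = self.obo is not None and self.gaf is not None
        has_custom = self.groups is not None
        if self.mode != "simulate" and has_go == has_custom:
            raise ConfigurationError(
                "exactly one annotation source required: obo+gaf or groups"
            )
        for name in ("model_p", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must be in (0,1), got {v}")
        for t in self.q_thresholds:
            if not 0.0 < t < 1.0:
                raise ConfigurationError(f"q threshold {t} outside (0,1)")
        if self.normalization not in ("cnv-raw", "comparison-quantile"):
            raise ConfigurationError(f"unknown normalization {self.normalization!r}")
        if isinstance(self.compartments, str) and self.compartments not in COMPARTMENT_SETS:
            raise ConfigurationError(
                f"compartments must be 'four', 'ten' or an explicit list, "
                f"got {self.compartments!r}"
            )
        if self.timepoints is not None and len(self.timepoints) != len(set(self.timepoints)):
            raise ConfigurationError("duplicate timepoint labels in config")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "conditions" in raw and raw["conditions"] is not None:
            raw["conditions"] = tuple(raw["conditions"])
        if "q_thresholds" in raw and raw["q_thresholds"] is not None:
            raw["q_thresholds"] = tuple(raw["q_thresholds"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _resolve_annotation(cfg: RunConfig):
    """Load the annotation and the list of compartments to analyze."""
    if cfg.groups is not None:
        ann = ann_mod.load_custom_groups(cfg.groups)
        if isinstance(cfg.compartments, list):
            unknown = set(cfg.compartments) - set(ann.compartments())
            if unknown:
                raise ConfigurationError(f"unknown compartments: {sorted(unknown)}")
            comps = list(cfg.compartments)
        else:
            comps = ann.compartments()
        return ann, comps
    graph = ann_mod.parse_ontology(cfg.obo)
    defs = ann_mod.build_compartment_definitions(graph)
    protein_terms = ann_mod.read_gaf(cfg.gaf)
    ann = ann_mod.assign_compartments(protein_terms, defs)
    if isinstance(cfg.compartments, list):
        unknown = set(cfg.compartments) - set(ann_mod.TEN_COMPARTMENTS)
        if unknown:
            raise ConfigurationError(f"unknown compartments: {sorted(unknown)}")
        comps = list(cfg.compartments)
    else:
        comps = COMPARTMENT_SETS[cfg.compartments]
    return ann, comps


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA", lineterminator="\n")


def run_compare(cfg: RunConfig) -> dict:
    """Full pairwise comparison: shift tests, CNV, comparator, overlap.

    Returns a dict with the in-memory results plus ``stages``, the ordered
    list of pipeline stages executed, and writes the output tables under
    ``cfg.outdir``.
    """
    if cfg.mode != "compare":
        raise ConfigurationError("run_compare requires mode='compare'")
    if cfg.conditions is None or len(cfg.conditions) != 2:
        raise ConfigurationError("compare mode needs exactly two conditions")
    ann, comps = _resolve_annotation(cfg)  # fail fast on bad config

    stages: list[str] = []
    chash = cfg.config_hash()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    m = read_abundance_table(cfg.matrix, cfg.design, value_scale=cfg.value_scale)
    m.is_ratio = cfg.is_ratio
    stages.append("read")
    counts = {"input": len(m.protein_ids)}

    m = filter_by_replicate_coverage(m, cfg.conditions)
    stages.append("filter")
    counts["after_coverage_filter"] = len(m.protein_ids)

    if cfg.normalization == "comparison-quantile":
        m_norm = quantile_normalize(m)
        stages.append("quantile_normalize[shared]")
        m_comparator = m_norm
        m_cnv = m_norm
    else:
        m_comparator = quantile_normalize(m)
        stages.append("quantile_normalize[comparator]")
        m_cnv = m  # raw values, no prior normalization for the CNV branch

    de = diffexp.moderated_ttest(m_comparator, cfg.conditions)
    stages.append("moderated_t")

    means = average_replicates(m_cnv, list(cfg.conditions))
    stages.append("average_replicates[cnv]")

    shifts = shift_analysis.shift_report(
        means, ann, cfg.conditions, compartments=comps,
        background=cfg.background, alpha=cfg.alpha,
    )
    stages.append("shift_tests")

    models, records = cnv_core.run_cnv(
        means, ann, cfg.conditions, compartments=comps,
        min_fit_size=cfg.min_fit_size, retention_p=cfg.model_p,
    )
    stages.append("cnv")

    summary = cnv_core.protein_cnv_summary(records, compartments=comps)
    classes, pct = diffexp.classify_overlap(de, summary, thresholds=cfg.q_thresholds)
    stages.append("overlap")

    _write_tsv(cnv_core.models_table(models), outdir / "models.tsv", chash)
    _write_tsv(records, outdir / "cnv_records.tsv", chash)
    _write_tsv(shifts, outdir / "shift_report.tsv", chash)
    _write_tsv(de, outdir / "de_records.tsv", chash)
    _write_tsv(classes, outdir / "overlap_classes.tsv", chash)
    _write_tsv(pct, outdir / "class_percentages.tsv", chash)
    _write_run_log(outdir, cfg, chash, stages, counts)

    return {
        "models": models,
        "cnv_records": records,
        "shift_report": shifts,
        "de_records": de,
        "overlap_classes": classes,
        "class_percentages": pct,
        "stages": stages,
        "config_hash": chash,
        "protein_counts": counts,
    }


def run_timecourse(cfg: RunConfig) -> dict:
    """Time-course run: Δ ratios, per-timepoint CNV, trajectories, groups."""
    if cfg.mode != "timecourse":
        raise ConfigurationError("run_timecourse requires mode='timecourse'")
    ann, comps = _resolve_annotation(cfg)
    chash = cfg.config_hash()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []

    series = timecourse.read_ratio_series(
        cfg.matrix, timepoints=cfg.timepoints, baseline=cfg.baseline
    )
    stages.append("read")
    if len(series.timepoints) < 2:
        raise ConfigurationError("time-course mode needs >=2 timepoints")

    deltas = timecourse.delta_ratios(series)
    stages.append("delta_ratios")
    _write_tsv(deltas.reset_index(), outdir / "delta_ratios.tsv", chash)

    per_t = timecourse.all_timepoint_cnv(
        series, ann, compartments=comps, min_fit_size=cfg.min_fit_size,
        retention_p=cfg.model_p,
    )
    stages.append("timepoint_cnv")
    for t, records in per_t.items():
        _write_tsv(records, outdir / f"cnv_records_{t}.tsv", chash)

    traj_frames = []
    for comp in comps:
        members = [p for p in ann.proteins_in(comp) if p in series.values.index]
        if len(members) < 2:
            continue
        tab = timecourse.compartment_trajectory_test(series, ann, comp, alpha=cfg.alpha)
        tab.insert(0, "compartment", comp)
        traj_frames.append(tab)
    trajectories = (pd.concat(traj_frames, ignore_index=True)
                    if traj_frames else pd.DataFrame())
    stages.append("trajectories")
    _write_tsv(trajectories, outdir / "compartment_trajectories.tsv", chash)

    group_tables = {}
    if cfg.complexes is not None:
        groups_ann = ann_mod.load_custom_groups(cfg.complexes)
        frames = []
        for grp in groups_ann.compartments():
            members = groups_ann.proteins_in(grp)
            for gmode in ("delta", "cnv"):
                tab = timecourse.group_trajectory_test(
                    series, ann, members, mode=gmode, alpha=0.05,
                    compartments=comps, min_fit_size=cfg.min_fit_size,
                )
                tab.insert(0, "group", grp)
                tab.insert(1, "mode", gmode)
                frames.append(tab)
        group_tables = pd.concat(frames, ignore_index=True)
        stages.append("group_tests")
        _write_tsv(group_tables, outdir / "group_tests.tsv", chash)

    _write_run_log(outdir, cfg, chash, stages,
                   {"input": int(series.values.shape[0])})
    return {
        "delta_ratios": deltas,
        "timepoint_cnv": per_t,
        "trajectories": trajectories,
        "group_tests": group_tables,
        "stages": stages,
        "config_hash": chash,
    }


def _write_run_log(outdir: Path, cfg: RunConfig, chash: str,
                   stages: list[str], counts: dict) -> None:
    manifest = {
        "config": asdict(cfg),
        "config_hash": chash,
        "stages": stages,
        "protein_counts": counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    lines = [f"config_hash={chash}"]
    lines += [f"stage: {s}" for s in stages]
    lines += [f"proteins[{k}]={v}" for k, v in counts.items()]
    (outdir / "run_log.txt").write_text("\n".join(lines) + "\n")
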