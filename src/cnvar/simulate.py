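"""Synthetic proteome comparisons with known compartment structure.

The generator emulates the situation the CNV method targets: two cell states
whose organelles differ in overall abundance. Protein i of compartment c has
a baseline log2 abundance a_i; the second condition's abundance is

    b_i = a_i + delta_c + eps_i + o_i,

where delta_c is the compartment-wide (log-additive) shift, eps_i ~
N(0, sigma_res^2) is protein-specific within-compartment variation, and o_i
is +/- gamma * sigma_res for a chosen fraction of outlier proteins (true
composition changes). Replicate measurements add N(0, sigma_rep^2) noise and
values go missing at random. A ground-truth table records every injected
effect, so detection performance can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cnvar.annotation import CompartmentAnnotation
from cnvar.errors import ConfigurationError
from cnvar.io_preprocess import AbundanceMatrix
from cnvar.timecourse import RatioSeries


@dataclass
class SimulationSpec:
    """Parameters of one synthetic two-condition comparison.

    Defaults describe a realistic label-free experiment: log2 intensities
    centered at 25 with SD 2 (iBAQ-like dynamic range), replicate noise
    0.2 log2 units, within-compartment residual SD 0.3 log2 units, 3
    replicates per condition.
    """

    n_proteins: dict[str, int] = field(
        default_factory=lambda: {"cytoplasm": 1000, "mitochondrion": 300}
    )
    shifts: dict[str, float] = field(default_factory=dict)  # delta_c, log2 units
    baseline_mean: float = 25.0
    baseline_sd: float = 2.0
    sigma_rep: float = 0.2
    sigma_res: float = 0.3
    outlier_fraction: float = 0.0
    outlier_effect: float = 4.0  # gamma, in units of sigma_res
    missing_rate: float = 0.0
    n_replicates: int = 3
    conditions: tuple[str, str] = ("A", "B")
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_proteins:
            raise ConfigurationError("invalid n_proteins: need >=1 compartment")
        for name, n in self.n_proteins.items():
            if n < 1:
                raise ConfigurationError(f"invalid n_proteins[{name!r}]: {n}")
        for fname in ("baseline_sd", "sigma_rep", "sigma_res"):
            if getattr(self, fname) < 0:
                raise ConfigurationError(f"invalid {fname}: must be >= 0")
        if not 0.0 <= self.outlier_fraction <= 1.0:
            raise ConfigurationError("invalid outlier_fraction: must be in [0,1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigurationError("invalid missing_rate: must be in [0,1]")
        if self.n_replicates < 1:
            raise ConfigurationError("invalid n_replicates: must be >= 1")
        unknown = set(self.shifts) - set(self.n_proteins)
        if unknown:
            raise ConfigurationError(f"invalid shifts: unknown compartments {sorted(unknown)}")


def generate_dataset(
    spec: SimulationSpec,
    left_censor: bool = False,
) -> tuple[AbundanceMatrix, CompartmentAnnotation, pd.DataFrame]:
    """Generate (abundance matrix, annotation, ground truth) per the spec.

    Outlier counts are exact (round(f_out * n) per compartment) with signs
    alternating between positive and negative so the compartment's model
    slope stays unbiased. Missingness is missing-completely-at-random by
    default; ``left_censor=True`` makes low-intensity measurements the ones
    that vanish (abundance-dependent missingness), which is more realistic
    but distorts null calibration.
    """
    rng = np.random.default_rng(spec.seed)
    cond_a, cond_b = spec.conditions

    proteins: list[str] = []
    mapping: dict[str, frozenset[str]] = {}
    truth_rows = []
    a_means = []
    b_means = []
    for comp in sorted(spec.n_proteins):
        n = spec.n_proteins[comp]
        delta = float(spec.shifts.get(comp, 0.0))
        ids = [f"{comp[:4].upper()}_{i:05d}" for i in range(n)]
        a = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n)
        eps = rng.normal(0.0, spec.sigma_res, size=n) if spec.sigma_res > 0 else np.zeros(n)
        n_out = int(round(spec.outlier_fraction * n))
        outlier_idx = rng.choice(n, size=n_out, replace=False)
        o = np.zeros(n)
        signs = np.where(np.arange(n_out) % 2 == 0, 1.0, -1.0)
        o[outlier_idx] = signs * spec.outlier_effect * spec.sigma_res
        b = a + delta + eps + o
        is_out = np.zeros(n, dtype=bool)
        is_out[outlier_idx] = True
        proteins.extend(ids)
        a_means.append(a)
        b_means.append(b)
        for j, pid in enumerate(ids):
            mapping[pid] = frozenset({comp})
            truth_rows.append((pid, comp, delta, bool(is_out[j]),
                               float(eps[j] + o[j]), float(o[j])))

    a_all = np.concatenate(a_means)
    b_all = np.concatenate(b_means)
    n_total = a_all.size

    cols = {}
    design_rows = []
    for r in range(spec.n_replicates):
        for cond, mu in ((cond_a, a_all), (cond_b, b_all)):
            sample = f"{cond}_r{r + 1}"
            noise = rng.normal(0.0, spec.sigma_rep, size=n_total) if spec.sigma_rep > 0 else 0.0
            cols[sample] = mu + noise
            design_rows.append((sample, cond, r + 1))
    values = pd.DataFrame(cols, index=pd.Index(proteins, name="protein"))

    if spec.missing_rate > 0:
        if left_censor:
            # drop preferentially from the low-intensity tail: missingness
            # probability proportional to the value's left-tail rank
            for col in values.columns:
                v = values[col].to_numpy()
                ranks = pd.Series(v).rank(pct=True).to_numpy()
                prob = spec.missing_rate * 2.0 * (1.0 - ranks)
                drop = rng.random(n_total) < np.clip(prob, 0.0, 1.0)
                values.loc[drop, col] = np.nan
        else:
            drop = rng.random(values.shape) < spec.missing_rate
            values = values.mask(drop)

    design = pd.DataFrame(
        design_rows, columns=["sample", "condition", "replicate"]
    ).set_index("sample")
    truth = pd.DataFrame(
        truth_rows,
        columns=["protein", "compartment", "delta", "is_outlier",
                 "residual_effect", "outlier_effect"],
    )
    matrix = AbundanceMatrix(values=values, design=design)
    annotation = CompartmentAnnotation(mapping=mapping, provenance="custom")
    return matrix, annotation, truth


def generate_timecourse(
    spec: SimulationSpec,
    timepoints: list[str],
    drift: dict[str, list[float]] | None = None,
    trajectory_effects: dict[str, dict[str, float]] | None = None,
) -> tuple[RatioSeries, CompartmentAnnotation, pd.DataFrame]:
    """Generate a common-reference log2 ratio series.

    ``drift[c]`` gives compartment c's mean ratio displacement per time point
    (length = number of time points; first entry is the baseline and is
    conventionally 0). ``trajectory_effects[t][protein]`` adds a
    protein-specific residual effect at time point t (e.g. to plant a
    protein that lags or overshoots its compartment).
    """
    if len(timepoints) < 2:
        raise ConfigurationError("need >=2 timepoints")
    if len(set(timepoints)) != len(timepoints):
        raise ConfigurationError("duplicate timepoint labels")
    drift = drift or {}
    for comp, sched in drift.items():
        if comp not in spec.n_proteins:
            raise ConfigurationError(f"drift names unknown compartment {comp!r}")
        if len(sched) != len(timepoints):
            raise ConfigurationError(
                f"drift[{comp!r}] must list one value per time point"
            )
    trajectory_effects = trajectory_effects or {}

    rng = np.random.default_rng(spec.seed)
    proteins: list[str] = []
    mapping: dict[str, frozenset[str]] = {}
    truth_rows = []
    baseline_parts = []
    comp_of = []
    for comp in sorted(spec.n_proteins):
        n = spec.n_proteins[comp]
        ids = [f"{comp[:4].upper()}_{i:05d}" for i in range(n)]
        # baseline log2 ratios vs the pooled reference scatter around 0
        r0 = rng.normal(0.0, spec.baseline_sd, size=n)
        proteins.extend(ids)
        baseline_parts.append(r0)
        comp_of.extend([comp] * n)
        for pid in ids:
            mapping[pid] = frozenset({comp})
    r_base = np.concatenate(baseline_parts)

    cols = {}
    for ti, t in enumerate(timepoints):
        d = np.array([drift.get(c, [0.0] * len(timepoints))[ti] for c in comp_of])
        noise = (rng.normal(0.0, spec.sigma_res, size=len(proteins))
                 if (spec.sigma_res > 0 and ti > 0) else np.zeros(len(proteins)))
        extra = np.zeros(len(proteins))
        for pid, eff in trajectory_effects.get(t, {}).items():
            if pid not in mapping:
                raise ConfigurationError(f"trajectory effect names unknown protein {pid!r}")
            extra[proteins.index(pid)] = eff
        cols[t] = r_base + d + noise + extra
        for j, pid in enumerate(proteins):
            truth_rows.append((pid, comp_of[j], t, float(d[j]), float(extra[j])))

    values = pd.DataFrame(cols, index=pd.Index(proteins, name="protein"))
    if spec.missing_rate > 0:
        drop = rng.random(values.shape) < spec.missing_rate
        drop[:, 0] = False  # keep the baseline complete
        values = values.mask(pd.DataFrame(drop, index=values.index, columns=values.columns))
    truth = pd.DataFrame(
        truth_rows, columns=["protein", "compartment", "timepoint", "drift", "effect"]
    )
    series = RatioSeries(values=values)
    annotation = CompartmentAnnotation(mapping=mapping, provenance="custom")
    return series, annotation, truth


def write_dataset(matrix: AbundanceMatrix, annotation: CompartmentAnnotation,
                  truth: pd.DataFrame, outdir) -> dict[str, str]:
    """Write a generated dataset in the same TSV formats the pipeline reads."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "abundance.tsv",
        "design": outdir / "design.tsv",
        "groups": outdir / "groups.tsv",
        "truth": outdir / "truth.tsv",
    }
    matrix.values.to_csv(paths["matrix"], sep="\t", na_rep="NA")
    matrix.design.reset_index().to_csv(paths["design"], sep="\t", index=False)
    rows = [(p, c) for p, comps in annotation.mapping.items() for c in sorted(comps)]
    pd.DataFrame(rows, columns=["protein", "group"]).to_csv(
        paths["groups"], sep="\t", index=False
    )
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
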