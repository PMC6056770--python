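"""Time-course mode for common-reference SILAC designs.

Each time point carries a log2 SILAC ratio against one pooled reference
sample, so any two time points can be compared directly. Three readouts:

* Δ ratios: r_t − r_baseline per protein — the raw trajectory;
* per-timepoint CNV: a compartment model fitted with x = baseline ratio and
  y = ratio at time t, so compartment-wide drift is absorbed and residual
  proteins (those changing against their compartment's trend) stand out;
* group tests: Mann-Whitney comparisons of a protein group's (e.g. complex
  members') values per time point, in Δ mode and CNV mode side by side —
  their dissociation distinguishes "the whole compartment moved" from
  "the group moved within the compartment".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cnvar.annotation import CompartmentAnnotation
from cnvar.cnv_core import CompartmentModel, run_cnv
from cnvar.errors import ConfigurationError, InputError
from cnvar.io_preprocess import ConditionMeans
from cnvar.shift_analysis import mann_whitney

logger = logging.getLogger(__name__)


@dataclass
class RatioSeries:
    """Proteins x ordered time points of log2 ratios vs a common reference."""

    values: pd.DataFrame  # index protein, columns timepoint labels, in order
    baseline: str | None = None  # defaults to the first column

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise InputError("a ratio series needs >=2 time points")
        if self.values.columns.has_duplicates:
            raise ConfigurationError("duplicate time point labels")
        if self.baseline is None:
            self.baseline = str(self.values.columns[0])
        elif self.baseline not in self.values.columns:
            raise ConfigurationError(f"baseline {self.baseline!r} not a time point")

    @property
    def timepoints(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def non_baseline(self) -> list[str]:
        return [t for t in self.timepoints if t != self.baseline]

    def as_condition_means(self) -> ConditionMeans:
        """View the series as per-"condition" means (one column per time
        point) for reuse of the pairwise machinery."""
        return ConditionMeans(
            values=self.values.copy(),
            n_observed=self.values.notna().astype(int),
            is_ratio=True,
        )


def read_ratio_series(path, timepoints: list[str] | None = None,
                      baseline: str | None = None) -> RatioSeries:
    """Read a wide TSV (protein x time points of log2 ratios)."""
    table = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    table = table.set_index(table.columns[0])
    values = table.apply(pd.to_numeric, errors="coerce")
    if timepoints is not None:
        missing = [t for t in timepoints if t not in values.columns]
        if missing:
            raise ConfigurationError(f"time points absent from table: {missing}")
        values = values[timepoints]
    return RatioSeries(values=values, baseline=baseline)


def delta_ratios(s: RatioSeries) -> pd.DataFrame:
    """Δr_t = r_t − r_baseline per protein; Δ at baseline is exactly zero.

    Proteins without a baseline value are excluded and counted; a missing
    r_t propagates a missing Δr_t.
    """
    base = s.values[s.baseline]
    has_base = base.notna()
    n_dropped = int((~has_base).sum())
    if n_dropped:
        logger.info("%d proteins lack a baseline ratio; excluded from deltas", n_dropped)
    vals = s.values.loc[has_base]
    delta = vals.sub(vals[s.baseline], axis=0)
    delta[s.baseline] = 0.0
    return delta


def timepoint_cnv(
    s: RatioSeries,
    ann: CompartmentAnnotation,
    timepoint: str,
    compartments=None,
    min_fit_size: int = 10,
    **kwargs,
) -> tuple[list[CompartmentModel], pd.DataFrame]:
    """CNV records for one time point: per compartment, fit x = baseline
    ratio, y = ratio at ``timepoint`` and standardize the residuals."""
    if timepoint == s.baseline:
        raise ConfigurationError("timepoint must differ from the baseline")
    if timepoint not in s.timepoints:
        raise ConfigurationError(f"unknown time point {timepoint!r}")
    means = s.as_condition_means()
    return run_cnv(
        means, ann, (s.baseline, timepoint), compartments=compartments,
        min_fit_size=min_fit_size, **kwargs,
    )


def all_timepoint_cnv(
    s: RatioSeries, ann: CompartmentAnnotation, compartments=None, **kwargs
) -> dict[str, pd.DataFrame]:
    """CNV records for every non-baseline time point."""
    out = {}
    for t in s.non_baseline:
        _, records = timepoint_cnv(s, ann, t, compartments=compartments, **kwargs)
        out[t] = records
    return out


def compartment_trajectory_test(
    s: RatioSeries,
    ann: CompartmentAnnotation,
    compartment: str,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-timepoint Mann-Whitney of the compartment's ratio distribution at
    t against the same compartment at baseline, plus the mean ratio."""
    members = [p for p in ann.proteins_in(compartment) if p in s.values.index]
    if len(members) < 2:
        raise ConfigurationError(
            f"compartment {compartment!r}: {len(members)} proteins, need >=2"
        )
    base_vals = s.values.loc[members, s.baseline].dropna().to_numpy()
    rows = []
    for t in s.timepoints:
        vals = s.values.loc[members, t].dropna().to_numpy()
        if t == s.baseline:
            rows.append((t, vals.size, float(np.mean(vals)), np.nan, np.nan, False))
            continue
        u, p = mann_whitney(vals, base_vals)
        rows.append((t, vals.size, float(np.mean(vals)), u, p, bool(p < alpha)))
    return pd.DataFrame(
        rows, columns=["timepoint", "n", "mean_ratio", "U", "p", "significant"]
    )


def group_trajectory_test(
    s: RatioSeries,
    ann: CompartmentAnnotation,
    group: set[str] | list[str],
    mode: str = "delta",
    alpha: float = 0.05,
    compartments=None,
    min_fit_size: int = 10,
    paired: bool = False,
) -> pd.DataFrame:
    """Per-timepoint test of a protein group's trajectory, plus its spread.

    ``mode="delta"`` compares the members' Δ ratios at each time point
    against their Δ at the first non-baseline point (the baseline itself is
    identically zero, hence degenerate). ``mode="cnv"`` compares the members'
    CNV values at each time point against their CNV at the first non-baseline
    point. The per-timepoint variance across members is reported as the
    stoichiometry-spread readout. Unpaired Mann-Whitney by default; a paired
    Wilcoxon signed-rank option exists behind ``paired=True``.
    """
    group = set(group)
    present = group & set(s.values.index)
    missing = sorted(group - present)
    if missing:
        raise ConfigurationError(f"group members absent from data: {missing}")
    if len(present) < 2:
        raise ConfigurationError("group needs >=2 members with data")
    members = sorted(present)

    if mode == "delta":
        table = delta_ratios(s).reindex(members)
        ref_point = s.non_baseline[0]
    elif mode == "cnv":
        per_t = all_timepoint_cnv(
            s, ann, compartments=compartments, min_fit_size=min_fit_size
        )
        cols = {}
        for t, records in per_t.items():
            # one cnv per protein: its best-covered compartment record
            cnv = records.groupby("protein")["cnv"].mean()
            cols[t] = cnv.reindex(members)
        table = pd.DataFrame(cols)
        ref_point = s.non_baseline[0]
    else:
        raise ConfigurationError(f"unknown group-test mode {mode!r}")

    ref_vals = table[ref_point].dropna().to_numpy()
    rows = []
    for t in table.columns:
        vals = table[t].dropna()
        spread = float(np.var(vals, ddof=1)) if vals.size > 1 else np.nan
        if t == ref_point or t == s.baseline or vals.size == 0 or ref_vals.size == 0:
            rows.append((t, int(vals.size), float(np.mean(vals)) if vals.size else np.nan,
                         spread, np.nan, np.nan, False))
            continue
        if paired:
            shared = table[[ref_point, t]].dropna()
            diffs = shared[t] - shared[ref_point]
            if np.allclose(diffs, 0):
                u, p = np.nan, 1.0
            else:
                from scipy.stats import wilcoxon
                stat = wilcoxon(shared[t], shared[ref_point])
                u, p = float(stat.statistic), float(stat.pvalue)
        else:
            u, p = mann_whitney(vals.to_numpy(), ref_vals)
        rows.append((t, int(vals.size), float(np.mean(vals)), spread, u, p,
                     bool(p < alpha)))
    return pd.DataFrame(
        rows,
        columns=["timepoint", "n", "mean_value", "spread", "U", "p", "significant"],
    )
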