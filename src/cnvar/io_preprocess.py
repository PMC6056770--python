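"""Reading, filtering and normalizing protein abundance matrices.

The pre-processing contract mirrors standard practice for label-free and
SILAC proteome comparisons:

* proteins must be quantified in more than half of the replicates of each
  compared condition, otherwise they are discarded;
* quantile normalization across samples precedes the moderated-t comparator;
* replicates are averaged per condition before the compartment-model (CNV)
  branch, which by default runs on the raw (un-normalized) averages.

Missing values are first-class: they are represented as NaN, never imputed,
and every statistic downstream is computed over observed values only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from cnvar.errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)


@dataclass
class AbundanceMatrix:
    """Proteins x samples table of log2 abundances with a sample design.

    Parameters
    ----------
    values
        DataFrame indexed by protein id, one column per sample, log2 scale;
        NaN marks a missing quantification (distinct from zero).
    design
        DataFrame indexed by sample id with columns ``condition`` and
        ``replicate``; every sample column of ``values`` must appear exactly
        once.
    is_ratio
        True when values are log2 ratios against a common reference (SILAC),
        in which case condition "fold changes" are the averaged ratios
        themselves.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    is_ratio: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise InputError(f"duplicate protein ids: {list(dups[:5])}")
        if self.values.shape[0] == 0:
            raise InputError("abundance table contains no proteins")
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise ConfigurationError(f"samples absent from design: {missing}")
        if self.design.index.has_duplicates:
            raise ConfigurationError("design lists a sample more than once")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.values.columns:
            c = self.design.loc[s, "condition"]
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, condition: str) -> list[str]:
        """Sample columns belonging to one condition, in column order."""
        cols = [
            s for s in self.values.columns
            if self.design.loc[s, "condition"] == condition
        ]
        if not cols:
            raise ConfigurationError(f"condition {condition!r} has no samples")
        return cols


@dataclass
class ConditionMeans:
    """Per-(protein, condition) mean log2 abundance over observed replicates."""

    values: pd.DataFrame       # proteins x conditions
    n_observed: pd.DataFrame   # same shape, integer counts
    is_ratio: bool = False

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)


def read_abundance_table(
    path,
    design_path,
    value_scale: str = "log2",
    sep: str | None = None,
) -> AbundanceMatrix:
    """Read an abundance table plus its design into an :class:`AbundanceMatrix`.

    The table's first column is the protein identifier; remaining columns are
    samples. The design file must have columns ``sample``, ``condition`` and
    ``replicate``. Both files may be gzip-compressed. ``value_scale="linear"``
    log2-transforms intensities, turning non-positive values into missing.
    """
    if value_scale not in ("linear", "log2"):
        raise ConfigurationError(f"unknown value_scale {value_scale!r}")
    sep = sep if sep is not None else _sniff_sep(path)
    table = pd.read_csv(path, sep=sep, comment="#", dtype={0: str})
    if table.shape[1] < 2:
        raise InputError("abundance table needs a protein column and >=1 sample")
    table = table.set_index(table.columns[0])
    table.index.name = "protein"
    values = table.apply(pd.to_numeric, errors="coerce")

    design = pd.read_csv(design_path, sep=_sniff_sep(design_path), comment="#")
    required = {"sample", "condition", "replicate"}
    if not required.issubset(design.columns):
        raise ConfigurationError(
            f"design must have columns {sorted(required)}, got {list(design.columns)}"
        )
    design = design.astype({"sample": str, "condition": str}).set_index("sample")

    if value_scale == "linear":
        raw = values.to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            arr = np.where(raw > 0, np.log2(np.where(raw > 0, raw, 1.0)), np.nan)
        values = pd.DataFrame(arr, index=values.index, columns=values.columns)
    return AbundanceMatrix(values=values, design=design)


def _sniff_sep(path) -> str:
    """Tab for .tsv/.txt, comma for .csv; default tab."""
    name = str(path)
    for ext in (".gz", ".bz2"):
        if name.endswith(ext):
            name = name[: -len(ext)]
    return "," if name.endswith(".csv") else "\t"


def filter_by_replicate_coverage(
    m: AbundanceMatrix,
    condition_pair: tuple[str, str],
    min_fraction: float = 0.5,
) -> AbundanceMatrix:
    """Keep proteins quantified in more than ``min_fraction`` of the
    replicates of both conditions; drop the rest.

    The default is "more than half" with a strict inequality on the
    per-condition replicate count: with 4 replicates a protein needs >= 3
    observed values, with 1 replicate the single value suffices.
    """
    a, b = condition_pair
    keep = pd.Series(True, index=m.values.index)
    for cond in (a, b):
        cols = m.samples_of(cond)
        n_obs = m.values[cols].notna().sum(axis=1)
        keep &= n_obs > len(cols) * min_fraction
    dropped = int((~keep).sum())
    logger.info(
        "coverage filter (%s vs %s): kept %d proteins, dropped %d",
        a, b, int(keep.sum()), dropped,
    )
    if keep.sum() == 0:
        raise InputError("coverage filter removed every protein")
    return replace(m, values=m.values.loc[keep])


def quantile_normalize(m: AbundanceMatrix) -> AbundanceMatrix:
    """Force every sample onto the common rank-wise mean distribution.

    Missing entries stay missing; ranks are computed over observed values
    only. Tied values receive the interpolated reference at their midrank,
    and samples with unequal numbers of observed values are mapped by
    interpolating the reference distribution at their quantile positions.
    """
    X = m.values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise InputError("quantile normalization needs >=2 samples")
    counts = np.sum(~np.isnan(X), axis=0)
    if np.any(counts == 0):
        bad = [m.values.columns[i] for i in np.flatnonzero(counts == 0)]
        raise InputError(f"samples with no observed values: {bad}")

    n_ref = int(counts.max())
    grid = np.linspace(0.0, 1.0, n_ref) if n_ref > 1 else np.array([0.5])
    # reference distribution: mean across samples of each sample's quantiles
    ref = np.zeros(len(grid))
    for j in range(X.shape[1]):
        obs = np.sort(X[~np.isnan(X[:, j]), j])
        pos = (np.linspace(0.0, 1.0, obs.size) if obs.size > 1
               else np.array([0.5]))
        ref += np.interp(grid, pos, obs)
    ref /= X.shape[1]

    out = np.full_like(X, np.nan)
    from scipy.stats import rankdata

    for j in range(X.shape[1]):
        mask = ~np.isnan(X[:, j])
        obs = X[mask, j]
        r = rankdata(obs, method="average")  # midranks for ties
        p = (r - 1.0) / (obs.size - 1.0) if obs.size > 1 else np.full(obs.size, 0.5)
        out[mask, j] = np.interp(p, grid, ref)
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return replace(m, values=values)


def average_replicates(
    m: AbundanceMatrix, conditions: list[str] | None = None
) -> ConditionMeans:
    """Arithmetic mean of observed log2 values per (protein, condition)."""
    conditions = conditions if conditions is not None else m.conditions
    means = {}
    counts = {}
    for cond in conditions:
        cols = m.samples_of(cond)
        means[cond] = m.values[cols].mean(axis=1, skipna=True)
        counts[cond] = m.values[cols].notna().sum(axis=1)
    return ConditionMeans(
        values=pd.DataFrame(means),
        n_observed=pd.DataFrame(counts).astype(int),
        is_ratio=m.is_ratio,
    )
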