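"""Compartment-wide fold-change shift detection.

A shifted organelle (more/fewer mitochondria, bigger nuclei) displaces the
whole fold-change distribution of its proteins. The test is a two-sided
Mann-Whitney comparison of the compartment's log2 fold changes against the
whole proteome's, reported together with the mean (headline) and median
log2FC of the compartment.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from cnvar.annotation import CompartmentAnnotation, FOUR_MAJOR_COMPARTMENTS
from cnvar.errors import ConfigurationError
from cnvar.io_preprocess import ConditionMeans

logger = logging.getLogger(__name__)

#: Exact Mann-Whitney enumeration limit on the combined sample size.
EXACT_LIMIT = 20


@dataclass
class ShiftResult:
    """Result of one compartment-vs-background fold-change comparison."""

    compartment: str
    n_proteins: int
    mean_log2fc: float
    median_log2fc: float
    u_statistic: float
    p_value: float
    significant: bool
    alpha: float = 0.01


def protein_fold_changes(
    means: ConditionMeans, conditions: tuple[str, str]
) -> pd.Series:
    """log2 fold change per protein: mean(test) - mean(reference).

    For ratio-mode data the values already are log2 ratios vs a common
    reference, so the fold change of a single condition is the averaged
    ratio itself; pass the same label twice to extract it.
    """
    ref, test = conditions
    for c in (ref, test):
        if c not in means.conditions:
            raise ConfigurationError(f"condition {c!r} absent from means")
    if means.is_ratio and ref == test:
        fc = means.values[test]
    else:
        fc = means.values[test] - means.values[ref]
    n_dropped = int(fc.isna().sum())
    if n_dropped:
        logger.info("%d proteins lack a mean in one condition; excluded", n_dropped)
    return fc.dropna()


def mann_whitney(
    a, b, mode: str = "auto", continuity: bool = True
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of sample a, p).

    ``mode="exact"`` enumerates the exact null distribution (valid without
    ties); ``mode="normal-approx"`` uses the normal approximation with
    tie-corrected variance and continuity correction; ``mode="auto"`` picks
    exact when the combined size is at most 20 and there are no ties.
    When every value in both samples is identical the test is vacuous and
    p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ConfigurationError("Mann-Whitney needs non-empty samples")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if np.unique(pooled).size == 1:
        return float(a.size * b.size / 2.0), 1.0
    if mode == "auto":
        mode = "exact" if (pooled.size <= EXACT_LIMIT and not has_ties) else "normal-approx"
    if mode == "exact":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    elif mode == "normal-approx":
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic",
            use_continuity=continuity,
        )
    else:
        raise ConfigurationError(f"unknown Mann-Whitney mode {mode!r}")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def mann_whitney_enumerate(a, b) -> tuple[float, float]:
    """Brute-force exact two-sided Mann-Whitney p by enumerating every
    C(n+m, n) assignment of the pooled values to the two groups (midranks
    for ties). Independent reference for small samples; O(C(n+m, n))."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n, m = a.size, b.size
    ranks = stats.rankdata(pooled, method="average")
    u_obs = float(ranks[:n].sum() - n * (n + 1) / 2.0)
    mid = n * m / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(n + m), n):
        u = float(ranks[list(combo)].sum() - n * (n + 1) / 2.0)
        if abs(u - mid) >= abs(u_obs - mid) - 1e-12:
            count += 1
        total += 1
    return u_obs, count / total


def compartment_shift_test(
    fc: pd.Series,
    ann: CompartmentAnnotation,
    compartment: str,
    background: str = "whole-proteome",
    alpha: float = 0.01,
    mode: str = "auto",
) -> ShiftResult:
    """Mann-Whitney comparison of one compartment's fold changes against the
    background.

    ``background="whole-proteome"`` compares against all quantified proteins
    including the compartment itself (the literal reading of the density-plot
    comparison); ``background="complement"`` excludes the compartment, which
    avoids diluting the null when the compartment is large.
    """
    members = [p for p in ann.proteins_in(compartment) if p in fc.index]
    if len(members) < 2:
        raise ConfigurationError(
            f"compartment {compartment!r}: {len(members)} quantified proteins, need >=2"
        )
    comp_fc = fc.loc[members].to_numpy()
    if background == "whole-proteome":
        bg = fc.to_numpy()
    elif background == "complement":
        bg = fc.drop(index=members).to_numpy()
    else:
        raise ConfigurationError(f"unknown background {background!r}")
    if bg.size == 0:
        raise ConfigurationError("empty background")
    u, p = mann_whitney(comp_fc, bg, mode=mode)
    return ShiftResult(
        compartment=compartment,
        n_proteins=len(members),
        mean_log2fc=float(np.mean(comp_fc)),
        median_log2fc=float(np.median(comp_fc)),
        u_statistic=u,
        p_value=p,
        significant=bool(p < alpha),
        alpha=alpha,
    )


def shift_report(
    means: ConditionMeans,
    ann: CompartmentAnnotation,
    conditions: tuple[str, str],
    compartments=FOUR_MAJOR_COMPARTMENTS,
    background: str = "whole-proteome",
    alpha: float = 0.01,
    min_size: int = 2,
) -> pd.DataFrame:
    """One ShiftResult row per analyzed compartment (four major by default,
    all ten by passing the full name list). Undersized compartments produce
    a skip row with NaN statistics."""
    fc = protein_fold_changes(means, conditions)
    rows = []
    for comp in compartments:
        members = [p for p in ann.proteins_in(comp) if p in fc.index]
        if len(members) < min_size:
            logger.info("compartment %s skipped: %d proteins", comp, len(members))
            rows.append(
                {"compartment": comp, "n": len(members), "mean_log2fc": np.nan,
                 "median_log2fc": np.nan, "U": np.nan, "p": np.nan,
                 "significant": False, "skipped": True}
            )
            continue
        r = compartment_shift_test(fc, ann, comp, background=background, alpha=alpha)
        rows.append(
            {"compartment": comp, "n": r.n_proteins, "mean_log2fc": r.mean_log2fc,
             "median_log2fc": r.median_log2fc, "U": r.u_statistic, "p": r.p_value,
             "significant": r.significant, "skipped": False}
        )
    return pd.DataFrame(rows)


def cross_compartment_shift_correlation(
    reports: list[pd.DataFrame],
) -> pd.DataFrame:
    """Correlation matrix of per-compartment mean shifts across several runs.

    Each input is a shift_report table from one contrast/dataset. Compartment
    pairs whose mean shifts track each other across runs (e.g. organelles
    that co-vary in abundance) approach correlation 1.
    """
    if len(reports) < 2:
        raise ConfigurationError("need >=2 shift reports for a correlation matrix")
    wide = pd.DataFrame(
        {i: rep.set_index("compartment")["mean_log2fc"] for i, rep in enumerate(reports)}
    )
    return wide.T.corr(method="pearson")
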