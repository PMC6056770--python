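"""Empirical-Bayes moderated-t differential expression and overlap classing.

The comparator is the standard two-group moderated t: per-protein pooled
within-group variances s_g^2 (d_g residual degrees of freedom) are shrunk
toward a prior s0^2 with d0 prior degrees of freedom,

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),
    t~_g   = (mean_B - mean_A) / (s~_g * sqrt(1/n_A + 1/n_B)),

with t~_g referred to a t distribution on d0 + d_g degrees of freedom.
(d0, s0^2) are estimated by moments matching on log s_g^2: under the scaled
chi-square model, e_g = log s_g^2 - digamma(d_g/2) + log(d_g/2) has mean
log s0^2 - digamma(d0/2) + log(d0/2) and variance trigamma(d_g/2) +
trigamma(d0/2), so d0 follows from inverting the trigamma function on the
excess variance of e_g.

Proteins are then classified by agreement between this comparator and the
compartment-normalized (CNV) analysis at a shared q threshold: significant in
both, standard-only (typically a compartment-wide abundance change the CNV
model absorbs), cnv-only (a composition change invisible to whole-proteome
statistics), or neither.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from cnvar.cnv_core import bh_qvalues
from cnvar.errors import ConfigurationError
from cnvar.io_preprocess import AbundanceMatrix

logger = logging.getLogger(__name__)

DE_COLUMNS = [
    "protein", "log2fc", "s2", "s2_post", "t", "df", "p", "q",
]

OVERLAP_CLASSES = ("both", "standard-only", "cnv-only", "neither")


def _trigamma(x):
    return polygamma(1, x)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Estimate (d0, s0^2) by closed-form moments matching on log s_g^2.

    Returns (inf, mean variance) when the observed log-variances are no more
    dispersed than sampling alone explains.
    """
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise ConfigurationError("too few positive variances to estimate the prior")
    z = np.log(s2[ok])
    d = df[ok].astype(float)
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    ebar = float(e.mean())
    n = e.size
    evar = float(np.sum((e - ebar) ** 2) / (n - 1)) - float(np.mean(_trigamma(d / 2.0)))
    if evar <= 0:
        return np.inf, float(np.mean(s2[ok]))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(ebar + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_ttest(
    m: AbundanceMatrix,
    conditions: tuple[str, str],
    d0_mode: str = "estimate",
    d0: float | None = None,
    s0_sq: float | None = None,
) -> pd.DataFrame:
    """Two-group moderated t-test per protein.

    The input should be quantile-normalized. Missing replicate values are
    dropped per protein; proteins without at least one residual degree of
    freedom across the two groups (and at least one value per group) are
    excluded and counted. ``d0_mode="fixed"`` uses the supplied (d0, s0_sq)
    instead of estimating them; d0 = 0 recovers the ordinary pooled t-test.
    """
    ref, test = conditions
    cols_a = m.samples_of(ref)
    cols_b = m.samples_of(test)
    A = m.values[cols_a].to_numpy(dtype=float)
    B = m.values[cols_b].to_numpy(dtype=float)

    na = np.sum(~np.isnan(A), axis=1)
    nb = np.sum(~np.isnan(B), axis=1)
    with np.errstate(invalid="ignore"):
        mean_a = np.nanmean(np.where(np.isnan(A), np.nan, A), axis=1)
        mean_b = np.nanmean(np.where(np.isnan(B), np.nan, B), axis=1)
        var_a = _nanvar(A, na)
        var_b = _nanvar(B, nb)
    dg = (na - 1) + (nb - 1)
    usable = (na >= 1) & (nb >= 1) & (dg >= 1)
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info("%d proteins lack residual df in both groups; excluded", n_excluded)
    if usable.sum() == 0:
        raise ConfigurationError("no protein has enough replicates for a variance")

    idx = np.flatnonzero(usable)
    na, nb, dg = na[idx], nb[idx], dg[idx]
    lfc = (mean_b - mean_a)[idx]
    ssa = np.where(na > 1, var_a[idx] * (na - 1), 0.0)
    ssb = np.where(nb > 1, var_b[idx] * (nb - 1), 0.0)
    s2 = (ssa + ssb) / dg

    if d0_mode == "estimate":
        d0_hat, s0_hat = estimate_prior(s2, dg)
    elif d0_mode == "fixed":
        if d0 is None:
            raise ConfigurationError("d0_mode='fixed' requires d0")
        d0_hat = float(d0)
        s0_hat = float(s0_sq) if s0_sq is not None else float(np.median(s2))
    else:
        raise ConfigurationError(f"unknown d0_mode {d0_mode!r}")

    if np.isinf(d0_hat):
        s2_post = np.full_like(s2, s0_hat)
        df_total = np.full_like(dg, np.inf, dtype=float)
    else:
        s2_post = (d0_hat * s0_hat + dg * s2) / (d0_hat + dg)
        df_total = d0_hat + dg.astype(float)

    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, np.where(lfc == 0, 0.0, np.inf * np.sign(lfc)))
    p = np.where(
        np.isinf(df_total),
        2.0 * stats.norm.sf(np.abs(t)),
        2.0 * stats.t.sf(np.abs(t), df_total),
    )
    p = np.clip(p, 0.0, 1.0)
    q = bh_qvalues(p)

    out = pd.DataFrame(
        {
            "protein": m.values.index.to_numpy()[idx],
            "log2fc": lfc,
            "s2": s2,
            "s2_post": s2_post,
            "t": t,
            "df": df_total,
            "p": p,
            "q": q,
        }
    )
    out.attrs["d0"] = d0_hat
    out.attrs["s0_sq"] = s0_hat
    out.attrs["n_excluded"] = n_excluded
    return out[DE_COLUMNS]


def _nanvar(X: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Per-row sample variance over observed values (ddof=1); NaN where n<2."""
    out = np.full(X.shape[0], np.nan)
    rows = np.flatnonzero(n > 1)
    for i in rows:
        v = X[i][~np.isnan(X[i])]
        out[i] = np.var(v, ddof=1)
    return out


def classify_overlap(
    de: pd.DataFrame,
    cnv_summary: pd.DataFrame,
    thresholds=(0.05, 0.1, 0.25),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify proteins by joint significance of the comparator and CNV q.

    Returns (classes, percentages): ``classes`` has one row per protein per
    threshold with its class; ``percentages`` gives the class composition per
    threshold. Proteins present in only one analysis are classified on the
    available side (the missing q counts as non-significant) and flagged.
    """
    qde = de.set_index("protein")["q"]
    qcnv = cnv_summary.set_index("protein")["q_cnv"]
    proteins = qde.index.union(qcnv.index)
    rows = []
    for tau in thresholds:
        for prot in proteins:
            in_de = prot in qde.index
            in_cnv = prot in qcnv.index
            sig_de = bool(in_de and qde[prot] < tau)
            sig_cnv = bool(in_cnv and qcnv[prot] < tau)
            if sig_de and sig_cnv:
                cls = "both"
            elif sig_de:
                cls = "standard-only"
            elif sig_cnv:
                cls = "cnv-only"
            else:
                cls = "neither"
            rows.append((prot, tau, cls, not (in_de and in_cnv)))
    classes = pd.DataFrame(rows, columns=["protein", "threshold", "class", "partial"])
    pct = (
        classes.groupby(["threshold", "class"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    totals = pct.groupby("threshold")["n"].transform("sum")
    pct["percent"] = 100.0 * pct["n"] / totals
    return classes, pct


def statistic_correlation(de: pd.DataFrame, cnv_summary: pd.DataFrame) -> float:
    """Pearson r between -log10 q of the comparator and of the CNV analysis
    over shared proteins; NaN when either vector is constant."""
    merged = de.merge(cnv_summary, on="protein")
    merged = merged[(merged["q"] > 0) & (merged["q_cnv"] > 0)].dropna(
        subset=["q", "q_cnv"]
    )
    if len(merged) < 3:
        raise ConfigurationError("need >=3 shared proteins for a correlation")
    x = -np.log10(merged["q"].to_numpy())
    y = -np.log10(merged["q_cnv"].to_numpy())
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)
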