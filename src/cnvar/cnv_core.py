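"""Per-compartment linear models and compartment-normalized variation values.

For one compartment, let x_i and y_i be protein i's mean log2 abundance in
the reference and test condition. An ordinary least-squares line

    y = b0 + b1 * x

absorbs any compartment-wide multiplicative shift (a wholesale change of the
organelle's abundance moves b0, not the residuals). The residual

    e_i = y_i - (b0 + b1 * x_i)

standardized across the compartment,

    cnv_i = (e_i - mean(e)) / sd(e),        sd with n-1 denominator,

is the protein's CNV value: how much it deviates from its own compartment's
trend, in compartment-residual standard deviations. Positive CNV means the
protein is relatively more abundant in the test condition than the
compartment trend predicts. Two-sided p-values use a standard-normal null on
the CNV z-score; q-values are Benjamini-Hochberg within each compartment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from cnvar.annotation import CompartmentAnnotation, FOUR_MAJOR_COMPARTMENTS
from cnvar.errors import ConfigurationError, ModelError
from cnvar.io_preprocess import ConditionMeans

logger = logging.getLogger(__name__)

#: Column order of the per-protein records table (bit-exact contract).
RECORD_COLUMNS = [
    "protein", "compartment", "x", "y", "residual", "cnv", "p", "q",
    "model_retained", "cnv_computable",
]

#: Column order of the per-compartment models table.
MODEL_COLUMNS = [
    "compartment", "n", "slope", "intercept", "R2", "model_p", "retained",
]


@dataclass
class CompartmentModel:
    """OLS fit of test-condition vs reference-condition log2 abundances."""

    compartment: str
    n_proteins: int
    slope: float
    intercept: float
    r_squared: float
    model_p: float
    retained: bool
    residual_sd: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def fit_compartment_model(
    x,
    y,
    compartment: str = "",
    min_fit_size: int = 10,
    retention_p: float = 0.05,
) -> CompartmentModel:
    """Fit y = b0 + b1*x by ordinary least squares.

    The model p-value is the two-sided t-test of the slope with n-2 degrees
    of freedom (equivalently the F-test of the simple regression); the model
    is flagged retained when model_p < ``retention_p``. Fits with fewer than
    3 points or constant x are refused.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or n < min(min_fit_size, 3):
        raise ModelError(
            f"compartment {compartment!r}: {n} points, need >=3 to fit"
        )
    if np.ptp(x) == 0:
        raise ModelError(f"compartment {compartment!r}: constant x, degenerate fit")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    sse = float(np.sum(resid**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    model_p = float(res.pvalue)
    return CompartmentModel(
        compartment=compartment,
        n_proteins=int(n),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        model_p=model_p,
        retained=bool(model_p < retention_p),
        residual_sd=float(np.std(resid, ddof=1)),
    )


def compute_cnv(
    model: CompartmentModel, protein_ids, x, y
) -> pd.DataFrame:
    """Residuals and standardized residuals (CNV values) under a fitted model.

    When all residuals are equal (perfect fit) the CNV value is undefined;
    records are still emitted with ``cnv_computable=False`` and NaN cnv.
    Records of non-retained models carry ``model_retained=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    resid = y - model.predict(x)
    sd = float(np.std(resid, ddof=1)) if resid.size > 1 else 0.0
    computable = sd > 0
    if computable:
        cnv = (resid - resid.mean()) / sd
    else:
        logger.warning(
            "compartment %s: zero residual spread, CNV not computable",
            model.compartment,
        )
        cnv = np.full_like(resid, np.nan)
    return pd.DataFrame(
        {
            "protein": list(protein_ids),
            "compartment": model.compartment,
            "x": x,
            "y": y,
            "residual": resid,
            "cnv": cnv,
            "model_retained": model.retained,
            "cnv_computable": computable,
        }
    )


def cnv_pvalues(cnv) -> np.ndarray:
    """Two-sided p-values for CNV z-scores under a standard-normal null."""
    z = np.asarray(cnv, dtype=float)
    p = np.full(z.shape, np.nan)
    finite = np.isfinite(z)
    p[finite] = 2.0 * stats.norm.sf(np.abs(z[finite]))
    # z = 0 must give exactly 1, not 2*0.5 with rounding slack
    return np.clip(p, 0.0, 1.0, out=p)


def bh_qvalues(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, clipped to 1.

    NaN p-values get NaN q-values and do not count toward the number of
    tests.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    finite = np.isfinite(p)
    pv = p[finite]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # step-up: running minimum from the largest p
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    q[finite] = out
    return q


def rescale_to_empirical_null(cnv) -> np.ndarray:
    """Rescale z-scores by a robust (MAD-based) null standard deviation.

    Approximates an empirical-null correction: when the bulk of CNV values is
    over- or under-dispersed relative to N(0,1), dividing by the MAD-derived
    SD restores calibration of the central mass before the normal-null
    p-values are computed.
    """
    z = np.asarray(cnv, dtype=float)
    finite = z[np.isfinite(z)]
    if finite.size == 0:
        return z
    mad_sd = stats.median_abs_deviation(finite, scale="normal")
    if mad_sd <= 0:
        return z
    return z / mad_sd


def run_cnv(
    means: ConditionMeans,
    ann: CompartmentAnnotation,
    conditions: tuple[str, str],
    compartments=None,
    min_fit_size: int = 10,
    retention_p: float = 0.05,
    empirical_null: bool = False,
    pooled_q: bool = False,
) -> tuple[list[CompartmentModel], pd.DataFrame]:
    """Fit every compartment's model and emit one CNV record per
    (protein, compartment) pair.

    ``conditions = (reference, test)`` fixes the axis convention
    (x = reference, y = test). Compartments with fewer than ``min_fit_size``
    quantified proteins are skipped and logged. q-values are BH-adjusted
    within each compartment by default, or across all records with
    ``pooled_q=True``.
    """
    ref, test = conditions
    for c in (ref, test):
        if c not in means.conditions:
            raise ConfigurationError(f"condition {c!r} absent from means")
    comp_list = list(compartments) if compartments is not None else ann.compartments()

    xs = means.values[ref]
    ys = means.values[test]
    quantified = xs.notna() & ys.notna()

    models: list[CompartmentModel] = []
    frames: list[pd.DataFrame] = []
    for comp in comp_list:
        members = [p for p in ann.proteins_in(comp) if p in xs.index and quantified.get(p, False)]
        if len(members) < min_fit_size:
            logger.info(
                "compartment %s skipped: %d proteins < min_fit_size %d",
                comp, len(members), min_fit_size,
            )
            continue
        x = xs.loc[members].to_numpy()
        y = ys.loc[members].to_numpy()
        model = fit_compartment_model(
            x, y, compartment=comp, min_fit_size=min_fit_size,
            retention_p=retention_p,
        )
        records = compute_cnv(model, members, x, y)
        z = records["cnv"].to_numpy()
        if empirical_null:
            z = rescale_to_empirical_null(z)
        records["p"] = cnv_pvalues(z)
        if not pooled_q:
            records["q"] = bh_qvalues(records["p"].to_numpy())
        models.append(model)
        frames.append(records)
    if not models:
        raise ConfigurationError("no compartment reached min_fit_size; nothing to fit")
    records = pd.concat(frames, ignore_index=True)
    if pooled_q:
        records["q"] = bh_qvalues(records["p"].to_numpy())
    return models, records[RECORD_COLUMNS]


def models_table(models: list[CompartmentModel]) -> pd.DataFrame:
    """Per-compartment models as a DataFrame with the contract columns."""
    return pd.DataFrame(
        {
            "compartment": [m.compartment for m in models],
            "n": [m.n_proteins for m in models],
            "slope": [m.slope for m in models],
            "intercept": [m.intercept for m in models],
            "R2": [m.r_squared for m in models],
            "model_p": [m.model_p for m in models],
            "retained": [m.retained for m in models],
        }
    )[MODEL_COLUMNS]


def protein_cnv_summary(
    records: pd.DataFrame, compartments=FOUR_MAJOR_COMPARTMENTS
) -> pd.DataFrame:
    """Per-protein summary: the minimum q across the protein's compartments
    (restricted to ``compartments``) and the compartment achieving it."""
    sub = records[records["compartment"].isin(set(compartments))]
    sub = sub.dropna(subset=["q"])
    if sub.empty:
        return pd.DataFrame(columns=["protein", "q_cnv", "compartment", "cnv"])
    idx = sub.groupby("protein")["q"].idxmin()
    out = sub.loc[idx, ["protein", "q", "compartment", "cnv"]].rename(
        columns={"q": "q_cnv"}
    )
    return out.reset_index(drop=True)


def compare_model_variants(
    records_all: pd.DataFrame, records_exclusive: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of CNV values between the all-proteins models and
    the compartment-exclusive models, per compartment, for shared proteins.

    Supports the robustness check that multi-compartment membership does not
    distort the models. Compartments with fewer than 3 shared proteins get a
    NaN correlation. The last row, compartment ``"__average__"``, is the mean
    correlation over compartments with a defined value.
    """
    rows = []
    comps = sorted(
        set(records_all["compartment"]) & set(records_exclusive["compartment"])
    )
    for comp in comps:
        a = records_all[records_all["compartment"] == comp].set_index("protein")["cnv"]
        b = records_exclusive[records_exclusive["compartment"] == comp].set_index("protein")["cnv"]
        shared = a.index.intersection(b.index)
        av = a.loc[shared].to_numpy(dtype=float)
        bv = b.loc[shared].to_numpy(dtype=float)
        ok = np.isfinite(av) & np.isfinite(bv)
        if ok.sum() < 3:
            rows.append((comp, int(ok.sum()), np.nan))
            continue
        r = float(stats.pearsonr(av[ok], bv[ok]).statistic)
        rows.append((comp, int(ok.sum()), r))
    df = pd.DataFrame(rows, columns=["compartment", "n_shared", "pearson_r"])
    mean_r = float(df["pearson_r"].mean()) if df["pearson_r"].notna().any() else np.nan
    df.loc[len(df)] = ("__average__", int(df["n_shared"].sum()), mean_r)
    return df
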