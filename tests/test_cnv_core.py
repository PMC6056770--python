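import numpy as np
import pandas as pd
import pytest

from cnvar.annotation import CompartmentAnnotation
from cnvar.cnv_core import (
    bh_qvalues,
    cnv_pvalues,
    compare_model_variants,
    compute_cnv,
    fit_compartment_model,
    models_table,
    protein_cnv_summary,
    run_cnv,
)
from cnvar.errors import ConfigurationError, ModelError
from cnvar.io_preprocess import ConditionMeans


def closed_form_ols(x, y):
    """Normal-equations oracle, independent of the fitting path."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    return slope, intercept


def grid_search_ols(x, y, slope0, intercept0, half_width=0.5, steps=101):
    """Brute-force SSE minimization over a parameter grid around a guess."""
    best = (None, None, np.inf)
    for b1 in np.linspace(slope0 - half_width, slope0 + half_width, steps):
        for b0 in np.linspace(intercept0 - half_width, intercept0 + half_width, steps):
            sse = np.sum((y - b0 - b1 * x) ** 2)
            if sse < best[2]:
                best = (b1, b0, sse)
    return best


def means_from_xy(proteins, x, y, conditions=("A", "B")) -> ConditionMeans:
    a, b = conditions
    values = pd.DataFrame({a: x, b: y}, index=pd.Index(proteins, name="protein"))
    return ConditionMeans(values=values, n_observed=values.notna().astype(int))


class TestFitCompartmentModel:
    def test_known_fit_statistics(self):
        m = fit_compartment_model([1, 2, 3, 4, 5], [1, 3, 2, 5, 4], min_fit_size=3)
        assert m.slope == pytest.approx(0.8)
        assert m.intercept == pytest.approx(0.6)
        assert m.r_squared == pytest.approx(0.64)
        assert m.model_p == pytest.approx(0.1041, abs=2e-4)
        assert m.retained is False
        assert m.residual_sd == pytest.approx(np.sqrt(0.9))

    def test_perfect_fit(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        m = fit_compartment_model(x, x, min_fit_size=3)
        assert m.slope == pytest.approx(1.0)
        assert m.intercept == pytest.approx(0.0, abs=1e-12)
        assert m.r_squared == pytest.approx(1.0)
        assert m.residual_sd == pytest.approx(0.0, abs=1e-12)

    def test_colinear_with_duplicated_points(self):
        m = fit_compartment_model([1, 1, 3], [2, 2, 6], min_fit_size=3)
        assert m.r_squared == pytest.approx(1.0)
        assert m.slope == pytest.approx(2.0)

    def test_too_few_points_is_model_error(self):
        with pytest.raises(ModelError, match="need >=3"):
            fit_compartment_model([1, 2], [1, 2], min_fit_size=3)

    def test_constant_x_is_degenerate(self):
        with pytest.raises(ModelError, match="constant x"):
            fit_compartment_model([2, 2, 2, 2], [1, 2, 3, 4], min_fit_size=3)

    def test_matches_closed_form_and_grid_oracles(self, rng):
        """100 random fits agree with the normal equations to 1e-10 and with
        brute-force SSE grid minimization to grid resolution."""
        for _ in range(100):
            n = rng.integers(5, 51)
            x = rng.normal(20, 2, n)
            y = 0.5 + 1.1 * x + rng.normal(0, 0.4, n)
            m = fit_compartment_model(x, y, min_fit_size=3)
            slope, intercept = closed_form_ols(x, y)
            assert m.slope == pytest.approx(slope, abs=1e-10)
            assert m.intercept == pytest.approx(intercept, abs=1e-10)
        # grid oracle on a handful (it is slow): grid step = 0.01
        for _ in range(3):
            x = rng.normal(20, 2, 20)
            y = 1.0 * x + rng.normal(0, 0.5, 20)
            m = fit_compartment_model(x, y, min_fit_size=3)
            b1, b0, _ = grid_search_ols(x, y, m.slope, m.intercept)
            assert abs(b1 - m.slope) <= 0.011
            assert abs(b0 - m.intercept) <= 0.011


class TestComputeCnv:
    def test_standardized_residuals_known_values(self):
        x = [1, 2, 3, 4, 5]
        y = [1, 3, 2, 5, 4]
        m = fit_compartment_model(x, y, min_fit_size=3)
        rec = compute_cnv(m, list("abcde"), x, y)
        np.testing.assert_allclose(
            rec["cnv"], [-0.4216, 0.8433, -1.0541, 1.2649, -0.6325], atol=1e-4
        )
        assert rec["residual"].mean() == pytest.approx(0.0, abs=1e-9)
        assert rec["cnv"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_perfect_fit_not_computable(self):
        x = np.arange(5.0)
        m = fit_compartment_model(x, 2 * x + 1, min_fit_size=3)
        rec = compute_cnv(m, list("abcde"), x, 2 * x + 1)
        assert not rec["cnv_computable"].any()
        assert rec["cnv"].isna().all()

    def test_constant_offset_absorbed_by_intercept(self, rng):
        x = rng.normal(20, 2, 30)
        y = x + rng.normal(0, 0.3, 30)
        m1 = fit_compartment_model(x, y, min_fit_size=3)
        r1 = compute_cnv(m1, range(30), x, y)
        m2 = fit_compartment_model(x, y + 2.5, min_fit_size=3)
        r2 = compute_cnv(m2, range(30), x, y + 2.5)
        np.testing.assert_allclose(r1["cnv"], r2["cnv"], atol=1e-8)
        assert m2.intercept - m1.intercept == pytest.approx(2.5, abs=1e-8)

    def test_affine_invariance(self, rng):
        """cnv unchanged under y -> a*y + b with a > 0 applied compartment-wide."""
        x = rng.normal(20, 2, 40)
        y = 0.9 * x + rng.normal(0, 0.3, 40)
        m1 = fit_compartment_model(x, y, min_fit_size=3)
        r1 = compute_cnv(m1, range(40), x, y)
        y2 = 1.7 * y - 4.0
        m2 = fit_compartment_model(x, y2, min_fit_size=3)
        r2 = compute_cnv(m2, range(40), x, y2)
        np.testing.assert_allclose(r1["cnv"], r2["cnv"], atol=1e-8)


class TestPQValues:
    def test_normal_null_pvalues(self):
        p = cnv_pvalues([0.0, 1.959964, -1.959964, np.nan])
        assert p[0] == pytest.approx(1.0)
        assert p[1] == pytest.approx(0.05, abs=1e-6)
        assert p[2] == p[1]  # symmetry
        assert np.isnan(p[3])

    def test_bh_stepup_by_hand(self):
        np.testing.assert_allclose(
            bh_qvalues([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(bh_qvalues([1.0]), [1.0])

    def test_bh_monotone_in_p_rank(self, rng):
        p = rng.random(200)
        q = bh_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all((q > 0) & (q <= 1))


class TestRunCnv:
    def _two_compartments(self, rng, n=50):
        xs, ys, ids, mapping = [], [], [], {}
        for comp in ("mito", "cyto"):
            x = rng.normal(20, 2, n)
            y = x + rng.normal(0, 0.3, n)
            pid = [f"{comp}{i}" for i in range(n)]
            xs.append(x)
            ys.append(y)
            ids.extend(pid)
            mapping.update({p: frozenset({comp}) for p in pid})
        means = means_from_xy(ids, np.concatenate(xs), np.concatenate(ys))
        return means, CompartmentAnnotation(mapping, provenance="custom")

    def test_record_and_model_counts(self, rng):
        means, ann = self._two_compartments(rng, n=50)
        models, records = run_cnv(means, ann, ("A", "B"))
        assert len(models) == 2
        assert len(records) == 100
        table = models_table(models)
        assert list(table.columns) == [
            "compartment", "n", "slope", "intercept", "R2", "model_p", "retained",
        ]
        assert list(records.columns[:8]) == [
            "protein", "compartment", "x", "y", "residual", "cnv", "p", "q",
        ]

    def test_small_compartment_skipped(self, rng):
        means, ann = self._two_compartments(rng, n=50)
        small = {f"s{i}": frozenset({"peroxi"}) for i in range(5)}
        mapping = dict(ann.mapping, **small)
        vals = means.values.copy()
        for p in small:
            vals.loc[p] = [20.0 + len(p), 20.0 + len(p)]
        means2 = ConditionMeans(vals, vals.notna().astype(int))
        ann2 = CompartmentAnnotation(mapping, provenance="custom")
        models, records = run_cnv(means2, ann2, ("A", "B"), min_fit_size=10)
        assert {m.compartment for m in models} == {"mito", "cyto"}
        assert "peroxi" not in set(records["compartment"])

    def test_multi_compartment_protein_gets_one_record_each(self, rng):
        means, ann = self._two_compartments(rng, n=50)
        mapping = dict(ann.mapping)
        mapping["mito0"] = frozenset({"mito", "cyto"})
        ann2 = CompartmentAnnotation(mapping, provenance="custom")
        models, records = run_cnv(means, ann2, ("A", "B"))
        sub = records[records["protein"] == "mito0"]
        assert set(sub["compartment"]) == {"mito", "cyto"}
        # total record count matches the sum of annotation set sizes
        expected = sum(len(s) for s in ann2.mapping.values())
        assert len(records) == expected

    def test_no_usable_compartment_is_error(self, rng):
        means, ann = self._two_compartments(rng, n=5)
        with pytest.raises(ConfigurationError):
            run_cnv(means, ann, ("A", "B"), min_fit_size=10)

    def test_unknown_condition_is_error(self, rng):
        means, ann = self._two_compartments(rng)
        with pytest.raises(ConfigurationError):
            run_cnv(means, ann, ("A", "Z"))

    def test_null_calibration(self, rng):
        """Slope-1 Gaussian data: cnv mean ~ 0, sd ~ 1, p<0.05 rate ~ 5%."""
        n = 2000
        x = rng.normal(20, 2, n)
        y = x + rng.normal(0, 0.3, n)
        ids = [f"p{i}" for i in range(n)]
        means = means_from_xy(ids, x, y)
        ann = CompartmentAnnotation(
            {p: frozenset({"comp"}) for p in ids}, provenance="custom"
        )
        _, records = run_cnv(means, ann, ("A", "B"))
        assert abs(records["cnv"].mean()) < 0.05
        assert 0.95 <= records["cnv"].std(ddof=1) <= 1.05
        frac = (records["p"] < 0.05).mean()
        assert 0.035 <= frac <= 0.065


class TestCompareModelVariants:
    def _records(self, comp, proteins, cnv):
        return pd.DataFrame(
            {"protein": proteins, "compartment": comp, "cnv": cnv}
        )

    def test_identical_records_give_r_one(self, rng):
        z = rng.normal(size=30)
        r = compare_model_variants(
            self._records("mito", range(30), z), self._records("mito", range(30), z)
        )
        assert r.set_index("compartment").loc["mito", "pearson_r"] == pytest.approx(1.0)

    def test_negated_records_give_r_minus_one(self, rng):
        z = rng.normal(size=30)
        r = compare_model_variants(
            self._records("mito", range(30), z), self._records("mito", range(30), -z)
        )
        assert r.set_index("compartment").loc["mito", "pearson_r"] == pytest.approx(-1.0)

    def test_independent_values_match_covariance_formula(self, rng):
        a = rng.normal(size=100)
        b = rng.normal(size=100)
        r = compare_model_variants(
            self._records("mito", range(100), a), self._records("mito", range(100), b)
        )
        got = r.set_index("compartment").loc["mito", "pearson_r"]
        manual = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
            np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)
        )
        assert got == pytest.approx(manual, abs=1e-12)
        assert abs(got) < 0.3

    def test_too_few_shared_proteins_missing(self):
        r = compare_model_variants(
            self._records("mito", [1, 2], [0.1, 0.2]),
            self._records("mito", [1, 2], [0.1, 0.2]),
        )
        assert np.isnan(r.set_index("compartment").loc["mito", "pearson_r"])


def test_protein_summary_takes_min_q_with_compartment(rng):
    records = pd.DataFrame(
        {
            "protein": ["P1", "P1", "P2"],
            "compartment": ["mitochondrion", "nucleus", "nucleus"],
            "cnv": [1.0, 2.0, -0.5],
            "q": [0.5, 0.01, 0.2],
        }
    )
    out = protein_cnv_summary(records)
    out = out.set_index("protein")
    assert out.loc["P1", "q_cnv"] == pytest.approx(0.01)
    assert out.loc["P1", "compartment"] == "nucleus"
    assert out.loc["P2", "q_cnv"] == pytest.approx(0.2)
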