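"""Tier-1 index suite, least-square means, heritability and summaries."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trlim import phenotypes as ph
from trlim.errors import (
    InvalidInputError,
    InvalidRecordError,
    MeasurementWarning,
    RankDeficiencyError,
    UndefinedDivisionError,
)

rates = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


class TestTranspirationRate:
    @pytest.mark.parametrize(
        "mi, mf, interval, area, expected",
        [
            (150.00, 150.00, 60.0, None, 0.0),
            (150.00, 149.40, 60.0, None, 10.0),
            # 10 mg/min over 0.01 m2, per second -> 50/3 mg m-2 s-1
            (150.00, 149.40, 60.0, 0.01, 50.0 / 3.0),
        ],
    )
    def test_rate_from_mass_loss(self, mi, mf, interval, area, expected):
        m = ph.TranspirationMeasurement(
            "g", "s1", 1, "water", mi, mf, interval, leaf_area=area
        )
        assert ph.transpiration_rate(m) == pytest.approx(expected)

    def test_nonpositive_interval_names_record(self):
        with pytest.raises(InvalidRecordError, match="g7"):
            ph.TranspirationMeasurement("g7", "s1", 1, "water", 150, 149, 0.0)

    def test_negative_rate_flagged_not_dropped(self):
        m = ph.TranspirationMeasurement("g", "s1", 1, "agno3", 150.0, 150.2, 60.0)
        with pytest.warns(MeasurementWarning):
            assert ph.transpiration_rate(m) < 0


class TestDecreaseIndices:
    @pytest.mark.parametrize(
        "h2o, ag, dtr, rtr, ndtr",
        [
            (1.0, 1.0, 0.0, 1.0, 0.0),
            (2.0, 1.0, 50.0, 2.0, 1 / 3),
            # parental water/inhibitor means of the reference screen
            (1.40, 0.94, 32.857142857, 1.489361702, 0.196581197),
        ],
    )
    def test_formulas(self, h2o, ag, dtr, rtr, ndtr):
        out = ph.decrease_indices(h2o, ag)
        assert out.dtr == pytest.approx(dtr)
        assert out.rtr == pytest.approx(rtr)
        assert out.ndtr == pytest.approx(ndtr)

    def test_zero_inhibitor_rate_keeps_dtr_ndtr(self):
        with pytest.warns(Warning):
            out = ph.decrease_indices(1.0, 0.0)
        assert math.isnan(out.rtr)
        assert out.dtr == 100.0 and out.ndtr == 1.0

    def test_nonpositive_water_rate_rejected(self):
        with pytest.raises(InvalidInputError):
            ph.decrease_indices(0.0, 0.5)

    @given(h2o=rates, ag=rates)
    @settings(max_examples=200, deadline=None)
    def test_algebraic_identities(self, h2o, ag):
        """ndtr = (rtr-1)/(rtr+1) and dtr = 100*(1 - 1/rtr) for positive rates."""
        out = ph.decrease_indices(h2o, ag)
        assert math.isclose(
            out.ndtr, (out.rtr - 1) / (out.rtr + 1), rel_tol=1e-9, abs_tol=1e-9
        )
        assert math.isclose(
            out.dtr, 100 * (1 - 1 / out.rtr), rel_tol=1e-9, abs_tol=1e-9
        )

    @given(h2o=rates)
    @settings(max_examples=50, deadline=None)
    def test_partial_inhibition_bounds(self, h2o):
        ag = h2o * 0.5
        out = ph.decrease_indices(h2o, ag)
        assert 0 <= out.dtr <= 100 and out.rtr >= 1 and 0 <= out.ndtr <= 1


class TestRelativeIndices:
    def test_parent_relative_to_itself_is_one(self):
        assert ph.relative_indices(2.0, 1.0, 2.0)[1] == 1.0

    def test_hand_arithmetic(self):
        assert ph.relative_indices(0.5, 1.0, 2.0) == (0.5, 0.25)

    def test_zero_numerator(self):
        assert ph.relative_indices(0.0, 1.0, 1.0) == (0.0, 0.0)

    def test_zero_reference_names_parent(self):
        with pytest.raises(UndefinedDivisionError, match="KS4895"):
            ph.relative_indices(1.0, 1.0, 0.0)


class TestWiltingClassification:
    @pytest.mark.parametrize(
        "value, cls",
        [
            (0.14, ph.WiltingClass.SLOW),
            (0.50, ph.WiltingClass.SLOW),
            (0.71, ph.WiltingClass.MODERATE),
            (1.00, ph.WiltingClass.MODERATE),
            (1.01, ph.WiltingClass.FAST),
            (3.05, ph.WiltingClass.FAST),
        ],
    )
    def test_boundaries(self, value, cls):
        assert ph.classify_wilting(value) == cls

    def test_negative_rejected(self):
        with pytest.raises(InvalidInputError):
            ph.classify_wilting(-0.1)

    @given(st.floats(min_value=0, max_value=20, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_total_and_monotone(self, v):
        order = [ph.WiltingClass.SLOW, ph.WiltingClass.MODERATE, ph.WiltingClass.FAST]
        c1 = ph.classify_wilting(v)
        c2 = ph.classify_wilting(v + 0.37)
        assert order.index(c2) >= order.index(c1)


class TestGenotypeLSM:
    def test_balanced_reduces_to_means(self):
        d = pd.DataFrame(
            {"genotype": list("AABB"), "set": ["s1"] * 4, "v": [1, 3, 2, 4]}
        )
        lsm = ph.genotype_lsm(d, "v")
        assert lsm["A"] == pytest.approx(2, abs=1e-9)
        assert lsm["B"] == pytest.approx(3, abs=1e-9)

    def test_unbalanced_matches_normal_equations(self):
        # hand-solved: 3*gA + s = 5, 3*gB + s = 8 -> gB - gA = 1
        d = pd.DataFrame(
            {
                "genotype": ["A", "A", "A", "B", "B", "B"],
                "set": ["s1", "s1", "s2", "s1", "s1", "s2"],
                "v": [1, 1, 3, 2, 2, 4],
            }
        )
        lsm = ph.genotype_lsm(d, "v")
        assert lsm["B"] - lsm["A"] == pytest.approx(1.0, abs=1e-9)

    def test_constant_data(self):
        d = pd.DataFrame(
            {"genotype": list("AABB"), "set": ["s1", "s2"] * 2, "v": [5.0] * 4}
        )
        assert np.allclose(ph.genotype_lsm(d, "v"), 5.0)

    def test_confounded_design_raises(self):
        # each genotype seen in exactly one set: genotype and set aliased
        d = pd.DataFrame(
            {"genotype": list("AABB"), "set": ["s1", "s1", "s2", "s2"], "v": [1, 2, 3, 4]}
        )
        with pytest.raises(RankDeficiencyError):
            ph.genotype_lsm(d, "v")

    def test_balanced_multiset_equals_arithmetic_mean(self, small_pop):
        rng = np.random.default_rng(1)
        genos = [f"g{i}" for i in range(10)]
        rows = []
        for s in range(3):
            for _ in range(2):
                rows.append(
                    pd.DataFrame(
                        {"genotype": genos, "set": f"s{s}", "v": rng.normal(size=10)}
                    )
                )
        d = pd.concat(rows)
        lsm = ph.genotype_lsm(d, "v")
        means = d.groupby("genotype")["v"].mean()
        assert np.allclose(lsm.sort_index(), means.sort_index(), atol=1e-9)


class TestTraitSummary:
    def test_hand_arithmetic(self):
        s = ph.trait_summary([1, 2, 3])
        assert (s.mean, s.sd, s.variance, s.n) == (2, 1, 1, 3)
        assert s.sem == pytest.approx(0.57735, abs=1e-4)
        assert s.cv_percent == pytest.approx(50)
        assert s.skewness == pytest.approx(0, abs=1e-12)
        assert s.upper95 > s.mean > s.lower95

    def test_constant_vector_markers(self):
        s = ph.trait_summary([4.0, 4.0, 4.0, 4.0])
        assert s.sd == 0 and s.cv_percent == 0
        assert math.isnan(s.skewness)

    def test_single_value_dispersion_undefined(self):
        s = ph.trait_summary([1.0])
        assert s.n == 1 and math.isnan(s.sd) and math.isnan(s.sem)


class TestVarianceComponentsAndHeritability:
    def _simulate(self, sg, sge, se, G=100, S=3, R=3, seed=0):
        rng = np.random.default_rng(seed)
        g = rng.normal(0, math.sqrt(sg), G)
        rows = []
        for s in range(S):
            ge = rng.normal(0, math.sqrt(sge), G) if sge else np.zeros(G)
            for r in range(R):
                rows.append(
                    pd.DataFrame(
                        {
                            "genotype": [f"g{i}" for i in range(G)],
                            "set": f"s{s}",
                            "v": g + ge + rng.normal(0, math.sqrt(se), G),
                        }
                    )
                )
        return pd.concat(rows)

    def test_null_genotype_effect(self):
        d = self._simulate(0, 0, 1, seed=3)
        vc = ph.variance_components(d, "v")
        assert vc["sigma_g2"] < 0.15

    def test_known_components_recovered(self):
        d = self._simulate(4, 1, 1, seed=5)
        vc = ph.variance_components(d, "v")
        assert vc["sigma_g2"] == pytest.approx(4, rel=0.3)
        assert vc["sigma_ge2"] == pytest.approx(1, rel=0.3)
        assert vc["sigma_e2"] == pytest.approx(1, rel=0.3)

    def test_zero_residual_deterministic(self):
        d = self._simulate(1, 0, 0, seed=7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vc = ph.variance_components(d, "v")
        assert vc["sigma_e2"] == pytest.approx(0, abs=1e-12)

    def test_missing_cell_rejected(self):
        d = self._simulate(1, 0, 1, G=4, S=2, R=2)
        d = d[~((d["genotype"] == "g0") & (d["set"] == "s1"))]
        with pytest.raises(InvalidInputError, match="cell"):
            ph.variance_components(d, "v")

    @pytest.mark.parametrize(
        "vc, E, R, expected",
        [
            ({"sigma_g2": 1, "sigma_ge2": 0, "sigma_e2": 0}, 4, 2, 1.0),
            ({"sigma_g2": 1, "sigma_ge2": 1, "sigma_e2": 1}, 6, 3, 0.81818),
            ({"sigma_g2": 0, "sigma_ge2": 1, "sigma_e2": 1}, 3, 3, 0.0),
        ],
    )
    def test_heritability_formula(self, vc, E, R, expected):
        assert ph.heritability(vc, E, R).h2 == pytest.approx(expected, abs=1e-5)

    def test_heritability_all_zero_undefined(self):
        with pytest.raises(UndefinedDivisionError):
            ph.heritability({"sigma_g2": 0, "sigma_ge2": 0, "sigma_e2": 0}, 2, 2)

    @given(
        sg=st.floats(0.1, 10),
        sge=st.floats(0, 5),
        se=st.floats(0, 5),
        E=st.integers(1, 10),
        R=st.integers(1, 10),
    )
    @settings(max_examples=100, deadline=None)
    def test_heritability_monotone(self, sg, sge, se, E, R):
        base = ph.heritability(
            {"sigma_g2": sg, "sigma_ge2": sge, "sigma_e2": se}, E, R
        ).h2
        more_g = ph.heritability(
            {"sigma_g2": sg + 1, "sigma_ge2": sge, "sigma_e2": se}, E, R
        ).h2
        more_e = ph.heritability(
            {"sigma_g2": sg, "sigma_ge2": sge, "sigma_e2": se}, E + 1, R
        ).h2
        more_r = ph.heritability(
            {"sigma_g2": sg, "sigma_ge2": sge, "sigma_e2": se}, E, R + 1
        ).h2
        assert more_g >= base - 1e-12
        assert more_e >= base - 1e-12
        assert more_r >= base - 1e-12


class TestCorrelationAndPolynomial:
    def test_self_and_perfect_linearity(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1, "c": np.sin(x)})
        r, p = ph.correlation_matrix(df)
        assert r.loc["a", "a"] == 1.0
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert r.equals(r.T)

    def test_small_table_matches_textbook_formula(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        df = pd.DataFrame({"x": x, "y": y})
        r, _ = ph.correlation_matrix(df)
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert r.loc["x", "y"] == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_marked_nan(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5]})
        r, _ = ph.correlation_matrix(df)
        assert math.isnan(r.loc["a", "b"])

    def test_quadratic_exact_and_constant(self):
        x = np.linspace(-2, 2, 9)
        assert ph.quadratic_fit(x, x**2)["r_squared"] == pytest.approx(1.0)
        assert ph.quadratic_fit(x, np.full_like(x, 3.0))["r_squared"] == 0.0

    def test_quadratic_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(8)
        x = np.linspace(25, 36, 30)
        y = 0.05 * (x - 30) ** 2 + rng.normal(0, 0.2, 30)
        fit = ph.quadratic_fit(x, y)
        X = np.column_stack([x**2, x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit["coefficients"], beta, atol=1e-8)


class TestIndexTable:
    def test_zero_noise_recovers_planted_sensitivity(self, balanced_weighing):
        table = ph.compute_index_table(balanced_weighing)
        assert table.at["Jackson", "dtr"] == pytest.approx(33.0, abs=1e-9)
        assert table.at["RIL001", "dtr"] == pytest.approx(10.0, abs=1e-9)
        assert table.at["KS4895", "rdtr_k"] == pytest.approx(1.0, abs=1e-12)
        assert table.at["KS4895", "rndtr_k"] == pytest.approx(1.0, abs=1e-12)
        assert table.at["RIL001", "wilting_class"] == "slow"

    def test_round_trip_csv(self, balanced_weighing, tmp_path):
        table = ph.compute_index_table(balanced_weighing)
        path = tmp_path / "idx.csv"
        table.to_csv(path)
        back = pd.read_csv(path, index_col=0)
        assert np.allclose(back["dtr"], table["dtr"])

    def test_summary_report_layout(self, balanced_weighing):
        table = ph.compute_index_table(balanced_weighing)
        rep = ph.summary_report(table, traits=["tr_h2o", "dtr"])
        assert list(rep.index)[:3] == ["Mean", "SD", "SEM"]
        assert rep.loc["N", "tr_h2o"] == 3
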