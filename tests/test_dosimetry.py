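"""Time-activity fitting, cumulated activity, S-factor doses, statistics."""

import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from prait.dosimetry import (
    IN111,
    LU177,
    ExponentialFit,
    IsotopeSpec,
    SFactorTable,
    TimeActivityCurve,
    absorbed_dose,
    compare_cohorts,
    compare_sessions,
    cumulated_activity,
    fit_time_activity,
    spearman_exact,
    translate_isotope,
)

LN2 = np.log(2.0)


class TestFitTimeActivity:
    def test_exact_monoexponential_recovered(self):
        t = np.array([1.0, 10.0, 30.0, 80.0])
        fit = fit_time_activity(t, 100.0 * np.exp(-0.05 * t))
        # four points -> biexponential form, but the curve itself must match
        assert np.allclose(fit(t), 100.0 * np.exp(-0.05 * t), rtol=1e-6)

    def test_three_points_forced_monoexponential(self):
        t = np.array([1.0, 24.0, 96.0])
        y = 80.0 * np.exp(-0.1 * t) + 20.0 * np.exp(-0.01 * t)
        fit = fit_time_activity(t, y)
        assert fit.form == "mono"
        assert len(fit.coefficients) == 1

    def test_mono_rate_recovered_exactly(self):
        t = np.array([2.0, 20.0, 60.0])
        fit = fit_time_activity(t, 50.0 * np.exp(-0.03 * t))
        assert fit.form == "mono"
        assert fit.rates[0] == pytest.approx(0.03, rel=1e-6)
        assert fit.coefficients[0] == pytest.approx(50.0, rel=1e-6)

    def test_monte_carlo_dominant_rate_bias(self):
        rng = np.random.default_rng(31)
        t = np.array([1.0, 6.0, 24.0, 72.0, 168.0])
        truth = 120.0 * np.exp(-0.15 * t) + 60.0 * np.exp(-0.01 * t)
        biases = []
        for _ in range(200):
            y = truth * np.exp(0.10 * rng.standard_normal(t.size))
            fit = fit_time_activity(t, y)
            biases.append((max(fit.rates) - 0.15) / 0.15)
        assert abs(np.median(biases)) < 0.10

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValueError):
            fit_time_activity(np.array([1.0]), np.array([5.0]))

    def test_accepts_time_activity_curve(self):
        curve = TimeActivityCurve(
            times=[1.0, 24.0, 96.0], activities=[50.0, 20.0, 5.0], organ="liver"
        )
        assert fit_time_activity(curve).form == "mono"


class TestCumulatedActivity:
    def test_pure_physical_decay(self):
        fit = ExponentialFit("mono", (1.0,), (1e-12,))
        iso = IsotopeSpec("X", 1.0)
        assert cumulated_activity(fit, iso) == pytest.approx(1.0 / LN2, rel=1e-9)

    def test_linear_in_coefficient(self):
        f1 = ExponentialFit("mono", (1.0,), (0.02,))
        f2 = ExponentialFit("mono", (2.0,), (0.02,))
        assert cumulated_activity(f2, LU177) == pytest.approx(
            2 * cumulated_activity(f1, LU177), rel=1e-12
        )

    def test_matches_quadrature_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            c = rng.uniform(1, 200, 2)
            lam = rng.uniform(0.005, 0.3, 2)
            fit = ExponentialFit("bi", tuple(c), tuple(lam))
            for iso in (IN111, LU177):
                lam_p = iso.decay_constant
                t_max = 50.0 / min(lam + lam_p)
                oracle, _ = quad(
                    lambda t: sum(ci * np.exp(-(li + lam_p) * t) for ci, li in zip(c, lam)),
                    0.0, t_max, limit=400,
                )
                assert cumulated_activity(fit, iso) == pytest.approx(oracle, rel=1e-6)


class TestTranslateIsotope:
    def test_zero_biological_clearance_scales_by_halflife_ratio(self):
        fit = ExponentialFit("mono", (10.0,), (1e-15,))
        a_in = cumulated_activity(fit, IN111)
        a_lu = translate_isotope(fit, IN111, LU177)
        assert a_lu / a_in == pytest.approx(LU177.half_life_h / IN111.half_life_h, rel=1e-9)

    def test_identity_translation(self):
        fit = ExponentialFit("bi", (5.0, 2.0), (0.1, 0.01))
        assert translate_isotope(fit, IN111, IN111) == cumulated_activity(fit, IN111)

    def test_algebraic_identity_random_fits(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            fit = ExponentialFit(
                "bi", tuple(rng.uniform(1, 100, 2)), tuple(rng.uniform(0.001, 0.5, 2))
            )
            assert translate_isotope(fit, IN111, LU177) == cumulated_activity(fit, LU177)


def _simple_table():
    return SFactorTable(
        entries={("kidneys", "kidneys"): 0.02, ("liver", "liver"): 0.01,
                 ("liver", "kidneys"): 0.001, ("kidneys", "liver"): 0.001},
        reference_masses={"kidneys": 0.31, "liver": 1.8},
    )


class TestAbsorbedDose:
    def test_zero_cumulated_activity_gives_zero_dose(self):
        report = absorbed_dose(
            {"kidneys": 0.0, "liver": 0.0}, _simple_table(),
            {"kidneys": 0.31, "liver": 1.8}, administered_MBq=185.0,
        )
        assert np.all(report.table["dose_mGy"] == 0.0)

    def test_self_dose_direct_product_at_reference_mass(self):
        table = SFactorTable(
            entries={("kidneys", "kidneys"): 0.02}, reference_masses={"kidneys": 0.31}
        )
        report = absorbed_dose(
            {"kidneys": 10.0}, table, {"kidneys": 0.31}, administered_MBq=100.0
        )
        assert report.table["dose_mGy"].iloc[0] == pytest.approx(0.2, rel=1e-12)
        assert report.table["dose_mGy_per_MBq"].iloc[0] == pytest.approx(0.002, rel=1e-12)

    def test_halving_organ_mass_doubles_self_dose(self):
        table = SFactorTable(
            entries={("kidneys", "kidneys"): 0.02}, reference_masses={"kidneys": 0.31}
        )
        full = absorbed_dose({"kidneys": 10.0}, table, {"kidneys": 0.31}, 100.0)
        half = absorbed_dose({"kidneys": 10.0}, table, {"kidneys": 0.155}, 100.0)
        assert half.table["dose_mGy"].iloc[0] == pytest.approx(
            2 * full.table["dose_mGy"].iloc[0], rel=1e-12
        )

    def test_cross_dose_not_mass_scaled(self):
        table = _simple_table()
        d1 = absorbed_dose({"kidneys": 0.0, "liver": 10.0}, table,
                           {"kidneys": 0.31, "liver": 1.8}, 100.0)
        d2 = absorbed_dose({"kidneys": 0.0, "liver": 10.0}, table,
                           {"kidneys": 0.155, "liver": 1.8}, 100.0)
        k1 = d1.table.set_index("organ").loc["kidneys", "dose_mGy"]
        k2 = d2.table.set_index("organ").loc["kidneys", "dose_mGy"]
        assert k1 == pytest.approx(k2, rel=1e-12)

    def test_missing_s_entry_names_the_pair(self):
        table = SFactorTable(
            entries={("kidneys", "kidneys"): 0.02, ("liver", "liver"): 0.01},
            reference_masses={"kidneys": 0.31, "liver": 1.8},
        )
        with pytest.raises(KeyError, match="liver.*kidneys"):
            absorbed_dose({"kidneys": 1.0, "liver": 1.0}, table,
                          {"kidneys": 0.31, "liver": 1.8}, 100.0)

    def test_normalized_dose_invariant_to_administered_activity(self):
        table = _simple_table()
        masses = {"kidneys": 0.31, "liver": 1.8}
        r1 = absorbed_dose({"kidneys": 10.0, "liver": 30.0}, table, masses, 185.0)
        r2 = absorbed_dose({"kidneys": 20.0, "liver": 60.0}, table, masses, 370.0)
        assert np.allclose(
            r1.table["dose_mGy_per_MBq"], r2.table["dose_mGy_per_MBq"], rtol=1e-12
        )


class TestSpearmanExact:
    def test_identical_vectors_rho_one(self):
        rho, _ = spearman_exact([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert rho == pytest.approx(1.0)

    def test_reversed_ranks_rho_minus_one(self):
        rho, _ = spearman_exact([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_matches_brute_force_enumeration_n5(self):
        rng = np.random.default_rng(23)
        x = rng.standard_normal(5)
        y = rng.standard_normal(5)
        rho, p = spearman_exact(x, y)
        # independent oracle: direct enumeration over all 120 permutations
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rho_oracle = np.corrcoef(rx, ry)[0, 1]
        count = sum(
            abs(np.corrcoef(rx, ry[list(perm)])[0, 1]) >= abs(rho_oracle) - 1e-12
            for perm in itertools.permutations(range(5))
        )
        assert rho == pytest.approx(rho_oracle, rel=1e-12)
        assert p == pytest.approx(count / 120.0, rel=1e-12)

    def test_large_n_uses_approximation_consistent_with_scipy(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(20)
        y = x + 0.5 * rng.standard_normal(20)
        rho, p = spearman_exact(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, rel=1e-9)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


class TestCompareSessions:
    def _report(self, doses, session):
        import pandas as pd
        from prait.dosimetry import DoseReport

        organs = [f"o{i}" for i in range(len(doses))]
        return DoseReport(
            table=pd.DataFrame(
                {"organ": organs, "cumulated_MBq_h": 1.0, "dose_mGy": doses,
                 "dose_mGy_per_MBq": doses}
            ),
            session=session,
        )

    def test_identical_reports_perfect_correlation(self):
        r = self._report([0.1, 0.2, 0.3, 0.15, 0.4], "S1")
        out = compare_sessions(r, self._report([0.1, 0.2, 0.3, 0.15, 0.4], "S2"))
        assert out["spearman_rho"] == pytest.approx(1.0)

    def test_mismatched_organs_rejected(self):
        r1 = self._report([0.1, 0.2, 0.3], "S1")
        r2 = self._report([0.1, 0.2, 0.3, 0.4], "S2")
        with pytest.raises(ValueError, match="organ sets differ"):
            compare_sessions(r1, r2)

    def test_kruskal_wallis_across_cohorts(self):
        out = compare_cohorts(
            {
                "I": [0.10, 0.12, 0.11, 0.09, 0.13],
                "II": [0.30, 0.33, 0.29, 0.35, 0.31],
                "III": [0.31, 0.35, 0.30, 0.36, 0.32],
            }
        )
        assert out["kruskal_p"] < 0.05
        with pytest.raises(ValueError):
            compare_cohorts({"I": [0.1, 0.2]})
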