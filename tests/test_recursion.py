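import numpy as np
import pandas as pd
import pytest

from khulan import (
    AnalysisWindow,
    PeriodicModelSpec,
    RecursionConfig,
    fit_poisson_periodicity,
    fit_visits_vs_hr,
    focal_visit_decomposition,
    km_curve,
    model_lambda,
    recursion_table,
    sample_recursion_durations,
)
from khulan.recursion import MODEL_DF, duration_counts

from conftest import bruteforce_recursion_record as oracle_record, make_traj


@pytest.fixture
def window2d():
    return AnalysisWindow.from_start("2013-08-12T00:00:00+00:00", days=2, season_label="summer")


class TestFocalDecomposition:
    def test_spec_example_two_runs(self, window2d):
        # in-circle at hours 0-2 and 27-29, outside otherwise
        xy = []
        for h in range(48):
            xy.append((0.0, 0.0) if h in (0, 1, 2, 27, 28, 29) else (5000.0, 0.0))
        traj = make_traj(xy, window2d)
        rec = focal_visit_decomposition(traj, 1)
        assert rec.residence_h == 3
        assert rec.recursion_h == 24
        assert not rec.recursion_censored
        assert rec.n_visits == 2

    def test_never_leaves(self, window2d):
        traj = make_traj([(0.0, 0.0)] * 48, window2d)
        rec = focal_visit_decomposition(traj, 10)
        assert rec.residence_h == 48  # whole window
        assert rec.recursion_censored
        assert rec.n_visits == 1

    def test_censored_after_final_exit(self, window2d):
        xy = [(0.0, 0.0)] * 3 + [(5000.0, 0.0)] * 45
        traj = make_traj(xy, window2d)
        rec = focal_visit_decomposition(traj, 0)
        assert rec.recursion_censored
        assert rec.recursion_h == 47 - 2  # window end hour minus exit hour

    def test_row_count(self, window2d):
        traj = make_traj([(100.0 * i, 0.0) for i in range(48)], window2d)
        table = recursion_table(traj)
        assert len(table) == 48

    def test_stationary_table(self, window2d):
        traj = make_traj([(0.0, 0.0)] * 48, window2d)
        table = recursion_table(traj)
        assert (table["n_visits"] == 1).all()
        assert table["censored"].all()

    def test_matches_oracle_on_random_walks(self, window2d):
        rng = np.random.default_rng(0)
        window = AnalysisWindow.from_start("2013-08-12T00:00:00+00:00", days=4)
        steps = rng.normal(scale=150, size=(96, 2)).cumsum(axis=0)
        hours = sorted(rng.choice(96, size=90, replace=False))
        traj = make_traj(steps[hours], window, hours=hours)
        table = recursion_table(traj)
        for i in range(len(traj)):
            res, rec, cens, nv = oracle_record(traj, i)
            row = table.iloc[i]
            assert row["residence_h"] == res
            assert row["recursion_h"] == rec
            assert row["censored"] == cens
            assert row["n_visits"] == nv

    def test_radius_monotonicity(self, window2d):
        rng = np.random.default_rng(1)
        window = AnalysisWindow.from_start("2013-08-12T00:00:00+00:00", days=3)
        steps = rng.normal(scale=120, size=(72, 2)).cumsum(axis=0)
        traj = make_traj(steps, window)
        t_small = recursion_table(traj, RecursionConfig(radius_m=150))
        t_big = recursion_table(traj, RecursionConfig(radius_m=300))
        assert (t_big["residence_h"] >= t_small["residence_h"]).all()
        # entering a bigger circle is never rarer per location
        assert (t_big["n_visits"] >= 1).all()


class TestKaplanMeier:
    def test_uncensored_median(self):
        km = km_curve([2, 4, 6])
        assert km.median_h == 4

    def test_hand_computed_censored(self):
        km = km_curve([2, 4, 6], censored=[True, False, False])
        # S(4) = 1 * (1 - 1/2) = 0.5 -> median 4
        i = np.where(km.times == 4)[0][0]
        assert km.survival[i] == pytest.approx(0.5)
        assert km.median_h == 4

    def test_all_censored_undefined_median(self):
        km = km_curve([5, 7, 9], censored=[True, True, True])
        assert np.isnan(km.median_h)
        assert (km.survival == 1.0).all()

    def test_no_censoring_equals_empirical_survivor(self):
        rng = np.random.default_rng(3)
        d = rng.integers(1, 50, size=200)
        km = km_curve(d)
        for t, s in zip(km.times, km.survival):
            if t == 0:
                continue
            emp = (d > t).mean()
            assert s == pytest.approx(emp, abs=1e-12)

    def test_survival_monotone_from_one(self):
        rng = np.random.default_rng(4)
        d = rng.integers(1, 100, size=150)
        c = rng.random(150) < 0.4
        km = km_curve(d, c)
        assert km.survival[0] <= 1.0 + 1e-12
        assert (np.diff(km.survival) <= 1e-12).all()


class TestPeriodicityFits:
    def test_flat_counts_recover_m1(self):
        rng = np.random.default_rng(5)
        durations = np.repeat(np.arange(1, 169), 5)
        fits, best = fit_poisson_periodicity(durations, RecursionConfig())
        m1 = next(f for f in fits if f.model_id == "M1")
        assert m1.alphas[1] == pytest.approx(0.0, abs=1e-8)
        assert m1.alphas[0] == pytest.approx(np.log(5.0), abs=1e-8)

    def test_df_bookkeeping(self):
        durations = np.repeat(np.arange(1, 169), 3)
        fits, _ = fit_poisson_periodicity(durations, RecursionConfig())
        by_id = {f.model_id: f for f in fits}
        assert by_id["M1"].df == 2 and by_id["M2"].df == 2
        assert by_id["M3"].df == 3
        assert by_id["M4"].df == 4 and by_id["M5"].df == 4
        for f in fits:
            assert f.aic == pytest.approx(2 * f.df - 2 * f.loglik)

    def test_phase_recovery_single(self):
        spec = PeriodicModelSpec("M4", (0.0, -0.005, -0.3, 0.8), k=11)
        d = sample_recursion_durations(spec, range(1, 169), n=5000, seed=42)
        _, best = fit_poisson_periodicity(d, RecursionConfig())
        assert best.model_id in ("M4", "M5")
        assert best.k == 11

    def test_lambda_peak_at_24_minus_k(self):
        spec = PeriodicModelSpec("M4", (2.0, 0.0, 0.0, 1.0), k=3)
        t = np.arange(1, 169)
        lam = model_lambda(spec, t)
        peaks = t[np.argsort(lam)[-7:]]
        assert 21 in peaks and 45 in peaks and 69 in peaks

    def test_minimum_count_enforced(self):
        with pytest.raises(ValueError, match="at least"):
            fit_poisson_periodicity(np.arange(1, 10), RecursionConfig())

    def test_duration_counts_include_zero_bins(self):
        counts = duration_counts([1, 1, 5], 10)
        assert counts.tolist() == [2, 0, 0, 0, 1, 0, 0, 0, 0, 0]


class TestVisitsVsHomeRange:
    def rows(self, c_by_season=None, noise_sd=0.05, animal_sd=0.0, seed=0,
             orthogonal_noise=True):
        """Animal-season rows obeying n_tilde = c_season / A up to noise.

        With ``orthogonal_noise`` the log-noise is residualized against
        (1, log A) within each season, so the constructed inverse law is
        exact: chance noise-area correlation cannot reward a free slope.
        """
        rng = np.random.default_rng(seed)
        animals = [f"A{i}" for i in range(1, 6)]
        animal_eff = {a: rng.normal(0, animal_sd) for a in animals}
        data = []
        for season in ("summer", "winter"):
            c = (c_by_season or {"summer": 100.0, "winter": 100.0})[season]
            areas = rng.uniform(5, 40, size=len(animals))
            eps = rng.normal(0, noise_sd, size=len(animals))
            if orthogonal_noise:
                X = np.column_stack([np.ones(len(areas)), np.log(areas)])
                eps = eps - X @ np.linalg.lstsq(X, eps, rcond=None)[0]
            for a, area, e in zip(animals, areas, eps):
                n_tilde = c / area * np.exp(animal_eff[a] + e)
                data.append(
                    {"animal": a, "season": season, "n_tilde": n_tilde, "area_km2": area}
                )
        return pd.DataFrame(data)

    def test_offset_model_wins_on_inverse_law(self):
        fits, best = fit_visits_vs_hr(self.rows())
        assert best.model_id in ("R4", "R7")
        intercepts = best.fixed[: len(best.fixed_names)]
        assert np.allclose(intercepts, np.log(100.0), atol=0.15)

    def test_seasonal_offset_prefers_r4(self):
        rows = self.rows(c_by_season={"summer": 300.0, "winter": 60.0})
        fits, best = fit_visits_vs_hr(rows)
        by_id = {f.model_id: f for f in fits}
        assert by_id["R4"].aicc < by_id["R7"].aicc
        assert best.model_id == "R4"

    def test_df_bookkeeping(self):
        fits, _ = fit_visits_vs_hr(self.rows())
        df = {f.model_id: f.df for f in fits}
        assert df == {"R1": 6, "R2": 5, "R3": 5, "R4": 4, "R5": 4, "R6": 4, "R7": 3, "R8": 3}
        for f in fits:
            p, n = f.df, 10
            assert f.aicc == pytest.approx(f.aic + 2 * p * (p + 1) / (n - p - 1))

    def test_cross_check_against_statsmodels_mixedlm(self):
        # R6: common intercept + common slope; compare ML loglik and beta
        import statsmodels.api as sm

        rows = self.rows(noise_sd=0.3, animal_sd=0.5, seed=3)
        fits, _ = fit_visits_vs_hr(rows)
        r6 = next(f for f in fits if f.model_id == "R6")
        y = np.log(rows["n_tilde"])
        X = sm.add_constant(np.log(rows["area_km2"]))
        md = sm.MixedLM(y, X, groups=rows["animal"]).fit(reml=False)
        assert r6.loglik == pytest.approx(md.llf, abs=1e-3)
        assert r6.fixed == pytest.approx(np.asarray(md.fe_params), abs=1e-3)

    def test_positive_inputs_required(self):
        rows = self.rows()
        rows.loc[0, "n_tilde"] = 0.0
        with pytest.raises(ValueError):
            fit_visits_vs_hr(rows)
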