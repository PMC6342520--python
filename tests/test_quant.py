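"""Radial quantification: R assignment, binning, densities, smoothing, tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from islandfate import quant
from islandfate.synthetic import (
    IslandSimConfig,
    LogisticMarkerModel,
    MARKER_PRESETS,
    generate_cell_table,
)


def one_island(radius=300.0):
    return pd.DataFrame(
        {
            "island_id": [0],
            "centroid_x": [0.0],
            "centroid_y": [0.0],
            "effective_radius": [radius],
        }
    )


def cells_at(points, island_id=0, **extra):
    df = pd.DataFrame(points, columns=["x", "y"])
    df.insert(0, "cell_id", np.arange(len(df)))
    df.insert(1, "island_id", island_id)
    for k, v in extra.items():
        df[k] = v
    return df


class TestAssignRadius:
    def test_cell_at_centroid(self):
        cells = quant.assign_dimensionless_radius(cells_at([(0.0, 0.0)]), one_island())
        assert cells["R"].iloc[0] == 0.0
        assert not cells["off_island"].iloc[0]

    def test_cell_on_rim(self):
        cells = quant.assign_dimensionless_radius(cells_at([(300.0, 0.0)]), one_island())
        assert cells["R"].iloc[0] == pytest.approx(1.0)

    def test_pythagorean_off_island_flag(self):
        cells = quant.assign_dimensionless_radius(cells_at([(400.0, 300.0)]), one_island())
        assert cells["R"].iloc[0] == pytest.approx(500.0 / 300.0)
        assert bool(cells["off_island"].iloc[0])

    def test_missing_island_reported(self):
        with pytest.raises(KeyError, match="99"):
            quant.assign_dimensionless_radius(cells_at([(0, 0)], island_id=99), one_island())


class TestRadialCounts:
    def test_hand_binned_toy_island(self):
        R = np.array([0.1, 0.1, 0.5, 0.9, 0.9, 0.9])
        cells = cells_at([(r * 300.0, 0.0) for r in R], m_positive=[False, False, False, True, True, False])
        cells = quant.assign_dimensionless_radius(cells, one_island())
        out = quant.radial_counts(cells, "m", n_bins=3, r_range=(0.0, 1.0))
        assert out["n_total"].tolist() == [2, 1, 3]
        assert out["n_positive"].tolist() == [0, 0, 2]
        assert out["percent"].tolist() == pytest.approx([0.0, 0.0, 200.0 / 3.0])

    def test_all_positive_percent_100(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-200, 200, size=(50, 2))
        cells = cells_at(pts, m_positive=True)
        cells = quant.assign_dimensionless_radius(cells, one_island())
        out = quant.radial_counts(cells, "m", n_bins=5)
        occupied = out["n_total"] > 0
        assert (out.loc[occupied, "percent"] == 100.0).all()
        assert out.loc[~occupied, "percent"].isna().all()

    def test_no_positives_percent_0(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-200, 200, size=(50, 2))
        cells = cells_at(pts, m_positive=False)
        cells = quant.assign_dimensionless_radius(cells, one_island())
        out = quant.radial_counts(cells, "m", n_bins=5)
        assert (out.loc[out["n_total"] > 0, "percent"] == 0.0).all()

    def test_counts_conserve_cells_and_percent_bounds(self):
        cfg = IslandSimConfig(n_islands=4, cells_per_island=200, seed=5)
        cells, islands, _ = generate_cell_table(cfg)
        cells = quant.assign_dimensionless_radius(cells, islands)
        out = quant.radial_counts(cells, "OPN")
        per_island = out.groupby("island_id")["n_total"].sum()
        expected = cells[~cells["off_island"]].groupby("island_id").size()
        assert per_island.to_dict() == expected.to_dict()
        pct = out["percent"].dropna()
        assert ((pct >= 0) & (pct <= 100)).all()

    def test_few_bins_rejected(self):
        cells = quant.assign_dimensionless_radius(
            cells_at([(0, 0)], m_positive=True), one_island()
        )
        with pytest.raises(ValueError, match="n_bins"):
            quant.radial_counts(cells, "m", n_bins=1)


class TestPositiveDensity:
    def test_mode_at_cluster(self):
        rng = np.random.default_rng(2)
        R = 0.9 + rng.normal(0, 0.01, 500)
        cells = cells_at([(r * 300, 0.0) for r in R], m_positive=True)
        cells = quant.assign_dimensionless_radius(cells, one_island())
        grid, dens = quant.positive_density(cells, "m")
        assert grid[np.argmax(dens)] == pytest.approx(0.9, abs=0.03)

    def test_uniform_sample_flat_density(self):
        rng = np.random.default_rng(3)
        R = rng.uniform(0, 1, 10_000)
        cells = cells_at([(r * 300, 0.0) for r in R], m_positive=True)
        cells = quant.assign_dimensionless_radius(cells, one_island())
        grid, dens = quant.positive_density(cells, "m")
        sel = (grid >= 0.1) & (grid <= 0.9)
        assert np.all(np.abs(dens[sel] - 1.0) < 0.1)

    def test_integrates_to_one(self):
        rng = np.random.default_rng(4)
        R = rng.beta(4, 2, 800)
        cells = cells_at([(r * 300, 0.0) for r in R], m_positive=True)
        cells = quant.assign_dimensionless_radius(cells, one_island())
        grid, dens = quant.positive_density(cells, "m")
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_too_few_positives_rejected(self):
        cells = quant.assign_dimensionless_radius(
            cells_at([(0, 0), (10, 10)], m_positive=[True, False]), one_island()
        )
        with pytest.raises(ValueError, match="at least 2"):
            quant.positive_density(cells, "m")


class TestSmoothProfile:
    def test_constant_data_fitted_exactly(self):
        rng = np.random.default_rng(5)
        R = rng.uniform(0, 1, 300)
        prof = quant.smooth_profile(R, np.full_like(R, 4.0))
        assert prof.values == pytest.approx(np.full_like(prof.values, 4.0))
        assert np.all((prof.ci_high - prof.ci_low) < 1e-6)

    def test_linear_trend_exact_at_interior(self):
        rng = np.random.default_rng(6)
        R = rng.uniform(0, 1, 400)
        y = 2.0 + 3.0 * R
        prof = quant.smooth_profile(R, y)
        expected = 2.0 + 3.0 * prof.centers
        interior = (prof.centers > 0.1) & (prof.centers < 0.9)
        assert prof.values[interior] == pytest.approx(expected[interior], abs=1e-6)

    def test_logistic_edge_profile_peak_location(self):
        model = LogisticMarkerModel(p_min=0.05, p_max=0.9, k=14.0, r0=0.8)
        rng = np.random.default_rng(7)
        R = np.sqrt(rng.uniform(0, 1, 6000))
        y = (rng.uniform(size=R.size) < model.probability(R)).astype(float) * 100
        grid = np.linspace(0.0, 1.0, 101)
        prof = quant.smooth_profile(R, y, eval_points=grid, span=0.3)
        truth = model.probability(grid) * 100
        peak_fit = grid[np.argmax(prof.values)]
        peak_truth = grid[np.argmax(truth)]
        assert abs(peak_fit - peak_truth) <= 0.05

    def test_needs_distinct_radii(self):
        with pytest.raises(ValueError, match="distinct"):
            quant.smooth_profile(np.ones(30), np.ones(30))

    def test_ribbon_overlap_comparison(self):
        rng = np.random.default_rng(8)
        R = rng.uniform(0, 1, 500)
        grid = np.linspace(0.05, 0.95, 40)
        low = quant.smooth_profile(R, rng.normal(0.0, 0.2, R.size), eval_points=grid)
        high = quant.smooth_profile(R, rng.normal(10.0, 0.2, R.size), eval_points=grid)
        same = quant.smooth_profile(R, rng.normal(0.0, 0.2, R.size), eval_points=grid)
        assert not quant.ribbons_overlap(low, high).any()
        assert quant.ribbons_overlap(low, same).mean() > 0.8


class TestCountRegression:
    @staticmethod
    def island_counts(effects, n_islands=12, sd=4.0, base=30.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for level, eff in effects.items():
            counts = rng.normal(base + eff, sd, n_islands)
            for c in counts:
                rows.append({"ligand": level, "count": max(float(np.round(c)), 0.0)})
        df = pd.DataFrame(rows)
        df.insert(0, "island_id", np.arange(len(df)))
        return df

    def test_identical_groups_beta_near_zero(self):
        df = self.island_counts({"IgG": 0.0, "DLL4": 0.0}, n_islands=30, seed=1)
        res = quant.fit_count_regression(df, factors=["ligand"], reference={"ligand": "IgG"})
        term = res["ligand[DLL4]"]
        assert term["ci_low"] < 0 < term["ci_high"]

    def test_balanced_two_level_beta_is_mean_difference(self):
        df = self.island_counts({"IgG": 0.0, "DLL4": 15.0}, seed=2)
        res = quant.fit_count_regression(df, factors=["ligand"], reference={"ligand": "IgG"})
        means = df.groupby("ligand")["count"].mean()
        assert res["ligand[DLL4]"]["beta"] == pytest.approx(
            means["DLL4"] - means["IgG"], rel=1e-10
        )

    def test_known_effect_recovered_across_replicates(self):
        hits, biases = 0, []
        n_rep = 100
        for seed in range(n_rep):
            df = self.island_counts({"IgG": 0.0, "DLL4": 20.0}, n_islands=18, seed=seed)
            res = quant.fit_count_regression(
                df, factors=["ligand"], reference={"ligand": "IgG"}
            )
            term = res["ligand[DLL4]"]
            hits += term["ci_low"] <= 20.0 <= term["ci_high"]
            biases.append(term["beta"] - 20.0)
        assert hits / n_rep >= 0.9
        assert abs(np.mean(biases)) < 0.05 * 20.0

    def test_ci_coverage_is_nominal(self):
        # 95% CIs should cover the true effect ~95% of the time
        hits = 0
        n_rep = 1000
        rng = np.random.default_rng(42)
        for _ in range(n_rep):
            a = rng.normal(30.0, 5.0, 10)
            b = rng.normal(42.0, 5.0, 10)
            df = pd.DataFrame(
                {
                    "island_id": np.arange(20),
                    "ligand": ["IgG"] * 10 + ["DLL4"] * 10,
                    "count": np.concatenate([a, b]),
                }
            )
            res = quant.fit_count_regression(
                df, factors=["ligand"], reference={"ligand": "IgG"}
            )
            term = res["ligand[DLL4]"]
            hits += term["ci_low"] <= 12.0 <= term["ci_high"]
        assert hits / n_rep == pytest.approx(0.95, abs=0.03)

    def test_diagnostics_reported(self):
        df = self.island_counts({"IgG": 0.0, "DLL4": 10.0}, seed=3)
        res = quant.fit_count_regression(df, factors=["ligand"], reference={"ligand": "IgG"})
        assert set(res.diagnostics) >= {"breusch_pagan_p", "jarque_bera_p",
                                        "homoscedastic", "residuals_normal"}

    def test_aliased_design_rejected(self):
        df = self.island_counts({"IgG": 0.0, "DLL4": 10.0}, seed=4)
        df["copy"] = df["ligand"]  # perfectly aliased factor
        with pytest.raises(ValueError, match="aliased"):
            quant.fit_count_regression(df, factors=["ligand", "copy"])

    def test_underpopulated_level_rejected(self):
        df = self.island_counts({"IgG": 0.0, "DLL4": 10.0}, seed=5)
        df = df.drop(df[df["ligand"] == "DLL4"].index[1:])
        with pytest.raises(ValueError, match="fewer than 2"):
            quant.fit_count_regression(df, factors=["ligand"])


def brute_force_ks(a, b):
    """Supremum distance by sweeping the empirical CDFs over all points."""
    pts = np.concatenate([a, b])
    d = 0.0
    for x in pts:
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        d = max(d, abs(fa - fb))
    return d


class TestKS:
    def test_identical_samples(self):
        a = np.array([0.1, 0.3, 0.7])
        res = quant.ks_two_sample(a, a)
        assert res.d_statistic == 0.0

    def test_disjoint_supports(self):
        res = quant.ks_two_sample(np.array([0.1, 0.2, 0.35]), np.array([0.6, 0.8, 1.0]))
        assert res.d_statistic == 1.0

    def test_matches_brute_force_sweep(self):
        a = np.array([0.1, 0.5, 0.9])
        b = np.array([0.2, 0.6])
        res = quant.ks_two_sample(a, b)
        assert res.d_statistic == pytest.approx(brute_force_ks(a, b))
        assert res.n_a == 3 and res.n_b == 2

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=30),
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=30),
    )
    def test_invariant_under_monotone_transform(self, xs, ys):
        a, b = np.array(xs), np.array(ys)
        d1 = quant.ks_two_sample(a, b).d_statistic
        d2 = quant.ks_two_sample(np.log(a), np.log(b)).d_statistic
        assert d1 == pytest.approx(d2)
        assert d1 == pytest.approx(brute_force_ks(a, b))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            quant.ks_two_sample(np.array([]), np.array([1.0]))


class TestWelch:
    def test_identical_groups(self):
        a = np.array([1.0, 1.0, 1.0])
        t, df, p = quant.welch_t(a, a)
        assert t == 0.0 and p == 1.0

    def test_clear_separation(self):
        a = np.array([1.0, 2.0, 3.0])
        t, df, p = quant.welch_t(a, a + 10.0)
        assert p < 0.01

    def test_matches_hand_formula(self):
        a = np.array([4.1, 5.2, 6.3, 5.5])
        b = np.array([5.0, 6.1, 7.4])
        t, df, p = quant.welch_t(a, b)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se = np.sqrt(va / 4 + vb / 3)
        t_hand = (a.mean() - b.mean()) / se
        df_hand = (va / 4 + vb / 3) ** 2 / ((va / 4) ** 2 / 3 + (vb / 3) ** 2 / 2)
        assert t == pytest.approx(t_hand)
        assert df == pytest.approx(df_hand)

    def test_needs_two_values(self):
        with pytest.raises(ValueError, match="at least 2"):
            quant.welch_t(np.array([1.0]), np.array([1.0, 2.0]))


class TestIntensityContrasts:
    @staticmethod
    def intensity_cells(inner=1.0, outer=1.0, n=400, seed=0):
        rng = np.random.default_rng(seed)
        R = np.sqrt(rng.uniform(0, 1, n))
        inten = np.where(R > 0.75, outer, inner).astype(float)
        cells = cells_at([(r * 300, 0.0) for r in R], ck_intensity=inten)
        return quant.assign_dimensionless_radius(cells, one_island())

    def test_uniform_intensity_ratio_one(self):
        out = quant.peripheral_central_intensity(self.intensity_cells(), "ck")
        assert out["ratio"] == pytest.approx(1.0)

    def test_step_intensity_ratio_two(self):
        out = quant.peripheral_central_intensity(self.intensity_cells(inner=1.0, outer=2.0), "ck")
        assert out["ratio"] == pytest.approx(2.0)

    def test_percent_change_recovers_group_means(self):
        mu_a, mu_b, sigma = 4.0, 3.7, 0.3
        expected = (np.exp(mu_a) - np.exp(mu_b)) / np.exp(mu_b) * 100.0
        changes = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 800
            ca = cells_at(
                [(0.0, 0.0)] * n, ck_intensity=rng.lognormal(mu_a, sigma, n)
            )
            cb = cells_at(
                [(0.0, 0.0)] * n, ck_intensity=rng.lognormal(mu_b, sigma, n)
            )
            changes.append(quant.percent_change(ca, cb, "ck")["percent_change"])
        # mean over replicates within ~2 SEM of the analytic percent change
        sem = np.std(changes) / 10.0
        assert np.mean(changes) == pytest.approx(expected, abs=3 * sem + 0.5)

    def test_empty_side_rejected(self):
        cells = self.intensity_cells(n=5, seed=1)
        cells = cells[cells["R"] < 0.7]
        with pytest.raises(ValueError, match="empty"):
            quant.peripheral_central_intensity(cells, "ck")
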