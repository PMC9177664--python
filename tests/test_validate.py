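"""VEcv, relative error, Moran's I, buffering, and buffered LOO-CV."""

import numpy as np
import pandas as pd
import pytest

import treetraits as tt
from treetraits.impute import ImputationConfig
from treetraits.validate import (
    buffer_partition,
    buffered_loocv,
    haversine_km,
    median_relative_abs_error,
    morans_i,
    morans_i_correlogram,
    random_split_cv,
    taxonomic_autocorrelation,
    vecv,
)


class TestVecv:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 5.0])
        assert vecv(y, y) == 1.0

    def test_mean_predictor_zero(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        assert vecv(y, np.full(4, y.mean())) == pytest.approx(0.0)

    def test_worked_case(self):
        assert vecv([1, 2, 3, 4], [2, 2, 3, 3]) == pytest.approx(0.6)

    def test_can_be_negative(self):
        assert vecv([1.0, 2.0, 3.0], [10.0, 10.0, 10.0]) < 0

    def test_constant_obs_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            vecv([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_equals_ols_r2(self, rng):
        """When predictions come from an OLS fit on the same data, VEcv is
        the classical R^2 (statsmodels as the independent oracle)."""
        import statsmodels.api as sm

        X = sm.add_constant(rng.standard_normal((100, 3)))
        y = X @ np.array([1.0, 0.5, -2.0, 0.3]) + rng.standard_normal(100)
        fit = sm.OLS(y, X).fit()
        assert vecv(y, fit.fittedvalues) == pytest.approx(fit.rsquared, abs=1e-10)

    def test_joint_shift_invariance(self, rng):
        y = rng.standard_normal(30)
        p = y + 0.3 * rng.standard_normal(30)
        # identical constant added to both leaves SSE and TSS unchanged;
        # shifting only the predictions degrades the score
        assert vecv(y + 5, p + 5) == pytest.approx(vecv(y, p), abs=1e-10)
        assert vecv(y, p + 5) < vecv(y, p)


class TestMRAE:
    def test_worked_cases(self):
        assert median_relative_abs_error([100.0], [71.0]) == pytest.approx(29.0)
        assert median_relative_abs_error([10, 100], [11, 90]) == pytest.approx(10.0)

    def test_perfect_zero(self):
        assert median_relative_abs_error([3.0, 4.0], [3.0, 4.0]) == 0.0

    def test_nonpositive_obs_rejected(self):
        with pytest.raises(ValueError):
            median_relative_abs_error([0.0, 1.0], [1.0, 1.0])


class TestMoransI:
    def test_iid_residuals_near_expectation(self, rng):
        n = 200
        lat = rng.uniform(35, 45, n)
        lon = rng.uniform(0, 10, n)
        Is = []
        for _ in range(20):
            cg = morans_i_correlogram(
                rng.standard_normal(n), lat, lon, [0, 300, 600, 1200]
            )
            Is.append(cg.morans_i)
        mean_i = np.nanmean(Is, axis=0)
        assert np.abs(mean_i - (-1 / (n - 1))).max() < 0.05

    def test_smooth_field_positive_short_range(self):
        df = tt.simulate_env_fields(1, 400, 0.15, seed=5)
        cg = morans_i_correlogram(
            df["env_01"], df["lat"], df["lon"], [0, 120, 400, 1000]
        )
        assert cg.morans_i[0] > 0.3

    def test_identical_locations_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            morans_i_correlogram(
                np.arange(12.0), np.full(12, 40.0), np.full(12, 5.0), [0, 100]
            )

    def test_empty_bin_missing_not_zero(self, rng):
        lat = rng.uniform(35, 36, 20)
        lon = rng.uniform(0, 1, 20)
        cg = morans_i_correlogram(
            rng.standard_normal(20), lat, lon, [0, 500, 5000, 6000]
        )
        assert np.isnan(cg.morans_i[-1])
        assert cg.pair_counts[-1] == 0

    def test_permutation_mean(self, rng):
        """Under label permutation E[I] = -1/(n-1) (permutation oracle)."""
        n = 60
        lat = rng.uniform(35, 40, n)
        lon = rng.uniform(0, 5, n)
        D = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
        W = ((D < 200) & (D > 0)).astype(float)
        z = rng.standard_normal(n)
        Is = [morans_i(z[rng.permutation(n)], W) for _ in range(999)]
        assert abs(np.mean(Is) - (-1 / (n - 1))) < 0.01


class TestTaxonomicAutocorrelation:
    def _table(self, genera, families=None):
        n = len(genera)
        return pd.DataFrame(
            {
                "genus": genera,
                "family": families if families is not None else ["f"] * n,
            }
        )

    def test_genus_constant_residuals_high(self, rng):
        genera = np.repeat([f"g{i}" for i in range(10)], 8)
        values = np.repeat(rng.standard_normal(10), 8)
        out = taxonomic_autocorrelation(values, self._table(genera))
        assert out["genus"] >= 0.8

    def test_iid_residuals_near_expectation(self, rng):
        n = 200
        genera = np.repeat([f"g{i}" for i in range(20)], 10)
        vals = [
            taxonomic_autocorrelation(rng.standard_normal(n), self._table(genera))[
                "genus"
            ]
            for _ in range(20)
        ]
        assert abs(np.mean(vals) - (-1 / (n - 1))) < 0.05

    def test_single_genus_missing(self, rng):
        # every row in one genus: no variation in adjacency -> I defined,
        # but all-singleton genera -> no pairs -> missing
        genera = [f"g{i}" for i in range(10)]
        out = taxonomic_autocorrelation(rng.standard_normal(10), self._table(genera))
        assert np.isnan(out["genus"])


class TestBufferPartition:
    def _toy(self):
        # six hand-placed rows around lat 40; 1 deg lat ~ 111 km
        return pd.DataFrame(
            {
                "obs_id": list("abcdef"),
                "species": ["S1", "S1", "S2", "S3", "S4", "S5"],
                "genus": ["G1", "G1", "G1", "G1", "G2", "G1"],
                "family": ["F"] * 6,
                "lat": [40.0, 40.1, 40.9, 43.8, 40.05, 40.2],
                "lon": [5.0, 5.0, 5.0, 5.0, 5.0, 5.0],
                "trait": [1.0, 2.0, 3.0, 4.0, 5.0, np.nan],
            }
        )

    def test_hand_enumeration(self):
        t = self._toy()
        test_idx, train_idx = buffer_partition(t, "S1", "trait", "genus", 250.0)
        # test: rows a,b. S2 congener at ~100 km -> excluded; S3 congener at
        # ~420 km -> kept; S4 different genus at ~5 km -> kept; S5 congener
        # but trait missing -> not in train anyway
        assert list(test_idx) == [0, 1]
        assert list(train_idx) == [3, 4]

    def test_congener_distances(self):
        t = self._toy()
        _, train_idx = buffer_partition(t, "S1", "trait", "genus", 250.0)
        assert 2 not in train_idx  # ~100 km congener excluded
        assert 3 in train_idx  # ~420 km congener retained

    def test_family_rank_widens_exclusion(self):
        t = self._toy()
        _, train_idx = buffer_partition(t, "S1", "trait", "family", 250.0)
        assert 4 not in train_idx  # same family, 5 km

    def test_disjoint_and_bounded(self, small_world):
        w = small_world
        trait = w.trait_names[0]
        sp = w.table["species"].iloc[0]
        test_idx, train_idx = buffer_partition(w.table, sp, trait)
        assert set(test_idx).isdisjoint(train_idx)
        n_observed = w.table[trait].notna().sum()
        assert len(test_idx) + len(train_idx) <= n_observed

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError):
            buffer_partition(self._toy(), "nope", "trait")


class TestBufferedLoocv:
    def test_every_species_once(self, small_world_covariates, fast_config):
        table, pc, ec = small_world_covariates
        trait = "leaf_area"
        n_species = table.loc[table[trait].notna(), "species"].nunique()
        cv = buffered_loocv(table, trait, pc + ec, fast_config,
                            n_iter=n_species, seed=1)
        used = [it["focal_species"] for it in cv.iterations]
        assert len(set(used)) == len(used)

    def test_noise_trait_low_vecv(self, fast_config):
        scores = []
        for s in range(3):
            w = tt.simulate_traits(
                n_species=50, n_traits=2, n_obs=300, n_blocks=1,
                phylo_sd=0.0, env_sd=0.0, noise_sd=1.0, seed=900 + s,
            )
            basis = tt.phylo_eigenvectors(tt.cophenetic_distances(w.tree), 10)
            table = tt.impute.attach_phylo_covariates(w.table, basis)
            cv = buffered_loocv(
                table, w.trait_names[0],
                list(basis.to_frame().columns) + w.env_names,
                ImputationConfig(n_trees=30, seed=s), n_iter=10, seed=s,
            )
            scores.append(cv.vecv)
        assert np.median(scores) <= 0.1

    def test_conservative_vs_random_split(self, fast_config):
        wins = 0
        for s in range(5):
            w = tt.simulate_traits(
                n_species=80, n_traits=2, n_obs=560, n_blocks=1, seed=950 + s
            )
            basis = tt.phylo_eigenvectors(tt.cophenetic_distances(w.tree), 16)
            table = tt.impute.attach_phylo_covariates(w.table, basis)
            pc, ec = tt.select_covariates(basis, table[w.env_names], 8, 6)
            cfg = ImputationConfig(n_trees=40, seed=s)
            cv = buffered_loocv(table, w.trait_names[0], pc + ec, cfg,
                                n_iter=12, seed=s)
            rnd = random_split_cv(table, w.trait_names[0], pc + ec, cfg, seed=s)
            wins += cv.vecv <= rnd.vecv
        assert wins >= 4

    def test_too_few_species_rejected(self, fast_config):
        t = pd.DataFrame(
            {"obs_id": ["a"], "species": ["S1"], "genus": ["G"],
             "family": ["F"], "lat": [40.0], "lon": [5.0], "trait": [1.0]}
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            buffered_loocv(t, "trait", [], fast_config)
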