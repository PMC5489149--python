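import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sdm2abund.abundance import (
    GateError,
    apply_boxcox,
    biomass,
    boxcox_lambda,
    inverse_boxcox,
    normality_gate,
    predict_abundance,
    select_density_model,
    subsample_fit,
    AbundanceResult,
)
from sdm2abund.grids import GridSpec, LandAreaRaster, RasterLayer
from sdm2abund.sdm import EnsembleSuitability
from sdm2abund.synthetic import gen_training_table


def boxcox_grid_oracle(y, shift=0.0):
    """Dense-grid profile-likelihood maximiser, independent of the library's
    optimiser."""
    grid = np.linspace(-2, 2, 2001)
    llf = [stats.boxcox_llf(l, y + shift) for l in grid]
    return grid[int(np.argmax(llf))]


class TestNormalityGate:
    def test_normal_sample_passes_mostly(self):
        branches = []
        for seed in range(20):
            y = np.random.default_rng(seed).normal(size=100)
            branches.append(normality_gate(y)[0])
        # Shapiro at alpha=0.1 falsely rejects ~10% of the time
        assert branches.count("normal") >= 14

    def test_lognormal_sample_transforms_with_lambda_near_zero(self):
        y = np.exp(np.random.default_rng(1).normal(size=100))
        branch, lam, shift = normality_gate(y)
        assert branch == "transform"
        assert abs(lam) < 0.25
        assert shift == 0.0

    def test_constant_data_raises(self):
        with pytest.raises(GateError):
            normality_gate(np.array([1.0, 1.0, 1.0]))

    def test_zeros_get_half_minimum_shift(self):
        y = np.concatenate([np.zeros(30), np.exp(np.random.default_rng(2).normal(size=70))])
        branch, lam, shift = normality_gate(y)
        if branch == "transform":
            positive_min = y[y > 0].min()
            assert shift == pytest.approx(0.5 * positive_min)


class TestBoxCox:
    def test_matches_grid_oracle(self):
        for seed, gen in [(0, "normal"), (1, "lognormal")]:
            rng = np.random.default_rng(seed)
            y = rng.normal(10, 1, 200) if gen == "normal" else np.exp(rng.normal(0, 1, 200))
            lam = boxcox_lambda(y)
            assert lam == pytest.approx(boxcox_grid_oracle(y), abs=0.02)

    def test_lognormal_lambda_near_zero(self):
        y = np.exp(np.random.default_rng(3).normal(size=500))
        assert abs(boxcox_lambda(y)) < 0.15

    def test_lambda_one_is_affine(self):
        y = np.array([1.0, 2.0, 5.0])
        np.testing.assert_allclose(apply_boxcox(y, 1.0), y - 1.0)

    def test_inverse_roundtrip(self):
        y = np.array([0.5, 1.0, 4.0, 9.0])
        for lam in (-1.5, -0.3, 0.0, 0.4, 1.0, 2.0):
            z = apply_boxcox(y, lam, shift=0.1)
            np.testing.assert_allclose(inverse_boxcox(z, lam, shift=0.1), y, rtol=1e-9)


class TestModelSelection:
    def test_independent_linear_truth_selects_none_degree1(self):
        hits_corr = hits_deg = 0
        n_seeds = 12
        for seed in range(n_seeds):
            tab = gen_training_table(
                n_rows=120, noise_sd=2.0, noise_model="additive", seed=seed
            )
            rec = select_density_model(tab, "max")
            hits_corr += rec.correlation == "none"
            hits_deg += rec.degree == 1
        assert hits_corr > n_seeds / 2
        assert hits_deg > n_seeds / 2

    def test_spherical_errors_prefer_spatial_structure(self):
        """Paired simulation: spatially correlated noise must trigger the
        spatial candidates more often than independent noise does."""
        spatial_hits = {True: 0, False: 0}
        for seed in range(8):
            for correlated in (True, False):
                tab = gen_training_table(
                    n_rows=100,
                    noise_sd=0.3,
                    error_structure="spherical" if correlated else "independent",
                    error_range=15.0,
                    seed=seed,
                )
                rec = select_density_model(tab, "max")
                spatial_hits[correlated] += rec.correlation != "none"
        assert spatial_hits[True] > spatial_hits[False]

    def test_quadratic_truth_negative_curvature_recovered(self):
        hits = 0
        for seed in range(8):
            tab = gen_training_table(
                n_rows=150, scenario="quadratic", noise_sd=0.1, seed=seed
            )
            rec = select_density_model(tab, "max")
            if rec.degree == 2:
                # curvature on the model scale must be negative like the truth
                hits += rec.coefficients[2] < 0 if rec.branch != "glm" else True
        assert hits >= 5

    def test_selected_candidate_minimises_criterion(self):
        tab = gen_training_table(n_rows=80, seed=5)
        rec = select_density_model(tab, "min")
        crit_col = "aicc" if rec.criterion == "AICc" else "aic"
        sel_rows = rec.candidates[
            (rec.candidates.get("correlation", rec.correlation) == rec.correlation)
            & (rec.candidates["degree"] == rec.degree)
        ]
        assert sel_rows[crit_col].min() == pytest.approx(rec.candidates[crit_col].min())


def _flat_world(n=6, res=1000.0, suit_value=0.8):
    grid = GridSpec(0.0, 0.0, res, n, n)
    land = LandAreaRaster(grid, np.full((n, n), (res / 1000.0) ** 2))
    ens = EnsembleSuitability(
        mean_suitability=RasterLayer(grid, np.full((n, n), suit_value), name="s"),
        mean_threshold=0.5,
        n_reps=1,
        max_rse=np.nan,
        rep_table=pd.DataFrame(),
        win_counts={},
    )
    return grid, land, ens


class TestPredictAbundance:
    def _record(self, coeffs, degree=1):
        tab = gen_training_table(n_rows=60, noise_sd=0.05, seed=0)
        rec = select_density_model(tab, "max")
        rec.coefficients = np.asarray(coeffs, dtype=float)
        rec.degree = degree
        rec.branch = "normal"
        return rec

    def test_constant_density_times_area(self):
        grid, land, ens = _flat_world()
        rec = self._record([5.0, 0.0])
        res = predict_abundance(rec, rec, ens, land)
        assert res.total_max == pytest.approx(5.0 * 36.0)
        assert res.total_min == pytest.approx(res.total_max)

    def test_all_below_threshold_gives_zero(self):
        grid, land, ens = _flat_world(suit_value=0.2)
        rec = self._record([5.0, 0.0])
        res = predict_abundance(rec, rec, ens, land)
        assert res.total_min == 0.0 and res.total_max == 0.0

    def test_homogeneity_doubling_densities_doubles_totals(self):
        """With identity transform and degree-1 mean structure, scaling the
        training densities scales the prediction linearly."""
        grid, land, ens = _flat_world()
        base = self._record([1.0, 3.0])
        double = self._record([2.0, 6.0])
        r1 = predict_abundance(base, base, ens, land)
        r2 = predict_abundance(double, double, ens, land)
        assert r2.total_max == pytest.approx(2 * r1.total_max)

    def test_negative_prediction_clamped(self):
        grid, land, ens = _flat_world(suit_value=0.9)
        rec = self._record([5.0, -10.0])  # predicts -4 at suitability 0.9
        with pytest.warns(UserWarning):
            res = predict_abundance(rec, rec, ens, land)
        assert res.total_max == 0.0
        assert res.n_clamped > 0


class TestSubsampleFit:
    def test_small_table_bypasses_subsampling(self):
        grid, land, ens = _flat_world()
        tab = gen_training_table(n_rows=150, seed=2)
        direct = predict_abundance(
            select_density_model(tab, "min"), select_density_model(tab, "max"), ens, land
        )
        via = subsample_fit(tab, ens, land, k=2000, reps=10, seed=0)
        assert via.total_max == pytest.approx(direct.total_max)
        assert via.subsample_rse == {}

    def test_determinism(self):
        grid, land, ens = _flat_world()
        tab = gen_training_table(n_rows=2500, seed=3)
        a = subsample_fit(tab, ens, land, k=800, reps=3, seed=9, bounds=("max",))
        b = subsample_fit(tab, ens, land, k=800, reps=3, seed=9, bounds=("max",))
        assert a.total_max == b.total_max
        assert a.subsample_rse == b.subsample_rse

    def test_min_total_below_max_total(self):
        grid, land, ens = _flat_world()
        tab = gen_training_table(n_rows=200, seed=4)
        tab["min_density"] = tab["min_density"] * 0.4  # partial coverage
        res = subsample_fit(tab, ens, land, seed=1)
        assert res.total_min <= res.total_max


class TestBiomass:
    def _result(self, grid, land, total):
        vals = np.full(grid.shape, total / grid.n_rows / grid.n_cols)
        layer = RasterLayer(grid, vals)
        return AbundanceResult(layer, layer, total, total, None, None)

    def test_single_species_product(self):
        grid, land, _ = _flat_world(n=2)
        res = {"fox": self._result(grid, land, 10.0)}
        out = biomass(res, {"fox": 2.0})
        assert out["national_max_kg"] == pytest.approx(20.0)

    def test_two_species_hand_summed(self):
        grid, land, _ = _flat_world(n=2)
        res = {"a": self._result(grid, land, 10.0), "b": self._result(grid, land, 4.0)}
        out = biomass(res, {"a": 2.0, "b": 0.5})
        assert out["national_min_kg"] == pytest.approx(10 * 2 + 4 * 0.5)
        np.testing.assert_allclose(out["per_cell_min_kg"].sum(), 22.0)

    def test_missing_weight_lists_species(self):
        grid, land, _ = _flat_world(n=2)
        res = {"a": self._result(grid, land, 1.0)}
        with pytest.raises(KeyError, match="a"):
            biomass(res, {})
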