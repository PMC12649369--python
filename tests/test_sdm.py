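import numpy as np
import pandas as pd
import pytest
from scipy import stats

from physiosdm.grids import GridDef, Raster
from physiosdm.metrics import MetricSet
from physiosdm.occurrences import OccurrenceSet
from physiosdm.sdm import (
    LEARNER_REGISTRY,
    ModelRun,
    build_ensemble,
    draw_pseudo_absences,
    fit_all_runs,
    fit_predict,
    response_curve,
    retain_models,
    split_calibration,
    variable_importance,
)
from physiosdm.synthetic import (
    LandscapeSpec,
    NicheSpec,
    make_landscape,
    make_virtual_species,
    sample_occurrences,
)


def presence_set(grid, cells, species="A"):
    rows = np.array([c[0] for c in cells])
    cols = np.array([c[1] for c in cells])
    lon, lat = grid.cell_center(rows, cols)
    return OccurrenceSet(pd.DataFrame({"species": species, "lon": lon, "lat": lat}))


class StubModel:
    """Constant-score classifier used to probe ensemble arithmetic."""

    def __init__(self, value):
        self.value = value

    def predict_proba(self, X):
        p = np.full(len(X), self.value)
        return np.column_stack([1 - p, p])


def stub_run(value, tss=0.9, learner="stub", features=("v0",)):
    X = np.zeros((4, len(features)))
    y = np.array([True, True, False, False])
    return ModelRun(
        learner_id=learner, pa_set_id="PA01", cv_rep=1,
        model=StubModel(value), feature_names=list(features),
        metrics=MetricSet(auc=0.9, tss=tss, tss_threshold=0.5,
                          kappa=0.8, kappa_threshold=0.5),
        test_X=X, test_y=y, seed=0,
    )


class TestDrawPseudoAbsences:
    def test_default_design_is_ten_sets_of_hundred(self, small_grid):
        occ = presence_set(small_grid, [(0, 0)])
        # 10 x 10 grid of 100 cells minus 1 presence cell: not enough for 100
        grid = GridDef(west_lon=85.0, north_lat=32.0, n_rows=20, n_cols=20,
                       cell_size=0.05)
        sets = draw_pseudo_absences(grid, occ, seed=0)
        assert len(sets) == 10
        assert all(s.n == 100 for s in sets)

    def test_points_avoid_presence_cells_and_repeat_no_cell(self, small_grid):
        occ = presence_set(small_grid, [(r, c) for r in range(5) for c in range(10)])
        sets = draw_pseudo_absences(small_grid, occ, n_sets=3, n_per_set=20, seed=1)
        prow, pcol = small_grid.cell_index(*occ.coords())
        presence_cells = set(zip(prow.tolist(), pcol.tolist()))
        for s in sets:
            row, col = small_grid.cell_index(s.lon, s.lat)
            cells = list(zip(row.tolist(), col.tolist()))
            assert len(set(cells)) == len(cells)  # distinct cells within a set
            assert not presence_cells & set(cells)

    def test_forced_choice_when_exactly_enough_cells(self, small_grid):
        # presences fill all but 20 cells; every free cell must be used
        free = [(r, c) for r in range(2) for c in range(10)]
        occupied = [(r, c) for r in range(2, 10) for c in range(10)]
        occ = presence_set(small_grid, occupied)
        sets = draw_pseudo_absences(small_grid, occ, n_sets=1, n_per_set=20, seed=2)
        row, col = small_grid.cell_index(sets[0].lon, sets[0].lat)
        assert set(zip(row.tolist(), col.tolist())) == set(free)

    def test_same_seed_identical(self, small_grid):
        occ = presence_set(small_grid, [(0, 0)])
        a = draw_pseudo_absences(small_grid, occ, n_sets=2, n_per_set=10, seed=9)
        b = draw_pseudo_absences(small_grid, occ, n_sets=2, n_per_set=10, seed=9)
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.lon, s2.lon)

    def test_too_few_free_cells_is_error(self, small_grid):
        occ = presence_set(small_grid, [(r, c) for r in range(10) for c in range(10)])
        with pytest.raises(ValueError, match="presence-free"):
            draw_pseudo_absences(small_grid, occ, n_sets=1, n_per_set=10, seed=0)


class TestSplitCalibration:
    def test_eighty_twenty_arithmetic(self):
        X = np.arange(75).reshape(-1, 1)
        y = np.array([1] * 60 + [0] * 15)
        Xtr, Xte, ytr, yte = split_calibration(X, y, rep=1, seed=0)
        assert (ytr == 1).sum() == 48 and (yte == 1).sum() == 12

    def test_reps_give_different_partitions_of_same_size(self):
        X = np.arange(100).reshape(-1, 1)
        y = np.array([1] * 50 + [0] * 50)
        _, Xte1, _, _ = split_calibration(X, y, rep=1, seed=0)
        _, Xte2, _, _ = split_calibration(X, y, rep=2, seed=0)
        assert Xte1.shape == Xte2.shape
        assert sorted(Xte1.ravel()) != sorted(Xte2.ravel())

    def test_stratification_preserves_class_ratio(self):
        X = np.arange(200).reshape(-1, 1)
        y = np.array([1] * 150 + [0] * 50)
        _, _, ytr, yte = split_calibration(X, y, rep=3, seed=1)
        assert (ytr == 1).sum() == 120 and (yte == 1).sum() == 30

    def test_tiny_class_rejected(self):
        y = np.array([1, 1, 1, 1, 0])
        with pytest.raises(ValueError, match="at least 2"):
            split_calibration(np.zeros((5, 1)), y)


class TestFitPredict:
    def test_separable_training_set_gets_perfect_auc(self):
        X = np.concatenate([np.linspace(2, 3, 20), np.linspace(-3, -2, 20)])[:, None]
        y = np.array([1] * 20 + [0] * 20)
        scores = fit_predict("logistic", X, y, X, seed=0)
        assert np.all(scores[:20] > scores[20:].max())
        assert np.all((scores >= 0) & (scores <= 1))

    def test_shuffled_labels_score_near_chance(self):
        from physiosdm.metrics import roc_auc

        aucs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.random((200, 3))
            y = rng.permutation(np.array([1] * 100 + [0] * 100))
            Xte = rng.random((200, 3))
            yte = rng.permutation(y)
            scores = fit_predict("logistic", X, y, Xte, seed=seed)
            aucs.append(roc_auc(scores, yte))
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_constant_predictor_gives_constant_scores(self):
        X = np.ones((40, 1))
        y = np.array([1] * 20 + [0] * 20)
        scores = fit_predict("logistic", X, y, np.ones((10, 1)), seed=0)
        assert np.ptp(scores) == pytest.approx(0.0, abs=1e-12)

    def test_unknown_learner_lists_registry(self):
        with pytest.raises(ValueError, match="registry"):
            fit_predict("nonsense", np.zeros((4, 1)), [1, 1, 0, 0], np.zeros((1, 1)))

    def test_registry_has_four_families(self):
        assert {"logistic", "tree", "bagged_trees", "boosted_trees"} <= set(
            LEARNER_REGISTRY
        )


class TestRetainModels:
    def test_all_thresholds_inclusive(self):
        ok = stub_run(0.5)
        ok.metrics = MetricSet(auc=0.7, tss=0.8, tss_threshold=0.5,
                               kappa=0.6, kappa_threshold=0.5)
        assert retain_models([ok]) == [ok]

    def test_one_failing_criterion_excludes(self):
        run = stub_run(0.5)
        run.metrics = MetricSet(auc=0.99, tss=0.79, tss_threshold=0.5,
                                kappa=0.9, kappa_threshold=0.5)
        assert retain_models([run]) == []

    def test_matches_elementwise_oracle_on_random_metric_tables(self):
        rng = np.random.default_rng(14)
        runs = []
        for _ in range(200):
            r = stub_run(0.5)
            r.metrics = MetricSet(
                auc=float(rng.uniform(0.4, 1.0)),
                tss=float(rng.uniform(0.0, 1.0)), tss_threshold=0.5,
                kappa=float(rng.uniform(0.0, 1.0)), kappa_threshold=0.5,
            )
            runs.append(r)
        kept = retain_models(runs)
        oracle = [
            r for r in runs
            if r.metrics.tss >= 0.8 and r.metrics.auc >= 0.7 and r.metrics.kappa >= 0.6
        ]
        assert kept == oracle


class TestBuildEnsemble:
    def _stack(self):
        grid = GridDef(west_lon=85.0, north_lat=32.0, n_rows=4, n_cols=4, cell_size=0.1)
        rng = np.random.default_rng(0)
        return [Raster(grid, rng.random((4, 4)), "v0")]

    def test_single_member_reproduces_member_prediction(self):
        stack = self._stack()
        ens = build_ensemble([stub_run(0.3)], stack)
        assert np.allclose(ens.suitability.values, 0.3)
        assert ens.member_count == 1

    def test_equal_weights_average_two_members(self):
        stack = self._stack()
        ens = build_ensemble([stub_run(0.2), stub_run(0.8)], stack, weighting="mean")
        assert np.allclose(ens.suitability.values, 0.5)

    def test_tss_weighting_tilts_towards_stronger_member(self):
        stack = self._stack()
        ens = build_ensemble([stub_run(0.2, tss=0.9), stub_run(0.8, tss=0.3)], stack)
        expected = (0.9 * 0.2 + 0.3 * 0.8) / 1.2
        assert np.allclose(ens.suitability.values, expected)

    def test_ensemble_lies_within_member_range(self):
        stack = self._stack()
        members = [stub_run(v, tss=t) for v, t in [(0.1, 0.8), (0.5, 0.9), (0.9, 0.85)]]
        ens = build_ensemble(members, stack)
        assert np.all(ens.suitability.values >= 0.1 - 1e-12)
        assert np.all(ens.suitability.values <= 0.9 + 1e-12)

    def test_member_counts_by_learner(self):
        stack = self._stack()
        members = [stub_run(0.5, learner="a"), stub_run(0.5, learner="a"),
                   stub_run(0.5, learner="b")]
        ens = build_ensemble(members, stack)
        assert ens.member_counts_by_learner() == {"a": 2, "b": 1}

    def test_empty_retained_set_is_error(self):
        with pytest.raises(ValueError, match="zero retained"):
            build_ensemble([], self._stack())


class TestRunAccounting:
    def test_total_runs_is_learners_times_sets_times_reps(self, small_grid):
        rng = np.random.default_rng(4)
        vals = rng.random(small_grid.shape)
        stack = [Raster(small_grid, vals, "v0")]
        cells = [(r, c) for r in range(10) for c in range(5)]
        occ = presence_set(small_grid, cells)
        pa_sets = draw_pseudo_absences(small_grid, occ, n_sets=3, n_per_set=15, seed=0)
        runs = fit_all_runs(occ, pa_sets, stack, ["logistic", "tree"],
                            n_cv_reps=4, seed=0)
        assert len(runs) == 2 * 3 * 4
        assert all(r.metrics.auc >= 0.0 for r in runs)


class TestVariableImportanceAndResponse:
    def _world(self):
        grid = GridDef(west_lon=85.0, north_lat=32.0, n_rows=30, n_cols=30,
                       cell_size=0.01)
        rng = np.random.default_rng(6)
        a = rng.random((30, 30))
        b = rng.random((30, 30))
        return [Raster(grid, a, "used"), Raster(grid, b, "ignored")]

    def _fit_single_var_ensemble(self, stack):
        grid = stack[0].grid
        used = stack[0].values
        pr, pc = np.nonzero(used > 0.7)
        ar, ac = np.nonzero(used < 0.3)
        rng = np.random.default_rng(0)
        occ = presence_set(grid, list(zip(pr.tolist(), pc.tolist()))[:100])
        pa_sets = draw_pseudo_absences(grid, occ, n_sets=1, n_per_set=80, seed=0)
        runs = fit_all_runs(occ, pa_sets, stack, ["logistic"], n_cv_reps=2, seed=0)
        return build_ensemble(runs, stack, presences=occ)

    def test_ignored_variable_gets_near_zero_contribution(self):
        stack = self._world()
        ens = self._fit_single_var_ensemble(stack)
        contrib = variable_importance(ens, stack, n_perm=3, seed=0)
        assert contrib["used"] > 90.0
        assert contrib["ignored"] < 10.0
        assert sum(contrib.values()) == pytest.approx(100.0)

    def test_symmetric_variables_share_contribution(self):
        grid = GridDef(west_lon=85.0, north_lat=32.0, n_rows=30, n_cols=30,
                       cell_size=0.01)
        rng = np.random.default_rng(7)
        a, b = rng.random((30, 30)), rng.random((30, 30))
        stack = [Raster(grid, a, "x1"), Raster(grid, b, "x2")]
        s = a + b
        pr, pc = np.nonzero(s > 1.4)
        occ = presence_set(grid, list(zip(pr.tolist(), pc.tolist()))[:100])
        pa_sets = draw_pseudo_absences(grid, occ, n_sets=1, n_per_set=80, seed=0)
        shares = []
        for seed in range(5):
            runs = fit_all_runs(occ, pa_sets, stack, ["logistic"], n_cv_reps=1,
                                seed=seed)
            ens = build_ensemble(runs, stack, presences=occ)
            c = variable_importance(ens, stack, n_perm=3, seed=seed)
            shares.append(c["x1"])
        assert abs(np.mean(shares) - 50.0) < 10.0

    def test_response_curve_monotone_for_monotone_model(self):
        stack = self._world()
        ens = self._fit_single_var_ensemble(stack)
        curve = response_curve(ens, "used", n_steps=25)
        suit = curve["suitability"].to_numpy()
        assert np.all((suit >= 0) & (suit <= 1))
        assert np.all(np.diff(suit) >= -1e-9)  # monotone increasing response

    def test_flat_curve_for_ignored_variable(self):
        stack = self._world()
        ens = self._fit_single_var_ensemble(stack)
        curve = response_curve(ens, "ignored", n_steps=25)
        assert np.ptp(curve["suitability"].to_numpy()) < 0.05

    def test_unknown_variable_rejected(self):
        stack = self._world()
        ens = self._fit_single_var_ensemble(stack)
        with pytest.raises(ValueError, match="unknown variable"):
            response_curve(ens, "nope")


class TestVirtualSpeciesRecovery:
    def test_ensemble_recovers_unconstrained_truth(self):
        """Without a winter constraint the fitted surface should rank cells
        like the true suitability (Spearman rho > 0.7)."""
        grid = GridDef(west_lon=85.0, north_lat=32.0, n_rows=50, n_cols=50)
        rhos = []
        for seed in range(3):
            spec = LandscapeSpec(n_climate_vars=3, temp_elevation_corr=0.0)
            rasters = make_landscape(spec, grid, seed=seed)
            clim = rasters[:-1]
            stress = Raster(grid, np.zeros(grid.shape), "stress")
            niche = NicheSpec({"clim1": (0.5, 0.5), "clim2": (0.0, 0.6)},
                              np.inf, 0.85)
            truth = make_virtual_species(clim, stress, niche)
            occ = sample_occurrences(truth, 800, seed=seed)
            from physiosdm.occurrences import thin_to_grid

            occ = thin_to_grid(occ, grid)
            pa_sets = draw_pseudo_absences(grid, occ, n_sets=2, n_per_set=100,
                                           seed=seed)
            runs = fit_all_runs(occ, pa_sets, clim, ["logistic"], n_cv_reps=2,
                                seed=seed)
            ens = build_ensemble(runs, clim, presences=occ)
            rho = stats.spearmanr(ens.suitability.values.ravel(),
                                  truth.suitability.values.ravel()).statistic
            rhos.append(rho)
        assert np.mean(rhos) > 0.7
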