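import warnings

import numpy as np
import pytest

from riskdex.grids import ClimateStack, GridSpec
from riskdex.occurrences import CalibrationArea
from riskdex.suitability import (EnvelopeLearner, LogisticQuadraticLearner,
                                 ModelReplicate, TreeLearner, ensemble,
                                 fit_replicates, preselect_variables,
                                 sample_pseudo_absences, split_records)
from riskdex.synthetic_world import ScenarioSpec


@pytest.fixture()
def noise_stack(grid, rng):
    return ClimateStack(grid, {f"v{i}": rng.normal(size=grid.shape)
                               for i in range(4)})


def _points(grid, rng, n=500):
    return np.column_stack([
        rng.uniform(grid.lon_min + 1e-6, grid.lon_max - 1e-6, n),
        rng.uniform(grid.lat_min + 1e-6, grid.lat_max - 1e-6, n)])


class TestPreselect:
    def test_identical_pair_keeps_exactly_one(self, grid, rng):
        base = rng.normal(size=grid.shape)
        stack = ClimateStack(grid, {"a": base, "b": base.copy(),
                                    "c": rng.normal(size=grid.shape)})
        kept = preselect_variables(stack, _points(grid, rng))
        assert ("a" in kept) != ("b" in kept)
        assert "c" in kept

    def test_independent_noise_all_retained(self, noise_stack, grid, rng):
        pts = _points(grid, rng)
        kept = preselect_variables(noise_stack, pts)
        assert kept == noise_stack.names
        X = noise_stack.sample(pts[:, 0], pts[:, 1], kept)
        r = np.abs(np.corrcoef(X, rowvar=False))
        np.fill_diagonal(r, 0)
        assert r.max() < 0.8

    def test_postcondition_on_collinear_world(self, small_world, small_config,
                                              rng):
        stack = small_world.landscape.climate[
            small_config.current_scenario.key]
        pts = _points(small_config.grid, rng)
        kept = preselect_variables(stack, pts)
        assert kept
        X = stack.sample(pts[:, 0], pts[:, 1], kept)
        r = np.abs(np.corrcoef(X, rowvar=False))
        np.fill_diagonal(r, 0)
        assert r.max() < 0.8

    def test_constant_variable_dropped_with_warning(self, grid, rng):
        stack = ClimateStack(grid, {"flat": np.ones(grid.shape),
                                    "x": rng.normal(size=grid.shape),
                                    "y": rng.normal(size=grid.shape)})
        with pytest.warns(UserWarning, match="constant"):
            kept = preselect_variables(stack, _points(grid, rng))
        assert kept == ["x", "y"]


class TestPseudoAbsences:
    def test_count_and_containment(self, grid, rng):
        mask = np.zeros(grid.shape, dtype=bool)
        mask[10:60, 10:60] = True
        pts = sample_pseudo_absences(mask, grid, n=1000, rng=rng)
        assert pts.shape == (1000, 2)
        row, col = grid.index_of(pts[:, 0], pts[:, 1])
        assert mask[row, col].all()

    def test_seed_reproducibility(self, grid):
        mask = np.ones(grid.shape, dtype=bool)
        a = sample_pseudo_absences(mask, grid, n=50, rng=7)
        b = sample_pseudo_absences(mask, grid, n=50, rng=7)
        assert np.array_equal(a, b)

    def test_zero_n_empty(self, grid, rng):
        assert sample_pseudo_absences(np.ones(grid.shape, bool), grid,
                                      n=0, rng=rng).shape == (0, 2)

    def test_small_area_warns_and_resamples(self, grid, rng):
        mask = np.zeros(grid.shape, dtype=bool)
        mask[0, :3] = True
        with pytest.warns(UserWarning, match="replacement"):
            pts = sample_pseudo_absences(mask, grid, n=10, rng=rng)
        assert len(pts) == 10

    def test_empty_area_rejected(self, grid, rng):
        with pytest.raises(ValueError, match="no grid cells"):
            sample_pseudo_absences(np.zeros(grid.shape, bool), grid, rng=rng)


class TestSplit:
    def test_100_splits_70_30(self, rng):
        pres = rng.normal(size=(100, 2))
        absn = rng.normal(size=(200, 2))
        (p_tr, a_tr), (p_te, a_te) = split_records(pres, absn, rng=rng)
        assert len(p_tr) == 70 and len(p_te) == 30
        assert len(a_tr) == 140 and len(a_te) == 60

    def test_25_presences_round_half_up(self, rng):
        pres = rng.normal(size=(25, 2))
        absn = rng.normal(size=(10, 2))
        (p_tr, _), (p_te, _) = split_records(pres, absn, rng=rng)
        assert len(p_tr) == 18 and len(p_te) == 7

    def test_partition_is_exact(self, rng):
        pres = rng.normal(size=(40, 3))
        absn = rng.normal(size=(60, 3))
        (p_tr, a_tr), (p_te, a_te) = split_records(pres, absn, rng=rng)
        joined = np.vstack([p_tr, p_te])
        assert sorted(map(tuple, joined)) == sorted(map(tuple, pres))
        assert len(a_tr) + len(a_te) == 60


class TestLearners:
    def test_single_replicate_single_family(self, rng):
        pres = rng.normal(loc=2.0, size=(30, 2))
        absn = rng.normal(loc=-2.0, size=(30, 2))
        reps = fit_replicates(pres, absn, learner_families=(EnvelopeLearner,),
                              n_replicates=1, rng=rng)
        assert len(reps) == 1

    def test_envelope_scores_training_presences_positive(self, rng):
        pres = rng.normal(size=(40, 3))
        learner = EnvelopeLearner().fit(pres, np.ones(40))
        assert (learner.score_samples(pres) > 0).all()

    def test_logistic_separable_auc_one(self, rng):
        pres = rng.normal(loc=5.0, scale=0.5, size=(40, 2))
        absn = rng.normal(loc=-5.0, scale=0.5, size=(40, 2))
        reps = fit_replicates(pres, absn,
                              learner_families=(LogisticQuadraticLearner,),
                              n_replicates=1, rng=rng)
        assert reps[0].metrics["auc"] == pytest.approx(1.0)

    def test_degenerate_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="class"):
            fit_replicates(rng.normal(size=(10, 2)), np.empty((0, 2)),
                           n_replicates=1, rng=rng)

    def test_replicate_count(self, rng):
        pres = rng.normal(loc=1.5, size=(30, 2))
        absn = rng.normal(loc=-1.5, size=(30, 2))
        reps = fit_replicates(pres, absn,
                              learner_families=(TreeLearner, EnvelopeLearner),
                              n_replicates=3, rng=rng)
        assert len(reps) == 6
        assert {r.family for r in reps} == {"tree", "envelope"}


class _ConstantLearner:
    """Stub learner scoring a fixed value everywhere."""

    def __init__(self, value):
        self.value = value
        self.name = f"const{value}"

    def score_samples(self, X):
        return np.full(len(X), self.value)


def _stub_replicate(value, auc_val, threshold=0.5):
    X = np.zeros((4, 2))
    y = np.array([1.0, 1.0, 0.0, 0.0])
    return ModelReplicate(family=f"stub{value}", replicate_index=1,
                          learner=_ConstantLearner(value), threshold=threshold,
                          metrics={"kappa": 0, "tss": 0, "auc": auc_val},
                          val_X=X, val_y=y)


class TestEnsemble:
    def _setup(self, grid):
        stack = ClimateStack(grid, {"a": np.zeros(grid.shape),
                                    "b": np.zeros(grid.shape)})
        mask = np.ones(grid.shape, dtype=bool)
        scen = ScenarioSpec("g", "s", "2070", 1.0, 0.0)
        return stack, mask, scen

    def test_weighted_mean_of_binary_maps(self, grid):
        stack, mask, scen = self._setup(grid)
        reps = [_stub_replicate(1.0, auc_val=1.0),
                _stub_replicate(0.0, auc_val=0.5 + 1e-9)]
        # second replicate has weight ~0.5 and votes 0 everywhere
        reps[1].metrics["auc"] = 0.5000001
        smap = ensemble([_stub_replicate(1.0, 1.0),
                         _stub_replicate(0.0, 0.5000001)],
                        stack, mask, ["a", "b"], "sp", scen)
        # weights 1.0 and ~0.5: continuous = 1.0/1.5
        vals = smap.continuous.values[mask]
        assert np.allclose(vals, 1.0 / 1.5000001, atol=1e-6)

    def test_identical_replicates_reproduce_map(self, grid):
        stack, mask, scen = self._setup(grid)
        reps = [_stub_replicate(1.0, 0.9) for _ in range(3)]
        smap = ensemble(reps, stack, mask, ["a", "b"], "sp", scen)
        assert np.allclose(smap.continuous.values[mask], 1.0)
        assert np.all(smap.binary.values[mask] == 1.0)

    def test_order_invariance(self, grid, rng):
        stack, mask, scen = self._setup(grid)
        reps = [_stub_replicate(v, a) for v, a in
                [(1.0, 0.9), (0.7, 0.8), (0.2, 0.7)]]
        m1 = ensemble(reps, stack, mask, ["a", "b"], "sp", scen)
        m2 = ensemble(reps[::-1], stack, mask, ["a", "b"], "sp", scen)
        assert np.array_equal(m1.continuous.values, m2.continuous.values,
                              equal_nan=True)

    def test_continuous_in_unit_interval(self, grid):
        stack, mask, scen = self._setup(grid)
        reps = [_stub_replicate(v, a) for v, a in
                [(0.9, 0.95), (0.4, 0.7), (0.1, 0.6)]]
        smap = ensemble(reps, stack, mask, ["a", "b"], "sp", scen)
        vals = smap.continuous.values[mask]
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_all_replicates_at_chance_rejected(self, grid):
        stack, mask, scen = self._setup(grid)
        with pytest.raises(ValueError, match="AUC"):
            ensemble([_stub_replicate(1.0, 0.5)], stack, mask,
                     ["a", "b"], "sp", scen)

    def test_low_auc_replicates_dropped_with_warning(self, grid):
        stack, mask, scen = self._setup(grid)
        with pytest.warns(UserWarning, match="dropped"):
            ensemble([_stub_replicate(1.0, 0.9), _stub_replicate(0.0, 0.4)],
                     stack, mask, ["a", "b"], "sp", scen)
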