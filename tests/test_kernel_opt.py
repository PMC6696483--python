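import numpy as np
import pytest

import thzopenset as tzo
from thzopenset.kernel_opt import (CVMCRObjective, KernelOptConfig,
                                   center_plateau_1d, cv_mcr_objective, mcr,
                                   nelder_mead, params_from_log,
                                   train_kernel_multistart)
from thzopenset.spectra_io import stratified_folds


class TestMCR:
    @pytest.mark.parametrize("pred,true,count", [
        ([1, 2, 3], [1, 2, 3], 0),
        ([1, 2, 3], [1, 2, 4], 1),
        ([2] * 30, [1] * 30, 30),
    ])
    def test_counts(self, pred, true, count):
        assert mcr(pred, true) == count

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            mcr([1, 2], [1])


class TestParamsFromLog:
    def test_exponential_map_is_positive(self):
        base = tzo.KernelParams()
        for z in ([-50.0], [0.0], [8.0]):
            p = params_from_log(np.array(z), base, ("sigma2",))
            assert p.sigma2 > 0

    def test_degree_rounds_to_integer(self):
        base = tzo.KernelParams(family="polynomial")
        p = params_from_log(np.log([2.2, 0.7]), base, ("degree", "beta0"))
        assert p.degree == 2 and p.beta0 == pytest.approx(0.7)


class TestCVObjective:
    def test_separable_task_reaches_zero(self, binary_scores):
        scores, y, labels = binary_scores
        folds = stratified_folds(labels, 2, seed=0)
        assert cv_mcr_objective(np.log([10.0]), scores, y, folds) == 0

    def test_invariant_to_fold_relabelling(self, binary_scores):
        """The summed CV-MCR does not depend on the order in which folds
        are visited (swap fold labels 1 and 2)."""
        scores, y, labels = binary_scores
        folds = stratified_folds(labels, 2, seed=1)
        swapped = tzo.FoldAssignment(fold_index=3 - folds.fold_index, n_folds=2)
        z = np.log([0.5])
        assert (cv_mcr_objective(z, scores, y, folds)
                == cv_mcr_objective(z, scores, y, swapped))

    def test_nonfinite_point_rejected(self, binary_scores):
        scores, y, labels = binary_scores
        folds = stratified_folds(labels, 2, seed=0)
        with pytest.raises(ValueError):
            cv_mcr_objective(np.array([np.nan]), scores, y, folds)

    def test_grid_oracle_brackets_nm_minimizer(self, binary_scores):
        """A 25-point brute-force grid over log sigma^2 in [-6, 6] finds
        the zero-MCR plateau; the NM-selected point lies inside the
        plateau the grid brackets and attains the grid minimum."""
        scores, y, labels = binary_scores
        folds = stratified_folds(labels, 2, seed=3)
        config = KernelOptConfig(n_folds=2, n_starts=10, seed=3)
        obj = CVMCRObjective(scores, y, folds, config)
        grid = np.linspace(-6, 6, 25)
        vals = np.array([obj(np.array([g])) for g in grid])
        best_val = vals.min()
        plateau = grid[vals == best_val]
        opt = train_kernel_multistart(scores, y, config=config, folds=folds)
        assert opt.best_cv_mcr == best_val
        z_star = np.log(opt.best_params.sigma2)
        step = grid[1] - grid[0]
        assert plateau.min() - step <= z_star <= plateau.max() + step


class TestNelderMead:
    def test_1d_quadratic(self):
        res = nelder_mead(lambda x: (x[0] - 2.0) ** 2, np.array([0.0]),
                          tol=1e-6, max_iter=500)
        assert abs(res.x[0] - 2.0) < 1e-4

    def test_2d_quadratic(self):
        res = nelder_mead(lambda x: (x[0] - 1) ** 2 + 2 * (x[1] + 3) ** 2,
                          np.array([4.0, 4.0]), tol=1e-7, max_iter=1000)
        np.testing.assert_allclose(res.x, [1.0, -3.0], atol=1e-4)

    def test_staircase_plateau_terminates_at_minimum(self):
        """On a piecewise-constant staircase the search terminates (stall
        rule) and returns a point on the lowest plateau it sampled."""
        def stair(x):
            return float(np.floor(np.clip(np.abs(x[0]), 0, 5)))

        res = nelder_mead(stair, np.array([4.2]), tol=1e-8, max_iter=300)
        sampled_min = 0.0  # plateau |x| < 1 has value 0 and is reachable
        assert res.fval in (sampled_min, 1.0)
        assert res.reason in ("stall", "tol")
        # from a start inside the bottom plateau the bottom value is kept
        res0 = nelder_mead(stair, np.array([0.2]), tol=1e-8, max_iter=300)
        assert res0.fval == 0.0

    def test_target_short_circuits(self):
        calls = []

        def f(x):
            calls.append(x.copy())
            return float(abs(x[0]))

        res = nelder_mead(f, np.array([0.0]), f_target=0.0)
        assert res.fval == 0.0 and res.n_evals == 1

    def test_nonfinite_start_raises(self):
        with pytest.raises(ValueError):
            nelder_mead(lambda x: float("nan"), np.array([1.0]))


class TestCenterPlateau:
    def test_moves_to_margin_point_of_plateau(self):
        f = lambda z: 0.0 if 1.0 <= z[0] <= 9.0 else 1.0
        picked = center_plateau_1d(f, 1.2, 0.0, lo=-10, hi=12,
                                   coarse_step=1.0, n_bisect=8)
        # lower edge 1 + margin 2 = 3, below the midpoint 5
        assert picked == pytest.approx(3.0, abs=0.1)
        assert f([picked]) == 0.0

    def test_respects_midpoint_cap(self):
        f = lambda z: 0.0 if 1.0 <= z[0] <= 3.0 else 1.0
        picked = center_plateau_1d(f, 2.5, 0.0, lo=-10, hi=12,
                                   coarse_step=0.5, n_bisect=8)
        assert picked == pytest.approx(2.0, abs=0.1)  # midpoint of [1, 3]


class TestMultistart:
    def test_single_start_equals_plain_nm_run(self, binary_scores):
        scores, y, labels = binary_scores
        folds = stratified_folds(labels, 2, seed=5)
        config = KernelOptConfig(n_starts=1, seed=5, center_plateau=False)
        opt = train_kernel_multistart(scores, y, config=config, folds=folds)
        rng = np.random.default_rng(np.random.SeedSequence([5, 0x0157]))
        x0 = rng.uniform(config.init_log_low, config.init_log_high, size=(1, 1))[0]
        obj = CVMCRObjective(scores, y, folds, config)
        ref = nelder_mead(obj, x0, tol=config.nm_tol,
                          max_iter=config.nm_max_iter, f_target=0.0)
        assert opt.best_cv_mcr == ref.fval
        np.testing.assert_allclose(np.log(opt.best_params.sigma2), ref.x[0])

    def test_best_objective_nonincreasing_in_starts(self, binary_scores):
        scores, y, labels = binary_scores
        folds = stratified_folds(labels, 2, seed=6)
        prev = None
        for n_starts in (1, 3, 6):
            config = KernelOptConfig(n_starts=n_starts, seed=6,
                                     stop_at_zero=False, center_plateau=False)
            opt = train_kernel_multistart(scores, y, config=config, folds=folds)
            if prev is not None:
                assert opt.best_cv_mcr <= prev
            prev = opt.best_cv_mcr

    def test_returned_parameters_strictly_positive(self, binary_scores):
        scores, y, labels = binary_scores
        folds = stratified_folds(labels, 2, seed=7)
        opt = train_kernel_multistart(scores, y,
                                      config=KernelOptConfig(n_starts=3, seed=7),
                                      folds=folds)
        p = opt.best_params
        assert p.sigma2 > 0 and p.c_xi > 0 and p.beta0 >= 0 and p.beta1 > 0

    def test_multistart_escapes_hostile_initialization(self, binary_scores):
        """A single start from a grid-identified worst-case init stalls at
        a nonzero CV-MCR; 30 starts recover the zero-MCR optimum."""
        scores, y, labels = binary_scores
        folds = stratified_folds(labels, 2, seed=8)
        base = KernelOptConfig(n_folds=2, seed=8)
        obj = CVMCRObjective(scores, y, folds, base)
        grid = np.linspace(-6, 6, 25)
        vals = np.array([obj(np.array([g])) for g in grid])
        hostile = grid[np.argmax(vals)]  # deep in the worst plateau
        res = nelder_mead(obj, np.array([hostile]), tol=1e-3, max_iter=200,
                          initial_step=0.05, f_target=0.0)
        assert res.fval > 0  # trapped on the bad plateau
        opt = train_kernel_multistart(scores, y,
                                      config=KernelOptConfig(n_starts=30, seed=8),
                                      folds=folds)
        assert opt.best_cv_mcr == 0
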