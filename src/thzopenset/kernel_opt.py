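"""Data-driven kernel training by CV misclassification minimization.

The kernel parameters are learnt from the training data itself: a
candidate parameter vector is scored by n-fold cross-validated
misclassification count (MCR), and that integer-valued, non-smooth
objective is minimized with the derivative-free Nelder-Mead simplex
method.  Positivity constraints on the parameters are removed by the
exponential reparameterization p = exp(p~), so the simplex search runs
unconstrained in log space.  Because the objective is non-convex and
piecewise constant, the search is restarted from many random initial
points and the best final vertex is kept.

By default only the GRBF length-scale sigma^2 is free (a one-variable
search; the simplex is then a 2-vertex interval) with the soft margin
fixed at C_xi = 1; the full vector {d, b0, b1, s2, C_xi} can be freed
through the configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ksvm import (KernelParams, SMONonConvergence, _apply_kernel, _sq_dists,
                   solve_dual)
from .spectra_io import FoldAssignment, stratified_folds

__all__ = [
    "KernelOptConfig",
    "NMResult",
    "OptResult",
    "mcr",
    "params_from_log",
    "CVMCRObjective",
    "cv_mcr_objective",
    "nelder_mead",
    "train_kernel_multistart",
]

logger = logging.getLogger(__name__)

#: parameters that may be freed for optimization, in canonical order
FREE_PARAM_NAMES = ("degree", "beta0", "beta1", "sigma2", "c_xi")


def mcr(predicted, true) -> int:
    """Misclassification count: number of positions where labels differ."""
    predicted = np.asarray(predicted).ravel()
    true = np.asarray(true).ravel()
    if predicted.size != true.size:
        raise ValueError(
            f"label vectors differ in length ({predicted.size} vs {true.size})"
        )
    return int(np.count_nonzero(predicted != true))


@dataclass(frozen=True)
class KernelOptConfig:
    """Everything the kernel-training loop needs, with study defaults."""

    base_params: KernelParams = field(default_factory=KernelParams)  # GRBF, C_xi = 1
    free_params: tuple[str, ...] = ("sigma2",)
    n_folds: int = 2
    n_starts: int = 30
    nm_tol: float = 1e-3
    nm_max_iter: int = 200
    init_log_low: float = float(np.log(1e-3))
    init_log_high: float = float(np.log(1e3))
    seed: int = 0
    stop_at_zero: bool = True  # MCR >= 0, so 0 certifies a global optimum
    center_plateau: bool = True  # 1-D search: move to the plateau midpoint
    smo_tol: float = 1e-3
    smo_max_iter: int | None = None

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        for name in self.free_params:
            if name not in FREE_PARAM_NAMES:
                raise ValueError(f"unknown free parameter {name!r}")


def params_from_log(z_tilde: np.ndarray, base: KernelParams,
                    free_params: tuple[str, ...]) -> KernelParams:
    """Map an unconstrained log-space vector to a valid parameter set.

    Each free component is exponentiated (hence strictly positive); the
    polynomial degree, inherently an integer >= 1, is rounded after the
    exponential map.
    """
    z_tilde = np.asarray(z_tilde, dtype=float).ravel()
    if z_tilde.size != len(free_params):
        raise ValueError("log-parameter vector does not match free_params")
    updates = {}
    for name, value in zip(free_params, np.exp(z_tilde)):
        updates[name] = max(1, int(round(value))) if name == "degree" else float(value)
    return base.with_updates(**updates)


class CVMCRObjective:
    """Callable CV-MCR objective over log-space kernel parameters.

    Precomputes the pairwise-distance (GRBF) or Gram (polynomial /
    perceptron) base matrix and the fold splits once, so each evaluation
    only applies the kernel nonlinearity and runs SMO per fold.  A solver
    failure on any fold maps to the worst case (all validation samples
    misclassified) with a logged warning, steering the search away.
    """

    def __init__(self, scores: np.ndarray, y: np.ndarray,
                 folds: FoldAssignment, config: KernelOptConfig):
        self.scores = np.atleast_2d(np.asarray(scores, dtype=float))
        self.y = np.asarray(y, dtype=float).ravel()
        if not np.all(np.isin(self.y, (-1.0, 1.0))):
            raise ValueError("labels must be +/-1")
        self.folds = folds
        self.config = config
        fam = config.base_params.family
        self._base = (_sq_dists(self.scores, self.scores) if fam == "grbf"
                      else self.scores @ self.scores.T)
        self._splits = [folds.split(f) for f in range(1, folds.n_folds + 1)]
        self.n_evals = 0

    def __call__(self, z_tilde: np.ndarray) -> int:
        if not np.all(np.isfinite(z_tilde)):
            raise ValueError("non-finite log-parameter vector")
        params = params_from_log(z_tilde, self.config.base_params,
                                 self.config.free_params)
        self.n_evals += 1
        K = _apply_kernel(params, self._base)
        total = 0
        for train_idx, val_idx in self._splits:
            Ktr = K[np.ix_(train_idx, train_idx)]
            ytr = self.y[train_idx]
            try:
                lam, bias = solve_dual(Ktr, ytr, params.c_xi,
                                       tol=self.config.smo_tol,
                                       max_iter=self.config.smo_max_iter)
            except SMONonConvergence as exc:
                logger.warning("SMO failed on a CV fold (%s); "
                               "scoring candidate as all-misclassified", exc)
                total += val_idx.size
                continue
            f_val = K[np.ix_(val_idx, train_idx)] @ (lam * ytr) + bias
            pred = np.where(f_val >= 0, 1.0, -1.0)
            total += mcr(pred, self.y[val_idx])
        return total


def cv_mcr_objective(z_tilde, scores, y, folds: FoldAssignment,
                     config: KernelOptConfig | None = None) -> int:
    """One-shot CV-MCR evaluation (see :class:`CVMCRObjective`)."""
    config = config if config is not None else KernelOptConfig()
    return CVMCRObjective(scores, y, folds, config)(z_tilde)


@dataclass(frozen=True)
class NMResult:
    x: np.ndarray
    fval: float
    n_evals: int
    reason: str  # "tol" | "stall" | "target" | "max_iter"


def nelder_mead(f, x0, *, tol: float = 1e-3, max_iter: int = 200,
                initial_step: float = 0.5, stall_iters: int | None = None,
                f_target: float | None = None) -> NMResult:
    """Nelder-Mead simplex minimization of a (possibly non-smooth) function.

    Classical coefficients: reflection 1, expansion 2, contraction 0.5,
    shrink 0.5.  Terminates when the simplex diameter falls below ``tol``,
    when the best value has not improved for ``stall_iters`` iterations
    (default 20 x dimension — integer-valued objectives plateau and would
    otherwise shrink forever), when ``f_target`` is reached (useful when a
    known lower bound certifies global optimality), or at ``max_iter``.
    A one-dimensional problem uses the 2-vertex simplex (an interval).
    """
    x0 = np.asarray(x0, dtype=float).ravel()
    dim = x0.size
    if stall_iters is None:
        stall_iters = 20 * dim

    def fe(x):
        return float(f(x))

    f0 = fe(x0)
    if not np.isfinite(f0):
        raise ValueError("objective is non-finite at the starting point")
    n_evals = 1
    if f_target is not None and f0 <= f_target:
        return NMResult(x0, f0, n_evals, "target")

    simplex = [x0]
    fvals = [f0]
    for k in range(dim):
        x = x0.copy()
        x[k] += initial_step if x0[k] == 0 else initial_step * max(1.0, abs(x0[k]))
        simplex.append(x)
        fvals.append(fe(x))
        n_evals += 1
    simplex = np.array(simplex)
    fvals = np.array(fvals)

    def hit_target(val):
        return f_target is not None and val <= f_target

    if hit_target(fvals.min()):
        best = int(np.argmin(fvals))
        return NMResult(simplex[best], fvals[best], n_evals, "target")

    best_so_far = fvals.min()
    since_improve = 0
    reason = "max_iter"
    for _ in range(max_iter):
        order = np.argsort(fvals, kind="stable")
        simplex, fvals = simplex[order], fvals[order]
        diam = np.max(np.linalg.norm(simplex[1:] - simplex[0], axis=1))
        if diam < tol:
            reason = "tol"
            break
        centroid = simplex[:-1].mean(axis=0)
        worst = simplex[-1]

        xr = centroid + (centroid - worst)  # reflection
        fr = fe(xr); n_evals += 1
        if hit_target(fr):
            return NMResult(xr, fr, n_evals, "target")
        if fr < fvals[0]:
            xe = centroid + 2.0 * (centroid - worst)  # expansion
            fex = fe(xe); n_evals += 1
            if hit_target(fex):
                return NMResult(xe, fex, n_evals, "target")
            if fex < fr:
                simplex[-1], fvals[-1] = xe, fex
            else:
                simplex[-1], fvals[-1] = xr, fr
        elif fr < fvals[-2]:
            simplex[-1], fvals[-1] = xr, fr
        else:
            if fr < fvals[-1]:  # outside contraction
                xc = centroid + 0.5 * (xr - centroid)
            else:  # inside contraction
                xc = centroid + 0.5 * (worst - centroid)
            fc = fe(xc); n_evals += 1
            if hit_target(fc):
                return NMResult(xc, fc, n_evals, "target")
            if fc < min(fr, fvals[-1]):
                simplex[-1], fvals[-1] = xc, fc
            else:  # shrink towards the best vertex
                for k in range(1, dim + 1):
                    simplex[k] = simplex[0] + 0.5 * (simplex[k] - simplex[0])
                    fvals[k] = fe(simplex[k]); n_evals += 1
                    if hit_target(fvals[k]):
                        return NMResult(simplex[k], fvals[k], n_evals, "target")

        if fvals.min() < best_so_far:
            best_so_far = fvals.min()
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= stall_iters:
                reason = "stall"
                break

    best = int(np.argmin(fvals))
    return NMResult(simplex[best], fvals[best], n_evals, reason)


#: log-space margin added above the lower plateau edge when re-centring
#: the 1-D kernel search (a factor e^2 ~ 7.4 in sigma^2)
PLATEAU_MARGIN = 2.0


def center_plateau_1d(f, x_star: float, f_star: float,
                      lo: float, hi: float,
                      coarse_step: float = 1.0, n_bisect: int = 5,
                      margin: float = PLATEAU_MARGIN) -> float:
    """Robust working point on the objective plateau around ``x_star`` (1-D).

    An integer-valued CV misclassification objective is piecewise
    constant, so every point of the plateau attaining the minimum is an
    equally valid minimizer — but the edges generalize differently.  For
    a GRBF length-scale the lower edge is the narrowest kernel the
    validation split barely tolerates: it fails on test batches displaced
    by measurement drift.  The upper half of the plateau gives decision
    regions that reach toward neighbouring clusters and erode rejection
    of compounds absent from training.  This walks outward from the
    solution in coarse steps until the objective leaves the plateau (or
    a bound is hit), sharpens each edge by bisection, and returns the
    lower edge plus a fixed log-space ``margin``, capped at the plateau
    midpoint.  Only the plateau connected to ``x_star`` is explored; the
    returned point attains the same objective value.
    """
    def on_plateau(x: float) -> bool:
        return f(np.array([x])) <= f_star

    def edge(inside: float, step: float, bound: float) -> float:
        out = inside
        while (out + step - bound) * np.sign(step) < 0:
            nxt = out + step
            if not on_plateau(nxt):
                # bisect between the last plateau point and the first outside
                a, b = out, nxt
                for _ in range(n_bisect):
                    mid = (a + b) / 2.0
                    if on_plateau(mid):
                        a = mid
                    else:
                        b = mid
                return a
            out = nxt
        return bound

    left = edge(x_star, -coarse_step, lo)
    right = edge(x_star, +coarse_step, hi)
    pick = min(left + margin, (left + right) / 2.0)
    # the picked point attains f_star by construction on a true plateau, but
    # a disconnected sub-level set could break that; keep x_star in that case
    return pick if on_plateau(pick) else x_star


@dataclass(frozen=True)
class StartResult:
    x0: np.ndarray
    x: np.ndarray
    objective: float


@dataclass(frozen=True)
class OptResult:
    """Outcome of multi-start kernel training."""

    best_params: KernelParams
    best_cv_mcr: int
    start_results: list[StartResult]
    n_folds: int
    seed: int

    def __post_init__(self) -> None:
        if self.start_results:
            assert self.best_cv_mcr == min(s.objective for s in self.start_results)
        assert self.best_cv_mcr >= 0
        # exponential reparameterization guarantees positivity
        p = self.best_params
        assert p.sigma2 > 0 and p.c_xi > 0 and p.beta1 > 0 and p.beta0 >= 0

    def to_dict(self) -> dict:
        return {
            "best_params": vars(self.best_params).copy() if hasattr(self.best_params, "__dict__")
            else {k: getattr(self.best_params, k) for k in
                  ("family", "degree", "beta0", "beta1", "sigma2", "c_xi")},
            "best_cv_mcr": self.best_cv_mcr,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "starts": [
                {"x0": s.x0.tolist(), "x": s.x.tolist(), "objective": s.objective}
                for s in self.start_results
            ],
        }


def train_kernel_multistart(scores: np.ndarray, y: np.ndarray,
                            config: KernelOptConfig | None = None,
                            folds: FoldAssignment | None = None) -> OptResult:
    """Learn kernel parameters by multi-start Nelder-Mead on the CV-MCR.

    ``y`` holds +/-1 labels for the binary subproblem.  ``folds`` should
    be the class-stratified assignment computed on the original multiclass
    labels; when omitted, folds are stratified on the binary labels.
    Initial log-space points are drawn uniformly from the configured
    range; ties between starts are broken by start order.  When
    ``stop_at_zero`` is set, the loop ends as soon as a start reaches
    CV-MCR 0 — the certified global minimum of a non-negative integer
    objective.
    """
    config = config if config is not None else KernelOptConfig()
    y = np.asarray(y, dtype=float).ravel()
    if folds is None:
        folds = stratified_folds(np.where(y > 0, 1, 2), config.n_folds,
                                 seed=config.seed)
    if folds.n_folds != config.n_folds:
        raise ValueError("fold assignment does not match config.n_folds")

    objective = CVMCRObjective(scores, y, folds, config)
    dim = len(config.free_params)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x0157]))
    inits = rng.uniform(config.init_log_low, config.init_log_high,
                        size=(config.n_starts, dim))

    results: list[StartResult] = []
    best_idx = 0
    for k in range(config.n_starts):
        nm = nelder_mead(objective, inits[k], tol=config.nm_tol,
                         max_iter=config.nm_max_iter,
                         f_target=0.0 if config.stop_at_zero else None)
        results.append(StartResult(x0=inits[k].copy(), x=nm.x, objective=nm.fval))
        if nm.fval < results[best_idx].objective:
            best_idx = k
        if config.stop_at_zero and results[best_idx].objective <= 0:
            break

    best = results[best_idx]
    best_x = best.x
    if config.center_plateau and dim == 1:
        centred = center_plateau_1d(objective, float(best_x[0]), best.objective,
                                    lo=config.init_log_low - 2.0,
                                    hi=config.init_log_high + 2.0)
        best_x = np.array([centred])
    return OptResult(
        best_params=params_from_log(best_x, config.base_params, config.free_params),
        best_cv_mcr=int(best.objective),
        start_results=results,
        n_folds=config.n_folds,
        seed=config.seed,
    )
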