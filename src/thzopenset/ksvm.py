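"""Binary soft-margin kernel SVM with an SMO dual solver.

The binary classifier separates two classes in the implicit feature space
of a kernel k(z, z').  Training solves the dual quadratic program

    min_l  1/2 l' H l - e' l     s.t.  y' l = 0,  0 <= l_r <= C_xi,

with H = [y_r y_s k(z_r, z_s)], by sequential minimal optimization: the
maximally KKT-violating pair of dual variables is updated analytically at
each step, which needs no generic QP solver and touches only two kernel
columns per iteration.  The feature map is never formed; decisions use
the kernel expansion f(z) = sum_r l_r y_r k(z_r, z) + b.

Kernel menu: d-degree polynomial (z'z + b0)^d, Gaussian RBF
exp(-||z - z'||^2 / (2 s2)), and the two-layer perceptron
tanh(b0 z'z + b1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "KernelParams",
    "BinarySVMModel",
    "SMONonConvergence",
    "kernel_value",
    "kernel_matrix",
    "cross_kernel",
    "solve_dual",
    "dual_objective",
    "fit_binary_svm",
    "decision_value",
    "decision_values",
]

#: dual variables below this are treated as exactly zero
SV_THRESHOLD = 1e-8


@dataclass(frozen=True)
class KernelParams:
    """Kernel family tag plus the full parameter vector {d, b0, b1, s2, C}.

    Only the family-relevant entries matter for kernel evaluation; the
    soft-margin bound ``c_xi`` rides along because kernel training treats
    the whole vector as one candidate point.
    """

    family: str = "grbf"  # polynomial | grbf | perceptron
    degree: int = 2  # d, polynomial only
    beta0: float = 1.0  # polynomial offset / perceptron gain
    beta1: float = 1.0  # perceptron bias
    sigma2: float = 1.0  # GRBF length-scale squared
    c_xi: float = 1.0  # soft-margin box bound

    def __post_init__(self) -> None:
        if self.family not in ("polynomial", "grbf", "perceptron"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family == "polynomial" and (self.degree < 1 or self.beta0 < 0):
            raise ValueError("polynomial kernel needs degree >= 1 and beta0 >= 0")
        if self.family == "grbf" and not self.sigma2 > 0:
            raise ValueError("GRBF kernel needs sigma2 > 0")
        if self.family == "perceptron" and not (self.beta0 > 0 and self.beta1 > 0):
            raise ValueError("perceptron kernel needs beta0, beta1 > 0")
        if not self.c_xi > 0:
            raise ValueError("c_xi must be > 0")

    def with_updates(self, **kwargs) -> "KernelParams":
        return replace(self, **kwargs)


class SMONonConvergence(RuntimeError):
    """SMO hit its iteration cap; carries the best iterate found."""

    def __init__(self, msg: str, lam: np.ndarray, bias: float, gap: float):
        super().__init__(msg)
        self.lam = lam
        self.bias = bias
        self.gap = gap


def _check_finite(*arrays) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite values in kernel input")


def _sq_dists(Z1: np.ndarray, Z2: np.ndarray) -> np.ndarray:
    sq1 = np.einsum("ij,ij->i", Z1, Z1)
    sq2 = np.einsum("ij,ij->i", Z2, Z2)
    d2 = sq1[:, None] + sq2[None, :] - 2.0 * (Z1 @ Z2.T)
    return np.maximum(d2, 0.0)


def _apply_kernel(params: KernelParams, gram_or_d2: np.ndarray) -> np.ndarray:
    if params.family == "grbf":
        return np.exp(-gram_or_d2 / (2.0 * params.sigma2))
    if params.family == "polynomial":
        return (gram_or_d2 + params.beta0) ** params.degree
    return np.tanh(params.beta0 * gram_or_d2 + params.beta1)


def kernel_value(params: KernelParams, zr: np.ndarray, zs: np.ndarray) -> float:
    """Scalar kernel evaluation k(zr, zs)."""
    zr = np.asarray(zr, dtype=float).ravel()
    zs = np.asarray(zs, dtype=float).ravel()
    if zr.size != zs.size:
        raise ValueError("kernel arguments must have equal length")
    _check_finite(zr, zs)
    if params.family == "grbf":
        d = zr - zs
        return float(np.exp(-(d @ d) / (2.0 * params.sigma2)))
    return float(_apply_kernel(params, zr @ zs))


def kernel_matrix(params: KernelParams, Z: np.ndarray) -> np.ndarray:
    """Full Gram matrix K = [k(z_r, z_s)]; symmetric, PSD for GRBF/polynomial."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    _check_finite(Z)
    base = _sq_dists(Z, Z) if params.family == "grbf" else Z @ Z.T
    K = _apply_kernel(params, base)
    return (K + K.T) / 2.0  # scrub round-off asymmetry


def cross_kernel(params: KernelParams, Z1: np.ndarray, Z2: np.ndarray) -> np.ndarray:
    """Rectangular kernel matrix between two point sets."""
    Z1 = np.atleast_2d(np.asarray(Z1, dtype=float))
    Z2 = np.atleast_2d(np.asarray(Z2, dtype=float))
    if Z1.shape[1] != Z2.shape[1]:
        raise ValueError("point sets have different dimensionality")
    _check_finite(Z1, Z2)
    base = _sq_dists(Z1, Z2) if params.family == "grbf" else Z1 @ Z2.T
    return _apply_kernel(params, base)


def dual_objective(K: np.ndarray, y: np.ndarray, lam: np.ndarray) -> float:
    """Value of the dual QP objective 1/2 l'Hl - e'l at ``lam``."""
    v = y * lam
    return float(0.5 * v @ K @ v - lam.sum())


def solve_dual(K: np.ndarray, y: np.ndarray, c_xi: float,
               tol: float = 1e-3, max_iter: int | None = None
               ) -> tuple[np.ndarray, float]:
    """Solve the soft-margin dual QP by SMO.

    Parameters
    ----------
    K : (R, R) symmetric kernel matrix.
    y : (R,) labels in {-1, +1}; both classes must be present.
    c_xi : soft-margin box bound (> 0).
    tol : KKT violation tolerance on the duality-gap proxy m - M.
    max_iter : pair-update cap; defaults to max(5000, 10 R).

    Returns
    -------
    (lam, bias) with 0 <= lam <= c_xi, |y' lam| ~ 0; bias averaged over
    free support vectors, falling back to the violation midpoint when no
    variable is strictly inside the box.
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    r = y.size
    if K.shape != (r, r):
        raise ValueError("K must be square and match y")
    if not (np.all(np.isin(y, (-1.0, 1.0))) and np.any(y > 0) and np.any(y < 0)):
        raise ValueError("labels must be +/-1 with both classes present")
    if max_iter is None:
        max_iter = max(5000, 10 * r)

    lam = np.zeros(r)
    grad = -np.ones(r)  # gradient of the dual objective at lam = 0
    diag = np.diag(K)
    pos = y > 0

    def neg_ygrad():
        return -y * grad

    gap = np.inf
    for _ in range(max_iter):
        v = neg_ygrad()
        up = (pos & (lam < c_xi - SV_THRESHOLD)) | (~pos & (lam > SV_THRESHOLD))
        low = (~pos & (lam < c_xi - SV_THRESHOLD)) | (pos & (lam > SV_THRESHOLD))
        # up/low can only empty out if every variable is pinned; then optimal
        if not up.any() or not low.any():
            gap = 0.0
            break
        i = np.flatnonzero(up)[np.argmax(v[up])]
        j = np.flatnonzero(low)[np.argmin(v[low])]
        m, mm = v[i], v[j]
        gap = m - mm
        if gap <= tol:
            break
        eta = diag[i] + diag[j] - 2.0 * K[i, j]
        t = gap / max(eta, 1e-12)
        # keep lam_i + y_i t and lam_j - y_j t inside the box
        t = min(t,
                c_xi - lam[i] if y[i] > 0 else lam[i],
                lam[j] if y[j] > 0 else c_xi - lam[j])
        lam[i] += y[i] * t
        lam[j] -= y[j] * t
        grad += t * y * (K[:, i] - K[:, j])
    else:
        bias = _bias_from_gradient(lam, y, grad, c_xi)
        raise SMONonConvergence(
            f"SMO did not reach tolerance {tol} within {max_iter} iterations "
            f"(remaining KKT gap {gap:.3g})", lam, bias, gap)

    np.clip(lam, 0.0, c_xi, out=lam)
    return lam, _bias_from_gradient(lam, y, grad, c_xi)


def _bias_from_gradient(lam, y, grad, c_xi) -> float:
    free = (lam > SV_THRESHOLD) & (lam < c_xi - SV_THRESHOLD)
    v = -y * grad  # equals the bias at every free support vector (KKT)
    if free.any():
        return float(v[free].mean())
    pos = y > 0
    up = (pos & (lam < c_xi - SV_THRESHOLD)) | (~pos & (lam > SV_THRESHOLD))
    low = (~pos & (lam < c_xi - SV_THRESHOLD)) | (pos & (lam > SV_THRESHOLD))
    hi = v[up].max() if up.any() else v.max()
    lo = v[low].min() if low.any() else v.min()
    return float((hi + lo) / 2.0)


@dataclass(frozen=True)
class BinarySVMModel:
    """Trained binary classifier stored as its kernel expansion."""

    support_vectors: np.ndarray  # (M, J)
    dual_coeffs: np.ndarray  # (M,), lam_r * y_r for stored vectors
    bias: float
    kernel: KernelParams
    positive_class: int = 1

    @property
    def n_support(self) -> int:
        return self.dual_coeffs.size

    @property
    def n_features(self) -> int:
        return self.support_vectors.shape[1]


def fit_binary_svm(Z: np.ndarray, y: np.ndarray, kernel: KernelParams,
                   positive_class: int = 1, tol: float = 1e-3,
                   max_iter: int | None = None,
                   precomputed_K: np.ndarray | None = None) -> BinarySVMModel:
    """Train a binary KSVM on score vectors Z with labels y in {-1, +1}."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    K = precomputed_K if precomputed_K is not None else kernel_matrix(kernel, Z)
    lam, bias = solve_dual(K, y, kernel.c_xi, tol=tol, max_iter=max_iter)
    sv = lam > SV_THRESHOLD
    return BinarySVMModel(
        support_vectors=Z[sv].copy(),
        dual_coeffs=(lam * y)[sv],
        bias=bias,
        kernel=kernel,
        positive_class=positive_class,
    )


def decision_values(model: BinarySVMModel, Z: np.ndarray) -> np.ndarray:
    """Batch decision function f(z) = sum_r l_r y_r k(x_r, z) + b."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[1] != model.n_features:
        raise ValueError(
            f"points have {Z.shape[1]} features, model expects {model.n_features}"
        )
    if model.n_support == 0:
        return np.full(Z.shape[0], model.bias)
    Kx = cross_kernel(model.kernel, Z, model.support_vectors)
    return Kx @ model.dual_coeffs + model.bias


def decision_value(model: BinarySVMModel, z: np.ndarray) -> float:
    """Decision function at a single point; classification is by sign."""
    return float(decision_values(model, np.asarray(z, dtype=float)[None, :])[0])
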