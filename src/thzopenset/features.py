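"""PCA feature extraction for high-resolution absorbance spectra.

Spectra digitized at ~1200 subbands are highly redundant: a few peak
positions, widths and amplitudes govern the whole curve, so the empirical
covariance of a spectral training set is effectively low rank.  Fitting
PCA on the *training* spectra only and projecting test spectra with the
training mean gives a compact score space (the classifier's input) without
leaking information from drifted, later-measured test batches.

The top-J loadings are the eigenvectors of the empirical covariance of
the centred training matrix, computed through its SVD for stability; the
eigenvector sign is fixed by making each loading's largest-magnitude
entry positive so fits are reproducible across linear-algebra backends.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .spectra_io import SpectraDataset

__all__ = ["PCAModel", "fit_pca", "project", "reconstruct", "save_pca", "load_pca"]


@dataclass(frozen=True)
class PCAModel:
    mean_spectrum: np.ndarray  # (I,)
    loadings: np.ndarray  # (I, J), orthonormal columns
    eigenvalues: np.ndarray  # (J,), non-increasing
    explained_ratio: np.ndarray  # (J,), fractions of total variance

    def __post_init__(self) -> None:
        lam = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(lam) > 1e-10 * max(lam[0], 1.0)):
            raise ValueError("eigenvalues must be sorted non-increasing")
        g = self.loadings.T @ self.loadings
        if not np.allclose(g, np.eye(self.n_components), atol=1e-8):
            raise ValueError("loadings are not orthonormal")
        if self.explained_ratio.sum() > 1.0 + 1e-10:
            raise ValueError("explained variance ratios sum above 1")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def n_subbands(self) -> int:
        return self.loadings.shape[0]


def fit_pca(train: SpectraDataset | np.ndarray, n_components: int) -> PCAModel:
    """Fit PCA on training spectra, keeping the top ``n_components`` PCs.

    ``n_components`` must not exceed min(N-1, I) nor the numerical rank of
    the centred training matrix.
    """
    X = train.absorbance if isinstance(train, SpectraDataset) else np.asarray(train, float)
    n, i = X.shape
    if n < 2:
        raise ValueError("need at least two training spectra")
    j_max = min(n - 1, i)
    if not 1 <= n_components <= j_max:
        raise ValueError(f"n_components must be in [1, {j_max}], got {n_components}")

    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD of the centred matrix: covariance eigenvalues are s^2/(N-1)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s**2 / (n - 1)
    total_var = eigvals.sum()
    rank = int(np.sum(s > s[0] * max(n, i) * np.finfo(float).eps)) if s[0] > 0 else 0
    if n_components > rank:
        raise ValueError(
            f"n_components={n_components} exceeds the attainable rank {rank} of the training spectra"
        )
    loadings = vt[:n_components].T.copy()
    # deterministic sign: largest-|.| entry of each loading made positive
    piv = np.argmax(np.abs(loadings), axis=0)
    signs = np.sign(loadings[piv, np.arange(n_components)])
    signs[signs == 0] = 1.0
    loadings *= signs
    lam = eigvals[:n_components]
    return PCAModel(mean_spectrum=mean, loadings=loadings, eigenvalues=lam,
                    explained_ratio=lam / total_var if total_var > 0 else np.zeros_like(lam))


def project(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project spectra onto the PC space: (X - mean) @ loadings."""
    X = np.asarray(X, dtype=float)
    one = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != model.n_subbands:
        raise ValueError(
            f"spectra have {X.shape[1]} subbands, model expects {model.n_subbands}"
        )
    scores = (X - model.mean_spectrum) @ model.loadings
    return scores[0] if one else scores


def reconstruct(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    """Map PC scores back to spectrum space (exact at full rank)."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[1] != model.n_components:
        raise ValueError("score dimensionality does not match the model")
    return scores @ model.loadings.T + model.mean_spectrum


def save_pca(model: PCAModel, prefix) -> None:
    """Serialize as a JSON header plus CSV matrices (mean and loadings)."""
    prefix = Path(prefix)
    header = {
        "n_subbands": model.n_subbands,
        "n_components": model.n_components,
        "eigenvalues": model.eigenvalues.tolist(),
        "explained_ratio": model.explained_ratio.tolist(),
        "mean_csv": prefix.name + "_mean.csv",
        "loadings_csv": prefix.name + "_loadings.csv",
    }
    prefix.with_suffix(".json").write_text(json.dumps(header, indent=1))
    np.savetxt(prefix.parent / header["mean_csv"], model.mean_spectrum[None, :], delimiter=",")
    np.savetxt(prefix.parent / header["loadings_csv"], model.loadings, delimiter=",")


def load_pca(prefix) -> PCAModel:
    prefix = Path(prefix)
    header = json.loads(prefix.with_suffix(".json").read_text())
    mean = np.loadtxt(prefix.parent / header["mean_csv"], delimiter=",").ravel()
    loadings = np.loadtxt(prefix.parent / header["loadings_csv"], delimiter=",")
    if loadings.ndim == 1:
        loadings = loadings[:, None]
    return PCAModel(mean_spectrum=mean, loadings=loadings,
                    eigenvalues=np.asarray(header["eigenvalues"], float),
                    explained_ratio=np.asarray(header["explained_ratio"], float))
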