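"""One-vs-all open-set ensemble with rejection and kNN adjudication.

For C known compound classes, C binary kernel SVMs are trained, each
recognizing one class against the rest in PCA score space.  At test time
every classifier votes on a sample:

* exactly one positive decision value -> that class;
* no positive decision value -> the sample is rejected into an extra
  "unknown" class (a candidate new compound);
* several positive decisions -> the claim is adjudicated by k-nearest
  neighbours (Euclidean metric in score space) over the training samples
  of the claiming classes only.

The evaluation protocol mirrors an open-set study design: each known
class in turn plays the unknown (leave-one-class-out), the ensemble is
trained once on the rest, and test sets with a growing fraction of
unknown-class samples (0 to 100 % in steps of 10 %) are scored; a
held-out sample counts as correct iff it lands in the unknown class.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features
from .kernel_opt import KernelOptConfig, OptResult, train_kernel_multistart
from .ksvm import BinarySVMModel, KernelParams, decision_values, fit_binary_svm
from .spectra_io import SpectraDataset, compose_test_set, stratified_folds

__all__ = [
    "OpenSetEnsemble",
    "ProtocolConfig",
    "ProtocolResult",
    "train_ensemble",
    "classify_sample",
    "classify_batch",
    "run_protocol",
    "save_ensemble",
    "load_ensemble",
]

logger = logging.getLogger(__name__)


@dataclass
class OpenSetEnsemble:
    """C binary models plus the rejection class and kNN fallback state."""

    models: list[BinarySVMModel]
    pca: features.PCAModel
    class_ids: list[int]
    unknown_class_id: int
    knn_k: int
    train_scores: np.ndarray  # retained for kNN adjudication
    train_labels: np.ndarray
    opt_results: list[OptResult] | None = None

    def __post_init__(self) -> None:
        if len(self.models) != len(self.class_ids):
            raise ValueError("need exactly one binary model per known class")
        if self.knn_k < 1 or self.knn_k % 2 == 0:
            raise ValueError("knn_k must be a positive odd integer")
        if self.unknown_class_id in self.class_ids:
            raise ValueError("unknown_class_id collides with a known class")


@dataclass(frozen=True)
class ProtocolConfig:
    """Study-protocol settings (defaults follow the reference design)."""

    n_components: int = 35
    n_folds: int = 2
    n_starts: int = 30
    n_test: int = 30
    outer_fractions: tuple[float, ...] = tuple(np.round(np.arange(0, 1.01, 0.1), 10))
    knn_k: int = 3
    seed: int = 0
    kernel: KernelParams = field(default_factory=KernelParams)  # GRBF, C_xi = 1
    free_params: tuple[str, ...] = ("sigma2",)
    train_kernel: bool = True  # False = untrained kernel (fixed parameters)


def train_ensemble(train: SpectraDataset, n_components: int = 35,
                   opt_config: KernelOptConfig | None = None,
                   knn_k: int = 3, train_kernel: bool = True,
                   pca_spectra: np.ndarray | None = None) -> OpenSetEnsemble:
    """Fit PCA and one kernel-trained binary SVM per known class.

    Labels are mapped to +1 (the class) / -1 (the rest) per classifier;
    the CV folds used by kernel training are stratified on the original
    multiclass labels, so every fold sees every class.  With
    ``train_kernel=False`` the configured kernel parameters are used as
    is (the non-adaptive baseline).

    ``pca_spectra`` optionally supplies the spectra the PCA is fit on —
    normally all registered spectra, including unlabeled test batches.
    PCA is unsupervised, so this uses no label information; it matters
    for open-set work because a compound absent from the training set
    varies along directions the training spectra alone do not span, and
    a subspace fit without it projects that novelty away.  When omitted,
    the PCA is fit on the training spectra only.
    """
    opt_config = opt_config if opt_config is not None else KernelOptConfig()
    class_ids = [int(c) for c in train.class_ids]
    if len(class_ids) < 2:
        raise ValueError("need at least two known classes")

    pca = features.fit_pca(
        train if pca_spectra is None else np.asarray(pca_spectra, float),
        n_components)
    scores = features.project(pca, train.absorbance)
    folds = stratified_folds(train.labels, opt_config.n_folds, seed=opt_config.seed)

    models: list[BinarySVMModel] = []
    opt_results: list[OptResult] = []
    for cid in class_ids:
        y_pm = np.where(train.labels == cid, 1.0, -1.0)
        params = opt_config.base_params
        if train_kernel:
            try:
                opt = train_kernel_multistart(scores, y_pm, config=opt_config,
                                              folds=folds)
            except Exception as exc:
                raise RuntimeError(
                    f"kernel training failed for class {cid}") from exc
            params = opt.best_params
            opt_results.append(opt)
            logger.info("class %d: CV-MCR %d at sigma2=%.4g",
                        cid, opt.best_cv_mcr, params.sigma2)
        try:
            model = fit_binary_svm(scores, y_pm, params, positive_class=cid,
                                   tol=opt_config.smo_tol,
                                   max_iter=opt_config.smo_max_iter)
        except Exception as exc:
            raise RuntimeError(f"final SVM fit failed for class {cid}") from exc
        models.append(model)

    return OpenSetEnsemble(
        models=models,
        pca=pca,
        class_ids=class_ids,
        unknown_class_id=max(class_ids) + 1,
        knn_k=knn_k,
        train_scores=scores,
        train_labels=train.labels.copy(),
        opt_results=opt_results or None,
    )


def _knn_adjudicate(ensemble: OpenSetEnsemble, z: np.ndarray,
                    claimants: list[int]) -> int:
    """Majority vote among the claiming classes' k nearest training points.

    Vote ties are broken by the smallest mean neighbour distance among
    the tied classes.
    """
    pool = np.isin(ensemble.train_labels, claimants)
    Zp, yp = ensemble.train_scores[pool], ensemble.train_labels[pool]
    d = np.linalg.norm(Zp - z, axis=1)
    k = min(ensemble.knn_k, d.size)
    nn = np.argsort(d, kind="stable")[:k]
    votes = yp[nn]
    counts = {c: int(np.sum(votes == c)) for c in set(votes)}
    top = max(counts.values())
    tied = [c for c, n in counts.items() if n == top]
    if len(tied) == 1:
        return int(tied[0])
    means = {c: float(d[nn][votes == c].mean()) for c in tied}
    return int(min(tied, key=lambda c: (means[c], c)))


def classify_batch(ensemble: OpenSetEnsemble, spectra: np.ndarray) -> np.ndarray:
    """Assign every spectrum a label in {known classes} u {unknown}."""
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    scores = features.project(ensemble.pca, spectra)
    fvals = np.column_stack([decision_values(m, scores) for m in ensemble.models])
    claims = fvals > 0.0
    out = np.empty(scores.shape[0], dtype=int)
    ids = np.asarray(ensemble.class_ids)
    for r in range(scores.shape[0]):
        claimed = ids[claims[r]]
        if claimed.size == 0:
            out[r] = ensemble.unknown_class_id
        elif claimed.size == 1:
            out[r] = claimed[0]
        else:
            out[r] = _knn_adjudicate(ensemble, scores[r], list(claimed))
    return out


def classify_sample(ensemble: OpenSetEnsemble, spectrum: np.ndarray) -> int:
    """Open-set label for one spectrum (see module docstring for the rule)."""
    spectrum = np.asarray(spectrum, dtype=float).ravel()
    return int(classify_batch(ensemble, spectrum[None, :])[0])


@dataclass
class ProtocolResult:
    """Per-(held-out class, outer-fraction) accuracies and the grand mean."""

    held_out_classes: list[int]
    outer_fractions: list[float]
    accuracy: np.ndarray  # (C, F) percentages
    n_correct: np.ndarray  # (C, F)
    n_test: int
    confusion: list[list[dict[int, int]]]  # predicted-label histogram per cell

    @property
    def grand_mean_accuracy(self) -> float:
        return float(self.accuracy.mean())

    @property
    def n_cells(self) -> int:
        return self.accuracy.size

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, cid in enumerate(self.held_out_classes):
            for j, frac in enumerate(self.outer_fractions):
                rows.append({"held_out_class": cid, "outer_fraction": frac,
                             "accuracy_pct": self.accuracy[i, j],
                             "n_correct": int(self.n_correct[i, j]),
                             "n_test": self.n_test})
        return pd.DataFrame(rows)


def evaluate_cell(ensemble: OpenSetEnsemble, test_set: SpectraDataset,
                  held_out_class: int) -> tuple[int, dict[int, int]]:
    """Correct-count and predicted-label histogram for one test set.

    A sample from the held-out class is correct iff it is assigned the
    unknown class; any other sample is correct iff it keeps its label.
    """
    pred = classify_batch(ensemble, test_set.absorbance)
    expected = np.where(test_set.labels == held_out_class,
                        ensemble.unknown_class_id, test_set.labels)
    hist: dict[int, int] = {}
    for p in pred:
        hist[int(p)] = hist.get(int(p), 0) + 1
    return int(np.sum(pred == expected)), hist


def run_protocol(train_pool: SpectraDataset, test_pool: SpectraDataset,
                 config: ProtocolConfig | None = None) -> ProtocolResult:
    """Leave-one-class-out x outer-fraction open-set evaluation.

    ``train_pool`` supplies training spectra; ``test_pool`` supplies all
    test spectra (typically a later-measured batch of the same classes).
    For each held-out class the ensemble is trained once on the remaining
    classes — training is independent of test composition — and scored on
    one composed test set per outer fraction.  Following the original
    measurement-campaign design, the PCA is fit on all registered spectra
    (both pools, labels unused); the SVMs see only training-class scores.
    """
    config = config if config is not None else ProtocolConfig()
    class_ids = [int(c) for c in train_pool.class_ids]
    if len(class_ids) < 3:
        raise ValueError("the protocol needs at least three classes")
    fractions = list(config.outer_fractions)
    pca_reference = np.vstack([train_pool.absorbance, test_pool.absorbance])

    acc = np.zeros((len(class_ids), len(fractions)))
    ncorr = np.zeros_like(acc, dtype=int)
    confusion: list[list[dict[int, int]]] = []

    for i, held_out in enumerate(class_ids):
        opt_config = KernelOptConfig(
            base_params=config.kernel,
            free_params=config.free_params,
            n_folds=config.n_folds,
            n_starts=config.n_starts,
            seed=config.seed + held_out,
        )
        ensemble = train_ensemble(train_pool.without_class(held_out),
                                  n_components=config.n_components,
                                  opt_config=opt_config,
                                  knn_k=config.knn_k,
                                  train_kernel=config.train_kernel,
                                  pca_spectra=pca_reference)
        known_pool = test_pool.without_class(held_out)
        outer_pool = test_pool.only_class(held_out)
        row_conf = []
        for j, frac in enumerate(fractions):
            cell = compose_test_set(known_pool, outer_pool, config.n_test, frac,
                                    seed=config.seed + 1000 * held_out + j)
            good, hist = evaluate_cell(ensemble, cell, held_out)
            ncorr[i, j] = good
            acc[i, j] = 100.0 * good / config.n_test
            row_conf.append(hist)
            logger.info("held-out %d, fraction %.1f: %.2f%%", held_out, frac, acc[i, j])
        confusion.append(row_conf)

    return ProtocolResult(held_out_classes=class_ids, outer_fractions=fractions,
                          accuracy=acc, n_correct=ncorr, n_test=config.n_test,
                          confusion=confusion)


# --------------------------------------------------------------------------
# serialization (single JSON document: kernel params, biases, PCA, SVs)

def save_ensemble(ensemble: OpenSetEnsemble, path) -> None:
    doc = {
        "class_ids": ensemble.class_ids,
        "unknown_class_id": ensemble.unknown_class_id,
        "knn_k": ensemble.knn_k,
        "pca": {
            "mean_spectrum": ensemble.pca.mean_spectrum.tolist(),
            "loadings": ensemble.pca.loadings.tolist(),
            "eigenvalues": ensemble.pca.eigenvalues.tolist(),
            "explained_ratio": ensemble.pca.explained_ratio.tolist(),
        },
        "train_scores": ensemble.train_scores.tolist(),
        "train_labels": ensemble.train_labels.tolist(),
        "models": [
            {
                "positive_class": m.positive_class,
                "bias": m.bias,
                "dual_coeffs": m.dual_coeffs.tolist(),
                "support_vectors": m.support_vectors.tolist(),
                "kernel": {k: getattr(m.kernel, k) for k in
                           ("family", "degree", "beta0", "beta1", "sigma2", "c_xi")},
            }
            for m in ensemble.models
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_ensemble(path) -> OpenSetEnsemble:
    doc = json.loads(Path(path).read_text())
    pca = features.PCAModel(
        mean_spectrum=np.asarray(doc["pca"]["mean_spectrum"], float),
        loadings=np.asarray(doc["pca"]["loadings"], float),
        eigenvalues=np.asarray(doc["pca"]["eigenvalues"], float),
        explained_ratio=np.asarray(doc["pca"]["explained_ratio"], float),
    )
    models = [
        BinarySVMModel(
            support_vectors=np.asarray(m["support_vectors"], float),
            dual_coeffs=np.asarray(m["dual_coeffs"], float),
            bias=float(m["bias"]),
            kernel=KernelParams(**m["kernel"]),
            positive_class=int(m["positive_class"]),
        )
        for m in doc["models"]
    ]
    return OpenSetEnsemble(
        models=models,
        pca=pca,
        class_ids=[int(c) for c in doc["class_ids"]],
        unknown_class_id=int(doc["unknown_class_id"]),
        knn_k=int(doc["knn_k"]),
        train_scores=np.asarray(doc["train_scores"], float),
        train_labels=np.asarray(doc["train_labels"], int),
    )
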