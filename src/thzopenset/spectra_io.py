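"""Spectral dataset container, CSV I/O, CV folds and test-set composition.

The on-disk format is deliberately plain: a spectra CSV whose first column
is the wavenumber grid (``wavenumber_cm-1``) and whose remaining columns
are one sample each, plus an optional labels CSV (``sample_id,class_label``).
Comma separator, '.' decimal, UTF-8, mandatory header.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpectraDataset",
    "FoldAssignment",
    "read_spectra",
    "write_spectra",
    "stratified_folds",
    "compose_test_set",
]

WAVENUMBER_COLUMN = "wavenumber_cm-1"


@dataclass
class SpectraDataset:
    """Sample x subband absorbance matrix with labels.

    ``labels`` are integer class ids; 0 marks an unlabeled sample.
    """

    wavenumbers: np.ndarray  # (I,), strictly increasing, cm^-1
    absorbance: np.ndarray  # (N, I)
    labels: np.ndarray  # (N,) ints, 0 = unlabeled
    class_names: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)
        if self.wavenumbers.ndim != 1:
            raise ValueError("wavenumbers must be 1-D")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if self.absorbance.shape != (self.labels.size, self.wavenumbers.size):
            raise ValueError(
                f"absorbance shape {self.absorbance.shape} does not match "
                f"{self.labels.size} samples x {self.wavenumbers.size} subbands"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")
        if np.any(self.labels < 0):
            raise ValueError("labels must be >= 0 (0 = unlabeled)")
        if not self.sample_ids:
            self.sample_ids = [f"s{k:04d}" for k in range(self.labels.size)]
        if len(self.sample_ids) != self.labels.size:
            raise ValueError("sample_ids length must match number of samples")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicated sample ids")

    @property
    def n_samples(self) -> int:
        return self.labels.size

    @property
    def n_subbands(self) -> int:
        return self.wavenumbers.size

    @property
    def class_ids(self) -> np.ndarray:
        """Sorted distinct labels, excluding the unlabeled marker 0."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def subset(self, mask_or_index: np.ndarray) -> "SpectraDataset":
        """Row subset (boolean mask or integer index), preserving order."""
        idx = np.arange(self.n_samples)[mask_or_index] \
            if np.asarray(mask_or_index).dtype == bool else np.asarray(mask_or_index)
        return SpectraDataset(
            wavenumbers=self.wavenumbers,
            absorbance=self.absorbance[idx],
            labels=self.labels[idx],
            class_names=list(self.class_names),
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    def without_class(self, class_id: int) -> "SpectraDataset":
        return self.subset(np.flatnonzero(self.labels != class_id))

    def only_class(self, class_id: int) -> "SpectraDataset":
        return self.subset(np.flatnonzero(self.labels == class_id))


@dataclass(frozen=True)
class FoldAssignment:
    """Per-sample fold indices in 1..n_folds, balanced within each class."""

    fold_index: np.ndarray  # (N,) ints in [1, n_folds]
    n_folds: int

    def __post_init__(self) -> None:
        idx = np.asarray(self.fold_index, dtype=int)
        if idx.min(initial=1) < 1 or idx.max(initial=self.n_folds) > self.n_folds:
            raise ValueError("fold indices must lie in [1, n_folds]")
        object.__setattr__(self, "fold_index", idx)

    def split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_idx, validation_idx) for one fold."""
        val = np.flatnonzero(self.fold_index == fold)
        train = np.flatnonzero(self.fold_index != fold)
        return train, val

    def to_frame(self, sample_ids: list[str]) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": sample_ids, "fold": self.fold_index})


def write_spectra(dataset: SpectraDataset, spectra_path, labels_path=None) -> None:
    """Write a dataset to the spectra/labels CSV pair."""
    df = pd.DataFrame(dataset.absorbance.T, columns=dataset.sample_ids)
    df.insert(0, WAVENUMBER_COLUMN, dataset.wavenumbers)
    df.to_csv(spectra_path, index=False)
    if labels_path is not None:
        pd.DataFrame({"sample_id": dataset.sample_ids,
                      "class_label": dataset.labels}).to_csv(labels_path, index=False)


def read_spectra(spectra_path, labels_path=None) -> SpectraDataset:
    """Read a spectra CSV (and optional labels CSV) into a dataset.

    Samples missing from the labels file — or all samples when no labels
    file is given — get label 0 (unlabeled).  Parse problems raise
    ``ValueError`` naming the offending row or cell.
    """
    spectra_path = Path(spectra_path)
    with open(spectra_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(",")
    raw_ids = header[1:]
    if len(set(raw_ids)) != len(raw_ids):  # pandas would silently mangle these
        dupes = sorted({s for s in raw_ids if raw_ids.count(s) > 1})
        raise ValueError(f"{spectra_path}: duplicated sample ids {dupes}")
    try:
        df = pd.read_csv(spectra_path, header=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{spectra_path}: malformed CSV ({exc})") from exc
    if df.shape[1] < 2:
        raise ValueError(f"{spectra_path}: need a wavenumber column plus >=1 sample column")
    if df.columns[0] != WAVENUMBER_COLUMN:
        raise ValueError(
            f"{spectra_path}: first column must be {WAVENUMBER_COLUMN!r}, got {df.columns[0]!r}"
        )
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if df[col].isna().any() or bad.any():
            row = int((df[col].isna() | bad).idxmax())
            raise ValueError(
                f"{spectra_path}: non-numeric or missing value in column {col!r}, "
                f"data row {row} (0-based, excluding header)"
            )
        df[col] = coerced
    sample_ids = [str(c) for c in df.columns[1:]]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"{spectra_path}: duplicated sample ids {dupes}")

    labels = np.zeros(len(sample_ids), dtype=int)
    if labels_path is not None:
        ldf = pd.read_csv(labels_path, header=0)
        if not {"sample_id", "class_label"} <= set(ldf.columns):
            raise ValueError(f"{labels_path}: need columns sample_id,class_label")
        if ldf["sample_id"].duplicated().any():
            dupes = ldf.loc[ldf["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"{labels_path}: duplicated sample ids {dupes}")
        mapping = dict(zip(ldf["sample_id"].astype(str), ldf["class_label"].astype(int)))
        labels = np.array([mapping.get(s, 0) for s in sample_ids], dtype=int)

    return SpectraDataset(
        wavenumbers=df.iloc[:, 0].to_numpy(),
        absorbance=df.iloc[:, 1:].to_numpy().T,
        labels=labels,
        sample_ids=sample_ids,
    )


def stratified_folds(labels: np.ndarray, n_folds: int, seed: int = 0) -> FoldAssignment:
    """Seeded n-fold partition balanced separately within each class.

    Every class is shuffled and dealt round-robin across folds, so within
    each class the fold sizes differ by at most one.
    """
    labels = np.asarray(labels, dtype=int)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF01D]))
    fold_index = np.zeros(labels.size, dtype=int)
    for cid in np.unique(labels):
        members = np.flatnonzero(labels == cid)
        if members.size < n_folds:
            raise ValueError(
                f"class {cid} has only {members.size} samples; needs >= {n_folds} for {n_folds}-fold CV"
            )
        perm = rng.permutation(members)
        fold_index[perm] = np.arange(perm.size) % n_folds + 1
    return FoldAssignment(fold_index=fold_index, n_folds=n_folds)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def compose_test_set(known_pool: SpectraDataset, outer_pool: SpectraDataset,
                     n_test: int, outer_fraction: float, seed: int = 0) -> SpectraDataset:
    """Compose a mixed test set of known-class and outer-class samples.

    ``round(outer_fraction * n_test)`` samples (round half away from zero)
    are drawn without replacement from the outer pool; the remainder comes
    from the known pool with classes cycled in label order for balance,
    then the whole set is shuffled.  Drawn samples keep their original
    labels, so callers can score rejection of the outer class.
    """
    if not 0.0 <= outer_fraction <= 1.0:
        raise ValueError("outer_fraction must be in [0, 1]")
    if n_test < 1:
        raise ValueError("n_test must be >= 1")
    n_outer = _round_half_away(outer_fraction * n_test)
    n_known = n_test - n_outer
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7E57]))

    if n_outer > outer_pool.n_samples:
        raise ValueError(
            f"outer pool has {outer_pool.n_samples} samples, {n_outer} requested"
        )
    rows_outer = rng.choice(outer_pool.n_samples, size=n_outer, replace=False)

    rows_known = np.empty(0, dtype=int)
    if n_known > 0:
        class_ids = known_pool.class_ids
        if class_ids.size == 0:
            raise ValueError("known pool has no labelled samples")
        # cycle classes in label order, then draw per-class without replacement
        wanted = class_ids[np.arange(n_known) % class_ids.size]
        picks = []
        for cid in class_ids:
            need = int(np.sum(wanted == cid))
            members = np.flatnonzero(known_pool.labels == cid)
            if need > members.size:
                raise ValueError(
                    f"known pool class {cid} has {members.size} samples, {need} requested"
                )
            picks.append(rng.choice(members, size=need, replace=False))
        rows_known = np.concatenate(picks) if picks else rows_known

    known = known_pool.subset(rows_known) if n_known else None
    outer = outer_pool.subset(rows_outer) if n_outer else None

    if known is None:
        combined = outer
    elif outer is None:
        combined = known
    else:
        combined = SpectraDataset(
            wavenumbers=known.wavenumbers,
            absorbance=np.vstack([known.absorbance, outer.absorbance]),
            labels=np.concatenate([known.labels, outer.labels]),
            class_names=list(known_pool.class_names),
            sample_ids=known.sample_ids + outer.sample_ids,
        )
    order = rng.permutation(combined.n_samples)
    return combined.subset(order)
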