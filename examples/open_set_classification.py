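"""Open-set recognition: known compounds identified, unknown rejected.

Twelve of the thirteen compounds are used for training; the thirteenth
plays a never-seen drug candidate.  Each test spectrum is voted on by
all twelve one-vs-rest classifiers: one positive vote names the class,
no positive vote rejects the sample into the extra "unknown" class, and
multiple votes are adjudicated by kNN among the claimants.
"""

import numpy as np

import thzopenset as tzo
from thzopenset.kernel_opt import KernelOptConfig

HELD_OUT = 13

train_pool = tzo.generate_dataset(13, 30, 1194, seed=42)
test_pool = tzo.generate_dataset(13, 30, 1194, seed=42,
                                 noise=tzo.NoiseConfig(seed=1042),
                                 measured_later=True)

ensemble = tzo.train_ensemble(
    train_pool.without_class(HELD_OUT), n_components=35,
    opt_config=KernelOptConfig(n_folds=2, n_starts=30, seed=0),
    pca_spectra=np.vstack([train_pool.absorbance, test_pool.absorbance]))
print(f"trained {len(ensemble.models)} one-vs-rest classifiers; "
      f"unknown-class id = {ensemble.unknown_class_id}")

known = test_pool.without_class(HELD_OUT)
pred_known = tzo.classify_batch(ensemble, known.absorbance)
acc = 100.0 * np.mean(pred_known == known.labels)
print(f"known compounds (later batch): {acc:.1f}% correctly identified "
      f"({known.n_samples} spectra)")

outer = test_pool.only_class(HELD_OUT)
pred_outer = tzo.classify_batch(ensemble, outer.absorbance)
rej = 100.0 * np.mean(pred_outer == ensemble.unknown_class_id)
print(f"held-out compound: {rej:.1f}% rejected into the unknown class "
      f"({outer.n_samples} spectra) - candidates for a new structure")
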