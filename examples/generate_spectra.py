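"""Generate a synthetic THz absorbance dataset and inspect its structure.

Each compound class is a fixed fingerprint of Lorentzian absorption peaks
on a rising baseline; replicate spectra add peak jitter, detector noise
and per-sample baseline drift.  A "later-measured" batch of the same
compounds carries an extra fixed drift, emulating spectra recorded days
after the training measurements.
"""

import numpy as np

import thzopenset as tzo
from thzopenset.synthdata import make_class_template

dataset = tzo.generate_dataset(n_classes=13, n_per_class=30, n_subbands=1194,
                               seed=42)
print(f"dataset: {dataset.n_samples} spectra x {dataset.n_subbands} subbands, "
      f"{dataset.class_ids.size} classes, "
      f"{dataset.wavenumbers[0]:.0f}-{dataset.wavenumbers[-1]:.0f} cm^-1")

tpl = make_class_template(1, seed=42)
print(f"class 1 fingerprint: peaks at "
      f"{np.round(tpl.peak_centers, 1)} cm^-1, "
      f"amplitudes {np.round(tpl.peak_amplitudes, 2)} a.u.")

late = tzo.generate_dataset(13, 30, 1194, seed=42,
                            noise=tzo.NoiseConfig(seed=1042),
                            measured_later=True)
shift = late.absorbance[:, -1].mean() - dataset.absorbance[:, -1].mean()
print(f"later batch baseline shift at 70 cm^-1: {shift:+.4f} a.u. "
      "(long-term drift between measurement campaigns)")

# classes are separable in raw spectral space: replicates of one compound
# lie closer together than spectra of different compounds
X, y = dataset.absorbance, dataset.labels
d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
same = (y[:, None] == y[None, :]) & ~np.eye(y.size, dtype=bool)
print(f"mean within-class distance {d[same].mean():.2f} vs "
      f"between-class {d[y[:, None] != y[None, :]].mean():.2f} (a.u.)")
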