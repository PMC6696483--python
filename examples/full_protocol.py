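"""Scaled-down leave-one-class-out x outer-fraction evaluation protocol.

Every class takes a turn as the unknown; for each hold-out the ensemble
is trained once and scored on 11 test sets whose unknown-compound share
grows from 0 to 100 % in steps of 10 %.  (The full study conditions —
13 classes x 30 spectra x 1194 subbands — run in a couple of minutes;
this example uses 6 classes x 12 spectra x 400 subbands for speed.)
"""

import thzopenset as tzo
from thzopenset.openset import ProtocolConfig

train_pool = tzo.generate_dataset(6, 12, 400, seed=42)
test_pool = tzo.generate_dataset(6, 12, 400, seed=42,
                                 noise=tzo.NoiseConfig(seed=1042),
                                 measured_later=True)

config = ProtocolConfig(n_components=12, n_folds=2, n_starts=15,
                        n_test=12, seed=0)
result = tzo.run_protocol(train_pool, test_pool, config)

print(f"{len(result.held_out_classes)} hold-outs x "
      f"{len(result.outer_fractions)} outer fractions = "
      f"{result.n_cells} cells, {result.n_test} test spectra each")
print("accuracy (%) per cell, rows = held-out class, cols = outer fraction:")
for cid, row in zip(result.held_out_classes, result.accuracy):
    print(f"  class {cid}: " + " ".join(f"{a:5.1f}" for a in row))
print(f"grand mean accuracy: {result.grand_mean_accuracy:.2f}%")
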