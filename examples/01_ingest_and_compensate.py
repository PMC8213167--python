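"""Write a synthetic FCS file, read it back and compensate at entry.

Spillover mixing leaks a fraction of each fluorochrome's signal into
neighbouring detectors; multiplying by the inverse spillover matrix undoes
it. The printed residual shows compensation recovering the pre-mixing signal.
"""
import tempfile
from pathlib import Path

import numpy as np

import autocyto as ac

rng = np.random.default_rng(0)
true_signal = ac.EventMatrix(rng.normal(3, 1, (2000, 3)),
                             ["FL1", "FL2", "FL3"], ["CD3", "CD4", "CD8"])
spill = ac.SpilloverMatrix(["FL1", "FL2", "FL3"],
                           [[1.00, 0.08, 0.00],
                            [0.03, 1.00, 0.05],
                            [0.00, 0.04, 1.00]])
observed = ac.decompensate(true_signal, spill)  # apply spillover mixing

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "sample.fcs"
    ac.write_fcs(observed, path, spillover=spill)
    matrix, embedded, meta = ac.read_fcs(path)

compensated = ac.compensate(matrix, embedded)
residual = np.abs(compensated.values - true_signal.values).max()

print(f"read {matrix.n_events} events x {len(matrix.channel_names)} channels "
      f"({meta['version']}, {meta['n_dropped']} dropped)")
print(f"embedded spillover FL1->FL2: {embedded.S[0, 1]:.3f}")
print(f"max |compensated - true| = {residual:.2e}")
print("A residual at float32 precision means compensation exactly inverted "
      "the spillover mixing.")
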