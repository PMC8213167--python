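"""Quantify batch effect with LISI and correct it through a plugin.

LISI (local inverse Simpson's index) is the effective number of batches in
each event's k-nearest neighbourhood: about 1 when batches are segregated,
about B when B batches are well mixed. The reference sample is the one whose
channel covariance is closest (Frobenius) to every other sample's.
"""
import numpy as np

import autocyto as ac

rng = np.random.default_rng(5)
batches = {
    "run1": rng.normal(0, 1, (600, 3)),
    "run2": rng.normal(0, 1, (600, 3)) + [3.0, 0, 0],   # location-shifted
    "run3": rng.normal(0, 1, (600, 3)) + [0, 3.0, 0],
}

assess = ac.select_reference(batches)
print(f"reference sample (closest covariance to all): "
      f"{assess.reference_sample_id}")

result = ac.correct_batches(batches, "mean_center")
before = np.median(ac.lisi(result.prepared, result.batch_labels, k=60))
after = np.median(ac.lisi(result.corrected, result.batch_labels, k=60))
print(f"corrector params: sigma={result.params['sigma']}, "
      f"max_iter={result.params['max_iter']}")
print(f"median LISI before correction: {before:.2f}  (1.0 = segregated)")
print(f"median LISI after correction:  {after:.2f}  (3.0 = fully mixed)")
print("Mean-centring removes the location shift between runs, so each "
      "event's neighbourhood now samples all three batches.")
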