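"""Autonomous gating of a synthetic cohort with ground-truth scoring.

A three-gate threshold strategy is defined on the first sample and applied
to the rest with exhaustive hyperparameter search and landmark registration.
The Pearson r compares the recovered per-sample population fractions with
the generator's ground truth — the cohort-scale analogue of comparing
autonomous gates to expert manual gates.
"""
import autocyto as ac
from autocyto.pipeline import gate_cohort_recovery

spec = ac.flagship_cohort(seed=7, events_per_sample=3000)
samples = ac.generate_cohort(spec)
project, recovery, r = gate_cohort_recovery(samples, spec, search=True,
                                            register=True, seed=7)

print(recovery.head(10).to_string(index=False))
print(f"\nPearson r (true vs recovered fractions, "
      f"{recovery.shape[0]} sample-population pairs): {r:.4f}")
worst = (recovery.true_fraction - recovery.recovered_fraction).abs().max()
print(f"worst absolute fraction error: {worst * 100:.2f} percentage points")
print("r close to 1 means the refitted density thresholds track each "
      "sample's batch-shifted populations, including the 1% rare subset.")
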