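"""Median-beat extraction from a noisy raw ECG.

Simulates one 15 s, 8-lead recording with sensor noise, baseline wander and
20% corrupted beats, runs the signal-averaging pipeline, and compares the
extracted beat with the noiseless ground truth.
"""

import numpy as np

from ecglvh import SyntheticCohortConfig, extract_median_beat, iter_cohort
from ecglvh.cohort import expected_beat_window

cfg = SyntheticCohortConfig(n_participants=1, seed=4)
participant = next(iter_cohort(cfg))

beat = extract_median_beat(participant.raw_ecg)
print(f"beats detected:  {beat.n_beats_detected}")
print(f"beats retained:  {beat.n_beats_retained} "
      f"({len(participant.corrupt_beat_indices)} corrupted beats were simulated)")
print(f"mean R-R:        {beat.mean_rr_ms:.0f} ms "
      f"-> ventricular rate {beat.ventricular_rate_bpm:.1f} bpm "
      f"(simulated {participant.true_heart_rate_bpm:.1f} bpm)")

rr_s = np.mean(np.diff(participant.true_r_peaks)) / cfg.sampling_rate_hz
truth = expected_beat_window(participant.true_template, 60.0 / rr_s, cfg)
corr = min(np.corrcoef(beat.waveforms[li], truth[li])[0, 1] for li in range(8))
print(f"worst per-lead correlation with the noiseless beat window: {corr:.4f} "
      "- the averaged beat is essentially noise-free")
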