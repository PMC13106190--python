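"""Denoise a noisy recording, segment it, and detect movement peaks.

Builds one score-1 finger-tapping recording, runs the db4 denoising +
segmentation + AMPD peak-detection chain, and compares detected peaks with
the simulator's ground truth.
"""

import numpy as np

from bradykin import (DEFAULT_PROFILES, detect_movement_peaks,
                      generate_linear_task_signal, preprocess_recording)

rec = generate_linear_task_signal(DEFAULT_PROFILES[1], duration=12.0, fs=80.0,
                                  seed=4, opening_ratio=0.25)
segments = preprocess_recording(rec)
print(f"recording: {rec.duration:.0f} s at {rec.fs:.0f} Hz "
      f"-> {len(segments)} windows of 4 s (50% overlap)")

hits = total_det = total_truth = 0
for seg in segments:
    peaks = detect_movement_peaks(seg)
    truth = seg.ground_truth_peaks
    matched = sum(1 for i in peaks.indices if np.any(np.abs(truth - i) <= 3))
    hits += matched
    total_det += len(peaks)
    total_truth += len(truth)
    removed = {v: list(peaks.provenance.values()).count(v)
               for v in ("boundary", "low_amplitude", "flat")}
    print(f"  window {seg.window_index}: {len(peaks)} retained "
          f"({matched} within 3 samples of truth), removed {removed}")

print(f"\nprecision {hits / total_det:.3f}, recall {hits / total_truth:.3f}")
# Retained peaks are the movement onsets; the filter provenance shows why each
# rejected AMPD candidate (opening peaks, noise blips) was discarded.
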