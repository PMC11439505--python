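"""Build the day-(N+1) prediction task for one participant.

Shows the FFT-based window-size selection (the prescribed weekly schedule
yields a dominant 7-day period), the 30/30 chronological split, and the
resulting labeled sliding windows.
"""

import numpy as np

import adherence_da as ad

log = ad.generate_participant("consistent_with_lapses", n_days=60, seed=4)

N = ad.select_window_size(log.durations()[:30])
print(f"dominant cyclic period of the training series: N = {N} days")

train, test, scaler = ad.participant_windows(log, N)
print(f"train windows: {len(train)} (days 1-30), test windows: {len(test)} (days 31-60)")
print(f"window shape: {train.X.shape[1:]} = (N days x 4 play variables)")
print(f"train adherence base rate: {train.y.mean():.2f}")

# each window k spans days k+1..k+N and predicts day k+N+1's adherence;
# features are z-scored with statistics from the training days only.
print("first window, duration feature (z-scored):", np.round(train.X[0, :, 0], 2))
print("label for day", N + 1, "=>", int(train.y[0]))
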