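"""Detect theta bursts with the dual-amplitude-threshold algorithm and
score them against ground truth.

A burst is a maximal interval where the median-normalised theta envelope
stays above the low threshold and reaches the high threshold at least once;
boundaries are refined by deconvolving the detection filter's width from
the envelope's full width at half maximum.
"""

import numpy as np

from thetaburst import SessionParams, detect_bursts, filter_min_duration, generate_lfp_session
from thetaburst.bursts import match_events
from thetaburst.spectral import THETA

params = SessionParams(
    duration_s=300.0,
    regions=("CA1",),
    burst_rate_per_min={"CA1": 6.0},
    coupling_probability=0.0,
    seed=11,
)
rec, truth = generate_lfp_session(params)

events = detect_bursts(rec.signals["CA1"], rec.fs, THETA, region="CA1")
events = filter_min_duration(events, min_duration_s=0.2)  # the >=200 ms theta rule
matched, n_det, n_true = match_events(events, truth.true_bursts["CA1"])

print(f"injected bursts: {n_true}, detected: {n_det}")
print(f"recall = {matched / n_true:.2f}, precision = {matched / n_det:.2f}")
durs = [e.duration_s for e in events]
print(f"detected durations: mean {np.mean(durs):.3f} s, range {min(durs):.3f}-{max(durs):.3f} s")

# Recall and precision near 1 at the default SNR mean the detector recovers
# exactly the injected events; the duration distribution feeds the
# condition comparisons (KS test) and the classifier.
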