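"""MS->CA1 burst pairing, phase locking, and envelope-lag directionality.

Pairs each MS theta burst with the next CA1 burst (within 1 s of the MS
burst's completion), computes session and peri-burst phase-locking values,
and estimates the MS->CA1 lag from amplitude-envelope cross-correlation.
"""

import numpy as np

from thetaburst import (
    SessionParams,
    classify_coupled,
    detect_bursts,
    envelope_lag,
    filter_min_duration,
    generate_lfp_session,
    pair_bursts,
    periburst_plv,
    session_plv,
)
from thetaburst.spectral import THETA, analytic, bandpass, event_bandpass

params = SessionParams(duration_s=600.0, regions=("MS", "CA1"), coupling_probability=0.9, seed=8)
rec, truth = generate_lfp_session(params)

ms = filter_min_duration(detect_bursts(rec.signals["MS"], rec.fs, THETA, region="MS"), min_duration_s=0.2)
ca1 = filter_min_duration(detect_bursts(rec.signals["CA1"], rec.fs, THETA, region="CA1"), min_duration_s=0.2)
pairs = pair_bursts(ms, ca1, max_delay_s=1.0)
coupled = classify_coupled(ca1, ms, window_s=0.4)
print(f"MS bursts: {len(ms)}, CA1 bursts: {len(ca1)}, pairs: {len(pairs)} "
      f"(true coupled pairs injected: {len(truth.true_pairs)})")
print(f"CA1 bursts coupled within 400 ms: {int(np.sum(coupled))}")
print(f"mean recovered delay: {np.mean([p.delay_s for p in pairs]) * 1000:.0f} ms")

# instantaneous phase at event scale (3-cycle kernel); envelopes from the
# narrow-transition filter
_, ph_ms = analytic(event_bandpass(rec.signals["MS"], rec.fs, THETA))
_, ph_ca1 = analytic(event_bandpass(rec.signals["CA1"], rec.fs, THETA))
plv_res = session_plv(ph_ms, ph_ca1, rec.fs, window_s=8.0)
peri = periburst_plv(pairs, ph_ms, ph_ca1, rec.fs)
print(f"session PLV (8-s windows): {plv_res.session_plv:.3f}")
print(f"peri-burst PLV: pre = {np.mean([d['pre'] for d in peri]):.3f}, "
      f"post = {np.mean([d['post'] for d in peri]):.3f}")

env_ms, _ = analytic(bandpass(rec.signals["MS"], rec.fs, THETA))
env_ca1, _ = analytic(bandpass(rec.signals["CA1"], rec.fs, THETA))
lag = envelope_lag(env_ms, env_ca1, rec.fs, max_lag_s=1.0)
print(f"median envelope lag: {lag.median_lag_s * 1000:.0f} ms (positive = MS leads), "
      f"|lag| SD: {lag.abs_lag_sd_s * 1000:.0f} ms")

# Post-burst PLV exceeding pre-burst PLV reflects the transient
# interregional synchrony that follows coupled burst events; a positive
# median lag is consistent with MS->CA1 directionality.
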