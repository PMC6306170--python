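"""Detect 10-14 Hz bursts and estimate the inter-areal propagation delay.

The generator injects sporadic sigma-band bursts common to CA1 and PFC
with the PFC copy delayed 35 ms. Differential recordings recover the
delay event by event; referential recordings are dominated by the
zero-lag volume-conducted common source and lose it.
"""

import numpy as np

from lfpvc import detect_bursts, lag_distribution, match_events, simulate_session

session = simulate_session({"Wake": 4, "NREM": 10, "REM": 12}, seed=3)
mask = session.hypnogram.state_mask("REM", session.fs, session.n_samples)
events = detect_bursts(session.dr("CA1"), session.fs, mask=mask, channel="CA1_DR")
sens, prec, _ = match_events(events, session.common_bursts())
print(f"detected {len(events)} bursts "
      f"(sensitivity {sens:.2f}, precision {prec:.2f} vs ground truth)")

for mode in ("DR", "RR"):
    dist = lag_distribution(session, events, mode=mode)
    print(f"{mode}: median peak lag {dist.median * 1e3:6.1f} ms, "
          f"IQR {dist.iqr * 1e3:6.1f} ms, "
          f"mean peak correlation {np.mean(dist.correlations):.2f}")
print("positive lag = PFC lags CA1; the DR median recovers the injected "
      "35 ms delay while the RR distribution is broad around zero.")
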