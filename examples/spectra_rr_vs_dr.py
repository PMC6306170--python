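"""State-averaged power spectra of the two recording modes.

The referential (RR) channel inherits the strong distal common source
through volume conduction, so it carries roughly an order of magnitude
more power than the differential (DR) channel of the same electrode pair.
"""

from lfpvc import simulate_session, state_spectrum

session = simulate_session({"Wake": 4, "NREM": 12, "REM": 10}, seed=2)
for mode in ("RR", "DR"):
    ps = state_spectrum(session, "REM", "CA1", mode)
    total = ps.total_power(0.5, 100.0)
    peak = ps.peak_frequency(2.0, 20.0)
    print(f"CA1 {mode} during REM: total power {total:9.1f} uV^2, "
          f"spectral peak at {peak:.2f} Hz")

rr = state_spectrum(session, "REM", "CA1", "RR").total_power(0.5, 100)
dr = state_spectrum(session, "REM", "CA1", "DR").total_power(0.5, 100)
print(f"RR/DR power ratio: {rr / dr:.1f} (the ~10x scale factor between "
      "monopolar and bipolar recordings)")
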