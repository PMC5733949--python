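"""Audit stimulus timing on synthetic audio-loopback sessions.

Each session injects a square-wave burst a known lag after every event
marker (lag ~ Normal(12.67 ms, 2.87 ms), floor-quantized to the 4 ms
sample grid).  The audit recovers per-trial latencies by the half-maximum
rule and summarises lag (mean/median) and jitter (SD); repeated sessions
are then compared, since across-session lag drift is the quantity that
actually threatens event-locked analyses.
"""

from attnbci import gen_timing_fixture, measure_latencies, session_compare

reports = []
for session_seed in range(3):
    rec, markers, truth = gen_timing_fixture(
        lag_mean=0.01267, jitter_sd=0.00287, n_trials=200, seed=session_seed)
    report = measure_latencies(rec, markers)
    reports.append(report)
    print(f"session {session_seed}: lag median {1e3 * report.lag_median:5.2f} ms, "
          f"mean {1e3 * report.lag_mean:5.2f} ms, "
          f"jitter {1e3 * report.jitter_sd:4.2f} ms, "
          f"outliers {len(report.outlier_indices)}, "
          f"resolution {1e3 * report.sample_period:.0f} ms")

cmp = session_compare(reports)
print(f"across sessions: median spread {1e3 * cmp.spread:.2f} ms, "
      f"negative-lag sessions {cmp.negative_lag_sessions}")

# Lag is recovered within one sample period (the 4 ms resolution floor at
# 250 Hz) and jitter within a few tenths of a millisecond of the injected
# value; the spread line shows how stable the lag is across sessions.
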