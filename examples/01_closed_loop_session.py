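"""Run one simulated closed-loop attention-decoding session.

A training block (40 trials, 20 per attended side) builds the left/right
templates; a feedback block (120 trials) is then classified trial by
trial, exactly as an online system would deliver feedback.  The session
accuracy is judged against the exact binomial chance level for 120
two-class trials.
"""

from attnbci import RunConfig, run_closed_loop

config = RunConfig(seed=1, noise_sd=4.0, mode="batch")
report = run_closed_loop(config)

print(f"feedback trials : {len(report.true_labels)}")
print(f"correct         : {report.n_correct}")
print(f"accuracy        : {100 * report.accuracy:.1f} %")
print(f"chance level    : {report.chance.threshold_percent:.1f} % "
      f"(n={report.chance.n}, alpha={report.chance.alpha})")
print(f"above chance    : {report.above_chance}")

# The chance level is the smallest accuracy that beats random guessing at
# alpha = .05: any session at or above it carries statistically meaningful
# attention information.
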