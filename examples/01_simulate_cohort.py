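"""Generate a calibrated synthetic training cohort and summarize it.

Builds 130 virtual participants with MCI-trial-like demographics, simulates
24 weeks of adaptive game-based training (~390 reaction-time/accuracy pairs
per participant with a planted per-person RT-accuracy coupling), and prints
the baseline demographics table.
"""

from rtacc import CohortConfig, summarize_cohort
from rtacc.simulate import generate_cohort_frames

config = CohortConfig(seed=1)
participants, log = generate_cohort_frames(config)

print(f"participants: {len(participants)}")
print(f"task records: {len(log)} "
      f"(~{len(log) / len(participants):.0f} pairs per participant)")
print()
print(summarize_cohort(participants).to_string(index=False))
print()
print("Continuous rows show mean with SD, binary rows show n with percent;")
print("the RBANS change row is the planted week-24 cognitive improvement.")
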