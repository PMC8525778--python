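"""Probe the reservoir's distribution of intrinsic time constants.

Drives the model with zero input, then a constant vector, then zero
again, and measures how many steps each unit needs to halve its distance
to the new asymptote after each transition.
"""

import numpy as np

from reservoir_events import init_reservoir, step_response, time_to_stabilize

params = init_reservoir(N=500, K=100, alpha=0.05, seed=1)
traj = step_response(params, pre_len=500, hold_len=400, post_len=600,
                     hold_value=0.2)

for name, transition, window in (("onset (0 -> c)", 500, 400),
                                 ("offset (c -> 0)", 900, 600)):
    res = time_to_stabilize(traj, transition, window)
    t = res.times[res.defined()]
    print(f"{name}: median {np.median(t):.0f} steps, "
          f"IQR {np.percentile(t, 25):.0f}-{np.percentile(t, 75):.0f}, "
          f"range {t.min():.0f}-{t.max():.0f} "
          f"({res.censored.sum()} censored, {res.undefined.sum()} undefined)")

print()
print("All units share the same leak rate (0.05), yet the recurrent")
print("connections give them a broad spread of effective time constants.")
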