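"""The construction/forgetting asymmetry on intact vs scrambled input.

Two identical reservoir copies hear ABCD and ACBD versions of a Gaussian
stream.  Their state difference is zero while inputs agree, jumps within
a couple of steps when the inputs diverge (forgetting), and decays over
tens of steps once they re-align (construction).
"""

import numpy as np

from reservoir_events import (
    construct_forget_independence,
    diff_trajectory,
    gaussian_abcd_pair,
    init_reservoir,
    run_paired,
    time_constants,
)

pair = gaussian_abcd_pair(len_a=100, len_bc=200, len_d=100, D=100, seed=0)
params = init_reservoir(N=1000, K=100, alpha=0.05, seed=0)
run = run_paired(params, pair)
diff = diff_trajectory(run)
tab = time_constants(run)

print(f"max |difference| before divergence : {np.abs(diff[:run.t_forget]).max():.1f}")
print(f"median forgetting time             : "
      f"{np.nanmedian(tab.forget.times):.0f} steps")
print(f"median construction time           : "
      f"{np.nanmedian(tab.construct.times):.0f} steps")
q1, q3 = np.nanpercentile(tab.construct.times, [25, 75])
print(f"construction-time IQR across units : {q3 - q1:.0f} steps")
rho, p = construct_forget_independence(tab)
print(f"construct vs forget Spearman       : rho = {rho:.3f}, p = {p:.2f}")
print()
print("Forgetting is input-driven and abrupt; construction is memory-")
print("driven and gradual, with a broad per-unit spread unrelated to")
print("forgetting speed.")
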