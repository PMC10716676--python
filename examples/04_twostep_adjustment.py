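"""Two-step cis-MR: removing a planted pleiotropic pathway.

Simulates instruments that reach the outcome both through the exposure
(true effect -0.0509) and through a mediator (per-variant effects b_gc,
mediator-outcome effect b_co), then compares the naive IVW estimate with
the estimate after subtracting the mediated component b_gc * b_co from
each variant-outcome association.
"""

import numpy as np

from cismr import (
    AR1,
    MediatorPath,
    SimulationConfig,
    adjusted_mr,
    harmonise,
    simulate_summary_stats,
)

THETA = -0.0509
B_GC = np.array([0.4, 0.3, 0.35, 0.45, 0.25])  # variant -> mediator
B_CO = 0.02                                    # mediator -> outcome

config = SimulationConfig(
    theta_true=THETA, pleiotropy=(B_GC, B_CO), ld_model=AR1(0.3), seed=7
)
path = MediatorPath("mediator", B_GC, np.full(5, 0.01), B_CO, 0.002)

unadj, adj = [], []
for rep in range(200):
    exposure, outcome, ld = simulate_summary_stats(config, replicate=rep)
    two = adjusted_mr(harmonise(exposure, outcome, ld), [path])
    unadj.append(two.unadjusted.estimate)
    adj.append(two.adjusted.estimate)

print(f"true causal effect:        {THETA}")
print(f"mean unadjusted estimate:  {np.mean(unadj):.4f} "
      f"(bias {np.mean(unadj) - THETA:+.4f})")
print(f"mean adjusted estimate:    {np.mean(adj):.4f} "
      f"(bias {np.mean(adj) - THETA:+.4f})")
print()
print("The pleiotropic pathway pushes the naive estimate away from the truth by")
print("roughly mean(b_gc)*b_co/mean(gamma); subtracting the mediated component")
print("per variant pulls the estimate back toward the true effect.")
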