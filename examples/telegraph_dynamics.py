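"""Biological zeros from transcriptional bursting.

Simulates the two-state (telegraph) gene expression model in three rate
regimes and compares the time-averaged mRNA copy number with the
Beta-Poisson stationary law. When both switching rates are small the
copy-number distribution is bimodal (modes at 0 and near s_m/delta), so a
snapshot across cells shows many biological zeros even though the gene is
expressed part of the time.
"""

import numpy as np

from sczeros import TelegraphParams, simulate_telegraph, telegraph_stationary_pmf

REGIMES = {
    "slow switching (bursty)": TelegraphParams(k_a=0.1, k_i=0.1, s_m=200, delta=1),
    "mostly active": TelegraphParams(k_a=5.0, k_i=0.1, s_m=200, delta=1),
    "mostly inactive": TelegraphParams(k_a=0.1, k_i=5.0, s_m=200, delta=1),
}

for name, params in REGIMES.items():
    traj = simulate_telegraph(params, t_max=5000.0, seed=1)
    pmf = telegraph_stationary_pmf(params)
    theory_mean = params.s_m / params.delta * params.k_a / (params.k_a + params.k_i)
    zero_prob = pmf[0]
    print(f"{name}:")
    print(f"  SSA time-averaged copies = {traj.time_average_copy_number():.1f}")
    print(f"  stationary mean (Beta-Poisson) = {theory_mean:.1f}")
    print(f"  P(copy number = 0) = {zero_prob:.3f}")

print(
    "\nThe bursty regime keeps a third of the probability mass at zero while"
    "\nthe mean stays near 100: biological zeros without zero expression."
)
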