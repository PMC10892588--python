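"""Estimate model parameters from data tables.

1. theta (herbivory growth constant) from the packaged codling-moth
   cumulative leaf-consumption means, via the closed-form least-squares
   solution of H = theta*t^2/2 through the origin.
2. (beta, gamma) (toxin formation and clearance) from a synthetic ITC
   time course, via multi-start nonlinear least squares.
"""

import numpy as np

from larvenet import (
    NoiseSpec,
    cumulative_times,
    fit_itc_curve,
    fit_theta,
    generate_itc_data,
    load_codling_moth_table,
)

table = load_codling_moth_table()
times = cumulative_times(table)
print("codling-moth table: instar-end times", times, "days")
print("                    cumulative mg   ", table.cumulative_mg)

result = fit_theta(times, table.cumulative_mg)
print(f"theta_hat = {result.estimates['theta']:.4f} mg/day^2  "
      f"(SSE = {result.sse:.2f} over n = {result.n} instars)")
print("fitted curve at instar ends:", np.round(result.fitted_values, 2))
print("The first three instars sit close to the parabola; the heavy final")
print("instar pulls the single growth constant upward.")

# --- toxin kinetics from a noisy synthetic ITC curve -------------------
beta_true, gamma_true = 0.2, 0.8
sample_times = np.arange(1.0, 15.0)
data = generate_itc_data(beta_true, gamma_true, sample_times, NoiseSpec(sigma=0.05, seed=11))
fit = fit_itc_curve(data["t_days"], data["value"])
beta_hat, gamma_hat = fit.estimates["beta"], fit.estimates["gamma"]
print(f"\nITC fit on sigma=5% noisy data (n={fit.n}):")
print(f"  beta_hat  = {beta_hat:.4f}  (true {beta_true})")
print(f"  gamma_hat = {gamma_hat:.4f}  (true {gamma_true})")
print("Both kinetic constants recover to within a few percent from a single")
print("noisy 14-point time course.")
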