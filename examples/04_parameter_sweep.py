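"""Sweep the cost/benefit constants: early versus late energy depletion.

Different larval groups (efficient specialists vs exposed generalists)
differ mainly in the toxin-cost constant mu and benefit constant kappa.
Sweeping each shows how the stopping time T — and with it the survival
verdict — shifts.
"""

from larvenet import REFERENCE_PARAMS, sweep_parameters

params = REFERENCE_PARAMS
print(f"development time b = {params.b} days\n")

print("toxin cost sweep (mu): higher exposure cost stops herbivory earlier")
print(sweep_parameters(params, "mu", [0.0, 0.05, 0.1, 0.2, 0.4]).to_string(index=False))

print("\nbenefit sweep (kappa): richer energy gain delays the stop")
print(sweep_parameters(params, "kappa", [0.15, 0.3, 0.45, 0.6]).to_string(index=False))

print("\nT is NaN where the energy budget never empties on the search horizon")
print("(pure survival); survived=False rows are larvae predicted to starve")
print("before completing development.")
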