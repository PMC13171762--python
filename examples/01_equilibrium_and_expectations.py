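"""Equilibrium XX/X0 mix and expected undeveloped-egg proportions.

A feminizing symbiont converts infected X0 individuals into functional
females with probability phi. Infected XX mothers produce half XX and half
X0 daughters; infected X0 mothers produce 1/4 XX, 1/2 X0 and 1/4 inviable
00 eggs. Iterating that transmission rule gives a stable mix of XX and X0
females, and with it the expected fraction of eggs that never develop.
"""

import femcost as fc

params = fc.FeminizationParams(phi=1.0)
eq = fc.solve_equilibrium(params)
print(f"perfect feminization: x_XX* = {eq.x_xx:.5f}, q_X0* = {eq.q_x0:.5f}")
print("  -> at equilibrium ~59% of infected females are feminized genetic "
      "males (X0)")

exp = fc.expected_undeveloped(eq.q_x0, b=0.0)
print(f"expected undeveloped eggs, no background mortality: {exp:.5f}")
print("  -> 0.25 * q_X0: only X0 mothers lose the quarter of 00 zygotes")

table = fc.expectations_for_symbiotypes(fc.DEFAULT_PHI, b=0.04)
print("\nper-symbiotype expectations with a 4% background failure rate:")
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print("  -> the symbiotype with the strongest feminization (RTW123) carries\n"
     "     the most X0 mothers and hence the highest expected egg loss")

# invert an observed brood sex ratio for the feminization success
m = fc.expected_male_fraction(fc.solve_equilibrium(fc.FeminizationParams(phi=0.9)),
                              fc.FeminizationParams(phi=0.9))
est = fc.estimate_phi_from_sex_ratio(m)
print(f"\nsex ratio {m:.4f} among viable offspring implies phi = {est.phi:.4f}")
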