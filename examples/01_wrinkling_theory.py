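"""Critical wrinkling wavelength of a growing biofilm trilayer.

Solves the linear-stability problem for a stiff film on a soft residual
layer on agar, compares with the closed-form bilayer law, and fits the
log-log scaling of wavelength vs stiffness contrast.
"""

import numpy as np

from biofilm_mech import LayerStack, bilayer_wavelength, scan_and_slope, solve_wrinkling

# a biofilm ~10x stiffer than the agar, with the soft residual interlayer
stack = LayerStack.from_ratios(gf_over_gs=10.0, gr_over_gf=0.1, hr_over_hf=0.3)
sol = solve_wrinkling(stack)
print(f"critical wavelength lambda_cr/h_f = {sol.lambda_cr:.3f}")
print(f"critical strain     eps_cr        = {sol.eps_cr:.4f}")
print(f"effective substrate modulus G'_s  = {sol.G_s_eff:.3f} x G_s")
# lambda_cr ~ 9.4 film thicknesses: the colony wrinkles at about 9x its
# own thickness once growth-induced compression reaches eps_cr.

lam_bi = bilayer_wavelength(10.0, 1.0, 1.0)
print(f"\nbilayer closed form (G_r = G_s):    {lam_bi:.3f}")

# the 1/3 scaling law holds asymptotically at large contrast
ratios = np.geomspace(10, 1000, 15)
_, slope = scan_and_slope(stack, ratios, (10, 1000))
print(f"log-log slope over G_f/G_s in [10, 1000]: {slope:.4f} (theory: 1/3)")

# below contrast ~1 the bilayer model has no physical solution branch, but
# the trilayer still wrinkles -- at a longer wavelength
soft = LayerStack.from_ratios(0.1, gr_over_gf=0.1, hr_over_hf=0.3)
sol_soft = solve_wrinkling(soft)
print(f"\nat G_f/G_s = 0.1: trilayer lambda/h_f = {sol_soft.lambda_cr:.3f}, "
      f"naive bilayer value = {bilayer_wavelength(0.1, 1, 1):.3f}")
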