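"""Blister side-profile metrics and the interfacial-energy hierarchy.

Delaminated blisters narrow and heighten as the film keeps growing, until
the two film walls meet: the final width at half height is twice the film
thickness.  The ordering of the interfacial energies predicts the
sequence of interface creation/annihilation events.
"""

from biofilm_mech import (
    InterfacialEnergySet, blister_metrics, gen_blister_series, interface_hierarchy,
)

profiles, truth = gen_blister_series(hf=0.1, n_stages=5)
print("stage   H (mm)   W (mm)   W/h_f")
for i, p in enumerate(profiles):
    H, W = blister_metrics(p)
    print(f"  {i}    {H:6.3f}   {W:6.3f}   {W / truth['hf']:5.2f}")
# W/h_f converges to 2: at contact the blister cross-section is just the
# two film walls standing against each other.

wild_type = InterfacialEnergySet(Gamma=5e-3, gamma_fl=49e-3, gamma_fa=30e-3)
print("\nwild-type energy hierarchy (Gamma < gamma_fa < gamma_fl):")
print(" ->", " -> ".join(interface_hierarchy(wild_type)))

mutant = InterfacialEnergySet(Gamma=0.0, gamma_fl=0.0, gamma_fa=40e-3)
print("\nadhesion-free matrix mutant:")
print(" ->", " -> ".join(interface_hierarchy(mutant)))
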