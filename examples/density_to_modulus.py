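"""Evaluate the density -> elasticity power law at a few mineral densities.

The quantitative-CT relationship converts hydroxyapatite-equivalent density
(g/cm^3 CaHA) to ash density and then to elastic modulus:
rho_ash = 0.8772 * rho_HA + 0.0789; E = 10200 * rho_ash^2.01 (MPa).
"""

from digitbone import ash_density, density_to_modulus

for rho_HA in (0.0, 0.25, 0.5, 0.75, 1.0, 1.2):
    rho_ash = ash_density(rho_HA)
    E = density_to_modulus(rho_HA)
    print(f"rho_HA = {rho_HA:4.2f} g/cm^3  ->  rho_ash = {rho_ash:.4f} g/cm^3"
          f"  ->  E = {E:7.3f} GPa")

print()
print("Each line maps one voxel-block mineral density to its predicted")
print("elastic modulus; a fully mineralised cortical block (~1 g/cm^3 CaHA)")
print("predicts ~9-10 GPa, while low-density regenerated trabecular bone")
print("predicts only a few GPa.")
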