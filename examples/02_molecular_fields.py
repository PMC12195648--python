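"""Grid fields around a single atom: the closed-form anchor cases.

CoMFA probes a lattice with an sp3-carbon atom (Lennard-Jones + Coulomb,
truncated at 30 kcal/mol); CoMSIA replaces hard potentials with Gaussian
similarity indices, exp(-0.3 r^2), which need no cutoff.
"""

import numpy as np

from fieldqsar import (Atom, AlignedMolecule, FieldConfig, Lattice,
                       comfa_probe, comfa_steric, comfa_electrostatic,
                       comsia_field, comsia_probe)

cfg = FieldConfig()
point = Lattice(origin=(0.0, 0.0, 0.0), spacing=1.0, dims=(1, 1, 1))


def atom_at(x, **kw):
    return AlignedMolecule("demo", [Atom("C", np.array([x, 0.0, 0.0]), **kw)])


rstar = 1.7 + 1.52  # atom + probe vdW radii
print("CoMFA steric energy (kcal/mol) vs atom-probe distance:")
for r in (rstar, 2.0, 0.0):
    e = comfa_steric(atom_at(r), point, comfa_probe(), cfg)[0]
    print(f"  r = {r:4.2f} A -> {e:8.3f}")
print("  (minimum -eps at contact distance; +30 cap inside the atom)")

e = comfa_electrostatic(atom_at(2.0, partial_charge=1.0), point,
                        comfa_probe(), cfg)[0]
print(f"CoMFA electrostatic, q=+1 at 2 A: {e:.3f} (Coulomb 83.0 clamped to 30)")

print("CoMSIA steric similarity, unit-weight atom:")
for r in (0.0, 1.0, 2.0):
    a = comsia_field(atom_at(r, vdw_radius=1.0), point, "S",
                     comsia_probe(), cfg)[0]
    print(f"  r = {r:3.1f} A -> {a:+.4f}   (closed form -exp(-0.3 r^2) = "
          f"{-np.exp(-0.3 * r * r):+.4f})")
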