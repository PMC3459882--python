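"""Evaluate residue-residue nonbonded interaction energies of a structure.

Electrostatics (Coulomb, k_e = 332.0636 kcal*A/mol/e^2) plus Lennard-Jones
with Lorentz-Berthelot combining, summed over all atom pairs of each
residue pair with |i - j| > 1; adjacent (bonded) residues are excluded.
"""

import numpy as np

from icnet import frame_energy_matrix, generate_toy_complex, pair_energy
from icnet.synthetic import Atom

# a bare ion pair at 3.320636 A gives exactly -100 kcal/mol of Coulomb energy
plus = Atom("NZ", np.array([0.0, 0.0, 0.0]), +1.0, 0.0, 3.2)
minus = Atom("OE1", np.array([3.320636, 0.0, 0.0]), -1.0, 0.0, 3.2)
dec = pair_energy([plus], [minus])
print(f"ion pair at 3.320636 A: elec = {dec.electrostatic:.4f} kcal/mol")

complex = generate_toy_complex(n_protein=10, seed=3)
fm = frame_energy_matrix(complex)
print(f"frame energy matrix: {fm.n_residues}x{fm.n_residues}, "
      f"symmetric, adjacent pairs stored as 0")
iu = np.triu_indices(fm.n_residues, k=2)
strongest = np.argmin(fm.total[iu])
i, j = iu[0][strongest] + 1, iu[1][strongest] + 1
print(f"strongest attraction: residues {i}-{j} "
      f"({fm.total[i - 1, j - 1]:.2f} kcal/mol; "
      f"elec {fm.electrostatic[i - 1, j - 1]:.2f}, "
      f"LJ {fm.lennard_jones[i - 1, j - 1]:.2f})")
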