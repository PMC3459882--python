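"""Generate a toy complex and a planted-network energy trajectory.

The generator plants factor groups of residue pairs whose interaction
energies co-fluctuate through a shared latent factor; everything downstream
can then be validated against this known ground truth.
"""

import numpy as np

from icnet import PlantedNetwork, generate_energy_trajectory, generate_toy_complex

complex = generate_toy_complex(n_protein=20, n_guide=4, n_target=4, seed=1)
print(f"complex: {complex.n_residues} residues "
      f"({len(complex.residues_with_role('protein'))} protein, "
      f"{len(complex.residues_with_role('guide'))} guide, "
      f"{len(complex.residues_with_role('target'))} target)")

# two pairs share a factor (loading 2, noise SD 1); one pair is independent
net = PlantedNetwork(
    n_residues=complex.n_residues,
    groups=({(1, 3): 2.0, (5, 7): 2.0}, {(10, 12): 2.0}),
)
traj = generate_energy_trajectory(net, n_frames=4000, seed=1)

r_shared = np.corrcoef(traj.series(1, 3), traj.series(5, 7))[0, 1]
r_indep = np.corrcoef(traj.series(1, 3), traj.series(10, 12))[0, 1]
print(f"shared-factor pair correlation: {r_shared:.3f} "
      "(theory: 2^2/(2^2+1^2) = 0.8)")
print(f"independent-pair correlation:   {r_indep:.3f} (theory: 0)")
print(f"planted pair mean energy: {traj.series(1, 3).mean():.2f} kcal/mol "
      "(baseline -15, passes the 10 kcal/mol selection cutoff)")
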