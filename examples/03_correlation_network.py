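"""From an energy trajectory to the residue correlation matrix M.

Pairs with |mean energy| >= 10 kcal/mol are selected, their time series
correlated into the pair correlation matrix C, and |C| is projected onto
residues: M_ij sums the correlation magnitudes between pairs containing i
and pairs containing j.
"""

import numpy as np

from icnet import (correlation_factor, pair_correlation, project_to_residues,
                   select_pairs)
from icnet.pipeline import reference_network
from icnet.synthetic import generate_energy_trajectory

net = reference_network(60)
traj = generate_energy_trajectory(net, n_frames=2000, seed=7)

sel = select_pairs(traj, cutoff=10.0)
print(f"{len(sel)} of {len(traj.pairs)} pairs pass the 10 kcal/mol cutoff "
      f"(planted: {len(net.planted_pairs())})")

C = pair_correlation(traj, sel)
off = np.abs(C.values[np.triu_indices(len(sel.pairs), 1)])
print(f"pair correlation matrix C: {C.values.shape}, "
      f"mean |C| = {off.mean():.3f}")

M = project_to_residues(C, sel, traj.n_residues, mode="max-normalized")
print(f"residue correlation matrix M: {M.values.shape}, "
      f"entries in [{M.values.min():.2f}, {M.values.max():.2f}]")

# how strongly does residue 26 (a core residue) couple to the whole protein?
F = correlation_factor(M, 26, list(range(1, 49)))
print(f"correlation factor F(26, protein) = {F:.2f} "
      "(sum of residue 26's couplings)")
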