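# Methods

## Model and pipeline

The package analyses equal-time correlations of residue–residue nonbonded
interaction energies.  The underlying assumption is that residues lying on
a common internal allosteric pathway exchange energy in a coordinated way,
so the fluctuations of their pairwise interaction energies are correlated
across an equilibrium ensemble, even when neither their positions nor their
direct interactions are.

**Interaction energies.**  For residues i, j with |i − j| > 1 (adjacent,
covalently bonded residues are excluded wholesale), the frame energy is the
sum over all atom pairs of the Coulomb term k\_e·q\_a·q\_b/r with
k\_e = 332.0636 kcal·Å/(mol·e²) and the Lennard-Jones term
4ε\_ab[(σ\_ab/r)¹² − (σ\_ab/r)⁶] with Lorentz–Berthelot combining
(σ arithmetic, ε geometric mean).  No distance cutoff, no periodic images,
no 1–4 scaling, uniform dielectric of 1.  Electrostatics therefore dominate
the magnitudes, as with real force-field energies; correlations, not
magnitudes, carry the signal downstream.

**Selection → C → M.**  Pairs with |⟨E⟩| ≥ cutoff (default 10 kcal/mol,
absolute value because interaction energies are predominantly negative) are
correlated pairwise (Pearson, over frames; zero-variance series are flagged
and set to 0).  The projection onto residues is

M\_ij = Σ\_{unordered {m,n}, m≠n, i∈m, j∈n} |C\_mn|,

implemented as B|C|Bᵀ − BBᵀ with B the residue-by-pair incidence matrix;
this is exact because two distinct pairs share at most one residue, so at
most one orientation of {m, n} can satisfy the membership constraint for
i ≠ j.  The absolute value makes anticorrelation count as coupling, giving
a nonnegative M displayable on a 0–1 scale once max-normalized.  Three
normalization modes are exposed (raw-sum, count-normalized,
max-normalized) because the projection's normalization is a genuine
modelling choice: raw-sum feeds correlation factors and the z-score stage
(which is scale-invariant), max-normalized is the display/similarity
default.

**Similarity and null.**  S = both-above / either-above over upper-triangle
cells, with per-matrix thresholds at the 92.6th percentile (top 7.4%) of
the (N² − N)/2 distinct values, linear interpolation, strict ">" so
threshold ties are excluded.  The bootstrap null resamples one index vector
per matrix (with replacement) applied to rows and columns alike — each
replicate reassigns whole residue correlation profiles while preserving
symmetry.  An `independent-axes` mode (separate row and column vectors) is
also implemented; the symmetric mode is the default because it preserves
the defining symmetry of a residue correlation matrix.

**Sensors.**  Each condition's M is standardized over its distinct
off-diagonal cells (z units), differences ΔM = M\_perturbed − M\_reference
are aggregated cell-wise as the root mean square across perturbations, and
the involvement vector v is the column sum of ΔM\_rms.  Sensors are
residues with |v\_i − mean(v)| > k·SD(v), default k = 2, two-sided (v is a
magnitude sum, so in practice the upper tail dominates).  Standardization
happens *before* differencing so conditions with different overall coupling
scales remain comparable.  No multiple-testing correction is applied; the
plain k-SD rule is the method's convention.

**Profile clustering.**  Rows of M are observation vectors; the distance
between residues i and j is Euclidean with columns i and j masked from both
rows (self-similarity must not leak into the metric; a correlation-based
row distance is available as an option).  Clustering is DIANA-style
divisive: split the cluster with the greatest average within-cluster
dissimilarity; seed the splinter with the member of maximal average
dissimilarity to its mates; migrate members closer (on average) to the
splinter than to the remainder until convergence.  All ties break toward
the lowest residue index, making the tree deterministic.  The tree is built
down to singletons so a flat cut exists at every count; the default cut is
6 clusters, exposed as a parameter.  The semantics matter: residues
clustering together share correlation *partners* and need not correlate
with each other — the recovered layers are cross-sections of pathway
bundles, not pathways.

**Annotation.**  SASA is Shrake–Rupley with a deterministic golden-spiral
point set (960 points/atom by default) and a Bondi-type radii table
(C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å), probe 1.4 Å, hydrogens
ignored; the table is overridable per call.  Salt bridges: any
acidic-oxygen (Asp OD1/OD2, Glu OE1/OE2, C-terminal OXT) to basic-nitrogen
(Lys NZ, Arg NE/NH1/NH2; His ND1/NE2 behind a flag) distance ≤ 3.2 Å.
Sensor classification: binding-groove membership (a user-supplied,
structure-specific residue set) takes precedence, then SASA strictly
greater than 70 Å² marks a surface sensor, else buried/other.

## Synthetic data: what it emulates and what it does not

The generator stands in for MD post-processing, not for MD.  Planted
factor groups tie sets of residue pairs to a shared latent scalar redrawn
independently every frame:

E\_p(t) = baseline\_p + loading\_p·z\_g(t) + noise\_p·ε\_p(t).

Two pairs sharing a factor have population correlation
loading²/(loading² + noise²); different groups are independent.  Defaults:
planted baseline −15 kcal/mol (passes the 10 kcal/mol cutoff), background
−2 kcal/mol (does not), loading 2.0 and noise SD 1.0 (correlation 0.8 —
strong but attenuated, so finite-sample effects are exercised).  Toy
complexes place protein residues on a coarse self-avoiding helix (radius
7 Å, rise 1.4 Å, 100°/residue) with guide/target strands alongside, so
inter-residue distances span tens of Å for distance-shell analyses;
residue names are chosen consistently with drawn charges so the same toys
exercise SASA and salt-bridge code.

Deliberately **not** modelled: temporal autocorrelation (the analysis uses
equal-time correlations only), realistic force-field energy distributions,
solvent/ions, conformational change, and anharmonicity.  Passing tests
therefore demonstrate correctness of the analysis machinery and its
statistical behaviour under a known generative model — they do not
demonstrate that any particular real complex has a particular network.

## The reference experiment

The packaged study mirrors a one-matched / five-mismatched design: 60
residues (48 protein, 6 guide, 6 target), four factor groups (a "core"
group of 12 pairs among 8 designated core residues — an 8-pair ring plus a
4-chord perfect matching, so each core residue has planted degree 3 — and
three 10-pair groups elsewhere), 2000 frames per condition.  Each of the
five perturbation variants removes the same 8 ring pairs
(remove-from-factor keeps baselines pinned, so selection is unchanged) and
rescales one variant-specific chord, giving the variants a shared
perturbation core plus individual character.  Ground truth for sensor
scoring is the 8 core residues.  Comparisons use quantile 0.926, 1000
bootstrap replicates, k = 2, across 5 trajectory seeds expanded
deterministically from one master seed (all derived seeds < 2³¹).  These
sizes keep a full 5-seed suite at a few seconds on one CPU while leaving
every statistic far from its decision boundary.

## Numerical choices and degenerate inputs

- Pearson correlations are clipped to [−1, 1]; zero-variance series give 0
  with a warning rather than an error (constant background pairs are
  legitimate in synthetic data).
- Quantile thresholds use linear interpolation over the sorted distinct
  upper-triangle values; cells strictly above the threshold count.
- A similarity denominator of 0 (both matrices constant) is flagged
  undefined (NaN), not raised.
- z-normalization refuses constant matrices; a constant involvement vector
  yields an empty sensor set with a warning.
- Energy tables round-trip float64 exactly (`%.17g` on write, round-trip
  float parsing on read); the reader rejects adjacency-violating rows and
  inconsistent pair sets across frames.
- The energy evaluator raises on coincident atoms (r = 0) and on missing
  or non-finite parameters.

## Known limitations

- The pipeline is built for desk-scale systems (≲ a few hundred residues,
  ≲ 10⁴ frames); the projection is dense and the SASA neighbour search is
  quadratic in atoms.
- Real trajectory ingestion (DCD/XTC) is an extension point; the package
  reads structures from PDB plus a sidecar parameter table and energies
  from its documented TSV format.
- SASA values depend on the radii table; per-residue agreement with any
  specific published table is not guaranteed and deviations should be
  reported rather than tuned away.
- Sensor identification inherits the arbitrariness of the k-SD rule;
  results near the threshold should be inspected, not over-interpreted.
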