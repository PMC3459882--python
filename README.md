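# icnet — interaction-energy correlation network analysis

`icnet` post-processes trajectories of residue–residue nonbonded
interaction energies into **interaction correlation networks**, the
energy-based analogue of dynamical cross-correlation analysis used to map
internal allosteric pathways in large biomolecular complexes such as an
Argonaute protein bound to a guide–target nucleic-acid duplex.  It is aimed
at structural bioinformaticians who want to ask: *which residues are
energetically coupled, how is the coupling architecture organized, and
which residues change their coupling when the complex is perturbed (e.g. by
a guide–target base-pair mismatch)?*

Because real MD trajectories are bulky and rarely deposited, the package
ships a first-class synthetic generator that plants a known correlation
structure into toy energy trajectories, so every stage of the analysis can
be validated against ground truth.

## The method

For each trajectory frame the residue interaction energy matrix *E* holds
the summed Coulomb + Lennard-Jones energy of every residue pair (i, j) with
|i − j| > 1 (kcal/mol; k\_e = 332.0636 kcal·Å/(mol·e²), Lorentz–Berthelot
combining, no cutoff, unit dielectric).  The pipeline then computes:

1. **Pair selection** — keep pairs with |⟨E\_ij⟩| ≥ 10 kcal/mol.
2. **Pair correlation matrix C** — Pearson correlation over frames between
   the energy time series of every two selected pairs.
3. **Residue correlation matrix M** — projection onto residues:
   M\_ij = Σ over unordered pairs-of-pairs {m, n}, m ≠ n, with i ∈ m and
   j ∈ n, of |C\_mn| (raw-sum, count-normalized or max-normalized).
4. **Correlation factor** — F(i, G) = Σ\_{j∈G, j≠i} M\_ij, optionally per
   distance shell around residue i.
5. **Similarity score** — S(A, B) = |top(A) ∩ top(B)| / |top(A) ∪ top(B)|
   where top(·) is the set of upper-triangle cells strictly above the
   per-matrix 92.6th-percentile threshold (top 7.4%); significance via a
   bootstrap null that resamples whole residue profiles with replacement.
6. **Sensor residues** — z-normalize each M, form ΔM = M\_perturbed −
   M\_reference per perturbation, aggregate cell-wise as ΔM\_rms, sum the
   columns into an involvement vector v, and flag residues with
   |v\_i − mean(v)| > 2·SD(v).
7. **Profile clustering** — DIANA-style divisive hierarchical clustering of
   the rows of M (residues cluster by *shared correlation partners*, not
   mutual correlation), yielding onion-skin layers orderable by distance
   from a center set.
8. **Structure annotation** — Shrake–Rupley SASA (1.4 Å probe), O–N
   salt-bridge detection (3.2 Å cutoff) and groove/surface/buried sensor
   classification.

## Worked example

```python
from icnet import demo_suite
suite = demo_suite(seed=1, n_seeds=5)
print(suite.summary())
```

prints (one matched network vs five perturbed variants, 60 residues,
2000 frames per condition, five independent trajectory seeds):

```
{
  "n_seeds": 5,
  "mean_matched_vs_perturbed_S": 0.771,
  "mean_perturbed_vs_perturbed_S": 0.872,
  "null_mean": 0.0381,
  "null_sd": 0.0166,
  "min_separation_null_sds": 42.5,
  "mean_sensor_recall": 1.0,
  "mean_sensor_precision": 1.0,
  "n_seeds_perturbed_closer": 5
}
```

Read: the network architecture survives each perturbation
(S ≈ 0.77 ≫ null 0.038, more than 40 null SDs away), the five perturbed
variants are more similar to each other (0.87) than to the matched network
on all five seeds — the signature of a shared perturbation core — and the
eight residues whose couplings were actually perturbed are recovered as
sensors with perfect precision and recall.

The `examples/` directory walks through each capability (synthetic
generation, energy evaluation, correlation networks, similarity + sensors,
clustering, annotation); each script prints the numbers it computes and
what they mean.  A thin CLI (`icnet simulate|energies|correlate|compare|
sensors|cluster|annotate|demo|run`) wraps the same stages for shell use.

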