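# armroot

Tools for studying how a two-armed protein complex evolved: whether it was
present in the last eukaryotic common ancestor (LECA) and decayed by
repeated independent loss, or spread later by horizontal transfer.  The
motivating system is the kinetochore's microtubule-coupling machinery,
where two non-homologous complexes — the ten-subunit Dam1 complex and the
three-subunit Ska complex — show a strikingly anti-correlated
presence/absence pattern across eukaryotes.

The package implements the full analysis chain as a reusable library plus
a CLI, and ships a synthetic-data generator with the statistical structure
the analyses assume, so every stage is testable without external
databases or search tools.

## What it computes

- **Co-occurrence profiles** (`armroot.profiles`): species × subunit
  presence matrices with three-valued cells (present / absent / unknown),
  complex presence calls (a species "has" a complex when ≥ *k* subunits
  are detected), co-occurrence counts conditioned on a hub gene (Ndc80),
  and a one-sided permutation test for mutual exclusivity — optionally
  with a tree-aware null that re-simulates Dollo losses instead of
  permuting labels, since species are not independent observations.
- **Dollo parsimony** (`armroot.dollo`): minimal loss reconstruction for a
  character gained once on a rooted species tree.  The minimal history
  places one loss on each maximal subtree (below the gain) without a
  present leaf; `count_independent_losses` applies this to a complex.
- **Paralogy networks** (`armroot.homology`): reciprocal best matches and
  connected components of profile-vs-profile E-value matrices, with
  direct-vs-transitive linkage reporting (two subunits may be homologous
  via a shared neighbour without a direct significant hit).
- **Structural superposition** (`armroot.superpose`): Kabsch/SVD rigid
  superposition of paralogous subunit Cα traces (reflections excluded) and
  per-pair RMSD tables with sequence-alignment-derived correspondence.
- **Arm supermatrices** (`armroot.supermatrix`): sub-MSA-preserving
  profile–profile merge of each subunit alignment with its cross-arm
  paralog, gap-threshold trimming (keep a column iff its residue fraction
  ≥ *gt*), the ≥ *k*-subunits-per-arm species filter, and a concatenation
  in which every species contributes one pseudo-taxon per arm
  (`sp__arm1` / `sp__arm2`).  A tree over these pseudo-taxa can be rooted
  on the branch separating the arms, because the arm-generating
  duplication predates the species radiation.
- **Likelihood phylogenetics** (`armroot.phylo`): Felsenstein-pruning site
  log-likelihoods under Poisson or LG models (+F frequencies, discrete-Γ
  rates), branch-length optimisation, NJ + NNI tree search with optional
  topology constraints, and topology testing from site log-likelihoods:
  RELL bootstrap, the Kishino–Hasegawa test, and the approximately
  unbiased (AU) test via multiscale bootstrap,
  `Φ⁻¹(1 − BP_r) ≈ d√r + c/√r`, `p_AU = 1 − Φ(d − c)`.
- **Genomic co-localization** (`armroot.colocalization`): scaffold-sharing
  classes per species and intergenic-gap statistics — a single horizontal
  transfer of a whole complex would favour physically clustered subunit
  genes, so dispersed present-day loci argue against it.
- **Synthetic data** (`armroot.simulate`): birth–death species trees,
  coupled Dollo loss histories for two complexes with an anti-correlation
  coupling knob, subunit sequences descending from a pre-root ancestor
  through two duplication waves (arms, then within-arm splits), and
  scaffold layouts.  Truth objects are always returned for
  parameter-recovery tests.

## Worked example

Simulate a 12-species dataset and run the profile and loss analyses:

```sh
armroot --out-dir run --seed 4 simulate --n-species 12 --seq-length 80
armroot --out-dir run presence run/presence.tsv
armroot --out-dir run dollo run/species_tree.nwk run/presence.tsv
```

which prints

```
conditioning species: 12; Dam1-C: 7; Ska-C: 6; both: 1; neither: 0
either (inclusive/exclusive): 1.000/0.917
mutual exclusivity p = 0.0140 (label_permutation, 1000 permutations)
Dam1-C: 3 independent losses
Ska-C: 2 independent losses
```

Seven of twelve species retain the first complex and six the second, but
only one species retains both — more exclusive than expected if the two
complexes were lost independently (permutation p ≈ 0.014).  The minimal
Dollo explanation of the observed pattern needs three independent losses
of the first complex and two of the second on the simulated species tree.
Continuing with `supermatrix`, `mltree` and `toptest` builds the
arm-pseudo-taxon concatenation, infers a tree, checks whether the
arm1/arm2 bipartition is recovered (rooting the tree on it), and runs the
AU/KH topology tests against alternative topologies.

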