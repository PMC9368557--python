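# Methods

This note documents the models and procedures implemented in `pocketdyn`,
the defaults they use, the design choices that were genuinely open, and
what the synthetic benchmarks do and do not demonstrate.

## Hydrogen-bond state model

A binding state is defined purely by which named hydrogen-bond pairs are
simultaneously formed. Each pair links one protein backbone atom (the
amide N of I33, G34, I35 or I37 in the canonical set) to the
hydrogen-bond-capable heavy atoms of a ligand group; the pair distance is
the minimum over those atoms, so the two chemically equivalent
carboxylate oxygens are interchangeable by construction. A pair is broken
when its distance exceeds the **break threshold, default 0.5 nm**, read
strictly: exactly 0.5 nm still counts as formed. The criterion is
heavy-atom distance only — no hydrogen positions or donor–H–acceptor
angles enter the state rule (a conventional 0.35 nm geometric detector
exists separately, solely to *suggest* candidate pairs).

Per-frame classification applies, in precedence order: *dissociated*
(from the sustained-exit scan), *state 0* if at least two of the three
carboxylate–backbone pairs are formed **and** both I37 pairs are broken,
*state 1* if I37–ketone is formed, *state 2* if I37–carboxyl is formed,
else *unassigned*. The ≥2-of-3 rule for state 0 is a deliberate choice:
requiring all three bonds would let a transient single-bond flicker
fragment an otherwise stable pose. The I37-broken condition keeps state 0
disjoint from the I37-bonded states; when both I37 pairs are formed the
ketone wins, because a formed ketone bond implies the flipped pose
regardless of where the carboxylate transiently sits.

**Dissociation** is a sustained-exit rule on the minimum heavy-atom
distance between the ligand and a pocket residue (default I37): the
ligand is dissociated from the first frame of a run of `window`
(default 50) consecutive frames beyond `cutoff` (default 0.8 nm), and
re-enters after an equally sustained run back inside. The pipeline
retains only frames before the first sustained exit, so post-dissociation
frames never contaminate state statistics.

**Distance distributions** report the sample mean/SD as the Gaussian fit
and count modes on a Gaussian KDE with Silverman's bandwidth, evaluated
on a 512-point grid. A local maximum counts as a mode only when its
prominence exceeds 5% of the peak density: without that floor, sampling
wiggles of the KDE register as spurious modes on perfectly Gaussian
samples often enough to make the unimodality flag useless. Samples of
fewer than 30 values get no modality verdict (flagged `None`); constant
samples (SD below a 1e-12 relative threshold) are unimodal by definition.

## Pose clustering

Frames are first superposed by a least-squares rigid-body fit (Kabsch,
proper rotation enforced) on the protein Cα atoms; clustering then acts
on ligand heavy-atom RMSD without refit — the quantity of interest is
the ligand pose *within the pocket frame*. Two schemes:

* **GROMOS/Daura** (default cutoff 0.2 nm): the frame with the most
  neighbors within the cutoff seeds a cluster with its neighbors, all are
  removed, repeat; ties go to the lowest frame index. This is the
  conventional choice for "top N clusters of a trajectory".
* **k-medoids** (PAM-style alternation on the precomputed RMSD matrix,
  default 10 seeded restarts keeping the lowest within-cluster cost) for
  analyses that fix the number of conformations a priori. No installed
  library offers k-medoids on a precomputed distance matrix, so the
  ~40-line alternation is implemented here.

Cluster ids are size-ranked (ties by earliest member frame), fractions
sum to 1 exactly, and each cluster's representative is its medoid.

## Contact maps

A ligand group and a residue are in contact when their minimum heavy-atom
cross distance is at or below the **contact cutoff, default 0.45 nm** (a
common heavy-atom convention; the value is recorded on every map).
Probabilities are exact counts over masked frames, which makes the maps
additive over disjoint masks and monotone in the cutoff. The residue side
uses all heavy atoms by default, with a side-chain-only option. The
"charged interaction" between a carboxylate and a lysine ammonium is
reported under the same distance rule — electrostatics belongs to the
force module, not the contact definition.

## Correlation networks

The DCCM uses the standard normalized displacement covariance with
3-vector displacements from the time-mean position, one Cα per residue
plus the ligand's heavy-atom centroid as one extra node. When a fit
selection is given the trajectory is superposed on its mean structure,
iterated twice so the mean is self-consistent; rigid-body motion of the
whole complex then leaves the DCCM unchanged to ~1e-10. Nodes with zero
displacement variance (below a 1e-18 relative floor that absorbs
mean-subtraction round-off) are an error, not a silent NaN.

The network convention is the standard dynamical-network one: an edge
joins nodes that stay in heavy-atom contact in at least **f_min = 0.75**
of the frames at the 0.45 nm cutoff, weighted **w_ij = −log|C_ij|**; the
ligand node participates under the same filter. Communities come from
Girvan–Newman removal of the highest weighted-betweenness edge (weights
as distances; ties broken by lexicographic edge order for determinism),
and the returned partition is the one maximizing weighted Newman–Girvan
modularity Q computed on the *original* graph — note the standard quirk
that betweenness treats weights as distances while Q treats them as
strengths; both choices are recorded in output metadata. Disconnected
inputs need no special casing: components are already communities, and
the pre-removal partition is scored too, so two disconnected triangles
yield Q = 0.5 immediately. On the six-node two-triangle bridge graph the
returned partition is the two triangles with Q = 5/14, which exhaustive
enumeration of all node partitions confirms as the global maximum.

The ligand-coupling report lists residues sharing the ligand's community,
aggregated by a user-supplied residue→secondary-structure-element map
("56-63: alphaA" style ranges in the config).

## Punctual stress

Per residue and frame, punctual stress is the **sum of the magnitudes**
of the individual pairwise nonbonded forces the ligand exerts on the
residue's atoms — absolute pairwise contributions, not the norm of the
net force, so opposing pulls do not cancel. The pair force is
Lennard-Jones plus Coulomb,
F = [24ε(2(σ/r)¹² − (σ/r)⁶)/r + k_e q_i q_j / r²] r̂,
with Lorentz–Berthelot combination, a plain cutoff at **1.2 nm**, and
k_e = 138.935458 kJ·mol⁻¹·nm·e⁻² (MD units throughout: nm, e, kJ/mol).
Only protein↔ligand pairs contribute, so no 1-4 exclusions arise. The
charge product is grouped as (q_i·q_j) so exchanged arguments give the
bit-identical scalar and Newton's third law holds exactly in floating
point. Aggregation is the per-trajectory mean over masked frames, summed
across trajectories; per-state profiles use state-label masks.

This is a trajectory-side approximation: no bonded terms, no
reaction-field or mesh electrostatics, no engine-internal force
decomposition. Absolute magnitudes are therefore not comparable to
engine-computed stresses; the supported outputs are comparative rankings
(top-N residues, per-state contrasts).

## Synthetic data: what is planted and what is not

`gen_toy_complex` fabricates a 12-residue pocket (I33/G34/I35/I37 strand,
a lysine with an explicit side chain reaching into the pocket, helix
residues, filler) and a 32-atom ligand whose named groups mirror the
analysis vocabulary. Geometry is hand-placed, not folded: only names and
interaction roles are meaningful. Since the model has no hydrogens, the
ammonium charge sits entirely on the lysine NZ and the carboxylate charge
is split over its three atoms; remaining parameters are generic
CHARMM-like values. The seed argument exists for interface uniformity —
the complex itself is a fixed template.

`gen_state_switching_trajectory` switches the ligand between fixed
per-state pose templates in which every canonical pair distance clears
the 0.5 nm rule by at least `margin` (default **0.1 nm**, validated
against the templates at generation time; the fixed geometry supports
margins to ~0.12 nm) and adds i.i.d. Gaussian jitter of scale
`noise_sigma` (default **0.01 nm**, required < margin/4). Dissociated
frames translate the ligand 3 nm out of the pocket. These defaults give
an order of magnitude of separation at the threshold, so classifier
recovery is exact by construction — which is the point: the benchmark
verifies the machinery, not the difficulty of real data.

`gen_correlated_trajectory` plants a target correlation matrix C* by
drawing each Cartesian component of the node displacements as an
independent zero-mean Gaussian vector with covariance C* (eigenvalue
factorization, negative round-off eigenvalues clipped at −1e-8). With
this isotropic construction the displacement-vector DCCM equals C*
exactly in expectation and converges at the usual 1/√n rate. A
per-node-direction construction (one scalar latent projected on a random
unit vector per node) was considered and rejected: the dot products
between differing node directions rescale every off-diagonal entry, so
the DCCM would converge to (û_i·û_j)·C*_ij rather than C*.

`gen_planted_graph` is a plain stochastic block model with unit edge
weights via networkx.

**What passing these benchmarks shows** is that each stage recovers
planted structure under clean, well-separated conditions and that the
oracles (brute-force force sums, exhaustive modularity enumeration,
direct distance recomputation) agree with the optimized paths. **What
they do not show** is performance on real MD data: no solvent, no
force-field sampling, no correlated noise, no marginal bond distances
hovering at the threshold, no partial state overlap.

## Numerical choices and degenerate inputs

* Coordinates are nm internally; PDB Å are divided by 10 at read time.
  Distances are computed without minimum-image by default (analysis
  exports are assumed whole/centered); per-frame boxes are preserved for
  readers that provide them.
* Superposition rejects fit selections with fewer than 3 atoms or rank
  < 2 (collinear) centered coordinates.
* The pairwise-RMSD matrix uses the Gram-matrix identity with clipping at
  0 and an exactly-zero diagonal; off-diagonal entries are accurate to
  ~1e-7 for near-identical frames (catastrophic cancellation bound).
* k-medoids and the GROMOS scheme break all ties deterministically
  (lowest index); Girvan–Newman breaks betweenness ties lexicographically.
* Modularity of an empty-edge graph is 0; an empty graph is an error.
* Atoms missing from the parameter table get zero charge/σ/ε and a
  `has_params=False` flag — they simply contribute nothing to forces.

## Benchmark problem sizes

The standard benchmarks use 1,000 frames for state recovery, 5,000 frames
for DCCM recovery (sampling error ≈ 3/√n ≈ 0.04), 100 seeds for the
stochastic-block-model and modality rates, 100 random fixtures for the
force oracle, and 200–300-frame trajectories for clustering and the
end-to-end pipeline — sizes at which every planted property is
comfortably resolved while the whole suite runs in well under a minute on
one core.

## Known limitations

* The H-bond state rule is distance-only and pocket-specific: the five
  canonical pairs are configuration, and systems with different bonding
  topology need different pair definitions and state rules.
* The network edge rule (contact filter + −log|C| weights) is a declared
  convention; other conventions (covalent-neighbor edges, mutual
  information) are not implemented.
* Punctual stress omits solvent screening entirely; rankings in highly
  charged pockets will overweight bare Coulomb interactions.
* The multi-model PDB reader trusts the file's frame order and fabricates
  a 0,1,2,… time axis (flagged) since PDB carries no times.
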