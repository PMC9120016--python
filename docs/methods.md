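# Methods

This note records the models behind each module, the defaults that matter,
what the synthetic generators do and do not emulate, and the numerical and
design choices made where the procedure was genuinely open.

## Reduced representation

All computation is Cα-only. Structures are reduced to one Cα per residue
on read; residues without a Cα are skipped with a logged count. Identity
is the author-assigned (chain, number, insertion code); internal indices
are 0-based. Coordinates are held in nanometres and converted to/from
ångströms only at the PDB boundary. This coarsening is a deliberate
fidelity trade: side-chain packing, hydrogen-bond chemistry and full-atom
energetics are out of scope, so every downstream statement about energies
or couplings is about the Cα geometry and residue identities, not atomic
detail.

Contacts default to a 0.8 nm Cα–Cα cutoff with a minimum same-chain
separation of 3 residues (cross-chain pairs count at any separation).
Interface classes (`vert_dim`, `lat_dim`, `kd_ad`) are configuration: a
chain-pair role map supplied by the user, never inferred from geometry.

## Constraint ensembles

`build_constraints` derives bounds from the reference: sequence neighbours
at ±5% of the native distance (these encode chain connectivity and are
never dropped), native contacts at ±15%, each contact bound retained with
probability `retain_fraction` (seeded). The retention rule is a stochastic
stand-in for the removal of contacts a solvation model would predict
unstable; no hydrogen-bond chemistry is modelled.

`generate` displaces every Cα uniformly inside a cube (default side
0.2 nm — chosen so the sampled fluctuation scale matches the ~0.1–0.3 nm
rmsf range typical of native-basin ensembles) and then projects violated
bounds pairwise, both atoms moved half-way, in a seeded random order
re-shuffled each sweep (randomization avoids directional bias; the
processing order is otherwise arbitrary). A trial that still violates a
bound after `max_iter` (default 500) sweeps is rejected and recounted; an
acceptance rate below 1% over the first 200 trials raises an infeasibility
error rather than looping forever. Accepted conformers satisfy every
bound within 1e-3 nm, and the same seed reproduces the ensemble
bit-for-bit.

`rmsf` best-fit superposes every conformer onto the reference ("crystal")
coordinates before accumulating deviations; the alternative `"mean"`
reference measures about the post-fit ensemble mean. The crystal
convention is the default because flexibility profiles are usually quoted
relative to the experimental structure.

## PCA, convergence, hinges

PCA runs on the superposed Cα coordinates via SVD; eigenvalue fractions
are quoted against the total variance. Superposition is to the reference
conformer, not an iterated mean — one pass, consistent with the rmsf
convention. Sign convention: each mode's largest-magnitude component is
made positive, so outputs are reproducible across BLAS implementations.

Subset convergence is RMSIP over the top 10 modes — the standard
essential-dynamics overlap measure; 10 modes covers the planted spectra
used throughout and matches common practice. RMSIP is symmetric and lies
in [0, 1].

Hinge descriptors reduce an interface to the inertial long axes of two
residue sets. The reference conformer defines the frame: e1 = reference
axis of set B, e3 = interface normal, e2 = e3 × e1. When the two axes are
not parallel the normal is their cross product; for parallel axes (stacked
helices) the normal falls back to the vector perpendicular to the B axis
within the plane spanned by the axis and the inter-set displacement. Each
conformer is anchored on set A before measurement, so the angles report
set B's motion relative to set A and are invariant to global rigid motion.
Conventions: **twist** = in-plane rotation about the interface normal,
**bend** = out-of-plane elevation toward the normal, **tilt** = change of
the inter-axis angle. (The twist/bend naming follows the constructed
rotation semantics — a rotation of one sheet about the interface normal
reads out as twist.) Axis sets whose top two inertia eigenvalues nearly
coincide are flagged degenerate per conformer.

## Structural alphabet and nMI networks

A fragment is four consecutive Cα of one chain (windows never cross
chains). Its descriptor is scale-free: the planar angles at triples
(1,2,3), (2,3,4), (1,3,4) and the torsion of (1,2,3,4), the torsion
embedded as (cos τ, sin τ) so Euclidean distance respects periodicity.
Encoding assigns the nearest prototype, ties to the lowest letter index.

The bundled 25-letter table (`data/alphabet25.tsv`) is **generic and
self-generated**: k-means centers fit once, seeded, on descriptors from
idealized helix, strand and random-coil builds with jitter. It is not a
literature alphabet; it simply spans the descriptor space well enough to
discretize conformers. `fit_alphabet` fits K prototypes de novo from any
ensemble (seeded k-means) when a data-adapted alphabet is preferable.

nMI uses plug-in entropies in natural log; the finite-size correction is
the Miller–Madow bias (r_i − 1)(r_j − 1)/2M with r the number of observed
letters — a closed-form estimate of the expected positive bias of plug-in
mutual information at sample size M. nMI is clipped to [0, 1]; a constant
joint column (H = 0) is defined as nMI = 0. Network retention applies
three filters: nMI > 0.15, window separation > 4 residues (or different
chains), and nMI above mean + 2s of the all-pairs corrected-nMI
distribution (s = population standard deviation). Centrality is the
leading eigenvector of the retained symmetric nMI matrix, unit-normalized,
non-negative; disconnected graphs are handled on the full matrix, where
the Perron vector concentrates on the dominant component. Per-residue
profiles average the centrality of the windows covering each residue.

## Frustration

The decoy scheme is mutational: geometry fixed, both residue identities
replaced. Decoys are drawn **without replacement** from the 400 ordered
identity combinations, so h = 400 is exactly the exhaustive enumeration
and sampled indices converge to it as h grows. The index is
(decoy mean − native)/decoy sd (population sd), so a native energy at the
favourable end of the decoy distribution scores positive — consistent with
the relaxed threshold being the positive one (+0.78) and stressed the
negative one (−1). The index is invariant to shifting the energy table by
a constant or scaling it by k > 0. Zero decoy sd leaves the index
undefined (NaN), the class neutral, and the contact flagged.

The default energy table is a hydrophobicity-product potential,
e(a,b) = −h(a)·h(b)/25 on the Kyte–Doolittle scale: matched hydrophobic
pairs are favourable, hydrophobic–polar mismatches unfavourable. It is a
deliberately simple knowledge-based stand-in with the qualitative
structure the frustration statistic needs; any 20×20 symmetric table can
be injected, and every frustration property tested (oracle convergence,
affine invariance, threshold semantics) is table-agnostic.

## Coevolution and rvET

Frequencies are redundancy-weighted (weight 1/n_neighbours at 80%
identity, identity measured over the full alignment length). Gaps are
excluded from frequencies; columns above 50% gaps are excluded from pair
scoring. The default raw score S_r is mutual information with the
average-product correction; it sits behind a scorer interface because the
scaling, separation, tiering and mapping logic are scorer-independent —
any function producing an (L, L) score matrix plugs in. Scaled scores
S_s = S_r / mean(S_r) average exactly 1 by construction; ranking uses the
raw score (the scaled ordering inverts if the raw mean is negative, which
can happen on pathological inputs). Pairs at separation ≤ 3 are never
scored. The contact-probability column is a pass-through annotation: it
requires an external scorer's calibration and is not recomputed here.

rvET cuts the tree into n = 1..N−1 groups by repeatedly splitting the
current subtree root closest to the overall root (path length, stable
tie-break), which mirrors dendrogram cuts at increasing depth. Weights:
w_node(n) = 1/n and w_group(g) ∝ 1/|g|, normalized over the n groups —
the weighting is under-determined in the source formulation; this choice
gives the required limiting behaviour (fully conserved → exactly 1; a
column whose entropy is uniform across groupings ranks by entropy) and is
recorded here as the package's convention. Group entropies are unweighted
within groups.

## Phylogenetics

Distances: fractional difference over ungapped column pairs, optionally
Kimura-corrected, −ln(1 − d − d²/5); the correction diverges near random
similarity, so the argument is floored at 0.01 (distance cap ≈ 4.6) with a
logged count — the standard saturation treatment. Neighbor joining is
delegated to dendropy; negative NJ branch lengths are clamped to zero with
the original value recorded on the node. Tree similarity r is the Pearson
correlation of the two trees' paired pairwise tip-distance vectors over
shared tips (tips are paired by identifier; unmatched tips are dropped
with a logged count). All-pairs distances are used rather than root-tip
depths because the statistic indexes one vector per tree. ΔX̄ is the mean
pairwise path distance within a tip subset. Greedy clustering is
longest-first with first-fit assignment (identity via edit distance);
the outcome depends on input order by construction, which is documented
and tested rather than hidden. H:P flags use the population standard
deviation of the *other* clades' finite ratios; infinite ratios (zero P)
are reported but excluded from the comparison mean.

## Sectors

Fragment-level network edges project to residue pairs (all 4×4 pairs of
the two windows, weight split evenly). Sectors are connected components of
the coevolved-edge subgraph; each component is expanded by one contact
step (configurable) and labelled by the majority interface class among the
contacts it touches — ties become `mixed`, components touching no
interface `unassigned`, never silent. Per-sector frustration counts are
computed on the component's internal edges and agree with the energetics
module's counts restricted to those contacts. The partition is
deterministic and independent of edge input order.

## Synthetic generators

The generators produce the statistics the pipeline measures, with known
ground truth serialized beside every dataset; they do not attempt real
fold geometry or real sequence composition.

* **Structures**: ideal Cα helices (radius 0.23 nm, rise 0.15 nm/residue,
  100°/residue → 0.38 nm Cα spacing) on a grid with 0.95 nm axis spacing,
  giving non-clashing chains with genuine interface contacts; vertical
  and lateral chain-pair roles are fixed by the layout.
* **Ensembles**: planted orthonormal internal modes (orthogonalized
  against rigid-body translations/rotations so superposition does not
  distort the spectrum) with Gaussian amplitudes set by the requested
  variance fractions, plus isotropic residual noise in the orthogonal
  complement. Default per-coordinate scale 0.15 nm reproduces rmsf values
  in the 0.2–0.3 nm range typical of native ensembles. Planted fragment
  couplings are two-state kinks of the window's middle residues (default
  0.08→0.2 nm amplitude), the partner window copying the state with a
  configurable error rate; coupling fixtures use a smaller residual
  (coord_sigma 0.05 nm) because real local geometry is dominated by
  collective motion, not per-atom noise, and fragment letters read local
  geometry. This is a planted-statistics model, **not** a force field:
  passing tests show the estimators recover known truth, not that the
  generator reproduces any real protein's dynamics.
* **Trees**: Kingman-style coalescents, optionally with monophyletic
  labelled clades joined along a backbone, and an optional constant
  terminal-branch extension (default 0.5 in the MSA fixtures) emulating
  the long terminal branches of identity-clustered sequence sets.
* **MSAs**: uniform-exchangeability substitution along the tree
  (probability 1 − exp(−rate·length) per site per branch). Covarying
  column pairs follow a latent multi-state variable (default 6
  compensatory states) evolving at the same rate; both columns read the
  same tip state with per-column error 1 − strength (default 0.9).
  Several compensatory states are needed because deep shared ancestry
  induces genuine mutual information between *independent* columns
  (phylogenetic confounding); a binary state's ln 2 ceiling can fall below
  that background, a multi-state pair's cannot at these depths. No
  substitution-model realism is claimed.
* **Sector systems**: two randomly wired coevolving communities, each
  touching a different interface class; inter-community edges are planted
  in the dynamic layer only, matching the sector definition (components of
  the coevolved subgraph).

## Problem sizes

Defaults used by the test suite and the acceptance script: 50-residue
builds with 20,000-conformer ensembles for spectrum recovery and 8,000 for
subset convergence; 400-sequence, 60-column MSAs over 20 seeds for
coevolution recovery; 50 random trees of 4–12 taxa for NJ exactness and
100 random 20-tip pairs for the similarity null; 20 seeded two-community
systems for sector recovery. These sizes give sampling errors comfortably
inside the tolerances being checked while keeping a full run in minutes on
one core.

## Known limitations

Cα-only energetics and a hydrophobicity-product potential are qualitative;
the constraint engine samples a native basin and makes no claim about
barrier crossing or kinetics; the coevolution default is MI/APC, not a
pseudo-likelihood model, so absolute raw scores are not comparable to
pseudo-likelihood outputs (the scaled-score machinery is scorer-agnostic
by design); rvET group weighting is a convention, stated above; greedy
clustering is order-dependent; tree statistics assume tip identifiers can
be paired across trees.
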