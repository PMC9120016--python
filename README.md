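# dynevo

**dynevo** links the conformational dynamics of an oligomeric protein
assembly to its molecular evolution. The motivating system is the CaMKII
holoenzyme: a ring-shaped hub of association domains (AD) whose vertical
(inter-stack, "Vert-Dim") and lateral (intra-stack, "Lat-Dim") dimer
interfaces propagate conformational fluctuations between subunits, while
the same interfaces sit under very different evolutionary pressure. The
package provides the full analysis chain needed to ask, for any such
fold: *which residue networks move together, which coevolve, which
contacts are energetically optimized versus metastable — and how do these
partition the fold into sectors tied to its interfaces?*

It is a library first: import the modules, or run the narrative scripts in
`examples/`. A thin `dynevo` CLI drives the same stages from a shell.

## What it computes

**Conformational ensembles** (`ensemble`). A reduced, Cα-only analogue of
geometry-based conformer generators: distance bounds from the native
structure (tight for bonded neighbours, ±15% for native contacts, with a
stochastic retention rule emulating solvent-destabilized bond removal) are
satisfied by random displacement plus iterative correction (up to 500
sweeps). Flexibility is the per-residue rmsf about the reference.

**Essential dynamics** (`dynamics`). PCA of the Cα covariance after
best-fit superposition; variance fractions λ_k / Σλ; convergence via the
root-mean-square inner product (RMSIP) between the top-k mode sets of
ensemble subsets; interface hinge descriptors (tilt / twist / bend angles
of β-sheet long axes).

**Dynamic coupling networks** (`couplings`). Conformers are encoded as
1D strings of four-residue fragment letters from a structural alphabet.
Correlation between fragment columns i, j is the bias-corrected normalized
mutual information

```
nMI(Ci; Cj) = ( I(Ci; Cj) − ε(Ci; Cj) ) / H(Ci,Cj)
```

with ε the Miller–Madow finite-size bias (r_i−1)(r_j−1)/2M (natural log
throughout). Top couplings (nMI > 0.15, fragment separation > 4, above
the 2s significance cut) form a network; node importance is eigenvector
centrality, E·λ = M_corr·E.

**Contact frustration** (`energetics`). Each native contact is z-scored
against decoys that randomize the two residue identities:

```
ΔE_fr = ( mean(E_decoy) − E_native ) / sd(E_decoy)
```

ΔE_fr > 0.78 → relaxed (minimally frustrated); ΔE_fr < −1 → stressed
(highly frustrated). h = 400 enumerates every identity combination.

**MSA evolution statistics** (`evolution`). Column conservation entropy
s_i = −Σ_a f_ia ln f_ia; coevolution via a plug-in scorer (default:
APC-corrected, redundancy-weighted mutual information) with the scaled
score S_s = S_r / mean(S_r), tiers S_s > 1.4 (top) and S_s > 0.5
(extended), and the alignment-depth figure T = Nseq/L; and the real-valued
Evolutionary Trace

```
rvET_i = 1 + Σ_{n=1..N−1} w_node(n) Σ_g w_group(g) · s_i(g)
```

over the groups obtained by cutting the phylogenetic tree into n parts
(fully conserved column → rvET = 1).

**Phylogenetics** (`phylo`). Kimura-corrected distances, neighbor joining,
tree-topology similarity as the Pearson r of paired pairwise tip-distance
vectors, mean tip distance ΔX̄ as a diversity measure, greedy identity
clustering (0.8 then 0.6 cutoffs), and clade composition statistics with
the homeotherm:poikilotherm (H:P) ratio flagged when outside mean ± 2s of
the other clades.

**Sectors** (`sector`). Dynamic couplings, coevolved pairs and frustration
classes are overlaid on one residue graph; connected components of the
coevolved subgraph, labelled by the interface class they touch, are the
fold's sectors.

**Synthetic data** (`synthetic`). Seed-deterministic generators for every
input class — idealized multi-chain structures with designated interfaces,
ensembles with planted mode spectra and fragment couplings, MSAs evolved
along known trees with planted covarying pairs, labelled coalescent trees
— each emitting a serialized ground truth, so the whole pipeline is
testable offline.

## Worked example

```
$ python examples/02_pca_and_convergence.py
planted fractions : [0.46, 0.14, 0.1]
recovered PC1–3   : [0.463, 0.137, 0.099]
cumulative PC1–3  : 0.699 (the essential subspace carries most of the motion)
RMSIP of two disjoint quarter-subsets (k=10): 0.9988 (≥ 0.99 means the sampling has converged)
```

The generator plants three collective modes carrying 46%, 14% and 10% of
the total variance; PCA returns those fractions to within a few parts per
thousand, and disjoint quarter-subsets of a converged ensemble agree on
their ten leading modes (RMSIP 0.999), the standard sign that the sampled
motion is reproducible rather than noise. The other examples walk through
the coupling network (`03`), frustration classes by interface (`04`),
coevolution / rvET / tree statistics (`05`) and sector recovery (`06`).

The same stages run from the shell:

```
dynevo all --seed 7 --out run_out      # synth → … → sector, with manifests
dynevo list-defaults                   # every threshold and its provenance
```

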