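"""Generate a constraint-based conformational ensemble and its rmsf profile.

A four-chain idealized assembly stands in for an oligomeric hub; distance
bounds derived from its native contacts are sampled by random displacement
plus iterative correction, and the per-residue flexibility (rmsf, nm) is
measured about the reference structure.
"""

import numpy as np

from dynevo import ensemble, synthetic

s, cmap, _ = synthetic.synth_structure(n_res=12, layout="tetramer", seed=0)
print(f"structure: {len(s.chains)} chains, {s.n_residues} residues, "
      f"{len(cmap)} native contacts")

cset = ensemble.build_constraints(s, retain_fraction=0.9, seed=0)
e = ensemble.generate(s, cset, m=200, displacement_limit=0.2, seed=0)
print(f"ensemble: {e.m} conformers accepted, {e.rejected} rejected, "
      f"{len(cset)} distance bounds all satisfied: {ensemble.check_bounds(e, cset)}")

prof = ensemble.rmsf(e)
print(f"rmsf (nm): mean {prof.rmsf.mean():.3f}, "
      f"min {prof.rmsf.min():.3f}, max {prof.rmsf.max():.3f}")
print("Chain-end residues fluctuate most; bounds keep the native fold intact.")
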