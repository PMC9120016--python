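"""Constraint-based conformational ensemble generation.

A reduced-representation analogue of geometry-based conformer generators:
distance bounds are derived from the reference Cα structure (tight bounds
for sequence neighbours, looser bounds for native contacts, with a
stochastic retention rule standing in for predicted-unstable-bond removal),
and conformers are produced by random displacement of every Cα inside a
cube followed by iterative pairwise projection onto violated bounds until
all bounds are satisfied or an iteration cap is reached.  Rejected trials
are counted; accepted conformers satisfy every bound within tolerance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from dynevo.structio import Structure, contacts as _contacts, kabsch

#: bound-satisfaction tolerance (nm) applied when accepting a conformer
BOUND_TOL = 1e-3

BOND_SLACK = 0.05     # ±5% of native distance for sequence neighbours
CONTACT_SLACK = 0.15  # ±15% for native contacts


@dataclass
class ConstraintSet:
    """Distance bounds (nm) between Cα indices, with a provenance rule each."""

    bounds: list[tuple[int, int, float, float]]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, j, dmin, dmax in self.bounds:
            if i == j:
                raise ValueError(f"self bound on index {i}")
            if dmin > dmax:
                raise ValueError(f"d_min > d_max for ({i},{j})")
        if not self.provenance:
            self.provenance = ["unknown"] * len(self.bounds)
        if len(self.provenance) != len(self.bounds):
            raise ValueError("provenance length mismatch")

    def __len__(self) -> int:
        return len(self.bounds)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        arr = np.array([(i, j, lo, hi) for i, j, lo, hi in self.bounds], float)
        if arr.size == 0:
            z = np.zeros(0)
            return z.astype(int), z.astype(int), z, z
        return arr[:, 0].astype(int), arr[:, 1].astype(int), arr[:, 2], arr[:, 3]


@dataclass
class Ensemble:
    """M conformers sharing one topology; coords (M, N, 3) in nm."""

    topology: Structure
    coords: np.ndarray
    seed: int = 0
    accepted: int = 0
    rejected: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 3 or self.coords.shape[1] != self.topology.n_residues:
            raise ValueError(f"bad ensemble shape {self.coords.shape}")
        if self.accepted == 0:
            self.accepted = self.coords.shape[0]

    @property
    def m(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    def save(self, prefix: str | Path) -> None:
        """Persist coords as .npy plus a JSON sidecar with provenance."""
        prefix = Path(prefix)
        np.save(prefix.with_suffix(".npy"), self.coords)
        meta = {
            "seed": self.seed,
            "accepted": self.accepted,
            "rejected": self.rejected,
            "m": self.m,
            "n_residues": self.n_residues,
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))


@dataclass
class FlexProfile:
    rmsf: np.ndarray            # per-residue, nm
    reference: Literal["crystal", "mean"]

    def __post_init__(self) -> None:
        self.rmsf = np.asarray(self.rmsf, float)
        if np.any(self.rmsf < 0):
            raise ValueError("negative rmsf")


def build_constraints(
    s: Structure,
    contact_cutoff: float = 0.8,
    retain_fraction: float = 1.0,
    seed: int = 0,
) -> ConstraintSet:
    """Derive distance bounds from the reference structure.

    Sequence-neighbour (bonded) bounds are always present at ±5% of the
    native distance.  Native-contact bounds (±15%) are each kept with
    probability *retain_fraction* (seeded), emulating the removal of
    contacts predicted unstable in solvent.
    """
    if s.n_residues == 0:
        raise ValueError("empty structure")
    if not 0.0 <= retain_fraction <= 1.0:
        raise ValueError("retain_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    bounds: list[tuple[int, int, float, float]] = []
    prov: list[str] = []
    # bonded: consecutive residues within each chain
    bonded = set()
    for chain in s.chains:
        idx = s.chain_indices(chain)
        for a, b in zip(idx[:-1], idx[1:]):
            d = float(np.linalg.norm(s.coords[a] - s.coords[b]))
            bounds.append((int(a), int(b), d * (1 - BOND_SLACK), d * (1 + BOND_SLACK)))
            prov.append("bonded")
            bonded.add((int(a), int(b)))
    # native contacts (any separation ≥ 2 same-chain, any cross-chain)
    cmap = _contacts(s, cutoff=contact_cutoff, min_seq_sep=2)
    for a, b in cmap.pairs:
        i = s.index_of(a[0], a[1])
        j = s.index_of(b[0], b[1])
        if (min(i, j), max(i, j)) in bonded:
            continue
        if rng.random() > retain_fraction:
            continue
        d = cmap.distances[(a, b)]
        bounds.append(
            (i, j, d * (1 - CONTACT_SLACK), d * (1 + CONTACT_SLACK))
        )
        prov.append("contact")
    return ConstraintSet(bounds=bounds, provenance=prov)


def generate(
    s: Structure,
    c: ConstraintSet,
    m: int,
    displacement_limit: float = 0.2,
    max_iter: int = 500,
    seed: int = 0,
    probe: int = 200,
) -> Ensemble:
    """Generate *m* bound-satisfying conformers.

    Each trial displaces every Cα uniformly within a cube of side
    *displacement_limit* (nm) about the reference, then repeatedly projects
    violated bounds (processed in seeded random order each sweep, both
    atoms moved half-way) until all bounds hold within tolerance or
    *max_iter* sweeps elapse.  Failed trials are rejected and recounted;
    if fewer than 1% of the first *probe* trials are accepted the
    constraint set is declared infeasible.
    """
    if m < 1:
        raise ValueError("m must be ≥ 1")
    if max_iter < 1:
        raise ValueError("max_iter must be ≥ 1")
    rng = np.random.default_rng(seed)
    ii, jj, lo, hi = c.as_arrays()
    ref = s.coords
    out = np.empty((m, s.n_residues, 3))
    accepted = 0
    rejected = 0
    trials = 0
    order = np.arange(len(ii))
    while accepted < m:
        trials += 1
        x = ref + rng.uniform(
            -displacement_limit / 2, displacement_limit / 2, size=ref.shape
        )
        ok = len(ii) == 0
        for _ in range(max_iter):
            d = np.linalg.norm(x[ii] - x[jj], axis=1)
            viol_mask = (d < lo - BOUND_TOL) | (d > hi + BOUND_TOL)
            if not viol_mask.any():
                ok = True
                break
            rng.shuffle(order)
            for k in order:
                if not viol_mask[k]:
                    continue
                i, j = ii[k], jj[k]
                v = x[j] - x[i]
                dist = np.linalg.norm(v)
                if dist < 1e-9:
                    v = rng.standard_normal(3)
                    dist = np.linalg.norm(v)
                target = np.clip(dist, lo[k], hi[k])
                corr = (dist - target) / dist * v / 2.0
                x[i] += corr
                x[j] -= corr
        if ok:
            out[accepted] = x
            accepted += 1
        else:
            rejected += 1
        if trials == probe and accepted < max(1, probe // 100):
            raise RuntimeError(
                f"infeasible constraints: {accepted}/{trials} trials accepted"
            )
    return Ensemble(topology=s, coords=out, seed=seed, accepted=accepted, rejected=rejected)


def check_bounds(e: Ensemble, c: ConstraintSet, tol: float = BOUND_TOL) -> bool:
    """True iff every conformer satisfies every bound within *tol* (nm)."""
    ii, jj, lo, hi = c.as_arrays()
    if len(ii) == 0:
        return True
    d = np.linalg.norm(e.coords[:, ii] - e.coords[:, jj], axis=2)
    return bool(np.all((d >= lo - tol) & (d <= hi + tol)))


def superpose_ensemble(e: Ensemble, ref: np.ndarray | None = None) -> np.ndarray:
    """Best-fit every conformer onto *ref* (default: topology coords)."""
    if ref is None:
        ref = e.topology.coords
    out = np.empty_like(e.coords)
    for k in range(e.m):
        rot, trans, _ = kabsch(ref, e.coords[k])
        out[k] = e.coords[k] @ rot.T + trans
    return out


def rmsf(e: Ensemble, reference: str = "crystal") -> FlexProfile:
    """Per-residue Cα root-mean-square fluctuation (nm).

    Each conformer is best-fit superposed onto the reference before the
    deviation is accumulated.  ``reference="crystal"`` measures about the
    topology (crystal) coordinates; ``"mean"`` measures about the ensemble
    mean after crystal fitting.
    """
    if e.m < 2:
        raise ValueError("need at least 2 conformers")
    fitted = superpose_ensemble(e)
    if reference == "crystal":
        ref = e.topology.coords
    elif reference == "mean":
        ref = fitted.mean(axis=0)
    else:
        raise ValueError("reference must be 'crystal' or 'mean'")
    dev = fitted - ref
    vals = np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))
    return FlexProfile(rmsf=vals, reference=reference)  # type: ignore[arg-type]
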