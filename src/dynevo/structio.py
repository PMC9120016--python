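"""Structure I/O on a reduced Cα representation.

Structures are read from PDB files and reduced to one Cα per residue.  All
coordinates are held internally in nanometres (PDB ångströms are converted
on read and write).  Residue identity is the author-assigned
(chain, number, insertion code) triple; internal indices are 0-based.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

NM_PER_ANGSTROM = 0.1

#: key identifying a residue in a contact map: (chain id, author number)
ResidueKey = tuple[str, int]

INTERFACE_CLASSES = ("intra", "vert_dim", "lat_dim", "kd_ad")


class Residue(NamedTuple):
    chain: str
    number: int
    icode: str
    aa: str


@dataclass
class Structure:
    """Cα-only protein structure with author numbering preserved."""

    id: str
    residues: list[Residue]
    coords: np.ndarray  # (N, 3) in nm

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.residues), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.residues)} residues"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain, None)
        return list(seen)

    def chain_indices(self, chain: str) -> np.ndarray:
        """0-based indices of the residues belonging to *chain*, in order."""
        return np.array([i for i, r in enumerate(self.residues) if r.chain == chain])

    def index_of(self, chain: str, number: int, icode: str = "") -> int:
        for i, r in enumerate(self.residues):
            if r.chain == chain and r.number == number and r.icode == icode:
                return i
        raise KeyError(f"residue {chain}/{number}{icode} not found")

    def sequence(self, chain: str | None = None) -> str:
        return "".join(
            r.aa for r in self.residues if chain is None or r.chain == chain
        )

    def subset(self, chains: Iterable[str]) -> "Structure":
        chains = list(chains)
        idx = [i for i, r in enumerate(self.residues) if r.chain in chains]
        missing = set(chains) - {r.chain for r in self.residues}
        if missing:
            raise KeyError(f"chains not present: {sorted(missing)}")
        return Structure(
            id=self.id,
            residues=[self.residues[i] for i in idx],
            coords=self.coords[idx],
        )


@dataclass
class ContactMap:
    """Symmetric set of Cα–Cα contacts with optional interface classes.

    Pairs are stored once with a canonical (sorted) key ordering; distances
    in nm.  ``interface_class`` defaults to ``intra`` and is reassigned by
    :meth:`classify_interfaces` from a user-supplied chain-pair role map —
    interface roles are configuration, not inference.
    """

    pairs: list[tuple[ResidueKey, ResidueKey]]
    distances: dict[tuple[ResidueKey, ResidueKey], float]
    interface_class: dict[tuple[ResidueKey, ResidueKey], str] = field(
        default_factory=dict
    )
    cutoff: float = np.inf

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self pair {a}")
        for p, d in self.distances.items():
            if d > self.cutoff + 1e-12:
                raise ValueError(f"pair {p} distance {d} exceeds cutoff {self.cutoff}")
        for p in self.pairs:
            self.interface_class.setdefault(p, "intra")

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[ResidueKey, ResidueKey]) -> bool:
        return canonical_pair(*pair) in self.distances

    def residues(self) -> set[ResidueKey]:
        return {k for p in self.pairs for k in p}

    def classify_interfaces(self, roles: Mapping[frozenset, str]) -> None:
        """Assign interface classes from a chain-pair role map.

        ``roles`` maps ``frozenset({chainA, chainB})`` to one of
        ``vert_dim | lat_dim | kd_ad``.  Same-chain pairs stay ``intra``;
        cross-chain pairs without a role also stay ``intra``.
        """
        bad = set(roles.values()) - set(INTERFACE_CLASSES)
        if bad:
            raise ValueError(f"unknown interface classes: {sorted(bad)}")
        for a, b in self.pairs:
            if a[0] != b[0]:
                role = roles.get(frozenset((a[0], b[0])))
                if role is not None:
                    self.interface_class[(a, b)] = role

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chainA\tresA\tchainB\tresB\tdist_nm\tclass\n")
            for a, b in self.pairs:
                fh.write(
                    f"{a[0]}\t{a[1]}\t{b[0]}\t{b[1]}\t"
                    f"{self.distances[(a, b)]:.4f}\t{self.interface_class[(a, b)]}\n"
                )


def canonical_pair(a: ResidueKey, b: ResidueKey) -> tuple[ResidueKey, ResidueKey]:
    return (a, b) if a <= b else (b, a)


def read_pdb(
    path: str | Path,
    model: int = 0,
    chain_filter: Sequence[str] | None = None,
) -> Structure:
    """Read a PDB file into a Cα-only :class:`Structure`.

    Coordinates are converted from Å to nm.  Residues without a Cα atom are
    skipped (count logged).  Only the first altloc is used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        parser = PDBParser(QUIET=True)
        struct = parser.get_structure(path.stem, str(path))
    models = list(struct)
    if model >= len(models):
        raise ValueError(f"model {model} not present ({len(models)} models)")
    mdl = models[model]
    available = [c.id for c in mdl]
    if chain_filter is not None:
        missing = set(chain_filter) - set(available)
        if missing:
            raise KeyError(f"chains not in file: {sorted(missing)}")
        chain_order = [c for c in chain_filter]
    else:
        chain_order = available

    residues: list[Residue] = []
    xyz: list[np.ndarray] = []
    skipped = 0
    for cid in chain_order:
        chain = mdl[cid]
        for res in chain:
            if "CA" not in res:
                if res.id[0] == " ":
                    skipped += 1
                continue
            ca = res["CA"]
            if ca.is_disordered():
                ca = ca.disordered_get_list()[0]
            resname = res.get_resname().strip()
            aa = protein_letters_3to1.get(resname, "X")
            residues.append(
                Residue(
                    chain=cid,
                    number=res.id[1],
                    icode=res.id[2].strip(),
                    aa=aa,
                )
            )
            xyz.append(ca.get_coord() * NM_PER_ANGSTROM)
    if skipped:
        logger.info("read_pdb(%s): skipped %d residues without Cα", path, skipped)
    if not residues:
        raise ValueError("zero Cα atoms")
    return Structure(id=path.stem, residues=residues, coords=np.array(xyz))


def contacts(s: Structure, cutoff: float = 0.8, min_seq_sep: int = 3) -> ContactMap:
    """All Cα pairs within *cutoff* (nm).

    Same-chain pairs require a residue-index separation of at least
    *min_seq_sep*; cross-chain pairs are kept at any separation.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    tree = cKDTree(s.coords)
    raw = tree.query_pairs(cutoff, output_type="ndarray")
    pairs: list[tuple[ResidueKey, ResidueKey]] = []
    dists: dict[tuple[ResidueKey, ResidueKey], float] = {}
    # position of each residue within its chain, for the separation rule
    chain_pos: dict[str, int] = {}
    pos = np.empty(s.n_residues, dtype=int)
    for i, r in enumerate(s.residues):
        pos[i] = chain_pos.get(r.chain, 0)
        chain_pos[r.chain] = pos[i] + 1
    for i, j in raw:
        ri, rj = s.residues[i], s.residues[j]
        if ri.chain == rj.chain and abs(int(pos[i]) - int(pos[j])) < min_seq_sep:
            continue
        key = canonical_pair((ri.chain, ri.number), (rj.chain, rj.number))
        pairs.append(key)
        dists[key] = float(np.linalg.norm(s.coords[i] - s.coords[j]))
    pairs.sort()
    return ContactMap(pairs=pairs, distances=dists, cutoff=cutoff)


def superpose(
    a: Structure,
    b: Structure,
    mapping: Sequence[tuple[tuple[str, int], tuple[str, int]]] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of *b* onto *a* over mapped Cα.

    ``mapping`` is a list of ((chainA, resnumA), (chainB, resnumB)) pairs;
    ``None`` means positional identity (requires equal lengths).  Returns
    ``(rotation, translation, rmsd_nm)`` such that
    ``b' = coords_b @ rotation.T + translation`` best fits *a*.
    """
    if mapping is None:
        if a.n_residues != b.n_residues:
            raise ValueError("positional mapping requires equal residue counts")
        ia = np.arange(a.n_residues)
        ib = np.arange(b.n_residues)
    else:
        if len(mapping) < 3:
            raise ValueError("underdetermined: need at least 3 mapped residues")
        ia = np.array([a.index_of(*ra) for ra, _ in mapping])
        ib = np.array([b.index_of(*rb) for _, rb in mapping])
    if len(ia) < 3:
        raise ValueError("underdetermined: need at least 3 mapped residues")
    return kabsch(a.coords[ia], b.coords[ib])


def kabsch(
    ref: np.ndarray, mov: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rotation/translation of point set *mov* onto *ref* (Kabsch)."""
    ref = np.asarray(ref, float)
    mov = np.asarray(mov, float)
    cr = ref.mean(axis=0)
    cm = mov.mean(axis=0)
    h = (mov - cm).T @ (ref - cr)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cr - rot @ cm
    moved = mov @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return rot, trans, rmsd


def write_scored_pdb(
    s: Structure,
    scores: Sequence[float] | Mapping[ResidueKey, float] | None,
    path: str | Path,
    fill: float | None = None,
) -> None:
    """Write the structure as CA-only ATOM records, scores in the B-factor.

    *scores* may be a per-residue sequence (length N), a mapping from
    (chain, resnum) keys, or None (then *fill* or 0).  Coordinates are
    written in Å to standard PDB precision (3 decimals), B-factors to 2.
    """
    n = s.n_residues
    if scores is None:
        vals = np.full(n, 0.0 if fill is None else fill)
    elif isinstance(scores, Mapping):
        default = fill
        vals = np.empty(n)
        for i, r in enumerate(s.residues):
            v = scores.get((r.chain, r.number), default)
            if v is None:
                raise ValueError(f"no score for {r.chain}/{r.number} and no fill")
            vals[i] = v
    else:
        if len(scores) != n:
            if fill is None:
                raise ValueError(
                    f"{len(scores)} scores for {n} residues and no fill value"
                )
            vals = np.full(n, fill)
            vals[: len(scores)] = scores
        else:
            vals = np.asarray(scores, float)

    one_to_three = {v: k for k, v in protein_letters_3to1.items()}
    with open(path, "w") as fh:
        serial = 1
        for i, r in enumerate(s.residues):
            x, y, z = s.coords[i] / NM_PER_ANGSTROM
            resname = one_to_three.get(r.aa, "UNK")
            fh.write(
                f"ATOM  {serial:>5d}  CA  {resname:<3s} {r.chain:1s}"
                f"{r.number:>4d}{r.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{vals[i]:6.2f}"
                f"          {'C':>2s}\n"
            )
            serial += 1
        fh.write("END\n")
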