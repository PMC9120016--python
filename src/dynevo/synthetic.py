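"""Seed-deterministic synthetic generators with serialized ground truth.

Every input class the pipeline consumes can be generated here with known
ground truth: idealized multi-chain Cα structures with designated
vertical/lateral interface contact sets, conformational ensembles with a
planted low-rank mode spectrum and planted fragment–fragment couplings,
MSAs evolved along a known tree with planted covarying column pairs and
inherited tip labels, annotated coalescent trees with planted clade
compositions, and two-community interface-wired overlay graphs for sector
recovery.  Generators emulate the statistics the pipeline measures, not
the physics or sequence composition of any real protein.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import networkx as nx
import numpy as np

from dynevo.energetics import AMINO_ACIDS
from dynevo.ensemble import Ensemble
from dynevo.evolution import MSA
from dynevo.phylo import AnnotatedTree
from dynevo.structio import ContactMap, Residue, ResidueKey, Structure, contacts

# idealized Cα helix geometry: ~0.38 nm between consecutive Cα
HELIX_RADIUS = 0.23
HELIX_RISE = 0.15
HELIX_TURN_DEG = 100.0
CLASH_NM = 0.35


@dataclass
class GroundTruth:
    """Planted truth serialized alongside every generated dataset."""

    kind: str
    seed: int
    data: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        payload = {"kind": self.kind, "seed": self.seed, "data": self.data}
        Path(path).write_text(json.dumps(payload, indent=1, default=_jsonable))

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# structures


def _helix_coords(n: int) -> np.ndarray:
    i = np.arange(n)
    theta = np.radians(HELIX_TURN_DEG) * i
    return np.stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * i],
        axis=1,
    )


_LAYOUTS = {
    "monomer": {"chains": ["A"], "offsets": {"A": (0.0, 0.0)}, "roles": {}},
    "dimer": {
        "chains": ["A", "C"],
        "offsets": {"A": (0.0, 0.0), "C": (0.0, 0.95)},
        "roles": {frozenset("AC"): "vert_dim"},
    },
    "tetramer": {
        "chains": ["A", "C", "G", "I"],
        "offsets": {
            "A": (0.0, 0.0),
            "C": (0.0, 0.95),
            "I": (0.95, 0.0),
            "G": (0.95, 0.95),
        },
        "roles": {
            frozenset("AC"): "vert_dim",
            frozenset("GI"): "vert_dim",
            frozenset("AI"): "lat_dim",
            frozenset("CG"): "lat_dim",
        },
    },
}


def synth_structure(
    n_res: int = 20,
    layout: str = "tetramer",
    seed: int = 0,
) -> tuple[Structure, ContactMap, GroundTruth]:
    """Idealized multi-chain Cα build with designated interface contacts.

    Chains are ideal Cα helices placed on a grid; the ``dimer`` layout has
    a vertical (vert_dim) interface, the ``tetramer`` layout both vertical
    and lateral (lat_dim) interfaces.  A deterministic sequence is assigned
    from a seeded RNG.  Layouts with Cα clashes below 0.35 nm are rejected.
    """
    if n_res < 8:
        raise ValueError("need at least 8 residues per chain")
    if layout not in _LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}")
    spec = _LAYOUTS[layout]
    rng = np.random.default_rng(seed)
    residues: list[Residue] = []
    coords = []
    base = _helix_coords(n_res)
    for chain in spec["chains"]:
        dx, dy = spec["offsets"][chain]
        xyz = base + np.array([dx, dy, 0.0])
        for k in range(n_res):
            residues.append(
                Residue(chain=chain, number=k + 1, icode="",
                        aa=AMINO_ACIDS[rng.integers(20)])
            )
        coords.append(xyz)
    s = Structure(id=f"synth_{layout}", residues=residues,
                  coords=np.concatenate(coords, axis=0))
    # clash check across chains
    if len(spec["chains"]) > 1:
        # consecutive same-chain Cα are ~0.38; only non-bonded pairs matter
        if len(contacts(s, cutoff=CLASH_NM, min_seq_sep=2)) > 0:
            raise ValueError("infeasible layout: Cα clash below 0.35 nm")
    cmap = contacts(s, cutoff=0.8, min_seq_sep=3)
    cmap.classify_interfaces(spec["roles"])
    iface = {
        "vert_dim": [p for p, c in cmap.interface_class.items() if c == "vert_dim"],
        "lat_dim": [p for p, c in cmap.interface_class.items() if c == "lat_dim"],
    }
    gt = GroundTruth(
        kind="structure",
        seed=seed,
        data={
            "layout": layout,
            "n_res": n_res,
            "chains": spec["chains"],
            "interfaces": {
                k: [[list(a), list(b)] for a, b in v] for k, v in iface.items()
            },
        },
    )
    return s, cmap, gt


# ---------------------------------------------------------------------------
# ensembles


def _rigid_body_basis(ref: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3N, 6) of rigid translations/rotations at ref."""
    n = ref.shape[0]
    c = ref - ref.mean(axis=0)
    basis = np.zeros((3 * n, 6))
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = 1.0
        basis[:, ax] = t.ravel()
    for ax, vec in enumerate(np.eye(3)):
        r = np.cross(np.tile(vec, (n, 1)), c)
        basis[:, 3 + ax] = r.ravel()
    q, _ = np.linalg.qr(basis)
    return q


def synth_ensemble(
    s: Structure,
    spectrum: Sequence[float] = (0.46, 0.14, 0.10),
    coupled_pairs: Sequence[tuple[int, int]] = (),
    noise: float = 0.0,
    m: int = 2000,
    seed: int = 0,
    coord_sigma: float = 0.15,
    deform: float = 0.2,
) -> tuple[Ensemble, GroundTruth]:
    """Ensemble with a planted mode spectrum and fragment couplings.

    *spectrum* lists the variance fractions of the planted orthonormal
    internal modes (orthogonal to rigid-body motion); the residual
    1 - sum(spectrum) is isotropic noise in the orthogonal complement, so a
    PCA after superposition recovers the planted fractions.  Each pair in
    *coupled_pairs* names two fragment windows (start residue indices)
    that deform in lockstep between two discrete sub-states; the partner
    copies the state with error probability *noise*.  ``coord_sigma`` sets
    the per-coordinate displacement scale (nm); ``deform`` the two-state
    window deformation amplitude (nm).
    """
    if m < 2:
        raise ValueError("m must be ≥ 2")
    spectrum = np.asarray(list(spectrum), float)
    if spectrum.sum() > 1 + 1e-9:
        raise ValueError("spectrum fractions must sum to ≤ 1")
    rng = np.random.default_rng(seed)
    n3 = 3 * s.n_residues
    k = spectrum.size
    rigid = _rigid_body_basis(s.coords)
    raw = rng.standard_normal((n3, k))
    raw -= rigid @ (rigid.T @ raw)
    modes, _ = np.linalg.qr(raw)

    total_var = n3 * coord_sigma**2
    amp_sd = np.sqrt(spectrum * total_var)
    amps = rng.standard_normal((m, k)) * amp_sd
    resid_var = max(0.0, 1.0 - spectrum.sum()) * total_var
    n_free = n3 - k - 6
    sigma_n = np.sqrt(resid_var / n_free) if n_free > 0 else 0.0
    eta = rng.standard_normal((m, n3)) * sigma_n
    eta -= (eta @ rigid) @ rigid.T
    eta -= (eta @ modes) @ modes.T
    disp = amps @ modes.T + eta
    coords = s.coords[None, :, :] + disp.reshape(m, s.n_residues, 3)

    states: dict[str, list[int]] = {}
    if coupled_pairs:
        dirs = rng.standard_normal((len(coupled_pairs), 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        for pidx, (wi, wj) in enumerate(coupled_pairs):
            spin = rng.integers(0, 2, size=m)
            flip = rng.random(m) < noise
            partner = np.where(flip, 1 - spin, spin)
            sgn_i = 2.0 * spin - 1.0
            sgn_j = 2.0 * partner - 1.0
            # kink the window: opposite displacement of the two middle
            # residues changes the internal fragment geometry strongly
            for off, sign in ((1, 1.0), (2, -1.0)):
                coords[:, wi + off] += sign * sgn_i[:, None] * deform * dirs[pidx]
                coords[:, wj + off] += sign * sgn_j[:, None] * deform * dirs[pidx]
            states[f"pair{pidx}"] = spin.tolist()
    e = Ensemble(topology=s, coords=coords, seed=seed)
    gt = GroundTruth(
        kind="ensemble",
        seed=seed,
        data={
            "spectrum": spectrum.tolist(),
            "coupled_pairs": [list(p) for p in coupled_pairs],
            "noise": noise,
            "m": m,
            "coord_sigma": coord_sigma,
            "deform": deform,
            "states": states,
        },
    )
    return e, gt


def converged_spectrum(k: int = 12, total: float = 0.97, decay: float = 0.75) -> np.ndarray:
    """Geometric mode spectrum for convergence studies.

    *k* planted fractions decaying by *decay*, normalized to sum to
    *total*; the small residual keeps the planted subspace far above the
    isotropic noise floor so disjoint ensemble subsets agree in their
    leading modes.
    """
    f = decay ** np.arange(k)
    return total * f / f.sum()


# ---------------------------------------------------------------------------
# trees and MSAs


def _coalescent_subtree(
    labels: list[str], rng: np.random.Generator, taxon_ns, scale: float
):
    """Random Kingman-style coalescent subtree over the given tip labels."""
    nodes = []
    heights = []
    for lab in labels:
        taxon = taxon_ns.require_taxon(label=lab)
        nd = dendropy.Node(taxon=taxon)
        nodes.append(nd)
        heights.append(0.0)
    h = 0.0
    while len(nodes) > 1:
        kk = len(nodes)
        h += float(rng.exponential(scale / (kk * (kk - 1) / 2.0)))
        i, j = rng.choice(kk, size=2, replace=False)
        i, j = int(i), int(j)
        parent = dendropy.Node()
        for idx in sorted((i, j), reverse=True):
            child = nodes.pop(idx)
            ch = heights.pop(idx)
            child.edge.length = h - ch
            parent.add_child(child)
        nodes.append(parent)
        heights.append(h)
    return nodes[0], h


def synth_tree(
    n_tips: int = 16,
    clade_spec: Sequence[dict] | None = None,
    seed: int = 0,
    scale: float = 0.3,
    tip_extend: float = 0.0,
) -> tuple[AnnotatedTree, GroundTruth]:
    """Random coalescent-style tree with planted clade labels.

    *clade_spec* is a list of clade plans, each a dict with keys ``size``
    and optionally ``name``, ``isoform``, ``phylum``, ``n_H``, ``n_P``
    (H/P = homeotherm/poikilotherm tip labels; remaining tips unknown).
    Clades are monophyletic: each is an internal coalescent subtree, and
    clades join a backbone in order.  Without a spec, a single unlabelled
    clade of *n_tips* is built.  *tip_extend* adds a constant length to
    every terminal branch, emulating the long terminal branches of
    identity-clustered sequence sets (tips largely independent given their
    clade).  Same seed → identical Newick string.
    """
    if clade_spec is None:
        clade_spec = [{"size": n_tips}]
    sizes = [int(c["size"]) for c in clade_spec]
    if sum(sizes) != n_tips:
        raise ValueError("clade sizes must sum to n_tips")
    if n_tips < 4:
        raise ValueError("need at least 4 tips")
    for c in clade_spec:
        if c.get("n_H", 0) + c.get("n_P", 0) > c["size"]:
            raise ValueError("infeasible plan: more labels than tips")
    rng = np.random.default_rng(seed)
    taxon_ns = dendropy.TaxonNamespace()
    annotations: dict[str, dict[str, str]] = {}
    clade_tips: dict[str, list[str]] = {}
    subtrees = []
    tip_counter = 0
    for ci, c in enumerate(clade_spec):
        name = c.get("name", f"clade{ci}")
        labels = []
        for kk in range(c["size"]):
            lab = f"t{tip_counter:04d}"
            tip_counter += 1
            labels.append(lab)
            thermo = "unknown"
            if kk < c.get("n_H", 0):
                thermo = "H"
            elif kk < c.get("n_H", 0) + c.get("n_P", 0):
                thermo = "P"
            annotations[lab] = {
                "isoform": c.get("isoform", "none"),
                "phylum": c.get("phylum", "unknown"),
                "thermo": thermo,
            }
        clade_tips[name] = labels
        if len(labels) == 1:
            taxon = taxon_ns.require_taxon(label=labels[0])
            root = dendropy.Node(taxon=taxon)
            subtrees.append((root, 0.0))
        else:
            subtrees.append(_coalescent_subtree(labels, rng, taxon_ns, scale))
    root, h = subtrees[0]
    for nxt, h2 in subtrees[1:]:
        join_h = max(h, h2) + float(rng.exponential(scale))
        parent = dendropy.Node()
        root.edge.length = join_h - h
        nxt.edge.length = join_h - h2
        parent.add_child(root)
        parent.add_child(nxt)
        root, h = parent, join_h
    tree = dendropy.Tree(taxon_namespace=taxon_ns, seed_node=root)
    if tip_extend > 0:
        for leaf in tree.leaf_node_iter():
            leaf.edge.length = (leaf.edge.length or 0.0) + tip_extend
    at = AnnotatedTree(tree=tree, annotations=annotations)
    gt = GroundTruth(
        kind="tree",
        seed=seed,
        data={
            "n_tips": n_tips,
            "clades": {k: v for k, v in clade_tips.items()},
            "spec": list(clade_spec),
            "newick": at.to_newick(),
        },
    )
    return at, gt


def synth_msa(
    t: AnnotatedTree,
    L: int = 60,
    rate: float = 1.0,
    coupled_cols: Sequence[tuple[int, int]] = (),
    coupling_strength: float = 0.9,
    n_states: int = 6,
    seed: int = 0,
) -> tuple[MSA, GroundTruth]:
    """MSA evolved tip-ward along *t* with planted covarying column pairs.

    Ordinary columns substitute independently along each branch with
    probability 1 - exp(-rate·length), to a uniformly random different
    amino acid.  Each coupled column pair follows a latent *n_states*-state
    variable evolving at the same rate; the state dictates a compensatory
    amino acid in both columns, and each tip copies it per column with
    error probability 1 - coupling_strength.  Several compensatory states
    keep the planted mutual information above the co-segregation signal
    deep clades induce between independent columns.  Tip labels are
    inherited from the tree's annotations.
    """
    if L < 20:
        raise ValueError("L must be ≥ 20")
    if rate <= 0:
        raise ValueError("zero substitution rate cannot generate divergence")
    rng = np.random.default_rng(seed)
    coupled_cols = [tuple(p) for p in coupled_cols]
    coupled_set = {c for p in coupled_cols for c in p}
    if len(coupled_set) != 2 * len(coupled_cols):
        raise ValueError("coupled columns overlap")
    if not 2 <= n_states <= 20:
        raise ValueError("n_states must lie in 2..20")
    # n_states compensatory amino acids per coupled column
    pair_states = {}
    for i, j in coupled_cols:
        for col in (i, j):
            pair_states[col] = tuple(
                int(v) for v in rng.choice(20, size=n_states, replace=False)
            )

    tree = t.tree
    root_seq = rng.integers(0, 20, size=L)
    seqs: dict[str, np.ndarray] = {}
    spins_at_tip: dict[str, dict[tuple[int, int], int]] = {}

    def evolve(node, seq, spins):
        for child in node.child_nodes():
            bl = child.edge.length or 0.0
            p_sub = 1.0 - np.exp(-rate * bl)
            cseq = seq.copy()
            hit = rng.random(L) < p_sub
            for col in np.where(hit)[0]:
                if col in coupled_set:
                    continue
                new = rng.integers(0, 19)
                cseq[col] = new if new < cseq[col] else new + 1
            cspins = dict(spins)
            for pair in coupled_cols:
                if rng.random() < p_sub:
                    shift = int(rng.integers(1, n_states))
                    cspins[pair] = (cspins[pair] + shift) % n_states
            if child.is_leaf():
                tip = child.taxon.label
                out = cseq.copy()
                for pair in coupled_cols:
                    for col in pair:
                        if rng.random() < coupling_strength:
                            out[col] = pair_states[col][cspins[pair]]
                        else:
                            out[col] = rng.integers(0, 20)
                seqs[tip] = out
                spins_at_tip[tip] = dict(cspins)
            else:
                evolve(child, cseq, cspins)

    root_spins = {pair: int(rng.integers(0, n_states)) for pair in coupled_cols}
    evolve(tree.seed_node, root_seq, root_spins)
    ids = t.tip_names
    msa = MSA(
        ids=ids,
        seqs=["".join(AMINO_ACIDS[c] for c in seqs[i]) for i in ids],
    )
    gt = GroundTruth(
        kind="msa",
        seed=seed,
        data={
            "L": L,
            "rate": rate,
            "coupled_cols": [list(p) for p in coupled_cols],
            "coupling_strength": coupling_strength,
            "n_states": n_states,
            "tip_labels": {i: t.annotations.get(i, {}) for i in ids},
        },
    )
    return msa, gt


# ---------------------------------------------------------------------------
# sector recovery systems


def synth_sector_system(
    n1: int = 12,
    n2: int = 12,
    inter_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[nx.Graph, ContactMap, GroundTruth]:
    """Two planted coevolving communities wired to different interfaces.

    Community 1 residues touch vert_dim interface contacts, community 2
    lat_dim contacts.  Coevolved edges are intra-community (a random
    connected wiring); a fraction *inter_fraction* of extra edges crosses
    between communities in the dynamic layer only, so the coevolved-edge
    subgraph keeps the communities separable.  Returns an overlay-style
    graph, the interface contact map and the planted membership.
    """
    rng = np.random.default_rng(seed)
    com1 = [("A", i + 1) for i in range(n1)]
    com2 = [("A", 100 + i + 1) for i in range(n2)]
    g = nx.Graph()

    def wire(community: list[ResidueKey]):
        order = list(community)
        rng.shuffle(order)
        for a, b in zip(order[:-1], order[1:]):  # random spanning path
            g.add_edge(a, b, coev_score=2.0, dynamic_weight=0.0, sources="coevolved")
        extra = max(1, len(community) // 2)
        for _ in range(extra):
            i, j = rng.choice(len(community), size=2, replace=False)
            if i != j and not g.has_edge(community[int(i)], community[int(j)]):
                g.add_edge(
                    community[int(i)], community[int(j)],
                    coev_score=1.5, dynamic_weight=0.0, sources="coevolved",
                )

    wire(com1)
    wire(com2)
    n_intra = g.number_of_edges()
    n_inter = int(round(inter_fraction * n_intra))
    for _ in range(n_inter):
        a = com1[int(rng.integers(n1))]
        b = com2[int(rng.integers(n2))]
        if not g.has_edge(a, b):
            g.add_edge(a, b, coev_score=0.0, dynamic_weight=0.3, sources="dynamic")

    # interface contacts: partner residues on chains B (vert) and C (lat)
    pairs = []
    dists = {}
    iface = {}
    for k, r in enumerate(com1):
        p = (("B", k + 1), r) if ("B", k + 1) < r else (r, ("B", k + 1))
        pairs.append(p)
        dists[p] = 0.6
        iface[p] = "vert_dim"
    for k, r in enumerate(com2):
        p = (("C", k + 1), r) if ("C", k + 1) < r else (r, ("C", k + 1))
        pairs.append(p)
        dists[p] = 0.6
        iface[p] = "lat_dim"
    cmap = ContactMap(pairs=pairs, distances=dists, interface_class=iface, cutoff=0.8)
    gt = GroundTruth(
        kind="sector_system",
        seed=seed,
        data={
            "community1": [list(r) for r in com1],
            "community2": [list(r) for r in com2],
            "inter_fraction": inter_fraction,
        },
    )
    return g, cmap, gt
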