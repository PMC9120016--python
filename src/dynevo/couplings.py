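"""Structural-alphabet encoding and nMI dynamic-coupling networks.

Conformer 3D structures are discretized into 1D strings of overlapping
four-residue fragments: each fragment is reduced to a scale-free geometric
descriptor and assigned the nearest prototype letter of a finite structural
alphabet.  Correlated conformational changes between two fragment columns
i, j of the resulting string alignment are scored as normalized mutual
information,

    nMI(Ci; Cj) = (I(Ci; Cj) - eps(Ci; Cj)) / H(Ci, Cj)

where I is the plug-in mutual information, H the joint entropy (natural
log) and eps the expected finite-size bias, estimated by the Miller–Madow
correction (r_i - 1)(r_j - 1) / (2M) with r the observed letter counts.
Top couplings form a network whose node importance is the eigenvector
centrality of the symmetric coupling matrix (leading eigenvector E of
M_corr, M_corr·E = λ·E).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from dynevo.ensemble import Ensemble

FRAG = 4  # residues per fragment window


class NmiResult(NamedTuple):
    nmi: float
    mi: float
    h_joint: float
    epsilon: float


@dataclass
class StructuralAlphabet:
    """K prototype fragment geometries in descriptor space.

    The descriptor of a 4-Cα fragment is scale-free: the three planar
    angles at triples (1,2,3), (2,3,4), (1,3,4) plus the torsion of
    (1,2,3,4), the torsion embedded as (cos τ, sin τ) so that Euclidean
    distance respects its periodicity.  Encoding assigns the unique nearest
    prototype; ties break to the lowest letter index.
    """

    prototypes: np.ndarray  # (K, 5)
    name: str = "custom"

    def __post_init__(self) -> None:
        self.prototypes = np.asarray(self.prototypes, float)
        if self.prototypes.ndim != 2 or self.prototypes.shape[1] != 5:
            raise ValueError("prototypes must be (K, 5) descriptors")
        d = np.linalg.norm(
            self.prototypes[:, None] - self.prototypes[None, :], axis=2
        )
        np.fill_diagonal(d, np.inf)
        if d.min() < 1e-9:
            raise ValueError("prototypes not pairwise distinct")

    @property
    def k(self) -> int:
        return self.prototypes.shape[0]

    def encode_descriptors(self, desc: np.ndarray) -> np.ndarray:
        """Nearest-prototype letters for an (..., 5) descriptor array."""
        flat = desc.reshape(-1, 5)
        # argmin breaks ties at the lowest index
        d2 = ((flat[:, None, :] - self.prototypes[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1).reshape(desc.shape[:-1])

    @classmethod
    def generic(cls) -> "StructuralAlphabet":
        """The bundled generic 25-letter alphabet.

        A synthetic prototype table (not a literature alphabet): 25 centers
        fit once by seeded k-means on fragment descriptors drawn from
        idealized helix, strand and coil geometries with jitter, shipped as
        package data.
        """
        ref = importlib.resources.files("dynevo") / "data" / "alphabet25.tsv"
        table = np.loadtxt(str(ref), delimiter="\t", skiprows=1)
        return cls(prototypes=table[:, 1:], name="generic25")


def fragment_descriptors(coords: np.ndarray) -> np.ndarray:
    """Descriptors for all 4-residue windows of a Cα trace.

    *coords*: (..., N, 3) → (..., N-3, 5) with columns
    (θ123, θ234, θ134, cos τ, sin τ).
    """
    p1 = coords[..., :-3, :]
    p2 = coords[..., 1:-2, :]
    p3 = coords[..., 2:-1, :]
    p4 = coords[..., 3:, :]

    def angle(a, b, c):
        u = a - b
        v = c - b
        cu = np.linalg.norm(u, axis=-1)
        cv = np.linalg.norm(v, axis=-1)
        cosang = np.sum(u * v, axis=-1) / np.clip(cu * cv, 1e-12, None)
        return np.arccos(np.clip(cosang, -1, 1))

    t123 = angle(p1, p2, p3)
    t234 = angle(p2, p3, p4)
    t134 = angle(p1, p3, p4)
    # torsion 1-2-3-4
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.clip(np.linalg.norm(b2, axis=-1, keepdims=True), 1e-12, None))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    tau = np.arctan2(y, x)
    return np.stack([t123, t234, t134, np.cos(tau), np.sin(tau)], axis=-1)


def fit_alphabet(e: Ensemble, k: int = 25, seed: int = 0) -> StructuralAlphabet:
    """Fit K prototypes de novo by k-means on the ensemble's fragments."""
    from sklearn.cluster import KMeans

    desc = []
    for chain in e.topology.chains:
        idx = e.topology.chain_indices(chain)
        if idx.size < FRAG:
            continue
        desc.append(fragment_descriptors(e.coords[:, idx]).reshape(-1, 5))
    data = np.concatenate(desc, axis=0)
    km = KMeans(n_clusters=k, random_state=seed, n_init=4).fit(data)
    return StructuralAlphabet(prototypes=km.cluster_centers_, name=f"kmeans{k}")


@dataclass
class StringAlignment:
    """M conformers × F fragment columns of alphabet letters.

    ``windows`` maps each column to (chain, start index into the full
    residue list); fragment f covers residues start..start+3.  Windows
    never cross chain boundaries.
    """

    matrix: np.ndarray          # (M, F) integer letters
    windows: list[tuple[str, int]]
    alphabet: StructuralAlphabet

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.shape[1] != len(self.windows):
            raise ValueError("window map length mismatch")

    @property
    def m(self) -> int:
        return self.matrix.shape[0]

    @property
    def f(self) -> int:
        return self.matrix.shape[1]

    def residues_of(self, col: int) -> list[int]:
        _, start = self.windows[col]
        return list(range(start, start + FRAG))


def encode(e: Ensemble, a: StructuralAlphabet | None = None) -> StringAlignment:
    """Encode every conformer as a string of fragment letters."""
    if a is None:
        a = StructuralAlphabet.generic()
    cols: list[np.ndarray] = []
    windows: list[tuple[str, int]] = []
    for chain in e.topology.chains:
        idx = e.topology.chain_indices(chain)
        if idx.size < FRAG:
            raise ValueError(f"chain {chain} shorter than one fragment window")
        desc = fragment_descriptors(e.coords[:, idx])   # (M, n_win, 5)
        letters = a.encode_descriptors(desc)
        cols.append(letters)
        windows.extend((chain, int(idx[w])) for w in range(idx.size - FRAG + 1))
    return StringAlignment(
        matrix=np.concatenate(cols, axis=1), windows=windows, alphabet=a
    )


def nmi(s: StringAlignment, i: int, j: int) -> NmiResult:
    """Bias-corrected normalized mutual information between two columns."""
    if i == j:
        raise ValueError("i must differ from j")
    ci = s.matrix[:, i]
    cj = s.matrix[:, j]
    m = ci.shape[0]
    if m < 2:
        raise ValueError("need at least 2 conformers")
    k = int(max(ci.max(), cj.max())) + 1
    joint = np.bincount(
        ci.astype(np.int64) * k + cj.astype(np.int64), minlength=k * k
    ).reshape(k, k).astype(float)
    joint /= m
    pi = joint.sum(axis=1)
    pj = joint.sum(axis=0)

    def ent(p):
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    h_i, h_j, h_ij = ent(pi), ent(pj), ent(joint.ravel())
    mi = h_i + h_j - h_ij
    r_i = int((pi > 0).sum())
    r_j = int((pj > 0).sum())
    eps = (r_i - 1) * (r_j - 1) / (2.0 * m)
    if h_ij <= 0:
        return NmiResult(0.0, mi, h_ij, eps)
    val = (mi - eps) / h_ij
    return NmiResult(float(np.clip(val, 0.0, 1.0)), mi, h_ij, eps)


@dataclass
class CouplingNetwork:
    """Fragment coupling network retained after threshold + 2s filters."""

    edges: pd.DataFrame          # columns: i, j, nmi, mi, h_joint, epsilon
    matrix: np.ndarray           # (F, F) symmetric retained-nMI, zero diagonal
    windows: list[tuple[str, int]]
    nmi_threshold: float
    significance_threshold: float
    centrality_: np.ndarray | None = field(default=None, repr=False)
    leading_eigenvalue: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)


def all_pair_nmi(s: StringAlignment) -> pd.DataFrame:
    """Corrected nMI for every unordered column pair."""
    rows = []
    for i in range(s.f):
        for j in range(i + 1, s.f):
            r = nmi(s, i, j)
            rows.append((i, j, r.nmi, r.mi, r.h_joint, r.epsilon))
    return pd.DataFrame(
        rows, columns=["i", "j", "nmi", "mi", "h_joint", "epsilon"]
    )


def build_network(
    s: StringAlignment,
    nmi_threshold: float = 0.15,
    min_sep: int = 4,
    significance: bool = True,
) -> CouplingNetwork:
    """Retain top couplings into a network.

    An edge (i, j) is kept iff its corrected nMI exceeds *nmi_threshold*,
    the windows are on different chains or separated by more than *min_sep*
    residues, and (when *significance*) the nMI lies above mean + 2s of the
    all-pairs corrected-nMI distribution.
    """
    table = all_pair_nmi(s)
    sep_ok = np.zeros(len(table), dtype=bool)
    for r, (i, j) in enumerate(zip(table["i"], table["j"])):
        ci, si = s.windows[i]
        cj, sj = s.windows[j]
        sep_ok[r] = (ci != cj) or (abs(si - sj) > min_sep)
    keep = (table["nmi"].to_numpy() > nmi_threshold) & sep_ok
    sig_threshold = float(table["nmi"].mean() + 2 * table["nmi"].std(ddof=0))
    if significance:
        keep &= table["nmi"].to_numpy() > sig_threshold
    edges = table[keep].reset_index(drop=True)
    mat = np.zeros((s.f, s.f))
    for _, row in edges.iterrows():
        a, b = int(row["i"]), int(row["j"])
        mat[a, b] = mat[b, a] = row["nmi"]
    return CouplingNetwork(
        edges=edges,
        matrix=mat,
        windows=list(s.windows),
        nmi_threshold=nmi_threshold,
        significance_threshold=sig_threshold if significance else -np.inf,
    )


def centrality(n: CouplingNetwork) -> np.ndarray:
    """Eigenvector centrality of the coupling matrix.

    Leading eigenvector of the symmetric retained-nMI matrix, unit
    normalized with a non-negative sign convention (Perron–Frobenius on the
    dominant component).  Computed on the full matrix even when the graph
    is disconnected.
    """
    if n.n_edges == 0:
        raise ValueError("empty network")
    w, v = np.linalg.eigh(n.matrix)
    lead = v[:, -1]
    if lead.sum() < 0:
        lead = -lead
    lead = np.clip(lead, 0.0, None)
    nrm = np.linalg.norm(lead)
    if nrm > 0:
        lead = lead / nrm
    n.centrality_ = lead
    n.leading_eigenvalue = float(w[-1])
    return lead


def residue_profile(n: CouplingNetwork) -> dict[tuple[str, int], float]:
    """Per-residue centrality: mean centrality of the windows covering it.

    Keys are (chain, index-into-the-full-residue-list) for each residue
    covered by at least one window.
    """
    cent = n.centrality_ if n.centrality_ is not None else centrality(n)
    acc: dict[tuple[str, int], list[float]] = {}
    for col, (chain, start) in enumerate(n.windows):
        for r in range(start, start + FRAG):
            acc.setdefault((chain, r), []).append(float(cent[col]))
    return {k: float(np.mean(v)) for k, v in acc.items()}
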