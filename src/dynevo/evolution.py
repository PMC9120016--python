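"""MSA statistics: conservation entropy, coevolution scores and rvET.

Conservation of an alignment column i is the natural-log Shannon entropy
of its amino-acid frequencies,  s_i = -Σ_a f_ia ln f_ia  (gaps excluded).

Coevolution between two columns is produced by a plug-in scorer (default:
APC-corrected mutual information on redundancy-weighted frequencies); the
raw score S_r of each pair at separation |i-j| > 3 is rescaled to
S_s = S_r / mean(S_r) so the scaled scores average exactly 1, with the
published tier selectors (S_s > 1.4 "top", S_s > 0.5 "extended") and the
alignment-depth significance figure T = Nseq / L.

The real-valued Evolutionary Trace of a column combines its entropy within
the groups produced by cutting a phylogenetic tree into n = 1..N-1 groups:

    rvET_i = 1 + Σ_n w_node(n) Σ_g w_group(g) · s_i(g)

with w_node(n) = 1/n and w_group the inverse group size normalized over
the n groups.  A fully conserved column scores exactly 1; lower scores
mark positions conserved early in the tree hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO

from dynevo.energetics import AA_INDEX, AMINO_ACIDS

GAP = "-"
GAP_CODE = 20


@dataclass
class MSA:
    """Aligned protein sequences (20 aa + gap)."""

    ids: list[str]
    seqs: list[str]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids/seqs length mismatch")
        lens = {len(s) for s in self.seqs}
        if len(lens) > 1:
            raise ValueError("ragged alignment")
        for s in self.seqs:
            bad = set(s) - set(AMINO_ACIDS) - {GAP}
            if bad:
                raise ValueError(f"invalid alignment characters: {sorted(bad)}")

    @property
    def nseq(self) -> int:
        return len(self.seqs)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def matrix(self) -> np.ndarray:
        """(Nseq, L) integer codes, gap = 20."""
        lut = np.full(128, -1, dtype=np.int8)
        for a, i in AA_INDEX.items():
            lut[ord(a)] = i
        lut[ord(GAP)] = GAP_CODE
        arr = np.frombuffer("".join(self.seqs).encode(), dtype=np.uint8)
        return lut[arr].reshape(self.nseq, self.length).astype(np.int64)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "MSA":
        aln = AlignIO.read(str(path), "fasta")
        return cls(
            ids=[r.id for r in aln],
            seqs=[str(r.seq).upper().replace(".", GAP) for r in aln],
        )

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, s in zip(self.ids, self.seqs):
                fh.write(f">{i}\n{s}\n")


@dataclass
class CoevolutionResult:
    """Scored column pairs with the scaled-score thresholds."""

    pairs: pd.DataFrame     # columns: i, j, s_r, s_s [, p_c]
    significance: float     # T = Nseq / L
    excluded_columns: list[int] = field(default_factory=list)

    def top(self, tier: float = 1.4) -> pd.DataFrame:
        """Pairs with S_s above *tier* (published tiers: 1.4 and 0.5)."""
        return (
            self.pairs[self.pairs.s_s > tier]
            .sort_values("s_r", ascending=False)
            .reset_index(drop=True)
        )

    def top_k(self, k: int) -> pd.DataFrame:
        """The *k* strongest pairs by raw score (robust to the sign of
        the raw-score mean, which the scaled score divides by)."""
        return self.pairs.sort_values("s_r", ascending=False).head(k).reset_index(drop=True)


@dataclass
class ETResult:
    """Per-position rvET scores (1 = fully conserved), entropies and ranks."""

    table: pd.DataFrame     # columns: position, entropy, rvet, rank


def column_frequencies(
    m: MSA, i: int, weights: np.ndarray | None = None
) -> np.ndarray:
    """Weighted amino-acid frequencies of column *i*, gaps excluded."""
    codes = m.matrix()[:, i]
    if weights is None:
        weights = m.weights if m.weights is not None else np.ones(m.nseq)
    w = np.asarray(weights, float)
    mask = codes != GAP_CODE
    freq = np.bincount(codes[mask], weights=w[mask], minlength=20)[:20]
    tot = freq.sum()
    return freq / tot if tot > 0 else freq


def column_entropy(
    m: MSA, i: int, weights: np.ndarray | None = None
) -> float:
    """Natural-log Shannon entropy of column *i* (0 for all-gap columns)."""
    f = column_frequencies(m, i, weights)
    f = f[f > 0]
    return float(-(f * np.log(f)).sum()) if f.size else 0.0


def sequence_weights(m: MSA, identity_cutoff: float = 0.8) -> np.ndarray:
    """Redundancy weights: 1 / (# sequences within cutoff identity, incl. self).

    Identity between two aligned rows is the fraction of columns (over the
    full alignment length) at which they carry the same symbol.
    """
    if not 0 < identity_cutoff < 1:
        raise ValueError("identity_cutoff must lie in (0, 1)")
    x = m.matrix()
    n = m.nseq
    counts = np.ones(n)
    # blockwise identity to bound memory
    for i in range(n):
        ident = (x == x[i]).mean(axis=1)
        counts[i] = np.sum(ident >= identity_cutoff)
    return 1.0 / counts


def _weighted_mi_matrix(m: MSA, weights: np.ndarray) -> np.ndarray:
    """Plug-in MI between all column pairs on weighted frequencies."""
    x = m.matrix()
    n, L = x.shape
    w = weights / weights.sum()
    # one-hot (L, 21) marginals and joint counts
    mi = np.zeros((L, L))
    # per-column weighted one-hot: (L, n, 21) too big for long L; loop pairs
    onehot = np.zeros((L, n, 21))
    for a in range(21):
        onehot[:, :, a] = (x.T == a)
    wf = onehot * w[None, :, None]          # (L, n, 21)
    for i in range(L):
        for jj in range(i + 1, L):
            p = wf[i].T @ onehot[jj]        # (21, 21) weighted joint
            # exclude gap states and renormalize
            p = p[:20, :20]
            tot = p.sum()
            if tot <= 0:
                continue
            p = p / tot
            pi = p.sum(axis=1)
            pj = p.sum(axis=0)
            nz = p > 0
            val = float((p[nz] * np.log(p[nz] / (pi[:, None] * pj[None, :])[nz])).sum())
            mi[i, jj] = mi[jj, i] = val
    return mi


def apc_mi_scorer(m: MSA, weights: np.ndarray) -> np.ndarray:
    """Default raw-score matrix: MI with average-product correction."""
    mi = _weighted_mi_matrix(m, weights)
    L = mi.shape[0]
    col_mean = mi.sum(axis=1) / (L - 1)
    overall = mi.sum() / (L * (L - 1))
    apc = np.outer(col_mean, col_mean) / overall if overall > 0 else 0.0
    out = mi - apc
    np.fill_diagonal(out, 0.0)
    return out


def coevolve(
    m: MSA,
    scorer: Callable[[MSA, np.ndarray], np.ndarray] | None = None,
    min_sep: int = 3,
    max_gap_fraction: float = 0.5,
    identity_cutoff: float = 0.8,
) -> CoevolutionResult:
    """Score residue coevolution for all column pairs with |i-j| > min_sep.

    *scorer* maps (MSA, weights) to an (L, L) raw-score matrix S_r; the
    default is APC-corrected weighted mutual information.  Columns with a
    gap fraction above *max_gap_fraction* are excluded from pair scoring.
    Scaled scores satisfy mean(S_s) = 1 exactly over the scored pairs.
    """
    if m.nseq < 2:
        raise ValueError("need at least 2 sequences")
    if m.length < 5:
        raise ValueError("alignment too short")
    weights = m.weights if m.weights is not None else sequence_weights(m, identity_cutoff)
    if scorer is None:
        scorer = apc_mi_scorer
    s_r = scorer(m, weights)
    x = m.matrix()
    gap_frac = (x == GAP_CODE).mean(axis=0)
    excluded = [int(i) for i in np.where(gap_frac > max_gap_fraction)[0]]
    rows = []
    L = m.length
    for i in range(L):
        if i in excluded:
            continue
        for j in range(i + 1, L):
            if j in excluded or (j - i) <= min_sep:
                continue
            rows.append((i, j, float(s_r[i, j])))
    pairs = pd.DataFrame(rows, columns=["i", "j", "s_r"])
    mean_sr = pairs.s_r.mean()
    if mean_sr == 0:
        pairs["s_s"] = 0.0
    else:
        pairs["s_s"] = pairs.s_r / mean_sr
    return CoevolutionResult(
        pairs=pairs,
        significance=m.nseq / m.length,
        excluded_columns=excluded,
    )


# ---------------------------------------------------------------------------
# real-valued Evolutionary Trace


def _tree_groups(tree, n_cuts_max: int) -> list[list[list[str]]]:
    """Tip groupings for n = 1..n_cuts_max groups.

    Groups are produced by successively splitting, at each step, the
    current subtree root closest to the tree root (by path length, ties by
    traversal order), mirroring dendrogram cuts at increasing depth.
    """
    import dendropy

    assert isinstance(tree, dendropy.Tree)
    tree = tree.clone(depth=1)
    if tree.seed_node is None:
        raise ValueError("empty tree")
    # root distances
    tree.calc_node_root_distances(return_leaf_distances_only=False)

    def tips(node) -> list[str]:
        return [lf.taxon.label for lf in node.leaf_iter()]

    groups_by_n: list[list[list[str]]] = []
    frontier = [tree.seed_node]
    groups_by_n.append([tips(tree.seed_node)])
    for _ in range(n_cuts_max - 1):
        # split the internal frontier node closest to the root
        internal = [nd for nd in frontier if not nd.is_leaf()]
        if not internal:
            break
        nd = min(internal, key=lambda v: (v.root_distance, id(v)))
        frontier = [v for v in frontier if v is not nd] + list(nd.child_nodes())
        groups_by_n.append([tips(v) for v in frontier])
    return groups_by_n


def rvet(m: MSA, tree, positions: Sequence[int] | None = None) -> ETResult:
    """Real-valued Evolutionary Trace for every alignment position.

    *tree* is a dendropy Tree (or a phylo.AnnotatedTree) whose tip labels
    are a subset of the MSA ids.  Lower scores mark positions conserved
    across the deepest tree groupings; a fully conserved column scores 1.
    """
    from dynevo.phylo import AnnotatedTree

    if isinstance(tree, AnnotatedTree):
        tree = tree.tree
    tip_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = tip_labels - set(m.ids)
    if missing:
        raise ValueError(f"tree tips not in MSA: {sorted(missing)[:5]}")
    id_row = {sid: k for k, sid in enumerate(m.ids)}
    n_tips = len(tip_labels)
    groupings = _tree_groups(tree, n_tips - 1 if n_tips > 1 else 1)
    x = m.matrix()
    L = m.length
    if positions is None:
        positions = range(L)

    def group_entropy(rows: np.ndarray, i: int) -> float:
        codes = x[rows, i]
        codes = codes[codes != GAP_CODE]
        if codes.size == 0:
            return 0.0
        f = np.bincount(codes, minlength=20)[:20].astype(float)
        f = f / f.sum()
        f = f[f > 0]
        return float(-(f * np.log(f)).sum())

    group_rows = [
        [np.array([id_row[t] for t in g]) for g in groups]
        for groups in groupings
    ]
    recs = []
    for i in positions:
        score = 1.0
        for n_idx, groups in enumerate(group_rows):
            n = n_idx + 1
            sizes = np.array([len(g) for g in groups], float)
            wg = (1.0 / sizes) / np.sum(1.0 / sizes)
            ent = np.array([group_entropy(g, i) for g in groups])
            score += (1.0 / n) * float(np.sum(wg * ent))
        recs.append((i, column_entropy(m, i), score))
    table = pd.DataFrame(recs, columns=["position", "entropy", "rvet"])
    table["rank"] = table.rvet.rank(method="min").astype(int)
    return ETResult(table=table)
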