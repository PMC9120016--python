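"""Distance-based phylogenetics and tree-composition statistics.

Trees are built by neighbor joining on corrected pairwise sequence
distances and carry per-tip annotations (isoform, phylum, thermoregulation
class H/P).  Two tree topologies over shared tips are compared by the
Pearson correlation r of their paired pairwise tip-distance vectors; tip
diversity is the mean pairwise tip path distance ΔX̄; clade composition
reports homeotherm:poikilotherm (H:P) ratios with an outlier flag at
mean ± 2s of the other clades.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from dynevo.evolution import MSA, GAP_CODE

logger = logging.getLogger(__name__)

ISOFORMS = ("alpha", "beta", "gamma", "delta", "none")
THERMO = ("H", "P", "unknown")


@dataclass
class AnnotatedTree:
    """Newick topology + branch lengths + per-tip annotation records."""

    tree: dendropy.Tree
    annotations: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [lf.taxon.label for lf in self.tree.leaf_node_iter()]
        if len(names) != len(set(names)):
            raise ValueError("tip names not unique")
        for e in self.tree.preorder_edge_iter():
            if e.length is not None and e.length < 0:
                raise ValueError("negative branch length")

    @property
    def tip_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def annotation(self, tip: str, key: str, default: str = "unknown") -> str:
        return self.annotations.get(tip, {}).get(key, default)

    def tip_distance_matrix(self) -> pd.DataFrame:
        pdm = self.tree.phylogenetic_distance_matrix()
        names = sorted(self.tip_names)
        taxa = {t.label: t for t in self.tree.taxon_namespace if t.label in set(names)}
        mat = np.zeros((len(names), len(names)))
        for i, a in enumerate(names):
            for j in range(i + 1, len(names)):
                d = pdm.patristic_distance(taxa[a], taxa[names[j]])
                mat[i, j] = mat[j, i] = d
        return pd.DataFrame(mat, index=names, columns=names)

    @classmethod
    def from_newick(
        cls,
        source: str | Path,
        annotations: Mapping[str, Mapping[str, str]] | None = None,
    ) -> "AnnotatedTree":
        text = (
            Path(source).read_text()
            if isinstance(source, Path) or str(source).endswith((".nwk", ".tre", ".newick"))
            else str(source)
        )
        tree = dendropy.Tree.get(data=text, schema="newick")
        ann = {k: dict(v) for k, v in (annotations or {}).items()}
        return cls(tree=tree, annotations=ann)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()

    def write_annotations(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("tip_id\tisoform\tphylum\tthermo\n")
            for tip in self.tip_names:
                a = self.annotations.get(tip, {})
                fh.write(
                    f"{tip}\t{a.get('isoform', 'none')}\t"
                    f"{a.get('phylum', 'unknown')}\t{a.get('thermo', 'unknown')}\n"
                )

    @staticmethod
    def read_annotations(path: str | Path) -> dict[str, dict[str, str]]:
        df = pd.read_csv(path, sep="\t", dtype=str)
        return {
            r.tip_id: {"isoform": r.isoform, "phylum": r.phylum, "thermo": r.thermo}
            for r in df.itertuples()
        }


@dataclass
class TreeComparison:
    """Paired tip-distance vectors and their Pearson r."""

    x: np.ndarray
    y: np.ndarray
    r: float
    shared_tips: list[str]
    dropped: int = 0


@dataclass
class NodeComposition:
    """Per-clade label histograms and H:P outlier flags."""

    table: pd.DataFrame
    # columns: clade, size, n_H, n_P, hp_ratio, flagged + isoform histogram


def distance_matrix(m: MSA, model: str = "identity") -> pd.DataFrame:
    """Pairwise sequence distances from an alignment.

    ``identity``: fractional difference d over columns where both rows are
    ungapped.  ``kimura``: the correction -ln(1 - d - d²/5).
    """
    if m.nseq < 3:
        raise ValueError("need at least 3 sequences")
    x = m.matrix()
    n = m.nseq
    out = np.zeros((n, n))
    for i in range(n):
        both = (x[i] != GAP_CODE) & (x != GAP_CODE)
        overlap = both.sum(axis=1)
        if np.any(overlap[np.arange(n) != i] == 0):
            raise ValueError("a sequence pair has zero aligned overlap")
        diff = ((x[i] != x) & both).sum(axis=1)
        out[i] = diff / np.maximum(overlap, 1)
    if model == "kimura":
        arg = 1.0 - out - out**2 / 5.0
        n_capped = int(np.sum(arg < 1e-2)) // 2
        if n_capped:
            # the correction diverges near random similarity; cap at -ln(0.01)
            logger.info("distance_matrix: capped %d saturated pairs", n_capped)
        out = -np.log(np.clip(arg, 1e-2, None))
    elif model != "identity":
        raise ValueError("model must be 'identity' or 'kimura'")
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=m.ids, columns=m.ids)


def nj_tree(
    d: pd.DataFrame,
    annotations: Mapping[str, Mapping[str, str]] | None = None,
) -> AnnotatedTree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Negative NJ branch lengths are clamped to zero with the original value
    recorded in the node annotation ``original_length``.
    """
    mat = d.to_numpy()
    if not np.allclose(mat, mat.T):
        raise ValueError("distance matrix not symmetric")
    if len(d) < 3:
        raise ValueError("need at least 3 taxa")
    buf = io.StringIO()
    buf.write("," + ",".join(str(c) for c in d.columns) + "\n")
    for name, row in zip(d.index, mat):
        buf.write(str(name) + "," + ",".join(f"{v:.12g}" for v in row) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    tree = pdm.nj_tree()
    clamped = 0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.head_node.annotations.add_new("original_length", edge.length)
            edge.length = 0.0
            clamped += 1
    if clamped:
        logger.info("nj_tree: clamped %d negative branch lengths", clamped)
    ann = {k: dict(v) for k, v in (annotations or {}).items()}
    return AnnotatedTree(tree=tree, annotations=ann)


def tree_similarity(
    a: AnnotatedTree,
    b: AnnotatedTree,
    pairing: Mapping[str, str] | None = None,
) -> TreeComparison:
    """Pearson r between the paired pairwise tip-distance vectors.

    *pairing* maps tip names in *a* to tip names in *b* (default:
    identical names).  Tips absent from either tree are dropped with a
    logged count; at least 3 shared tips are required.
    """
    tips_a = set(a.tip_names)
    tips_b = set(b.tip_names)
    if pairing is None:
        pairing = {t: t for t in tips_a}
    shared = sorted(t for t in pairing if t in tips_a and pairing[t] in tips_b)
    dropped = len(tips_a | {p for p in pairing}) - len(shared)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared tips")
    if dropped:
        logger.info("tree_similarity: dropped %d unmatched tips", dropped)
    da = a.tip_distance_matrix()
    db = b.tip_distance_matrix()
    xs, ys = [], []
    for i in range(len(shared)):
        for j in range(i + 1, len(shared)):
            xs.append(da.loc[shared[i], shared[j]])
            ys.append(db.loc[pairing[shared[i]], pairing[shared[j]]])
    x = np.array(xs)
    y = np.array(ys)
    r = float(stats.pearsonr(x, y).statistic) if x.std() > 0 and y.std() > 0 else np.nan
    return TreeComparison(x=x, y=y, r=r, shared_tips=shared, dropped=dropped)


def diversity(t: AnnotatedTree, tips: Sequence[str]) -> float:
    """Mean pairwise tip path distance ΔX̄ over a tip subset."""
    tips = list(tips)
    if len(tips) < 2:
        raise ValueError("need at least 2 tips")
    missing = set(tips) - set(t.tip_names)
    if missing:
        raise KeyError(f"tips absent from tree: {sorted(missing)}")
    d = t.tip_distance_matrix()
    vals = [
        d.loc[tips[i], tips[j]]
        for i in range(len(tips))
        for j in range(i + 1, len(tips))
    ]
    return float(np.mean(vals))


def _identity(a: str, b: str) -> float:
    """Sequence identity via edit distance (CD-Hit-style greedy criterion)."""
    import edlib

    if not a or not b:
        return 0.0
    res = edlib.align(a, b, task="distance")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


def cluster(
    seqs: Mapping[str, str],
    cutoff: float = 0.8,
    then: float | None = None,
) -> tuple[dict[str, str], dict[str, list[str]]]:
    """Greedy longest-first identity clustering.

    Sequences are visited longest first (ties by input order); each joins
    the first existing cluster whose representative identity is ≥ *cutoff*,
    else founds a new cluster.  An optional second pass re-clusters the
    representatives at the *then* cutoff and merges memberships.  Returns
    (member → representative, representative → members).
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie in (0, 1)")
    order = sorted(seqs, key=lambda k: -len(seqs[k]))
    reps: list[str] = []
    assign: dict[str, str] = {}
    for sid in order:
        for rep in reps:
            if _identity(seqs[sid], seqs[rep]) >= cutoff:
                assign[sid] = rep
                break
        else:
            reps.append(sid)
            assign[sid] = sid
    if then is not None:
        rep_seqs = {r: seqs[r] for r in reps}
        rep_assign, _ = cluster(rep_seqs, cutoff=then)
        assign = {sid: rep_assign[rep] for sid, rep in assign.items()}
    members: dict[str, list[str]] = {}
    for sid, rep in assign.items():
        members.setdefault(rep, []).append(sid)
    return assign, members


def node_composition(
    t: AnnotatedTree,
    clades: Sequence[Sequence[str] | dendropy.Node],
    clade_names: Sequence[str] | None = None,
) -> NodeComposition:
    """Label histograms and H:P ratios per clade, with the ±2s flag rule.

    Each clade is an internal node (or its list of tip names).  The H:P
    ratio is the homeotherm / poikilotherm tip count; clades with zero P
    report an infinite ratio and are excluded from the comparison means.  A
    clade is flagged when its ratio falls outside mean ± 2s (population s)
    of the *other* clades' finite ratios.
    """
    rows = []
    clade_tip_sets: list[list[str]] = []
    for c in clades:
        if isinstance(c, dendropy.Node):
            clade_tip_sets.append([lf.taxon.label for lf in c.leaf_iter()])
        else:
            clade_tip_sets.append(list(c))
    names = list(clade_names) if clade_names else [f"clade{i}" for i in range(len(clades))]
    for name, tips in zip(names, clade_tip_sets):
        labeled = [t.annotation(tip, "thermo") for tip in tips]
        n_h = labeled.count("H")
        n_p = labeled.count("P")
        if n_h + n_p == 0:
            raise ValueError(f"clade {name} has zero thermo-labeled tips")
        ratio = np.inf if n_p == 0 else n_h / n_p
        iso = [t.annotation(tip, "isoform", "none") for tip in tips]
        hist = {f"n_{k}": iso.count(k) for k in ISOFORMS}
        rows.append({"clade": name, "size": len(tips), "n_H": n_h, "n_P": n_p,
                     "hp_ratio": ratio, **hist})
    df = pd.DataFrame(rows)
    flags = []
    for i in range(len(df)):
        others = df.hp_ratio.drop(index=i)
        finite = others[np.isfinite(others)]
        if len(finite) < 2 or not np.isfinite(df.hp_ratio[i]):
            flags.append(False)
            continue
        mu = finite.mean()
        s = finite.std(ddof=0)
        flags.append(bool(abs(df.hp_ratio[i] - mu) > 2 * s))
    df["flagged"] = flags
    return NodeComposition(table=df)
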