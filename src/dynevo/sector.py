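"""Sector partitioning: overlaying dynamics, coevolution and frustration.

A residue-level graph is assembled from the fragment-level dynamic
coupling network (each fragment edge contributes to all 4×4 residue pairs
of its windows, weight split evenly), the top coevolved column pairs, and
— where a native contact exists — the contact's frustration class.
Sectors are the connected components of the coevolved-edge subgraph; each
component is assigned the interface class holding the majority of the
interface contacts within one contact step of its residues (ties labelled
``mixed``, components touching no interface ``unassigned``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from dynevo.couplings import FRAG, CouplingNetwork
from dynevo.energetics import FrustrationProfile
from dynevo.evolution import CoevolutionResult
from dynevo.structio import ContactMap, ResidueKey, canonical_pair


@dataclass
class SectorPartition:
    """Disjoint named residue sectors with per-sector summaries."""

    sectors: dict[str, set[ResidueKey]]
    summary: pd.DataFrame
    # columns: sector, size, interface, n_coevolved_edges, mean_centrality,
    #          n_relaxed, n_neutral, n_stressed
    residue_sector: dict[ResidueKey, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.residue_sector:
            self.residue_sector = {
                r: name for name, rs in self.sectors.items() for r in rs
            }

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chain\tresnum\tsector\n")
            for (chain, num), name in sorted(self.residue_sector.items()):
                fh.write(f"{chain}\t{num}\t{name}\n")


def _fragment_edge_residue_pairs(
    net: CouplingNetwork, residue_keys: Sequence[ResidueKey]
) -> list[tuple[ResidueKey, ResidueKey, float, float]]:
    out = []
    for row in net.edges.itertuples():
        i, j, w = int(row.i), int(row.j), float(row.nmi)
        ci, si = net.windows[i]
        cj, sj = net.windows[j]
        share = w / (FRAG * FRAG)
        for a in range(si, si + FRAG):
            for b in range(sj, sj + FRAG):
                out.append((residue_keys[a], residue_keys[b], w, share))
    return out


def overlay(
    net: CouplingNetwork | None,
    coev: CoevolutionResult | None,
    frus: FrustrationProfile | None,
    cmap: ContactMap,
    residue_keys: Sequence[ResidueKey],
    coev_positions: Mapping[int, ResidueKey] | None = None,
    coev_top: float = 1.4,
) -> nx.Graph:
    """Union graph of dynamic and coevolved residue-level edges.

    *residue_keys* lists the (chain, resnum) key of every residue in full
    topology order (fragment windows index into it); *coev_positions* maps
    MSA column indices to residue keys (default: positional, column k →
    residue_keys[k]).  Edges carry a ``sources`` tag in
    {"dynamic", "coevolved", "both"}, the supporting weights, and the
    frustration class where the pair is a native contact.
    """
    residue_keys = list(residue_keys)
    g = nx.Graph()
    if net is not None:
        for a, b, w, share in _fragment_edge_residue_pairs(net, residue_keys):
            if a == b:
                continue
            if g.has_edge(a, b):
                g[a][b]["dynamic_weight"] += share
            else:
                g.add_edge(a, b, dynamic_weight=share, coev_score=0.0)
    if coev is not None:
        if coev_positions is None:
            coev_positions = {k: residue_keys[k] for k in range(len(residue_keys))}
        offenders = []
        for row in coev.top(coev_top).itertuples():
            i, j = int(row.i), int(row.j)
            if i not in coev_positions or j not in coev_positions:
                offenders.append((i, j))
                continue
            a, b = coev_positions[i], coev_positions[j]
            if g.has_edge(a, b):
                g[a][b]["coev_score"] = max(g[a][b].get("coev_score", 0.0), float(row.s_s))
            else:
                g.add_edge(a, b, dynamic_weight=0.0, coev_score=float(row.s_s))
        if offenders:
            raise KeyError(
                f"coevolution columns without residue mapping: {offenders[:10]}"
            )
    frus_class: dict[tuple[ResidueKey, ResidueKey], str] = {}
    if frus is not None:
        for row in frus.table.itertuples():
            key = canonical_pair((row.chainA, row.resA), (row.chainB, row.resB))
            frus_class[key] = row[9]
    for a, b, data in g.edges(data=True):
        dyn = data["dynamic_weight"] > 0
        cv = data["coev_score"] > 0
        data["sources"] = "both" if (dyn and cv) else ("dynamic" if dyn else "coevolved")
        key = canonical_pair(a, b)
        if key in cmap.distances:
            data["contact"] = True
            if key in frus_class:
                data["frustration"] = frus_class[key]
        else:
            data["contact"] = False
    return g


def partition(
    g: nx.Graph,
    cmap: ContactMap,
    merge_steps: int = 1,
    min_size: int = 2,
) -> SectorPartition:
    """Partition the coevolved subgraph into interface-labelled sectors.

    Connected components of the coevolved-edge subgraph are each expanded
    by *merge_steps* contact steps; the interface contacts touched by the
    expanded residue set vote for the component's interface label
    (majority; ties → ``mixed``; no interface contact → ``unassigned``).
    Deterministic and independent of edge input order.
    """
    coev_edges = [
        (a, b) for a, b, d in g.edges(data=True) if d.get("coev_score", 0) > 0
    ]
    sub = nx.Graph(coev_edges)
    comps = [c for c in nx.connected_components(sub) if len(c) >= min_size]
    comps.sort(key=lambda c: (-len(c), sorted(c)))

    # contact adjacency for the merge expansion
    adj: dict[ResidueKey, set[ResidueKey]] = {}
    for a, b in cmap.pairs:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    iface_pairs = {
        p: cl for p, cl in cmap.interface_class.items() if cl != "intra"
    }

    sectors: dict[str, set[ResidueKey]] = {}
    rows = []
    for idx, comp in enumerate(comps):
        expanded = set(comp)
        for _ in range(merge_steps):
            grown = set(expanded)
            for r in expanded:
                grown |= adj.get(r, set())
            expanded = grown
        votes: dict[str, int] = {}
        for (a, b), cl in iface_pairs.items():
            if a in expanded or b in expanded:
                votes[cl] = votes.get(cl, 0) + 1
        if not votes:
            label = "unassigned"
        else:
            best = max(votes.values())
            winners = sorted(k for k, v in votes.items() if v == best)
            label = winners[0] if len(winners) == 1 else "mixed"
        name = f"sector_{idx}_{label}"
        sectors[name] = set(comp)
        n_edges = sub.subgraph(comp).number_of_edges()
        frus_counts = {"relaxed": 0, "neutral": 0, "stressed": 0}
        for a, b, d in g.subgraph(comp).edges(data=True):
            fc = d.get("frustration")
            if fc in frus_counts:
                frus_counts[fc] += 1
        rows.append(
            {
                "sector": name,
                "size": len(comp),
                "interface": label,
                "n_coevolved_edges": n_edges,
                "n_relaxed": frus_counts["relaxed"],
                "n_neutral": frus_counts["neutral"],
                "n_stressed": frus_counts["stressed"],
            }
        )
    summary = pd.DataFrame(
        rows,
        columns=[
            "sector", "size", "interface", "n_coevolved_edges",
            "n_relaxed", "n_neutral", "n_stressed",
        ],
    )
    return SectorPartition(sectors=sectors, summary=summary)
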