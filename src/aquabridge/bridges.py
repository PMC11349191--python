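"""Water-bridge detection on the hydrogen-bond graph of one frame.

Two complementary views of the same graph:

* the *chain method* finds pairs of protein residues connected through a
  path whose interior vertices are exclusively waters, at most
  ``maxDepth`` of them;
* the *cluster method* finds connected components of waters and the
  protein residues touching them, truncating water chains at
  ``maxDepth`` hops from the nearest protein-bonded water.

Direct protein-protein hydrogen bonds are never bridges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import networkx as nx
import numpy as np

from .hbond import Criteria, HydrogenBond
from .structio import Structure, residue_id

__all__ = [
    "WaterBridge",
    "WaterCluster",
    "chain_method",
    "cluster_method",
    "bridges_to_residue_pairs",
    "write_bridge_table",
    "write_cluster_table",
]

ResidueId = tuple[str, int, str]  # (chain, resnum, resname)


@dataclass(frozen=True)
class WaterBridge:
    """Two protein residues linked through >=1 waters in one frame.

    ``water_path`` is the retained shortest path (ties broken by
    lexicographically smallest water identifiers); ``waters`` is the set
    of distinct waters appearing in *any* qualifying path for the pair;
    ``atom_pairs`` lists every qualifying polar-heavy-atom endpoint pair
    (indices into the structure's atom table).  ``distance_AB`` is the
    separation of the retained path's endpoint atoms.
    """

    residue_a: ResidueId
    residue_b: ResidueId
    atom_a: int
    atom_b: int
    water_path: tuple[ResidueId, ...]
    depth: int
    frame: int
    distance_AB: float
    waters: frozenset[ResidueId] = frozenset()
    atom_pairs: tuple[tuple[int, int], ...] = ()

    @property
    def pair(self) -> tuple[ResidueId, ResidueId]:
        return (self.residue_a, self.residue_b)


@dataclass(frozen=True)
class WaterCluster:
    """A connected set of waters and the protein residues touching it."""

    waters: frozenset[ResidueId]
    residues: frozenset[ResidueId]
    frame: int

    @property
    def n_waters(self) -> int:
        return len(self.waters)

    @property
    def n_residues(self) -> int:
        return len(self.residues)


def _bridge_adjacency(structure: Structure, bonds: Iterable[HydrogenBond]):
    """Collapse the atom-level H-bond list to the bridge graph.

    Returns (prot_to_waters, water_to_prots, water_adj) where waters are
    keyed by residue identity and protein endpoints by polar-atom index.
    Bond direction is irrelevant for connectivity.
    """
    prot_to_waters: dict[int, set[ResidueId]] = {}
    water_to_prots: dict[ResidueId, set[int]] = {}
    water_adj: dict[ResidueId, set[ResidueId]] = {}
    for hb in bonds:
        if hb.kind == "protein-protein":
            continue
        d, a = hb.donor_atom, hb.acceptor_atom
        d_at, a_at = structure.atoms[d], structure.atoms[a]
        if hb.kind == "water-water":
            wd, wa = residue_id(d_at), residue_id(a_at)
            if wd == wa:
                continue
            water_adj.setdefault(wd, set()).add(wa)
            water_adj.setdefault(wa, set()).add(wd)
            water_to_prots.setdefault(wd, set())
            water_to_prots.setdefault(wa, set())
        else:  # protein-water
            if d_at.is_water:
                w, p = residue_id(d_at), a
            else:
                w, p = residue_id(a_at), d
            prot_to_waters.setdefault(p, set()).add(w)
            water_to_prots.setdefault(w, set()).add(p)
            water_adj.setdefault(w, set())
    return prot_to_waters, water_to_prots, water_adj


def chain_method(
    structure: Structure,
    bonds: Sequence[HydrogenBond],
    criteria: Criteria | None = None,
    frame: int = 0,
    include_intra_residue: bool = False,
) -> list[WaterBridge]:
    """Find residue pairs bridged through at most ``maxDepth`` waters.

    Every simple path whose interior vertices are exclusively waters is
    enumerated (depth-first, depth-capped); one :class:`WaterBridge` is
    emitted per unordered residue pair, carrying the shortest path and
    the multiplicity information of all qualifying paths.  Pairs within
    the same residue are excluded unless ``include_intra_residue``.
    """
    crit = criteria or Criteria()
    coords = structure.coords[frame]
    prot_to_waters, water_to_prots, water_adj = _bridge_adjacency(
        structure, bonds
    )
    # records[(res_pair)] -> list of (path, atom_a, atom_b) with atom_a on
    # the residue_a side of the canonical pair
    records: dict[tuple[ResidueId, ResidueId], list] = {}
    for p, first_waters in prot_to_waters.items():
        res_p = residue_id(structure.atoms[p])

        def visit(w: ResidueId, path: tuple[ResidueId, ...]) -> None:
            for q in water_to_prots.get(w, ()):
                res_q = residue_id(structure.atoms[q])
                if q == p:
                    continue
                if res_q == res_p and not include_intra_residue:
                    continue
                if (res_p, p) < (res_q, q) or res_p == res_q:
                    key, rec = (res_p, res_q), (path, p, q)
                    if res_p == res_q and p > q:
                        rec = (path, q, p)
                else:
                    key, rec = (res_q, res_p), (tuple(reversed(path)), q, p)
                bucket = records.setdefault(key, [])
                if rec not in bucket:
                    bucket.append(rec)
            if len(path) < crit.maxDepth:
                for w2 in water_adj.get(w, ()):
                    if w2 not in path:
                        visit(w2, path + (w2,))

        for w in sorted(first_waters):
            visit(w, (w,))

    bridges: list[WaterBridge] = []
    for (res_a, res_b), recs in sorted(records.items()):
        recs.sort(key=lambda r: (len(r[0]), r[0], r[1], r[2]))
        path, atom_a, atom_b = recs[0]
        waters = frozenset(w for r in recs for w in r[0])
        atom_pairs = tuple(
            sorted({(min(r[1], r[2]), max(r[1], r[2])) for r in recs})
        )
        bridges.append(
            WaterBridge(
                residue_a=res_a,
                residue_b=res_b,
                atom_a=atom_a,
                atom_b=atom_b,
                water_path=path,
                depth=len(path),
                frame=frame,
                distance_AB=float(
                    np.linalg.norm(coords[atom_a] - coords[atom_b])
                ),
                waters=waters,
                atom_pairs=atom_pairs,
            )
        )
    return bridges


def cluster_method(
    structure: Structure,
    bonds: Sequence[HydrogenBond],
    criteria: Criteria | None = None,
    frame: int = 0,
) -> list[WaterCluster]:
    """Connected components of the water/protein hydrogen-bond graph.

    Water membership is truncated at ``maxDepth`` water hops from the
    nearest protein-bonded water (which sits at depth 1, mirroring the
    chain method's depth count).  Components that touch no protein
    anywhere are reported whole as bulk clusters with ``n_residues`` 0.
    """
    crit = criteria or Criteria()
    _, water_to_prots, water_adj = _bridge_adjacency(structure, bonds)
    g = nx.Graph()
    g.add_nodes_from(water_adj)
    g.add_nodes_from(water_to_prots)
    for w, others in water_adj.items():
        g.add_edges_from((w, o) for o in others)
    sources = [w for w, prots in water_to_prots.items() if prots]
    depth = {w: d + 1 for w, d in nx.multi_source_dijkstra_path_length(
        g, sources, weight=None
    ).items()} if sources else {}
    clusters: list[WaterCluster] = []
    for comp in nx.connected_components(g):
        touched = any(w in depth for w in comp)
        if touched:
            kept = {w for w in comp if depth.get(w, np.inf) <= crit.maxDepth}
            if not kept:
                continue
            # truncation may split the component
            sub = g.subgraph(kept)
            for part in nx.connected_components(sub):
                residues = frozenset(
                    residue_id(structure.atoms[p])
                    for w in part
                    for p in water_to_prots.get(w, ())
                )
                clusters.append(
                    WaterCluster(frozenset(part), residues, frame)
                )
        else:
            clusters.append(WaterCluster(frozenset(comp), frozenset(), frame))
    clusters.sort(key=lambda c: (-c.n_waters, sorted(c.waters)))
    return clusters


def bridges_to_residue_pairs(
    bridges: Iterable[WaterBridge],
) -> dict[tuple[ResidueId, ResidueId], dict]:
    """Aggregate bridges of one frame by unordered residue pair.

    Each pair maps to its minimal depth and water multiplicity (number
    of distinct waters appearing in any qualifying path).
    """
    out: dict[tuple[ResidueId, ResidueId], dict] = {}
    for b in bridges:
        key = tuple(sorted((b.residue_a, b.residue_b)))
        entry = out.setdefault(
            key, {"depth": b.depth, "waters": set(), "multiplicity": 0}
        )
        entry["depth"] = min(entry["depth"], b.depth)
        entry["waters"] |= set(b.waters)
    for entry in out.values():
        entry["multiplicity"] = len(entry["waters"])
    return out


def _fmt_res(res: ResidueId) -> tuple[str, str]:
    chain, resnum, resname = res
    return chain, f"{resname}{resnum}"


def _fmt_water(res: ResidueId) -> str:
    chain, resnum, resname = res
    return f"{chain}.{resname}{resnum}"


def write_bridge_table(
    bridges: Iterable[WaterBridge], fh: TextIO, header: bool = True
) -> None:
    """Write one tab-separated row per bridge."""
    if header:
        fh.write(
            "frame\tchainA\tresA\tatomA\tchainB\tresB\tatomB\tdepth\t"
            "waters\tdistance_AB\n"
        )
    for b in bridges:
        chain_a, res_a = _fmt_res(b.residue_a)
        chain_b, res_b = _fmt_res(b.residue_b)
        fh.write(
            f"{b.frame}\t{chain_a}\t{res_a}\t{b.atom_a}\t"
            f"{chain_b}\t{res_b}\t{b.atom_b}\t{b.depth}\t"
            f"{';'.join(_fmt_water(w) for w in b.water_path)}\t"
            f"{b.distance_AB:.2f}\n"
        )


def write_cluster_table(
    clusters: Iterable[WaterCluster], fh: TextIO, header: bool = True
) -> None:
    """Write one tab-separated row per water cluster."""
    if header:
        fh.write("frame\tn_waters\tn_residues\twaters\tresidues\n")
    for c in clusters:
        fh.write(
            f"{c.frame}\t{c.n_waters}\t{c.n_residues}\t"
            f"{';'.join(_fmt_water(w) for w in sorted(c.waters))}\t"
            f"{';'.join(r[0] + '.' + r[2] + str(r[1]) for r in sorted(c.residues))}\n"
        )
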