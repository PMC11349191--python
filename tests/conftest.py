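"""Shared builders and independent brute-force oracles for the tests.

The oracles deliberately avoid the library's own graph/clustering code:
path enumeration uses itertools over explicit adjacency sets, and the
reference density clustering uses exhaustive O(n^2) neighbour scans.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from aquabridge.bridges import ResidueId
from aquabridge.hbond import HydrogenBond
from aquabridge.structio import Atom, Structure


def mini_structure(specs, coords) -> Structure:
    """Build a Structure from (name, element, resname, resnum, chain) rows."""
    atoms = []
    for i, (name, element, resname, resnum, chain) in enumerate(specs):
        element = element.upper()
        atoms.append(
            Atom(
                serial=i + 1,
                name=name,
                element=element,
                resname=resname,
                resnum=resnum,
                chain=chain,
                is_water=resname.upper() in ("HOH", "WAT", "SOL"),
                is_hydrogen=element in ("H", "D"),
            )
        )
    return Structure(atoms, np.asarray(coords, dtype=float))


def water(resnum: int, o, h1=None, h2=None, chain="W"):
    """Rows + coords of one water (O only, or O with two hydrogens)."""
    specs = [("O", "O", "HOH", resnum, chain)]
    coords = [o]
    if h1 is not None:
        specs.append(("H1", "H", "HOH", resnum, chain))
        coords.append(h1)
    if h2 is not None:
        specs.append(("H2", "H", "HOH", resnum, chain))
        coords.append(h2)
    return specs, coords


def random_bridge_graph(rng, n_prot=4, n_water=8, p_pw=0.3, p_ww=0.3):
    """A random abstract H-bond graph over single-atom residues.

    Protein vertices are lone backbone-O GLY residues, waters lone HOH
    oxygens; the bond list is generated directly, so the graph topology
    is arbitrary (chain_method only consumes connectivity, residue
    identity, and coordinates for reporting).
    """
    specs, coords = [], []
    for i in range(n_prot):
        specs.append(("O", "O", "GLY", i + 1, "A"))
        coords.append(rng.uniform(0, 30, 3))
    for j in range(n_water):
        specs.append(("O", "O", "HOH", j + 1, "W"))
        coords.append(rng.uniform(0, 30, 3))
    structure = mini_structure(specs, np.asarray(coords)[None])
    bonds = []
    for i in range(n_prot):
        for j in range(n_water):
            if rng.random() < p_pw:
                bonds.append(
                    HydrogenBond(i, n_prot + j, 2.8, kind="protein-water")
                )
    for j, k in itertools.combinations(range(n_water), 2):
        if rng.random() < p_ww:
            bonds.append(
                HydrogenBond(n_prot + j, n_prot + k, 2.8, kind="water-water")
            )
    return structure, bonds, n_prot, n_water


def brute_force_pairs(structure, bonds, n_prot, n_water, max_depth):
    """All residue pairs linked by a simple water-interior path of
    length <= max_depth, by exhaustive enumeration over water orderings."""
    pw = set()
    ww = set()
    for hb in bonds:
        a, b = hb.donor_atom, hb.acceptor_atom
        if hb.kind == "protein-water":
            p, w = (a, b) if a < n_prot else (b, a)
            pw.add((p, w))
        elif hb.kind == "water-water":
            ww.add(frozenset((a, b)))
    waters = range(n_prot, n_prot + n_water)
    found = set()
    for p, q in itertools.combinations(range(n_prot), 2):
        ok = False
        for k in range(1, max_depth + 1):
            for path in itertools.permutations(waters, k):
                if (p, path[0]) not in pw or (q, path[-1]) not in pw:
                    continue
                if all(
                    frozenset((path[i], path[i + 1])) in ww
                    for i in range(k - 1)
                ):
                    ok = True
                    break
            if ok:
                break
        if ok:
            ra: ResidueId = ("A", p + 1, "GLY")
            rb: ResidueId = ("A", q + 1, "GLY")
            found.add(tuple(sorted((ra, rb))))
    return found


def chain_pairs(bridges):
    return {tuple(sorted((b.residue_a, b.residue_b))) for b in bridges}


def brute_force_density_clusters(obs, eps, min_samples):
    """Reference DBSCAN-style partition by exhaustive neighbour scans.

    Returns per-point labels (-1 noise), with border points joined to
    their nearest core point's cluster, matching the documented
    deterministic rules but sharing no code with the implementation.
    """
    obs = np.asarray(obs, float)
    n = len(obs)
    dist = np.linalg.norm(obs[:, None] - obs[None, :], axis=2)
    neigh = [set(np.flatnonzero(dist[i] <= eps)) for i in range(n)]
    core = [len(neigh[i]) >= min_samples for i in range(n)]
    labels = [-1] * n
    cluster = 0
    for s in range(n):
        if not core[s] or labels[s] != -1:
            continue
        frontier = [s]
        labels[s] = cluster
        while frontier:
            p = frontier.pop()
            for q in neigh[p]:
                if core[q] and labels[q] == -1:
                    labels[q] = cluster
                    frontier.append(q)
        cluster += 1
    for p in range(n):
        if core[p] or labels[p] != -1:
            continue
        cands = [
            (dist[p, q], labels[q]) for q in neigh[p] if core[q]
        ]
        if cands:
            labels[p] = min(cands)[1]
    return labels


def partition(labels):
    """Cluster label list -> set of frozensets (noise excluded)."""
    groups: dict[int, set[int]] = {}
    for i, lab in enumerate(labels):
        if lab != -1:
            groups.setdefault(lab, set()).add(i)
    return {frozenset(g) for g in groups.values()}


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)
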