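"""Density-based clustering of water-oxygen positions.

Observations may come from a single frame (water clusters of one
conformation) or be pooled across a trajectory (recurrent hydration
sites); the operation is the same, only the observation pool differs.

The clustering is DBSCAN-style with fully deterministic assignment: a
core point has at least ``min_samples`` neighbours within ``eps``
(counting itself); clusters are connected unions of core
neighbourhoods; a border point joins the cluster of its nearest core
point (Euclidean ties broken by lower cluster index); everything else
is noise.  The resulting partition is invariant under permutation of
the observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .hbond import Criteria
from .structio import Atom, Structure, select, write_pdb

__all__ = ["HydrationSite", "cluster_waters", "write_site_centers"]


@dataclass(frozen=True)
class HydrationSite:
    """A recurrently occupied water position.

    ``occupancy`` is members per frame and can exceed 1 when several
    waters co-occupy the site in one frame; ``spread`` is the RMS
    member-to-center distance in Å.
    """

    center: tuple[float, float, float]
    n_members: int
    occupancy: float
    spread: float
    members: tuple[int, ...] = ()
    nearby_residues: tuple[tuple[str, int, str], ...] = ()


def cluster_waters(
    observations: np.ndarray,
    eps: float = 1.0,
    min_samples: int = 4,
    n_frames: int = 1,
    structure: Structure | None = None,
    criteria: Criteria | None = None,
) -> tuple[list[HydrationSite], list[int]]:
    """Cluster water-oxygen observations into hydration sites.

    Returns the sites sorted by descending member count, plus the
    indices of noise observations.  When ``structure`` is given, each
    site also lists the protein residues with a polar atom within
    ``distWR`` of its center.
    """
    obs = np.asarray(observations, dtype=np.float64)
    if obs.ndim != 2 or obs.shape[1] != 3:
        raise ValueError("observations must have shape (n, 3)")
    if obs.shape[0] < 1:
        raise ValueError("at least one observation is required")
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_samples < 1:
        raise ValueError("min_samples must be at least 1")

    tree = cKDTree(obs)
    neighbors = tree.query_ball_point(obs, r=eps)
    counts = np.array([len(nb) for nb in neighbors])  # includes self
    core = counts >= min_samples
    core_idx = np.flatnonzero(core)

    # connected components of core points under eps-adjacency
    labels = np.full(obs.shape[0], -1, dtype=int)
    n_clusters = 0
    for seed in core_idx:
        if labels[seed] != -1:
            continue
        stack = [int(seed)]
        labels[seed] = n_clusters
        while stack:
            p = stack.pop()
            for q in neighbors[p]:
                if core[q] and labels[q] == -1:
                    labels[q] = n_clusters
                    stack.append(int(q))
        n_clusters += 1

    # border points: nearest core neighbour decides, ties -> lower label
    for p in np.flatnonzero(~core):
        best: tuple[float, int] | None = None
        for q in neighbors[p]:
            if not core[q]:
                continue
            d = float(np.linalg.norm(obs[p] - obs[q]))
            cand = (d, int(labels[q]))
            if best is None or cand < best:
                best = cand
        if best is not None:
            labels[p] = best[1]

    polar_idx: np.ndarray | None = None
    if structure is not None:
        crit = criteria or Criteria()
        polar_idx = np.asarray(
            select(structure, "protein-polar-heavy"), dtype=int
        )

    sites: list[HydrationSite] = []
    for c in range(n_clusters):
        members = np.flatnonzero(labels == c)
        center = obs[members].mean(axis=0)
        spread = float(
            np.sqrt(np.mean(np.sum((obs[members] - center) ** 2, axis=1)))
        )
        nearby: tuple = ()
        if structure is not None and polar_idx is not None and polar_idx.size:
            d = np.linalg.norm(
                structure.coords[0][polar_idx] - center, axis=1
            )
            crit = criteria or Criteria()
            res = {
                (
                    structure.atoms[i].chain,
                    structure.atoms[i].resnum,
                    structure.atoms[i].resname,
                )
                for i in polar_idx[d <= crit.distWR]
            }
            nearby = tuple(sorted(res))
        sites.append(
            HydrationSite(
                center=tuple(float(x) for x in center),
                n_members=int(members.size),
                occupancy=members.size / n_frames,
                spread=spread,
                members=tuple(int(m) for m in members),
                nearby_residues=nearby,
            )
        )
    sites.sort(key=lambda s: (-s.n_members, s.center))
    noise = [int(i) for i in np.flatnonzero(labels == -1)]
    return sites, noise


def write_site_centers(sites: list[HydrationSite]) -> str:
    """Render site centers as PDB pseudo-atoms for visualisation.

    One HETATM per site (resname DUM, atom name O), occupancy column
    clamped to 1.0, B-factor column carrying the site spread.
    """
    if not sites:
        return "END\n"
    atoms = [
        Atom(
            serial=i + 1,
            name="O",
            element="O",
            resname="DUM",
            resnum=i + 1,
            chain="X",
            occupancy=min(site.occupancy, 1.0),
            bfactor=site.spread,
        )
        for i, site in enumerate(sites)
    ]
    coords = np.array([s.center for s in sites])[None, :, :]
    return write_pdb(Structure(atoms, coords))
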