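"""Synthetic structures and trajectories with exactly known ground truth.

Every generated input is geometric, not simulated: planted water bridges
use ideal hydrogen-bond geometry (O···O 2.8 Å, linear D-H···A), decoy
waters sit outside any bonding distance, and hydration-site pools are
Gaussian scatters around stated centers.  A fixed seed makes every
output bit-identical (NumPy PCG64 generator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .hbond import Criteria, _water_h_positions
from .structio import Atom, Structure, Trajectory

__all__ = [
    "FixtureSpec",
    "make_bridge_fixture",
    "make_trajectory_fixture",
    "make_site_fixture",
]

_OO = 2.8  # ideal donor-acceptor spacing, Å
_NH = 0.98  # amide N-H, Å
_PAIR_SPACING = 14.0  # Å between planted chains
_DECOY_SPACING = 6.0  # Å between decoy waters


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a planted-truth fixture."""

    n_residue_pairs: int = 1
    planted_depths: tuple[int, ...] = (1,)
    occupancy_p: float = 1.0
    n_frames: int = 1
    n_decoy_waters: int = 0
    site_centers: tuple[tuple[float, float, float], ...] = ()
    site_sigma: float = 0.3
    seed: int = 0
    box_size: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy_p <= 1.0:
            raise ValueError("occupancy_p must be in [0, 1]")
        if any(d < 1 for d in self.planted_depths):
            raise ValueError("planted depths must be >= 1")
        if len(self.planted_depths) != self.n_residue_pairs:
            raise ValueError(
                "planted_depths must have one entry per residue pair"
            )


def _water_atoms(resnum: int, serial: int, chain: str = "W"):
    return [
        Atom(serial, "O", "O", "HOH", resnum, chain,
             is_water=True),
        Atom(serial + 1, "H1", "H", "HOH", resnum, chain,
             is_water=True, is_hydrogen=True),
        Atom(serial + 2, "H2", "H", "HOH", resnum, chain,
             is_water=True, is_hydrogen=True),
    ]


def _chain_geometry(depth: int, y: float, span: float | None = None):
    """Ideal linear bridge: donor N-H, `depth` waters, acceptor O.

    Returns (positions dict) with keys 'N','H','O_acc' and per-water
    (O, H1, H2) triples.  ``span`` overrides the N···O_acc distance
    (waters then spread evenly between the endpoints).
    """
    n_pos = np.array([0.0, y, 0.0])
    total = span if span is not None else _OO * (depth + 1)
    step = total / (depth + 1)
    axis = np.array([1.0, 0.0, 0.0])
    h_pos = n_pos + _NH * axis
    waters = []
    for k in range(depth):
        o = n_pos + step * (k + 1) * axis
        nxt = n_pos + step * (k + 2) * axis
        h1, h2 = _water_h_positions(o, nxt)
        waters.append((o, h1, h2))
    o_acc = n_pos + total * axis
    return n_pos, h_pos, waters, o_acc


def _build_structure(spec: FixtureSpec, spans=None):
    """Atom table + single-frame coordinates for the planted bridges."""
    crit = Criteria()
    atoms: list[Atom] = []
    xyz: list[np.ndarray] = []
    truth = []
    serial = 1
    resnum = 1
    water_resnum = 1
    water_cols: list[list[int]] = []  # per pair, atom indices of its waters
    for i, depth in enumerate(spec.planted_depths):
        y = _PAIR_SPACING * i
        span = spans[i] if spans is not None else None
        n_pos, h_pos, waters, o_acc = _chain_geometry(depth, y, span)
        atoms.append(Atom(serial, "N", "N", "GLY", resnum, "A"))
        xyz.append(n_pos)
        atoms.append(
            Atom(serial + 1, "H", "H", "GLY", resnum, "A", is_hydrogen=True)
        )
        xyz.append(h_pos)
        serial += 2
        donor_res = ("A", resnum, "GLY")
        resnum += 1
        cols = []
        for o, h1, h2 in waters:
            for atom in _water_atoms(water_resnum, serial):
                atoms.append(atom)
            cols.append(len(xyz))
            xyz.extend([o, h1, h2])
            serial += 3
            water_resnum += 1
        water_cols.append(cols)
        atoms.append(Atom(serial, "O", "O", "GLY", resnum, "A"))
        xyz.append(o_acc)
        acceptor_res = ("A", resnum, "GLY")
        serial += 1
        resnum += 1
        truth.append(
            {
                "pair": (donor_res, acceptor_res),
                "depth": depth,
                "atom_a": len(xyz) - 3 * depth - 3,  # donor N index
                "atom_b": len(xyz) - 1,
            }
        )
    # decoy waters on a remote grid, > distDA + 1 Å from everything
    decoy_y0 = -2 * _PAIR_SPACING
    for j in range(spec.n_decoy_waters):
        o = np.array(
            [
                _DECOY_SPACING * (j % 10),
                decoy_y0 - _DECOY_SPACING * (j // 10),
                0.0,
            ]
        )
        h1, h2 = _water_h_positions(o, None)
        for atom in _water_atoms(water_resnum, serial):
            atoms.append(atom)
        xyz.extend([o, h1, h2])
        serial += 3
        water_resnum += 1
    extent = max(
        _PAIR_SPACING * spec.n_residue_pairs,
        _OO * (max(spec.planted_depths, default=1) + 1),
        abs(decoy_y0) + _DECOY_SPACING * (spec.n_decoy_waters // 10 + 1),
    )
    if spec.box_size is not None and extent > spec.box_size:
        raise ValueError(
            f"fixture needs {extent:.0f} Å but the box is "
            f"{spec.box_size:.0f} Å; too many chains for the box"
        )
    coords = np.asarray(xyz)[None, :, :]
    structure = Structure(atoms, coords)
    # soundness check: decoys must sit outside bonding range of all
    # polar atoms
    if spec.n_decoy_waters and spec.n_residue_pairs:
        from .structio import select

        polar = select(structure, "protein-polar-heavy")
        n_planted_waters = sum(spec.planted_depths)
        decoy_o = [
            i
            for i, a in enumerate(atoms)
            if a.is_water and a.element == "O"
            and a.resnum > n_planted_waters
        ]
        d = np.linalg.norm(
            coords[0][decoy_o][:, None, :] - coords[0][polar][None, :, :],
            axis=2,
        )
        assert d.min() > crit.distDA + 1.0, "decoy placed too close"
    return structure, truth, water_cols


def make_bridge_fixture(spec: FixtureSpec):
    """Single-frame structure with planted bridges and decoy waters.

    Returns ``(structure, truth)`` where truth lists every planted pair
    with its depth and endpoint atom indices.
    """
    structure, truth, _ = _build_structure(spec)
    return structure, truth


def make_trajectory_fixture(
    spec: FixtureSpec,
    frame_distances: list[float] | None = None,
    timestep_ps: float | None = None,
):
    """Multi-frame trajectory with Bernoulli bridge occupancy.

    Each planted bridge is "on" in a frame with probability
    ``occupancy_p`` (seeded); off-frames displace that bridge's waters
    by three times ``distDA`` so no alternative path survives.
    ``frame_distances`` (only with a single depth-1 bridge) plants an
    exact per-frame donor-acceptor span for distance-moment tests.

    Returns ``(trajectory, truth)``; truth carries the realized on/off
    matrix and per-frame endpoint distances.
    """
    crit = Criteria()
    rng = np.random.default_rng(spec.seed)
    if frame_distances is not None:
        if spec.n_residue_pairs != 1 or spec.planted_depths != (1,):
            raise ValueError(
                "frame_distances requires a single depth-1 bridge"
            )
        if len(frame_distances) != spec.n_frames:
            raise ValueError("need one distance per frame")
    base, truth_pairs, water_cols = _build_structure(spec)
    n_pairs = spec.n_residue_pairs
    on = rng.random((spec.n_frames, n_pairs)) < spec.occupancy_p
    frames = np.repeat(base.coords, spec.n_frames, axis=0)
    distances = np.full((spec.n_frames, n_pairs), np.nan)
    for f in range(spec.n_frames):
        if frame_distances is not None and on[f, 0]:
            alt, _, _ = _build_structure(spec, spans=[frame_distances[f]])
            frames[f] = alt.coords[0]
        for i in range(n_pairs):
            cols = water_cols[i]
            if on[f, i]:
                a, b = truth_pairs[i]["atom_a"], truth_pairs[i]["atom_b"]
                distances[f, i] = float(
                    np.linalg.norm(frames[f, a] - frames[f, b])
                )
            else:
                for c in cols:
                    frames[f, c: c + 3, 2] += 3.0 * crit.distDA
    topology = base.with_frames(base.coords)

    def reader():
        for f in range(spec.n_frames):
            yield frames[f]

    traj = Trajectory(topology, reader, spec.n_frames, timestep_ps)
    truth = {
        "pairs": [t["pair"] for t in truth_pairs],
        "depths": [t["depth"] for t in truth_pairs],
        "on": on,
        "on_fraction": on.mean(axis=0),
        "distances": distances,
        "coords": frames,
    }
    return traj, truth


def make_site_fixture(
    spec: FixtureSpec,
    n_obs_per_site: int = 50,
    n_noise: int = 0,
    noise_box: float = 30.0,
):
    """Gaussian-scattered observations around planted site centers.

    Returns ``(observations, truth)`` with truth carrying the centers
    and the per-observation site assignment (-1 for noise).  Centers
    must be pairwise at least five sigma apart.
    """
    if spec.site_sigma <= 0:
        raise ValueError("site_sigma must be positive")
    centers = np.asarray(spec.site_centers, dtype=np.float64)
    if centers.size == 0:
        raise ValueError("at least one site center is required")
    if centers.shape[0] > 1:
        d = np.linalg.norm(
            centers[:, None, :] - centers[None, :, :], axis=2
        )
        np.fill_diagonal(d, np.inf)
        if d.min() < 5.0 * spec.site_sigma:
            raise ValueError(
                "site centers overlap: minimum separation is "
                f"{d.min():.2f} Å < 5 sigma"
            )
    rng = np.random.default_rng(spec.seed)
    obs = []
    assignment = []
    for i, c in enumerate(centers):
        pts = rng.normal(c, spec.site_sigma, size=(n_obs_per_site, 3))
        obs.append(pts)
        assignment.extend([i] * n_obs_per_site)
    if n_noise:
        lo = centers.min(axis=0) - noise_box / 2
        pts = lo + rng.random((n_noise, 3)) * noise_box
        obs.append(pts)
        assignment.extend([-1] * n_noise)
    observations = np.vstack(obs)
    truth = {"centers": centers, "assignment": np.asarray(assignment)}
    return observations, truth
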