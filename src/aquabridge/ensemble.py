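"""Frame-wise bridge detection across an ensemble or trajectory, and the
aggregate statistics derived from it.

A bridge's identity across frames is its unordered residue pair, so
water exchange does not interrupt a bridge's continuity.  Frequencies
are fractions of analysed frames; distance moments use the endpoint
polar heavy atoms and the population (not sample) standard deviation
over the frames where the bridge exists.  "Duration" is reported both
as the longest and the mean run of consecutive bridged frames, and in
ps when the trajectory carries a timestep.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bridges import ResidueId, WaterBridge, chain_method
from .hbond import Criteria, hbond_graph
from .structio import Structure, Trajectory, residue_id

__all__ = [
    "BridgeEnsembleStats",
    "FrequencyMatrix",
    "EnsembleResult",
    "analyze_ensemble",
    "frequency_matrix",
    "stats_matrix",
    "color_code_structure",
    "plot_matrix",
]

Pair = tuple[ResidueId, ResidueId]


@dataclass(frozen=True)
class BridgeEnsembleStats:
    """Aggregate of one residue pair over the analysed frames."""

    pair: Pair
    frequency: float
    mean_distance: float
    sd_distance: float
    mean_waters: float
    max_consecutive: int
    mean_consecutive: float
    n_frames_present: int
    n_frames_total: int
    max_consecutive_ps: float | None = None


@dataclass
class FrequencyMatrix:
    """Symmetric residue-by-residue matrix of values in [0, 1]."""

    residue_index: list[ResidueId]
    values: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        labels = [f"{c}.{n}{i}" for c, i, n in self.residue_index]
        return pd.DataFrame(self.values, index=labels, columns=labels)


@dataclass
class EnsembleResult:
    """Per-frame bridges plus pair statistics for one analysis run."""

    structure_residues: list[ResidueId]
    frame_indices: list[int]
    per_frame: list[list[WaterBridge]]
    stats: list[BridgeEnsembleStats]
    timestep: float | None = None

    @property
    def n_frames(self) -> int:
        return len(self.frame_indices)

    def trace(self, pair: Pair) -> pd.DataFrame:
        """Per-frame presence/distance series for one residue pair.

        A pair of known residues that is never bridged yields an
        all-absent series; a pair naming residues absent from the
        structure is an error.
        """
        key = tuple(sorted(pair))
        for res in key:
            if res not in self.structure_residues:
                raise KeyError(f"residue {res} not present in the structure")
        rows = []
        for fi, bridges in zip(self.frame_indices, self.per_frame):
            hit = next(
                (
                    b
                    for b in bridges
                    if tuple(sorted((b.residue_a, b.residue_b))) == key
                ),
                None,
            )
            rows.append(
                {
                    "frame": fi,
                    "present": hit is not None,
                    "distance_AB": hit.distance_AB if hit else np.nan,
                    "n_waters": len(hit.waters) if hit else 0,
                }
            )
        return pd.DataFrame(rows)

    def stats_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.stats:
            (ca, ia, na), (cb, ib, nb) = s.pair
            rows.append(
                {
                    "residue_a": f"{ca}.{na}{ia}",
                    "residue_b": f"{cb}.{nb}{ib}",
                    "frequency": s.frequency,
                    "mean_distance": s.mean_distance,
                    "sd_distance": s.sd_distance,
                    "mean_waters": s.mean_waters,
                    "max_consecutive": s.max_consecutive,
                    "mean_consecutive": s.mean_consecutive,
                    "n_frames_present": s.n_frames_present,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "residue_a", "residue_b", "frequency", "mean_distance",
                "sd_distance", "mean_waters", "max_consecutive",
                "mean_consecutive", "n_frames_present",
            ],
        )


def _runs(mask: Sequence[bool]) -> list[int]:
    runs, current = [], 0
    for flag in mask:
        if flag:
            current += 1
        elif current:
            runs.append(current)
            current = 0
    if current:
        runs.append(current)
    return runs


def analyze_ensemble(
    source: Structure | Trajectory,
    criteria: Criteria | None = None,
    frame_stride: int = 1,
) -> EnsembleResult:
    """Run the chain method on every ``frame_stride``-th frame and
    aggregate per unordered residue pair.

    Results are sorted by descending frequency, ties by residue order.
    """
    crit = criteria or Criteria()
    if frame_stride < 1:
        raise ValueError("frame_stride must be >= 1")
    if isinstance(source, Trajectory):
        topology = source.topology
        timestep = source.timestep

        def frames():
            for i, xyz in enumerate(source.frames()):
                if i % frame_stride == 0:
                    yield i, xyz
    else:
        topology = source
        timestep = None

        def frames():
            for i in range(source.n_frames):
                if i % frame_stride == 0:
                    yield i, source.coords[i]

    frame_indices: list[int] = []
    per_frame: list[list[WaterBridge]] = []
    for fi, xyz in frames():
        frame_struct = topology.with_frames(xyz[None, :, :])
        bonds = hbond_graph(frame_struct, 0, crit)
        bridges = [
            _dc_replace(b, frame=fi)
            for b in chain_method(frame_struct, bonds, crit, frame=0)
        ]
        frame_indices.append(fi)
        per_frame.append(bridges)
    if not frame_indices:
        raise ValueError("frame stride selected zero frames")

    total = len(frame_indices)
    presence: dict[Pair, list[bool]] = {}
    distances: dict[Pair, list[float]] = {}
    waters: dict[Pair, list[int]] = {}
    for k, bridges in enumerate(per_frame):
        for b in bridges:
            key: Pair = tuple(sorted((b.residue_a, b.residue_b)))
            mask = presence.setdefault(key, [False] * total)
            if mask[k]:
                continue
            mask[k] = True
            distances.setdefault(key, []).append(b.distance_AB)
            waters.setdefault(key, []).append(len(b.waters))

    stride_timestep = timestep * frame_stride if timestep else None
    stats = []
    for key, mask in presence.items():
        runs = _runs(mask)
        d = np.asarray(distances[key])
        stats.append(
            BridgeEnsembleStats(
                pair=key,
                frequency=sum(mask) / total,
                mean_distance=float(d.mean()),
                sd_distance=float(d.std()),  # population SD
                mean_waters=float(np.mean(waters[key])),
                max_consecutive=max(runs),
                mean_consecutive=float(np.mean(runs)),
                n_frames_present=int(sum(mask)),
                n_frames_total=total,
                max_consecutive_ps=(
                    max(runs) * stride_timestep if stride_timestep else None
                ),
            )
        )
    stats.sort(key=lambda s: (-s.frequency, s.pair))

    protein_residues: list[ResidueId] = []
    seen = set()
    for atom in topology.atoms:
        if atom.is_water:
            continue
        rid = residue_id(atom)
        if rid not in seen:
            seen.add(rid)
            protein_residues.append(rid)
    return EnsembleResult(
        structure_residues=protein_residues,
        frame_indices=frame_indices,
        per_frame=per_frame,
        stats=stats,
        timestep=timestep,
    )


def frequency_matrix(
    stats: Iterable[BridgeEnsembleStats], residues: Sequence[ResidueId]
) -> FrequencyMatrix:
    """Symmetric residue-by-residue bridge-frequency matrix."""
    return stats_matrix(stats, residues, "frequency")


def stats_matrix(
    stats: Iterable[BridgeEnsembleStats],
    residues: Sequence[ResidueId],
    value: str = "frequency",
) -> FrequencyMatrix:
    """Symmetric residue-pair matrix of any per-pair statistic.

    Pairs absent from ``stats`` are zero; a statistic naming a residue
    outside ``residues`` is an error.
    """
    residues = list(residues)
    pos = {r: i for i, r in enumerate(residues)}
    mat = np.zeros((len(residues), len(residues)))
    for s in stats:
        a, b = s.pair
        if a not in pos:
            raise KeyError(f"residue {a} not in the residue list")
        if b not in pos:
            raise KeyError(f"residue {b} not in the residue list")
        v = getattr(s, value)
        mat[pos[a], pos[b]] = v
        mat[pos[b], pos[a]] = v
    return FrequencyMatrix(residues, mat)


def plot_matrix(
    matrix: FrequencyMatrix,
    path: str,
    label: str = "bridge frequency",
) -> None:
    """Render a residue-pair matrix as a heat map image.

    The CSV written alongside is the authoritative numeric output; the
    image is convenience for quick inspection.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = matrix.to_dataframe()
    fig, ax = plt.subplots(
        figsize=(max(4, 0.3 * len(df)), max(3.5, 0.3 * len(df)))
    )
    im = ax.imshow(df.values, cmap="coolwarm", vmin=0.0)
    ax.set_xticks(range(len(df)), df.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(df)), df.index, fontsize=7)
    fig.colorbar(im, ax=ax, label=label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def color_code_structure(
    structure: Structure, stats: Iterable[BridgeEnsembleStats]
) -> Structure:
    """Structure whose B-factors carry per-residue bridge frequencies.

    Every atom of a residue participating in at least one bridge gets
    that residue's maximum bridge frequency, clamped to [0, 1]; all
    other atoms get 0.  Written to PDB, the B-factor column colour-codes
    from 0 (blue) to 1 (red) in standard viewers.
    """
    freq: dict[ResidueId, float] = {}
    for s in stats:
        for res in s.pair:
            f = min(max(s.frequency, 0.0), 1.0)
            freq[res] = max(freq.get(res, 0.0), f)
    atoms = [
        _dc_replace(a, bfactor=freq.get(residue_id(a), 0.0))
        for a in structure.atoms
    ]
    return Structure(atoms, structure.coords.copy(), structure.frame_labels)
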