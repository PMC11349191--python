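# Methods

## Problem and model

Water molecules mediate many functionally important residue–residue
contacts in proteins: two hydrophilic residues that never touch
directly may be held together by one or more waters hydrogen-bonded in
a chain between them.  `aquabridge` detects these **water bridges** in
single structures, multi-model ensembles, and MD trajectories, and
summarises how persistent they are.

All detection reduces to a hydrogen-bond graph over the protein's
polar heavy atoms (N/O/S of non-water residues) and the water oxygens
of one coordinate frame.  A donor→acceptor contact is a hydrogen bond
when

* the donor-heavy-atom to acceptor-heavy-atom distance is at most
  `distDA`, and
* in *with-hydrogens* mode, some hydrogen covalently attached to the
  donor (same residue, ≤ 1.25 Å) gives an angle at the hydrogen —
  between the H→donor and H→acceptor vectors — inside the applicable
  range: `anglePDWA` for protein-donor→water, `anglePAWD` for
  water-donor→protein, `angleWW` for water→water.  An ideal linear
  D–H···A bond scores 180°.

In *angle-free* mode only the distance criterion applies; this mode is
selected automatically when the input carries no hydrogens (typical
crystal structures), and it always accepts a superset of the
with-hydrogens decisions on identical coordinates.

Each water oxygen may donate at most two and accept at most two
hydrogen bonds.  The cap is enforced after graph construction by
ranking each water's bonds by distance (ties by partner atom index)
and discarding the excess, which makes the pruned graph deterministic.

## Defaults

| parameter | default | meaning |
|---|---|---|
| `distDA` | 3.5 Å | max donor–acceptor heavy-atom distance |
| `distWR` | 4.0 Å | residue–water interaction shell (reporting, site annotation) |
| `anglePDWA`, `anglePAWD` | [100°, 180°] | protein–water angle ranges at H |
| `angleWW` | [140°, 180°] | water–water angle range at H |
| `maxDepth` | 2 | max waters in a bridging chain |
| `angle_mode` | auto | with-hydrogens iff any H present |

These are canonical hydrogen-bond geometry choices; every value is
user-overridable on the command line or through a `key=value` config
file.  The angle convention (measured at the hydrogen) is a package
decision and is stated here prominently because other tools sometimes
measure at the donor.

Donors whose hydrogens are rotatable and typically unresolved
(Ser/Thr/Tyr hydroxyls, Lys NZ) fall back to distance-only acceptance
when no hydrogen is present, rather than fabricating rotamer-dependent
positions.  Bare waters can be protonated with
`place_missing_hydrogens` (O–H 0.96 Å, H–O–H 104.5°, first H aimed at
the nearest acceptor within `distDA`); protein donors are never
modified.  Deuterium counts as hydrogen.

## Chain and cluster methods

The **chain method** enumerates, from every protein polar atom, all
simple paths whose interior vertices are waters, capped at `maxDepth`
waters (depth-first search; `maxDepth` is small so exhaustive
enumeration is cheap).  One bridge is reported per unordered residue
pair, carrying the shortest path (ties broken by lexicographically
smallest water identifiers), every qualifying endpoint atom pair, and
the set of all distinct waters seen in any qualifying path (the pair's
water multiplicity).  Direct protein–protein hydrogen bonds are
recorded in the graph but are never bridges, and same-residue pairs
are excluded by default.

The **cluster method** reports connected components of the
water–water / protein–water subgraph.  A water's depth is its hop
count from the nearest protein-bonded water (depth 1); members beyond
`maxDepth` are truncated, mirroring the chain method's semantics, and
truncation may split a component.  Components that touch no protein
anywhere are reported whole as bulk clusters with zero residues.
Waters with no hydrogen bonds at all appear in no cluster, since the
component analysis operates on the bond list.

## Ensemble statistics

The chain method runs on every `stride`-th frame.  A bridge's identity
across frames is its unordered residue pair, so water exchange does
not interrupt continuity.  Per pair we report: frequency (bridged
frames / analysed frames), mean and standard deviation of the endpoint
heavy-atom distance over bridged frames (population SD, zero for a
single frame), mean water multiplicity, and — because "duration" has
two common readings — both the longest and the mean run of consecutive
bridged frames, converted to ps when the trajectory has a timestep.
Pair statistics fill symmetric residue-by-residue matrices
(frequency, mean distance, mean water count); the numeric CSV is the
authoritative output and plots are convenience.  For visualisation,
each residue's maximum bridge frequency is written into the B-factor
column of a PDB copy, clamped to [0, 1], so viewers can colour from 0
(blue) to 1 (red); non-participating residues carry exactly 0.

## Hydration sites

Water-oxygen positions — one frame, or pooled over a trajectory — are
clustered density-based (DBSCAN-style): a core point has at least
`min_samples` neighbours within `eps` (counting itself, the sklearn
convention); clusters are connected unions of core neighbourhoods; a
border point joins its *nearest* core point's cluster, Euclidean ties
broken by lower cluster index; the rest is noise.  The nearest-core
rule (rather than first-come scan order) makes the partition invariant
under permutation of the observations, which is why the clustering is
implemented here rather than delegated; scikit-learn's DBSCAN serves
as an independent cross-check on core-point partitions in the tests.
Defaults `eps` = 1.0 Å, `min_samples` = 4 suit typical water–water
spacing; sites report centroid, member count, occupancy (members per
frame, may exceed 1), RMS spread, and protein residues with a polar
atom within `distWR`.

## File formats and numerics

PDB and mmCIF parsing is delegated to gemmi; the mmCIF path is a
minimal `atom_site` reader (identity, model number, xyz, occupancy,
B).  Multi-MODEL files become coordinate frames over the first model's
atom table; a model with a different atom count is a parse error
naming the model.  Altloc duplicates keep the highest-occupancy
conformer, ties broken by altloc letter.  The PDB writer is
fixed-column v3.3 (coordinates to 3 decimals, hence round-trip
agreement to 10⁻³ Å).  DCD read/write handles the NAMD/CHARMM layout
directly — 4-byte Fortran record markers, both byte orders, CHARMM
unit-cell blocks skipped — and stores single-precision coordinates;
MDAnalysis is the independent reader used to cross-validate in tests.
No periodic-boundary unwrapping is performed; trajectories are assumed
pre-imaged.

## Synthetic inputs and what they show

The fixture generator plants bridges with ideal geometry: donor N–H
and acceptor O pseudo-residues (GLY-named so role assignment needs no
special cases) joined by a collinear water chain at 2.8 Å spacing, so
every planted bond passes the default criteria by construction and
chains separated by 14 Å cannot cross-talk.  Decoy waters sit on a
remote grid, ≥ `distDA` + 1 Å from all polar atoms (asserted at
generation).  Trajectories switch each bridge on with probability
`occupancy_p` per frame (PCG64, fixed seed ⇒ bit-identical output);
off-frames displace the chain's waters by 3 × `distDA`.  Optional
per-frame endpoint spans support exact distance-moment checks.
Site pools are isotropic Gaussians (σ = 0.3 Å, centers ≥ 5σ apart)
plus uniform noise.

These fixtures are geometric, not physical: no thermal jitter around
on-state geometry, no competing near-threshold contacts, no
correlated water motion, no periodic box.  Passing tests therefore
demonstrate algorithmic correctness (graph search, counting,
statistics, I/O) — not robustness of the default thresholds on real
crystallographic or simulation data, which users should assess on
their own systems.

Test and demonstration problem sizes (≈ 200 random graphs of ≤ 12
waters, 50-frame trajectories, 150-observation site pools) were chosen
as the smallest scales at which every code path and tie-break is
exercised; the whole suite runs in seconds.

## Known limitations

* Protein donors other than the rotatable set are rejected in
  with-hydrogens mode when the input lacks their hydrogens; use
  angle-free mode for H-free structures (the automatic default).
* No energetic scoring; criteria are purely geometric.
* Bulk-water clusters require at least one water–water hydrogen bond;
  isolated unbonded waters are not reported as clusters.
* mmCIF writing and TRR/CRD trajectory formats are out of scope
  (convert externally); no PDB fetching over the network.
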