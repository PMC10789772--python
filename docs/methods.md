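# Methods

## Senary classification and divergence flagging

Backbone dihedrals are computed from four consecutive atoms with the
IUPAC sign convention: φ(i) from C(i−1)–N(i)–CA(i)–C(i), ψ(i) from
N(i)–CA(i)–C(i)–N(i+1), ω(i) from CA(i−1)–C(i−1)–N(i)–CA(i).  Values live
in (−180°, +180°], with +180° for trans; angles undefined at termini or
across chain breaks are represented as missing, never as 0.  A chain
break is declared when the peptide C–N bond exceeds 2.5 Å — a standard
heuristic choice.

Each defined angle is assigned to one of six 60° classes
(±sp→0, +sc→1, +ac→2, ±ap→3, −ac→4, −sc→5).  The class intervals as
usually written ("30° to 90°", "90° to 150°", …) overlap at their edges,
so a boundary convention is mandatory: **bins are half-open, closed at
the lower edge** — [−30, 30), [30, 90), [90, 150), [150, 180] ∪
(−180, −150), [−150, −90), [−90, −30) — and ±180° always belongs to ±ap.
The opposite (upper-closed) convention is selectable
(`classify_senary(..., closed="upper")`) and only moves exact-edge
angles.  Inputs outside (−180, 180] are normalised, never rejected.

Divergence between two structures is the cyclic difference of class
codes, min(|a−b|, 6−|a−b|), a metric on the 6-cycle with maximum 3.  A
residue is flagged when **any** of its defined main-chain angles has
difference 3; ω is included by default because it is a main-chain
dihedral, and can be toggled off (`include_omega=False`) for the
φ/ψ-only reading.  Reports carry raw angle values alongside classes so
near-boundary flags can be audited.  Residue pairing uses global
alignment (match +1, mismatch 0, gap −2), which generalises the fixed
one-residue numbering offset between close paralogs to arbitrary indels.

Rationale for the difference-3 criterion: a transition between opposite
classes must cross at least one torsional potential-energy barrier, so
such residues are the plausible local drivers of a global rearrangement.
The flag is a geometric screen, not a statistical test; no significance
is attached to flag counts.

## Domain geometry

Superposition is the Kabsch least-squares fit over proper rotations
(reflections excluded), computed via `scipy`'s rotation alignment on
centred coordinates.  The inter-domain angle aligns the CA atoms of a
reference domain of structure B onto structure A, then takes the Kabsch
rotation R that would superpose the measured domain and reports
θ = arccos((tr R − 1)/2), with the cosine clamped to [−1, 1] for numeric
safety.  CA-only alignment is the conventional choice for domain-motion
measurement.  Side-chain contact distance is the minimum heavy-atom pair
distance with side chain = heavy atoms excluding N/CA/C/O; glycine falls
back to CA so the quantity stays defined.

## Trajectory clustering

Snapshot bookkeeping: a run of duration T sampled every Δt yields
⌊T/Δt⌋ + 1 snapshots when t = 0 is recorded (1 μs at 1 ns → 1001).
Frames are consecutive blocks of at most `frame_size` snapshots; the
frame count is **⌈n/size⌉ with a short final frame** — note that
101 frames × 10 snapshots would be 1010, not 1001, so for the canonical
1001/10 case the last frame holds a single snapshot.  A frame's
structure for RMSD purposes is, by default, the coordinate-wise mean of
its snapshots after superposing each onto the frame's first snapshot;
the central snapshot is selectable (`mode="central"`) since "RMSD
between frames" does not by itself define a frame's coordinates.

The frame–frame RMSD is Kabsch-minimised over the selected main-chain
atom set (default N, CA, C; N, CA, C, O selectable; raw non-superposed
RMSD available for sensitivity checks).  Clustering joins frames with
RMSD strictly below the threshold (default 2 Å) and takes connected
components — single-linkage transitive closure, since pairwise "same
cluster" assignments must yield disjoint clusters.  Each cluster's
representative is its medoid; ties break to the lowest frame index for
determinism.

## In-silico proteolysis

Trypsin specificity is the Keil rule — cleavage C-terminal to K or R
except before P — the community standard when no experimental rule is
given; the C-terminal residue is never a site, and non-standard letters
warn and are treated as non-cleavable.  Limited digestion is modelled by
enumerating all fragments bounded by chain ends or sites with at most
`max_missed` internal (missed) sites; the default is unlimited because
partial digestion produces all such products, while `max_missed=0`
models digestion to completion.  Domain mapping reports, per annotated
domain, overlap residues divided by fragment length; fractions sum to at
most 1 when the annotation leaves gaps.  Relative peptide scores divide
each band's peptide score by the same peptide's score in the designated
"Total" band; a peptide missing from Total is flagged without a score
and a zero Total produces an explicit division-undefined entry rather
than an infinity.  Score computation itself (e.g. Mascot) is out of
scope; scores are consumed from a TSV table.

## Synthetic data: what it emulates, what it does not

The generators produce exactly the inputs the analyses consume, with
ground truth attached:

* `build_backbone` places N/CA/C (plus carbonyl O and CB) sequentially
  by NeRF from fixed textbook peptide geometry (N–CA 1.458 Å, CA–C
  1.525 Å, C–N 1.329 Å; N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°).
  Only dihedrals matter to the analyses under test, so bond lengths and
  angles are constants.  The module's central contract is the
  round-trip: re-measuring a built backbone reproduces the dihedral
  specification to below 10⁻⁶ degrees.
* Homolog pairs share base angles at senary bin centers (φ = −120°,
  ψ = 120°, ω = 180°); planted transitions move one angle between the
  centers of two chosen classes; both structures get independent uniform
  dihedral noise (default ±2°, required < 5° so no bin boundary can be
  crossed), and the second structure an arbitrary rigid motion.  Noise
  is applied in dihedral space here because the senary analysis measures
  dihedrals.
* Trajectories sample k hinge conformers (helix before, extended strand
  after a hinge residue placed differently per conformer) whose mutual
  main-chain RMSD is verified > 4 Å at construction, with isotropic
  Cartesian noise per snapshot (default σ = 0.3 Å per coordinate, i.e.
  pairwise intra-conformer RMSD ≈ σ√6 ≈ 0.73 Å, comfortably under the
  2 Å threshold); Cartesian noise is used because the clustering
  measures Cartesian RMSD.  Snapshots are blocked by conformer so frame
  grouping stays pure.
* Digest fixtures draw from a K/R/P-free alphabet and plant K/R at known
  positions with three equal-thirds domains.

All generators are deterministic given a seed.  What passing these tests
does **not** show: real structures have variable bond geometry,
side-chain packing, prolines/glycines with restricted or extended
Ramachandran behaviour, angles sitting near bin boundaries, and
trajectories with gradual interconversion rather than well-separated
conformers.  Tests on the synthetic inputs validate the computations and
conventions, not the biological discrimination power of the 2 Å or
difference-3 thresholds on real data.

Default problem sizes in the tests and worked examples (20–50-residue
backbones, tens of snapshots) are chosen so each property is exercised
well past its edge cases while the whole suite runs in seconds.

## Known limitations

* Senary profiles cover main-chain φ/ψ/ω only; side-chain χ angles are
  not classified.
* The inter-domain angle reports a magnitude, not a hinge axis or screw
  decomposition.
* Structure I/O resolves alternate locations to the highest-occupancy
  conformer (ties by alt-loc letter) and ignores hydrogens, waters and —
  by default — all heteroatoms; mmCIF writing and biological-assembly
  expansion are not provided.
* Clustering treats frames as exchangeable items; no kinetic or
  thermodynamic weighting of clusters is attempted.
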