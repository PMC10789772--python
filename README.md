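# confdiff

Structural-bioinformatics toolkit for explaining **why two closely related
protein structures adopt different global conformations** — the situation
typified by paralogous DEAD-box RNA helicases whose N- and C-terminal
RecA-like domains sit in different relative orientations in the apo
(nucleotide-free) state.  It is written for structural biologists who have
two homologous coordinate sets (crystal structures, or a structure and an
MD-derived model) and want to localise the backbone changes that drive the
domain rearrangement, plus the supporting analyses around that question.

## What it computes

**Senary dihedral classification and cyclic-difference scoring** (the core
method).  Every main-chain dihedral (φ, ψ, ω) is binned into one of six
60°-wide conformational classes, encoded 0–5 around the circle:

| code | label | interval |
|------|-------|----------|
| 0 | ±sp (±synperiplanar) | −30° … 30° |
| 1 | +sc (+synclinal) | 30° … 90° |
| 2 | +ac (+anticlinal) | 90° … 150° |
| 3 | ±ap (±antiperiplanar) | 150° … 180° and −180° … −150° |
| 4 | −ac (−anticlinal) | −150° … −90° |
| 5 | −sc (−synclinal) | −90° … −30° |

Conformational change between homologs is the **cyclic difference** of the
class codes — the shorter walk around the 6-cycle, so d(5, 1) = 2, not 4,
and d ≤ 3 always.  A difference of 3 is the *most distant* transition,
separated by at least one torsional energy barrier; residues carrying a
difference-3 transition in any main-chain angle are flagged as candidate
drivers of the global structural divergence.  Residues of the two
structures are paired by global sequence alignment (Needleman–Wunsch),
which absorbs numbering offsets between paralogs.

**Domain geometry.**  Kabsch least-squares superposition, RMSD, the
inter-domain rotation angle θ = arccos((tr R − 1)/2) of the residual
rotation R that maps one domain after the other has been aligned, and
minimum side-chain heavy-atom contact distances.

**Trajectory clustering.**  Snapshots of a coordinate trajectory
(multi-model PDB) are grouped into consecutive frames (⌈n/size⌉ frames;
1001 snapshots at size 10 → 101 frames), a pairwise Kabsch-minimised
main-chain RMSD matrix over frames is built, frames with RMSD < 2 Å are
merged by single-linkage transitive closure, and each cluster is
represented by its medoid (minimal summed RMSD to the other members).

**In-silico limited proteolysis.**  Tryptic cleavage sites under the Keil
rule (after K/R, not before P), enumeration of partial-digest fragments
with missed cleavages, mapping of fragments onto annotated domains
(N-domain / linker / C-domain), and relative peptide scores — each band's
peptide prot-score divided by the same peptide's score in the undigested
"Total" band.

**Synthetic structures.**  A NeRF (internal-to-Cartesian) backbone builder
and generators for homolog pairs with planted difference-3 residues,
multi-conformer trajectories with controlled noise, and digest fixtures —
so every analysis is testable against known ground truth without
downloading coordinates.

## Worked example

Generate fixtures with a known planted divergence (a ψ flip from class 3
to class 0 at residue 15 of a 30-residue backbone), then compare:

```sh
$ confdiff make-fixtures --out fixtures --seed 1 --n-residues 30
fixtures written to fixtures
$ confdiff compare fixtures/homolog_a.pdb fixtures/homolog_b.pdb --out compare_out
compared residue pairs: 30
flagged (difference-3) residues: 1
  A/ALA15  <->  A/ALA15
```

The planted residue — and only it — is flagged: its ψ moved between the
two most distant senary classes, while sub-boundary dihedral noise and the
rigid-body motion of the whole second structure produce no false
positives.  `compare_out/divergence.tsv` holds the full per-residue audit
trail (raw angles, class codes, per-angle cyclic differences).

Cluster the synthetic three-conformer trajectory (30 snapshots, frames of
5) and digest the fixture sequence:

```sh
$ confdiff cluster fixtures/trajectory.pdb --out cluster_out --frame-size 5
6 frames -> 3 clusters; representatives (medoids): [1, 3, 5]
$ confdiff digest fixtures/digest.fasta --out digest_out
3 sites, 10 fragments
```

The six frames fall into exactly the three planted conformers (two frames
each), and the three planted K/R sites yield the 10 partial-digest
fragments bounded by sites or chain ends.  The same operations are
available as library functions (`confdiff.compare_structures`,
`confdiff.cluster_trajectory`, `confdiff.predict_trypsin_sites`, …).

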