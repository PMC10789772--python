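"""Senary conformational classification and backbone-divergence flagging.

The central idea: every main-chain dihedral angle is binned into one of six
60°-wide conformational classes, numbered 0–5 around the circle,

====  ======  =============================
code  label   interval (degrees)
====  ======  =============================
0     ±sp     −30 … 30   (±synperiplanar)
1     +sc     30 … 90    (+synclinal)
2     +ac     90 … 150   (+anticlinal)
3     ±ap     150 … 180 and −180 … −150 (±antiperiplanar)
4     −ac     −150 … −90 (−anticlinal)
5     −sc     −90 … −30  (−synclinal)
====  ======  =============================

and conformational change between two homologous structures is measured as
the cyclic difference between class codes — the shorter walk around the
6-cycle, so the difference between 5 and 1 is 2, not 4.  A difference of 3
is the most distant transition, separated by at least one potential-energy
barrier, and residues carrying such a transition in any main-chain angle
are flagged as drivers of the global structural divergence.

Bin boundaries are half-open, closed at the lower edge ([−30, 30),
[30, 90), …), with +180 belonging to ±ap; the opposite convention is
selectable via ``closed="upper"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import floor
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align

from .backbone_geometry import BackboneDihedralSet, backbone_dihedrals, _normalize_angle
from .structure_io import ResidueId, StructureModel

__all__ = [
    "SENARY_LABELS",
    "SenaryClass",
    "classify_senary",
    "cyclic_difference",
    "SenaryProfile",
    "senary_profile",
    "ResidueCorrespondence",
    "residue_correspondence",
    "structure_correspondence",
    "DivergenceRecord",
    "compare_structures",
    "flag_divergent_residues",
    "divergence_table",
    "THREE_TO_ONE",
    "sequence_of",
]

#: Fixed code ↔ label bijection for the six conformational classes.
SENARY_LABELS: tuple[str, ...] = ("±sp", "+sc", "+ac", "±ap", "−ac", "−sc")

ANGLE_KINDS: tuple[str, ...] = ("phi", "psi", "omega")


@dataclass(frozen=True)
class SenaryClass:
    code: int

    def __post_init__(self) -> None:
        if self.code not in range(6):
            raise ValueError(f"senary code must be 0..5, got {self.code}")

    @property
    def label(self) -> str:
        return SENARY_LABELS[self.code]

    def __int__(self) -> int:
        return self.code


def classify_senary(angle: float, closed: str = "lower") -> SenaryClass:
    """Assign a dihedral angle (degrees) to its senary conformational class.

    The angle is first normalised into (−180, +180].  With the default
    ``closed="lower"`` convention each 60° bin includes its lower edge
    (so 30° → +sc); ``closed="upper"`` includes the upper edge instead
    (30° → ±sp).  ±180° always maps to ±ap (code 3), which straddles the
    branch cut by definition.
    """
    if closed not in ("lower", "upper"):
        raise ValueError("closed must be 'lower' or 'upper'")
    a = _normalize_angle(angle)
    shifted = a + 30.0
    code = floor(shifted / 60.0)
    if closed == "upper" and shifted % 60.0 == 0.0:
        code -= 1
    return SenaryClass(code % 6)


def cyclic_difference(a: SenaryClass | int, b: SenaryClass | int) -> int:
    """Distance between two senary codes along the 6-cycle (shorter walk).

    Symmetric, zero iff equal, and at most 3 — e.g. the difference between
    5 and 1 is 2, not 4.
    """
    d = abs(int(a) - int(b))
    return min(d, 6 - d)


# ---------------------------------------------------------------------------
# profiles


@dataclass
class SenaryProfile:
    """Per-residue, per-angle senary classes for one structure."""

    residues: list[ResidueId]
    classes: dict[tuple[str, int, str], dict[str, SenaryClass | None]]
    angles: dict[tuple[str, int, str], dict[str, float | None]]

    def cls(self, rid: ResidueId, kind: str) -> SenaryClass | None:
        return self.classes[rid.key][kind]


def senary_profile(
    dihedrals: BackboneDihedralSet, closed: str = "lower"
) -> SenaryProfile:
    """Classify every defined dihedral of a structure; undefined stays missing."""
    classes: dict = {}
    angles: dict = {}
    for rid in dihedrals.residues:
        entry = dihedrals[rid.key]
        classes[rid.key] = {
            k: (classify_senary(entry[k], closed) if entry[k] is not None else None)
            for k in ANGLE_KINDS
        }
        angles[rid.key] = {k: entry[k] for k in ANGLE_KINDS}
    return SenaryProfile(residues=dihedrals.residues, classes=classes, angles=angles)


# ---------------------------------------------------------------------------
# residue correspondence


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def sequence_of(s: StructureModel) -> str:
    """One-letter sequence of a model's residues ('X' for non-standard)."""
    return "".join(THREE_TO_ONE.get(r.id.residue_name, "X") for r in s.residues)


@dataclass
class ResidueCorrespondence:
    """Order-preserving pairing of residues between two structures.

    ``pairs`` holds 0-based positions into the two sequences; residues
    caught in gaps are listed per side.
    """

    pairs: list[tuple[int, int]]
    unaligned_a: list[int] = field(default_factory=list)
    unaligned_b: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)


def residue_correspondence(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = -2.0,
) -> ResidueCorrespondence:
    """Pair positions of two protein sequences by global alignment.

    Needleman–Wunsch with match +1, mismatch 0, gap −2 by default; gapped
    positions are left unpaired.  This generalises the fixed one-residue
    numbering offset between close homologs (such as UAP56 vs URH49) to
    arbitrary indels.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    aln = aligner.align(seq_a, seq_b)[0]
    pairs: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    paired_a = {i for i, _ in pairs}
    paired_b = {j for _, j in pairs}
    return ResidueCorrespondence(
        pairs=pairs,
        unaligned_a=[i for i in range(len(seq_a)) if i not in paired_a],
        unaligned_b=[j for j in range(len(seq_b)) if j not in paired_b],
    )


def structure_correspondence(
    a: StructureModel, b: StructureModel, **kwargs
) -> list[tuple[ResidueId, ResidueId]]:
    """Residue-level pairing of two structures via sequence alignment."""
    corr = residue_correspondence(sequence_of(a), sequence_of(b), **kwargs)
    return [(a.residues[i].id, b.residues[j].id) for i, j in corr.pairs]


# ---------------------------------------------------------------------------
# divergence records


@dataclass
class DivergenceRecord:
    """Cyclic class differences for one aligned residue pair.

    ``flagged`` is true iff some defined per-angle difference equals 3 —
    the most distant conformational transition.
    """

    residue_a: ResidueId
    residue_b: ResidueId
    differences: dict[str, int | None]
    angles_a: dict[str, float | None]
    angles_b: dict[str, float | None]
    classes_a: dict[str, SenaryClass | None]
    classes_b: dict[str, SenaryClass | None]

    @property
    def max_difference(self) -> int:
        defined = [d for d in self.differences.values() if d is not None]
        return max(defined) if defined else 0

    @property
    def flagged(self) -> bool:
        return any(d == 3 for d in self.differences.values() if d is not None)


def compare_structures(
    a: StructureModel,
    b: StructureModel,
    corr: Sequence[tuple[ResidueId, ResidueId]] | None = None,
    include_omega: bool = True,
    closed: str = "lower",
) -> list[DivergenceRecord]:
    """Senary-difference every aligned residue pair of two structures.

    Computes φ/ψ/ω for both structures, classifies them, and returns one
    :class:`DivergenceRecord` per aligned pair in structure-A order.  A
    per-angle difference is missing whenever either angle is undefined.
    Dihedrals are invariant under rigid motion, so structures differing by
    a global rotation/translation produce all-zero differences.
    """
    if corr is None:
        corr = structure_correspondence(a, b)
    if not corr:
        raise ValueError("empty residue correspondence")
    kinds = ANGLE_KINDS if include_omega else ("phi", "psi")
    prof_a = senary_profile(backbone_dihedrals(a), closed)
    prof_b = senary_profile(backbone_dihedrals(b), closed)
    records: list[DivergenceRecord] = []
    for rid_a, rid_b in corr:
        ca, cb = prof_a.classes.get(rid_a.key), prof_b.classes.get(rid_b.key)
        if ca is None or cb is None:
            continue
        diffs: dict[str, int | None] = {}
        for k in ANGLE_KINDS:
            if k in kinds and ca[k] is not None and cb[k] is not None:
                diffs[k] = cyclic_difference(ca[k], cb[k])
            else:
                diffs[k] = None
        records.append(
            DivergenceRecord(
                residue_a=rid_a,
                residue_b=rid_b,
                differences=diffs,
                angles_a=prof_a.angles[rid_a.key],
                angles_b=prof_b.angles[rid_b.key],
                classes_a=ca,
                classes_b=cb,
            )
        )
    if not any(
        d is not None for r in records for d in r.differences.values()
    ):
        raise ValueError("nothing comparable: no aligned pair has defined dihedrals")
    return records


def flag_divergent_residues(
    records: Iterable[DivergenceRecord],
) -> list[tuple[ResidueId, ResidueId]]:
    """Residue pairs whose senary code changed by 3 in any main-chain angle."""
    return [(r.residue_a, r.residue_b) for r in records if r.flagged]


def divergence_table(records: Sequence[DivergenceRecord]) -> pd.DataFrame:
    """Tabulate records with raw angles and classes so flags are auditable."""
    rows = []
    for r in records:
        row: dict = {
            "chain_a": r.residue_a.chain_id,
            "res_a": r.residue_a.seq_number,
            "name_a": r.residue_a.residue_name,
            "chain_b": r.residue_b.chain_id,
            "res_b": r.residue_b.seq_number,
            "name_b": r.residue_b.residue_name,
        }
        for k in ANGLE_KINDS:
            row[f"{k}_a"] = r.angles_a[k]
            row[f"{k}_b"] = r.angles_b[k]
            row[f"{k}_class_a"] = (
                r.classes_a[k].code if r.classes_a[k] is not None else None
            )
            row[f"{k}_class_b"] = (
                r.classes_b[k].code if r.classes_b[k] is not None else None
            )
            row[f"{k}_diff"] = r.differences[k]
        row["max_diff"] = r.max_difference
        row["flagged"] = r.flagged
        rows.append(row)
    df = pd.DataFrame(rows)
    int_cols = [c for c in df.columns if c.endswith(("_class_a", "_class_b", "_diff"))]
    df[int_cols] = df[int_cols].astype("Int64")
    return df
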