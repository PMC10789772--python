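"""Hierarchical structure model and PDB input/output.

Structures are read from PDB files (single- or multi-MODEL) into a small
chain/residue/atom hierarchy that the geometry and comparison modules
consume.  Parsing and serialisation are delegated to :mod:`gemmi`; this
module owns the alternate-location policy, heteroatom filtering and the
residue/atom selection helpers.

Conventions
-----------
* Author residue numbering (1-based, as deposited); ranges inclusive on
  both ends.
* Alternate locations: the highest-occupancy conformer is kept, ties are
  broken by alt-loc letter order, so downstream geometry always sees a
  single conformer per atom.
* HETATM records and waters are excluded by default.
* Hydrogens are dropped everywhere; only heavy atoms participate in
  distances and RMSD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueId",
    "Residue",
    "StructureModel",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "select_residue_range",
    "backbone_atoms",
    "BACKBONE_ATOM_SETS",
]

#: Named main-chain atom sets selectable wherever "main chain" is measured.
BACKBONE_ATOM_SETS: dict[str, tuple[str, ...]] = {
    "N_CA_C": ("N", "CA", "C"),
    "N_CA_C_O": ("N", "CA", "C", "O"),
}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed into a structure model."""


@dataclass(frozen=True)
class ResidueId:
    """Identifier of a residue under author numbering.

    ``(chain_id, seq_number, insertion_code)`` is unique within a model.
    """

    chain_id: str
    seq_number: int
    insertion_code: str = ""
    residue_name: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def __str__(self) -> str:  # e.g. "A/VAL224"
        return f"{self.chain_id}/{self.residue_name}{self.seq_number}{self.insertion_code}"


@dataclass
class AtomRecord:
    """One heavy atom after alt-loc resolution."""

    atom_name: str
    element: str
    coords: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    b_factor: float = 0.0
    alt_loc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.atom_name}: coordinates must be a finite 3-vector")


@dataclass
class Residue:
    id: ResidueId
    atoms: list[AtomRecord] = field(default_factory=list)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        return None

    @property
    def name(self) -> str:
        return self.id.residue_name


@dataclass
class StructureModel:
    """One coordinate model: ordered residues, each with ordered atoms."""

    model_index: int = 1
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.id.chain_id, None)
        return list(seen)

    def residue(self, rid: ResidueId) -> Residue:
        for r in self.residues:
            if r.id.key == rid.key:
                return r
        raise KeyError(f"residue {rid} not in model")

    def coordinates(self) -> np.ndarray:
        """All atom coordinates in residue/atom order, shape (n_atoms, 3)."""
        return np.array([a.coords for r in self.residues for a in r.atoms], dtype=float)


# ---------------------------------------------------------------------------
# reading


def _resolve_altlocs(atoms: list[gemmi.Atom]) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by alt-loc letter."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for a in atoms:
        by_name.setdefault(a.name, []).append(a)
    kept = []
    for name, group in by_name.items():
        best = min(group, key=lambda a: (-a.occ, a.altloc or "~"))
        kept.append(best)
    return kept


def _convert_model(model: gemmi.Model, index: int, include_het: bool) -> StructureModel:
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            if res.name in _WATER_NAMES:
                continue
            is_het = res.het_flag == "H"
            if is_het and not include_het:
                continue
            rid = ResidueId(
                chain_id=chain.name,
                seq_number=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
                residue_name=res.name,
            )
            atoms = []
            for a in _resolve_altlocs(list(res)):
                if a.element.is_hydrogen:
                    continue
                atoms.append(
                    AtomRecord(
                        atom_name=a.name,
                        element=a.element.name,
                        coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        occupancy=a.occ,
                        b_factor=a.b_iso,
                        alt_loc=a.altloc or "",
                    )
                )
            if atoms:
                residues.append(Residue(id=rid, atoms=atoms))
    return StructureModel(model_index=index, residues=residues)


def read_pdb(
    path: str | Path,
    model: int | None = None,
    include_het: bool = False,
) -> StructureModel | list[StructureModel]:
    """Read a PDB file into one or more :class:`StructureModel`.

    Parameters
    ----------
    path : str or Path
        PDB file with ATOM/HETATM records; MODEL/ENDMDL blocks yield
        multiple models.
    model : int, optional
        1-based model index to return.  When omitted, a single-model file
        returns one :class:`StructureModel` and a multi-model file returns
        a list with one entry per MODEL block.
    include_het : bool
        Keep non-water HETATM residues (default off: ligands such as
        sulfate or PEG are excluded from geometry).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi reports the offending line
        raise PDBParseError(f"{path}: {exc}") from exc
    models = [
        _convert_model(m, i + 1, include_het) for i, m in enumerate(st)
    ]
    models = [m for m in models if m.residues]
    if not models:
        raise PDBParseError(f"{path}: no atoms")
    if model is not None:
        for m in models:
            if m.model_index == model:
                return m
        raise KeyError(f"model {model} not present in {path}")
    if len(models) == 1:
        return models[0]
    return models


# ---------------------------------------------------------------------------
# writing


def write_pdb(models: StructureModel | Sequence[StructureModel], path: str | Path) -> None:
    """Write one or several models as a (multi-model) PDB file."""
    if isinstance(models, StructureModel):
        models = [models]
    st = gemmi.Structure()
    st.name = "confdiff"
    for i, sm in enumerate(models):
        # MODEL numbers must be unique in a file; renumber sequentially
        gm = gemmi.Model(i + 1)
        chains: dict[str, gemmi.Chain] = {}
        for res in sm.residues:
            cid = res.id.chain_id
            if cid not in chains:
                chains[cid] = gemmi.Chain(cid)
            gr = gemmi.Residue()
            gr.name = res.id.residue_name
            gr.seqid = gemmi.SeqId(res.id.seq_number, res.id.insertion_code or " ")
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.atom_name
                ga.element = gemmi.Element(a.element or a.atom_name[0])
                ga.pos = gemmi.Position(*a.coords)
                ga.occ = a.occupancy
                ga.b_iso = a.b_factor
                ga.altloc = "\0"
                gr.add_atom(ga)
            chains[cid].add_residue(gr)
        for ch in chains.values():
            gm.add_chain(ch)
        st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# selection


def select_residue_range(
    s: StructureModel, chain: str, first: int, last: int
) -> StructureModel:
    """Return the sub-model with ``first <= seq_number <= last`` in ``chain``.

    The range is inclusive on both ends under author numbering, so a
    gap-free chain numbered 13..388 selected as (13, 388) yields 376
    residues.
    """
    if first > last:
        raise ValueError(f"range start {first} exceeds end {last}")
    if chain not in s.chains():
        raise KeyError(f"chain {chain!r} not in model (has {s.chains()})")
    kept = [
        r
        for r in s.residues
        if r.id.chain_id == chain and first <= r.id.seq_number <= last
    ]
    if not kept:
        warnings.warn(
            f"selection {chain}:{first}-{last} is empty", stacklevel=2
        )
    return StructureModel(model_index=s.model_index, residues=kept)


def backbone_atoms(
    s: StructureModel, atom_set: str = "N_CA_C"
) -> tuple[np.ndarray, list[ResidueId]]:
    """Collect main-chain coordinates in residue order.

    Returns ``(coords, incomplete)`` where ``coords`` has one row per
    requested atom of every residue that carries the full atom set, and
    ``incomplete`` lists residues missing at least one requested atom
    (reported, never fatal).
    """
    names = BACKBONE_ATOM_SETS[atom_set] if isinstance(atom_set, str) else tuple(atom_set)
    coords: list[np.ndarray] = []
    incomplete: list[ResidueId] = []
    for res in s.residues:
        picked = [res.atom(n) for n in names]
        if any(a is None for a in picked):
            incomplete.append(res.id)
            continue
        coords.extend(a.coords for a in picked)  # type: ignore[union-attr]
    out = np.array(coords, dtype=float) if coords else np.empty((0, 3))
    return out, incomplete
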