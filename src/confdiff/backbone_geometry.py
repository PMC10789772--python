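"""Core 3-D geometry: dihedral angles, Kabsch superposition, RMSD,
inter-domain rotation angles and side-chain contact distances.

Angles follow the IUPAC sign convention and live in the half-open interval
(−180°, +180°]; +180° is the trans value.  Missing angles (chain termini,
chain breaks) are represented as ``None``, never as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import Residue, ResidueId, StructureModel

__all__ = [
    "DegenerateGeometryError",
    "DihedralAngle",
    "BackboneDihedralSet",
    "SuperpositionResult",
    "SidechainContact",
    "dihedral",
    "backbone_dihedrals",
    "kabsch_superpose",
    "apply_superposition",
    "coordinate_rmsd",
    "interdomain_angle",
    "rotation_angle",
    "min_sidechain_distance",
    "CHAIN_BREAK_CN",
]

#: Peptide-bond C–N distance (Å) above which a chain break is declared.
CHAIN_BREAK_CN = 2.5

_MAINCHAIN = {"N", "CA", "C", "O", "OXT"}


class DegenerateGeometryError(ValueError):
    """Coincident or collinear points make the requested angle undefined."""


@dataclass(frozen=True)
class DihedralAngle:
    value: float  # degrees in (−180, +180]
    kind: str  # "phi" | "psi" | "omega"
    residue: ResidueId


def _normalize_angle(angle: float) -> float:
    """Map any angle in degrees into (−180, +180]."""
    a = float(angle) % 360.0
    if a > 180.0:
        a -= 360.0
    if a == -180.0:
        a = 180.0
    return a


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (degrees) defined by four points.

    Looking down the p2→p3 axis, the angle rotates the p1 branch onto the
    p4 branch; positive is clockwise (IUPAC).  The value is invariant under
    rigid motions of all four points and negated by reflection.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for a, b in ((p1, p2), (p2, p3), (p3, p4)):
        if np.linalg.norm(b - a) < 1e-9:
            raise DegenerateGeometryError("consecutive points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise DegenerateGeometryError("collinear points: dihedral undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2)))
    return _normalize_angle(np.degrees(np.arctan2(y, x)))


class BackboneDihedralSet(Mapping[tuple[str, int, str], dict]):
    """Per-residue φ/ψ/ω angles keyed by residue.

    Behaves as a mapping from ``ResidueId.key`` to a dict with keys
    ``"phi"``, ``"psi"``, ``"omega"`` (values in degrees or ``None``) plus
    the ``ResidueId`` under ``"residue"``.
    """

    def __init__(self, entries: list[tuple[ResidueId, dict[str, float | None]]]):
        self._order = [rid for rid, _ in entries]
        self._data = {
            rid.key: {"residue": rid, **angles} for rid, angles in entries
        }

    def __getitem__(self, key):
        return self._data[key]

    def __iter__(self):
        return iter(k.key for k in self._order)

    def __len__(self):
        return len(self._order)

    @property
    def residues(self) -> list[ResidueId]:
        return list(self._order)

    def angle(self, rid: ResidueId, kind: str) -> float | None:
        return self._data[rid.key][kind]


def _backbone_triplet(res: Residue):
    return res.atom("N"), res.atom("CA"), res.atom("C")


def backbone_dihedrals(s: StructureModel) -> BackboneDihedralSet:
    """Compute φ, ψ and ω for every residue of a structure.

    φ(i) = C(i−1)–N(i)–CA(i)–C(i); ψ(i) = N(i)–CA(i)–C(i)–N(i+1);
    ω(i) = CA(i−1)–C(i−1)–N(i)–CA(i).  Angles at termini, across chains
    and across breaks (peptide C–N longer than ``CHAIN_BREAK_CN``) are
    ``None``.
    """
    residues = s.residues
    if len(residues) < 2:
        raise ValueError("need at least 2 consecutive residues")

    def bonded(prev: Residue, cur: Residue) -> bool:
        if prev.id.chain_id != cur.id.chain_id:
            return False
        c, n = prev.atom("C"), cur.atom("N")
        if c is None or n is None:
            return False
        d = float(np.linalg.norm(c.coords - n.coords))
        if d > CHAIN_BREAK_CN:
            warnings.warn(
                f"chain break between {prev.id} and {cur.id} (C–N {d:.2f} Å)",
                stacklevel=2,
            )
            return False
        return True

    entries: list[tuple[ResidueId, dict[str, float | None]]] = []
    for i, res in enumerate(residues):
        n, ca, c = _backbone_triplet(res)
        phi = psi = omega = None
        prev = residues[i - 1] if i > 0 else None
        nxt = residues[i + 1] if i + 1 < len(residues) else None
        complete = all(a is not None for a in (n, ca, c))
        if prev is not None and complete and bonded(prev, res):
            pc = prev.atom("C")
            pca = prev.atom("CA")
            if pc is not None:
                phi = dihedral(pc.coords, n.coords, ca.coords, c.coords)
                if pca is not None:
                    omega = dihedral(pca.coords, pc.coords, n.coords, ca.coords)
        if nxt is not None and complete and bonded(res, nxt):
            nn = nxt.atom("N")
            if nn is not None:
                psi = dihedral(n.coords, ca.coords, c.coords, nn.coords)
        entries.append((res.id, {"phi": phi, "psi": psi, "omega": omega}))
    return BackboneDihedralSet(entries)


# ---------------------------------------------------------------------------
# superposition


@dataclass
class SuperpositionResult:
    """Optimal proper rigid transform ``x ↦ rotation @ x + translation``."""

    rotation: np.ndarray  # (3, 3), det +1
    translation: np.ndarray  # (3,)
    rmsd: float  # Å after applying the transform


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares superposition of paired point sets (Kabsch).

    Finds the proper rotation + translation minimising the RMSD of
    ``mobile`` onto ``reference``; reflections are never returned.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"paired coordinate lists differ in shape: {mobile.shape} vs {reference.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need at least 3 paired 3-D points")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc)
    R = rot.as_matrix()
    t = rc - R @ mc
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def apply_superposition(coords: np.ndarray, sup: SuperpositionResult) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ sup.rotation.T + sup.translation


def coordinate_rmsd(a: np.ndarray, b: np.ndarray, superpose: bool = True) -> float:
    """RMSD between paired coordinate sets, Kabsch-minimised by default."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if superpose:
        return kabsch_superpose(a, b).rmsd
    if a.shape != b.shape:
        raise ValueError("paired coordinate lists differ in shape")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rotation_angle(R: np.ndarray) -> float:
    """Rotation angle (degrees in [0, 180]) of a proper rotation matrix."""
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _range_ca(
    s: StructureModel, chain: str, first: int, last: int
) -> dict[tuple[str, int, str], np.ndarray]:
    out = {}
    for r in s.residues:
        if r.id.chain_id == chain and first <= r.id.seq_number <= last:
            ca = r.atom("CA")
            if ca is not None:
                out[r.id.key] = ca.coords
    return out


def interdomain_angle(
    struct_a: StructureModel,
    struct_b: StructureModel,
    align_domain: tuple[str, int, int],
    measure_domain: tuple[str, int, int],
    correspondence: Sequence[tuple[ResidueId, ResidueId]] | None = None,
) -> float:
    """Rotation angle between domains after aligning on a reference domain.

    The CA atoms of ``align_domain`` of structure B are superposed onto
    structure A; the Kabsch rotation that then superposes the
    ``measure_domain`` CA atoms is converted to its rotation angle
    θ = arccos((trace R − 1)/2).  For two identical structures θ = 0; a
    rigid rotation of the measured domain by α is recovered as θ = α.

    ``correspondence`` pairs residues of A with residues of B; when omitted
    residues are paired by identical (chain, number, insertion-code).
    Domain ranges are given as ``(chain, first, last)`` on structure A.
    """
    if correspondence is None:
        pairs = [(r.id, r.id) for r in struct_a.residues]
    else:
        pairs = list(correspondence)
    b_for_a = {ra.key: rb for ra, rb in pairs}
    ca_b = {r.id.key: r.atom("CA").coords for r in struct_b.residues if r.atom("CA")}

    def paired(domain: tuple[str, int, int]) -> tuple[np.ndarray, np.ndarray]:
        chain, first, last = domain
        a_coords, b_coords = [], []
        for key, xyz in _range_ca(struct_a, chain, first, last).items():
            rb = b_for_a.get(key)
            if rb is not None and rb.key in ca_b:
                a_coords.append(xyz)
                b_coords.append(ca_b[rb.key])
        if len(a_coords) < 3:
            raise ValueError(
                f"domain {chain}:{first}-{last} has {len(a_coords)} paired CA atoms (<3)"
            )
        return np.array(a_coords), np.array(b_coords)

    ref_a, mob_b = paired(align_domain)
    sup = kabsch_superpose(mob_b, ref_a)
    meas_a, meas_b = paired(measure_domain)
    meas_b_aligned = apply_superposition(meas_b, sup)
    residual = kabsch_superpose(meas_b_aligned, meas_a)
    return rotation_angle(residual.rotation)


# ---------------------------------------------------------------------------
# side-chain contacts


@dataclass
class SidechainContact:
    distance: float  # Å
    atom_1: str
    atom_2: str


def _sidechain_atoms(res: Residue):
    side = [a for a in res.atoms if a.atom_name not in _MAINCHAIN]
    if not side:  # glycine: fall back to CA so the distance stays defined
        ca = res.atom("CA")
        if ca is not None:
            side = [ca]
    return side


def min_sidechain_distance(
    s: StructureModel, r1: ResidueId, r2: ResidueId
) -> SidechainContact:
    """Minimum heavy-atom distance between two side chains.

    Side chain = heavy atoms excluding N, CA, C, O (and OXT); glycine uses
    CA as fallback.  Returns the distance and the attaining atom pair.
    """
    res1 = s.residue(r1)
    res2 = s.residue(r2)
    if res1.id.key == res2.id.key:
        warnings.warn(f"min_sidechain_distance of {r1} with itself is 0", stacklevel=2)
        return SidechainContact(0.0, "", "")
    a1 = _sidechain_atoms(res1)
    a2 = _sidechain_atoms(res2)
    if not a1 or not a2:
        raise ValueError("residue without side-chain atoms (and no CA fallback)")
    best = None
    for x in a1:
        for y in a2:
            d = float(np.linalg.norm(x.coords - y.coords))
            if best is None or d < best.distance:
                best = SidechainContact(d, x.atom_name, y.atom_name)
    return best
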