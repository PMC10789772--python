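"""Synthetic structures with known ground truth.

Every analysis stage in this package can be exercised without external
coordinate files: backbones are built from specified dihedral angles by
sequential internal-to-Cartesian (NeRF) placement, homolog pairs carry
planted senary-class transitions at known residues, trajectories sample a
few well-separated conformers with controlled Cartesian noise, and digest
fixtures place tryptic sites at known positions.

The module's central contract is the dihedral round-trip: measuring φ/ψ/ω
on a built backbone reproduces the specification to well below 1e−6°.
Only dihedrals matter to the analyses under test, so bond lengths and
angles are fixed at standard peptide values (N–CA 1.458 Å, CA–C 1.525 Å,
C–N 1.329 Å; N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°).

All generators are deterministic given a seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from math import cos, radians, sin

import numpy as np

from .backbone_geometry import coordinate_rmsd
from .insilico_proteolysis import ProteinSequence
from .senary_divergence import SenaryClass, cyclic_difference
from .structure_io import AtomRecord, Residue, ResidueId, StructureModel, backbone_atoms
from .trajectory_clustering import Trajectory

__all__ = [
    "BOND_LENGTHS",
    "BOND_ANGLES",
    "BackboneSpec",
    "TrajectorySpec",
    "PlantedDivergence",
    "HomologPairTruth",
    "place_atom",
    "build_backbone",
    "senary_bin_center",
    "make_homolog_pair",
    "make_trajectory",
    "make_digest_fixture",
    "random_rigid_motion",
]

BOND_LENGTHS = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231, "CA-CB": 1.521}
BOND_ANGLES = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.5, "N-CA-CB": 110.4}


@dataclass
class BackboneSpec:
    """Per-residue φ/ψ/ω targets in degrees, all in (−180, 180]."""

    phi: list[float]
    psi: list[float]
    omega: list[float]
    chain_id: str = "A"
    first_number: int = 1
    residue_name: str = "ALA"
    with_oxygen: bool = True
    with_cbeta: bool = True

    def __post_init__(self) -> None:
        n = len(self.phi)
        if not (len(self.psi) == len(self.omega) == n):
            raise ValueError("phi/psi/omega lists must have equal length")
        if n < 2:
            raise ValueError("need at least 2 residues")
        for seq in (self.phi, self.psi, self.omega):
            for a in seq:
                if not (-180.0 < a <= 180.0):
                    raise ValueError(f"angle {a} outside (−180, 180]")

    def __len__(self) -> int:
        return len(self.phi)

    @classmethod
    def uniform(cls, n: int, phi: float, psi: float, omega: float = 180.0, **kw) -> "BackboneSpec":
        return cls(phi=[phi] * n, psi=[psi] * n, omega=[omega] * n, **kw)


def place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement: position D with |CD|=bond, ∠(B,C,D)=angle and
    dihedral(A,B,C,D)=dihedral."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    if angle_deg % 180.0 == 0.0:
        raise ValueError("bond angle of exactly 0/180° gives degenerate geometry")
    theta = radians(angle_deg)
    chi = radians(dihedral_deg)
    d_local = np.array(
        [-bond * cos(theta), bond * sin(theta) * cos(chi), bond * sin(theta) * sin(chi)]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ValueError("collinear reference atoms: placement frame undefined")
    n /= nn
    m = np.cross(n, bc)
    return c + np.column_stack([bc, m, n]) @ d_local


def build_backbone(spec: BackboneSpec) -> StructureModel:
    """Build a poly-peptide backbone from dihedral targets (NeRF).

    Atoms N/CA/C (optionally O and CB) are placed sequentially, each from
    the previous three via the fixed bond length, bond angle and the
    specified dihedral: ψ(i) positions N(i+1), ω(i) positions CA(i) and
    φ(i) positions C(i).  φ(1), ω(1) and ψ(n) do not correspond to a
    measurable backbone dihedral; remeasuring the result reproduces every
    defined target to below 1e−6°.
    """
    n_res = len(spec)
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    # first residue in the xy-plane
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_LENGTHS["N-CA"], 0.0, 0.0)
    th = radians(BOND_ANGLES["N-CA-C"])
    C[0] = CA[0] + BOND_LENGTHS["CA-C"] * np.array([-cos(th), sin(th), 0.0])
    for i in range(1, n_res):
        N[i] = place_atom(
            N[i - 1], CA[i - 1], C[i - 1],
            BOND_LENGTHS["C-N"], BOND_ANGLES["CA-C-N"], spec.psi[i - 1],
        )
        CA[i] = place_atom(
            CA[i - 1], C[i - 1], N[i],
            BOND_LENGTHS["N-CA"], BOND_ANGLES["C-N-CA"], spec.omega[i],
        )
        C[i] = place_atom(
            C[i - 1], N[i], CA[i],
            BOND_LENGTHS["CA-C"], BOND_ANGLES["N-CA-C"], spec.phi[i],
        )
    residues = []
    for i in range(n_res):
        rid = ResidueId(
            chain_id=spec.chain_id,
            seq_number=spec.first_number + i,
            residue_name=spec.residue_name,
        )
        atoms = [
            AtomRecord("N", "N", N[i]),
            AtomRecord("CA", "C", CA[i]),
            AtomRecord("C", "C", C[i]),
        ]
        if spec.with_oxygen:
            # carbonyl O is anti to the following N: dihedral N-CA-C-O = psi + 180
            o = place_atom(
                N[i], CA[i], C[i],
                BOND_LENGTHS["C-O"], BOND_ANGLES["CA-C-O"],
                spec.psi[i] + 180.0,
            )
            atoms.append(AtomRecord("O", "O", o))
        if spec.with_cbeta and spec.residue_name != "GLY":
            cb = place_atom(
                C[i], N[i], CA[i],
                BOND_LENGTHS["CA-CB"], BOND_ANGLES["N-CA-CB"], -122.0,
            )
            atoms.append(AtomRecord("CB", "C", cb))
        residues.append(Residue(id=rid, atoms=atoms))
    return StructureModel(model_index=1, residues=residues)


# ---------------------------------------------------------------------------
# homolog pairs with planted divergences


def senary_bin_center(cls: SenaryClass | int) -> float:
    """Center angle (degrees) of a senary class bin: 0, 60, …, −60."""
    a = (int(cls) * 60.0) % 360.0
    return a - 360.0 if a > 180.0 else a


def random_rigid_motion(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random proper rotation and a translation of ~20 Å scale."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-20.0, 20.0, size=3)
    return R, t


def _transform_model(s: StructureModel, R: np.ndarray, t: np.ndarray) -> StructureModel:
    out = copy.deepcopy(s)
    for res in out.residues:
        for a in res.atoms:
            a.coords = R @ a.coords + t
    return out


@dataclass(frozen=True)
class PlantedDivergence:
    residue: int  # 1-based position along the chain
    kind: str  # "phi" | "psi" | "omega"
    from_class: int
    to_class: int

    @property
    def difference(self) -> int:
        return cyclic_difference(self.from_class, self.to_class)


@dataclass
class HomologPairTruth:
    planted: list[PlantedDivergence]
    expected_flagged: list[tuple[ResidueId, ResidueId]]


def make_homolog_pair(
    n_residues: int,
    planted: list[tuple[int, str, int, int]] | list[PlantedDivergence] = (),
    rigid_motion: bool = True,
    noise_deg: float = 2.0,
    seed: int = 0,
) -> tuple[StructureModel, StructureModel, HomologPairTruth]:
    """A pair of homologous backbones differing only at planted dihedrals.

    Both structures share base angles at senary bin centers (φ=−120,
    ψ=120, ω=180); each planted ``(residue, kind, from_class, to_class)``
    sets that angle to the center of ``from_class`` in structure A and of
    ``to_class`` in structure B.  Independent uniform dihedral noise of
    ±``noise_deg`` (must stay below 5° so no class boundary is crossed)
    and an optional random rigid motion of B are applied.  The returned
    ground truth lists the planted transitions and the residue pairs a
    difference-3 flag scan must recover.
    """
    if not (0.0 <= noise_deg < 5.0):
        raise ValueError("noise_deg must be in [0, 5) to keep angles 5° off bin edges")
    plants = [
        p if isinstance(p, PlantedDivergence) else PlantedDivergence(*p)
        for p in planted
    ]
    for p in plants:
        if not (1 <= p.residue <= n_residues):
            raise ValueError(f"planted residue {p.residue} outside 1..{n_residues}")
        if p.kind not in ("phi", "psi", "omega"):
            raise ValueError(f"unknown angle kind {p.kind!r}")
    rng = np.random.default_rng(seed)
    base = {
        "phi": [-120.0] * n_residues,
        "psi": [120.0] * n_residues,
        "omega": [180.0] * n_residues,
    }
    angles_a = {k: list(v) for k, v in base.items()}
    angles_b = {k: list(v) for k, v in base.items()}
    for p in plants:
        angles_a[p.kind][p.residue - 1] = senary_bin_center(p.from_class)
        angles_b[p.kind][p.residue - 1] = senary_bin_center(p.to_class)
    for angles in (angles_a, angles_b):
        for k in angles:
            noise = rng.uniform(-noise_deg, noise_deg, size=n_residues)
            angles[k] = [
                _wrap(a + dn) for a, dn in zip(angles[k], noise)
            ]
    a = build_backbone(BackboneSpec(**angles_a))
    b = build_backbone(BackboneSpec(**angles_b))
    if rigid_motion:
        R, t = random_rigid_motion(rng)
        b = _transform_model(b, R, t)
    expected = [
        (a.residues[p.residue - 1].id, b.residues[p.residue - 1].id)
        for p in plants
        if p.difference == 3
    ]
    return a, b, HomologPairTruth(planted=plants, expected_flagged=expected)


def _wrap(a: float) -> float:
    a = a % 360.0
    if a > 180.0:
        a -= 360.0
    if a == -180.0:
        a = 180.0
    return a


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class TrajectorySpec:
    """k well-separated conformers, each sampled with Cartesian noise."""

    n_conformers: int = 3
    snapshots_per_conformer: int = 10
    noise_scale: float = 0.3  # Å, isotropic per coordinate
    n_residues: int = 40
    seed: int = 0
    min_separation: float = 4.0  # Å, guaranteed minimum inter-conformer RMSD

    def __post_init__(self) -> None:
        if self.n_conformers < 1 or self.snapshots_per_conformer < 1:
            raise ValueError("need at least one conformer and one snapshot")
        if self.noise_scale < 0:
            raise ValueError("noise must be nonnegative")


def _hinge_conformer(n: int, hinge: int) -> StructureModel:
    """Helix before the hinge residue, extended strand after it."""
    phi = [-57.0] * n
    psi = [-47.0] * n
    for i in range(hinge, n):
        phi[i], psi[i] = -139.0, 135.0
    return build_backbone(
        BackboneSpec(phi=phi, psi=psi, omega=[180.0] * n, with_cbeta=False)
    )


def make_trajectory(spec: TrajectorySpec) -> tuple[Trajectory, list[int]]:
    """Sample a synthetic trajectory around k distinct conformers.

    Conformers are helix/strand hinge variants whose mutual main-chain
    RMSD exceeds ``spec.min_separation`` (checked at construction);
    snapshots are conformer coordinates plus isotropic Gaussian noise,
    ordered in consecutive blocks so that frame grouping stays pure.
    Returns the trajectory and the 0-based conformer label per snapshot.
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_residues, spec.n_conformers
    lo, hi = max(2, n // 5), max(3, 4 * n // 5)
    hinges = np.linspace(lo, hi, k).round().astype(int) if k > 1 else np.array([n // 2])
    if len(set(hinges.tolist())) < k:
        raise ValueError(f"chain of {n} residues too short for {k} distinct conformers")
    conformers = [_hinge_conformer(n, int(h)) for h in hinges]
    for i in range(k):
        for j in range(i + 1, k):
            xi, _ = backbone_atoms(conformers[i])
            xj, _ = backbone_atoms(conformers[j])
            sep = coordinate_rmsd(xi, xj)
            if sep <= spec.min_separation:
                raise ValueError(
                    f"conformers {i},{j} separated by only {sep:.2f} Å; "
                    f"increase n_residues or reduce n_conformers"
                )
    snapshots: list[StructureModel] = []
    labels: list[int] = []
    idx = 1
    for ci, conf in enumerate(conformers):
        for _ in range(spec.snapshots_per_conformer):
            snap = copy.deepcopy(conf)
            snap.model_index = idx
            for res in snap.residues:
                for atom in res.atoms:
                    atom.coords = atom.coords + rng.normal(
                        0.0, spec.noise_scale, size=3
                    ) if spec.noise_scale > 0 else atom.coords
            snapshots.append(snap)
            labels.append(ci)
            idx += 1
    return Trajectory(snapshots=snapshots, time_spacing_ns=1.0), labels


# ---------------------------------------------------------------------------
# digestion fixtures


_NONSITE_AA = "ACDEFGHILMNQSTVWY"  # no K/R (sites) and no P (blocker)


def make_digest_fixture(
    n_residues: int, n_sites: int, seed: int = 0
) -> tuple[ProteinSequence, list[int]]:
    """A protein sequence with tryptic sites planted at known positions.

    K or R residues are placed at ``n_sites`` random internal positions,
    never followed by P (the fixture alphabet contains no proline), and
    the sequence is annotated with three equal-thirds domains
    (N-domain / linker / C-domain).  Returns the sequence and the sorted
    expected cleavage-site list.
    """
    if not (0 <= n_sites < n_residues):
        raise ValueError("need 0 <= n_sites < n_residues")
    rng = np.random.default_rng(seed)
    letters = list(rng.choice(list(_NONSITE_AA), size=n_residues))
    positions = sorted(
        int(p) for p in rng.choice(np.arange(1, n_residues), size=n_sites, replace=False)
    )
    for p in positions:
        letters[p - 1] = str(rng.choice(["K", "R"]))
    third = n_residues // 3
    domains = [
        ("N-domain", 1, third),
        ("linker", third + 1, 2 * third),
        ("C-domain", 2 * third + 1, n_residues),
    ]
    seq = ProteinSequence(
        identifier=f"digest-fixture-{seed}", residues="".join(letters), domains=domains
    )
    return seq, positions
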