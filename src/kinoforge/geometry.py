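"""Geometric kernel: dihedrals, Cα pseudotorsions, distances, χ angles,
Kabsch superposition and backbone RMSD.

All angles cross the interface in degrees, range (−180°, 180°], with the
IUPAC sign convention (cis = 0°, trans = ±180°).  Distances are in Å.
Operations taking a numbered domain accept any object exposing
``residue_by_ref(reference_id) -> Residue | None``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, MissingAtomError

__all__ = [
    "dihedral",
    "ca_pseudotorsion",
    "backbone_psi",
    "backbone_phi",
    "ca_distance",
    "min_atom_distance",
    "sidechain_chi",
    "CHI_ATOMS",
    "RigidTransform",
    "SuperpositionResult",
    "superpose",
    "backbone_rmsd",
    "backbone_rmsd_report",
    "wrap_angle",
]

_DEGENERACY_TOL = 1e-10

#: Standard χ-angle atom quadruples per residue type (χ1 … as applicable).
CHI_ATOMS = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}


def wrap_angle(deg: float) -> float:
    """Map an angle in degrees to (−180, 180]."""
    a = (float(deg) + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle of four points, degrees in (−180, 180].

    Invariant under rigid motion; negated by mirror reflection; equal to the
    reversed-order dihedral.
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 < _DEGENERACY_TOL:
        raise DegenerateGeometryError("dihedral: central axis has zero length")
    if np.linalg.norm(n1) < _DEGENERACY_TOL or np.linalg.norm(n2) < _DEGENERACY_TOL:
        raise DegenerateGeometryError("dihedral: collinear points, angle undefined")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / nb2
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def _need_atom(domain, ref_id: int, name: str) -> np.ndarray:
    res = domain.residue_by_ref(ref_id)
    if res is None:
        raise MissingAtomError(f"missing residue at reference {ref_id}")
    coord = res.coord(name)
    if coord is None:
        raise MissingAtomError(f"missing {name} at reference {ref_id}")
    return coord


def ca_pseudotorsion(domain, start_id: int) -> float:
    """Dihedral over the Cα atoms of four consecutive reference positions
    ``start_id … start_id+3``."""
    pts = [_need_atom(domain, start_id + k, "CA") for k in range(4)]
    return dihedral(*pts)


def backbone_psi(domain, ref_id: int) -> float:
    """Standard ψ: N(i), CA(i), C(i), N(i+1)."""
    return dihedral(_need_atom(domain, ref_id, "N"),
                    _need_atom(domain, ref_id, "CA"),
                    _need_atom(domain, ref_id, "C"),
                    _need_atom(domain, ref_id + 1, "N"))


def backbone_phi(domain, ref_id: int) -> float:
    """Standard φ: C(i−1), N(i), CA(i), C(i)."""
    return dihedral(_need_atom(domain, ref_id - 1, "C"),
                    _need_atom(domain, ref_id, "N"),
                    _need_atom(domain, ref_id, "CA"),
                    _need_atom(domain, ref_id, "C"))


def ca_distance(domain, id_a: int, id_b: int) -> float:
    """Euclidean Cα–Cα distance between two reference positions."""
    return float(np.linalg.norm(_need_atom(domain, id_a, "CA")
                                - _need_atom(domain, id_b, "CA")))


def min_atom_distance(domain, id_a: int, atoms_a, id_b, atoms_b) -> float:
    """Minimum distance over the cross product of two named-atom sets."""
    res_a = domain.residue_by_ref(id_a)
    res_b = domain.residue_by_ref(id_b)
    coords_a = [] if res_a is None else [res_a.coord(n) for n in atoms_a]
    coords_b = [] if res_b is None else [res_b.coord(n) for n in atoms_b]
    coords_a = [c for c in coords_a if c is not None]
    coords_b = [c for c in coords_b if c is not None]
    if not coords_a:
        raise MissingAtomError(
            f"no atom of {sorted(atoms_a)} present at reference {id_a}")
    if not coords_b:
        raise MissingAtomError(
            f"no atom of {sorted(atoms_b)} present at reference {id_b}")
    a = np.asarray(coords_a)
    b = np.asarray(coords_b)
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return float(d.min())


def sidechain_chi(residue, chi_index: int = 1) -> float:
    """Standard side-chain χ angle (1-based index) of a residue."""
    quads = CHI_ATOMS.get(residue.name)
    if not quads:
        raise MissingAtomError(f"{residue.name} has no sidechain chi")
    if not 1 <= chi_index <= len(quads):
        raise MissingAtomError(
            f"{residue.name} has no chi{chi_index} (max chi{len(quads)})")
    pts = []
    for name in quads[chi_index - 1]:
        c = residue.coord(name)
        if c is None:
            raise MissingAtomError(
                f"missing {name} for chi{chi_index} of {residue.name} {residue.author_id}")
        pts.append(c)
    return dihedral(*pts)


@dataclass
class RigidTransform:
    """Proper rotation plus translation, applied as ``R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float)
        self.translation = np.asarray(self.translation, float)
        rtr = self.rotation.T @ self.rotation
        if not np.allclose(rtr, np.eye(3), atol=1e-8):
            raise DegenerateGeometryError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise DegenerateGeometryError("rotation is improper (det < 0)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_atoms: int
    selection: str = ""


def superpose(mobile: np.ndarray, reference: np.ndarray,
              selection: str = "") -> SuperpositionResult:
    """Least-squares optimal rigid superposition (Kabsch, SVD form).

    Finds the proper rotation ``R`` and translation ``t`` minimising
    ``|R·mobile + t − reference|``; a reflection is never returned even for
    mirror-image inputs.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise DegenerateGeometryError("superpose: paired (n,3) coordinate sets required")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError("superpose: at least 3 atom pairs required")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    x = mobile - cm
    y = reference - cr
    # collinearity check: need rank >= 2 to pin the rotation down
    if np.linalg.matrix_rank(x, tol=1e-8) < 2 or np.linalg.matrix_rank(y, tol=1e-8) < 2:
        raise DegenerateGeometryError("superpose: degenerate (collinear) coordinates")
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = cr - rot @ cm
    transform = RigidTransform(rot, t)
    moved = transform.apply(mobile)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=-1))))
    return SuperpositionResult(transform, rmsd, n, selection)


_BACKBONE = ("N", "CA", "C", "O")


@dataclass
class RmsdReport:
    rmsd: float
    used_ids: list
    dropped_ids: list
    n_atoms: int


def backbone_rmsd_report(domain_a, domain_b, id_set=None, fit: bool = True) -> RmsdReport:
    """Backbone (N, CA, C, O) RMSD over common reference IDs.

    IDs missing a complete backbone on either side are dropped and listed in
    the report.  With ``fit=True`` the selection is superposed first.
    """
    if id_set is None:
        id_set = sorted(set(domain_a.reference_ids()) & set(domain_b.reference_ids()))
    used, dropped = [], []
    ca_list, cb_list = [], []
    for rid in id_set:
        ra = domain_a.residue_by_ref(rid)
        rb = domain_b.residue_by_ref(rid)
        coords_a = None if ra is None else [ra.coord(n) for n in _BACKBONE]
        coords_b = None if rb is None else [rb.coord(n) for n in _BACKBONE]
        if coords_a is None or coords_b is None \
                or any(c is None for c in coords_a) or any(c is None for c in coords_b):
            dropped.append(rid)
            continue
        used.append(rid)
        ca_list.extend(coords_a)
        cb_list.extend(coords_b)
    if not used:
        raise DegenerateGeometryError("backbone_rmsd: empty common selection")
    a = np.asarray(ca_list)
    b = np.asarray(cb_list)
    if fit:
        rmsd = superpose(a, b).rmsd
    else:
        rmsd = float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))
    return RmsdReport(rmsd, used, dropped, len(used) * len(_BACKBONE))


def backbone_rmsd(domain_a, domain_b, id_set=None, fit: bool = True) -> float:
    return backbone_rmsd_report(domain_a, domain_b, id_set, fit).rmsd
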