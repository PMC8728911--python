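"""Backbone reconstruction from phi/psi torsions and RMSD scoring.

A chain is grown residue by residue from a 20-entry residue library.  Each
template stores local-frame coordinates for N, CA, C (and CB except glycine).
Atoms are placed sequentially by internal coordinates (NeRF): each new atom is
positioned from the bond length, bond angle and torsion relative to the three
previously placed atoms.  The peptide geometry is fixed: omega = 180 degrees
and a C-N peptide-bond length of 1.33 A; phi and psi are the free torsions.
The structure is scored against a reference by optimal rigid-body
superposition RMSD (rotation + translation, no reflection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import BackboneChain, read_pdb

__all__ = [
    "ResidueTemplate",
    "ResidueLibrary",
    "default_library",
    "library_from_pdb",
    "place_atom",
    "build_backbone",
    "superpose_rmsd",
    "PEPTIDE_C_N_LENGTH",
    "OMEGA_TRANS",
]

#: peptide-bond length between C of residue i-1 and N of residue i (Angstrom)
PEPTIDE_C_N_LENGTH = 1.33
#: trans peptide torsion CA_{i-1}-C_{i-1}-N_i-CA_i (degrees)
OMEGA_TRANS = 180.0

# canonical inter-residue junction bond angles (degrees)
ANGLE_CA_C_N = 116.2   # CA_{i-1} - C_{i-1} - N_i
ANGLE_C_N_CA = 121.7   # C_{i-1} - N_i - CA_i

# canonical intra-residue geometry used for the idealized default templates
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_CA_CB = 1.530
ANGLE_N_CA_C = 111.2
ANGLE_N_CA_CB = 110.5
# improper torsion N-C-CA-CB placing CB below the backbone plane (L-amino acids)
TORSION_N_C_CA_CB = -122.6

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ResidueTemplate:
    """One amino acid's local-frame coordinates for N, CA, C (and CB)."""

    letter: str
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    cb: np.ndarray | None

    @property
    def bond_n_ca(self) -> float:
        return float(np.linalg.norm(self.n - self.ca))

    @property
    def bond_ca_c(self) -> float:
        return float(np.linalg.norm(self.c - self.ca))

    @property
    def angle_n_ca_c(self) -> float:
        u = self.n - self.ca
        v = self.c - self.ca
        c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return float(np.degrees(np.arccos(np.clip(c, -1, 1))))


class ResidueLibrary(dict):
    """Map amino-acid letter -> ResidueTemplate; must cover all 20 standards."""

    def __init__(self, templates: dict[str, ResidueTemplate]):
        missing = set(AA20) - set(templates)
        if missing:
            raise ValueError(f"library missing templates for {sorted(missing)}")
        super().__init__(templates)


def _local_frame_template(letter: str) -> ResidueTemplate:
    # local frame: CA at origin, C on +x, N in the xy-plane (y > 0)
    ca = np.zeros(3)
    c = np.array([BOND_CA_C, 0.0, 0.0])
    ang = np.radians(ANGLE_N_CA_C)
    n = BOND_N_CA * np.array([np.cos(ang), np.sin(ang), 0.0])
    cb = None
    if letter != "G":
        cb = place_atom(n, c, ca, BOND_CA_CB, ANGLE_N_CA_CB, TORSION_N_C_CA_CB)
    return ResidueTemplate(letter, n, ca, c, cb)


def default_library() -> ResidueLibrary:
    """Idealized residue library with canonical bond lengths and angles.

    Every template shares the canonical backbone geometry; CB is placed
    tetrahedrally (absent for glycine).
    """
    return ResidueLibrary({aa: _local_frame_template(aa) for aa in AA20})


def library_from_pdb(path, chain_id: str | None = None) -> ResidueLibrary:
    """Build a residue library from a user-supplied structure.

    Takes the first occurrence of each amino acid with complete N/CA/C and
    re-centres it into the local frame; falls back to the idealized template
    for amino acids absent from the structure.
    """
    chain = read_pdb(path, chain_id)
    templates: dict[str, ResidueTemplate] = {}
    for i, aa in enumerate(chain.sequence):
        if aa in templates or aa not in AA20:
            continue
        n, ca, c = chain.atom(i, "N"), chain.atom(i, "CA"), chain.atom(i, "C")
        if n is None or ca is None or c is None:
            continue
        cb = chain.atom(i, "CB")
        templates[aa] = _reframe(aa, n, ca, c, cb)
    for aa in AA20:
        templates.setdefault(aa, _local_frame_template(aa))
    return ResidueLibrary(templates)


def _reframe(aa, n, ca, c, cb):
    ex = (c - ca) / np.linalg.norm(c - ca)
    v = n - ca
    ey = v - np.dot(v, ex) * ex
    ey = ey / np.linalg.norm(ey)
    ez = np.cross(ex, ey)
    R = np.stack([ex, ey, ez])
    tr = lambda p: R @ (p - ca)
    return ResidueTemplate(aa, tr(n), np.zeros(3), tr(c), tr(cb) if cb is not None else None)


def place_atom(a, b, c, bond_length, bond_angle_deg, torsion_deg) -> np.ndarray:
    """Position atom d given the three previous atoms a-b-c (NeRF step).

    d satisfies |c-d| = bond_length, angle(b, c, d) = bond_angle_deg and
    dihedral(a, b, c, d) = torsion_deg.
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:
        raise ValueError("collinear support atoms in NeRF placement")
    n = n / norm
    m = np.cross(n, bc)
    theta = np.radians(bond_angle_deg)
    chi = np.radians(torsion_deg)
    d_local = bond_length * (
        -np.cos(theta) * bc + np.sin(theta) * np.cos(chi) * m + np.sin(theta) * np.sin(chi) * n
    )
    return c + d_local


def build_backbone(
    sequence: str,
    phi: np.ndarray,
    psi: np.ndarray,
    library: ResidueLibrary | None = None,
    omega: float = OMEGA_TRANS,
    c_n_length: float = PEPTIDE_C_N_LENGTH,
) -> BackboneChain:
    """Grow a backbone from per-residue phi/psi (degrees).

    phi[0] and psi[-1] may be NaN (those torsions do not exist); all other
    entries must be finite.  Residue 1 is placed in the canonical frame
    (CA at the origin, C along +x, N in the xy-plane).
    """
    library = library or default_library()
    phi = np.asarray(phi, float)
    psi = np.asarray(psi, float)
    L = len(sequence)
    if len(phi) != L or len(psi) != L:
        raise ValueError("phi/psi length must equal sequence length")
    unknown = set(sequence) - set(AA20)
    if unknown:
        raise ValueError(f"unknown amino-acid letters {sorted(unknown)}")
    if L == 0:
        raise ValueError("empty sequence")
    if not np.all(np.isfinite(phi[1:])):
        raise ValueError("phi undefined at an interior residue")
    if not np.all(np.isfinite(psi[:-1])):
        raise ValueError("psi undefined at an interior residue")

    coords = {k: np.full((L, 3), np.nan) for k in ("N", "CA", "C", "CB")}
    t0 = library[sequence[0]]
    coords["N"][0] = t0.n
    coords["CA"][0] = t0.ca
    coords["C"][0] = t0.c
    if t0.cb is not None:
        coords["CB"][0] = t0.cb

    for i in range(1, L):
        t = library[sequence[i]]
        n_prev, ca_prev, c_prev = coords["N"][i - 1], coords["CA"][i - 1], coords["C"][i - 1]
        n_i = place_atom(n_prev, ca_prev, c_prev, c_n_length, ANGLE_CA_C_N, psi[i - 1])
        ca_i = place_atom(ca_prev, c_prev, n_i, t.bond_n_ca, ANGLE_C_N_CA, omega)
        c_i = place_atom(c_prev, n_i, ca_i, t.bond_ca_c, t.angle_n_ca_c, phi[i])
        coords["N"][i] = n_i
        coords["CA"][i] = ca_i
        coords["C"][i] = c_i
        if t.cb is not None:
            coords["CB"][i] = _superposed_cb(t, n_i, ca_i, c_i)
    return BackboneChain(sequence, coords)


def _superposed_cb(t: ResidueTemplate, n, ca, c) -> np.ndarray:
    """Carry the template's CB along the rigid motion mapping its backbone onto
    the placed backbone atoms (exact when the intra-residue geometry matches)."""
    src = np.stack([t.n, t.ca, t.c])
    dst = np.stack([n, ca, c])
    R, tvec = _kabsch(src, dst)
    return R @ t.cb + tvec


def _kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation+translation mapping src onto dst (least squares, no reflection)."""
    sc = src.mean(axis=0)
    dc = dst.mean(axis=0)
    H = (src - sc).T @ (dst - dc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = dc - R @ sc
    return R, t


def superpose_rmsd(a: BackboneChain, b: BackboneChain, atoms: str = "ca") -> float:
    """Least-squares superposition RMSD (Angstrom) between two chains.

    ``atoms`` selects "ca" (default) or "backbone" (N, CA, C).  Only residues
    with all selected atoms present in both chains contribute.
    """
    if len(a) != len(b):
        raise ValueError(f"chain length mismatch: {len(a)} vs {len(b)}")
    names = ("CA",) if atoms == "ca" else ("N", "CA", "C")
    pa, pb = [], []
    for i in range(len(a)):
        pts_a = [a.atom(i, nm) for nm in names]
        pts_b = [b.atom(i, nm) for nm in names]
        if any(p is None for p in pts_a + pts_b):
            continue
        pa.extend(pts_a)
        pb.extend(pts_b)
    if not pa:
        raise ValueError("no common atoms for superposition")
    A = np.array(pa)
    B = np.array(pb)
    R, t = _kabsch(A, B)
    diff = A @ R.T + t - B
    return float(np.sqrt((diff**2).sum() / len(A)))
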