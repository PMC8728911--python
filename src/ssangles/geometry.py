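"""Backbone geometry: torsion/planar angle extraction and periodic-angle arithmetic.

Angle conventions
-----------------
All angles are in degrees.  Dihedrals follow the IUPAC sign convention:
looking down the p2->p3 axis, a clockwise rotation of p4 relative to p1 is
positive.  Periodic angles live on the half-open interval (-180, 180]; the
planar angle theta lives on [0, 180].

Per-residue backbone angles of a chain of length L:

* phi_i   = dihedral(C_{i-1}, N_i, CA_i, C_i)        defined for i >= 2
* psi_i   = dihedral(N_i, CA_i, C_i, N_{i+1})        defined for i <= L-1
* theta_i = planar(CA_{i-1}, CA_i, CA_{i+1})         defined for 2 <= i <= L-1
* tau_i   = dihedral(CA_{i-1}, CA_i, CA_{i+1}, CA_{i+2})  for 2 <= i <= L-2

Undefined entries (termini, or residues with missing atoms) are stored as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DegenerateGeometryError",
    "BackboneChain",
    "AngleTable",
    "wrap_angle",
    "dihedral",
    "planar_angle",
    "compute_backbone_angles",
    "read_pdb",
    "write_pdb",
]

#: cross-product norm (A^2) below which three points are treated as collinear
COLLINEARITY_TOL = 1e-10

BACKBONE_ATOMS = ("N", "CA", "C")

ANGLE_NAMES = ("phi", "psi", "theta", "tau")


class DegenerateGeometryError(ValueError):
    """Raised when points are coincident or collinear where an angle needs a plane."""


def wrap_angle(x):
    """Wrap angle(s) in degrees onto the half-open interval (-180, 180].

    Any value above 180 has 360 subtracted; any value of -180 or below has
    360 added, so the map is a function (180 is kept, -180 maps to +180).
    NaN passes through (undefined stays undefined).
    """
    x = np.asarray(x, dtype=float)
    r = np.mod(x, 360.0)          # [0, 360)
    r = np.where(r > 180.0, r - 360.0, r)
    # np.mod maps exact -180 to +180 already; 0 and 180 are fixed points
    if r.ndim == 0:
        return float(r)
    return r


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("point has non-finite components")
    return a


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (degrees) of the planes (p1,p2,p3) and (p2,p3,p4).

    IUPAC sign: viewed along p2->p3, clockwise rotation of p4 relative to p1
    is positive.  Result lies in (-180, 180].

    Raises
    ------
    DegenerateGeometryError
        if either point triple is (near-)collinear or points coincide.
    """
    p1, p2, p3, p4 = (_as_point(p) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.dot(n1, n1) < COLLINEARITY_TOL**2 or np.dot(n2, n2) < COLLINEARITY_TOL**2:
        raise DegenerateGeometryError("collinear or coincident points: dihedral plane undefined")
    b2n = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2n))
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def planar_angle(p1, p2, p3) -> float:
    """Interior angle at p2 (degrees), in [0, 180]."""
    p1, p2, p3 = (_as_point(p) for p in (p1, p2, p3))
    u = p1 - p2
    v = p3 - p2
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < 1e-10 or nv < 1e-10:
        raise DegenerateGeometryError("coincident points: planar angle undefined")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


@dataclass
class BackboneChain:
    """Per-residue backbone coordinates (N, CA, C, optional CB) plus sequence.

    ``coords`` maps atom name -> (L, 3) float array; missing atoms are NaN rows.
    """

    sequence: str
    coords: dict[str, np.ndarray]
    chain_id: str = "A"

    def __post_init__(self) -> None:
        L = len(self.sequence)
        for name, arr in self.coords.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (L, 3):
                raise ValueError(
                    f"coords[{name!r}] has shape {arr.shape}, expected ({L}, 3)"
                )
            self.coords[name] = arr
        for name in BACKBONE_ATOMS:
            if name not in self.coords:
                raise ValueError(f"backbone atom {name!r} missing from chain")

    def __len__(self) -> int:
        return len(self.sequence)

    def atom(self, i: int, name: str) -> np.ndarray | None:
        """Coordinates of atom `name` of residue i (0-based), or None if absent."""
        arr = self.coords.get(name)
        if arr is None:
            return None
        p = arr[i]
        if not np.all(np.isfinite(p)):
            return None
        return p

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BackboneChain":
        """Chain with every coordinate mapped x -> R x + t (rigid motion)."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        new = {k: v @ R.T + t for k, v in self.coords.items()}
        return BackboneChain(self.sequence, new, self.chain_id)


@dataclass
class AngleTable:
    """Per-residue phi/psi/theta/tau in degrees; NaN marks an undefined angle."""

    phi: np.ndarray
    psi: np.ndarray
    theta: np.ndarray
    tau: np.ndarray
    sequence: str = ""
    protein_id: str = ""

    def __post_init__(self) -> None:
        L = len(self.phi)
        for name in ANGLE_NAMES:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (L,):
                raise ValueError(f"angle column {name} has wrong length")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.phi)

    def angle(self, name: str) -> np.ndarray:
        if name not in ANGLE_NAMES:
            raise KeyError(f"unknown angle {name!r}; expected one of {ANGLE_NAMES}")
        return getattr(self, name)

    def defined(self, name: str) -> np.ndarray:
        """Boolean mask of residues where the named angle is defined."""
        return np.isfinite(self.angle(name))

    def to_frame(self) -> pd.DataFrame:
        L = len(self)
        return pd.DataFrame(
            {
                "residue_index": np.arange(1, L + 1),
                "aa": list(self.sequence) if self.sequence else ["X"] * L,
                "phi": self.phi,
                "psi": self.psi,
                "theta": self.theta,
                "tau": self.tau,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6f")

    @classmethod
    def from_tsv(cls, path, protein_id: str = "") -> "AngleTable":
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        return cls(
            phi=df["phi"].to_numpy(float),
            psi=df["psi"].to_numpy(float),
            theta=df["theta"].to_numpy(float),
            tau=df["tau"].to_numpy(float),
            sequence="".join(df["aa"].astype(str)),
            protein_id=protein_id,
        )

    @classmethod
    def concatenate(cls, tables: list["AngleTable"]) -> "AngleTable":
        """Stack tables row-wise (used to align targets with a feature matrix)."""
        return cls(
            phi=np.concatenate([t.phi for t in tables]),
            psi=np.concatenate([t.psi for t in tables]),
            theta=np.concatenate([t.theta for t in tables]),
            tau=np.concatenate([t.tau for t in tables]),
            sequence="".join(t.sequence for t in tables),
        )

    def take(self, idx: np.ndarray) -> "AngleTable":
        seq = "".join(self.sequence[i] for i in idx) if self.sequence else ""
        return AngleTable(
            self.phi[idx], self.psi[idx], self.theta[idx], self.tau[idx], seq, self.protein_id
        )


def _safe_dihedral(*pts) -> float:
    if any(p is None for p in pts):
        return np.nan
    try:
        return dihedral(*pts)
    except DegenerateGeometryError:
        return np.nan


def _safe_planar(*pts) -> float:
    if any(p is None for p in pts):
        return np.nan
    try:
        return planar_angle(*pts)
    except DegenerateGeometryError:
        return np.nan


def compute_backbone_angles(chain: BackboneChain) -> AngleTable:
    """Extract phi/psi/theta/tau for every residue of a chain.

    Residues whose supporting atoms are missing get NaN for the affected
    angles rather than aborting, so chains with gaps still yield a table.
    """
    L = len(chain)
    if L == 0:
        raise ValueError("cannot compute angles of an empty chain")
    phi = np.full(L, np.nan)
    psi = np.full(L, np.nan)
    theta = np.full(L, np.nan)
    tau = np.full(L, np.nan)
    for i in range(L):
        N_i = chain.atom(i, "N")
        CA_i = chain.atom(i, "CA")
        C_i = chain.atom(i, "C")
        if i >= 1:
            phi[i] = _safe_dihedral(chain.atom(i - 1, "C"), N_i, CA_i, C_i)
        if i <= L - 2:
            psi[i] = _safe_dihedral(N_i, CA_i, C_i, chain.atom(i + 1, "N"))
        if 1 <= i <= L - 2:
            theta[i] = _safe_planar(chain.atom(i - 1, "CA"), CA_i, chain.atom(i + 1, "CA"))
        if 1 <= i <= L - 3:
            tau[i] = _safe_dihedral(
                chain.atom(i - 1, "CA"), CA_i, chain.atom(i + 1, "CA"), chain.atom(i + 2, "CA")
            )
    return AngleTable(phi, psi, theta, tau, chain.sequence)


# ---------------------------------------------------------------------------
# PDB input / output (via biotite)
# ---------------------------------------------------------------------------

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


def read_pdb(path, chain_id: str | None = None) -> BackboneChain:
    """Read the backbone of one chain from a PDB file.

    First model only; first alternate location.  If ``chain_id`` is None the
    first chain in the file is used.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, altloc="first")
    atoms = atoms[struc.filter_amino_acids(atoms)]
    if atoms.array_length() == 0:
        raise ValueError(f"no amino-acid atoms in {path}")
    if chain_id is None:
        chain_id = str(atoms.chain_id[0])
    atoms = atoms[atoms.chain_id == chain_id]
    if atoms.array_length() == 0:
        raise ValueError(f"chain {chain_id!r} not found in {path}")

    starts = struc.get_residue_starts(atoms)
    L = len(starts)
    seq = []
    coords = {name: np.full((L, 3), np.nan) for name in ("N", "CA", "C", "CB")}
    bounds = list(starts) + [atoms.array_length()]
    for r, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
        res_name = str(atoms.res_name[lo])
        seq.append(_THREE_TO_ONE.get(res_name, "X"))
        for k in range(lo, hi):
            name = str(atoms.atom_name[k])
            if name in coords and np.isnan(coords[name][r]).all():
                coords[name][r] = atoms.coord[k]
    return BackboneChain("".join(seq), coords, chain_id)


def write_pdb(chain: BackboneChain, path) -> None:
    """Write a backbone chain as ATOM records (N, CA, C, CB where present)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    records = []
    for i, aa in enumerate(chain.sequence):
        for name, element in (("N", "N"), ("CA", "C"), ("C", "C"), ("CB", "C")):
            p = chain.atom(i, name)
            if p is None:
                continue
            atom = struc.Atom(
                p,
                chain_id=chain.chain_id,
                res_id=i + 1,
                res_name=_ONE_TO_THREE.get(aa, "UNK"),
                atom_name=name,
                element=element,
                hetero=False,
            )
            records.append(atom)
    arr = struc.array(records)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))
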