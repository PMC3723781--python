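"""Torsion-space backbone models built with ideal covalent geometry.

A conformation is a poly-peptide backbone described by per-residue
(phi, psi, omega) dihedral angles.  Cartesian N/CA/C coordinates are derived
from the torsions by sequential natural-extension (NeRF-style) chain building
with fixed bond lengths and angles, so torsions are the only degrees of
freedom.  The module also provides fragment insertion with provenance
tracking, optimal-superposition CA RMSD, and a minimal backbone PDB
reader/writer.

Conventions
-----------
* Residue indices are 1-based in every public interface.
* Torsions are degrees in the half-open range (-180, +180]; -180 is
  canonicalized to +180.
* phi(1), psi(n) and omega(n) have no flanking atoms and therefore do not
  influence the geometry; they are stored verbatim and reported as NaN by
  :func:`measure_torsions`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "IdealGeometry",
    "IDEAL_GEOMETRY",
    "Conformation",
    "canonicalize_torsion",
    "extended_conformation",
    "build_coords",
    "measure_torsions",
    "insert_fragment",
    "ca_rmsd",
    "backbone_rmsd",
    "write_pdb",
    "read_pdb",
    "rebuild_deviation",
]

VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")

# Extended-state torsions used as the common starting point of every model.
EXTENDED_PHI = -150.0
EXTENDED_PSI = 150.0
EXTENDED_OMEGA = 180.0


@dataclass(frozen=True)
class IdealGeometry:
    """Fixed bond lengths (A) and bond angles (degrees) of the backbone.

    Engh--Huber-like constants; held constant for a run so that torsions are
    the only degrees of freedom.
    """

    bond_n_ca: float = 1.458
    bond_ca_c: float = 1.525
    bond_c_n: float = 1.329
    angle_n_ca_c: float = 111.2
    angle_ca_c_n: float = 116.2
    angle_c_n_ca: float = 121.7

    def __post_init__(self) -> None:
        for name in (
            "bond_n_ca",
            "bond_ca_c",
            "bond_c_n",
            "angle_n_ca_c",
            "angle_ca_c_n",
            "angle_c_n_ca",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"IdealGeometry.{name} must be positive")


IDEAL_GEOMETRY = IdealGeometry()


def canonicalize_torsion(value: float) -> float:
    """Wrap a torsion in degrees to the canonical range (-180, +180]."""
    t = (float(value) + 180.0) % 360.0 - 180.0
    if t <= -180.0:
        t = 180.0
    return t


def canonicalize_torsions(arr: np.ndarray) -> np.ndarray:
    """Vectorized :func:`canonicalize_torsion`."""
    t = (np.asarray(arr, dtype=float) + 180.0) % 360.0 - 180.0
    t[t <= -180.0] = 180.0
    return t


# ---------------------------------------------------------------------------
# Chain building (internal -> Cartesian)
# ---------------------------------------------------------------------------


def _build_chain(tr, coords, start, b_nca, b_cac, b_cn,
                 ang_ncac, ang_cacn, ang_cnca):  # pragma: no cover - thin kernel
    """Sequential NeRF placement of residues ``start``..n-1 (radians in)."""
    n = tr.shape[0]
    nx, ny, nz = coords[start - 1, 0, 0], coords[start - 1, 0, 1], coords[start - 1, 0, 2]
    cax, cay, caz = coords[start - 1, 1, 0], coords[start - 1, 1, 1], coords[start - 1, 1, 2]
    cx, cy, cz = coords[start - 1, 2, 0], coords[start - 1, 2, 1], coords[start - 1, 2, 2]
    for i in range(start, n):
        phi = tr[i, 0]
        psi = tr[i - 1, 1]
        omega = tr[i - 1, 2]

        # N(i) from (N(i-1), CA(i-1), C(i-1)); dihedral = psi(i-1)
        ux, uy, uz = cx - cax, cy - cay, cz - caz
        inv = 1.0 / math.sqrt(ux * ux + uy * uy + uz * uz)
        ux, uy, uz = ux * inv, uy * inv, uz * inv
        vx, vy, vz = cax - nx, cay - ny, caz - nz
        wx = vy * uz - vz * uy
        wy = vz * ux - vx * uz
        wz = vx * uy - vy * ux
        inv = 1.0 / math.sqrt(wx * wx + wy * wy + wz * wz)
        wx, wy, wz = wx * inv, wy * inv, wz * inv
        mx = wy * uz - wz * uy
        my = wz * ux - wx * uz
        mz = wx * uy - wy * ux
        d0 = -b_cn * math.cos(ang_cacn)
        d1 = b_cn * math.sin(ang_cacn) * math.cos(psi)
        d2 = -b_cn * math.sin(ang_cacn) * math.sin(psi)
        nnx = cx + d0 * ux + d1 * mx + d2 * wx
        nny = cy + d0 * uy + d1 * my + d2 * wy
        nnz = cz + d0 * uz + d1 * mz + d2 * wz

        # CA(i) from (CA(i-1), C(i-1), N(i)); dihedral = omega(i-1)
        ux, uy, uz = nnx - cx, nny - cy, nnz - cz
        inv = 1.0 / math.sqrt(ux * ux + uy * uy + uz * uz)
        ux, uy, uz = ux * inv, uy * inv, uz * inv
        vx, vy, vz = cx - cax, cy - cay, cz - caz
        wx = vy * uz - vz * uy
        wy = vz * ux - vx * uz
        wz = vx * uy - vy * ux
        inv = 1.0 / math.sqrt(wx * wx + wy * wy + wz * wz)
        wx, wy, wz = wx * inv, wy * inv, wz * inv
        mx = wy * uz - wz * uy
        my = wz * ux - wx * uz
        mz = wx * uy - wy * ux
        d0 = -b_nca * math.cos(ang_cnca)
        d1 = b_nca * math.sin(ang_cnca) * math.cos(omega)
        d2 = -b_nca * math.sin(ang_cnca) * math.sin(omega)
        ncax = nnx + d0 * ux + d1 * mx + d2 * wx
        ncay = nny + d0 * uy + d1 * my + d2 * wy
        ncaz = nnz + d0 * uz + d1 * mz + d2 * wz

        # C(i) from (C(i-1), N(i), CA(i)); dihedral = phi(i)
        ux, uy, uz = ncax - nnx, ncay - nny, ncaz - nnz
        inv = 1.0 / math.sqrt(ux * ux + uy * uy + uz * uz)
        ux, uy, uz = ux * inv, uy * inv, uz * inv
        vx, vy, vz = nnx - cx, nny - cy, nnz - cz
        wx = vy * uz - vz * uy
        wy = vz * ux - vx * uz
        wz = vx * uy - vy * ux
        inv = 1.0 / math.sqrt(wx * wx + wy * wy + wz * wz)
        wx, wy, wz = wx * inv, wy * inv, wz * inv
        mx = wy * uz - wz * uy
        my = wz * ux - wx * uz
        mz = wx * uy - wy * ux
        d0 = -b_cac * math.cos(ang_ncac)
        d1 = b_cac * math.sin(ang_ncac) * math.cos(phi)
        d2 = -b_cac * math.sin(ang_ncac) * math.sin(phi)
        ncx = ncax + d0 * ux + d1 * mx + d2 * wx
        ncy = ncay + d0 * uy + d1 * my + d2 * wy
        ncz = ncaz + d0 * uz + d1 * mz + d2 * wz

        coords[i, 0, 0], coords[i, 0, 1], coords[i, 0, 2] = nnx, nny, nnz
        coords[i, 1, 0], coords[i, 1, 1], coords[i, 1, 2] = ncax, ncay, ncaz
        coords[i, 2, 0], coords[i, 2, 1], coords[i, 2, 2] = ncx, ncy, ncz
        nx, ny, nz = nnx, nny, nnz
        cax, cay, caz = ncax, ncay, ncaz
        cx, cy, cz = ncx, ncy, ncz


try:  # JIT the placement kernel when numba is available (it is a listed
    # dependency); the plain-Python loop is the same code and stays usable.
    from numba import njit as _njit

    _build_chain = _njit(cache=True)(_build_chain)
except ImportError:  # pragma: no cover
    pass


def build_coords(
    torsions: np.ndarray,
    geometry: IdealGeometry = IDEAL_GEOMETRY,
    coords: np.ndarray | None = None,
    start: int = 0,
) -> np.ndarray:
    """Build backbone N/CA/C coordinates from (phi, psi, omega) torsions.

    The first residue is placed in a fixed canonical frame (N at the origin,
    CA on +x, C in the xy plane), which makes the construction deterministic.
    Each subsequent atom is placed from the three preceding backbone atoms
    using its ideal bond length, bond angle, and the connecting dihedral.

    Parameters
    ----------
    torsions:
        Array of shape (n, 3) with per-residue (phi, psi, omega) in degrees.
    coords:
        Optional preallocated (n, 3, 3) array.  When ``start > 0`` the
        residues before ``start`` are taken as already built (incremental
        rebuild after a local change); residue coordinates from ``start``
        onward are overwritten.
    start:
        First residue (0-based) to rebuild.  Ignored when ``coords`` is None.
    """
    t = np.asarray(torsions, dtype=float)
    if t.ndim != 2 or t.shape[1] != 3:
        raise ValueError("torsions must have shape (n, 3)")
    n = t.shape[0]
    if coords is None:
        coords = np.empty((n, 3, 3), dtype=float)
        start = 0
    elif coords.shape != (n, 3, 3):
        raise ValueError("coords must have shape (n, 3, 3)")

    b_nca = geometry.bond_n_ca
    b_cac = geometry.bond_ca_c
    b_cn = geometry.bond_c_n
    ang_ncac = math.radians(geometry.angle_n_ca_c)
    ang_cacn = math.radians(geometry.angle_ca_c_n)
    ang_cnca = math.radians(geometry.angle_c_n_ca)

    if start == 0:
        # Canonical frame for residue 1; phi(1) is geometrically inert.
        coords[0, 0] = (0.0, 0.0, 0.0)
        coords[0, 1] = (b_nca, 0.0, 0.0)
        coords[0, 2] = (
            b_nca - b_cac * math.cos(ang_ncac),
            b_cac * math.sin(ang_ncac),
            0.0,
        )
        start = 1

    if start < 1:
        start = 1
    if start >= n:
        return coords

    _build_chain(
        np.radians(t), coords, start,
        b_nca, b_cac, b_cn, ang_ncac, ang_cacn, ang_cnca,
    )
    return coords


def _chain_dihedrals(atoms: np.ndarray) -> np.ndarray:
    """Dihedral (degrees) of every 4 consecutive atoms along a chain."""
    b1 = atoms[1:-2] - atoms[:-3]
    b2 = atoms[2:-1] - atoms[1:-2]
    b3 = atoms[3:] - atoms[2:-1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2u = b2 / np.linalg.norm(b2, axis=1, keepdims=True)
    m1 = np.cross(n1, b2u)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    return np.degrees(np.arctan2(y, x))


def measure_torsions(coords: np.ndarray) -> np.ndarray:
    """Measure (phi, psi, omega) in degrees from backbone coordinates.

    Entries without four flanking atoms -- phi of the first residue and
    psi/omega of the last -- are NaN.
    """
    c = np.asarray(coords, dtype=float)
    if c.ndim != 3 or c.shape[1:] != (3, 3):
        raise ValueError("coords must have shape (n, 3, 3)")
    n = c.shape[0]
    out = np.full((n, 3), np.nan)
    flat = c.reshape(-1, 3)
    if n < 2:
        return out
    dih = _chain_dihedrals(flat)  # dihedral j spans atoms j..j+3
    # atom window starting at 3i   -> psi(i)
    # atom window starting at 3i+1 -> omega(i)
    # atom window starting at 3i+2 -> phi(i+1)
    idx = np.arange(n - 1)
    out[idx, 1] = dih[3 * idx]
    out[idx, 2] = dih[3 * idx + 1]
    out[idx + 1, 0] = dih[3 * idx + 2]
    # atan2 returns (-180, 180]; map an exact -180 to +180 for consistency
    defined = ~np.isnan(out)
    out[defined] = canonicalize_torsions(out[defined])
    return out


# ---------------------------------------------------------------------------
# Conformation
# ---------------------------------------------------------------------------


@dataclass
class Conformation:
    """Backbone model: torsions, derived coordinates, fragment provenance.

    ``provenance9``/``provenance3`` map a window start (1-based) to the index
    of the library fragment whose insertion last wrote that window and was
    not partially overwritten since.  Absence of a key means "none".
    """

    sequence: str
    torsions: np.ndarray
    coords: np.ndarray
    provenance9: dict[int, int] = field(default_factory=dict)
    provenance3: dict[int, int] = field(default_factory=dict)
    geometry: IdealGeometry = IDEAL_GEOMETRY

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def ca(self) -> np.ndarray:
        """(n, 3) array of CA coordinates."""
        return self.coords[:, 1, :]

    def copy(self) -> "Conformation":
        return replace(
            self,
            torsions=self.torsions.copy(),
            coords=self.coords.copy(),
            provenance9=dict(self.provenance9),
            provenance3=dict(self.provenance3),
        )


def _validate_sequence(sequence: str) -> str:
    seq = str(sequence).upper()
    if len(seq) < 9:
        raise ValueError(f"sequence length {len(seq)} < 9 (one 9-mer window)")
    bad = sorted(set(seq) - VALID_AA)
    if bad:
        raise ValueError(f"non-standard amino-acid letters: {''.join(bad)}")
    return seq


def extended_conformation(
    sequence: str, geometry: IdealGeometry = IDEAL_GEOMETRY
) -> Conformation:
    """Fully extended chain: phi=-150, psi=+150, omega=180, empty provenance."""
    seq = _validate_sequence(sequence)
    n = len(seq)
    torsions = np.tile(
        np.array([EXTENDED_PHI, EXTENDED_PSI, EXTENDED_OMEGA]), (n, 1)
    )
    coords = build_coords(torsions, geometry)
    return Conformation(sequence=seq, torsions=torsions, coords=coords, geometry=geometry)


def apply_provenance(
    provenance: dict[int, int],
    start: int,
    length: int,
    frag_index: int,
    policy: str = "invalidate",
) -> None:
    """Record an insertion under one of two overwrite policies.

    ``"invalidate"`` (strict, last-writer-wins): any previously recorded
    window of the same fragment length whose residue range intersects
    [start, start+length) is cleared, then the inserted window is set --
    provenance then only names windows whose torsions are still entirely the
    recorded fragment's.  ``"keep"`` (usage-tracking): only an insertion at
    the same start overwrites; partially overlapping records survive, so the
    map reads as "the last fragment used at this window during
    construction".  Mutates ``provenance`` in place.
    """
    if policy == "invalidate":
        lo, hi = start, start + length - 1
        for s in list(provenance):
            if s == start:
                continue
            if s <= hi and s + length - 1 >= lo:
                del provenance[s]
    elif policy != "keep":
        raise ValueError(f"unknown provenance policy '{policy}'")
    provenance[start] = frag_index


def insert_fragment(conf: Conformation, window, frag_index: int) -> Conformation:
    """Insert a library fragment; returns a new conformation.

    Replaces the torsions of residues [start, start+L), rebuilds coordinates
    from the first affected residue, and updates the provenance map of the
    matching fragment length.
    """
    frags = window.fragments
    if not (0 <= frag_index < len(frags)):
        raise IndexError(f"fragment index {frag_index} out of range")
    frag = frags[frag_index]
    length = frag.length
    start = window.start
    n = len(conf)
    if start < 1 or start + length - 1 > n:
        raise ValueError(
            f"window [{start}, {start + length - 1}] outside sequence of length {n}"
        )
    out = conf.copy()
    s0 = start - 1
    out.torsions[s0 : s0 + length] = frag.torsions
    build_coords(out.torsions, conf.geometry, coords=out.coords, start=max(s0, 1))
    prov = out.provenance9 if length == 9 else out.provenance3 if length == 3 else None
    if prov is not None:
        apply_provenance(prov, start, length, frag_index)
    return out


def rebuild_deviation(conf: Conformation) -> float:
    """Max atom deviation (A) between stored coords and a fresh rebuild."""
    fresh = build_coords(conf.torsions, conf.geometry)
    return float(np.abs(fresh - conf.coords).max())


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------


def _kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = pc.T @ qc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u) * np.linalg.det(vt))
    ssd = (pc * pc).sum() + (qc * qc).sum() - 2.0 * (s[0] + s[1] + d * s[2])
    return math.sqrt(max(ssd, 0.0) / len(p))


def _as_ca(x) -> np.ndarray:
    if isinstance(x, Conformation):
        return x.ca
    a = np.asarray(x, dtype=float)
    if a.ndim == 3 and a.shape[1:] == (3, 3):
        return a[:, 1, :]
    if a.ndim == 2 and a.shape[1] == 3:
        return a
    raise ValueError("expected (n,3) CA coords, (n,3,3) backbone, or Conformation")


def ca_rmsd(a, b) -> float:
    """Minimum CA RMSD (A) over all rigid-body superpositions (Kabsch)."""
    p = _as_ca(a)
    q = _as_ca(b)
    if p.shape != q.shape:
        raise ValueError(f"coordinate shapes differ: {p.shape} vs {q.shape}")
    return _kabsch_rmsd(p, q)


def backbone_rmsd(a, b) -> float:
    """Superposition RMSD over all backbone N/CA/C atoms."""
    p = (a.coords if isinstance(a, Conformation) else np.asarray(a, float)).reshape(-1, 3)
    q = (b.coords if isinstance(b, Conformation) else np.asarray(b, float)).reshape(-1, 3)
    if p.shape != q.shape:
        raise ValueError(f"coordinate shapes differ: {p.shape} vs {q.shape}")
    return _kabsch_rmsd(p, q)


# ---------------------------------------------------------------------------
# PDB I/O (backbone only)
# ---------------------------------------------------------------------------

_AA_1TO3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
_AA_3TO1 = {v: k for k, v in _AA_1TO3.items()}


def write_pdb(conf: Conformation, path) -> None:
    """Write backbone ATOM records (chain A, occupancy 1.00).

    The B-factor column carries the 9-mer provenance window start covering
    the residue, or 0.00 when no recorded window covers it.
    """
    cover: dict[int, int] = {}
    for s in conf.provenance9:
        for r in range(s, s + 9):
            cover[r] = s
    lines = []
    serial = 1
    for i, aa in enumerate(conf.sequence):
        res3 = _AA_1TO3[aa]
        resseq = i + 1
        b = float(cover.get(resseq, 0))
        for name, xyz in zip(("N", "CA", "C"), conf.coords[i]):
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} {res3:>3s} A{resseq:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{b:6.2f}"
                f"          {name[0]:>2s}"
            )
            serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_pdb(path) -> tuple[str, np.ndarray]:
    """Read a backbone PDB; returns (sequence, (n,3,3) N/CA/C coordinates)."""
    import warnings

    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = PDBParser(QUIET=True).get_structure("m", str(path))
    model = next(structure.get_models())
    chain = next(model.get_chains())
    seq = []
    coords = []
    for res in chain.get_residues():
        if not all(a in res for a in ("N", "CA", "C")):
            continue
        seq.append(_AA_3TO1.get(res.get_resname(), "X"))
        coords.append([res["N"].coord, res["CA"].coord, res["C"].coord])
    if not coords:
        raise ValueError(f"no backbone residues found in {path}")
    return "".join(seq), np.asarray(coords, dtype=float)
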