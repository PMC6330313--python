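"""Loop backbones: PDB input, psi torsions, and Ca-trace embedding.

Real loop conformations enter as backbone N/CA/C coordinates read from
standard PDB files (first model, first altloc, ATOM records only); the
psi backbone dihedral N(i)-CA(i)-C(i)-N(i+1) is the torsion coordinate
used throughout the pipeline.

For synthetic torsion trajectories the inverse direction is needed: an
idealized Ca-trace embedding turns a torsion vector into a 3D point chain
(virtual bond 3.8 A, virtual bond angle 120 deg, one pseudo-dihedral per
torsion) so coordinate-based stages — Kabsch RMSD, clustering, PCA — can
run on toy data exactly as they would on a real loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Tuple

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .angles import wrap_angle
from .errors import DegenerateGeometryError, ParseError, ValidationError
from .toy_dynamics import TorsionTrajectory

__all__ = ["BackboneChain", "CoordinateTrajectory", "read_pdb_backbone",
           "write_pdb_backbone", "dihedral", "psi_torsions", "embed_ca_trace",
           "CA_VIRTUAL_BOND", "CA_VIRTUAL_ANGLE"]

#: virtual Ca-Ca bond length of the idealized trace, Angstrom
CA_VIRTUAL_BOND = 3.8
#: virtual bond angle of the idealized trace, radians
CA_VIRTUAL_ANGLE = np.deg2rad(120.0)

_BACKBONE_ATOMS = ("N", "CA", "C")


@dataclass
class BackboneChain:
    """Backbone N/CA/C coordinates for an ordered residue stretch."""

    residue_ids: Tuple[str, ...]
    coords: np.ndarray          # n_res x 3(atoms) x 3(xyz), order N, CA, C
    chain_id: str = "A"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (3, 3):
            raise ValidationError("coords must be n_res x 3 x 3")
        if len(self.residue_ids) != self.coords.shape[0]:
            raise ValidationError("residue_ids length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite backbone coordinates")

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    def atom(self, i_res: int, name: str) -> np.ndarray:
        return self.coords[i_res, _BACKBONE_ATOMS.index(name)]


@dataclass
class CoordinateTrajectory:
    """Frames x n_points x 3 Cartesian coordinates (Angstrom)."""

    coords: np.ndarray
    labels: Tuple[str, ...]
    frame_interval: float = 1.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("coords must be frames x n_points x 3")
        if len(self.labels) != self.coords.shape[1]:
            raise ValidationError("labels length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite coordinates")
        if not self.frame_interval > 0:
            raise ValidationError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_points(self) -> int:
        return self.coords.shape[1]


def read_pdb_backbone(path, chain_id: str,
                      residue_range: Tuple[int, int]) -> BackboneChain:
    """Read N/CA/C coordinates for residues first..last (inclusive).

    Only ATOM records of the first model are considered; alternate
    locations beyond the first are ignored. Missing backbone atoms inside
    the range raise a :class:`ParseError` naming the residue.
    """
    path = Path(path)
    pdb_file = pdb.PDBFile.read(str(path))
    atoms = pdb.get_structure(pdb_file, model=1, altloc="first")
    atoms = atoms[~atoms.hetero]
    atoms = atoms[atoms.chain_id == chain_id]
    if atoms.array_length() == 0:
        raise ParseError(f"chain '{chain_id}' not found in {path.name}")
    first, last = residue_range
    residues = []
    coords = []
    for res_id in range(first, last + 1):
        sel = atoms[atoms.res_id == res_id]
        if sel.array_length() == 0:
            raise ParseError(
                f"residue {res_id} of chain {chain_id} missing "
                f"in {path.name}")
        res_coords = np.empty((3, 3))
        for a, name in enumerate(_BACKBONE_ATOMS):
            hit = sel[sel.atom_name == name]
            if hit.array_length() == 0:
                raise ParseError(
                    f"residue {res_id} of chain {chain_id} lacks backbone "
                    f"atom {name} in {path.name}")
            res_coords[a] = hit.coord[0]
        ins = sel.ins_code[0] if hasattr(sel, "ins_code") else ""
        residues.append(f"{res_id}{ins}".strip())
        coords.append(res_coords)
    return BackboneChain(tuple(residues), np.array(coords), chain_id)


def write_pdb_backbone(chain: BackboneChain, path) -> None:
    """Write the backbone as a minimal wwPDB-style file (round-trip aid)."""
    n = chain.n_residues * 3
    arr = struc.AtomArray(n)
    k = 0
    for i, rid in enumerate(chain.residue_ids):
        for a, name in enumerate(_BACKBONE_ATOMS):
            arr.coord[k] = chain.coords[i, a]
            arr.chain_id[k] = chain.chain_id
            arr.res_id[k] = int("".join(c for c in rid if c.isdigit() or
                                        c == "-") or i + 1)
            arr.res_name[k] = "ALA"
            arr.atom_name[k] = name
            arr.element[k] = name[0]
            arr.hetero[k] = False
            k += 1
    f = pdb.PDBFile()
    pdb.set_structure(f, arr)
    f.write(str(path))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral of four points, IUPAC sign, in (-pi, pi].

    Looking from atom 2 toward atom 3, the angle from the projection of
    bond 2->1 to the projection of bond 3->4; trans is pi, cis is 0.
    """
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 == 0:
        raise DegenerateGeometryError("coincident central atoms")
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < 1e-12 or np.linalg.norm(w) < 1e-12:
        raise DegenerateGeometryError("collinear atoms define no dihedral")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(wrap_angle(np.arctan2(y, x)))


def psi_torsions(chain: BackboneChain) -> np.ndarray:
    """psi dihedrals N(i)-CA(i)-C(i)-N(i+1) for residues 1..n-1 (radians)."""
    if chain.n_residues < 2:
        raise ValidationError("psi requires at least 2 residues")
    out = np.empty(chain.n_residues - 1)
    for i in range(chain.n_residues - 1):
        out[i] = dihedral(chain.atom(i, "N"), chain.atom(i, "CA"),
                          chain.atom(i, "C"), chain.atom(i + 1, "N"))
    return out


def _embed_frame(torsions: np.ndarray, bond: float,
                 theta: float) -> np.ndarray:
    """Sequential internal-coordinate chain build (NeRF-style).

    The first three points are gauge-fixed: origin, +x axis, xy-plane.
    Point k+3 is placed at bond length/angle with dihedral torsions[k],
    measured with the same sign convention as :func:`dihedral`.
    """
    n = torsions.size + 3
    pts = np.zeros((n, 3))
    pts[1] = [bond, 0.0, 0.0]
    pts[2] = pts[1] + bond * np.array([-np.cos(theta), np.sin(theta), 0.0])
    for k, phi in enumerate(torsions):
        a, b_, c = pts[k], pts[k + 1], pts[k + 2]
        bc = c - b_
        bc /= np.linalg.norm(bc)
        ab = b_ - a
        n_vec = np.cross(ab, bc)
        n_vec /= np.linalg.norm(n_vec)
        m_vec = np.cross(n_vec, bc)
        d_local = bond * np.array([-np.cos(theta),
                                   np.sin(theta) * np.cos(phi),
                                   np.sin(theta) * np.sin(phi)])
        pts[k + 3] = c + (d_local[0] * bc + d_local[1] * m_vec
                          + d_local[2] * n_vec)
    return pts


def embed_ca_trace(traj: TorsionTrajectory, bond: float = CA_VIRTUAL_BOND,
                   theta: float = CA_VIRTUAL_ANGLE) -> CoordinateTrajectory:
    """Deterministic Ca-trace embedding of a torsion trajectory.

    Each frame becomes a chain of ``n_torsions + 3`` points with fixed
    virtual bond length and angle, the k-th torsion serving as the k-th
    pseudo-dihedral. Identical torsions give identical coordinates; the
    first three points remove the rigid-body gauge.
    """
    frames = np.empty((traj.n_frames, traj.n_torsions + 3, 3))
    for f in range(traj.n_frames):
        frames[f] = _embed_frame(traj.angles[f], bond, theta)
    labels = tuple(f"CA{i}" for i in range(traj.n_torsions + 3))
    return CoordinateTrajectory(frames, labels, traj.frame_interval)


def trace_torsions(coords: np.ndarray) -> np.ndarray:
    """Pseudo-dihedrals of a point chain (inverse of the embedding)."""
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    if n < 4:
        raise ValidationError("need at least 4 points for a dihedral")
    return np.array([dihedral(coords[k], coords[k + 1], coords[k + 2],
                              coords[k + 3]) for k in range(n - 3)])
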