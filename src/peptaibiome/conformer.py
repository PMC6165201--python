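"""Conformational-ensemble statistics for peptaibol backbones.

Peptaibols rich in Aib fluctuate between right- and left-handed helical
states; the analyses here quantify that behaviour for an ensemble of frames
(e.g. snapshots of an implicit-solvent trajectory read from a multi-model
PDB):

* backbone phi/psi dihedrals and per-residue Ramachandran free-energy
  surfaces, Delta G = -RT ln(P / P_max),
* rectangular-region classification (alpha / 3_10, right- and left-handed,
  beta, polyproline II),
* backbone hydrogen-bond detection with turn-type classes (i+2 gamma turn,
  i+3 3_10 helix, i+4 alpha helix),
* RMSD of each frame to the ensemble-average structure (Kabsch
  superposition), radius of gyration, and the 2D free-energy landscape over
  (RMSD, RoG).

All coordinates are in Angstrom, angles in degrees, energies in kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import InsufficientEnsembleError, TopologyError

#: Gas constant, kcal mol^-1 K^-1.
R_KCAL = 1.9872e-3

DEFAULT_TEMPERATURE = 300.0

BACKBONE_ATOMS = ("N", "CA", "C")


# -- ensembles ----------------------------------------------------------------


@dataclass
class Ensemble:
    """Backbone coordinates of an ensemble of frames with shared topology.

    ``coords`` has shape (n_frames, n_atoms, 3); ``atom_names`` and
    ``atom_res`` (1-based residue index) describe each atom column;
    ``res_names`` is one label per residue.
    """

    coords: np.ndarray
    atom_names: tuple[str, ...]
    atom_res: tuple[int, ...]
    res_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atom_names) != len(self.atom_res):
            raise ValueError("atom annotation length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        index: dict[tuple[int, str], int] = {}
        for i, (res, name) in enumerate(zip(self.atom_res, self.atom_names)):
            index[(res, name)] = i
        self._index = index

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return len(self.res_names)

    def atom_index(self, residue: int, name: str) -> int:
        try:
            return self._index[(residue, name)]
        except KeyError:
            raise TopologyError(
                f"residue {residue} ({self.res_names[residue - 1]}) has no atom {name!r}"
            ) from None

    def has_atom(self, residue: int, name: str) -> bool:
        return (residue, name) in self._index

    def select(self, names: Sequence[str] = BACKBONE_ATOMS) -> np.ndarray:
        """Indices of all atoms whose name is in ``names``, chain order."""
        wanted = set(names)
        return np.array([i for i, n in enumerate(self.atom_names) if n in wanted],
                        dtype=int)


def read_pdb_ensemble(path: str | Path) -> Ensemble:
    """Read a multi-model PDB (MODEL/ENDMDL records) into an :class:`Ensemble`."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ensemble", str(path))
    models = list(structure)
    if not models:
        raise TopologyError(f"{path}: no models found")
    atom_names: list[str] = []
    atom_res: list[int] = []
    res_names: list[str] = []
    frames: list[np.ndarray] = []
    for m_i, model in enumerate(models):
        xyz: list[np.ndarray] = []
        r_count = 0
        for chain in model:
            for residue in chain:
                r_count += 1
                if m_i == 0:
                    res_names.append(residue.get_resname().strip())
                for atom in residue:
                    if m_i == 0:
                        atom_names.append(atom.get_name().strip())
                        atom_res.append(r_count)
                    xyz.append(atom.coord)
        frames.append(np.asarray(xyz, dtype=float))
    coords = np.stack(frames)
    return Ensemble(coords, tuple(atom_names), tuple(atom_res), tuple(res_names))


def write_pdb_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB readable by standard tools."""
    with open(path, "w", encoding="utf-8") as fh:
        for f in range(ensemble.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for a, (name, res) in enumerate(zip(ensemble.atom_names, ensemble.atom_res)):
                x, y, z = ensemble.coords[f, a]
                resname = ensemble.res_names[res - 1][:3].upper()
                pdb_name = f" {name:<3s}" if len(name) < 4 else name
                fh.write(
                    f"ATOM  {a + 1:5d} {pdb_name}{'':1s}{resname:>3s} A{res:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# -- dihedrals ----------------------------------------------------------------


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                   p3: np.ndarray) -> np.ndarray:
    """Signed torsion angle(s) in degrees for points of shape (..., 3)."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    return np.degrees(np.arctan2(y, x))


@dataclass
class DihedralSeries:
    """phi/psi per residue per frame, degrees; NaN where undefined (termini)."""

    phi: np.ndarray  # (n_frames, n_residues)
    psi: np.ndarray


def backbone_dihedrals(ensemble: Ensemble) -> DihedralSeries:
    """Standard phi(C_{i-1}, N_i, CA_i, C_i) and psi(N_i, CA_i, C_i, N_{i+1})."""
    n_res = ensemble.n_residues
    idx = {name: [ensemble.atom_index(r, name) for r in range(1, n_res + 1)]
           for name in BACKBONE_ATOMS}
    X = ensemble.coords
    phi = np.full((ensemble.n_frames, n_res), np.nan)
    psi = np.full((ensemble.n_frames, n_res), np.nan)
    for r in range(1, n_res + 1):
        if r > 1:
            phi[:, r - 1] = dihedral_angle(
                X[:, idx["C"][r - 2]], X[:, idx["N"][r - 1]],
                X[:, idx["CA"][r - 1]], X[:, idx["C"][r - 1]])
        if r < n_res:
            psi[:, r - 1] = dihedral_angle(
                X[:, idx["N"][r - 1]], X[:, idx["CA"][r - 1]],
                X[:, idx["C"][r - 1]], X[:, idx["N"][r]])
    return DihedralSeries(phi=phi, psi=psi)


# -- free-energy surfaces -----------------------------------------------------


@dataclass
class FESGrid:
    """Relative free energies over a 2D histogram; empty bins are masked."""

    xedges: np.ndarray
    yedges: np.ndarray
    delta_g: np.ndarray  # (nx, ny), NaN where masked
    mask: np.ndarray  # True where the bin is empty
    temperature: float

    def minimum_bin(self) -> tuple[int, int]:
        """Indices of the occupied bin with Delta G = 0."""
        filled = np.where(self.mask, np.inf, self.delta_g)
        return tuple(int(i) for i in np.unravel_index(np.argmin(filled),
                                                      self.delta_g.shape))


def _fes_from_histogram(H: np.ndarray, xedges: np.ndarray, yedges: np.ndarray,
                        T: float) -> FESGrid:
    total = H.sum()
    if total == 0:
        raise ValueError("no samples to histogram")
    P = H / total
    mask = P == 0
    with np.errstate(divide="ignore"):
        dg = -R_KCAL * T * np.log(np.where(mask, np.nan, P) / P.max())
    dg = np.where(mask, np.nan, dg)
    return FESGrid(xedges=xedges, yedges=yedges, delta_g=dg, mask=mask, temperature=T)


def rama_free_energy(phi: np.ndarray, psi: np.ndarray, bins: int = 72,
                     T: float = DEFAULT_TEMPERATURE) -> FESGrid:
    """Per-residue Ramachandran free-energy surface over [-180, 180]^2.

    Delta G = -RT ln(P / P_max) over the (phi, psi) occupancy histogram; the
    occupied minimum is exactly 0 and empty bins are masked.
    """
    phi = np.asarray(phi, dtype=float).ravel()
    psi = np.asarray(psi, dtype=float).ravel()
    keep = np.isfinite(phi) & np.isfinite(psi)
    phi, psi = phi[keep], psi[keep]
    if phi.size == 0:
        raise ValueError("no defined dihedrals (terminal residue?)")
    if bins < 2:
        raise ValueError("need at least 2 bins per axis")
    H, xe, ye = np.histogram2d(phi, psi, bins=bins, range=[[-180, 180], [-180, 180]])
    return _fes_from_histogram(H, xe, ye, T)


def fes_2d(x: np.ndarray, y: np.ndarray, bins: int = 50,
           T: float = DEFAULT_TEMPERATURE) -> FESGrid:
    """Free-energy landscape over two order parameters (e.g. RMSD vs RoG)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"series length mismatch: {x.size} vs {y.size}")
    H, xe, ye = np.histogram2d(x, y, bins=bins)
    return _fes_from_histogram(H, xe, ye, T)


# -- Ramachandran regions -----------------------------------------------------

# Rectangular (phi, psi) boxes, degrees.  The 3_10 boxes are subsets of the
# alpha boxes and take precedence; left-handed boxes are the point
# reflections of the right-handed ones.
_BOXES_RIGHT = {
    "three10_R": ((-80.0, -40.0), (-45.0, -10.0)),
    "alpha_R": ((-100.0, -30.0), (-80.0, -5.0)),
    "beta": ((-180.0, -90.0), (90.0, 180.0)),
    "ppII": ((-90.0, -20.0), (120.0, 180.0)),
}


def _in_box(phi: float, psi: float, box) -> bool:
    (plo, phi_hi), (slo, shi) = box
    return plo <= phi <= phi_hi and slo <= psi <= shi


def classify_region(phi: float, psi: float) -> str:
    """Classify a (phi, psi) pair into a named Ramachandran region.

    Order of precedence: 3_10 (right then left), alpha (right then left),
    beta, polyproline II; anything else is ``other``.
    """
    if not (np.isfinite(phi) and np.isfinite(psi)):
        raise ValueError("both angles must be defined")
    for name in ("three10_R", "alpha_R"):
        if _in_box(phi, psi, _BOXES_RIGHT[name]):
            return name
        if _in_box(-phi, -psi, _BOXES_RIGHT[name]):
            return name.replace("_R", "_L")
    for name in ("beta", "ppII"):
        if _in_box(phi, psi, _BOXES_RIGHT[name]):
            return name
    return "other"


# -- hydrogen bonds -----------------------------------------------------------

TURN_CLASSES = {2: "i+2_gamma", 3: "i+3_310", 4: "i+4_alpha"}


@dataclass(frozen=True)
class HBondStat:
    """One backbone H-bond aggregated over frames."""

    acceptor: int  # residue index i (C=O)
    donor: int  # residue index j (N-H)
    fraction: float
    mean_distance: float
    turn_class: str
    acceptor_name: str = ""
    donor_name: str = ""


def reconstruct_amide_h(ensemble: Ensemble, residue: int) -> np.ndarray:
    """Place the amide H 1.01 A from N, opposite the C(prev)/CA bisector."""
    if residue < 2:
        raise TopologyError("residue 1 has no reconstructable amide H")
    N = ensemble.coords[:, ensemble.atom_index(residue, "N")]
    CA = ensemble.coords[:, ensemble.atom_index(residue, "CA")]
    Cp = ensemble.coords[:, ensemble.atom_index(residue - 1, "C")]
    u1 = Cp - N
    u1 /= np.linalg.norm(u1, axis=-1, keepdims=True)
    u2 = CA - N
    u2 /= np.linalg.norm(u2, axis=-1, keepdims=True)
    bis = u1 + u2
    bis /= np.linalg.norm(bis, axis=-1, keepdims=True)
    return N - 1.01 * bis


def detect_hbonds(ensemble: Ensemble, dist_cut: float = 3.0,
                  ang_cut: float = 135.0,
                  reconstruct_h: bool = True) -> list[HBondStat]:
    """Backbone H-bonds O(i)...H-N(j) aggregated over all frames.

    A bond exists in a frame when the heavy-atom N...O distance is at most
    ``dist_cut`` and the N-H...O angle (at H) is at least ``ang_cut``.
    Proline and the N-terminal residue cannot donate.  The turn class follows
    from the donor-acceptor separation j - i (2: gamma turn, 3: 3_10 helix,
    4: alpha helix, anything else ``other``).  Results sort by descending
    fraction.
    """
    n_res = ensemble.n_residues
    n_frames = ensemble.n_frames

    donors: dict[int, np.ndarray] = {}
    for j in range(2, n_res + 1):
        if ensemble.res_names[j - 1].upper().startswith("PRO"):
            continue
        if ensemble.has_atom(j, "H"):
            donors[j] = ensemble.coords[:, ensemble.atom_index(j, "H")]
        elif reconstruct_h:
            donors[j] = reconstruct_amide_h(ensemble, j)
        else:
            raise TopologyError(
                f"residue {j} has no amide H and reconstruction is disabled")

    acceptors = {i: ensemble.coords[:, ensemble.atom_index(i, "O")]
                 for i in range(1, n_res + 1) if ensemble.has_atom(i, "O")}
    if not acceptors:
        raise TopologyError("no backbone carbonyl O atoms in ensemble")

    stats: list[HBondStat] = []
    for i, O in acceptors.items():
        N_all = {j: ensemble.coords[:, ensemble.atom_index(j, "N")] for j in donors}
        for j, H in donors.items():
            if abs(j - i) < 2:
                continue
            N = N_all[j]
            dist = np.linalg.norm(N - O, axis=-1)
            v1 = N - H
            v2 = O - H
            cosang = np.sum(v1 * v2, axis=-1) / (
                np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1))
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            hit = (dist <= dist_cut) & (ang >= ang_cut)
            n_hit = int(hit.sum())
            if n_hit == 0:
                continue
            stats.append(HBondStat(
                acceptor=i, donor=j,
                fraction=n_hit / n_frames,
                mean_distance=float(dist[hit].mean()),
                turn_class=TURN_CLASSES.get(j - i, "other"),
                acceptor_name=ensemble.res_names[i - 1],
                donor_name=ensemble.res_names[j - 1],
            ))
    stats.sort(key=lambda s: (-s.fraction, s.acceptor, s.donor))
    return stats


# -- superposition, RMSD, radius of gyration ----------------------------------


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal rotation matrix aligning centred P onto centred Q."""
    C = P.T @ Q
    V, _, Wt = np.linalg.svd(C)
    d = np.sign(np.linalg.det(V @ Wt))
    D = np.diag([1.0, 1.0, d])
    return V @ D @ Wt


def _superpose_all(frames: np.ndarray, reference: np.ndarray) -> np.ndarray:
    ref = reference - reference.mean(axis=0)
    out = np.empty_like(frames)
    for f in range(frames.shape[0]):
        X = frames[f] - frames[f].mean(axis=0)
        out[f] = X @ kabsch_rotation(X, ref)
    return out


def rmsd_to_average(ensemble: Ensemble,
                    atom_selection: Sequence[str] = BACKBONE_ATOMS) -> np.ndarray:
    """Per-frame RMSD to the ensemble-average structure (backbone N, CA, C).

    Frames are superposed (Kabsch) onto their running coordinate average:
    align to the first frame, average, re-align to the average, recompute the
    average once, then report each frame's RMSD to it.
    """
    if ensemble.n_frames < 2:
        raise InsufficientEnsembleError("rmsd_to_average needs >= 2 frames")
    sel = ensemble.select(atom_selection)
    if sel.size == 0:
        raise TopologyError(f"no atoms selected from {atom_selection}")
    frames = ensemble.coords[:, sel]
    aligned = _superpose_all(frames, frames[0])
    avg = aligned.mean(axis=0)
    aligned = _superpose_all(aligned, avg)
    avg = aligned.mean(axis=0)
    diff = aligned - (avg - avg.mean(axis=0))
    return np.sqrt(np.mean(np.sum(diff ** 2, axis=-1), axis=-1))


def radius_of_gyration(frame_coords: np.ndarray,
                       masses: np.ndarray | None = None) -> float:
    """Mass-weighted root-mean-square distance from the centre of mass.

    ``frame_coords`` has shape (n_atoms, 3); unit masses by default (the
    selection, not the weighting, carries the physics here).
    """
    X = np.asarray(frame_coords, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3 or X.shape[0] == 0:
        raise ValueError("frame_coords must be a non-empty (n_atoms, 3) array")
    w = np.ones(X.shape[0]) if masses is None else np.asarray(masses, dtype=float)
    com = np.average(X, axis=0, weights=w)
    sq = np.sum((X - com) ** 2, axis=-1)
    return float(np.sqrt(np.average(sq, weights=w)))


def rog_series(ensemble: Ensemble,
               atom_selection: Sequence[str] = BACKBONE_ATOMS) -> np.ndarray:
    """Radius of gyration of the selected atoms for every frame."""
    sel = ensemble.select(atom_selection)
    if sel.size == 0:
        raise TopologyError(f"no atoms selected from {atom_selection}")
    return np.array([radius_of_gyration(ensemble.coords[f, sel])
                     for f in range(ensemble.n_frames)])


def mirror(ensemble: Ensemble) -> Ensemble:
    """Mirror-image the ensemble (x -> -x); flips all dihedral signs."""
    coords = ensemble.coords.copy()
    coords[..., 0] *= -1
    return Ensemble(coords, ensemble.atom_names, ensemble.atom_res,
                    ensemble.res_names)
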