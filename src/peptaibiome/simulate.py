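"""Synthetic-data generators: simulated peak lists and designed helix ensembles.

These generators make every pipeline stage testable without instrument data:

* :func:`simulate_peaklist` is a forward model of what a unit-resolution ESI
  ion trap reports for a peptaibol -- sodiated precursors, the acetyl-capped
  b-series with the characteristic dropouts (b1 is rarely seen; b13/b14
  vanish after the Aib12-Pro13 bond), the y7 fragment and optional MS2
  sub-ions, each perturbed by Gaussian centroid noise.

* :func:`generate_helix_ensemble` builds backbone ensembles with designed
  secondary structure (alpha or 3_10, either handedness) from canonical
  (phi, psi) values with per-frame Gaussian angle jitter, using standard
  peptide geometry.

Both are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chem import PeptaibolSequence, adduct_mz, b_ion_mz, neutral_mass, y_ion_mz
from .conformer import Ensemble
from .sequencer import Peak, PeakList

# -- spectra ------------------------------------------------------------------


@dataclass(frozen=True)
class SpectrumSimConfig:
    """Instrument imperfections applied to the theoretical ion set.

    ``noise_sigma`` is Gaussian centroid jitter in Da; ``dropout`` names
    fragments to omit (default mirrors the study spectra: b1, and b13/b14
    suppressed by the Aib-Pro bond); ``ms2_depth`` emits the y1..y_depth
    sub-ion series of the y7 fragment.
    """

    noise_sigma: float = 0.05
    dropout: frozenset[str] = frozenset({"b1", "b13", "b14"})
    adducts: tuple[str, ...] = ("M+Na", "M+2Na")
    ms2_depth: int = 0
    seed: int = 0
    rt: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.ms2_depth < 0 or self.ms2_depth > 6:
            raise ValueError("ms2_depth must be in 0..6")


_ADDUCT_KIND = {"M+Na": "MNa", "M+2Na": "M2Na"}


def simulate_peaklist(seq: PeptaibolSequence,
                      cfg: SpectrumSimConfig = SpectrumSimConfig()) -> PeakList:
    """Simulate the characteristic-ion peak list of one peptaibol compound."""
    rng = np.random.default_rng(cfg.seed)
    peaks: list[Peak] = []

    def emit(mz: float, kind: str) -> None:
        noisy = mz + rng.normal(0.0, cfg.noise_sigma) if cfg.noise_sigma else mz
        intensity = float(10 ** rng.uniform(3.0, 6.0))
        peaks.append(Peak(mz=noisy, intensity=intensity, kind=kind))

    M = neutral_mass(seq)
    for adduct in cfg.adducts:
        emit(adduct_mz(M, adduct), _ADDUCT_KIND[adduct])
    for n in range(1, len(seq)):
        if f"b{n}" not in cfg.dropout:
            emit(b_ion_mz(seq, n), "b")
    if len(seq) >= 7 and "y7" not in cfg.dropout:
        emit(y_ion_mz(seq, 7), "y7")
        for k in range(1, cfg.ms2_depth + 1):
            emit(y_ion_mz(seq, k), "ms2")
    return PeakList(tuple(peaks), rt=cfg.rt)


# -- helices ------------------------------------------------------------------

#: Canonical right-handed (phi, psi), degrees; left-handed is the sign flip.
CANONICAL_ANGLES = {"alpha": (-57.0, -47.0), "three10": (-49.0, -26.0)}

# Standard peptide backbone geometry (bond lengths in Angstrom, angles deg).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 110.0
ANGLE_CA_C_N = 117.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
OMEGA = 180.0


@dataclass(frozen=True)
class HelixSimConfig:
    n_residues: int = 12
    helix_type: str = "three10"  # alpha | three10
    handedness: str = "right"  # right | left
    jitter_sigma: float = 0.0  # degrees, applied per frame per angle
    n_frames: int = 1
    seed: int = 0
    res_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise ValueError("need at least 4 residues for a helix")
        if self.helix_type not in CANONICAL_ANGLES:
            raise ValueError(f"helix_type must be one of {sorted(CANONICAL_ANGLES)}")
        if self.handedness not in ("right", "left"):
            raise ValueError("handedness must be 'right' or 'left'")
        if self.n_frames < 1 or self.jitter_sigma < 0:
            raise ValueError("n_frames >= 1 and jitter_sigma >= 0 required")

    @property
    def canonical(self) -> tuple[float, float]:
        phi, psi = CANONICAL_ANGLES[self.helix_type]
        return (phi, psi) if self.handedness == "right" else (-phi, -psi)


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float,
                angle: float, torsion: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom d from internal coordinates."""
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phi: Sequence[float], psi: Sequence[float]) -> tuple[np.ndarray, ...]:
    """Build N/CA/C/O coordinates for one frame from phi/psi (omega = 180).

    ``phi[0]`` is unused (undefined at the N-terminus); ``psi[-1]`` is used
    only to place the final carbonyl O.
    """
    n_res = len(phi)
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    O = np.zeros((n_res, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    ang = np.radians(ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(n_res - 1):
        N[i + 1] = _place_atom(N[i], CA[i], C[i], BOND_C_N, ANGLE_CA_C_N, psi[i])
        CA[i + 1] = _place_atom(CA[i], C[i], N[i + 1], BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        C[i + 1] = _place_atom(C[i], N[i + 1], CA[i + 1], BOND_CA_C, ANGLE_N_CA_C,
                               phi[i + 1])
    for i in range(n_res):
        O[i] = _place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, psi[i] + 180.0)
    return N, CA, C, O


def generate_helix_ensemble(cfg: HelixSimConfig = HelixSimConfig()) -> Ensemble:
    """Generate a backbone ensemble around canonical helix dihedrals."""
    rng = np.random.default_rng(cfg.seed)
    phi0, psi0 = cfg.canonical
    res_names = cfg.res_names or tuple("AIB" for _ in range(cfg.n_residues))
    if len(res_names) != cfg.n_residues:
        raise ValueError("res_names length must equal n_residues")
    atom_names: list[str] = []
    atom_res: list[int] = []
    for r in range(1, cfg.n_residues + 1):
        for name in ("N", "CA", "C", "O"):
            atom_names.append(name)
            atom_res.append(r)
    frames = np.empty((cfg.n_frames, 4 * cfg.n_residues, 3))
    for f in range(cfg.n_frames):
        phi = phi0 + rng.normal(0.0, cfg.jitter_sigma, cfg.n_residues) \
            if cfg.jitter_sigma else np.full(cfg.n_residues, phi0)
        psi = psi0 + rng.normal(0.0, cfg.jitter_sigma, cfg.n_residues) \
            if cfg.jitter_sigma else np.full(cfg.n_residues, psi0)
        N, CA, C, O = build_backbone(phi, psi)
        frames[f] = np.stack([N, CA, C, O], axis=1).reshape(-1, 3)
    return Ensemble(frames, tuple(atom_names), tuple(atom_res), tuple(res_names))
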