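"""Idealized main-chain generation: backbones, decoy sets, training corpora.

Backbones are built by sequential internal-coordinate placement (the
NeRF construction) with ideal bond lengths and angles (Engh & Huber
stereochemical values), so a structure is fully determined by its
sequence and per-residue (φ, ψ, ω) dihedrals.  Decoys perturb a native's
φ/ψ with Gaussian noise; training corpora mix helix, strand and
Ramachandran-like coil segments.  Everything is deterministic given an
explicit seed.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .frames import dihedral
from .structures import AMINO_ACIDS, DecoySet, MainChainStructure, Residue, build_decoy_set

# ideal main-chain geometry (Engh & Huber values), Å and degrees
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-120.0, 130.0)

#: Ramachandran-like mixture for coil: (φ center, ψ center, weight, sd).
COIL_BASINS = (
    (-63.0, -43.0, 0.35, 12.0),   # alpha-R
    (-120.0, 130.0, 0.35, 15.0),  # beta
    (-75.0, 150.0, 0.20, 12.0),   # PPII-like
    (60.0, 45.0, 0.10, 10.0),     # alpha-L
)


@dataclass
class DihedralSpec:
    """Sequence plus per-residue (φ, ψ, ω) in degrees.

    φ of the first residue and ψ/ω of the last are undefined for a
    chain and ignored by the builder.
    """

    sequence: str
    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        n = len(self.sequence)
        if not (len(self.phi) == len(self.psi) == len(self.omega) == n):
            raise ValueError("sequence and angle arrays must have equal length")
        if any(aa not in AMINO_ACIDS for aa in self.sequence):
            raise ValueError("sequence contains a nonstandard type")

    def __len__(self) -> int:
        return len(self.sequence)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d given the a-b-c chain: |cd| = bond, angle(b,c,d) and
    dihedral(a,b,c,d) as requested (NeRF construction)."""
    theta = math.radians(angle_deg)
    chi = math.radians(torsion_deg)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(chi),
        bond * math.sin(theta) * math.sin(chi),
    ])
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc_hat)
    n_hat = n / np.linalg.norm(n)
    m = np.column_stack([bc_hat, np.cross(n_hat, bc_hat), n_hat])
    return c + m @ d_local


def build_backbone(spec: DihedralSpec, id: str = "synthetic") -> MainChainStructure:
    """Construct N/CA/C coordinates realizing a dihedral specification.

    Recomputing φ/ψ/ω from the result recovers the spec to well under
    1e-6 degrees at every defined position.
    """
    n_res = len(spec)
    coords = np.empty((n_res, 3, 3))  # residue, (N, CA, C), xyz
    # first residue laid out in the z = 0 plane
    theta = math.radians(ANGLE_N_CA_C)
    coords[0, 0] = (0.0, 0.0, 0.0)
    coords[0, 1] = (BOND_N_CA, 0.0, 0.0)
    coords[0, 2] = coords[0, 1] + BOND_CA_C * np.array(
        [-math.cos(theta), math.sin(theta), 0.0])
    for k in range(1, n_res):
        n_prev, ca_prev, c_prev = coords[k - 1]
        n_k = place_atom(n_prev, ca_prev, c_prev,
                         BOND_C_N, ANGLE_CA_C_N, spec.psi[k - 1])
        ca_k = place_atom(ca_prev, c_prev, n_k,
                          BOND_N_CA, ANGLE_C_N_CA, spec.omega[k - 1])
        c_k = place_atom(c_prev, n_k, ca_k,
                         BOND_CA_C, ANGLE_N_CA_C, spec.phi[k])
        coords[k] = (n_k, ca_k, c_k)
    residues = [Residue(index=k, aa=spec.sequence[k], n=coords[k, 0],
                        ca=coords[k, 1], c=coords[k, 2], seq_num=k + 1)
                for k in range(n_res)]
    return MainChainStructure(id=id, residues=residues)


def extract_dihedrals(s: MainChainStructure) -> DihedralSpec:
    """Recover (φ, ψ, ω) from coordinates; undefined end angles are 0."""
    n = len(s)
    phi = np.zeros(n)
    psi = np.zeros(n)
    omega = np.zeros(n)
    for k in range(n):
        r = s.residues[k]
        if k > 0:
            phi[k] = dihedral(s.residues[k - 1].c, r.n, r.ca, r.c)
        if k < n - 1:
            nxt = s.residues[k + 1]
            psi[k] = dihedral(r.n, r.ca, r.c, nxt.n)
            omega[k] = dihedral(r.ca, r.c, nxt.n, nxt.ca)
    return DihedralSpec(sequence=s.sequence, phi=phi, psi=psi, omega=omega)


def _random_sequence(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


def ideal_helix(n: int = 20, sequence: Optional[str] = None,
                id: str = "helix") -> MainChainStructure:
    """A canonical α-helix (φ = -57°, ψ = -47°, ω = 180°)."""
    seq = sequence or ("A" * n)
    spec = DihedralSpec(sequence=seq,
                        phi=np.full(len(seq), HELIX_PHI_PSI[0]),
                        psi=np.full(len(seq), HELIX_PHI_PSI[1]),
                        omega=np.full(len(seq), 180.0))
    return build_backbone(spec, id=id)


def make_decoys(native: MainChainStructure, n: int, sigma: float, seed: int,
                omega_sigma: float = 0.0, name: Optional[str] = None) -> DecoySet:
    """Perturbation decoys: Gaussian noise (sd ``sigma``, degrees) on the
    native's φ/ψ; ω untouched unless ``omega_sigma`` > 0.  RMSD labels
    are computed against the native; deterministic given ``seed``."""
    if n < 1:
        raise ValueError("need n >= 1 decoys")
    if sigma < 0 or omega_sigma < 0:
        raise ValueError("noise levels must be nonnegative")
    rng = np.random.default_rng(seed)
    base = extract_dihedrals(native)
    decoys = []
    for k in range(n):
        phi = base.phi + rng.normal(0.0, sigma, len(base))
        psi = base.psi + rng.normal(0.0, sigma, len(base))
        omega = base.omega + (rng.normal(0.0, omega_sigma, len(base))
                              if omega_sigma > 0 else 0.0)
        spec = DihedralSpec(sequence=base.sequence,
                            phi=_wrap(phi), psi=_wrap(psi), omega=_wrap(omega))
        decoys.append(build_backbone(spec, id=f"{native.id}_decoy{k:03d}"))
    return build_decoy_set(name or f"{native.id}_decoys", native, decoys)


def _wrap(angles: np.ndarray) -> np.ndarray:
    """Wrap degrees into (-180, 180]."""
    a = np.mod(np.asarray(angles, dtype=float) + 180.0, 360.0) - 180.0
    a[a == -180.0] = 180.0
    return a


def _segment_angles(kind: str, length: int, rng: np.random.Generator,
                    jitter: float) -> tuple[np.ndarray, np.ndarray]:
    if kind == "helix":
        center = HELIX_PHI_PSI
    elif kind == "strand":
        center = STRAND_PHI_PSI
    else:
        weights = np.array([b[2] for b in COIL_BASINS])
        phi = np.empty(length)
        psi = np.empty(length)
        for t in range(length):
            b = COIL_BASINS[rng.choice(len(COIL_BASINS), p=weights / weights.sum())]
            phi[t] = rng.normal(b[0], b[3])
            psi[t] = rng.normal(b[1], b[3])
        return _wrap(phi), _wrap(psi)
    phi = rng.normal(center[0], jitter, length)
    psi = rng.normal(center[1], jitter, length)
    return _wrap(phi), _wrap(psi)


_SEGMENT_LENGTHS = {"helix": (8, 18), "strand": (4, 10), "coil": (2, 6)}


def make_training_corpus(n_structures: int,
                         length_range: tuple[int, int] = (30, 80),
                         mixture: dict[str, float] = None,
                         seed: int = 0,
                         jitter: float = 3.0) -> list[MainChainStructure]:
    """Reproducible corpus of mixed secondary-structure chains.

    ``mixture`` weights the helix/strand/coil content (default 50/25/25);
    φ/ψ within segments get Gaussian jitter (sd ``jitter`` degrees) and
    coil draws from the declared Ramachandran-like basin mixture.  ω is
    always the planar 180°.
    """
    if n_structures < 1:
        raise ValueError("need n_structures >= 1")
    mixture = mixture or {"helix": 0.5, "strand": 0.25, "coil": 0.25}
    kinds = [k for k in ("helix", "strand", "coil") if mixture.get(k, 0) > 0]
    weights = np.array([mixture[k] for k in kinds], dtype=float)
    weights /= weights.sum()
    rng = np.random.default_rng(seed)
    corpus = []
    for si in range(n_structures):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        phi = np.empty(0)
        psi = np.empty(0)
        while len(phi) < length:
            kind = kinds[rng.choice(len(kinds), p=weights)]
            lo, hi = _SEGMENT_LENGTHS[kind]
            seg_len = min(int(rng.integers(lo, hi + 1)), length - len(phi))
            sp, ss = _segment_angles(kind, seg_len, rng, jitter)
            phi = np.concatenate([phi, sp])
            psi = np.concatenate([psi, ss])
        spec = DihedralSpec(sequence=_random_sequence(length, rng),
                            phi=phi, psi=psi, omega=np.full(length, 180.0))
        corpus.append(build_backbone(spec, id=f"synth{si:04d}"))
    return corpus
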