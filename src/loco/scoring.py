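"""Structure scoring with a compiled potential, plus the ω-angle baseline.

Lower totals are more native-like.  Every unordered residue pair
contributes two lookups, one from each residue's local frame, exactly
mirroring how observations were counted during training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .potential import (LoCoParams, PotentialDatabase, eligibility_mask,
                        iter_observations, lookup)
from .errors import DatabaseError
from .frames import BIN_CONVENTION_ID, dihedral
from .structures import MainChainStructure

logger = logging.getLogger(__name__)

#: Half-width (degrees) of the window around 180° inside which an ω
#: angle counts toward the baseline discriminator's standard deviation.
OMEGA_WINDOW = 15.0


@dataclass
class ScoreReport:
    """Total and per-observing-residue scores for one structure."""

    structure_id: str
    total: float
    per_residue: list[float]
    n_interactions: int


def eligible_partners(s: MainChainStructure, u: int, params: LoCoParams) -> list[int]:
    """Partner indices of observer u: within cutoff, beyond the excluded
    sequence neighbors."""
    if not 0 <= u < len(s):
        raise IndexError(f"residue index {u} out of range")
    if len(s) < 2:
        return []
    return np.nonzero(eligibility_mask(s, params)[u])[0].tolist()


def score_structure(db: PotentialDatabase, s: MainChainStructure) -> ScoreReport:
    """Sum the potential over all observer→partner interactions of s."""
    if db.params.bin_convention != BIN_CONVENTION_ID:
        raise DatabaseError(
            f"database bin convention {db.params.bin_convention!r} does not "
            f"match this build ({BIN_CONVENTION_ID!r})")
    per_residue = [0.0] * len(s)
    n_inter = 0
    if len(s) < 2:
        logger.warning("%s: fewer than 2 residues; score is trivially 0", s.id)
        return ScoreReport(s.id, 0.0, per_residue, 0)
    aa = [r.aa_index for r in s.residues]
    for u, partners, bins in iter_observations(s, db.params):
        acc = 0.0
        for v, b in zip(partners, bins):
            acc += lookup(db, aa[u], aa[v], (int(b[0]), int(b[1]), int(b[2])))
            n_inter += 1
        per_residue[u] = acc
    return ScoreReport(s.id, float(sum(per_residue)), per_residue, n_inter)


def score_report_tsv(reports: list[ScoreReport]) -> str:
    lines = ["structure_id\ttotal_score\tn_residues\tn_interactions"]
    for r in reports:
        lines.append(f"{r.structure_id}\t{r.total:.6f}\t{len(r.per_residue)}"
                     f"\t{r.n_interactions}")
    return "\n".join(lines) + "\n"


def omega_angles(s: MainChainStructure) -> list[float]:
    """Peptide ω dihedrals CA(k)-C(k)-N(k+1)-CA(k+1), degrees, one per
    consecutive bonded residue pair (pairs across chain breaks skipped)."""
    out = []
    for k in range(len(s) - 1):
        if k in s.breaks:
            continue
        a, b = s.residues[k], s.residues[k + 1]
        out.append(dihedral(a.ca, a.c, b.n, b.ca))
    return out


def _unwrap_around_180(angle: float) -> float:
    """Map an angle in (-180, 180] to its equivalent nearest 180°."""
    return angle + 360.0 if angle < 0 else angle


def omega_sd(s: MainChainStructure, window: float = OMEGA_WINDOW) -> float:
    """Sample SD of the near-planar ω angles (within ``window`` of 180°).

    Angles are unwrapped around 180° before the SD so that e.g. -178°
    and 178° are 4° apart.  Returns NaN when fewer than two ω qualify
    (the sample SD is then undefined).
    """
    unwrapped = [_unwrap_around_180(w) for w in omega_angles(s)]
    qualifying = [w for w in unwrapped if abs(w - 180.0) <= window]
    if len(qualifying) < 2:
        return float("nan")
    return float(np.std(qualifying, ddof=1))


def omega_set_scores(structures: list[MainChainStructure],
                     window: float = OMEGA_WINDOW) -> dict[str, float]:
    """Set-relative ω discriminator: |own σ − mean σ over the set|.

    σ is each structure's near-planar ω standard deviation; structures
    with undefined σ are excluded from the mean and scored NaN.  Larger
    scores flag main chains whose ω spread is atypical for the set;
    ranking direction is chosen by the caller (descending by default in
    the evaluation drivers).
    """
    if len(structures) < 2:
        raise ValueError("omega_set_scores needs at least 2 structures")
    sds = {s.id: omega_sd(s, window) for s in structures}
    defined = [v for v in sds.values() if not np.isnan(v)]
    if not defined:
        raise ValueError("no structure has enough qualifying omega angles")
    mean_sd = float(np.mean(defined))
    return {sid: (abs(v - mean_sd) if not np.isnan(v) else float("nan"))
            for sid, v in sds.items()}
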