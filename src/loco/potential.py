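"""Training and compilation of the local-coordinates interaction potential.

Observation counting walks every ordered (observer, partner) pair of a
training corpus: a partner is eligible when its CA lies within the
cutoff distance of the observer's CA and the two residues are separated
along the chain by more than ``exclude_neighbors`` positions (each
unordered pair is therefore counted twice, once from each residue's
frame).  Counts per (observer type, partner type, bin) are converted to
Boltzmann log-odds scores

    score(i, j, b) = -ln( j_obs(i, j, b) / j_exp(b) )

against a reference state j_exp(b) equal to the mean count over all
20 x 20 = 400 ordered type pairs at that bin (zero-count pairs
included in the mean).  Bin/pair combinations never observed in
training are charged a per-pair penalty equal to ``penalty_mult`` times
the worst (most positive) observed score for that type pair.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .errors import BinRangeError, DatabaseError, DegenerateGeometryError, LocoError
from .frames import BIN_CONVENTION_ID, assign_bins, build_frame, to_local
from .structures import AMINO_ACIDS, MainChainStructure

logger = logging.getLogger(__name__)

N_TYPES = len(AMINO_ACIDS)
#: Ordered amino-acid type pairs: the reference-state denominator.
N_TYPE_PAIRS = N_TYPES * N_TYPES

FORMAT_VERSION = 1

BinKey = tuple[int, int, int]
ScoreKey = tuple[int, int, int, int, int]  # (i_type, j_type, bx, by, bz)


@dataclass(frozen=True)
class LoCoParams:
    """The three interaction parameters plus the bin-convention stamp.

    Defaults are the cross-validated optimum: 14Å cutoff, one excluded
    sequence neighbor per side, 3x zero-count penalty.
    """

    cutoff: float = 14.0
    exclude_neighbors: int = 1
    penalty_mult: float = 3.0
    bin_convention: str = BIN_CONVENTION_ID

    def __post_init__(self):
        if not (self.cutoff > 0 and math.isfinite(self.cutoff)):
            raise ValueError("cutoff must be positive and finite")
        if self.exclude_neighbors < 0:
            raise ValueError("exclude_neighbors must be >= 0")
        if not self.penalty_mult > 0:
            raise ValueError("penalty_mult must be positive")

    def to_dict(self) -> dict:
        return {"cutoff": self.cutoff, "exclude_neighbors": self.exclude_neighbors,
                "penalty_mult": self.penalty_mult, "bin_convention": self.bin_convention}

    @classmethod
    def from_dict(cls, d: dict) -> "LoCoParams":
        return cls(cutoff=d["cutoff"], exclude_neighbors=d["exclude_neighbors"],
                   penalty_mult=d["penalty_mult"], bin_convention=d["bin_convention"])


def eligibility_mask(s: MainChainStructure, params: LoCoParams,
                     dist: Optional[np.ndarray] = None) -> np.ndarray:
    """Boolean (n, n) mask: entry [u, v] is True when v may partner u.

    Eligibility: CA-CA distance <= cutoff and chain separation (author
    residue-number difference) > exclude_neighbors.  Residues flanking a
    numbering gap are thus not excluded as sequence neighbors.
    """
    if dist is None:
        ca = s.ca_coords()
        dist = squareform(pdist(ca)) if len(s) > 1 else np.zeros((len(s), len(s)))
    nums = s.seq_nums()
    sep = np.abs(nums[:, None] - nums[None, :])
    mask = (dist <= params.cutoff) & (sep > params.exclude_neighbors)
    np.fill_diagonal(mask, False)
    return mask


def iter_observations(s: MainChainStructure, params: LoCoParams):
    """Yield (observer index, partner indices, partner bins) per observer.

    Observers with degenerate N/CA/C geometry are skipped (logged); they
    still appear as partners of other residues.
    """
    n = len(s)
    if n < 2:
        return
    ca = s.ca_coords()
    mask = eligibility_mask(s, params)
    for u in range(n):
        partners = np.nonzero(mask[u])[0]
        if partners.size == 0:
            continue
        try:
            frame = build_frame(s.residues[u])
        except DegenerateGeometryError:
            logger.warning("%s: residue %d has a degenerate frame; "
                           "skipped as observer", s.id, u)
            continue
        local = to_local(frame, ca[partners])
        yield u, partners, assign_bins(local)


@dataclass
class CountTable:
    """Sparse per-(i_type, j_type, bin) observation counts."""

    counts: dict[ScoreKey, int]
    totals_per_bin: dict[BinKey, int]
    params: LoCoParams
    n_structures: int = 0
    n_observations: int = 0


def accumulate_counts(corpus: Iterable[MainChainStructure],
                      params: Optional[LoCoParams] = None) -> CountTable:
    """Count all eligible observer→partner observations over a corpus."""
    params = params or LoCoParams()
    counts: dict[ScoreKey, int] = {}
    totals: dict[BinKey, int] = {}
    n_structures = 0
    n_obs = 0
    for s in corpus:
        n_structures += 1
        aa_idx = [r.aa_index for r in s.residues]
        for u, partners, bins in iter_observations(s, params):
            i = aa_idx[u]
            for v, b in zip(partners, bins):
                key = (i, aa_idx[v], int(b[0]), int(b[1]), int(b[2]))
                counts[key] = counts.get(key, 0) + 1
                bkey = key[2:]
                totals[bkey] = totals.get(bkey, 0) + 1
                n_obs += 1
    if n_structures == 0:
        raise LocoError("empty training corpus")
    return CountTable(counts=counts, totals_per_bin=totals, params=params,
                      n_structures=n_structures, n_observations=n_obs)


def reference_state(counts: CountTable) -> dict[BinKey, float]:
    """Expected count per bin: the mean over all 400 ordered type pairs."""
    return {b: t / N_TYPE_PAIRS for b, t in counts.totals_per_bin.items()}


@dataclass
class PotentialDatabase:
    """Compiled sparse scores plus the dense per-type-pair penalty table."""

    scores: dict[ScoreKey, float]
    penalty: np.ndarray  # (20, 20)
    params: LoCoParams
    provenance: str = ""

    def max_bin_component(self) -> int:
        return int(math.ceil(self.params.cutoff))


def compile_potential(counts: CountTable, provenance: str = "") -> PotentialDatabase:
    """Turn a count table into log-odds scores and zero-count penalties."""
    if counts.n_observations == 0:
        raise LocoError("count table has zero total observations")
    j_exp = reference_state(counts)
    scores: dict[ScoreKey, float] = {}
    worst = np.full((N_TYPES, N_TYPES), -np.inf)
    for key, c in counts.counts.items():
        s = -math.log(c / j_exp[key[2:]])
        scores[key] = s
        i, j = key[0], key[1]
        if s > worst[i, j]:
            worst[i, j] = s
    observed_worst = worst[np.isfinite(worst)]
    positive_worst = observed_worst[observed_worst > 0]
    # global fallback: worst positive score anywhere; ln(400) covers the
    # degenerate corpus in which no bin ever scores unfavorably
    global_base = float(positive_worst.max()) if positive_worst.size else math.log(N_TYPE_PAIRS)
    base = np.where(np.isfinite(worst) & (worst > 0), worst, global_base)
    penalty = counts.params.penalty_mult * base
    return PotentialDatabase(scores=scores, penalty=penalty,
                             params=counts.params, provenance=provenance)


def lookup(db: PotentialDatabase, i_type: str, j_type: str, bin: BinKey) -> float:
    """Score of (observer type, partner type, bin); penalty when unseen.

    Requesting any bin component beyond ceil(cutoff) is a contract
    violation (the scorer's distance gate makes it unreachable).
    """
    i = AMINO_ACIDS.index(i_type) if isinstance(i_type, str) else i_type
    j = AMINO_ACIDS.index(j_type) if isinstance(j_type, str) else j_type
    limit = db.max_bin_component()
    if any(c == 0 or abs(c) > limit for c in bin):
        raise BinRangeError(f"bin {bin} outside cutoff range (|component| <= {limit})")
    return db.scores.get((i, j, bin[0], bin[1], bin[2]),
                         float(db.penalty[i, j]))


def _payload_dict(db: PotentialDatabase) -> dict:
    records = [[k[0], k[1], k[2], k[3], k[4], v]
               for k, v in sorted(db.scores.items())]
    return {"penalty": db.penalty.tolist(), "scores": records}


def _checksum(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return "sha256:" + hashlib.sha256(blob.encode()).hexdigest()


def serialize_db(db: PotentialDatabase) -> bytes:
    """Lossless serialization: JSON header + checksummed sparse records.

    JSON float text uses repr, which round-trips every IEEE double
    bit-exactly.
    """
    payload = _payload_dict(db)
    doc = {
        "format": "loco-potential",
        "format_version": FORMAT_VERSION,
        "header": {
            "bin_convention": db.params.bin_convention,
            "params": db.params.to_dict(),
            "provenance": db.provenance,
            "alphabet": AMINO_ACIDS,
            "n_scores": len(db.scores),
        },
        "checksum": _checksum(payload),
        **payload,
    }
    return json.dumps(doc).encode()


def read_db(data: bytes) -> PotentialDatabase:
    """Inverse of :func:`serialize_db`, with version and integrity checks."""
    try:
        doc = json.loads(data.decode())
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise DatabaseError(f"unreadable database payload: {exc}") from None
    if doc.get("format") != "loco-potential":
        raise DatabaseError("not a loco potential database")
    version = doc.get("format_version")
    if version != FORMAT_VERSION:
        raise DatabaseError(f"unsupported database format version {version!r} "
                            f"(this build reads version {FORMAT_VERSION})")
    payload = {"penalty": doc["penalty"], "scores": doc["scores"]}
    if _checksum(payload) != doc.get("checksum"):
        raise DatabaseError("checksum mismatch: database is corrupt or truncated")
    header = doc["header"]
    params = LoCoParams.from_dict(header["params"])
    scores = {(r[0], r[1], r[2], r[3], r[4]): float(r[5]) for r in doc["scores"]}
    return PotentialDatabase(scores=scores,
                             penalty=np.array(doc["penalty"], dtype=float),
                             params=params, provenance=header.get("provenance", ""))


def save_db(db: PotentialDatabase, path: str | os.PathLike) -> None:
    Path(path).write_bytes(serialize_db(db))


def load_db(path: str | os.PathLike) -> PotentialDatabase:
    return read_db(Path(path).read_bytes())


def export_tsv(db: PotentialDatabase) -> str:
    """Inspection-friendly lossless TSV of the sparse score records."""
    lines = ["i\tj\tbx\tby\tbz\tscore"]
    for (i, j, bx, by, bz), s in sorted(db.scores.items()):
        lines.append(f"{AMINO_ACIDS[i]}\t{AMINO_ACIDS[j]}\t{bx}\t{by}\t{bz}\t{s!r}")
    return "\n".join(lines) + "\n"
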