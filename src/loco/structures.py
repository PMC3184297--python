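"""Main-chain structure model and PDB input/output.

A :class:`MainChainStructure` is the ordered list of residues of one
polypeptide chain, each carrying the N, CA and C coordinates that the
local-coordinate scoring machinery needs (CB is parsed when present but
never scored).  Parsing is delegated to gemmi for the PDB format
mechanics; on top of that this module resolves altlocs by occupancy,
maps modified residues to their standard parents, drops residues with
incomplete main chains, and records chain breaks.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

from .errors import (
    EmptySetError,
    EmptyStructureError,
    FormatError,
    SequenceMismatchError,
)

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid types, one-letter codes in alphabetical order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX = {aa: k for k, aa in enumerate(AMINO_ACIDS)}

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass(frozen=True)
class Residue:
    """One residue of a main chain.

    Coordinates are in Å, kept exactly as read.  ``seq_num`` is the
    author residue number from the source file; it drives the
    sequence-neighbor exclusion rule (a numbering gap means the two
    flanking residues are not treated as peptide-bonded neighbors).
    """

    index: int
    aa: str
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    cb: Optional[np.ndarray] = None
    seq_num: int = 0

    def __post_init__(self):
        if self.aa not in AA_INDEX:
            raise ValueError(f"not a standard amino acid type: {self.aa!r}")
        for name in ("n", "ca", "c"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be a finite 3-vector")
            object.__setattr__(self, name, v)
        if self.cb is not None:
            object.__setattr__(self, "cb", np.asarray(self.cb, dtype=float))

    @property
    def aa_index(self) -> int:
        return AA_INDEX[self.aa]


@dataclass
class MainChainStructure:
    """Ordered residues of a single chain with N/CA/C coordinates.

    ``breaks`` holds indices ``i`` such that a chain break (missing
    residues or a dropped incomplete residue) lies between
    ``residues[i]`` and ``residues[i + 1]``.
    """

    id: str
    residues: list[Residue]
    source_path: Optional[str] = None
    breaks: frozenset[int] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        """(n, 3) array of CA positions in chain order."""
        return np.array([r.ca for r in self.residues], dtype=float)

    def seq_nums(self) -> np.ndarray:
        return np.array([r.seq_num for r in self.residues], dtype=int)

    def is_consecutive(self, i: int, j: int) -> bool:
        """True if residues i and j (adjacent in the list) are peptide-bonded."""
        return abs(i - j) == 1 and min(i, j) not in self.breaks


def _read_modres(pdb_text: str) -> dict[str, str]:
    """Map modified residue names to standard parents from MODRES records."""
    mapping: dict[str, str] = {}
    for line in pdb_text.splitlines():
        if line.startswith("MODRES") and len(line) >= 27:
            het = line[12:15].strip()
            std = line[24:27].strip()
            if het and std in THREE_TO_ONE:
                mapping[het] = std
    return mapping


def _map_residue_type(name: str, modres: dict[str, str]) -> Optional[str]:
    """One-letter type for a residue name, or None if unmappable."""
    if name in THREE_TO_ONE:
        return THREE_TO_ONE[name]
    if name in modres:
        return THREE_TO_ONE[modres[name]]
    info = gemmi.find_tabulated_residue(name)
    if info is not None and info.is_amino_acid():
        one = info.one_letter_code.upper()
        if one in AA_INDEX:
            return one
    return None


def _pick_atom(res: gemmi.Residue, name: str) -> Optional[np.ndarray]:
    # altloc policy: highest occupancy wins, ties go to the first listed
    best = None
    best_occ = -1.0
    for atom in res:
        if atom.name == name and atom.occ > best_occ:
            best, best_occ = atom, atom.occ
    if best is None:
        return None
    return np.array([best.pos.x, best.pos.y, best.pos.z], dtype=float)


def parse_mainchain(
    pdb_text: str,
    id: str,
    chain_id: Optional[str] = None,
    source_path: Optional[str] = None,
) -> MainChainStructure:
    """Parse one chain of PDB text into a :class:`MainChainStructure`.

    Only the first MODEL is read.  The first chain is used unless
    ``chain_id`` selects another.  Residues missing any of N/CA/C (or
    with unmappable types) are dropped with a warning and a chain break
    is recorded between their neighbors.
    """
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{id}: unparsable PDB text: {exc}") from None
    if len(st) == 0 or all(len(ch) == 0 for ch in st[0]):
        raise FormatError(f"{id}: no ATOM records found")

    model = st[0]
    chain = None
    if chain_id is None:
        chain = model[0]
    else:
        for ch in model:
            if ch.name == chain_id:
                chain = ch
                break
        if chain is None:
            raise FormatError(f"{id}: chain {chain_id!r} not present")

    modres = _read_modres(pdb_text)
    residues: list[Residue] = []
    breaks: set[int] = set()
    pending_break = False
    prev_seq_num: Optional[int] = None
    for gres in chain:
        if gres.is_water():
            continue
        aa = _map_residue_type(gres.name, modres)
        n = _pick_atom(gres, "N")
        ca = _pick_atom(gres, "CA")
        c = _pick_atom(gres, "C")
        if aa is None or n is None or ca is None or c is None:
            reason = "no standard-type mapping" if aa is None else "incomplete main chain"
            if ca is not None or n is not None or c is not None or aa is not None:
                logger.warning("%s: dropping residue %s %d (%s)", id, gres.name,
                               gres.seqid.num, reason)
                pending_break = bool(residues)
            continue
        # guard against degenerate bond geometry slipping through
        if np.linalg.norm(n - ca) <= 0 or np.linalg.norm(ca - c) <= 0:
            logger.warning("%s: dropping residue %s %d (zero-length bond)", id,
                           gres.name, gres.seqid.num)
            pending_break = bool(residues)
            continue
        seq_num = gres.seqid.num
        if prev_seq_num is not None and seq_num - prev_seq_num != 1:
            pending_break = True
        if pending_break and residues:
            breaks.add(len(residues) - 1)
        residues.append(Residue(index=len(residues), aa=aa, n=n, ca=ca, c=c,
                                cb=_pick_atom(gres, "CB"), seq_num=seq_num))
        prev_seq_num = seq_num
        pending_break = False

    if not residues:
        raise EmptyStructureError(f"{id}: no residues with complete main chains")
    return MainChainStructure(id=id, residues=residues,
                              source_path=source_path, breaks=frozenset(breaks))


def parse_mainchain_file(path: str | os.PathLike, id: Optional[str] = None,
                         chain_id: Optional[str] = None) -> MainChainStructure:
    path = Path(path)
    return parse_mainchain(path.read_text(), id=id or path.stem,
                           chain_id=chain_id, source_path=str(path))


def write_pdb(structure: MainChainStructure) -> str:
    """Render a structure as PDB ATOM records (N, CA, C and any CB)."""
    lines = []
    serial = 1
    for res in structure.residues:
        res3 = ONE_TO_THREE[res.aa]
        atoms = [("N", res.n, "N"), ("CA", res.ca, "C"), ("C", res.c, "C")]
        if res.cb is not None:
            atoms.append(("CB", res.cb, "C"))
        for name, xyz, element in atoms:
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s}{res3:>4s} A{res.seq_num:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_pdb_file(structure: MainChainStructure, path: str | os.PathLike) -> None:
    Path(path).write_text(write_pdb(structure))


@dataclass
class DecoySet:
    """A native structure plus decoy conformations of the same sequence.

    ``rmsd_to_native`` caches the optimal-superposition CA RMSD of every
    member (the native maps to 0).  ``rejections`` lists inputs that
    failed the identical-sequence invariant.
    """

    name: str
    native: MainChainStructure
    decoys: list[MainChainStructure]
    rmsd_to_native: dict[str, float]
    rejections: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_decoys(self) -> int:
        return len(self.decoys)

    def decoy_rmsds(self) -> np.ndarray:
        return np.array([self.rmsd_to_native[d.id] for d in self.decoys])


def build_decoy_set(name: str, native: MainChainStructure,
                    decoys: Iterable[MainChainStructure]) -> DecoySet:
    """Assemble a DecoySet from parsed structures, enforcing invariants."""
    from .frames import ca_rmsd  # local import: frames depends on nothing here

    accepted: list[MainChainStructure] = []
    rejections: list[tuple[str, str]] = []
    rmsds: dict[str, float] = {native.id: 0.0}
    for s in decoys:
        if s.sequence != native.sequence:
            logger.warning("decoy set %s: rejecting %s (sequence mismatch)", name, s.id)
            rejections.append((s.id, "sequence mismatch"))
            continue
        rmsds[s.id] = ca_rmsd(native, s)
        accepted.append(s)
    if not accepted:
        raise EmptySetError(f"decoy set {name}: no accepted decoys")
    return DecoySet(name=name, native=native, decoys=accepted,
                    rmsd_to_native=rmsds, rejections=rejections)


def load_decoy_set(native_path: str | os.PathLike,
                   decoy_dir: str | os.PathLike,
                   name: Optional[str] = None) -> DecoySet:
    """Load ``native.pdb`` plus every decoy file in a directory.

    Files that fail to parse or whose sequence differs from the native
    are rejected (listed in the returned set's ``rejections``).
    """
    native_path = Path(native_path)
    decoy_dir = Path(decoy_dir)
    native = parse_mainchain_file(native_path)
    decoys = []
    rejections = []
    for p in sorted(decoy_dir.iterdir()):
        if not p.is_file() or p.resolve() == native_path.resolve():
            continue
        if p.suffix.lower() not in {".pdb", ".ent"}:
            continue
        try:
            decoys.append(parse_mainchain_file(p))
        except (FormatError, EmptyStructureError) as exc:
            logger.warning("decoy set: rejecting %s (%s)", p.name, exc)
            rejections.append((str(p), str(exc)))
    dset = build_decoy_set(name or decoy_dir.name, native, decoys)
    dset.rejections = rejections + dset.rejections
    return dset


def load_decoy_manifest(manifest_path: str | os.PathLike,
                        name: Optional[str] = None) -> DecoySet:
    """Load a decoy set from a TSV manifest with columns ``path<TAB>role``.

    Exactly one row must have role ``native``; all others are decoys.
    Relative paths resolve against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    native = None
    decoy_paths: list[Path] = []
    for line in manifest_path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        path_str, role = line.split("\t")[:2]
        p = base / path_str
        if role.strip().lower() == "native":
            if native is not None:
                raise FormatError(f"{manifest_path}: multiple native rows")
            native = p
        else:
            decoy_paths.append(p)
    if native is None:
        raise FormatError(f"{manifest_path}: no native row")
    decoys = [parse_mainchain_file(p) for p in decoy_paths]
    return build_decoy_set(name or manifest_path.stem,
                           parse_mainchain_file(native), decoys)
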