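"""Single-chain Cα models with per-residue confidence.

Predicted protein models (AlphaFold-style) store the per-residue pLDDT
confidence in the temperature-factor column of PDB ``ATOM`` records.  This
module reads such files down to an ordered Cα trace, computes the mean
confidence of a chain, and applies the strict ``mean pLDDT > threshold``
retention filter used to discard low-confidence predictions before any
pairwise structural comparison.

Only Cα atoms are kept: all downstream geometry (superposition, TM-score)
operates on Cα traces, so other atoms are ignored on read.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# Plausible band for consecutive Calpha-Calpha distances (trans peptide ~3.8 A).
_CA_CA_MIN = 2.0
_CA_CA_MAX = 4.5


class PDBParseError(ValueError):
    """Raised when a PDB text cannot be reduced to a Cα trace."""


@dataclass(frozen=True)
class Residue:
    """One residue of a Cα trace.

    Parameters
    ----------
    index : int
        Residue sequence number (1-based within the chain, strictly
        increasing along the trace).
    name : str
        Three-letter residue code (e.g. ``ALA``).
    coord : numpy.ndarray
        Cα position in Å, shape ``(3,)``.
    plddt : float
        Per-residue confidence in ``[0, 100]``.
    """

    index: int
    name: str
    coord: np.ndarray
    plddt: float

    def __post_init__(self) -> None:
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError(f"residue {self.index}: coord must be a finite 3-vector")
        object.__setattr__(self, "coord", coord)
        if not (0.0 <= self.plddt <= 100.0):
            raise ValueError(f"residue {self.index}: plddt {self.plddt} outside [0, 100]")


class ProteinStructure:
    """An ordered Cα trace for one chain; the unit of pairwise comparison."""

    def __init__(self, id: str, residues: Sequence[Residue]):
        residues = list(residues)
        if not residues:
            raise ValueError(f"structure {id!r}: needs at least one residue")
        indices = [r.index for r in residues]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError(f"structure {id!r}: residue indices must be strictly increasing")
        self.id = id
        self.residues = residues
        self._coords = np.array([r.coord for r in residues], dtype=float)
        self._plddt = np.array([r.plddt for r in residues], dtype=float)
        self._warn_bond_lengths()

    def _warn_bond_lengths(self) -> None:
        if len(self.residues) < 2:
            return
        d = np.linalg.norm(np.diff(self._coords, axis=0), axis=1)
        bad = (d <= _CA_CA_MIN) | (d >= _CA_CA_MAX)
        if np.any(bad):
            i = int(np.argmax(bad))
            logger.warning(
                "structure %s: %d consecutive Ca-Ca distances outside (%.1f, %.1f) A "
                "(first at residue pair %d-%d: %.2f A)",
                self.id, int(bad.sum()), _CA_CA_MIN, _CA_CA_MAX,
                self.residues[i].index, self.residues[i + 1].index, d[i],
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        """Cα coordinates, shape ``(L, 3)`` (copy-safe view)."""
        return self._coords

    @property
    def plddt(self) -> np.ndarray:
        """Per-residue confidences, shape ``(L,)``."""
        return self._plddt

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ProteinStructure(id={self.id!r}, L={self.length})"


@dataclass
class StructureSet:
    """A collection of structures with optional subfamily labels."""

    structures: list[ProteinStructure]
    labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        ids = [s.id for s in self.structures]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate structure ids: {dupes}")

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.structures]

    def __len__(self) -> int:
        return len(self.structures)

    def __iter__(self):
        return iter(self.structures)

    def get(self, id: str) -> ProteinStructure:
        for s in self.structures:
            if s.id == id:
                return s
        raise KeyError(id)


def _parse_atom_line(line: str) -> tuple[str, str, str, int, float, float, float, float, float]:
    """Parse one ATOM record → (atom, altloc, resname, resseq, x, y, z, occ, b).

    Tries the wwPDB v3.3 fixed-width layout first and falls back to a
    whitespace-separated dialect (ATOM serial name resname chain resseq
    x y z occ b) for minimal writers.
    """
    try:
        atom = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip()
        resseq = int(line[22:26])
        x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
        occ = float(line[54:60]) if line[54:60].strip() else 1.0
        b = float(line[60:66]) if len(line) >= 66 and line[60:66].strip() else 0.0
        return atom, altloc, resname, chain, resseq, x, y, z, occ, b
    except (ValueError, IndexError):
        pass
    tok = line.split()
    if len(tok) < 9:
        raise PDBParseError(f"unparseable ATOM record: {line!r}")
    try:
        resseq = int(tok[5])
        x, y, z = float(tok[6]), float(tok[7]), float(tok[8])
        occ = float(tok[9]) if len(tok) > 9 else 1.0
        b = float(tok[10]) if len(tok) > 10 else 0.0
    except ValueError as exc:
        raise PDBParseError(f"unparseable ATOM record: {line!r}") from exc
    return tok[2], "", tok[3], tok[4], resseq, x, y, z, occ, b


def parse_structure(pdb_text: str, id: str = "structure", chain: str | None = None) -> ProteinStructure:
    """Read a single-chain Cα trace from PDB text.

    Confidence is taken from the temperature-factor column.  If every
    confidence on the chain is ≤ 1.0 the values are assumed to be on a
    0–1 scale and rescaled ×100 (with a logged warning).  Alternate
    locations are resolved to the highest occupancy, ties to the first
    occurrence.  Only the requested chain is read; without a ``chain``
    argument the first chain encountered is used (logged if the file has
    more than one).
    """
    chains_seen: list[str] = []
    # resseq -> (altloc, occ, order, Residue fields)
    picked: dict[int, tuple[str, float, int, str, tuple[float, float, float]]] = {}
    selected_chain: str | None = chain
    order = 0
    for line in pdb_text.splitlines():
        if not line.startswith("ATOM"):
            continue
        atom, altloc, resname, ch, resseq, x, y, z, occ, b = _parse_atom_line(line)
        if ch not in chains_seen:
            chains_seen.append(ch)
        if atom != "CA":
            continue
        if selected_chain is None:
            selected_chain = ch
        if ch != selected_chain:
            continue
        order += 1
        if resseq in picked:
            prev_altloc, prev_occ, prev_order, *_ = picked[resseq]
            if altloc == prev_altloc:
                raise PDBParseError(
                    f"{id}: duplicate CA for residue {resseq} with identical altloc {altloc!r}"
                )
            if occ > prev_occ:
                picked[resseq] = (altloc, occ, prev_order, resname, (x, y, z, b))
            continue
        picked[resseq] = (altloc, occ, order, resname, (x, y, z, b))
    if not picked:
        raise PDBParseError(f"{id}: no CA atoms found" + (f" for chain {chain!r}" if chain else ""))
    if len(chains_seen) > 1 and chain is None:
        logger.info("structure %s: multiple chains %s; using first (%r)", id, chains_seen, selected_chain)

    entries = sorted(picked.items(), key=lambda kv: kv[1][2])  # file order
    bvals = np.array([e[1][4][3] for e in entries], dtype=float)
    if bvals.max() <= 1.0:
        logger.warning("structure %s: confidences <= 1.0; rescaling x100 (0-1 -> 0-100)", id)
        bvals = bvals * 100.0
    residues = [
        Residue(index=resseq, name=resname, coord=np.array(xyzb[:3]), plddt=float(bv))
        for (resseq, (_a, _o, _ord, resname, xyzb)), bv in zip(entries, bvals)
    ]
    residues.sort(key=lambda r: r.index)
    return ProteinStructure(id=id, residues=residues)


def read_structure_file(path: str | Path, chain: str | None = None) -> ProteinStructure:
    path = Path(path)
    return parse_structure(path.read_text(), id=path.stem, chain=chain)


def read_structure_dir(path: str | Path, pattern: str = "*.pdb", chain: str | None = None) -> StructureSet:
    """Read every PDB file in a directory into a StructureSet (sorted by id)."""
    path = Path(path)
    files = sorted(path.glob(pattern))
    if not files:
        raise FileNotFoundError(f"no {pattern} files in {path}")
    return StructureSet([read_structure_file(f, chain=chain) for f in files])


def mean_plddt(s: ProteinStructure) -> float:
    """Arithmetic mean of the per-residue confidences (all residues)."""
    return float(np.mean(s.plddt))


def filter_structures(
    structure_set: StructureSet, threshold: float = 80.0
) -> tuple[StructureSet, list[str]]:
    """Retain structures whose mean pLDDT is strictly greater than ``threshold``.

    Returns the kept set (input order preserved, labels restricted to the
    kept ids) and the list of removed ids.  A mean of exactly ``threshold``
    is removed: retention requires confidence *greater than* the cutoff.
    """
    kept, removed = [], []
    for s in structure_set:
        (kept if mean_plddt(s) > threshold else removed).append(s)
    labels = None
    if structure_set.labels is not None:
        labels = {s.id: structure_set.labels[s.id] for s in kept if s.id in structure_set.labels}
    return StructureSet(kept, labels=labels), [s.id for s in removed]


_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL", "X": "UNK",
}


def three_letter(aa: str) -> str:
    """One-letter amino-acid code → three-letter PDB residue name."""
    return _AA3.get(aa.upper(), "UNK")


def write_pdb(s: ProteinStructure, path: str | Path | None = None, chain: str = "A") -> str:
    """Serialize a Cα trace as fixed-width PDB ATOM records (pLDDT in B-factor)."""
    lines = []
    for serial, r in enumerate(s.residues, start=1):
        x, y, z = r.coord
        lines.append(
            f"ATOM  {serial:5d}  CA  {r.name:>3s} {chain}{r.index:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{r.plddt:6.2f}          "
            f"{'C':>2s}"
        )
    lines.append("TER")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
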