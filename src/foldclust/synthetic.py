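"""Synthetic protein-fold families with known ground truth.

Generates sets of single-chain Cα models organized into structural
families, mimicking what a structure-prediction run over a protein family
produces: per family a distinct template fold (ideal α-helices joined by
random-walk coils), per member a noised, rigidly displaced copy of the
template (optionally terminally truncated), simulated per-residue pLDDT
written into the B-factor field, and co-generated sequences whose family
assignment can be made deliberately *discordant* with structure by
swapping some members' sequences to another family's consensus.

Every downstream stage therefore has ground truth: the planted family
labels, the planted low-confidence members, and the planted
sequence-swapped ids.

All randomness flows from a single integer seed through numpy's PCG64
(``numpy.random.default_rng``) via spawned ``SeedSequence`` children, so
one spec + seed reproduces the dataset bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .structures import ProteinStructure, Residue, StructureSet, three_letter, write_pdb
from .tree_compare import SequenceRecord, write_fasta

# ideal alpha-helix Calpha geometry
_HELIX_RISE = 1.5  # Å per residue along the axis
_HELIX_RADIUS = 2.3  # Å
_HELIX_TWIST = math.radians(100.0)  # per residue
_STEP = 3.8  # Å, consecutive Calpha distance in coils and at joins
_CLASH = 3.0  # Å, minimal allowed non-bonded Calpha-Calpha distance
_MAX_RETRIES = 1000

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


class ClashError(RuntimeError):
    """Raised when clash-free segment placement fails within the retry budget."""


@dataclass(frozen=True)
class SyntheticFamilySpec:
    """Generative parameters for a synthetic structure family set.

    members_per_family may be a single count or one count per family
    (so totals like 82 = 17+17+16+16+16 are expressible).
    """

    n_families: int = 5
    members_per_family: int | tuple[int, ...] = 6
    length: int = 200
    sigma: float = 0.5  # coordinate noise, Å (sd per coordinate)
    indel_rate: float = 0.1  # per-member probability of a terminal truncation
    seq_mut_rate: float = 0.05  # per-site substitution probability within family
    swap_fraction: float = 0.0  # fraction of members given another family's sequence
    plddt_core: float = 90.0
    plddt_tail: float = 70.0
    low_confidence_members: int = 0  # members forced to mean pLDDT <= 80
    seed: int = 0

    def member_counts(self) -> tuple[int, ...]:
        if isinstance(self.members_per_family, int):
            counts = (self.members_per_family,) * self.n_families
        else:
            counts = tuple(self.members_per_family)
            if len(counts) != self.n_families:
                raise ValueError("members_per_family list must have one entry per family")
        if any(c < 1 for c in counts):
            raise ValueError("every family needs at least one member")
        return counts

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.length < 20:
            raise ValueError("need n_families >= 1 and length >= 20")
        for r in (self.indel_rate, self.seq_mut_rate, self.swap_fraction):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must be in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.low_confidence_members < 0:
            raise ValueError("low_confidence_members must be >= 0")
        self.member_counts()


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated structure set plus its planted ground truth."""

    structures: StructureSet
    sequences: list[SequenceRecord]
    labels: dict[str, str]
    swapped_ids: tuple[str, ...]
    low_confidence_ids: tuple[str, ...]
    spec: SyntheticFamilySpec


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalized random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _helix(length: int) -> np.ndarray:
    i = np.arange(length)
    theta = i * _HELIX_TWIST
    return np.stack(
        [_HELIX_RADIUS * np.cos(theta), _HELIX_RADIUS * np.sin(theta), _HELIX_RISE * i],
        axis=1,
    )


def _coil(length: int, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding random walk with 3.8 Å steps."""
    pts = [np.zeros(3)]
    for _ in range(length - 1):
        for attempt in range(_MAX_RETRIES):
            cand = pts[-1] + _STEP * _random_unit(rng)
            if len(pts) < 2:
                break
            d = np.linalg.norm(np.array(pts[:-1]) - cand, axis=1)
            if np.all(d >= _CLASH):
                break
        else:
            raise ClashError("coil generation: no clash-free step found")
        pts.append(cand)
    return np.array(pts)


def make_fold(
    segments: Sequence[tuple[str, int]], seed: int | np.random.Generator
) -> np.ndarray:
    """Build a Cα trace from helix/coil segments joined clash-free.

    Each segment is generated in a local frame (ideal helix geometry or a
    self-avoiding 3.8 Å random walk), then attached to the growing chain
    under a random rigid placement whose link step is 3.8 Å; placements
    producing any non-bonded Cα pair closer than 3 Å are rejected
    (bounded retries).
    """
    total = sum(n for _, n in segments)
    if total < 20:
        raise ValueError("fold must have at least 20 residues in total")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chain: np.ndarray | None = None
    for kind, n in segments:
        if kind == "helix":
            local = _helix(n)
        elif kind == "coil":
            local = _coil(n, rng)
        else:
            raise ValueError(f"unknown segment type {kind!r}")
        if chain is None:
            chain = local - local[0]
            continue
        placed = None
        for _ in range(_MAX_RETRIES):
            R = _random_rotation(rng)
            rotated = (local - local[0]) @ R.T
            start = chain[-1] + _STEP * _random_unit(rng)
            cand = rotated + start
            d = np.linalg.norm(chain[:, None, :] - cand[None, :, :], axis=2)
            d[-1, 0] = np.inf  # the bonded link (exactly 3.8 Å) is not a clash
            if d.min() >= _CLASH:
                placed = cand
                break
        if placed is None:
            raise ClashError("segment placement: no clash-free placement in retry budget")
        chain = np.vstack([chain, placed])
    assert chain is not None
    return chain


def random_segments(length: int, rng: np.random.Generator) -> list[tuple[str, int]]:
    """A random alternating helix/coil layout summing to ``length``."""
    segments: list[tuple[str, int]] = []
    remaining = length
    kind = "helix"
    while remaining > 0:
        if kind == "helix":
            n = int(rng.integers(10, 21))
        else:
            n = int(rng.integers(3, 8))
        n = min(n, remaining)
        segments.append((kind, n))
        remaining -= n
        kind = "coil" if kind == "helix" else "helix"
    return segments


def make_family_member(
    template: np.ndarray,
    sigma: float,
    indel_rate: float,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, tuple[str, int] | None]:
    """A noised, rigidly displaced (optionally truncated) copy of a template.

    Returns the coordinates and the applied truncation as
    ``(terminus, n_cut)`` (``'N'`` or ``'C'``) or ``None``.  Truncations
    remove 1 to 10% of the residues from one terminus.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coords = template + rng.normal(0.0, sigma, size=template.shape)
    R = _random_rotation(rng)
    t = rng.uniform(-20.0, 20.0, size=3)
    coords = coords @ R.T + t
    truncation = None
    L = len(template)
    max_cut = L // 10
    if max_cut >= 1 and rng.random() < indel_rate:
        n_cut = int(rng.integers(1, max_cut + 1))
        terminus = "N" if rng.random() < 0.5 else "C"
        coords = coords[n_cut:] if terminus == "N" else coords[:-n_cut]
        truncation = (terminus, n_cut)
    return coords, truncation


def simulate_plddt(
    length: int,
    plddt_core: float,
    plddt_tail: float,
    target_mean: float | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Per-residue confidences: noisy core level with lower 10-residue termini.

    Core residues draw from Normal(plddt_core, 3) and the first/last 10
    residues from Normal(plddt_tail, 3), clipped to [0, 100].  If
    ``target_mean`` is given the profile is shifted (re-clipping as
    needed) until the mean matches it within 0.01.
    """
    for v in (plddt_core, plddt_tail):
        if not (0.0 <= v <= 100.0):
            raise ValueError("confidence levels must be in [0, 100]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tail = min(10, length // 2)
    values = rng.normal(plddt_core, 3.0, size=length)
    values[:tail] = rng.normal(plddt_tail, 3.0, size=tail)
    if tail:
        values[-tail:] = rng.normal(plddt_tail, 3.0, size=tail)
    values = np.clip(values, 0.0, 100.0)
    if target_mean is not None:
        if not (0.0 <= target_mean <= 100.0):
            raise ValueError("target_mean must be in [0, 100]")
        for _ in range(100):
            delta = target_mean - values.mean()
            if abs(delta) <= 0.01:
                break
            values = np.clip(values + delta, 0.0, 100.0)
    return values


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = []
    for ch in seq:
        if rng.random() < rate:
            choices = [a for a in _AA20 if a != ch]
            out.append(choices[int(rng.integers(0, len(choices)))])
        else:
            out.append(ch)
    return "".join(out)


def generate_dataset(spec: SyntheticFamilySpec) -> SyntheticDataset:
    """Generate structures, sequences and planted truth from a family spec.

    Families get independent template folds; members are noised copies.
    Exactly ``spec.low_confidence_members`` members (chosen reproducibly)
    are forced to a mean pLDDT ≤ 80 so the confidence filter has known
    casualties; ``swap_fraction`` of the members receive a sequence
    derived from the *next* family's consensus, making their sequence
    grouping deliberately discordant with their structural family.
    """
    counts = spec.member_counts()
    n_total = sum(counts)
    if spec.low_confidence_members > n_total:
        raise ValueError("low_confidence_members exceeds the total member count")
    root = np.random.SeedSequence(spec.seed)
    ss_folds, ss_members, ss_plddt, ss_seq, ss_pick = root.spawn(5)
    fold_rngs = [np.random.default_rng(s) for s in ss_folds.spawn(spec.n_families)]
    templates = []
    for rng in fold_rngs:
        templates.append(make_fold(random_segments(spec.length, rng), rng))
    seq_rng = np.random.default_rng(ss_seq)
    consensus = [
        "".join(_AA20[int(seq_rng.integers(0, 20))] for _ in range(spec.length))
        for _ in range(spec.n_families)
    ]

    member_ids: list[str] = []
    fam_of: dict[str, int] = {}
    for f, c in enumerate(counts):
        for m in range(c):
            mid = f"F{f + 1}_M{m + 1:02d}"
            member_ids.append(mid)
            fam_of[mid] = f

    pick_rng = np.random.default_rng(ss_pick)
    low_ids = set(
        pick_rng.choice(member_ids, size=spec.low_confidence_members, replace=False)
    ) if spec.low_confidence_members else set()
    n_swap = int(round(spec.swap_fraction * n_total))
    swap_ids = set(pick_rng.choice(member_ids, size=n_swap, replace=False)) if n_swap else set()

    member_rngs = [np.random.default_rng(s) for s in ss_members.spawn(n_total)]
    plddt_rngs = [np.random.default_rng(s) for s in ss_plddt.spawn(n_total)]

    structures: list[ProteinStructure] = []
    sequences: list[SequenceRecord] = []
    labels: dict[str, str] = {}
    for k, mid in enumerate(member_ids):
        f = fam_of[mid]
        rng = member_rngs[k]
        coords, truncation = make_family_member(
            templates[f], spec.sigma, spec.indel_rate, rng
        )
        L = len(coords)
        if mid in low_ids:
            target = float(plddt_rngs[k].uniform(70.0, 79.0))
        else:
            target = None
        plddt = simulate_plddt(
            L, spec.plddt_core, spec.plddt_tail, target_mean=target, seed=plddt_rngs[k]
        )
        donor = (f + 1) % spec.n_families if mid in swap_ids else f
        seq = _mutate(consensus[donor], spec.seq_mut_rate, rng)
        struct_seq = consensus[f]
        if truncation is not None:
            terminus, n_cut = truncation
            if terminus == "N":
                seq = seq[n_cut:]
                struct_seq = struct_seq[n_cut:]
                first_index = n_cut + 1
            else:
                seq = seq[:-n_cut]
                struct_seq = struct_seq[:-n_cut]
                first_index = 1
        else:
            first_index = 1
        residues = [
            Residue(
                index=first_index + i,
                name=three_letter(struct_seq[i]),
                coord=coords[i],
                plddt=float(plddt[i]),
            )
            for i in range(L)
        ]
        structures.append(ProteinStructure(id=mid, residues=residues))
        sequences.append(SequenceRecord(mid, seq))
        labels[mid] = f"F{f + 1}"

    return SyntheticDataset(
        structures=StructureSet(structures, labels=dict(labels)),
        sequences=sequences,
        labels=labels,
        swapped_ids=tuple(sorted(swap_ids)),
        low_confidence_ids=tuple(sorted(low_ids)),
        spec=spec,
    )


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write PDB files, sequences.fasta and labels.tsv; returns the paths."""
    out = Path(out_dir)
    pdb_dir = out / "structures"
    pdb_dir.mkdir(parents=True, exist_ok=True)
    for s in dataset.structures:
        write_pdb(s, pdb_dir / f"{s.id}.pdb")
    fasta = out / "sequences.fasta"
    write_fasta(dataset.sequences, fasta)
    labels = out / "labels.tsv"
    with open(labels, "w") as fh:
        fh.write("id\tlabel\n")
        for mid in sorted(dataset.labels):
            fh.write(f"{mid}\t{dataset.labels[mid]}\n")
    truth = out / "truth.tsv"
    with open(truth, "w") as fh:
        fh.write("id\tswapped\tlow_confidence\n")
        for mid in sorted(dataset.labels):
            fh.write(
                f"{mid}\t{int(mid in dataset.swapped_ids)}\t"
                f"{int(mid in dataset.low_confidence_ids)}\n"
            )
    return {"structures": pdb_dir, "fasta": fasta, "labels": labels, "truth": truth}
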