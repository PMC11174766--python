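"""End-to-end orchestration: filter → all-pairs scoring → UPGMA → comparison.

Runs the whole analysis on either a directory of PDB models (with
optional FASTA sequences and a subfamily-label TSV) or a synthetic family
spec, writing every intermediate artifact to an output directory:

* ``filter_report.tsv``   — per-structure mean pLDDT and kept/removed status
* ``pair_scores.tsv``     — idA, idB, tm_ab, tm_ba, tm_sym, rmsd, n_aligned, combined
* ``similarity.tsv``      — symmetric combined-similarity matrix
* ``distance.tsv``        — 1 − similarity
* ``structure_tree.nwk``  — UPGMA tree over structural distances
* ``sequence_tree.nwk``   — UPGMA tree over alignment-identity distances
* ``comparison.json``     — structure-vs-sequence concordance report
* ``manifest.json``       — artifact list with SHA-256 checksums, config echo

Outputs are deterministic for a fixed config and seed (fixed-precision
numeric formats, no timestamps in checksummed artifacts).
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .clustering import upgma, write_newick
from .similarity import (
    PairwiseScore,
    ScoringConfig,
    combined_similarity,
    similarity_matrix,
    to_distance,
    write_distance_tsv,
)
from .structures import StructureSet, filter_structures, mean_plddt, read_structure_dir
from .superpose import structural_align
from .synthetic import SyntheticFamilySpec, generate_dataset
from .tree_compare import (
    SequenceRecord,
    compare_trees,
    read_fasta,
    sequence_distance_matrix,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full run; exactly one input source must be set."""

    input_dir: str | Path | None = None
    synthetic: SyntheticFamilySpec | None = None
    fasta: str | Path | None = None
    labels_file: str | Path | None = None
    plddt_min: float = 80.0
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    tm_normalization: str = "average"  # 'average' (tm_sym) or 'shorter'
    gap_open: float = -0.6
    max_iter: int = 30
    stride: int = 1
    max_refined: int = 5
    k: int | None = None
    max_structures: int = 200
    output_dir: str | Path = "foldclust_out"

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.synthetic is None):
            raise ValueError("set exactly one of input_dir / synthetic")
        if self.tm_normalization not in ("average", "shorter"):
            raise ValueError("tm_normalization must be 'average' or 'shorter'")


def align_all_pairs(
    structure_set: StructureSet,
    scoring: ScoringConfig = ScoringConfig(),
    **align_kwargs,
) -> list[PairwiseScore]:
    """Structural alignment + combined similarity for every unordered pair."""
    out = []
    for A, B in itertools.combinations(structure_set.structures, 2):
        res = structural_align(A, B, **align_kwargs)
        out.append(
            PairwiseScore(
                A.id, B.id, tm_sym=res.tm_sym, rmsd=res.rmsd,
                combined=combined_similarity(res.tm_sym, res.rmsd, scoring),
            )
        )
    return out


def structure_tree(
    structure_set: StructureSet,
    scoring: ScoringConfig = ScoringConfig(),
    **align_kwargs,
):
    """All-pairs scoring → similarity → UPGMA tree (in-memory convenience)."""
    pairs = align_all_pairs(structure_set, scoring, **align_kwargs)
    sim = similarity_matrix(pairs, structure_set.ids)
    return upgma(to_distance(sim), sim.ids), pairs


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_labels(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"id", "label"} <= set(df.columns):
        raise ValueError("labels TSV must have 'id' and 'label' columns")
    return dict(zip(df["id"], df["label"]))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    root_logger = logging.getLogger("foldclust")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)
    artifacts: list[Path] = []
    try:
        return _run(cfg, out, artifacts)
    finally:
        root_logger.removeHandler(handler)
        handler.close()


def _run(cfg: PipelineConfig, out: Path, artifacts: list[Path]) -> dict:
    t0 = time.time()
    sequences: list[SequenceRecord] | None = None
    labels: dict[str, str] | None = None
    if cfg.synthetic is not None:
        dataset = generate_dataset(cfg.synthetic)
        structures = dataset.structures
        sequences = dataset.sequences
        labels = dataset.labels
        logger.info("stage=generate n=%d seed=%d elapsed=%.2fs",
                    len(structures), cfg.synthetic.seed, time.time() - t0)
    else:
        structures = read_structure_dir(cfg.input_dir)
        if cfg.fasta is not None:
            sequences = read_fasta(cfg.fasta)
        if cfg.labels_file is not None:
            labels = _load_labels(cfg.labels_file)
        logger.info("stage=load n=%d dir=%s", len(structures), cfg.input_dir)
    if len(structures) > cfg.max_structures:
        raise ValueError(
            f"{len(structures)} structures exceed max_structures={cfg.max_structures}; "
            "raise the guard explicitly for large runs"
        )

    # --- confidence filter ---
    t1 = time.time()
    means = {s.id: mean_plddt(s) for s in structures}
    kept, removed = filter_structures(structures, cfg.plddt_min)
    report = pd.DataFrame(
        {
            "id": [s.id for s in structures],
            "mean_plddt": [round(means[s.id], 4) for s in structures],
            "kept": [int(s.id not in removed) for s in structures],
        }
    )
    filter_path = out / "filter_report.tsv"
    report.to_csv(filter_path, sep="\t", index=False, float_format="%.4f")
    artifacts.append(filter_path)
    logger.info("stage=filter kept=%d removed=%d threshold=%.2f elapsed=%.2fs",
                len(kept), len(removed), cfg.plddt_min, time.time() - t1)
    if len(kept) < 2:
        raise ValueError(
            f"only {len(kept)} structures survive the pLDDT > {cfg.plddt_min} filter; "
            "need at least 2 to compare"
        )

    # --- all-pairs structural alignment ---
    t2 = time.time()
    ids = kept.ids
    rows = []
    pair_scores = []
    for A, B in itertools.combinations(kept.structures, 2):
        res = structural_align(
            A, B, gap_open=cfg.gap_open, max_iter=cfg.max_iter,
            stride=cfg.stride, max_refined=cfg.max_refined,
        )
        if cfg.tm_normalization == "shorter":
            tm_used = res.tm_ab if A.length <= B.length else res.tm_ba
        else:
            tm_used = res.tm_sym
        combined = combined_similarity(tm_used, res.rmsd, cfg.scoring)
        rows.append(
            (A.id, B.id, res.tm_ab, res.tm_ba, res.tm_sym, res.rmsd, res.n_aligned, combined)
        )
        pair_scores.append(
            PairwiseScore(A.id, B.id, tm_sym=res.tm_sym, rmsd=res.rmsd, combined=combined)
        )
    pairs_df = pd.DataFrame(
        rows, columns=["idA", "idB", "tm_ab", "tm_ba", "tm_sym", "rmsd", "n_aligned", "combined"]
    )
    pairs_path = out / "pair_scores.tsv"
    pairs_df.to_csv(pairs_path, sep="\t", index=False, float_format="%.6f")
    artifacts.append(pairs_path)
    logger.info("stage=score pairs=%d elapsed=%.2fs", len(rows), time.time() - t2)

    # --- matrices and structure tree ---
    sim = similarity_matrix(pair_scores, ids)
    sim_path = out / "similarity.tsv"
    sim.write_tsv(sim_path)
    artifacts.append(sim_path)
    D = to_distance(sim)
    dist_path = out / "distance.tsv"
    write_distance_tsv(D, ids, dist_path)
    artifacts.append(dist_path)
    structure_tree = upgma(D, ids)
    stree_path = out / "structure_tree.nwk"
    write_newick(structure_tree, stree_path)
    artifacts.append(stree_path)
    logger.info("stage=cluster leaves=%d", len(ids))

    # --- sequence tree and comparison ---
    comparison = None
    if sequences is not None:
        seq_by_id = {r.id: r for r in sequences}
        missing = [i for i in ids if i not in seq_by_id]
        if missing:
            logger.warning("comparison skipped: %d kept ids missing sequences (%s...)",
                           len(missing), missing[:3])
        else:
            kept_records = [seq_by_id[i] for i in ids]
            Dseq, seq_ids = sequence_distance_matrix(kept_records)
            seq_tree = upgma(Dseq, seq_ids)
            qtree_path = out / "sequence_tree.nwk"
            write_newick(seq_tree, qtree_path)
            artifacts.append(qtree_path)
            kept_labels = {i: labels[i] for i in ids} if labels else None
            comparison = compare_trees(structure_tree, seq_tree, labels=kept_labels, k=cfg.k)
            cmp_path = out / "comparison.json"
            cmp_path.write_text(comparison.to_json() + "\n")
            artifacts.append(cmp_path)
            logger.info("stage=compare rf=%d discordant=%d",
                        comparison.rf, len(comparison.discordant_ids))
    else:
        logger.warning("no sequences provided; structure-vs-sequence comparison skipped")

    manifest = {
        "version": __version__,
        "config": _config_dict(cfg),
        "n_input": len(structures),
        "n_kept": len(kept),
        "removed": removed,
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    if comparison is not None:
        manifest["comparison"] = comparison.to_dict()
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("stage=done artifacts=%d elapsed=%.2fs", len(artifacts), time.time() - t0)
    return manifest


def _config_dict(cfg: PipelineConfig) -> dict:
    d = {
        "input_dir": str(cfg.input_dir) if cfg.input_dir else None,
        "synthetic": asdict(cfg.synthetic) if cfg.synthetic else None,
        "fasta": str(cfg.fasta) if cfg.fasta else None,
        "labels_file": str(cfg.labels_file) if cfg.labels_file else None,
        "plddt_min": cfg.plddt_min,
        "scoring": {"w_tm": cfg.scoring.w_tm, "r_max": cfg.scoring.r_max},
        "tm_normalization": cfg.tm_normalization,
        "gap_open": cfg.gap_open,
        "max_iter": cfg.max_iter,
        "stride": cfg.stride,
        "max_refined": cfg.max_refined,
        "k": cfg.k,
    }
    if cfg.synthetic is not None and not isinstance(cfg.synthetic.members_per_family, int):
        d["synthetic"]["members_per_family"] = list(cfg.synthetic.members_per_family)
    return d
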