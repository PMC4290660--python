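"""Staged decoy selection and CASP-style evaluation.

Selection follows the production protocol this package models: cluster the
pool and keep one representative per topology, rank representatives by the
cumulative physico-chemical score (CS), pass the 10 best to structure-quality
ranking, refine the quality-best model through a pluggable hook (identity by
default — real refiners are external engines), merge the refined candidates
with the quality top 5, and re-rank the merged set by CS to emit at most
five final models.

Evaluation aligns the model and native sequences globally (BLOSUM62, affine
gaps 10/0.5), drops aligned pairs where either side lacks a Calpha (the
"missing coordinates removed" rule), and reports Calpha RMSD and TM-score
per model plus threshold summaries over targets (best-of-five, TM >= 0.5
and RMSD <= 5.0 A inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from . import cluster as _cluster
from . import descriptors as _descriptors
from . import pcsm as _pcsm
from . import quality as _quality
from . import superpose as _superpose
from . import tmscore as _tmscore
from .descriptors import DescriptorVector, SSString
from .pdbio import DecoyPool, Structure, extract_sequence

__all__ = [
    "SelectionReport",
    "EvaluationRecord",
    "SummaryReport",
    "align_for_eval",
    "evaluate",
    "summarize",
    "select_top5",
]

logger = logging.getLogger(__name__)

RefineHook = Callable[[DecoyPool], DecoyPool]


@dataclass
class SelectionReport:
    stage_trace: dict[str, list[str]]
    final: list[tuple[str, float]]
    descriptors: dict[str, DescriptorVector] = field(default_factory=dict)
    quality: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class EvaluationRecord:
    model_id: str
    ca_rmsd: float
    tm: _tmscore.TmResult
    n_aligned: int


@dataclass(frozen=True)
class SummaryReport:
    n_targets: int
    frac_tm_ge: float
    frac_rmsd_le: float
    per_target_best: dict[str, dict[str, float]]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def align_for_eval(model_seq: str, native_seq: str) -> list[tuple[int, int]]:
    """Globally align two sequences; return (model index, native index)
    pairs for aligned (non-gap) columns."""
    if not model_seq or not native_seq:
        raise ValueError("empty sequence")
    aligner = _make_aligner()
    aln = aligner.align(model_seq, native_seq)[0]
    pairs: list[tuple[int, int]] = []
    for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
        pairs.extend(
            (int(a_start) + k, int(b_start) + k) for k in range(int(a_end) - int(a_start))
        )
    return pairs


def evaluate(predictions: DecoyPool, native: Structure) -> list[EvaluationRecord]:
    """Calpha RMSD and TM-score of each prediction against the native.

    Aligned pairs where either residue lacks a Calpha are removed before
    scoring, so the compared coordinate sets match exactly.
    """
    native_seq = extract_sequence(native)
    records = []
    for sid in predictions.ids():
        model = predictions.decoys[sid]
        mapping = align_for_eval(extract_sequence(model), native_seq)
        mapping = [
            (i, j)
            for i, j in mapping
            if model.residues[i].get_atom("CA") is not None
            and native.residues[j].get_atom("CA") is not None
        ]
        if not mapping:
            raise ValueError(f"no mappable residues between {sid} and native")
        ca_rmsd = _superpose.rmsd(model, native, subset="ca", mapping=mapping)
        tm = _tmscore.tm_score(model, native, mapping=mapping)
        records.append(
            EvaluationRecord(model_id=sid, ca_rmsd=ca_rmsd, tm=tm, n_aligned=len(mapping))
        )
    return records


def summarize(
    records: Mapping[str, Sequence[EvaluationRecord]],
    tm_cut: float = 0.5,
    rmsd_cut: float = 5.0,
) -> SummaryReport:
    """Best-of-predictions fractions over targets (inclusive thresholds)."""
    if not records:
        raise ValueError("no targets to summarize")
    per_target = {}
    n_tm = n_rmsd = 0
    for target, recs in records.items():
        if not recs:
            raise ValueError(f"target {target!r} has no evaluation records")
        best_tm = max(r.tm.score for r in recs)
        best_rmsd = min(r.ca_rmsd for r in recs)
        per_target[target] = {"best_tm": best_tm, "best_ca_rmsd": best_rmsd}
        n_tm += best_tm >= tm_cut
        n_rmsd += best_rmsd <= rmsd_cut
    n = len(records)
    return SummaryReport(
        n_targets=n,
        frac_tm_ge=n_tm / n,
        frac_rmsd_le=n_rmsd / n,
        per_target_best=per_target,
    )


def identity_refine(pool: DecoyPool) -> DecoyPool:
    """Default refinement hook: return the input unchanged."""
    return pool


def select_top5(
    pool: DecoyPool,
    predicted_ss: SSString,
    refine: RefineHook = identity_refine,
    radius: float = 1.0,
    atom_subset: str = "heavy",
    n_points: int = 960,
) -> SelectionReport:
    """Run the full staged selection protocol and return up to five models.

    Stages: (1) RMSD-radius clustering, one representative per cluster;
    (2) CS-rank representatives, keep 10; (3) quality-rank those 10, keep 5,
    send the best to the refinement hook; (4) CS-rank the refined pool, keep
    up to 10; (5) merge with the stage-3 five, de-duplicating by id;
    (6) CS re-rank the merged set; final = best min(5, distinct).
    """
    if len(pool) == 0:
        raise ValueError("empty pool")
    if len(predicted_ss) != len(pool.shared_sequence):
        raise ValueError("predicted secondary structure length mismatch")

    trace: dict[str, list[str]] = {}

    cs_set = _cluster.kclust(pool, radius=radius, atom_subset=atom_subset)
    reps = _cluster.representatives(cs_set, pool)
    trace["post_cluster"] = sorted(reps.ids())
    logger.info("clustering: %d decoys -> %d representatives", len(pool), len(reps))

    descriptors: dict[str, DescriptorVector] = {
        sid: _descriptors.describe(reps.decoys[sid], predicted_ss, n_points=n_points)
        for sid in reps.ids()
    }
    top10 = _pcsm.rank(reps, descriptors, k=10)
    trace["pcsm_top10"] = top10.ids()
    logger.info("pcSM top10: %s", trace["pcsm_top10"])

    qualities = {
        sid: _quality.composite_quality(pool.decoys[sid]).composite
        for sid in top10.ids()
    }
    quality_order = sorted(top10.ids(), key=lambda s: (qualities[s], top10.ids().index(s)))
    quality_top5 = quality_order[:5]
    trace["quality_top5"] = quality_top5
    logger.info("quality (protsav-standin) top5: %s", quality_top5)

    refined_pool = refine(pool.subset([quality_order[0]]))
    trace["refined"] = sorted(refined_pool.ids())
    refined_desc = {
        sid: (
            descriptors[sid]
            if sid in descriptors
            else _descriptors.describe(
                refined_pool.decoys[sid], predicted_ss, n_points=n_points
            )
        )
        for sid in refined_pool.ids()
    }
    refined_ranked = _pcsm.rank(refined_pool, refined_desc, k=10)
    trace["refined_ranked"] = refined_ranked.ids()

    merged_ids = list(dict.fromkeys(refined_ranked.ids() + quality_top5))
    trace["merged"] = merged_ids
    merged_desc = {sid: refined_desc.get(sid, descriptors.get(sid)) for sid in merged_ids}
    merged_structs = {
        sid: (refined_pool.decoys[sid] if sid in refined_pool.decoys else pool.decoys[sid])
        for sid in merged_ids
    }
    merged_pool = DecoyPool(
        decoys=merged_structs,
        shared_sequence=pool.shared_sequence,
        provenance=pool.provenance,
    )
    final_ranked = _pcsm.rank(merged_pool, merged_desc, k=5)
    trace["final"] = final_ranked.ids()
    logger.info("final five: %s", trace["final"])

    all_desc = dict(descriptors)
    all_desc.update(refined_desc)
    return SelectionReport(
        stage_trace=trace,
        final=list(final_ranked),
        descriptors=all_desc,
        quality=qualities,
    )
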