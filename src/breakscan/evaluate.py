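"""Scoring predicted calls against an implanted-variant truth table.

Matching is greedy one-to-one within each variant class: a prediction
matches a truth record when their positions agree within a tolerance
(default 0 for SNVs, whose alleles must also agree exactly, and 5 for
indels and inversions, whose lengths must agree within the same
tolerance).  Complex calls contribute their decomposed components as
individual predictions.  Sensitivity, positive predictive value and
F-measure are reported per class, for indels pooled, and overall.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

from .consensus_typing import COMPLEX, DELETION, INSERTION, INVERSION, SNV, UNASSIGNED
from .locate_report import LOCATED, CallReport
from .simulate import TruthRecord

logger = logging.getLogger(__name__)

_CLASSES = (SNV, INSERTION, DELETION, INVERSION)


@dataclass(frozen=True)
class PredictedVariant:
    """A located prediction in truth-table coordinates."""

    vtype: str
    contig: str
    pos: int  # 1-based, same convention as TruthRecord.pos
    normal_allele: str
    mutated_allele: str
    cluster_id: int

    @property
    def length(self) -> int:
        return max(len(self.normal_allele), len(self.mutated_allele))


def report_to_predictions(report: CallReport) -> tuple[list[PredictedVariant], int]:
    """Flatten a located report into matchable predictions.

    Complex calls are replaced by their located components; calls that
    are unassigned, unmapped or ambiguous cannot match any truth record
    and are returned only in the unmatched count (second element).
    """
    preds: list[PredictedVariant] = []
    n_unmatchable = 0
    for call in report.calls:
        loc = call.location
        if loc is None or loc.status != LOCATED or call.vtype == UNASSIGNED:
            n_unmatchable += 1
            continue
        if call.vtype == COMPLEX:
            if not loc.components:
                n_unmatchable += 1
                continue
            for comp in loc.components:
                preds.append(
                    PredictedVariant(
                        vtype=comp.vtype,
                        contig=loc.contig,
                        pos=comp.pos,
                        normal_allele=comp.normal_allele,
                        mutated_allele=comp.mutated_allele,
                        cluster_id=call.cluster_id,
                    )
                )
        else:
            preds.append(
                PredictedVariant(
                    vtype=call.vtype,
                    contig=loc.contig,
                    pos=loc.pos,
                    normal_allele=loc.ref_normal_allele,
                    mutated_allele=loc.ref_mutated_allele,
                    cluster_id=call.cluster_id,
                )
            )
    return preds, n_unmatchable


def tsv_to_predictions(path: str | Path) -> tuple[list[PredictedVariant], int]:
    """Predictions from a call TSV written by the report module."""
    from .locate_report import read_calls_tsv

    df = read_calls_tsv(path)
    preds: list[PredictedVariant] = []
    n_unmatchable = 0
    for row in df.itertuples(index=False):
        if row.status != LOCATED or row.vtype == UNASSIGNED:
            n_unmatchable += 1
            continue
        if row.vtype == COMPLEX:
            if row.components in (".", ""):
                n_unmatchable += 1
                continue
            for token in row.components.split(";"):
                vtype, pos, na, ma = token.split(":")
                preds.append(
                    PredictedVariant(
                        vtype=vtype,
                        contig=row.contig,
                        pos=int(pos),
                        normal_allele="" if na == "." else na,
                        mutated_allele="" if ma == "." else ma,
                        cluster_id=int(row.cluster_id),
                    )
                )
        else:
            preds.append(
                PredictedVariant(
                    vtype=row.vtype,
                    contig=row.contig,
                    pos=int(row.pos),
                    normal_allele="" if row.normal_allele == "." else row.normal_allele,
                    mutated_allele="" if row.mutated_allele == "." else row.mutated_allele,
                    cluster_id=int(row.cluster_id),
                )
            )
    return preds, n_unmatchable


# ---------------------------------------------------------------------------
# matching


@dataclass
class Matching:
    pairs: list[tuple[TruthRecord, PredictedVariant]]
    unmatched_truth: list[TruthRecord]
    unmatched_predictions: list[PredictedVariant]
    n_unmatchable_predictions: int = 0
    tol_snv: int = 0
    tol_indel: int = 5


def match_calls(
    predictions: list[PredictedVariant],
    truth: list[TruthRecord],
    *,
    tol_snv: int = 0,
    tol_indel: int = 5,
    n_unmatchable: int = 0,
) -> Matching:
    """Greedy one-to-one matching of predictions to truth records.

    Candidate pairs within one variant class are ranked by position
    difference (ties by truth position, then prediction cluster id) and
    taken greedily.  SNVs must agree in alleles exactly; indels and
    inversions must agree in length within ``tol_indel``.
    """
    pairs: list[tuple[TruthRecord, PredictedVariant]] = []
    used_t: set[int] = set()
    used_p: set[int] = set()
    for vclass in _CLASSES:
        tol = tol_snv if vclass == SNV else tol_indel
        t_idx = [i for i, t in enumerate(truth) if t.vtype == vclass]
        p_idx = [i for i, p in enumerate(predictions) if p.vtype == vclass]
        candidates = []
        for ti in t_idx:
            t = truth[ti]
            for pi in p_idx:
                p = predictions[pi]
                if p.contig != t.contig or abs(p.pos - t.pos) > tol:
                    continue
                if vclass == SNV and (
                    p.normal_allele != t.normal_allele
                    or p.mutated_allele != t.mutated_allele
                ):
                    continue
                if vclass != SNV and abs(p.length - t.length) > tol:
                    continue
                candidates.append((abs(p.pos - t.pos), t.pos, p.cluster_id, ti, pi))
        for _d, _tp, _cid, ti, pi in sorted(candidates):
            if ti in used_t or pi in used_p:
                continue
            used_t.add(ti)
            used_p.add(pi)
            pairs.append((truth[ti], predictions[pi]))
    unmatched_truth = [t for i, t in enumerate(truth) if i not in used_t]
    unmatched_preds = [p for i, p in enumerate(predictions) if i not in used_p]
    return Matching(
        pairs=pairs,
        unmatched_truth=unmatched_truth,
        unmatched_predictions=unmatched_preds,
        n_unmatchable_predictions=n_unmatchable,
        tol_snv=tol_snv,
        tol_indel=tol_indel,
    )


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class ClassMetrics:
    tp: int
    fp: int
    fn: int
    sensitivity: float
    ppv: float
    f_measure: float
    ppv_defined: bool = True

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "ClassMetrics":
        sens = tp / (tp + fn) if tp + fn else 0.0
        ppv_defined = (tp + fp) > 0
        ppv = tp / (tp + fp) if ppv_defined else 0.0
        f = 2 * sens * ppv / (sens + ppv) if sens + ppv else 0.0
        return cls(tp, fp, fn, sens, ppv, f, ppv_defined)


@dataclass
class EvalResult:
    per_class: dict[str, ClassMetrics]
    overall: ClassMetrics
    matching: Matching
    tol_snv: int
    tol_indel: int

    def to_dict(self) -> dict:
        def enc(m: ClassMetrics) -> dict:
            return {
                "TP": m.tp,
                "FP": m.fp,
                "FN": m.fn,
                "sensitivity": m.sensitivity,
                "PPV": m.ppv,
                "F": m.f_measure,
                "PPV_defined": m.ppv_defined,
            }

        return {
            "tolerance": {"SNV": self.tol_snv, "indel": self.tol_indel},
            "per_class": {k: enc(m) for k, m in self.per_class.items()},
            "overall": enc(self.overall),
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def compute_metrics(matching: Matching, truth: list[TruthRecord] | None = None) -> EvalResult:
    """Per-class and overall sensitivity = TP/(TP+FN), PPV = TP/(TP+FP)
    and F-measure (their harmonic mean; PPV is reported as 0 with a flag
    when there are no predictions in a class).

    The ``indel`` entry pools insertions and deletions.
    """
    per_class: dict[str, ClassMetrics] = {}

    def counts(vclasses: tuple[str, ...]) -> tuple[int, int, int]:
        tp = sum(1 for t, _p in matching.pairs if t.vtype in vclasses)
        fp = sum(1 for p in matching.unmatched_predictions if p.vtype in vclasses)
        fn = sum(1 for t in matching.unmatched_truth if t.vtype in vclasses)
        return tp, fp, fn

    for vclass in _CLASSES:
        per_class[vclass] = ClassMetrics.from_counts(*counts((vclass,)))
    per_class["indel"] = ClassMetrics.from_counts(*counts((INSERTION, DELETION)))
    overall = ClassMetrics.from_counts(*counts(_CLASSES))
    return EvalResult(
        per_class=per_class,
        overall=overall,
        matching=matching,
        tol_snv=matching.tol_snv,
        tol_indel=matching.tol_indel,
    )


def evaluate_report(
    report: CallReport,
    truth: list[TruthRecord],
    *,
    tol_snv: int = 0,
    tol_indel: int = 5,
) -> EvalResult:
    """Convenience wrapper: flatten, match and score a located report."""
    preds, n_unmatchable = report_to_predictions(report)
    matching = match_calls(
        preds, truth, tol_snv=tol_snv, tol_indel=tol_indel, n_unmatchable=n_unmatchable
    )
    return compute_metrics(matching)
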