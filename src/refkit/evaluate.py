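"""Per-rank scoring of predicted against expected taxonomies.

Predictions are compared rank by rank.  In group-aware mode a merged
label ("Staphylococcus aureus/schweitzeri/argenteus") on either side
matches when one side's expanded name set contains the other's — the
formalization of "a merged group is correct for any of its members".
Unassigned ranks (empty predicted label) count against recall but never
against precision, the usual open-set convention.

Headline numbers are macro-averaged (unweighted mean over taxa with at
least one expected query); micro averages are also reported.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .derep import expand_merged_label
from .schema import Lineage, RankSchema

__all__ = [
    "Outcome",
    "LabelMatch",
    "EvalReport",
    "labels_compatible",
    "match_labels",
    "compute_metrics",
    "summarize",
]


class Outcome(str, enum.Enum):
    MATCH = "match"
    MISMATCH = "mismatch"
    UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class LabelMatch:
    rank: str
    expected: str
    predicted: str
    outcome: Outcome


def labels_compatible(expected: str, predicted: str, group_aware: bool) -> bool:
    """True when the predicted label counts as correct for the expected one."""
    if expected == predicted:
        return True
    if not group_aware:
        return False
    exp_set = expand_merged_label(expected)
    pred_set = expand_merged_label(predicted)
    return exp_set <= pred_set or pred_set <= exp_set


def match_labels(
    expected: Lineage,
    predicted: Lineage,
    schema: RankSchema,
    group_aware: bool = True,
) -> List[LabelMatch]:
    """Compare two lineages rank by rank."""
    if len(expected) != len(schema) or len(predicted) != len(schema):
        raise ValueError("lineages do not fit the schema")
    out: List[LabelMatch] = []
    for rank, e, p in zip(schema.ranks, expected.labels, predicted.labels):
        if not p:
            outcome = Outcome.UNASSIGNED
        elif labels_compatible(e, p, group_aware):
            outcome = Outcome.MATCH
        else:
            outcome = Outcome.MISMATCH
        out.append(LabelMatch(rank, e, p, outcome))
    return out


@dataclass
class EvalReport:
    """Per-rank confusion counts and macro metrics for one condition."""

    condition: Tuple[str, str, str]
    per_rank: Dict[str, Dict[str, object]]
    n_queries: int

    def macro_f1(self, rank: str) -> float:
        return float(self.per_rank[rank]["macro_f1"])  # type: ignore[arg-type]

    def to_dict(self) -> Dict[str, object]:
        return {
            "condition": list(self.condition),
            "n_queries": self.n_queries,
            "per_rank": self.per_rank,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, stats in self.per_rank.items():
            rows.append(
                {
                    "rank": rank,
                    "macro_precision": stats["macro_precision"],
                    "macro_recall": stats["macro_recall"],
                    "macro_f1": stats["macro_f1"],
                    "micro_f1": stats["micro_f1"],
                    "n_taxa": stats["n_taxa"],
                }
            )
        return pd.DataFrame(rows)


def compute_metrics(
    pairs: Sequence[Tuple[Lineage, Lineage]],
    schema: RankSchema,
    group_aware: bool = True,
    condition: Tuple[str, str, str] = ("nbc", "processed", "amplicon"),
) -> EvalReport:
    """Aggregate per-taxon TP/FP/FN and macro precision/recall/F1 per rank.

    For each rank and expected taxon t: TP counts queries expected t whose
    prediction matches; FN counts expected-t queries that mismatch or are
    unassigned; FP counts non-matching queries whose prediction names t
    (exactly, or via a merged group containing t).  Queries with an empty
    expected label at a rank are excluded at that rank.
    """
    if not pairs:
        raise ValueError("no (expected, predicted) pairs to score")
    per_rank: Dict[str, Dict[str, object]] = {}
    for ri, rank in enumerate(schema.ranks):
        tp: Dict[str, int] = {}
        fp: Dict[str, int] = {}
        fn: Dict[str, int] = {}
        taxa: set = set()
        for expected, predicted in pairs:
            e = expected.labels[ri]
            p = predicted.labels[ri]
            if not e:
                continue
            taxa.add(e)
            if not p:
                fn[e] = fn.get(e, 0) + 1
                continue
            if labels_compatible(e, p, group_aware):
                tp[e] = tp.get(e, 0) + 1
            else:
                fn[e] = fn.get(e, 0) + 1
                for t in expand_merged_label(p) if group_aware else {p}:
                    fp[t] = fp.get(t, 0) + 1
        per_taxon: Dict[str, Dict[str, float]] = {}
        psum = rsum = fsum = 0.0
        tot_tp = tot_fp = tot_fn = 0
        for t in sorted(taxa):
            t_tp, t_fp, t_fn = tp.get(t, 0), fp.get(t, 0), fn.get(t, 0)
            prec = t_tp / (t_tp + t_fp) if t_tp + t_fp else 0.0
            rec = t_tp / (t_tp + t_fn) if t_tp + t_fn else 0.0
            f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            per_taxon[t] = {
                "tp": t_tp,
                "fp": t_fp,
                "fn": t_fn,
                "precision": prec,
                "recall": rec,
                "f1": f1,
            }
            psum += prec
            rsum += rec
            fsum += f1
            tot_tp += t_tp
            tot_fp += t_fp
            tot_fn += t_fn
        n_taxa = len(taxa)
        micro_p = tot_tp / (tot_tp + tot_fp) if tot_tp + tot_fp else 0.0
        micro_r = tot_tp / (tot_tp + tot_fn) if tot_tp + tot_fn else 0.0
        micro_f1 = (
            2 * micro_p * micro_r / (micro_p + micro_r) if micro_p + micro_r else 0.0
        )
        per_rank[rank] = {
            "per_taxon": per_taxon,
            "n_taxa": n_taxa,
            "macro_precision": psum / n_taxa if n_taxa else 0.0,
            "macro_recall": rsum / n_taxa if n_taxa else 0.0,
            "macro_f1": fsum / n_taxa if n_taxa else 0.0,
            "micro_f1": micro_f1,
        }
    return EvalReport(condition=condition, per_rank=per_rank, n_queries=len(pairs))


def summarize(reports: Sequence[EvalReport], schema: RankSchema) -> pd.DataFrame:
    """Mean and median macro F1 per (condition, rank) across replicate reports.

    Rows are sorted by rank (schema order) then condition; permuting the
    input reports leaves the table unchanged.
    """
    rows = []
    by_key: Dict[Tuple[str, Tuple[str, str, str]], List[float]] = {}
    for rep in reports:
        for rank in rep.per_rank:
            by_key.setdefault((rank, rep.condition), []).append(rep.macro_f1(rank))
    rank_order = {r: i for i, r in enumerate(schema.ranks)}
    for (rank, condition), vals in sorted(
        by_key.items(), key=lambda kv: (rank_order.get(kv[0][0], 99), kv[0][1])
    ):
        s = pd.Series(vals, dtype=float)
        rows.append(
            {
                "rank": rank,
                "classifier": condition[0],
                "database": condition[1],
                "region": condition[2],
                "n_reports": len(vals),
                "mean_f1": float(s.mean()),
                "median_f1": float(s.median()),
            }
        )
    return pd.DataFrame(rows)
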