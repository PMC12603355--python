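"""Taxonomy curation: convergence detection, duplicate names, rank propagation.

Reference taxonomies exported from the large 16S databases routinely carry
three anomalies that break single-parent classifiers:

* **convergent evolution** — the same taxon name under different parents
  (e.g. one species epithet listed in two genera).  A naive-Bayes training
  tree cannot represent a child with two parents, so this is detected and,
  by default, treated as a fatal validation failure.
* **duplicated names** — the same label at two ranks of one lineage
  (e.g. family and genus both "Clostridium"), which makes rank-labelled
  output ambiguous; resolved by suffixing the deeper occurrence with the
  rank initial ("Clostridium_g").
* **empty ranks** — missing labels filled by copying the nearest non-empty
  ancestor label down (rank propagation), with provenance marked so later
  steps can tell propagation artifacts from source labels.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .schema import Lineage, Provenance, RefRecord, ReferenceDatabase

__all__ = [
    "ConvergenceConflict",
    "CurationReport",
    "detect_convergent_taxa",
    "resolve_duplicate_names",
    "propagate_ranks",
    "curate",
]


@dataclass(frozen=True)
class ConvergenceConflict:
    """A taxon label appearing under two or more distinct ancestor lineages."""

    rank: str
    label: str
    parent_lineages: Tuple[Tuple[str, ...], ...]
    example_ids: Tuple[str, ...]

    def __str__(self) -> str:
        parents = " | ".join("; ".join(p) for p in self.parent_lineages)
        return f"{self.rank} {self.label!r} under {len(self.parent_lineages)} parents: {parents}"


@dataclass
class CurationReport:
    conflicts: List[ConvergenceConflict] = field(default_factory=list)
    duplicates_resolved: List[Tuple[str, str, str, int]] = field(default_factory=list)
    ranks_propagated: Dict[str, int] = field(default_factory=dict)

    @property
    def n_propagated(self) -> int:
        return sum(self.ranks_propagated.values())

    def to_dict(self) -> Dict[str, object]:
        return {
            "conflicts": [
                {
                    "rank": c.rank,
                    "label": c.label,
                    "parent_lineages": [list(p) for p in c.parent_lineages],
                    "example_ids": list(c.example_ids),
                }
                for c in self.conflicts
            ],
            "duplicates_resolved": [
                {"rank": r, "old": o, "new": n, "records": k}
                for r, o, n, k in self.duplicates_resolved
            ],
            "ranks_propagated": dict(self.ranks_propagated),
        }


def detect_convergent_taxa(db: ReferenceDatabase) -> List[ConvergenceConflict]:
    """Report every label whose set of ancestor-label tuples has size >= 2.

    Checked at every rank below the first, against the full tuple of
    shallower-rank labels.  Empty labels never conflict.  Output is ordered
    by (rank index, label) and is deterministic.
    """
    schema = db.schema
    conflicts: List[ConvergenceConflict] = []
    for ri in range(1, len(schema)):
        # label -> ancestor tuple -> example record ids (first seen)
        by_label: Dict[str, Dict[Tuple[str, ...], str]] = defaultdict(dict)
        for rec in db.sorted_records():
            label = rec.lineage.labels[ri]
            if not label:
                continue
            ancestors = rec.lineage.labels[:ri]
            by_label[label].setdefault(ancestors, rec.id)
        for label in sorted(by_label):
            parents = by_label[label]
            if len(parents) >= 2:
                ordered = sorted(parents)
                conflicts.append(
                    ConvergenceConflict(
                        rank=schema.ranks[ri],
                        label=label,
                        parent_lineages=tuple(ordered),
                        example_ids=tuple(parents[p] for p in ordered),
                    )
                )
    return conflicts


def resolve_duplicate_names(
    db: ReferenceDatabase, policy: str = "suffix"
) -> Tuple[ReferenceDatabase, CurationReport]:
    """Resolve labels repeated at two ranks within a single lineage.

    Only source-provenance labels are considered (propagation artifacts are
    exempt).  Under ``suffix`` policy each deeper occurrence is rewritten to
    ``<label>_<rank initial>``; under ``error`` policy offenders are fatal.
    """
    if policy not in ("suffix", "error"):
        raise ValueError(f"unknown duplicate policy {policy!r}")
    schema = db.schema
    report = CurationReport()
    # (rank, old, new) -> record count
    tally: Dict[Tuple[str, str, str], int] = defaultdict(int)
    offenders: List[str] = []
    new_records: List[RefRecord] = []
    for rec in db.sorted_records():
        lin = rec.lineage
        seen: Dict[str, int] = {}
        changed = lin
        for ri, (label, prov) in enumerate(zip(lin.labels, lin.provenance)):
            if not label or prov is not Provenance.SOURCE:
                continue
            if label in seen:
                rank = schema.ranks[ri]
                new_label = f"{label}_{schema.rank_initial(rank)}"
                if policy == "error":
                    offenders.append(
                        f"{rec.id}: {label!r} at both {schema.ranks[seen[label]]} and {rank}"
                    )
                else:
                    changed = changed.with_label(ri, new_label, Provenance.SOURCE)
                    tally[(rank, label, new_label)] += 1
            else:
                seen[label] = ri
        new_records.append(RefRecord(rec.id, rec.sequence, changed))
    if offenders:
        preview = "; ".join(offenders[:10])
        raise ValueError(
            f"{len(offenders)} lineage(s) with duplicated names across ranks: {preview}"
        )
    report.duplicates_resolved = [
        (r, o, n, k) for (r, o, n), k in sorted(tally.items())
    ]
    return db.replace(new_records), report


def propagate_ranks(db: ReferenceDatabase) -> Tuple[ReferenceDatabase, CurationReport]:
    """Fill every empty rank with the nearest non-empty shallower label.

    The copied label is verbatim, with provenance set to ``propagated``.
    Idempotent; errors if any record has an empty first rank.
    """
    schema = db.schema
    report = CurationReport()
    counts: Dict[str, int] = defaultdict(int)
    bad: List[str] = []
    new_records: List[RefRecord] = []
    for rec in db.sorted_records():
        lin = rec.lineage
        if not lin.labels[0]:
            bad.append(rec.id)
            continue
        changed = lin
        last = lin.labels[0]
        for ri in range(1, len(schema)):
            label = changed.labels[ri]
            if label:
                last = label
            else:
                changed = changed.with_label(ri, last, Provenance.PROPAGATED)
                counts[schema.ranks[ri]] += 1
        new_records.append(RefRecord(rec.id, rec.sequence, changed))
    if bad:
        preview = ", ".join(bad[:10])
        raise ValueError(
            f"{len(bad)} record(s) with an empty {schema.ranks[0]} rank "
            f"(cannot propagate): {preview}"
        )
    report.ranks_propagated = dict(counts)
    return db.replace(new_records), report


def curate(
    db: ReferenceDatabase,
    duplicates: str = "suffix",
    allow_convergence: bool = False,
) -> Tuple[ReferenceDatabase, CurationReport]:
    """Full curation pass: detect conflicts, resolve duplicates, propagate.

    Convergence is fatal unless ``allow_convergence``, in which case
    offending labels are renamed by suffixing the first ancestor label so
    every child has a single parent.  Duplicate resolution runs before
    propagation so that propagation artifacts never trigger suffixing.
    """
    conflicts = detect_convergent_taxa(db)
    if conflicts:
        if not allow_convergence:
            preview = "; ".join(str(c) for c in conflicts[:5])
            raise ValueError(
                f"{len(conflicts)} convergent taxa found (child labels with "
                f"multiple parents): {preview}"
            )
        db = _rename_convergent(db, conflicts)
    out, dup_report = resolve_duplicate_names(db, policy=duplicates)
    out, prop_report = propagate_ranks(out)
    report = CurationReport(
        conflicts=conflicts,
        duplicates_resolved=dup_report.duplicates_resolved,
        ranks_propagated=prop_report.ranks_propagated,
    )
    return out, report


def _rename_convergent(
    db: ReferenceDatabase, conflicts: List[ConvergenceConflict]
) -> ReferenceDatabase:
    """Disambiguate convergent labels by suffixing the nearest ancestor label."""
    schema = db.schema
    conflicted = {(schema.index(c.rank), c.label) for c in conflicts}
    new_records = []
    for rec in db.sorted_records():
        lin = rec.lineage
        for ri in range(1, len(schema)):
            label = lin.labels[ri]
            if label and (ri, label) in conflicted:
                parent = next(
                    (l for l in reversed(lin.labels[:ri]) if l), "unknown"
                )
                lin = lin.with_label(ri, f"{label}_{parent}", lin.provenance[ri])
        new_records.append(RefRecord(rec.id, rec.sequence, lin))
    return db.replace(new_records)
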