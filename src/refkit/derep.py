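"""Dereplication of identical amplicons and merged-taxonomy assignment.

After primer-region extraction, distinct taxa frequently collapse onto the
same amplicon sequence: the target region simply cannot distinguish them
(the classic clinical example being Staphylococcus aureus, S. schweitzeri
and S. argenteus on V3-V4).  Identical sequences are grouped by exact
full-length identity (no similarity clustering), and each group's lineages
are merged rank by rank into a single "merged taxonomy" label such as
``Staphylococcus aureus/schweitzeri/argenteus``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

import pandas as pd

from .schema import Lineage, Provenance, RefRecord, ReferenceDatabase, normalize_sequence

__all__ = [
    "DerepCluster",
    "dereplicate",
    "merge_labels",
    "merge_lineages",
    "expand_merged_label",
    "build_processed_db",
    "MERGE_NAME_CAP",
]

# Merged labels longer than this many names are truncated to the first
# cap-1 names plus a "+K" overflow marker, to keep labels usable.
MERGE_NAME_CAP = 6


@dataclass(frozen=True)
class DerepCluster:
    """A group of records whose extracted sequences are exactly identical."""

    representative: str
    member_ids: Tuple[str, ...]
    member_lineages: Tuple[Lineage, ...]
    merged: Lineage

    @property
    def size(self) -> int:
        return len(self.member_ids)

    @property
    def cluster_id(self) -> str:
        digest = hashlib.sha256(self.representative.encode()).hexdigest()
        return f"drv_{digest[:8]}"


def dereplicate(db: ReferenceDatabase) -> List[DerepCluster]:
    """Group records by exact sequence identity (case/U-normalized, plus strand).

    Clusters are ordered by descending size, then representative sequence;
    members within a cluster keep id order.  Every record lands in exactly
    one cluster.
    """
    groups: Dict[str, List[RefRecord]] = {}
    for rec in db.sorted_records():
        groups.setdefault(normalize_sequence(rec.sequence), []).append(rec)
    clusters = [
        DerepCluster(
            representative=seq,
            member_ids=tuple(r.id for r in members),
            member_lineages=tuple(r.lineage for r in members),
            merged=merge_lineages([r.lineage for r in members]),
        )
        for seq, members in groups.items()
    ]
    clusters.sort(key=lambda c: (-c.size, c.representative))
    return clusters


def _factor_names(names: Sequence[str], cap: int | None) -> str:
    """Join distinct names with '/', factoring the shared leading words.

    Names that open with the same word sequence print those words once on
    the first name only; the others contribute their distinct remainders
    (``Staphylococcus aureus/schweitzeri/argenteus``).  The shared prefix is
    capped below the shortest name's length so every remainder is non-empty.
    """
    if cap is not None and len(names) > cap:
        shown = list(names[: cap - 1])
        overflow = len(names) - (cap - 1)
        return _factor_names(shown, None) + f"/+{overflow}"
    words = [n.split() for n in names]
    max_common = min(len(w) for w in words) - 1
    common = 0
    while common < max_common and all(w[common] == words[0][common] for w in words):
        common += 1
    parts = [names[0]] + [" ".join(w[common:]) for w in words[1:]]
    return "/".join(parts)


def merge_labels(labels: Sequence[str], cap: int | None = MERGE_NAME_CAP) -> str:
    """Merge per-rank labels: distinct names in first-appearance order.

    A single distinct name is returned verbatim; several are '/'-joined
    after shared-leading-word factoring.
    """
    distinct: List[str] = []
    for lab in labels:
        if lab not in distinct:
            distinct.append(lab)
    if len(distinct) == 1:
        return distinct[0]
    return _factor_names(distinct, cap)


def merge_lineages(
    lineages: Sequence[Lineage], cap: int | None = MERGE_NAME_CAP
) -> Lineage:
    """Merge a group's lineages rank by rank.

    Ranks where all members agree keep the label and its provenance; ranks
    with several distinct labels get the '/'-joined merged name with
    provenance ``merged``.
    """
    if not lineages:
        raise ValueError("cannot merge an empty list of lineages")
    n_ranks = len(lineages[0])
    if any(len(l) != n_ranks for l in lineages):
        raise ValueError("lineages must share one schema")
    labels: List[str] = []
    provs: List[Provenance] = []
    for ri in range(n_ranks):
        col = [l.labels[ri] for l in lineages]
        merged = merge_labels(col, cap)
        labels.append(merged)
        if len(set(col)) == 1:
            provs.append(lineages[0].provenance[ri])
        else:
            provs.append(Provenance.MERGED)
    return Lineage(tuple(labels), tuple(provs))


def expand_merged_label(label: str) -> Set[str]:
    """Reconstruct the full name set of a '/'-joined merged label.

    Inverse of the factoring rule: each later part replaces the trailing
    ``len(part words)`` words of the first, fully printed, name.  A ``+K``
    overflow marker expands to itself (the hidden names are unrecoverable).
    """
    if "/" not in label:
        return {label}
    parts = label.split("/")
    first_words = parts[0].split()
    names = {parts[0]}
    for part in parts[1:]:
        if part.startswith("+"):
            names.add(part)
            continue
        w = part.split()
        keep = max(len(first_words) - len(w), 0)
        names.add(" ".join(first_words[:keep] + w))
    return names


def build_processed_db(
    db: ReferenceDatabase, cap: int | None = MERGE_NAME_CAP
) -> Tuple[ReferenceDatabase, pd.DataFrame]:
    """Collapse a database to one record per dereplication cluster.

    Record ids are ``drv_<8-hex>`` hashes of the representative sequence so
    output is stable across runs and input orders.  The mapping table lists
    every source id with its cluster id and cluster size.
    """
    clusters = dereplicate(db)
    records = []
    rows = []
    for c in clusters:
        merged = (
            c.merged
            if cap == MERGE_NAME_CAP
            else merge_lineages(list(c.member_lineages), cap)
        )
        records.append(RefRecord(c.cluster_id, c.representative, merged))
        for mid in c.member_ids:
            rows.append((mid, c.cluster_id, c.size))
    mapping = pd.DataFrame(rows, columns=["source_id", "cluster_id", "cluster_size"])
    return db.replace(records), mapping
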