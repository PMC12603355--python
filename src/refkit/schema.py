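"""Core domain types: rank schemas, lineages, records and databases.

A reference database couples nucleotide sequences with taxonomic lineages
over a fixed, ordered rank schema (broadest rank first).  Lineages carry a
per-rank provenance flag so that downstream curation steps can distinguish
labels read from the source database from labels created by rank
propagation or by merged-taxonomy collapsing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

__all__ = [
    "Provenance",
    "RankSchema",
    "Lineage",
    "RefRecord",
    "ReferenceDatabase",
    "DEFAULT_RANKS",
    "DEFAULT_PREFIXES",
    "normalize_sequence",
]

DEFAULT_RANKS: Tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

DEFAULT_PREFIXES: Tuple[str, ...] = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")

# Degenerate nucleotide codes are legal in reference sequences and primers.
IUPAC_LETTERS = frozenset("ACGTRYSWKMBDHVN")


class Provenance(str, enum.Enum):
    """Origin of a lineage label at one rank."""

    SOURCE = "source"
    PROPAGATED = "propagated"
    MERGED = "merged"


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and normalize RNA U to DNA T."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class RankSchema:
    """Ordered taxonomic ranks with optional per-rank label prefixes.

    Index 0 is the broadest rank (domain by default); deeper ranks follow.
    Prefixes are the ``d__``-style tags used by SILVA / Greengenes2-family
    exports; they are stripped on read and re-applied on canonical write.
    """

    ranks: Tuple[str, ...] = DEFAULT_RANKS
    prefixes: Optional[Tuple[str, ...]] = DEFAULT_PREFIXES

    def __post_init__(self) -> None:
        if not self.ranks:
            raise ValueError("rank schema must have at least one rank")
        if len(set(self.ranks)) != len(self.ranks):
            raise ValueError("rank names must be unique")
        if self.prefixes is not None and len(self.prefixes) != len(self.ranks):
            raise ValueError("prefixes must match ranks in number")
        object.__setattr__(self, "ranks", tuple(self.ranks))
        if self.prefixes is not None:
            object.__setattr__(self, "prefixes", tuple(self.prefixes))

    def __len__(self) -> int:
        return len(self.ranks)

    def index(self, rank: str) -> int:
        return self.ranks.index(rank)

    def rank_initial(self, rank: str) -> str:
        return rank[0]


@dataclass(frozen=True)
class Lineage:
    """One taxon label per rank; empty string means the rank is missing."""

    labels: Tuple[str, ...]
    provenance: Tuple[Provenance, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        if not self.provenance:
            object.__setattr__(
                self, "provenance", tuple(Provenance.SOURCE for _ in self.labels)
            )
        else:
            object.__setattr__(self, "provenance", tuple(self.provenance))
        if len(self.provenance) != len(self.labels):
            raise ValueError("provenance length must equal label length")
        for lab, prov in zip(self.labels, self.provenance):
            if prov is Provenance.PROPAGATED and not lab:
                raise ValueError("a propagated label cannot be empty")

    def __len__(self) -> int:
        return len(self.labels)

    def with_label(self, i: int, label: str, prov: Provenance) -> "Lineage":
        labels = list(self.labels)
        provs = list(self.provenance)
        labels[i] = label
        provs[i] = prov
        return Lineage(tuple(labels), tuple(provs))

    def format(self, schema: RankSchema) -> str:
        """Render as a semicolon-delimited lineage string with schema prefixes."""
        if len(self.labels) != len(schema):
            raise ValueError("lineage does not fit schema")
        prefixes = schema.prefixes or tuple("" for _ in schema.ranks)
        return "; ".join(p + lab for p, lab in zip(prefixes, self.labels))

    def plain(self) -> str:
        return "; ".join(self.labels)


@dataclass(frozen=True)
class RefRecord:
    """One reference sequence with its lineage."""

    id: str
    sequence: str
    lineage: Lineage

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        seq = normalize_sequence(self.sequence)
        bad = set(seq) - IUPAC_LETTERS
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-IUPAC letters {sorted(bad)} in sequence"
            )
        object.__setattr__(self, "sequence", seq)


class ReferenceDatabase:
    """Id-keyed collection of reference records under one rank schema."""

    def __init__(self, schema: RankSchema, records: Iterable[RefRecord] = ()) -> None:
        self.schema = schema
        self._records: Dict[str, RefRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: RefRecord) -> None:
        if len(rec.lineage) != len(self.schema):
            raise ValueError(
                f"record {rec.id!r}: lineage has {len(rec.lineage)} labels, "
                f"schema has {len(self.schema)} ranks"
            )
        if rec.id in self._records:
            raise ValueError(f"duplicate record id {rec.id!r}")
        self._records[rec.id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[RefRecord]:
        return iter(self._records.values())

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self._records

    def __getitem__(self, rec_id: str) -> RefRecord:
        return self._records[rec_id]

    def ids(self) -> List[str]:
        return list(self._records)

    def sorted_records(self) -> List[RefRecord]:
        """Records in canonical (id-sorted) order."""
        return [self._records[i] for i in sorted(self._records)]

    def replace(self, records: Iterable[RefRecord]) -> "ReferenceDatabase":
        return ReferenceDatabase(self.schema, records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferenceDatabase):
            return NotImplemented
        return self.schema == other.schema and dict(self._records) == dict(
            other._records
        )
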