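"""In-silico PCR: degenerate primer site search, amplicon extraction, locus counts.

Primer matching uses IUPAC compatible-set semantics: a position mismatches
only when the base sets encoded by the primer letter and the template
letter are disjoint, so degenerate letters on either side (including N)
never inflate the mismatch count.  The mismatch model is a per-primer
maximum substitution count with no indels, which keeps the search exact
and oracle-checkable.

Coordinates are 0-based, half-open, on the plus strand of the stored
contig; hits found on the reverse complement are mapped back and reported
with strand '-', the amplicon given in template orientation (forward
primer to reverse primer).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .schema import RefRecord, ReferenceDatabase, normalize_sequence

__all__ = [
    "IUPAC_SETS",
    "Primer",
    "PrimerPair",
    "AmpliconHit",
    "reverse_complement",
    "iupac_mismatch_count",
    "find_primer_sites",
    "amplify",
    "count_loci",
    "extract_region",
    "ExtractionReport",
]

IUPAC_SETS: Dict[str, frozenset] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Primer:
    """A PCR primer, written 5'->3', with its mismatch budget."""

    name: str
    sequence: str
    max_mismatches: int = 2

    def __post_init__(self) -> None:
        seq = normalize_sequence(self.sequence)
        if not seq:
            raise ValueError(f"primer {self.name!r}: empty sequence")
        bad = set(seq) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"primer {self.name!r}: non-IUPAC letters {sorted(bad)}")
        if not 0 <= self.max_mismatches < len(seq):
            raise ValueError(
                f"primer {self.name!r}: max_mismatches must be in [0, {len(seq) - 1}]"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse primers with a product-length window.

    ``min_product``/``max_product`` bound the full primer-to-primer span
    (both primers included); ``include_primers`` controls only whether the
    primer-covered intervals are kept in the emitted amplicon string.
    """

    forward: Primer
    reverse: Primer
    min_product: int = 50
    max_product: int = 2000
    include_primers: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.min_product <= self.max_product:
            raise ValueError("need 0 < min_product <= max_product")


@dataclass(frozen=True)
class AmpliconHit:
    """One primer-delimited interval on a contig.

    ``start``/``end`` span the full product (primers included) on the plus
    strand of the stored contig; ``amplicon`` is the extracted sequence in
    template orientation, trimmed of primer intervals unless the pair asked
    to keep them.
    """

    source_id: str
    contig: str
    start: int
    end: int
    strand: str
    fwd_mismatches: int
    rev_mismatches: int
    amplicon: str

    @property
    def total_mismatches(self) -> int:
        return self.fwd_mismatches + self.rev_mismatches

    @property
    def span(self) -> int:
        return self.end - self.start


def iupac_mismatch_count(pattern: str, window: str) -> int:
    """Count positions where the pattern and window base sets are disjoint."""
    if len(pattern) != len(window):
        raise ValueError(
            f"length mismatch: pattern {len(pattern)} vs window {len(window)}"
        )
    n = 0
    for p, w in zip(pattern, window):
        if IUPAC_SETS[p].isdisjoint(IUPAC_SETS[w]):
            n += 1
    return n


# 4-bit base masks (A=1, C=2, G=4, T=8); two letters are compatible iff
# their masks intersect, which is exactly the set-disjointness rule above.
_MASK = np.zeros(256, dtype=np.uint8)
for _letter, _bases in IUPAC_SETS.items():
    _MASK[ord(_letter)] = sum(1 << "ACGT".index(b) for b in _bases)


def find_primer_sites(seq: str, primer: Primer) -> List[Tuple[int, int]]:
    """All offsets where the primer binds within its mismatch budget.

    Returns ascending (start, mismatches) pairs; every window is scanned
    (no 3'-anchoring).
    """
    seq = normalize_sequence(seq)
    k = len(primer)
    if len(seq) < k:
        return []
    seq_masks = _MASK[np.frombuffer(seq.encode(), dtype=np.uint8)]
    pat_masks = _MASK[np.frombuffer(primer.sequence.encode(), dtype=np.uint8)]
    windows = np.lib.stride_tricks.sliding_window_view(seq_masks, k)
    mismatches = ((windows & pat_masks) == 0).sum(axis=1)
    hits = np.nonzero(mismatches <= primer.max_mismatches)[0]
    return [(int(i), int(mismatches[i])) for i in hits]


def _amplify_one_strand(
    source_id: str,
    contig_name: str,
    seq: str,
    pair: PrimerPair,
    strand: str,
    contig_len: int,
) -> List[AmpliconHit]:
    """Hits with the forward primer on ``seq``'s plus strand; ``seq`` is the
    template as read in this orientation."""
    fwd_sites = find_primer_sites(seq, pair.forward)
    if not fwd_sites:
        return []
    rc_rev = Primer(
        pair.reverse.name,
        reverse_complement(pair.reverse.sequence),
        pair.reverse.max_mismatches,
    )
    rev_sites = find_primer_sites(seq, rc_rev)
    if not rev_sites:
        return []
    lf, lr = len(pair.forward), len(pair.reverse)
    hits: List[AmpliconHit] = []
    for fs, fmm in fwd_sites:
        for rs, rmm in rev_sites:
            if rs < fs + lf:  # primers must not overlap
                continue
            span = rs + lr - fs
            if not pair.min_product <= span <= pair.max_product:
                continue
            if pair.include_primers:
                amp = seq[fs : rs + lr]
            else:
                amp = seq[fs + lf : rs]
            if strand == "+":
                start, end = fs, rs + lr
            else:
                start, end = contig_len - (rs + lr), contig_len - fs
            hits.append(
                AmpliconHit(
                    source_id=source_id,
                    contig=contig_name,
                    start=start,
                    end=end,
                    strand=strand,
                    fwd_mismatches=fmm,
                    rev_mismatches=rmm,
                    amplicon=amp,
                )
            )
    return hits


def amplify(
    source_id: str, contig_name: str, seq: str, pair: PrimerPair
) -> List[AmpliconHit]:
    """Find every primer-pair product on both strands of a contig.

    Nested and overlapping site pairs each yield a hit; sites are not
    consumed.  Hits are ordered by (start, end, strand).
    """
    seq = normalize_sequence(seq)
    n = len(seq)
    hits = _amplify_one_strand(source_id, contig_name, seq, pair, "+", n)
    hits += _amplify_one_strand(
        source_id, contig_name, reverse_complement(seq), pair, "-", n
    )
    hits.sort(key=lambda h: (h.start, h.end, h.strand))
    return hits


def count_loci(
    genomes: Dict[str, Sequence[Tuple[str, str]]], pair: PrimerPair
) -> Dict[str, int]:
    """Per-genome total amplicon count across contigs and strands.

    ``genomes`` maps genome id -> list of (contig name, sequence).
    """
    counts: Dict[str, int] = {}
    for gid, contigs in genomes.items():
        n = 0
        for contig_name, seq in contigs:
            n += len(amplify(gid, contig_name, seq, pair))
        counts[gid] = n
    return counts


@dataclass
class ExtractionReport:
    """Bookkeeping for reference-region extraction."""

    n_input: int = 0
    n_extracted: int = 0
    n_dropped: int = 0
    dropped_ids: List[str] = field(default_factory=list)
    multi_hit: Dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> Dict[str, object]:
        return {
            "n_input": self.n_input,
            "n_extracted": self.n_extracted,
            "n_dropped": self.n_dropped,
            "dropped_ids": self.dropped_ids,
            "multi_hit": self.multi_hit,
        }


def extract_region(
    db: ReferenceDatabase, pair: PrimerPair
) -> Tuple[ReferenceDatabase, ExtractionReport]:
    """Replace each reference sequence by its primer-targeted region.

    Records with no product are dropped (and counted); records with several
    products keep the best hit — fewest total mismatches, then leftmost,
    then plus strand — and the multiplicity is logged.  Lineages carry over
    unchanged.  Multi-copy products are expected for rRNA operons, hence
    the deterministic tie-break rather than an error.
    """
    report = ExtractionReport(n_input=len(db))
    new_records: List[RefRecord] = []
    for rec in db.sorted_records():
        hits = amplify(rec.id, rec.id, rec.sequence, pair)
        hits = [h for h in hits if h.amplicon]
        if not hits:
            report.n_dropped += 1
            report.dropped_ids.append(rec.id)
            continue
        if len(hits) > 1:
            report.multi_hit[rec.id] = len(hits)
        best = min(
            hits, key=lambda h: (h.total_mismatches, h.start, h.end, h.strand)
        )
        new_records.append(RefRecord(rec.id, best.amplicon, rec.lineage))
        report.n_extracted += 1
    return db.replace(new_records), report
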