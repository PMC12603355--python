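"""Deterministic synthetic fixtures: taxonomies, references, genomes, queries.

The generator emulates the structure of a 16S-style reference set so the
whole toolkit can be exercised without downloads:

* a balanced seven-rank taxonomy (three species per genus, two genera per
  family, and so on up the tree) with a configurable number of planted
  anomalies — convergent species labels, cross-rank duplicate names,
  empty deep ranks — each annotated in a ground-truth record;
* full-length reference sequences laid out as
  ``5'-flank | forward-primer site | conserved core with a species-specific
  variable window | reverse-primer site | 3'-flank``, so primer extraction
  recovers exactly one amplicon per record.  Species in an
  identical-amplicon group share the whole inter-primer region but differ
  in their flanks, which makes merged-taxonomy collapsing appear only
  after extraction;
* genomes embedding each species' amplicon locus a known number of times
  in random background (multi-copy rRNA-operon style);
* mutated query reads with per-base substitution noise and a truth table
  of expected lineages.

All randomness flows from one seed through per-component substreams, so
the same spec and seed give byte-identical outputs and adding one anomaly
type does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .pcr import IUPAC_SETS, Primer, PrimerPair, reverse_complement
from .schema import Lineage, RankSchema, RefRecord, ReferenceDatabase

__all__ = ["FixtureSpec", "FixtureTruth", "simulate_taxonomy",
           "simulate_reference_sequences", "simulate_genomes",
           "mutate_queries", "default_primer_pair", "simulate_database"]

# V3-V4 16S primers (341F / 805R), the classic clinical target region.
DEFAULT_FWD = "CCTACGGGNGGCWGCAG"
DEFAULT_REV = "GACTACHVGGGTATCTAATCC"

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureSpec:
    """Everything the generator needs; same spec + seed -> identical output."""

    n_species: int = 50
    seed: int = 0
    schema: RankSchema = field(default_factory=RankSchema)
    # anomaly plan
    n_convergent: int = 0
    n_duplicates: int = 0
    n_empty_cells: int = 0
    amplicon_groups: Tuple[int, ...] = ()
    # sequence plan
    conserved_len: int = 80
    variable_len: int = 60
    flank_len: int = 60
    fwd_primer: str = DEFAULT_FWD
    rev_primer: str = DEFAULT_REV
    # genome plan
    loci_min: int = 1
    loci_max: int = 5
    # spacers longer than the default product window, so neighbouring loci
    # can never pair into one extra in-range product
    genome_spacer_len: int = 2100

    def validate(self) -> None:
        need = (
            sum(self.amplicon_groups)
            + 2 * self.n_convergent
            + self.n_duplicates
            + -(-self.n_empty_cells // 2)
        )
        if need > self.n_species:
            raise ValueError(
                f"anomaly plan needs {need} species but only {self.n_species} requested"
            )
        if any(g < 2 for g in self.amplicon_groups):
            raise ValueError("identical-amplicon groups must have size >= 2")
        if self.n_species < 1:
            raise ValueError("need at least one species")


@dataclass
class FixtureTruth:
    """Ground truth for every planted feature."""

    convergent: List[Tuple[str, str]] = field(default_factory=list)  # (rank, label)
    duplicates: List[Tuple[str, str, str]] = field(default_factory=list)  # (id, rank, label)
    empty_cells: List[Tuple[str, str]] = field(default_factory=list)  # (id, rank)
    groups: List[List[str]] = field(default_factory=list)  # member ids
    loci: Dict[str, int] = field(default_factory=dict)  # genome id -> planted count


def _rng(spec: FixtureSpec, component: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, component])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _species_id(i: int) -> str:
    return f"sp{i:03d}"


def _base_lineage(i: int) -> Tuple[str, ...]:
    g = i // 3
    f = g // 2
    o = f // 2
    c = o // 2
    p = c // 2
    return (
        "Bacteria",
        f"Phylum{p:02d}",
        f"Class{c:02d}",
        f"Order{o:02d}",
        f"Family{f:02d}",
        f"Genus{g:03d}",
        f"Genus{g:03d} species{i:03d}",
    )


def simulate_taxonomy(spec: FixtureSpec) -> Tuple[Dict[str, Lineage], FixtureTruth]:
    """Build the lineage skeleton with exactly the planted anomaly counts.

    Anomalies are planted in disjoint species so each is recovered by
    exactly one detection downstream: a convergent species label is copied
    onto a species of another genus; a cross-rank duplicate overwrites one
    record's genus with its family label; empty cells blank the deepest
    one or two ranks of a record (deep-suffix emptiness, as in real
    exports, never introduces spurious convergence).
    """
    spec.validate()
    truth = FixtureTruth()
    labels = {_species_id(i): list(_base_lineage(i)) for i in range(spec.n_species)}
    pool = list(range(spec.n_species))

    for size in spec.amplicon_groups:
        members = [_species_id(pool.pop(0)) for _ in range(size)]
        truth.groups.append(members)

    for _ in range(spec.n_convergent):
        a = pool.pop(0)
        b_pos = next(
            (j for j, x in enumerate(pool) if x // 3 != a // 3), None
        )
        if b_pos is None:
            raise ValueError("cannot place a convergent pair in distinct genera")
        b = pool.pop(b_pos)
        label = labels[_species_id(a)][6]
        labels[_species_id(b)][6] = label
        truth.convergent.append(("species", label))

    used_families: set = set()
    for _ in range(spec.n_duplicates):
        d_pos = next(
            (j for j, x in enumerate(pool) if (x // 3) // 2 not in used_families),
            0,
        )
        d = pool.pop(d_pos)
        used_families.add((d // 3) // 2)
        rec = _species_id(d)
        labels[rec][5] = labels[rec][4]  # genus := family label
        truth.duplicates.append((rec, "genus", labels[rec][4]))

    remaining = spec.n_empty_cells
    while remaining > 0:
        e = pool.pop(0)
        rec = _species_id(e)
        labels[rec][6] = ""
        truth.empty_cells.append((rec, "species"))
        remaining -= 1
        if remaining > 0:
            labels[rec][5] = ""
            truth.empty_cells.append((rec, "genus"))
            remaining -= 1

    skeleton = {rid: Lineage(tuple(labs)) for rid, labs in labels.items()}
    return skeleton, truth


def _instantiate_primer(primer: str, rng: np.random.Generator) -> str:
    """Replace degenerate letters with one concrete compatible base."""
    out = []
    for ch in primer:
        bases = sorted(IUPAC_SETS[ch])
        out.append(bases[rng.integers(0, len(bases))])
    return "".join(out)


def simulate_reference_sequences(
    skeleton: Dict[str, Lineage], spec: FixtureSpec, truth: FixtureTruth
) -> ReferenceDatabase:
    """Attach full-length sequences to the lineage skeleton.

    Group members share the whole inter-primer core; everyone else gets a
    unique variable window, so post-extraction dereplication recovers the
    planted groups and nothing else.
    """
    rng = _rng(spec, 1)
    fwd_site = _instantiate_primer(spec.fwd_primer, rng)
    rev_site = reverse_complement(_instantiate_primer(spec.rev_primer, rng))
    half = spec.conserved_len // 2
    conserved = _random_seq(rng, spec.conserved_len)

    group_of = {m: gi for gi, members in enumerate(truth.groups) for m in members}
    group_windows: Dict[int, str] = {}
    seen_windows: set = set()

    def fresh_window() -> str:
        while True:
            w = _random_seq(rng, spec.variable_len)
            if w not in seen_windows:
                seen_windows.add(w)
                return w

    records = []
    for rid in sorted(skeleton):
        gi = group_of.get(rid)
        if gi is not None:
            if gi not in group_windows:
                group_windows[gi] = fresh_window()
            window = group_windows[gi]
        else:
            window = fresh_window()
        core = conserved[:half] + window + conserved[half:]
        seq = (
            _random_seq(rng, spec.flank_len)
            + fwd_site
            + core
            + rev_site
            + _random_seq(rng, spec.flank_len)
        )
        records.append(RefRecord(rid, seq, skeleton[rid]))
    return ReferenceDatabase(spec.schema, records)


def simulate_genomes(
    db: ReferenceDatabase, spec: FixtureSpec, truth: FixtureTruth
) -> Dict[str, List[Tuple[str, str]]]:
    """Embed each species' primer-flanked locus L times in random background.

    L is drawn uniformly from [loci_min, loci_max] per genome and recorded
    in ``truth.loci``; roughly half the insertions are reverse-complemented
    so both strands are exercised.
    """
    rng = _rng(spec, 2)
    fwd = Primer("fwd", spec.fwd_primer)
    rc_rev = Primer("rev_rc", reverse_complement(spec.rev_primer))
    genomes: Dict[str, List[Tuple[str, str]]] = {}
    for rec in db.sorted_records():
        # the planted locus is the primer-to-primer span of the reference
        start = spec.flank_len
        end = len(rec.sequence) - spec.flank_len
        locus = rec.sequence[start:end]
        L = int(rng.integers(spec.loci_min, spec.loci_max + 1))
        parts = [_random_seq(rng, spec.genome_spacer_len)]
        for _ in range(L):
            ins = locus if rng.random() < 0.5 else reverse_complement(locus)
            parts.append(ins)
            parts.append(_random_seq(rng, spec.genome_spacer_len))
        gid = f"genome_{rec.id}"
        genomes[gid] = [("contig1", "".join(parts))]
        truth.loci[gid] = L
    return genomes


def mutate_queries(
    db: ReferenceDatabase, rate: float, seed: int, prefix: str = "q_"
) -> Tuple[Dict[str, str], Dict[str, Lineage]]:
    """Per-base substitution noise over each record's sequence.

    Each position mutates with probability ``rate`` to one of the three
    other bases, uniformly.  Returns queries keyed ``<prefix><record id>``
    and the truth map of expected lineages.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("mutation rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    queries: Dict[str, str] = {}
    truth: Dict[str, Lineage] = {}
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for rec in db.sorted_records():
        seq = np.array(list(rec.sequence))
        hit = rng.random(len(seq)) < rate
        if hit.any():
            for pos in np.nonzero(hit)[0]:
                b = seq[pos]
                if b in base_idx:
                    others = [x for x in "ACGT" if x != b]
                    seq[pos] = others[rng.integers(0, 3)]
        qid = prefix + rec.id
        queries[qid] = "".join(seq)
        truth[qid] = rec.lineage
    return queries, truth


def default_primer_pair(
    max_mismatches: int = 2,
    min_product: int = 50,
    max_product: int = 2000,
    include_primers: bool = False,
    fwd: str = DEFAULT_FWD,
    rev: str = DEFAULT_REV,
) -> PrimerPair:
    """The fixture's V3-V4-style primer pair with standard search settings."""
    return PrimerPair(
        forward=Primer("341F", fwd, max_mismatches),
        reverse=Primer("805R", rev, max_mismatches),
        min_product=min_product,
        max_product=max_product,
        include_primers=include_primers,
    )


def simulate_database(spec: FixtureSpec) -> Tuple[ReferenceDatabase, FixtureTruth]:
    """Taxonomy + sequences in one call."""
    skeleton, truth = simulate_taxonomy(spec)
    db = simulate_reference_sequences(skeleton, spec, truth)
    return db, truth
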