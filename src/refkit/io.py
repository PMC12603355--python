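"""Reading, assembling and writing reference databases (QIIME-style dialect).

A reference database on disk is a sequence FASTA plus a two-column,
tab-delimited taxonomy table whose second column is a semicolon-delimited
lineage, with or without ``d__``-style rank prefixes and with or without a
``Feature ID\tTaxon`` header row.  Canonical output is byte-reproducible:
records sorted by id, lineages rendered with schema prefixes, LF endings,
and a JSON manifest of SHA-256 digests so that identical inputs always
yield identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from Bio import SeqIO

from .schema import (
    Lineage,
    Provenance,
    RankSchema,
    RefRecord,
    ReferenceDatabase,
    normalize_sequence,
)

__all__ = [
    "Manifest",
    "read_reference_fasta",
    "read_taxonomy_table",
    "parse_lineage_string",
    "assemble_database",
    "write_database",
    "read_database",
    "TOOL_VERSION",
]

TOOL_VERSION = "refkit 0.1.0"

SEQ_FILE = "sequences.fasta"
TAX_FILE = "taxonomy.tsv"
MANIFEST_FILE = "manifest.json"

_HEADER_TOKENS = {"feature id", "feature-id", "featureid", "#otu id", "id", "seqid"}


@dataclass
class Manifest:
    """Reproducibility record: per-file SHA-256 digests plus a parameter snapshot."""

    entries: List[Dict[str, object]] = field(default_factory=list)
    version: str = TOOL_VERSION
    params: Dict[str, object] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"entries": self.entries, "version": self.version, "params": self.params},
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "Manifest":
        d = json.loads(text)
        return cls(entries=d["entries"], version=d["version"], params=d["params"])

    def verify(self, directory: Path) -> bool:
        """Recompute digests over the named files; True iff all match."""
        for e in self.entries:
            p = Path(directory) / str(e["file"])
            if not p.exists():
                return False
            data = p.read_bytes()
            if len(data) != e["bytes"] or _sha256(data) != e["sha256"]:
                return False
        return True


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def read_reference_fasta(path: str | Path) -> Dict[str, str]:
    """Read a FASTA file into an id -> sequence map.

    Ids are the header token before the first whitespace.  Sequences are
    uppercased with U normalized to T.  Duplicate ids and empty files are
    hard errors.
    """
    seqs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seqs[rec.id] = normalize_sequence(str(rec.seq))
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return seqs


def parse_lineage_string(text: str, schema: RankSchema) -> Lineage:
    """Parse one semicolon-delimited lineage, handling optional rank prefixes.

    Prefixes must be used consistently within a lineage (all labels carry a
    schema prefix, or none do); short lineages are padded with empty labels
    at the deep end; lineages longer than the schema are an error.
    """
    parts = [p.strip() for p in text.split(";")]
    # A trailing separator ("...;") yields one empty tail part; keep interior
    # empties (genuinely missing ranks) but drop a single trailing empty only
    # when the lineage would otherwise overflow the schema.
    if len(parts) > len(schema) and parts[-1] == "":
        parts = parts[:-1]
    if len(parts) > len(schema):
        raise ValueError(
            f"lineage has {len(parts)} labels but schema has {len(schema)} ranks: "
            f"{text!r}"
        )
    prefixes = schema.prefixes
    labels: List[str] = []
    if prefixes is not None:
        non_empty = [p for p in parts if p]
        prefixed = [
            p
            for p in non_empty
            if any(p.startswith(pref) for pref in prefixes if pref)
        ]
        if prefixed and len(prefixed) != len(non_empty):
            raise ValueError(
                f"mixed prefixed and unprefixed labels within one lineage: {text!r}"
            )
        use_prefixes = bool(prefixed)
    else:
        use_prefixes = False
    for i, part in enumerate(parts):
        if use_prefixes and part:
            pref = prefixes[i] if prefixes else ""
            if pref and part.startswith(pref):
                part = part[len(pref) :]
            else:
                # Prefixed dialect but this label carries another rank's tag:
                # strip whichever schema prefix matches.
                for cand in prefixes or ():
                    if cand and part.startswith(cand):
                        part = part[len(cand) :]
                        break
        labels.append(part.strip())
    labels.extend("" for _ in range(len(schema) - len(labels)))
    return Lineage(tuple(labels))


def read_taxonomy_table(path: str | Path, schema: RankSchema) -> Dict[str, Lineage]:
    """Read a two-column taxonomy TSV into an id -> Lineage map."""
    taxa: Dict[str, Lineage] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two tab-delimited columns"
                )
            rec_id, lineage_text = cols[0].strip(), cols[1]
            if lineno == 1 and rec_id.lower() in _HEADER_TOKENS:
                continue
            if rec_id in taxa:
                raise ValueError(f"duplicate taxonomy id {rec_id!r} in {path}")
            taxa[rec_id] = parse_lineage_string(lineage_text, schema)
    if not taxa:
        raise ValueError(f"no taxonomy rows found in {path}")
    return taxa


def assemble_database(
    seqs: Dict[str, str],
    taxa: Dict[str, Lineage],
    schema: RankSchema,
    on_orphan: str = "strict",
) -> ReferenceDatabase:
    """Inner-join sequences and taxonomies on id.

    ``on_orphan='strict'`` errors on any id present in only one input;
    ``'intersect'`` drops orphans and records the counts on the returned
    database as ``db.orphan_report``.
    """
    if on_orphan not in ("strict", "intersect"):
        raise ValueError(f"unknown orphan policy {on_orphan!r}")
    seq_only = sorted(set(seqs) - set(taxa))
    tax_only = sorted(set(taxa) - set(seqs))
    if (seq_only or tax_only) and on_orphan == "strict":
        preview = ", ".join((seq_only + tax_only)[:10])
        raise ValueError(
            f"{len(seq_only)} sequence(s) without taxonomy and {len(tax_only)} "
            f"taxonomy row(s) without sequence (e.g. {preview})"
        )
    shared = sorted(set(seqs) & set(taxa))
    db = ReferenceDatabase(
        schema, (RefRecord(i, seqs[i], taxa[i]) for i in shared)
    )
    db.orphan_report = {  # type: ignore[attr-defined]
        "sequences_without_taxonomy": len(seq_only),
        "taxonomies_without_sequence": len(tax_only),
    }
    return db


def write_database(
    db: ReferenceDatabase,
    outdir: str | Path,
    params: Optional[Dict[str, object]] = None,
) -> Manifest:
    """Write the canonical FASTA + taxonomy TSV + manifest triple.

    Output is byte-identical for identical databases regardless of record
    insertion order: records are sorted by id and lines use LF endings.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = db.sorted_records()

    fasta_lines = []
    tax_lines = []
    for rec in records:
        fasta_lines.append(f">{rec.id}\n{rec.sequence}\n")
        tax_lines.append(f"{rec.id}\t{rec.lineage.format(db.schema)}\n")
    fasta_bytes = "".join(fasta_lines).encode()
    tax_bytes = "".join(tax_lines).encode()

    (outdir / SEQ_FILE).write_bytes(fasta_bytes)
    (outdir / TAX_FILE).write_bytes(tax_bytes)

    manifest = Manifest(
        entries=[
            {"file": SEQ_FILE, "bytes": len(fasta_bytes), "sha256": _sha256(fasta_bytes)},
            {"file": TAX_FILE, "bytes": len(tax_bytes), "sha256": _sha256(tax_bytes)},
        ],
        params=dict(params or {}),
    )
    (outdir / MANIFEST_FILE).write_text(manifest.to_json() + "\n", encoding="utf-8")
    return manifest


def read_database(
    directory: str | Path,
    schema: Optional[RankSchema] = None,
    on_orphan: str = "strict",
) -> ReferenceDatabase:
    """Read a database directory written by :func:`write_database`."""
    directory = Path(directory)
    schema = schema or RankSchema()
    seqs = read_reference_fasta(directory / SEQ_FILE)
    taxa = read_taxonomy_table(directory / TAX_FILE, schema)
    return assemble_database(seqs, taxa, schema, on_orphan=on_orphan)
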