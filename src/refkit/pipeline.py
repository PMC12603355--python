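"""The end-to-end database-processing pipeline: validate → curate → extract
→ dereplicate → merge.

Order matters: convergence is checked on the raw taxonomy (it is a source
defect, not something curation should paper over), duplicate names are
resolved before rank propagation so propagation artifacts never trigger
suffixing, and primer-region extraction precedes dereplication because
taxa are only indistinguishable within the target region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import pandas as pd

from .curation import CurationReport, curate
from .derep import MERGE_NAME_CAP, build_processed_db
from .pcr import ExtractionReport, PrimerPair, extract_region
from .schema import ReferenceDatabase

__all__ = ["ProcessResult", "process_database"]


@dataclass
class ProcessResult:
    """All intermediate and final products of one processing run."""

    curated: ReferenceDatabase
    extracted: ReferenceDatabase
    processed: ReferenceDatabase
    mapping: pd.DataFrame
    curation_report: CurationReport
    extraction_report: ExtractionReport


def process_database(
    db: ReferenceDatabase,
    pair: PrimerPair,
    duplicates: str = "suffix",
    allow_convergence: bool = False,
    merge_cap: Optional[int] = MERGE_NAME_CAP,
) -> ProcessResult:
    """Run the full preprocessing pipeline on a raw reference database."""
    curated, curation_report = curate(
        db, duplicates=duplicates, allow_convergence=allow_convergence
    )
    extracted, extraction_report = extract_region(curated, pair)
    processed, mapping = build_processed_db(extracted, cap=merge_cap)
    return ProcessResult(
        curated=curated,
        extracted=extracted,
        processed=processed,
        mapping=mapping,
        curation_report=curation_report,
        extraction_report=extraction_report,
    )
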