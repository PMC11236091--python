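"""End-to-end orchestration: PSMs -> events -> the three result tables."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import error_rates as _rates
from .io_formats import ParseReport, PsmRecord, validate_cds, write_outputs
from .substitution_detection import (
    DetectionConfig,
    DetectionResult,
    detect_substitutions,
)

__all__ = ["DatasetResult", "analyze_dataset", "analyze_and_write"]


@dataclass
class DatasetResult:
    """All per-dataset pipeline output."""

    detection: DetectionResult
    peptide_counts: pd.DataFrame
    codon_counts: pd.DataFrame
    substitutions: pd.DataFrame
    occupancy_skipped: int


def analyze_dataset(
    psms: Sequence[PsmRecord],
    proteins: Mapping[str, str],
    cds: Mapping[str, str],
    mods: pd.DataFrame,
    config: DetectionConfig | None = None,
    normalized_site_rate: bool = False,
    valid_accessions: set[str] | None = None,
) -> DatasetResult:
    """Run detection and compute all three result tables for one dataset.

    Codon occupancy (the rate denominator) counts the zero-shift PSMs plus
    the PSMs underlying accepted events, at PSM granularity.
    """
    config = DetectionConfig() if config is None else config
    if valid_accessions is None:
        valid_accessions = validate_cds(proteins, cds).valid
    detection = detect_substitutions(psms, proteins, cds, mods, config, valid_accessions)
    counted_psms = detection.zero_shift_psms + detection.accepted_psms
    occupancy, skipped = _rates.codon_occupancy(counted_psms, proteins, cds, valid_accessions)
    codon_counts = _rates.codon_error_rates(occupancy, detection.events)
    anchored = [
        p
        for p in counted_psms
        if p.protein_id in valid_accessions
        and proteins[p.protein_id][p.protein_start - 1 : p.protein_start - 1 + len(p.peptide)]
        == p.peptide
    ]
    peptide_counts = _rates.protein_peptide_counts(anchored, detection.events)
    substitutions = _rates.substitutions_frame(
        detection.events, normalized_site_rate=normalized_site_rate
    )
    return DatasetResult(detection, peptide_counts, codon_counts, substitutions, skipped)


def analyze_and_write(
    psms: Sequence[PsmRecord],
    proteins: Mapping[str, str],
    cds: Mapping[str, str],
    mods: pd.DataFrame,
    out_dir: str | Path,
    config: DetectionConfig | None = None,
    normalized_site_rate: bool = False,
) -> DatasetResult:
    """Analyze one dataset and write its three CSVs into ``out_dir``."""
    result = analyze_dataset(
        psms, proteins, cds, mods, config, normalized_site_rate=normalized_site_rate
    )
    write_outputs(result.peptide_counts, result.codon_counts, result.substitutions, out_dir)
    return result
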