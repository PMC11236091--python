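"""Translation error-rate statistics computed from detection output.

Two published styles of rate are supported:

* **codon-aggregated, count-based** — the number of times codon *i* was
  observed mistranslated divided by the total number of times codon *i*
  was observed in any peptide (all at PSM granularity, so numerator and
  denominator are commensurate);
* **site-specific, intensity-based** — the ratio of summed MS1 intensities
  of the substituted peptide to its error-free base peptide at one site.

Plus per-protein peptide counts (PSMs with / without an error) and pooling
of codon tables across datasets (counts are summed, rates recomputed).
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    PEPTIDE_COUNT_COLUMNS,
    PsmRecord,
    SUBSTITUTION_COLUMNS,
)
from .substitution_detection import (
    CODON_TO_AA,
    DESTINATION_CLASSES,
    SENSE_CODONS,
    SubstitutionEvent,
)

__all__ = [
    "codon_occupancy",
    "codon_error_rates",
    "protein_peptide_counts",
    "site_specific_rates",
    "substitutions_frame",
    "pool_datasets",
    "CODON_COUNT_COLUMNS",
]

CODON_COUNT_COLUMNS = (
    ["codon", "total_observations", "error_observations", "codon_error_rate"]
    + list(DESTINATION_CLASSES)
    + ["no_coverage"]
)


def codon_occupancy(
    psms: Iterable[PsmRecord],
    proteins: Mapping[str, str],
    cds: Mapping[str, str],
    valid_accessions: set[str],
) -> tuple[pd.Series, int]:
    """Per-codon observation totals over a set of anchored PSMs.

    Every residue position of every counted PSM contributes one observation
    to its codon (PSM-level counting: identical spectra count separately).
    PSMs that fail the anchor check or reference an unvalidated accession
    are skipped; the second return value counts them.
    """
    counts = Counter()
    skipped = 0
    # group identical (protein, start, length) anchors so each unique
    # peptide's codons are sliced once
    grouped: Counter[tuple[str, int, int]] = Counter()
    for psm in psms:
        seq = proteins.get(psm.protein_id)
        start = psm.protein_start - 1
        if (
            psm.protein_id not in valid_accessions
            or seq is None
            or seq[start : start + len(psm.peptide)] != psm.peptide
        ):
            skipped += 1
            continue
        grouped[(psm.protein_id, psm.protein_start, len(psm.peptide))] += 1
    for (accession, start, length), n in grouped.items():
        cds_seq = cds[accession]
        for pos in range(start, start + length):  # 1-based protein positions
            codon = cds_seq[3 * (pos - 1) : 3 * pos]
            counts[codon] += n
    total = pd.Series(0, index=list(SENSE_CODONS), dtype=int)
    for codon, n in counts.items():
        total[codon] = n
    return total, skipped


def codon_error_rates(
    occupancy: pd.Series,
    events: Sequence[SubstitutionEvent],
) -> pd.DataFrame:
    """Build the codon count table from occupancy totals and accepted events.

    One row per sense codon: total observations, error observations (PSM
    level, i.e. each event contributes its spectrum count), the
    count-based error rate, one column per destination class, and a
    ``no_coverage`` flag for codons never observed (their rate is reported
    as 0 rather than NaN for stable CSV output).
    """
    table = pd.DataFrame(
        0,
        index=list(SENSE_CODONS),
        columns=["total_observations", "error_observations"] + list(DESTINATION_CLASSES),
        dtype=int,
    )
    table["total_observations"] = occupancy.reindex(table.index).fillna(0).astype(int)
    for event in events:
        n = event.spectrum_count
        if table.at[event.codon, "total_observations"] == 0:
            raise ValueError(
                f"event at codon {event.codon} but codon has zero occupancy; "
                "occupancy must include the PSMs underlying accepted events"
            )
        table.at[event.codon, "error_observations"] += n
        table.at[event.codon, event.destination_class] += n
    if (table["error_observations"] > table["total_observations"]).any():
        raise ValueError("error observations exceed total observations")
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = table["error_observations"] / table["total_observations"]
    table["codon_error_rate"] = rate.fillna(0.0)
    table["no_coverage"] = table["total_observations"] == 0
    table = table.reset_index(names="codon")
    return table[CODON_COUNT_COLUMNS]


def protein_peptide_counts(
    psms: Iterable[PsmRecord],
    events: Sequence[SubstitutionEvent],
) -> pd.DataFrame:
    """Per-protein PSM counts with and without an accepted error.

    ``psms`` must be the PSMs actually counted — the zero-shift PSMs plus
    the PSMs underlying accepted events; a PSM is "with error" exactly when
    it underlies an event.  Proteins absent from ``psms`` do not appear.
    """
    total: Counter[str] = Counter()
    for psm in psms:
        total[psm.protein_id] += 1
    with_error: Counter[str] = Counter()
    for event in events:
        with_error[event.protein_id] += event.spectrum_count
    rows = []
    for protein_id in sorted(total):
        n = total[protein_id]
        err = with_error.get(protein_id, 0)
        rows.append(
            {
                "protein_id": protein_id,
                "peptides_total": n,
                "peptides_with_error": err,
                "peptides_without_error": n - err,
                "protein_error_rate": err / n,
            }
        )
    return pd.DataFrame(rows, columns=PEPTIDE_COUNT_COLUMNS)


def site_specific_rates(
    events: Sequence[SubstitutionEvent],
    normalized: bool = False,
) -> list[float | None]:
    """Intensity-based site-specific error rate per event.

    The default form is the plain ratio I_error / I_base (it may exceed 1
    and is reported as-is); ``normalized=True`` uses the bounded form
    I_error / (I_error + I_base).  The rate is absent (None, not 0) when
    either intensity is missing or the denominator is zero.
    """
    rates: list[float | None] = []
    for event in events:
        ie, ib = event.intensity_error, event.intensity_base
        if ie is None or ib is None:
            rates.append(None)
            continue
        denom = ie + ib if normalized else ib
        rates.append(ie / denom if denom > 0 else None)
    return rates


def substitutions_frame(
    events: Sequence[SubstitutionEvent],
    normalized_site_rate: bool = False,
) -> pd.DataFrame:
    """The substitutions result table, one row per accepted event."""
    rates = site_specific_rates(events, normalized=normalized_site_rate)
    rows = []
    for event, rate in zip(events, rates):
        rows.append(
            {
                "dataset_id": event.dataset_id,
                "protein_id": event.protein_id,
                "protein_position": event.protein_position,
                "codon": event.codon,
                "origin_aa": event.origin_aa,
                "destination_class": event.destination_class,
                "peptide": event.peptide,
                "delta_mass": event.delta_mass,
                "spectrum_count": event.spectrum_count,
                "intensity_error": event.intensity_error,
                "intensity_base": event.intensity_base,
                "site_error_rate": rate,
            }
        )
    return pd.DataFrame(rows, columns=SUBSTITUTION_COLUMNS)


def pool_datasets(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Pool codon count tables by summing counts and recomputing rates.

    Rates are recomputed from pooled counts, never averaged, so datasets
    with more observations weigh proportionally more.
    """
    if not tables:
        raise ValueError("nothing to pool")
    count_cols = ["total_observations", "error_observations"] + list(DESTINATION_CLASSES)
    pooled = tables[0].set_index("codon")[count_cols].copy()
    for table in tables[1:]:
        other = table.set_index("codon")[count_cols]
        if not pooled.index.equals(other.index):
            raise ValueError("codon count tables cover different codon universes")
        pooled += other
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = pooled["error_observations"] / pooled["total_observations"]
    pooled["codon_error_rate"] = rate.fillna(0.0)
    pooled["no_coverage"] = pooled["total_observations"] == 0
    pooled = pooled.reset_index()
    return pooled[CODON_COUNT_COLUMNS]
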