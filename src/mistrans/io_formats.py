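"""Readers and writers for the external file formats of the pipeline.

Covers open-search PSM tables (MSFragger ``psm.tsv`` dialect), protein and
coding-sequence FASTA, the curated modification-mass snapshot, tRNA abundance
tables, and the three CSV result files (peptide counts, codon counts,
substitutions).  All parsing is strict: rows that violate an invariant are
either skipped-and-counted (row-level problems) or raise (file-level
problems), so downstream code never sees malformed records.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "PsmRecord",
    "ParseReport",
    "CdsValidationReport",
    "read_psm_table",
    "read_fasta",
    "read_cds",
    "validate_cds",
    "read_modification_table",
    "load_default_modifications",
    "read_trna_table",
    "write_outputs",
    "read_peptide_counts",
    "read_codon_counts",
    "read_substitutions",
    "CANONICAL_RESIDUES",
]

#: The 20 canonical residues; B/J/O/U/X/Z records are rejected at parse time.
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_PEPTIDE_RE = re.compile(f"^[{CANONICAL_RESIDUES}]+$")
_DNA_RE = re.compile("^[ACGT]+$")
_RNA3_RE = re.compile("^[ACGU]{3}$")

#: Default logical-name -> header mapping for the MSFragger psm.tsv dialect.
DEFAULT_PSM_COLUMNS: Mapping[str, str] = {
    "spectrum": "Spectrum",
    "peptide": "Peptide",
    "delta_mass": "Delta Mass",
    "protein": "Protein",
    "protein_start": "Protein Start",
    "intensity": "Intensity",
    "assigned_mods": "Assigned Modifications",
}
_REQUIRED_PSM_FIELDS = ("spectrum", "peptide", "delta_mass", "protein", "protein_start")


@dataclass(slots=True)
class PsmRecord:
    """One peptide-spectrum match from an open search.

    ``delta_mass`` is the signed monoisotopic difference (Da) between the
    observed precursor and the theoretical mass of the database peptide.
    ``protein_start`` is the 1-based index of the peptide's first residue in
    the protein.
    """

    spectrum_id: str
    peptide: str
    delta_mass: float
    protein_id: str
    protein_start: int
    intensity: float | None = None
    assigned_mods: str | None = None
    dataset_id: str = ""


@dataclass
class ParseReport:
    """Row-level accounting for a PSM table parse.

    Invariant: ``rows_read == records_returned + rows_skipped``.
    """

    rows_read: int = 0
    records_returned: int = 0
    skipped: Counter = field(default_factory=Counter)

    @property
    def rows_skipped(self) -> int:
        return sum(self.skipped.values())


def _split_proteins(value: str) -> list[str]:
    return [tok for tok in re.split(r"[,;\s]+", value.strip()) if tok]


def read_psm_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    dataset_id: str | None = None,
) -> tuple[list[PsmRecord], ParseReport]:
    """Parse an open-search PSM table (tab-separated, psm.tsv dialect).

    ``column_map`` overrides the default MSFragger header names per logical
    field (keys: spectrum, peptide, delta_mass, protein, protein_start,
    intensity, assigned_mods) to absorb dialect drift across versions.

    Returns the accepted records plus a :class:`ParseReport`; rows with
    unparseable required fields, non-canonical residues or ambiguous
    multi-protein mapping are skipped and counted by reason.
    """
    path = Path(path)
    columns = dict(DEFAULT_PSM_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(columns)
        if unknown:
            raise ValueError(f"unknown logical column names in column_map: {sorted(unknown)}")
        columns.update(column_map)

    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValueError(f"PSM table {path} is empty") from None
    if frame.empty and frame.columns.empty:
        raise ValueError(f"PSM table {path} is empty")

    for logical in _REQUIRED_PSM_FIELDS:
        if columns[logical] not in frame.columns:
            raise ValueError(
                f"PSM table {path} lacks required column {columns[logical]!r} "
                f"(logical field {logical!r}; remap it via column_map)"
            )
    has_intensity = columns["intensity"] in frame.columns
    has_mods = columns["assigned_mods"] in frame.columns

    if dataset_id is None:
        dataset_id = path.stem

    records: list[PsmRecord] = []
    report = ParseReport()
    for row in frame.itertuples(index=False):
        report.rows_read += 1
        # itertuples mangles header names containing spaces; index positionally
        vals = {logical: row[frame.columns.get_loc(columns[logical])] for logical in _REQUIRED_PSM_FIELDS}
        peptide = str(vals["peptide"]).strip()
        if not _PEPTIDE_RE.match(peptide):
            report.skipped["non-canonical residue"] += 1
            continue
        proteins = _split_proteins(str(vals["protein"]))
        if len(proteins) != 1:
            report.skipped["multi-protein mapping"] += 1
            continue
        try:
            delta = float(vals["delta_mass"])
            if not np.isfinite(delta):
                raise ValueError
        except (TypeError, ValueError):
            report.skipped["unparseable delta mass"] += 1
            continue
        try:
            start = int(float(vals["protein_start"]))
            if start < 1:
                raise ValueError
        except (TypeError, ValueError):
            report.skipped["bad protein start"] += 1
            continue
        intensity: float | None = None
        if has_intensity:
            raw = str(row[frame.columns.get_loc(columns["intensity"])]).strip()
            if raw not in ("", "nan", "NA"):
                intensity = float(raw)
                if intensity < 0:
                    raise ValueError(
                        f"negative intensity {intensity} in row {report.rows_read} of {path}"
                    )
        mods: str | None = None
        if has_mods:
            raw = str(row[frame.columns.get_loc(columns["assigned_mods"])]).strip()
            mods = raw or None
        records.append(
            PsmRecord(
                spectrum_id=str(vals["spectrum"]),
                peptide=peptide,
                delta_mass=delta,
                protein_id=proteins[0],
                protein_start=start,
                intensity=intensity,
                assigned_mods=mods,
                dataset_id=dataset_id,
            )
        )
    report.records_returned = len(records)
    return records, report


def _read_fasta_map(path: str | Path, accession_regex: str | None) -> dict[str, str]:
    pattern = re.compile(accession_regex) if accession_regex else None
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = rec.id.split()[0]
        if pattern is not None:
            m = pattern.search(rec.description)
            if m:
                accession = m.group(1)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for accession {accession!r} in {path}")
        if accession in out:
            raise ValueError(f"duplicate accession {accession!r} in {path}")
        out[accession] = seq
    return out


def read_fasta(path: str | Path, accession_regex: str | None = None) -> dict[str, str]:
    """Read a protein FASTA into an accession -> sequence map.

    The accession is the first whitespace-delimited token of the header;
    ``accession_regex`` (with one capture group) overrides this for e.g.
    UniProt ``sp|ACC|NAME`` headers: ``r"sp\\|([^|]+)\\|"``.
    """
    return _read_fasta_map(path, accession_regex)


def read_cds(path: str | Path, accession_regex: str | None = None) -> dict[str, str]:
    """Read a coding-sequence (nucleotide) FASTA, validating the DNA alphabet
    and that every sequence length is divisible by 3."""
    db = _read_fasta_map(path, accession_regex)
    for accession, seq in db.items():
        if not _DNA_RE.match(seq):
            raise ValueError(f"CDS {accession!r} contains non-ACGT characters")
        if len(seq) % 3 != 0:
            raise ValueError(f"CDS {accession!r} length {len(seq)} not divisible by 3")
    return db


@dataclass
class CdsValidationReport:
    """Cross-check of a protein database against its coding sequences.

    Every accession of either database lands in exactly one of the four
    buckets; only ``valid`` accessions may be used for codon assignment.
    """

    valid: set[str] = field(default_factory=set)
    mismatch: list[str] = field(default_factory=list)
    missing_protein: list[str] = field(default_factory=list)
    missing_cds: list[str] = field(default_factory=list)


def translate_cds(seq: str) -> str:
    """Standard-genetic-code translation, dropping one trailing stop codon."""
    aa = str(Seq(seq).translate(table=1))
    if aa.endswith("*"):
        aa = aa[:-1]
    return aa


def validate_cds(proteins: Mapping[str, str], cds: Mapping[str, str]) -> CdsValidationReport:
    """Check that each CDS translates (standard code, trailing stop dropped)
    to the protein sequence of the same accession."""
    report = CdsValidationReport()
    for accession in sorted(set(proteins) | set(cds)):
        if accession not in cds:
            report.missing_cds.append(accession)
        elif accession not in proteins:
            report.missing_protein.append(accession)
        elif translate_cds(cds[accession]) == proteins[accession]:
            report.valid.add(accession)
        else:
            report.mismatch.append(accession)
    return report


def read_modification_table(path: str | Path) -> pd.DataFrame:
    """Read a modification-mass table (TSV: name, delta_mass, optional
    composition column documenting the elemental formula)."""
    frame = pd.read_csv(path, sep="\t")
    for col in ("name", "delta_mass"):
        if col not in frame.columns:
            raise ValueError(f"modification table {path} lacks column {col!r}")
    if frame["name"].duplicated().any():
        dupes = sorted(frame.loc[frame["name"].duplicated(), "name"])
        raise ValueError(f"duplicate modification names: {dupes}")
    if not np.isfinite(frame["delta_mass"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite modification delta mass")
    frame["delta_mass"] = frame["delta_mass"].astype(float)
    return frame.reset_index(drop=True)


def load_default_modifications() -> pd.DataFrame:
    """The curated offline modification snapshot shipped with the package."""
    with resources.as_file(resources.files("mistrans") / "data" / "modifications.tsv") as p:
        return read_modification_table(p)


def read_trna_table(path: str | Path) -> pd.DataFrame:
    """Read a tRNA abundance table (TSV: anticodon, amino_acid, abundance).

    Anticodons are RNA 3-mers written 5'->3'.  Abundances must be positive.
    The same anticodon listed with two different amino acids is rejected:
    the competition model needs an unambiguous anticodon -> amino-acid map.
    """
    frame = pd.read_csv(path, sep="\t")
    for col in ("anticodon", "amino_acid", "abundance"):
        if col not in frame.columns:
            raise ValueError(f"tRNA table {path} lacks column {col!r}")
    frame["anticodon"] = frame["anticodon"].astype(str).str.upper().str.replace("T", "U")
    bad = [a for a in frame["anticodon"] if not _RNA3_RE.match(a)]
    if bad:
        raise ValueError(f"invalid anticodons (need RNA 3-mers): {sorted(set(bad))}")
    bad_aa = [a for a in frame["amino_acid"] if a not in CANONICAL_RESIDUES]
    if bad_aa:
        raise ValueError(f"invalid amino acids in tRNA table: {sorted(set(bad_aa))}")
    if (frame["abundance"].astype(float) <= 0).any():
        raise ValueError("tRNA abundances must be strictly positive")
    if frame["anticodon"].duplicated().any():
        dupes = sorted(frame.loc[frame["anticodon"].duplicated(), "anticodon"])
        raise ValueError(f"duplicate anticodons in tRNA table: {dupes}")
    frame["abundance"] = frame["abundance"].astype(float)
    return frame.reset_index(drop=True)


# ---------------------------------------------------------------------------
# result tables

PEPTIDE_COUNT_COLUMNS = [
    "protein_id",
    "peptides_total",
    "peptides_with_error",
    "peptides_without_error",
    "protein_error_rate",
]
SUBSTITUTION_COLUMNS = [
    "dataset_id",
    "protein_id",
    "protein_position",
    "codon",
    "origin_aa",
    "destination_class",
    "peptide",
    "delta_mass",
    "spectrum_count",
    "intensity_error",
    "intensity_base",
    "site_error_rate",
]


def write_outputs(
    peptide_counts: pd.DataFrame,
    codon_counts: pd.DataFrame,
    substitutions: pd.DataFrame,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the three per-dataset result files.

    Emits ``peptide_counts.csv``, ``codon_counts.csv`` and
    ``substitutions.csv`` into ``out_dir`` (created if needed) with the
    documented headers, and returns the paths.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    paths = {
        "peptide_counts": out_dir / "peptide_counts.csv",
        "codon_counts": out_dir / "codon_counts.csv",
        "substitutions": out_dir / "substitutions.csv",
    }
    peptide_counts.to_csv(paths["peptide_counts"], index=False)
    codon_counts.to_csv(paths["codon_counts"], index=False)
    substitutions.to_csv(paths["substitutions"], index=False)
    return paths


def read_peptide_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_codon_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_substitutions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
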