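"""Detection of amino-acid misincorporations from open-search mass shifts.

A substitution a->b in a peptide shifts the precursor mass by the residue
mass difference m(b) - m(a).  Given a PSM with a non-zero delta mass, the
detector enumerates every (position, destination) whose expected shift
matches the observed delta within tolerance and accepts the PSM as a
substitution event only if

  (i)   the same peptide was also observed without a mass shift (the "base
        peptide" — evidence the unmodified form is really there),
  (ii)  the shift is uniquely assignable to one position/destination, and
  (iii) the shift cannot instead be explained by a known post-translational
        modification mass.

Accepted events are anchored to the protein and mapped to the codon read
from the coding sequence, so error rates can be aggregated per codon.

Isoleucine and leucine are isobaric: destinations I and L are merged into a
single class ``"I/L"`` (origins stay distinct — the origin is read from the
database sequence, not inferred from mass), and the zero-shift I<->L
channels are undetectable and excluded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable
from pyteomics import mass as _pyteomics_mass

from .io_formats import CANONICAL_RESIDUES, PsmRecord, validate_cds

__all__ = [
    "AMINO_ACIDS",
    "SENSE_CODONS",
    "CODON_TO_AA",
    "ILE_LEU_CLASS",
    "DESTINATION_CLASSES",
    "RESIDUE_FORMULAS",
    "residue_masses",
    "destination_class_of",
    "substitution_deltas",
    "DetectionConfig",
    "SubstitutionCandidate",
    "SubstitutionEvent",
    "BaseEvidence",
    "FilterReport",
    "DetectionResult",
    "enumerate_candidates",
    "ptm_conflict",
    "base_peptide_index",
    "detect_substitutions",
]

AMINO_ACIDS = CANONICAL_RESIDUES
ILE_LEU_CLASS = "I/L"

#: Destination classes: the 18 residues distinguishable by mass plus the
#: merged isobaric I/L class.
DESTINATION_CLASSES = tuple(sorted([aa for aa in AMINO_ACIDS if aa not in "IL"] + [ILE_LEU_CLASS]))

_standard_table = CodonTable.unambiguous_dna_by_id[1]
#: codon -> amino acid for the 61 sense codons of the standard genetic code.
CODON_TO_AA: Mapping[str, str] = MappingProxyType(dict(_standard_table.forward_table))
SENSE_CODONS = tuple(sorted(CODON_TO_AA))

#: Elemental composition of each amino-acid residue (peptide-bond form,
#: i.e. the free amino acid minus water).
RESIDUE_FORMULAS: Mapping[str, str] = MappingProxyType({
    "G": "C2H3NO",
    "A": "C3H5NO",
    "S": "C3H5NO2",
    "P": "C5H7NO",
    "V": "C5H9NO",
    "T": "C4H7NO2",
    "C": "C3H5NOS",
    "L": "C6H11NO",
    "I": "C6H11NO",
    "N": "C4H6N2O2",
    "D": "C4H5NO3",
    "Q": "C5H8N2O2",
    "K": "C6H12N2O",
    "E": "C5H7NO3",
    "M": "C5H9NOS",
    "H": "C6H7N3O",
    "F": "C9H9NO",
    "R": "C6H12N4O",
    "Y": "C9H9NO2",
    "W": "C11H10N2O",
})

_RESIDUE_MASSES: Mapping[str, float] | None = None


def residue_masses() -> Mapping[str, float]:
    """Monoisotopic residue masses (Da), computed from elemental composition.

    Masses are derived from :data:`RESIDUE_FORMULAS` using the NIST
    monoisotopic atomic masses, not typed-in decimals; I and L are exactly
    equal by construction.  The returned mapping is immutable and cached.
    """
    global _RESIDUE_MASSES
    if _RESIDUE_MASSES is None:
        _RESIDUE_MASSES = MappingProxyType({
            aa: _pyteomics_mass.calculate_mass(formula=formula)
            for aa, formula in RESIDUE_FORMULAS.items()
        })
    return _RESIDUE_MASSES


def destination_class_of(aa: str) -> str:
    """Map an amino acid to its mass-distinguishable destination class."""
    if aa in "IL":
        return ILE_LEU_CLASS
    if aa not in AMINO_ACIDS:
        raise ValueError(f"not a canonical amino acid: {aa!r}")
    return aa


_DELTAS: Mapping[tuple[str, str], float] | None = None


def substitution_deltas(
    masses: Mapping[str, float] | None = None,
) -> Mapping[tuple[str, str], float]:
    """Expected mass shift for every detectable substitution channel.

    Keys are ``(origin_aa, destination_class)`` over all ordered pairs with
    distinct origin and destination; destinations I and L are merged into
    :data:`ILE_LEU_CLASS` and the zero-shift I<->L channels (the only exact
    zero) are excluded entirely.
    """
    global _DELTAS
    if masses is None and _DELTAS is not None:
        return _DELTAS
    m = residue_masses() if masses is None else masses
    class_mass = {cls: m[cls[0]] for cls in DESTINATION_CLASSES}  # "I/L" -> m["I"]
    deltas: dict[tuple[str, str], float] = {}
    for origin in AMINO_ACIDS:
        for cls in DESTINATION_CLASSES:
            if destination_class_of(origin) == cls:
                continue
            deltas[(origin, cls)] = class_mass[cls] - m[origin]
    result = MappingProxyType(deltas)
    if masses is None:
        _DELTAS = result
    return result


@dataclass(frozen=True)
class DetectionConfig:
    """Tolerances and thresholds of the detector.

    match_tolerance
        Maximum |observed - expected| (Da) for a substitution assignment.
        0.005 Da separates every non-isobaric residue pair on
        high-resolution data (the closest distinct pair, Q vs K, differs
        by ~0.036 Da).
    zero_window
        |delta| (Da) below which a PSM counts as unmodified (a base
        peptide observation).
    ptm_tolerance
        Tolerance (Da) of the signed comparison against modification
        masses; any match vetoes the PSM.
    min_peptide_length
        Shorter peptides are dropped: very short sequences produce
        spuriously unique assignments.
    strict_mods
        If true, PSMs carrying a non-empty upstream variable-modification
        annotation are dropped instead of being processed on their
        residual delta mass.
    """

    match_tolerance: float = 0.005
    zero_window: float = 0.01
    ptm_tolerance: float = 0.005
    min_peptide_length: int = 7
    strict_mods: bool = False

    def __post_init__(self) -> None:
        if min(self.match_tolerance, self.zero_window, self.ptm_tolerance) <= 0:
            raise ValueError("tolerances must be positive")
        if self.min_peptide_length < 1:
            raise ValueError("min_peptide_length must be >= 1")


@dataclass(frozen=True)
class SubstitutionCandidate:
    """One possible assignment of an observed delta to a peptide position."""

    peptide_position: int  # 1-based
    origin_aa: str
    destination_class: str
    expected_delta: float
    match_error: float


@dataclass
class SubstitutionEvent:
    """One accepted misincorporation, anchored to protein and codon."""

    dataset_id: str
    protein_id: str
    protein_position: int  # 1-based
    codon: str
    origin_aa: str
    destination_class: str
    peptide: str
    delta_mass: float
    spectrum_ids: list[str]
    intensity_error: float | None = None
    intensity_base: float | None = None

    @property
    def spectrum_count(self) -> int:
        return len(self.spectrum_ids)


@dataclass
class BaseEvidence:
    """Zero-shift evidence for one peptide: PSM count and summed intensity."""

    spectrum_count: int = 0
    intensity: float | None = None


def enumerate_candidates(
    psm: PsmRecord,
    deltas: Mapping[tuple[str, str], float] | None = None,
    config: DetectionConfig | None = None,
) -> list[SubstitutionCandidate]:
    """All (position, destination) assignments matching the observed delta.

    Exhaustive over every peptide position and destination class; results
    are ordered by position, then destination code.
    """
    deltas = substitution_deltas() if deltas is None else deltas
    config = DetectionConfig() if config is None else config
    out: list[SubstitutionCandidate] = []
    for pos, origin in enumerate(psm.peptide, start=1):
        for cls in DESTINATION_CLASSES:
            expected = deltas.get((origin, cls))
            if expected is None:
                continue
            err = abs(psm.delta_mass - expected)
            if err <= config.match_tolerance:
                out.append(SubstitutionCandidate(pos, origin, cls, expected, err))
    return out


def ptm_conflict(
    delta_mass: float,
    mods: pd.DataFrame,
    config: DetectionConfig | None = None,
) -> list[str]:
    """Modification names whose mass explains the observed delta.

    The comparison is signed: a +14.0157 methylation does not veto a
    -14.0157 shift.
    """
    config = DetectionConfig() if config is None else config
    if mods is None or len(mods) == 0:
        return []
    close = (mods["delta_mass"] - delta_mass).abs() <= config.ptm_tolerance
    return mods.loc[close, "name"].tolist()


def base_peptide_index(
    psms: Iterable[PsmRecord],
    config: DetectionConfig | None = None,
) -> dict[tuple[str, str], BaseEvidence]:
    """Index the peptides observed without a mass shift.

    Maps ``(dataset_id, peptide)`` to the count and summed MS1 intensity of
    its zero-shift PSMs; contains exactly the peptides with at least one PSM
    with |delta| <= zero_window in that dataset.
    """
    config = DetectionConfig() if config is None else config
    index: dict[tuple[str, str], BaseEvidence] = {}
    for psm in psms:
        if abs(psm.delta_mass) > config.zero_window:
            continue
        ev = index.setdefault((psm.dataset_id, psm.peptide), BaseEvidence())
        ev.spectrum_count += 1
        if psm.intensity is not None:
            ev.intensity = (ev.intensity or 0.0) + psm.intensity
    return index


@dataclass
class FilterReport:
    """Additive accounting of what happened to every PSM.

    ``total = strict_mods_dropped + short_peptide + zero_shift + (sum of
    the shifted-PSM bins)``; the shifted bins are ``unknown_protein``,
    ``anchor_mismatch``, ``no_candidate``, ``ambiguous``,
    ``no_base_peptide``, ``ptm_conflict`` and ``accepted_psms``.
    """

    total: int = 0
    strict_mods_dropped: int = 0
    short_peptide: int = 0
    zero_shift: int = 0
    unknown_protein: int = 0
    anchor_mismatch: int = 0
    no_candidate: int = 0
    ambiguous: int = 0
    no_base_peptide: int = 0
    ptm_conflict: int = 0
    accepted_psms: int = 0

    @property
    def shifted(self) -> int:
        return (
            self.unknown_protein
            + self.anchor_mismatch
            + self.no_candidate
            + self.ambiguous
            + self.no_base_peptide
            + self.ptm_conflict
            + self.accepted_psms
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "total": self.total,
            "strict_mods_dropped": self.strict_mods_dropped,
            "short_peptide": self.short_peptide,
            "zero_shift": self.zero_shift,
            "unknown_protein": self.unknown_protein,
            "anchor_mismatch": self.anchor_mismatch,
            "no_candidate": self.no_candidate,
            "ambiguous": self.ambiguous,
            "no_base_peptide": self.no_base_peptide,
            "ptm_conflict": self.ptm_conflict,
            "accepted_psms": self.accepted_psms,
        }


@dataclass
class DetectionResult:
    """Everything the detector produced for one batch of PSMs."""

    events: list[SubstitutionEvent]
    report: FilterReport
    zero_shift_psms: list[PsmRecord]
    accepted_psms: list[PsmRecord]
    base_index: dict[tuple[str, str], BaseEvidence]


def _anchored(psm: PsmRecord, proteins: Mapping[str, str]) -> bool:
    seq = proteins.get(psm.protein_id)
    if seq is None:
        return False
    start = psm.protein_start - 1
    return seq[start : start + len(psm.peptide)] == psm.peptide


def detect_substitutions(
    psms: Sequence[PsmRecord],
    proteins: Mapping[str, str],
    cds: Mapping[str, str],
    mods: pd.DataFrame,
    config: DetectionConfig | None = None,
    valid_accessions: set[str] | None = None,
) -> DetectionResult:
    """Run the full detection cascade over a batch of PSMs.

    Filter order: strict-mods drop (optional) -> minimum length -> anchor
    checks (validated accession, peptide matches the protein at its declared
    start) -> zero/shifted split -> candidate enumeration -> uniqueness ->
    base-peptide requirement -> modification-mass veto.  Surviving PSMs of
    the same substitution channel (dataset, protein, position, destination,
    peptide) are merged into one :class:`SubstitutionEvent`.

    ``valid_accessions`` defaults to the accessions whose CDS translation
    matches the protein sequence (see
    :func:`mistrans.io_formats.validate_cds`).
    """
    config = DetectionConfig() if config is None else config
    if valid_accessions is None:
        valid_accessions = validate_cds(proteins, cds).valid
    deltas = substitution_deltas()

    report = FilterReport()
    zero_psms: list[PsmRecord] = []
    accepted_psms: list[PsmRecord] = []

    # Base-peptide evidence is indexed over all length-passing PSMs first:
    # the base of a shifted peptide may sit anywhere in the input order.
    usable: list[PsmRecord] = []
    for psm in psms:
        report.total += 1
        if config.strict_mods and psm.assigned_mods:
            report.strict_mods_dropped += 1
            continue
        if len(psm.peptide) < config.min_peptide_length:
            report.short_peptide += 1
            continue
        usable.append(psm)
    base_index = base_peptide_index(usable, config)

    merged: dict[tuple[str, str, int, str, str], SubstitutionEvent] = {}
    deltas_per_event: dict[tuple[str, str, int, str, str], list[float]] = {}

    for psm in usable:
        if abs(psm.delta_mass) <= config.zero_window:
            report.zero_shift += 1
            zero_psms.append(psm)
            continue
        if psm.protein_id not in valid_accessions:
            report.unknown_protein += 1
            continue
        if not _anchored(psm, proteins):
            report.anchor_mismatch += 1
            continue
        candidates = enumerate_candidates(psm, deltas, config)
        if not candidates:
            report.no_candidate += 1
            continue
        if len(candidates) > 1:
            report.ambiguous += 1
            continue
        if (psm.dataset_id, psm.peptide) not in base_index:
            report.no_base_peptide += 1
            continue
        if ptm_conflict(psm.delta_mass, mods, config):
            report.ptm_conflict += 1
            continue

        cand = candidates[0]
        protein_position = psm.protein_start + cand.peptide_position - 1
        codon = cds[psm.protein_id][3 * (protein_position - 1) : 3 * protein_position]
        # the CDS is validated, so the codon must encode the origin residue
        assert CODON_TO_AA[codon] == cand.origin_aa

        key = (psm.dataset_id, psm.protein_id, protein_position, cand.destination_class, psm.peptide)
        if key not in merged:
            merged[key] = SubstitutionEvent(
                dataset_id=psm.dataset_id,
                protein_id=psm.protein_id,
                protein_position=protein_position,
                codon=codon,
                origin_aa=cand.origin_aa,
                destination_class=cand.destination_class,
                peptide=psm.peptide,
                delta_mass=psm.delta_mass,
                spectrum_ids=[],
            )
            deltas_per_event[key] = []
        event = merged[key]
        event.spectrum_ids.append(psm.spectrum_id)
        deltas_per_event[key].append(psm.delta_mass)
        if psm.intensity is not None:
            event.intensity_error = (event.intensity_error or 0.0) + psm.intensity
        report.accepted_psms += 1
        accepted_psms.append(psm)

    for key, event in merged.items():
        event.delta_mass = sum(deltas_per_event[key]) / len(deltas_per_event[key])
        base = base_index.get((event.dataset_id, event.peptide))
        if base is not None:
            event.intensity_base = base.intensity

    events = sorted(
        merged.values(),
        key=lambda e: (e.dataset_id, e.protein_id, e.protein_position, e.destination_class, e.peptide),
    )
    return DetectionResult(events, report, zero_psms, accepted_psms, base_index)
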