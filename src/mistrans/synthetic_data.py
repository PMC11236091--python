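"""Ground-truth-annotated synthetic data for the whole pipeline.

Emulates every external input the pipeline consumes — a random proteome
with matching coding sequences, open-search PSM tables with planted
amino-acid substitutions, modification-mass decoys, log-normal MS1
intensities, and a tRNA abundance table — with exact residue-level
bookkeeping, so detection and rate estimation can be validated against a
known truth without any real mass-spectrometry data.

What the generator emulates (and what it does not): tryptic digestion with
Poisson PSM coverage, Gaussian mass noise well inside the match tolerance,
per-codon substitution rates in the experimentally reported range, PTM
decoy mass shifts and missing intensities.  It does not simulate spectra,
retention times, identification FDR, or shared peptides between proteins
(shared peptides are excluded by construction so the multi-protein
ambiguity rule is never triggered accidentally).

Substitutions are planted only on channels the detector could in principle
accept: destinations with a usable mass shift that is uniquely assignable
within the carrier peptide (and, when a modification table is supplied to
the generator, not masked by a modification mass).  The ground truth
records the realized planted counts and codon totals, which is what
rate-recovery checks compare against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .io_formats import load_default_modifications
from .mtel_model import MtelParameters, class_probabilities
from .substitution_detection import (
    CODON_TO_AA,
    DESTINATION_CLASSES,
    DetectionConfig,
    SENSE_CODONS,
    destination_class_of,
    substitution_deltas,
)
from .mtel_model import build_detectability_mask

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_proteome",
    "tryptic_peptides",
    "generate_psm_dataset",
    "generate_trna_table",
    "simulate_codon_counts",
    "write_fixture",
]


@dataclass
class SimulationConfig:
    """Study conditions of one simulated experiment.

    The seed is mandatory — every random draw flows from it.  Default
    per-codon error rates are drawn log-uniformly from [1e-4, 5e-3],
    matching the range reported for proteome-wide misincorporation rates;
    mass noise (sd 0.001 Da) sits well below the 0.005 Da match tolerance
    so planted events are recoverable by design.
    """

    seed: int
    n_proteins: int = 20
    protein_length: tuple[int, int] = (150, 400)  # residues, uniform
    psm_coverage: float = 25.0  # mean PSMs per tryptic peptide
    peptide_length: tuple[int, int] = (7, 30)
    error_rates: float | Mapping[str, float] | None = None  # None -> log-uniform draw
    mtel_params: MtelParameters | None = None  # destination sampling from the model
    trnas: pd.DataFrame | None = None
    fixed_destination: str | None = None  # force one destination class
    restrict_origin: str | None = None  # plant errors only at codons of this residue
    ptm_decoy_rate: float = 0.05  # fraction of shifted PSMs that are PTM decoys
    mask_mods: pd.DataFrame | None = None  # plant only channels unmasked under these mods
    intensity_mu: float = 20.0  # log-scale location of base peptide intensity
    intensity_sigma: float = 1.0
    missing_intensity_fraction: float = 0.1
    mass_noise_sd: float = 0.001  # Da
    detection: DetectionConfig = field(default_factory=DetectionConfig)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 <= self.ptm_decoy_rate < 1:
            raise ValueError("ptm_decoy_rate must be in [0, 1)")
        if not 0 <= self.missing_intensity_fraction <= 1:
            raise ValueError("missing_intensity_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """Everything that was planted, for validation against pipeline output."""

    events: pd.DataFrame  # protein_id, protein_position, codon, origin_aa, destination_class, count
    codon_totals: pd.Series  # residue-level occupancy of emitted base+error PSMs
    error_rates: pd.Series  # the generating per-codon rates
    decoy_count: int
    n_base_psms: int
    n_error_psms: int

    def planted_rates(self) -> pd.Series:
        """Realized per-codon error rate: planted events / planted totals."""
        errors = (
            self.events.groupby("codon")["count"].sum().reindex(list(SENSE_CODONS)).fillna(0)
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            rates = errors / self.codon_totals.reindex(list(SENSE_CODONS)).replace(0, np.nan)
        return rates.fillna(0.0)


def _random_cds(rng: np.random.Generator, n_residues: int) -> str:
    body = rng.choice(len(SENSE_CODONS), size=n_residues - 1)
    return "ATG" + "".join(SENSE_CODONS[i] for i in body) + "TAA"


def tryptic_peptides(
    sequence: str, bounds: tuple[int, int] = (7, 30)
) -> list[tuple[str, int]]:
    """Fully tryptic digestion: cleave after K/R except before P.

    Returns (peptide, 1-based start) for peptides within the length bounds;
    no missed cleavages.
    """
    lo, hi = bounds
    out: list[tuple[str, int]] = []
    start = 0
    for i, aa in enumerate(sequence):
        if aa in "KR" and (i + 1 >= len(sequence) or sequence[i + 1] != "P"):
            out.append((sequence[start : i + 1], start + 1))
            start = i + 1
    if start < len(sequence):
        out.append((sequence[start:], start + 1))
    return [(p, s) for p, s in out if lo <= len(p) <= hi]


def generate_proteome(config: SimulationConfig) -> tuple[dict[str, str], dict[str, str]]:
    """Random proteome + coding sequences, consistent by construction.

    Every CDS starts with ATG, uses only sense codons, and ends with one
    stop codon; tryptic peptides are unique across the proteome (proteins
    are re-drawn on collision) so peptide anchoring is unambiguous.
    """
    rng = np.random.default_rng([config.seed, 0])
    lo, hi = config.protein_length
    proteins: dict[str, str] = {}
    cds: dict[str, str] = {}
    seen_peptides: set[str] = set()
    for i in range(config.n_proteins):
        accession = f"SYN{i + 1:04d}"
        for _attempt in range(200):
            n_res = int(rng.integers(lo, hi + 1))
            nt = _random_cds(rng, n_res)
            aa = str(Seq(nt).translate(table=1))[:-1]
            peptides = {p for p, _ in tryptic_peptides(aa, config.peptide_length)}
            if peptides and not (peptides & seen_peptides):
                seen_peptides |= peptides
                proteins[accession] = aa
                cds[accession] = nt
                break
        else:
            raise RuntimeError("could not generate a collision-free proteome")
    return proteins, cds


def _resolve_error_rates(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.Series:
    if config.error_rates is None:
        lo, hi = np.log10(1e-4), np.log10(5e-3)
        rates = pd.Series(
            10 ** rng.uniform(lo, hi, size=len(SENSE_CODONS)), index=list(SENSE_CODONS)
        )
    elif np.isscalar(config.error_rates):
        rates = pd.Series(float(config.error_rates), index=list(SENSE_CODONS))
    else:
        rates = pd.Series(0.0, index=list(SENSE_CODONS))
        for codon, r in dict(config.error_rates).items():
            rates[codon] = float(r)
    if config.restrict_origin is not None:
        keep = [c for c in SENSE_CODONS if CODON_TO_AA[c] == config.restrict_origin]
        rates[~rates.index.isin(keep)] = 0.0
    if ((rates < 0) | (rates > 1)).any():
        raise ValueError("error rates must lie in [0, 1]")
    return rates


def _allowed_destinations(
    peptide: str,
    codons: Sequence[str],
    deltas: Mapping[tuple[str, str], float],
    mask: pd.DataFrame | None,
    tol: float,
) -> list[list[str]]:
    """Per position: destination classes uniquely assignable in this peptide."""
    all_deltas = []
    for aa in peptide:
        for cls in DESTINATION_CLASSES:
            d = deltas.get((aa, cls))
            if d is not None:
                all_deltas.append(d)
    all_deltas = np.sort(np.asarray(all_deltas))
    allowed: list[list[str]] = []
    for q, origin in enumerate(peptide):
        here: list[str] = []
        for cls in DESTINATION_CLASSES:
            d = deltas.get((origin, cls))
            if d is None:
                continue
            if mask is not None and not mask.at[codons[q], cls]:
                continue
            hits = np.searchsorted(all_deltas, d + tol, side="right") - np.searchsorted(
                all_deltas, d - tol, side="left"
            )
            if hits == 1:  # uniquely assignable within this peptide
                here.append(cls)
        allowed.append(here)
    return allowed


def generate_psm_dataset(
    config: SimulationConfig,
    proteins: Mapping[str, str],
    cds: Mapping[str, str],
    dataset_id: str = "sim",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one open-search PSM table with planted substitutions.

    Each tryptic peptide receives Poisson(psm_coverage) PSMs; a PSM becomes
    a substitution with probability equal to the summed per-codon rates of
    its residues, carrying the expected mass shift plus Gaussian noise.
    PTM decoys are then added so they make up ``ptm_decoy_rate`` of all
    shifted PSMs.  Returns the table in the psm.tsv dialect plus the
    :class:`GroundTruth`.
    """
    rng = np.random.default_rng([config.seed, 1])
    deltas = substitution_deltas()
    rates = _resolve_error_rates(config, rng)
    mask = (
        build_detectability_mask(config.mask_mods, config.detection)
        if config.mask_mods is not None
        else None
    )
    model_p = (
        class_probabilities(config.mtel_params, config.trnas)
        if config.mtel_params is not None and config.trnas is not None
        else None
    )

    rows: list[tuple] = []
    planted: dict[tuple[str, int, str, str, str], int] = {}
    codon_totals = pd.Series(0, index=list(SENSE_CODONS), dtype=int)
    spectrum_no = 0
    n_base = n_error = 0
    decoy_sites: list[tuple[str, str, int, float]] = []  # peptide anchors for decoys

    def new_spectrum() -> str:
        nonlocal spectrum_no
        spectrum_no += 1
        return f"{dataset_id}.{spectrum_no:06d}"

    def intensity_or_none(value: float) -> float | None:
        return None if rng.random() < config.missing_intensity_fraction else value

    for accession in sorted(proteins):
        seq, nt = proteins[accession], cds[accession]
        for peptide, start in tryptic_peptides(seq, config.peptide_length):
            pep_codons = [nt[3 * (start - 1 + q) : 3 * (start + q)] for q in range(len(peptide))]
            n_psms = int(rng.poisson(config.psm_coverage))
            if n_psms == 0:
                continue
            site_rates = np.array([rates[c] for c in pep_codons])
            p_any = site_rates.sum()
            k_err = rng.binomial(n_psms, min(p_any, 1.0)) if p_any > 0 else 0
            allowed = _allowed_destinations(
                peptide, pep_codons, deltas, mask, config.detection.match_tolerance
            )
            base_level = rng.lognormal(config.intensity_mu, config.intensity_sigma)
            decoy_sites.append((accession, peptide, start, base_level))

            emitted_err = 0
            for _ in range(k_err):
                q = int(rng.choice(len(peptide), p=site_rates / p_any))
                choices = allowed[q]
                if model_p is not None and choices:
                    weights = model_p.loc[pep_codons[q], choices].to_numpy(dtype=float)
                    cls = (
                        str(rng.choice(choices, p=weights / weights.sum()))
                        if weights.sum() > 0
                        else None
                    )
                elif config.fixed_destination is not None:
                    cls = config.fixed_destination if config.fixed_destination in choices else None
                elif choices:
                    cls = str(choices[int(rng.choice(len(choices)))])
                else:
                    cls = None
                if cls is None:
                    # no uniquely assignable channel here; emit as base PSM
                    delta = rng.normal(0.0, config.mass_noise_sd)
                    rows.append(
                        (new_spectrum(), peptide, delta, accession, start,
                         intensity_or_none(base_level * rng.lognormal(0.0, 0.2)))
                    )
                    n_base += 1
                    continue
                origin = peptide[q]
                delta = deltas[(origin, cls)] + rng.normal(0.0, config.mass_noise_sd)
                site_rate = site_rates[q] if site_rates[q] > 0 else 1e-4
                err_intensity = base_level * site_rate * rng.lognormal(0.0, 0.3)
                rows.append(
                    (new_spectrum(), peptide, delta, accession, start,
                     intensity_or_none(err_intensity))
                )
                key = (accession, start + q, pep_codons[q], origin, cls)
                planted[key] = planted.get(key, 0) + 1
                emitted_err += 1
                n_error += 1

            n_zero = n_psms - k_err
            for _ in range(n_zero):
                delta = rng.normal(0.0, config.mass_noise_sd)
                rows.append(
                    (new_spectrum(), peptide, delta, accession, start,
                     intensity_or_none(base_level * rng.lognormal(0.0, 0.2)))
                )
            n_base += n_zero
            # every drawn PSM was emitted (failed error draws fell back to
            # base PSMs), so each residue saw the peptide n_psms times
            for codon in pep_codons:
                codon_totals[codon] += n_psms

    # PTM decoys: fraction d of all shifted PSMs carry a modification mass
    decoy_count = 0
    d = config.ptm_decoy_rate
    if d > 0 and n_error > 0:
        decoy_mods = load_default_modifications()
        decoy_count = int(round(n_error * d / (1.0 - d)))
        mod_masses = decoy_mods["delta_mass"].to_numpy(dtype=float)
        for _ in range(decoy_count):
            accession, peptide, start, base_level = decoy_sites[
                int(rng.integers(len(decoy_sites)))
            ]
            delta = float(rng.choice(mod_masses)) + rng.normal(0.0, config.mass_noise_sd)
            rows.append(
                (new_spectrum(), peptide, delta, accession, start,
                 intensity_or_none(base_level * rng.lognormal(0.0, 0.3)))
            )

    frame = pd.DataFrame(
        rows,
        columns=["Spectrum", "Peptide", "Delta Mass", "Protein", "Protein Start", "Intensity"],
    )
    events = pd.DataFrame(
        [
            {
                "protein_id": k[0],
                "protein_position": k[1],
                "codon": k[2],
                "origin_aa": k[3],
                "destination_class": k[4],
                "count": v,
            }
            for k, v in sorted(planted.items())
        ],
        columns=["protein_id", "protein_position", "codon", "origin_aa", "destination_class", "count"],
    )
    truth = GroundTruth(
        events=events,
        codon_totals=codon_totals,
        error_rates=rates,
        decoy_count=decoy_count,
        n_base_psms=n_base,
        n_error_psms=n_error,
    )
    return frame, truth


def generate_trna_table(seed: int, max_isoacceptors: int = 2) -> pd.DataFrame:
    """Synthetic tRNA abundance table covering all 20 amino acids.

    Each amino acid gets 1..max_isoacceptors isoacceptors whose anticodons
    are reverse complements of that amino acid's codons; abundances are
    log-uniform over one decade either side of 1.
    """
    rng = np.random.default_rng([seed, 2])
    rows = []
    for aa in sorted(set(CODON_TO_AA.values())):
        codons = sorted(c for c, a in CODON_TO_AA.items() if a == aa)
        k = int(rng.integers(1, min(max_isoacceptors, len(codons)) + 1))
        chosen = rng.choice(len(codons), size=k, replace=False)
        for idx in sorted(chosen):
            anticodon = str(Seq(codons[idx]).reverse_complement_rna())
            rows.append(
                {
                    "anticodon": anticodon,
                    "amino_acid": aa,
                    "abundance": float(10 ** rng.uniform(-1, 1)),
                }
            )
    return pd.DataFrame(rows).sort_values(["amino_acid", "anticodon"]).reset_index(drop=True)


def simulate_codon_counts(
    params: MtelParameters,
    trnas: pd.DataFrame,
    mask: pd.DataFrame,
    n_per_codon: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw a codon count table directly from the competition model.

    For each sense codon, ``n_per_codon`` observations are distributed
    multinomially over the detectable destination classes plus a lumped
    "no detectable error" outcome.  Used for parameter-recovery studies.
    """
    p_class = class_probabilities(params, trnas)
    table = pd.DataFrame(
        0, index=list(SENSE_CODONS), columns=list(DESTINATION_CLASSES), dtype=int
    )
    for codon in SENSE_CODONS:
        detectable = [c for c in DESTINATION_CLASSES if mask.at[codon, c]]
        probs = p_class.loc[codon, detectable].to_numpy(dtype=float)
        probs = np.append(probs, max(1.0 - probs.sum(), 0.0))
        draw = rng.multinomial(n_per_codon, probs / probs.sum())
        for cls, count in zip(detectable, draw[:-1]):
            table.at[codon, cls] = count
    out = table.reset_index(names="codon")
    out.insert(1, "total_observations", n_per_codon)
    out.insert(2, "error_observations", table.sum(axis=1).to_numpy())
    out["codon_error_rate"] = out["error_observations"] / out["total_observations"]
    out["no_coverage"] = False
    return out


def write_fixture(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete ready-to-run fixture directory.

    Emits proteome.fasta, cds.fasta, trna.tsv, modifications.tsv (the
    shipped snapshot), sample1.psm.tsv and ground_truth.csv; fully
    deterministic for a fixed seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    proteins, cds = generate_proteome(config)
    frame, truth = generate_psm_dataset(config, proteins, cds, dataset_id="sample1")
    trnas = generate_trna_table(config.seed)

    paths = {
        "proteome": out_dir / "proteome.fasta",
        "cds": out_dir / "cds.fasta",
        "trna": out_dir / "trna.tsv",
        "modifications": out_dir / "modifications.tsv",
        "psm": out_dir / "sample1.psm.tsv",
        "ground_truth": out_dir / "ground_truth.csv",
        "planted_codon_totals": out_dir / "planted_codon_totals.csv",
    }
    SeqIO.write(
        [SeqRecord(Seq(seq), id=acc, description="") for acc, seq in proteins.items()],
        paths["proteome"],
        "fasta",
    )
    SeqIO.write(
        [SeqRecord(Seq(seq), id=acc, description="") for acc, seq in cds.items()],
        paths["cds"],
        "fasta",
    )
    trnas.to_csv(paths["trna"], sep="\t", index=False)
    load_default_modifications().to_csv(paths["modifications"], sep="\t", index=False)
    frame.to_csv(paths["psm"], sep="\t", index=False)
    truth.events.to_csv(paths["ground_truth"], index=False)
    truth.codon_totals.rename_axis("codon").rename("total").to_frame().to_csv(
        paths["planted_codon_totals"]
    )
    return paths
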