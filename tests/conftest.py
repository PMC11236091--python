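"""Shared fixtures: a hand-traceable toy proteome and PSM table.

The toy is built around three tiny proteins whose codons are written out
explicitly, so every expected codon assignment in the tests is hand-derived
from the standard genetic code rather than computed by the code under test.
"""

from __future__ import annotations

import pandas as pd
import pytest

from mistrans.io_formats import PsmRecord, load_default_modifications
from mistrans.substitution_detection import DetectionConfig

# protein sequences and codon-explicit CDS (one trailing stop each)
TOY_PROTEINS = {
    "p1": "MAFKNWGR",  # ATG GCG TTT AAA AAT TGG GGT CGT TAA
    "p2": "MATKNW",    # ATG GCG ACC AAA AAT TGG TAA
    "p3": "MAGFNWK",   # ATG GCT GGG TTT AAT TGG AAA TAA
}
TOY_CDS = {
    "p1": "ATGGCGTTTAAAAATTGGGGTCGTTAA",
    "p2": "ATGGCGACCAAAAATTGGTAA",
    "p3": "ATGGCTGGGTTTAATTGGAAATAA",
}


@pytest.fixture(scope="session")
def toy_proteins():
    return dict(TOY_PROTEINS)


@pytest.fixture(scope="session")
def toy_cds():
    return dict(TOY_CDS)


@pytest.fixture(scope="session")
def default_mods():
    return load_default_modifications()


@pytest.fixture
def toy_config():
    # length 5 so the toy's 4-mer exercises the short-peptide filter
    return DetectionConfig(min_peptide_length=5)


def toy_psm_frame() -> pd.DataFrame:
    """Twelve PSMs exercising every filter of the detection cascade.

    Hand-derived outcomes (tolerance 0.005 Da, zero window 0.01 Da,
    minimum length 5):

    1.  AFKNW @p1:2, delta 0.0002      -> zero shift (base peptide)
    2.  ATKNW @p2:2, delta 0.0010      -> zero shift (base peptide)
    3.  AFKNW @p1:2, delta -14.0157    -> accepted, unique A->G (codon GCG)
    4.  AFKNW @p1:2, delta -14.0158    -> accepted, merges with row 3
    5.  ATKNW @p2:2, delta -14.0157    -> ambiguous (A->G and T->S)
    6.  AGFNW @p3:2, delta -14.0157    -> unique A->G but base never seen
    7.  AFKNW @p1:2, delta +0.9840     -> unique N->D but masked by deamidation
    8.  AFKNW @"p1;p2", delta -14.0157 -> multi-protein mapping (parse drop)
    9.  AFKNW @p1:3, delta -14.0157    -> anchor mismatch (p1[3..] = FKNWG)
    10. AFKN  @p1:2, delta -14.0157    -> short peptide (4 < 5)
    11. AFKNW @p1:2, delta +123.4567   -> no candidate within tolerance
    12. AFKNW @p1:2, delta 0.0003      -> zero shift (base peptide)
    """
    rows = [
        ("s01", "AFKNW", 0.0002, "p1", 2, 5000.0),
        ("s02", "ATKNW", 0.0010, "p2", 2, 3000.0),
        ("s03", "AFKNW", -14.0157, "p1", 2, 5.0),
        ("s04", "AFKNW", -14.0158, "p1", 2, 7.0),
        ("s05", "ATKNW", -14.0157, "p2", 2, 2.0),
        ("s06", "AGFNW", -14.0157, "p3", 2, 2.0),
        ("s07", "AFKNW", 0.9840, "p1", 2, 2.0),
        ("s08", "AFKNW", -14.0157, "p1;p2", 2, 2.0),
        ("s09", "AFKNW", -14.0157, "p1", 3, 2.0),
        ("s10", "AFKN", -14.0157, "p1", 2, 2.0),
        ("s11", "AFKNW", 123.4567, "p1", 2, 2.0),
        ("s12", "AFKNW", 0.0003, "p1", 2, 7000.0),
    ]
    return pd.DataFrame(
        rows, columns=["Spectrum", "Peptide", "Delta Mass", "Protein", "Protein Start", "Intensity"]
    )


@pytest.fixture
def toy_psm_path(tmp_path):
    path = tmp_path / "toy.psm.tsv"
    toy_psm_frame().to_csv(path, sep="\t", index=False)
    return path


def make_psm(
    peptide: str,
    delta: float,
    protein: str = "p1",
    start: int = 2,
    spectrum: str = "s1",
    intensity: float | None = None,
    dataset: str = "d1",
) -> PsmRecord:
    return PsmRecord(spectrum, peptide, delta, protein, start, intensity, None, dataset)
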