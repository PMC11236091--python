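"""Write a complete ground-truth fixture directory to disk.

The directory holds everything the shell pipeline consumes — proteome and
CDS FASTA, a PSM table in the psm.tsv dialect, tRNA abundances, the
modification snapshot — plus the planted ground truth, and is re-runnable
with the command-line interface:

    mistrans detect --psm <dir>/sample1.psm.tsv --fasta <dir>/proteome.fasta \\
        --cds <dir>/cds.fasta --mods <dir>/modifications.tsv --out out/
"""

import tempfile
from pathlib import Path

from mistrans import SimulationConfig, load_default_modifications
from mistrans.synthetic_data import write_fixture

config = SimulationConfig(seed=7, n_proteins=5, psm_coverage=30.0,
                          mask_mods=load_default_modifications())
out = Path(tempfile.mkdtemp(prefix="mistrans_fixture_"))
paths = write_fixture(config, out)

print(f"fixture written to {out}")
for name, path in paths.items():
    print(f"  {name:<22} {path.name:<28} {path.stat().st_size:>8} bytes")

# ground_truth.csv lists every planted substitution (protein, position,
# codon, origin, destination, count); planted_codon_totals.csv the codon
# occupancy — together they define exactly what a correct detector should
# recover from sample1.psm.tsv.
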