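# Methods

## Scope and data flow

`mistrans` turns open-search peptide-spectrum matches (PSMs) into amino-acid
substitution events, aggregates them into translation error rates, and fits
a mechanistic model of tRNA competition to the per-codon counts.  Inputs are
a PSM table (tab-separated, MSFragger `psm.tsv` dialect; a column map
absorbs header drift across versions), the protein FASTA used for the
search, a coding-sequence FASTA keyed to the same accessions, a
modification-mass table, and (for the model) a tRNA abundance table.
Executing the upstream search engine itself, spectrum-level processing, and
FDR estimation are out of scope: the package starts from the PSM table.

## Detection cascade

A substitution a→b shifts the peptide's monoisotopic mass by
m(b) − m(a), where m(·) are residue masses computed from elemental
compositions and NIST monoisotopic atomic masses (never typed-in
decimals).  Isoleucine and leucine are exactly isobaric, so destination
I and L form one merged class `I/L`; origins stay distinct because the
origin residue is read from the database sequence.  The I↔L channels have
zero shift and are excluded as undetectable.

Filters, in order (each PSM is counted in exactly one bin, so the report
decomposes the input additively):

1. optional strict-modification drop (PSMs with upstream variable-mod
   annotations; off by default — such PSMs are otherwise processed on
   their residual delta);
2. minimum peptide length (default 7; very short peptides produce
   spuriously unique matches);
3. protein validation and anchoring: the accession must have a CDS whose
   standard-genetic-code translation (one trailing stop dropped) equals
   the protein sequence, and the peptide must match the protein at its
   declared 1-based start.  Anchor mismatches signal corrupt input and are
   counted, not fatal;
4. zero/shifted split: |Δ| ≤ 0.01 Da counts as an unmodified (base
   peptide) observation;
5. candidate enumeration: every (position, destination class) whose
   expected shift matches the observed delta within 0.005 Da;
6. uniqueness: exactly one candidate survives, otherwise the PSM is
   discarded (never ranked — no localization evidence is modeled);
7. base-peptide requirement: the same peptide must have ≥1 zero-shift PSM
   in the same dataset;
8. modification veto: if the delta matches any modification mass within
   0.005 Da (signed comparison: +14.0157 methylation does not veto a
   −14.0157 shift), the PSM is rejected regardless of site specificity.

Accepted PSMs of the same channel (dataset, protein, position, destination
class, peptide) merge into one event carrying all spectrum ids, the mean
delta, and summed MS1 intensities of the error and base forms.  Event
codons are sliced from the CDS at `[3(pos−1), 3pos)`; by construction they
translate to the origin residue.

Tolerance rationale: the closest non-isobaric residue pair (Q vs K)
differs by ≈0.036 Da, so 0.005 Da separates all distinguishable channels
on high-resolution instruments while absorbing calibration noise.  All
four thresholds are configurable.

The shipped modification table is a curated offline snapshot of common
modifications (oxidation, deamidation, mono/di/tri-methylation,
acetylation, phosphorylation, formylation, carbamidomethylation,
carbamylation, Na/K adducts, water and ammonia loss), each documented with
its elemental formula so the masses are recomputable.  Several
substitution channels collide with these masses — N→D and Q→E with
deamidation, G→A-type +CH₂ shifts with methylation, A→S and F→Y with
oxidation — and are therefore undetectable under the default table; the
detectability mask makes this explicit.

## Error-rate statistics

- **Codon-aggregated (count-based).**  Occupancy counts every residue
  position of every counted PSM (the zero-shift PSMs plus the PSMs
  underlying accepted events) toward its codon; the rate is
  errors/total per codon.  Counting is at PSM level so numerator and
  denominator are commensurate; a peptide-level denominator would mix
  granularities.  Codons never observed get rate 0 with a `no_coverage`
  flag rather than NaN, for stable CSV output.
- **Site-specific (intensity-based).**  Per event,
  I_error / I_base over summed MS1 intensities.  The plain ratio may
  exceed 1 and is reported as-is; a bounded alternative
  I_error/(I_error+I_base) is available behind a flag.  The rate is
  absent — not 0 — when either intensity is missing or the base intensity
  is 0.
- **Pooling.**  Codon tables pool by summing counts and recomputing rates,
  never by averaging rates, so datasets weigh in proportion to their
  evidence.

## The tRNA-competition model

Decoding of codon *i* is modeled as a softmax competition over all tRNA
species *j*: p(j|i) ∝ a_j·exp(s_ij), with normalized arrival rates a_j
from tRNA abundances and binding score
s_ij = Σ_p w_p·b[codon_i[p], anticodon_j[4−p]] (antiparallel pairing).
This is the minimal form containing both stated ingredients — abundance
competition and position-weighted nucleotide pairing — and is documented
as this package's concrete instantiation rather than a bit-exact clone of
any other implementation.  Wobble is not special-cased: any position-3
leniency must emerge through w₃ and the fitted b entries.

Identifiability: adding a constant to all binding scores of a codon leaves
the softmax unchanged, so the overall scale of w is absorbed by
constraining w to the simplex, and the additive gauge is pinned by fixing
b[A,U] = 0.  Residual flat directions (per-codon-nucleotide shifts of b)
do not affect probabilities and are left to the optimizer; fitted
*probabilities* are identified even where individual b entries are not.

The likelihood is multinomial per codon over the *detectable* destination
classes (non-cognate, non-isobaric, no modification collision), with all
undetectable outcomes lumped with the cognate outcome:

    ll_i = Σ_c k_ic·log p(c|i) + (n_i − Σ_c k_ic)·log(1 − Σ_c p(c|i))

Counts on masked channels are an input inconsistency and raise; a
detectable channel with zero model probability and positive count yields
−∞ (flagged, not hidden).  The softmax is evaluated with max-subtraction,
so results are invariant to uniform score shifts and immune to overflow.

Fitting is multi-start Nelder–Mead (adaptive) on the unconstrained
reparameterization — softmax logits for w (first logit fixed at 0), free
reals for the 15 unpinned b entries — with 20 seeded restarts by default
and a polish run from the best restart; an optional bootstrap resamples
codons with replacement.  The fit refuses to run when no errors are
observed (unidentifiable) or when an observed destination has no tRNA
support (probability identically zero).  With counts simulated at 10⁵ per
codon the fit recovers detectable-channel probabilities with log-scale
correlation ≈ 1 and weights to ±0.001 (see `scripts/acceptance.py`).

## Synthetic data

The generator emulates the pipeline's entire input contract with exact
bookkeeping: a random proteome (uniform sense codons, ATG start, one stop;
default 150–400 residues), fully tryptic digestion (cleave after K/R
except before P, lengths 7–30, no missed cleavages), Poisson PSM coverage
per peptide, planted substitutions with Gaussian mass noise (sd 0.001 Da,
well inside the 0.005 Da tolerance, so planted events are recoverable by
design), modification-mass decoy PSMs (5% of shifted PSMs by default),
log-normal MS1 intensities with error intensity = base × site rate ×
noise, and a 10% missing-intensity fraction.  Default per-codon error
rates are drawn log-uniformly from [10⁻⁴, 5×10⁻³], the range reported for
proteome-wide misincorporation.  Tryptic peptides are unique across the
proteome by rejection sampling so the multi-protein ambiguity rule never
fires accidentally.

Two deliberate design choices shape what the ground truth means.
Substitutions are planted only on channels that are uniquely assignable
within the carrier peptide (and, when a modification table is given to the
generator, not masked by it): the estimator-consistency claim is about
unbiased channels, and events the detector is *structurally* blind to
(ambiguous or masked) would otherwise contaminate rate comparisons with a
bias that is a property of mass spectrometry, not of the estimator.  The
ground truth records realized planted counts and codon totals, and
recovery is judged against those realized rates.

The generator does not simulate spectra, retention time, chromatography,
identification FDR, shared peptides, or missed cleavages.  Passing tests
therefore show the estimators are correct when the upstream search behaves
nominally; they do not validate robustness to search-engine artifacts.

## Problem sizes and numerical choices

Validation runs use a 50-protein proteome at ≈2×10⁵ PSMs for rate
recovery, 30 proteins at ≈1.7×10⁴ PSMs for the masked-channel experiment,
and 10⁵ observations per codon for model recovery — large enough for tight
recovery statistics while keeping the full suite fast on one CPU.
Determinism is end-to-end: all randomness flows through seeded NumPy
generators, iteration orders are sorted, and the byte-identity of repeated
pipeline runs at the same seed is itself under test.

## Known limitations

- No localization from fragment ions: uniqueness is decided purely on
  precursor mass, so near-isobaric channel pairs (e.g. N→D vs Q→E, both
  +0.98402 Da) are discarded whenever both origins occur in one peptide.
- The modification veto applies to the whole PSM regardless of residue
  specificity; a site-aware veto would recover some masked channels.
- Arrival rates use raw normalized tRNA abundances; no codon-usage
  adjustment.
- The site-specific intensity ratio inherits all MS1 quantification
  biases; no cross-run normalization is attempted.
- Stop-codon readthrough and frameshifts are different error types and
  are not modeled.
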