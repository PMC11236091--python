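"""Mechanistic model of translation errors via tRNA competition.

The model pictures decoding of codon *i* as a competition among all tRNA
species: tRNA *j* arrives at the ribosomal A site at a rate proportional to
its cellular abundance (its *arrival rate* ``a_j``) and is accepted with a
weight governed by how well its anticodon pairs with the codon.  The
codon/anticodon binding score is a linear combination of per-nucleotide
pairing contributions ``b[codon_nt, anticodon_nt]`` weighted by
per-codon-position importances ``w_1..w_3`` (pairing is antiparallel:
codon position 1 pairs anticodon position 3; position 3 is the wobble
position, which is not special-cased — any leniency there must emerge
through the fitted ``w_3`` and ``b`` entries):

    s_ij = sum_p  w_p * b[codon_i[p], anticodon_j[4-p]]
    p(j | i) = a_j * exp(s_ij) / sum_k a_k * exp(s_ik)

Summing ``p(j|i)`` over the tRNAs carrying each amino acid gives the
codon -> amino-acid (mis)incorporation matrix.  The pairing matrix and
position weights are fitted by maximum likelihood to the per-codon
substitution counts produced by the empirical detector, restricted to the
*detectable* channels (non-cognate, non-isobaric, not masked by a known
modification mass); the fitted model then extrapolates to the channels the
mass-spectrometry pipeline cannot observe.

Identifiability: the weights live on the simplex (the overall binding
scale is absorbed into ``b``) and the pairing entry b[A, U] is pinned to 0
(row-wise normalization of the softmax makes an additive gauge direction;
the pin makes fitted values comparable across runs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .substitution_detection import (
    AMINO_ACIDS,
    CODON_TO_AA,
    DESTINATION_CLASSES,
    DetectionConfig,
    SENSE_CODONS,
    destination_class_of,
    ptm_conflict,
    substitution_deltas,
)

__all__ = [
    "CODON_NUCLEOTIDES",
    "ANTICODON_NUCLEOTIDES",
    "PIN_ENTRY",
    "MtelParameters",
    "IncorporationMatrix",
    "FitConfig",
    "FitResult",
    "arrival_rates",
    "binding_score",
    "incorporation_matrix",
    "build_detectability_mask",
    "log_likelihood",
    "fit",
    "random_parameters",
]

CODON_NUCLEOTIDES = "ACGT"
ANTICODON_NUCLEOTIDES = "ACGU"
#: pairing entry fixed at 0 for identifiability: (codon A, anticodon U)
PIN_ENTRY = (0, 3)

_CODON_NT_INDEX = {nt: i for i, nt in enumerate(CODON_NUCLEOTIDES)}
_ANTI_NT_INDEX = {nt: i for i, nt in enumerate(ANTICODON_NUCLEOTIDES)}


@dataclass(frozen=True)
class MtelParameters:
    """Pairing matrix and position weights of the competition model.

    ``pairing`` is 4x4 over codon nucleotides (rows, ACGT) x anticodon
    nucleotides (columns, ACGU), dimensionless; ``weights`` are the three
    codon-position importances on the simplex.
    """

    pairing: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        pairing = np.asarray(self.pairing, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "pairing", pairing)
        object.__setattr__(self, "weights", weights)
        if pairing.shape != (4, 4) or not np.isfinite(pairing).all():
            raise ValueError("pairing must be a finite 4x4 matrix")
        if pairing[PIN_ENTRY] != 0.0:
            raise ValueError("identifiability pin violated: pairing[A, U] must be exactly 0")
        if weights.shape != (3,) or (weights < 0).any() or abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must lie on the 3-simplex")


def arrival_rates(trnas: pd.DataFrame) -> np.ndarray:
    """Normalized tRNA arrival rates (abundance / total abundance)."""
    abundance = trnas["abundance"].to_numpy(dtype=float)
    if (abundance <= 0).any() or not np.isfinite(abundance).all():
        raise ValueError("tRNA abundances must be positive and finite")
    return abundance / abundance.sum()


def binding_score(codon: str, anticodon: str, params: MtelParameters) -> float:
    """Binding score of one codon/anticodon pair.

    Antiparallel pairing: codon position p pairs anticodon position 4-p.
    """
    if len(codon) != 3 or any(nt not in _CODON_NT_INDEX for nt in codon):
        raise ValueError(f"invalid codon {codon!r}")
    if len(anticodon) != 3 or any(nt not in _ANTI_NT_INDEX for nt in anticodon):
        raise ValueError(f"invalid anticodon {anticodon!r}")
    score = 0.0
    for p in range(3):
        score += params.weights[p] * params.pairing[
            _CODON_NT_INDEX[codon[p]], _ANTI_NT_INDEX[anticodon[2 - p]]
        ]
    return float(score)


class _ModelContext:
    """Precomputed index arrays for fast vectorized model evaluation."""

    def __init__(self, trnas: pd.DataFrame):
        self.trnas = trnas.reset_index(drop=True)
        self.anticodons = self.trnas["anticodon"].tolist()
        self.amino_acids = self.trnas["amino_acid"].tolist()
        self.log_arrival = np.log(arrival_rates(self.trnas))
        n_codons, n_trnas = len(SENSE_CODONS), len(self.trnas)
        # flat indices into pairing.ravel() per position: shape (3, 61, J)
        self.flat_idx = np.empty((3, n_codons, n_trnas), dtype=np.intp)
        for p in range(3):
            rows = np.array([_CODON_NT_INDEX[c[p]] for c in SENSE_CODONS])
            cols = np.array([_ANTI_NT_INDEX[a[2 - p]] for a in self.anticodons])
            self.flat_idx[p] = rows[:, None] * 4 + cols[None, :]
        # tRNA -> amino-acid aggregation (J x 20)
        self.aa_order = list(AMINO_ACIDS)
        self.aa_membership = np.zeros((n_trnas, 20))
        for j, aa in enumerate(self.amino_acids):
            self.aa_membership[j, self.aa_order.index(aa)] = 1.0
        # amino acid -> destination class aggregation (20 x 19)
        self.class_membership = np.zeros((20, len(DESTINATION_CLASSES)))
        for a, aa in enumerate(self.aa_order):
            self.class_membership[a, DESTINATION_CLASSES.index(destination_class_of(aa))] = 1.0

    def scores(self, params: MtelParameters) -> np.ndarray:
        flat = params.pairing.ravel()
        w = params.weights
        return (
            w[0] * flat[self.flat_idx[0]]
            + w[1] * flat[self.flat_idx[1]]
            + w[2] * flat[self.flat_idx[2]]
        )

    def decoding_probabilities(self, params: MtelParameters) -> np.ndarray:
        """p(j | i): 61 x J, rows sum to 1; softmax with max subtraction."""
        z = self.scores(params) + self.log_arrival[None, :]
        z -= z.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=1, keepdims=True)

    def amino_acid_probabilities(self, params: MtelParameters) -> np.ndarray:
        return self.decoding_probabilities(params) @ self.aa_membership

    def class_probabilities(self, params: MtelParameters) -> np.ndarray:
        return self.amino_acid_probabilities(params) @ self.class_membership


@dataclass(frozen=True)
class IncorporationMatrix:
    """Codon -> amino-acid incorporation probabilities and the underlying
    per-tRNA decoding probabilities."""

    probabilities: pd.DataFrame  # 61 codons x 20 amino acids, rows sum to 1
    decoding: pd.DataFrame  # 61 codons x tRNA anticodons


def incorporation_matrix(params: MtelParameters, trnas: pd.DataFrame) -> IncorporationMatrix:
    """Evaluate the competition model into an incorporation matrix.

    Warns and zero-fills the column of any amino acid carried by no tRNA
    (such channels have no model support and block fitting if observed).
    """
    ctx = _ModelContext(trnas)
    missing = sorted(set(AMINO_ACIDS) - set(ctx.amino_acids))
    if missing:
        warnings.warn(
            f"no tRNA carries amino acid(s) {missing}; their incorporation "
            "probabilities are identically zero",
            stacklevel=2,
        )
    p_aa = ctx.amino_acid_probabilities(params)
    probabilities = pd.DataFrame(p_aa, index=list(SENSE_CODONS), columns=ctx.aa_order)
    decoding = pd.DataFrame(
        ctx.decoding_probabilities(params), index=list(SENSE_CODONS), columns=ctx.anticodons
    )
    return IncorporationMatrix(probabilities, decoding)


def build_detectability_mask(
    mods: pd.DataFrame | None,
    config: DetectionConfig | None = None,
) -> pd.DataFrame:
    """Which (codon, destination class) channels the detector could observe.

    A channel is detectable iff the destination differs from the codon's
    cognate amino acid, the substitution has a usable mass shift (this
    excludes the isobaric I<->L channels), and that shift does not collide
    with any modification mass in ``mods`` within the PTM tolerance.
    """
    config = DetectionConfig() if config is None else config
    deltas = substitution_deltas()
    mask = pd.DataFrame(
        False, index=list(SENSE_CODONS), columns=list(DESTINATION_CLASSES), dtype=bool
    )
    for codon in SENSE_CODONS:
        origin = CODON_TO_AA[codon]
        for cls in DESTINATION_CLASSES:
            delta = deltas.get((origin, cls))
            if delta is None:
                continue
            if mods is not None and ptm_conflict(delta, mods, config):
                continue
            mask.at[codon, cls] = True
    return mask


def _counts_arrays(codon_counts: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(n_i totals, k_{i,c} destination counts) aligned to SENSE_CODONS."""
    table = codon_counts.set_index("codon").reindex(list(SENSE_CODONS))
    n = table["total_observations"].fillna(0).to_numpy(dtype=float)
    k = table[list(DESTINATION_CLASSES)].fillna(0).to_numpy(dtype=float)
    return n, k


def log_likelihood(
    params: MtelParameters,
    codon_counts: pd.DataFrame,
    mask: pd.DataFrame,
    trnas: pd.DataFrame,
    _ctx: _ModelContext | None = None,
) -> float:
    """Masked multinomial log-likelihood of the codon count table.

    For codon *i* with ``n_i`` total observations and error counts
    ``k_{i,c}`` over detectable destination classes *c*:

        ll_i = sum_c k_{i,c} log p(c|i)
               + (n_i - sum_c k_{i,c}) log(1 - sum_c p(c|i))

    where the second term lumps the cognate outcome together with every
    undetectable channel.  Errors observed on masked channels are an input
    inconsistency and raise; a detectable channel with zero model
    probability but positive count yields -inf.
    """
    ctx = _ModelContext(trnas) if _ctx is None else _ctx
    n, k = _counts_arrays(codon_counts)
    m = mask.reindex(index=list(SENSE_CODONS), columns=list(DESTINATION_CLASSES)).to_numpy(
        dtype=bool
    )
    if (k[~m] > 0).any():
        raise ValueError("error counts present on undetectable (masked) channels")
    return _masked_loglik(ctx.class_probabilities(params), n, k, m)


def _masked_loglik(p_class: np.ndarray, n: np.ndarray, k: np.ndarray, m: np.ndarray) -> float:
    kd = np.where(m, k, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(kd > 0, kd * np.log(np.where(m, p_class, 1.0)), 0.0)
    detect_mass = np.where(m, p_class, 0.0).sum(axis=1)
    rest = n - kd.sum(axis=1)
    with np.errstate(divide="ignore"):
        log_rest = np.log1p(-np.clip(detect_mass, 0.0, 1.0))
    rest_term = np.where(rest > 0, rest * log_rest, 0.0)
    total = term.sum() + rest_term.sum()
    return float(total) if np.isfinite(total) else float("-inf")


# --- fitting ---------------------------------------------------------------

_FREE_PAIRING = [  # flat indices of the 15 free pairing entries (pin excluded)
    i for i in range(16) if i != PIN_ENTRY[0] * 4 + PIN_ENTRY[1]
]


def _unpack(theta: np.ndarray) -> MtelParameters:
    v = np.concatenate([[0.0], theta[:2]])  # first weight logit fixed at 0
    v -= v.max()
    w = np.exp(v)
    w /= w.sum()
    pairing = np.zeros(16)
    pairing[_FREE_PAIRING] = theta[2:]
    return MtelParameters(pairing.reshape(4, 4), w)


def _pack(params: MtelParameters) -> np.ndarray:
    w = np.clip(params.weights, 1e-12, None)
    v = np.log(w) - np.log(w[0])
    return np.concatenate([v[1:], params.pairing.ravel()[_FREE_PAIRING]])


@dataclass(frozen=True)
class FitConfig:
    """Multi-start optimizer settings for the maximum-likelihood fit."""

    restarts: int = 20
    seed: int = 0
    max_iter: int = 4000
    xatol: float = 1e-6
    fatol: float = 1e-8
    init_scale: float = 0.5
    n_bootstrap: int = 0

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class FitResult:
    """Point estimate and diagnostics of a maximum-likelihood fit."""

    params: MtelParameters
    log_likelihood: float
    restart_objectives: list[float]
    n_iterations: int
    converged: bool
    bootstrap: list[MtelParameters] = field(default_factory=list)

    @property
    def restart_spread(self) -> float:
        return float(np.max(self.restart_objectives) - np.min(self.restart_objectives))


def fit(
    codon_counts: pd.DataFrame,
    trnas: pd.DataFrame,
    mask: pd.DataFrame,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit pairing parameters and position weights by maximum likelihood.

    Multi-start derivative-free local search (Nelder-Mead on the
    unconstrained reparameterization: softmax logits for the weights, free
    reals for the unpinned pairing entries), followed by a polish run from
    the best restart.  Deterministic for a fixed seed.
    """
    config = FitConfig() if config is None else config
    ctx = _ModelContext(trnas)
    n, k = _counts_arrays(codon_counts)
    m = mask.reindex(index=list(SENSE_CODONS), columns=list(DESTINATION_CLASSES)).to_numpy(
        dtype=bool
    )
    if (k[~m] > 0).any():
        raise ValueError("error counts present on undetectable (masked) channels")
    kd = np.where(m, k, 0.0)
    if kd.sum() == 0:
        raise ValueError("model unidentifiable: no errors observed")
    observed_classes = {DESTINATION_CLASSES[c] for c in np.nonzero(kd.sum(axis=0) > 0)[0]}
    supported = {destination_class_of(aa) for aa in ctx.amino_acids}
    unsupported = observed_classes - supported
    if unsupported:
        raise ValueError(
            f"observed destination class(es) {sorted(unsupported)} have no tRNA "
            "support; the model assigns them probability zero"
        )

    def objective(theta: np.ndarray) -> float:
        p_class = ctx.class_probabilities(_unpack(theta))
        return -_masked_loglik(p_class, n, kd, m)

    rng = np.random.default_rng(config.seed)
    options = {"maxiter": config.max_iter, "xatol": config.xatol, "fatol": config.fatol, "adaptive": True}
    best = None
    objectives: list[float] = []
    for _ in range(config.restarts):
        theta0 = rng.normal(0.0, config.init_scale, size=2 + len(_FREE_PAIRING))
        res = minimize(objective, theta0, method="Nelder-Mead", options=options)
        objectives.append(-float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    polish = minimize(objective, best.x, method="Nelder-Mead", options=options)
    if polish.fun < best.fun:
        best = polish

    bootstrap: list[MtelParameters] = []
    if config.n_bootstrap > 0:
        idx_all = np.arange(len(SENSE_CODONS))
        for _ in range(config.n_bootstrap):
            resampled = rng.choice(idx_all, size=len(idx_all), replace=True)
            nb, kb, mb = n[resampled], kd[resampled], m[resampled]
            ctx_flat = ctx.flat_idx[:, resampled, :]

            def boot_objective(theta: np.ndarray) -> float:
                params = _unpack(theta)
                flat = params.pairing.ravel()
                w = params.weights
                s = w[0] * flat[ctx_flat[0]] + w[1] * flat[ctx_flat[1]] + w[2] * flat[ctx_flat[2]]
                z = s + ctx.log_arrival[None, :]
                z -= z.max(axis=1, keepdims=True)
                ez = np.exp(z)
                p_trna = ez / ez.sum(axis=1, keepdims=True)
                p_class = p_trna @ ctx.aa_membership @ ctx.class_membership
                return -_masked_loglik(p_class, nb, kb, mb)

            bres = minimize(boot_objective, best.x, method="Nelder-Mead", options=options)
            bootstrap.append(_unpack(bres.x))

    params = _unpack(best.x)
    return FitResult(
        params=params,
        log_likelihood=-float(best.fun),
        restart_objectives=objectives,
        n_iterations=int(best.nit),
        converged=bool(best.success),
        bootstrap=bootstrap,
    )


def class_probabilities(params: MtelParameters, trnas: pd.DataFrame) -> pd.DataFrame:
    """Codon -> destination-class probabilities (isobaric I/L aggregated).

    Rows are the 61 sense codons, columns the 19 destination classes; note
    the cognate amino acid's class is included, so rows need not sum to 1
    over non-cognate channels.
    """
    ctx = _ModelContext(trnas)
    return pd.DataFrame(
        ctx.class_probabilities(params),
        index=list(SENSE_CODONS),
        columns=list(DESTINATION_CLASSES),
    )


def random_parameters(rng: np.random.Generator, scale: float = 1.0) -> MtelParameters:
    """Draw random model parameters honoring the pin and simplex constraints."""
    pairing = rng.normal(0.0, scale, size=(4, 4))
    pairing[PIN_ENTRY] = 0.0
    weights = rng.dirichlet(np.ones(3))
    return MtelParameters(pairing, weights)


def write_model_outputs(
    params: MtelParameters,
    trnas: pd.DataFrame,
    out_dir,
) -> dict:
    """Write the three model result files into ``out_dir``.

    ``mtel_parameters.csv`` holds the pairing matrix in long form plus the
    position weights; ``codon_affinity.csv`` the binding score and decoding
    probability of every codon/anticodon pair; and
    ``misincorporation_matrix.csv`` the codon x amino-acid incorporation
    probabilities.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ci, cnt in enumerate(CODON_NUCLEOTIDES):
        for ai, ant in enumerate(ANTICODON_NUCLEOTIDES):
            rows.append(
                {"parameter": "pairing", "codon_nt": cnt, "anticodon_nt": ant,
                 "position": "", "value": params.pairing[ci, ai]}
            )
    for p in range(3):
        rows.append(
            {"parameter": "weight", "codon_nt": "", "anticodon_nt": "",
             "position": p + 1, "value": params.weights[p]}
        )
    params_frame = pd.DataFrame(rows, columns=["parameter", "codon_nt", "anticodon_nt", "position", "value"])

    matrix = incorporation_matrix(params, trnas)
    affinity_rows = []
    for codon in SENSE_CODONS:
        for anticodon in matrix.decoding.columns:
            affinity_rows.append(
                {
                    "codon": codon,
                    "anticodon": anticodon,
                    "binding_score": binding_score(codon, anticodon, params),
                    "decoding_probability": matrix.decoding.at[codon, anticodon],
                }
            )
    affinity = pd.DataFrame(affinity_rows)
    misinc = matrix.probabilities.reset_index(names="codon")

    paths = {
        "mtel_parameters": out_dir / "mtel_parameters.csv",
        "codon_affinity": out_dir / "codon_affinity.csv",
        "misincorporation_matrix": out_dir / "misincorporation_matrix.csv",
    }
    params_frame.to_csv(paths["mtel_parameters"], index=False)
    affinity.to_csv(paths["codon_affinity"], index=False)
    misinc.to_csv(paths["misincorporation_matrix"], index=False)
    return paths
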