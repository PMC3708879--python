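"""Synthetic genomes and expression data with the structure the analysis assumes.

The generator emulates the features the pipeline measures on real genomes:
genes with variable-length 5'UTRs, codon-usage-biased ORFs that begin with ATG
and end with a stop (stop-free internally in frame 0), a tunable ATG-depletion
zone flanking the START in all three frames, a START context drawn from a
mixture of a "strong" initiation-context PSSM and a uniform one with mixture
weight tied to the gene's latent expression, and log-normal expression
measurements with noise.  All randomness flows from a single seeded generator,
so a given SimParams is byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from . import pssm_context
from .sequence_io import GeneRecord, GeneSet, make_expression_table
from .pssm_context import Pssm, DEFAULT_WINDOW, NT_ORDER

_TABLE = unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
STOPS: tuple[str, ...] = ("TAA", "TAG", "TGA")
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))
SYNONYMS: dict[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa))
    for aa in sorted(set(CODON_TO_AA.values()))
}

# Typical proteome amino-acid frequencies (yeast-like), used to spread the
# default codon usage over amino acids with a realistic Met rate (~2%).
_AA_FREQ = {
    "A": 0.055, "C": 0.013, "D": 0.058, "E": 0.065, "F": 0.045,
    "G": 0.050, "H": 0.022, "I": 0.066, "K": 0.073, "L": 0.096,
    "M": 0.021, "N": 0.061, "P": 0.044, "Q": 0.039, "R": 0.044,
    "S": 0.090, "T": 0.059, "V": 0.056, "W": 0.010, "Y": 0.034,
}
_STOP_FREQ = {"TAA": 0.47, "TAG": 0.23, "TGA": 0.30}


def default_codon_usage() -> dict[str, float]:
    """Mildly biased unconditional codon probabilities over the 61 sense codons.

    Within each synonymous family the first codon (alphabetically) is favored
    2:1 over the next, decaying geometrically — a simple stand-in for codon
    usage bias; amino-acid frequencies follow a typical proteome.
    """
    total_aa = sum(_AA_FREQ.values())
    usage: dict[str, float] = {}
    for aa, codons in SYNONYMS.items():
        weights = np.array([0.5 ** i for i in range(len(codons))])
        weights /= weights.sum()
        for c, w in zip(codons, weights):
            usage[c] = _AA_FREQ[aa] / total_aa * w
    return usage


def strong_context_pssm(consensus_prob: float = 0.7) -> Pssm:
    """The 'strong' initiation-context PSSM used to couple context to expression.

    Consensus follows the Kozak optimum at -3..-1/+1 (A,C,C,G) with A-rich
    further upstream; each position puts ``consensus_prob`` on the consensus
    nucleotide and splits the rest uniformly.
    """
    consensus = {-6: "A", -5: "A", -4: "A", -3: "A", -2: "C", -1: "C",
                 1: "G", 2: "C", 3: "T"}
    rest = (1.0 - consensus_prob) / 3.0
    probs = np.full((len(DEFAULT_WINDOW), 4), rest)
    for i, o in enumerate(DEFAULT_WINDOW):
        probs[i, NT_ORDER.index(consensus[o])] = consensus_prob
    return Pssm(DEFAULT_WINDOW, probs)


#: Reference effect sizes (per standardized feature, log-expression scale) for
#: plant_feature_expression when exercising the predictor ladder.  The
#: downstream-ATG count carries the largest weight because it is the only
#: feature orthogonal to the shared START-context factor (the Kozak distance,
#: the START score and the relative alternative-context mean are mutually
#: correlated by construction); the noise level keeps binned correlations in
#: the mid-range observed for real expression data rather than saturating.
DEFAULT_PLANT_EFFECTS: dict[str, float] = {
    "kozak_dist": -0.15,
    "start_context": 0.3,
    "alt_atg_count_30": -0.9,
    "alt_context_mean_30": -0.6,
}
DEFAULT_PLANT_NOISE_SD: float = 2.0


class SimulationError(RuntimeError):
    """Infeasible simulation constraints (e.g. strength=1 with forced ATGs)."""


@dataclass(frozen=True)
class DepletionZone:
    """ATG rejection zone flanking the START, in codons on either side."""

    utr_len_codons: int = 16
    orf_len_codons: int = 8
    strength: float = 0.8

    def __post_init__(self):
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must be in [0,1]")
        if self.utr_len_codons < 0 or self.orf_len_codons < 0:
            raise ValueError("zone lengths must be non-negative")


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one simulated genome."""

    n_genes: int = 500
    utr_len_mean: float = 82.0  # nt; yeast-like mean 5'UTR length
    orf_len_codons_mean: float = 450.0
    codon_usage: dict[str, float] = field(default_factory=default_codon_usage)
    stop_usage: dict[str, float] = field(default_factory=lambda: dict(_STOP_FREQ))
    gc_utr: float = 0.36
    depletion: DepletionZone = field(default_factory=DepletionZone)
    context_effect: float = 1.0  # strength of START-context <-> expression coupling
    expr_noise_sd: float = 0.5  # log-scale measurement noise
    seed: int = 0
    min_utr_len: int = 6
    min_orf_codons: int = 110  # internal codons floor; keeps 300-nt analyses in range

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not 0.0 <= self.gc_utr <= 1.0:
            raise ValueError("gc_utr must be a probability")
        total = sum(self.codon_usage.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError("codon_usage must sum to 1 over sense codons")
        # Per-amino-acid conditionals must be proper distributions.
        for aa, codons in SYNONYMS.items():
            fam = sum(self.codon_usage.get(c, 0.0) for c in codons)
            if fam <= 0:
                raise ValueError(f"amino acid {aa} has zero total codon probability")


def _utr_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T


_MAX_REPAIR_PASSES = 200


def _repair_zone(
    utr: list[str],
    codons: list[str],
    zone: DepletionZone,
    rng: np.random.Generator,
    codon_list: list[str],
    codon_probs: np.ndarray,
    utr_probs: np.ndarray,
    gene_idx: int,
) -> None:
    """Rejection-resample ATG triplets (any frame) inside the depletion zone.

    Scans ATG start positions p in [-3*utr_zone, 3*orf_zone], p != 0, on the
    transcript; each occurrence is resampled with probability ``strength``
    (UTR nucleotides from the background UTR distribution, ORF codons from the
    codon usage).  Codon 0 is the START and is never touched.
    """
    if zone.strength == 0.0 or (zone.utr_len_codons == 0 and zone.orf_len_codons == 0):
        return
    lo = -min(3 * zone.utr_len_codons, len(utr))
    hi = min(3 * zone.orf_len_codons, 3 * len(codons) - 3)
    if hi < lo:
        return
    nt = list(NT_ORDER)
    accepted: set[int] = set()

    def triplet(p: int) -> str:
        out = []
        for q in (p, p + 1, p + 2):
            out.append(utr[len(utr) + q] if q < 0 else codons[q // 3][q % 3])
        return "".join(out)

    for _ in range(_MAX_REPAIR_PASSES):
        hits = [
            p
            for p in range(lo, hi + 1)
            if p != 0 and p not in accepted and triplet(p) == "ATG"
        ]
        if not hits:
            return
        changed = False
        for p in hits:
            if zone.strength < 1.0 and rng.random() >= zone.strength:
                accepted.add(p)
                continue
            changed = True
            resampled_codons: set[int] = set()
            for q in (p, p + 1, p + 2):
                if q < 0:
                    utr[len(utr) + q] = nt[rng.choice(4, p=utr_probs)]
                else:
                    c = q // 3
                    if c == 0 or c in resampled_codons:
                        continue
                    codons[c] = codon_list[rng.choice(len(codon_list), p=codon_probs)]
                    resampled_codons.add(c)
        if not changed:
            return
    raise SimulationError(
        f"gene {gene_idx}: could not clear depletion zone of ATGs after "
        f"{_MAX_REPAIR_PASSES} passes"
    )


def simulate_genome(params: SimParams) -> tuple[GeneSet, pd.DataFrame]:
    """Generate a genome and matched expression table; deterministic given seed."""
    rng = np.random.default_rng(params.seed)
    n = params.n_genes

    codon_list = list(SENSE_CODONS)
    codon_probs = np.array([params.codon_usage[c] for c in codon_list])
    codon_probs /= codon_probs.sum()
    stop_list = list(STOPS)
    stop_probs = np.array([params.stop_usage[s] for s in stop_list])
    stop_probs /= stop_probs.sum()
    utr_probs = _utr_probs(params.gc_utr)

    # Lengths: gamma-shaped with floors so every gene supports the analyses.
    utr_lens = np.maximum(
        params.min_utr_len,
        np.round(rng.gamma(2.0, params.utr_len_mean / 2.0, size=n)).astype(int),
    )
    orf_internal = np.maximum(
        params.min_orf_codons,
        np.round(rng.gamma(6.0, params.orf_len_codons_mean / 6.0, size=n)).astype(int)
        - 2,
    )

    # Latent (log-scale) expression and the strong-context mixture component.
    latent = rng.normal(0.0, 1.0, size=n)
    w_strong = 1.0 / (1.0 + np.exp(-params.context_effect * latent))
    is_strong = rng.random(n) < w_strong

    # Bulk-sample all UTR nucleotides and all internal codons at once.
    utr_total = int(utr_lens.sum())
    utr_idx = rng.choice(4, size=utr_total, p=utr_probs)
    nt_arr = np.array(list(NT_ORDER))
    all_utr = nt_arr[utr_idx]
    cod_total = int(orf_internal.sum())
    cod_idx = rng.choice(len(codon_list), size=cod_total, p=codon_probs)
    codon_arr = np.array(codon_list)
    all_codons = codon_arr[cod_idx]
    stop_idx = rng.choice(len(stop_list), size=n, p=stop_probs)

    strong = strong_context_pssm()
    uniform = Pssm.uniform()

    genes: list[GeneRecord] = []
    u0 = 0
    c0 = 0
    for i in range(n):
        ul, cl = int(utr_lens[i]), int(orf_internal[i])
        utr = list(all_utr[u0 : u0 + ul])
        codons = ["ATG"] + list(all_codons[c0 : c0 + cl]) + [stop_list[stop_idx[i]]]
        u0 += ul
        c0 += cl

        # Plant the START context from the gene's mixture component.
        pssm = strong if is_strong[i] else uniform
        for j, o in enumerate(pssm.offsets):
            if o < 0:
                if ul + o - 0 >= 0:  # offset within the UTR
                    utr[ul + o] = NT_ORDER[rng.choice(4, p=pssm.probs[j])]
        for _ in range(50):
            codon1 = "".join(
                NT_ORDER[rng.choice(4, p=pssm.probs[pssm.offsets.index(o)])]
                for o in (1, 2, 3)
            )
            if codon1 not in STOPS:
                codons[1] = codon1
                break
        else:  # pragma: no cover - uniform/strong PSSMs always admit non-stops
            raise SimulationError("could not draw a non-stop context codon")

        _repair_zone(
            utr, codons, params.depletion, rng, codon_list, codon_probs, utr_probs, i
        )
        genes.append(
            GeneRecord(f"g{i:05d}", "".join(utr), "".join(codons))
        )

    sd = params.expr_noise_sd
    half_sd = sd / math.sqrt(2.0)
    mrna = np.exp(0.5 * latent + rng.normal(0.0, half_sd, size=n))
    rd = np.exp(0.5 * latent + rng.normal(0.0, half_sd, size=n))
    pa = np.exp(latent + rng.normal(0.0, sd, size=n))
    ids = [g.gene_id for g in genes]
    expr = make_expression_table(
        mrna=pd.Series(mrna, index=ids),
        rd=pd.Series(rd, index=ids),
        pa=pd.Series(pa, index=ids),
    )
    return GeneSet(genes, min_utr_len=params.min_utr_len), expr


def plant_feature_expression(
    genes: GeneSet,
    effects: dict[str, float],
    noise_sd: float,
    seed: int,
    pssm: Pssm | None = None,
) -> pd.DataFrame:
    """Expression generated from initiation features: exp(sum effect*z + noise).

    Features are the predictor module's per-gene features, computed under
    ``pssm`` (default: the generator's strong-context PSSM), standardized;
    missing values are mean-imputed (z = 0) before combination.  The returned
    table carries the generated expression as mrna, pa and ribosomal load.
    """
    from . import predictors  # deferred: predictors imports pssm_context only

    known = set(predictors.FEATURE_NAMES)
    unknown = set(effects) - known
    if unknown:
        raise ValueError(f"unknown feature name(s): {sorted(unknown)}")
    feats = predictors.compute_features(genes, pssm or strong_context_pssm())
    rng = np.random.default_rng(seed)
    log_expr = pd.Series(0.0, index=feats.index)
    for name, effect in effects.items():
        col = feats[name]
        z = (col - col.mean()) / col.std(ddof=0) if col.std(ddof=0) > 0 else col * 0.0
        log_expr = log_expr + effect * z.fillna(0.0)
    log_expr = log_expr + rng.normal(0.0, noise_sd, size=len(log_expr))
    expr = np.exp(log_expr)
    return make_expression_table(
        mrna=expr, rd=pd.Series(1.0, index=expr.index), pa=expr
    )
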