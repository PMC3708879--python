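"""START-context PSSM, positional entropy, and the relative ATG context score.

The context window spans 6 nt upstream and 3 nt downstream of the ATG triplet
(offsets -6..-1 and +1..+3; the invariant ATG itself is excluded).  The raw
context score of an ATG is the geometric mean of the PSSM probabilities of its
flanking nucleotides; the *relative* score divides by the raw score of the
gene's own START ATG, so a START scores exactly 1 and alternative ATGs score
above/below 1 according to how much their context resembles the initiation
context of highly translated genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence_io import GeneRecord, GeneSet, AtgSite, enumerate_atgs

NT_ORDER = "ACGT"
NT_INDEX = {n: i for i, n in enumerate(NT_ORDER)}

DEFAULT_WINDOW: tuple[int, ...] = (-6, -5, -4, -3, -2, -1, 1, 2, 3)

#: Kozak's optimal initiation context ACC|ATG|G: offsets -3,-2,-1,+1.
KOZAK_OPTIMUM = {-3: "A", -2: "C", -1: "C", 1: "G"}


@dataclass(frozen=True)
class Pssm:
    """Per-position nucleotide probability matrix over the context window."""

    offsets: tuple[int, ...]
    probs: np.ndarray  # shape (len(offsets), 4), columns in NT_ORDER
    pseudocount: float = 0.0

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (len(self.offsets), 4):
            raise ValueError("probs must be (n_offsets, 4)")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each position's probabilities must sum to 1")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "_row", {o: i for i, o in enumerate(self.offsets)})

    def prob(self, offset: int, nt: str) -> float:
        return float(self.probs[self._row[offset], NT_INDEX[nt]])

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.probs, index=list(self.offsets), columns=list(NT_ORDER))
        df.index.name = "offset"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, pseudocount: float = 0.0) -> "Pssm":
        df = pd.read_csv(path, sep="\t", index_col="offset")
        return cls(tuple(df.index), df[list(NT_ORDER)].to_numpy(), pseudocount)

    @classmethod
    def uniform(cls, offsets: tuple[int, ...] = DEFAULT_WINDOW) -> "Pssm":
        return cls(offsets, np.full((len(offsets), 4), 0.25))


@dataclass(frozen=True)
class EntropyProfile:
    offsets: tuple[int, ...]
    entropy: np.ndarray  # bits, in [0, 2]
    zscores: np.ndarray | None = None


@dataclass(frozen=True)
class RelativeContextScore:
    raw: float
    relative: float
    partial: bool = False


def context_offsets_to_index(gene: GeneRecord, pos: int, offset: int) -> int:
    """Transcript string index of a context offset around the ATG at ``pos``.

    Negative offsets count nucleotides upstream of the 'A'; positive offsets
    count nucleotides downstream of the ATG triplet (offset +1 is the nt right
    after the 'G').
    """
    rel = offset if offset < 0 else offset + 2
    return len(gene.utr5) + pos + rel


def context_nucleotides(
    gene: GeneRecord, pos: int, offsets: tuple[int, ...]
) -> dict[int, str]:
    """Available context nucleotides around the ATG at ``pos``; absent offsets omitted."""
    transcript = gene.transcript
    out: dict[int, str] = {}
    for o in offsets:
        idx = context_offsets_to_index(gene, pos, o)
        if 0 <= idx < len(transcript):
            out[o] = transcript[idx]
    return out


def select_training_set(
    expr: pd.DataFrame,
    top_frac: float = 0.02,
    pool_frac: float = 0.04,
    seed: int = 0,
) -> set[str]:
    """Pick the PSSM training set: a random half of the top genes by ribosomal load.

    The pool is the top ``pool_frac`` of genes ranked by ribosomal load; the
    training set is a seeded random sample of size ``round(top_frac * n)``
    from that pool (with the default 2%/4% this is half the pool).  The
    returned ids should be excluded from downstream profile/predictor stages
    to avoid over-fitting.
    """
    rl = expr["ribosomal_load"].dropna()
    n = len(rl)
    pool_size = int(round(pool_frac * n))
    k = int(round(top_frac * n))
    if k < 1 or pool_size < k:
        raise ValueError(
            f"too few scored genes: n={n}, pool={pool_size}, training={k}"
        )
    pool = rl.sort_values(ascending=False, kind="stable").index[:pool_size]
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=k, replace=False)
    return set(pool[sorted(chosen)])


def build_pssm(
    genes: GeneSet,
    training_ids: set[str],
    window: tuple[int, ...] = DEFAULT_WINDOW,
    pseudocount: float = 0.5,
) -> Pssm:
    """Nucleotide frequency matrix of the START contexts of the training genes.

    probs[i][n] = (count + pseudocount) / (N + 4 * pseudocount).
    """
    if not training_ids:
        raise ValueError("empty training set")
    counts = np.zeros((len(window), 4))
    n_used = 0
    for gid in training_ids:
        gene = genes[gid]
        ctx = context_nucleotides(gene, 0, window)
        if len(ctx) != len(window):
            raise ValueError(
                f"training gene {gid} lacks a full START context "
                f"(5'UTR length {len(gene.utr5)})"
            )
        for i, o in enumerate(window):
            counts[i, NT_INDEX[ctx[o]]] += 1
        n_used += 1
    probs = (counts + pseudocount) / (n_used + 4 * pseudocount)
    return Pssm(tuple(window), probs, pseudocount)


def positional_entropy(pssm: Pssm, zscore: bool = False) -> EntropyProfile:
    """Shannon entropy (bits) of each context position; optionally z-scored.

    0*log(0) is taken as 0, so point-mass columns score 0 bits and uniform
    columns 2 bits.  Z-scoring centers and scales across the window's
    positions, giving the number of SDs each position sits from the mean.
    """
    p = pssm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    h = terms.sum(axis=1)
    z = None
    if zscore:
        sd = h.std()
        z = (h - h.mean()) / sd if sd > 0 else np.zeros_like(h)
    return EntropyProfile(pssm.offsets, h, z)


def _raw_score(pssm: Pssm, ctx: dict[int, str]) -> float | None:
    """Geometric mean of PSSM probabilities over the available context positions."""
    if not ctx:
        return None
    logs = [math.log(pssm.prob(o, nt)) for o, nt in ctx.items()]
    return math.exp(sum(logs) / len(logs))


def context_score(
    pssm: Pssm, site: AtgSite, gene: GeneRecord
) -> RelativeContextScore | None:
    """Relative context score of an ATG site (raw / raw of the gene's START).

    A site whose context window is truncated by a transcript end is scored
    over its available positions (geometric mean renormalized to the available
    count) and flagged partial.  If the gene's own START lacks a full context
    (5'UTR shorter than the window) the site is unscored (None), never zero.
    """
    start_ctx = context_nucleotides(gene, 0, pssm.offsets)
    if len(start_ctx) != len(pssm.offsets):
        return None
    start_raw = _raw_score(pssm, start_ctx)
    ctx = context_nucleotides(gene, site.pos, pssm.offsets)
    raw = _raw_score(pssm, ctx)
    if raw is None:
        return None
    return RelativeContextScore(
        raw=raw, relative=raw / start_raw, partial=len(ctx) != len(pssm.offsets)
    )


def kozak_hamming(site: AtgSite, gene: GeneRecord) -> int | None:
    """Mismatches of the (-3,-2,-1,+1) context against Kozak's ACC|ATG|G optimum.

    Returns None (missing) when the context is truncated.
    """
    ctx = context_nucleotides(gene, site.pos, tuple(KOZAK_OPTIMUM))
    if len(ctx) != len(KOZAK_OPTIMUM):
        return None
    return sum(1 for o, nt in KOZAK_OPTIMUM.items() if ctx[o] != nt)


def context_score_profile(
    genes: GeneSet,
    pssm: Pssm,
    up_span: int,
    down_span: int = 600,
    window: int = 30,
    exclude: set[str] | frozenset[str] = frozenset(),
) -> pd.DataFrame:
    """Sliding-window mean relative context score of alternative ATGs.

    For each nucleotide position in [-up_span, down_span) the mean relative
    score of all alternative-ATG sites (START excluded) whose position falls
    in the ``window``-nt window centered there; positions with no sites are
    missing.  ``exclude`` should contain the PSSM training set.
    """
    site_pos: list[int] = []
    site_score: list[float] = []
    for gene in genes.with_utr():
        if gene.gene_id in exclude:
            continue
        for site in enumerate_atgs(gene, up_span + window, down_span + window):
            if site.pos == 0:
                continue
            sc = context_score(pssm, site, gene)
            if sc is not None:
                site_pos.append(site.pos)
                site_score.append(sc.relative)
    positions = np.arange(-up_span, down_span)
    mean_score = np.full(len(positions), np.nan)
    n_sites = np.zeros(len(positions), dtype=int)
    if site_pos:
        pos_arr = np.asarray(site_pos)
        score_arr = np.asarray(site_score)
        half = window // 2
        for i, t in enumerate(positions):
            mask = (pos_arr >= t - half) & (pos_arr <= t + half - 1)
            k = int(mask.sum())
            n_sites[i] = k
            if k:
                mean_score[i] = score_arr[mask].mean()
    out = pd.DataFrame(
        {"mean_score": mean_score, "n_sites": n_sites},
        index=pd.Index(positions, name="pos"),
    )
    return out
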