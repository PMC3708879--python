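"""Null genomes preserving protein identity, and empirical per-position flags.

Three null schemes:

* CODON_RESAMPLE - every internal codon is redrawn from its amino acid's
  genome-wide synonymous-codon distribution, so each gene translates to the
  identical protein while genome codon bias is preserved in expectation.
* CODON_PERMUTE - the internal codons of each gene are permuted (START and
  terminal stop fixed), preserving each gene's codon multiset exactly.
* RAMP_PRESERVING - like CODON_RESAMPLE, but the synonymous frequencies for
  the first ``ramp_len`` codons of the ORF are estimated from, and applied to,
  that region only, preserving the atypical codon distribution at the start
  of coding sequences.

5'UTRs are randomized by permuting their own nucleotides in every scheme,
which preserves each UTR's nucleotide multiset (hence GC content) exactly.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .sequence_io import GeneRecord, GeneSet
from .synthetic_data import CODON_TO_AA, SYNONYMS, STOPS

logger = logging.getLogger(__name__)


class Flag(str, Enum):
    DEPLETED = "DEPLETED"
    ENRICHED = "ENRICHED"
    NS = "NS"


@dataclass(frozen=True)
class NullScheme:
    kind: str = "CODON_RESAMPLE"  # CODON_RESAMPLE | CODON_PERMUTE | RAMP_PRESERVING
    ramp_len: int = 40  # codons, RAMP_PRESERVING only
    n_replicates: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("CODON_RESAMPLE", "CODON_PERMUTE", "RAMP_PRESERVING"):
            raise ValueError(f"unknown null scheme {self.kind!r}")
        if self.n_replicates < 1 or self.ramp_len < 1:
            raise ValueError("n_replicates and ramp_len must be >= 1")

    def randomize(self, genes: GeneSet, replicate: int = 0) -> GeneSet:
        """Replicate ``r`` uses seed ``seed + r`` so each is independently reproducible."""
        seed = self.seed + replicate
        if self.kind == "CODON_RESAMPLE":
            return randomize_codon_resample(genes, seed)
        if self.kind == "CODON_PERMUTE":
            return randomize_codon_permute(genes, seed)
        return randomize_ramp_preserving(genes, self.ramp_len, seed)


def _internal_codons(orf: str) -> list[str]:
    return [orf[i : i + 3] for i in range(3, len(orf) - 3, 3)]


def _permuted_utr(utr: str, rng: np.random.Generator) -> str:
    if len(utr) < 2:
        return utr
    return "".join(np.array(list(utr))[rng.permutation(len(utr))])


def _family_tables(
    counts: Counter[str],
) -> dict[str, tuple[list[str], np.ndarray]]:
    """Per-amino-acid synonymous codon lists with genome-frequency probabilities."""
    tables: dict[str, tuple[list[str], np.ndarray]] = {}
    for aa, codons in SYNONYMS.items():
        c = np.array([counts.get(cod, 0) for cod in codons], dtype=float)
        if c.sum() == 0:
            continue
        tables[aa] = (list(codons), c / c.sum())
    return tables


def _stop_table(genes: GeneSet) -> tuple[list[str], np.ndarray]:
    counts = Counter(g.orf[-3:] for g in genes)
    stops = list(STOPS)
    c = np.array([counts.get(s, 0) for s in stops], dtype=float)
    return stops, c / c.sum()


def _resample_genome(
    genes: GeneSet,
    seed: int,
    ramp_len: int | None = None,
) -> GeneSet:
    """Synonymous resampling against genome-wide (and optionally ramp) frequencies."""
    rng = np.random.default_rng(seed)
    genome_counts: Counter[str] = Counter()
    ramp_counts: Counter[str] = Counter()
    per_gene: list[tuple[GeneRecord, list[str]]] = []
    for g in genes:
        internal = _internal_codons(g.orf)
        genome_counts.update(internal)
        if ramp_len is not None:
            ramp_counts.update(internal[:ramp_len])
        per_gene.append((g, internal))

    genome_tables = _family_tables(genome_counts)
    ramp_tables = _family_tables(ramp_counts) if ramp_len is not None else {}
    if ramp_len is not None:
        missing = sorted(set(genome_tables) - set(ramp_tables))
        if missing:
            logger.info(
                "ramp region lacks amino acid(s) %s; using genome-wide frequencies",
                missing,
            )
    stops, stop_probs = _stop_table(genes)

    # Vectorized per-family resampling: one draw batch per (family, region).
    slots: dict[tuple[str, bool], list[tuple[int, int]]] = {}
    for gi, (g, internal) in enumerate(per_gene):
        for ci, codon in enumerate(internal):
            aa = CODON_TO_AA[codon]
            in_ramp = ramp_len is not None and ci < ramp_len and aa in ramp_tables
            slots.setdefault((aa, in_ramp), []).append((gi, ci))

    new_codons: list[list[str]] = [list(internal) for _, internal in per_gene]
    for (aa, in_ramp), positions in slots.items():
        codons, probs = ramp_tables[aa] if in_ramp else genome_tables[aa]
        draws = rng.choice(len(codons), size=len(positions), p=probs)
        for (gi, ci), d in zip(positions, draws):
            new_codons[gi][ci] = codons[d]

    new_stops = rng.choice(len(stops), size=len(per_gene), p=stop_probs)
    out = []
    for gi, (g, _) in enumerate(per_gene):
        orf = "ATG" + "".join(new_codons[gi]) + stops[new_stops[gi]]
        out.append(
            GeneRecord(g.gene_id, _permuted_utr(g.utr5, rng), orf, g.utr3)
        )
    return GeneSet(out, min_utr_len=genes.min_utr_len, validate=False)


def randomize_codon_resample(genes: GeneSet, seed: int = 0) -> GeneSet:
    """Null genome with identical proteins and genome-wide codon bias."""
    return _resample_genome(genes, seed, ramp_len=None)


def randomize_ramp_preserving(
    genes: GeneSet, ramp_len: int = 40, seed: int = 0
) -> GeneSet:
    """Like CODON_RESAMPLE, but the first ``ramp_len`` ORF codons are resampled
    against frequencies estimated from that region only."""
    return _resample_genome(genes, seed, ramp_len=ramp_len)


def randomize_codon_permute(genes: GeneSet, seed: int = 0) -> GeneSet:
    """Per-gene permutation of internal codons; START and stop stay in place."""
    rng = np.random.default_rng(seed)
    out = []
    for g in genes:
        internal = _internal_codons(g.orf)
        if len(internal) > 1:
            internal = [internal[i] for i in rng.permutation(len(internal))]
        orf = g.orf[:3] + "".join(internal) + g.orf[-3:]
        out.append(GeneRecord(g.gene_id, _permuted_utr(g.utr5, rng), orf, g.utr3))
    return GeneSet(out, min_utr_len=genes.min_utr_len, validate=False)


def empirical_position_flags(
    real_counts: pd.Series,
    null_counts: pd.DataFrame,
    level: float = 0.95,
) -> pd.Series:
    """Per-position depletion/enrichment flags against replicate null profiles.

    A position is DEPLETED iff at least ``ceil(level * n_replicates)`` null
    replicates have *more* ATGs than the real genome there, ENRICHED for the
    mirror rule, NS otherwise.  Ties count to neither side (conservative).

    ``null_counts``: rows = replicates, columns = positions matching
    ``real_counts.index``.
    """
    real = pd.Series(real_counts)
    nulls = pd.DataFrame(null_counts)
    if not real.index.equals(nulls.columns):
        raise ValueError("real and null profiles have mismatched position axes")
    n = len(nulls)
    need = math.ceil(level * n)
    greater = (nulls.gt(real, axis=1)).sum(axis=0)
    less = (nulls.lt(real, axis=1)).sum(axis=0)
    flags = pd.Series(Flag.NS.value, index=real.index, name="flag")
    flags[greater >= need] = Flag.DEPLETED.value
    flags[less >= need] = Flag.ENRICHED.value
    return flags
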