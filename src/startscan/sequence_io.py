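"""Gene models, coordinates, frames and ATG enumeration.

Coordinate convention used throughout the package: positions are 0-based and
signed on the transcript (5'UTR + ORF).  Position 0 is the 'A' of the main
START ATG, position -1 the last nucleotide of the 5'UTR.  With this choice
``frame = pos mod 3`` holds exactly: frame 0 is the reading frame of the ORF,
frames 1 and 2 are shifts of 1 and 2 nt.  ATGs overlapping the UTR/ORF
junction (which can only start at pos <= -3, since positions -1/-2 would have
to overlap the START's own nucleotides) are assigned to the region given by
the sign of their start position.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")
NUCLEOTIDES = "ACGT"

UTR5 = "UTR5"
ORF = "ORF"


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene's transcript regions as plain uppercase DNA strings."""

    gene_id: str
    utr5: str
    orf: str
    utr3: str = ""

    @property
    def transcript(self) -> str:
        return self.utr5 + self.orf

    def nt_at(self, pos: int) -> str | None:
        """Nucleotide at a signed transcript position, or None if outside."""
        idx = pos + len(self.utr5)
        if 0 <= idx < len(self.utr5) + len(self.orf):
            return self.transcript[idx]
        return None


@dataclass(frozen=True)
class AtgSite:
    """An ATG occurrence on a gene transcript.

    ``pos`` is the signed position of the 'A'; ``frame = pos mod 3``;
    ``region`` is UTR5 for negative positions, ORF otherwise.
    """

    gene_id: str
    pos: int
    frame: int
    region: str

    @classmethod
    def at(cls, gene_id: str, pos: int) -> "AtgSite":
        return cls(
            gene_id=gene_id,
            pos=pos,
            frame=pos % 3,
            region=UTR5 if pos < 0 else ORF,
        )


def validate_gene(gene: GeneRecord) -> str | None:
    """Return a rejection reason, or None if the record is a valid gene model."""
    for name, seq in (("utr5", gene.utr5), ("orf", gene.orf), ("utr3", gene.utr3)):
        if any(c not in NUCLEOTIDES for c in seq):
            return f"non_acgt_{name}"
    if len(gene.orf) < 6 or len(gene.orf) % 3 != 0:
        return "orf_length"
    if not gene.orf.startswith("ATG"):
        return "no_start_atg"
    if gene.orf[-3:] not in STOP_CODONS:
        return "no_stop"
    return None


class GeneSet:
    """An ordered collection of validated GeneRecords.

    Genes whose 5'UTR is shorter than ``min_utr_len`` are retained but flagged
    (``flagged_short_utr``): they take part in ORF-only analyses and are
    excluded from UTR/context analyses.  Records failing the gene-model
    invariants are dropped at construction with per-reason counts in
    ``exclusions``.
    """

    def __init__(
        self,
        genes: Iterable[GeneRecord],
        min_utr_len: int = 6,
        validate: bool = True,
    ):
        self.min_utr_len = min_utr_len
        self.exclusions: Counter[str] = Counter()
        self.flagged_short_utr: set[str] = set()
        self._genes: dict[str, GeneRecord] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise FormatError(f"duplicate gene_id: {g.gene_id}")
            if validate:
                reason = validate_gene(g)
                if reason is not None:
                    self.exclusions[reason] += 1
                    continue
            if len(g.utr5) < min_utr_len:
                self.flagged_short_utr.add(g.gene_id)
            self._genes[g.gene_id] = g
        if self.exclusions:
            logger.info("excluded records at load: %s", dict(self.exclusions))

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self._genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._genes[gene_id]

    def ids(self) -> list[str]:
        return list(self._genes)

    def with_utr(self) -> Iterator[GeneRecord]:
        """Genes whose 5'UTR passes the minimum-length filter."""
        for g in self:
            if g.gene_id not in self.flagged_short_utr:
                yield g


def _read_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in out:
                raise FormatError(f"duplicate gene_id: {rec.id}")
            out[rec.id] = str(rec.seq).upper()
    except ValueError as exc:  # biopython parse errors
        raise FormatError(f"malformed FASTA {path}: {exc}") from exc
    if not out:
        raise FormatError(f"no FASTA records in {path}")
    return out


def load_gene_set(
    utr5_source: str | Path,
    orf_source: str | Path,
    min_utr_len: int = 6,
    utr3_source: str | Path | None = None,
) -> GeneSet:
    """Load a gene set from a pair of FASTA files (one record per gene each).

    Gene ids must match across files; genes present only in one file are
    dropped with a logged count.
    """
    utrs = _read_fasta(utr5_source)
    orfs = _read_fasta(orf_source)
    utr3s = _read_fasta(utr3_source) if utr3_source else {}
    shared = [gid for gid in orfs if gid in utrs]
    n_unmatched = len(set(utrs) ^ set(orfs))
    if n_unmatched:
        logger.info("dropped %d records without a partner region", n_unmatched)
    genes = (
        GeneRecord(gid, utrs[gid], orfs[gid], utr3s.get(gid, "")) for gid in shared
    )
    return GeneSet(genes, min_utr_len=min_utr_len)


def load_gene_table(path: str | Path, min_utr_len: int = 6) -> GeneSet:
    """Load a gene set from a single annotation TSV (gene_id, utr5, orf[, utr3])."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"gene_id", "utr5", "orf"}
    if not required.issubset(df.columns):
        raise FormatError(f"annotation TSV must have columns {sorted(required)}")
    genes = (
        GeneRecord(
            r.gene_id,
            r.utr5.upper(),
            r.orf.upper(),
            getattr(r, "utr3", "").upper(),
        )
        for r in df.itertuples(index=False)
    )
    return GeneSet(genes, min_utr_len=min_utr_len)


def write_gene_set(genes: GeneSet, utr5_path: str | Path, orf_path: str | Path) -> None:
    """Write a gene set back to the FASTA pair dialect load_gene_set reads."""
    with open(utr5_path, "w") as fu, open(orf_path, "w") as fo:
        SeqIO.write(
            (SeqRecord(Seq(g.utr5), id=g.gene_id, description="") for g in genes),
            fu,
            "fasta",
        )
        SeqIO.write(
            (SeqRecord(Seq(g.orf), id=g.gene_id, description="") for g in genes),
            fo,
            "fasta",
        )


def enumerate_atgs(gene: GeneRecord, up_span: int, down_span: int) -> list[AtgSite]:
    """Every ATG start position in [-min(up_span,|utr5|), min(down_span,|orf|-3)].

    Includes position 0 (the main START).  Spans are in nucleotides.
    """
    if up_span < 0 or down_span < 0:
        raise ValueError("spans must be non-negative")
    transcript = gene.transcript
    off = len(gene.utr5)
    lo = -min(up_span, len(gene.utr5))
    hi = min(down_span, len(gene.orf) - 3)
    sites = []
    start = lo + off
    end = hi + off  # last allowed triplet start index
    i = transcript.find("ATG", start)
    while 0 <= i <= end:
        sites.append(AtgSite.at(gene.gene_id, i - off))
        i = transcript.find("ATG", i + 1)
    return sites


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

EXPRESSION_COLUMNS = ("mrna", "rd", "pa")


def combine_expression(tables: list[pd.Series]) -> pd.Series:
    """Combine replicate measurements of one quantity across datasets.

    Each table (a gene-indexed Series) is divided by its own mean over
    non-missing entries, then the per-gene arithmetic mean across tables is
    taken.  Genes present in any table appear in the output; missing values
    propagate as missing, never as zero.
    """
    if not tables:
        raise ValueError("need at least one expression table")
    normed = []
    for t in tables:
        t = pd.Series(t, dtype=float)
        m = t.mean(skipna=True)
        if pd.isna(m):
            raise ValueError("expression table with all-missing values")
        normed.append(t / m)
    return pd.concat(normed, axis=1).mean(axis=1, skipna=True)


def make_expression_table(
    mrna: pd.Series | None = None,
    rd: pd.Series | None = None,
    pa: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble an expression table; ribosomal_load = mrna * rd where both exist."""
    parts = {}
    for name, s in (("mrna", mrna), ("rd", rd), ("pa", pa)):
        if s is not None:
            parts[name] = pd.Series(s, dtype=float)
    if not parts:
        raise ValueError("no expression measurements given")
    df = pd.DataFrame(parts)
    for col in EXPRESSION_COLUMNS:
        if col not in df:
            df[col] = float("nan")
    df["ribosomal_load"] = df["mrna"] * df["rd"]
    df.index.name = "gene_id"
    return df[list(EXPRESSION_COLUMNS) + ["ribosomal_load"]]


def load_expression(path: str | Path) -> pd.DataFrame:
    """Read an expression TSV (gene_id, mrna, rd, pa) and derive ribosomal_load."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "gene_id" not in df.columns:
        raise FormatError("expression TSV must have a gene_id column")
    df = df.set_index("gene_id")
    return make_expression_table(
        mrna=df.get("mrna"), rd=df.get("rd"), pa=df.get("pa")
    )


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.loc[:, list(EXPRESSION_COLUMNS)].to_csv(path, sep="\t")
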