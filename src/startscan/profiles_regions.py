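"""Frame-resolved ATG/codon count profiles and region-of-selection estimators.

Two complementary estimators of the region with fewer ATGs than expected:

* ``detect_region_ks`` - sliding 11-codon windows against the remainder of a
  90-nt span (two-sample KS test, gated on the window mean being *below* the
  remainder), anchored at the boundary; region length =
  (window - 1) + number of consecutive significant windows, or 0 when the
  first window is not significant.
* ``detect_region_vs_null`` - the boundary-anchored run of positions flagged
  DEPLETED against replicate null genomes.

On genomes with partial depletion the two bracket the planted zone from below
and above respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .randomization import Flag
from .sequence_io import GeneRecord, GeneSet, UTR5, ORF

VALID_NT = set("ACGT")


@dataclass
class CountProfile:
    """Per-position codon occurrence counts for one frame.

    ``positions`` are the signed in-frame positions; ``counts[p]`` is the
    number of genes with the codon starting at p; ``denominators[p]`` the
    number of genes whose transcript covers the full triplet at p.
    """

    frame: int
    positions: np.ndarray
    counts: np.ndarray
    denominators: np.ndarray
    codon: str = "ATG"

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=pd.Index(self.positions, name="pos"))

    def scaled(self, normalize: bool = False) -> np.ndarray:
        """Counts as SD units from the segment mean, UTR and ORF separately.

        With ``normalize`` the counts are first divided by the per-position
        denominators (the maximal possible number of appearances), as used for
        non-ATG control codons.
        """
        x = self.counts.astype(float)
        if normalize:
            with np.errstate(invalid="ignore", divide="ignore"):
                x = np.where(self.denominators > 0, x / self.denominators, np.nan)
        out = np.full_like(x, np.nan, dtype=float)
        for mask in (self.positions < 0, self.positions >= 0):
            seg = x[mask]
            ok = ~np.isnan(seg)
            if ok.sum() < 2:
                continue
            mu, sd = seg[ok].mean(), seg[ok].std()
            out[mask] = (seg - mu) / sd if sd > 0 else 0.0
        return out


@dataclass
class RegionResult:
    frame: int
    region: str  # UTR5 | ORF
    length_codons: int
    window_pvalues: list[float] = field(default_factory=list)


def codon_count_profile(
    genes: GeneSet,
    codon: str,
    frame: int,
    up_span: int = 90,
    down_span: int = 90,
) -> CountProfile:
    """Per-position count of genes carrying ``codon`` at each in-frame position.

    Positions run over [-up_span, down_span); only positions congruent to
    ``frame`` mod 3 are reported.  Genes contribute only the positions their
    transcript covers (per-position denominators are tracked).  Position 0
    (the START) is included for frame 0 and stores the raw count.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    if len(codon) != 3 or not set(codon) <= VALID_NT:
        raise ValueError(f"invalid codon {codon!r}")
    positions = np.array(
        [p for p in range(-up_span, down_span) if p % 3 == frame]
    )
    pos_index = {int(p): i for i, p in enumerate(positions)}
    counts = np.zeros(len(positions), dtype=int)
    denom = np.zeros(len(positions), dtype=int)
    for gene in genes:
        ul, ol = len(gene.utr5), len(gene.orf)
        lo = max(-up_span, -ul)
        hi = min(down_span - 1, ol - 3)
        if hi < lo:
            continue
        denom += (positions >= lo) & (positions <= hi)
        transcript = gene.transcript
        i = transcript.find(codon, lo + ul)
        while 0 <= i <= hi + ul:
            p = i - ul
            if p % 3 == frame:
                counts[pos_index[p]] += 1
            i = transcript.find(codon, i + 1)
    return CountProfile(frame, positions, counts, denom, codon=codon)


def atg_count_profile(
    genes: GeneSet, frame: int, up_span: int = 90, down_span: int = 90
) -> CountProfile:
    """ATG occurrence profile for one frame (see codon_count_profile)."""
    return codon_count_profile(genes, "ATG", frame, up_span, down_span)


def _boundary_ordered_positions(
    profile: CountProfile, region: str, span: int
) -> np.ndarray:
    """In-frame positions of a region ordered outward from the START boundary.

    Positions whose triplet overlaps the START codon (-2 <= p <= 2) are not
    scanned: no alternative ATG can start there (p = 0 is the START itself;
    the others would have to overwrite its nucleotides), so they carry
    structural zeros that are not evidence of selection.  The ORF scan runs
    ascending from p = 3, the UTR scan descending from p = -3.
    """
    pos = profile.positions
    if region == ORF:
        sel = pos[(pos >= 3) & (pos < span)]
        return np.sort(sel)
    sel = pos[(pos <= -3) & (pos >= -span)]
    return np.sort(sel)[::-1]


def detect_region_ks(
    profile: CountProfile,
    window: int = 11,
    span: int = 90,
    alpha: float = 0.05,
    region: str = ORF,
) -> RegionResult:
    """Sliding-window KS estimate of the boundary-anchored depleted region.

    Windows of ``window`` in-frame positions (codons) slide one codon at a
    time from the boundary outward over the first ``span`` nt; each window's
    per-position counts are KS-tested against all remaining in-frame positions
    of the span.  A window extends the region only if significant *and* its
    mean is below the remainder's mean.
    """
    ordered = _boundary_ordered_positions(profile, region, span)
    pos_to_count = dict(zip(profile.positions.tolist(), profile.counts.tolist()))
    try:
        c = np.array([pos_to_count[int(p)] for p in ordered], dtype=float)
    except KeyError as exc:
        raise ValueError(f"profile does not cover the span: missing {exc}") from exc
    if window > len(c):
        raise ValueError(f"window ({window}) longer than span ({len(c)} codons)")
    pvalues: list[float] = []
    run = 0
    extending = True
    for k in range(len(c) - window + 1):
        x = c[k : k + window]
        y = np.concatenate([c[:k], c[k + window :]])
        # Asymptotic two-sided KS (the classical kstest2 default), slightly
        # conservative at these window sizes.
        p = float(stats.ks_2samp(x, y, method="asymp").pvalue)
        pvalues.append(p)
        if extending and p < alpha and x.mean() < y.mean():
            run += 1
        else:
            extending = False
    length = 0 if run == 0 else (window - 1) + run
    return RegionResult(profile.frame, region, length, pvalues)


def detect_region_vs_null(
    flags: pd.Series, frame: int, region: str = ORF, span: int = 90
) -> RegionResult:
    """Boundary-anchored run of consecutive in-frame DEPLETED positions, in codons.

    As in the KS estimator, positions overlapping the START triplet
    (-2 <= p <= 2) are skipped: they are structural zeros in both real and
    null genomes and always tie.
    """
    pos = np.array(sorted(int(p) for p in flags.index))
    if region == ORF:
        ordered = [p for p in pos if 3 <= p < span and p % 3 == frame]
    else:
        ordered = [p for p in sorted(pos, reverse=True) if -span <= p <= -3 and p % 3 == frame]
    run = 0
    for p in ordered:
        if flags[p] == Flag.DEPLETED.value:
            run += 1
        else:
            break
    return RegionResult(frame, region, run)


def mean_region(
    results: dict[str, dict[int, float]], frames: tuple[int, ...] = (0, 1, 2)
) -> float:
    """Two-stage mean: frames within organism, then across organisms."""
    if not results:
        raise ValueError("no organisms")
    per_org = []
    for org, by_frame in results.items():
        vals = [by_frame[f] for f in frames if f in by_frame]
        if not vals:
            raise ValueError(f"organism {org} has no values for frames {frames}")
        per_org.append(float(np.mean(vals)))
    return float(np.mean(per_org))


def _per_gene_window_counts(
    gene: GeneRecord, span_codons: int
) -> dict[tuple[str, int], int]:
    """ATG counts per (region, frame) in the span_codons windows flanking the START."""
    out = {(r, f): 0 for r in (UTR5, ORF) for f in (0, 1, 2)}
    transcript = gene.transcript
    ul = len(gene.utr5)
    lo = max(-3 * span_codons, -ul)
    hi = min(3 * span_codons, len(gene.orf) - 3)
    i = transcript.find("ATG", lo + ul)
    while 0 <= i <= hi + ul:
        p = i - ul
        if p != 0:
            out[(UTR5 if p < 0 else ORF, p % 3)] += 1
        i = transcript.find("ATG", i + 1)
    return out


def stratified_atg_comparison(
    genes: GeneSet,
    expr: pd.DataFrame,
    frac: float = 0.15,
    span_codons: int = 30,
) -> pd.DataFrame:
    """KS comparison of per-gene ATG counts between expression strata.

    Genes are ranked by ribosomal load; the top and bottom ``frac`` strata are
    compared on their per-gene number of ATGs in the first ``span_codons``
    codons upstream (5'UTR) and downstream (ORF, START excluded) of the main
    ATG, per frame and with all frames pooled - 8 KS tests in total.
    """
    rl = expr["ribosomal_load"].dropna()
    scored = [g for g in genes.with_utr() if g.gene_id in rl.index]
    if not scored:
        raise ValueError("no genes with both sequence and ribosomal load")
    order = rl.loc[[g.gene_id for g in scored]].sort_values(
        ascending=False, kind="stable"
    )
    k = int(round(frac * len(order)))
    if k < 2:
        raise ValueError("fewer than 2 genes per stratum")
    top_ids = set(order.index[:k])
    bottom_ids = set(order.index[-k:])

    counts = {g.gene_id: _per_gene_window_counts(g, span_codons) for g in scored}
    rows = []
    for region in (UTR5, ORF):
        for frame in (0, 1, 2, "all"):
            def total(gid: str) -> int:
                if frame == "all":
                    return sum(counts[gid][(region, f)] for f in (0, 1, 2))
                return counts[gid][(region, frame)]

            top = np.array([total(g) for g in top_ids])
            bottom = np.array([total(g) for g in bottom_ids])
            p = float(stats.ks_2samp(top, bottom).pvalue)
            rows.append(
                {
                    "region": region,
                    "frame": frame,
                    "p_value": p,
                    "mean_top": float(top.mean()),
                    "mean_bottom": float(bottom.mean()),
                }
            )
    return pd.DataFrame(rows)


def profile_matrix(
    profiles: dict[str, CountProfile], normalize: bool = False
) -> pd.DataFrame:
    """Heatmap-ready matrix (rows = labels, columns = positions, scaled counts)."""
    rows = {}
    for label, prof in profiles.items():
        rows[label] = pd.Series(prof.scaled(normalize=normalize), index=prof.positions)
    return pd.DataFrame(rows).T
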