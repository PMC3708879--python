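"""Distance-to-stop and metabolic-cost statistics for alternative ATGs.

An alternative initiation event translates a spurious peptide until the first
in-frame stop codon.  Its burden on the cell is quantified as the biosynthesis
cost of that peptide (sum of per-amino-acid ATP costs, respiratory values by
default) plus, optionally, the polymerization cost of ~7 ATP per incorporated
amino acid.  Scanning continues from 5'UTR sites into the ORF: a uORF may
terminate downstream of the main START.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .sequence_io import GeneRecord, GeneSet, AtgSite, enumerate_atgs, UTR5, ORF
from .synthetic_data import CODON_TO_AA, STOPS
from .randomization import NullScheme

logger = logging.getLogger(__name__)

#: Biosynthesis cost in ATP equivalents per amino acid under respiratory
#: conditions (Wagner 2005), the default table for yeast-like analyses.
RESPIRATORY_AA_COST: dict[str, float] = {
    "A": 14.5, "R": 20.5, "N": 18.5, "D": 15.5, "C": 26.5,
    "E": 9.5, "Q": 10.5, "G": 14.5, "H": 29.0, "I": 38.0,
    "L": 37.0, "K": 36.0, "M": 36.5, "F": 61.0, "P": 14.5,
    "S": 14.5, "T": 21.5, "W": 75.5, "Y": 59.0, "V": 29.0,
}

TRANSLATION_COST_PER_AA = 7.0  # ATP per incorporated amino acid in vivo


@dataclass(frozen=True)
class CostTable:
    aa_cost: dict[str, float]
    translation_cost_per_aa: float = TRANSLATION_COST_PER_AA

    def __post_init__(self):
        missing = set(RESPIRATORY_AA_COST) - set(self.aa_cost)
        if missing:
            raise ValueError(f"cost table missing amino acid(s): {sorted(missing)}")
        if any(v < 0 for v in self.aa_cost.values()) or self.translation_cost_per_aa < 0:
            raise ValueError("costs must be non-negative")

    @classmethod
    def default(cls) -> "CostTable":
        return cls(dict(RESPIRATORY_AA_COST))

    @classmethod
    def from_tsv(cls, path: str | Path, **kw) -> "CostTable":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["aa"], df["atp"].astype(float))), **kw)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"aa": list(self.aa_cost), "atp": list(self.aa_cost.values())}
        ).to_csv(path, sep="\t", index=False)

    def peptide_cost(self, peptide: str, include_translation: bool = False) -> float:
        c = sum(self.aa_cost[aa] for aa in peptide)
        if include_translation:
            c += self.translation_cost_per_aa * len(peptide)
        return c


@dataclass(frozen=True)
class AltOrfStats:
    site: AtgSite
    stop_distance_nt: int | None  # None when open-ended
    peptide_len_aa: int
    synthesis_cost: float | None
    total_cost: float | None  # synthesis + 7 ATP x length

    @property
    def open_ended(self) -> bool:
        return self.stop_distance_nt is None


def distance_to_stop(
    transcript: str,
    site: AtgSite | int,
    utr5_len: int = 0,
    cost: CostTable | None = None,
    include_met: bool = True,
) -> AltOrfStats:
    """Scan in-frame triplets from an ATG to the first stop codon.

    ``stop_distance_nt`` is the offset from the ATG's first nt to the stop's
    first nt; the peptide runs from the ATG's Met (included by default) up to,
    excluding, the stop.  A site with no stop before the transcript end is
    flagged open-ended (distance None) and should be excluded from means.
    """
    if isinstance(site, AtgSite):
        pos = site.pos
    else:
        pos = int(site)
        site = AtgSite.at("", pos)
    idx = pos + utr5_len
    if transcript[idx : idx + 3] != "ATG":
        raise ValueError(f"no ATG at position {pos}")
    codons = []
    stop_at = None
    for j in range(idx, len(transcript) - 2, 3):
        codon = transcript[j : j + 3]
        if codon in STOPS:
            stop_at = j
            break
        codons.append(codon)
    if stop_at is None:
        return AltOrfStats(site, None, len(codons), None, None)
    peptide = "".join(CODON_TO_AA[c] for c in codons)
    if not include_met:
        peptide = peptide[1:]
    dist = stop_at - idx
    synth = total = None
    if cost is not None:
        synth = cost.peptide_cost(peptide)
        total = synth + cost.translation_cost_per_aa * len(peptide)
    return AltOrfStats(site, dist, len(peptide), synth, total)


def alt_site_stats(
    genes: GeneSet,
    span: int = 300,
    frames: tuple[int, ...] = (1, 2),
    cost: CostTable | None = None,
    include_met: bool = True,
) -> pd.DataFrame:
    """AltOrfStats for every alternative ATG within ``span`` nt of the START.

    One row per site: gene_id, pos, frame, region, stop_distance_nt (NaN when
    open-ended), peptide_len_aa, synthesis_cost, total_cost.
    """
    cost = cost or CostTable.default()
    rows = []
    for gene in genes.with_utr():
        for site in enumerate_atgs(gene, span, span):
            if site.pos == 0 or site.frame not in frames:
                continue
            st = distance_to_stop(
                gene.transcript, site, len(gene.utr5), cost, include_met
            )
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "pos": site.pos,
                    "frame": site.frame,
                    "region": site.region,
                    "stop_distance_nt": np.nan if st.open_ended else st.stop_distance_nt,
                    "peptide_len_aa": st.peptide_len_aa,
                    "synthesis_cost": np.nan if st.open_ended else st.synthesis_cost,
                    "total_cost": np.nan if st.open_ended else st.total_cost,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "pos", "frame", "region", "stop_distance_nt",
            "peptide_len_aa", "synthesis_cost", "total_cost",
        ],
    )


def near_far_comparison(
    genes: GeneSet,
    near_cutoff: int = 6,
    span: int = 300,
    cost: CostTable | None = None,
    include_translation: bool = False,
) -> dict[str, dict]:
    """Near-START vs far out-of-frame ATGs: stop distances and peptide costs.

    Sites within ``near_cutoff`` codons (< 3*near_cutoff nt) of the START form
    the near group, the rest of the ``span``-nt region the far group, per
    region (5'UTR / ORF).  Open-ended sites are excluded.  Returns per-region
    group means and two-sample KS p-values; an empty group leaves that
    comparison missing (logged).
    """
    stats_df = alt_site_stats(genes, span=span, cost=cost)
    stats_df = stats_df.dropna(subset=["stop_distance_nt"])
    cost_col = "total_cost" if include_translation else "synthesis_cost"
    cut = 3 * near_cutoff
    out: dict[str, dict] = {}
    for region in (UTR5, ORF):
        sub = stats_df[stats_df["region"] == region]
        near = sub[sub["pos"].abs() < cut]
        far = sub[sub["pos"].abs() >= cut]
        if near.empty or far.empty:
            logger.info("near/far comparison in %s missing a group", region)
            out[region] = {"missing": True}
            continue
        res = {
            "missing": False,
            "n_near": len(near),
            "n_far": len(far),
            "mean_stop_distance_near": float(near["stop_distance_nt"].mean()),
            "mean_stop_distance_far": float(far["stop_distance_nt"].mean()),
            "p_stop_distance": float(
                stats.ks_2samp(near["stop_distance_nt"], far["stop_distance_nt"]).pvalue
            ),
            "mean_cost_near": float(near[cost_col].mean()),
            "mean_cost_far": float(far[cost_col].mean()),
            "p_cost": float(stats.ks_2samp(near[cost_col], far[cost_col]).pvalue),
        }
        out[region] = res
    return out


def _plant_atg(gene: GeneRecord, pos: int) -> GeneRecord | None:
    """Overwrite the triplet at ``pos`` with ATG; None if it collides with the
    START codon or the terminal stop."""
    ul, ol = len(gene.utr5), len(gene.orf)
    idx = pos + ul
    if idx < 0 or idx + 3 > ul + ol:
        return None
    if -2 <= pos <= 2 and pos != 0:  # overlaps the START codon
        return None
    if pos > 0 and pos + 3 > ol - 3:  # overlaps the terminal stop
        return None
    t = gene.transcript
    new = t[:idx] + "ATG" + t[idx + 3 :]
    return GeneRecord(gene.gene_id, new[:ul], new[ul:], gene.utr3)


def cost_vs_null(
    genes: GeneSet,
    scheme: NullScheme,
    cost: CostTable | None = None,
    span: int = 300,
    frames: tuple[int, ...] = (1, 2),
) -> dict:
    """Cost of alternative initiation in the real genome vs ATG-planted nulls.

    Null genomes are drawn with the scheme (codon-resampling based); in each
    null gene the real genome's alternative ATGs are planted at their original
    positions, and the cost of the peptide up to the closest stop is measured
    on the null sequence.  Returns per-region real/null mean costs and a
    one-sided KS p-value for real costs being lower.
    """
    if scheme.kind == "CODON_PERMUTE":
        raise ValueError("cost_vs_null requires a codon-resampling scheme")
    cost = cost or CostTable.default()
    real = alt_site_stats(genes, span=span, frames=frames, cost=cost)
    real = real.dropna(subset=["synthesis_cost"])
    sites_by_gene: dict[str, list[int]] = {}
    for row in real.itertuples(index=False):
        sites_by_gene.setdefault(row.gene_id, []).append(int(row.pos))

    null_costs: dict[str, list[float]] = {UTR5: [], ORF: []}
    null_dists: dict[str, list[float]] = {UTR5: [], ORF: []}
    n_skipped = 0
    for r in range(scheme.n_replicates):
        null_genes = scheme.randomize(genes, replicate=r)
        for gid, positions in sites_by_gene.items():
            g = null_genes[gid]
            for pos in positions:
                planted = _plant_atg(g, pos)
                if planted is None:
                    n_skipped += 1
                    continue
                st = distance_to_stop(planted.transcript, pos, len(planted.utr5), cost)
                if st.open_ended:
                    continue
                region = UTR5 if pos < 0 else ORF
                null_costs[region].append(st.synthesis_cost)
                null_dists[region].append(st.stop_distance_nt)
    if n_skipped:
        logger.info("planting skipped %d colliding sites", n_skipped)

    out: dict = {"n_replicates": scheme.n_replicates, "regions": {}}
    for region in (UTR5, ORF):
        real_c = real.loc[real["region"] == region, "synthesis_cost"].to_numpy()
        null_c = np.asarray(null_costs[region])
        entry: dict = {"n_real": int(real_c.size), "n_null": int(null_c.size)}
        if real_c.size and null_c.size:
            entry.update(
                real_mean_cost=float(real_c.mean()),
                null_mean_cost=float(null_c.mean()),
                real_mean_stop_distance=float(
                    real.loc[real["region"] == region, "stop_distance_nt"].mean()
                ),
                null_mean_stop_distance=float(np.mean(null_dists[region])),
                p_real_lower=float(
                    stats.ks_2samp(real_c, null_c, alternative="greater").pvalue
                ),
            )
        out["regions"][region] = entry
    return out
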