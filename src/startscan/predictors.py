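"""The A-D predictor ladder: initiation features, binning, cross-validated correlation.

Per-gene features:

1. ``kozak_dist`` - hamming distance of the START context from Kozak's
   ACC|ATG|G optimum (enters predictors negated, so larger = better context);
2. ``start_context`` - raw PSSM context score of the START;
3. ``alt_atg_count_30`` - number of alternative ATGs (any frame) starting less
   than 30 codons downstream of the START;
4. ``alt_context_mean_30`` - mean relative context score of those sites
   (missing when there are none).

Predictor A uses feature 1; B feature 2; C features 2-3; D features 2-4.
Expression targets are noise-filtered by binning genes in descending target
order (15 per bin); a linear combination of the binned features is fit on a
train half and scored by Pearson correlation on the test half, repeated over
100 random 2-fold splits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sequence_io import GeneSet, enumerate_atgs
from .pssm_context import Pssm, context_score, kozak_hamming, context_nucleotides, _raw_score
from .sequence_io import AtgSite

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("kozak_dist", "start_context", "alt_atg_count_30", "alt_context_mean_30")

#: Features whose larger values predict *lower* expression; negated on entry.
NEGATED_FEATURES = ("kozak_dist", "alt_atg_count_30", "alt_context_mean_30")

LADDER: dict[str, tuple[str, ...]] = {
    "A": ("kozak_dist",),
    "B": ("start_context",),
    "C": ("start_context", "alt_atg_count_30"),
    "D": ("start_context", "alt_atg_count_30", "alt_context_mean_30"),
}


@dataclass(frozen=True)
class PredictorSpec:
    id: str
    features: tuple[str, ...]

    def __post_init__(self):
        if self.id in LADDER and tuple(self.features) != LADDER[self.id]:
            raise ValueError(f"predictor {self.id} must use features {LADDER[self.id]}")

    @classmethod
    def ladder(cls) -> list["PredictorSpec"]:
        return [cls(pid, feats) for pid, feats in LADDER.items()]


def compute_features(
    genes: GeneSet,
    pssm: Pssm,
    window_codons: int = 30,
    exclude: set[str] | frozenset[str] = frozenset(),
) -> pd.DataFrame:
    """Per-gene initiation-rule features under a trained PSSM.

    ``exclude`` should hold the PSSM training set (dropped to avoid scoring
    genes the PSSM was fit on).  Genes without a scoreable START context get
    missing context features, never zeros.
    """
    rows = {}
    for gene in genes.with_utr():
        if gene.gene_id in exclude:
            continue
        start = AtgSite.at(gene.gene_id, 0)
        kd = kozak_hamming(start, gene)
        ctx = context_nucleotides(gene, 0, pssm.offsets)
        start_raw = _raw_score(pssm, ctx) if len(ctx) == len(pssm.offsets) else None
        alt_scores = []
        count = 0
        for site in enumerate_atgs(gene, 0, 3 * window_codons - 1):
            if site.pos == 0:
                continue
            count += 1
            sc = context_score(pssm, site, gene)
            if sc is not None:
                alt_scores.append(sc.relative)
        rows[gene.gene_id] = {
            "kozak_dist": np.nan if kd is None else float(kd),
            "start_context": np.nan if start_raw is None else start_raw,
            "alt_atg_count_30": float(count),
            "alt_context_mean_30": float(np.mean(alt_scores)) if alt_scores else np.nan,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene_id"
    return df[list(FEATURE_NAMES)]


def bin_by_target(
    values: pd.DataFrame | pd.Series,
    target: pd.Series,
    bin_size: int = 15,
) -> tuple[pd.DataFrame, pd.Series]:
    """Noise-filtering bins: genes sorted by descending target, bins of bin_size.

    The last partial bin is kept.  Returns per-bin means of the features and
    of the target.  With bin_size 1 this is the identity up to ordering.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    values = pd.DataFrame(values)
    shared = values.dropna().index.intersection(target.dropna().index)
    if len(shared) < bin_size:
        raise ValueError(f"fewer genes ({len(shared)}) than one bin ({bin_size})")
    t = target.loc[shared].sort_values(ascending=False, kind="stable")
    v = values.loc[t.index]
    bins = np.arange(len(t)) // bin_size
    return v.groupby(bins).mean(), t.groupby(bins).mean()


def _prepare_features(features: pd.DataFrame, names: tuple[str, ...]) -> pd.DataFrame:
    """Select, direction-align and mean-impute the predictor's feature columns."""
    x = features[list(names)].copy()
    for name in names:
        if name in NEGATED_FEATURES:
            x[name] = -x[name]
        x[name] = x[name].fillna(x[name].mean())
    return x


def _ols_predict(
    x_train: np.ndarray, y_train: np.ndarray, x_test: np.ndarray
) -> np.ndarray:
    xt = np.column_stack([np.ones(len(x_train)), x_train])
    beta, *_ = np.linalg.lstsq(xt, y_train, rcond=None)
    return np.column_stack([np.ones(len(x_test)), x_test]) @ beta


def adjusted_correlation(r: float, n_bins: int, k: int) -> float:
    """Shrink a correlation for the number of features (adjusted-R^2 form).

    sqrt(max(0, 1 - (1 - r^2)(n-1)/(n-k-1))); 0 when n <= k + 1.
    """
    if n_bins - k - 1 <= 0:
        return 0.0
    r2_adj = 1.0 - (1.0 - r * r) * (n_bins - 1) / (n_bins - k - 1)
    return math.sqrt(max(0.0, r2_adj))


def evaluate_predictor(
    spec: PredictorSpec,
    features: pd.DataFrame,
    target: pd.Series,
    bin_size: int = 15,
    folds: int = 2,
    reps: int = 100,
    seed: int = 0,
) -> dict:
    """Repeated k-fold cross-validated correlation of one predictor.

    Per repetition genes are randomly split into ``folds`` groups; on each
    train portion the binned features are combined by OLS against the binned
    target, and the fit is scored by Pearson correlation between prediction
    and binned target on the held-out portion.  Returns the mean correlation,
    its feature-count-adjusted version, and a Spearman companion.
    """
    x = _prepare_features(features, spec.features)
    shared = x.index.intersection(target.dropna().index)
    x = x.loc[shared]
    t = target.loc[shared]
    if len(shared) < folds * bin_size:
        raise ValueError(
            f"need at least {folds * bin_size} usable genes, have {len(shared)}"
        )
    rng = np.random.default_rng(seed)
    rs: list[float] = []
    rhos: list[float] = []
    test_bins: list[int] = []
    skipped = 0
    for _ in range(reps):
        perm = rng.permutation(len(shared))
        for f in range(folds):
            test_idx = shared[perm[f::folds]]
            train_idx = shared.difference(test_idx)
            bx_tr, bt_tr = bin_by_target(x.loc[train_idx], t.loc[train_idx], bin_size)
            bx_te, bt_te = bin_by_target(x.loc[test_idx], t.loc[test_idx], bin_size)
            pred = _ols_predict(
                bx_tr.to_numpy(), bt_tr.to_numpy(), bx_te.to_numpy()
            )
            if np.std(pred) == 0 or np.std(bt_te) == 0:
                skipped += 1
                continue
            rs.append(float(stats.pearsonr(pred, bt_te).statistic))
            rhos.append(float(stats.spearmanr(pred, bt_te).statistic))
            test_bins.append(len(bt_te))
    if not rs:
        raise ValueError("all repetitions degenerate (zero-variance bins)")
    if skipped:
        logger.info("predictor %s: skipped %d degenerate folds", spec.id, skipped)
    r = float(np.mean(rs))
    n_bins = int(np.mean(test_bins))
    return {
        "predictor": spec.id,
        "r": r,
        "r_adjusted": adjusted_correlation(r, n_bins, len(spec.features)),
        "spearman": float(np.mean(rhos)),
        "n_bins": n_bins,
        "n_genes": int(len(shared)),
        "reps": reps,
        "folds": folds,
        "skipped": skipped,
    }


def ladder_report(
    features: pd.DataFrame,
    target: pd.Series,
    seed: int = 0,
    bin_size: int = 15,
    folds: int = 2,
    reps: int = 100,
) -> dict:
    """Cross-validated correlations for predictors A-D plus a monotonicity check."""
    results = {}
    for spec in PredictorSpec.ladder():
        results[spec.id] = evaluate_predictor(
            spec, features, target, bin_size=bin_size, folds=folds, reps=reps, seed=seed
        )
    order = [results[p]["r"] for p in "ABCD"]
    return {
        "predictors": results,
        "monotone_increasing": bool(np.all(np.diff(order) > 0)),
        "seed": seed,
    }
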