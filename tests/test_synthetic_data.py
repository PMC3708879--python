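import numpy as np
import pytest
from scipy import stats

from startscan.sequence_io import enumerate_atgs
from startscan.synthetic_data import (
    DEFAULT_PLANT_EFFECTS,
    DepletionZone,
    SENSE_CODONS,
    SimParams,
    default_codon_usage,
    plant_feature_expression,
    simulate_genome,
)


def small_params(**kw) -> SimParams:
    base = dict(n_genes=100, utr_len_mean=40.0, orf_len_codons_mean=120.0,
                min_orf_codons=60, seed=7)
    base.update(kw)
    return SimParams(**base)


class TestSimulateGenome:
    def test_deterministic_given_seed(self):
        g1, e1 = simulate_genome(small_params())
        g2, e2 = simulate_genome(small_params())
        assert [(g.utr5, g.orf) for g in g1] == [(g.utr5, g.orf) for g in g2]
        assert e1.equals(e2)

    def test_gene_models_valid(self):
        gs, _ = simulate_genome(small_params())
        for g in gs:
            assert g.orf.startswith("ATG")
            assert g.orf[-3:] in ("TAA", "TAG", "TGA")
            assert len(g.orf) % 3 == 0
            # stop-free internally in frame 0
            internal = [g.orf[i:i + 3] for i in range(3, len(g.orf) - 3, 3)]
            assert not any(c in ("TAA", "TAG", "TGA") for c in internal)

    def test_full_strength_zone_has_no_alternative_atgs(self):
        params = small_params(
            n_genes=200,
            depletion=DepletionZone(utr_len_codons=0, orf_len_codons=5, strength=1.0),
        )
        gs, _ = simulate_genome(params)
        for g in gs:
            # no ATG triplet anywhere in ORF nt 3..17 (starts 3..15), any frame
            for p in range(3, 16):
                assert g.orf[p:p + 3] != "ATG"

    def test_full_strength_utr_zone(self):
        params = small_params(
            n_genes=200,
            depletion=DepletionZone(utr_len_codons=4, orf_len_codons=0, strength=1.0),
        )
        gs, _ = simulate_genome(params)
        for g in gs:
            t = g.transcript
            for p in range(-12, 0):
                idx = p + len(g.utr5)
                if idx >= 0:
                    assert t[idx:idx + 3] != "ATG"

    def test_zero_strength_zone_matches_background_rate(self):
        # per-position ATG frequency inside the nominal zone within 3 binomial
        # SDs of the outside-zone frequency
        params = SimParams(
            n_genes=10_000, utr_len_mean=40.0, orf_len_codons_mean=80.0,
            min_orf_codons=60, seed=11,
            depletion=DepletionZone(utr_len_codons=0, orf_len_codons=8, strength=0.0),
        )
        gs, _ = simulate_genome(params)
        in_zone = np.zeros(22)  # starts 3..24
        out_zone = []
        for g in gs:
            for s in enumerate_atgs(g, 0, 90):
                if 3 <= s.pos <= 24:
                    in_zone[s.pos - 3] += 1
                elif s.pos > 24:
                    out_zone.append(s.pos)
        n = len(gs)
        p_out = len(out_zone) / (n * (90 - 24))
        sd = np.sqrt(p_out * (1 - p_out) / n)
        assert abs(in_zone.mean() / n - p_out) < 3 * sd

    def test_infeasible_full_strength_with_forced_atg_raises(self):
        eps = 1e-12
        usage = {c: eps / 60 for c in SENSE_CODONS}
        usage["ATG"] = 1.0 - eps  # essentially every codon is Met
        params = small_params(
            n_genes=2, codon_usage=usage,
            depletion=DepletionZone(utr_len_codons=0, orf_len_codons=5, strength=1.0),
        )
        with pytest.raises(Exception, match="clear depletion zone"):
            simulate_genome(params)

    def test_codon_usage_recovered(self):
        usage = default_codon_usage()
        params = SimParams(n_genes=1000, utr_len_mean=20.0,
                           orf_len_codons_mean=80.0, min_orf_codons=60, seed=5,
                           depletion=DepletionZone(0, 0, 0.0))
        gs, _ = simulate_genome(params)
        counts = {c: 0 for c in SENSE_CODONS}
        for g in gs:
            # codon 1 carries the planted START context, not the background
            # usage, so the GOF test starts at codon 2
            for i in range(6, len(g.orf) - 3, 3):
                counts[g.orf[i:i + 3]] += 1
        total = sum(counts.values())
        observed = np.array([counts[c] for c in SENSE_CODONS])
        expected = np.array([usage[c] for c in SENSE_CODONS]) * total
        res = stats.chisquare(observed, expected * observed.sum() / expected.sum())
        assert res.pvalue > 0.001

    def test_utr_gc_content(self):
        params = SimParams(n_genes=500, utr_len_mean=60.0, gc_utr=0.36,
                           orf_len_codons_mean=70.0, min_orf_codons=60, seed=9,
                           depletion=DepletionZone(0, 0, 0.0))
        gs, _ = simulate_genome(params)
        gc = total = 0
        for g in gs:
            gc += sum(g.utr5.count(c) for c in "GC")
            total += len(g.utr5)
        sd = np.sqrt(0.36 * 0.64 / total)
        assert abs(gc / total - 0.36) < 3 * sd

    def test_context_expression_coupling_recoverable(self):
        # genes in the top expression decile carry stronger START contexts
        from startscan.pssm_context import build_pssm, context_score, select_training_set
        from startscan.sequence_io import AtgSite

        gs, expr = simulate_genome(SimParams(n_genes=1000, seed=13))
        training = select_training_set(expr, seed=1)
        pssm = build_pssm(gs, training)
        rl = expr["ribosomal_load"].sort_values(ascending=False)
        deciles = {}
        for label, ids in (("top", rl.index[:100]), ("bottom", rl.index[-100:])):
            raws = [
                context_score(pssm, AtgSite.at(g, 0), gs[g]).raw
                for g in ids if g not in training
            ]
            deciles[label] = np.mean(raws)
        assert deciles["top"] > deciles["bottom"]


class TestPlantFeatureExpression:
    def test_single_feature_zero_noise_is_rank_perfect(self):
        gs, _ = simulate_genome(small_params(n_genes=200))
        expr = plant_feature_expression(gs, {"alt_atg_count_30": 1.0}, 0.0, seed=3)
        from startscan.synthetic_data import strong_context_pssm
        from startscan import predictors

        feats = predictors.compute_features(gs, strong_context_pssm())
        rho = stats.spearmanr(feats["alt_atg_count_30"], expr["pa"]).statistic
        assert np.isclose(abs(rho), 1.0)

    def test_zero_effects_give_independent_expression(self):
        gs, _ = simulate_genome(SimParams(n_genes=2000, utr_len_mean=40.0,
                                          orf_len_codons_mean=120.0,
                                          min_orf_codons=60, seed=21))
        expr = plant_feature_expression(
            gs, {k: 0.0 for k in DEFAULT_PLANT_EFFECTS}, 1.0, seed=4
        )
        from startscan.synthetic_data import strong_context_pssm
        from startscan import predictors

        feats = predictors.compute_features(gs, strong_context_pssm())
        y = np.log(expr["pa"])
        for col in feats:
            r = feats[col].corr(y)
            assert abs(r) < 0.1

    def test_opposite_sign_effects_recovered_by_regression(self):
        gs, _ = simulate_genome(small_params(n_genes=1000, orf_len_codons_mean=120.0))
        expr = plant_feature_expression(
            gs, {"alt_atg_count_30": -0.8, "start_context": 0.8}, 0.3, seed=5
        )
        from startscan.synthetic_data import strong_context_pssm
        from startscan import predictors

        feats = predictors.compute_features(gs, strong_context_pssm())
        y = np.log(expr["pa"])
        x = feats[["alt_atg_count_30", "start_context"]].dropna()
        x = (x - x.mean()) / x.std()
        beta, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(len(x)), x.to_numpy()]),
            y.loc[x.index].to_numpy(), rcond=None,
        )
        assert beta[1] < 0 < beta[2]

    def test_unknown_feature_name_rejected(self):
        gs, _ = simulate_genome(small_params())
        with pytest.raises(ValueError, match="unknown feature"):
            plant_feature_expression(gs, {"codon_adaptation": 1.0}, 0.1, seed=0)

    def test_deterministic(self):
        gs, _ = simulate_genome(small_params())
        e1 = plant_feature_expression(gs, DEFAULT_PLANT_EFFECTS, 0.5, seed=8)
        e2 = plant_feature_expression(gs, DEFAULT_PLANT_EFFECTS, 0.5, seed=8)
        assert e1.equals(e2)
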