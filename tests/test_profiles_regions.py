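import numpy as np
import pandas as pd
import pytest

from startscan.profiles_regions import (
    CountProfile,
    atg_count_profile,
    codon_count_profile,
    detect_region_ks,
    detect_region_vs_null,
    mean_region,
    profile_matrix,
    stratified_atg_comparison,
)
from startscan.randomization import Flag
from startscan.sequence_io import make_expression_table
from startscan.synthetic_data import DepletionZone, SimParams, simulate_genome
from conftest import gene, geneset


class TestCountProfiles:
    def test_three_copies_of_known_gene(self):
        gs = geneset(*[
            gene(f"g{i}", "ATGCAT", "ATGATGTAA") for i in range(3)
        ])
        prof0 = atg_count_profile(gs, 0, 6, 9)
        s = prof0.as_series()
        assert s[-6] == 3 and s[0] == 3 and s[3] == 3
        assert s.drop([-6, 0, 3]).eq(0).all()
        for f in (1, 2):
            assert atg_count_profile(gs, f, 6, 9).counts.sum() == 0

    def test_empty_gene_set_zero_profile(self):
        gs = geneset()
        prof = atg_count_profile(gs, 1, 30, 30)
        assert prof.counts.sum() == 0 and prof.denominators.sum() == 0

    def test_denominators_decrease_with_utr_distance(self):
        gs = geneset(
            gene("g1", "C" * 10, "ATG" + "AAA" * 10 + "TAA"),
            gene("g2", "C" * 30, "ATG" + "AAA" * 10 + "TAA"),
        )
        prof = atg_count_profile(gs, 0, 30, 30)
        d = pd.Series(prof.denominators, index=prof.positions)
        assert d[-9] == 2 and d[-12] == 1  # only the long UTR reaches -12

    def test_atg_codon_profile_consistency(self, toy_genes):
        a = atg_count_profile(toy_genes, 0, 30, 30)
        c = codon_count_profile(toy_genes, "ATG", 0, 30, 30)
        assert np.array_equal(a.counts, c.counts)

    def test_stop_codon_absent_from_frame0_interior(self):
        gs, _ = simulate_genome(
            SimParams(n_genes=100, utr_len_mean=30.0, orf_len_codons_mean=80.0,
                      min_orf_codons=60, seed=3)
        )
        prof = codon_count_profile(gs, "TAA", 0, 30, 90)
        s = prof.as_series()
        assert s[(s.index >= 0) & (s.index < 90)].sum() == 0

    def test_invalid_codon_rejected(self, toy_genes):
        with pytest.raises(ValueError, match="invalid codon"):
            codon_count_profile(toy_genes, "AUGG", 0, 30, 30)

    def test_scaled_zero_mean_per_segment(self):
        gs, _ = simulate_genome(
            SimParams(n_genes=200, utr_len_mean=40.0, orf_len_codons_mean=80.0,
                      min_orf_codons=60, seed=5)
        )
        prof = atg_count_profile(gs, 1, 90, 90)
        z = prof.scaled()
        for mask in (prof.positions < 0, prof.positions >= 0):
            assert abs(np.nanmean(z[mask])) < 1e-9

    def test_profile_matrix_shape(self, toy_genes):
        m = profile_matrix({"a": atg_count_profile(toy_genes, 0, 30, 30)})
        assert m.shape[0] == 1


def _flat_profile(frame: int, rng: np.random.Generator) -> CountProfile:
    positions = np.array([p for p in range(-90, 90) if p % 3 == frame])
    counts = rng.poisson(30, len(positions))
    return CountProfile(frame, positions, counts, np.full(len(positions), 1000))


class TestDetectRegionKs:
    def test_flat_profile_detects_nothing(self):
        rng = np.random.default_rng(0)
        for frame in (0, 1, 2):
            res = detect_region_ks(_flat_profile(frame, rng))
            assert res.length_codons == 0

    def test_window_longer_than_span_raises(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError, match="window"):
            detect_region_ks(_flat_profile(0, rng), window=40, span=90)

    def test_clean_zone_recovery_within_band(self):
        # planted zone of L codons recovered within [L-1, L+window-1]
        L, window = 12, 11
        hits = 0
        n_seeds = 8
        for seed in range(n_seeds):
            gs, _ = simulate_genome(SimParams(
                n_genes=1000, utr_len_mean=40.0, orf_len_codons_mean=80.0,
                min_orf_codons=60, seed=40 + seed,
                depletion=DepletionZone(utr_len_codons=0, orf_len_codons=L,
                                        strength=1.0),
            ))
            ok = True
            for f in (1, 2):
                res = detect_region_ks(atg_count_profile(gs, f, 90, 90))
                ok &= (L - 1) <= res.length_codons <= (L + window - 1)
            hits += ok
        assert hits >= 0.9 * n_seeds

    def test_utr_zone_detected_on_utr_side_only(self):
        gs, _ = simulate_genome(SimParams(
            n_genes=1000, utr_len_mean=60.0, orf_len_codons_mean=80.0,
            min_orf_codons=60, seed=50,
            depletion=DepletionZone(utr_len_codons=10, orf_len_codons=0,
                                    strength=1.0),
        ))
        prof = atg_count_profile(gs, 1, 90, 90)
        utr = detect_region_ks(prof, region="UTR5")
        orf = detect_region_ks(prof, region="ORF")
        assert utr.length_codons >= 9
        assert orf.length_codons == 0

    def test_directional_gate_blocks_enriched_first_window(self):
        # an *excess* of ATGs at the boundary must not register as depletion
        positions = np.array([p for p in range(-90, 90) if p % 3 == 1])
        counts = np.full(len(positions), 30)
        counts[(positions >= 3) & (positions < 36)] = 300
        prof = CountProfile(1, positions, counts, np.full(len(positions), 1000))
        assert detect_region_ks(prof, region="ORF").length_codons == 0


class TestDetectRegionVsNull:
    def _flags(self, depleted_positions, frame):
        idx = list(range(-90, 90))
        flags = pd.Series(Flag.NS.value, index=idx)
        flags[depleted_positions] = Flag.DEPLETED.value
        return flags

    def test_all_ns_gives_zero(self):
        assert detect_region_vs_null(self._flags([], 1), 1).length_codons == 0

    def test_boundary_anchored_run_counted_in_codons(self):
        # frame-1 ORF positions from the boundary: 4, 7, 10, 13, 16
        flags = self._flags([4, 7, 10, 13, 16], 1)
        assert detect_region_vs_null(flags, 1).length_codons == 5

    def test_detached_run_does_not_count(self):
        flags = self._flags([13, 16, 19], 1)  # run not touching the boundary
        assert detect_region_vs_null(flags, 1).length_codons == 0

    def test_utr_run_counts_outward(self):
        flags = self._flags([-5, -8, -11], 1)  # frame-1 UTR positions
        assert detect_region_vs_null(flags, 1, region="UTR5").length_codons == 3


class TestMeanRegion:
    def test_frames_then_organisms(self):
        res = {"org1": {0: 12.0, 1: 6.0, 2: 0.0}}
        assert mean_region(res) == 6.0

    def test_across_organisms(self):
        res = {"a": {1: 10.0, 2: 10.0}, "b": {1: 20.0, 2: 20.0}}
        assert mean_region(res, frames=(1, 2)) == 15.0

    def test_frame_subset_ignores_frame0(self):
        res = {"a": {0: 99.0, 1: 4.0, 2: 8.0}}
        assert mean_region(res, frames=(1, 2)) == 6.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mean_region({})


class TestStratifiedComparison:
    def _uniform_genes(self, n):
        return geneset(*[
            gene(f"g{i}", "CCCCCC" * 3, "ATG" + "AAA" * 40 + "TAA")
            for i in range(n)
        ])

    def test_identical_strata_give_maximal_pvalue(self):
        gs = self._uniform_genes(40)
        expr = make_expression_table(
            mrna=pd.Series(np.linspace(1, 2, 40), index=gs.ids()),
            rd=pd.Series(1.0, index=gs.ids()),
        )
        out = stratified_atg_comparison(gs, expr, frac=0.25)
        assert (out["p_value"] == 1.0).all()

    def test_half_fraction_partitions_all_genes(self):
        gs = self._uniform_genes(40)
        expr = make_expression_table(
            mrna=pd.Series(np.linspace(1, 2, 40), index=gs.ids()),
            rd=pd.Series(1.0, index=gs.ids()),
        )
        out = stratified_atg_comparison(gs, expr, frac=0.5)
        assert out.shape[0] == 8  # 2 regions x (3 frames + pooled)

    def test_expression_coupled_depletion_detected(self):
        # stronger ORF depletion in highly expressed genes -> pooled ORF signal
        rng = np.random.default_rng(8)
        genes = []
        expr_rows = {}
        for i in range(2000):
            hi = i < 1000
            gs_i, _ = simulate_genome(SimParams(
                n_genes=1, utr_len_mean=30.0, orf_len_codons_mean=60.0,
                min_orf_codons=40, seed=60_000 + i,
                depletion=DepletionZone(utr_len_codons=0, orf_len_codons=30,
                                        strength=0.95 if hi else 0.0),
            ))
            g = next(iter(gs_i))
            gid = f"g{i}"
            genes.append(gene(gid, g.utr5, g.orf))
            expr_rows[gid] = 1000.0 - i + rng.normal(0, 0.1)
        gs = geneset(*genes)
        expr = make_expression_table(
            mrna=pd.Series(expr_rows), rd=pd.Series(1.0, index=list(expr_rows))
        )
        out = stratified_atg_comparison(gs, expr, frac=0.15)
        pooled_orf = out[(out.region == "ORF") & (out.frame == "all")]
        assert float(pooled_orf["p_value"].iloc[0]) < 0.01
        assert float(pooled_orf["mean_top"].iloc[0]) < float(pooled_orf["mean_bottom"].iloc[0])

    def test_too_small_strata_raise(self):
        gs = self._uniform_genes(6)
        expr = make_expression_table(
            mrna=pd.Series(np.linspace(1, 2, 6), index=gs.ids()),
            rd=pd.Series(1.0, index=gs.ids()),
        )
        with pytest.raises(ValueError, match="stratum"):
            stratified_atg_comparison(gs, expr, frac=0.15)
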