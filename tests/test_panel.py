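"""Panel-design criteria, greedy autosomal selection, numt screening and
mtDNA panel construction."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from leopanel import panel, simulate as sim
from leopanel.datamodel import HET, HOM_ALT, HOM_REF, MISSING, NUCLEOTIDES, SiteRecord


def make_candidate(
    rng=None,
    calls=None,
    window_depth=None,
    offsets=(),
    scaffold="sc0",
    position=500,
    chromosome="A1",
    mapping_stats=None,
):
    rng = rng or np.random.default_rng(0)
    if calls is None:
        calls = rng.integers(0, 3, size=10).astype(np.int8)
    if window_depth is None:
        window_depth = np.full(101, 30)
    seq = "".join(rng.choice(list(NUCLEOTIDES), size=101))
    site = SiteRecord(scaffold, position, "A", "G", chromosome)
    seq = seq[:50] + "A" + seq[51:]
    return panel.PanelCandidate(
        site=site,
        flank_seq=seq,
        flank_variant_offsets=tuple(offsets),
        calls=np.asarray(calls, dtype=np.int8),
        depths=np.full(len(calls), 5, dtype=np.int32),
        window_depth=np.asarray(window_depth),
        mapping_stats=mapping_stats,
    )


class TestFlankCoverage:
    def test_constant_depth_at_threshold_passes(self):
        cand = make_candidate(window_depth=np.full(101, 20))
        assert panel.check_flank_coverage(cand, min_combined=20)

    def test_single_position_below_threshold_fails(self):
        profile = np.full(101, 30)
        profile[77] = 19
        cand = make_candidate(window_depth=profile)
        assert not panel.check_flank_coverage(cand, min_combined=20)

    def test_agrees_with_brute_force_min_scan(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            profile = rng.integers(0, 40, size=101)
            cand = make_candidate(window_depth=profile)
            assert panel.check_flank_coverage(cand, 20) == (
                min(int(x) for x in profile) >= 20
            )

    def test_truncated_window_fails_with_edge_flag(self):
        cand = make_candidate(window_depth=np.full(80, 30))
        assert not panel.check_flank_coverage(cand)
        assert "edge" in cand.flags


class TestFlankVariants:
    def test_zero_variants_pass(self):
        assert panel.check_flank_variants(make_candidate(offsets=()))

    def test_one_per_flank_fails_under_total_reading(self):
        cand = make_candidate(offsets=(10, 90))
        assert not panel.check_flank_variants(cand, max_variants=1)
        assert panel.check_flank_variants(cand, max_variants=1, per_flank=True)

    def test_detected_count_equals_generator_truth(self, discovery_pieces):
        flanks = discovery_pieces["flanks"]
        observed = discovery_pieces["observed"]
        cands = panel.build_candidates(observed, flanks)
        for cand in cands[:200]:
            expected = len(flanks[cand.site.snp_id].variant_offsets)
            assert len(cand.flank_variant_offsets) == expected


class TestMappingQualityProxy:
    def test_absent_stats_pass_with_flag(self):
        cand = make_candidate()
        assert panel.check_mapping_quality_proxy(cand)
        assert "unassessed" in cand.flags

    def test_nearby_indel_fails(self):
        cand = make_candidate(mapping_stats={"indel_distance": 3})
        assert not panel.check_mapping_quality_proxy(cand, max_indel_near=5)

    def test_threshold_sweep_is_monotone(self):
        rng = np.random.default_rng(2)
        cands = [
            make_candidate(rng, mapping_stats={"softclip_frac": rng.random()})
            for _ in range(40)
        ]
        sizes = []
        for thr in (0.05, 0.2, 0.5, 0.9):
            sizes.append(
                sum(panel.check_mapping_quality_proxy(c, max_softclip_frac=thr) for c in cands)
            )
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))


class TestMinIndividuals:
    @pytest.mark.parametrize("n_called,expected", [(8, True), (7, False)])
    def test_boundary(self, n_called, expected):
        calls = np.full(10, MISSING, dtype=np.int8)
        calls[:n_called] = HOM_REF
        assert panel.check_min_individuals(make_candidate(calls=calls)) is expected

    def test_random_matrices_equal_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            calls = rng.integers(-1, 3, size=10).astype(np.int8)
            cand = make_candidate(calls=calls)
            assert panel.check_min_individuals(cand, 8) == (
                sum(1 for g in calls if g != MISSING) >= 8
            )


class TestGenotypeComposition:
    def test_all_het_hard_fails(self):
        hard_ok, _ = panel.check_genotype_composition(
            make_candidate(calls=np.full(10, HET, dtype=np.int8))
        )
        assert not hard_ok

    def test_mixed_passes_with_bonus(self):
        calls = np.array([HOM_REF, HET, HOM_ALT, HET, HOM_REF], dtype=np.int8)
        hard_ok, bonus = panel.check_genotype_composition(make_candidate(calls=calls))
        assert hard_ok and bonus == 1

    def test_all_hom_passes_without_bonus(self):
        calls = np.full(10, HOM_REF, dtype=np.int8)
        hard_ok, bonus = panel.check_genotype_composition(make_candidate(calls=calls))
        assert hard_ok and bonus == 0


class TestAutosomalSelection:
    def _evaluated(self, cands):
        return panel.evaluate_candidates(cands)

    def test_one_per_scaffold_keeps_higher_score(self):
        rng = np.random.default_rng(4)
        hi = make_candidate(rng, calls=np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 0], dtype=np.int8),
                            scaffold="scX", position=100)
        lo_calls = np.array([0, 0, 0, 0, 0, 0, 0, 0, MISSING, MISSING], dtype=np.int8)
        lo = make_candidate(rng, calls=lo_calls, scaffold="scX", position=900)
        selected = panel.select_autosomal_panel(self._evaluated([hi, lo]), target_n=5)
        assert selected.autosomal_ids == [hi.site.snp_id]

    def test_target_above_eligible_returns_all(self):
        rng = np.random.default_rng(5)
        cands = [
            make_candidate(rng, scaffold=f"sc{i}", chromosome=f"chr{i % 3}")
            for i in range(6)
        ]
        selected = panel.select_autosomal_panel(self._evaluated(cands), target_n=100)
        assert len(selected.autosomal) == 6

    def test_no_eligible_candidates_raises(self):
        cand = make_candidate(calls=np.full(10, HET, dtype=np.int8))
        with pytest.raises(ValueError):
            panel.select_autosomal_panel(self._evaluated([cand]))

    def test_selection_is_deterministic_byte_for_byte(self, tmp_path):
        rng = np.random.default_rng(6)
        cands = [
            make_candidate(
                rng,
                calls=rng.integers(-1, 3, size=10).astype(np.int8),
                scaffold=f"sc{i}",
                chromosome=f"chr{i % 5}",
                window_depth=rng.integers(20, 41, size=101),
            )
            for i in range(200)
        ]
        a = panel.select_autosomal_panel(self._evaluated(cands), 40)
        b = panel.select_autosomal_panel(self._evaluated(cands), 40)
        a.to_csv(tmp_path / "a.csv")
        b.to_csv(tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_ablation_never_shrinks_eligible_set(self):
        rng = np.random.default_rng(7)
        cands = [
            make_candidate(
                rng,
                calls=rng.integers(-1, 3, size=10).astype(np.int8),
                offsets=tuple(rng.choice(100, size=rng.integers(0, 4), replace=False) + 1),
                window_depth=rng.integers(10, 40, size=101),
                scaffold=f"sc{i}",
            )
            for i in range(150)
        ]
        panel.evaluate_candidates(cands)
        full = {c.site.snp_id for c in cands if c.hard_pass}
        for dropped in panel.HARD_CRITERIA:
            ablated = {
                c.site.snp_id
                for c in cands
                if all(c.criteria[k] for k in panel.HARD_CRITERIA if k != dropped)
            }
            assert full <= ablated


class TestNumtScreening:
    def test_verbatim_copy_is_risk(self):
        rng = np.random.default_rng(8)
        flank = "".join(rng.choice(list(NUCLEOTIDES), size=101))
        numt = "".join(rng.choice(list(NUCLEOTIDES), size=300)) + flank
        risk, flags = panel.screen_numts(flank, {"n0": numt})
        assert risk and not flags

    def test_unrelated_numt_is_clean(self):
        rng = np.random.default_rng(9)
        flank = "".join(rng.choice(list(NUCLEOTIDES), size=101))
        numt = "".join(rng.choice(list(NUCLEOTIDES), size=400))
        risk, _ = panel.screen_numts(flank, {"n0": numt})
        assert not risk

    def test_empty_numt_set_unscreened(self):
        risk, flags = panel.screen_numts("ACGT" * 25 + "A", {})
        assert not risk and flags == {"unscreened"}

    @pytest.mark.parametrize("divergence,expected_risk", [(0.15, True), (0.30, False)])
    def test_divergence_thresholds(self, divergence, expected_risk):
        rng = np.random.default_rng(10)
        flank = "".join(rng.choice(list(NUCLEOTIDES), size=101))
        mutated = list(flank)
        for i in np.flatnonzero(rng.random(101) < divergence):
            mutated[i] = NUCLEOTIDES[(NUCLEOTIDES.index(mutated[i]) + 2) % 4]
        risk, _ = panel.screen_numts(flank, {"n0": "".join(mutated)}, min_identity=0.8)
        assert risk is expected_risk


class TestMtdnaSelection:
    def _model_run(self, seed=12, **kw):
        model = sim.MtDNAModel(**kw)
        _, key, numts, genome = sim.simulate_mtdna(
            model, sim.discovery_samples(), seed=seed
        )
        return key, numts, genome

    def test_valid_panel_is_separable_with_two_subspecies_snps(self):
        key, numts, genome = self._model_run()
        pdef = panel.select_mtdna_panel(key, numts, genome, target_n=14)
        assert len(pdef.mtdna) == 14
        assert pdef.mtdna["subspecies_diagnostic"].sum() == 2
        sub = key[pdef.mtdna_ids]
        haplogroups = list(key.index)
        for i, a in enumerate(haplogroups):
            for b in haplogroups[i + 1 :]:
                assert (sub.loc[a] != sub.loc[b]).any()

    def test_contaminated_branch_raises_naming_it(self):
        key, numts, genome = self._model_run()
        meta = key.attrs["site_meta"]
        branch = "South West Africa"
        # plant numts carrying every candidate flank of one branch
        planted = dict(numts)
        for i, (snp, row) in enumerate(meta[meta["branch"] == branch].iterrows()):
            planted[f"planted_{i}"] = sim.mt_flank(genome, row["position"])
        with pytest.raises(ValueError, match="South West Africa"):
            panel.select_mtdna_panel(key, planted, genome, target_n=14)

    def test_infeasible_target_raises(self):
        key, numts, genome = self._model_run()
        with pytest.raises(ValueError, match="infeasible"):
            panel.select_mtdna_panel(key, numts, genome, target_n=7)


class TestPanelApplication:
    def test_cohort_coverage_of_panel_snps(self, discovery_pieces):
        from leopanel import filters

        config = discovery_pieces["config"]
        observed = discovery_pieces["observed"]
        flanks = discovery_pieces["flanks"]
        masked = filters.mask_low_coverage(observed, 3)
        _, smap = sim._make_sites(config, np.random.default_rng(0))
        attributed = filters.attribute_chromosomes(masked, smap)
        cands = panel.evaluate_candidates(panel.build_candidates(attributed, flanks))
        pdef = panel.select_autosomal_panel(cands, 125)
        assert len(pdef.autosomal) == 125
        assert pdef.autosomal["scaffold"].is_unique

        ccfg = sim.cohort_config(seed=config.seed, n_sites=config.n_sites)
        cfreqs = sim.simulate_allele_frequencies(ccfg)
        cobs = sim.simulate_coverage_and_calls(sim.simulate_genotypes(cfreqs, ccfg), ccfg)
        calls = panel.apply_panel(cobs, pdef)
        high_cov = [s.id for s in ccfg.samples if s.depth >= 3.0]
        call_rate = (calls.autosomal().loc[high_cov] != MISSING).mean(axis=1)
        assert (call_rate >= 0.9).mean() >= 0.95

    def test_panel_csv_roundtrip(self, tmp_path, discovery_pieces):
        from leopanel import filters

        config = discovery_pieces["config"]
        observed = discovery_pieces["observed"]
        masked = filters.mask_low_coverage(observed, 3)
        _, smap = sim._make_sites(config, np.random.default_rng(0))
        attributed = filters.attribute_chromosomes(masked, smap)
        cands = panel.evaluate_candidates(
            panel.build_candidates(attributed, discovery_pieces["flanks"])
        )
        pdef = panel.select_autosomal_panel(cands, 30)
        key, numts, genome = TestMtdnaSelection()._model_run()
        combined = panel.combine_panels(
            pdef, panel.select_mtdna_panel(key, numts, genome)
        )
        combined.to_csv(tmp_path / "p.csv")
        back = panel.read_panel_csv(tmp_path / "p.csv")
        assert back.autosomal_ids == combined.autosomal_ids
        assert back.mtdna_ids == combined.mtdna_ids
        assert back.mtdna["subspecies_diagnostic"].sum() == 2
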