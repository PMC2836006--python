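"""Family enrichment arithmetic, local background sampling, class pooling."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_tags
from temark import enrichment as en
from temark.io_formats import IntervalSet
from temark.models import TEInsertion
from temark.simulate import EnrichmentSpec, generate_genome, generate_tags
from temark.stats import CorrelationResult


def interval_set(label, triples):
    return IntervalSet(label=label, intervals=pd.DataFrame(
        triples, columns=["chrom", "start", "end"]))


class TestGlobalEnrichment:
    def test_density_ratio_arithmetic(self):
        # 500 of 10,000 tags in 100 kb of TE on a 10 Mb genome:
        # (0.005 / 0.001) -> log2 = 2.3219
        rng = np.random.default_rng(0)
        pos = np.concatenate([
            rng.integers(0, 100_000, size=500),            # inside TE block
            rng.integers(100_000, 10_000_000, size=9_500),  # outside
        ])
        tags = make_tags(np.sort(pos))
        fam = interval_set("Alu", [("chr1", 0, 100_000)])
        rec = en.global_enrichment(tags, fam, 10_000_000)
        assert rec.te_tag_count == 500
        assert rec.log2_enrichment == pytest.approx(math.log2(5.0), abs=1e-12)
        assert rec.G > 0 and rec.p < 1e-10

    def test_null_uniform_tags_near_zero(self):
        rng = np.random.default_rng(3)
        tags = make_tags(np.sort(rng.integers(0, 10_000_000, size=50_000)))
        fam = interval_set("Alu", [("chr1", 2_000_000, 2_500_000)])
        rec = en.global_enrichment(tags, fam, 10_000_000)
        assert abs(rec.log2_enrichment) < 0.1
        assert not rec.significant

    def test_zero_te_count_flagged(self):
        tags = make_tags([5_000_000])
        fam = interval_set("Alu", [("chr1", 0, 1000)])
        rec = en.global_enrichment(tags, fam, 10_000_000)
        assert math.isnan(rec.log2_enrichment)
        assert "undefined-log2" in rec.flagged
        assert np.isfinite(rec.G)  # 0 ln 0 convention

    def test_count_conservation(self):
        rng = np.random.default_rng(5)
        tags = make_tags(np.sort(rng.integers(0, 1_000_000, size=2_000)))
        fam = interval_set("Alu", [("chr1", 100_000, 150_000), ("chr1", 400_000, 420_000)])
        rec = en.global_enrichment(tags, fam, 1_000_000)
        inside = rec.te_tag_count
        outside = tags.total_count - inside
        assert inside + outside == tags.total_count

    def test_scale_invariance_of_log2_and_growth_of_G(self):
        rng = np.random.default_rng(7)
        pos = np.sort(rng.integers(0, 1_000_000, size=3_000))
        fam = interval_set("Alu", [("chr1", 0, 100_000)])
        single = en.global_enrichment(make_tags(pos), fam, 1_000_000)
        tripled = en.global_enrichment(make_tags(np.sort(np.tile(pos, 3))), fam, 1_000_000)
        assert tripled.log2_enrichment == pytest.approx(single.log2_enrichment, abs=1e-12)
        assert tripled.G > single.G


def te(start, end, family="Alu", subfamily="AluY", chrom="chr1", div=3.0):
    return TEInsertion(chrom, start, end, "+", family, subfamily, div)


class TestLocalBackground:
    def test_sampled_segments_match_lengths_and_avoid_tes(self):
        tes = [te(i * 10_000, i * 10_000 + 300) for i in range(20)]
        all_te = pd.DataFrame([(t.chrom, t.start, t.end) for t in tes],
                              columns=["chrom", "start", "end"])
        sample = en.sample_local_segments(tes, all_te, {"chr1": 1_000_000}, seed=1)
        assert sample.n_sampled == 20 and sample.n_skipped == 0
        from temark.intervals import ChromArrays

        blocked = ChromArrays.from_frame(all_te)
        for row in sample.segments.itertuples(index=False):
            assert row.end - row.start == 300
            assert not blocked.overlaps(row.chrom, row.start, row.end)

    def test_forced_placement_into_single_gap(self):
        # one TE occupies its whole window except a gap of exactly its length
        window = 10_000
        gap = (2_000, 2_300)
        blockers = [te(0, gap[0]), te(gap[1], 4_700), te(5_000, window)]
        target = te(4_700, 5_000, subfamily="AluSx")
        all_te = pd.DataFrame(
            [(t.chrom, t.start, t.end) for t in blockers + [target]],
            columns=["chrom", "start", "end"])
        for seed in range(5):
            sample = en.sample_local_segments([target], all_te, {"chr1": window},
                                              window_bp=window, seed=seed)
            assert sample.segments.iloc[0][["start", "end"]].tolist() == list(gap)

    def test_fully_tiled_chromosome_skips_all(self):
        tes = [te(0, 5_000), te(5_000, 10_000)]
        all_te = pd.DataFrame([(t.chrom, t.start, t.end) for t in tes],
                              columns=["chrom", "start", "end"])
        sample = en.sample_local_segments(tes, all_te, {"chr1": 10_000}, window_bp=9_000, seed=0)
        assert sample.n_sampled == 0 and sample.n_skipped == 2
        bg = en.local_background(sample, make_tags([]))
        assert math.isnan(bg.density) and bg.unreliable

    def test_window_smaller_than_element_rejected(self):
        t = te(0, 5_000)
        all_te = pd.DataFrame([(t.chrom, t.start, t.end)], columns=["chrom", "start", "end"])
        with pytest.raises(ValueError, match="window"):
            en.sample_local_segments([t], all_te, {"chr1": 100_000}, window_bp=4_000, seed=0)

    def test_density_converges_to_uniform_rate(self):
        # single TE amid uniform tags at rate 0.01: pooled density over many
        # resamples approaches the rate (law of large numbers)
        rng = np.random.default_rng(11)
        tags = make_tags(np.sort(rng.integers(0, 1_000_000, size=10_000)))
        target = te(500_000, 502_000)
        all_te = pd.DataFrame([(target.chrom, target.start, target.end)],
                              columns=["chrom", "start", "end"])
        densities = []
        for seed in range(300):
            sample = en.sample_local_segments([target], all_te, {"chr1": 1_000_000}, seed=seed)
            densities.append(en.local_background(sample, tags).density)
        assert np.mean(densities) == pytest.approx(0.01, rel=0.05)


class TestLocalEnrichment:
    def test_matches_global_when_densities_agree(self):
        rng = np.random.default_rng(2)
        tags = make_tags(np.sort(rng.integers(0, 1_000_000, size=5_000)))
        fam = interval_set("Alu", [("chr1", 100_000, 130_000)])
        glob = en.global_enrichment(tags, fam, 1_000_000)
        bg = en.LocalBackgroundEstimate(
            family="Alu", modification="H3", sampled_counts=np.array([150]),
            sampled_lengths=np.array([30_000]), density=tags.total_count / 1_000_000,
            n_sampled=1, n_skipped=0)
        loc = en.local_enrichment(tags, fam, bg)
        assert loc.log2_enrichment == pytest.approx(glob.log2_enrichment, abs=1e-12)
        assert loc.background_kind == "local"


class TestClassEnrichment:
    def _classification(self, mods, klasses):
        return pd.DataFrame({"modification": mods, "klass": klasses})

    def test_singleton_class_equals_library_result(self):
        rng = np.random.default_rng(4)
        tags = make_tags(np.sort(rng.integers(0, 1_000_000, size=4_000)), modification="m1")
        fam_sets = {"Alu": interval_set("Alu", [("chr1", 0, 50_000)])}
        single = en.global_enrichment(tags, fam_sets["Alu"], 1_000_000)
        recs = en.class_enrichment({"m1": tags}, self._classification(["m1"], ["active"]),
                                   fam_sets, 1_000_000)
        active = [r for r in recs if r.modification == "active"][0]
        assert active.te_tag_count == single.te_tag_count
        assert active.log2_enrichment == pytest.approx(single.log2_enrichment, abs=1e-12)

    def test_duplicated_library_leaves_log2_unchanged(self):
        rng = np.random.default_rng(6)
        pos = np.sort(rng.integers(0, 1_000_000, size=4_000))
        fam_sets = {"Alu": interval_set("Alu", [("chr1", 0, 50_000)])}
        one = en.class_enrichment(
            {"m1": make_tags(pos, modification="m1")},
            self._classification(["m1"], ["active"]), fam_sets, 1_000_000)
        two = en.class_enrichment(
            {"m1": make_tags(pos, modification="m1"), "m2": make_tags(pos, modification="m2")},
            self._classification(["m1", "m2"], ["active", "active"]), fam_sets, 1_000_000)
        a1 = [r for r in one if r.modification == "active"][0]
        a2 = [r for r in two if r.modification == "active"][0]
        assert a2.log2_enrichment == pytest.approx(a1.log2_enrichment, abs=1e-12)
        assert a2.te_tag_count == 2 * a1.te_tag_count

    def test_unclassified_library_rejected(self):
        tags = make_tags([10], modification="m1")
        fam_sets = {"Alu": interval_set("Alu", [("chr1", 0, 1_000)])}
        with pytest.raises(ValueError, match="unclassified"):
            en.class_enrichment({"m1": tags}, self._classification(["other"], ["active"]),
                                fam_sets, 1_000_000)

    def test_planted_active_only_enrichment_in_mir(self):
        from temark.simulate import GenomeConfig, SubfamilyConfig

        cfg_families = {"MIR": {"MIRb": SubfamilyConfig(count=150, mean_length=250,
                                                        mean_divergence=18.0)}}
        genome = generate_genome(GenomeConfig(chromosomes=[("chr1", 2_000_000)],
                                              families=cfg_families), seed=3)
        spec = EnrichmentSpec(modifications=["act", "rep"], background_rate=0.01,
                              nonunique_fraction=0.0, family_fold={("MIR", "act"): 4.0})
        libs = {m: generate_tags(genome, spec, m, seed=5) for m in ("act", "rep")}
        fam_sets = en.family_interval_sets(genome.te_insertions)
        recs = en.class_enrichment(libs, self._classification(["act", "rep"],
                                                              ["active", "repressive"]),
                                   fam_sets, genome.genome_length)
        by_class = {r.modification: r for r in recs}
        assert by_class["active"].log2_enrichment > 1.5
        assert abs(by_class["repressive"].log2_enrichment) < 0.3


class TestFamilyAgeCorrelation:
    def _records(self, log2s, klass="active"):
        fams = ["Alu", "L1", "LTR", "DNA", "L2", "MIR"]
        return [en.EnrichmentRecord(f, klass, 100, 1000, 0.1, v, "global",
                                    1.0, 1, 0.5, False, 0.05)
                for f, v in zip(fams, log2s)]

    def test_monotone_increase_gives_rho_one(self):
        res = en.family_age_correlation(self._records([-1.0, -0.5, 0.0, 0.5, 1.0, 1.5]), "active")
        assert isinstance(res, CorrelationResult)
        assert res.coefficient == 1.0

    def test_constant_enrichment_surfaces_stats_error(self):
        with pytest.raises(ValueError, match="constant"):
            en.family_age_correlation(self._records([0.3] * 6), "active")

    def test_missing_family_rejected(self):
        recs = self._records([-1, 0, 1, 2, 3, 4])[:5]
        with pytest.raises(ValueError, match="missing"):
            en.family_age_correlation(recs, "active")
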