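"""Subfamily age tables, nearest-gene distances, distance binning."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_tags
from temark import age_distance as ad
from temark.intervals import distance_to_spans
from temark.models import Gene, TEInsertion


def te(start, end, family="Alu", subfamily="AluY", div=3.0, chrom="chr1"):
    return TEInsertion(chrom, start, end, "+", family, subfamily, div)


def gene(start, end, gid="g1", chrom="chr1"):
    return Gene(gid, chrom, start, "+", start, end, 1.0)


EMPTY = make_tags([], modification="repressive")


class TestSubfamilyAgeTable:
    def test_mean_divergence_is_unweighted_mean(self):
        tes = [te(0, 100, div=5.0), te(1000, 1100, div=7.0), te(2000, 2300, div=6.0)]
        table = ad.subfamily_age_table(tes, EMPTY, EMPTY)
        assert table.loc[0, "mean_divergence"] == pytest.approx(6.0)
        assert table.loc[0, "n_elements"] == 3
        assert table.loc[0, "total_length"] == 500

    def test_no_tags_gives_zero_density(self):
        table = ad.subfamily_age_table([te(0, 100)], EMPTY, EMPTY)
        assert table.loc[0, "active_density"] == 0.0

    def test_density_counts_class_tags_per_bp(self):
        tes = [te(0, 1000)]
        active = make_tags([10, 20, 30, 2000], modification="active")  # 3 inside
        table = ad.subfamily_age_table(tes, active, EMPTY)
        assert table.loc[0, "active_density"] == pytest.approx(3 / 1000)

    def test_splitting_an_element_preserves_density(self):
        active = make_tags(np.arange(0, 1000, 50), modification="active")
        whole = ad.subfamily_age_table([te(0, 1000)], active, EMPTY)
        split = ad.subfamily_age_table([te(0, 400), te(400, 1000)], active, EMPTY)
        assert split.loc[0, "active_density"] == pytest.approx(whole.loc[0, "active_density"])

    def test_element_order_invariance(self):
        tes = [te(0, 100, div=2.0), te(500, 800, div=9.0)]
        a = ad.subfamily_age_table(tes, EMPTY, EMPTY)
        b = ad.subfamily_age_table(tes[::-1], EMPTY, EMPTY)
        pd.testing.assert_frame_equal(a, b)


class TestAgeDensityCorrelation:
    def _table(self, divs, densities):
        return pd.DataFrame({
            "family": "Alu", "subfamily": [f"s{i}" for i in range(len(divs))],
            "mean_divergence": divs, "total_length": 1000,
            "active_density": densities, "repressive_density": densities,
            "n_elements": 10,
        })

    def test_monotone_density_gives_rho_one(self):
        res = ad.age_density_correlation(self._table([1, 5, 9, 13], [0.1, 0.2, 0.3, 0.4]), "active")
        assert res.coefficient == 1.0

    def test_constant_density_raises(self):
        with pytest.raises(ValueError, match="constant"):
            ad.age_density_correlation(self._table([1, 5, 9], [0.2, 0.2, 0.2]), "active")

    def test_too_few_subfamilies(self):
        with pytest.raises(ValueError, match="3 subfamilies"):
            ad.age_density_correlation(self._table([1, 5], [0.1, 0.2]), "active")


class TestNearestGeneDistance:
    def test_te_inside_gene(self):
        genes = [gene(5_000, 20_000)]
        recs = ad.distance_records([te(10_000, 10_300)], genes, EMPTY, EMPTY)
        assert recs.loc[0, "distance_bp"] == 0 and bool(recs.loc[0, "inside_gene"])

    def test_boundary_gap(self):
        genes = [gene(5_000, 8_000)]
        recs = ad.distance_records([te(10_000, 10_300)], genes, EMPTY, EMPTY)
        assert recs.loc[0, "distance_bp"] == 2_000
        assert not bool(recs.loc[0, "inside_gene"])

    def test_equidistant_tie_breaks_to_lower_start(self):
        q = pd.DataFrame({"chrom": ["chr1"], "start": [10_000], "end": [10_300]})
        spans = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [5_000, 12_300],
                              "end": [8_000, 15_000]})
        dist, inside, nearest = distance_to_spans(q, spans)
        assert dist[0] == 2_000 and not inside[0]
        assert nearest[0] == 5_000  # lower-start span wins the tie

    def test_chromosome_without_genes_flagged_nan(self):
        recs = ad.distance_records([te(100, 400, chrom="chr2")],
                                   [gene(0, 1000, chrom="chr1")], EMPTY, EMPTY)
        assert np.isnan(recs.loc[0, "distance_bp"])


class TestDistanceBinProfile:
    def _records(self, distances, counts, inside=None):
        n = len(distances)
        return pd.DataFrame({
            "te_id": [f"te{i}" for i in range(n)], "family": "Alu", "chrom": "chr1",
            "start": 0, "end": 300, "te_length": 300,
            "distance_bp": np.asarray(distances, dtype=float),
            "inside_gene": inside if inside is not None else [d == 0 for d in distances],
            "active_count": counts, "repressive_count": 0,
        })

    def test_bin_arithmetic(self):
        recs = self._records([25_000.0, 3_000.0], [5, 5], inside=[False, False])
        profile = ad.distance_bin_profile(recs, "active")
        assert set(profile.bins["bin"]) == {0, 2}  # 25 kb -> bin 2

    def test_inside_gene_separated_from_first_bin(self):
        recs = self._records([0.0, 0.0, 4_000.0], [10, 10, 2],
                             inside=[True, True, False])
        profile = ad.distance_bin_profile(recs, "active")
        bins0 = profile.bins[profile.bins["bin"] == 0]
        assert len(bins0) == 2  # inside-gene row and 0-10 kb gap row
        assert set(bins0["inside_gene"]) == {True, False}

    def test_all_zero_distance_correlation_flagged(self):
        recs = self._records([0.0, 0.0, 0.0], [1, 2, 3])
        profile = ad.distance_bin_profile(recs, "active")
        assert profile.correlation is None
        assert "correlation-undefined" in profile.flagged

    def test_bin_totals_conserve_class_tags(self):
        rng = np.random.default_rng(0)
        recs = self._records(rng.integers(0, 100_000, size=50).astype(float),
                             rng.integers(0, 20, size=50),
                             inside=[False] * 50)
        profile = ad.distance_bin_profile(recs, "active")
        assert profile.bins["total_count"].sum() == recs["active_count"].sum()

    def test_correlation_is_computed_unbinned(self):
        # craft records where binned means and unbinned values disagree in rank
        distances = [1_000.0, 9_000.0, 11_000.0, 19_000.0, 21_000.0, 29_000.0]
        counts = [9, 2, 8, 1, 7, 0]
        recs = self._records(distances, counts, inside=[False] * 6)
        profile = ad.distance_bin_profile(recs, "active")
        from temark.stats import correlate

        unbinned = correlate(np.array(distances), np.array(counts) / 300.0, method="spearman")
        assert profile.correlation.coefficient == pytest.approx(unbinned.coefficient)
        # a deliberately binned recomputation differs
        binned = profile.bins.sort_values("bin")
        binned_corr = correlate(binned["bin"].to_numpy(float), binned["density"].to_numpy(),
                                method="spearman")
        assert binned_corr.coefficient != pytest.approx(unbinned.coefficient)

    def test_unique_only_filters_counts(self):
        tes = [te(0, 1000)]
        genes = [gene(5_000, 8_000)]
        active = make_tags([10, 20, 30], modification="active", unique=[True, False, True])
        rec_u = ad.distance_records(tes, genes, active, EMPTY, unique_only=True)
        rec_all = ad.distance_records(tes, genes, active, EMPTY, unique_only=False)
        assert rec_u.loc[0, "active_count"] == 2
        assert rec_all.loc[0, "active_count"] == 3
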