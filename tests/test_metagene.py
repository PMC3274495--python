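import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metachip.annotation import GeneModel, GenomeLayout, derive_intergenic_regions
from metachip.metagene import (
    TrackIndex,
    bin_region,
    composite_average_gene,
    region_summary,
    smooth_moving_window,
    stratified_profiles,
)
from metachip.normalize import normalize_probe_table
from metachip.simulate import mirror_genome, simulate_bundle

from conftest import flat_orf_level, flat_params


def track_from(positions, values, chrom="chr1"):
    return pd.DataFrame({"chrom": [chrom] * len(positions), "pos": positions, "value": values})


def brute_force_bins(length, n_bins):
    """Independent oracle: bin b holds offsets in [ceil(bL/B), ceil((b+1)L/B))."""
    edges = [(b * length + n_bins - 1) // n_bins for b in range(n_bins + 1)]
    return [(edges[b], edges[b + 1]) for b in range(n_bins)]


class TestBinRegion:
    def test_per_bp_identity(self):
        track = track_from(np.arange(40), np.arange(1, 41, dtype=float))
        means = bin_region((0, 40), "+", 40, track, "chr1")
        np.testing.assert_allclose(means, np.arange(1, 41))

    def test_minus_strand_flips(self):
        track = track_from(np.arange(40), np.arange(1, 41, dtype=float))
        means = bin_region((0, 40), "-", 40, track, "chr1")
        np.testing.assert_allclose(means, 41 - np.arange(1, 41))

    def test_sparse_probes_match_oracle(self):
        # 35 bp, 10 bins, probes every 5 bp
        pos = np.arange(0, 35, 5)
        vals = np.arange(len(pos), dtype=float)
        means = bin_region((0, 35), "+", 10, track_from(pos, vals), "chr1")
        for b, (lo, hi) in enumerate(brute_force_bins(35, 10)):
            members = [v for p, v in zip(pos, vals) if lo <= p < hi]
            if members:
                assert means[b] == pytest.approx(np.mean(members))
            else:
                assert np.isnan(means[b])

    @given(st.integers(0, 2**31 - 1), st.integers(1, 1000), st.integers(1, 80),
           st.sampled_from(["+", "-"]))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, seed, length, n_bins, strand):
        n_bins = min(n_bins, length)
        rng = np.random.default_rng(seed)
        start = int(rng.integers(0, 100))
        pos = start + np.flatnonzero(rng.random(length) < 0.4)
        vals = rng.normal(size=len(pos))
        means = bin_region((start, start + length), strand, n_bins, track_from(pos, vals), "chr1")
        offsets = (pos - start) if strand == "+" else (start + length - 1 - pos)
        for b, (lo, hi) in enumerate(brute_force_bins(length, n_bins)):
            members = vals[(offsets >= lo) & (offsets < hi)]
            if len(members):
                assert means[b] == pytest.approx(members.mean(), abs=1e-12)
            else:
                assert np.isnan(means[b])

    def test_too_many_bins_rejected(self):
        with pytest.raises(ValueError):
            bin_region((0, 5), "+", 10, track_from([0], [1.0]), "chr1")


class TestSmoothing:
    def test_centre_is_window_mean(self):
        out = smooth_moving_window(np.array([1.0, 2, 3, 4, 5]))
        assert out[2] == pytest.approx(3.0)

    def test_constant_unchanged(self):
        np.testing.assert_allclose(smooth_moving_window(np.full(20, 2.5)), np.full(20, 2.5))

    def test_spike_spread(self):
        out = smooth_moving_window(np.array([0.0, 0, 5, 0, 0]))
        assert out[2] == pytest.approx(1.0)

    def test_keep_edges_policy(self):
        vals = np.arange(10, dtype=float)
        out = smooth_moving_window(vals)
        np.testing.assert_allclose(out[:2], vals[:2])
        np.testing.assert_allclose(out[-2:], vals[-2:])

    def test_missing_values_excluded_from_window(self):
        vals = np.array([1.0, 1.0, np.nan, 1.0, 1.0])
        out = smooth_moving_window(vals)
        assert out[2] == pytest.approx(1.0)

    def test_window_longer_than_vector_warns(self):
        with pytest.warns(UserWarning):
            out = smooth_moving_window(np.array([1.0, 2.0]), window=5)
        np.testing.assert_allclose(out, [1.0, 2.0])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_moving_window(np.arange(10.0), window=4)


class TestComposite:
    def setup_method(self):
        self.layout = GenomeLayout(chrom_sizes={"chr1": 2000})
        self.genes = [GeneModel("a", "chr1", 400, 800, "+"),
                      GeneModel("b", "chr1", 1200, 1600, "+")]
        self.intergenic = derive_intergenic_regions(self.genes, self.layout)

    def test_equal_gene_weighting(self):
        pos = np.arange(0, 2000, 5)
        vals = np.where((pos >= 400) & (pos < 800), 1.0, np.where((pos >= 1200) & (pos < 1600), 3.0, 0.0))
        prof = composite_average_gene(track_from(pos, vals), self.genes, self.intergenic,
                                      smooth_window=None)
        orf = prof.values[prof.segment_slice("ORF")]
        np.testing.assert_allclose(orf, 2.0)  # (1 + 3) / 2 regardless of probe counts

    def test_single_gene_equals_its_bin_means(self):
        pos = np.arange(0, 2000, 5)
        vals = np.sin(pos / 50.0)
        track = track_from(pos, vals)
        prof_one = composite_average_gene(track, [self.genes[0]],
                                          {"a": self.intergenic["a"]}, smooth_window=None)
        own = np.concatenate([
            bin_region((0, 400), "+", 20, track, "chr1"),
            bin_region((400, 800), "+", 40, track, "chr1"),
            bin_region((800, 1200), "+", 20, track, "chr1"),
        ])
        np.testing.assert_allclose(prof_one.values, own)

    def test_duplicating_probes_no_change_but_duplicate_gene_pulls(self):
        pos = np.arange(0, 2000, 5)
        vals = np.where((pos >= 400) & (pos < 800), 1.0, np.where((pos >= 1200) & (pos < 1600), 3.0, 0.0))
        base = composite_average_gene(track_from(pos, vals), self.genes, self.intergenic,
                                      smooth_window=None)
        # doubling probe density of gene a (same values) changes nothing
        extra_pos = np.arange(402, 800, 5)
        dense = pd.concat([track_from(pos, vals), track_from(extra_pos, np.ones(len(extra_pos)))])
        dense_prof = composite_average_gene(dense, self.genes, self.intergenic, smooth_window=None)
        orf = base.segment_slice("ORF")
        np.testing.assert_allclose(dense_prof.values[orf], base.values[orf])
        # adding gene a again as a third gene pulls the composite toward it
        genes3 = self.genes + [GeneModel("a2", "chr1", 400, 800, "+")]
        inter3 = derive_intergenic_regions(genes3, self.layout)
        prof3 = composite_average_gene(track_from(pos, vals), genes3, inter3, smooth_window=None)
        assert np.nanmean(prof3.values[orf]) < np.nanmean(base.values[orf])

    def test_probe_count_weighting_pools_probes(self):
        # optional mode: genes contribute per bin in proportion to probes
        pos = np.arange(0, 2000, 5)
        vals = np.where((pos >= 400) & (pos < 800), 1.0, np.where((pos >= 1200) & (pos < 1600), 3.0, 0.0))
        extra = np.arange(402, 800, 5)  # double gene a's probe density
        dense = pd.concat([track_from(pos, vals), track_from(extra, np.ones(len(extra)))])
        prof = composite_average_gene(dense, self.genes, self.intergenic,
                                      smooth_window=None, weight_by_probe_count=True)
        orf = prof.values[prof.segment_slice("ORF")]
        assert np.nanmean(orf) < 2.0  # pulled toward the probe-dense gene a

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError):
            composite_average_gene(track_from([0], [1.0]), [], {})


class TestSyntheticRecovery:
    def test_noise_free_flat_recovery(self):
        params = flat_params(fraction_intron_containing=0.0)
        layout, genes, rates, probes, _ = simulate_bundle(params)
        track = normalize_probe_table(probes)
        intergenic = derive_intergenic_regions(genes, layout)
        prof = composite_average_gene(track, genes, intergenic, smooth_window=5)
        level = flat_orf_level(params)
        np.testing.assert_allclose(prof.values[prof.segment_slice("ORF")], level, atol=1e-9)
        for seg in ("5p_intergenic", "3p_intergenic"):
            seg_vals = prof.values[prof.segment_slice(seg)]
            np.testing.assert_allclose(seg_vals[~np.isnan(seg_vals)],
                                       params.intergenic_baseline, atol=1e-9)

    def test_region_summary_uniform_track(self):
        params = flat_params(n_genes=12)
        layout, genes, _, probes, _ = simulate_bundle(params)
        pos = probes["pos"].to_numpy()
        track = pd.DataFrame({"chrom": probes["chrom"], "pos": pos, "value": 1.0})
        summary = region_summary(track, genes, layout, telomere_window=1000)
        for region, mean in summary.means.items():
            assert mean == pytest.approx(1.0), region

    def test_region_summary_recovers_baseline(self):
        params = flat_params(n_genes=20, seed=13)
        layout, genes, _, probes, _ = simulate_bundle(params)
        track = normalize_probe_table(probes)
        summary = region_summary(track, genes, layout, telomere_window=500)
        assert summary.means["intergenic"] == pytest.approx(params.intergenic_baseline, abs=1e-9)
        assert summary.means["ORF"] == pytest.approx(flat_orf_level(params), abs=1e-9)
        assert summary.means["rDNA"] == pytest.approx(params.intergenic_baseline, abs=1e-9)

    def test_stratified_disjoint_planted_levels(self):
        layout = GenomeLayout(chrom_sizes={"chr1": 4000})
        genes = [GeneModel("lo", "chr1", 500, 1000, "+", transcription_rate=1.0),
                 GeneModel("hi", "chr1", 2500, 3000, "+", transcription_rate=50.0)]
        intergenic = derive_intergenic_regions(genes, layout)
        pos = np.arange(0, 4000, 5)
        vals = np.where((pos >= 500) & (pos < 1000), 0.5,
                        np.where((pos >= 2500) & (pos < 3000), 1.5, 0.0))
        profs = stratified_profiles(track_from(pos, vals), genes,
                                    {"lo": "A", "hi": "B"}, intergenic, smooth_window=None)
        orf = profs["A"].segment_slice("ORF")
        np.testing.assert_allclose(profs["A"].values[orf], 0.5)
        np.testing.assert_allclose(profs["B"].values[orf], 1.5)

    def test_single_class_equals_unstratified(self, noisy_bundle):
        genes = noisy_bundle["genes"]
        profs = stratified_profiles(noisy_bundle["track"], genes,
                                    {g.gene_id: "all" for g in genes},
                                    noisy_bundle["intergenic"])
        base = composite_average_gene(noisy_bundle["track"], genes, noisy_bundle["intergenic"])
        np.testing.assert_allclose(profs["all"].values, base.values, equal_nan=True)


class TestStrandSymmetry:
    def test_mirrored_genome_same_composite(self, noisy_bundle):
        layout, genes, track = (noisy_bundle["layout"], noisy_bundle["genes"], noisy_bundle["track"])
        base = composite_average_gene(track, genes, noisy_bundle["intergenic"], smooth_window=None)
        mlayout, mgenes, mtrack = mirror_genome(layout, genes, track)
        minter = derive_intergenic_regions(mgenes, mlayout)
        mirrored = composite_average_gene(mtrack, mgenes, minter, smooth_window=None)
        np.testing.assert_allclose(mirrored.values, base.values, atol=1e-12, equal_nan=True)
        np.testing.assert_array_equal(mirrored.n_genes, base.n_genes)
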