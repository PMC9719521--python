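import numpy as np
import pytest

from nucleoprof import (
    FragmentTable,
    MappabilityTrack,
    ReferenceGenome,
    RegionSet,
    composite_profile,
    estimate_mappability_bias,
    mappability_fragment_weight,
    profile_site_list,
    smooth_and_normalize,
)
from nucleoprof.profiling import (
    BIN_SIZE,
    N_BINS,
    WINDOW,
    CompositeProfile,
    MappabilityBiasModel,
    SiteProfiles,
    bin_centers,
)
from nucleoprof.sites import SiteList

from conftest import whole_genome


def make_sites(positions, chrom="chr1"):
    positions = np.asarray(positions)
    return SiteList("s", np.array([chrom] * len(positions), dtype=object),
                    positions, np.ones(len(positions)))


def flat_genome(length=40_000):
    r = np.random.default_rng(1)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return ReferenceGenome({"chr1": bases[r.integers(0, 4, length)].tobytes()})


def brute_force_bins(spans, weights, site, window=WINDOW, bin_size=BIN_SIZE):
    """Per-base midpoint counting, then 15 bp aggregation — the oracle."""
    per_base = np.zeros(2 * window // bin_size * bin_size)
    for (s, e), w in zip(spans, weights):
        mid = (s + e - 1) // 2
        off = mid - (site - window)
        if 0 <= off < len(per_base):
            per_base[off] += w
    return per_base.reshape(-1, bin_size).sum(axis=1)


class TestBinning:
    def test_midpoint_at_site_center_lands_in_bin_333(self):
        genome = flat_genome()
        site = 20_000
        # fragment with midpoint exactly at the site
        frags = FragmentTable({"chr1": np.array([[site - 74, site + 76]])})
        sp = profile_site_list(frags, make_sites([site]), genome, whole_genome(genome),
                               length_range=(100, 200))
        assert sp.counts[0, 333] == pytest.approx(1.0)
        assert sp.counts.sum() == pytest.approx(1.0)

    def test_offsets_zero_and_seven_share_a_bin(self):
        genome = flat_genome()
        site = 20_000
        spans = np.array([[site - 74, site + 76], [site - 67, site + 83]])  # mids +0, +7
        sp = profile_site_list(FragmentTable({"chr1": spans}), make_sites([site]),
                               genome, whole_genome(genome), length_range=(100, 200))
        assert sp.counts[0, 333] == pytest.approx(2.0)

    def test_fragment_length_outside_range_excluded(self):
        genome = flat_genome()
        site = 20_000
        spans = np.array([[site, site + 99]])  # 99 bp < (100, 200)
        sp = profile_site_list(FragmentTable({"chr1": spans}), make_sites([site]),
                               genome, whole_genome(genome), length_range=(100, 200))
        assert sp.counts.sum() == 0

    def test_midpoint_beyond_window_excluded(self):
        genome = flat_genome()
        site = 20_000
        spans = np.array([[site + 5025, site + 5175]])  # midpoint site+5100
        sp = profile_site_list(FragmentTable({"chr1": spans}), make_sites([site]),
                               genome, whole_genome(genome), length_range=(100, 200))
        assert sp.counts.sum() == 0

    def test_site_near_contig_edge_skipped(self):
        genome = flat_genome(12_000)
        sp = profile_site_list(FragmentTable(), make_sites([1000]), genome,
                               whole_genome(genome))
        assert sp.n_sites_skipped == 1
        assert len(sp.counts) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_binning_equals_per_base_brute_force(self, seed):
        r = np.random.default_rng(seed)
        genome = flat_genome()
        site = int(r.integers(6_000, 34_000))
        n = int(r.integers(1, 200))
        starts = r.integers(0, 39_800, n)
        lengths = r.integers(100, 201, n)
        spans = np.stack([starts, np.minimum(starts + lengths, 40_000)], axis=1)
        spans = spans[spans[:, 1] - spans[:, 0] >= 100]
        frags = FragmentTable({"chr1": spans})
        sp = profile_site_list(frags, make_sites([site]), genome, whole_genome(genome),
                               length_range=(100, 200), outlier_sd=1e9)
        # oracle on the table's own (sorted) spans with unit weights
        expected = brute_force_bins(frags.spans("chr1"), np.ones(len(frags)), site)
        np.testing.assert_array_equal(sp.counts[0], expected)


class TestMasking:
    def _world(self):
        genome = flat_genome()
        site = 20_000
        r = np.random.default_rng(2)
        starts = r.integers(14_000, 25_000, 3000)
        spans = np.stack([starts, starts + 150], axis=1)
        return genome, site, FragmentTable({"chr1": spans})

    def test_bin_overlapping_exclusion_masked(self):
        genome, site, frags = self._world()
        valid = whole_genome(genome).subtract(
            RegionSet.from_intervals([("chr1", site - 3, site + 3)])
        )
        sp = profile_site_list(frags, make_sites([site]), genome, valid)
        assert sp.mask[0, 333]
        assert not sp.mask[0, 100]

    def test_outlier_bin_masked(self):
        genome, site, frags = self._world()
        # pile a huge spike into one bin
        spike = np.tile(np.array([[site + 1000 - 75, site + 1000 + 75]]), (2000, 1))
        frags = FragmentTable({"chr1": np.concatenate([frags.spans("chr1"), spike])})
        sp = profile_site_list(frags, make_sites([site]), genome, whole_genome(genome),
                               outlier_sd=10)
        spike_bin = int(np.argmax(sp.counts[0]))
        assert sp.counts[0, spike_bin] > 1000
        assert sp.mask[0, spike_bin]

    def test_masking_is_monotone(self):
        """Adding an exclusion interval never changes unmasked bin values."""
        genome, site, frags = self._world()
        base = profile_site_list(frags, make_sites([site]), genome, whole_genome(genome))
        valid2 = whole_genome(genome).subtract(
            RegionSet.from_intervals([("chr1", site + 500, site + 700)])
        )
        more = profile_site_list(frags, make_sites([site]), genome, valid2)
        still = ~more.mask[0]
        np.testing.assert_allclose(more.counts[0][still], base.counts[0][still])
        assert more.mask.sum() > base.mask.sum()


class TestComposite:
    def _profiles(self, counts, mask=None):
        counts = np.asarray(counts, float)
        mask = np.zeros_like(counts, dtype=bool) if mask is None else np.asarray(mask)
        return SiteProfiles(counts, mask, "t")

    def test_mean_of_two_sites(self):
        sp = self._profiles([[1, 2], [3, 4]])
        comp = composite_profile(sp)
        assert comp.values.tolist() == [2.0, 3.0]

    def test_masked_bin_uses_remaining_site(self):
        sp = self._profiles([[1, 2], [3, 4]], mask=[[False, True], [False, False]])
        comp = composite_profile(sp)
        assert comp.values.tolist() == [2.0, 4.0]

    def test_single_site_is_identity(self):
        sp = self._profiles([[5, 7]])
        assert composite_profile(sp).values.tolist() == [5.0, 7.0]

    def test_bin_masked_everywhere_stays_masked(self):
        sp = self._profiles([[1, 2], [3, 4]], mask=[[True, False], [True, False]])
        comp = composite_profile(sp)
        assert comp.mask.tolist() == [True, False]


class TestSmoothNormalizeTrim:
    def _composite(self, values, mask=None):
        values = np.asarray(values, float)
        mask = np.zeros(N_BINS, dtype=bool) if mask is None else mask
        return CompositeProfile(bin_centers(), values, mask)

    def test_constant_profile_becomes_ones(self):
        out = smooth_and_normalize(self._composite(np.full(N_BINS, 3.7)))
        np.testing.assert_allclose(out.values, 1.0, atol=1e-12)
        assert out.state == "trimmed"

    def test_cubic_polynomial_reproduced_exactly(self):
        x = bin_centers() / 5000.0
        cubic = 5 + 0.5 * x + 0.2 * x**2 - 0.1 * x**3
        out = smooth_and_normalize(self._composite(cubic))
        keep = np.abs(bin_centers()) <= 1000
        np.testing.assert_allclose(out.values, cubic[keep] / cubic.mean(), rtol=1e-9)

    def test_normalized_mean_is_one_over_full_window(self):
        r = np.random.default_rng(0)
        vals = 1 + 0.1 * r.random(N_BINS)
        comp = self._composite(vals)
        from scipy.signal import savgol_filter

        sm = savgol_filter(vals, 11, 3, mode="interp")
        out = smooth_and_normalize(comp)
        assert (sm / sm.mean()).mean() == pytest.approx(1.0, abs=1e-9)
        keep = np.abs(bin_centers()) <= 1000
        np.testing.assert_allclose(out.values, (sm / sm.mean())[keep])

    def test_trim_keeps_bins_with_centers_within_1kb(self):
        out = smooth_and_normalize(self._composite(np.ones(N_BINS)))
        assert len(out.values) == 133
        assert np.abs(out.offsets).max() <= 1000

    def test_all_masked_raises(self):
        comp = self._composite(np.full(N_BINS, np.nan), mask=np.ones(N_BINS, dtype=bool))
        with pytest.raises(ValueError, match="empty profile"):
            smooth_and_normalize(comp)


class TestCNACorrection:
    def test_constant_coverage_becomes_unit(self):
        genome = flat_genome(140_000)
        site = 70_000
        starts = np.arange(10_000, 130_000, 5)  # exactly 3 midpoints per 15 bp bin
        spans = np.stack([starts, starts + 150], axis=1)
        sp = profile_site_list(FragmentTable({"chr1": spans}), make_sites([site]),
                               genome, whole_genome(genome), cna_correction=True)
        np.testing.assert_allclose(sp.counts[0][~sp.mask[0]], 1.0, atol=1e-9)

    def test_local_mean_scales_values(self):
        """CNA-corrected counts equal raw counts divided by the measured
        mean coverage of the surrounding ±50 kb window."""
        genome = flat_genome(140_000)
        site = 70_000
        r = np.random.default_rng(9)
        starts = r.integers(10_000, 130_000, 40_000)
        spans = np.stack([starts, starts + 150], axis=1)
        frags = FragmentTable({"chr1": spans})
        kwargs = dict(length_range=(100, 200), outlier_sd=1e12)
        raw = profile_site_list(frags, make_sites([site]), genome,
                                whole_genome(genome), **kwargs)
        cna = profile_site_list(frags, make_sites([site]), genome,
                                whole_genome(genome), cna_correction=True, **kwargs)
        mids = frags.midpoints("chr1")
        in_local = (mids >= site - 50_000) & (mids < site + 50_000)
        local_mean = in_local.sum() / (100_000 / 15)
        np.testing.assert_allclose(cna.counts[0], raw.counts[0] / local_mean)

    def test_zero_local_coverage_masks_site(self):
        genome = flat_genome(140_000)
        sp = profile_site_list(FragmentTable(), make_sites([70_000]), genome,
                               whole_genome(genome), cna_correction=True)
        assert sp.mask[0].all()


class TestMappabilityCorrection:
    def test_uniform_coverage_flat_bias(self):
        genome_len = 200_000
        starts = np.arange(0, genome_len - 150, 25)
        frags = FragmentTable({"chr1": np.stack([starts, starts + 150], axis=1)})
        track = MappabilityTrack({"chr1": np.ones(genome_len)})
        model = estimate_mappability_bias(frags, track, {"chr1": genome_len},
                                          segment=100_000, stride=100)
        assert np.allclose(model.bias, 1.0, atol=0.1)

    def test_half_coverage_at_half_mappability(self):
        genome_len = 200_000
        vals = np.ones(genome_len)
        vals[:100_000] = 0.5
        starts_lo = np.arange(0, 100_000 - 150, 50)  # half density
        starts_hi = np.arange(100_000, genome_len - 150, 25)
        spans = np.concatenate(
            [np.stack([s, s + 150], axis=1) for s in (starts_lo, starts_hi)]
        )
        frags = FragmentTable({"chr1": spans})
        model = estimate_mappability_bias(frags, MappabilityTrack({"chr1": vals}),
                                          {"chr1": genome_len}, segment=200_000, stride=100)
        ratio = model.weight(np.array([1.0]))[0] / model.weight(np.array([0.5]))[0]
        assert ratio == pytest.approx(0.5, rel=0.15)

    def test_weight_reciprocal_and_product(self):
        model = MappabilityBiasModel(np.array([0.0, 1.0]), np.array([0.8, 0.8]))
        assert mappability_fragment_weight(model, 0.5) == pytest.approx(1.25)
        assert mappability_fragment_weight(model, 0.5, gc_weight=0.5) == pytest.approx(0.625)

    def test_undefined_mappability_excludes_fragment(self):
        model = MappabilityBiasModel(np.array([0.0, 1.0]), np.array([1.0, 1.0]))
        assert mappability_fragment_weight(model, float("nan")) == 0.0
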