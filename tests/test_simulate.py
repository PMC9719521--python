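import numpy as np
import pytest
from scipy import stats as sps

from nucleoprof import (
    FragmentTable,
    QualityRules,
    SampleSpec,
    SiteAccessibilitySpec,
    SyntheticGenomeSpec,
    simulate_fragments,
    simulate_genome,
    simulate_site_list,
)
from nucleoprof.simulate import InjectedGCBias
from nucleoprof.sites import SiteList


def empty_sites():
    return SiteList("none", np.array([], object), np.array([], int), np.array([], float))


def uniform_spec(**kw):
    return SiteAccessibilitySpec(dip_depth=0.0, phasing_amplitude=0.0, **kw)


class TestGenomeSimulation:
    def test_same_seed_identical_sequence(self):
        spec = SyntheticGenomeSpec({"chr1": 5000})
        g1 = simulate_genome(spec, np.random.default_rng(9))
        g2 = simulate_genome(spec, np.random.default_rng(9))
        assert g1.sequence("chr1") == g2.sequence("chr1")

    def test_background_gc_within_two_percent_per_10kb(self):
        spec = SyntheticGenomeSpec({"chr1": 50_000}, background_gc=0.5)
        g = simulate_genome(spec, np.random.default_rng(0))
        gc = g.is_gc("chr1")
        for s in range(0, 40_000, 10_000):
            assert abs(gc[s : s + 10_000].mean() - 0.5) < 0.02

    def test_site_enrichment_raises_local_gc(self):
        lengths = {"chr1": 60_000}
        sites = SiteList("s", np.array(["chr1"] * 2, object), np.array([20_000, 40_000]),
                         np.ones(2))
        spec = SyntheticGenomeSpec(lengths, background_gc=0.4, site_gc=0.7,
                                   site_gc_halfwidth=150)
        g = simulate_genome(spec, np.random.default_rng(1), sites=sites)
        gc = g.is_gc("chr1")
        assert gc[19_850:20_151].mean() > 0.6
        assert abs(gc[:10_000].mean() - 0.4) < 0.02


class TestSiteListSimulation:
    def test_zero_sites(self):
        assert len(simulate_site_list({"chr1": 100_000}, 0, np.random.default_rng(0))) == 0

    def test_min_spacing_guaranteed(self):
        sl = simulate_site_list({"chr1": 3_000_000}, 100, np.random.default_rng(2),
                                min_spacing=12_000)
        gaps = np.diff(np.sort(sl.positions))
        assert gaps.min() >= 12_000

    def test_positions_near_uniform(self):
        sl = simulate_site_list({"chr1": 40_000_000}, 150, np.random.default_rng(3),
                                min_spacing=12_000)
        span = 40_000_000
        p = sps.kstest(sl.positions / span, "uniform").pvalue
        assert p > 0.01

    def test_impossible_packing_rejected(self):
        with pytest.raises(ValueError):
            simulate_site_list({"chr1": 50_000}, 100, np.random.default_rng(0),
                               min_spacing=12_000)


class TestAccessibilityDensity:
    def test_negative_density_refused(self):
        spec = SiteAccessibilitySpec(dip_depth=0.5, phasing_amplitude=2.0,
                                     decay_length=1e9)
        with pytest.raises(ValueError, match="clip"):
            spec.density(np.arange(-5000, 5000))

    def test_flat_spec_is_uniform(self):
        lam = uniform_spec().density(np.arange(-5000, 5000))
        assert np.allclose(lam, 1.0)

    def test_dip_and_phasing_shape(self):
        spec = SiteAccessibilitySpec(dip_depth=0.6, phasing_amplitude=0.2, period=190)
        lam = spec.density(np.arange(-5000, 5000))
        assert lam[5000] == pytest.approx(0.4 + 0.2, abs=1e-9)  # dip + cos(0) peak
        assert lam[5000] < lam[0]


class TestFragmentSimulation:
    def _genome(self, n=60_000):
        return simulate_genome(SyntheticGenomeSpec({"chr1": n}), np.random.default_rng(5))

    def test_uniform_unbiased_midpoints_pass_gof(self):
        genome = self._genome()
        spec = SampleSpec(n_fragments=30_000, length_support=(100, 200),
                          background_fraction=1.0)
        frags, _ = simulate_fragments(genome, empty_sites(), uniform_spec(),
                                      uniform_spec(), spec, np.random.default_rng(6))
        mids = frags.midpoints("chr1")
        hist, _ = np.histogram(mids, bins=20, range=(5000, 55_000))
        p = sps.chisquare(hist).pvalue
        assert p > 0.01

    def test_zero_tumor_fraction_uses_background_density_only(self):
        genome = self._genome()
        sites = SiteList("s", np.array(["chr1"], object), np.array([30_000]), np.ones(1))
        tumor = SiteAccessibilitySpec(dip_depth=0.9, dip_width=500.0,
                                      phasing_amplitude=0.0)
        spec = SampleSpec(tumor_fraction=0.0, n_fragments=40_000,
                          length_support=(100, 200), background_fraction=0.0)
        frags, _ = simulate_fragments(genome, sites, tumor, uniform_spec(), spec,
                                      np.random.default_rng(7))
        mids = frags.midpoints("chr1")
        central = np.abs(mids - 30_000) < 500
        flank = (np.abs(mids - 30_000) > 2000) & (np.abs(mids - 30_000) < 2500)
        # no dip: central density matches flanking density
        assert central.sum() / flank.sum() == pytest.approx(1.0, abs=0.15)

    def test_tumor_dip_thins_central_midpoints(self):
        genome = self._genome()
        sites = SiteList("s", np.array(["chr1"], object), np.array([30_000]), np.ones(1))
        tumor = SiteAccessibilitySpec(dip_depth=0.9, dip_width=500.0,
                                      phasing_amplitude=0.0)
        spec = SampleSpec(tumor_fraction=1.0, n_fragments=40_000,
                          length_support=(100, 200), background_fraction=0.0)
        frags, _ = simulate_fragments(genome, sites, tumor, uniform_spec(), spec,
                                      np.random.default_rng(8))
        mids = frags.midpoints("chr1")
        central = np.abs(mids - 30_000) < 500
        flank = (np.abs(mids - 30_000) > 2000) & (np.abs(mids - 30_000) < 2500)
        assert central.sum() / flank.sum() < 0.5

    def test_injected_bias_shifts_gc_spectrum(self):
        genome = self._genome()
        base = SampleSpec(n_fragments=20_000, length_support=(100, 200),
                          background_fraction=1.0)
        biased = SampleSpec(n_fragments=20_000, length_support=(100, 200),
                            background_fraction=1.0,
                            gc_bias=InjectedGCBias(strength=4.0))
        out = {}
        for name, spec in (("flat", base), ("biased", biased)):
            frags, _ = simulate_fragments(genome, empty_sites(), uniform_spec(),
                                          uniform_spec(), spec, np.random.default_rng(10))
            spans = frags.spans("chr1")
            g = genome.gc_counts("chr1", spans[:, 0], spans[:, 1])
            out[name] = (g / (spans[:, 1] - spans[:, 0])).mean()
        # slope * within-length GC variance predicts a shift of ~0.007
        assert out["biased"] > out["flat"] + 0.004

    def test_deterministic_given_seed(self):
        genome = self._genome()
        spec = SampleSpec(n_fragments=5000, length_support=(100, 200),
                          background_fraction=1.0)
        a, _ = simulate_fragments(genome, empty_sites(), uniform_spec(), uniform_spec(),
                                  spec, np.random.default_rng(11))
        b, _ = simulate_fragments(genome, empty_sites(), uniform_spec(), uniform_spec(),
                                  spec, np.random.default_rng(11))
        np.testing.assert_array_equal(a.spans("chr1"), b.spans("chr1"))


class TestAlignmentRoundTrip:
    def test_bam_write_read_preserves_spans(self, tmp_path):
        genome = simulate_genome(SyntheticGenomeSpec({"chr1": 30_000}),
                                 np.random.default_rng(12))
        spec = SampleSpec(n_fragments=2000, length_support=(100, 200),
                          background_fraction=1.0)
        frags, _ = simulate_fragments(genome, empty_sites(), uniform_spec(),
                                      uniform_spec(), spec, np.random.default_rng(13))
        path = frags.to_bam(tmp_path / "s.bam", genome.lengths)
        back = FragmentTable.from_bam(path, QualityRules())
        a = frags.spans("chr1")
        b = back.spans("chr1")
        np.testing.assert_array_equal(
            a[np.lexsort((a[:, 1], a[:, 0]))], b[np.lexsort((b[:, 1], b[:, 0]))]
        )

    def test_short_fragments_yield_overlapping_mates(self, tmp_path):
        import pysam

        frags = FragmentTable({"chr1": np.array([[100, 240]])})  # 140 bp < 2 x 100
        path = frags.to_bam(tmp_path / "o.bam", {"chr1": 1000})
        with pysam.AlignmentFile(path, "rb") as bam:
            reads = list(bam.fetch("chr1"))
        assert len(reads) == 2
        r1, r2 = sorted(reads, key=lambda r: r.is_read2)
        assert r1.reference_start < r2.reference_end
        assert r2.reference_start < r1.reference_end  # mates overlap
        assert all(r.is_proper_pair and r.mapping_quality == 60 for r in reads)


class TestExpectedComposite:
    def test_zero_tumor_fraction_equals_background_profile(self):
        from nucleoprof import expected_composite

        backgr = SiteAccessibilitySpec(dip_depth=0.3, phasing_amplitude=0.1)
        tumor = SiteAccessibilitySpec(dip_depth=0.9, phasing_amplitude=0.3)
        prof_mix, _ = expected_composite(tumor, backgr, tumor_fraction=0.0)
        prof_bg, _ = expected_composite(backgr, backgr, tumor_fraction=1.0)
        np.testing.assert_allclose(prof_mix.values, prof_bg.values, atol=1e-12)

    def test_profile_normalization_invariant(self):
        from nucleoprof import expected_composite
        from nucleoprof.profiling import bin_centers

        spec = SiteAccessibilitySpec(dip_depth=0.5, phasing_amplitude=0.2)
        prof, _ = expected_composite(spec, spec, 1.0)
        assert prof.state == "trimmed"
        assert len(prof.values) == 133


class TestEndToEndRecovery:
    def test_pipeline_reproduces_expected_composite(self):
        """Full pipeline on a simulated sample matches the closed-form
        profile within Monte-Carlo error."""
        from nucleoprof import (
            composite_profile,
            profile_site_list,
            smooth_and_normalize,
        )
        from nucleoprof.experiments import _whole_genome_regions, build_site_world

        genome, sites, valid, _ = build_site_world(20, n_sites=600, site_gc=None,
                                                   need_freqs=False)
        acc = SiteAccessibilitySpec(dip_depth=0.5, phasing_amplitude=0.2)
        spec = SampleSpec(tumor_fraction=1.0, n_fragments=1_200_000,
                          length_support=(100, 200), length_mean=160.0,
                          length_sd=20.0, background_fraction=0.15)
        frags, truth = simulate_fragments(genome, sites, acc, acc, spec,
                                          np.random.default_rng(21))
        sp = profile_site_list(frags, sites, genome, valid, length_range=(100, 200))
        observed = smooth_and_normalize(composite_profile(sp))
        expected = truth.expected_composite()
        assert np.abs(observed.values - expected.values).max() < 0.05
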