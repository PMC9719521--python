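# nucleoprof

Nucleosome profiling of cell-free DNA (cfDNA) with fragment-length-aware
GC-bias correction.

## The problem

Plasma cfDNA is released mostly by dying blood cells, and a fraction of it
by tumor cells in cancer patients.  Because cfDNA is protected by
nucleosomes, the genomic positions of fragment midpoints trace chromatin
structure: around a transcription-factor binding site (TFBS) that is active
in the contributing tissue, coverage shows a central protection dip and
flanking peaks with ~190 bp spacing.  Averaged over tens of thousands of a
factor's sites, this *composite profile* is measurable even at ultra-low-pass
whole-genome sequencing (~0.1×), making chromatin accessibility a practical
liquid-biopsy readout for cancer detection and tumor subtyping.

The confounder is GC bias: library preparation over- or under-represents
fragments as a joint function of fragment length and GC content, differently
in every sample, and regulatory regions are GC-rich — so uncorrected
profiles mix biology with artifact.

## The method

1. **GC-bias model** (Benjamini–Speed fragment-length position model).
   For each fragment length *L*, the observed count of sample fragments
   with GC count *g* is divided by the number of admissible genomic
   *L*-mers with that GC count ("genome GC frequencies", computed over
   uniquely mappable, non-excluded regions):

   `bias(L, g) = count_sample(L, g) / freq_genome(L, g)`, normalized to
   mean 1 per length, then smoothed by pooling lengths within ±10 bp,
   sorting by GC fraction, and taking the median of k nearest neighbours
   (k = max(50, 5% of the pooled vector)).

2. **Composite profiles.**  Fragments of 100–200 bp around each site are
   weighted `1/bias(L, g)`; weighted midpoints are summed in 15 bp bins
   over ±5 kb, unreliable bins (unmappable, excluded, or >10 SD above the
   mean) are masked, sites are averaged, and the composite is smoothed with
   a Savitzky–Golay filter (165 bp window, order 3), normalized to mean 1,
   and trimmed to ±1 kb.

3. **Three features** per (sample × site list): *central coverage* (mean
   within ±30 bp), *mean coverage* (±1 kb), and *amplitude* (modulus of DFT
   term 10 over the 128 bins in ±960 bp — the ~190 bp nucleosome period).

4. **Classification.**  Ridge-penalized logistic regression over the
   feature matrix, evaluated by bootstrap: resample samples (or patients,
   so biological replicates never straddle the split) with replacement,
   standardize and optionally PCA-reduce (80% variance) on the training
   resample only, select C by 10-fold CV, score out-of-bag samples, repeat.

A fully synthetic cohort simulator (genome, site lists, nucleosome-phased
fragment midpoints, injected GC bias, tumor-fraction mixing) provides
ground truth for every stage.

## Worked example

```python
import numpy as np
from nucleoprof import (SampleSpec, SiteAccessibilitySpec, SyntheticGenomeSpec,
                        simulate_genome, simulate_site_list, simulate_fragments,
                        RegionSet, compute_genome_gc_frequencies, estimate_gc_bias,
                        profile_site_list, composite_profile, smooth_and_normalize,
                        profile_features)
from nucleoprof.simulate import InjectedGCBias

rng = np.random.default_rng(1)
lengths = {"chr1": 2_600_000}
sites = simulate_site_list(lengths, 200, rng)
genome = simulate_genome(SyntheticGenomeSpec(lengths, site_gc=0.65), rng, sites=sites)
valid = RegionSet({"chr1": np.array([[0, 2_600_000]])})

spec = SampleSpec(tumor_fraction=0.3, n_fragments=400_000, length_support=(100, 200),
                  gc_bias=InjectedGCBias(strength=1.0), background_fraction=0.15)
tumor = SiteAccessibilitySpec(dip_depth=0.6, phasing_amplitude=0.2)
blood = SiteAccessibilitySpec(dip_depth=0.1, phasing_amplitude=0.2)
frags, truth = simulate_fragments(genome, sites, tumor, blood, spec, rng)

freqs = compute_genome_gc_frequencies(genome, valid, (100, 200))
model = estimate_gc_bias(frags, genome, valid, freqs)
prof = smooth_and_normalize(composite_profile(
    profile_site_list(frags, sites, genome, valid, gc_model=model)))
f = profile_features(prof)
print(f"central={f.central_coverage:.3f} mean={f.mean_coverage:.3f} "
      f"amplitude={f.amplitude:.3f}")
```

Output:

```
central=0.935 mean=0.979 amplitude=6.255
```

The central coverage sits below 1 (the site set is partially open in this
30%-tumor-fraction sample), mean coverage is near the normalization
target, and the amplitude term reflects the simulated nucleosome phasing.
Re-running the same profile with `gc_model=None` prints
`central=1.164`: the sample's GC bias inflates coverage at the GC-enriched
site centers by ~23% — exactly the artifact the correction removes.

There is also a CLI mirroring the library stages:

```bash
nucleoprof simulate --out demo --n-sites 200 --n-fragments 100000 --seed 1
nucleoprof gc-bias --alignments demo/sample.bam --genome demo/genome.fa \
    --valid-regions demo/valid_regions.bed --out demo/gc_bias.tsv --length-range 100 200
nucleoprof profile --alignments demo/sample.bam --gc-bias demo/gc_bias.tsv \
    --sites demo/sites.tsv --genome demo/genome.fa \
    --valid-regions demo/valid_regions.bed --out demo/profile.tsv
nucleoprof features --profiles demo/profile.tsv --out demo/features.tsv
```

## Layout

- `src/nucleoprof/regions.py` — valid-region masks, genome GC frequencies
- `src/nucleoprof/gcbias.py` — fragment-length GC-bias estimation/weights
- `src/nucleoprof/sites.py` — site-list selection, overlap filters, GC profiling
- `src/nucleoprof/profiling.py` — composite midpoint-coverage profiles
- `src/nucleoprof/features.py` — central/mean coverage and FFT amplitude
- `src/nucleoprof/stats.py` — correlation/RMSE, BH-FDR, Wilcoxon, MAD, ANCOVA
- `src/nucleoprof/classify.py` — bootstrap ridge logistic regression + PCA
- `src/nucleoprof/simulate.py` — synthetic cohort generator
- `src/nucleoprof/experiments.py` — simulation-backed property studies
- `docs/methods.md` — model, parameters, numerical conventions, limitations
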