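# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `nucleoprof`.  It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and admissibility conventions

All coordinates are 0-based, half-open; conversions happen only at file
I/O.  An L-mer (and, symmetrically, a sample fragment span) is *admissible*
when it is fully contained in a single valid interval and contains no
ambiguous base.  Full containment — rather than any-overlap — was chosen so
genome frequencies and sample counts share one admissibility rule; it is
the denominators and numerators agreeing, not the specific rule, that makes
the bias ratio meaningful.  Fragments with ambiguous reference bases have
undefined GC and are excluded on both sides.

## GC-bias model

The observed fragment count per (length L, GC count g) cell is divided by
the number of admissible genomic L-mers with that GC count, then
normalized to mean 1 per length over *observed* cells (cells never seen in
the genome are missing, not zero).  GC is always computed from the
reference sequence under the fragment span, so sequencing errors do not
perturb the model.

**Smoothing.**  For each L, observed bias values at lengths within ±10 bp
are pooled and sorted by GC *fraction* g/L (fractions are comparable
across lengths; sorting by absolute GC count would interleave unlike
cells).  Each of L's own entries is replaced by the median of its
k = max(50, 5% of the pooled vector length) nearest neighbours.
"Nearest" is measured in rank space — a contiguous window of k elements
around the entry, clipped at the vector ends — rather than in GC-fraction
value space; the two agree wherever cells are dense and the rank-space
form is exactly vectorizable.  Each length's curve is then re-normalized
to mean 1.  After smoothing, |mean − 1| < 1e-6 per length is an enforced
invariant.

**Weights.**  A fragment's correction weight is 1/bias.  Cells with
missing or zero bias yield weight 0: the fragment is excluded from
profiles and counted in a diagnostic, rather than silently given weight 1.

**Single-length variant.**  For comparison, a model that treats every read
as a 165 bp pseudo-fragment extending from its 5' end (forward reads
[start, start+165), reverse reads [end−165, end)); lookups map any
fragment to the closest 165 bp GC content.  It exists to quantify what the
multi-length model adds, not for production use.

## Composite profiles

- **Bin grid (frozen):** 666 bins of 15 bp; bin i spans
  [−5000+15i, −4985+15i) relative to the site center, so offset 0 falls in
  bin 333.  The grid phase is a free convention; freezing it keeps every
  windowed feature consistent.
- **Fragment admission:** length in [100, 200] bp by default (alternative
  ranges are parameters), midpoint = floor((start+end−1)/2) inside the
  grid.  Midpoint-on-grid admission means each fragment contributes to
  exactly one bin.
- **Masking:** a bin is masked when not fully contained in the valid
  regions, or when its raw count exceeds mean + 10 SD.  The outlier
  statistic is pooled over all bins of all sites of the site list within
  the sample; the pooling scope is a design choice — per-site statistics
  would be too noisy at ultra-low pass.
- **Compositing:** per-bin mean over sites ignoring masked bins; a bin
  masked at every site stays masked.
- **Smoothing/normalization/trim:** Savitzky–Golay, 165 bp window
  (11 bins), polynomial order 3, `mode="interp"` (so polynomials of degree
  ≤3 are reproduced exactly, including at the edges); masked bins are
  linearly interpolated before filtering but remain masked afterwards.
  Normalization divides by the mean over unmasked bins of the full ±5 kb
  window; trimming keeps the 133 bins whose centers lie within ±1000 bp
  (edge bins are grid-phase dependent; the center rule is unambiguous).
- **Optional corrections:** per-fragment mappability weighting (per-5 Mb
  segment bias per mappability value, pooled and lowess-smoothed,
  span 2/3 — the span is a free choice, exposed as a parameter) and local
  copy-number correction (divide each site's profile by its mean coverage
  in ±50 kb).  Both are off by default; in development they did not change
  the synthetic-study outcomes, mirroring their role as diagnostics.

## Features

- *Central coverage*: mean over unmasked bins with centers within ±30 bp
  (4 bins under the frozen grid).
- *Mean coverage*: same over ±1000 bp (the whole trimmed profile).
- *Amplitude*: modulus of term 10 of the unnormalized forward DFT of the
  128 bins whose start offsets lie in [−960, +960).  Term 10 of a 128-bin
  (1920 bp) window corresponds to a 192 bp period — the closest DFT bin to
  the ~190 bp nucleosome spacing at an active site.  Indexing from 0 is
  the only reading consistent with that rationale, and the unnormalized
  convention is frozen because the amplitude scales with it (a flat unit
  profile has amplitude 0; a cosine of amplitude A at term k has amplitude
  N·A/2 = 32 for A = 0.5, N = 128).

Features are computed on the smoothed, normalized, trimmed profile.

## Cohort statistics

Feature–tumor-fraction relationships are summarized by an ordinary
least-squares line (Pearson r, two-sided p via the t transform, RMSE of
the fit's residuals).  p-values are BH-adjusted per feature type across
site lists.  Paired before/after comparisons use the two-sided Wilcoxon
signed-rank test: zero differences dropped, exact null for n ≤ 25 without
ties, normal approximation with continuity correction otherwise.  "MAD" is
the **mean** absolute deviation about the **mean** — the centering
statistic is a convention choice, exposed nowhere else, and documented
here because both mean- and median-centered readings exist in the field.
Differential accessibility between phenotype groups is tested by ANCOVA:
OLS of the feature on group + tumor fraction, Type II F-test for the group
term, no interaction.

## Classifier

Ridge (L2) logistic regression with balanced class weights.  Features are
standardized to mean 0, population SD 1 (scikit-learn's convention);
zero-variance columns map to 0.  Per bootstrap iteration: resample with
replacement (at sample or patient granularity — under patient resampling
every sample of a drawn patient enters training with the patient's
multiplicity and undrawn patients form the test set), standardize and
optionally PCA-reduce (smallest component count reaching 80% explained
variance) on the training resample only, select C over
{1e−3, …, 1e2} by 10-fold stratified CV on AUC (the grid is a free choice;
ties break toward stronger regularization), fit, score out-of-bag.
Iterations drawing a single-class training set are redrawn and counted.
Metrics can be restricted to each patient's first timepoint so multi-sample
patients do not dominate.  One master seed spawns independent per-iteration
substreams, so any iteration is reproducible in isolation.  The final model
for external validation re-fits on the full cohort with the modal bootstrap
C (ties toward smaller C); validation CIs come from resampling the
validation cohort 1000 times.

## Synthetic cohort generator

The generator emulates the features of plasma WGS this pipeline is
sensitive to:

- **Midpoint density** around a site:
  λ(x) = 1 − a·exp(−x²/2σ²) + b·cos(2πx/T)·exp(−|x|/τ), with central dip
  depth a, dip width σ = 100 bp, phasing amplitude b, period T = 190 bp,
  phasing decay τ = 1000 bp by default.  Densities that would clip more
  than 1% of their mass at 0 are refused.  A sample mixes tumor and
  background states as tf·λ_tumor + (1−tf)·λ_background, plus a uniform
  off-site floor.
- **Fragment lengths**: truncated normal peaked at 167 bp (SD 25) with a
  10% uniform component, support 35–500 bp by default.  Studies that
  estimate GC bias restrict the support to the profiled 100–200 bp range
  so the bias model covers exactly the lengths being corrected.
- **GC structure**: background GC 0.41 (genome-like); optionally
  GC-enriched intervals (default ±150 bp) at site centers, emulating the
  elevated GC of regulatory regions that makes GC bias a confounder of
  accessibility in the first place.
- **Injected bias**: w(L, gf) = exp(β(gf−0.5) + γ(gf−0.5)(L−150)/50) —
  monotone in GC fraction with a mild length interaction; candidates are
  accepted with probability w/max(w), which is exactly the generative
  process the estimation pipeline inverts.
- **Alignments**: fragments can be written as coordinate-sorted, indexed
  BAM of proper FR pairs, mapping quality 60, read length 100 bp (mates of
  sub-200 bp fragments overlap, deliberately).

What the simulator does **not** model: sequencing errors and base
qualities, mapping ambiguity (every synthetic position is perfectly
mappable unless a mask says otherwise), duplicate fragments, chromosome-
scale copy-number structure, and the correlated site-to-site biology of
real TF programs.  Passing tests therefore demonstrate that the machinery
recovers what it is designed to recover under its own generative
assumptions — not clinical performance on real cohorts, which are
controlled-access and out of scope.

## Problem sizes of the property studies

Study sizes are the package's own choices, set from an a-priori
Monte-Carlo noise budget so sampling error sits well inside each
tolerance:

- *Bias recovery*: 200k fragments, 30 kb genome, lengths 140–170 (31
  per-length curves).  The cell-occupancy requirement drives the genome
  size: a (L, g) cell at the ≥500-genome-occurrence threshold must expect
  several fragments, or a median smoother sits on zeros.
- *Correction efficacy*: 2000 sites, ~20× in-window coverage per sample
  (~3.1M fragments) — per-composite-bin counting noise ~1% after
  smoothing, giving a max-abs band comfortably below 0.05.
- *RMSE reduction*: 40 samples × 20 interleaved site lists of 100 sites,
  ~5× in-window coverage, tumor fractions 0.1–0.5, bias strengths β ∈
  [−1.5, 1.5].
- *Tumor-fraction sweep*: 6 points, 2000 sites, ~12× in-window coverage,
  no injected bias (isolating the accessibility signal).
- *Classifier sanity*: 80 patients (~30% with a replicate sample), 12
  features, 100 bootstrap iterations.  The cohort is sized so one fixed
  random label permutation has negligible chance separability; at a few
  dozen patients the true AUC of a permuted labelling deviates
  appreciably from 1/2.

## Degenerate inputs and tie-breaks

- Site ranking ties break by (chromosome lexical, position ascending);
  duplicate (chrom, position) sites collapse keeping the maximum score.
- "Within 500 bp / ±250 bp" overlap distances are inclusive (≤) and
  configurable.
- Strand is ignored throughout (meta-cluster site lists carry none).
- An all-masked composite, a profile with a non-positive mean, all-zero
  paired differences, and a config whose window cannot hold one bin all
  raise immediately with specific messages rather than propagating NaNs.
- External TF-identity filtering is consumed as an allow-list input; this
  package does not query catalog databases.
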