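"""Simulation-backed property studies.

Each function builds a synthetic world (genome, sites, samples) from an
explicit seed, runs the relevant pipeline stages end to end, and returns
the measured quantities.  These studies are the package's substitute for
controlled-access cohorts: they verify that the machinery behaves the way
the method is designed to — bias surfaces are recovered, correction makes
biased samples agree, correction tightens feature/tumor-fraction fits,
classification behaves sanely, and the central-coverage feature tracks
tumor fraction linearly.

Problem sizes default to desk scale (a few-minute budget per study on one
core); they were chosen from an a-priori Monte-Carlo noise budget so that
sampling error sits well inside each property's tolerance.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import BootstrapConfig, bootstrap_train_eval
from .features import FeatureMatrix, central_coverage, fft_amplitude, profile_features
from .gcbias import estimate_gc_bias
from .profiling import (
    CompositeProfile,
    SiteProfiles,
    bin_centers,
    composite_profile,
    profile_site_list,
    smooth_and_normalize,
)
from .regions import RegionSet, compute_genome_gc_frequencies
from .simulate import (
    InjectedGCBias,
    SampleSpec,
    SiteAccessibilitySpec,
    SyntheticGenomeSpec,
    simulate_fragments,
    simulate_genome,
    simulate_site_list,
)
from .sites import SiteList
from .stats import compare_correction_modes


def _whole_genome_regions(genome) -> RegionSet:
    return RegionSet({c: np.array([[0, n]]) for c, n in genome.lengths.items()})


# --------------------------------------------------------------------------
# 1. GC-bias parameter recovery
# --------------------------------------------------------------------------
def bias_recovery_study(
    seed: int,
    n_fragments: int = 200_000,
    genome_length: int = 30_000,
    length_range: Tuple[int, int] = (140, 170),
    min_genome_occurrences: int = 500,
) -> Dict:
    """Inject a known bias surface, re-estimate it, and measure the error.

    Fragments are drawn uniformly over a homogeneous synthetic genome and
    accepted with probability proportional to the injected w(L, GC); the
    smoothed estimate is compared to the mean-1-normalized truth at every
    (L, g) cell with at least ``min_genome_occurrences`` admissible L-mers.
    """
    rng = np.random.default_rng(seed)
    spec = SyntheticGenomeSpec({"chr1": genome_length // 2, "chr2": genome_length // 2},
                               background_gc=0.45)
    genome = simulate_genome(spec, rng)
    valid = _whole_genome_regions(genome)
    freqs = compute_genome_gc_frequencies(genome, valid, length_range)
    bias = InjectedGCBias(strength=0.8, length_coupling=0.3)
    sample = SampleSpec(
        n_fragments=n_fragments,
        length_support=length_range,
        length_uniform_mix=0.25,
        gc_bias=bias,
        background_fraction=1.0,
    )
    empty_sites = SiteList("none", np.array([], object), np.array([], int), np.array([], float))
    acc = SiteAccessibilitySpec(dip_depth=0.0, phasing_amplitude=0.0)
    frags, _ = simulate_fragments(genome, empty_sites, acc, acc, sample, rng)
    model = estimate_gc_bias(frags, genome, valid, freqs, length_range)
    truth = bias.normalized_truth(freqs)
    errs = []
    n_cells = 0
    for L in model.lengths:
        freq = freqs.counts[L]
        cell = (freq >= min_genome_occurrences) & np.isfinite(model.smoothed[L]) & np.isfinite(truth[L])
        if cell.any():
            errs.append(np.abs(model.smoothed[L][cell] - truth[L][cell]).max())
            n_cells += int(cell.sum())
    return {
        "max_abs_error": float(np.max(errs)),
        "n_cells": n_cells,
        "n_fragments": len(frags),
        "model": model,
        "truth": truth,
    }


# --------------------------------------------------------------------------
# Shared site-cohort world
# --------------------------------------------------------------------------
def build_site_world(
    seed: int,
    n_sites: int = 2000,
    site_spacing: int = 12_000,
    site_gc: Optional[float] = 0.65,
    background_gc: float = 0.45,
    need_freqs: bool = True,
    length_range: Tuple[int, int] = (100, 200),
):
    """Genome + site list (+ GC frequencies) shared by the profile studies."""
    rng = np.random.default_rng(seed)
    margin = 6_000
    clen = n_sites * site_spacing + int(0.05 * n_sites * site_spacing) + 2 * margin
    lengths = {"chr1": clen}
    sites = simulate_site_list(lengths, n_sites, rng, min_spacing=site_spacing, margin=margin)
    spec = SyntheticGenomeSpec(lengths, background_gc=background_gc, site_gc=site_gc)
    genome = simulate_genome(spec, rng, sites=sites)
    valid = _whole_genome_regions(genome)
    freqs = compute_genome_gc_frequencies(genome, valid, length_range) if need_freqs else None
    return genome, sites, valid, freqs


def _coverage_to_fragments(n_sites: int, coverage: float, mean_length: float = 150.0,
                           window: int = 5000, background_fraction: float = 0.15) -> int:
    in_window = n_sites * 2 * window * coverage / mean_length
    return int(in_window / (1 - background_fraction))


# --------------------------------------------------------------------------
# 2. Correction efficacy
# --------------------------------------------------------------------------
def correction_efficacy_study(
    seed: int,
    n_sites: int = 2000,
    coverage: float = 20.0,
    bias_strengths: Tuple[float, float] = (1.5, -1.5),
) -> Dict:
    """Two samples, identical nucleosome signal, opposite GC-bias curves.

    Measures the max-abs difference between the two trimmed composite
    profiles with and without GC correction.  Site centers are GC-enriched
    so uncorrected bias shows up as a center-specific coverage distortion.
    """
    genome, sites, valid, freqs = build_site_world(seed, n_sites)
    acc = SiteAccessibilitySpec(dip_depth=0.4, phasing_amplitude=0.15)
    length_range = (100, 200)
    n_frag = _coverage_to_fragments(n_sites, coverage)
    profiles = {"corrected": [], "uncorrected": []}
    for i, strength in enumerate(bias_strengths):
        rng = np.random.default_rng(seed + 1000 + i)
        sample = SampleSpec(
            n_fragments=n_frag,
            length_support=length_range,
            length_mean=160.0,
            length_sd=20.0,
            gc_bias=InjectedGCBias(strength=strength, length_coupling=0.3 * np.sign(strength)),
            background_fraction=0.15,
        )
        frags, _ = simulate_fragments(genome, sites, acc, acc, sample, rng)
        model = estimate_gc_bias(frags, genome, valid, freqs, length_range)
        for mode, m in (("corrected", model), ("uncorrected", None)):
            sp = profile_site_list(frags, sites, genome, valid, gc_model=m,
                                   length_range=length_range)
            profiles[mode].append(smooth_and_normalize(composite_profile(sp)))
    out = {}
    for mode in profiles:
        a, b = profiles[mode]
        out[f"{mode}_max_abs_diff"] = float(np.abs(a.values - b.values).max())
    out["profiles"] = profiles
    out["n_fragments_per_sample"] = n_frag
    return out


# --------------------------------------------------------------------------
# 6. RMSE reduction across a heterogeneous cohort
# --------------------------------------------------------------------------
def rmse_reduction_study(
    seed: int,
    n_samples: int = 40,
    n_site_lists: int = 20,
    sites_per_list: int = 100,
    coverage: float = 5.0,
    tumor_fraction_range: Tuple[float, float] = (0.1, 0.5),
) -> Dict:
    """Does GC correction tighten the central-coverage / tumor-fraction fit?

    Samples carry heterogeneous bias curves and tumor fractions; for each
    site list the linear-fit RMSE of central coverage on tumor fraction is
    compared before vs after correction.
    """
    n_sites = n_site_lists * sites_per_list
    genome, sites, valid, freqs = build_site_world(seed, n_sites)
    # deal sites round-robin into lists so lists are spatially interleaved;
    # site positions are ascending, so list j owns rows j, j+n_lists, ...
    list_ids = np.arange(n_sites) % n_site_lists
    tumor = SiteAccessibilitySpec(dip_depth=0.6, phasing_amplitude=0.15)
    backgr = SiteAccessibilitySpec(dip_depth=0.1, phasing_amplitude=0.15)
    length_range = (100, 200)
    n_frag = _coverage_to_fragments(n_sites, coverage)
    master = np.random.default_rng(seed)
    tfs = master.uniform(*tumor_fraction_range, size=n_samples)
    strengths = master.uniform(-1.5, 1.5, size=n_samples)
    couplings = master.uniform(-0.3, 0.3, size=n_samples)
    before = np.zeros((n_samples, n_site_lists))
    after = np.zeros((n_samples, n_site_lists))
    for i in range(n_samples):
        rng = np.random.default_rng(seed + 5000 + i)
        sample = SampleSpec(
            tumor_fraction=float(tfs[i]),
            n_fragments=n_frag,
            length_support=length_range,
            length_mean=160.0,
            length_sd=20.0,
            gc_bias=InjectedGCBias(float(strengths[i]), float(couplings[i])),
            background_fraction=0.15,
        )
        frags, _ = simulate_fragments(genome, sites, tumor, backgr, sample, rng)
        model = estimate_gc_bias(frags, genome, valid, freqs, length_range)
        for mat, m in ((after, model), (before, None)):
            sp = profile_site_list(frags, sites, genome, valid, gc_model=m,
                                   length_range=length_range)
            assert len(sp.counts) == n_sites  # margin > window: no skipped sites
            for j in range(n_site_lists):
                rows = list_ids == j
                sub = SiteProfiles(sp.counts[rows], sp.mask[rows], f"list{j:02d}")
                mat[i, j] = central_coverage(smooth_and_normalize(composite_profile(sub)))
    cols = [f"list{j:02d}" for j in range(n_site_lists)]
    comparison = compare_correction_modes(
        pd.DataFrame(before, columns=cols), pd.DataFrame(after, columns=cols), tfs
    )
    comparison["tumor_fractions"] = tfs
    comparison["n_fragments_per_sample"] = n_frag
    return comparison


# --------------------------------------------------------------------------
# 7. Classifier sanity
# --------------------------------------------------------------------------
def synthetic_feature_cohort(
    seed: int,
    n_patients: int = 40,
    n_features: int = 12,
    effect: float = 2.5,
    replicate_fraction: float = 0.3,
) -> FeatureMatrix:
    """Feature-level synthetic cohort: two classes separated on a few axes.

    Some patients contribute two samples (biological replicates sharing the
    patient's class and a patient-level random effect), exercising the
    patient-aware bootstrap.
    """
    rng = np.random.default_rng(seed)
    rows, meta = [], []
    for p in range(n_patients):
        label = "pos" if p % 2 == 0 else "neg"
        base = rng.normal(0, 1, n_features)
        if label == "pos":
            base[:4] += effect
        n_rep = 2 if rng.random() < replicate_fraction else 1
        for t in range(n_rep):
            rows.append(base + rng.normal(0, 0.5, n_features))
            meta.append((f"P{p:03d}_t{t}", label, 0.2, f"P{p:03d}", t))
    X = pd.DataFrame(rows, index=[m[0] for m in meta],
                     columns=[f"f{i:02d}" for i in range(n_features)])
    metadata = pd.DataFrame(
        meta, columns=["sample", "label", "tumor_fraction", "patient_id", "timepoint"]
    ).set_index("sample")
    return FeatureMatrix(X, metadata)


def classifier_sanity_study(seed: int, n_iterations: int = 100, n_patients: int = 80) -> Dict:
    """Bootstrap AUC on a separable cohort and on permuted labels.

    The cohort is sized so that a fixed random label permutation has
    negligible chance separability — at small n the true AUC of one
    permutation draw deviates appreciably from 1/2.
    """
    fm = synthetic_feature_cohort(seed, n_patients=n_patients)
    config = BootstrapConfig(
        n_iterations=n_iterations, seed=seed, pca_variance_target=0.80,
        resample_unit="patient", first_timepoint_only=True,
    )
    res = bootstrap_train_eval(fm, config)
    # permute labels at the patient level (replicates keep a common label)
    rng = np.random.default_rng(seed + 1)
    patients = fm.metadata["patient_id"].unique()
    perm = dict(zip(patients, rng.permutation(
        [fm.metadata[fm.metadata["patient_id"] == p]["label"].iloc[0] for p in patients]
    )))
    meta_perm = fm.metadata.copy()
    meta_perm["label"] = [perm[p] for p in meta_perm["patient_id"]]
    fm_perm = FeatureMatrix(fm.X, meta_perm)
    res_perm = bootstrap_train_eval(fm_perm, config)
    return {
        "separable_mean_auc": float(np.nanmean(res.auc)),
        "permuted_mean_auc": float(np.nanmean(res_perm.auc)),
        "n_iterations": n_iterations,
        "result": res,
    }


# --------------------------------------------------------------------------
# 8. Tumor-fraction sweep
# --------------------------------------------------------------------------
def tumor_fraction_sweep_study(
    seed: int,
    tumor_fractions: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    n_sites: int = 2000,
    coverage: float = 12.0,
) -> Dict:
    """Central coverage at tumor-open sites across a tumor-fraction sweep.

    No GC bias is injected, isolating the accessibility signal: coverage
    should fall strictly and linearly as tumor fraction rises.
    """
    genome, sites, valid, _ = build_site_world(seed, n_sites, site_gc=None, need_freqs=False)
    tumor = SiteAccessibilitySpec(dip_depth=0.6, phasing_amplitude=0.15)
    backgr = SiteAccessibilitySpec(dip_depth=0.0, phasing_amplitude=0.15)
    length_range = (100, 200)
    n_frag = _coverage_to_fragments(n_sites, coverage)
    ccs = []
    for i, tf in enumerate(tumor_fractions):
        rng = np.random.default_rng(seed + 9000 + i)
        sample = SampleSpec(
            tumor_fraction=float(tf), n_fragments=n_frag, length_support=length_range,
            length_mean=160.0, length_sd=20.0, background_fraction=0.15,
        )
        frags, _ = simulate_fragments(genome, sites, tumor, backgr, sample, rng)
        sp = profile_site_list(frags, sites, genome, valid, gc_model=None,
                               length_range=length_range)
        ccs.append(central_coverage(smooth_and_normalize(composite_profile(sp))))
    ccs = np.array(ccs)
    tfs = np.asarray(tumor_fractions, dtype=float)
    fit = sps.linregress(tfs, ccs)
    return {
        "tumor_fractions": tfs,
        "central_coverages": ccs,
        "strictly_decreasing": bool(np.all(np.diff(ccs) < 0)),
        "r_squared": float(fit.rvalue**2),
        "slope": float(fit.slope),
        "n_fragments_per_sample": n_frag,
    }


# --------------------------------------------------------------------------
# 3. Feature closed forms
# --------------------------------------------------------------------------
def feature_closed_forms() -> Dict:
    """Flat-profile features and the 10-cycle cosine FFT amplitude."""
    offsets = bin_centers()
    keep = np.abs(offsets) <= 1000
    flat = CompositeProfile(offsets[keep], np.ones(keep.sum()),
                            np.zeros(keep.sum(), dtype=bool), state="trimmed")
    flat_feats = profile_features(flat)
    starts = flat.offsets - 7.5
    fft_sel = (starts >= -960) & (starts < 960)
    j = np.arange(int(fft_sel.sum()))
    values = np.ones(keep.sum())
    values[fft_sel] = 1 + 0.5 * np.cos(2 * np.pi * 10 * j / 128)
    cosine = CompositeProfile(flat.offsets, values, flat.mask.copy(), state="trimmed")
    return {
        "flat_central": flat_feats.central_coverage,
        "flat_mean": flat_feats.mean_coverage,
        "flat_amplitude": flat_feats.amplitude,
        "cosine_amplitude": fft_amplitude(cosine),
    }
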