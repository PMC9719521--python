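"""GC-corrected composite midpoint-coverage profiles around site lists.

Organized nucleosomes around an accessible site leave a characteristic
footprint in cfDNA: a dip in fragment-midpoint coverage at the site center
and flanking peaks with ~190 bp spacing.  This module turns a fragment
table plus a site list into that composite signal: weighted midpoints are
summed in 15 bp bins over a ±5 kb window per site, unreliable bins are
masked, sites are averaged, and the mean profile is Savitzky-Golay
smoothed, normalized to mean 1, and trimmed to ±1 kb.

Bin grid convention (frozen): 666 bins of 15 bp, bin i spanning
[-5000 + 15*i, -4985 + 15*i) relative to the site center, so offset 0 falls
in bin 333.  All windowed features downstream use this grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.signal import savgol_filter

from .fragments import FragmentTable
from .gcbias import GCBiasModel
from .genome import ReferenceGenome
from .regions import MappabilityTrack, RegionSet
from .sites import SiteList

WINDOW = 5000
BIN_SIZE = 15
N_BINS = 2 * WINDOW // BIN_SIZE  # 666


def bin_centers(window: int = WINDOW, bin_size: int = BIN_SIZE) -> np.ndarray:
    starts = np.arange(-window, window - bin_size + 1, bin_size, dtype=np.float64)
    return starts + (bin_size - 1) / 2 + 0.5  # center of the half-open span


@dataclass
class SiteProfiles:
    """Per-site binned weighted midpoint counts with exclusion masks."""

    counts: np.ndarray  # (n_sites, N_BINS) float
    mask: np.ndarray  # (n_sites, N_BINS) bool, True = excluded
    site_list: str = ""
    n_sites_skipped: int = 0
    n_fragments_used: int = 0
    n_fragments_zero_weight: int = 0


@dataclass
class CompositeProfile:
    """Binned composite signal with offsets, mask and processing state."""

    offsets: np.ndarray  # bin center offsets (bp)
    values: np.ndarray
    mask: np.ndarray  # True = excluded
    state: str = "raw-mean"  # raw-mean | trimmed
    provenance: Dict = field(default_factory=dict)

    def unmasked(self) -> np.ndarray:
        return self.values[~self.mask]


def fragment_gc_weights(
    fragments: FragmentTable,
    genome: ReferenceGenome,
    gc_model: Optional[GCBiasModel],
) -> Dict[str, np.ndarray]:
    """1/bias weight per fragment, keyed by chromosome.

    Fragments whose span contains ambiguous bases, or whose (length, GC)
    cell is missing from the bias model, get weight 0 and are thereby
    excluded from profiles.
    """
    out: Dict[str, np.ndarray] = {}
    for chrom in fragments.chromosomes:
        spans = fragments.spans(chrom)
        if gc_model is None:
            out[chrom] = np.ones(len(spans))
            continue
        n = genome.lengths[chrom]
        w = np.zeros(len(spans))
        inside = (spans[:, 0] >= 0) & (spans[:, 1] <= n)
        sp = spans[inside]
        g = genome.gc_counts(chrom, sp[:, 0], sp[:, 1])
        amb = genome.contains_ambiguous(chrom, sp[:, 0], sp[:, 1])
        wi = gc_model.weights(sp[:, 1] - sp[:, 0], g)
        wi[amb] = 0.0
        w[inside] = wi
        out[chrom] = w
    return out


def profile_site_list(
    fragments: FragmentTable,
    sites: SiteList,
    genome: ReferenceGenome,
    valid: RegionSet,
    gc_model: Optional[GCBiasModel] = None,
    length_range: Tuple[int, int] = (100, 200),
    outlier_sd: float = 10.0,
    mappability_model: Optional["MappabilityBiasModel"] = None,
    mappability: Optional[MappabilityTrack] = None,
    cna_correction: bool = False,
    cna_halfwidth: int = 50_000,
    read_length: int = 100,
    window: int = WINDOW,
    bin_size: int = BIN_SIZE,
) -> SiteProfiles:
    """Bin weighted fragment midpoints around every site of a list.

    Fragments are admitted by length range and by midpoint-on-grid (each
    fragment lands in exactly one bin).  A bin is masked when it is not
    fully contained in the valid regions or when its raw count exceeds the
    pooled mean + ``outlier_sd`` standard deviations.  Sites whose window
    leaves the chromosome are skipped and counted.
    """
    n_bins = 2 * window // bin_size
    frag = fragments.subset_by_length(length_range)
    weights = fragment_gc_weights(frag, genome, gc_model)
    if mappability_model is not None:
        if mappability is None:
            raise ValueError("mappability track required for mappability correction")
        for chrom in frag.chromosomes:
            spans = frag.spans(chrom)
            m = _mean_read_mappability(mappability, chrom, spans, read_length)
            mw = mappability_model.weight(m)
            weights[chrom] = weights[chrom] * mw

    sites_by_chrom = sites.by_chrom()
    rows, masks = [], []
    skipped = 0
    used = 0
    zero_w = 0
    local_means = []
    for chrom, positions in sites_by_chrom.items():
        n = genome.lengths.get(chrom)
        if n is None:
            skipped += len(positions)
            continue
        spans = frag.spans(chrom)
        mids = (spans[:, 0] + spans[:, 1] - 1) // 2
        order = np.argsort(mids, kind="stable")
        mids = mids[order]
        w = weights.get(chrom, np.ones(0))[order]
        vcc = valid.containment_cumsum(chrom, n)
        for site in positions:
            lo_bp = site - window
            if lo_bp < 0 or site + window > n:
                skipped += 1
                continue
            lo = np.searchsorted(mids, lo_bp, side="left")
            hi = np.searchsorted(mids, lo_bp + n_bins * bin_size, side="left")
            bins = (mids[lo:hi] - lo_bp) // bin_size
            wi = w[lo:hi]
            row = np.bincount(bins, weights=wi, minlength=n_bins)
            used += int((wi > 0).sum())
            zero_w += int((wi == 0).sum())
            edges = lo_bp + np.arange(n_bins + 1, dtype=np.int64) * bin_size
            bin_valid = (vcc[edges[1:]] - vcc[edges[:-1]]) == bin_size
            mask = ~bin_valid
            if cna_correction:
                clo = np.searchsorted(mids, site - cna_halfwidth, side="left")
                chi = np.searchsorted(mids, site + cna_halfwidth, side="left")
                local = w[clo:chi].sum() / (2 * cna_halfwidth / bin_size)
                if local <= 0:
                    warnings.warn("zero local coverage in CNA window; site masked")
                    mask[:] = True
                else:
                    row = row / local
                    local_means.append(local)
            rows.append(row)
            masks.append(mask)
    counts = np.array(rows) if rows else np.empty((0, n_bins))
    mask = np.array(masks) if masks else np.empty((0, n_bins), dtype=bool)
    # outlier masking: statistic pooled over all unmasked bins of all sites
    if counts.size:
        vals = counts[~mask]
        if vals.size:
            cutoff = vals.mean() + outlier_sd * vals.std()
            mask |= counts > cutoff
    return SiteProfiles(
        counts, mask, sites.name, skipped, used, zero_w
    )


def composite_profile(profiles: SiteProfiles, window: int = WINDOW, bin_size: int = BIN_SIZE) -> CompositeProfile:
    """Mean over sites per bin, ignoring each site's excluded bins."""
    ok = ~profiles.mask
    denom = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(ok, profiles.counts, 0.0).sum(axis=0) / denom
    mask = denom == 0
    values[mask] = np.nan
    return CompositeProfile(
        bin_centers(window, bin_size),
        values,
        mask,
        state="raw-mean",
        provenance={"site_list": profiles.site_list, "n_sites": len(profiles.counts)},
    )


def smooth_and_normalize(
    composite: CompositeProfile,
    filter_bp: int = 165,
    polyorder: int = 3,
    bin_size: int = BIN_SIZE,
    trim_bp: int = 1000,
) -> CompositeProfile:
    """Savitzky-Golay smooth, normalize to mean 1, trim to the center.

    The filter window is ``filter_bp / bin_size`` bins (11 by default);
    masked bins are linearly interpolated before filtering but stay masked.
    Normalization divides by the mean over unmasked bins of the full
    window; trimming keeps bins whose centers lie within ±``trim_bp``.
    """
    if composite.mask.all():
        raise ValueError("empty profile: all bins masked")
    nbins = max(3, int(round(filter_bp / bin_size)))
    if nbins % 2 == 0:
        nbins += 1
    values = composite.values.astype(float).copy()
    if composite.mask.any():
        good = ~composite.mask
        values[composite.mask] = np.interp(
            composite.offsets[composite.mask], composite.offsets[good], values[good]
        )
    sm = savgol_filter(values, window_length=nbins, polyorder=polyorder, mode="interp")
    mean = sm[~composite.mask].mean()
    if mean <= 0:
        raise ValueError("profile mean is non-positive; cannot normalize")
    sm = sm / mean
    keep = np.abs(composite.offsets) <= trim_bp
    return CompositeProfile(
        composite.offsets[keep],
        sm[keep],
        composite.mask[keep],
        state="trimmed",
        provenance=dict(composite.provenance, smoothing=f"savgol:{filter_bp}bp,order{polyorder}"),
    )


def compute_composite_profile(
    fragments: FragmentTable,
    sites: SiteList,
    genome: ReferenceGenome,
    valid: RegionSet,
    gc_model: Optional[GCBiasModel] = None,
    **kwargs,
) -> CompositeProfile:
    """Full pipeline: per-site binning -> composite mean -> smooth/normalize/trim."""
    sp = profile_site_list(fragments, sites, genome, valid, gc_model, **kwargs)
    return smooth_and_normalize(composite_profile(sp))


# --------------------------------------------------------------------------
# Mappability bias (optional correction, off by default)
# --------------------------------------------------------------------------
@dataclass
class MappabilityBiasModel:
    """Smoothed relative coverage as a function of mappability value."""

    mappability: np.ndarray  # sorted distinct mappability values
    bias: np.ndarray  # locally-weighted-regression smoothed bias

    def weight(self, m: np.ndarray) -> np.ndarray:
        """1/bias at mappability m; undefined (NaN) m excludes the fragment."""
        m = np.asarray(m, dtype=float)
        b = np.interp(m, self.mappability, self.bias)
        w = np.zeros_like(b)
        ok = np.isfinite(m) & np.isfinite(b) & (b > 0)
        w[ok] = 1.0 / b[ok]
        return w


def _read_coverage_at(
    fragments: FragmentTable, chrom: str, positions: np.ndarray, chrom_len: int, read_length: int
) -> np.ndarray:
    """Number of reads overlapping each position (both mates per fragment)."""
    spans = fragments.spans(chrom)
    rl = np.minimum(read_length, spans[:, 1] - spans[:, 0])
    starts = np.concatenate([spans[:, 0], spans[:, 1] - rl])
    ends = np.concatenate([spans[:, 0] + rl, spans[:, 1]])
    diff = np.zeros(chrom_len + 1, dtype=np.int32)
    np.add.at(diff, np.clip(starts, 0, chrom_len), 1)
    np.add.at(diff, np.clip(ends, 0, chrom_len), -1)
    cov = np.cumsum(diff[:-1])
    return cov[positions]


def _mean_read_mappability(
    track: MappabilityTrack, chrom: str, spans: np.ndarray, read_length: int
) -> np.ndarray:
    out = np.empty(len(spans))
    for i, (s, e) in enumerate(spans):
        rl = min(read_length, e - s)
        vals = np.concatenate(
            [track.values(chrom, s, s + rl), track.values(chrom, e - rl, e)]
        )
        out[i] = np.nan if np.isnan(vals).any() else float(vals.mean())
    return out


def estimate_mappability_bias(
    fragments: FragmentTable,
    mappability: MappabilityTrack,
    chrom_lengths: Dict[str, int],
    valid: Optional[RegionSet] = None,
    segment: int = 5_000_000,
    stride: int = 100,
    outlier_sd: float = 5.0,
    read_length: int = 100,
    lowess_frac: float = 2 / 3,
) -> MappabilityBiasModel:
    """Per-segment read count per mappability value, pooled and smoothed.

    The genome is split into segments; within each, every ``stride``-th
    position outside excluded regions is sampled, positions with read
    counts more than ``outlier_sd`` SD above the mean are dropped, and
    bias(m) = total reads at positions with mappability m divided by the
    number of such positions.  Pooled (m, bias) pairs over all segments are
    smoothed with locally weighted regression.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    samples_m, samples_c = [], []
    for chrom, clen in chrom_lengths.items():
        pos = np.arange(0, clen, stride, dtype=np.int64)
        if valid is not None:
            keep = valid.coverage_mask(chrom, clen)[pos]
            pos = pos[keep]
        if not len(pos):
            continue
        m = np.array([mappability.value(chrom, int(p)) for p in pos])
        ok = np.isfinite(m)
        pos, m = pos[ok], m[ok]
        cov = _read_coverage_at(fragments, chrom, pos, clen, read_length)
        seg = pos // segment
        samples_m.append((m, cov, seg, chrom))
    if not samples_m:
        raise ValueError("no sampled positions for mappability bias")
    all_cov = np.concatenate([c for _, c, _, _ in samples_m]).astype(float)
    cutoff = all_cov.mean() + outlier_sd * all_cov.std()
    mean_cov = all_cov[all_cov <= cutoff].mean()
    pairs_m, pairs_b = [], []
    for m, cov, seg, _ in samples_m:
        keep = cov <= cutoff
        m, cov, seg = m[keep], cov[keep], seg[keep]
        for s in np.unique(seg):
            sel = seg == s
            for mv in np.unique(m[sel]):
                at = sel & (m == mv)
                pairs_m.append(mv)
                pairs_b.append(cov[at].sum() / at.sum() / mean_cov)
    pairs_m = np.array(pairs_m)
    pairs_b = np.array(pairs_b)
    if len(np.unique(pairs_m)) < 4:
        # too few distinct mappability values for a local regression:
        # aggregate the per-segment biases at each value instead
        xs = np.unique(pairs_m)
        ys = np.array([pairs_b[pairs_m == x].mean() for x in xs])
        return MappabilityBiasModel(xs, np.maximum(ys, 1e-12))
    sm = lowess(pairs_b, pairs_m, frac=lowess_frac, return_sorted=True)
    xs, ys = sm[:, 0], np.maximum(sm[:, 1], 1e-12)
    xs, idx = np.unique(xs, return_index=True)
    return MappabilityBiasModel(xs, ys[idx])


def mappability_fragment_weight(
    model: MappabilityBiasModel, mean_mappability: float, gc_weight: float = 1.0
) -> float:
    """Combined correction weight: (1/mappability bias) x GC weight."""
    return float(model.weight(np.array([mean_mappability]))[0] * gc_weight)
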