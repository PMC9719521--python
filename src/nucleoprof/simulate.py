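"""Synthetic cfDNA cohorts with known ground truth.

Real cfDNA cohorts for nucleosome profiling are controlled-access, so every
stage of this package is exercised on simulated data instead.  The
generator emulates the salient structure of plasma WGS around accessible
sites:

* fragment **midpoint density** around a site follows
  ``lambda(x) = 1 - a*exp(-x^2 / 2 sigma^2) + b*cos(2 pi x / T)*exp(-|x|/tau)``
  — a central protection dip of depth ``a`` and width ``sigma`` plus
  nucleosome phasing of amplitude ``b``, period ``T`` (190 bp) and decay
  length ``tau``;
* a sample mixes a tumor and a background accessibility state in
  proportion to its **tumor fraction**;
* fragment lengths follow a truncated-normal mixture peaked near 167 bp;
* per-sample **GC bias** is injected by accepting each candidate fragment
  with probability proportional to an arbitrary weight surface w(L, GC).

Everything is seeded explicitly; no global RNG state is touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .fragments import FragmentTable
from .genome import ReferenceGenome
from .profiling import BIN_SIZE, WINDOW, CompositeProfile, bin_centers, smooth_and_normalize
from .features import ProfileFeatures, profile_features
from .sites import SiteList

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticGenomeSpec:
    """Base-composition model: background GC, optional site-center enrichment."""

    chrom_lengths: Dict[str, int]
    background_gc: float = 0.41
    site_gc: Optional[float] = None  # GC fraction of enriched intervals at sites
    site_gc_halfwidth: int = 150


@dataclass
class SiteAccessibilitySpec:
    """Parameters of the site-centered midpoint density."""

    dip_depth: float = 0.5  # a in [0, 1]
    phasing_amplitude: float = 0.2  # b >= 0
    period: float = 190.0  # T (bp)
    decay_length: float = 1000.0  # tau (bp)
    dip_width: float = 100.0  # sigma (bp)

    def density(self, offsets: np.ndarray) -> np.ndarray:
        """lambda(x), clipped at 0; refuses specs clipping >1% of mass."""
        x = np.asarray(offsets, dtype=float)
        lam = (
            1.0
            - self.dip_depth * np.exp(-(x**2) / (2 * self.dip_width**2))
            + self.phasing_amplitude
            * np.cos(2 * np.pi * x / self.period)
            * np.exp(-np.abs(x) / self.decay_length)
        )
        clipped = -lam[lam < 0].sum()
        lam = np.clip(lam, 0.0, None)
        total = lam.sum()
        if total <= 0 or clipped > 0.01 * total:
            raise ValueError("density parameters clip more than 1% of probability mass")
        return lam


@dataclass
class InjectedGCBias:
    """Smooth ground-truth bias surface w(L, GC fraction).

    ``w = exp(strength * (gf - 0.5) + length_coupling * (gf - 0.5) * (L - 150)/50)``
    — monotone in GC fraction with an optional mild length interaction,
    mimicking the per-length bias curves that differ between samples.
    """

    strength: float = 1.0
    length_coupling: float = 0.0

    def __call__(self, lengths: np.ndarray, gc_fraction: np.ndarray) -> np.ndarray:
        L = np.asarray(lengths, dtype=float)
        gf = np.asarray(gc_fraction, dtype=float)
        return np.exp(
            self.strength * (gf - 0.5)
            + self.length_coupling * (gf - 0.5) * (L - 150.0) / 50.0
        )

    def max_weight(self, length_range: Tuple[int, int]) -> float:
        Ls = np.array(length_range, dtype=float)
        corners = [self(np.full(2, l), np.array([0.0, 1.0])) for l in Ls]
        return float(np.max(corners))

    def normalized_truth(self, genome_freqs) -> Dict[int, np.ndarray]:
        """w on the (L, g) grid, mean-1 per length over observed cells —
        directly comparable to a fitted GC bias model."""
        out = {}
        for L, freq in genome_freqs.counts.items():
            g = np.arange(L + 1)
            w = self(np.full(L + 1, L), g / L)
            w = np.where(freq > 0, w, np.nan)
            m = np.nanmean(w)
            out[L] = w / m if np.isfinite(m) and m > 0 else w
        return out


@dataclass
class SampleSpec:
    """Per-sample generation parameters."""

    tumor_fraction: float = 0.0
    n_fragments: int = 100_000
    length_mean: float = 167.0
    length_sd: float = 25.0
    length_uniform_mix: float = 0.1
    length_support: Tuple[int, int] = (35, 500)
    gc_bias: Optional[InjectedGCBias] = None
    background_fraction: float = 0.2  # uniform off-site fragments

    def __post_init__(self):
        if not (0 <= self.tumor_fraction <= 1):
            raise ValueError("tumor_fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    """All generation parameters plus the closed-form expected composite."""

    tumor_spec: SiteAccessibilitySpec
    background_spec: SiteAccessibilitySpec
    sample: SampleSpec
    n_sites: int
    genome_length: int
    window: int = WINDOW

    def mixture_density(self, offsets: np.ndarray) -> np.ndarray:
        tf = self.sample.tumor_fraction
        return tf * self.tumor_spec.density(offsets) + (1 - tf) * self.background_spec.density(
            offsets
        )

    def expected_composite(self) -> CompositeProfile:
        """Expected trimmed composite profile (smoothing and normalization
        applied to the analytic midpoint density, including the uniform
        off-site background floor)."""
        n_bins = 2 * self.window // BIN_SIZE
        offsets = np.arange(-self.window, -self.window + n_bins * BIN_SIZE)
        lam = self.mixture_density(offsets)
        f = self.sample.background_fraction
        if f > 0 and self.n_sites > 0:
            floor = f * self.n_sites * lam.sum() / ((1 - f) * self.genome_length)
            lam = lam + floor
        binned = lam.reshape(n_bins, BIN_SIZE).sum(axis=1)
        raw = CompositeProfile(
            bin_centers(self.window), binned, np.zeros(len(binned), dtype=bool),
            state="raw-mean", provenance={"analytic": True},
        )
        return smooth_and_normalize(raw)

    def expected_features(self) -> ProfileFeatures:
        return profile_features(self.expected_composite())

    def to_json(self, path) -> None:
        payload = {
            "tumor_spec": vars(self.tumor_spec),
            "background_spec": vars(self.background_spec),
            "sample": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(self.sample).items()
                if k != "gc_bias"
            },
            "gc_bias": None if self.sample.gc_bias is None else vars(self.sample.gc_bias),
            "n_sites": self.n_sites,
            "genome_length": self.genome_length,
            "window": self.window,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# --------------------------------------------------------------------------
# Generators
# --------------------------------------------------------------------------
def simulate_genome(
    spec: SyntheticGenomeSpec,
    rng: np.random.Generator,
    sites: Optional[SiteList] = None,
) -> ReferenceGenome:
    """Random sequence with the requested GC composition.

    Site-centered GC-enriched intervals (when configured) emulate the
    elevated GC content observed around regulatory sites.
    """
    seqs = {}
    for chrom, n in spec.chrom_lengths.items():
        gc = rng.random(n) < spec.background_gc
        if sites is not None and spec.site_gc is not None:
            hw = spec.site_gc_halfwidth
            for pos in sites.by_chrom().get(chrom, ()):  # noqa: B020
                s, e = max(0, pos - hw), min(n, pos + hw + 1)
                gc[s:e] = rng.random(e - s) < spec.site_gc
        strand = rng.random(n) < 0.5
        codes = np.where(gc, np.where(strand, 1, 2), np.where(strand, 0, 3))
        seqs[chrom] = _BASES[codes].tobytes()
    return ReferenceGenome(seqs)


def simulate_site_list(
    chrom_lengths: Dict[str, int],
    n: int,
    rng: np.random.Generator,
    min_spacing: int = 12_000,
    margin: int = 6_000,
    name: str = "synthetic_sites",
) -> SiteList:
    """n non-overlapping site centers, near-uniform over the genome.

    Per chromosome the admissible span is sampled by the ordered-gap
    construction, guaranteeing ``min_spacing`` between consecutive centers
    and ``margin`` to the contig edges.
    """
    if n == 0:
        return SiteList(name, np.array([], dtype=object), np.array([], int), np.array([], float))
    chroms = list(chrom_lengths)
    spans = np.array([max(0, chrom_lengths[c] - 2 * margin) for c in chroms], dtype=float)
    alloc = np.floor(spans / spans.sum() * n).astype(int)
    for i in np.argsort(-spans):
        if alloc.sum() >= n:
            break
        alloc[i] += n - alloc.sum()
    all_c, all_p = [], []
    for chrom, k in zip(chroms, alloc):
        if k == 0:
            continue
        lo, hi = margin, chrom_lengths[chrom] - margin
        free = (hi - lo) - (k - 1) * min_spacing
        if free <= 0:
            raise ValueError(f"cannot place {k} sites with spacing {min_spacing} on {chrom}")
        u = np.sort(rng.random(k)) * free
        pos = (lo + u + np.arange(k) * min_spacing).astype(np.int64)
        all_c.extend([chrom] * k)
        all_p.extend(pos.tolist())
    return SiteList(name, np.array(all_c, dtype=object), np.array(all_p, dtype=np.int64),
                    np.ones(len(all_p)), provenance="custom")


def _draw_lengths(spec: SampleSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.length_support
    uniform = rng.random(size) < spec.length_uniform_mix
    n_u = int(uniform.sum())
    out = np.empty(size, dtype=np.int64)
    out[uniform] = rng.integers(lo, hi + 1, size=n_u)
    n_n = size - n_u
    vals = rng.normal(spec.length_mean, spec.length_sd, size=int(n_n * 1.6) + 16)
    vals = vals[(vals >= lo) & (vals <= hi)]
    while len(vals) < n_n:  # top up the truncated tail
        extra = rng.normal(spec.length_mean, spec.length_sd, size=n_n)
        vals = np.concatenate([vals, extra[(extra >= lo) & (extra <= hi)]])
    out[~uniform] = np.round(vals[:n_n]).astype(np.int64)
    return out


def simulate_fragments(
    genome: ReferenceGenome,
    sites: SiteList,
    tumor_spec: SiteAccessibilitySpec,
    background_spec: SiteAccessibilitySpec,
    sample: SampleSpec,
    rng: np.random.Generator,
    window: int = WINDOW,
) -> Tuple[FragmentTable, GroundTruth]:
    """Sample fragments from the mixture density and inject GC bias.

    Midpoints of on-site fragments follow the tumor/background mixture
    density around a uniformly chosen site; off-site fragments are uniform
    over the genome.  Each candidate is accepted with probability
    proportional to the injected bias at its reference (length, GC) — the
    generative model the correction pipeline is meant to invert.
    """
    chroms = list(genome.lengths)
    clens = np.array([genome.lengths[c] for c in chroms], dtype=np.int64)
    G = int(clens.sum())
    offsets = np.arange(-window, window)
    if len(sites):
        lam = sample.tumor_fraction * tumor_spec.density(offsets) + (
            1 - sample.tumor_fraction
        ) * background_spec.density(offsets)
        lam_p = lam / lam.sum()
        lookup = {c: i for i, c in enumerate(chroms)}
        site_ci = np.array([lookup[c] for c in sites.chroms], dtype=np.int64)
        site_pos = sites.positions
    wmax = sample.gc_bias.max_weight(sample.length_support) if sample.gc_bias else 1.0

    kept: Dict[str, list] = {c: [] for c in chroms}
    n_kept = 0
    bg_frac = sample.background_fraction if len(sites) else 1.0
    acc_est = 0.7
    while n_kept < sample.n_fragments:
        batch = int((sample.n_fragments - n_kept) / acc_est * 1.2) + 64
        L = _draw_lengths(sample, batch, rng)
        is_bg = rng.random(batch) < bg_frac
        mid = np.empty(batch, dtype=np.int64)
        chrom_idx = np.empty(batch, dtype=np.int64)
        n_bg = int(is_bg.sum())
        if n_bg:
            ci = rng.choice(len(chroms), size=n_bg, p=clens / G)
            chrom_idx[is_bg] = ci
            mid[is_bg] = (rng.random(n_bg) * clens[ci]).astype(np.int64)
        n_site = batch - n_bg
        if n_site:
            si = rng.integers(0, len(sites), size=n_site)
            off = rng.choice(len(offsets), size=n_site, p=lam_p) - window
            mid[~is_bg] = site_pos[si] + off
            chrom_idx[~is_bg] = site_ci[si]
        start = mid - (L - 1) // 2
        end = start + L
        ok = (start >= 0) & (end <= clens[chrom_idx])
        if sample.gc_bias is not None:
            g = np.zeros(batch, dtype=np.int64)
            for i, c in enumerate(chroms):
                sel = ok & (chrom_idx == i)
                if sel.any():
                    g[sel] = genome.gc_counts(c, start[sel], end[sel])
            w = sample.gc_bias(L, g / L)
            ok &= rng.random(batch) < (w / wmax)
        idx = np.flatnonzero(ok)
        take = idx[: sample.n_fragments - n_kept]
        for i, c in enumerate(chroms):
            sel = take[chrom_idx[take] == i]
            if len(sel):
                kept[c].append(np.stack([start[sel], end[sel]], axis=1))
        got = len(take)
        n_kept += got
        acc_est = max(0.05, got / batch)
    table = FragmentTable(
        {c: np.concatenate(v) for c, v in kept.items() if v}
    )
    truth = GroundTruth(tumor_spec, background_spec, sample, len(sites), G, window)
    return table, truth


def expected_composite(
    tumor_spec: SiteAccessibilitySpec,
    background_spec: SiteAccessibilitySpec,
    tumor_fraction: float,
    background_fraction: float = 0.0,
    n_sites: int = 0,
    genome_length: int = 0,
    window: int = WINDOW,
) -> Tuple[CompositeProfile, ProfileFeatures]:
    """Closed-form trimmed profile and features for a parameter set."""
    gt = GroundTruth(
        tumor_spec,
        background_spec,
        SampleSpec(tumor_fraction=tumor_fraction, background_fraction=background_fraction),
        n_sites,
        genome_length,
        window,
    )
    prof = gt.expected_composite()
    return prof, profile_features(prof)
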