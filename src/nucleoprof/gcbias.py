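"""Fragment-length-stratified GC bias estimation and correction.

cfDNA library preparation and sequencing over- or under-represent fragments
as a joint function of fragment length and GC content, and the effect is
sample specific.  Following the Benjamini–Speed fragment-length position
model, the observed GC-count spectrum of a sample's fragments is divided by
the genome-wide GC-count spectrum of all admissible L-mers to give a bias
value per (length, GC) cell; the noisy surface is then smoothed by pooling
nearby lengths (±10 bp), sorting by GC fraction, and taking running medians
of k nearest neighbours.  Each fragment in downstream coverage profiles is
weighted by the reciprocal of its smoothed bias.

A single-fragment-length variant (every read treated as a 165 bp fragment,
deepTools-style) is provided for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .fragments import FragmentTable
from .genome import ReferenceGenome
from .regions import GenomeGCFrequencies, RegionSet, compute_genome_gc_frequencies


def default_k_rule(n: int) -> int:
    """k = 5% of the pooled vector length or 50, whichever is greater."""
    return max(50, int(round(0.05 * n)))


@dataclass
class GCCounts:
    """Observed fragment counts per (length, GC count) cell for one sample."""

    counts: Dict[int, np.ndarray] = field(default_factory=dict)
    n_fragments_used: int = 0

    def count(self, length: int, gc: int) -> int:
        if length not in self.counts:
            return 0
        return int(self.counts[length][gc])


def count_sample_gc(
    fragments: FragmentTable,
    genome: ReferenceGenome,
    valid: RegionSet,
    length_range: Tuple[int, int],
) -> GCCounts:
    """Tally reference-GC counts of accepted fragments.

    A fragment is admissible under the same rule as the genome frequencies:
    its span must be fully contained in a single valid interval and contain
    no ambiguous base.  Quality filtering (mapq, duplicates, pairing) is
    assumed to have happened at alignment parsing.
    """
    lo, hi = length_range
    counts = {L: np.zeros(L + 1, dtype=np.int64) for L in range(lo, hi + 1)}
    n_used = 0
    for chrom in fragments.chromosomes:
        if chrom not in genome.lengths:
            continue
        n = genome.lengths[chrom]
        spans = fragments.spans(chrom)
        L = spans[:, 1] - spans[:, 0]
        in_range = (L >= lo) & (L <= hi) & (spans[:, 0] >= 0) & (spans[:, 1] <= n)
        spans = spans[in_range]
        if not len(spans):
            continue
        vcc = valid.containment_cumsum(chrom, n)
        contained = (vcc[spans[:, 1]] - vcc[spans[:, 0]]) == (spans[:, 1] - spans[:, 0])
        spans = spans[contained]
        if not len(spans):
            continue
        ambiguous = genome.contains_ambiguous(chrom, spans[:, 0], spans[:, 1])
        spans = spans[~ambiguous]
        if not len(spans):
            continue
        g = genome.gc_counts(chrom, spans[:, 0], spans[:, 1])
        L = spans[:, 1] - spans[:, 0]
        for length in np.unique(L):
            sel = g[L == length]
            counts[int(length)] += np.bincount(sel, minlength=int(length) + 1).astype(np.int64)
        n_used += len(spans)
    if n_used == 0:
        warnings.warn("no accepted fragments; GC counts are all zero")
    return GCCounts(counts, n_used)


def compute_raw_gc_bias(
    sample: GCCounts, genome_freqs: GenomeGCFrequencies
) -> Dict[int, np.ndarray]:
    """Per-cell bias = sample count / genome frequency, mean-1 per length.

    Cells never observed in the genome (frequency 0) are MISSING (NaN).
    The mean is taken over observed cells only.
    """
    raw: Dict[int, np.ndarray] = {}
    for L, cnt in sample.counts.items():
        if L not in genome_freqs.counts:
            raise KeyError(f"fragment length {L} absent from genome GC frequencies")
        freq = genome_freqs.counts[L]
        bias = np.full(L + 1, np.nan)
        observed = freq > 0
        bias[observed] = cnt[observed] / freq[observed]
        m = np.nanmean(bias) if observed.any() else np.nan
        if np.isfinite(m) and m > 0:
            bias /= m
        raw[L] = bias
    return raw


def smooth_gc_bias(
    raw: Dict[int, np.ndarray],
    k_rule: Optional[Callable[[int], int]] = None,
    pool_halfwidth: int = 10,
) -> Dict[int, np.ndarray]:
    """Running-median smoothing of the bias surface, one curve per length.

    For each length L, all observed bias values at lengths within
    ``L ± pool_halfwidth`` are pooled, sorted by GC fraction g/L', and each
    of L's own entries is replaced by the median of its k nearest neighbours
    in that sorted order (a contiguous window of k elements, clipped at the
    ends).  Each length's smoothed curve is re-normalized to mean 1 over its
    observed cells.
    """
    if k_rule is None:
        k_rule = default_k_rule
    smoothed: Dict[int, np.ndarray] = {}
    lengths = sorted(raw)
    # pre-extract observed entries per length
    entries = {}
    for L in lengths:
        g = np.flatnonzero(np.isfinite(raw[L]))
        entries[L] = (g, raw[L][g], g / L)
    for L in lengths:
        pool_g, pool_v, pool_f, pool_len = [], [], [], []
        for Lp in lengths:
            if abs(Lp - L) > pool_halfwidth:
                continue
            g, v, f = entries[Lp]
            pool_g.append(g)
            pool_v.append(v)
            pool_f.append(f)
            pool_len.append(np.full(len(g), Lp))
        out = np.full(L + 1, np.nan)
        if not pool_g:
            smoothed[L] = out
            continue
        g_all = np.concatenate(pool_g)
        v_all = np.concatenate(pool_v)
        f_all = np.concatenate(pool_f)
        l_all = np.concatenate(pool_len)
        order = np.lexsort((g_all, l_all, f_all))
        v_sorted = v_all[order]
        n = len(v_sorted)
        k = k_rule(n)
        if k > n:
            warnings.warn(f"k={k} exceeds pooled vector length {n}; clamped")
            k = n
        if k >= n:
            med = np.full(1, np.median(v_sorted))
            starts = np.zeros(n, dtype=np.int64)
        else:
            windows = np.lib.stride_tricks.sliding_window_view(v_sorted, k)
            med = np.median(windows, axis=1)
            idx = np.arange(n)
            starts = np.clip(idx - (k - 1) // 2, 0, n - k)
        sm_sorted = med[starts]
        own = l_all[order] == L
        out[g_all[order][own]] = sm_sorted[own]
        m = np.nanmean(out)
        if np.isfinite(m) and m > 0:
            out /= m
        smoothed[L] = out
    return smoothed


@dataclass
class GCBiasModel:
    """Smoothed expected relative coverage per (fragment length, GC count).

    ``mode`` is either ``"multi"`` (one curve per fragment length) or
    ``"single165"`` (a single 165 bp curve applied to all lengths via the
    closest 165 bp GC content).
    """

    raw: Dict[int, np.ndarray]
    smoothed: Dict[int, np.ndarray]
    mode: str = "multi"
    n_fragments_used: int = 0
    n_excluded_missing_bias: int = 0

    @property
    def lengths(self) -> list:
        return sorted(self.smoothed)

    def bias(self, length: int, gc: int) -> float:
        if self.mode == "single165":
            curve = self.smoothed[165]
            g165 = int(round(gc / max(length, 1) * 165))
            return float(curve[min(g165, 165)])
        if length not in self.smoothed:
            return float("nan")
        return float(self.smoothed[length][gc])

    def weights(self, lengths: np.ndarray, gcs: np.ndarray) -> np.ndarray:
        """1/bias per fragment; MISSING or zero bias yields weight 0.

        Weight-0 fragments are excluded from profiles and counted in
        ``n_excluded_missing_bias``.
        """
        lengths = np.asarray(lengths, dtype=np.int64)
        gcs = np.asarray(gcs, dtype=np.int64)
        if self.mode == "single165":
            curve = self.smoothed[165]
            g165 = np.clip(np.round(gcs / np.maximum(lengths, 1) * 165).astype(np.int64), 0, 165)
            b = curve[g165]
        else:
            Ls = self.lengths
            lmin, lmax = Ls[0], Ls[-1]
            table = np.full((lmax - lmin + 1, lmax + 2), np.nan)
            for L in Ls:
                table[L - lmin, : L + 1] = self.smoothed[L]
            b = np.full(len(lengths), np.nan)
            ok = (lengths >= lmin) & (lengths <= lmax)
            b[ok] = table[lengths[ok] - lmin, gcs[ok]]
        w = np.zeros(len(lengths))
        good = np.isfinite(b) & (b > 0)
        w[good] = 1.0 / b[good]
        self.n_excluded_missing_bias += int((~good).sum())
        return w

    def check_normalization(self, tol: float = 1e-6) -> bool:
        for L, curve in self.smoothed.items():
            if np.isfinite(curve).any():
                m = np.nanmean(curve)
                if m > 0 and abs(m - 1) > tol:
                    return False
        return True

    # ----------------------------------------------------------------- I/O
    def as_frame(self) -> pd.DataFrame:
        rows = []
        for L in self.lengths:
            for g in range(L + 1):
                rows.append((L, g, self.raw.get(L, np.full(L + 1, np.nan))[g], self.smoothed[L][g]))
        return pd.DataFrame(rows, columns=["length", "gc_count", "raw_bias", "smoothed_bias"])

    def to_tsv(self, path) -> None:
        self.as_frame().to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path, mode: str = "multi") -> "GCBiasModel":
        df = pd.read_csv(path, sep="\t", na_values="NA")
        raw, smoothed = {}, {}
        for L, grp in df.groupby("length"):
            L = int(L)
            r = np.full(L + 1, np.nan)
            s = np.full(L + 1, np.nan)
            r[grp["gc_count"].to_numpy()] = grp["raw_bias"].to_numpy()
            s[grp["gc_count"].to_numpy()] = grp["smoothed_bias"].to_numpy()
            raw[L], smoothed[L] = r, s
        return cls(raw, smoothed, mode=mode)


def fragment_weight(model: GCBiasModel, length: int, gc: int) -> float:
    """Correction weight 1/bias for a single fragment; 0 signals exclusion."""
    return float(model.weights(np.array([length]), np.array([gc]))[0])


def estimate_gc_bias(
    fragments: FragmentTable,
    genome: ReferenceGenome,
    valid: RegionSet,
    genome_freqs: GenomeGCFrequencies,
    length_range: Optional[Tuple[int, int]] = None,
    k_rule: Optional[Callable[[int], int]] = None,
) -> GCBiasModel:
    """Full multi-length pipeline: count, divide, smooth, normalize."""
    if length_range is None:
        length_range = genome_freqs.length_range
    sample = count_sample_gc(fragments, genome, valid, length_range)
    raw = compute_raw_gc_bias(sample, genome_freqs)
    smoothed = smooth_gc_bias(raw, k_rule=k_rule)
    return GCBiasModel(raw, smoothed, mode="multi", n_fragments_used=sample.n_fragments_used)


def single_length_gc_bias(
    fragments: FragmentTable,
    genome: ReferenceGenome,
    valid: RegionSet,
    genome_freqs_165: Optional[GenomeGCFrequencies] = None,
    pseudo_length: int = 165,
    k_rule: Optional[Callable[[int], int]] = None,
) -> GCBiasModel:
    """Single-fragment-length bias model: every read becomes a 165 bp span.

    Each mate of a pair contributes a pseudo-fragment extending from its 5'
    end: forward reads span [start, start+165), reverse reads [end-165, end).
    """
    if genome_freqs_165 is None:
        genome_freqs_165 = compute_genome_gc_frequencies(
            genome, valid, (pseudo_length, pseudo_length)
        )
    pseudo = {}
    for chrom in fragments.chromosomes:
        n = genome.lengths.get(chrom)
        if n is None:
            continue
        spans = fragments.spans(chrom)
        fwd = np.stack([spans[:, 0], spans[:, 0] + pseudo_length], axis=1)
        rev = np.stack([spans[:, 1] - pseudo_length, spans[:, 1]], axis=1)
        both = np.concatenate([fwd, rev])
        both = both[(both[:, 0] >= 0) & (both[:, 1] <= n)]
        if len(both):
            pseudo[chrom] = both
    ptable = FragmentTable(pseudo)
    sample = count_sample_gc(ptable, genome, valid, (pseudo_length, pseudo_length))
    raw = compute_raw_gc_bias(sample, genome_freqs_165)
    smoothed = smooth_gc_bias(raw, k_rule=k_rule)
    return GCBiasModel(
        raw, smoothed, mode="single165", n_fragments_used=sample.n_fragments_used
    )
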