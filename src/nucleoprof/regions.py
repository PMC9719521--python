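"""Valid-region masks and genome GC frequencies.

Coverage bias estimation needs two genome-level inputs: the set of positions
where alignment is trustworthy (high mappability, outside exclusion lists),
and, for every fragment length L, how often each GC count occurs among L-mers
of the reference restricted to those positions.  Dividing a sample's observed
fragment GC counts by these genome frequencies yields the sample's GC bias.

Coordinates are 0-based half-open throughout; conversions happen only at
file I/O boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .genome import ReferenceGenome, autosome_names


# --------------------------------------------------------------------------
# RegionSet
# --------------------------------------------------------------------------
class RegionSet:
    """Sorted, merged, non-overlapping genomic intervals (0-based half-open)."""

    def __init__(self, intervals: Mapping[str, np.ndarray] | None = None):
        self._ivals: Dict[str, np.ndarray] = {}
        if intervals:
            for chrom in sorted(intervals):
                arr = np.asarray(intervals[chrom], dtype=np.int64).reshape(-1, 2)
                if len(arr):
                    if (arr[:, 0] >= arr[:, 1]).any():
                        raise ValueError(f"empty or inverted interval on {chrom}")
                    self._ivals[chrom] = _merge(arr)

    @classmethod
    def from_intervals(cls, intervals: Iterable[Tuple[str, int, int]]) -> "RegionSet":
        by_chrom: Dict[str, list] = {}
        for chrom, start, end in intervals:
            by_chrom.setdefault(chrom, []).append((start, end))
        return cls({c: np.array(v) for c, v in by_chrom.items()})

    @classmethod
    def from_bed(cls, path) -> "RegionSet":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                rows.append((f[0], int(f[1]), int(f[2])))
        return cls.from_intervals(rows)

    def to_bed(self, path, value: Optional[float] = None) -> None:
        """Write BED (3 columns) or bedGraph (4 columns, constant value)."""
        with open(path, "w") as fh:
            for chrom, start, end in self:
                if value is None:
                    fh.write(f"{chrom}\t{start}\t{end}\n")
                else:
                    fh.write(f"{chrom}\t{start}\t{end}\t{value}\n")

    # ------------------------------------------------------------- algebra
    def subtract(self, other: "RegionSet") -> "RegionSet":
        out: Dict[str, np.ndarray] = {}
        for chrom, ivals in self._ivals.items():
            cut = other._ivals.get(chrom)
            if cut is None or not len(cut):
                out[chrom] = ivals
                continue
            pieces = []
            for s, e in ivals:
                pos = s
                sel = cut[(cut[:, 0] < e) & (cut[:, 1] > s)]
                for cs, ce in sel:
                    if cs > pos:
                        pieces.append((pos, min(cs, e)))
                    pos = max(pos, ce)
                if pos < e:
                    pieces.append((pos, e))
            if pieces:
                out[chrom] = np.array(pieces, dtype=np.int64)
        return RegionSet(out)

    def intersect(self, other: "RegionSet") -> "RegionSet":
        return self.subtract(self.subtract(other))

    def restrict_chromosomes(self, keep: Iterable[str]) -> "RegionSet":
        keep = set(keep)
        return RegionSet({c: v for c, v in self._ivals.items() if c in keep})

    # ------------------------------------------------------------- queries
    @property
    def chromosomes(self) -> list:
        return list(self._ivals)

    def intervals(self, chrom: str) -> np.ndarray:
        return self._ivals.get(chrom, np.empty((0, 2), dtype=np.int64))

    def __iter__(self):
        for chrom, arr in self._ivals.items():
            for s, e in arr:
                yield chrom, int(s), int(e)

    def __len__(self) -> int:
        return sum(len(a) for a in self._ivals.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        if set(self._ivals) != set(other._ivals):
            return False
        return all(np.array_equal(self._ivals[c], other._ivals[c]) for c in self._ivals)

    def total_length(self) -> int:
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self._ivals.values()))

    def coverage_mask(self, chrom: str, length: int) -> np.ndarray:
        """Boolean per-base membership array of the given chromosome length."""
        mask = np.zeros(length, dtype=bool)
        for s, e in self.intervals(chrom):
            mask[max(0, s) : min(length, e)] = True
        return mask

    def contains(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) lies entirely inside one interval."""
        ivals = self.intervals(chrom)
        if not len(ivals):
            return False
        i = np.searchsorted(ivals[:, 0], start, side="right") - 1
        return i >= 0 and ivals[i, 1] >= end

    def containment_cumsum(self, chrom: str, length: int) -> np.ndarray:
        """int32 cumulative sum of the membership mask, length+1 entries.

        A span [s, e) is fully contained iff cs[e] - cs[s] == e - s.
        """
        cs = np.zeros(length + 1, dtype=np.int32)
        np.cumsum(self.coverage_mask(chrom, length), out=cs[1:], dtype=np.int32)
        return cs


def _merge(arr: np.ndarray) -> np.ndarray:
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    merged = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged, dtype=np.int64)


# --------------------------------------------------------------------------
# MappabilityTrack
# --------------------------------------------------------------------------
class MappabilityTrack:
    """Per-base mappability values in [0, 1].

    Each chromosome stores a contiguous value array starting at some offset;
    queries outside the covered span are explicit misses (NaN), never 0.
    """

    def __init__(self, data: Mapping[str, np.ndarray], starts: Mapping[str, int] | None = None):
        self._values: Dict[str, np.ndarray] = {}
        self._starts: Dict[str, int] = {}
        for chrom, vals in data.items():
            vals = np.asarray(vals, dtype=np.float64)
            finite = vals[np.isfinite(vals)]
            if len(finite) and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("mappability values must lie in [0, 1]")
            self._values[chrom] = vals
            self._starts[chrom] = int(starts[chrom]) if starts else 0

    @classmethod
    def from_bedgraph(cls, path) -> "MappabilityTrack":
        spans: Dict[str, list] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                chrom, s, e, v = line.split("\t")[:4]
                spans.setdefault(chrom, []).append((int(s), int(e), float(v)))
        data, starts = {}, {}
        for chrom, rows in spans.items():
            rows.sort()
            lo, hi = rows[0][0], max(r[1] for r in rows)
            vals = np.full(hi - lo, np.nan)
            for s, e, v in rows:
                vals[s - lo : e - lo] = v
            data[chrom], starts[chrom] = vals, lo
        return cls(data, starts)

    @classmethod
    def from_bigwig(cls, path) -> "MappabilityTrack":
        import pyBigWig

        bw = pyBigWig.open(str(path))
        data = {}
        for chrom, length in bw.chroms().items():
            data[chrom] = np.asarray(bw.values(chrom, 0, length), dtype=np.float64)
        bw.close()
        return cls(data)

    @property
    def chromosomes(self) -> list:
        return list(self._values)

    def value(self, chrom: str, position: int) -> float:
        """Value at a position; NaN signals an explicit miss."""
        if chrom not in self._values:
            return float("nan")
        i = position - self._starts[chrom]
        if i < 0 or i >= len(self._values[chrom]):
            return float("nan")
        return float(self._values[chrom][i])

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        out = np.full(end - start, np.nan)
        if chrom not in self._values:
            return out
        off = self._starts[chrom]
        vals = self._values[chrom]
        lo, hi = max(start, off), min(end, off + len(vals))
        if hi > lo:
            out[lo - start : hi - start] = vals[lo - off : hi - off]
        return out

    def regions_at_least(self, threshold: float) -> RegionSet:
        out = {}
        for chrom, vals in self._values.items():
            good = np.isfinite(vals) & (vals >= threshold)
            if not good.any():
                continue
            edges = np.flatnonzero(np.diff(np.concatenate(([0], good.view(np.int8), [0]))))
            ivals = edges.reshape(-1, 2) + self._starts[chrom]
            out[chrom] = ivals
        return RegionSet(out)


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------
def build_valid_regions(
    mappability: MappabilityTrack,
    exclusions: RegionSet | None = None,
    threshold: float = 1.0,
    autosomes_only: bool = False,
) -> RegionSet:
    """Positions with mappability >= threshold, minus exclusion intervals.

    The default threshold of 1.0 keeps only uniquely mappable bases.  For
    synthetic genomes a lower threshold may be configured.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    valid = mappability.regions_at_least(threshold)
    if exclusions is not None and len(exclusions):
        known = set(mappability.chromosomes)
        missing = [c for c in exclusions.chromosomes if c not in known]
        if missing:
            warnings.warn(
                f"exclusion intervals on chromosomes absent from mappability skipped: {missing}"
            )
        valid = valid.subtract(exclusions.restrict_chromosomes(known))
    if autosomes_only:
        valid = valid.restrict_chromosomes(autosome_names(valid.chromosomes))
    return valid


@dataclass
class GenomeGCFrequencies:
    """Counts of (fragment length, GC count) over all admissible L-mers.

    ``counts[L]`` is an int64 array of length L+1 indexed by GC count.  An
    L-mer is admissible iff it is fully contained in a single valid interval
    and contains no ambiguous base.
    """

    counts: Dict[int, np.ndarray] = field(default_factory=dict)
    length_range: Tuple[int, int] = (15, 500)

    def frequency(self, length: int, gc: int) -> int:
        return int(self.counts[length][gc])

    def total(self, length: int) -> int:
        return int(self.counts[length].sum())

    @property
    def lengths(self) -> list:
        return sorted(self.counts)

    def as_frame(self) -> pd.DataFrame:
        rows = [
            (L, g, int(n))
            for L in self.lengths
            for g, n in enumerate(self.counts[L])
        ]
        return pd.DataFrame(rows, columns=["length", "gc_count", "frequency"])

    def to_tsv(self, path) -> None:
        self.as_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenomeGCFrequencies":
        df = pd.read_csv(path, sep="\t")
        counts = {}
        for L, grp in df.groupby("length"):
            arr = np.zeros(int(L) + 1, dtype=np.int64)
            arr[grp["gc_count"].to_numpy()] = grp["frequency"].to_numpy()
            counts[int(L)] = arr
        lengths = sorted(counts)
        return cls(counts, (lengths[0], lengths[-1]))


def compute_genome_gc_frequencies(
    genome: ReferenceGenome,
    valid: RegionSet,
    length_range: Tuple[int, int],
) -> GenomeGCFrequencies:
    """Count the GC content of every admissible L-mer for each length L.

    Deterministic; intervals shorter than L simply contribute nothing at
    that length.
    """
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError("length_range must be a non-empty positive range")
    counts = {L: np.zeros(L + 1, dtype=np.int64) for L in range(lo, hi + 1)}
    for chrom in valid.chromosomes:
        if chrom not in genome.lengths:
            raise KeyError(f"chromosome {chrom} in valid regions but not in genome")
        n = genome.lengths[chrom]
        vcc = valid.containment_cumsum(chrom, n)
        genome._ensure_cumsums(chrom)
        gcc = genome._gc_cumsum[chrom]
        has_n = genome.has_ambiguous(chrom)
        ncc = genome._n_cumsum.get(chrom)
        for L in range(lo, hi + 1):
            if n < L:
                continue
            contained = (vcc[L:] - vcc[: n - L + 1]) == L
            if has_n:
                contained &= (ncc[L:] - ncc[: n - L + 1]) == 0
            if not contained.any():
                continue
            g = (gcc[L:] - gcc[: n - L + 1])[contained]
            counts[L] += np.bincount(g, minlength=L + 1).astype(np.int64)
    return GenomeGCFrequencies(counts, (lo, hi))
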