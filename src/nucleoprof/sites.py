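"""Site list construction, filtering, and characterization.

Composite coverage profiles are averaged over *site lists*: thousands of
single-coordinate genomic positions sharing a biological identity — the
binding sites of one transcription factor (ChIP-seq meta-clusters ranked by
peak count), tissue-specific DNase I hypersensitive sites (ranked by the
number of samples observing them), or differentially accessible ATAC-seq
peaks split by phenotype and by overlap with hematopoietic open chromatin.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .genome import ReferenceGenome, autosome_names
from .regions import RegionSet

logger = logging.getLogger(__name__)

#: Sentinel returned when a factor has too few autosomal sites to rank.
EXCLUDED = None

_FEATURE_SMOOTH_BP = 165


@dataclass
class SiteList:
    """Named collection of single-coordinate sites with scores.

    Duplicate (chrom, position) pairs are collapsed keeping the maximum
    score.  Ordering is deterministic: score descending, ties broken by
    (chrom lexical, position ascending).
    """

    name: str
    chroms: np.ndarray
    positions: np.ndarray
    scores: np.ndarray
    provenance: str = "custom"

    def __post_init__(self):
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if (self.positions < 0).any():
            raise ValueError("site positions must be non-negative")
        # deduplicate on (chrom, position), keep max score
        df = pd.DataFrame(
            {"chrom": self.chroms, "position": self.positions, "score": self.scores}
        )
        df = (
            df.groupby(["chrom", "position"], as_index=False, sort=True)["score"]
            .max()
            .sort_values(
                ["score", "chrom", "position"], ascending=[False, True, True]
            )
        )
        self.chroms = df["chrom"].to_numpy(dtype=object)
        self.positions = df["position"].to_numpy(dtype=np.int64)
        self.scores = df["score"].to_numpy(dtype=np.float64)

    def __len__(self) -> int:
        return len(self.positions)

    def by_chrom(self) -> Dict[str, np.ndarray]:
        """Sorted position arrays keyed by chromosome."""
        out: Dict[str, np.ndarray] = {}
        for chrom in np.unique(self.chroms.astype(str)):
            pos = self.positions[self.chroms == chrom]
            out[str(chrom)] = np.sort(pos)
        return out

    def head(self, n: int) -> "SiteList":
        return SiteList(
            self.name, self.chroms[:n], self.positions[:n], self.scores[:n], self.provenance
        )

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chroms, "position": self.positions, "score": self.scores}
        )

    def to_tsv(self, path) -> None:
        self.as_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, name: Optional[str] = None) -> "SiteList":
        df = pd.read_csv(path, sep="\t")
        return cls(name or str(path), df["chrom"], df["position"], df["score"])


@dataclass
class DifferentialSiteSets:
    """Four site lists keyed by (phenotype, shared-with-hematopoietic)."""

    lists: Dict[Tuple[str, str], SiteList] = field(default_factory=dict)

    def get(self, phenotype: str, shared: str) -> SiteList:
        return self.lists[(phenotype, shared)]


# --------------------------------------------------------------------------
# Selection
# --------------------------------------------------------------------------
def _autosomal(df: pd.DataFrame, chrom_col: str) -> pd.DataFrame:
    keep = set(autosome_names(df[chrom_col].unique()))
    return df[df[chrom_col].isin(keep)]


def select_top_sites(
    rows: pd.DataFrame,
    n: int = 10_000,
    score_column: str = "peak.count",
    min_sites: int = 10_000,
    name: str = "TF",
    chrom_col: str = "chrom",
    start_col: str = "start",
    end_col: str = "end",
    autosomes_only: bool = True,
):
    """Rank meta-cluster peaks by score and keep the top n.

    The site position is the floor of the mean of start and end.  Factors
    with fewer than ``min_sites`` autosomal sites are excluded entirely
    (returns the EXCLUDED sentinel) rather than profiled on a thin list.
    """
    df = rows[[chrom_col, start_col, end_col, score_column]].copy()
    bad = df[[start_col, end_col, score_column]].isna().any(axis=1)
    if bad.any():
        logger.info("select_top_sites(%s): skipped %d malformed rows", name, int(bad.sum()))
        df = df[~bad]
    if autosomes_only:
        df = _autosomal(df, chrom_col)
    if len(df) < min_sites:
        return EXCLUDED
    position = (df[start_col].to_numpy(np.int64) + df[end_col].to_numpy(np.int64)) // 2
    sl = SiteList(name, df[chrom_col].to_numpy(object), position,
                  df[score_column].to_numpy(float), provenance="TFBS")
    return sl.head(n)


def select_dhs_sites(
    rows: pd.DataFrame,
    n: int = 10_000,
    name: str = "DHS",
    chrom_col: str = "chrom",
    summit_col: str = "summit",
    count_col: str = "numsamples",
    autosomes_only: bool = True,
) -> SiteList:
    """Top-n most frequently observed DNase hypersensitive sites.

    The summit column is used verbatim as the site position and sites are
    ranked by the number of samples in which they were observed.
    """
    df = rows.copy()
    if autosomes_only:
        df = _autosomal(df, chrom_col)
    if n > len(df):
        warnings.warn(f"requested {n} sites but only {len(df)} available; keeping all")
    sl = SiteList(name, df[chrom_col].to_numpy(object), df[summit_col].to_numpy(np.int64),
                  df[count_col].to_numpy(float), provenance="DHS")
    return sl.head(n)


def filter_differential_sites(
    rows: pd.DataFrame,
    padj_max: float = 5e-4,
    lfc_min: float = 0.5,
    chrom_col: str = "chrom",
    position_col: str = "position",
    padj_col: str = "padj",
    lfc_col: str = "log2FoldChange",
    names: Tuple[str, str] = ("pos", "neg"),
) -> Tuple[SiteList, SiteList]:
    """Split a differential-accessibility results table into two site lists.

    Rows passing the adjusted-p gate are classified by the sign of their
    log2 fold change at ``±lfc_min``; rows with missing padj are dropped.
    Both thresholds are sweepable for cutoff-selection harnesses.
    """
    df = rows.dropna(subset=[padj_col])
    gate = df[df[padj_col] < padj_max]
    pos = gate[gate[lfc_col] > lfc_min]
    neg = gate[gate[lfc_col] < -lfc_min]

    def build(sub: pd.DataFrame, name: str) -> SiteList:
        return SiteList(
            name,
            sub[chrom_col].to_numpy(object),
            sub[position_col].to_numpy(np.int64),
            np.abs(sub[lfc_col].to_numpy(float)),
            provenance="ATAC-diff",
        )

    return build(pos, names[0]), build(neg, names[1])


# --------------------------------------------------------------------------
# Overlap machinery
# --------------------------------------------------------------------------
def overlap_flags(a: SiteList, b: SiteList, max_dist: int) -> np.ndarray:
    """Per-site flag: does any site of b lie within max_dist (inclusive)?

    Sorted two-pointer (searchsorted) implementation; equals the O(n^2)
    brute force.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    flags = np.zeros(len(a), dtype=bool)
    b_by_chrom = b.by_chrom()
    for chrom, bpos in b_by_chrom.items():
        sel = a.chroms == chrom
        if not sel.any():
            continue
        apos = a.positions[sel]
        lo = np.searchsorted(bpos, apos - max_dist, side="left")
        hi = np.searchsorted(bpos, apos + max_dist, side="right")
        flags[sel] = hi > lo
    return flags


def count_overlaps(a: SiteList, b: SiteList, max_dist: int) -> Tuple[int, np.ndarray]:
    """Number of sites in a whose center is within max_dist of any b center."""
    flags = overlap_flags(a, b, max_dist)
    return int(flags.sum()), flags


def split_by_shared(
    sites: SiteList, reference: SiteList, max_dist: int = 500
) -> Tuple[SiteList, SiteList]:
    """Exact partition into (shared with reference, not shared)."""
    flags = overlap_flags(sites, reference, max_dist)
    def sub(mask: np.ndarray, suffix: str) -> SiteList:
        return SiteList(
            f"{sites.name}.{suffix}",
            sites.chroms[mask],
            sites.positions[mask],
            sites.scores[mask],
            sites.provenance,
        )
    return sub(flags, "shared"), sub(~flags, "not_shared")


def filter_shared_tfs(
    candidates: Dict[str, SiteList],
    opposite: Dict[str, SiteList],
    overlap_mean_max: float = 400.0,
    max_dist: int = 250,
) -> List[str]:
    """Drop factors sharing too many sites with the opposite phenotype class.

    For each candidate factor, the mean (over all opposite-class factors) of
    the number of candidate sites within ``max_dist`` of an opposite-class
    site is computed; candidates at or above ``overlap_mean_max`` are
    excluded.  An empty opposite class retains everything (mean 0).
    """
    retained = []
    for name, sl in candidates.items():
        if opposite:
            mean_overlap = float(
                np.mean([count_overlaps(sl, opp, max_dist)[0] for opp in opposite.values()])
            )
        else:
            mean_overlap = 0.0
        if mean_overlap >= overlap_mean_max:
            logger.info("factor %s excluded: mean shared sites %.1f", name, mean_overlap)
        else:
            retained.append(name)
    return retained


def build_differential_site_sets(
    rows: pd.DataFrame,
    hematopoietic: SiteList,
    padj_max: float = 5e-4,
    lfc_min: float = 0.5,
    max_dist: int = 500,
    names: Tuple[str, str] = ("pos", "neg"),
    **kwargs,
) -> DifferentialSiteSets:
    """Differential filtering followed by the hematopoietic shared/not split."""
    pos, neg = filter_differential_sites(rows, padj_max, lfc_min, names=names, **kwargs)
    out = DifferentialSiteSets()
    for pheno, sl in ((names[0], pos), (names[1], neg)):
        shared, not_shared = split_by_shared(sl, hematopoietic, max_dist)
        out.lists[(pheno, "shared")] = shared
        out.lists[(pheno, "not_shared")] = not_shared
    return out


# --------------------------------------------------------------------------
# GC content at sites
# --------------------------------------------------------------------------
def gc_content_profile(
    sites: SiteList,
    genome: ReferenceGenome,
    valid: Optional[RegionSet] = None,
    flank: int = 1000,
    center_halfwidth: int = 30,
    smooth_bp: int = _FEATURE_SMOOTH_BP,
):
    """Mean per-offset GC fraction around site centers, with a summary.

    Per site the base-level GC indicator over ±flank is masked at invalid
    positions, smoothed with an order-0 (moving average) filter of
    ``smooth_bp``, then averaged across sites.  The summary is the pair
    (mean within ±center_halfwidth, mean outside it); sites whose window
    leaves the chromosome are skipped with a warning count.
    """
    width = 2 * flank + 1
    total = np.zeros(width)
    count = np.zeros(width)
    kernel = np.ones(smooth_bp) / smooth_bp
    skipped = 0
    for chrom, pos, _ in zip(sites.chroms, sites.positions, sites.scores):
        n = genome.lengths.get(str(chrom))
        if n is None or pos - flank < 0 or pos + flank + 1 > n:
            skipped += 1
            continue
        s, e = int(pos) - flank, int(pos) + flank + 1
        gc = genome.is_gc(str(chrom))[s:e].astype(float)
        ok = np.ones(width, dtype=bool)
        if valid is not None:
            ok = valid.coverage_mask(str(chrom), n)[s:e]
        vals = np.where(ok, gc, 0.0)
        # NaN-aware moving average: smooth values and mask jointly
        num = np.convolve(vals, kernel, mode="same")
        den = np.convolve(ok.astype(float), kernel, mode="same")
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = num / den
        good = den > 0
        total[good] += sm[good]
        count[good] += 1
    if skipped:
        warnings.warn(f"{skipped} sites skipped: window exits chromosome")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_gc = total / count
    offsets = np.arange(-flank, flank + 1)
    central = np.abs(offsets) <= center_halfwidth
    center_mean = float(np.nanmean(mean_gc[central]))
    flank_mean = float(np.nanmean(mean_gc[~central]))
    return offsets, mean_gc, (center_mean, flank_mean)
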