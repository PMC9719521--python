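"""Fragment containers and paired-end alignment I/O.

A *fragment* is the outer span of a properly paired read pair: leftmost
mate start to rightmost mate end, 0-based half-open.  Reads failing the
quality rules (low mapping quality, duplicates, QC-fail, unpaired,
secondary/supplementary) never enter a :class:`FragmentTable`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np


@dataclass(frozen=True)
class QualityRules:
    """Read-pair admission rules applied when parsing alignments."""

    min_mapping_quality: int = 20
    exclude_duplicates: bool = True
    exclude_qcfail: bool = True
    require_proper_pair: bool = True


class FragmentTable:
    """Per-chromosome arrays of fragment spans, sorted by start.

    The single in-memory currency of the pipeline: alignment files are
    parsed into one of these, and the simulator emits one directly, so
    downstream code has exactly one path.
    """

    def __init__(self, spans: Mapping[str, np.ndarray] | None = None):
        # spans[chrom]: (n, 2) int64 [start, end), sorted by start
        self._spans: Dict[str, np.ndarray] = {}
        if spans:
            for chrom, arr in spans.items():
                arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
                order = np.lexsort((arr[:, 1], arr[:, 0]))
                self._spans[chrom] = arr[order]

    # ------------------------------------------------------------- queries
    @property
    def chromosomes(self) -> list:
        return list(self._spans)

    def spans(self, chrom: str) -> np.ndarray:
        return self._spans.get(chrom, np.empty((0, 2), dtype=np.int64))

    def starts(self, chrom: str) -> np.ndarray:
        return self.spans(chrom)[:, 0]

    def ends(self, chrom: str) -> np.ndarray:
        return self.spans(chrom)[:, 1]

    def lengths(self, chrom: str) -> np.ndarray:
        s = self.spans(chrom)
        return s[:, 1] - s[:, 0]

    def midpoints(self, chrom: str) -> np.ndarray:
        """Fragment midpoint: floor((start + end - 1) / 2)."""
        s = self.spans(chrom)
        return (s[:, 0] + s[:, 1] - 1) // 2

    def __len__(self) -> int:
        return sum(len(a) for a in self._spans.values())

    def subset_by_length(self, length_range: Tuple[int, int]) -> "FragmentTable":
        lo, hi = length_range
        out = {}
        for chrom, arr in self._spans.items():
            L = arr[:, 1] - arr[:, 0]
            sel = arr[(L >= lo) & (L <= hi)]
            if len(sel):
                out[chrom] = sel
        return FragmentTable(out)

    def concat(self, other: "FragmentTable") -> "FragmentTable":
        out = {}
        for chrom in set(self._spans) | set(other._spans):
            out[chrom] = np.concatenate([self.spans(chrom), other.spans(chrom)])
        return FragmentTable(out)

    # ----------------------------------------------------------------- I/O
    @classmethod
    def from_bam(
        cls,
        path: str | os.PathLike,
        quality: QualityRules = QualityRules(),
        length_range: Optional[Tuple[int, int]] = None,
    ) -> "FragmentTable":
        """Parse a coordinate-sorted indexed BAM/SAM into fragment spans.

        Each proper pair is counted once, from its leftmost read (positive
        template length); the admission rules are evaluated on that read.
        """
        import pysam

        by_chrom: Dict[str, list] = {}
        mode = "r" if str(path).endswith(".sam") else "rb"
        with pysam.AlignmentFile(str(path), mode) as bam:
            for read in bam.fetch(until_eof=True):
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                if not read.is_paired:
                    continue
                if quality.require_proper_pair and not read.is_proper_pair:
                    continue
                if quality.exclude_duplicates and read.is_duplicate:
                    continue
                if quality.exclude_qcfail and read.is_qcfail:
                    continue
                if read.mapping_quality < quality.min_mapping_quality:
                    continue
                tlen = read.template_length
                if tlen <= 0:  # keep only the leftmost mate of each pair
                    continue
                start = read.reference_start
                end = start + tlen
                if length_range is not None and not (length_range[0] <= tlen <= length_range[1]):
                    continue
                by_chrom.setdefault(read.reference_name, []).append((start, end))
        return cls({c: np.array(v, dtype=np.int64) for c, v in by_chrom.items()})

    def to_bam(
        self,
        path: str | os.PathLike,
        chrom_lengths: Mapping[str, int],
        read_length: int = 100,
        mapping_quality: int = 60,
    ) -> str:
        """Write fragments as coordinate-sorted, indexed proper pairs.

        Each fragment becomes an FR read pair of fixed read length (clipped
        to the fragment length, so short fragments yield fully overlapping
        mates), mapping quality 60, no duplicates.
        """
        import pysam

        path = str(path)
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_lengths.items()],
        }
        tids = {c: i for i, c in enumerate(chrom_lengths)}
        unsorted = path + ".unsorted.bam"
        with pysam.AlignmentFile(unsorted, "wb", header=header) as out:
            idx = 0
            for chrom in self.chromosomes:
                tid = tids[chrom]
                for start, end in self._spans[chrom]:
                    L = int(end - start)
                    rl = min(read_length, L)
                    for is_r1 in (True, False):
                        a = pysam.AlignedSegment()
                        a.query_name = f"frag{idx}"
                        a.reference_id = tid
                        a.next_reference_id = tid
                        a.mapping_quality = mapping_quality
                        a.query_sequence = "A" * rl
                        a.cigarstring = f"{rl}M"
                        if is_r1:
                            a.reference_start = int(start)
                            a.next_reference_start = int(end) - rl
                            a.template_length = L
                            a.flag = 0x1 | 0x2 | 0x20 | 0x40
                        else:
                            a.reference_start = int(end) - rl
                            a.next_reference_start = int(start)
                            a.template_length = -L
                            a.flag = 0x1 | 0x2 | 0x10 | 0x80
                        out.write(a)
                    idx += 1
        pysam.sort("-o", path, unsorted)
        os.remove(unsorted)
        pysam.index(path)
        return path
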