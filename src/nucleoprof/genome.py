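"""Reference sequence access with cached GC/ambiguity cumulative sums.

The GC content of a fragment is always computed from the *reference* sequence
spanned by the fragment, never from read sequences, so that sequencing errors
do not perturb the bias model.  Cumulative-sum caches make GC lookups for
millions of fragment spans a pair of vectorized subtractions.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, Mapping

import numpy as np

_GC_BYTES = frozenset(b"GCgc")
_N_BYTES = frozenset(b"Nn")


class ReferenceGenome:
    """In-memory reference genome keyed by chromosome name.

    Sequences are held as raw byte arrays; boolean GC / N indicators and their
    int32 cumulative sums are built lazily per chromosome and cached.
    """

    def __init__(self, sequences: Mapping[str, bytes]):
        self._seq: Dict[str, np.ndarray] = {}
        for chrom, seq in sequences.items():
            if isinstance(seq, str):
                seq = seq.encode("ascii")
            self._seq[chrom] = np.frombuffer(bytes(seq).upper(), dtype=np.uint8)
        self._gc_cumsum: Dict[str, np.ndarray] = {}
        self._n_cumsum: Dict[str, np.ndarray] = {}
        self._has_n: Dict[str, bool] = {}

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_dict(cls, sequences: Mapping[str, str]) -> "ReferenceGenome":
        return cls({c: s.encode("ascii") for c, s in sequences.items()})

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "ReferenceGenome":
        import pysam

        with pysam.FastaFile(str(path)) as fa:
            return cls({name: fa.fetch(name).encode("ascii") for name in fa.references})

    def to_fasta(self, path: str | os.PathLike, line_width: int = 70) -> str:
        """Write FASTA plus a .fai index; returns the FASTA path."""
        import pysam

        path = str(path)
        with open(path, "w") as fh:
            for chrom in self.chromosomes:
                fh.write(f">{chrom}\n")
                seq = self._seq[chrom].tobytes().decode("ascii")
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")
        pysam.faidx(path)
        return path

    # ------------------------------------------------------------- queries
    @property
    def chromosomes(self) -> list:
        return list(self._seq)

    @property
    def lengths(self) -> Dict[str, int]:
        return {c: len(a) for c, a in self._seq.items()}

    def sequence(self, chrom: str, start: int | None = None, end: int | None = None) -> str:
        arr = self._seq[chrom]
        return arr[slice(start, end)].tobytes().decode("ascii")

    def is_gc(self, chrom: str) -> np.ndarray:
        arr = self._seq[chrom]
        return (arr == ord("G")) | (arr == ord("C"))

    def _ensure_cumsums(self, chrom: str) -> None:
        if chrom in self._gc_cumsum:
            return
        arr = self._seq[chrom]
        gc = (arr == ord("G")) | (arr == ord("C"))
        cs = np.zeros(len(arr) + 1, dtype=np.int32)
        np.cumsum(gc, out=cs[1:], dtype=np.int32)
        self._gc_cumsum[chrom] = cs
        is_n = ~((arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T")))
        has_n = bool(is_n.any())
        self._has_n[chrom] = has_n
        if has_n:
            ns = np.zeros(len(arr) + 1, dtype=np.int32)
            np.cumsum(is_n, out=ns[1:], dtype=np.int32)
            self._n_cumsum[chrom] = ns

    def gc_counts(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Vectorized G+C base count over [start, end) spans."""
        self._ensure_cumsums(chrom)
        cs = self._gc_cumsum[chrom]
        return (cs[ends] - cs[starts]).astype(np.int64)

    def contains_ambiguous(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Boolean per span: does [start, end) contain any non-ACGT base?"""
        self._ensure_cumsums(chrom)
        if not self._has_n[chrom]:
            return np.zeros(len(np.atleast_1d(starts)), dtype=bool)
        ns = self._n_cumsum[chrom]
        return (ns[ends] - ns[starts]) > 0

    def has_ambiguous(self, chrom: str) -> bool:
        self._ensure_cumsums(chrom)
        return self._has_n[chrom]


def autosome_names(chromosomes: Iterable[str]) -> list:
    """Filter chromosome names down to autosomes (chr1..chr22 / 1..22 style)."""
    keep = []
    for c in chromosomes:
        stem = c[3:] if c.lower().startswith("chr") else c
        if stem.isdigit():
            keep.append(c)
    return keep
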