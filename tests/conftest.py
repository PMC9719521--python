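import numpy as np
import pysam
import pytest

from nucleoprof import ReferenceGenome, RegionSet


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def uniform_genome():
    """Deterministic 20 kb single-chromosome genome, ~50% GC."""
    r = np.random.default_rng(42)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = bases[r.integers(0, 4, 20_000)].tobytes()
    return ReferenceGenome({"chr1": seq})


def whole_genome(genome: ReferenceGenome) -> RegionSet:
    return RegionSet({c: np.array([[0, n]]) for c, n in genome.lengths.items()})


def write_pairs_bam(path, chrom_lengths, pairs):
    """Write proper read pairs to a sorted indexed BAM.

    ``pairs``: list of dicts with chrom, start, end and optional flags
    (mapq, duplicate, qcfail, proper) controlling the quality fields.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_lengths.items()],
    }
    tids = {c: i for i, c in enumerate(chrom_lengths)}
    unsorted = str(path) + ".tmp.bam"
    with pysam.AlignmentFile(unsorted, "wb", header=header) as out:
        for i, p in enumerate(pairs):
            L = p["end"] - p["start"]
            rl = min(p.get("read_length", 100), L)
            mapq = p.get("mapq", 60)
            flag_extra = (0x400 if p.get("duplicate") else 0) | (0x200 if p.get("qcfail") else 0)
            proper = 0x2 if p.get("proper", True) else 0
            for is_r1 in (True, False):
                a = pysam.AlignedSegment()
                a.query_name = f"p{i}"
                a.reference_id = tids[p["chrom"]]
                a.next_reference_id = tids[p["chrom"]]
                a.mapping_quality = mapq
                a.query_sequence = "A" * rl
                a.cigarstring = f"{rl}M"
                if is_r1:
                    a.reference_start = p["start"]
                    a.next_reference_start = p["end"] - rl
                    a.template_length = L
                    a.flag = 0x1 | proper | 0x20 | 0x40 | flag_extra
                else:
                    a.reference_start = p["end"] - rl
                    a.next_reference_start = p["start"]
                    a.template_length = -L
                    a.flag = 0x1 | proper | 0x10 | 0x80 | flag_extra
                out.write(a)
    pysam.sort("-o", str(path), unsorted)
    pysam.index(str(path))
    return str(path)
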