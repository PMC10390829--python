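"""Shared fixtures: tiny panels, hand-built BAMs, and brute-force oracles."""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pysam
import pytest

from tandemcall.alignment import SpanningRead
from tandemcall.simulate import default_panel


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def cigar_columns(ops: Sequence[Tuple[int, int]], ref_start: int):
    """Expand a CIGAR into per-base alignment columns.

    Yields ("M", q, r) for aligned bases, ("I", q, anchor_r) for inserted
    bases, ("D", None, r) for deleted reference positions; soft clips consume
    query silently, hard clips nothing.
    """
    q, r = 0, ref_start
    cols = []
    for op, ln in ops:
        if op in (0, 7, 8):
            for i in range(ln):
                cols.append(("M", q + i, r + i))
            q += ln
            r += ln
        elif op == 1:
            for i in range(ln):
                cols.append(("I", q + i, r))
            q += ln
        elif op in (2, 3):
            for i in range(ln):
                cols.append(("D", None, r + i))
            r += ln
        elif op == 4:
            q += ln
    return cols, r


def project_interval_oracle(
    read: SpanningRead, ref_start: int, ref_end: int
) -> Optional[Tuple[int, int]]:
    """Per-base column-walk reference implementation of interval projection.

    Valid for CIGARs in which insertions and deletions are separated by
    matches (standard aligner output): the included query positions are the
    match columns inside the interval plus insertion columns whose anchor is
    strictly inside; an empty set with both boundaries inside the aligned
    span denotes an interval erased by a deletion.
    """
    cols, aln_end = cigar_columns(read.alignment_ops, read.ref_start)
    if ref_start < read.ref_start or ref_end > aln_end:
        return None
    included = [
        q
        for kind, q, r in cols
        if (kind == "M" and ref_start <= r < ref_end)
        or (kind == "I" and ref_start < r < ref_end)
    ]
    if included:
        assert included == list(range(included[0], included[-1] + 1))
        return included[0], included[-1] + 1
    snap = [q for kind, q, r in cols if kind == "M" and r >= ref_start]
    assert snap, "boundaries inside aligned span must have a snap target"
    return snap[0], snap[0]


def random_aligner_cigar(
    rng: np.random.Generator, n_blocks: int = 4
) -> List[Tuple[int, int]]:
    """Random CIGAR with aligner-like structure: [S] M ((I|D) M)* [S]."""
    ops: List[Tuple[int, int]] = []
    if rng.random() < 0.3:
        ops.append((4, int(rng.integers(1, 20))))
    ops.append((0, int(rng.integers(5, 60))))
    for _ in range(int(rng.integers(0, n_blocks))):
        ops.append((int(rng.choice([1, 2])), int(rng.integers(1, 15))))
        ops.append((0, int(rng.integers(5, 60))))
    if rng.random() < 0.3:
        ops.append((4, int(rng.integers(1, 20))))
    return ops


def make_spanning_read(
    ops: Sequence[Tuple[int, int]],
    ref_start: int = 0,
    name: str = "r",
    chrom: str = "chr1",
    bases: Optional[str] = None,
    mapq: int = 60,
) -> SpanningRead:
    qlen = sum(ln for op, ln in ops if op in (0, 1, 4, 7, 8))
    if bases is None:
        bases = ("ACGT" * (qlen // 4 + 1))[:qlen]
    return SpanningRead(
        read_name=name,
        chrom=chrom,
        ref_start=ref_start,
        alignment_ops=tuple(ops),
        bases=bases,
        mapq=mapq,
    )


# ---------------------------------------------------------------------------
# BAM construction
# ---------------------------------------------------------------------------

def write_bam(
    path: Path,
    references: Sequence[Tuple[str, int]],
    records: Sequence[dict],
    sort: bool = True,
) -> Path:
    """Build an indexed BAM from record dicts.

    Each record: name, chrom, pos, cigar (op tuples), seq (optional, derived
    from CIGAR length), flag, mapq.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate" if sort else "unknown"},
            "SQ": [{"SN": name, "LN": length} for name, length in references],
        }
    )
    tid = {name: i for i, (name, _) in enumerate(references)}
    recs = list(records)
    if sort:
        recs.sort(key=lambda r: (tid[r["chrom"]], r["pos"]))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for r in recs:
            seg = pysam.AlignedSegment(header)
            seg.query_name = r["name"]
            seg.flag = r.get("flag", 0)
            seg.reference_id = tid[r["chrom"]]
            seg.reference_start = r["pos"]
            seg.mapping_quality = r.get("mapq", 60)
            seg.cigartuples = list(r["cigar"])
            qlen = sum(ln for op, ln in r["cigar"] if op in (0, 1, 4, 7, 8))
            seg.query_sequence = r.get("seq") or ("ACGT" * (qlen // 4 + 1))[:qlen]
            bam.write(seg)
    if sort:
        pysam.index(str(path))
    return path


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def small_panel():
    """A 6-locus synthetic panel for fast simulator round trips."""
    return default_panel(n_loci=6, contig_length=3000, seed=11)


@pytest.fixture(scope="session")
def full_panel():
    """The default 20-locus panel used by the sensitivity experiments."""
    return default_panel(n_loci=20, contig_length=3000, seed=11)
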