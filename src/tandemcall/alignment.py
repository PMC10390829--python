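"""Indexed-alignment access: spanning-read retrieval and BAM preprocessing.

Only reads whose aligned reference span fully contains a target interval plus
a required flank on each side carry complete allele evidence; everything else
is retrieved lazily through the BAM index, never by a full-file scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import pysam

from .targets import TargetLocus

logger = logging.getLogger(__name__)

# CIGAR operation codes (SAM spec / pysam cigartuples).
CMATCH, CINS, CDEL, CREF_SKIP, CSOFT_CLIP, CHARD_CLIP, CPAD, CEQUAL, CDIFF = range(9)

#: operations that consume query bases present in SEQ
QUERY_OPS = frozenset({CMATCH, CINS, CSOFT_CLIP, CEQUAL, CDIFF})
#: operations that consume reference positions (N skips treated like deletions)
REF_OPS = frozenset({CMATCH, CDEL, CREF_SKIP, CEQUAL, CDIFF})
#: aligned (both-consuming) operations
ALIGN_OPS = frozenset({CMATCH, CEQUAL, CDIFF})


class MissingIndexError(RuntimeError):
    """The alignment file has no companion index."""


@dataclass(frozen=True)
class ReadFilters:
    """Read-level inclusion policy for spanning-read retrieval.

    Secondary, supplementary, duplicate and QC-fail records never represent an
    independent molecule observation and are always excluded; ``min_mapq``
    guards against multi-placed reads, the dominant error mode at repeats.
    """

    min_mapq: int = 1
    exclude_secondary: bool = True
    exclude_supplementary: bool = True
    exclude_duplicates: bool = True
    exclude_qcfail: bool = True


@dataclass(frozen=True)
class SpanningRead:
    """An aligned read retained for a locus, in reference orientation."""

    read_name: str
    chrom: str
    ref_start: int
    alignment_ops: Tuple[Tuple[int, int], ...]
    bases: str
    mapq: int
    flag: int = 0

    @property
    def ref_end(self) -> int:
        """0-based exclusive end of the aligned reference span."""
        return self.ref_start + sum(
            ln for op, ln in self.alignment_ops if op in REF_OPS
        )

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & 0x10)


def _as_alignment(
    alignment: Union[str, Path, pysam.AlignmentFile],
) -> Tuple[pysam.AlignmentFile, bool]:
    if isinstance(alignment, pysam.AlignmentFile):
        return alignment, False
    return pysam.AlignmentFile(str(alignment)), True


def _require_index(af: pysam.AlignmentFile) -> None:
    try:
        has_index = af.check_index()
    except (ValueError, AttributeError, OSError):
        has_index = False
    if not has_index:
        raise MissingIndexError(
            f"{af.filename.decode() if isinstance(af.filename, bytes) else af.filename}"
            " has no index; run sort_and_index (CLI: `tandemcall sort-index`) first"
        )


def _passes(read: pysam.AlignedSegment, filters: ReadFilters) -> bool:
    if read.is_unmapped:
        return False
    if filters.exclude_secondary and read.is_secondary:
        return False
    if filters.exclude_supplementary and read.is_supplementary:
        return False
    if filters.exclude_duplicates and read.is_duplicate:
        return False
    if filters.exclude_qcfail and read.is_qcfail:
        return False
    return read.mapping_quality >= filters.min_mapq


def fetch_spanning_reads(
    alignment: Union[str, Path, pysam.AlignmentFile],
    locus: TargetLocus,
    flank: int = 5,
    filters: ReadFilters = ReadFilters(),
) -> List[SpanningRead]:
    """Retrieve the reads whose aligned span covers the locus plus flanks.

    Uses the BAM/CRAM index to visit only the target region. A read is kept
    iff it passes ``filters`` and its aligned reference span contains
    ``[locus.start - flank, locus.end + flank)``. Both mates of a pair are
    judged independently.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    af, owned = _as_alignment(alignment)
    try:
        _require_index(af)
        if locus.chrom not in af.references:
            logger.warning(
                "locus %s: chromosome %s absent from alignment header",
                locus.name,
                locus.chrom,
            )
            return []
        lo = max(0, locus.start - flank)
        hi = locus.end + flank
        out: List[SpanningRead] = []
        for read in af.fetch(locus.chrom, lo, hi):
            if not _passes(read, filters):
                continue
            if read.reference_start <= locus.start - flank and read.reference_end >= hi:
                out.append(
                    SpanningRead(
                        read_name=read.query_name,
                        chrom=locus.chrom,
                        ref_start=read.reference_start,
                        alignment_ops=tuple(read.cigartuples or ()),
                        bases=(read.query_sequence or "").upper(),
                        mapq=read.mapping_quality,
                        flag=read.flag,
                    )
                )
        return out
    finally:
        if owned:
            af.close()


def sort_and_index(in_path: Union[str, Path], out_path: Union[str, Path]) -> Path:
    """Coordinate-sort an alignment file and build its index (idempotent)."""
    in_path, out_path = Path(in_path), Path(out_path)
    pysam.sort("-o", str(out_path), str(in_path))
    pysam.index(str(out_path))
    return out_path


def reduce_to_targets(
    alignment: Union[str, Path],
    loci: Sequence[TargetLocus],
    flank: int,
    out_path: Union[str, Path],
) -> Path:
    """Write a reduced BAM holding only reads overlapping any target region.

    Every read overlapping ``[start - flank, end + flank)`` of any locus is
    kept exactly once (loci may share reads); calling on the reduced file is
    equivalent to calling on the original because overlap is a superset of
    the spanning predicate.
    """
    out_path = Path(out_path)
    af, _ = _as_alignment(alignment)
    with af:
        _require_index(af)
        tmp = out_path.with_suffix(out_path.suffix + ".unsorted.tmp")
        seen = set()
        with pysam.AlignmentFile(str(tmp), "wb", template=af) as out:
            for locus in loci:
                if locus.chrom not in af.references:
                    logger.warning(
                        "locus %s: chromosome %s absent from alignment header",
                        locus.name,
                        locus.chrom,
                    )
                    continue
                lo = max(0, locus.start - flank)
                for read in af.fetch(locus.chrom, lo, locus.end + flank):
                    key = (read.query_name, read.flag, read.reference_start)
                    if key in seen:
                        continue
                    seen.add(key)
                    out.write(read)
    sort_and_index(tmp, out_path)
    tmp.unlink()
    return out_path


__all__ = [
    "SpanningRead",
    "ReadFilters",
    "MissingIndexError",
    "fetch_spanning_reads",
    "sort_and_index",
    "reduce_to_targets",
    "CMATCH",
    "CINS",
    "CDEL",
    "CREF_SKIP",
    "CSOFT_CLIP",
    "CHARD_CLIP",
    "CEQUAL",
    "CDIFF",
    "QUERY_OPS",
    "REF_OPS",
    "ALIGN_OPS",
]
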