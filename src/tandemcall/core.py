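"""Tandem-repeat allele detection from spanning reads.

The calling model: every read that fully spans a target interval (plus
flanks) carries one complete observation of the allele it was sequenced
from. The read segment aligned to the interval is located by a single
left-to-right walk of the CIGAR operations, trimmed out, validated for motif
content, and grouped with identical segments from other reads into candidate
haplotypes. Candidates are then filtered by read coverage, by proportion of
classified reads, by a PCR-stutter count ratio (single-source samples only),
and finally capped at ploidy x donors alleles per locus. Surviving haplotypes
are reported both as sequences and as forensic length-based designations.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .alignment import (
    ALIGN_OPS,
    CDEL,
    CHARD_CLIP,
    CINS,
    CPAD,
    CREF_SKIP,
    CSOFT_CLIP,
    QUERY_OPS,
    SpanningRead,
    ReadFilters,
    fetch_spanning_reads,
)
from .targets import TargetLocus

logger = logging.getLogger(__name__)


class MalformedAlignmentError(ValueError):
    """A read whose CIGAR does not account for its sequence length."""


class SkipReason(str, enum.Enum):
    """Why a fetched read contributed no allele observation."""

    NOT_FULLY_SPANNED = "not_fully_spanned"


class CallStatus(str, enum.Enum):
    CALLED = "called"
    FILTERED_COVERAGE = "filtered_coverage"
    FILTERED_PROPORTION = "filtered_proportion"
    FILTERED_STUTTER = "filtered_stutter"
    FILTERED_CAP = "filtered_cap"


@dataclass(frozen=True)
class CallerConfig:
    """Run-level thresholds.

    ``min_coverage`` is reads per haplotype (2 suits ~30x whole-genome data;
    ~10 suits deep targeted amplicon data). ``min_proportion`` is the fraction
    of classified reads at the locus a haplotype must reach. ``donors`` is the
    assumed number of DNA contributors d; the per-locus allele cap is
    ploidy x d, and d > 1 switches the run into mixture mode, where the
    stutter filter is disabled.
    """

    min_coverage: int = 2
    min_proportion: float = 0.10
    donors: int = 1
    default_stutter_ratio: float = 0.25
    flank: int = 5
    min_mapq: int = 1

    def __post_init__(self):
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if not 0.0 <= self.min_proportion <= 1.0:
            raise ValueError("min_proportion must be in [0, 1]")
        if self.donors < 1:
            raise ValueError("donors must be >= 1")
        if not 0.0 <= self.default_stutter_ratio <= 1.0:
            raise ValueError("default_stutter_ratio must be in [0, 1]")

    @property
    def mixture_mode(self) -> bool:
        return self.donors > 1

    @property
    def read_filters(self) -> ReadFilters:
        return ReadFilters(min_mapq=self.min_mapq)


@dataclass(frozen=True)
class HaplotypeObservation:
    """One distinct extracted TR sequence with its read support at a locus."""

    locus_name: str
    sequence: str
    read_count: int
    proportion: float


@dataclass(frozen=True)
class AlleleCall:
    """A haplotype observation with its filter outcome and length designation."""

    locus_name: str
    sequence: str
    allele_label: Optional[str]
    allele_length: int
    read_count: int
    proportion: float
    status: CallStatus


@dataclass
class LocusTallies:
    """Per-locus read accounting: fetched = skipped + motif_invalid + classified."""

    fetched: int = 0
    skipped_incomplete: int = 0
    motif_invalid: int = 0
    classified: int = 0


@dataclass
class LocusResult:
    locus: TargetLocus
    calls: List[AlleleCall]
    tallies: LocusTallies
    warning: Optional[str] = None

    @property
    def called(self) -> List[AlleleCall]:
        return [c for c in self.calls if c.status is CallStatus.CALLED]


def project_interval(
    read: SpanningRead, ref_start: int, ref_end: int
) -> Optional[Tuple[int, int]]:
    """Project a reference interval onto read (query) coordinates.

    Walks the alignment operations once, left to right, accumulating
    reference and query offsets, and returns the 0-based half-open query
    coordinates of the read segment aligned to ``[ref_start, ref_end)``.

    Boundary conventions:

    * insertions whose reference anchor lies strictly inside the interval are
      included; insertions anchored exactly at ``ref_start`` or ``ref_end``
      belong to the flanks and are excluded;
    * a boundary falling inside a deletion (or reference skip) moves to the
      nearest aligned base inside the interval;
    * ``None`` (spanning failure) if either boundary falls inside a soft clip
      or outside the aligned span.
    """
    if ref_end <= ref_start:
        raise ValueError("empty reference interval")
    query_len = sum(
        ln for op, ln in read.alignment_ops if op in QUERY_OPS and op != CHARD_CLIP
    )
    if query_len != len(read.bases):
        raise MalformedAlignmentError(
            f"read {read.read_name}: CIGAR query length {query_len} != "
            f"sequence length {len(read.bases)}"
        )
    if ref_start < read.ref_start:
        return None

    q = 0
    r = read.ref_start
    q_start: Optional[int] = None
    q_end: Optional[int] = None
    for op, ln in read.alignment_ops:
        if op in (CHARD_CLIP, CPAD):
            continue
        if op == CSOFT_CLIP:
            q += ln
            continue
        if op in ALIGN_OPS:
            if q_start is None:
                if r <= ref_start < r + ln:
                    q_start = q + (ref_start - r)
                elif r > ref_start:  # left boundary was inside a deletion: snap right
                    q_start = q
            if q_end is None and r <= ref_end <= r + ln:
                q_end = q + (ref_end - r)
            q += ln
            r += ln
        elif op == CINS:
            # insertion anchored exactly at the right boundary is flank material
            if q_end is None and r == ref_end and q_start is not None:
                q_end = q
            q += ln
        elif op in (CDEL, CREF_SKIP):
            if q_end is None and r < ref_end <= r + ln:
                q_end = q  # right boundary inside a deletion: snap left
            r += ln
    if q_start is None or q_end is None or ref_end > r:
        return None
    return q_start, q_end


def extract_tr_sequence(
    read: SpanningRead, locus: TargetLocus
) -> Union[str, SkipReason]:
    """Trim a spanning read down to the bases aligned within the locus.

    Reads in which the allele is not fully represented (clipped or not
    spanned) yield a :class:`SkipReason`, which is tallied, never fatal.
    """
    span = project_interval(read, locus.start, locus.end)
    if span is None:
        return SkipReason.NOT_FULLY_SPANNED
    q_start, q_end = span
    return read.bases[q_start:q_end]


def validate_motif(sequence: str, motif: str) -> bool:
    """True iff the motif occurs as an exact substring (case-insensitive)."""
    if not sequence or not motif:
        return False
    return motif.upper() in sequence.upper()


def classify_haplotypes(
    sequences: Sequence[str], locus_name: str
) -> List[HaplotypeObservation]:
    """Group motif-validated sequences into haplotypes by exact identity.

    Returns observations sorted by (read count desc, sequence asc), with
    proportions over the classified reads at the locus.
    """
    if not sequences:
        return []
    counts = Counter(sequences)
    total = len(sequences)
    return [
        HaplotypeObservation(
            locus_name=locus_name,
            sequence=seq,
            read_count=n,
            proportion=n / total,
        )
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def max_alleles(ploidy: int, donors: int) -> int:
    """Maximum number of callable alleles at a locus: ploidy x donors."""
    if ploidy < 1 or donors < 1:
        raise ValueError("ploidy and donors must be positive")
    return ploidy * donors


def stutter_filter(
    observations: Sequence[HaplotypeObservation],
    motif_length: int,
    stutter_ratio: float,
    mixture_mode: bool,
) -> Tuple[List[HaplotypeObservation], List[HaplotypeObservation]]:
    """Partition observations into (kept, filtered_stutter).

    A candidate is flagged as PCR stutter iff some already-kept haplotype is
    exactly one motif longer and the candidate's read count falls below
    ``stutter_ratio`` times that parent's count (one-sided n-1 slippage).
    Candidates are examined in descending count order, so a filtered stutter
    can never shelter a product of its own. In mixture mode nothing is
    filtered: a minor contributor's true allele is indistinguishable from a
    major contributor's stutter by count ratio alone. A ratio of 0 disables
    the filter.
    """
    obs = sorted(observations, key=lambda o: (-o.read_count, o.sequence))
    if mixture_mode or stutter_ratio <= 0.0:
        return obs, []
    kept: List[HaplotypeObservation] = []
    filtered: List[HaplotypeObservation] = []
    for o in obs:
        is_stutter = any(
            len(p.sequence) - len(o.sequence) == motif_length
            and o.read_count < stutter_ratio * p.read_count
            for p in kept
        )
        (filtered if is_stutter else kept).append(o)
    return kept, filtered


def to_length_allele(
    allele_length: int, internal_offset: int, motif_length: int
) -> str:
    """Convert a sequence length to the forensic length-based designation.

    The integer part is ``floor((allele_length - internal_offset) /
    motif_length)`` complete repeats; the fractional part is the remainder in
    bp, omitted when zero (e.g. 15 bp with offset 2 and a 4 bp motif ->
    ``"3.1"``; an exact multiple -> ``"21"``).
    """
    if motif_length < 1:
        raise ValueError("motif_length must be >= 1")
    if allele_length <= internal_offset:
        raise ValueError(
            f"allele length {allele_length} not larger than internal offset "
            f"{internal_offset}"
        )
    effective = allele_length - internal_offset
    integer_part, fractional_part = divmod(effective, motif_length)
    if fractional_part == 0:
        return str(integer_part)
    return f"{integer_part}.{fractional_part}"


def parse_length_allele(
    label: str, internal_offset: int, motif_length: int
) -> int:
    """Inverse of :func:`to_length_allele`: reconstruct the bp length."""
    integer_part, _, fractional = label.partition(".")
    return (
        int(integer_part) * motif_length
        + (int(fractional) if fractional else 0)
        + internal_offset
    )


def _label_or_none(length: int, locus: TargetLocus) -> Optional[str]:
    if length <= locus.internal_offset:
        return None
    return to_length_allele(length, locus.internal_offset, locus.motif_length)


def apply_filters(
    observations: Sequence[HaplotypeObservation],
    locus: TargetLocus,
    config: CallerConfig,
) -> List[AlleleCall]:
    """Assign every observation the status of the first filter it fails.

    Filter order: minimum coverage -> minimum proportion -> stutter ->
    allele-count cap. The cap keeps the highest counts, ties broken by
    shorter allele then lexicographic sequence, so output is deterministic.
    """
    ordered = sorted(observations, key=lambda o: (-o.read_count, o.sequence))
    status: Dict[str, CallStatus] = {}
    survivors: List[HaplotypeObservation] = []
    for o in ordered:
        if o.read_count < config.min_coverage:
            status[o.sequence] = CallStatus.FILTERED_COVERAGE
        elif o.proportion < config.min_proportion:
            status[o.sequence] = CallStatus.FILTERED_PROPORTION
        else:
            survivors.append(o)
    ratio = (
        locus.stutter_ratio
        if locus.stutter_ratio is not None
        else config.default_stutter_ratio
    )
    kept, stutters = stutter_filter(
        survivors, locus.motif_length, ratio, config.mixture_mode
    )
    for o in stutters:
        status[o.sequence] = CallStatus.FILTERED_STUTTER
    cap = max_alleles(locus.ploidy, config.donors)
    capped_order = sorted(
        kept, key=lambda o: (-o.read_count, len(o.sequence), o.sequence)
    )
    for rank, o in enumerate(capped_order):
        status[o.sequence] = (
            CallStatus.CALLED if rank < cap else CallStatus.FILTERED_CAP
        )
    return [
        AlleleCall(
            locus_name=o.locus_name,
            sequence=o.sequence,
            allele_label=_label_or_none(len(o.sequence), locus),
            allele_length=len(o.sequence),
            read_count=o.read_count,
            proportion=o.proportion,
            status=status[o.sequence],
        )
        for o in ordered
    ]


def call_locus(alignment, locus: TargetLocus, config: CallerConfig = CallerConfig()) -> LocusResult:
    """Genotype one locus: fetch -> extract -> validate -> classify -> filter.

    Deterministic: identical inputs and configuration give identical results.
    A locus whose chromosome is absent from the alignment yields a no-call
    result with a warning rather than an error.
    """
    reads = fetch_spanning_reads(
        alignment, locus, flank=config.flank, filters=config.read_filters
    )
    tallies = LocusTallies(fetched=len(reads))
    sequences: List[str] = []
    for read in reads:
        extracted = extract_tr_sequence(read, locus)
        if isinstance(extracted, SkipReason):
            tallies.skipped_incomplete += 1
        elif not validate_motif(extracted, locus.motif):
            tallies.motif_invalid += 1
        else:
            sequences.append(extracted)
    tallies.classified = len(sequences)
    observations = classify_haplotypes(sequences, locus.name)
    calls = apply_filters(observations, locus, config)
    warning = None
    if tallies.fetched == 0:
        warning = f"locus {locus.name}: no spanning reads"
    return LocusResult(locus=locus, calls=calls, tallies=tallies, warning=warning)


def call_all(
    alignment, loci: Sequence[TargetLocus], config: CallerConfig = CallerConfig()
) -> List[LocusResult]:
    """Genotype every locus in order against one alignment file."""
    import pysam

    if isinstance(alignment, (str, bytes)) or hasattr(alignment, "__fspath__"):
        with pysam.AlignmentFile(str(alignment)) as af:
            return [call_locus(af, locus, config) for locus in loci]
    return [call_locus(alignment, locus, config) for locus in loci]


__all__ = [
    "CallerConfig",
    "HaplotypeObservation",
    "AlleleCall",
    "CallStatus",
    "SkipReason",
    "LocusResult",
    "LocusTallies",
    "MalformedAlignmentError",
    "project_interval",
    "extract_tr_sequence",
    "validate_motif",
    "classify_haplotypes",
    "max_alleles",
    "stutter_filter",
    "to_length_allele",
    "parse_length_allele",
    "apply_filters",
    "call_locus",
    "call_all",
]
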