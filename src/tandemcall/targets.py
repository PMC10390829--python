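"""Target-locus definitions and the extended BED dialect that carries them.

A target file is a tab-separated BED-like file, one tandem-repeat locus per
line, with ``#`` comment lines allowed::

    chrom  start  end  name  motif  motif_length  internal_offset  [stutter_ratio]  [ploidy]

Coordinates are 0-based half-open (standard BED). ``internal_offset`` is the
number of bases inside the interval that are excluded when converting an
allele's sequence length into a repeat-count designation (e.g. a non-repeat
spacer embedded in the tract). ``stutter_ratio`` may be ``.`` (unset);
``ploidy`` defaults to 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

logger = logging.getLogger(__name__)

_DNA = set("ACGT")

#: chrom, start, end, name, motif, motif_length, internal_offset are mandatory.
N_MANDATORY_COLUMNS = 7


class TargetBedError(ValueError):
    """A malformed line in a target BED file."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class TargetLocus:
    """One targeted tandem-repeat locus.

    Parameters
    ----------
    name : str
        Locus identifier (e.g. ``D21S11``); reports are keyed by it.
    chrom : str
        Reference sequence name.
    start, end : int
        0-based half-open interval of the repeat tract on the reference.
    motif : str
        Repeat motif, uppercase DNA.
    motif_length : int
        Length of the motif in bp; must equal ``len(motif)``.
    internal_offset : int
        Bases excluded from repeat counting in the length-based designation.
    stutter_ratio : float, optional
        Per-locus stutter count-ratio threshold in [0, 1]; ``None`` means use
        the run-level default.
    ploidy : int
        Copy number of the locus in one donor genome (1 for X/Y loci in
        males, 2 for autosomes).
    """

    name: str
    chrom: str
    start: int
    end: int
    motif: str
    motif_length: int
    internal_offset: int
    stutter_ratio: Optional[float] = None
    ploidy: int = 2

    def __post_init__(self):
        if not self.name:
            raise ValueError("locus name must be non-empty")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"{self.name}: invalid interval [{self.start}, {self.end})"
            )
        object.__setattr__(self, "motif", self.motif.upper())
        if not self.motif or set(self.motif) - _DNA:
            raise ValueError(f"{self.name}: motif {self.motif!r} is not DNA")
        if self.motif_length != len(self.motif) or self.motif_length < 1:
            raise ValueError(
                f"{self.name}: motif_length {self.motif_length} != "
                f"len(motif) == {len(self.motif)}"
            )
        if self.internal_offset < 0:
            raise ValueError(f"{self.name}: negative internal_offset")
        if self.internal_offset >= self.end - self.start:
            raise ValueError(
                f"{self.name}: internal_offset {self.internal_offset} not "
                f"smaller than the reference tract ({self.end - self.start} bp)"
            )
        if self.stutter_ratio is not None and not 0.0 <= self.stutter_ratio <= 1.0:
            raise ValueError(f"{self.name}: stutter_ratio outside [0, 1]")
        if self.ploidy < 1:
            raise ValueError(f"{self.name}: ploidy must be >= 1")

    @property
    def length(self) -> int:
        """Reference tract length in bp."""
        return self.end - self.start


def _parse_line(fields: Sequence[str], line_number: int) -> TargetLocus:
    if len(fields) < N_MANDATORY_COLUMNS:
        raise TargetBedError(
            f"expected >= {N_MANDATORY_COLUMNS} tab-separated columns, "
            f"got {len(fields)}",
            line_number,
        )
    chrom, start_s, end_s, name, motif = fields[:5]
    try:
        start, end = int(start_s), int(end_s)
        motif_length = int(fields[5])
        internal_offset = int(fields[6])
    except ValueError as exc:
        raise TargetBedError(f"malformed integer field ({exc})", line_number)
    stutter_ratio: Optional[float] = None
    if len(fields) > 7 and fields[7] not in (".", ""):
        try:
            stutter_ratio = float(fields[7])
        except ValueError as exc:
            raise TargetBedError(f"malformed stutter_ratio ({exc})", line_number)
    ploidy = 2
    if len(fields) > 8 and fields[8] not in (".", ""):
        try:
            ploidy = int(fields[8])
        except ValueError as exc:
            raise TargetBedError(f"malformed ploidy ({exc})", line_number)
    try:
        return TargetLocus(
            name=name,
            chrom=chrom,
            start=start,
            end=end,
            motif=motif,
            motif_length=motif_length,
            internal_offset=internal_offset,
            stutter_ratio=stutter_ratio,
            ploidy=ploidy,
        )
    except ValueError as exc:
        raise TargetBedError(str(exc), line_number)


def parse_targets(path: Union[str, Path], strict: bool = True) -> List[TargetLocus]:
    """Parse an extended BED file of target loci.

    Order is preserved. In strict mode any malformed line (or duplicate locus
    name) aborts with a :class:`TargetBedError` naming the line; otherwise bad
    lines are skipped with a logged warning.
    """
    path = Path(path)
    loci: List[TargetLocus] = []
    seen = set()
    with open(path) as fh:
        for line_number, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            try:
                locus = _parse_line(line.split("\t"), line_number)
                if locus.name in seen:
                    raise TargetBedError(
                        f"duplicate locus name {locus.name!r}", line_number
                    )
            except TargetBedError as exc:
                if strict:
                    raise
                logger.warning("%s: skipping %s", path, exc)
                continue
            seen.add(locus.name)
            loci.append(locus)
    return loci


def write_targets(loci: Iterable[TargetLocus], path: Union[str, Path]) -> None:
    """Write loci to the extended BED dialect (round-trips with parse_targets)."""
    with open(path, "w") as fh:
        for locus in loci:
            stutter = "." if locus.stutter_ratio is None else repr(locus.stutter_ratio)
            fh.write(
                "\t".join(
                    [
                        locus.chrom,
                        str(locus.start),
                        str(locus.end),
                        locus.name,
                        locus.motif,
                        str(locus.motif_length),
                        str(locus.internal_offset),
                        stutter,
                        str(locus.ploidy),
                    ]
                )
                + "\n"
            )


__all__ = [
    "TargetLocus",
    "TargetBedError",
    "parse_targets",
    "write_targets",
    "N_MANDATORY_COLUMNS",
]
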