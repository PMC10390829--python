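"""Run reports: called-allele TSV, unfiltered raw-allele TSV, JSON sidecar.

The main reports are tab-separated with ``#``-prefixed metadata lines carrying
the tool version, input identifiers, every threshold used in the run, and a
per-locus QC summary; loci appear in target-file order and alleles by read
count descending. Reports contain nothing non-deterministic, so identical
inputs give byte-identical files; a JSON sidecar repeats the same content in
machine-readable form (plus a timestamp).
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

from . import __version__
from .core import AlleleCall, CallStatus, CallerConfig, LocusResult

CALLED_COLUMNS = (
    "locus",
    "allele_label",
    "allele_length",
    "sequence",
    "read_count",
    "proportion",
)
RAW_COLUMNS = CALLED_COLUMNS + ("status",)


def _config_echo(config: CallerConfig) -> Dict[str, object]:
    return {
        "min_coverage": config.min_coverage,
        "min_proportion": config.min_proportion,
        "donors": config.donors,
        "default_stutter_ratio": config.default_stutter_ratio,
        "flank": config.flank,
        "min_mapq": config.min_mapq,
        "mixture_mode": config.mixture_mode,
    }


def _metadata_lines(
    config: CallerConfig, inputs: Optional[Dict[str, str]]
) -> List[str]:
    lines = [f"#tandemcall={__version__}"]
    if inputs:
        for key, value in inputs.items():
            lines.append(f"#input.{key}={value}")
    for key, value in _config_echo(config).items():
        lines.append(f"#{key}={value}")
    return lines


def _summary_lines(results: Sequence[LocusResult]) -> List[str]:
    lines = []
    for r in results:
        t = r.tallies
        lines.append(
            f"#LOCUS\t{r.locus.name}\tfetched={t.fetched}\t"
            f"skipped_incomplete={t.skipped_incomplete}\t"
            f"motif_invalid={t.motif_invalid}\tclassified={t.classified}\t"
            f"called={len(r.called)}"
        )
    return lines


def _row(call: AlleleCall) -> str:
    return "\t".join(
        [
            call.locus_name,
            call.allele_label if call.allele_label is not None else ".",
            str(call.allele_length),
            call.sequence,
            str(call.read_count),
            f"{call.proportion:.6g}",
        ]
    )


def write_called_report(
    results: Sequence[LocusResult],
    path: Union[str, Path],
    config: CallerConfig = CallerConfig(),
    inputs: Optional[Dict[str, str]] = None,
) -> Path:
    """Write the called-allele report: one row per called allele.

    Loci keep their target-file order; alleles are sorted by read count
    descending (then sequence). No-call loci contribute no allele rows but
    stay visible in the ``#LOCUS`` summary lines.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for line in _metadata_lines(config, inputs) + _summary_lines(results):
            fh.write(line + "\n")
        fh.write("\t".join(CALLED_COLUMNS) + "\n")
        for result in results:
            for call in sorted(
                result.called, key=lambda c: (-c.read_count, c.sequence)
            ):
                fh.write(_row(call) + "\n")
    return path


def write_raw_alleles(
    results: Sequence[LocusResult],
    path: Union[str, Path],
    config: CallerConfig = CallerConfig(),
    inputs: Optional[Dict[str, str]] = None,
) -> Path:
    """Write every haplotype observation with its filter status (superset of
    the called report), for the user's further consideration."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in _metadata_lines(config, inputs) + _summary_lines(results):
            fh.write(line + "\n")
        fh.write("\t".join(RAW_COLUMNS) + "\n")
        for result in results:
            for call in sorted(
                result.calls, key=lambda c: (-c.read_count, c.sequence)
            ):
                fh.write(_row(call) + f"\t{call.status.value}\n")
    return path


def read_report(path: Union[str, Path]) -> List[AlleleCall]:
    """Re-parse a called or raw report back into AlleleCall rows."""
    calls: List[AlleleCall] = []
    with open(path) as fh:
        header: Optional[List[str]] = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            rec = dict(zip(header, line.split("\t")))
            calls.append(
                AlleleCall(
                    locus_name=rec["locus"],
                    sequence=rec["sequence"],
                    allele_label=None
                    if rec["allele_label"] == "."
                    else rec["allele_label"],
                    allele_length=int(rec["allele_length"]),
                    read_count=int(rec["read_count"]),
                    proportion=float(rec["proportion"]),
                    status=CallStatus(rec.get("status", "called")),
                )
            )
    return calls


def write_json_sidecar(
    results: Sequence[LocusResult],
    path: Union[str, Path],
    config: CallerConfig = CallerConfig(),
    inputs: Optional[Dict[str, str]] = None,
    timestamp: Optional[str] = None,
) -> Path:
    """Write the full run record (config echo, calls, QC tallies) as JSON."""
    path = Path(path)
    payload = {
        "tool": "tandemcall",
        "version": __version__,
        "timestamp": timestamp
        or datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "inputs": inputs or {},
        "config": _config_echo(config),
        "loci": [
            {
                "locus": r.locus.name,
                "chrom": r.locus.chrom,
                "start": r.locus.start,
                "end": r.locus.end,
                "warning": r.warning,
                "tallies": dataclasses.asdict(r.tallies),
                "alleles": [
                    {
                        "sequence": c.sequence,
                        "allele_label": c.allele_label,
                        "allele_length": c.allele_length,
                        "read_count": c.read_count,
                        "proportion": c.proportion,
                        "status": c.status.value,
                    }
                    for c in r.calls
                ],
            }
            for r in results
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    return path


__all__ = [
    "CALLED_COLUMNS",
    "RAW_COLUMNS",
    "write_called_report",
    "write_raw_alleles",
    "write_json_sidecar",
    "read_report",
]
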