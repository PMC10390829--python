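"""Synthetic spanning-read data with machine-readable truth.

The generator emulates a targeted sensitivity study: small synthetic contigs
stand in for a reference genome, each carrying one tandem-repeat tract;
donor haplotypes receive known repeat expansions/contractions and SNPs inside
the tracts (identical to the reference elsewhere); reads are drawn uniformly
over each haplotype at a requested mean depth and are emitted as a
coordinate-sorted, indexed BAM whose alignments are constructed directly from
the known read coordinates ("truth alignment"), decoupling caller tests from
any external aligner. A FASTQ export supports optional end-to-end runs
through a real aligner.

Read modes
----------
``pe150`` / ``pe250``
    Illumina-style paired ends (150/250 bp) with independent substitution
    errors (default rate 0.001/base) and Gaussian fragment sizes.
``long_ccs``
    Long circular-consensus-style single reads (mean 2 kb) with mixed
    substitution/indel errors at a 1:1 ratio (default total rate 0.05,
    i.e. 95% base accuracy).

``mean_depth`` is the per-haplotype depth at the locus midpoint: a sample
described as "30x" provides 30 read-bases per position from *each* donor
haplotype, scaled by the donor's mixture weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import pysam

from .alignment import CDEL, CINS, CMATCH, CSOFT_CLIP
from .core import CallerConfig, LocusResult, call_all, to_length_allele
from .targets import TargetLocus

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i
_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")


# --------------------------------------------------------------------------
# panel construction
# --------------------------------------------------------------------------

#: (motif, reference repeat count, internal spacer sequence or "") for the
#: default 20-locus panel; tract lengths span ~24-65 bp, the small-to-mid
#: range of forensic core STR tracts, so every allele is spannable by 150 bp
#: reads with flanks. A few loci carry a non-repeat internal spacer to
#: exercise the internal-offset arm of the length conversion.
DEFAULT_PANEL_DESIGN: Tuple[Tuple[str, int, str], ...] = (
    ("AGAT", 8, ""),
    ("TCTA", 11, ""),
    ("GATA", 7, ""),
    ("AATG", 13, ""),
    ("TATC", 9, "GG"),
    ("CTAT", 12, ""),
    ("TAGA", 10, ""),
    ("GGAA", 6, ""),
    ("TCCT", 14, ""),
    ("ACAG", 9, ""),
    ("TGCC", 8, ""),
    ("CTTT", 12, ""),
    ("ATCG", 7, "GG"),
    ("GAAT", 10, ""),
    ("AGC", 16, ""),
    ("ATG", 9, ""),
    ("TCC", 11, ""),
    ("AAGGA", 8, ""),
    ("ATCTC", 13, "TG"),
    ("GAAAG", 10, ""),
)


def random_dna(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _reference_tract(motif: str, repeats: int, spacer: str) -> str:
    """Reference tract: spacer (if any) sits after the first two motif copies,
    so contractions/expansions can always be applied at the tract tail."""
    if not spacer:
        return motif * repeats
    if repeats < 3:
        raise ValueError("spacer loci need >= 3 reference repeats")
    return motif * 2 + spacer + motif * (repeats - 2)


def default_panel(
    n_loci: int = 20,
    contig_length: int = 3000,
    seed: Union[int, np.random.SeedSequence] = 2024,
) -> Tuple[Dict[str, str], List[TargetLocus]]:
    """Build a synthetic reference and its target panel, one locus per contig.

    Each contig is ``contig_length`` bp of seeded random sequence with the
    repeat tract centred, leaving multi-hundred-bp flanks on both sides.
    """
    rng = np.random.default_rng(seed)
    reference: Dict[str, str] = {}
    loci: List[TargetLocus] = []
    for i in range(n_loci):
        motif, repeats, spacer = DEFAULT_PANEL_DESIGN[i % len(DEFAULT_PANEL_DESIGN)]
        if i >= len(DEFAULT_PANEL_DESIGN):
            repeats += 1 + i // len(DEFAULT_PANEL_DESIGN)
        tract = _reference_tract(motif, repeats, spacer)
        if len(tract) + 400 > contig_length:
            raise ValueError("contig_length too small for the tract plus flanks")
        chrom = f"contig{i + 1:02d}"
        start = (contig_length - len(tract)) // 2
        left = random_dna(start, rng)
        right = random_dna(contig_length - start - len(tract), rng)
        reference[chrom] = left + tract + right
        loci.append(
            TargetLocus(
                name=f"TR{i + 1:02d}",
                chrom=chrom,
                start=start,
                end=start + len(tract),
                motif=motif,
                motif_length=len(motif),
                internal_offset=len(spacer),
                ploidy=2,
            )
        )
    return reference, loci


# --------------------------------------------------------------------------
# truth genomes
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class HaplotypeEdit:
    """Edits applied to one haplotype at one locus.

    ``repeat_delta`` adds (or removes) whole motif copies at the tract tail;
    ``snps`` are (position within the edited tract, replacement base) pairs.
    """

    repeat_delta: int = 0
    snps: Tuple[Tuple[int, str], ...] = ()


#: locus name -> one (edit for haplotype 0, edit for haplotype 1) per donor
GenotypeSpec = Dict[str, List[Tuple[HaplotypeEdit, HaplotypeEdit]]]


def _edited_tract(ref_tract: str, motif: str, edit: HaplotypeEdit) -> str:
    ml = len(motif)
    if edit.repeat_delta > 0:
        tract = ref_tract + motif * edit.repeat_delta
    elif edit.repeat_delta < 0:
        n = -edit.repeat_delta
        if not ref_tract.endswith(motif * n):
            raise ValueError(
                f"cannot contract by {n} motifs: tract tail is not {n} copies of {motif}"
            )
        tract = ref_tract[: len(ref_tract) - n * ml]
    else:
        tract = ref_tract
    if edit.snps:
        chars = list(tract)
        for pos, base in edit.snps:
            if not 0 <= pos < len(chars):
                raise ValueError(f"SNP position {pos} outside the edited tract")
            chars[pos] = base
        tract = "".join(chars)
    return tract


def random_genotype_spec(
    reference: Mapping[str, str],
    loci: Sequence[TargetLocus],
    n_donors: int = 1,
    seed: Union[int, np.random.Generator, np.random.SeedSequence] = 0,
    delta_range: Tuple[int, int] = (-3, 3),
    snp_prob: float = 0.15,
) -> GenotypeSpec:
    """Draw a random diploid genotype per donor for every locus.

    Repeat deltas are uniform over ``delta_range`` clamped so every allele
    keeps at least three motif copies; each haplotype additionally carries a
    single SNP inside the tract with probability ``snp_prob``, so that
    same-length alleles distinguishable only by sequence occur in truth sets.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    spec: GenotypeSpec = {}
    for locus in loci:
        ref_tract = reference[locus.chrom][locus.start : locus.end]
        k_ref = (locus.length - locus.internal_offset) // locus.motif_length
        lo = max(delta_range[0], -(k_ref - 3))
        hi = max(lo, delta_range[1])
        per_donor = []
        for _ in range(n_donors):
            pair = []
            for _hap in range(2):
                delta = int(rng.integers(lo, hi + 1))
                snps: Tuple[Tuple[int, str], ...] = ()
                if rng.random() < snp_prob:
                    tract = _edited_tract(
                        ref_tract, locus.motif, HaplotypeEdit(repeat_delta=delta)
                    )
                    pos = int(rng.integers(0, len(tract)))
                    current = tract[pos]
                    choices = [b for b in "ACGT" if b != current]
                    snps = ((pos, choices[int(rng.integers(0, 3))]),)
                pair.append(HaplotypeEdit(repeat_delta=delta, snps=snps))
            per_donor.append((pair[0], pair[1]))
        spec[locus.name] = per_donor
    return spec


@dataclass
class Haplotype:
    """One donor haplotype: contig sequences plus their reference alignment.

    ``chains`` map each contig to a CIGAR-like op list (M/I/D over the whole
    contig) relating haplotype to reference coordinates; indels sit strictly
    inside the repeat tracts, one motif length after each tract start.
    """

    seqs: Dict[str, str]
    chains: Dict[str, List[Tuple[int, int]]]
    tracts: Dict[str, str]  # locus name -> allele sequence


@dataclass
class Donor:
    index: int
    weight: float
    haplotypes: List[Haplotype]
    edits: Dict[str, Tuple[HaplotypeEdit, HaplotypeEdit]]


@dataclass(frozen=True)
class TruthAllele:
    locus_name: str
    donor: int
    haplotype: int
    sequence: str
    allele_label: str
    allele_length: int
    donor_weight: float


@dataclass
class TruthSet:
    """Ground truth: per-locus, per-donor haplotype allele sequences/labels."""

    alleles: List[TruthAllele]

    def expected_sequences(self) -> Dict[str, set]:
        out: Dict[str, set] = {}
        for a in self.alleles:
            out.setdefault(a.locus_name, set()).add(a.sequence)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "locus": a.locus_name,
                    "donor": a.donor,
                    "haplotype": a.haplotype,
                    "allele_label": a.allele_label,
                    "allele_length": a.allele_length,
                    "donor_weight": a.donor_weight,
                    "sequence": a.sequence,
                }
                for a in self.alleles
            ]
        )

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class Sample:
    """A simulated sample: reference, panel, donor haplotypes and truth."""

    reference: Dict[str, str]
    loci: List[TargetLocus]
    donors: List[Donor]
    truth: TruthSet


def _merge_ops(ops: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    merged: List[Tuple[int, int]] = []
    for op, ln in ops:
        if ln <= 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    return merged


def _build_haplotype(
    reference: Mapping[str, str],
    loci: Sequence[TargetLocus],
    edits: Mapping[str, HaplotypeEdit],
) -> Haplotype:
    by_chrom: Dict[str, List[TargetLocus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chrom, []).append(locus)
    seqs: Dict[str, str] = {}
    chains: Dict[str, List[Tuple[int, int]]] = {}
    tracts: Dict[str, str] = {}
    for chrom, ref_seq in reference.items():
        parts: List[str] = []
        ops: List[Tuple[int, int]] = []
        pos = 0
        for locus in sorted(by_chrom.get(chrom, []), key=lambda l: l.start):
            if locus.end > len(ref_seq):
                raise ValueError(f"locus {locus.name} exceeds contig {chrom}")
            parts.append(ref_seq[pos : locus.start])
            ops.append((CMATCH, locus.start - pos))
            edit = edits.get(locus.name, HaplotypeEdit())
            ref_tract = ref_seq[locus.start : locus.end]
            tract = _edited_tract(ref_tract, locus.motif, edit)
            tracts[locus.name] = tract
            parts.append(tract)
            lr, lh = len(ref_tract), len(tract)
            anchor = locus.motif_length  # strictly inside both tract versions
            if lh == lr:
                ops.append((CMATCH, lr))
            elif lh > lr:
                ops.extend([(CMATCH, anchor), (CINS, lh - lr), (CMATCH, lr - anchor)])
            else:
                ops.extend([(CMATCH, anchor), (CDEL, lr - lh), (CMATCH, lh - anchor)])
            pos = locus.end
        parts.append(ref_seq[pos:])
        ops.append((CMATCH, len(ref_seq) - pos))
        seqs[chrom] = "".join(parts)
        chains[chrom] = _merge_ops(ops)
    return Haplotype(seqs=seqs, chains=chains, tracts=tracts)


def build_truth_genomes(
    reference: Mapping[str, str],
    loci: Sequence[TargetLocus],
    genotype_spec: GenotypeSpec,
    donor_weights: Optional[Sequence[float]] = None,
) -> Sample:
    """Materialise donor haplotype genomes and the truth set for a genotype.

    Outside the target tracts every haplotype is identical to the reference;
    inside, it carries exactly the specified repeat-count edits and SNPs.
    """
    n_donors = max(len(v) for v in genotype_spec.values()) if genotype_spec else 1
    if donor_weights is None:
        donor_weights = [1.0 / n_donors] * n_donors
    if len(donor_weights) != n_donors:
        raise ValueError("donor_weights length does not match the genotype spec")
    if abs(sum(donor_weights) - 1.0) > 1e-9:
        raise ValueError("donor_weights must sum to 1")
    donors: List[Donor] = []
    truth: List[TruthAllele] = []
    for d in range(n_donors):
        edits_by_locus = {
            name: pairs[d] for name, pairs in genotype_spec.items() if d < len(pairs)
        }
        haplotypes = []
        for h in range(2):
            hap = _build_haplotype(
                reference, loci, {n: e[h] for n, e in edits_by_locus.items()}
            )
            haplotypes.append(hap)
            for locus in loci:
                tract = hap.tracts[locus.name]
                truth.append(
                    TruthAllele(
                        locus_name=locus.name,
                        donor=d,
                        haplotype=h,
                        sequence=tract,
                        allele_label=to_length_allele(
                            len(tract), locus.internal_offset, locus.motif_length
                        ),
                        allele_length=len(tract),
                        donor_weight=donor_weights[d],
                    )
                )
        donors.append(
            Donor(
                index=d,
                weight=donor_weights[d],
                haplotypes=haplotypes,
                edits=edits_by_locus,
            )
        )
    return Sample(
        reference=dict(reference),
        loci=list(loci),
        donors=donors,
        truth=TruthSet(truth),
    )


# --------------------------------------------------------------------------
# read simulation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadMode:
    name: str
    paired: bool
    read_length: int
    frag_mean: int = 0
    frag_sd: float = 0.0
    length_sd: float = 0.0
    error_rate: float = 0.0
    indel_fraction: float = 0.0  # fraction of errors that are indels (half ins, half del)


READ_MODES: Dict[str, ReadMode] = {
    "pe150": ReadMode(
        "pe150", paired=True, read_length=150, frag_mean=450, frag_sd=50.0,
        error_rate=0.001,
    ),
    "pe250": ReadMode(
        "pe250", paired=True, read_length=250, frag_mean=700, frag_sd=70.0,
        error_rate=0.001,
    ),
    "long_ccs": ReadMode(
        "long_ccs", paired=False, read_length=2000, length_sd=200.0,
        error_rate=0.05, indel_fraction=0.5,
    ),
}


def get_read_mode(mode: Union[str, ReadMode]) -> ReadMode:
    if isinstance(mode, ReadMode):
        return mode
    key = mode.lower()
    if key not in READ_MODES:
        raise ValueError(f"unknown read mode {mode!r}; choose from {sorted(READ_MODES)}")
    return READ_MODES[key]


def _edge_clip(ops: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Collapse leading/trailing runs of insertions/clips into soft clips."""
    lead = 0
    while lead < len(ops) and ops[lead][0] in (CSOFT_CLIP, CINS):
        lead += 1
    tail = 0
    while tail < len(ops) - lead and ops[len(ops) - 1 - tail][0] in (CSOFT_CLIP, CINS):
        tail += 1
    out: List[Tuple[int, int]] = []
    if lead:
        out.append((CSOFT_CLIP, sum(ln for _, ln in ops[:lead])))
    out.extend(ops[lead : len(ops) - tail])
    if tail:
        out.append((CSOFT_CLIP, sum(ln for _, ln in ops[len(ops) - tail :])))
    return _merge_ops(out)


def _chain_slice(
    chain: Sequence[Tuple[int, int]], s: int, e: int
) -> Tuple[List[Tuple[int, int]], int]:
    """CIGAR and reference start for haplotype-coordinate slice [s, e)."""
    ops: List[Tuple[int, int]] = []
    ref_start = -1
    hap = 0
    ref = 0
    for op, ln in chain:
        if op == CMATCH:
            lo, hi = max(hap, s), min(hap + ln, e)
            if lo < hi:
                if ref_start < 0:
                    ref_start = ref + (lo - hap)
                ops.append((CMATCH, hi - lo))
            hap += ln
            ref += ln
        elif op == CINS:
            lo, hi = max(hap, s), min(hap + ln, e)
            if lo < hi:
                ops.append((CINS, hi - lo))
            hap += ln
        else:  # deletion: zero haplotype width at position `hap`
            if s < hap < e:
                ops.append((CDEL, ln))
            ref += ln
        if hap >= e:
            break
    if ref_start < 0:
        raise ValueError("read lies entirely within an insertion")
    # edges: leading/trailing insertions become soft clips; stray edge deletions drop
    while ops and ops[0][0] == CDEL:
        ops.pop(0)
    while ops and ops[-1][0] == CDEL:
        ops.pop()
    return _edge_clip(_merge_ops(ops)), ref_start


def _apply_substitutions(
    seq: np.ndarray, rate: float, rng: np.random.Generator
) -> int:
    """In-place substitution errors on a uint8 base array; returns the count."""
    if rate <= 0 or len(seq) == 0:
        return 0
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return 0
    idx = rng.choice(len(seq), size=n, replace=False)
    shift = rng.integers(1, 4, size=n)
    seq[idx] = _BASES[(_BASE_INDEX[seq[idx]] + shift) % 4]
    return int(n)


def _apply_mixed_errors(
    seq: str,
    ops: Sequence[Tuple[int, int]],
    ref_start: int,
    rate: float,
    indel_fraction: float,
    rng: np.random.Generator,
) -> Tuple[str, List[Tuple[int, int]], int]:
    """Substitution + indel errors for long reads, updating the CIGAR.

    Every read base independently suffers a substitution (rate x (1 - f)), a
    deletion (rate x f / 2) or has a random base inserted before it
    (rate x f / 2). Deleting a reference-aligned base leaves a 1 bp deletion;
    deleting an inserted/clipped base simply removes it.
    """
    sub_hi = rate * (1.0 - indel_fraction)
    del_hi = sub_hi + rate * indel_fraction / 2.0
    ins_hi = rate
    # expand per-base ops, with inter-base deletion markers
    per_base: List[int] = []
    del_before: Dict[int, int] = {}
    i = 0
    for op, ln in ops:
        if op == CDEL:
            del_before[i] = del_before.get(i, 0) + ln
        else:
            per_base.extend([op] * ln)
            i += ln
    assert len(per_base) == len(seq)
    u = rng.random(len(seq))
    out_seq: List[str] = []
    out_ops: List[Tuple[int, int]] = []

    def emit(op: int, ln: int) -> None:
        out_ops.append((op, ln))

    for i, base in enumerate(seq):
        if i in del_before:
            emit(CDEL, del_before[i])
        x = u[i]
        op = per_base[i]
        if x < sub_hi:
            choices = [b for b in "ACGT" if b != base]
            out_seq.append(choices[int(rng.integers(0, 3))])
            emit(op, 1)
        elif x < del_hi:
            if op == CMATCH:
                emit(CDEL, 1)
            # inserted/clipped base: drop silently
        elif x < ins_hi:
            out_seq.append("ACGT"[int(rng.integers(0, 4))])
            emit(CINS, 1)
            out_seq.append(base)
            emit(op, 1)
        else:
            out_seq.append(base)
            emit(op, 1)
    if len(seq) in del_before:
        pass  # deletion beyond the read end: outside the alignment, drop
    merged = _merge_ops(out_ops)
    while merged and merged[0][0] == CDEL:
        ref_start += merged[0][1]
        merged.pop(0)
    while merged and merged[-1][0] == CDEL:
        merged.pop()
    return "".join(out_seq), _edge_clip(merged), ref_start


@dataclass(frozen=True)
class ReadProvenance:
    qname: str
    donor: int
    haplotype: int
    chrom: str
    hap_start: int
    hap_end: int


@dataclass
class SimulateResult:
    bam_path: Path
    n_reads: int
    n_bases: int
    mode: ReadMode
    mean_depth: float
    provenance: Optional[List[ReadProvenance]] = None


def _pair_records(
    qname: str,
    chrom: str,
    hap_seq: str,
    chain: Sequence[Tuple[int, int]],
    s: int,
    frag: int,
    read_length: int,
    error_rate: float,
    rng: np.random.Generator,
):
    records = []
    mate_spans = [(s, s + read_length), (s + frag - read_length, s + frag)]
    for mate, (a, b) in enumerate(mate_spans):
        ops, ref_start = _chain_slice(chain, a, b)
        arr = np.frombuffer(hap_seq[a:b].encode(), dtype=np.uint8).copy()
        _apply_substitutions(arr, error_rate, rng)
        flag = 0x1 | 0x2 | (0x40 if mate == 0 else 0x80) | (0x20 if mate == 0 else 0x10)
        records.append(
            {
                "qname": qname,
                "flag": flag,
                "chrom": chrom,
                "pos": ref_start,
                "cigar": ops,
                "seq": arr.tobytes().decode(),
                "span": (a, b),
            }
        )
    r1, r2 = records
    r1["pnext"], r2["pnext"] = r2["pos"], r1["pos"]
    ref_len2 = sum(ln for op, ln in r2["cigar"] if op in (CMATCH, CDEL))
    tlen = r2["pos"] + ref_len2 - r1["pos"]
    r1["tlen"], r2["tlen"] = tlen, -tlen
    return records


def _n_long_reads(hap_len: int, read_length: int, depth: float) -> int:
    """Read count giving `depth` coverage at the contig midpoint."""
    rl = min(read_length, hap_len)
    span = hap_len - rl  # uniform start range [0, span]
    m = hap_len // 2
    covering = min(span, m) - max(0, m - rl + 1) + 1
    p = covering / (span + 1)
    return int(round(depth / p))


def simulate_reads(
    sample: Sample,
    mode: Union[str, ReadMode],
    mean_depth: float,
    out_bam: Union[str, Path],
    error_rate: Optional[float] = None,
    seed: Union[int, np.random.SeedSequence] = 0,
    fastq_prefix: Optional[Union[str, Path]] = None,
    stutter_rate: float = 0.0,
    flank: int = 5,
    keep_provenance: bool = False,
) -> SimulateResult:
    """Draw reads from every donor haplotype and write a sorted, indexed BAM.

    Reads start uniformly over each haplotype; read counts are scaled so the
    realized depth at the locus midpoints matches ``mean_depth`` times the
    donor weight. Alignments (CIGAR + position) are constructed from the known
    haplotype-to-reference correspondence. The same seed reproduces the exact
    record stream. ``stutter_rate`` optionally injects reads from one-motif-
    contracted copies of each allele (geometric across contraction levels),
    for exercising the stutter filter.
    """
    mode = get_read_mode(mode)
    if error_rate is None:
        error_rate = mode.error_rate
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    out_bam = Path(out_bam)
    records: List[dict] = []
    provenance: List[ReadProvenance] = [] if keep_provenance else None
    serial = 0
    loci_by_chrom: Dict[str, List[TargetLocus]] = {}
    for locus in sample.loci:
        loci_by_chrom.setdefault(locus.chrom, []).append(locus)

    def add_single(
        qname: str, chrom: str, hap_seq: str, chain, s: int, rl: int
    ) -> None:
        ops, ref_start = _chain_slice(chain, s, s + rl)
        seq = hap_seq[s : s + rl]
        if mode.indel_fraction > 0 and error_rate > 0:
            seq, ops, ref_start = _apply_mixed_errors(
                seq, ops, ref_start, error_rate, mode.indel_fraction, rng
            )
        elif error_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            _apply_substitutions(arr, error_rate, rng)
            seq = arr.tobytes().decode()
        records.append(
            {
                "qname": qname,
                "flag": 0,
                "chrom": chrom,
                "pos": ref_start,
                "cigar": ops,
                "seq": seq,
                "pnext": -1,
                "tlen": 0,
            }
        )

    for donor in sample.donors:
        for h, hap in enumerate(donor.haplotypes):
            depth_h = mean_depth * donor.weight
            for chrom, hap_seq in hap.seqs.items():
                chain = hap.chains[chrom]
                hap_len = len(hap_seq)
                if mode.paired:
                    frag_mean = min(mode.frag_mean, hap_len)
                    n_pairs = int(
                        round(depth_h * (hap_len - frag_mean + 1) / (2 * mode.read_length))
                    )
                    if n_pairs == 0:
                        logger.warning(
                            "%s donor %d hap %d: expected reads < 1 at depth %.2f",
                            chrom, donor.index, h, depth_h,
                        )
                    frags = np.clip(
                        np.rint(rng.normal(mode.frag_mean, mode.frag_sd, n_pairs)),
                        mode.read_length,
                        hap_len,
                    ).astype(int)
                    starts = rng.integers(0, hap_len - frags + 1)
                    for s, frag in zip(starts, frags):
                        qname = f"sim.d{donor.index}.h{h}.{serial:08d}"
                        serial += 1
                        pair = _pair_records(
                            qname, chrom, hap_seq, chain, int(s), int(frag),
                            mode.read_length, error_rate, rng,
                        )
                        for rec in pair:
                            a, b = rec.pop("span")
                            if provenance is not None:
                                provenance.append(
                                    ReadProvenance(qname, donor.index, h, chrom, a, b)
                                )
                            records.append(rec)
                else:
                    n = _n_long_reads(hap_len, mode.read_length, depth_h)
                    if n == 0:
                        logger.warning(
                            "%s donor %d hap %d: expected reads < 1 at depth %.2f",
                            chrom, donor.index, h, depth_h,
                        )
                    lens = np.clip(
                        np.rint(rng.normal(mode.read_length, mode.length_sd, n)),
                        min(200, hap_len),
                        hap_len,
                    ).astype(int)
                    starts = rng.integers(0, hap_len - lens + 1)
                    for s, rl in zip(starts, lens):
                        qname = f"sim.d{donor.index}.h{h}.{serial:08d}"
                        serial += 1
                        if provenance is not None:
                            provenance.append(
                                ReadProvenance(
                                    qname, donor.index, h, chrom, int(s), int(s + rl)
                                )
                            )
                        add_single(qname, chrom, hap.seqs[chrom], chain, int(s), int(rl))
                # stutter artifact reads, single-ended, spanning the locus
                if stutter_rate > 0:
                    for locus in loci_by_chrom.get(chrom, []):
                        edit = donor.edits.get(
                            locus.name, (HaplotypeEdit(), HaplotypeEdit())
                        )[h]
                        level = 1
                        while True:
                            k_now = (
                                len(hap.tracts[locus.name]) - locus.internal_offset
                            ) // locus.motif_length
                            if k_now - level < 3:
                                break
                            st_edit = HaplotypeEdit(
                                repeat_delta=edit.repeat_delta - level, snps=edit.snps
                            )
                            try:
                                st_hap = _build_haplotype(
                                    {chrom: sample.reference[chrom]},
                                    [locus],
                                    {locus.name: st_edit},
                                )
                            except ValueError:
                                break
                            st_seq = st_hap.seqs[chrom]
                            tract_len = len(st_hap.tracts[locus.name])
                            window = (
                                locus.start - flank,
                                locus.start + tract_len + flank,
                            )
                            rl = mode.read_length
                            lam = (
                                depth_h
                                * (stutter_rate ** level)
                                * max(0, rl - (window[1] - window[0]) + 1)
                                / rl
                            )
                            n_st = rng.poisson(lam)
                            if n_st == 0:
                                break
                            lo = max(0, window[1] - rl)
                            hi = min(window[0], len(st_seq) - rl)
                            if hi < lo:
                                break
                            for _ in range(n_st):
                                s = int(rng.integers(lo, hi + 1))
                                qname = f"stut.d{donor.index}.h{h}.{serial:08d}"
                                serial += 1
                                add_single(
                                    qname, chrom, st_seq, st_hap.chains[chrom], s, rl
                                )
                            level += 1

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": chrom, "LN": len(seq)}
                for chrom, seq in sample.reference.items()
            ],
        }
    )
    tid = {chrom: i for i, chrom in enumerate(sample.reference)}
    records.sort(key=lambda r: (tid[r["chrom"]], r["pos"], r["qname"], r["flag"]))
    n_bases = 0
    with pysam.AlignmentFile(str(out_bam), "wb", header=header) as bam:
        for rec in records:
            seg = pysam.AlignedSegment(header)
            seg.query_name = rec["qname"]
            seg.flag = rec["flag"]
            seg.reference_id = tid[rec["chrom"]]
            seg.reference_start = rec["pos"]
            seg.mapping_quality = 60
            seg.cigartuples = rec["cigar"]
            seg.query_sequence = rec["seq"]
            if rec["flag"] & 0x1:
                seg.next_reference_id = tid[rec["chrom"]]
                seg.next_reference_start = rec["pnext"]
                seg.template_length = rec["tlen"]
            bam.write(seg)
            n_bases += len(rec["seq"])
    pysam.index(str(out_bam))
    if fastq_prefix is not None:
        _write_fastq(records, mode, Path(fastq_prefix))
    return SimulateResult(
        bam_path=out_bam,
        n_reads=len(records),
        n_bases=n_bases,
        mode=mode,
        mean_depth=mean_depth,
        provenance=provenance,
    )


def _write_fastq(records: List[dict], mode: ReadMode, prefix: Path) -> None:
    def fq_entry(rec: dict, revcomp: bool) -> str:
        seq = rec["seq"]
        if revcomp:
            seq = seq.encode().translate(_COMPLEMENT)[::-1].decode()
        return f"@{rec['qname']}\n{seq}\n+\n{'I' * len(seq)}\n"

    if mode.paired:
        with open(f"{prefix}_R1.fastq", "w") as r1, open(f"{prefix}_R2.fastq", "w") as r2:
            for rec in records:
                if rec["flag"] & 0x40:
                    r1.write(fq_entry(rec, revcomp=False))
                elif rec["flag"] & 0x80:
                    r2.write(fq_entry(rec, revcomp=True))
                else:
                    r1.write(fq_entry(rec, revcomp=False))
    else:
        with open(f"{prefix}.fastq", "w") as fq:
            for rec in records:
                fq.write(fq_entry(rec, revcomp=False))


# --------------------------------------------------------------------------
# scoring and the sensitivity experiment
# --------------------------------------------------------------------------


def score_calls(results: Sequence[LocusResult], truth: TruthSet) -> Dict[str, float]:
    """Score called alleles against a truth set with the two sensitivity ratios.

    ``allele_recall`` = correctly called alleles / expected alleles;
    ``locus_dropout`` = incorrectly called loci / expected loci (a locus is
    incorrect unless its called allele set equals its truth set exactly).
    """
    expected = truth.expected_sequences()
    n_expected = n_called = n_correct = n_loci_ok = 0
    for result in results:
        truth_set = expected.get(result.locus.name, set())
        called_set = {c.sequence for c in result.called}
        n_expected += len(truth_set)
        n_called += len(called_set)
        n_correct += len(called_set & truth_set)
        n_loci_ok += int(called_set == truth_set)
    n_loci = len(results)
    return {
        "allele_recall": n_correct / n_expected if n_expected else 1.0,
        "allele_precision": n_correct / n_called if n_called else 1.0,
        "allele_dropout": 1.0 - (n_correct / n_expected if n_expected else 1.0),
        "locus_recall": n_loci_ok / n_loci if n_loci else 1.0,
        "locus_dropout": 1.0 - (n_loci_ok / n_loci if n_loci else 1.0),
        "n_expected": n_expected,
        "n_called": n_called,
        "n_correct": n_correct,
        "n_loci": n_loci,
    }


def sensitivity_experiment(
    modes: Sequence[Union[str, ReadMode]],
    depths: Sequence[float],
    replicates: int,
    seed: int = 0,
    reference: Optional[Mapping[str, str]] = None,
    loci: Optional[Sequence[TargetLocus]] = None,
    config: CallerConfig = CallerConfig(),
    n_donors: int = 1,
    out_path: Optional[Union[str, Path]] = None,
    workdir: Optional[Union[str, Path]] = None,
) -> pd.DataFrame:
    """Recall/dropout across a (mode x depth x replicate) grid.

    Per replicate a fresh random diploid genotype is drawn over the panel,
    genomes are built, reads are simulated, the caller runs with ``config``,
    and calls are scored against the truth set. The same replicate shares its
    genotype across modes and depths, so depth trends are paired. Returns (and
    optionally writes) a tidy table with one row per (mode, depth, replicate).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    import tempfile

    root_ss = np.random.SeedSequence(seed)
    panel_ss, *rep_seqs = root_ss.spawn(replicates + 1)
    if reference is None or loci is None:
        reference, loci = default_panel(seed=panel_ss)
    mode_objs = [get_read_mode(m) for m in modes]
    rows = []
    with tempfile.TemporaryDirectory(
        dir=None if workdir is None else str(workdir)
    ) as tmp:
        tmp = Path(tmp)
        for rep, rep_ss in enumerate(rep_seqs):
            geno_ss, reads_root = rep_ss.spawn(2)
            spec = random_genotype_spec(
                reference, loci, n_donors=n_donors,
                seed=np.random.default_rng(geno_ss),
            )
            sample = build_truth_genomes(reference, loci, spec)
            read_seqs = reads_root.spawn(len(mode_objs) * len(depths))
            k = 0
            for mode in mode_objs:
                for depth in depths:
                    bam = tmp / f"rep{rep}_{mode.name}_{depth}.bam"
                    simulate_reads(
                        sample, mode, depth, out_bam=bam, seed=read_seqs[k]
                    )
                    k += 1
                    results = call_all(bam, loci, config)
                    scores = score_calls(results, sample.truth)
                    rows.append(
                        {"mode": mode.name, "depth": depth, "replicate": rep, **scores}
                    )
                    bam.unlink()
                    Path(str(bam) + ".bai").unlink(missing_ok=True)
    table = pd.DataFrame(rows)
    if out_path is not None:
        table.to_csv(out_path, sep="\t", index=False)
    return table


def write_reference_fasta(
    reference: Mapping[str, str], path: Union[str, Path], width: int = 80
) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


__all__ = [
    "DEFAULT_PANEL_DESIGN",
    "READ_MODES",
    "ReadMode",
    "get_read_mode",
    "HaplotypeEdit",
    "GenotypeSpec",
    "Haplotype",
    "Donor",
    "TruthAllele",
    "TruthSet",
    "Sample",
    "SimulateResult",
    "ReadProvenance",
    "default_panel",
    "random_dna",
    "random_genotype_spec",
    "build_truth_genomes",
    "simulate_reads",
    "score_calls",
    "sensitivity_experiment",
    "write_reference_fasta",
]
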