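"""Allele detection: extraction, classification, filters, length labels."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_spanning_read, write_bam
from tandemcall.core import (
    AlleleCall,
    CallStatus,
    CallerConfig,
    HaplotypeObservation,
    apply_filters,
    call_locus,
    classify_haplotypes,
    extract_tr_sequence,
    max_alleles,
    parse_length_allele,
    stutter_filter,
    to_length_allele,
    validate_motif,
    SkipReason,
)
from tandemcall.targets import TargetLocus

M, I, D, S = 0, 1, 2, 4


def obs(seq, count, total):
    return HaplotypeObservation("L", seq, count, count / total)


# ---------------------------------------------------------------------------
# extraction and motif validation
# ---------------------------------------------------------------------------


def test_extract_pure_match_read():
    locus = TargetLocus("L", "c", 120, 160, "AGAT", 4, 0)
    bases = "T" * 20 + "AGAT" * 10 + "C" * 40
    read = make_spanning_read([(M, 100)], ref_start=100, bases=bases)
    assert extract_tr_sequence(read, locus) == "AGAT" * 10


def test_extract_expanded_allele_includes_insertion():
    # a 2-motif (8 bp) expansion inside a 40 bp locus gives a 48 bp allele
    locus = TargetLocus("L", "c", 120, 160, "AGAT", 4, 0)
    # M24 aligns query 0-23 to ref [100,124): 20 bp flank + first motif; the
    # 8 bp insertion is anchored at ref 124, strictly inside the locus
    bases = "T" * 20 + "AGAT" * 12 + "C" * 40
    read = make_spanning_read(
        [(M, 24), (I, 8), (M, 76)], ref_start=100, bases=bases
    )
    extracted = extract_tr_sequence(read, locus)
    assert extracted == "AGAT" * 12
    assert len(extracted) == 48


def test_extract_skips_clipped_read():
    locus = TargetLocus("L", "c", 120, 160, "AGAT", 4, 0)
    read = make_spanning_read([(S, 30), (M, 70)], ref_start=130)
    assert extract_tr_sequence(read, locus) is SkipReason.NOT_FULLY_SPANNED


@pytest.mark.parametrize(
    "sequence, motif, expected",
    [
        ("ATCGATCGggATCGA", "ATCG", True),
        ("TTTTT", "ATCG", False),
        ("atcgatcg", "ATCG", True),
        ("", "ATCG", False),
    ],
)
def test_validate_motif(sequence, motif, expected):
    assert validate_motif(sequence, motif) is expected


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def test_classify_counts_and_proportions():
    out = classify_haplotypes(["AAC", "AAC", "AACAAC"], "L")
    assert [(o.sequence, o.read_count) for o in out] == [("AAC", 2), ("AACAAC", 1)]
    assert out[0].proportion == pytest.approx(2 / 3)
    assert out[1].proportion == pytest.approx(1 / 3)


def test_classify_single_haplotype_and_empty():
    (only,) = classify_haplotypes(["ACGT"] * 100, "L")
    assert only.read_count == 100 and only.proportion == 1.0
    assert classify_haplotypes([], "L") == []


def test_classify_proportions_sum_to_one():
    seqs = ["A" * 40] * 50 + ["A" * 44] * 30 + ["A" * 36] * 20
    out = classify_haplotypes(seqs, "L")
    assert [o.proportion for o in out] == [0.5, 0.3, 0.2]
    assert sum(o.proportion for o in out) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# thresholds, stutter, cap
# ---------------------------------------------------------------------------


def test_max_alleles():
    assert max_alleles(2, 1) == 2
    assert max_alleles(2, 2) == 4
    assert max_alleles(1, 1) == 1
    with pytest.raises(ValueError):
        max_alleles(0, 1)
    with pytest.raises(ValueError):
        max_alleles(2, 0)


def test_stutter_filter_removes_one_motif_shorter_minor_product():
    parent = obs("A" * 40, 100, 120)
    cand = obs("A" * 36, 20, 120)
    kept, filtered = stutter_filter([parent, cand], 4, 0.25, mixture_mode=False)
    assert kept == [parent] and filtered == [cand]  # 20 < 0.25 * 100


def test_stutter_filter_boundary_kept():
    parent = obs("A" * 40, 100, 130)
    cand = obs("A" * 36, 30, 130)
    kept, filtered = stutter_filter([parent, cand], 4, 0.25, mixture_mode=False)
    assert filtered == [] and cand in kept  # 30 >= 25


def test_stutter_filter_disabled_in_mixture_mode_and_at_zero_ratio():
    parent = obs("A" * 40, 100, 120)
    cand = obs("A" * 36, 20, 120)
    kept, filtered = stutter_filter([parent, cand], 4, 0.25, mixture_mode=True)
    assert filtered == [] and len(kept) == 2
    kept, filtered = stutter_filter([parent, cand], 4, 0.0, mixture_mode=False)
    assert filtered == [] and len(kept) == 2


def test_filtered_stutter_cannot_shelter_its_own_product():
    # 36-mer is stutter of the kept 40-mer; the 32-mer is one motif below the
    # *filtered* 36-mer only, so it survives (no cascading through stutters)
    a = obs("A" * 40, 100, 125)
    b = obs("A" * 36, 20, 125)
    c = obs("A" * 32, 5, 125)
    kept, filtered = stutter_filter([a, b, c], 4, 0.25, mixture_mode=False)
    assert filtered == [b]
    assert c in kept


def test_length_diff_must_equal_motif_length():
    a = obs("A" * 40, 100, 110)
    b = obs("A" * 32, 10, 110)  # two motifs shorter: not stutter
    kept, filtered = stutter_filter([a, b], 4, 0.25, mixture_mode=False)
    assert filtered == []


# ---------------------------------------------------------------------------
# length-based designation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "length, offset, motif_length, label",
    [
        (15, 2, 4, "3.1"),
        (16, 0, 4, "4"),
        (127, 43, 4, "21"),
        (33, 0, 4, "8.1"),
        (30, 2, 4, "7"),
    ],
)
def test_to_length_allele(length, offset, motif_length, label):
    assert to_length_allele(length, offset, motif_length) == label


def test_to_length_allele_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        to_length_allele(2, 2, 4)
    with pytest.raises(ValueError):
        to_length_allele(10, 0, 0)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    length=st.integers(1, 2000),
    offset=st.integers(0, 60),
    motif_length=st.integers(1, 8),
)
def test_label_reconstructs_length(length, offset, motif_length):
    """I x motif_length + F + internal_offset always recovers the bp length."""
    if length <= offset:
        return
    label = to_length_allele(length, offset, motif_length)
    assert parse_length_allele(label, offset, motif_length) == length


# ---------------------------------------------------------------------------
# filter composition
# ---------------------------------------------------------------------------

LOCUS = TargetLocus("L", "c", 100, 140, "AGAT", 4, 0)


def _calls(counts_and_seqs, config):
    total = sum(c for c, _ in counts_and_seqs)
    observations = [obs(s, c, total) for c, s in counts_and_seqs]
    return apply_filters(observations, LOCUS, config)


def status_by_count(calls):
    return {c.read_count: c.status for c in calls}


def test_min_coverage_first_failure_status():
    calls = _calls(
        [(50, "A" * 40), (45, "C" * 44), (1, "G" * 48)],
        CallerConfig(min_coverage=2, min_proportion=0.0),
    )
    assert status_by_count(calls) == {
        50: CallStatus.CALLED,
        45: CallStatus.CALLED,
        1: CallStatus.FILTERED_COVERAGE,
    }


def test_cap_filters_third_haplotype_for_single_diploid_donor():
    calls = _calls(
        [(50, "A" * 40), (48, "C" * 44), (47, "G" * 48)],
        CallerConfig(min_proportion=0.0),
    )
    assert status_by_count(calls)[47] == CallStatus.FILTERED_CAP


def test_two_donor_cap_allows_four_alleles():
    calls = _calls(
        [(50, "A" * 40), (48, "C" * 44), (47, "G" * 48), (40, "T" * 52)],
        CallerConfig(min_proportion=0.0, donors=2),
    )
    assert all(c.status is CallStatus.CALLED for c in calls)


def test_proportion_filter_uses_classified_denominator():
    calls = _calls(
        [(90, "A" * 40), (9, "C" * 44)], CallerConfig(min_proportion=0.10)
    )
    assert status_by_count(calls)[9] == CallStatus.FILTERED_PROPORTION


def test_cap_tie_breaks_prefer_shorter_then_lexicographic():
    calls = _calls(
        [(50, "A" * 44), (50, "C" * 40), (50, "A" * 40)],
        CallerConfig(min_proportion=0.0),
    )
    called = {c.sequence for c in calls if c.status is CallStatus.CALLED}
    assert called == {"A" * 40, "C" * 40}  # shorter first, then lexicographic


def test_allele_label_attached_to_every_call():
    calls = _calls([(50, "A" * 40), (45, "C" * 46)], CallerConfig(min_proportion=0.0))
    by_seq = {c.sequence: c for c in calls}
    assert by_seq["A" * 40].allele_label == "10"
    assert by_seq["C" * 46].allele_label == "11.2"
    for c in calls:
        assert c.allele_length == len(c.sequence)


def test_raising_thresholds_never_expands_the_called_set():
    """Monotonicity: stricter coverage/proportion => called subset shrinks."""
    rng = np.random.default_rng(5)
    for _ in range(25):
        n = int(rng.integers(1, 8))
        counts = sorted(rng.integers(1, 120, n), reverse=True)
        total = int(sum(counts))
        observations = [
            obs("A" * int(40 + 4 * i), int(c), total) for i, c in enumerate(counts)
        ]
        base = {
            c.sequence
            for c in apply_filters(observations, LOCUS, CallerConfig())
            if c.status is CallStatus.CALLED
        }
        for cfg in (
            CallerConfig(min_coverage=10),
            CallerConfig(min_proportion=0.3),
            CallerConfig(min_coverage=10, min_proportion=0.3),
        ):
            stricter = {
                c.sequence
                for c in apply_filters(observations, LOCUS, cfg)
                if c.status is CallStatus.CALLED
            }
            assert stricter <= base


# ---------------------------------------------------------------------------
# call_locus end to end on hand-built alignments
# ---------------------------------------------------------------------------


def _tract_bam(tmp_path, locus, alleles_with_counts, contig_len=1000):
    """Reads spanning the locus, each carrying a given allele sequence."""
    records = []
    i = 0
    for allele, count in alleles_with_counts:
        lr = locus.length
        lh = len(allele)
        if lh == lr:
            cigar = [(M, 200 + lh)]
        elif lh > lr:
            cigar = [(M, 100 + locus.motif_length), (I, lh - lr), (M, 100 + lr - locus.motif_length)]
        else:
            cigar = [(M, 100 + locus.motif_length), (D, lr - lh), (M, 100 + lh - locus.motif_length)]
        seq = "T" * 100 + allele + "C" * 100
        for _ in range(count):
            records.append(
                {"name": f"r{i}", "chrom": locus.chrom, "pos": locus.start - 100,
                 "cigar": cigar, "seq": seq}
            )
            i += 1
    path = tmp_path / "reads.bam"
    write_bam(path, [(locus.chrom, contig_len)], records)
    return path


def test_call_locus_homozygous(tmp_path):
    locus = TargetLocus("HOM", "c", 400, 440, "AGAT", 4, 0)
    bam = _tract_bam(tmp_path, locus, [("AGAT" * 10, 30)])
    result = call_locus(bam, locus)
    (call,) = result.called
    assert call.sequence == "AGAT" * 10
    assert call.read_count == 30
    assert call.allele_label == "10"


def test_call_locus_heterozygous_15_17(tmp_path):
    locus = TargetLocus("HET", "c", 400, 460, "AGAT", 4, 0)
    bam = _tract_bam(
        tmp_path, locus, [("AGAT" * 15, 26), ("AGAT" * 17, 24)]
    )
    result = call_locus(bam, locus)
    assert sorted((c.allele_label, c.read_count) for c in result.called) == [
        ("15", 26),
        ("17", 24),
    ]


def test_call_locus_conservation_of_reads(tmp_path):
    locus = TargetLocus("QC", "c", 400, 440, "AGAT", 4, 0)
    records = []
    # 10 good reads, 3 non-spanning, 2 spanning but motif-free
    for i in range(10):
        records.append({"name": f"g{i}", "chrom": "c", "pos": 300,
                        "cigar": [(M, 240)], "seq": "T" * 100 + "AGAT" * 10 + "C" * 100})
    for i in range(3):
        records.append({"name": f"p{i}", "chrom": "c", "pos": 300,
                        "cigar": [(M, 110), (S, 130)],
                        "seq": "T" * 240})
    for i in range(2):
        records.append({"name": f"m{i}", "chrom": "c", "pos": 300,
                        "cigar": [(M, 240)], "seq": "T" * 240})
    bam = write_bam(tmp_path / "qc.bam", [("c", 1000)], records)
    result = call_locus(bam, locus)
    t = result.tallies
    # the 3 clipped reads are rejected by the spanning fetch itself
    assert t.fetched == 12
    assert t.fetched == t.skipped_incomplete + t.motif_invalid + t.classified
    assert t.motif_invalid == 2
    assert t.classified == 10
    assert sum(c.read_count for c in result.calls) == t.classified


def test_call_locus_absent_chromosome_is_a_warned_no_call(tmp_path):
    locus = TargetLocus("NC", "nowhere", 400, 440, "AGAT", 4, 0)
    other = TargetLocus("X", "c", 400, 440, "AGAT", 4, 0)
    bam = _tract_bam(tmp_path, other, [("AGAT" * 10, 5)])
    result = call_locus(bam, locus)
    assert result.calls == [] and result.warning is not None
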