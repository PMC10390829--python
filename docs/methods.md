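# Methods

## Calling model and assumptions

`tandemcall` genotypes a tandem-repeat locus exclusively from reads whose
aligned reference span contains the locus interval plus a required flank on
each side (default 5 bp, configurable). The model assumes that (a) the
aligner has placed spanning reads correctly at the locus — mapping failure
and mis-mapping are the dominant error modes, mitigated by the MAPQ filter
but not modelled further; (b) within a spanning read, the CIGAR faithfully
relates read bases to reference coordinates; and (c) two reads sequenced
from the same allele yield the identical extracted sequence unless a
sequencing error intervenes. Alleles longer than the read length minus
flanks are by construction uncallable (no inference of unspanned
expansions); this is a deliberate scope boundary, not a defect, and the
structural-dropout test asserts it.

### Boundary projection

The locus interval is projected into read coordinates by one left-to-right
pass over the CIGAR with reference and query cursors:

* insertions whose anchor lies strictly inside `(start, end)` are part of
  the allele; insertions anchored exactly at `start` or `end` are assigned
  to the flank (a half-open-interval convention; some aligners left-shift
  tract indels to the tract boundary, in which case those bases would be
  attributed to the flank — see Limitations);
* a boundary inside a deletion (or `N` skip) snaps to the nearest aligned
  base inside the interval, so a tract-internal deletion shortens the
  extracted allele rather than invalidating the read;
* a boundary inside a soft clip, or outside the aligned span, is a spanning
  failure — the read is tallied and skipped, never fatal.

The projection is validated against an independent per-base
alignment-column oracle on 1000+ random aligner-shaped CIGARs.

### Classification and filters

Haplotypes are exact-identity groups of extracted sequences. No
error-tolerant clustering is attempted: the reported haplotypes are
verbatim observations, and sequencing errors surface as low-count singleton
haplotypes that the coverage/proportion filters remove. Filters run in a
fixed order — coverage, proportion, stutter, allele cap — and every
observation keeps the status of the first filter it failed, so the raw
report is fully auditable.

The stutter filter is one-sided: a candidate exactly one motif *shorter*
than a kept haplotype, with read count below `stutter_ratio ×` the parent's
count, is marked as a PCR slippage product. Contraction stutter dominates
PCR slippage, and a two-sided rule would risk deleting genuine short
alleles. Candidates are processed in descending count order so a filtered
stutter cannot shelter further products; it is applied only to single-source
runs (in a mixture a minor contributor's allele is indistinguishable from a
major contributor's stutter by count ratio) and a ratio of 0 disables it.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `min_coverage` | 2 reads | haplotype support floor; ~2 suits 30x WGS, ~10 suits deep amplicon data |
| `min_proportion` | 0.10 | fraction of classified reads at the locus; denominator excludes unspanned/motif-invalid reads so junk cannot dilute real alleles |
| `donors` (`d`) | 1 | assumed contributors; cap = ploidy × d; d > 1 disables the stutter filter |
| `default_stutter_ratio` | 0.25 | count ratio for the stutter rule; per-locus BED values override |
| `flank` | 5 bp | required aligned flank on each side of the tract |
| `min_mapq` | 1 | excludes multi-placed (MAPQ 0) reads |

Ties at the allele cap break by higher count, then shorter allele, then
lexicographic sequence — output is deterministic byte-for-byte, including
under per-locus multithreading (ordered merge).

## The synthetic-data generator

The simulator emulates a coverage-titration sensitivity study on a 20-locus
panel. Because the caller is coordinate-generic, small synthetic contigs
(default 3 kb, one centred tract each) stand in for a human reference.

* **Panel.** Motifs of 3–5 bp with reference tract lengths of 24–65 bp,
  the small-to-mid range of forensic core STR tracts; three loci carry a
  2 bp non-repeat internal spacer to exercise the internal-offset arm of
  the length conversion. All alleles remain spannable by 150 bp reads.
* **Genotypes.** Per donor haplotype and locus: a repeat delta uniform on
  [−3, +3] (clamped to keep ≥ 3 motif copies) and, with probability 0.15, a
  single SNP inside the tract, so same-length alleles that differ only in
  sequence occur in truth sets.
* **Depth semantics.** `mean_depth` is the depth contributed by *each*
  donor haplotype at the locus midpoint, scaled by the donor's mixture
  weight (read counts are solved from the uniform-start geometry so the
  realized midpoint depth matches the request; an invariant test checks
  ±10%).
* **Read modes.** `pe150`/`pe250`: paired ends with Gaussian fragment sizes
  (450 ± 50, 700 ± 70 bp) and independent substitution errors at 0.001/base,
  the scale of modern Illumina platforms. `long_ccs`: single reads of
  2000 ± 200 bp with mixed substitution/indel errors (1:1) totalling
  0.05/base, i.e. 95% base accuracy. Error rates are per-mode defaults and
  overridable per run.
* **Truth alignments.** Haplotype-to-reference correspondence is known, so
  each read's CIGAR and position are constructed exactly (indels placed one
  motif length inside the tract), decoupling caller tests from any external
  aligner; FASTQ export exists for optional end-to-end runs through a real
  aligner. Injected indel errors update the CIGAR consistently.
* **Stutter injector.** For filter testing only: extra reads drawn from
  one-motif-contracted allele copies at a configurable rate, geometric
  across contraction levels. No attempt is made to model PCR chemistry.

What passing simulations do **not** show about real data: mapping and
reference bias, non-uniform coverage, platform-specific error motifs
(e.g. homopolymer indels), PCR duplicate structure, and aligner-specific
indel placement at tract boundaries are all outside the generator.

## Sensitivity scoring

Per replicate, allele recall = correctly called alleles / expected alleles
and locus dropout = incorrectly called loci / expected loci, where an
expected allele is a distinct truth sequence at a locus and a locus is
incorrect unless its called set equals its truth set exactly. Precision
(correct called / all called) is reported alongside.

Measured under the defaults (100 seeded replicates, 20 loci): recall at
25x PE150 exceeds 99.9%, and called alleles match truth in every PE250
replicate at 30x and above. At 5x with 95%-accuracy long reads, recall is
far lower (~20%): with exact-identity classification an allele needs at
least `min_coverage` *error-free* copies of the tract, and at a 5% per-base
error rate the chance a read crosses a 24–65 bp tract cleanly is only
0.04–0.29, so clean coverage at 5x is fractional. High long-read recall at
low depth therefore requires high consensus accuracy (real CCS reads are
~Q20–Q30, far above 95%). Similarly, at 10x PE250 the spanning-read count
per haplotype is Poisson with mean ≈ 6–9, so the ≥ 2-read requirement alone
leaves recall near 99.5%, not arbitrarily close to 100%.

## Numerical and design choices

* BED coordinates are 0-based half-open throughout; motifs are upper-cased
  on ingest; duplicate locus names are rejected in strict parsing.
* Reverse-strand reads are consumed in reference orientation as stored in
  the BAM; motif matching is forward-only.
* Both mates of a pair count independently; only a mate that itself spans
  the locus contributes.
* `N` (reference skip) operations are treated as deletions for span and
  projection purposes.
* A degenerate extracted sequence not longer than the internal offset gets
  no length label (reported as `.`); an empty extraction fails motif
  validation and is tallied.
* The TSV reports contain no timestamp so repeated runs are byte-identical;
  the JSON sidecar carries the timestamp.
* Seeding uses `numpy` `SeedSequence` spawning: one root seed
  deterministically derives panel, genotype, and per-replicate read streams.

## Known limitations

* Alleles that real aligners represent with indels anchored exactly at the
  tract boundary (left-aligned indels) lose those bases to the flank under
  the projection convention; truth alignments avoid this by construction,
  real BAMs may not.
* Exact-identity classification trades error tolerance for auditability:
  high error rates convert recall loss into singleton noise rather than
  wrong calls (precision stays at 100% in all measured conditions).
* The stutter rule is count-based only; it does not model locus-specific
  stutter propensity beyond the per-locus ratio column.
* Mixtures are supported through the allele cap and disabled stutter
  filtering; donor deconvolution (assigning alleles to contributors) is out
  of scope.
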