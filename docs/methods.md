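# Methods

`retronscan` models the computational side of a retron-recombineering-based
directed-evolution experiment: the design of single-stranded DNA donor pools
that program edits into a phage-carried sensor-effector transgene, and the
short- and long-read sequencing analyses that quantify how those edits fare
under selection. This note records the model, the defaults, and the design
choices made where the problem was genuinely open.

## The reference model

The transgene is a single in-frame CDS partitioned into five codon-aligned
regions: `effector_N | left_linker (SG) | insert_domain | right_linker (GS) |
effector_C`. This mirrors the common architecture of allosteric
sensor-effector chimeras in which a light-sensing LOV2-type domain is
inserted into a transcription factor behind short serine-glycine junction
linkers. Nucleotide coordinates are 0-based half-open everywhere inside the
package; residue numbers in reports are 1-based and carry a per-region
offset so that insert-domain residues can be reported in the numbering of
the full-length parent photoreceptor (the packaged fixture maps its
141-residue insert to residues 404-544) while effector residues continue the
effector's own numbering across the insertion.

The packaged fixture construct is synthetic: a deterministic RNG stream
draws sense codons at ~50% GC for a 170-codon N-effector, a 141-codon
insert, and a 351-codon C-effector (1998 nt total, inside the long-read QC
window), with the SG/GS linkers fixed and the insert terminating in the
IDEAA motif that anchors the C-terminal helix series. Candidate sequences
are redrawn until (i) the CDS is stop-free, (ii) the twelve-nt junction
anchor motifs are unique, and (iii) no donor of the two default libraries
contains a BsaI-style recognition site on either strand, so the designed
pools are clonable as-is. No natural sequence is redistributed.

## Donor design

Every programmed edit is an interval replacement on the reference
(`nt_start`, `nt_end`, `payload`); all designed edits are in-frame and
bounded at |net change| <= 15 nt. The homology donor is 90 nt of the
*edited* sequence with the payload centered; when 90 - payload is odd the
left arm is one nt shorter (left = floor((90-p)/2)). Donors are emitted for
the coding strand; a reverse-complement option exists for retrons that
target the other strand, which is a wet-lab choice the designer cannot
infer.

The scanning (DMS) library substitutes every codon of the target region to
all 20 residues using the host's most preferred codon (embedded E. coli
K-12 usage fractions; argmax per residue with a lexicographic tie-break;
the table is user-replaceable). Recodings whose preferred codon equals the
native codon are retained and flagged no-op: they keep the library
enumeration exact (region codons x 20) and measure recoding background.

The junction library emits, per junction: deletions removing the 2-aa
linker plus 1-3 adjacent effector residues (net -9/-12/-15 nt — the only
reading of "del1-del3" consistent with a 15-bp maximum payload change); a
no-linker deletion (-6); all 20 single-residue replacements (the `LdelK`
nomenclature); flexible (GG, GXG expanded over all 20 X, GGSG, GSGG, GSGSG)
and rigid (PP, GPPG, GPPPG, GPPPPG) panels, where a peptide containing an
SG/GS motif is inserted adjacent to the native junction and one lacking it
replaces the junction; a silent preferred-codon recoding of each native
linker (aa-identical, nt-distinct — silent junction variants are observed
and must be nameable); and, at the right junction, a C-terminal helix
series I...IDEAAKEL replacing the insert's terminal IDEAA (net -12..+9 nt).
With default panels this is 113 donors and the library-wide maximum |net
change| is exactly 15 bp.

Oligos are `fwd_barcode | TypeIIS flank | donor | TypeIIS flank |
rev_barcode`. The default flanks model a BsaI-style 6-nt recognition site
plus 4-nt fusion sites; donors carrying the recognition site on either
strand are rejected rather than silently recoded. Barcode schemes are
validated exhaustively (pairwise Hamming >= 3 by default, GC within 25-75%,
site-free); a greedy seeded generator is provided for simulation use.

## Synthetic data

The simulator exists so every pipeline stage is testable against known
ground truth; it emulates the statistical structure the analyses assume,
not the platform physics.

* **Pools** map variant names to (full edited sequence, frequency);
  frequencies are validated to sum to 1.
* **Selection** is multiplicative fitness per condition followed by an
  optional multinomial bottleneck (`n = 0` means deterministic
  reweighting), emulating alternating positive/negative selection passages
  with ~1:100 dilutions.
* **Short reads** are dual-barcoded paired 250-nt amplicon reads
  (barcode + primer + template prefix; mate 2 is the reverse complement
  end) with substitution errors only — the platform's dominant error mode.
* **Long reads** are full-length amplicons with substitution and indel
  errors, plus an optional labelled junk fraction (truncated or uniformly
  low-quality reads) to exercise QC.
* Qualities are Phred+33 with correct bases near Q30 and erroneous bases
  near Q12, so Q<20 trimming and the mean-quality filter see realistic
  input. Identical seeds give byte-identical FASTQ.

Not modelled: homopolymer-dependent Nanopore error structure, PCR chimeras,
quality-by-cycle decay. Passing tests therefore demonstrate correctness of
the counting/filtering logic under the stated error model, not robustness
to every artifact of real flow cells.

## Alignment

Both pipelines share one affine-gap aligner (match +1, mismatch -2, gap
open -4 on the first gapped base, extend -1): Smith-Waterman local mode for
short reads, end-gap-free overlap mode for full-length long reads. The
engine is Bio.Align.PairwiseAligner's C implementation behind a tiered fast
path: exact substring match, then a seeded ungapped placement accepted only
when a prefix/suffix guard (trimming k terminal columns with t mismatches
changes the score by 3t - k; the guard requires this to be <= 0 for every
prefix and suffix, and under this scoring a mismatch column can never be
profitably replaced by gap columns) certifies the placement is
Smith-Waterman optimal. Reads failing the guard — in particular any read
with a genuine indel — fall through to the full dynamic program. The test
suite holds the aligner to an independent exhaustive Gotoh oracle on all
instances up to 30 nt and checks fast-path/DP score agreement on realistic
reads. Alignments below half the read length in score are reported
unaligned. "Shifted" alignments are those starting more than 3 nt from the
expected amplicon start.

## Short-read pipeline defaults

* Demultiplexing requires exact forward AND reverse barcode matches
  (minimizes index swapping); everything else is rejected, and
  assigned + rejected always equals input.
* Primers must match the read start within 5 mismatches (mutagenesis can
  hit primer sites); reads are then truncated at the first base with Q < 20.
* Scanning mode drops indel-containing and shifted alignments and tallies
  per-position nt/codon/aa counts; positions below 2,000 reads are masked
  at reporting time only, so raw counts remain re-thresholdable and raising
  the floor can never unmask a position.
* Junction mode allows in-frame indels (net length divisible by 3), requires
  reads to span the junction window (linker +- 9 nt by default), and
  collapses reads to nt-level window sequences with aa translations.
* Pair classification: wild type only when both mates align event-free;
  any event makes the pair mutant; pairs whose combined reference span is
  below 80% of the reference are excluded. The three classes partition the
  input.
* A `forward_only` flag supports runs whose reverse reads are unusable, and
  a user exclusion list drops known-artifact reference positions from
  reports.

## Long-read pipeline defaults

* QC: strict bounds 1800 < length < 2200 and mean quality > Q20, with the
  mean computed on the error-probability scale and converted back to Phred
  (the convention of standard long-read QC tools; the arithmetic mean of
  Phred values is deliberately not used and a test guards the difference).
* Scanning mode projects each aligned read onto a uniform reference window:
  insertions removed, deletions refilled with reference bases, output length
  always equal to the window length; reads not covering the window are
  dropped. Projection is idempotent on substitution-only reads.
* Junction mode never "corrects" indels: junction windows are located per
  read by two conserved 12-nt flanking motifs (<= 1 mismatch each; ties are
  ambiguous and filtered). The anchors bracket the *editable* window — 9 nt
  into the effector on each side and 15 nt into the insert terminus on the
  right — so junction deletions and the helix series do not destroy their
  own anchors. Frame-shifting junction indels are filtered; variants below
  a 0.01% noise floor are dropped from tables; reads partition into
  WT / left-only / right-only / both / filtered.
* Temporal enrichment subtracts the first-mutagenesis-passage baseline
  column from per-step residue mutation rates; corrected values are signed
  (depletion stays negative) and the correction is exactly invertible. The
  uncorrected matrix is always kept alongside.
* Artifact flagging lists residues whose control-sample mutation rate
  exceeds a threshold (default 0.5 — consistent systematic basecalling
  errors stand far above real background, so the default is permissive).
* Co-occurrence includes mutations present in >= 9.5% of reads; joint
  within-read frequencies are checked against the joint <= min(marginals)
  bound on every construction.
* Variance ranking reports the top-k (default 10) variants by frequency
  variance across steps with a lexicographic tie-break; logo tables retain
  non-reference residues above 1% per position, grouped into fixed
  physicochemical classes (KRH positive, DE negative, STNQCY polar,
  AVLIMFW hydrophobic, GP special).

## Problem sizes used by the test suite

The round-trip recovery properties run at 10^5 short reads (exact recovery
at zero error; 3-binomial-sigma recovery at substitution rate 0.005) and at
2x10^4 long reads with a substitution-only noise model; indel-rich noise,
junk-read filtering and junction calling are exercised at a few hundred to
a few thousand reads. These sizes make every binomial bound tight at the n
actually simulated. The acceptance script runs the single-site editing
round trip at 10^4 reads.

## Known limitations

* The junction anchors assume the flanking motifs stay unedited; libraries
  that mutate the anchor regions themselves (e.g. scanning edits inside the
  insert's last five codons) will shed those reads as unanchored rather
  than call them.
* The overlap aligner reports one optimal alignment; co-optimal indel
  placements (repeats) resolve deterministically but not necessarily at the
  biologically "true" position.
* Frequencies are per-read maximum-parsimony calls; no error-aware
  probabilistic genotyping is attempted.
* `compare_libraries` ranks over the union of variants with missing entries
  as zero, which depresses rank correlation when universes differ wildly;
  this matches the normalize-both-to-1 convention it implements.
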