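"""Long-read (full-length amplicon) analysis.

Nanopore-style reads are noisy and indel-rich, so the workflow differs from
the short-read pipeline: strict length/mean-quality QC, end-gap-free
alignment of the whole amplicon, and either (a) substitution-scanning mode,
where CIGAR-equivalent event lists are used to *correct* indels (insertions
removed, deletions refilled from the reference) and reads are projected onto
a uniform reference window, or (b) junction mode, where indels are genuine
signal and junction windows are located by conserved flanking motifs rather
than by alignment.  Downstream summaries -- temporal enrichment with
baseline subtraction, artifact flagging, within-read co-occurrence, variance
ranking, and per-position residue-class tables -- all operate on these
projections.

Mean read quality follows the error-probability convention: the per-base
Phred scores are converted to error probabilities, averaged, and converted
back (NOT the arithmetic mean of Phred values).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .alignment import AlignmentRecord, ReferenceIndex, align_overlap
from .codon_usage import translate
from .illumina_pipeline import PositionCounts, Read, read_fastq
from .reference_model import TransgeneConstruct, junction_ref_windows, locate_junctions

_PHRED_OFFSET = 33

#: physicochemical classes used in enrichment-logo tables
AA_CLASSES: Dict[str, str] = {}
for _aa in "KRH":
    AA_CLASSES[_aa] = "positive"
for _aa in "DE":
    AA_CLASSES[_aa] = "negative"
for _aa in "STNQCY":
    AA_CLASSES[_aa] = "polar"
for _aa in "AVLIMFW":
    AA_CLASSES[_aa] = "hydrophobic"
for _aa in "GP":
    AA_CLASSES[_aa] = "special"


class LongReadError(ValueError):
    pass


@dataclass(frozen=True)
class LongReadQC:
    """Length and mean-quality gates (all strict inequalities)."""

    min_len: int = 1800
    max_len: int = 2200
    min_mean_q: float = 20.0

    def __post_init__(self) -> None:
        if not 0 < self.min_len < self.max_len:
            raise LongReadError("require 0 < min_len < max_len")


def mean_read_quality(qual: str) -> float:
    """Mean quality on the error-probability scale, reported as Phred."""
    q = np.frombuffer(qual.encode(), dtype=np.uint8).astype(float) - _PHRED_OFFSET
    p = np.power(10.0, -q / 10.0)
    return float(-10.0 * np.log10(p.mean()))


def filter_longreads(
    reads: Iterable[Read],
    qc: Optional[LongReadQC] = None,
) -> Tuple[List[Read], Dict[str, int]]:
    """Retain reads with min_len < length < max_len and mean Q > threshold."""
    qc = qc or LongReadQC()
    kept: List[Read] = []
    report = {"input": 0, "retained": 0, "failed_length": 0, "failed_quality": 0}
    for read in reads:
        report["input"] += 1
        rid, seq, qual = read
        if not qc.min_len < len(seq) < qc.max_len:
            report["failed_length"] += 1
            continue
        if not mean_read_quality(qual) > qc.min_mean_q:
            report["failed_quality"] += 1
            continue
        kept.append(read)
        report["retained"] += 1
    return kept, report


def filter_longread_file(fastq_path, qc: Optional[LongReadQC] = None):
    return filter_longreads(read_fastq(fastq_path), qc)


# -- substitution-scanning mode ---------------------------------------------


def align_longreads(
    reads: Iterable[Read],
    construct: TransgeneConstruct,
) -> List[Optional[AlignmentRecord]]:
    index = ReferenceIndex(construct.cds)
    return [align_overlap(seq, index, read_id=rid) for rid, seq, _ in reads]


def correct_indels_dms(
    alignment: Optional[AlignmentRecord],
    reference: str,
    window: Tuple[int, int],
) -> Optional[str]:
    """Substitution-only projection of an aligned read onto a uniform window.

    Insertions are removed and deletions are filled with reference bases, so
    the output length always equals the window length; reads not covering
    the window are dropped (None).
    """
    if alignment is None:
        return None
    return alignment.projected(reference, window[0], window[1])


def position_frequencies(
    projections: Sequence[str],
    construct: TransgeneConstruct,
    window_start: int = 0,
) -> PositionCounts:
    """Per-position counts from equal-length substitution-only projections."""
    if not projections:
        raise LongReadError("no projections to count")
    W = len(projections[0])
    ref_window = construct.cds[window_start : window_start + W]
    if any(len(p) != W for p in projections):
        raise LongReadError("projections must share the uniform window length")
    counts = PositionCounts(ref_seq=ref_window, window_start=window_start)
    n = len(projections)
    counts.nt_depth += n
    counts.codon_depth += n
    counts.n_reads_used = n
    ref_arr = np.frombuffer(ref_window.encode(), dtype=np.uint8)
    mat = np.frombuffer("".join(projections).encode(), dtype=np.uint8).reshape(n, W)
    diff_rows, diff_cols = np.nonzero(mat != ref_arr)
    base_index = {65: 0, 67: 1, 71: 2, 84: 3}
    for r, c in zip(diff_rows, diff_cols):
        bi = base_index.get(int(mat[r, c]))
        if bi is not None:
            counts.nt_alt[c, bi] += 1
    # sparse codon tallies: only reads x codons touched by a mismatch
    touched: Dict[int, set] = {}
    for r, c in zip(diff_rows, diff_cols):
        touched.setdefault(int(r), set()).add(int(c) // 3)
    for r, codons in touched.items():
        row = projections[r]
        for local_ci in codons:
            codon = row[3 * local_ci : 3 * local_ci + 3]
            ci = window_start // 3 + local_ci
            counts.codon_alt.setdefault(ci, Counter())[codon] += 1
    return counts


# -- junction mode ----------------------------------------------------------


@dataclass
class LinkerCallResult:
    table: pd.DataFrame  # junction, nt_seq, aa_seq, count, frequency, is_reference
    classes: List[str]  # per retained read: WT / left-only / right-only / both
    class_counts: Dict[str, int]  # includes 'filtered'; partitions the input


def extract_linker_variants(
    reads: Iterable[Read],
    construct: TransgeneConstruct,
    noise_floor: float = 0.0001,
    motif_len: int = 12,
    max_mismatch: int = 1,
) -> LinkerCallResult:
    """Motif-anchored junction variant calling on raw long reads.

    Junction windows are located by conserved flanking motifs (indels stay
    genuine); reads whose motifs are missing or ambiguous, or whose net
    junction indel is frame-shifting, are filtered.  Each retained read is
    classed by which junctions deviate from the reference linker sequence;
    variants below ``noise_floor`` are dropped from the table.
    """
    windows = junction_ref_windows(construct)
    ref_left = construct.cds[windows["left"][0] : windows["left"][1]]
    ref_right = construct.cds[windows["right"][0] : windows["right"][1]]
    classes: List[str] = []
    tallies = {"left": Counter(), "right": Counter()}
    class_counts: Dict[str, int] = Counter({"filtered": 0})
    for rid, seq, _qual in reads:
        anchors = locate_junctions(seq, construct, motif_len, max_mismatch)
        if anchors.left is None or anchors.right is None:
            class_counts["filtered"] += 1
            continue
        left_nt = seq[anchors.left[0] : anchors.left[1]]
        right_nt = seq[anchors.right[0] : anchors.right[1]]
        if (len(left_nt) - len(ref_left)) % 3 or (len(right_nt) - len(ref_right)) % 3:
            class_counts["filtered"] += 1
            continue
        tallies["left"][left_nt] += 1
        tallies["right"][right_nt] += 1
        edited_left = left_nt != ref_left
        edited_right = right_nt != ref_right
        cls = (
            "both" if edited_left and edited_right
            else "left-only" if edited_left
            else "right-only" if edited_right
            else "WT"
        )
        classes.append(cls)
        class_counts[cls] += 1
    rows = []
    for junction, tally in tallies.items():
        total = sum(tally.values())
        ref_nt = ref_left if junction == "left" else ref_right
        for nt_seq, count in tally.most_common():
            freq = count / total if total else 0.0
            if freq < noise_floor:
                continue
            aa = translate(nt_seq) if len(nt_seq) % 3 == 0 else ""
            rows.append((junction, nt_seq, aa, count, freq, nt_seq == ref_nt))
    df = pd.DataFrame(
        rows, columns=["junction", "nt_seq", "aa_seq", "count", "frequency", "is_reference"]
    )
    return LinkerCallResult(df, classes, dict(class_counts))


# -- temporal enrichment ----------------------------------------------------


@dataclass
class TemporalMatrix:
    """Residues x pipeline-steps mutation-rate matrix with baseline correction.

    ``raw`` holds per-step residue mutation rates in [0, 1]; ``corrected``
    subtracts the baseline column (signed: depletion stays negative)."""

    raw: pd.DataFrame
    corrected: pd.DataFrame
    baseline_step: str


def temporal_enrichment(
    per_step_counts: Sequence[Tuple[str, PositionCounts]],
    baseline_label: str,
) -> TemporalMatrix:
    """Residue-level mutation rates per step, baseline-subtracted."""
    if len(per_step_counts) < 2:
        raise LongReadError("need at least two pipeline steps")
    labels = [lbl for lbl, _ in per_step_counts]
    if baseline_label not in labels:
        raise LongReadError(f"baseline step {baseline_label!r} not among {labels}")
    first = per_step_counts[0][1]
    residues = np.arange(
        first.window_start // 3 + 1, first.window_start // 3 + 1 + len(first.codon_depth)
    )
    raw = pd.DataFrame(
        {lbl: counts.aa_mutation_rate() for lbl, counts in per_step_counts},
        index=pd.Index(residues, name="residue"),
    )
    corrected = raw.sub(raw[baseline_label], axis=0)
    return TemporalMatrix(raw, corrected, baseline_label)


def flag_artifact_positions(
    control_counts: PositionCounts,
    threshold: float = 0.5,
) -> List[int]:
    """Residues whose control (pre-selection) mutation rate exceeds threshold.

    Systematic basecalling artifacts show up as high 'mutation' rates in a
    control sample; they are listed (1-based residue index) for exclusion
    from downstream reports.
    """
    rates = control_counts.aa_mutation_rate()
    base = control_counts.window_start // 3 + 1
    return [int(base + i) for i in np.flatnonzero(rates > threshold)]


# -- co-occurrence ----------------------------------------------------------


@dataclass
class CooccurrenceMatrix:
    marginals: pd.Series  # mutation label -> within-read frequency
    joint: pd.DataFrame  # symmetric pairwise within-read joint frequencies
    n_reads: int

    def __post_init__(self) -> None:
        for a in self.joint.index:
            for b in self.joint.columns:
                if self.joint.loc[a, b] > min(self.marginals[a], self.marginals[b]) + 1e-12:
                    raise LongReadError(f"joint({a},{b}) exceeds a marginal frequency")


def read_mutations(projection: str, ref_window: str, window_start: int) -> List[str]:
    """Residue-level mutation labels (e.g. 'V223M') carried by one projection."""
    out = []
    for i in range(0, len(ref_window) - 2, 3):
        ref_codon = ref_window[i : i + 3]
        codon = projection[i : i + 3]
        if codon != ref_codon:
            ref_aa, alt_aa = translate(ref_codon), translate(codon)
            if alt_aa != ref_aa:
                out.append(f"{ref_aa}{window_start // 3 + i // 3 + 1}{alt_aa}")
    return out


def cooccurrence(
    projections: Sequence[str],
    construct: TransgeneConstruct,
    window_start: int = 0,
    min_marginal: float = 0.095,
) -> CooccurrenceMatrix:
    """Pairwise within-read joint frequencies of frequent mutations.

    Only mutations present in at least ``min_marginal`` of reads enter the
    matrix; joint(i, j) is the fraction of reads carrying both.
    """
    if not projections:
        raise LongReadError("no projections")
    W = len(projections[0])
    ref_window = construct.cds[window_start : window_start + W]
    per_read: List[set] = []
    marg: Counter = Counter()
    for p in projections:
        muts = set(read_mutations(p, ref_window, window_start))
        per_read.append(muts)
        marg.update(muts)
    n = len(projections)
    keep = sorted(m for m, c in marg.items() if c / n >= min_marginal)
    joint = pd.DataFrame(0.0, index=keep, columns=keep)
    for muts in per_read:
        present = [m for m in keep if m in muts]
        for i, a in enumerate(present):
            for b in present[i:]:
                joint.loc[a, b] += 1
                if a != b:
                    joint.loc[b, a] += 1
    joint /= n
    marginals = pd.Series({m: marg[m] / n for m in keep}, dtype=float)
    return CooccurrenceMatrix(marginals, joint, n)


# -- ranking and logos ------------------------------------------------------


def rank_by_variance(
    variant_table_series: Mapping[str, Mapping[str, float]],
    k: int = 10,
) -> pd.DataFrame:
    """Top-k variants by frequency variance across pipeline steps.

    ``variant_table_series`` maps step label -> {variant -> frequency};
    variants absent from a step count as frequency 0.  Ties break
    deterministically by variant name.
    """
    if len(variant_table_series) < 2:
        raise LongReadError("need at least two steps to rank variance")
    steps = list(variant_table_series)
    variants = sorted({v for step in steps for v in variant_table_series[step]})
    mat = np.array(
        [[variant_table_series[s].get(v, 0.0) for s in steps] for v in variants]
    )
    var = mat.var(axis=1)
    order = sorted(range(len(variants)), key=lambda i: (-var[i], variants[i]))
    top = order[: min(k, len(variants))]
    return pd.DataFrame(
        {
            "variant": [variants[i] for i in top],
            "variance": var[top],
            **{s: mat[top, j] for j, s in enumerate(steps)},
        }
    )


def enrichment_logo(
    final_counts: PositionCounts,
    min_frac: float = 0.01,
    include_reference: bool = False,
) -> pd.DataFrame:
    """Per-position retained amino acids with fractions and class labels.

    Non-reference residues whose within-position fraction exceeds
    ``min_frac`` are retained (set ``include_reference`` to keep the
    wild-type residue rows as well).
    """
    rows = []
    c0 = final_counts.window_start // 3
    for local_ci in range(len(final_counts.codon_depth)):
        ci = c0 + local_ci
        depth = int(final_counts.codon_depth[local_ci])
        if depth == 0:
            continue
        ref_aa = translate(final_counts.ref_seq[3 * local_ci : 3 * local_ci + 3])
        for aa, count in sorted(final_counts.aa_counts(ci).items()):
            frac = count / depth
            if aa == ref_aa and not include_reference:
                continue
            if frac <= min_frac:
                continue
            rows.append((ci + 1, ref_aa, aa, frac, AA_CLASSES.get(aa, "other")))
    return pd.DataFrame(rows, columns=["residue", "ref_aa", "aa", "fraction", "aa_class"])
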