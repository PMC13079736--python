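"""Short-read (paired-end amplicon) analysis.

Stages mirror a conventional amplicon variant-frequency workflow:
exact dual-barcode demultiplexing, primer + quality trimming, local
alignment, and three counting modes -- substitution scanning (indel and
shifted alignments excluded, per-position nt/codon/aa counts), junction
("linker") analysis (in-frame indels allowed, reads must span the junction
window), and paired wild-type/mutant classification.  Thresholds live in
:class:`PipelineConfig` and default to conservative published practice:
up to 5 primer mismatches, Q<20 quality truncation, a 2,000-read
per-position depth floor (applied at reporting, so re-thresholding is
possible), and an 80% combined-span rule for pair classification.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from scipy import stats

from .alignment import AlignmentRecord, ReferenceIndex, align_local
from .codon_usage import translate
from .library_design import BarcodeScheme, RetronDonor
from .reference_model import TransgeneConstruct

_PHRED_OFFSET = 33

Read = Tuple[str, str, str]  # (id, sequence, quality)


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    max_primer_mismatch: int = 5
    qual_trim_threshold: int = 20
    min_depth: int = 2000
    min_pair_span_frac: float = 0.80
    start_tolerance: int = 3
    min_read_len: int = 20
    forward_only: bool = False
    position_exclusions: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.max_primer_mismatch <= 20:
            raise PipelineError("max_primer_mismatch outside [0, 20]")
        if not 0 <= self.min_pair_span_frac <= 1:
            raise PipelineError("min_pair_span_frac outside [0, 1]")
        if self.min_depth < 0 or self.qual_trim_threshold < 0:
            raise PipelineError("thresholds must be non-negative")


def _open_in(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path) -> Iterator[Read]:
    with _open_in(path) as fh:
        yield from FastqGeneralIterator(fh)


def read_fastq_pairs(r1_path, r2_path) -> Iterator[Tuple[Read, Read]]:
    for fwd, rev in zip(read_fastq(r1_path), read_fastq(r2_path)):
        if fwd[0].split()[0] != rev[0].split()[0]:
            raise PipelineError(f"unpaired mates: {fwd[0]} vs {rev[0]}")
        yield fwd, rev


# -- demultiplexing ---------------------------------------------------------


@dataclass
class DemuxResult:
    assigned: Dict[str, List[Tuple[Read, Read]]]
    rejected: int

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.assigned.values())


def demultiplex(
    pairs: Iterable[Tuple[Read, Read]],
    scheme: BarcodeScheme,
    strip_barcodes: bool = True,
) -> DemuxResult:
    """Assign read pairs to samples by exact dual-barcode match.

    A pair is assigned iff BOTH mates begin with the exact forward and
    reverse barcode of the same sample; anything else (one-mismatch
    barcodes, mixed pairs) is rejected, which minimizes index swapping.
    """
    lookup: Dict[Tuple[str, str], str] = {}
    for sample, (fwd, rev) in scheme.pairs.items():
        key = (fwd, rev)
        if key in lookup:
            raise PipelineError(f"barcode collision between {lookup[key]} and {sample}")
        lookup[key] = sample
    blen = scheme.barcode_length
    assigned: Dict[str, List[Tuple[Read, Read]]] = {s: [] for s in scheme.pairs}
    rejected = 0
    for fwd, rev in pairs:
        key = (fwd[1][:blen], rev[1][:blen])
        sample = lookup.get(key)
        if sample is None:
            rejected += 1
            continue
        if strip_barcodes:
            fwd = (fwd[0], fwd[1][blen:], fwd[2][blen:])
            rev = (rev[0], rev[1][blen:], rev[2][blen:])
        assigned[sample].append((fwd, rev))
    return DemuxResult(assigned, rejected)


# -- trimming ---------------------------------------------------------------


def trim_read(read: Read, expected_primer: str, cfg: PipelineConfig) -> Tuple[Optional[Read], str]:
    """Locate and remove the primer, then quality-truncate.

    The primer must sit at the read start within ``max_primer_mismatch``
    mismatches (mutagenesis can hit primer-binding sites).  The remainder is
    truncated at the first base with Q below the quality threshold.  Returns
    (trimmed read or None, reason).
    """
    rid, seq, qual = read
    p = len(expected_primer)
    if p >= len(seq):
        return None, "primer_longer_than_read"
    mism = sum(a != b for a, b in zip(seq[:p], expected_primer))
    if mism > cfg.max_primer_mismatch:
        return None, "primer_not_found"
    seq, qual = seq[p:], qual[p:]
    q = np.frombuffer(qual.encode(), dtype=np.uint8) - _PHRED_OFFSET
    low = np.flatnonzero(q < cfg.qual_trim_threshold)
    if len(low):
        cut = int(low[0])
        seq, qual = seq[:cut], qual[:cut]
    if not seq:
        return None, "empty_after_trimming"
    return (rid, seq, qual), "ok"


# -- position counts --------------------------------------------------------


@dataclass
class PositionCounts:
    """Per-position depth and variant counts at nt, codon and aa levels.

    Reference (matching) counts are implicit: ref count = depth - sum of
    alternative counts.  Codon/aa tallies keep only non-reference
    observations (sparse) plus a per-codon depth of fully covering reads.
    ``window_start`` anchors the arrays on the construct CDS.
    """

    ref_seq: str
    window_start: int = 0
    nt_depth: np.ndarray = None
    nt_alt: np.ndarray = None  # (L, 4) counts of non-reference A/C/G/T
    codon_depth: np.ndarray = None
    codon_alt: Dict[int, Counter] = None  # construct codon index -> Counter(codon)
    n_reads_used: int = 0
    n_excluded: int = 0

    def __post_init__(self) -> None:
        L = len(self.ref_seq)
        if self.nt_depth is None:
            self.nt_depth = np.zeros(L, dtype=np.int64)
        if self.nt_alt is None:
            self.nt_alt = np.zeros((L, 4), dtype=np.int64)
        if self.codon_depth is None:
            self.codon_depth = np.zeros(L // 3, dtype=np.int64)
        if self.codon_alt is None:
            self.codon_alt = {}

    @property
    def window_end(self) -> int:
        return self.window_start + len(self.ref_seq)

    def nt_mutation_rate(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = self.nt_alt.sum(axis=1) / self.nt_depth
        return np.nan_to_num(rate)

    def codon_mutation_rate(self) -> np.ndarray:
        out = np.zeros(len(self.codon_depth))
        for ci, counter in self.codon_alt.items():
            i = ci - self.window_start // 3
            if self.codon_depth[i]:
                out[i] = sum(counter.values()) / self.codon_depth[i]
        return out

    def aa_mutation_rate(self) -> np.ndarray:
        """Fraction of reads whose codon translates to a non-reference residue."""
        out = np.zeros(len(self.codon_depth))
        for ci, counter in self.codon_alt.items():
            i = ci - self.window_start // 3
            ref_aa = translate(self.ref_seq[3 * i : 3 * i + 3])
            n = sum(c for codon, c in counter.items() if translate(codon) != ref_aa)
            if self.codon_depth[i]:
                out[i] = n / self.codon_depth[i]
        return out

    def aa_counts(self, codon_index: int) -> Counter:
        """Residue counts at a construct codon index (reference included)."""
        i = codon_index - self.window_start // 3
        ref_codon = self.ref_seq[3 * i : 3 * i + 3]
        counter: Counter = Counter()
        alt_total = 0
        for codon, c in self.codon_alt.get(codon_index, Counter()).items():
            counter[translate(codon)] += c
            alt_total += c
        counter[translate(ref_codon)] += int(self.codon_depth[i]) - alt_total
        return counter

    def depth_mask(self, min_depth: int) -> np.ndarray:
        """Boolean mask of positions below the reporting depth floor."""
        return self.nt_depth < min_depth

    def to_frame(self, min_depth: Optional[int] = None) -> pd.DataFrame:
        rate = self.nt_mutation_rate()
        df = pd.DataFrame(
            {
                "position": np.arange(self.window_start, self.window_end),
                "ref": list(self.ref_seq),
                "depth": self.nt_depth,
                "count_A": self.nt_alt[:, 0],
                "count_C": self.nt_alt[:, 1],
                "count_G": self.nt_alt[:, 2],
                "count_T": self.nt_alt[:, 3],
                "mutation_rate": rate,
            }
        )
        if min_depth is not None:
            df["masked"] = self.depth_mask(min_depth)
        return df


_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


def _accumulate_alignment(counts: PositionCounts, aln: AlignmentRecord, ref: str) -> None:
    """Add one indel-free alignment to the tallies."""
    w0 = counts.window_start
    start = max(aln.ref_start, w0)
    end = min(aln.ref_end, counts.window_end)
    if end <= start:
        return
    counts.nt_depth[start - w0 : end - w0] += 1
    # codons fully covered by the aligned span
    c0 = -(-start // 3)
    c1 = end // 3
    if c1 > c0:
        counts.codon_depth[c0 - w0 // 3 : c1 - w0 // 3] += 1
    mismatches = [e for e in aln.events if e[0] == "mismatch" and start <= e[1] < end]
    if not mismatches:
        return
    touched_codons = set()
    for _, pos, read_base, _ref_base in mismatches:
        bi = _BASE_INDEX[ord(read_base)]
        if bi >= 0:
            counts.nt_alt[pos - w0, bi] += 1
        touched_codons.add(pos // 3)
    for ci in touched_codons:
        if not (c0 <= ci < c1):
            continue
        rpos = aln.read_start + (3 * ci - aln.ref_start)
        codon = aln.read_seq[rpos : rpos + 3]
        counts.codon_alt.setdefault(ci, Counter())[codon] += 1


def count_dms(
    alignments: Iterable[AlignmentRecord],
    construct: TransgeneConstruct,
    cfg: Optional[PipelineConfig] = None,
) -> PositionCounts:
    """Substitution-scanning counts over the whole CDS.

    Alignments containing indels or flagged as shifted are excluded; the
    depth floor is applied at reporting time via ``to_frame``/``depth_mask``
    so raw counts stay available.
    """
    cfg = cfg or PipelineConfig()
    counts = PositionCounts(ref_seq=construct.cds)
    for aln in alignments:
        if aln is None or aln.has_indel or aln.shifted:
            counts.n_excluded += 1
            continue
        _accumulate_alignment(counts, aln, construct.cds)
        counts.n_reads_used += 1
    return counts


# -- junction (linker) counting --------------------------------------------


@dataclass
class VariantTable:
    """Collapsed (nt, aa) variant frequencies for one junction window."""

    table: pd.DataFrame  # columns: nt_seq, aa_seq, count, frequency, is_reference
    window: Tuple[int, int]
    n_reads_used: int
    n_excluded_frameshift: int
    n_excluded_span: int

    def frequency(self, nt_seq: str) -> float:
        rows = self.table[self.table.nt_seq == nt_seq]
        return float(rows.frequency.iloc[0]) if len(rows) else 0.0


def junction_window(construct: TransgeneConstruct, junction: str, pad: int = 9) -> Tuple[int, int]:
    """Codon-aligned analysis window around a junction linker.

    ``pad`` nt of flanking effector/insert sequence are included so junction
    deletions that reach into the neighbouring region stay inside the window.
    """
    label = "left_linker" if junction == "left" else "right_linker"
    r = construct.region(label)
    if pad % 3:
        raise PipelineError("window pad must be codon-aligned")
    return r.start - pad, r.end + pad


def count_linker(
    alignments: Iterable[AlignmentRecord],
    construct: TransgeneConstruct,
    cfg: Optional[PipelineConfig] = None,
    junction: str = "left",
    pad: int = 9,
) -> VariantTable:
    """Junction variant table from indel-tolerant alignments.

    Reads with a net indel length not divisible by three are excluded
    (frameshifts); reads must span the full junction window.  Remaining
    reads are collapsed to their nt-level window sequence, with the aa-level
    translation alongside.
    """
    cfg = cfg or PipelineConfig()
    wstart, wend = junction_window(construct, junction, pad)
    ref_window = construct.cds[wstart:wend]
    tally: Counter = Counter()
    n_frame = n_span = 0
    for aln in alignments:
        if aln is None:
            n_span += 1
            continue
        if aln.net_indel % 3:
            n_frame += 1
            continue
        window_seq = aln.window_read_seq(construct.cds, wstart, wend)
        if window_seq is None:
            n_span += 1
            continue
        tally[window_seq] += 1
    total = sum(tally.values())
    rows = []
    for nt_seq, count in tally.most_common():
        aa = translate(nt_seq) if len(nt_seq) % 3 == 0 else ""
        rows.append((nt_seq, aa, count, count / total if total else 0.0, nt_seq == ref_window))
    df = pd.DataFrame(rows, columns=["nt_seq", "aa_seq", "count", "frequency", "is_reference"])
    return VariantTable(df, (wstart, wend), total, n_frame, n_span)


# -- pair classification ----------------------------------------------------


def classify_pairs(
    pairs: Iterable[Tuple[Optional[AlignmentRecord], Optional[AlignmentRecord]]],
    reference: str,
    cfg: Optional[PipelineConfig] = None,
) -> Dict[str, int]:
    """Three-way wild-type / mutant / excluded partition of read pairs.

    A pair is wild type only when both mates align without any event; any
    mismatch (or indel) makes it a mutant.  Pairs whose combined reference
    span is below ``min_pair_span_frac`` of the reference -- or with a
    missing/unaligned mate -- are excluded.
    """
    cfg = cfg or PipelineConfig()
    out = {"wt_count": 0, "mutant_count": 0, "excluded_count": 0}
    min_span = cfg.min_pair_span_frac * len(reference)
    for fwd, rev in pairs:
        if fwd is None or rev is None:
            out["excluded_count"] += 1
            continue
        if fwd.aligned_len + rev.aligned_len < min_span:
            out["excluded_count"] += 1
            continue
        if fwd.events or rev.events:
            out["mutant_count"] += 1
        else:
            out["wt_count"] += 1
    return out


# -- codon complexity -------------------------------------------------------


def codon_complexity(
    observed: PositionCounts,
    designed: Sequence[RetronDonor],
    construct: TransgeneConstruct,
) -> pd.DataFrame:
    """Single/double/triple base-change category frequencies, observed vs expected.

    Observed frequencies come from the non-reference codon tallies; expected
    frequencies from categorizing every designed (non-no-op) codon
    substitution, assuming uniform library coverage.
    """
    def category(ref_codon: str, alt_codon: str) -> int:
        return sum(a != b for a, b in zip(ref_codon, alt_codon))

    obs = Counter()
    for ci, counter in observed.codon_alt.items():
        ref_codon = construct.cds[3 * ci : 3 * ci + 3]
        for codon, c in counter.items():
            k = category(ref_codon, codon)
            if k:
                obs[k] += c
    exp = Counter()
    for d in designed:
        if d.edit.kind != "substitution" or d.edit.net_delta != 0:
            continue
        ref_codon = construct.cds[d.edit.nt_start : d.edit.nt_end]
        k = category(ref_codon, d.edit.payload)
        if k:
            exp[k] += 1
    obs_total = sum(obs.values()) or 1
    exp_total = sum(exp.values()) or 1
    return pd.DataFrame(
        {
            "n_base_changes": [1, 2, 3],
            "observed_freq": [obs[k] / obs_total for k in (1, 2, 3)],
            "expected_freq": [exp[k] / exp_total for k in (1, 2, 3)],
        }
    )


# -- library comparison -----------------------------------------------------


def compare_libraries(
    input_freqs: Mapping[str, float],
    output_freqs: Mapping[str, float],
) -> Tuple[float, pd.DataFrame]:
    """Spearman rank correlation over the shared variant universe.

    Both distributions are completed over the union of variants (missing =
    0) and renormalized to sum to 1 before ranking.
    """
    universe = sorted(set(input_freqs) | set(output_freqs))
    if len(universe) < 3:
        raise PipelineError("fewer than 3 variants to compare")
    a = np.array([input_freqs.get(v, 0.0) for v in universe], dtype=float)
    b = np.array([output_freqs.get(v, 0.0) for v in universe], dtype=float)
    if a.sum() == 0 or b.sum() == 0:
        raise PipelineError("empty frequency vector")
    a, b = a / a.sum(), b / b.sum()
    rho = stats.spearmanr(a, b).statistic
    df = pd.DataFrame({"variant": universe, "input_freq": a, "output_freq": b})
    return float(rho), df


# -- driver -----------------------------------------------------------------


def run_sample(
    pairs: Sequence[Tuple[Read, Read]],
    construct: TransgeneConstruct,
    fwd_primer: str,
    rev_primer: str,
    cfg: Optional[PipelineConfig] = None,
    expected_start: int = 0,
) -> Dict[str, object]:
    """Trim and align one demultiplexed sample; returns alignments + stats.

    Forward reads align to the CDS directly; reverse reads are
    reverse-complemented first.  In ``forward_only`` mode the reverse mates
    are ignored (useful when reverse-read quality collapses).
    """
    cfg = cfg or PipelineConfig()
    index = ReferenceIndex(construct.cds)
    fwd_alns: List[Optional[AlignmentRecord]] = []
    rev_alns: List[Optional[AlignmentRecord]] = []
    stats_: Dict[str, int] = Counter()
    comp = str.maketrans("ACGT", "TGCA")
    for fwd, rev in pairs:
        tf, reason = trim_read(fwd, fwd_primer, cfg)
        if tf is None or len(tf[1]) < cfg.min_read_len:
            stats_[f"fwd_{reason if tf is None else 'too_short'}"] += 1
            fwd_alns.append(None)
        else:
            fwd_alns.append(
                align_local(tf[1], index, read_id=tf[0], expected_start=expected_start,
                            start_tolerance=cfg.start_tolerance)
            )
        if cfg.forward_only:
            rev_alns.append(None)
            continue
        tr, reason = trim_read(rev, rev_primer, cfg)
        if tr is None or len(tr[1]) < cfg.min_read_len:
            stats_[f"rev_{reason if tr is None else 'too_short'}"] += 1
            rev_alns.append(None)
        else:
            rc = tr[1].translate(comp)[::-1]
            rev_alns.append(align_local(rc, index, read_id=tr[0]))
    return {"fwd": fwd_alns, "rev": rev_alns, "stats": dict(stats_)}
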