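"""Reference model of the phage-carried sensor-effector transgene.

The transgene is a single in-frame coding sequence partitioned into five
codon-aligned regions: the N-terminal effector part, a short left junction
linker (SG), an inserted sensor domain, a right junction linker (GS), and the
C-terminal effector part.  Nucleotide coordinates are 0-based half-open
throughout the package; residue numbers in reports are 1-based with an
optional per-region offset so that, e.g., inserted-domain residues can be
reported in the numbering of the full-length parent photoreceptor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codon_usage import CodonUsageTable, STOP_CODONS, translate

REGION_LABELS = ("effector_N", "left_linker", "insert_domain", "right_linker", "effector_C")

_BASES = frozenset("ACGT")


class ConstructError(ValueError):
    """Raised when a construct violates its invariants."""


@dataclass(frozen=True)
class Region:
    label: str
    start: int  # 0-based, inclusive
    end: int  # 0-based, exclusive
    offset: int = 0  # added to 1-based within-region residue index at report time

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TransgeneConstruct:
    name: str
    cds: str
    regions: Tuple[Region, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))
        if set(self.cds) - _BASES:
            raise ConstructError(f"non-ACGT characters in cds: {sorted(set(self.cds) - _BASES)}")
        if len(self.cds) % 3:
            raise ConstructError(f"cds length {len(self.cds)} not divisible by 3")
        if not self.regions:
            raise ConstructError("construct has no regions")
        pos = 0
        for r in self.regions:
            if r.label not in REGION_LABELS:
                raise ConstructError(f"unknown region label {r.label!r}")
            if r.start != pos:
                raise ConstructError(f"region {r.label} starts at {r.start}, expected {pos} (gap/overlap)")
            if r.end > len(self.cds):
                raise ConstructError(f"region {r.label} end {r.end} beyond cds length {len(self.cds)}")
            if r.start % 3 or r.end % 3:
                raise ConstructError(f"region {r.label} not codon-aligned: [{r.start}, {r.end})")
            if r.end < r.start:
                raise ConstructError(f"region {r.label} has negative length")
            pos = r.end
        if pos != len(self.cds):
            raise ConstructError(f"regions cover [0, {pos}) but cds has length {len(self.cds)}")
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ConstructError("duplicate region labels")
        aa = translate(self.cds)
        if "*" in aa[:-1]:
            raise ConstructError(f"internal stop codon at residue {aa.index('*') + 1}")
        if aa.endswith("*") and len(aa) == 1:
            raise ConstructError("cds is a lone stop codon")

    # -- lookups ------------------------------------------------------------

    def region(self, label: str) -> Region:
        for r in self.regions:
            if r.label == label:
                return r
        raise KeyError(f"no region labelled {label!r}")

    def region_seq(self, label: str) -> str:
        r = self.region(label)
        return self.cds[r.start : r.end]

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3

    def codon(self, index: int) -> str:
        return self.cds[3 * index : 3 * index + 3]

    def residue_number(self, codon_index: int) -> int:
        """Reported (offset) residue number of a construct codon index."""
        pos = 3 * codon_index
        for r in self.regions:
            if r.start <= pos < r.end:
                return (pos - r.start) // 3 + 1 + r.offset
        raise IndexError(f"codon index {codon_index} outside cds")

    # -- serialization ------------------------------------------------------

    def to_files(self, fasta_path, annotation_path) -> None:
        rec = SeqRecord(Seq(self.cds), id=self.name, description="")
        with open(fasta_path, "w") as fh:
            SeqIO.write([rec], fh, "fasta")
        df = pd.DataFrame(
            [(r.label, r.start, r.end, r.offset) for r in self.regions],
            columns=["label", "start", "end", "offset"],
        )
        df.to_csv(annotation_path, sep="\t", index=False)


def translate_region(construct: TransgeneConstruct, label: str) -> str:
    """Amino-acid sequence of a region (standard genetic code).

    Raises on an internal stop codon, which a valid in-frame region never
    contains (the construct-level invariant only guards the full CDS).
    """
    seq = construct.region_seq(label)
    aa = translate(seq)
    if "*" in aa:
        raise ConstructError(f"region {label!r} contains a stop codon")
    return aa


def load_construct(fasta_path, annotation_path) -> TransgeneConstruct:
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ConstructError(f"expected exactly one FASTA record, found {len(records)}")
    df = pd.read_csv(annotation_path, sep="\t")
    required = {"label", "start", "end"}
    if not required <= set(df.columns):
        raise ConstructError(f"annotation TSV must have columns {sorted(required)}")
    if "offset" not in df.columns:
        df["offset"] = 0
    regions = tuple(
        Region(str(row.label), int(row.start), int(row.end), int(row.offset))
        for row in df.itertuples()
    )
    return TransgeneConstruct(records[0].id, str(records[0].seq).upper(), regions)


# -- junction anchoring ----------------------------------------------------


@dataclass(frozen=True)
class JunctionAnchors:
    """Query-coordinate brackets of the two junction windows.

    ``left``/``right`` are (gap_start, gap_end) query intervals holding the
    observed junction sequence, or None when an anchor motif was not found.
    ``*_status`` is one of 'ok', 'not_found', 'ambiguous'.
    """

    left: Optional[Tuple[int, int]]
    right: Optional[Tuple[int, int]]
    left_status: str = "ok"
    right_status: str = "ok"


def _best_motif_hit(seq_arr: np.ndarray, motif: str, max_mismatch: int) -> Tuple[Optional[int], str]:
    """Best approximate placement of ``motif``; flags ties as ambiguous."""
    m = np.frombuffer(motif.encode(), dtype=np.uint8)
    k = len(m)
    if len(seq_arr) < k:
        return None, "not_found"
    windows = np.lib.stride_tricks.sliding_window_view(seq_arr, k)
    mismatches = (windows != m).sum(axis=1)
    best = int(mismatches.min())
    if best > max_mismatch:
        return None, "not_found"
    hits = np.flatnonzero(mismatches == best)
    if len(hits) > 1:
        return None, "ambiguous"
    return int(hits[0]), "ok"


def junction_ref_windows(
    construct: TransgeneConstruct,
    effector_pad: int = 9,
    insert_pad: int = 15,
) -> Dict[str, Tuple[int, int]]:
    """Reference intervals of the two editable junction windows.

    The windows extend past the 2-codon junction linkers to cover every
    programmed junction edit: ``effector_pad`` nt into the adjacent effector
    part (junction deletions remove up to 3 effector residues) and
    ``insert_pad`` nt into the insert's C-terminus on the right (the
    C-terminal helix series rewrites the terminal motif).
    """
    ll = construct.region("left_linker")
    rl = construct.region("right_linker")
    return {
        "left": (ll.start - effector_pad, ll.end),
        "right": (rl.start - insert_pad, rl.end + effector_pad),
    }


def locate_junctions(
    seq: str,
    construct: TransgeneConstruct,
    motif_len: int = 12,
    max_mismatch: int = 1,
    effector_pad: int = 9,
    insert_pad: int = 15,
) -> JunctionAnchors:
    """Bracket both junction windows in a query using conserved flanking motifs.

    Each junction's anchors are the ``motif_len`` reference nt immediately
    up- and downstream of its editable window (see
    :func:`junction_ref_windows`); each motif is matched allowing
    ``max_mismatch`` mismatches.  Equally good alternative placements flag
    the junction ambiguous so the read can be excluded downstream.
    """
    if motif_len < 9:
        raise ValueError("motif_len must be >= 9")
    windows = junction_ref_windows(construct, effector_pad, insert_pad)
    motifs = {
        side: (
            construct.cds[w0 - motif_len : w0],
            construct.cds[w1 : w1 + motif_len],
        )
        for side, (w0, w1) in windows.items()
    }
    for side, (up, down) in motifs.items():
        for m in (up, down):
            if len(m) != motif_len or construct.cds.count(m) != 1:
                raise ConstructError(f"{side} junction motif {m!r} not unique in reference")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out: Dict[str, Optional[Tuple[int, int]]] = {}
    status: Dict[str, str] = {}
    for side, (up, down) in motifs.items():
        up_pos, up_status = _best_motif_hit(arr, up, max_mismatch)
        down_pos, down_status = _best_motif_hit(arr, down, max_mismatch)
        if up_status == "ok" and down_status == "ok":
            gap = (up_pos + motif_len, down_pos)
            if gap[1] < gap[0]:
                out[side], status[side] = None, "not_found"
            else:
                out[side], status[side] = gap, "ok"
        else:
            out[side] = None
            status[side] = "ambiguous" if "ambiguous" in (up_status, down_status) else "not_found"
    return JunctionAnchors(out["left"], out["right"], status["left"], status["right"])


# -- packaged fixture -------------------------------------------------------

_FIXTURE_SIZES = {"effector_N": 170, "insert_domain": 141, "effector_C": 351}  # codons
_LEFT_LINKER = "AGCGGT"  # SG
_RIGHT_LINKER = "GGTAGC"  # GS
_TYPE_IIS_SITE = "GGTCTC"  # BsaI-style recognition used by the default cloning flanks
_JALPHA_TERMINUS = "IDEAA"  # encoded at the insert C-terminus (preferred codons)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def make_fixture_construct(name: str = "sensor_effector_fixture") -> TransgeneConstruct:
    """Deterministic packaged test construct.

    A synthetic (non-natural) arabinose-effector-like coding sequence with a
    141-codon sensor-domain insert flanked by SG/GS junction linkers, ~50% GC,
    no internal stops, unique 12-nt junction motifs and no BsaI-style
    recognition site on either strand.  Built from a fixed RNG stream, so
    repeated calls return identical sequences.
    """
    rng = np.random.default_rng(2026)
    sense = sorted(set(
        a + b + c
        for a in "ACGT" for b in "ACGT" for c in "ACGT"
    ) - set(STOP_CODONS))
    table = CodonUsageTable.ecoli_k12()
    jalpha_nt = "".join(table.preferred(a) for a in _JALPHA_TERMINUS)
    for _ in range(500):
        parts = {}
        for label, n in _FIXTURE_SIZES.items():
            idx = rng.integers(0, len(sense), size=n)
            parts[label] = "".join(sense[i] for i in idx)
        insert = parts["insert_domain"][: -3 * len(_JALPHA_TERMINUS)] + jalpha_nt
        cds = parts["effector_N"] + _LEFT_LINKER + insert + _RIGHT_LINKER + parts["effector_C"]
        if _TYPE_IIS_SITE in cds or _TYPE_IIS_SITE in _revcomp(cds):
            continue
        n0 = 3 * _FIXTURE_SIZES["effector_N"]
        ins_len = 3 * _FIXTURE_SIZES["insert_domain"]
        regions = (
            Region("effector_N", 0, n0, offset=0),
            Region("left_linker", n0, n0 + 6, offset=0),
            Region("insert_domain", n0 + 6, n0 + 6 + ins_len, offset=403),
            Region("right_linker", n0 + 6 + ins_len, n0 + 12 + ins_len, offset=0),
            Region("effector_C", n0 + 12 + ins_len, len(cds), offset=_FIXTURE_SIZES["effector_N"]),
        )
        try:
            construct = TransgeneConstruct(name, cds, regions)
        except ConstructError:
            continue
        try:
            locate_junctions(cds, construct)
        except ConstructError:
            continue  # junction motifs not unique; redraw
        # deferred import (library_design depends on this module): every donor
        # of the default libraries must be free of the Type-IIS site, or the
        # pools could not be cloned
        from .library_design import design_dms, design_linker_library

        donors = design_dms(construct, table=table) + design_linker_library(construct, table=table)
        if any(
            _TYPE_IIS_SITE in d.donor or _TYPE_IIS_SITE in _revcomp(d.donor)
            for d in donors
        ):
            continue
        return construct
    raise RuntimeError("failed to generate a valid fixture construct")
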