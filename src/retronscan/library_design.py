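"""Retron donor oligo pool design.

Every programmed edit (substitution, in-frame insertion or deletion) is
embodied as a 90-nt single-stranded homology donor with the edited bases
centered in the donor, wrapped into a synthesis oligo carrying subpool
barcodes and Type-IIS cloning flanks:

    fwd_barcode | left_flank | 90-nt donor | right_flank | rev_barcode

Two pool generators are provided: a deep-mutational-scanning (DMS) library
substituting every codon of a target region to all 20 residues via the
host's preferred codons, and a junction ("linker") library of deletions,
replacements, insertions and C-terminal helix truncations/extensions at the
two sensor-effector junctions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codon_usage import AMINO_ACIDS, CodonUsageTable, translate
from .reference_model import TransgeneConstruct, _revcomp

DONOR_LENGTH = 90
MAX_NET_DELTA = 15
MIN_HOMOLOGY_ARM = 20

EDIT_KINDS = ("substitution", "insertion", "deletion", "compound")


class DesignError(ValueError):
    """Raised when a requested edit cannot be realized as a valid donor."""


def preferred_codon(aa: str, table: CodonUsageTable) -> str:
    """Most preferred codon for ``aa`` (deterministic lexicographic tie-break)."""
    return table.preferred(aa)


@dataclass(frozen=True)
class EditSpec:
    """A programmed edit on the reference transgene.

    ``nt_start``/``nt_end`` delimit the replaced reference interval (0-based
    half-open; empty for a pure insertion); ``payload`` is the replacement
    sequence.  All designed edits are in-frame and fit the donor payload
    capacity (|net change| <= 15 nt).
    """

    kind: str
    nt_start: int
    nt_end: int
    payload: str
    aa_label: str
    name: str = ""  # unique nt-level name; defaults to aa_label

    def __post_init__(self) -> None:
        if self.kind not in EDIT_KINDS:
            raise DesignError(f"unknown edit kind {self.kind!r}")
        if self.nt_end < self.nt_start:
            raise DesignError("nt_end < nt_start")
        if self.net_delta % 3:
            raise DesignError(f"{self.aa_label}: net change {self.net_delta} nt is frame-shifting")
        if abs(self.net_delta) > MAX_NET_DELTA:
            raise DesignError(
                f"{self.aa_label}: |net change| {abs(self.net_delta)} nt exceeds donor capacity {MAX_NET_DELTA}"
            )
        if not self.name:
            object.__setattr__(self, "name", self.aa_label)

    @property
    def net_delta(self) -> int:
        return len(self.payload) - (self.nt_end - self.nt_start)


def apply_edit(cds: str, edit: EditSpec) -> str:
    return cds[: edit.nt_start] + edit.payload + cds[edit.nt_end :]


@dataclass(frozen=True)
class RetronDonor:
    """A 90-nt homology donor realizing one programmed edit.

    The donor is a window of the *edited* sequence with the payload centered;
    when exact centering is impossible the left homology arm is one nt
    shorter.  ``donor_ref_window`` is the reference interval the donor spans.
    """

    edit: EditSpec
    donor: str
    donor_ref_window: Tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.donor) != DONOR_LENGTH:
            raise DesignError(f"{self.edit.name}: donor length {len(self.donor)} != {DONOR_LENGTH}")

    @property
    def name(self) -> str:
        return self.edit.name

    def is_noop(self, construct: TransgeneConstruct) -> bool:
        s, e = self.donor_ref_window
        return self.donor == construct.cds[s:e]


def build_donor(construct: TransgeneConstruct, edit: EditSpec) -> RetronDonor:
    """Center ``edit`` in a 90-nt window of the edited sequence."""
    p = len(edit.payload)
    left = (DONOR_LENGTH - p) // 2
    right = DONOR_LENGTH - p - left
    start = edit.nt_start - left
    end_ref = edit.nt_end + right
    if start < 0 or end_ref > len(construct.cds):
        raise DesignError(
            f"{edit.name}: edit too close to construct end for a {DONOR_LENGTH}-nt donor"
        )
    edited = apply_edit(construct.cds, edit)
    donor = edited[start : start + DONOR_LENGTH]
    rec = RetronDonor(edit, donor, (start, end_ref))
    # bidirectional consistency: re-extracting the window from the edited
    # sequence must reproduce the donor
    assert edited[start : start + DONOR_LENGTH] == donor
    return rec


# -- DMS library ------------------------------------------------------------


def design_dms(
    construct: TransgeneConstruct,
    target_label: str = "insert_domain",
    table: Optional[CodonUsageTable] = None,
) -> List[RetronDonor]:
    """One donor per (codon position, amino acid) over the target region.

    Emits exactly ``region codons x 20`` donors, including recodings to the
    wild-type residue's preferred codon; donors identical to the reference
    window are retained (no-op entries).  Variant names use the reported
    (offset) residue numbering; ``aa_label`` carries it, and the nt-level
    ``name`` appends the construct residue index when the two differ.
    """
    table = table or CodonUsageTable.ecoli_k12()
    region = construct.region(target_label)
    if len(region) < 3:
        raise DesignError(f"region {target_label!r} shorter than one codon")
    donors: List[RetronDonor] = []
    for nt in range(region.start, region.end, 3):
        codon_index = nt // 3
        ref_codon = construct.codon(codon_index)
        ref_aa = translate(ref_codon)
        reported = construct.residue_number(codon_index)
        construct_pos = codon_index + 1
        for aa in AMINO_ACIDS:
            payload = preferred_codon(aa, table)
            aa_label = f"{ref_aa}{reported}{aa}"
            name = aa_label if reported == construct_pos else f"{aa_label}|c{construct_pos}"
            edit = EditSpec("substitution", nt, nt + 3, payload, aa_label, name)
            donors.append(build_donor(construct, edit))
    return donors


# -- linker / InDel library --------------------------------------------------


@dataclass(frozen=True)
class LinkerPanelConfig:
    """Junction diversification panels.

    ``flexible`` entries given with an ``X`` wildcard are expanded over all
    20 residues.  Panel peptides containing an SG/GS motif are inserted next
    to the native junction linker; those lacking one replace it.  The
    ``jalpha`` series applies at the right junction only, replacing the
    insert's C-terminal reference motif.
    """

    deletions: Tuple[int, ...] = (1, 2, 3)
    no_linker: bool = True
    single_residues: str = AMINO_ACIDS
    flexible: Tuple[str, ...] = ("GG", "GXG", "GGSG", "GSGG", "GSGSG")
    rigid: Tuple[str, ...] = ("PP", "GPPG", "GPPPG", "GPPPPG")
    jalpha: Tuple[str, ...] = ("I", "ID", "IDE", "IDEA", "IDEAA", "IDEAAKE", "IDEAAKEL")
    jalpha_reference: str = "IDEAA"
    silent_recode: bool = True

    @classmethod
    def from_dict(cls, d: Mapping) -> "LinkerPanelConfig":
        kwargs = {}
        for f in ("deletions", "flexible", "rigid", "jalpha"):
            if f in d:
                kwargs[f] = tuple(d[f])
        for f in ("no_linker", "silent_recode", "single_residues", "jalpha_reference"):
            if f in d:
                kwargs[f] = d[f]
        return cls(**kwargs)


def _encode(peptide: str, table: CodonUsageTable) -> str:
    return "".join(preferred_codon(aa, table) for aa in peptide)


def _expand_wildcards(panel: Sequence[str]) -> List[str]:
    out: List[str] = []
    for pep in panel:
        if "X" in pep:
            out.extend(pep.replace("X", aa, 1) for aa in AMINO_ACIDS)
        else:
            out.append(pep)
    return out


def design_linker_library(
    construct: TransgeneConstruct,
    panel: Optional[LinkerPanelConfig] = None,
    table: Optional[CodonUsageTable] = None,
) -> List[RetronDonor]:
    """Junction deletion / replacement / insertion panels at both junctions.

    Per junction: delN variants removing the 2-aa junction linker plus N
    adjacent effector residues; a no-linker variant; all 20 single-residue
    replacements; flexible and rigid panels (replace or insert per the SG/GS
    rule); a silent preferred-codon recoding of the native linker; and, at
    the right junction, the C-terminal helix truncation/extension series.
    """
    panel = panel or LinkerPanelConfig()
    table = table or CodonUsageTable.ecoli_k12()
    donors: List[RetronDonor] = []

    for side, prefix in (("left_linker", "L"), ("right_linker", "R")):
        linker = construct.region(side)
        linker_nt = construct.region_seq(side)
        linker_aa = translate(linker_nt)

        # (i) delN: junction linker plus N adjacent effector residues.
        # Left junction deletions extend into the upstream effector part,
        # right junction deletions into the downstream effector part.
        for n in panel.deletions:
            if side == "left_linker":
                edit = EditSpec(
                    "deletion", linker.start - 3 * n, linker.end, "", f"{prefix}_del{n}"
                )
            else:
                edit = EditSpec(
                    "deletion", linker.start, linker.end + 3 * n, "", f"{prefix}_del{n}"
                )
            donors.append(build_donor(construct, edit))

        # (ii) no-linker
        if panel.no_linker:
            donors.append(
                build_donor(
                    construct,
                    EditSpec("deletion", linker.start, linker.end, "", f"{prefix}_nolinker"),
                )
            )

        # (iii) single-residue replacements ("LdelK" nomenclature)
        for aa in panel.single_residues:
            edit = EditSpec(
                "substitution",
                linker.start,
                linker.end,
                preferred_codon(aa, table),
                f"{prefix}del{aa}",
            )
            donors.append(build_donor(construct, edit))

        # (iv) flexible + rigid panels: replace the junction unless the
        # peptide itself carries an SG/GS motif, in which case it is inserted
        # adjacent to the native linker (between linker and insert domain).
        for pep in _expand_wildcards(list(panel.flexible) + list(panel.rigid)):
            payload = _encode(pep, table)
            if "SG" in pep or "GS" in pep:
                point = linker.end if side == "left_linker" else linker.start
                edit = EditSpec("insertion", point, point, payload, f"{prefix}_ins_{pep}")
            else:
                edit = EditSpec(
                    "substitution", linker.start, linker.end, payload, f"{prefix}_{pep}"
                )
            donors.append(build_donor(construct, edit))

        # silent recoding of the native junction (aa-identical, nt-distinct
        # unless the native linker already uses preferred codons)
        if panel.silent_recode:
            edit = EditSpec(
                "substitution",
                linker.start,
                linker.end,
                _encode(linker_aa, table),
                f"{prefix}_{linker_aa}_silent",
            )
            donors.append(build_donor(construct, edit))

    # (v) C-terminal helix series at the right junction: replace the insert's
    # terminal reference motif with each series member.
    insert = construct.region("insert_domain")
    ref_motif = panel.jalpha_reference
    motif_nt_len = 3 * len(ref_motif)
    terminal_aa = translate(construct.cds[insert.end - motif_nt_len : insert.end])
    if terminal_aa != ref_motif:
        raise DesignError(
            f"insert terminus {terminal_aa!r} does not match the configured helix reference {ref_motif!r}"
        )
    for pep in panel.jalpha:
        edit = EditSpec(
            "compound" if len(pep) != len(ref_motif) else "substitution",
            insert.end - motif_nt_len,
            insert.end,
            _encode(pep, table),
            f"R_Ja_{pep}",
        )
        donors.append(build_donor(construct, edit))

    return donors


# -- barcoding and pool export ----------------------------------------------


@dataclass(frozen=True)
class CloningFlanks:
    """Type-IIS recognition + fusion-site sequences around the donor."""

    left: str = "GGTCTCT" + "CAGT"  # recognition + 1-nt spacer convention, 4-nt fusion
    right: str = "TGGC" + "AGAGACC"
    recognition_site: str = "GGTCTC"


def _gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def _hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("barcode length mismatch")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class BarcodeScheme:
    """Per-subpool primer-binding barcode pairs.

    All barcodes must be mutually separated by ``min_pairwise_hamming``,
    respect the GC bounds, and avoid the Type-IIS recognition site on either
    strand (exhaustively checked at construction).
    """

    pairs: Mapping[str, Tuple[str, str]]
    min_pairwise_hamming: int = 3
    gc_bounds: Tuple[float, float] = (0.25, 0.75)
    recognition_site: str = "GGTCTC"

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", dict(self.pairs))
        all_codes = [bc for fwd, rev in self.pairs.values() for bc in (fwd, rev)]
        if len(set(all_codes)) != len(all_codes):
            raise DesignError("barcode collision: duplicated barcode sequence")
        lo, hi = self.gc_bounds
        for bc in all_codes:
            if not lo <= _gc(bc) <= hi:
                raise DesignError(f"barcode {bc} violates GC bounds {self.gc_bounds}")
            if self.recognition_site in bc or self.recognition_site in _revcomp(bc):
                raise DesignError(f"barcode {bc} contains the Type-IIS recognition site")
        for i, a in enumerate(all_codes):
            for b in all_codes[i + 1 :]:
                if _hamming(a, b) < self.min_pairwise_hamming:
                    raise DesignError(
                        f"barcodes {a}/{b} closer than Hamming {self.min_pairwise_hamming}"
                    )

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.pairs.values()))[0])

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            [(sp, f, r) for sp, (f, r) in self.pairs.items()],
            columns=["subpool", "fwd_barcode", "rev_barcode"],
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "BarcodeScheme":
        df = pd.read_csv(path, sep="\t")
        pairs = {
            str(row.subpool): (str(row.fwd_barcode), str(row.rev_barcode))
            for row in df.itertuples()
        }
        return cls(pairs=pairs, **kwargs)


def make_barcode_scheme(
    n_subpools: int,
    length: int = 8,
    min_pairwise_hamming: int = 3,
    gc_bounds: Tuple[float, float] = (0.25, 0.75),
    seed: int = 0,
) -> BarcodeScheme:
    """Greedy random barcode generator satisfying the scheme invariants."""
    import numpy as np

    rng = np.random.default_rng(seed)
    chosen: List[str] = []
    attempts = 0
    while len(chosen) < 2 * n_subpools:
        bc = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
        attempts += 1
        if attempts > 100000:
            raise DesignError("could not generate a barcode scheme; relax constraints")
        if not gc_bounds[0] <= _gc(bc) <= gc_bounds[1]:
            continue
        if "GGTCTC" in bc or "GGTCTC" in _revcomp(bc):
            continue
        if any(_hamming(bc, other) < min_pairwise_hamming for other in chosen):
            continue
        chosen.append(bc)
    pairs = {
        f"SP{i + 1}": (chosen[2 * i], chosen[2 * i + 1]) for i in range(n_subpools)
    }
    return BarcodeScheme(pairs, min_pairwise_hamming, gc_bounds)


@dataclass(frozen=True)
class OligoRecord:
    donor: RetronDonor
    subpool_id: str
    fwd_barcode: str
    rev_barcode: str
    flanks: CloningFlanks = field(default_factory=CloningFlanks)

    @property
    def full_oligo(self) -> str:
        return (
            self.fwd_barcode
            + self.flanks.left
            + self.donor.donor
            + self.flanks.right
            + self.rev_barcode
        )

    @property
    def name(self) -> str:
        return self.donor.name


def assign_barcodes(
    donors: Iterable[RetronDonor],
    scheme: BarcodeScheme,
    subpool_map: Union[str, Mapping[str, str]] = "SP1",
    flanks: Optional[CloningFlanks] = None,
) -> List[OligoRecord]:
    """Wrap each donor into a barcoded synthesis oligo.

    ``subpool_map`` is either a single subpool id for the whole pool or a
    mapping from donor name to subpool id.  Donors carrying the Type-IIS
    recognition site on either strand are rejected: they would be cut during
    Golden Gate assembly.
    """
    flanks = flanks or CloningFlanks()
    records: List[OligoRecord] = []
    for donor in donors:
        sp = subpool_map if isinstance(subpool_map, str) else subpool_map[donor.name]
        if sp not in scheme.pairs:
            raise DesignError(f"subpool {sp!r} has no barcode pair in the scheme")
        site = flanks.recognition_site
        if site in donor.donor or site in _revcomp(donor.donor):
            raise DesignError(
                f"donor {donor.name} contains the Type-IIS recognition site {site}"
            )
        fwd, rev = scheme.pairs[sp]
        records.append(OligoRecord(donor, sp, fwd, rev, flanks))
    return records


_MANIFEST_COLUMNS = [
    "name", "aa_label", "subpool", "kind", "nt_start", "nt_end", "payload",
    "net_delta", "donor", "window_start", "window_end", "fwd_barcode", "rev_barcode",
]


def export_pool(oligos: Sequence[OligoRecord], fasta_path, table_path) -> None:
    """Write the pool FASTA (full oligos) and the TSV manifest."""
    if not oligos:
        raise DesignError("empty oligo pool")
    names = [o.name for o in oligos]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise DesignError(f"duplicate variant names: {dupes[:5]}")
    records = [
        SeqRecord(Seq(o.full_oligo), id=o.name, description="") for o in oligos
    ]
    with open(fasta_path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    rows = []
    for o in oligos:
        e = o.donor.edit
        rows.append(
            (o.name, e.aa_label, o.subpool_id, e.kind, e.nt_start, e.nt_end,
             e.payload, e.net_delta, o.donor.donor, *o.donor.donor_ref_window,
             o.fwd_barcode, o.rev_barcode)
        )
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(table_path, sep="\t", index=False)


def import_pool(fasta_path, table_path, flanks: Optional[CloningFlanks] = None) -> List[OligoRecord]:
    """Rebuild OligoRecords from an exported pool; verifies oligo assembly."""
    flanks = flanks or CloningFlanks()
    df = pd.read_csv(table_path, sep="\t", keep_default_na=False)
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    oligos: List[OligoRecord] = []
    for row in df.itertuples():
        edit = EditSpec(
            row.kind, int(row.nt_start), int(row.nt_end), str(row.payload),
            str(row.aa_label), str(row.name),
        )
        donor = RetronDonor(edit, str(row.donor), (int(row.window_start), int(row.window_end)))
        rec = OligoRecord(donor, str(row.subpool), str(row.fwd_barcode), str(row.rev_barcode), flanks)
        if seqs.get(rec.name) != rec.full_oligo:
            raise DesignError(f"manifest/FASTA mismatch for {rec.name}")
        oligos.append(rec)
    return oligos
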