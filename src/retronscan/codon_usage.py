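"""Codon usage tables for donor design.

The library designer recodes every targeted position with the host's most
preferred codon, so the only table shipped with the package is a relative
synonymous codon usage table for *E. coli* K-12 (per-amino-acid fractions,
Kazusa-style genome-wide counts rounded to two decimals and renormalized).
Users working in another host can supply their own table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping

from Bio.Data.CodonTable import standard_dna_table

#: codon -> amino acid (one-letter), sense codons only
GENETIC_CODE: Dict[str, str] = dict(standard_dna_table.forward_table)

STOP_CODONS = tuple(standard_dna_table.stop_codons)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Relative usage per amino acid (fractions sum to 1 for each residue).
_ECOLI_K12_WEIGHTS: Dict[str, float] = {
    # Ala
    "GCT": 0.16, "GCC": 0.27, "GCA": 0.21, "GCG": 0.36,
    # Arg
    "CGT": 0.38, "CGC": 0.40, "CGA": 0.06, "CGG": 0.10, "AGA": 0.04, "AGG": 0.02,
    # Asn
    "AAT": 0.45, "AAC": 0.55,
    # Asp
    "GAT": 0.63, "GAC": 0.37,
    # Cys
    "TGT": 0.45, "TGC": 0.55,
    # Gln
    "CAA": 0.35, "CAG": 0.65,
    # Glu
    "GAA": 0.69, "GAG": 0.31,
    # Gly
    "GGT": 0.34, "GGC": 0.40, "GGA": 0.11, "GGG": 0.15,
    # His
    "CAT": 0.57, "CAC": 0.43,
    # Ile
    "ATT": 0.51, "ATC": 0.42, "ATA": 0.07,
    # Leu
    "TTA": 0.13, "TTG": 0.13, "CTT": 0.10, "CTC": 0.10, "CTA": 0.04, "CTG": 0.50,
    # Lys
    "AAA": 0.76, "AAG": 0.24,
    # Met
    "ATG": 1.00,
    # Phe
    "TTT": 0.57, "TTC": 0.43,
    # Pro
    "CCT": 0.16, "CCC": 0.12, "CCA": 0.19, "CCG": 0.53,
    # Ser
    "TCT": 0.15, "TCC": 0.15, "TCA": 0.12, "TCG": 0.15, "AGT": 0.15, "AGC": 0.28,
    # Thr
    "ACT": 0.17, "ACC": 0.44, "ACA": 0.12, "ACG": 0.27,
    # Trp
    "TGG": 1.00,
    # Tyr
    "TAT": 0.57, "TAC": 0.43,
    # Val
    "GTT": 0.26, "GTC": 0.22, "GTA": 0.15, "GTG": 0.37,
}


@dataclass(frozen=True)
class CodonUsageTable:
    """Relative codon usage, expressed as per-amino-acid fractions."""

    organism: str
    weights: Mapping[str, float] = field(repr=False)

    def __post_init__(self) -> None:
        missing = set(GENETIC_CODE) - set(self.weights)
        if missing:
            raise ValueError(f"usage table missing {len(missing)} sense codons: {sorted(missing)[:5]}...")
        extra = set(self.weights) - set(GENETIC_CODE)
        if extra:
            raise ValueError(f"usage table has non-sense codons: {sorted(extra)}")
        sums: Dict[str, float] = {}
        for codon, w in self.weights.items():
            sums[GENETIC_CODE[codon]] = sums.get(GENETIC_CODE[codon], 0.0) + w
        bad = {aa: s for aa, s in sums.items() if abs(s - 1.0) > 1e-6}
        if bad:
            raise ValueError(f"per-amino-acid weights do not sum to 1: {bad}")

    def preferred(self, aa: str) -> str:
        """Most-used codon for ``aa``; lexicographic tie-break."""
        if aa not in AMINO_ACIDS:
            raise KeyError(f"unknown residue symbol: {aa!r}")
        candidates = [c for c, a in GENETIC_CODE.items() if a == aa]
        return max(sorted(candidates), key=lambda c: self.weights[c])

    @classmethod
    def ecoli_k12(cls) -> "CodonUsageTable":
        return cls(organism="E. coli K-12", weights=dict(_ECOLI_K12_WEIGHTS))


def translate(seq: str) -> str:
    """Translate an in-frame DNA sequence with the standard code ('*' = stop)."""
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    return "".join(
        GENETIC_CODE.get(seq[i : i + 3], "*") for i in range(0, len(seq), 3)
    )
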