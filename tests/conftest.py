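import numpy as np
import pytest

from retronscan.codon_usage import CodonUsageTable
from retronscan.library_design import design_dms, design_linker_library
from retronscan.reference_model import Region, TransgeneConstruct, make_fixture_construct


@pytest.fixture(scope="session")
def fixture_construct():
    return make_fixture_construct()


@pytest.fixture(scope="session")
def dms_library(fixture_construct):
    return design_dms(fixture_construct)


@pytest.fixture(scope="session")
def linker_library(fixture_construct):
    return design_linker_library(fixture_construct)


@pytest.fixture(scope="session")
def usage_table():
    return CodonUsageTable.ecoli_k12()


@pytest.fixture
def toy_construct():
    # 9 codons; SG / GS junction linkers around a 3-codon insert
    cds = (
        "ATGGCACGT"  # effector_N: M A R
        + "AGCGGT"  # left_linker: S G
        + "AAATTTCCC"  # insert_domain: K F P
        + "GGTAGC"  # right_linker: G S
        + "GAACTGTAA"  # effector_C: E L *
    )
    regions = (
        Region("effector_N", 0, 9),
        Region("left_linker", 9, 15),
        Region("insert_domain", 15, 24),
        Region("right_linker", 24, 30),
        Region("effector_C", 30, 39),
    )
    return TransgeneConstruct("toy", cds, regions)


def affine_local_score(a: str, b: str, match=1, mismatch=-2, gap_open=-4, gap_extend=-1):
    """Exhaustive Gotoh local-alignment score (independent oracle)."""
    n, m = len(a), len(b)
    NEG = -10**9
    M = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    Ix = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    Iy = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    M[0, :] = 0
    M[:, 0] = 0
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = s + max(0, M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            Ix[i, j] = max(M[i - 1, j] + gap_open, Ix[i - 1, j] + gap_extend)
            Iy[i, j] = max(M[i, j - 1] + gap_open, Iy[i, j - 1] + gap_extend)
            best = max(best, M[i, j], Ix[i, j], Iy[i, j])
    return int(best)


def score_from_record(rec):
    """Recompute an AlignmentRecord's score from its events (cross-check)."""
    matched_cols = rec.aligned_len - sum(
        len(e[3]) for e in rec.events if e[0] == "deletion"
    )
    n_mm = rec.n_mismatch
    score = (matched_cols - n_mm) * 1 + n_mm * -2
    for e in rec.events:
        if e[0] == "insertion":
            score += -4 - (len(e[2]) - 1)
        elif e[0] == "deletion":
            score += -4 - (len(e[3]) - 1)
    return score
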