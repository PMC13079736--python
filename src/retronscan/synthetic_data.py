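"""Synthetic variant pools, selection trajectories and sequencing reads.

Everything here is ground-truth-labelled and seeded so the analysis
pipelines can be exercised end to end without external data: variant pools
with programmed frequencies, a multiplicative fitness/bottleneck selection
model emulating alternating positive/negative selection passages, and
Illumina-style paired-end and Nanopore-style long reads with configurable
substitution- or indel-rich error profiles.

Read names encode the originating variant (``sim:<i>:<variant>``, with a
``:junk`` suffix for deliberately unusable long reads), which serves as the
ground truth for tests; an explicit TSV can be written alongside.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .codon_usage import translate
from .library_design import RetronDonor, apply_edit
from .reference_model import TransgeneConstruct

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)
_PHRED_OFFSET = 33


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class VariantPool:
    """Variant genotypes with frequencies at one timepoint."""

    variants: Mapping[str, Tuple[str, float]]
    timepoint: str = "t0"

    def __post_init__(self) -> None:
        object.__setattr__(self, "variants", dict(self.variants))
        freqs = np.array([f for _, f in self.variants.values()], dtype=float)
        if len(freqs) == 0:
            raise SimulationError("empty pool")
        if (freqs < 0).any():
            raise SimulationError("negative frequency")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise SimulationError(f"frequencies sum to {freqs.sum()!r}, not 1")
        for name, (seq, _) in self.variants.items():
            if len(seq) % 3:
                raise SimulationError(f"variant {name} is not in frame")

    @property
    def names(self) -> List[str]:
        return list(self.variants)

    @property
    def frequencies(self) -> Dict[str, float]:
        return {k: f for k, (_, f) in self.variants.items()}

    def sequence(self, name: str) -> str:
        return self.variants[name][0]


@dataclass(frozen=True)
class FitnessModel:
    """Per-variant multiplicative weights under each selection condition."""

    fitness: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        for name, conds in self.fitness.items():
            for cond, w in conds.items():
                if not np.isfinite(w) or w <= 0:
                    raise SimulationError(f"fitness weight for {name}/{cond} must be finite and > 0")

    def weight(self, name: str, condition: str) -> float:
        try:
            return self.fitness[name][condition]
        except KeyError:
            raise SimulationError(f"no fitness for variant {name!r} under condition {condition!r}")


@dataclass(frozen=True)
class SeqErrorModel:
    """Per-base error rates and the quality model tied to them.

    Correct bases get Phred qualities around ``q_correct`` and erroneous
    bases around ``q_error``, so Q-threshold filters see realistic input.
    """

    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    q_correct: int = 30
    q_error: int = 12

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0 <= r <= 0.2:
                raise SimulationError(f"error rate {r} outside [0, 0.2]")

    @property
    def is_error_free(self) -> bool:
        return self.sub_rate == self.ins_rate == self.del_rate == 0


@dataclass(frozen=True)
class AmpliconLayout:
    """Barcoded amplicon read structure for paired-end simulation."""

    fwd_barcode: str
    fwd_primer: str
    rev_barcode: str
    rev_primer: str


def pool_from_library(
    construct: TransgeneConstruct,
    donors: Sequence[RetronDonor],
    background_freq: float,
    edited_mass: Optional[Mapping[str, float]] = None,
    timepoint: str = "t0",
) -> VariantPool:
    """Pool with wild type at ``background_freq`` and donors sharing the rest.

    ``edited_mass`` optionally assigns each donor an absolute frequency;
    it must sum to 1 - background_freq.  By default the edited mass is
    spread uniformly.
    """
    if not 0 <= background_freq <= 1:
        raise SimulationError("background_freq outside [0, 1]")
    edited_total = 1.0 - background_freq
    variants: Dict[str, Tuple[str, float]] = {}
    if background_freq > 0 or not donors:
        variants["WT"] = (construct.cds, background_freq if donors else 1.0)
    if donors:
        if edited_mass is None:
            edited_mass = {d.name: edited_total / len(donors) for d in donors}
        total = sum(edited_mass.values())
        if abs(total - edited_total) > 1e-9:
            raise SimulationError(
                f"edited mass sums to {total}, expected {edited_total}"
            )
        for d in donors:
            variants[d.name] = (apply_edit(construct.cds, d.edit), edited_mass[d.name])
    return VariantPool(variants, timepoint)


def apply_selection(
    pool: VariantPool,
    model: FitnessModel,
    schedule: Sequence[Tuple[str, int]],
    seed: int = 0,
) -> List[VariantPool]:
    """Reweight-and-bottleneck trajectory across a selection schedule.

    Per step, frequencies are reweighted f' ~ f * w(condition) and then
    multinomially resampled at the bottleneck size (0 = deterministic
    reweighting only).  Returns the trajectory including the input pool.
    """
    if not schedule:
        raise SimulationError("empty selection schedule")
    rng = np.random.default_rng(seed)
    trajectory = [pool]
    current = pool
    for i, (condition, bottleneck_n) in enumerate(schedule, start=1):
        names = current.names
        f = np.array([current.frequencies[n] for n in names])
        w = np.array([model.weight(n, condition) for n in names])
        f = f * w
        f = f / f.sum()
        if bottleneck_n:
            counts = rng.multinomial(int(bottleneck_n), f)
            f = counts / counts.sum()
        variants = {n: (current.sequence(n), float(fi)) for n, fi in zip(names, f)}
        current = VariantPool(variants, timepoint=f"{i}_{condition}")
        trajectory.append(current)
    return trajectory


# -- read simulation --------------------------------------------------------


def _open_out(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def _revcomp(seq: str) -> str:
    comp = str.maketrans("ACGT", "TGCA")
    return seq.translate(comp)[::-1]


def _draw_variants(pool: VariantPool, n: int, rng) -> List[str]:
    names = pool.names
    p = np.array([pool.frequencies[x] for x in names])
    idx = rng.choice(len(names), size=n, p=p)
    return [names[i] for i in idx]


def _sub_errors(arr: np.ndarray, rate: float, rng) -> Tuple[np.ndarray, np.ndarray]:
    """Apply substitution errors in place; returns (array, error mask)."""
    if rate == 0:
        return arr, np.zeros(len(arr), dtype=bool)
    mask = rng.random(len(arr)) < rate
    n = int(mask.sum())
    if n:
        shift = rng.integers(1, 4, size=n)
        codes = {65: 0, 67: 1, 71: 2, 84: 3}
        lut = np.zeros(256, dtype=np.uint8)
        for b, i in codes.items():
            lut[b] = i
        cur = lut[arr[mask]]
        arr[mask] = _BASE_ARR[(cur + shift) % 4]
    return arr, mask


def _qual_string(n: int, err_mask: np.ndarray, err: SeqErrorModel, rng) -> str:
    q = np.full(n, err.q_correct, dtype=np.int16)
    q += rng.integers(-2, 3, size=n)
    q[err_mask[:n]] = err.q_error + rng.integers(-2, 3, size=int(err_mask[:n].sum()))
    q = np.clip(q, 2, 41)
    return (q + _PHRED_OFFSET).astype(np.uint8).tobytes().decode("ascii")


def simulate_illumina(
    pool: VariantPool,
    n_pairs: int,
    read_len: int,
    layout: AmpliconLayout,
    err: SeqErrorModel,
    seed: int,
    r1_path,
    r2_path,
    truth_path=None,
) -> Dict[str, int]:
    """Paired-end amplicon reads: R1 = barcode+primer+template prefix,
    R2 = barcode+primer+reverse-complement template prefix.

    Substitution errors only (the platform's dominant mode), with quality
    strings consistent with the error positions.  Byte-identical output for
    identical seeds.  Returns per-variant read-pair counts.
    """
    prefix_len = len(layout.fwd_barcode) + len(layout.fwd_primer)
    if read_len <= max(prefix_len, len(layout.rev_barcode) + len(layout.rev_primer)):
        raise SimulationError("read_len shorter than barcode+primer")
    rng = np.random.default_rng(seed)
    assignments = _draw_variants(pool, n_pairs, rng)
    counts: Dict[str, int] = {}
    templates_r1: Dict[str, str] = {}
    templates_r2: Dict[str, str] = {}
    for name in pool.names:
        amplicon = pool.sequence(name)
        if read_len - prefix_len > len(amplicon):
            raise SimulationError("read_len exceeds amplicon length")
        templates_r1[name] = (layout.fwd_barcode + layout.fwd_primer + amplicon)[:read_len]
        templates_r2[name] = (layout.rev_barcode + layout.rev_primer + _revcomp(amplicon))[:read_len]
    rows = []
    with _open_out(r1_path) as f1, _open_out(r2_path) as f2:
        for i, name in enumerate(assignments):
            counts[name] = counts.get(name, 0) + 1
            rid = f"sim:{i}:{name}"
            for tmpl, fh in ((templates_r1[name], f1), (templates_r2[name], f2)):
                arr = np.frombuffer(tmpl.encode(), dtype=np.uint8).copy()
                arr, mask = _sub_errors(arr, err.sub_rate, rng)
                qual = _qual_string(len(arr), mask, err, rng)
                fh.write(f"@{rid}\n{arr.tobytes().decode('ascii')}\n+\n{qual}\n")
            rows.append((rid, name))
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            fh.write("read_id\tvariant\n")
            for rid, name in rows:
                fh.write(f"{rid}\t{name}\n")
    return counts


def _indel_errors(arr: np.ndarray, err: SeqErrorModel, rng) -> Tuple[np.ndarray, np.ndarray]:
    """Apply insertion/deletion errors; returns (array, error mask for quals)."""
    n = len(arr)
    keep = rng.random(n) >= err.del_rate if err.del_rate else np.ones(n, dtype=bool)
    arr = arr[keep]
    err_mask = np.zeros(len(arr), dtype=bool)
    if err.ins_rate:
        ins_sites = np.flatnonzero(rng.random(len(arr)) < err.ins_rate)
        if len(ins_sites):
            bases = _BASE_ARR[rng.integers(0, 4, size=len(ins_sites))]
            arr = np.insert(arr, ins_sites, bases)
            err_mask = np.insert(err_mask, ins_sites, True)
    return arr, err_mask


def simulate_longread(
    pool: VariantPool,
    n_reads: int,
    err: SeqErrorModel,
    seed: int,
    path,
    junk_frac: float = 0.0,
    truth_path=None,
) -> Dict[str, int]:
    """Full-length amplicon long reads with substitution AND indel errors.

    A ``junk_frac`` fraction of reads is deliberately unusable (truncated or
    uniformly low-quality, alternating) to exercise QC filters; junk reads
    carry a ``:junk`` name suffix.  Byte-identical output for identical
    seeds.  Returns per-variant counts over non-junk reads.
    """
    if not 0 <= junk_frac <= 1:
        raise SimulationError("junk_frac outside [0, 1]")
    rng = np.random.default_rng(seed)
    assignments = _draw_variants(pool, n_reads, rng)
    junk = rng.random(n_reads) < junk_frac
    counts: Dict[str, int] = {}
    rows = []
    n_junk = 0
    with _open_out(path) as fh:
        for i, name in enumerate(assignments):
            template = pool.sequence(name)
            arr = np.frombuffer(template.encode(), dtype=np.uint8).copy()
            arr, sub_mask = _sub_errors(arr, err.sub_rate, rng)
            arr, ins_mask = _indel_errors(arr, err, rng)
            if err.del_rate:  # sub_mask no longer aligned after deletions; fold in
                err_mask = ins_mask
            else:
                err_mask = sub_mask[: len(arr)] | ins_mask
            if junk[i]:
                n_junk += 1
                rid = f"sim:{i}:{name}:junk"
                if n_junk % 2:  # truncated read
                    cut = max(50, int(0.5 * len(arr)))
                    arr = arr[:cut]
                    qual = _qual_string(len(arr), err_mask[:cut], err, rng)
                else:  # uniformly low quality
                    q = np.full(len(arr), 8, dtype=np.uint8) + _PHRED_OFFSET
                    qual = q.tobytes().decode("ascii")
                fh.write(f"@{rid}\n{arr.tobytes().decode('ascii')}\n+\n{qual}\n")
                rows.append((rid, name))
                continue
            counts[name] = counts.get(name, 0) + 1
            rid = f"sim:{i}:{name}"
            qual = _qual_string(len(arr), err_mask, err, rng)
            fh.write(f"@{rid}\n{arr.tobytes().decode('ascii')}\n+\n{qual}\n")
            rows.append((rid, name))
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            fh.write("read_id\tvariant\n")
            for rid, name in rows:
                fh.write(f"{rid}\t{name}\n")
    return counts
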