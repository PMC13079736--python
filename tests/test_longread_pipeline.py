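import math

import numpy as np
import pandas as pd
import pytest

from retronscan.alignment import align_overlap
from retronscan.library_design import EditSpec, apply_edit, build_donor
from retronscan.longread_pipeline import (
    AA_CLASSES,
    LongReadQC,
    align_longreads,
    cooccurrence,
    correct_indels_dms,
    enrichment_logo,
    extract_linker_variants,
    filter_longread_file,
    filter_longreads,
    flag_artifact_positions,
    mean_read_quality,
    position_frequencies,
    rank_by_variance,
    temporal_enrichment,
)
from retronscan.synthetic_data import SeqErrorModel, pool_from_library, simulate_longread


def _q(n, q=30):
    return chr(q + 33) * n


def _flip(b):
    return {"A": "C", "C": "G", "G": "T", "T": "A"}[b]


class TestQcFilter:
    def test_length_1800_excluded_strict_bound(self):
        reads = [("a", "A" * 1800, _q(1800)), ("b", "A" * 1801, _q(1801)),
                 ("c", "A" * 2199, _q(2199)), ("d", "A" * 2200, _q(2200))]
        kept, report = filter_longreads(reads, LongReadQC())
        assert [r[0] for r in kept] == ["b", "c"]
        assert report["failed_length"] == 2

    def test_q30_read_of_length_2000_retained(self):
        kept, _ = filter_longreads([("r", "A" * 2000, _q(2000, q=30))], LongReadQC())
        assert len(kept) == 1

    def test_mean_error_probability_convention(self):
        # mean error probability 0.011 -> Q about 19.6 -> excluded at Q>20
        # build a quality string mixing Q10 (p=0.1) and Q40 (p=1e-4):
        # 11% at Q10 gives mean p = 0.11*0.1 + 0.89*1e-4 = 0.011089
        n = 2000
        n_low = 220
        qual = chr(10 + 33) * n_low + chr(40 + 33) * (n - n_low)
        expected_q = -10 * math.log10((n_low * 0.1 + (n - n_low) * 1e-4) / n)
        assert mean_read_quality(qual) == pytest.approx(expected_q)
        assert expected_q < 20
        kept, report = filter_longreads([("r", "A" * n, qual)], LongReadQC())
        assert not kept and report["failed_quality"] == 1
        # the arithmetic mean of Phred scores would have passed: guard against
        # accidentally using that convention
        assert (10 * n_low + 40 * (n - n_low)) / n > 20


class TestIndelCorrection:
    def test_insertion_only_read_projects_to_reference(self, fixture_construct):
        ref = fixture_construct.cds
        read = ref[:1000] + "G" + ref[1000:]
        aln = align_overlap(read, ref)
        proj = correct_indels_dms(aln, ref, (0, len(ref)))
        assert proj == ref

    def test_substitution_survives_nearby_deletion_fill(self, fixture_construct):
        ref = fixture_construct.cds
        read = list(ref)
        read[500] = _flip(read[500])
        read = "".join(read[:520]) + "".join(read[523:])  # 3-nt deletion at 520
        aln = align_overlap(read, ref)
        proj = correct_indels_dms(aln, ref, (0, len(ref)))
        assert len(proj) == len(ref)
        diffs = [i for i in range(len(ref)) if proj[i] != ref[i]]
        assert diffs == [500]

    def test_error_free_read_is_identity(self, fixture_construct):
        ref = fixture_construct.cds
        aln = align_overlap(ref, ref)
        assert correct_indels_dms(aln, ref, (0, len(ref))) == ref

    def test_window_length_always_preserved(self, fixture_construct):
        ref = fixture_construct.cds
        rng = np.random.default_rng(3)
        for _ in range(10):
            read = list(ref)
            for _ in range(5):
                read[int(rng.integers(0, len(read)))] = "ACGT"[int(rng.integers(0, 4))]
            read = "".join(read)
            cut = int(rng.integers(100, 1900))
            read = read[:cut] + read[cut + int(rng.integers(1, 4)):]
            aln = align_overlap(read, ref)
            proj = correct_indels_dms(aln, ref, (60, 1860))
            assert proj is None or len(proj) == 1800

    def test_read_not_covering_window_dropped(self, fixture_construct):
        ref = fixture_construct.cds
        aln = align_overlap(ref[100:], ref)
        assert correct_indels_dms(aln, ref, (0, len(ref))) is None


class TestPositionFrequencies:
    def test_all_wild_type_gives_zero_rates(self, fixture_construct):
        ref = fixture_construct.cds
        counts = position_frequencies([ref] * 10, fixture_construct)
        assert counts.nt_mutation_rate().sum() == 0
        assert counts.aa_mutation_rate().sum() == 0

    def test_programmed_variant_rate_within_3_sigma(self, fixture_construct, tmp_path):
        c = fixture_construct
        # non-silent codon substitution ~25% of the pool
        edit = EditSpec("substitution", 666, 669, "ATG" if c.cds[666:669] != "ATG" else "TGG", "V")
        donor = build_donor(c, edit)
        pool = pool_from_library(c, [donor], background_freq=0.75)
        n = 3000
        simulate_longread(pool, n, SeqErrorModel(), 13, tmp_path / "lr.fq")
        kept, _ = filter_longread_file(tmp_path / "lr.fq")
        alns = align_longreads(kept, c)
        projs = [p for p in (correct_indels_dms(a, c.cds, (0, len(c.cds))) for a in alns) if p]
        counts = position_frequencies(projs, c)
        rate = counts.aa_mutation_rate()[222]
        sigma = math.sqrt(0.25 * 0.75 / n)
        assert abs(rate - 0.25) < 3 * sigma

    def test_silent_change_counts_at_nt_level_only(self, fixture_construct):
        c = fixture_construct
        # find a position where a synonymous change exists: use codon 200
        ci = 200
        from retronscan.codon_usage import GENETIC_CODE, translate

        ref_codon = c.codon(ci)
        synonyms = [k for k, v in GENETIC_CODE.items()
                    if v == translate(ref_codon) and k != ref_codon]
        silent = synonyms[0]
        variant = c.cds[: 3 * ci] + silent + c.cds[3 * ci + 3 :]
        counts = position_frequencies([variant, c.cds], c)
        assert counts.aa_mutation_rate()[ci] == 0
        assert counts.nt_mutation_rate()[3 * ci : 3 * ci + 3].sum() > 0
        assert counts.codon_mutation_rate()[ci] == 0.5


class TestLinkerExtraction:
    def test_left_only_edit_classified(self, fixture_construct, linker_library):
        c = fixture_construct
        donor = {d.name: d for d in linker_library}["LdelK"]
        variant = apply_edit(c.cds, donor.edit)
        res = extract_linker_variants([("r", variant, _q(len(variant)))], c)
        assert res.classes == ["left-only"]

    def test_class_partition_sums_to_total(self, fixture_construct, linker_library, tmp_path):
        c = fixture_construct
        by_name = {d.name: d for d in linker_library}
        sel = [by_name[n] for n in ("LdelK", "R_Ja_IDEAAKEL", "L_del2", "RdelG")]
        pool = pool_from_library(c, sel, background_freq=0.4)
        n = 800
        simulate_longread(pool, n, SeqErrorModel(sub_rate=0.003), 19, tmp_path / "lr.fq")
        kept, _ = filter_longread_file(tmp_path / "lr.fq")
        res = extract_linker_variants(kept, c)
        assert sum(res.class_counts.values()) == len(kept)
        non_filtered = sum(v for k, v in res.class_counts.items() if k != "filtered")
        assert non_filtered == len(res.classes)

    def test_low_frequency_variants_dropped_by_noise_floor(self, fixture_construct):
        c = fixture_construct
        reads = [("wt%d" % i, c.cds, _q(len(c.cds))) for i in range(999)]
        rare = c.cds[:510] + "AAAGGC" + c.cds[516:]  # rare left-junction variant
        reads.append(("rare", rare, _q(len(rare))))
        res = extract_linker_variants(reads, c, noise_floor=0.002)
        assert "AAAGGC" not in "".join(res.table.nt_seq.tolist())
        # but it still participated in classification
        assert res.class_counts["left-only"] == 1

    def test_frameshifted_reads_filtered(self, fixture_construct):
        c = fixture_construct
        reads = []
        for i in (1, 2, 4, 5):  # all non-multiple-of-3 shifts
            fs = c.cds[:513] + "A" * i + c.cds[513:]
            reads.append((f"fs{i}", fs, _q(len(fs))))
        res = extract_linker_variants(reads, c)
        assert res.class_counts["filtered"] == len(reads)
        assert not res.classes


class TestTemporalEnrichment:
    def _counts_for(self, construct, rate_by_residue, n=200):
        """Synthesize projections giving target per-residue aa mutation rates."""
        ref = construct.cds
        projections = []
        for k in range(n):
            read = list(ref)
            for residue, rate in rate_by_residue.items():
                if k < int(rate * n):
                    i = 3 * residue
                    codon = ref[i : i + 3]
                    read[i : i + 3] = "ATG" if codon != "ATG" else "TGG"
            projections.append("".join(read))
        return position_frequencies(projections, construct)

    def test_baseline_column_becomes_zero(self, fixture_construct):
        steps = [
            ("mut1", self._counts_for(fixture_construct, {50: 0.05})),
            ("neg1", self._counts_for(fixture_construct, {50: 0.20})),
        ]
        tm = temporal_enrichment(steps, "mut1")
        assert (tm.corrected["mut1"] == 0).all()

    def test_rising_variant_corrected_value(self, fixture_construct):
        steps = [
            ("mut1", self._counts_for(fixture_construct, {60: 0.05})),
            ("pos1", self._counts_for(fixture_construct, {60: 0.40})),
        ]
        tm = temporal_enrichment(steps, "mut1")
        assert tm.corrected.loc[61, "pos1"] == pytest.approx(0.35, abs=0.01)

    def test_constant_background_corrects_to_zero(self, fixture_construct):
        steps = [
            ("mut1", self._counts_for(fixture_construct, {70: 0.02})),
            ("neg1", self._counts_for(fixture_construct, {70: 0.02})),
            ("pos1", self._counts_for(fixture_construct, {70: 0.02})),
        ]
        tm = temporal_enrichment(steps, "mut1")
        assert np.allclose(tm.corrected.values, 0)

    def test_correction_exactly_invertible(self, fixture_construct):
        rng = np.random.default_rng(23)
        steps = [
            (f"s{i}", self._counts_for(
                fixture_construct,
                {int(r): float(p) for r, p in
                 zip(rng.integers(0, 600, 5), rng.random(5) * 0.5)},
            ))
            for i in range(4)
        ]
        tm = temporal_enrichment(steps, "s0")
        restored = tm.corrected.add(tm.raw["s0"], axis=0)
        assert np.allclose(restored.values, tm.raw.values)

    def test_missing_baseline_rejected(self, fixture_construct):
        steps = [("a", self._counts_for(fixture_construct, {})),
                 ("b", self._counts_for(fixture_construct, {}))]
        with pytest.raises(Exception, match="baseline"):
            temporal_enrichment(steps, "zzz")


class TestArtifactFlagging:
    def test_high_background_position_flagged(self, fixture_construct):
        c = fixture_construct
        ref = c.cds
        projections = []
        for k in range(100):
            read = list(ref)
            if k < 95:  # 95% background at residue 38
                i = 3 * 37
                read[i : i + 3] = "ATG" if ref[i : i + 3] != "ATG" else "TGG"
            projections.append("".join(read))
        counts = position_frequencies(projections, c)
        assert flag_artifact_positions(counts, threshold=0.5) == [38]

    def test_clean_control_gives_empty_list(self, fixture_construct):
        counts = position_frequencies([fixture_construct.cds] * 20, fixture_construct)
        assert flag_artifact_positions(counts) == []

    def test_threshold_one_flags_nothing(self, fixture_construct):
        c = fixture_construct
        read = list(c.cds)
        read[0:3] = "ATG" if c.cds[:3] != "ATG" else "TGG"
        counts = position_frequencies(["".join(read)] * 10, c)
        assert flag_artifact_positions(counts, threshold=1.0) == []


class TestCooccurrence:
    def _variant(self, construct, residues):
        read = list(construct.cds)
        for r in residues:
            i = 3 * r
            codon = construct.cds[i : i + 3]
            read[i : i + 3] = "ATG" if codon != "ATG" else "TGG"
        return "".join(read)

    def test_perfectly_linked_mutations(self, fixture_construct):
        c = fixture_construct
        both = self._variant(c, [10, 20])
        projs = [both] * 50 + [c.cds] * 50
        m = cooccurrence(projs, c)
        assert len(m.marginals) == 2
        a, b = m.marginals.index
        assert m.joint.loc[a, b] == pytest.approx(0.5)
        assert m.marginals[a] == m.marginals[b] == pytest.approx(0.5)

    def test_mutually_exclusive_mutations_have_zero_joint(self, fixture_construct):
        c = fixture_construct
        projs = [self._variant(c, [10])] * 30 + [self._variant(c, [20])] * 30 + [c.cds] * 40
        m = cooccurrence(projs, c)
        a, b = sorted(m.marginals.index)
        assert m.joint.loc[a, b] == 0

    def test_independent_mutations_joint_within_3_sigma(self, fixture_construct):
        c = fixture_construct
        rng = np.random.default_rng(29)
        n = 4000
        pa, pb = 0.4, 0.3
        has_a = rng.random(n) < pa
        has_b = rng.random(n) < pb
        projs = [
            self._variant(c, ([10] if a else []) + ([20] if b else []))
            for a, b in zip(has_a, has_b)
        ]
        m = cooccurrence(projs, c)
        a, b = sorted(m.marginals.index)
        p = pa * pb
        sigma = math.sqrt(p * (1 - p) / n)
        assert abs(m.joint.loc[a, b] - p) < 3 * sigma

    def test_marginal_threshold_excludes_rare_mutations(self, fixture_construct):
        c = fixture_construct
        projs = [self._variant(c, [10])] * 9 + [c.cds] * 91  # 9% < 9.5%
        m = cooccurrence(projs, c, min_marginal=0.095)
        assert len(m.marginals) == 0

    def test_joint_bounded_by_marginals_on_randomized_pools(self, fixture_construct):
        c = fixture_construct
        rng = np.random.default_rng(31)
        residues = [5, 15, 25, 35]
        projs = []
        for _ in range(500):
            muts = [r for r in residues if rng.random() < 0.3]
            projs.append(self._variant(c, muts))
        m = cooccurrence(projs, c, min_marginal=0.05)
        for a in m.joint.index:
            for b in m.joint.columns:
                assert m.joint.loc[a, b] <= min(m.marginals[a], m.marginals[b]) + 1e-12


class TestRankingAndLogo:
    def test_variance_ranking_with_tie_break(self):
        series = {
            "s1": {"const": 0.1, "rise": 0.0, "mild": 0.1, "zzz": 0.2, "aaa": 0.2},
            "s2": {"const": 0.1, "rise": 0.4, "mild": 0.15, "zzz": 0.3, "aaa": 0.3},
        }
        top = rank_by_variance(series, k=3)
        assert top.variant.tolist()[0] == "rise"  # 0 -> 0.4 beats 0.1 -> 0.2
        # aaa and zzz tie; lexicographic break
        assert top.variant.tolist()[1:] == ["aaa", "zzz"]
        assert top.variance.iloc[0] == pytest.approx(np.var([0.0, 0.4]))

    def test_constant_variant_ranks_last(self):
        series = {"s1": {"a": 0.2, "b": 0.1}, "s2": {"a": 0.2, "b": 0.3}}
        full = rank_by_variance(series, k=10)
        assert full.variant.tolist()[-1] == "a"
        assert full.variance.iloc[-1] == 0

    def test_k_larger_than_table_returns_all(self):
        series = {"s1": {"a": 0.5}, "s2": {"a": 0.1}}
        assert len(rank_by_variance(series, k=10)) == 1

    def test_logo_retains_only_fractions_above_threshold(self, fixture_construct):
        c = fixture_construct
        ref = c.cds
        projections = []
        for k in range(1000):
            read = list(ref)
            if k < 400:  # 40% substitution at residue 31
                read[90:93] = "ATG" if ref[90:93] != "ATG" else "TGG"
            if k < 9:  # 0.9% substitution at residue 41 -> dropped
                read[120:123] = "TGG" if ref[120:123] != "TGG" else "ATG"
            projections.append("".join(read))
        counts = position_frequencies(projections, c)
        logo = enrichment_logo(counts, min_frac=0.01)
        assert set(logo.residue) == {31}
        assert logo.fraction.iloc[0] == pytest.approx(0.4)

    def test_basic_and_acidic_classes(self):
        assert AA_CLASSES["K"] == AA_CLASSES["R"] == "positive"
        assert AA_CLASSES["D"] == AA_CLASSES["E"] == "negative"
        assert set(AA_CLASSES) == set("ACDEFGHIKLMNPQRSTVWY")
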