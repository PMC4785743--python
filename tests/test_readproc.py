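"""Read-processing chain: merge, demultiplex, filters, dereplication,
denoising, chimera and contaminant screens."""

import numpy as np
import pytest

from metaprofiler.primertools import DegeneratePrimer
from metaprofiler.readproc import (
    MergedRead,
    ReadPair,
    PipelineLedger,
    UniqueAmplicon,
    chimera_screen,
    decontaminate,
    demultiplex,
    denoise_by_abundance,
    dereplicate,
    expected_errors,
    merge_pairs,
    quality_filter,
    size_filter_and_trim,
)
from metaprofiler.seqcore import NucSequence, ReferenceRecord, TaxonLineage, reverse_complement

LINEAGE = TaxonLineage.from_string("Eukaryota;Chlorophyta")


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _ref(rec_id, bases):
    return ReferenceRecord(NucSequence(rec_id, bases), LINEAGE)


class TestMergePairs:
    def test_perfect_overlap_reconstructs_template(self):
        rng = np.random.default_rng(20)
        template = _rand(rng, 80)
        r1 = template[:60]
        r2 = reverse_complement(template[-60:])
        pair = ReadPair("p", r1, (30,) * 60, r2, (30,) * 60)
        merged, failed = merge_pairs([pair], min_overlap=16)
        assert failed == 0
        assert merged[0].bases == template
        assert len(merged[0].quals) == 80

    def test_higher_quality_base_wins_in_conflict(self):
        rng = np.random.default_rng(21)
        template = _rand(rng, 80)
        r1 = template[:60]
        # read 2 carries one wrong base in the overlap, at low quality
        tail = list(template[-60:])
        tail[30] = {"A": "C", "C": "G", "G": "T", "T": "A"}[tail[30]]
        r2 = reverse_complement("".join(tail))
        pair = ReadPair("p", r1, (40,) * 60, r2, (10,) * 60)
        merged, _ = merge_pairs([pair], min_overlap=16)
        assert merged[0].bases == template  # r1's Q40 call retained
        assert merged[0].quals[50] == 40

    def test_agreement_keeps_max_quality(self):
        rng = np.random.default_rng(22)
        template = _rand(rng, 60)
        pair = ReadPair("p", template[:40], (20,) * 40,
                        reverse_complement(template[-40:]), (35,) * 40)
        merged, _ = merge_pairs([pair], min_overlap=16)
        overlap_start = 60 - 40
        assert merged[0].quals[overlap_start + 1] == 35

    def test_no_overlap_pair_dropped_and_counted(self):
        rng = np.random.default_rng(23)
        pair = ReadPair("p", _rand(rng, 50), (30,) * 50, _rand(rng, 50), (30,) * 50)
        merged, failed = merge_pairs([pair], min_overlap=30,
                                     max_overlap_mismatch_frac=0.05)
        assert merged == [] and failed == 1


class TestDemultiplex:
    PRIMER = DegeneratePrimer("fwd", "GCAGATGGTCCAATGCCWCAAAC")
    INDEXES = {"S1": "ACGTACGT", "S2": "TTGGCCAA"}

    def _read(self, index, primer_seq, insert="ACGT" * 30):
        bases = index + primer_seq + insert
        return MergedRead("r", bases, (30,) * len(bases))

    def test_exact_index_assigned_and_stripped(self):
        insert = "ACGT" * 30
        read = self._read("ACGTACGT", self.PRIMER.bases.replace("W", "A"), insert)
        out, dropped = demultiplex([read], self.INDEXES, self.PRIMER, 1)
        assert dropped == 0
        assert out[0].sample == "S1"
        assert out[0].bases == insert

    def test_one_index_mismatch_discards(self):
        """Index matching allows no mismatches at all."""
        read = self._read("ACGTACGA", self.PRIMER.bases.replace("W", "A"))
        out, dropped = demultiplex([read], self.INDEXES, self.PRIMER, 2)
        assert out == [] and dropped == 1

    def test_primer_mismatch_budget_enforced(self):
        site = list(self.PRIMER.bases.replace("W", "A"))
        site[2] = "T" if site[2] != "T" else "A"
        site[5] = "T" if site[5] != "T" else "A"
        read = self._read("ACGTACGT", "".join(site))
        out, dropped = demultiplex([read], self.INDEXES, self.PRIMER, 1)
        assert out == [] and dropped == 1
        out, dropped = demultiplex([read], self.INDEXES, self.PRIMER, 2)
        assert dropped == 0 and out[0].sample == "S1"

    def test_duplicate_index_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            demultiplex([], {"A": "ACGT", "B": "ACGT"}, self.PRIMER, 1)


class TestQualityFilter:
    def _read(self, quals):
        return MergedRead("r", "A" * len(quals), tuple(quals), "S1")

    def test_expected_error_formula(self):
        assert expected_errors([20] * 10) == pytest.approx(0.1)
        assert expected_errors([2]) == pytest.approx(10 ** -0.2)

    def test_low_error_read_kept(self):
        kept, dropped = quality_filter([self._read([20] * 10)])
        assert len(kept) == 1 and dropped == 0

    def test_single_q2_base_exceeds_half_error(self):
        # E = 10^(-0.2) ≈ 0.631 > 0.5
        kept, dropped = quality_filter([self._read([2])])
        assert kept == [] and dropped == 1

    def test_boundary_is_inclusive(self):
        # 50 bases at Q20: E = 0.5 exactly, kept
        kept, _ = quality_filter([self._read([20] * 50)])
        assert len(kept) == 1

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(24)
        reads = [
            self._read(list(rng.integers(2, 41, size=int(rng.integers(5, 60)))))
            for _ in range(40)
        ]
        kept, _ = quality_filter(reads, 0.5)
        expected = [r for r in reads if sum(10 ** (-q / 10) for q in r.quals) <= 0.5]
        assert kept == expected


class TestSizeFilterAndTrim:
    def _read(self, n):
        return MergedRead("r", "A" * n, (30,) * n, "S1")

    def test_default_window_drops_445(self):
        kept, dropped = size_filter_and_trim([self._read(445)])
        assert kept == [] and dropped == 1

    def test_445_with_raised_ceiling_trims_to_375(self):
        kept, _ = size_filter_and_trim([self._read(445)], max_len=450)
        assert len(kept[0].bases) == 375
        assert kept[0].quals is None  # qualities end at trimming

    def test_bounds_inclusive(self):
        kept, _ = size_filter_and_trim([self._read(400), self._read(440)])
        assert [len(r.bases) for r in kept] == [330, 370]

    def test_degenerate_crop_rejected(self):
        with pytest.raises(ValueError, match="crop"):
            size_filter_and_trim([], min_len=60, crop5=20, crop3=50)


class TestDereplicate:
    def _reads(self, spec):
        out = []
        for i, (bases, sample) in enumerate(spec):
            out.append(MergedRead(f"r{i}", bases, None, sample))
        return out

    def test_counts_per_sample(self):
        reads = self._reads([("AAAA", "A")] * 5 + [("AAAA", "B")] * 2)
        amps = dereplicate(reads)
        assert len(amps) == 1
        assert amps[0].total_count == 7
        assert amps[0].per_sample_counts == {"A": 5, "B": 2}

    def test_all_distinct(self):
        reads = self._reads([("AAAA", "A"), ("CCCC", "A"), ("GGGG", "A")])
        assert [a.total_count for a in dereplicate(reads)] == [1, 1, 1]

    def test_deterministic_tie_break_is_lexicographic(self):
        reads = self._reads([("TTTT", "A")] * 3 + [("AAAA", "A")] * 3)
        amps = dereplicate(reads)
        assert [a.bases for a in amps] == ["AAAA", "TTTT"]

    def test_totals_conserved(self):
        rng = np.random.default_rng(25)
        reads = self._reads([
            (_rand(rng, 8), rng.choice(["A", "B"])) for _ in range(200)
        ])
        amps = dereplicate(reads)
        assert sum(a.total_count for a in amps) == 200

    def test_missing_sample_label_rejected(self):
        with pytest.raises(ValueError, match="sample"):
            dereplicate([MergedRead("r", "AAAA", None, None)])


class TestDenoise:
    def _amp(self, bases, n):
        return UniqueAmplicon(bases, n, {"A": n})

    @pytest.mark.parametrize("count, survives", [(1, False), (3, False), (4, True)])
    def test_total_count_boundary(self, count, survives):
        kept, _ = denoise_by_abundance([self._amp("AAAA", count)])
        assert bool(kept) is survives

    def test_empty_input(self):
        assert denoise_by_abundance([]) == ([], 0)


class TestChimeraScreen:
    def _parents(self, rng, ident=0.8, n=375):
        a = _rand(rng, n)
        b = list(a)
        k = int(round((1 - ident) * n))
        for i in rng.choice(n, size=k, replace=False):
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        return a, "".join(b)

    def test_constructed_bimera_flagged(self):
        rng = np.random.default_rng(26)
        a, b = self._parents(rng)
        bimera = a[:200] + b[200:]
        amp = UniqueAmplicon(bimera, 10, {"A": 10})
        clean, flagged = chimera_screen([amp], [_ref("a", a), _ref("b", b)])
        assert flagged == [amp] and clean == []

    def test_reference_identical_amplicon_clean(self):
        rng = np.random.default_rng(27)
        a, b = self._parents(rng)
        amp = UniqueAmplicon(a, 10, {"A": 10})
        clean, flagged = chimera_screen([amp], [_ref("a", a), _ref("b", b)])
        assert clean == [amp] and flagged == []

    def test_decisions_equal_exhaustive_oracle(self):
        """Flagging decisions match a brute-force scan over every parent
        pair and crossover point on a divergence-ladder fixture."""
        rng = np.random.default_rng(28)
        n = 200
        refs = []
        base = _rand(rng, n)
        for i in range(8):
            seq = list(base)
            for p in rng.choice(n, size=8 * (i + 1), replace=False):
                seq[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[p]]
            refs.append("".join(seq))
        queries = []
        for i in range(6):
            ia, ib = rng.choice(len(refs), size=2, replace=False)
            cut = int(rng.integers(40, n - 40))
            queries.append(refs[ia][:cut] + refs[ib][cut:])
        queries += refs[:2]
        amps = [UniqueAmplicon(q, 5, {"A": 5}) for q in queries]
        ref_records = [_ref(f"r{i}", s) for i, s in enumerate(refs)]
        _, flagged = chimera_screen(amps, ref_records)

        def oracle(query):
            match = [
                [1 if x == y else 0 for x, y in zip(query, r)] for r in refs
            ]
            totals = [sum(m) for m in match]
            best_single = 100 * max(totals) / n
            best_two = 0.0
            for ia in range(len(refs)):
                pre = np.concatenate(([0], np.cumsum(match[ia])))
                for ib in range(len(refs)):
                    if ia == ib:
                        continue
                    preb = np.concatenate(([0], np.cumsum(match[ib])))
                    combo = pre[1:n] + totals[ib] - preb[1:n]
                    best_two = max(best_two, 100 * combo.max() / n)
            return best_two - best_single >= 3.0 and best_two >= 99.0

        expected = {a.bases for a in amps if oracle(a.bases)}
        assert {a.bases for a in flagged} == expected

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            chimera_screen([], [])


class TestDecontaminate:
    def test_reference_sequence_kept(self):
        rng = np.random.default_rng(29)
        ref = _rand(rng, 375)
        amp = UniqueAmplicon(ref, 5, {"A": 5})
        kept, removed = decontaminate([amp], [_ref("r", ref)])
        assert kept == [amp] and removed == []

    def test_random_sequences_removed_at_default_floor(self):
        """Unrelated random sequences sit near the alignment noise floor,
        well under 60 % identity, across seeds."""
        rng = np.random.default_rng(30)
        refs = [_ref(f"r{i}", _rand(rng, 375)) for i in range(3)]
        amps = [UniqueAmplicon(_rand(rng, 375), 5, {"A": 5}) for _ in range(20)]
        kept, removed = decontaminate(amps, refs)
        assert kept == [] and len(removed) == 20

    def test_diverged_marker_kept(self):
        rng = np.random.default_rng(31)
        ref = _rand(rng, 375)
        seq = list(ref)
        for i in rng.choice(375, size=130, replace=False):  # 35 % divergence
            seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        amp = UniqueAmplicon("".join(seq), 5, {"A": 5})
        kept, _ = decontaminate([amp], [_ref("r", ref)])
        assert kept == [amp]


class TestLedger:
    def test_percent_of_raw_and_monotonicity(self):
        ledger = PipelineLedger()
        ledger.add("raw", 1000)
        ledger.add("merge", 960)
        assert ledger.rows[-1] == ("merge", 960, 96)
        with pytest.raises(ValueError, match="non-increasing"):
            ledger.add("bad", 970)
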