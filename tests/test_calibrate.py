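"""Threshold calibration: rank divergences, conservative and relaxed
cutoffs, OTU annotation and database performance."""

import numpy as np
import pytest

from metaprofiler.calibrate import (
    ThresholdEntry,
    ThresholdSet,
    annotate_otu,
    calibrate_thresholds,
    conservative_threshold,
    db_performance,
    rank_divergence,
    relaxed_threshold,
    round_up_threshold,
)
from metaprofiler.otucluster import OTU
from metaprofiler.readproc import UniqueAmplicon
from metaprofiler.seqcore import (
    UNRESOLVED,
    NucSequence,
    ReferenceRecord,
    TaxonLineage,
    aligned_identity,
)
from tests.conftest import simulated_db


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _mutate(seq, positions):
    chars = list(seq)
    for i in positions:
        chars[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[i]]
    return "".join(chars)


def _spread(k, length):
    """k well-separated positions, so gapped alignment cannot shrink the
    planted Hamming distance."""
    step = length // k
    return [i * step for i in range(k)]


def _rec(rec_id, bases, lineage):
    return ReferenceRecord(NucSequence(rec_id, bases), TaxonLineage.from_string(lineage))


def _two_family_db(rng, n_cross_mismatch, length=375):
    """Two families whose closest cross pair differs by exactly
    ``n_cross_mismatch`` positions; within-family haplotypes differ by 2
    at reserved positions so the cross-family minimum is never eroded."""
    root = _rand(rng, length)
    cross = list(range(n_cross_mismatch))
    fam_b = _mutate(root, cross)
    reserved = iter(range(n_cross_mismatch, n_cross_mismatch + 40))
    records = []
    for fam, consensus in (("famA", root), ("famB", fam_b)):
        lineage = f"Euk;Chloro;Ulvo;Bryo;Ostreo;{fam};{fam}_sp"
        records.append(_rec(f"{fam}_h0", consensus, lineage))
        for h in (1, 2):
            pos = [next(reserved), next(reserved)]
            records.append(_rec(f"{fam}_h{h}", _mutate(consensus, pos), lineage))
    return records


class TestRankDivergence:
    def test_two_clade_separation(self):
        rng = np.random.default_rng(70)
        records = _two_family_db(rng, n_cross_mismatch=56)  # ~85 %
        div = rank_divergence(records, "family")
        assert div.intra.min() >= 98.9
        assert div.inter.max() <= 85.1
        assert len(div.intra) + len(div.inter) == 15  # C(6,2): full partition

    def test_singleton_clades_have_empty_intra(self):
        rng = np.random.default_rng(71)
        a, b = _rand(rng, 100), _rand(rng, 100)
        records = [_rec("a", a, "E;P;C;O;S;famA"), _rec("b", b, "E;P;C;O;S;famB")]
        div = rank_divergence(records, "family")
        assert div.intra.size == 0 and div.inter.size == 1

    def test_unresolved_records_excluded(self):
        rng = np.random.default_rng(72)
        seq = _rand(rng, 100)
        records = [
            _rec("a", seq, "E;P;C;O;S;famA"),
            _rec("b", seq, "E;P;C;O;S;famA"),
            _rec("c", seq, "E;P;C"),          # unresolved at family
        ]
        div = rank_divergence(records, "family")
        assert len(div.intra) == 1 and len(div.inter) == 0
        assert div.single_clade

    def test_distributions_match_pair_enumeration(self):
        """Four planted clades: distributions equal a brute-force all-pairs
        classification."""
        rng = np.random.default_rng(73)
        clades = {}
        records = []
        for f in range(4):
            consensus = _rand(rng, 200)
            for h in range(3):
                rec = _rec(f"f{f}h{h}", _mutate(consensus, list(range(h))),
                           f"E;P;C;O;S;fam{f}")
                records.append(rec)
                clades[rec.id] = f
        div = rank_divergence(records, "family")
        intra, inter = [], []
        for i in range(len(records)):
            for j in range(i + 1, len(records)):
                ident = aligned_identity(records[i].seq.bases, records[j].seq.bases)
                (intra if clades[records[i].id] == clades[records[j].id]
                 else inter).append(ident)
        assert sorted(div.intra) == pytest.approx(sorted(intra))
        assert sorted(div.inter) == pytest.approx(sorted(inter))


class TestConservativeThreshold:
    def test_rounding_is_ceiling(self):
        assert round_up_threshold(91.2) == 92
        assert round_up_threshold(84.0) == 84

    def test_exact_raw_from_constructed_pair(self):
        """33 mismatches over 375 columns set the raw threshold at exactly
        91.2, rounded up to 92."""
        rng = np.random.default_rng(74)
        records = _two_family_db(rng, n_cross_mismatch=33)
        entry = conservative_threshold(rank_divergence(records, "family"))
        assert entry.raw == pytest.approx(91.2)
        assert entry.rounded == 92
        assert "famA_h0" in entry.provenance and "famB_h0" in entry.provenance

    def test_planted_ceiling_recovered(self):
        rng = np.random.default_rng(75)
        records = _two_family_db(rng, n_cross_mismatch=45)  # 88.0 exactly
        entry = conservative_threshold(rank_divergence(records, "family"))
        assert entry.raw == pytest.approx(100 * 330 / 375)
        assert entry.rounded == 88

    def test_single_clade_raises(self):
        rng = np.random.default_rng(76)
        seq = _rand(rng, 100)
        records = [_rec("a", seq, "E;P;C;O;S;famA"),
                   _rec("b", seq, "E;P;C;O;S;famA")]
        with pytest.raises(ValueError, match="no inter-clade"):
            conservative_threshold(rank_divergence(records, "family"))

    def test_recovers_manifest_oracle_across_seeds(self):
        """Across 20 simulated databases, the conservative threshold equals
        the ceiling of the manifest's realized maximum inter-clade identity
        at every rank."""
        ranks = ("domain", "phylum", "class", "order", "suborder", "family")
        for seed in range(1, 21):
            _, records, manifest = simulated_db(seed)
            thresholds, _ = calibrate_thresholds(records, ranks=ranks)
            for rank in ranks:
                want_raw = manifest.realized_max_inter_identity(rank)
                entry = thresholds.conservative[rank]
                assert entry.raw == pytest.approx(want_raw, abs=1e-9)
                assert entry.rounded == round_up_threshold(want_raw)

    def test_every_inter_pair_below_threshold(self):
        _, records, _ = simulated_db(11)
        thresholds, divergences = calibrate_thresholds(records)
        for rank, div in divergences.items():
            entry = thresholds.conservative[rank]
            assert np.all(div.inter <= entry.raw + 1e-9)


class TestRelaxedThreshold:
    def test_all_correct_hits_is_unbounded_below(self):
        rng = np.random.default_rng(77)
        records = _two_family_db(rng, n_cross_mismatch=56)
        entry, table = relaxed_threshold(records, "family")
        assert table["correct"].all()
        assert entry.unbounded_below
        assert entry.min_correct_identity is not None

    def test_single_incorrect_hit_sets_raw(self):
        """One misclassified best hit at 84.5 % (31/200 mismatches) fixes
        the relaxed threshold at raw 84.5, rounded 85."""
        rng = np.random.default_rng(78)
        root = _rand(rng, 200)
        # lone famA query whose nearest neighbour is famB at 84.5 %
        query = root
        wrong = _mutate(root, list(range(31)))          # 169/200 = 84.5
        wrong2 = _mutate(wrong, [190, 191])
        far_a = _mutate(root, list(range(60, 120)))     # 70 %: same family, far
        records = [
            _rec("qa", query, "E;P;C;O;S;famA"),
            _rec("fa", far_a, "E;P;C;O;S;famA"),
            _rec("b1", wrong, "E;P;C;O;S;famB"),
            _rec("b2", wrong2, "E;P;C;O;S;famB"),
        ]
        entry, table = relaxed_threshold(records, "family")
        assert entry.raw == pytest.approx(84.5)
        assert entry.rounded == 85
        row = table[table["query"] == "qa"].iloc[0]
        assert not row["correct"] and row["hit"] == "b1"

    def test_matches_nearest_neighbour_oracle(self):
        """Leave-one-out raw threshold equals the exhaustive
        misassigned-nearest-neighbour maximum on a simulated database."""
        _, records, _ = simulated_db(6)
        rank = "family"
        entry, _ = relaxed_threshold(records, rank)
        worst = None
        for i, q in enumerate(records):
            best_ident, best_j = -1.0, None
            for j, r in enumerate(records):
                if i == j:
                    continue
                ident = aligned_identity(q.seq.bases, r.seq.bases)
                if ident > best_ident:
                    best_ident, best_j = ident, j
            if records[best_j].lineage.get(rank) != q.lineage.get(rank):
                worst = best_ident if worst is None else max(worst, best_ident)
        if worst is None:
            assert entry.unbounded_below
        else:
            assert entry.raw == pytest.approx(worst)


class TestAnnotateOTU:
    def _thresholds(self):
        ts = ThresholdSet()
        for rank, value in (("family", 92), ("suborder", 84), ("order", 79)):
            ts.conservative[rank] = ThresholdEntry(rank, "conservative",
                                                   float(value), value)
        return ts

    def _refs(self, rng):
        seq = _rand(rng, 375)
        return seq, [_rec("ref1", seq, "Euk;Chloro;Ulvo;Bryo;Ostreo;Odoaceae;sp23")]

    def test_identity_93_reaches_family(self):
        rng = np.random.default_rng(79)
        seq, refs = self._refs(rng)
        query = _mutate(seq, _spread(26, 375))  # 93.07 %
        ann = annotate_otu(query, refs, self._thresholds())
        assert ann.assigned_rank == "family"
        assert ann.lineage.get("family") == "Odoaceae"
        assert ann.lineage.get("species") == UNRESOLVED

    def test_identity_80_reaches_order_only(self):
        rng = np.random.default_rng(80)
        seq, refs = self._refs(rng)
        query = _mutate(seq, _spread(75, 375))  # 80.0 %
        ann = annotate_otu(query, refs, self._thresholds())
        assert ann.assigned_rank == "order"
        assert ann.lineage.get("order") == "Bryo"
        assert ann.lineage.get("suborder") == UNRESOLVED

    def test_full_identity_assigns_species(self):
        rng = np.random.default_rng(81)
        seq, refs = self._refs(rng)
        ann = annotate_otu(seq, refs, self._thresholds())
        assert ann.assigned_rank == "species"
        assert ann.lineage.get("species") == "sp23"
        assert ann.identity == 100.0

    def test_below_all_thresholds_fully_unresolved(self):
        rng = np.random.default_rng(82)
        seq, refs = self._refs(rng)
        query = _rand(rng, 375)
        ann = annotate_otu(query, refs, self._thresholds())
        assert ann.assigned_rank is None
        assert all(label == UNRESOLVED for label in ann.lineage.labels)

    def test_conflicting_ties_unresolved_at_disputed_rank(self):
        rng = np.random.default_rng(83)
        seq = _rand(rng, 375)
        refs = [
            _rec("r1", seq, "Euk;Chloro;Ulvo;Bryo;Ostreo;famA;sp1"),
            _rec("r2", seq, "Euk;Chloro;Ulvo;Bryo;Ostreo;famB;sp2"),
        ]
        ann = annotate_otu(seq, refs, self._thresholds())
        assert ann.lineage.get("order") == "Bryo"
        assert ann.lineage.get("family") == UNRESOLVED

    def test_never_misannotates_on_leave_one_out(self):
        """With conservative thresholds calibrated on the database, no
        leave-one-out annotation carries a wrong clade at any assigned rank
        — the defining guarantee of the clade-based thresholds."""
        _, records, _ = simulated_db(3)
        ranks = ("domain", "phylum", "class", "order", "suborder", "family")
        thresholds, _ = calibrate_thresholds(records, ranks=ranks)
        for i, rec in enumerate(records):
            rest = records[:i] + records[i + 1:]
            ann = annotate_otu(rec.seq.bases, rest, thresholds, "conservative")
            for rank in ranks:
                label = ann.lineage.get(rank)
                if label != UNRESOLVED:
                    assert label == rec.lineage.get(rank), (rec.id, rank)


class TestDBPerformance:
    def test_identical_otus_hit_100(self):
        rng = np.random.default_rng(84)
        seq = _rand(rng, 200)
        refs = [_rec("r", seq, "E;P;C;O;S;F;sp")]
        otus = [OTU(seq, [UniqueAmplicon(seq, 5, {"A": 5})], id="O1")]
        perf = db_performance(otus, refs)
        assert perf["identity"].iloc[0] == 100.0

    def test_planted_divergence_measured(self):
        rng = np.random.default_rng(85)
        seq = _rand(rng, 300)
        refs = [_rec("r", seq, "E;P;C;O;S;F;sp")]
        query = _mutate(seq, _spread(30, 300))  # 10 % divergent
        otus = [OTU(query, [UniqueAmplicon(query, 5, {"A": 5})], id="O1")]
        perf = db_performance(otus, refs)
        assert perf["identity"].iloc[0] == pytest.approx(90.0, abs=0.5)

    def test_abundant_subset_is_subset(self, pipeline_cfg):
        from tests.conftest import clean_run

        _, records, _, result = clean_run(2)
        perf = db_performance(result.core_otus, records, table=result.table)
        assert perf[perf["abundant"]]["otu"].isin(perf["otu"]).all()
        assert perf["abundant"].sum() >= 1
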