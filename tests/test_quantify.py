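"""Phage quantification: contig classification thresholds, read
recruitment, counting rules, detection threshold, normalisation and
screens."""

import numpy as np
import pandas as pd
import pytest

from phagoscope.quantify import (PhageGenomeDB,
                                 aggregate_by_family,
                                 apply_detection_threshold, classify_contigs,
                                 count_phage_abundance, group_presence_screen,
                                 prevalence_filter, recruit_reads,
                                 relative_abundance)
from phagoscope.simulate import ReadSet


@pytest.fixture(scope="module")
def phage_db():
    rng = np.random.default_rng(42)
    seqs = {"phageA": rng.integers(0, 4, 2000).astype(np.uint8),
            "phageB": rng.integers(0, 4, 2000).astype(np.uint8)}
    annot = pd.DataFrame([
        {"phage_id": "phageA", "family": "Siphoviridae",
         "host_genus": "Lactococcus", "lifestyle": "lytic"},
        {"phage_id": "phageB", "family": "Myoviridae",
         "host_genus": "Bacteroides", "lifestyle": "temperate"}])
    return PhageGenomeDB(seqs=seqs, annotations=annot)


def random_seq(rng, n):
    return rng.integers(0, 4, n).astype(np.uint8)


class TestClassifyContigs:
    def test_short_contig_unassigned(self, phage_db):
        # perfect 150-base copy of a database phage, but length <= 200
        contig = phage_db.seqs["phageA"][100:250]
        assert classify_contigs({"c": contig}, phage_db) == []

    def test_boundary_length_strict(self, phage_db):
        at_200 = phage_db.seqs["phageA"][100:300]
        above = phage_db.seqs["phageA"][100:301]
        assert classify_contigs({"c": at_200}, phage_db) == []
        out = classify_contigs({"c": above}, phage_db)
        assert len(out) == 1 and out[0].phage_id == "phageA"

    def test_alignment_fraction_rule(self, phage_db):
        rng = np.random.default_rng(7)
        # 300-base contig with only a 140-base phage segment: best aligned
        # length ~140 <= 150 = 0.5 * 300, so it stays unassigned
        mixed = np.concatenate([random_seq(rng, 80),
                                phage_db.seqs["phageA"][500:640],
                                random_seq(rng, 80)])
        assert classify_contigs({"c": mixed}, phage_db) == []
        # with a 200-base segment the alignment covers > 50%
        mixed2 = np.concatenate([random_seq(rng, 50),
                                 phage_db.seqs["phageA"][500:700],
                                 random_seq(rng, 50)])
        out = classify_contigs({"c": mixed2}, phage_db)
        assert len(out) == 1
        assert out[0].best_hit.aligned_length > 150

    def test_good_contig_assigned_with_low_evalue(self, phage_db):
        contig = phage_db.seqs["phageB"][200:500]
        out = classify_contigs({"c": contig}, phage_db)
        assert len(out) == 1
        a = out[0]
        assert a.phage_id == "phageB"
        assert a.best_hit.e_value < 1e-7
        assert a.best_hit.aligned_length == 300

    def test_random_contig_unassigned(self, phage_db):
        rng = np.random.default_rng(99)
        assert classify_contigs({"c": random_seq(rng, 400)}, phage_db) == []

    def test_empty_db_rejected(self):
        empty = PhageGenomeDB(seqs={}, annotations=pd.DataFrame(
            columns=["phage_id", "family", "host_genus", "lifestyle"]))
        with pytest.raises(ValueError):
            classify_contigs({"c": "ACGT" * 100}, empty)


def _simulate_reads_from(rng, genome, n, length=110, err=0.005):
    reads = []
    for _ in range(n):
        s0 = int(rng.integers(0, len(genome) - length))
        r = genome[s0:s0 + length].copy()
        errs = rng.random(length) < err
        r[errs] = (r[errs] + rng.integers(1, 4, errs.sum()).astype(np.uint8)) % 4
        reads.append(r)
    return ReadSet(ids=[f"s:r{i}" for i in range(n)],
                   seqs=np.vstack(reads))


class TestRecruitReads:
    def test_reads_from_db_phage_recruited(self, phage_db):
        rng = np.random.default_rng(5)
        genome = phage_db.seqs["phageA"]
        contigs = {"k1": genome[:700], "k2": genome[700:1400],
                   "k3": genome[1400:]}
        assignments = classify_contigs(contigs, phage_db)
        assert len(assignments) == 3
        reads = {"s": _simulate_reads_from(rng, genome, 200)}
        ra = recruit_reads(reads, assignments, contigs)
        assert len(ra) >= 0.95 * 200
        assert set(ra["phage_id"]) == {"phageA"}

    def test_unrelated_reads_not_recruited(self, phage_db):
        rng = np.random.default_rng(6)
        contigs = {"k1": phage_db.seqs["phageA"][:700]}
        assignments = classify_contigs(contigs, phage_db)
        other = random_seq(rng, 3000)
        reads = {"s": _simulate_reads_from(rng, other, 100)}
        assert len(recruit_reads(reads, assignments, contigs)) == 0

    def test_no_assigned_contigs_empty(self, phage_db):
        rng = np.random.default_rng(8)
        reads = {"s": _simulate_reads_from(rng, phage_db.seqs["phageA"], 10)}
        out = recruit_reads(reads, [], {})
        assert len(out) == 0


def make_assignments(rows):
    return pd.DataFrame(rows, columns=["sample", "read_id", "contig_id",
                                       "phage_id", "score",
                                       "percent_identity", "aligned_length"])


class TestCounting:
    def test_counts_combine_contigs_per_phage(self):
        rows = ([("s1", f"r{i}", "c1", "pA", 100.0, 99.0, 110) for i in range(3)]
                + [("s1", f"q{i}", "c2", "pA", 100.0, 99.0, 110) for i in range(4)]
                + [("s2", "z0", "c3", "pB", 100.0, 99.0, 110)])
        t = count_phage_abundance(make_assignments(rows))
        assert t.counts.at["pA", "s1"] == 7
        assert t.counts.at["pB", "s2"] == 1
        assert "pC" not in t.counts.index  # unobserved phage absent
        assert t.total() == len(rows)  # read conservation

    def test_empty_assignments(self):
        t = count_phage_abundance(make_assignments([]), samples=["s1"])
        assert t.counts.shape[0] == 0


class TestDetectionThreshold:
    def base_table(self, rows):
        return count_phage_abundance(make_assignments(rows),
                                     samples=["s1", "s2"])

    def test_single_qualifying_read_zeroed(self):
        t = self.base_table([("s1", "r0", "c", "pA", 100.0, 99.0, 110)])
        out = apply_detection_threshold(t)
        assert out.counts.at["pA", "s1"] == 0

    def test_two_good_reads_retained(self):
        t = self.base_table([("s1", "r0", "c", "pA", 100.0, 95.0, 120),
                             ("s1", "r1", "c", "pA", 100.0, 95.0, 120)])
        out = apply_detection_threshold(t)
        assert out.counts.at["pA", "s1"] == 2

    def test_low_identity_reads_never_counted(self):
        rows = [("s1", f"r{i}", "c", "pA", 100.0, 85.0, 120) for i in range(5)]
        out = apply_detection_threshold(self.base_table(rows))
        assert out.counts.at["pA", "s1"] == 0

    def test_boundary_values_strict(self):
        rows = [("s1", "r0", "c", "pA", 100.0, 90.0, 120),  # identity not >90
                ("s1", "r1", "c", "pA", 100.0, 90.1, 100),  # aligned not >100
                ("s1", "r2", "c", "pA", 100.0, 90.1, 101),
                ("s1", "r3", "c", "pA", 100.0, 90.1, 101)]
        out = apply_detection_threshold(self.base_table(rows))
        assert out.counts.at["pA", "s1"] == 2  # only r2, r3 qualify

    def test_idempotent_and_never_increases(self):
        rows = ([("s1", f"r{i}", "c", "pA", 100.0, 99.0, 110) for i in range(3)]
                + [("s2", "q0", "c", "pA", 100.0, 80.0, 110)])
        t = self.base_table(rows)
        once = apply_detection_threshold(t)
        twice = apply_detection_threshold(once)
        assert once.counts.equals(twice.counts)
        assert (once.counts.to_numpy() <= t.counts.to_numpy()).all()

    def test_length_clause_can_be_disabled(self):
        rows = [("s1", "r0", "c", "pA", 80.0, 95.0, 80),
                ("s1", "r1", "c", "pA", 80.0, 95.0, 80)]
        strict = apply_detection_threshold(self.base_table(rows))
        relaxed = apply_detection_threshold(self.base_table(rows),
                                            apply_length_to_reads=False)
        assert strict.counts.at["pA", "s1"] == 0
        assert relaxed.counts.at["pA", "s1"] == 2


class TestNormalisationAndFilters:
    def test_relative_abundance_values(self):
        counts = pd.DataFrame({"s1": [2, 8]}, index=["a", "b"])
        rel = relative_abundance(counts)
        assert rel["s1"].tolist() == [0.2, 0.8]
        single = relative_abundance(pd.DataFrame({"s1": [5]}, index=["a"]))
        assert single["s1"].tolist() == [1.0]

    def test_columns_sum_to_one(self, toy_quant):
        sums = toy_quant.relative.sum(axis=0)
        assert np.allclose(sums[sums > 0], 1.0, atol=1e-9)

    def test_all_zero_sample_flagged(self):
        counts = pd.DataFrame({"s1": [2, 2], "s2": [0, 0]}, index=["a", "b"])
        with pytest.warns(UserWarning, match="no assigned reads"):
            rel = relative_abundance(counts)
        assert (rel["s2"] == 0).all()

    def test_prevalence_floor(self):
        rel = pd.DataFrame({"s1": [5e-5, 1e-3, 0.9989],
                            "s2": [4e-5, 0.0, 0.99]},
                           index=["rare", "patchy", "common"])
        out = prevalence_filter(rel, floor=1e-4)
        assert "rare" not in out.index  # below floor in all samples
        assert "patchy" in out.index  # reaches floor in one sample
        assert prevalence_filter(out, floor=1e-4).equals(out)  # idempotent
        empty = prevalence_filter(rel.iloc[:0], floor=1e-4)
        assert empty.empty

    def test_total_read_denominator_switch(self):
        counts = pd.DataFrame({"s1": [2, 8]}, index=["a", "b"])
        rel = relative_abundance(counts, total_reads=pd.Series({"s1": 100}))
        assert rel["s1"].tolist() == [0.02, 0.08]
        with pytest.raises(ValueError, match="total_reads"):
            relative_abundance(counts, total_reads=pd.Series({"s1": 5}))

    def test_exact_floor_value_kept(self):
        rel = pd.DataFrame({"s1": [1e-4]}, index=["edge"])
        assert "edge" in prevalence_filter(rel, floor=1e-4).index


class TestPresenceScreen:
    meta = pd.DataFrame({"sample_id": ["p1", "p2", "p3", "c1", "c2", "c3"],
                         "group": ["PD"] * 3 + ["control"] * 3})

    def table(self, rows):
        return pd.DataFrame(rows, index=["sp"],
                            columns=["p1", "p2", "p3", "c1", "c2", "c3"])

    def test_exclusive_to_cases(self):
        rel = self.table([[2e-4, 2e-4, 0, 0, 0, 0]])
        out = group_presence_screen(rel, self.meta)
        assert bool(out.at["sp", "present_PD"])
        assert bool(out.at["sp", "exclusive_PD"])
        assert not bool(out.at["sp", "present_control"])

    def test_single_sample_not_present(self):
        rel = self.table([[2e-4, 0, 0, 0, 0, 0]])
        out = group_presence_screen(rel, self.meta)
        assert not out.loc["sp"].any()

    def test_both_groups_not_exclusive(self):
        rel = self.table([[2e-4, 2e-4, 0, 2e-4, 2e-4, 0]])
        out = group_presence_screen(rel, self.meta)
        assert bool(out.at["sp", "present_PD"])
        assert bool(out.at["sp", "present_control"])
        assert not bool(out.at["sp", "exclusive_PD"])
        assert not bool(out.at["sp", "exclusive_control"])

    def test_unknown_sample_rejected(self):
        rel = pd.DataFrame({"mystery": [1.0]}, index=["sp"])
        with pytest.raises(ValueError, match="group"):
            group_presence_screen(rel, self.meta)


class TestFamilyAggregation:
    def test_families_sum_members(self, phage_db):
        rel = pd.DataFrame({"s1": [0.3, 0.2, 0.5]},
                           index=["phageA", "phageA2", "phageB"])
        db = PhageGenomeDB(seqs=phage_db.seqs, annotations=pd.DataFrame([
            {"phage_id": "phageA", "family": "Siphoviridae",
             "host_genus": "", "lifestyle": "lytic"},
            {"phage_id": "phageA2", "family": "Siphoviridae",
             "host_genus": "", "lifestyle": "lytic"},
            {"phage_id": "phageB", "family": "Myoviridae",
             "host_genus": "", "lifestyle": "temperate"}]))
        fam = aggregate_by_family(rel, db)
        assert fam.at["Siphoviridae", "s1"] == pytest.approx(0.5)
        assert fam["s1"].sum() == pytest.approx(rel["s1"].sum())

    def test_unannotated_pool_into_unclassified(self, phage_db):
        rel = pd.DataFrame({"s1": [0.4, 0.6]}, index=["x", "y"])
        fam = aggregate_by_family(rel, phage_db)
        assert list(fam.index) == ["unclassified"]
        assert fam.at["unclassified", "s1"] == pytest.approx(1.0)


class TestEndToEndRecovery:
    def test_rank_correlation_with_truth(self):
        """On a free-phage cohort (error rate 0.005, phage coverage >= 5x)
        the estimated per-sample phage relative abundances track the
        simulated truth: pooled Spearman rank correlation >= 0.9.  Lytic
        phages only, so phage-domain truth and sequenced DNA coincide."""
        from scipy import stats

        from phagoscope.simulate import (free_phage_config, phage_db_from,
                                         simulate_cohort)
        cfg = free_phage_config(seed=17)
        cohort = simulate_cohort(cfg)
        from phagoscope.quantify import quantify_cohort
        q = quantify_cohort(cohort.contigs, cohort.reads,
                            phage_db_from(cfg, cohort.genomes))
        truth = cohort.truth.phages
        est = q.relative.reindex(index=truth.index,
                                 columns=truth.columns).fillna(0.0)
        rho = stats.spearmanr(truth.to_numpy().ravel(),
                              est.to_numpy().ravel()).statistic
        assert rho >= 0.9
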