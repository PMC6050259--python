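"""Synthetic cohort generator: determinism, marker uniqueness, prophage
integration, abundance effects, read model and contig fragmentation."""

import numpy as np
import pytest

from phagoscope.seqs import revcomp
from phagoscope.simulate import (GenusSpec, PhageSpec, SimConfig,
                                 emit_contigs, generate_genomes,
                                 integrate_prophages, prophage_config,
                                 sample_abundances, simulate_reads,
                                 toy_config)


def small_config(**overrides) -> SimConfig:
    base = dict(
        genera=(GenusSpec("Alpha", genome_length=2000, n_markers=3,
                          marker_length=120),
                GenusSpec("Beta", genome_length=2000, n_markers=3,
                          marker_length=120)),
        phages=(PhageSpec("Alpha_phage_T1", "Alpha", "temperate",
                          genome_length=800),
                PhageSpec("Beta_phage_L1", "Beta", "lytic",
                          genome_length=800)),
        base_abundance={"Alpha": (np.log(0.5), 0.3), "Beta": (np.log(0.5), 0.3),
                        "Alpha_phage_T1": (0.0, 0.3),
                        "Beta_phage_L1": (0.0, 0.3)},
        n_cases=2, n_controls=2, depth=3.0, read_length=100, seed=7)
    base.update(overrides)
    return SimConfig(**base)


class TestGenomes:
    def test_deterministic_for_seed(self):
        cfg = small_config()
        g1 = generate_genomes(cfg)
        g2 = generate_genomes(cfg)
        for sid in g1.bacteria:
            assert g1.bacteria[sid].tobytes() == g2.bacteria[sid].tobytes()
        for pid in g1.phages:
            assert g1.phages[pid].tobytes() == g2.phages[pid].tobytes()

    def test_markers_are_embedded_substrings(self):
        g = generate_genomes(small_config())
        assert len(g.bacteria) == 2
        for row in g.markers.itertuples():
            genome = g.bacteria[row.species_id]
            sub = genome[row.offset:row.offset + row.length]
            assert sub.tobytes() == g.marker_seqs[row.marker_id].tobytes()

    def test_markers_unique_across_genera(self):
        """Exhaustive substring search: no marker occurs (either strand)
        in any other genus's genome."""
        g = generate_genomes(small_config())
        for row in g.markers.itertuples():
            mseq = g.marker_seqs[row.marker_id]
            for sid, genome in g.bacteria.items():
                if g.species_genus[sid] == row.genus:
                    continue
                gb = genome.tobytes()
                assert mseq.tobytes() not in gb
                assert revcomp(mseq).tobytes() not in gb

    def test_duplicate_taxon_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            small_config(phages=(
                PhageSpec("Alpha_phage_T1", "Alpha", "temperate"),
                PhageSpec("Alpha_phage_T1", "Alpha", "lytic")))

    def test_alphabet_is_acgt(self):
        g = generate_genomes(small_config())
        for seq in list(g.bacteria.values()) + list(g.phages.values()):
            assert seq.max() <= 3


class TestProphages:
    def test_insertion_grows_host_by_phage_length(self):
        cfg = small_config()
        base = generate_genomes(cfg)
        mod, placements = integrate_prophages(base, cfg)
        assert len(placements) == 1  # one temperate phage, one host genome
        sid, pid, off = placements[0]
        assert pid == "Alpha_phage_T1"
        assert len(mod.bacteria[sid]) == len(base.bacteria[sid]) + 800
        inserted = mod.bacteria[sid][off:off + 800]
        assert inserted.tobytes() == base.phages[pid].tobytes()
        assert 0 <= off <= len(base.bacteria[sid])

    def test_lytic_never_inserted(self):
        cfg = small_config()
        base = generate_genomes(cfg)
        mod, placements = integrate_prophages(base, cfg)
        assert all(p != "Beta_phage_L1" for _, p, _ in placements)
        assert len(mod.bacteria["Beta_sp1"]) == len(base.bacteria["Beta_sp1"])

    def test_no_temperate_phages_is_identity(self):
        cfg = small_config(
            phages=(PhageSpec("Beta_phage_L1", "Beta", "lytic",
                              genome_length=800),),
            base_abundance={"Alpha": (0.0, 0.3), "Beta": (0.0, 0.3),
                            "Beta_phage_L1": (0.0, 0.3)})
        base = generate_genomes(cfg)
        mod, placements = integrate_prophages(base, cfg)
        assert placements == []
        for sid in base.bacteria:
            assert mod.bacteria[sid].tobytes() == base.bacteria[sid].tobytes()

    def test_temperate_host_missing_rejected(self):
        with pytest.raises(ValueError, match="host genus"):
            small_config(phages=(
                PhageSpec("Gamma_phage_X", "Gamma", "temperate"),),
                base_abundance={"Alpha": (0.0, 0.3), "Beta": (0.0, 0.3),
                                "Gamma_phage_X": (0.0, 0.3)})


class TestAbundances:
    def test_depletion_factor_recovered(self):
        """A 0.1 case factor yields a control/case mean ratio near 10
        within 3 Monte-Carlo standard errors at n = 1000 per group."""
        cfg = small_config(n_cases=1000, n_controls=1000,
                           base_abundance={"Alpha": (np.log(0.99), 0.3),
                                           "Beta": (np.log(0.01), 0.3),
                                           "Alpha_phage_T1": (0.0, 0.3),
                                           "Beta_phage_L1": (0.0, 0.3)},
                           case_effects={"Beta": 0.1})
        bact, _, meta = sample_abundances(cfg)
        case = meta["group"] == "PD"
        x = bact.loc["Beta"].to_numpy()
        m_ctrl, m_case = x[~case].mean(), x[case].mean()
        ratio = m_ctrl / m_case
        se = ratio * np.sqrt(x[~case].var() / (1000 * m_ctrl ** 2)
                             + x[case].var() / (1000 * m_case ** 2))
        # closed normalisation biases the ratio down by about the depleted
        # taxon's share (0.01 here); allow that on top of 3 MC SEs
        assert abs(ratio - 10.0) < 3 * se + 10 * 0.012

    def test_null_effects_groups_exchangeable(self):
        """With all factors 1, a two-sample test on true abundances gives
        uniform p-values across seeds (Kolmogorov-Smirnov check)."""
        from scipy import stats
        pvals = []
        for seed in range(120):
            cfg = small_config(seed=seed, n_cases=8, n_controls=8)
            bact, _, meta = sample_abundances(cfg)
            case = (meta["group"] == "PD").to_numpy()
            x = bact.loc["Alpha"].to_numpy()
            pvals.append(stats.mannwhitneyu(x[case], x[~case],
                                            alternative="two-sided").pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_single_taxon_is_one(self):
        cfg = SimConfig(
            genera=(GenusSpec("Solo", genome_length=1500, n_markers=2,
                              marker_length=100),),
            phages=(), base_abundance={"Solo": (0.0, 0.5)},
            n_cases=3, n_controls=3, seed=1)
        bact, phage, _ = sample_abundances(cfg)
        assert np.allclose(bact.loc["Solo"], 1.0)
        assert phage.empty

    def test_domains_sum_to_one(self, toy_cohort):
        assert np.allclose(toy_cohort.truth.bacteria.sum(axis=0), 1.0,
                           atol=1e-9)
        assert np.allclose(toy_cohort.truth.phages.sum(axis=0), 1.0,
                           atol=1e-9)

    def test_phage_tracks_host(self):
        cfg = prophage_config(3, n_cases=2, n_controls=2)
        bact, phage, _ = sample_abundances(cfg)
        # each phage inherits its host's (renormalised) abundance profile
        ratio = phage.loc["Bacteroides_phage_B124"] / phage.loc[
            "Lactococcus_phage_TP901-1"]
        ratio_host = bact.loc["Bacteroides"] / bact.loc["Lactococcus"]
        assert np.allclose(ratio, ratio_host)


class TestReads:
    def test_read_count_matches_poisson_model(self):
        cfg = small_config(n_cases=1, n_controls=1, depth=4.0)
        base = generate_genomes(cfg)
        genomes, _ = integrate_prophages(base, cfg)
        bact, phage, _ = sample_abundances(cfg)
        reads, _ = simulate_reads(genomes, bact, phage, cfg)
        total_len = sum(len(s) for s in genomes.bacteria.values())
        total_len += sum(len(s) for s in genomes.phages.values())
        lam = cfg.depth * total_len / cfg.read_length
        for sample, rs in reads.items():
            assert abs(len(rs.ids) - lam) < 3 * np.sqrt(lam)

    def test_zero_error_reads_are_exact_substrings(self):
        cfg = small_config(substitution_error_rate=0.0, n_cases=1,
                           n_controls=1)
        base = generate_genomes(cfg)
        genomes, _ = integrate_prophages(base, cfg)
        bact, phage, _ = sample_abundances(cfg)
        reads, origin = simulate_reads(genomes, bact, phage, cfg)
        pool = dict(genomes.bacteria)
        pool.update(genomes.phages)
        for sample, rs in reads.items():
            for rid, row in zip(rs.ids, rs.seqs):
                src = pool[origin[rid]].tobytes()
                assert row.tobytes() in src or revcomp(row).tobytes() in src

    def test_substitution_rate_recovered(self):
        """At error rate 0.01 the observed mismatch fraction against the
        error-free twin matches a binomial 3-sigma band."""
        cfg_clean = small_config(substitution_error_rate=0.0, n_cases=1,
                                 n_controls=1,
                                 genera=(GenusSpec("Solo", genome_length=4000,
                                                   n_markers=2,
                                                   marker_length=100),),
                                 phages=(),
                                 base_abundance={"Solo": (0.0, 0.3)})
        cfg_err = small_config(substitution_error_rate=0.01, n_cases=1,
                               n_controls=1,
                               genera=(GenusSpec("Solo", genome_length=4000,
                                                 n_markers=2,
                                                 marker_length=100),),
                               phages=(),
                               base_abundance={"Solo": (0.0, 0.3)})
        genomes, _ = integrate_prophages(generate_genomes(cfg_clean), cfg_clean)
        bact, phage, _ = sample_abundances(cfg_clean)
        clean, _ = simulate_reads(genomes, bact, phage, cfg_clean)
        err, _ = simulate_reads(genomes, bact, phage, cfg_err)
        sample = "case01"
        a = clean[sample].seqs
        b = err[sample].seqs
        n = min(len(a), len(b))
        # single genome: read positions identical up to the error step
        mism = (a[:n] != b[:n]).mean()
        nbases = a[:n].size
        assert nbases > 10_000
        sigma = np.sqrt(0.01 * 0.99 / nbases)
        assert abs(mism - 0.01) < 3 * sigma

    def test_read_longer_than_genome_rejected(self):
        cfg = small_config(
            read_length=3000,
            genera=(GenusSpec("Tiny", genome_length=2000, n_markers=2,
                              marker_length=100),),
            phages=(), base_abundance={"Tiny": (0.0, 0.3)},
            n_cases=1, n_controls=1)
        genomes, _ = integrate_prophages(generate_genomes(cfg), cfg)
        bact, phage, _ = sample_abundances(cfg)
        with pytest.raises(ValueError, match="read_length"):
            simulate_reads(genomes, bact, phage, cfg)

    def test_every_read_in_origin_map(self, toy_cohort):
        for rs in toy_cohort.reads.values():
            for rid in rs.ids:
                assert rid in toy_cohort.truth.read_origin

    def test_paired_reads_emitted_as_mates(self):
        cfg = small_config(paired=True, n_cases=1, n_controls=1)
        genomes, _ = integrate_prophages(generate_genomes(cfg), cfg)
        bact, phage, _ = sample_abundances(cfg)
        reads, _ = simulate_reads(genomes, bact, phage, cfg)
        ids = reads["case01"].ids
        assert len(ids) % 2 == 0
        assert ids[0].endswith("/1") and ids[1].endswith("/2")


class TestContigs:
    def test_lengths_within_bounds(self):
        cfg = small_config(fragment_min=100, fragment_max=900)
        genomes, _ = integrate_prophages(generate_genomes(cfg), cfg)
        contigs = emit_contigs(genomes, cfg)
        lengths = [len(c) for c in contigs.values()]
        assert all(100 <= l <= 900 for l in lengths)
        assert any(l < 200 for l in lengths)  # short-contig filter exercised

    def test_unperturbed_contigs_are_exact_substrings(self):
        cfg = small_config()
        genomes, _ = integrate_prophages(generate_genomes(cfg), cfg)
        pool = dict(genomes.bacteria)
        pool.update(genomes.phages)
        contigs = emit_contigs(genomes, cfg)
        for cid, seq in contigs.items():
            gid = cid.rsplit("|", 1)[0]
            assert seq.tobytes() in pool[gid].tobytes()

    def test_deterministic_bytes(self):
        cfg = small_config()
        genomes, _ = integrate_prophages(generate_genomes(cfg), cfg)
        c1 = emit_contigs(genomes, cfg)
        c2 = emit_contigs(genomes, cfg)
        assert list(c1) == list(c2)
        assert all(c1[k].tobytes() == c2[k].tobytes() for k in c1)


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [
        dict(n_cases=0), dict(substitution_error_rate=1.0),
        dict(depth=-1.0), dict(fragment_min=0),
        dict(free_particle_fraction=1.5),
        dict(case_effects={"Alpha": -2.0}),
        dict(case_effects={"Nobody": 2.0}),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            small_config(**bad)

    def test_toy_config_shape(self):
        cfg = toy_config(0)
        assert len(cfg.genera) == 2 and len(cfg.phages) == 3
        assert cfg.n_cases == 3 and cfg.n_controls == 3
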