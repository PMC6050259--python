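"""End-to-end orchestration: simulate -> quantify -> profile -> diversity
-> lytic-potential, with a reproducibility manifest.

Every output TSV carries header comments (tool version, seed, config hash,
coordinate convention); re-running with an identical configuration
reproduces byte-identical outputs and checksums.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .diversity import (alpha_diversity_table, bray_curtis, group_compare,
                        pcoa, permanova, spearman_dissimilarity)
from .io import (config_hash, sha256_file, write_fasta, write_fastq,
                 write_metadata, write_table)
from .lytic import (classify_lifestyle, cluster_by_host, group_fold_change,
                    lifestyle_abundance, lifestyle_log_ratio,
                    load_lifestyle_table, phage_bacteria_ratio, ratio_report)
from .markers import profile_markers
from .quantify import group_presence_screen, quantify_cohort
from .simulate import (Cohort, SimConfig, marker_db_from, phage_db_from,
                       simulate_cohort, toy_config)

log = logging.getLogger("phagoscope")

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]


@dataclass
class RunConfig:
    """All knobs of a full pipeline run."""

    sim: SimConfig
    out_dir: str | Path = "phagoscope_out"
    e_max: float = 1e-5
    min_contig: int = 200
    min_frac: float = 0.5
    min_reads: int = 2
    min_identity: float = 90.0
    min_aligned: int = 100
    prevalence_floor: float = 1e-4
    screen_min_abund: float = 1e-4
    screen_min_samples: int = 2
    n_permutations: int = 999
    seed: int = 0
    log_level: str = "INFO"
    lifestyle_table: str | Path | None = None
    write_reads: bool = True

    def __post_init__(self) -> None:
        if self.e_max <= 0:
            raise ValueError("e_max must be positive")
        if self.min_contig <= 0:
            raise ValueError("min_contig must be positive")
        if not (0 < self.min_frac < 1):
            raise ValueError("min_frac must be in (0, 1)")
        if self.min_reads < 1 or self.min_aligned < 1:
            raise ValueError("min_reads and min_aligned must be >= 1")
        if not (0 <= self.min_identity <= 100):
            raise ValueError("min_identity must be a percentage")
        if self.prevalence_floor < 0 or self.screen_min_abund < 0:
            raise ValueError("abundance floors must be non-negative")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(d["out_dir"])
        d["lifestyle_table"] = (str(d["lifestyle_table"])
                                if d["lifestyle_table"] else None)
        return d

    def science_dict(self) -> dict:
        """Configuration fields that determine results (excludes output
        location and logging); this is what the config hash covers."""
        d = self.to_dict()
        for k in ("out_dir", "log_level", "write_reads"):
            d.pop(k, None)
        return d


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    stages: list[str] = field(default_factory=list)
    checksums: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _headers(cfg: RunConfig, chash: str) -> list[str]:
    return [f"phagoscope v{__version__}", f"seed={cfg.seed}",
            f"config={chash}", "coordinates: 0-based half-open"]


def run_pipeline(cfg: RunConfig, cohort: Cohort | None = None) -> RunManifest:
    """Run every stage; a stage failure aborts after saving a manifest of
    the stages completed so far."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg.science_dict())
    hdr = _headers(cfg, chash)
    manifest = RunManifest(version=__version__, config_hash=chash,
                           seed=cfg.seed)

    def checkpoint(stage: str, files: list[Path]) -> None:
        manifest.stages.append(stage)
        for f in files:
            manifest.checksums[f.name] = sha256_file(f)
        manifest.save(out / "manifest.json")

    caught: list[warnings.WarningMessage] = []
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")

            # --- simulate
            log.info("stage simulate")
            if cohort is None:
                cohort = simulate_cohort(cfg.sim)
            phage_db = phage_db_from(cohort.config, cohort.genomes)
            marker_db = marker_db_from(cohort.genomes)
            files = []
            write_fasta(out / "contigs.fasta", cohort.contigs)
            files.append(out / "contigs.fasta")
            write_fasta(out / "phage_db.fasta", phage_db.seqs)
            files.append(out / "phage_db.fasta")
            write_table(out / "phage_db_annotations.tsv",
                        phage_db.annotations.set_index("phage_id"), hdr)
            files.append(out / "phage_db_annotations.tsv")
            write_metadata(out / "metadata.tsv", cohort.metadata, hdr)
            files.append(out / "metadata.tsv")
            write_table(out / "truth_bacteria.tsv", cohort.truth.bacteria, hdr)
            write_table(out / "truth_phages.tsv", cohort.truth.phages, hdr)
            files += [out / "truth_bacteria.tsv", out / "truth_phages.tsv"]
            origin = pd.Series(cohort.truth.read_origin, name="genome_id")
            origin.index.name = "read_id"
            write_table(out / "read_origin.tsv", origin.to_frame(), hdr)
            files.append(out / "read_origin.tsv")
            if cfg.write_reads:
                rdir = out / "reads"
                rdir.mkdir(exist_ok=True)
                for sample, rs in cohort.reads.items():
                    write_fastq(rdir / f"{sample}.fastq", rs)
                    files.append(rdir / f"{sample}.fastq")
            checkpoint("simulate", files)

            # --- quantify
            log.info("stage quantify")
            q = quantify_cohort(
                cohort.contigs, cohort.reads, phage_db, e_max=cfg.e_max,
                min_contig=cfg.min_contig, min_frac=cfg.min_frac,
                min_reads=cfg.min_reads, min_identity=cfg.min_identity,
                min_aligned=cfg.min_aligned,
                prevalence_floor=cfg.prevalence_floor)
            files = []
            write_table(out / "phage_counts.tsv", q.detected.counts, hdr)
            write_table(out / "phage_relative.tsv", q.relative, hdr)
            write_table(out / "phage_filtered.tsv", q.filtered, hdr)
            write_table(out / "phage_family.tsv", q.family, hdr)
            write_table(out / "read_assignments.tsv",
                        q.read_assignments.set_index("read_id")
                        if len(q.read_assignments) else q.read_assignments, hdr)
            screen = group_presence_screen(q.relative, cohort.metadata,
                                           min_abund=cfg.screen_min_abund,
                                           min_samples=cfg.screen_min_samples)
            write_table(out / "presence_screen.tsv", screen, hdr)
            files += [out / f for f in
                      ["phage_counts.tsv", "phage_relative.tsv",
                       "phage_filtered.tsv", "phage_family.tsv",
                       "read_assignments.tsv", "presence_screen.tsv"]]
            checkpoint("quantify", files)

            # --- profile
            log.info("stage profile")
            prof = profile_markers(cohort.reads, marker_db)
            write_table(out / "bacteria_genus.tsv", prof.genus, hdr)
            write_table(out / "bacteria_family.tsv", prof.family, hdr)
            checkpoint("profile", [out / "bacteria_genus.tsv",
                                   out / "bacteria_family.tsv"])

            # --- diversity
            log.info("stage diversity")
            alpha = alpha_diversity_table(q.detected.counts)
            write_table(out / "phage_alpha.tsv", alpha, hdr)
            tests = []
            for index in alpha.columns:
                vals = alpha[index].dropna()
                if vals.nunique() < 2:
                    continue
                for method in ("mann_whitney", "anova"):
                    t = group_compare(vals, cohort.metadata, method=method)
                    tests.append({"quantity": index, "method": t.method,
                                  "statistic": t.statistic, "p_value": t.p_value})
            bc = bray_curtis(q.relative)
            write_table(out / "phage_bray_curtis.tsv", bc, hdr)
            sp = spearman_dissimilarity(q.relative) if q.relative.shape[0] >= 2 else None
            if sp is not None:
                write_table(out / "phage_spearman_diss.tsv", sp, hdr)
            ord_res = pcoa(bc)
            write_table(out / "phage_pcoa.tsv", ord_res.coordinates, hdr)
            perm = permanova(bc, cohort.metadata,
                             n_permutations=cfg.n_permutations, seed=cfg.seed)
            tests.append({"quantity": "bray_curtis", "method": perm.method,
                          "statistic": perm.statistic, "p_value": perm.p_value})
            bcb = bray_curtis(prof.genus)
            permb = permanova(bcb, cohort.metadata,
                              n_permutations=cfg.n_permutations, seed=cfg.seed)
            tests.append({"quantity": "bacteria_bray_curtis",
                          "method": permb.method, "statistic": permb.statistic,
                          "p_value": permb.p_value})
            write_table(out / "diversity_tests.tsv",
                        pd.DataFrame(tests).set_index("quantity"), hdr)
            checkpoint("diversity", [out / f for f in
                                     ["phage_alpha.tsv", "phage_bray_curtis.tsv",
                                      "phage_pcoa.tsv", "diversity_tests.tsv"]])

            # --- lytic potential
            log.info("stage lytic-potential")
            hosts = cluster_by_host(q.relative, phage_db)
            ratios = phage_bacteria_ratio(hosts, prof.genus, cohort.metadata)
            write_table(out / "lytic_potential.tsv",
                        ratio_report(ratios).set_index("host_genus"), hdr)
            ls_table = load_lifestyle_table(cfg.lifestyle_table)
            cls = classify_lifestyle(list(q.relative.index), ls_table)
            write_table(out / "lifestyles.tsv", cls.set_index("phage_id"), hdr)
            la = lifestyle_abundance(q.relative, cohort.metadata, cls)
            write_table(out / "lifestyle_abundance.tsv", la, hdr)
            lr = lifestyle_log_ratio(q.relative, cohort.metadata)
            write_table(out / "phage_log_ratios.tsv", lr, hdr)
            folds = []
            for genus in prof.genus.index:
                if prof.genus.loc[genus].sum() == 0:
                    continue
                fc = group_fold_change(prof.genus, genus, cohort.metadata,
                                       seed=cfg.seed)
                folds.append({"taxon": genus, "fold_control_over_case": fc.fold,
                              "ci_low": fc.ci_low, "ci_high": fc.ci_high,
                              "status": fc.status})
            write_table(out / "fold_changes.tsv",
                        pd.DataFrame(folds).set_index("taxon"), hdr)
            checkpoint("lytic_potential",
                       [out / f for f in
                        ["lytic_potential.tsv", "lifestyles.tsv",
                         "lifestyle_abundance.tsv", "phage_log_ratios.tsv",
                         "fold_changes.tsv"]])
    finally:
        manifest.warnings = sorted({str(w.message) for w in caught})
        manifest.save(out / "manifest.json")
    return manifest


@dataclass
class CohortAnalysis:
    """In-memory result of the full analysis chain on one synthetic cohort."""

    cohort: Cohort
    quantify: object
    profile: object
    ratios: list
    fold_changes: dict


def analyze_cohort(sim_config: SimConfig, n_bootstrap: int = 200,
                   seed: int | None = None) -> CohortAnalysis:
    """Simulate a cohort and run quantification, marker profiling, host
    clustering, phage/bacteria ratios and per-genus fold changes without
    touching the filesystem."""
    from .lytic import cluster_by_host, group_fold_change, phage_bacteria_ratio

    cohort = simulate_cohort(sim_config)
    phage_db = phage_db_from(sim_config, cohort.genomes)
    marker_db = marker_db_from(cohort.genomes)
    q = quantify_cohort(cohort.contigs, cohort.reads, phage_db)
    prof = profile_markers(cohort.reads, marker_db)
    hosts = cluster_by_host(q.relative, phage_db)
    ratios = phage_bacteria_ratio(hosts, prof.genus, cohort.metadata)
    folds = {}
    bseed = sim_config.seed if seed is None else seed
    for genus in prof.genus.index:
        if prof.genus.loc[genus].sum() > 0:
            folds[genus] = group_fold_change(prof.genus, genus,
                                             cohort.metadata,
                                             n_bootstrap=n_bootstrap,
                                             seed=bseed)
    return CohortAnalysis(cohort=cohort, quantify=q, profile=prof,
                          ratios=ratios, fold_changes=folds)


def run_toy(out_dir, seed: int = 0) -> RunManifest:
    """Run the bundled toy fixture (2 genera, 3 phages, 6 samples)."""
    cfg = RunConfig(sim=toy_config(seed), out_dir=out_dir, seed=seed,
                    n_permutations=199)
    return run_pipeline(cfg)
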