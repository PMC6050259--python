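"""Synthetic two-group metagenome cohorts with known ground truth.

Generates bacterial genomes carrying clade-specific marker loci, phage
genomes coupled to hosts (temperate phages integrated as prophages),
per-sample taxon abundances from independent log-normals with multiplicative
case-group effects, shotgun reads with substitution errors, and fragmented
"assembly" contigs.  Every output is a pure function of the configuration,
including its seed.

The default study-like configuration mirrors a faecal cohort of 31 cases and
28 controls in which a *Lactococcus*-like genus is depleted about 10-fold in
cases while its strictly lytic phages are boosted — the statistical
structure the downstream quantification and lytic-potential analysis are
meant to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .seqs import random_seq, revcomp

LYTIC = "lytic"
TEMPERATE = "temperate"


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class GenusSpec:
    name: str
    genome_length: int = 3000
    n_species: int = 1
    n_markers: int = 6
    marker_length: int = 200
    family: str = ""

    def __post_init__(self) -> None:
        if min(self.genome_length, self.n_species, self.n_markers,
               self.marker_length) <= 0:
            raise ValueError(f"genus {self.name}: all sizes must be positive")
        if self.n_markers * self.marker_length > self.genome_length:
            raise ValueError(f"genus {self.name}: markers do not fit in genome")
        if not self.family:
            object.__setattr__(self, "family", f"{self.name}aceae")


@dataclass(frozen=True)
class PhageSpec:
    name: str
    host_genus: str
    lifestyle: str
    family: str = "Siphoviridae"
    genome_length: int = 2500

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError(f"phage {self.name}: genome_length must be positive")
        if self.lifestyle not in (LYTIC, TEMPERATE):
            raise ValueError(f"phage {self.name}: lifestyle must be lytic or temperate")


@dataclass(frozen=True)
class SimConfig:
    """Full description of a synthetic cohort.

    ``base_abundance`` maps taxon name to log-normal (mu, sigma) parameters
    of its pre-normalisation abundance; ``case_effects`` maps taxon name to
    the multiplicative factor applied in the case group.
    ``phage_dna_fraction`` sets the free phage DNA mass relative to
    bacterial DNA mass; ``free_particle_fraction`` is the fraction of a
    temperate phage's abundance present as free particles (its integrated
    copies are sequenced through the host genome either way).
    """

    genera: tuple[GenusSpec, ...]
    phages: tuple[PhageSpec, ...]
    base_abundance: dict[str, tuple[float, float]]
    case_effects: dict[str, float] = field(default_factory=dict)
    n_cases: int = 31
    n_controls: int = 28
    read_length: int = 110
    substitution_error_rate: float = 0.005
    depth: float = 5.0
    seed: int = 0
    free_particle_fraction: float = 0.5
    phage_dna_fraction: float = 0.05
    fragment_min: int = 120
    fragment_max: int = 600
    contig_error_rate: float = 0.0
    phage_tracks_host: bool = False
    paired: bool = False
    group_names: tuple[str, str] = ("PD", "control")

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("both groups need at least one sample")
        if not (0.0 <= self.substitution_error_rate < 1.0):
            raise ValueError("substitution_error_rate must be in [0, 1)")
        if not (0.0 <= self.contig_error_rate < 1.0):
            raise ValueError("contig_error_rate must be in [0, 1)")
        if self.read_length <= 0 or self.depth <= 0:
            raise ValueError("read_length and depth must be positive")
        if not (0 < self.fragment_min <= self.fragment_max):
            raise ValueError("need 0 < fragment_min <= fragment_max")
        if not (0.0 <= self.free_particle_fraction <= 1.0):
            raise ValueError("free_particle_fraction must be in [0, 1]")
        if self.phage_dna_fraction < 0:
            raise ValueError("phage_dna_fraction must be >= 0")
        names = [g.name for g in self.genera] + [p.name for p in self.phages]
        if len(set(names)) != len(names):
            raise ValueError("duplicate taxon names in configuration")
        genus_names = {g.name for g in self.genera}
        for p in self.phages:
            if p.lifestyle == TEMPERATE and p.host_genus not in genus_names:
                raise ValueError(
                    f"temperate phage {p.name}: host genus {p.host_genus!r} absent")
        for t in names:
            if t not in self.base_abundance:
                raise ValueError(f"taxon {t} missing from base_abundance")
        for t, f in self.case_effects.items():
            if t not in names:
                raise ValueError(f"case effect for unknown taxon {t}")
            if f <= 0:
                raise ValueError("case-effect factors must be positive")

    @property
    def taxa(self) -> list[str]:
        return [g.name for g in self.genera] + [p.name for p in self.phages]


# ---------------------------------------------------------------------------
# Ground-truth containers


@dataclass
class GenomeSet:
    """Bacterial species genomes (markers embedded, prophages if integrated)
    and free phage genomes, all as uint8 arrays."""

    bacteria: dict[str, np.ndarray]
    phages: dict[str, np.ndarray]
    species_genus: dict[str, str]
    markers: pd.DataFrame  # marker_id, genus, family, species_id, offset, length
    marker_seqs: dict[str, np.ndarray]


@dataclass
class CohortTruth:
    bacteria: pd.DataFrame  # genera x samples, relative per sample
    phages: pd.DataFrame  # phages x samples, relative per sample
    read_origin: dict[str, str]
    prophage_placements: list[tuple[str, str, int]]


@dataclass
class ReadSet:
    ids: list[str]
    seqs: np.ndarray  # (n_reads, read_length) uint8
    quality_char: str = "I"


@dataclass
class Cohort:
    config: SimConfig
    genomes: GenomeSet
    truth: CohortTruth
    reads: dict[str, ReadSet]
    contigs: dict[str, np.ndarray]
    metadata: pd.DataFrame


# ---------------------------------------------------------------------------
# Genomes


def _place_markers(glen: int, n: int, mlen: int) -> list[int]:
    """Evenly spaced, non-overlapping marker offsets."""
    seg = glen // n
    return [i * seg + (seg - mlen) // 2 for i in range(n)]


def generate_genomes(config: SimConfig) -> GenomeSet:
    """Random genomes with embedded, genus-unique marker loci.

    Marker substrings are re-drawn (rejection sampling) until they occur
    nowhere in any other genus's genomes, so a full-length exact match
    identifies the genus unambiguously.
    """
    rng = np.random.default_rng(config.seed)
    bacteria: dict[str, np.ndarray] = {}
    species_genus: dict[str, str] = {}
    marker_rows = []
    marker_seqs: dict[str, np.ndarray] = {}
    for g in config.genera:
        for si in range(g.n_species):
            sid = f"{g.name}_sp{si + 1}"
            bacteria[sid] = random_seq(rng, g.genome_length)
            species_genus[sid] = g.name
            for mi, off in enumerate(_place_markers(g.genome_length,
                                                    g.n_markers,
                                                    g.marker_length)):
                marker_rows.append({
                    "marker_id": f"{sid}_m{mi + 1}", "genus": g.name,
                    "family": g.family, "species_id": sid,
                    "offset": off, "length": g.marker_length})
    phages = {p.name: random_seq(rng, p.genome_length) for p in config.phages}

    markers = pd.DataFrame(marker_rows)
    # enforce cross-genus uniqueness of marker substrings
    genome_bytes = {sid: seq.tobytes() for sid, seq in bacteria.items()}
    for row in markers.itertuples():
        sid, off, mlen = row.species_id, row.offset, row.length
        genus = row.genus
        others = [genome_bytes[o] for o, gn in species_genus.items()
                  if gn != genus]
        for _attempt in range(50):
            mseq = bacteria[sid][off:off + mlen]
            mb = mseq.tobytes()
            mrc = revcomp(mseq).tobytes()
            if not any(mb in ob or mrc in ob for ob in others):
                break
            bacteria[sid][off:off + mlen] = random_seq(rng, mlen)
            genome_bytes[sid] = bacteria[sid].tobytes()
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError(f"could not make marker {row.marker_id} unique")
        marker_seqs[row.marker_id] = bacteria[sid][off:off + mlen].copy()
    return GenomeSet(bacteria=bacteria, phages=phages,
                     species_genus=species_genus, markers=markers,
                     marker_seqs=marker_seqs)


def integrate_prophages(genomes: GenomeSet, config: SimConfig,
                        seed: int | None = None,
                        copies_per_host: int = 1,
                        ) -> tuple[GenomeSet, list[tuple[str, str, int]]]:
    """Insert every temperate phage into each genome of its host genus.

    Host genome length grows by exactly the phage length per insertion;
    lytic phages are never inserted.  Marker offsets downstream of an
    insertion point are shifted accordingly.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    bacteria = {sid: seq.copy() for sid, seq in genomes.bacteria.items()}
    markers = genomes.markers.copy()
    placements: list[tuple[str, str, int]] = []
    genus_species = {}
    for sid, gn in genomes.species_genus.items():
        genus_species.setdefault(gn, []).append(sid)
    for p in config.phages:
        if p.lifestyle != TEMPERATE:
            continue
        hosts = genus_species.get(p.host_genus)
        if not hosts:
            raise ValueError(f"temperate phage {p.name}: no host genomes "
                             f"for genus {p.host_genus!r}")
        for sid in hosts:
            for _ in range(copies_per_host):
                off = int(rng.integers(0, len(bacteria[sid]) + 1))
                pg = genomes.phages[p.name]
                bacteria[sid] = np.concatenate(
                    [bacteria[sid][:off], pg, bacteria[sid][off:]])
                shift = (markers["species_id"] == sid) & (markers["offset"] >= off)
                markers.loc[shift, "offset"] += len(pg)
                placements.append((sid, p.name, off))
    return (GenomeSet(bacteria=bacteria, phages=genomes.phages,
                      species_genus=genomes.species_genus, markers=markers,
                      marker_seqs=genomes.marker_seqs), placements)


# ---------------------------------------------------------------------------
# Abundances


def _sample_names(config: SimConfig) -> tuple[list[str], pd.DataFrame]:
    case, ctrl = config.group_names
    names = ([f"case{i + 1:02d}" for i in range(config.n_cases)]
             + [f"ctrl{i + 1:02d}" for i in range(config.n_controls)])
    groups = [case] * config.n_cases + [ctrl] * config.n_controls
    meta = pd.DataFrame({"sample_id": names, "group": groups})
    return names, meta


def sample_abundances(config: SimConfig, seed: int | None = None,
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw per-sample true relative abundances for bacteria and phages.

    Each taxon is an independent log-normal; case samples get their
    multiplicative effect before closed (sum-to-one) normalisation within
    each domain.  With ``phage_tracks_host`` every phage inherits its host
    genus's abundance before normalisation (the pure-prophage scenario).
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    names, meta = _sample_names(config)
    n = len(names)
    is_case = np.array([g == config.group_names[0] for g in meta["group"]])

    def draw(taxa: Iterable[str]) -> pd.DataFrame:
        rows = {}
        for t in taxa:
            mu, sigma = config.base_abundance[t]
            x = rng.lognormal(mu, sigma, size=n)
            f = config.case_effects.get(t, 1.0)
            x = np.where(is_case, x * f, x)
            rows[t] = x
        return pd.DataFrame(rows, index=names).T

    bact = draw([g.name for g in config.genera])
    bact = bact / bact.sum(axis=0)
    if config.phage_tracks_host:
        host = {p.name: p.host_genus for p in config.phages}
        phage = pd.DataFrame({p: bact.loc[host[p]] for p in host}).T
        phage.index.name = None
    else:
        phage = draw([p.name for p in config.phages])
    if len(phage):
        phage = phage / phage.sum(axis=0)
    return bact, phage, meta


# ---------------------------------------------------------------------------
# Reads


def _read_weights(genomes: GenomeSet, config: SimConfig,
                  bact_col: pd.Series, phage_col: pd.Series,
                  ) -> tuple[list[str], np.ndarray]:
    """Per-genome sampling weights for one sample: abundance x length, with
    the free-phage pool scaled to ``phage_dna_fraction`` of bacterial mass."""
    n_species = {}
    for sid, gn in genomes.species_genus.items():
        n_species[gn] = n_species.get(gn, 0) + 1
    ids: list[str] = []
    w: list[float] = []
    for sid, seq in genomes.bacteria.items():
        gn = genomes.species_genus[sid]
        ids.append(sid)
        w.append(float(bact_col.get(gn, 0.0)) / n_species[gn] * len(seq))
    bact_mass = float(np.sum(w))
    lifestyles = {p.name: p.lifestyle for p in config.phages}
    pw_ids: list[str] = []
    pw: list[float] = []
    for pid, seq in genomes.phages.items():
        frac = 1.0 if lifestyles[pid] == LYTIC else config.free_particle_fraction
        pw_ids.append(pid)
        pw.append(float(phage_col.get(pid, 0.0)) * frac * len(seq))
    pmass = float(np.sum(pw))
    if pmass > 0 and bact_mass > 0:
        scale = config.phage_dna_fraction * bact_mass / pmass
        pw = [x * scale for x in pw]
    ids.extend(pw_ids)
    w.extend(pw)
    return ids, np.asarray(w, float)


def simulate_reads(genomes: GenomeSet, bact: pd.DataFrame, phage: pd.DataFrame,
                   config: SimConfig, seed: int | None = None,
                   ) -> tuple[dict[str, ReadSet], dict[str, str]]:
    """Shotgun reads per sample plus the read-origin truth map.

    The number of reads in a sample is Poisson with mean
    ``depth * L / read_length`` where L is the total length of genomes with
    positive sampling weight; reads are drawn from genomes proportionally to
    abundance x genome length, reverse-complemented with probability 0.5,
    and substituted per base at the configured error rate.
    """
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    l = config.read_length
    all_genomes = dict(genomes.bacteria)
    all_genomes.update(genomes.phages)
    reads: dict[str, ReadSet] = {}
    origin: dict[str, str] = {}
    for sample in bact.columns:
        ids, w = _read_weights(genomes, config, bact[sample],
                               phage[sample] if len(phage) else pd.Series(dtype=float))
        pos = w > 0
        if not pos.any():
            reads[sample] = ReadSet(ids=[], seqs=np.empty((0, l), np.uint8))
            continue
        for gid, keep in zip(ids, pos):
            if keep and len(all_genomes[gid]) < l:
                raise ValueError(
                    f"read_length {l} exceeds genome {gid} "
                    f"({len(all_genomes[gid])} bases)")
        L = sum(len(all_genomes[g]) for g, keep in zip(ids, pos) if keep)
        n_frag = int(rng.poisson(config.depth * L / l))
        if config.paired and n_frag % 2:
            n_frag += 1
        counts = rng.multinomial(n_frag, w / w.sum())
        sample_ids: list[str] = []
        chunks: list[np.ndarray] = []
        serial = 0
        for gid, c in zip(ids, counts):
            if c == 0:
                continue
            seq = all_genomes[gid]
            starts = rng.integers(0, len(seq) - l + 1, size=c)
            block = seq[starts[:, None] + np.arange(l)[None, :]]
            flip = rng.random(c) < 0.5
            if flip.any():
                rc = (3 - block[flip])[:, ::-1]
                np.putmask(rc, block[flip][:, ::-1] == 4, 4)
                block[flip] = rc
            if config.substitution_error_rate > 0:
                errs = rng.random(block.shape) < config.substitution_error_rate
                shift = rng.integers(1, 4, size=int(errs.sum())).astype(np.uint8)
                block[errs] = (block[errs] + shift) % 4
            for _ in range(c):
                if config.paired:
                    mate = 1 + serial % 2
                    rid = f"{sample}:r{serial // 2:06d}/{mate}"
                else:
                    rid = f"{sample}:r{serial:06d}"
                sample_ids.append(rid)
                origin[rid] = gid
                serial += 1
            chunks.append(block)
        seqs = np.vstack(chunks) if chunks else np.empty((0, l), np.uint8)
        reads[sample] = ReadSet(ids=sample_ids, seqs=seqs)
    return reads, origin


# ---------------------------------------------------------------------------
# Contigs


def emit_contigs(genomes: GenomeSet, config: SimConfig, seed: int | None = None,
                 ) -> dict[str, np.ndarray]:
    """Fragment every genome into contig-like pieces (simulated assembly).

    Fragment lengths are uniform in [fragment_min, fragment_max]; trailing
    pieces shorter than fragment_min are dropped, so all contig lengths fall
    inside the configured bounds.  With fragment_min below ~200 the output
    exercises the downstream short-contig filter.
    """
    rng = np.random.default_rng(config.seed + 4 if seed is None else seed)
    all_genomes = dict(genomes.bacteria)
    all_genomes.update(genomes.phages)
    contigs: dict[str, np.ndarray] = {}
    for gid in sorted(all_genomes):
        seq = all_genomes[gid]
        pos = 0
        idx = 0
        while len(seq) - pos >= config.fragment_min:
            fl = int(rng.integers(config.fragment_min, config.fragment_max + 1))
            frag = seq[pos:pos + fl].copy()
            pos += fl
            if len(frag) < config.fragment_min:
                break
            if config.contig_error_rate > 0:
                errs = rng.random(len(frag)) < config.contig_error_rate
                shift = rng.integers(1, 4, size=int(errs.sum())).astype(np.uint8)
                frag[errs] = (frag[errs] + shift) % 4
            idx += 1
            contigs[f"{gid}|c{idx}"] = frag
    return contigs


# ---------------------------------------------------------------------------
# Whole-cohort convenience


def simulate_cohort(config: SimConfig) -> Cohort:
    """Run the full generator: genomes, prophages, abundances, reads, contigs."""
    base = generate_genomes(config)
    genomes, placements = integrate_prophages(base, config)
    bact, phage, meta = sample_abundances(config)
    reads, origin = simulate_reads(genomes, bact, phage, config)
    contigs = emit_contigs(genomes, config)
    truth = CohortTruth(bacteria=bact, phages=phage, read_origin=origin,
                        prophage_placements=placements)
    return Cohort(config=config, genomes=genomes, truth=truth, reads=reads,
                  contigs=contigs, metadata=meta)


def phage_db_from(config: SimConfig, genomes: GenomeSet):
    """Build the phage genome database (sequences + annotation) the
    quantification stage searches against."""
    from .quantify import PhageGenomeDB

    annot = pd.DataFrame([
        {"phage_id": p.name, "family": p.family, "host_genus": p.host_genus,
         "lifestyle": p.lifestyle} for p in config.phages])
    return PhageGenomeDB(seqs=dict(genomes.phages), annotations=annot)


def marker_db_from(genomes: GenomeSet):
    """Build the clade-specific marker database for bacterial profiling."""
    from .markers import MarkerDB

    table = genomes.markers.copy()
    table["clade"] = ("k__Bacteria|f__" + table["family"]
                      + "|g__" + table["genus"])
    return MarkerDB(seqs=dict(genomes.marker_seqs),
                    table=table[["marker_id", "genus", "family", "length",
                                 "clade"]].copy())


# ---------------------------------------------------------------------------
# Scenario configurations


def study_config(seed: int = 0, **overrides) -> SimConfig:
    """Study-like cohort: 31 cases / 28 controls, four bacterial genera with
    a Lactococcus-like genus depleted 10x in cases, and a phage community in
    which strictly lytic lactococcal phages (c2 and 936 groups) are boosted
    while temperate phages ride along with their hosts."""
    genera = (
        GenusSpec("Bacteroides", genome_length=4000, family="Bacteroidaceae"),
        GenusSpec("Prevotella", genome_length=3500, family="Prevotellaceae"),
        GenusSpec("Streptococcus", genome_length=3000, family="Streptococcaceae"),
        GenusSpec("Lactococcus", genome_length=3000, family="Streptococcaceae"),
    )
    phages = (
        PhageSpec("Bacteroides_phage_B124", "Bacteroides", TEMPERATE,
                  family="Siphoviridae"),
        PhageSpec("Streptococcus_phage_2972", "Streptococcus", TEMPERATE,
                  family="Siphoviridae"),
        PhageSpec("Lactococcus_phage_c2", "Lactococcus", LYTIC,
                  family="Siphoviridae"),
        PhageSpec("Lactococcus_phage_jj50", "Lactococcus", LYTIC,
                  family="Siphoviridae"),
        PhageSpec("Lactococcus_phage_TP901-1", "Lactococcus", TEMPERATE,
                  family="Siphoviridae"),
    )
    base = {
        "Bacteroides": (np.log(0.50), 0.5),
        "Prevotella": (np.log(0.25), 0.5),
        "Streptococcus": (np.log(0.15), 0.5),
        "Lactococcus": (np.log(0.10), 0.5),
        "Bacteroides_phage_B124": (np.log(0.35), 0.5),
        "Streptococcus_phage_2972": (np.log(0.20), 0.5),
        "Lactococcus_phage_c2": (np.log(0.15), 0.5),
        "Lactococcus_phage_jj50": (np.log(0.15), 0.5),
        "Lactococcus_phage_TP901-1": (np.log(0.15), 0.5),
    }
    effects = {
        "Lactococcus": 0.1,
        "Lactococcus_phage_c2": 10.0,
        "Lactococcus_phage_jj50": 5.0,
    }
    cfg = dict(genera=genera, phages=phages, base_abundance=base,
               case_effects=effects, seed=seed)
    cfg.update(overrides)
    return SimConfig(**cfg)


def recovery_config(seed: int = 0, **overrides) -> SimConfig:
    """Reduced two-genus cohort for parameter-recovery simulations: a
    dominant genus with a temperate prophage and a Lactococcus-like genus
    (base share 0.10) depleted 10x in cases, whose strictly lytic phage is
    boosted 10x.  Sized so one replicate runs in seconds."""
    genera = (
        GenusSpec("Bacteroides", genome_length=3000, family="Bacteroidaceae"),
        GenusSpec("Lactococcus", genome_length=3000, family="Streptococcaceae"),
    )
    phages = (
        PhageSpec("Bacteroides_phage_B124", "Bacteroides", TEMPERATE),
        PhageSpec("Lactococcus_phage_c2", "Lactococcus", LYTIC),
    )
    base = {
        "Bacteroides": (np.log(0.90), 0.3),
        "Lactococcus": (np.log(0.10), 0.3),
        "Bacteroides_phage_B124": (np.log(0.5), 0.3),
        "Lactococcus_phage_c2": (np.log(0.5), 0.3),
    }
    effects = {"Lactococcus": 0.1, "Lactococcus_phage_c2": 10.0}
    cfg = dict(genera=genera, phages=phages, base_abundance=base,
               case_effects=effects, seed=seed)
    cfg.update(overrides)
    return SimConfig(**cfg)


def prophage_config(seed: int = 0, **overrides) -> SimConfig:
    """Pure-prophage scenario: two genera of equal expected abundance, each
    carrying one temperate prophage of equal length, no free phage
    particles, and phage abundance tied to host abundance.  The recovered
    phage/host ratio should sit in the integrated band (log10 R near 0)."""
    genera = (
        GenusSpec("Bacteroides", genome_length=3000, family="Bacteroidaceae"),
        GenusSpec("Lactococcus", genome_length=3000, family="Streptococcaceae"),
    )
    phages = (
        PhageSpec("Bacteroides_phage_B124", "Bacteroides", TEMPERATE),
        PhageSpec("Lactococcus_phage_TP901-1", "Lactococcus", TEMPERATE),
    )
    base = {
        "Bacteroides": (np.log(0.5), 0.3),
        "Lactococcus": (np.log(0.5), 0.3),
        "Bacteroides_phage_B124": (np.log(0.5), 0.3),
        "Lactococcus_phage_TP901-1": (np.log(0.5), 0.3),
    }
    cfg = dict(genera=genera, phages=phages, base_abundance=base,
               case_effects={}, seed=seed, phage_dna_fraction=0.0,
               free_particle_fraction=0.0, phage_tracks_host=True,
               fragment_min=120, fragment_max=500)
    cfg.update(overrides)
    return SimConfig(**cfg)


def free_phage_config(seed: int = 0, **overrides) -> SimConfig:
    """Lytic-phages-only cohort for estimator-vs-truth recovery checks:
    with no prophages, the phage-domain truth coincides with the sequenced
    free phage DNA, so estimated relative abundances should track the true
    ones directly.  Sized for >= 5x phage coverage."""
    genera = (
        GenusSpec("Bacteroides", genome_length=2500),
        GenusSpec("Lactococcus", genome_length=2500),
    )
    phages = (
        PhageSpec("Lactococcus_phage_c2", "Lactococcus", LYTIC,
                  genome_length=1500),
        PhageSpec("Lactococcus_phage_sk1", "Lactococcus", LYTIC,
                  genome_length=1500),
        PhageSpec("Bacteroides_phage_B40", "Bacteroides", LYTIC,
                  genome_length=1500),
    )
    base = {
        "Bacteroides": (np.log(0.6), 0.4),
        "Lactococcus": (np.log(0.4), 0.4),
        "Lactococcus_phage_c2": (np.log(0.5), 0.6),
        "Lactococcus_phage_sk1": (np.log(0.3), 0.6),
        "Bacteroides_phage_B40": (np.log(0.2), 0.6),
    }
    cfg = dict(genera=genera, phages=phages, base_abundance=base,
               case_effects={}, n_cases=3, n_controls=3, depth=10.0,
               phage_dna_fraction=0.4, seed=seed)
    cfg.update(overrides)
    return SimConfig(**cfg)


def toy_config(seed: int = 0, **overrides) -> SimConfig:
    """Tiny fixture: 2 genera, 3 phages, 6 samples; runs in about a second."""
    genera = (
        GenusSpec("Bacteroides", genome_length=2000, n_markers=3,
                  family="Bacteroidaceae"),
        GenusSpec("Lactococcus", genome_length=2000, n_markers=3,
                  family="Streptococcaceae"),
    )
    phages = (
        PhageSpec("Bacteroides_phage_B124", "Bacteroides", TEMPERATE,
                  genome_length=1500),
        PhageSpec("Lactococcus_phage_c2", "Lactococcus", LYTIC,
                  genome_length=1500),
        PhageSpec("Lactococcus_phage_TP901-1", "Lactococcus", TEMPERATE,
                  genome_length=1500),
    )
    base = {
        "Bacteroides": (np.log(0.7), 0.4),
        "Lactococcus": (np.log(0.3), 0.4),
        "Bacteroides_phage_B124": (np.log(0.4), 0.4),
        "Lactococcus_phage_c2": (np.log(0.3), 0.4),
        "Lactococcus_phage_TP901-1": (np.log(0.3), 0.4),
    }
    effects = {"Lactococcus": 0.1, "Lactococcus_phage_c2": 10.0}
    cfg = dict(genera=genera, phages=phages, base_abundance=base,
               case_effects=effects, n_cases=3, n_controls=3, depth=3.0,
               seed=seed)
    cfg.update(overrides)
    return SimConfig(**cfg)
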