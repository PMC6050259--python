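"""Phage abundance quantification from contigs and reads.

The custom virome counting scheme: contigs longer than 200 bases are
assigned to the phage genome with the best local-alignment hit (e-value
below 1e-5 and alignment covering more than half the contig); all reads are
then re-mapped to the phage-assigned contigs; read counts are combined per
phage taxon per sample; a detection threshold (at least 2 reads with >90%
identity over >100 aligned bases) is applied before normalisation to
relative abundance within the phage domain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .align import AlignmentHit, ReadMapper, Scoring, seed_and_extend_align
from .simulate import ReadSet

__all__ = [
    "PhageGenomeDB",
    "ContigAssignment",
    "PhageCountTable",
    "classify_contigs",
    "recruit_reads",
    "count_phage_abundance",
    "apply_detection_threshold",
    "relative_abundance",
    "prevalence_filter",
    "group_presence_screen",
    "aggregate_by_family",
    "quantify_cohort",
]


@dataclass
class PhageGenomeDB:
    """Phage genome sequences plus a family / host-genus / lifestyle
    annotation table (columns: phage_id, family, host_genus, lifestyle)."""

    seqs: dict[str, np.ndarray]
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"phage_id", "family", "host_genus", "lifestyle"}
        missing = need - set(self.annotations.columns)
        if missing:
            raise ValueError(f"phage annotation table missing {sorted(missing)}")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.seqs.values())

    def annotation_for(self, phage_id: str) -> pd.Series | None:
        rows = self.annotations[self.annotations["phage_id"] == phage_id]
        return rows.iloc[0] if len(rows) else None


@dataclass
class ContigAssignment:
    contig_id: str
    phage_id: str
    best_hit: AlignmentHit


@dataclass
class PhageCountTable:
    """Read counts per phage taxon per sample, with the per-read assignment
    records (identity, aligned length) retained for thresholding."""

    counts: pd.DataFrame  # phages x samples, integer counts
    assignments: pd.DataFrame  # sample, read_id, contig_id, phage_id, ...

    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


# ---------------------------------------------------------------------------


def classify_contigs(contigs: Mapping[str, object], phage_db: PhageGenomeDB,
                     e_max: float = 1e-5, min_len: int = 200,
                     min_frac: float = 0.5, *, scoring: Scoring = Scoring(),
                     min_score: float = 25.0, k: int = 13,
                     ) -> list[ContigAssignment]:
    """Assign each sufficiently long contig to its best-matching phage.

    A contig is assigned only if its length strictly exceeds ``min_len``,
    the best hit's e-value is below ``e_max`` and the alignment covers
    strictly more than ``min_frac`` of the contig.  Ties among equal-scoring
    phages break toward the lower e-value, then the lexicographically
    smaller phage id.
    """
    if e_max <= 0 or min_len <= 0 or not (0 < min_frac < 1):
        raise ValueError("thresholds must be positive (and min_frac in (0,1))")
    if not phage_db.seqs:
        raise ValueError("phage database is empty")
    out: list[ContigAssignment] = []
    db_len = phage_db.total_length
    for cid in sorted(contigs):
        seq = contigs[cid]
        clen = len(seq)
        if clen <= min_len:
            continue
        hits = seed_and_extend_align(seq, phage_db.seqs, query_id=cid,
                                     scoring=scoring, min_score=min_score,
                                     k=k, db_length=db_len)
        if not hits:
            continue
        best = hits[0]
        if best.e_value >= e_max:
            continue
        if best.aligned_length <= min_frac * clen:
            continue
        out.append(ContigAssignment(contig_id=cid, phage_id=best.subject_id,
                                    best_hit=best))
    return out


def recruit_reads(reads: Mapping[str, ReadSet],
                  assignments: list[ContigAssignment],
                  contigs: Mapping[str, object], *,
                  min_score: float = 40.0, k: int = 13,
                  scoring: Scoring = Scoring()) -> pd.DataFrame:
    """Re-map all reads to the phage-assigned contigs.

    Each read goes to at most one contig (best alignment score); ties break
    by lexicographic phage id then contig id.  Unmapped reads are dropped.
    Returns one row per recruited read with identity and aligned length.
    """
    cols = ["sample", "read_id", "contig_id", "phage_id", "score",
            "percent_identity", "aligned_length"]
    if not assignments:
        return pd.DataFrame(columns=cols)
    contig_phage = {a.contig_id: a.phage_id for a in assignments}
    subjects = {cid: contigs[cid] for cid in contig_phage}
    mapper = ReadMapper(subjects, k=k, scoring=scoring, min_score=min_score)
    rows = []
    for sample in sorted(reads):
        rs = reads[sample]
        if not rs.ids:
            continue
        results = mapper.map_reads(rs.seqs)
        for rid, hits in zip(rs.ids, results):
            if not hits:
                continue
            top_score = hits[0].score
            tied = [h for h in hits if h.score == top_score]
            h = min(tied, key=lambda h: (contig_phage[h.subject_id],
                                         h.subject_id))
            rows.append((sample, rid, h.subject_id,
                         contig_phage[h.subject_id], h.score,
                         h.percent_identity, h.aligned_length))
    return pd.DataFrame(rows, columns=cols)


def count_phage_abundance(read_assignments: pd.DataFrame,
                          assignments: list[ContigAssignment] | None = None,
                          samples: list[str] | None = None,
                          ) -> PhageCountTable:
    """Combine recruited-read counts per phage taxon per sample."""
    df = read_assignments
    if samples is None:
        samples = sorted(df["sample"].unique()) if len(df) else []
    if len(df):
        counts = (df.groupby(["phage_id", "sample"]).size().unstack(fill_value=0)
                  .reindex(columns=samples, fill_value=0))
        counts = counts.sort_index()
    else:
        counts = pd.DataFrame(index=pd.Index([], name="phage_id"),
                              columns=samples, dtype=int)
    counts.index.name = "taxon"
    counts.columns.name = "sample"
    return PhageCountTable(counts=counts.astype(int), assignments=df.copy())


def apply_detection_threshold(table: PhageCountTable, min_reads: int = 2,
                              min_identity: float = 90.0,
                              min_aligned: int = 100,
                              apply_length_to_reads: bool = True,
                              ) -> PhageCountTable:
    """Apply the per-sample phage detection threshold.

    A read qualifies if its identity strictly exceeds ``min_identity``
    percent and (when the length clause is enabled) its aligned length
    strictly exceeds ``min_aligned`` bases.  A phage is detected in a sample
    only when at least ``min_reads`` qualifying reads support it; cells with
    fewer qualifying reads are zeroed and non-qualifying reads are never
    counted.  The operation is idempotent.
    """
    df = table.assignments
    if not len(df):
        return PhageCountTable(counts=table.counts.copy(), assignments=df.copy())
    ok = df["percent_identity"] > min_identity
    if apply_length_to_reads:
        ok &= df["aligned_length"] > min_aligned
    kept = df[ok]
    counts = (kept.groupby(["phage_id", "sample"]).size().unstack(fill_value=0)
              .reindex(index=table.counts.index,
                       columns=table.counts.columns, fill_value=0))
    counts = counts.where(counts >= min_reads, 0).astype(int)
    counts.index.name = "taxon"
    counts.columns.name = "sample"
    # retain only reads supporting detected cells
    detected = counts.stack()
    detected = set(detected[detected > 0].index)
    keep_mask = [(r.phage_id, r.sample) in detected for r in kept.itertuples()]
    return PhageCountTable(counts=counts, assignments=kept[np.asarray(keep_mask, bool)]
                           if len(kept) else kept.copy())


def relative_abundance(counts: pd.DataFrame,
                       total_reads: pd.Series | None = None) -> pd.DataFrame:
    """Normalise a count table to per-sample relative abundance.

    By default the denominator is the sample's phage-assigned read total
    (phage-domain-relative, phages among phages); pass per-sample
    ``total_reads`` to normalise against whole-metagenome read counts
    instead.  All-zero samples are flagged with a warning and emitted as
    all-zero columns rather than NaN.
    """
    counts = counts.astype(float)
    if total_reads is not None:
        totals = pd.Series(total_reads).reindex(counts.columns)
        if totals.isna().any() or (totals < counts.sum(axis=0) - 1e-9).any():
            raise ValueError("total_reads must cover every sample and be at "
                             "least the assigned-read count")
    else:
        totals = counts.sum(axis=0)
    zero = totals[totals == 0].index.tolist()
    if zero:
        warnings.warn(f"samples with no assigned reads: {zero}", stacklevel=2)
    safe = totals.replace(0, np.nan)
    rel = counts.div(safe, axis=1).fillna(0.0)
    return rel


def prevalence_filter(rel: pd.DataFrame, floor: float = 1e-4) -> pd.DataFrame:
    """Drop taxa whose relative abundance stays below ``floor`` in every
    sample (a taxon survives iff it reaches the floor somewhere)."""
    if rel.empty:
        return rel.copy()
    keep = (rel >= floor).any(axis=1)
    return rel[keep].copy()


def group_presence_screen(rel: pd.DataFrame, metadata: pd.DataFrame,
                          min_abund: float = 1e-4, min_samples: int = 2,
                          ) -> pd.DataFrame:
    """Per-group presence / exclusivity screen.

    A species is *present* in a group when at least ``min_samples`` of that
    group's samples have relative abundance >= ``min_abund`` (default 0.01%),
    and *exclusive* to the group when present there and in no other group.
    Returns one row per taxon with boolean presence and exclusivity flags.
    """
    meta = metadata.set_index("sample_id")["group"]
    unknown = [s for s in rel.columns if s not in meta.index]
    if unknown:
        raise ValueError(f"samples without group label: {unknown}")
    groups = sorted(meta.loc[list(rel.columns)].unique())
    out = pd.DataFrame(index=rel.index)
    for g in groups:
        cols = [s for s in rel.columns if meta[s] == g]
        out[f"present_{g}"] = (rel[cols] >= min_abund).sum(axis=1) >= min_samples
    for g in groups:
        others = [f"present_{h}" for h in groups if h != g]
        out[f"exclusive_{g}"] = out[f"present_{g}"] & ~out[others].any(axis=1)
    out.index.name = "taxon"
    return out


def aggregate_by_family(rel: pd.DataFrame, phage_db: PhageGenomeDB,
                        ) -> pd.DataFrame:
    """Sum member-phage abundances per phage family; phages without a family
    annotation pool into "unclassified"."""
    fam = phage_db.annotations.set_index("phage_id")["family"]
    labels = [fam.get(p) if isinstance(fam.get(p), str) and fam.get(p)
              else "unclassified" for p in rel.index]
    out = rel.groupby(pd.Index(labels, name="family")).sum()
    return out


# ---------------------------------------------------------------------------


@dataclass
class QuantifyResult:
    contig_assignments: list[ContigAssignment]
    read_assignments: pd.DataFrame
    raw_counts: PhageCountTable
    detected: PhageCountTable
    relative: pd.DataFrame
    filtered: pd.DataFrame
    family: pd.DataFrame


def quantify_cohort(contigs: Mapping[str, object], reads: Mapping[str, ReadSet],
                    phage_db: PhageGenomeDB, *, e_max: float = 1e-5,
                    min_contig: int = 200, min_frac: float = 0.5,
                    min_reads: int = 2, min_identity: float = 90.0,
                    min_aligned: int = 100, read_min_score: float = 40.0,
                    contig_min_score: float = 25.0,
                    prevalence_floor: float = 1e-4,
                    apply_length_to_reads: bool = True,
                    normalize_by: str = "phage_reads",
                    ) -> QuantifyResult:
    """Run the full phage quantification chain on one cohort.

    ``normalize_by`` selects the relative-abundance denominator:
    "phage_reads" (default, phage-domain-relative) or "total_reads"
    (each sample's full read count).
    """
    ca = classify_contigs(contigs, phage_db, e_max=e_max, min_len=min_contig,
                          min_frac=min_frac, min_score=contig_min_score)
    ra = recruit_reads(reads, ca, contigs, min_score=read_min_score)
    samples = sorted(reads)
    raw = count_phage_abundance(ra, ca, samples=samples)
    det = apply_detection_threshold(raw, min_reads=min_reads,
                                    min_identity=min_identity,
                                    min_aligned=min_aligned,
                                    apply_length_to_reads=apply_length_to_reads)
    if normalize_by == "total_reads":
        totals = pd.Series({s: len(reads[s].ids) for s in samples})
    elif normalize_by == "phage_reads":
        totals = None
    else:
        raise ValueError("normalize_by must be 'phage_reads' or 'total_reads'")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rel = relative_abundance(det.counts, total_reads=totals)
    filt = prevalence_filter(rel, floor=prevalence_floor)
    fam = aggregate_by_family(rel, phage_db)
    return QuantifyResult(contig_assignments=ca, read_assignments=ra,
                          raw_counts=raw, detected=det, relative=rel,
                          filtered=filt, family=fam)
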