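"""Bacterial profiling from clade-specific marker genes.

A simplified marker-gene profiler in the spirit of MetaPhlAn-style tools:
reads are mapped to a database of clade-specific marker sequences, the
per-clade mean per-base marker coverage (aligned bases divided by total
marker length) gives the clade's abundance, and per-sample abundances are
normalised to sum to one.  Reads aligning to markers of more than one clade
are discarded, mirroring the clade-specificity assumption.  An adapter loads
externally produced MetaPhlAn-style tabular profiles.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .align import ReadMapper, Scoring
from .simulate import ReadSet

__all__ = ["MarkerDB", "profile_markers", "load_external_profile",
           "ProfileResult"]

_RANK_ORDER = ["k", "p", "c", "o", "f", "g", "s"]


@dataclass
class MarkerDB:
    """Marker sequences plus their clade map.

    ``table`` columns: marker_id, genus, family, length, clade (a
    MetaPhlAn-style pipe-separated clade string, e.g.
    ``k__Bacteria|f__Streptococcaceae|g__Lactococcus``).
    """

    seqs: dict[str, np.ndarray]
    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"marker_id", "genus", "family", "length", "clade"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValueError(f"marker table missing columns {sorted(missing)}")
        if (self.table["length"] <= 0).any():
            raise ValueError("marker lengths must be positive")
        if self.table["marker_id"].duplicated().any():
            raise ValueError("duplicate marker ids")


@dataclass
class ProfileResult:
    genus: pd.DataFrame  # genera x samples, fractions summing to 1
    family: pd.DataFrame  # families x samples (sum of member genera)
    coverage: pd.DataFrame  # raw per-clade mean coverage before normalisation


def profile_markers(reads: Mapping[str, ReadSet], marker_db: MarkerDB, *,
                    min_score: float = 40.0, k: int = 13,
                    scoring: Scoring = Scoring()) -> ProfileResult:
    """Estimate bacterial genus and family relative abundance from reads.

    Clade abundance is proportional to mean per-base coverage over the
    clade's markers: total aligned bases on those markers divided by their
    total length.  Doubling marker lengths at doubled coverage therefore
    leaves the estimates unchanged.
    """
    if not marker_db.seqs:
        raise ValueError("marker database is empty")
    info = marker_db.table.set_index("marker_id")
    genus_len = marker_db.table.groupby("genus")["length"].sum()
    genus_family = marker_db.table.set_index("genus")["family"].to_dict()
    mapper = ReadMapper(marker_db.seqs, k=k, scoring=scoring,
                        min_score=min_score)
    samples = sorted(reads)
    cov = pd.DataFrame(0.0, index=sorted(genus_len.index), columns=samples)
    any_mapped = False
    for sample in samples:
        rs = reads[sample]
        if not rs.ids:
            continue
        results = mapper.map_reads(rs.seqs)
        bases: dict[str, float] = {}
        for hits in results:
            if not hits:
                continue
            clades = {info.at[h.subject_id, "genus"] for h in hits}
            if len(clades) > 1:
                continue  # not clade-specific for this read; discard
            h = hits[0]
            g = info.at[h.subject_id, "genus"]
            bases[g] = bases.get(g, 0.0) + (h.subject_span[1] - h.subject_span[0])
        for g, b in bases.items():
            cov.at[g, sample] = b / float(genus_len[g])
            any_mapped = True
    if not any_mapped:
        warnings.warn("no read mapped to any marker; empty profile",
                      stacklevel=2)
    totals = cov.sum(axis=0).replace(0, np.nan)
    genus = cov.div(totals, axis=1).fillna(0.0)
    fam_index = pd.Index([genus_family[g] for g in genus.index], name="family")
    family = genus.groupby(fam_index).sum()
    genus.index.name = "taxon"
    return ProfileResult(genus=genus, family=family, coverage=cov)


# ---------------------------------------------------------------------------
# External profile adapter


def _parse_clade(clade: str) -> tuple[str, str, bool]:
    """Return (rank, name, flagged): the deepest named rank in a clade
    string.  ``flagged`` is True when the genus rank is missing and the
    entry was assigned to the nearest named higher rank."""
    parts = [p for p in str(clade).split("|") if p]
    named = [(p[0], p[3:]) for p in parts
             if re.match(r"^[kpcofgs]__.+", p)]
    if not named:
        return ("", str(clade), True)
    rank, name = named[-1]
    flagged = rank != "g" and not any(r == "g" for r, _ in named)
    return rank, name, flagged


def load_external_profile(path) -> pd.DataFrame:
    """Load a MetaPhlAn-style tabular profile (rows = clade strings,
    columns = samples, values = relative percent or fraction).

    Values are normalised to per-sample fractions; parsed rank and name and
    a flag for entries missing a genus rank are attached in
    ``df.attrs["clades"]``.  Non-numeric cells or duplicate clades raise.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate clades in profile: {dupes}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in profile: {exc}") from exc
    totals = df.sum(axis=0).replace(0, np.nan)
    out = df.div(totals, axis=1).fillna(0.0)
    clades = pd.DataFrame(
        [_parse_clade(c) for c in out.index],
        index=out.index, columns=["rank", "name", "missing_genus_rank"])
    out.attrs["clades"] = clades
    out.index.name = "clade"
    return out
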