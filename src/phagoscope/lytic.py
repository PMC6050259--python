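"""Phage/bacteria ratio ("lytic potential") and lifestyle analysis.

Phages are clustered by their annotated bacterial host genus; the ratio
R = A_phage / A_host of (domain-relative) phage abundance to host-genus
abundance is the lytic potential of that host cluster.  R near 1 is read as
a stably integrated prophage, R < 1 as a prophage absent from part of the
host population, and R > 1 as a phage at least partially in the lytic
phase.  Lactococcal phages are additionally split into strictly virulent
(lytic; c2 and 936 groups) versus temperate (P335-like) lifestyles via a
shipped, overridable lookup table, and per-group abundance sums and
per-phage log-ratios quantify the case/control contrast.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .quantify import PhageGenomeDB

__all__ = [
    "RatioResult", "cluster_by_host", "phage_bacteria_ratio",
    "load_lifestyle_table", "classify_lifestyle", "lifestyle_abundance",
    "group_fold_change", "lifestyle_log_ratio", "FoldChange",
]

STATUS_DEFINED = "defined"
STATUS_HOST_ABSENT = "host_absent"
STATUS_PHAGE_ABSENT = "phage_absent"
STATUS_BOTH_ABSENT = "both_absent"


@dataclass
class RatioResult:
    host_genus: str
    level: str  # "sample" or "group"
    unit: str  # sample id or group name
    a_phage: float
    a_host: float
    ratio: float  # NaN when undefined
    log10_ratio: float
    status: str

    @property
    def interpretation(self) -> str:
        if self.status != STATUS_DEFINED:
            return self.status
        if abs(self.log10_ratio) <= 0.3:
            return "integrated"
        return "partially_lytic" if self.log10_ratio > 0 else "prophage_partial"


def _infer_host(phage_id: str) -> str:
    """Host genus implied by the conventional "<Genus>_phage_<name>" or
    "<Genus> phage <name>" naming."""
    m = re.match(r"^([A-Za-z]+)[ _][Pp]hage(?:[ _]|$)", str(phage_id))
    return m.group(1) if m else ""


def cluster_by_host(phage_table: pd.DataFrame, phage_db: PhageGenomeDB,
                    ) -> pd.DataFrame:
    """Sum phage abundances per annotated host genus.

    Falls back to the host implied by the phage's name when the annotation
    is empty; phages with no resolvable host pool into "unassigned_host".
    Total abundance is conserved exactly.
    """
    annot = phage_db.annotations.set_index("phage_id")["host_genus"]
    hosts = []
    for p in phage_table.index:
        h = annot.get(p, "")
        if not isinstance(h, str) or not h:
            h = _infer_host(p)
        hosts.append(h if h else "unassigned_host")
    out = phage_table.groupby(pd.Index(hosts, name="host_genus")).sum()
    return out


def _ratio_row(genus: str, level: str, unit: str, ap: float, ah: float,
               ) -> RatioResult:
    if ap > 0 and ah > 0:
        r = ap / ah
        return RatioResult(genus, level, unit, ap, ah, r, float(np.log10(r)),
                           STATUS_DEFINED)
    if ah == 0 and ap > 0:
        status = STATUS_HOST_ABSENT
    elif ap == 0 and ah > 0:
        status = STATUS_PHAGE_ABSENT
    else:
        status = STATUS_BOTH_ABSENT
    return RatioResult(genus, level, unit, ap, ah, np.nan, np.nan, status)


def phage_bacteria_ratio(host_table: pd.DataFrame, bact_table: pd.DataFrame,
                         metadata: pd.DataFrame) -> list[RatioResult]:
    """Per-sample and per-group phage/host abundance ratios.

    Group-level ratios divide group *mean* phage abundance by group mean
    host abundance.  Both inputs must be relative tables over the same
    samples; host clusters without a matching bacterial genus get
    host-absent status rather than a finite ratio.
    """
    if set(host_table.columns) != set(bact_table.columns):
        raise ValueError("phage and bacteria tables must cover the same samples")
    meta = metadata.set_index("sample_id")["group"]
    missing = [s for s in host_table.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    results: list[RatioResult] = []
    genera = [g for g in host_table.index if g != "unassigned_host"]
    for genus in genera:
        ap_s = host_table.loc[genus]
        ah_s = (bact_table.loc[genus] if genus in bact_table.index
                else pd.Series(0.0, index=host_table.columns))
        for sample in host_table.columns:
            results.append(_ratio_row(genus, "sample", sample,
                                      float(ap_s[sample]), float(ah_s[sample])))
        for grp in sorted(meta.loc[list(host_table.columns)].unique()):
            cols = [s for s in host_table.columns if meta[s] == grp]
            results.append(_ratio_row(genus, "group", grp,
                                      float(ap_s[cols].mean()),
                                      float(ah_s[cols].mean())))
    return results


def ratio_report(results: list[RatioResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "host_genus": r.host_genus, "level": r.level, "unit": r.unit,
        "A_phage": r.a_phage, "A_host": r.a_host, "R": r.ratio,
        "log10_R": r.log10_ratio, "status": r.status,
        "interpretation": r.interpretation} for r in results])


# ---------------------------------------------------------------------------
# Lifestyle classification


def load_lifestyle_table(path=None) -> pd.DataFrame:
    """Load a phage-lifestyle lookup (columns: phage_pattern, lifestyle,
    provenance).  Without a path, the shipped lactococcal table (c2/936
    groups lytic, P335-like temperate) is used."""
    if path is None:
        ref = resources.files("phagoscope.data") / "lactococcus_lifestyle.tsv"
        with resources.as_file(ref) as p:
            table = pd.read_csv(p, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    need = {"phage_pattern", "lifestyle"}
    if need - set(table.columns):
        raise ValueError("lifestyle table needs phage_pattern and lifestyle columns")
    bad = set(table["lifestyle"]) - {"lytic", "temperate", "unknown"}
    if bad:
        raise ValueError(f"unknown lifestyle values: {sorted(bad)}")
    return table


def classify_lifestyle(phage_ids, lifestyle_table: pd.DataFrame,
                       ) -> pd.DataFrame:
    """Deterministically classify phages as lytic / temperate / unknown.

    A phage matches a table row when the row's pattern occurs in the phage
    id (case-insensitive); longer patterns win, then earlier rows.  Phages
    matching nothing are "unknown" and flagged with a warning.
    """
    pats = lifestyle_table.assign(_len=lifestyle_table["phage_pattern"].str.len())
    pats = pats.sort_values(["_len"], ascending=False, kind="stable")
    rows = []
    unknown = []
    for pid in phage_ids:
        low = str(pid).lower()
        life, prov = "unknown", ""
        for row in pats.itertuples():
            if str(row.phage_pattern).lower() in low:
                life = row.lifestyle
                prov = getattr(row, "provenance", "")
                break
        if life == "unknown":
            unknown.append(pid)
        rows.append({"phage_id": pid, "lifestyle": life, "provenance": prov})
    if unknown:
        warnings.warn(f"phages with unknown lifestyle: {unknown}", stacklevel=2)
    return pd.DataFrame(rows)


def lifestyle_abundance(phage_table: pd.DataFrame, metadata: pd.DataFrame,
                        classification: pd.DataFrame) -> pd.DataFrame:
    """Group-mean abundance summed per lifestyle class (lytic, temperate,
    unknown).  Lytic + temperate + unknown equals the table total."""
    meta = metadata.set_index("sample_id")["group"]
    life = classification.set_index("phage_id")["lifestyle"]
    labels = [life.get(p, "unknown") for p in phage_table.index]
    per_life = phage_table.groupby(pd.Index(labels, name="lifestyle")).sum()
    out = {}
    for grp in sorted(meta.loc[list(phage_table.columns)].unique()):
        cols = [s for s in phage_table.columns if meta[s] == grp]
        out[grp] = per_life[cols].mean(axis=1)
    return pd.DataFrame(out).reindex(["lytic", "temperate", "unknown"],
                                     fill_value=0.0).fillna(0.0)


# ---------------------------------------------------------------------------
# Effect sizes


@dataclass
class FoldChange:
    taxon: str
    fold: float  # control mean / case mean
    ci_low: float
    ci_high: float
    status: str  # "finite" or "infinite"
    n_bootstrap: int
    seed: int


def group_fold_change(table: pd.DataFrame, taxon: str, metadata: pd.DataFrame,
                      n_bootstrap: int = 1000, seed: int = 0,
                      case_group: str | None = None) -> FoldChange:
    """Fold change of a taxon's mean abundance, control over case, with a
    percentile bootstrap confidence interval over samples.

    ``case_group`` defaults to the first group name in sorted order being
    treated as control — pass it explicitly for two-group metadata where
    the case label does not sort last.
    """
    meta = metadata.set_index("sample_id")["group"]
    groups = sorted(meta.loc[list(table.columns)].unique())
    if len(groups) != 2:
        raise ValueError("fold change needs exactly two groups")
    if case_group is None:
        case_group = groups[0] if groups[0].lower() != "control" else groups[1]
    control_group = [g for g in groups if g != case_group][0]
    x = table.loc[taxon]
    case = x[[s for s in table.columns if meta[s] == case_group]].to_numpy(float)
    ctrl = x[[s for s in table.columns if meta[s] == control_group]].to_numpy(float)
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("both groups need samples")
    mc, mx = ctrl.mean(), case.mean()
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_bootstrap):
        bc = ctrl[rng.integers(0, ctrl.size, ctrl.size)].mean()
        bx = case[rng.integers(0, case.size, case.size)].mean()
        boots.append(bc / bx if bx > 0 else np.inf)
    boots = np.asarray(boots)
    lo = float(np.nanpercentile(np.where(np.isinf(boots), np.nan, boots), 2.5))
    if mx == 0:
        return FoldChange(taxon, np.inf, lo, np.inf, "infinite",
                          n_bootstrap, seed)
    hi = float(np.percentile(boots[np.isfinite(boots)], 97.5))
    return FoldChange(taxon, mc / mx, lo, hi, "finite", n_bootstrap, seed)


def lifestyle_log_ratio(phage_table: pd.DataFrame, metadata: pd.DataFrame,
                        pseudocount: float | None = None,
                        case_group: str | None = None) -> pd.DataFrame:
    """Per-phage log10(case mean / control mean) with direction labels.

    Zero means are handled by a pseudocount, by default half the smallest
    nonzero abundance in the table.  Positive values are up in cases,
    negative down, zero equal.
    """
    meta = metadata.set_index("sample_id")["group"]
    groups = sorted(meta.loc[list(phage_table.columns)].unique())
    if len(groups) != 2:
        raise ValueError("log ratio needs exactly two groups")
    if case_group is None:
        case_group = groups[0] if groups[0].lower() != "control" else groups[1]
    control_group = [g for g in groups if g != case_group][0]
    if pseudocount is None:
        nz = phage_table.to_numpy(float)
        nz = nz[nz > 0]
        pseudocount = float(nz.min() / 2.0) if nz.size else 1e-12
    case_cols = [s for s in phage_table.columns if meta[s] == case_group]
    ctrl_cols = [s for s in phage_table.columns if meta[s] == control_group]
    mc = phage_table[case_cols].mean(axis=1)
    mx = phage_table[ctrl_cols].mean(axis=1)
    lr = np.log10((mc + pseudocount) / (mx + pseudocount))
    direction = np.where(lr > 0, "up", np.where(lr < 0, "down", "equal"))
    return pd.DataFrame({"log10_ratio": lr, "direction": direction,
                         "case_mean": mc, "control_mean": mx,
                         "pseudocount": pseudocount})
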