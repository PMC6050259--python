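"""Alpha / beta diversity estimators, ordination, and group tests.

All estimators are implemented directly from their formulas on integer
count vectors (richness estimators are undefined on fractions):

* Shannon H = -sum p_i ln p_i (natural log)
* Simpson D = 1 - sum p_i^2; inverse Simpson = 1 / sum p_i^2
* Chao1 = S_obs + F1^2 / (2 F2) (bias-corrected fallback when F2 = 0)
* ACE with the standard rare/abundant split at 10 individuals
* Bray-Curtis dissimilarity, a Spearman-correlation-based dissimilarity
  d = (1 - rho) / 2, classical-scaling PCoA, Mann-Whitney / one-way ANOVA
  group comparison, and a permutation PERMANOVA with pseudo-F.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FrequencyCounts", "OrdinationResult", "TestResult",
    "frequency_counts", "shannon", "simpson_indices", "chao1", "ace",
    "alpha_diversity_table", "bray_curtis", "spearman_dissimilarity",
    "pcoa", "group_compare", "permanova",
]


# ---------------------------------------------------------------------------
# Containers


@dataclass
class FrequencyCounts:
    """Abundance-frequency summary behind the richness estimators."""

    s_obs: int
    f: dict[int, int]  # F_i: number of taxa seen exactly i times
    n: int
    rare_cutoff: int
    n_rare: int
    s_rare: int
    s_abund: int

    @property
    def c_ace(self) -> float:
        f1 = self.f.get(1, 0)
        return 1.0 - f1 / self.n_rare if self.n_rare > 0 else np.nan


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_permutations: int | None = None
    seed: int | None = None


def _clean_counts(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    if x.sum() <= 0:
        raise ValueError("counts must have positive total")
    return x


# ---------------------------------------------------------------------------
# Alpha diversity


def frequency_counts(counts, rare_cutoff: int = 10) -> FrequencyCounts:
    x = np.asarray(counts)
    if not np.allclose(x, np.round(x)):
        raise ValueError("richness estimators need integer counts")
    x = np.round(x).astype(int)
    x = x[x > 0]
    vals, freq = np.unique(x, return_counts=True)
    f = dict(zip(vals.tolist(), freq.tolist()))
    rare = x[x <= rare_cutoff]
    return FrequencyCounts(
        s_obs=int(x.size), f=f, n=int(x.sum()), rare_cutoff=rare_cutoff,
        n_rare=int(rare.sum()), s_rare=int(rare.size),
        s_abund=int((x > rare_cutoff).sum()))


def shannon(counts) -> float:
    """H = -sum p_i ln p_i over taxa with p_i > 0."""
    x = _clean_counts(counts)
    p = x[x > 0] / x.sum()
    return float(-(p * np.log(p)).sum())


def simpson_indices(counts) -> tuple[float, float]:
    """(Simpson D = 1 - sum p_i^2, inverse Simpson = 1 / sum p_i^2)."""
    x = _clean_counts(counts)
    p = x / x.sum()
    ss = float((p ** 2).sum())
    return 1.0 - ss, 1.0 / ss


def chao1(counts) -> float:
    """Classic Chao1: S_obs + F1^2/(2 F2); S_obs + F1(F1-1)/2 when F2 = 0."""
    fc = frequency_counts(counts)
    f1 = fc.f.get(1, 0)
    f2 = fc.f.get(2, 0)
    if f2 > 0:
        return fc.s_obs + f1 * f1 / (2.0 * f2)
    return fc.s_obs + f1 * (f1 - 1) / 2.0


def ace(counts, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator.

    ACE = S_abund + S_rare / C_ace + (F1 / C_ace) * gamma^2 with
    gamma^2 = max(S_rare/C_ace * sum i(i-1)F_i / (N_rare (N_rare - 1)) - 1, 0).
    When every rare individual is a singleton (C_ace = 0) the estimator is
    undefined and Chao1 is returned with a warning.
    """
    fc = frequency_counts(counts, rare_cutoff)
    if fc.s_rare == 0:
        return float(fc.s_obs)
    c = fc.c_ace
    if not np.isfinite(c) or c == 0:
        warnings.warn("ACE undefined (all rare individuals are singletons); "
                      "falling back to Chao1", stacklevel=2)
        return chao1(counts)
    f1 = fc.f.get(1, 0)
    ssum = sum(i * (i - 1) * fi for i, fi in fc.f.items() if i <= rare_cutoff)
    if fc.n_rare > 1:
        gamma2 = max(fc.s_rare / c * ssum / (fc.n_rare * (fc.n_rare - 1)) - 1.0,
                     0.0)
    else:
        gamma2 = 0.0
    return float(fc.s_abund + fc.s_rare / c + f1 / c * gamma2)


def alpha_diversity_table(counts: pd.DataFrame) -> pd.DataFrame:
    """All alpha indices for every sample of a taxa-by-samples count table."""
    rows = {}
    for sample in counts.columns:
        x = counts[sample].to_numpy()
        if x.sum() <= 0:
            rows[sample] = dict.fromkeys(
                ["ace", "chao1", "shannon", "simpson", "inv_simpson",
                 "observed"], np.nan)
            continue
        d, inv = simpson_indices(x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = ace(x)
        rows[sample] = {
            "observed": float((x > 0).sum()), "ace": a, "chao1": chao1(x),
            "shannon": shannon(x), "simpson": d, "inv_simpson": inv}
    return pd.DataFrame(rows).T[["observed", "ace", "chao1", "shannon",
                                 "simpson", "inv_simpson"]]


# ---------------------------------------------------------------------------
# Beta diversity


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between samples (columns of the table):
    BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i)."""
    x = table.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    samples = list(table.columns)
    n = len(samples)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            num = np.abs(x[:, i] - x[:, j]).sum()
            den = (x[:, i] + x[:, j]).sum()
            if den == 0:
                warnings.warn(f"Bray-Curtis undefined for all-zero pair "
                              f"({samples[i]}, {samples[j]})", stacklevel=2)
                d[i, j] = d[j, i] = np.nan
            else:
                d[i, j] = d[j, i] = num / den
    return pd.DataFrame(d, index=samples, columns=samples)


def spearman_dissimilarity(table: pd.DataFrame) -> pd.DataFrame:
    """d = (1 - rho)/2 with rho the Spearman rank correlation of two
    samples' taxon abundance vectors; 0 for identical rank order, 1 for
    exactly reversed ranks."""
    if table.shape[0] < 2:
        raise ValueError("need at least two taxa for rank correlation")
    x = table.to_numpy(dtype=float)
    samples = list(table.columns)
    n = len(samples)
    const = [i for i in range(n) if np.ptp(x[:, i]) == 0]
    if const:
        warnings.warn(f"constant abundance vector(s) {[samples[i] for i in const]}: "
                      "Spearman dissimilarity undefined there", stacklevel=2)
    rho = stats.spearmanr(x).statistic
    if np.isscalar(rho):  # two samples
        rho = np.array([[1.0, rho], [rho, 1.0]])
    d = (1.0 - rho) / 2.0
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=samples, columns=samples)


def pcoa(dm: pd.DataFrame | np.ndarray, n_axes: int | None = None,
         ) -> OrdinationResult:
    """Classical scaling (principal coordinate analysis).

    Double-centres -D^2/2, eigendecomposes, and keeps axes with positive
    eigenvalues; coordinates are eigenvectors scaled by sqrt(eigenvalue).
    For a Euclidean distance matrix the retained space reproduces the
    distances exactly.
    """
    if isinstance(dm, pd.DataFrame):
        labels = list(dm.index)
        d = dm.to_numpy(dtype=float)
    else:
        d = np.asarray(dm, dtype=float)
        labels = list(range(d.shape[0]))
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    tol = max(abs(evals[0]), 1.0) * 1e-12 if n else 0.0
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    if n_axes is not None:
        coords = coords[:, :n_axes]
    pos_sum = evals[pos].sum()
    prop = (evals / pos_sum if pos_sum > 0 else np.zeros_like(evals))
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=labels, columns=cols),
        eigenvalues=evals, proportion_explained=prop)


# ---------------------------------------------------------------------------
# Group tests


def _mw_u(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic for sample a: number of (a_i, b_j) pairs with a_i > b_j,
    counting ties as 1/2."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def _mw_exact_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by full enumeration of all group
    assignments of the pooled values (ties handled by the permutation
    distribution of U)."""
    pooled = np.concatenate([a, b])
    n1 = a.size
    u_obs = _mw_u(a, b)
    idx = range(pooled.size)
    us = []
    for comb in combinations(idx, n1):
        mask = np.zeros(pooled.size, bool)
        mask[list(comb)] = True
        us.append(_mw_u(pooled[mask], pooled[~mask]))
    us = np.asarray(us)
    eps = 1e-9
    lo = (us <= u_obs + eps).mean()
    hi = (us >= u_obs - eps).mean()
    return u_obs, min(1.0, 2.0 * min(lo, hi))


def _mw_asymptotic_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Normal approximation with tie correction."""
    n1, n2 = a.size, b.size
    n = n1 + n2
    u = _mw_u(a, b)
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([a, b])
    _, t = np.unique(pooled, return_counts=True)
    tie = (t ** 3 - t).sum() / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * (n + 1 - tie)
    if var <= 0:
        return u, 1.0
    z = abs(u - mu) / np.sqrt(var)
    return u, float(min(1.0, 2.0 * stats.norm.sf(z)))


def group_compare(values, metadata: pd.DataFrame, method: str = "mann_whitney",
                  exact_max_n: int = 12) -> TestResult:
    """Compare a per-sample quantity between groups.

    ``mann_whitney`` (two groups) uses exact enumeration when the combined
    sample size is at most ``exact_max_n`` and the tie-corrected normal
    approximation otherwise; ``anova`` is the one-way fixed-effects F test
    for two or more groups.
    """
    values = pd.Series(values)
    meta = metadata.set_index("sample_id")["group"]
    groups = {}
    for g in sorted(meta.loc[list(values.index)].unique()):
        sel = [s for s in values.index if meta[s] == g]
        groups[g] = values.loc[sel].to_numpy(dtype=float)
    if any(len(v) == 0 for v in groups.values()) or not groups:
        raise ValueError("every group needs at least one observation")
    if method == "mann_whitney":
        if len(groups) != 2:
            raise ValueError("mann_whitney requires exactly two groups")
        a, b = groups.values()
        if a.size + b.size <= exact_max_n:
            u, p = _mw_exact_p(a, b)
            name = "mann_whitney_exact"
        else:
            u, p = _mw_asymptotic_p(a, b)
            name = "mann_whitney_normal"
        return TestResult(statistic=u, p_value=p, method=name)
    if method == "anova":
        if len(groups) < 2:
            raise ValueError("anova requires at least two groups")
        arrays = list(groups.values())
        if np.ptp(np.concatenate(arrays)) == 0:
            return TestResult(statistic=0.0, p_value=1.0, method="anova")
        means = [x.mean() for x in arrays]
        if np.ptp(means) == 0:
            return TestResult(statistic=0.0, p_value=1.0, method="anova")
        res = stats.f_oneway(*arrays)
        return TestResult(statistic=float(res.statistic),
                          p_value=float(res.pvalue), method="anova")
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# PERMANOVA


def _permanova_ss(d2: np.ndarray, labels: np.ndarray,
                  groups: np.ndarray) -> tuple[float, float]:
    n = d2.shape[0]
    ss_t = d2[np.triu_indices(n, 1)].sum() / n
    ss_w = 0.0
    for g in groups:
        idx = np.nonzero(labels == g)[0]
        sub = d2[np.ix_(idx, idx)]
        ss_w += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    return ss_t, ss_w


def permanova(dm: pd.DataFrame, metadata: pd.DataFrame,
              n_permutations: int = 999, seed: int = 0) -> TestResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Pseudo-F = (SS_between/(a-1)) / (SS_within/(N-a)) from the squared-
    distance partition (equivalent to the trace of the Gower-centred
    matrix); the p-value is the add-one permutation estimator
    (1 + #{F_perm >= F_obs}) / (1 + n_permutations) over random label
    permutations drawn with the given seed.
    """
    meta = metadata.set_index("sample_id")["group"]
    samples = list(dm.index)
    labels = meta.loc[samples].to_numpy()
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    sizes = pd.Series(labels).value_counts()
    if (sizes < 2).any():
        raise ValueError("every group needs at least two samples")
    d = dm.to_numpy(dtype=float)
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    d2 = d ** 2
    n = d2.shape[0]
    a = groups.size
    ss_t, ss_w = _permanova_ss(d2, labels, groups)
    ss_b = ss_t - ss_w
    f_obs = (ss_b / (a - 1)) / (ss_w / (n - a)) if ss_w > 0 else np.inf

    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_permutations, n)), axis=1)
    perm_labels = labels[perms]  # (B, n)
    # vectorised within-group SS over all permutations
    ss_w_perm = np.zeros(n_permutations)
    for g in groups:
        z = (perm_labels == g).astype(float)  # (B, n)
        ng = z.sum(axis=1)
        quad = np.einsum("bi,ij,bj->b", z, d2, z) / 2.0
        ss_w_perm += quad / ng
    ss_b_perm = ss_t - ss_w_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = (ss_b_perm / (a - 1)) / (ss_w_perm / (n - a))
    f_perm = np.where(ss_w_perm > 0, f_perm, np.inf)
    hits = int((f_perm >= f_obs - 1e-12).sum())
    p = (1 + hits) / (1 + n_permutations)
    return TestResult(statistic=float(f_obs), p_value=float(p),
                      method="permanova", n_permutations=n_permutations,
                      seed=seed)
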