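"""Distance-matrix inference: PERMANOVA with individual-identity strata,
multivariate dispersion contrast (betadisper-style), and the Mantel test.

The paired design makes samples non-independent: the PERMANOVA null is built
by shuffling region labels only *within* an individual (strata).  For the
study layout -- a handful of individuals sampled in both regions plus
singletons -- the strata-respecting permutation space is tiny and is
enumerated completely instead of sampled.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .beta_diversity import DistanceMatrix, gower_eigensystem
from .core_tables import SampleMetadata

__all__ = [
    "PermutationSet", "strata_permutations",
    "PermanovaResult", "permanova",
    "DispersionResult", "dispersion_test",
    "MantelResult", "mantel_test",
    "write_community_table",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# strata-constrained label permutations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PermutationSet:
    """Label permutations; ``exhaustive`` marks complete enumeration."""

    labels: np.ndarray        # (k, n) permuted label vectors
    exhaustive: bool
    n_distinct: int


def _count_distinct(labels: np.ndarray, strata: np.ndarray) -> int:
    total = 1
    for s in np.unique(strata):
        sub = labels[strata == s]
        n = sub.size
        c = math.factorial(n)
        for _, cnt in zip(*np.unique(sub, return_counts=True)):
            c //= math.factorial(int(cnt))
        total *= c
    return total


def _label_permutations(labels, strata, n_perm: int, seed,
                        force_monte_carlo: bool = False) -> PermutationSet:
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    n = labels.size
    if strata is None:
        strata = np.zeros(n, dtype=int)
    else:
        strata = np.asarray(strata)
        if strata.size != n:
            raise ValueError("strata must align with labels")
    n_distinct = _count_distinct(labels, strata)
    stratum_ids = np.unique(strata)
    idx_by_stratum = [np.flatnonzero(strata == s) for s in stratum_ids]
    if n_distinct <= n_perm and not force_monte_carlo:
        per_stratum = [sorted(set(itertools.permutations(labels[idx])))
                       for idx in idx_by_stratum]
        out = np.empty((n_distinct, n), dtype=labels.dtype)
        for k, combo in enumerate(itertools.product(*per_stratum)):
            row = np.empty(n, dtype=labels.dtype)
            for idx, arrangement in zip(idx_by_stratum, combo):
                row[idx] = arrangement
            out[k] = row
        return PermutationSet(out, exhaustive=True, n_distinct=n_distinct)
    rng = np.random.default_rng(seed)
    out = np.tile(labels, (n_perm, 1))
    for idx in idx_by_stratum:
        if idx.size < 2:
            continue
        block = out[:, idx]
        rng.permuted(block, axis=1, out=block)
        out[:, idx] = block
    return PermutationSet(out, exhaustive=False, n_distinct=n_distinct)


def strata_permutations(meta: SampleMetadata, n_perm: int,
                        seed) -> PermutationSet:
    """Region-label permutations constrained to shuffle within individuals.

    When the number of distinct strata-respecting permutations does not
    exceed `n_perm`, the whole space is enumerated (``exhaustive=True``,
    identity included); otherwise `n_perm` within-stratum shuffles are drawn.
    """
    region = meta.df["region"].to_numpy()
    individual = meta.df["individual_id"].to_numpy()
    return _label_permutations(region, individual, n_perm, seed)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PermanovaResult:
    """Distance-based one-factor ANOVA (adonis-style) with permutation p."""

    df_effect: int
    df_residual: int
    ss_effect: float
    ss_within: float
    ss_total: float
    ms_effect: float
    ms_within: float
    pseudo_f: float
    r2: float
    p: float
    n_permutations_used: int
    exhaustive: bool


def _ss_within_batch(D2: np.ndarray, label_rows: np.ndarray,
                     levels) -> np.ndarray:
    """SS_within for each row of permuted labels (vectorised over rows)."""
    ssw = np.zeros(label_rows.shape[0])
    for lv in levels:
        M = (label_rows == lv).astype(float)          # (k, n)
        n_g = M.sum(axis=1)
        within = np.einsum("ki,ij,kj->k", M, D2, M)   # counts each pair twice
        ssw += within / (2.0 * n_g)
    return ssw


def permanova(d: DistanceMatrix, groups, strata=None, n_perm: int = 9_999,
              seed: int = 0, method: str = "auto") -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    SS_total = sum_{i<j} d_ij^2 / n, SS_within pools within-group pair sums
    scaled by group size, pseudo-F = (SS_effect/df_e)/(SS_within/df_r).
    The p-value uses strata-respecting permutations: the Monte-Carlo
    convention (1 + exceedances)/(1 + draws), or the plain exceedance
    fraction over the complete enumeration (identity included) when the
    permutation space is exhausted.  Ties count as exceedances.
    ``method="monte-carlo"`` disables the automatic exhaustive enumeration.
    """
    if method not in ("auto", "monte-carlo"):
        raise ValueError("method must be 'auto' or 'monte-carlo'")
    groups = _align_groups(d, groups)
    strata_arr = None if strata is None else np.asarray(strata)
    levels, counts = np.unique(groups, return_counts=True)
    if levels.size < 2:
        raise ValueError("need at least 2 groups")
    n = d.n
    D2 = d.data ** 2
    sst = D2[np.triu_indices(n, k=1)].sum() / n
    ssw = float(_ss_within_batch(D2, groups[None, :], levels)[0])
    ssa = sst - ssw
    df_e = levels.size - 1
    df_r = n - levels.size
    ms_e = ssa / df_e
    ms_w = ssw / df_r
    f_obs = ms_e / ms_w
    perms = _label_permutations(groups, strata_arr, n_perm, seed,
                                force_monte_carlo=(method == "monte-carlo"))
    ssw_perm = _ss_within_batch(D2, perms.labels, levels)
    f_perm = ((sst - ssw_perm) / df_e) / (ssw_perm / df_r)
    exceed = int(np.count_nonzero(f_perm >= f_obs - _EPS))
    if perms.exhaustive:
        p = exceed / perms.labels.shape[0]
    else:
        p = (1.0 + exceed) / (1.0 + perms.labels.shape[0])
    return PermanovaResult(
        df_effect=df_e, df_residual=df_r, ss_effect=float(ssa),
        ss_within=float(ssw), ss_total=float(sst), ms_effect=float(ms_e),
        ms_within=float(ms_w), pseudo_f=float(f_obs), r2=float(ssa / sst),
        p=float(p), n_permutations_used=int(perms.labels.shape[0]),
        exhaustive=perms.exhaustive)


def _align_groups(d: DistanceMatrix, groups) -> np.ndarray:
    if isinstance(groups, pd.Series):
        missing = [s for s in d.sample_ids if s not in groups.index]
        if missing:
            raise KeyError(f"samples without a group label: {missing}")
        return groups.loc[list(d.sample_ids)].to_numpy()
    groups = np.asarray(groups)
    if groups.size != d.n:
        raise ValueError("groups must align with the distance matrix")
    return groups


# ---------------------------------------------------------------------------
# multivariate dispersion (betadisper-style)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DispersionResult:
    """Distances to own-group centroid and their one-way ANOVA contrast."""

    distances: pd.Series
    group_means: dict
    F: float
    df_num: int
    df_den: int
    p: float


def dispersion_test(d: DistanceMatrix, groups) -> DispersionResult:
    """Compare groups' average distance to their multivariate centroid.

    Samples are embedded by classical scaling keeping negative-eigenvalue
    axes as imaginary coordinates: the squared distance to the own-group
    centroid is the positive-axis sum minus the negative-axis sum, floored
    at zero.  F and p come from a parametric one-way ANOVA on the distances.
    """
    groups = _align_groups(d, groups)
    levels, counts = np.unique(groups, return_counts=True)
    if levels.size < 2:
        raise ValueError("need at least 2 groups")
    if np.any(counts < 2):
        small = levels[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    vals, vecs = gower_eigensystem(d)
    scale = max(float(np.abs(vals).max()), 1.0)
    keep = np.abs(vals) > 1e-10 * scale
    vals, vecs = vals[keep], vecs[:, keep]
    axes = vecs * np.sqrt(np.abs(vals))
    sign = np.where(vals > 0, 1.0, -1.0)
    sq = np.zeros(d.n)
    for lv in levels:
        mask = groups == lv
        centroid = axes[mask].mean(axis=0)
        delta2 = (axes[mask] - centroid) ** 2
        sq[mask] = delta2 @ sign
    dist = np.sqrt(np.maximum(sq, 0.0))
    by_group = [dist[groups == lv] for lv in levels]
    F, p = stats.f_oneway(*by_group)
    return DispersionResult(
        distances=pd.Series(dist, index=list(d.sample_ids), name="centroid_distance"),
        group_means={str(lv): float(v.mean()) for lv, v in zip(levels, by_group)},
        F=float(F), df_num=levels.size - 1, df_den=d.n - levels.size,
        p=float(p))


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_permutations_used: int
    alternative: str


def mantel_test(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 9_999,
                seed: int = 0, alternative: str = "greater") -> MantelResult:
    """Pearson correlation between two distance matrices, permutation p.

    The correlation is computed on the strictly-lower-triangle entries; the
    null jointly permutes the second matrix's rows and columns.
    """
    if d1.sample_ids != d2.sample_ids:
        raise ValueError("distance matrices must share sample ids and order")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError("alternative must be greater/less/two-sided")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = d1.n
    iu = np.tril_indices(n, k=-1)
    v1 = d1.data[iu]
    v2 = d2.data[iu]
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("a distance matrix is constant; r undefined")
    r_obs = float(np.corrcoef(v1, v2)[0, 1])
    rng = np.random.default_rng(seed)
    r_perm = np.empty(n_perm)
    for k in range(n_perm):
        idx = rng.permutation(n)
        r_perm[k] = np.corrcoef(v1, d2.data[np.ix_(idx, idx)][iu])[0, 1]
    if alternative == "greater":
        exceed = np.count_nonzero(r_perm >= r_obs - _EPS)
    elif alternative == "less":
        exceed = np.count_nonzero(r_perm <= r_obs + _EPS)
    else:
        exceed = np.count_nonzero(np.abs(r_perm) >= abs(r_obs) - _EPS)
    p = (1.0 + exceed) / (1.0 + n_perm)
    return MantelResult(r=r_obs, p=float(p), n_permutations_used=n_perm,
                        alternative=alternative)


# ---------------------------------------------------------------------------
# report writer
# ---------------------------------------------------------------------------


def write_community_table(results: dict, path) -> None:
    """Write per-metric composition + dispersion blocks as one TSV.

    `results` maps metric name -> (PermanovaResult, DispersionResult).
    """
    rows = []
    for metric, (perm, disp) in results.items():
        rows.append({
            "metric": metric, "term": "region",
            "df": perm.df_effect, "mean_sq": perm.ms_effect,
            "F": perm.pseudo_f, "R2": perm.r2, "p": perm.p,
            "dispersion_F": disp.F, "dispersion_p": disp.p})
        rows.append({
            "metric": metric, "term": "residual",
            "df": perm.df_residual, "mean_sq": perm.ms_within,
            "F": "", "R2": "", "p": "",
            "dispersion_F": "", "dispersion_p": ""})
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
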