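"""Per-sample alpha diversity and its host-level contrasts.

Three per-sample indices: observed richness, Shannon entropy (natural log)
and the bias-corrected Chao1 total-richness estimate.  The oral/faecal
contrast is tested with a likelihood-ratio test on random-intercept linear
mixed models (individual identity as the grouping factor, fitted by ML);
sex and scaled-body-mass-index effects are tested per region with one-way
ANOVA / single-slope regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_tables import CountTable, SampleMetadata, REGIONS
from .diff_abundance import lme_fit_ml
from .host_traits import body_condition

__all__ = [
    "observed_richness", "shannon", "chao1", "alpha_diversity_table",
    "LrtResult", "alpha_region_contrast",
    "CovariateAnova", "alpha_covariate_anova",
    "write_contrast_table",
]

METRICS = ("observed_richness", "shannon", "chao1")


def observed_richness(counts) -> int:
    """Number of taxa with a positive count."""
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    return int(np.count_nonzero(counts))


def shannon(counts, base: float = None) -> float:
    """Shannon entropy -sum p ln p over positive proportions (nats).

    `base` rescales to another logarithm base (e.g. 2 for bits).
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("all-zero abundance vector")
    p = counts[counts > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton/doubleton frequencies.

    Bias-corrected form S_obs + F1 (F1 - 1) / (2 (F2 + 1)), defined even
    when no doubletons exist; ``bias_corrected=False`` gives the classic
    S_obs + F1^2 / (2 F2) variant (infinite at F2 = 0 with singletons).
    Counts should be integers (rarefaction always yields integers); a
    non-integer input is rounded with a warning-free best effort.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if counts.sum() == 0:
        raise ValueError("all-zero abundance vector")
    counts = np.rint(counts)
    s_obs = float(np.count_nonzero(counts))
    f1 = float(np.count_nonzero(counts == 1))
    f2 = float(np.count_nonzero(counts == 2))
    if bias_corrected:
        return s_obs + f1 * (f1 - 1.0) / (2.0 * (f2 + 1.0))
    if f2 == 0:
        return math.inf if f1 > 0 else s_obs
    return s_obs + f1 ** 2 / (2.0 * f2)


def alpha_diversity_table(table: CountTable) -> pd.DataFrame:
    """Observed richness, Shannon (nats) and Chao1 for every sample."""
    rows = {
        sid: (observed_richness(row), shannon(row), chao1(row))
        for sid, row in zip(table.sample_ids, table.counts)
    }
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(METRICS))
    out.index.name = "sample_id"
    return out


@dataclass(frozen=True)
class LrtResult:
    """Likelihood-ratio contrast of a diversity metric between regions."""

    metric: str
    chi2: float
    df: int
    p: float
    group_stats: dict  # region -> (mean, se, n)


def _group_stats(values: pd.Series, region: np.ndarray) -> dict:
    out = {}
    for reg in REGIONS:
        v = values.to_numpy()[region == reg]
        se = v.std(ddof=1) / math.sqrt(v.size) if v.size > 1 else math.nan
        out[reg] = (float(v.mean()), float(se), int(v.size))
    return out


def alpha_region_contrast(alpha: pd.DataFrame, meta: SampleMetadata,
                          metric: str) -> LrtResult:
    """LRT for a region effect on one diversity metric.

    Fits ``metric ~ region + (1 | individual)`` and ``metric ~ 1 +
    (1 | individual)`` by ML; chi2 is the deviance difference on 1 df.
    Also reports the descriptive per-region mean +/- SE.
    """
    if metric not in alpha.columns:
        raise KeyError(f"unknown metric {metric!r}")
    values = alpha[metric]
    sample_ids = list(alpha.index)
    region = meta.region_of(sample_ids)
    individual = meta.individual_of(sample_ids)
    for reg in REGIONS:
        if np.sum(region == reg) < 2:
            raise ValueError(f"need >= 2 samples in region {reg!r}")
    y = values.to_numpy(dtype=float)
    full = lme_fit_ml(y, region=region, individual=individual)
    null = lme_fit_ml(y, region=None, individual=individual)
    chi2 = max(0.0, null.deviance - full.deviance)
    p = float(stats.chi2.sf(chi2, df=1))
    return LrtResult(metric=metric, chi2=float(chi2), df=1, p=p,
                     group_stats=_group_stats(values, region))


@dataclass(frozen=True)
class CovariateAnova:
    metric: str
    covariate: str
    region: str
    F: float
    df_num: int
    df_den: int
    p: float


def alpha_covariate_anova(alpha: pd.DataFrame, meta: SampleMetadata,
                          covariate: str, metric: str,
                          region: str) -> CovariateAnova:
    """Test sex (one-way ANOVA) or SMI (single-slope regression) per region.

    Samples with a missing covariate are excluded; with sex, both sexes must
    be present in the region.
    """
    if covariate not in ("sex", "smi"):
        raise ValueError("covariate must be 'sex' or 'smi'")
    if region not in REGIONS:
        raise ValueError(f"region must be one of {REGIONS}")
    if metric not in alpha.columns:
        raise KeyError(f"unknown metric {metric!r}")
    sample_ids = [s for s in alpha.index
                  if meta.df.loc[s, "region"] == region]
    y = alpha.loc[sample_ids, metric].to_numpy(dtype=float)
    if covariate == "sex":
        sex = meta.df.loc[sample_ids, "sex"].to_numpy()
        keep = sex != "unknown"
        y, sex = y[keep], sex[keep]
        levels = sorted(set(sex))
        if len(levels) < 2:
            raise ValueError(f"only one sex present in region {region!r}")
        groups = [y[sex == lv] for lv in levels]
        F, p = stats.f_oneway(*groups)
        df_num, df_den = len(levels) - 1, y.size - len(levels)
    else:
        smi = body_condition(meta)["smi"]
        ok = [s for s in sample_ids if s in smi.index]
        if len(ok) < 4:
            raise ValueError("need >= 4 samples with SMI for the regression")
        y = alpha.loc[ok, metric].to_numpy(dtype=float)
        x = smi.loc[ok].to_numpy(dtype=float)
        res = stats.linregress(x, y)
        df_num, df_den = 1, len(ok) - 2
        F = res.rvalue ** 2 * df_den / max(1.0 - res.rvalue ** 2, 1e-300)
        p = res.pvalue
    return CovariateAnova(metric=metric, covariate=covariate, region=region,
                          F=float(F), df_num=df_num, df_den=df_den,
                          p=float(p))


def write_contrast_table(results, path) -> None:
    """Write LRT contrasts as a table: metric, per-region mean +/- SE, chi2, p."""
    rows = []
    for r in results:
        oral_m, oral_se, _ = r.group_stats["oral"]
        fae_m, fae_se, _ = r.group_stats["faecal"]
        rows.append({"metric": r.metric,
                     "oral_mean": oral_m, "oral_se": oral_se,
                     "faecal_mean": fae_m, "faecal_se": fae_se,
                     "chi2": r.chi2, "p": r.p})
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
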