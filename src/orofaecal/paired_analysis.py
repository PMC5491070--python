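"""Within-individual oral/faecal concordance.

For the individuals sampled in both regions: Pearson correlation of paired
alpha-diversity values, Mantel comparison of the two within-region distance
sub-matrices, and per-OTU Spearman correlations of relative abundances on
the OTUs detected in both regions of the paired subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .beta_diversity import DistanceMatrix
from .community_tests import MantelResult, mantel_test
from .core_tables import CountTable, SampleMetadata

__all__ = [
    "PairedSet", "paired_subset", "paired_alpha_pearson",
    "paired_otu_spearman", "paired_composition_mantel",
]


@dataclass(frozen=True)
class PairedSet:
    """(individual, oral sample, faecal sample) triples, one per individual."""

    pairs: tuple  # of (individual_id, oral_sample_id, faecal_sample_id)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def individual_ids(self) -> list:
        return [p[0] for p in self.pairs]

    @property
    def oral_ids(self) -> list:
        return [p[1] for p in self.pairs]

    @property
    def faecal_ids(self) -> list:
        return [p[2] for p in self.pairs]


def paired_subset(meta: SampleMetadata) -> PairedSet:
    """All individuals with exactly one sample in each region."""
    df = meta.df
    pairs = []
    for ind, sub in df.groupby("individual_id", sort=True):
        regions = dict(zip(sub["region"], sub.index))
        if "oral" in regions and "faecal" in regions:
            pairs.append((ind, regions["oral"], regions["faecal"]))
    if not pairs:
        raise ValueError("no individual has samples from both regions")
    return PairedSet(tuple(pairs))


def paired_alpha_pearson(alpha: pd.DataFrame, pairs: PairedSet,
                         metric: str) -> tuple:
    """Pearson r (and two-sided p) between paired oral and faecal diversity."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 paired individuals")
    if metric not in alpha.columns:
        raise KeyError(f"unknown metric {metric!r}")
    oral = alpha.loc[pairs.oral_ids, metric].to_numpy(dtype=float)
    faecal = alpha.loc[pairs.faecal_ids, metric].to_numpy(dtype=float)
    r, p = stats.pearsonr(oral, faecal)
    return float(r), float(p)


def paired_otu_spearman(table: CountTable, pairs: PairedSet) -> pd.DataFrame:
    """Per-OTU Spearman rho of relative abundances across paired individuals.

    Restricted to OTUs with a non-zero count in at least one oral and one
    faecal sample of the paired subset.  Ranks use average tie handling; an
    OTU whose oral or faecal vector has fewer than 3 distinct values gets a
    missing rho.  The result's ``attrs`` carry the mean and interquartile
    range of the defined rhos.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 paired individuals")
    oral = table.select_samples(pairs.oral_ids)
    faecal = table.select_samples(pairs.faecal_ids)
    p_oral = oral.relative_abundance()
    p_faecal = faecal.relative_abundance()
    in_oral = (oral.counts > 0).any(axis=0)
    in_faecal = (faecal.counts > 0).any(axis=0)
    keep = in_oral & in_faecal
    if not np.any(keep):
        raise ValueError("no OTU is present in both regions of the paired set")
    rows = []
    for j in np.flatnonzero(keep):
        x, y = p_oral[:, j], p_faecal[:, j]
        if np.unique(x).size < 3 or np.unique(y).size < 3:
            rho = np.nan
        else:
            rho = stats.spearmanr(x, y).statistic
        rows.append({"otu_id": table.otu_ids[j], "rho": rho})
    out = pd.DataFrame(rows).set_index("otu_id")
    defined = out["rho"].dropna().to_numpy()
    out.attrs["n_otus"] = int(keep.sum())
    out.attrs["mean_rho"] = float(defined.mean()) if defined.size else np.nan
    if defined.size:
        q1, q3 = np.percentile(defined, [25, 75])
        out.attrs["iqr"] = (float(q1), float(q3))
    else:
        out.attrs["iqr"] = (np.nan, np.nan)
    return out


def paired_composition_mantel(d: DistanceMatrix, pairs: PairedSet,
                              n_perm: int = 9_999, seed: int = 0,
                              alternative: str = "greater") -> MantelResult:
    """Mantel test between the oral and faecal sub-matrices of paired birds.

    Both sub-matrices are ordered by individual, then relabelled by
    individual id so that entry (i, j) compares the same two individuals in
    each region.
    """
    if len(pairs) < 4:
        raise ValueError("need at least 4 paired individuals for a Mantel test")
    ids = pairs.individual_ids
    d_oral = DistanceMatrix(tuple(ids), d.subset(pairs.oral_ids).data)
    d_faecal = DistanceMatrix(tuple(ids), d.subset(pairs.faecal_ids).data)
    return mantel_test(d_oral, d_faecal, n_perm=n_perm, seed=seed,
                       alternative=alternative)
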