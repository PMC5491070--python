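"""Data containers and table-level operations for paired body-site OTU surveys.

The central object is :class:`CountTable`, an integer samples x OTUs abundance
matrix.  Around it sit a six-rank :class:`TaxonomyTable`, per-sample
:class:`SampleMetadata` for a two-region (oral vs. faecal) design with
individual identity, and a rooted :class:`PhyloTree` over OTUs.

All operations are pure functions: inputs are never modified, new objects are
returned.  On disk, count tables follow the common amplicon convention of
OTUs as rows and samples as columns; in memory the matrix is samples x OTUs.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
REGIONS = ("oral", "faecal")
SEXES = ("M", "F", "unknown")

#: class/order labels treated as plant-derived contamination (diet material).
#: The reference 16S taxonomies place chloroplast sequences as a class within
#: Cyanobacteria; some dialects use the order label "Streptophyta" instead.
CONTAMINANT_LABELS = frozenset({"chloroplast", "streptophyta"})

#: phylum labels treated as "not assigned to any bacterial phylum"
UNASSIGNED_LABELS = frozenset({"", "unassigned", "unclassified", "na", "none"})


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dupes = set(), []
        for i in ids:
            if i in seen:
                dupes.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what}: {sorted(set(dupes))}")


@dataclass(frozen=True)
class CountTable:
    """Integer abundance matrix (samples x OTUs) with row/column identifiers.

    Invariants enforced at construction: unique sample and OTU ids, all
    counts >= 0, and every sample (row) has at least one read.  The count
    matrix is stored read-only so that shared references cannot be mutated.
    """

    sample_ids: tuple
    otu_ids: tuple
    counts: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "otu_ids", tuple(str(o) for o in self.otu_ids))
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.otu_ids, "OTU ids")
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded, atol=1e-9):
                raise ValueError("counts must be integers")
            counts = rounded
        counts = counts.astype(np.int64, copy=True)
        rs = counts.sum(axis=1)
        if np.any(rs == 0):
            empty = [self.sample_ids[i] for i in np.flatnonzero(rs == 0)]
            raise ValueError(f"samples with zero total counts: {empty}")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def presence(self) -> np.ndarray:
        """Boolean samples x OTUs presence matrix."""
        return self.counts > 0

    def relative_abundance(self) -> np.ndarray:
        """Row-normalised proportions (float matrix, rows sum to 1)."""
        return self.counts / self.sample_sums()[:, None]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id}") from None

    def otu_vector(self, otu_id: str) -> np.ndarray:
        try:
            j = self.otu_ids.index(otu_id)
        except ValueError:
            raise KeyError(f"unknown OTU id: {otu_id}") from None
        return self.counts[:, j].copy()

    # -- subsetting --------------------------------------------------------

    def select_otus(self, otu_ids) -> "CountTable":
        otu_ids = list(otu_ids)
        pos = {o: j for j, o in enumerate(self.otu_ids)}
        missing = [o for o in otu_ids if o not in pos]
        if missing:
            raise KeyError(f"unknown OTU ids: {missing}")
        cols = [pos[o] for o in otu_ids]
        return CountTable(self.sample_ids, tuple(otu_ids), self.counts[:, cols])

    def select_samples(self, sample_ids) -> "CountTable":
        sample_ids = list(sample_ids)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        rows = [pos[s] for s in sample_ids]
        return CountTable(tuple(sample_ids), self.otu_ids, self.counts[rows])

    # -- I/O ---------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts.copy(), index=list(self.sample_ids),
                            columns=list(self.otu_ids))

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        """Read a tab-separated OTU table (OTUs as rows, samples as columns).

        The BIOM-TSV dialect, whose header line starts with ``#OTU ID``, is
        tolerated; a leading ``# Constructed from ...`` comment line is
        skipped.
        """
        text = Path(path).read_text(encoding="utf-8")
        lines = text.splitlines()
        if lines and lines[0].startswith("#") and not lines[0].lstrip("#").lstrip().lower().startswith("otu"):
            lines = lines[1:]
        df = pd.read_csv(io.StringIO("\n".join(lines)), sep="\t", index_col=0)
        counts = df.to_numpy().T
        return cls(tuple(df.columns), tuple(df.index.astype(str)), counts)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.counts.T, index=list(self.otu_ids),
                          columns=list(self.sample_ids))
        df.index.name = "otu_id"
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            df.to_csv(fh, sep="\t")


@dataclass(frozen=True)
class TaxonomyTable:
    """OTU -> (kingdom, phylum, class, order, family, genus) assignments.

    Empty strings mark unassigned ranks.  Rank labels are plain strings with
    no prefix convention imposed.
    """

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df.copy()
        if df.index.name is None:
            df.index.name = "otu_id"
        df.index = df.index.astype(str)
        _check_unique(list(df.index), "taxonomy OTU ids")
        missing = [r for r in RANKS if r not in df.columns]
        if missing:
            raise ValueError(f"taxonomy missing rank columns: {missing}")
        df = df.loc[:, list(RANKS)].fillna("").astype(str)
        object.__setattr__(self, "df", df)

    def ranks_for(self, otu_id: str) -> dict:
        if otu_id not in self.df.index:
            raise KeyError(f"no taxonomy row for OTU {otu_id!r}")
        return dict(self.df.loc[otu_id])

    def lineage(self, otu_id: str, sep: str = "; ") -> str:
        r = self.ranks_for(otu_id)
        return sep.join(v for v in r.values() if v)

    def check_covers(self, table: CountTable) -> None:
        missing = [o for o in table.otu_ids if o not in self.df.index]
        if missing:
            raise KeyError(f"OTUs without taxonomy rows: {missing[:10]}"
                           + ("..." if len(missing) > 10 else ""))

    @classmethod
    def from_tsv(cls, path) -> "TaxonomyTable":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
        df.columns = [c.lower() for c in df.columns]
        return cls(df)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            self.df.to_csv(fh, sep="\t")


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample design information for the two-region paired layout.

    Columns: ``sample_id`` (index), ``individual_id``, ``region`` in
    {oral, faecal}, ``sex`` in {M, F, unknown}, ``body_mass`` (g, NaN when
    missing) and ``tarsus`` (mm, NaN when missing).  Each individual may
    contribute at most one sample per region.
    """

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df.copy()
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        df.index = df.index.astype(str)
        df.index.name = "sample_id"
        _check_unique(list(df.index), "metadata sample ids")
        required = {"individual_id", "region"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        df["individual_id"] = df["individual_id"].astype(str)
        df["region"] = df["region"].astype(str).str.lower()
        bad = sorted(set(df["region"]) - set(REGIONS))
        if bad:
            raise ValueError(f"unknown region labels: {bad} (expected {REGIONS})")
        if "sex" not in df.columns:
            df["sex"] = "unknown"
        df["sex"] = df["sex"].astype(str).replace({"nan": "unknown", "": "unknown"})
        bad = sorted(set(df["sex"]) - set(SEXES))
        if bad:
            raise ValueError(f"unknown sex labels: {bad} (expected {SEXES})")
        for col in ("body_mass", "tarsus"):
            if col not in df.columns:
                df[col] = np.nan
            df[col] = pd.to_numeric(df[col], errors="coerce")
            if np.any(df[col].dropna() <= 0):
                raise ValueError(f"{col} must be positive where present")
        dup = df.groupby(["individual_id", "region"]).size()
        if (dup > 1).any():
            offenders = dup[dup > 1].index.tolist()
            raise ValueError(f"individuals with >1 sample in a region: {offenders}")
        object.__setattr__(self, "df", df)

    @property
    def sample_ids(self) -> tuple:
        return tuple(self.df.index)

    def region_of(self, sample_ids) -> np.ndarray:
        return self.df.loc[list(sample_ids), "region"].to_numpy()

    def individual_of(self, sample_ids) -> np.ndarray:
        return self.df.loc[list(sample_ids), "individual_id"].to_numpy()

    def subset(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.df.loc[list(sample_ids)].copy())

    @classmethod
    def from_tsv(cls, path) -> "SampleMetadata":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str,
                                                      "individual_id": str}))

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            self.df.to_csv(fh, sep="\t")


@dataclass(frozen=True)
class PhyloTree:
    """Rooted, branch-length-bearing phylogeny with OTU ids on the leaves."""

    tree: TreeNode

    def __post_init__(self):
        names = self.leaf_names()
        _check_unique(names, "tree leaf names")
        for node in self.tree.traverse(include_self=False):
            if node.length is None:
                raise ValueError("tree has a branch without a length")
            if not math.isfinite(node.length) or node.length < 0:
                raise ValueError(f"invalid branch length {node.length!r}")

    @classmethod
    def from_newick(cls, source) -> "PhyloTree":
        """Parse a newick tree; midpoint-root if the root is not bifurcating.

        UniFrac needs a root; an unrooted (trifurcating-root) newick is
        midpoint-rooted with a logged notice.
        """
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            tree = TreeNode.read(str(source), format="newick")
        else:
            tree = TreeNode.read(io.StringIO(str(source)), format="newick")
        if len(tree.children) > 2:
            logger.info("input tree is unrooted; midpoint-rooting for UniFrac")
            tree = tree.root_at_midpoint()
        if tree.length is None:
            tree.length = None  # root carries no branch
        return cls(tree)

    def leaf_names(self) -> list:
        return [t.name for t in self.tree.tips()]

    def to_newick(self, path=None):
        buf = io.StringIO()
        self.tree.write(buf, format="newick")
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    def shear(self, otu_ids) -> "PhyloTree":
        names = list(otu_ids)
        sub = self.tree.shear(names)
        sub.prune()
        return PhyloTree(sub)


# ---------------------------------------------------------------------------
# table-level operations
# ---------------------------------------------------------------------------


def _drop_empty_samples(sample_ids, otu_ids, counts) -> CountTable:
    rs = counts.sum(axis=1)
    keep = rs > 0
    if not np.all(keep):
        dropped = [sample_ids[i] for i in np.flatnonzero(~keep)]
        logger.warning("dropping samples emptied by filtering: %s", dropped)
    if not np.any(keep):
        raise ValueError("filtering removed every read in every sample")
    return CountTable(tuple(np.asarray(sample_ids)[keep]), tuple(otu_ids),
                      counts[keep])


def is_nonbacterial(tax: TaxonomyTable) -> pd.Series:
    """Boolean per-OTU flag: chloroplast/Streptophyta or unassigned phylum."""
    cls = tax.df["class"].str.strip().str.lower()
    order = tax.df["order"].str.strip().str.lower()
    phylum = tax.df["phylum"].str.strip().str.lower()
    contaminant = cls.isin(CONTAMINANT_LABELS) | order.isin(CONTAMINANT_LABELS)
    unassigned = phylum.isin(UNASSIGNED_LABELS)
    return contaminant | unassigned


def filter_nonbacterial(table: CountTable, tax: TaxonomyTable) -> CountTable:
    """Drop chloroplast/Streptophyta OTUs and OTUs with no bacterial phylum.

    These are diet contamination and sequencing artefacts, respectively.
    Samples whose read total falls to zero are dropped with a logged warning.
    Raises ``KeyError`` if any OTU in `table` lacks a taxonomy row.
    """
    tax.check_covers(table)
    flags = is_nonbacterial(tax)
    keep = [o for o in table.otu_ids if not flags.loc[o]]
    removed = table.n_otus - len(keep)
    if removed == 0:
        return table
    if not keep:
        raise ValueError("all OTUs flagged as non-bacterial")
    pos = {o: j for j, o in enumerate(table.otu_ids)}
    cols = [pos[o] for o in keep]
    counts = table.counts[:, cols]
    total = table.counts.sum()
    logger.info("filter_nonbacterial: removed %d/%d OTUs (%.2f%% of reads)",
                removed, table.n_otus, 100 * (1 - counts.sum() / total))
    return _drop_empty_samples(table.sample_ids, keep, counts)


def prevalence_filter(table: CountTable, min_samples: int) -> CountTable:
    """Keep OTUs with non-zero counts in at least `min_samples` samples."""
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if min_samples > table.n_samples:
        raise ValueError(
            f"min_samples={min_samples} exceeds the number of samples "
            f"({table.n_samples})")
    nnz = (table.counts > 0).sum(axis=0)
    keep = nnz >= min_samples
    if not np.any(keep):
        raise ValueError("no OTU passes the prevalence filter")
    counts = table.counts[:, keep]
    frac = counts.sum() / table.counts.sum()
    logger.info("prevalence_filter(>=%d samples): retained %d/%d OTUs "
                "(%.1f%% of reads)", min_samples, int(keep.sum()),
                table.n_otus, 100 * frac)
    return _drop_empty_samples(table.sample_ids,
                               [o for o, k in zip(table.otu_ids, keep) if k],
                               counts)


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample to exactly `depth` reads without replacement.

    Draws are multivariate hypergeometric per sample, so an OTU absent from a
    sample stays absent and row sums are exactly `depth`.  Deterministic for
    a given seed.
    """
    depth = int(depth)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    sums = table.sample_sums()
    shallow = [s for s, t in zip(table.sample_ids, sums) if t < depth]
    if shallow:
        raise ValueError(
            f"rarefaction depth {depth} exceeds the total reads of samples: "
            f"{shallow}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for i in range(table.n_samples):
        out[i] = rng.multivariate_hypergeometric(table.counts[i], depth)
    return CountTable(table.sample_ids, table.otu_ids, out)


@dataclass(frozen=True)
class SharedOtuSummary:
    """Counts and fractions of OTUs detected in both regions or only one."""

    n_both: int
    n_oral_only: int
    n_faecal_only: int

    @property
    def n_total(self) -> int:
        return self.n_both + self.n_oral_only + self.n_faecal_only

    @property
    def fractions(self) -> dict:
        t = self.n_total
        return {"both": self.n_both / t, "oral_only": self.n_oral_only / t,
                "faecal_only": self.n_faecal_only / t}


def shared_otu_summary(table: CountTable, meta: SampleMetadata) -> SharedOtuSummary:
    """Partition OTUs into detected-in-both / oral-only / faecal-only."""
    region = meta.region_of(table.sample_ids)
    present = table.presence()
    in_oral = present[region == "oral"].any(axis=0) if np.any(region == "oral") else None
    in_faecal = present[region == "faecal"].any(axis=0) if np.any(region == "faecal") else None
    if in_oral is None or in_faecal is None:
        raise ValueError("shared_otu_summary needs samples from both regions")
    # an OTU absent everywhere (possible after sample subsetting) is ignored
    both = int(np.sum(in_oral & in_faecal))
    oral_only = int(np.sum(in_oral & ~in_faecal))
    faecal_only = int(np.sum(~in_oral & in_faecal))
    return SharedOtuSummary(both, oral_only, faecal_only)


def taxon_rank_proportions(table: CountTable, tax: TaxonomyTable,
                           rank: str) -> pd.DataFrame:
    """Per-sample read proportions aggregated at one taxonomic rank.

    OTUs with an empty label at `rank` are pooled as ``"Unassigned"``.  Each
    row (sample) sums to 1.
    """
    if rank not in RANKS[1:]:
        raise ValueError(f"rank must be one of {RANKS[1:]}, got {rank!r}")
    tax.check_covers(table)
    labels = tax.df.loc[list(table.otu_ids), rank].replace("", "Unassigned")
    props = pd.DataFrame(table.relative_abundance(),
                         index=list(table.sample_ids),
                         columns=list(table.otu_ids))
    agg = props.T.groupby(labels.values).sum().T
    agg.index.name = "sample_id"
    return agg.loc[:, sorted(agg.columns)]
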