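"""Dirichlet-multinomial simulator for paired two-region microbiome surveys.

The generator emulates the statistical structure the downstream analyses
assume: a partially paired oral/faecal design, uneven lognormal sequencing
depth, higher oral richness (a larger pool of OTUs with non-negligible
baseline abundance), stronger faecal overdispersion (a lower Dirichlet
concentration), a known subset of region-differential OTUs, per-individual
random intercepts shared between an individual's two samples, and a sprinkle
of chloroplast / unassigned-phylum OTUs to exercise the contaminant filter.

Counts are drawn OTU-composition-first: per sample, a Dirichlet draw around
the region- and individual-specific expected composition, then a multinomial
at the sample's depth.  Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core_tables import (CountTable, PhyloTree, SampleMetadata,
                          TaxonomyTable, RANKS)

__all__ = ["SyntheticSpec", "GroundTruth", "SyntheticDataset",
           "generate_tree", "generate_dataset", "write_dataset"]

# OTU pool split mirroring the observed region overlap (34% detected in both,
# 48% oral-only, 18% faecal-only).
_POOL_SHARED, _POOL_ORAL, _POOL_FAECAL = 0.34, 0.48, 0.18
# log-scale penalty making an OTU effectively absent from the other region
_EXCLUSIVE_PENALTY = 7.0

_PHYLA = {
    "Proteobacteria": ("Gammaproteobacteria", "Alphaproteobacteria",
                       "Betaproteobacteria"),
    "Firmicutes": ("Bacilli", "Clostridia"),
    "Actinobacteria": ("Actinobacteria",),
    "Bacteroidetes": ("Flavobacteriia", "Sphingobacteriia"),
    "Tenericutes": ("Mollicutes",),
    "Deinococcus-Thermus": ("Deinococci",),
}
_PHYLUM_WEIGHTS = (0.40, 0.22, 0.18, 0.10, 0.06, 0.04)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic survey; defaults follow the study design:
    29 individuals, 8 sampled in both regions, 20 oral + 17 faecal samples,
    1127 OTUs, depths lognormal with minimum around 2000 reads."""

    n_individuals: int = 29
    n_paired: int = 8
    n_otus: int = 1127
    n_differential: int = 30
    region_log2_fold_effect: float = 2.0
    individual_sd: float = 0.6
    concentration_oral: float = 150.0
    concentration_faecal: float = 60.0
    depth_log_mean: float = math.log(6000.0)
    depth_log_sd: float = 0.4
    fraction_chloroplast: float = 0.07
    fraction_unassigned_phylum: float = 0.04
    baseline_sd: float = 1.2
    region_pools: bool = True      # False: all bacterial OTUs shared
    oral_fraction_unpaired: float = 12.0 / 21.0
    sex_effect: float = 0.0        # log-scale shift for males; 0 = null
    seed: int = 0

    def __post_init__(self):
        if self.n_paired > self.n_individuals:
            raise ValueError("n_paired cannot exceed n_individuals")
        if self.n_differential > self.n_otus:
            raise ValueError("n_differential cannot exceed n_otus")
        if self.concentration_oral <= 0 or self.concentration_faecal <= 0:
            raise ValueError("Dirichlet concentrations must be positive")
        if self.n_otus < 2 or self.n_individuals < 2:
            raise ValueError("need at least 2 OTUs and 2 individuals")
        fc = self.fraction_chloroplast + self.fraction_unassigned_phylum
        if not 0 <= fc < 0.5:
            raise ValueError("contaminant fractions must be small and >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually planted, for recovery scoring."""

    differential_effects: dict     # otu_id -> signed log2 fold (oral excess)
    contaminant_otus: tuple
    sample_regions: dict           # sample_id -> region
    sample_individuals: dict       # sample_id -> individual_id
    oral_pool: tuple
    faecal_pool: tuple
    shared_pool: tuple


@dataclass(frozen=True)
class SyntheticDataset:
    table: CountTable
    metadata: SampleMetadata
    taxonomy: TaxonomyTable
    tree: PhyloTree
    truth: GroundTruth
    spec: SyntheticSpec


def generate_tree(n_leaves: int, seed, otu_ids=None) -> PhyloTree:
    """Random rooted bifurcating tree by sequential coalescence.

    Clusters are merged two at a time in random order; each child branch
    gets an Exponential(1) length.  A tree over n leaves therefore has
    exactly n - 1 internal nodes and 2n - 2 branches.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    if otu_ids is None:
        otu_ids = [f"OTU_{k + 1:05d}" for k in range(n_leaves)]
    else:
        otu_ids = [str(o) for o in otu_ids]
        if len(otu_ids) != n_leaves:
            raise ValueError("otu_ids length must equal n_leaves")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=name) for name in otu_ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        left.length = float(rng.exponential(1.0))
        right.length = float(rng.exponential(1.0))
        nodes.append(TreeNode(children=[left, right]))
    root = nodes[0]
    root.length = None
    return PhyloTree(root)


def _design_samples(spec: SyntheticSpec):
    """Assign individuals to paired / oral-only / faecal-only roles.

    The unpaired individuals are split oral-heavy (12:9 for the default 21)
    to reproduce the 20 oral / 17 faecal sample layout.
    """
    individuals = [f"bird{k + 1:02d}" for k in range(spec.n_individuals)]
    paired = individuals[:spec.n_paired]
    rest = individuals[spec.n_paired:]
    n_oral_only = int(round(len(rest) * spec.oral_fraction_unpaired)) if rest else 0
    oral_only = rest[:n_oral_only]
    faecal_only = rest[n_oral_only:]
    samples = []  # (sample_id, individual, region)
    for ind in paired + oral_only:
        samples.append((f"{ind}_oral", ind, "oral"))
    for ind in paired + faecal_only:
        samples.append((f"{ind}_faecal", ind, "faecal"))
    return individuals, samples


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one complete synthetic survey from `spec`."""
    rng = np.random.default_rng(spec.seed)
    individuals, samples = _design_samples(spec)
    otu_ids = [f"OTU_{k + 1:05d}" for k in range(spec.n_otus)]

    # --- contaminant assignment -----------------------------------------
    n_chloro = int(round(spec.fraction_chloroplast * spec.n_otus))
    n_unass = int(round(spec.fraction_unassigned_phylum * spec.n_otus))
    contaminant_idx = rng.choice(spec.n_otus, size=n_chloro + n_unass,
                                 replace=False)
    chloro_idx = set(contaminant_idx[:n_chloro].tolist())
    unass_idx = set(contaminant_idx[n_chloro:].tolist())
    bacterial_idx = [k for k in range(spec.n_otus)
                     if k not in chloro_idx and k not in unass_idx]

    # --- region pools over the bacterial OTUs ---------------------------
    pool_draw = rng.random(spec.n_otus)
    pool = np.full(spec.n_otus, "shared", dtype=object)
    if spec.region_pools:
        pool[pool_draw < _POOL_ORAL] = "oral"
        pool[(pool_draw >= _POOL_ORAL)
             & (pool_draw < _POOL_ORAL + _POOL_FAECAL)] = "faecal"
    for k in chloro_idx | unass_idx:
        pool[k] = "shared"  # contaminants are region-independent

    base = rng.normal(0.0, spec.baseline_sd, size=spec.n_otus)
    log_oral = base.copy()
    log_faecal = base.copy()
    log_oral[pool == "faecal"] -= _EXCLUSIVE_PENALTY
    log_faecal[pool == "oral"] -= _EXCLUSIVE_PENALTY

    # --- differential OTUs (from the shared bacterial pool) -------------
    shared_bact = [k for k in bacterial_idx if pool[k] == "shared"]
    if spec.n_differential > len(shared_bact):
        raise ValueError("spec infeasible: not enough shared bacterial OTUs "
                         "to host the differential effects")
    diff_idx = rng.choice(shared_bact, size=spec.n_differential, replace=False)
    signs = np.ones(spec.n_differential)
    signs[1::2] = -1.0  # balanced +oral / +faecal
    effects = {}
    for k, sgn in zip(diff_idx, signs):
        delta = sgn * spec.region_log2_fold_effect * math.log(2.0)
        log_oral[k] += delta / 2.0
        log_faecal[k] -= delta / 2.0
        effects[otu_ids[k]] = float(sgn * spec.region_log2_fold_effect)

    # --- per-individual random intercepts (shared across regions) -------
    ind_effect = rng.normal(0.0, spec.individual_sd,
                            size=(spec.n_individuals, spec.n_otus))
    ind_index = {ind: i for i, ind in enumerate(individuals)}

    # --- metadata -------------------------------------------------------
    sex = {ind: ("M" if rng.random() < 0.5 else "F") for ind in individuals}
    mass = {ind: float(rng.normal(18.0, 1.2)) for ind in individuals}
    tarsus = {ind: float(rng.normal(19.8, 0.6)) for ind in individuals}

    # --- counts ---------------------------------------------------------
    counts = np.zeros((len(samples), spec.n_otus), dtype=np.int64)
    depths = np.maximum(
        np.rint(rng.lognormal(spec.depth_log_mean, spec.depth_log_sd,
                              size=len(samples))), 100).astype(np.int64)
    conc = {"oral": spec.concentration_oral,
            "faecal": spec.concentration_faecal}
    for s, (sid, ind, region) in enumerate(samples):
        logs = (log_oral if region == "oral" else log_faecal).copy()
        logs = logs + ind_effect[ind_index[ind]]
        if spec.sex_effect and sex[ind] == "M":
            logs = logs + spec.sex_effect
        logs -= logs.max()
        theta = np.exp(logs)
        theta /= theta.sum()
        alpha = np.maximum(conc[region] * theta, 1e-9)
        probs = rng.dirichlet(alpha)
        counts[s] = rng.multinomial(depths[s], probs)

    table = CountTable(tuple(s[0] for s in samples), tuple(otu_ids), counts)
    meta = SampleMetadata(pd.DataFrame({
        "sample_id": [s[0] for s in samples],
        "individual_id": [s[1] for s in samples],
        "region": [s[2] for s in samples],
        "sex": [sex[s[1]] for s in samples],
        "body_mass": [mass[s[1]] for s in samples],
        "tarsus": [tarsus[s[1]] for s in samples],
    }))
    taxonomy = _make_taxonomy(otu_ids, chloro_idx, unass_idx,
                              np.random.default_rng(spec.seed + 1))
    tree = generate_tree(spec.n_otus, np.random.default_rng(spec.seed + 2),
                         otu_ids=otu_ids)
    truth = GroundTruth(
        differential_effects=effects,
        contaminant_otus=tuple(otu_ids[k] for k in sorted(chloro_idx | unass_idx)),
        sample_regions={s[0]: s[2] for s in samples},
        sample_individuals={s[0]: s[1] for s in samples},
        oral_pool=tuple(otu_ids[k] for k in np.flatnonzero(pool == "oral")),
        faecal_pool=tuple(otu_ids[k] for k in np.flatnonzero(pool == "faecal")),
        shared_pool=tuple(otu_ids[k] for k in np.flatnonzero(pool == "shared")),
    )
    return SyntheticDataset(table=table, metadata=meta, taxonomy=taxonomy,
                            tree=tree, truth=truth, spec=spec)


def _make_taxonomy(otu_ids, chloro_idx, unass_idx, rng) -> TaxonomyTable:
    phyla = list(_PHYLA)
    rows = []
    for k, otu in enumerate(otu_ids):
        if k in chloro_idx:
            rows.append(("Bacteria", "Cyanobacteria", "Chloroplast",
                         "Streptophyta", "", ""))
        elif k in unass_idx:
            rows.append(("Bacteria", "", "", "", "", ""))
        else:
            ph = phyla[rng.choice(len(phyla), p=_PHYLUM_WEIGHTS)]
            cl = _PHYLA[ph][rng.integers(len(_PHYLA[ph]))]
            rows.append(("Bacteria", ph, cl,
                         f"Order{rng.integers(40):02d}",
                         f"Family{rng.integers(80):02d}",
                         f"Genus{rng.integers(200):03d}"))
    df = pd.DataFrame(rows, columns=list(RANKS),
                      index=pd.Index(otu_ids, name="otu_id"))
    return TaxonomyTable(df)


def write_dataset(ds: SyntheticDataset, outdir) -> dict:
    """Write counts/taxonomy/metadata/tree plus ground truth and spec sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "metadata": outdir / "metadata.tsv",
        "tree": outdir / "tree.nwk",
        "ground_truth": outdir / "ground_truth.tsv",
        "spec": outdir / "spec.txt",
    }
    ds.table.to_tsv(paths["counts"])
    ds.taxonomy.to_tsv(paths["taxonomy"])
    ds.metadata.to_tsv(paths["metadata"])
    ds.tree.to_newick(paths["tree"])
    gt = pd.DataFrame(
        [{"otu_id": o, "log2_fold_oral": e}
         for o, e in sorted(ds.truth.differential_effects.items())])
    with open(paths["ground_truth"], "w", encoding="utf-8", newline="\n") as fh:
        gt.to_csv(fh, sep="\t", index=False)
    with open(paths["spec"], "w", encoding="utf-8", newline="\n") as fh:
        for key, val in asdict(ds.spec).items():
            fh.write(f"{key}={val}\n")
    return {k: str(v) for k, v in paths.items()}
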