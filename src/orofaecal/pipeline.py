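"""End-to-end orchestration: filter -> rarefy -> alpha -> beta -> community
tests -> paired correlations -> differential abundance -> artifact files.

A single master seed is split deterministically per stage (via
``numpy.random.SeedSequence``) so identical configs give byte-identical
numeric outputs and individual stages can be rerun in isolation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import alpha_diversity as alpha_mod
from . import beta_diversity as beta_mod
from . import community_tests as comm_mod
from . import diff_abundance as diff_mod
from . import paired_analysis as paired_mod
from .core_tables import (CountTable, PhyloTree, SampleMetadata,
                          TaxonomyTable, filter_nonbacterial,
                          prevalence_filter, rarefy, shared_otu_summary,
                          taxon_rank_proportions)
from .host_traits import body_condition

logger = logging.getLogger(__name__)

_STAGES = ("rarefy", "alpha", "beta", "community", "paired", "diffabund")


@dataclass(frozen=True)
class PipelineConfig:
    """Validated knobs of a full run.  Unknown keys are rejected on load."""

    counts: str
    metadata: str
    out_dir: str
    taxonomy: str = ""
    tree: str = ""
    depth: object = "auto"          # "auto" = min sample sum after filtering
    metrics: tuple = beta_mod.METRICS
    n_perm_community: int = 9_999
    n_perm_mantel: int = 9_999
    n_perm_diffabund: int = 10_000
    prevalence_min_samples: int = 5
    significance_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.metrics, str):
            object.__setattr__(self, "metrics",
                               tuple(m.strip() for m in self.metrics.split(",")))
        bad = set(self.metrics) - set(beta_mod.METRICS)
        if bad:
            raise ValueError(f"unknown metrics: {sorted(bad)}")
        if self.depth != "auto":
            object.__setattr__(self, "depth", int(self.depth))
        for key in ("n_perm_community", "n_perm_mantel", "n_perm_diffabund",
                    "prevalence_min_samples", "seed"):
            object.__setattr__(self, key, int(getattr(self, key)))
        object.__setattr__(self, "significance_alpha",
                           float(self.significance_alpha))

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Parse a flat ``key = value`` text config (# comments allowed)."""
        known = set(cls.__dataclass_fields__)
        values = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            values[key] = val
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)


@dataclass
class Manifest:
    """Artifacts written by a run, plus non-fatal warnings."""

    artifacts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    complete: bool = False

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"artifacts": self.artifacts, "warnings": self.warnings,
             "complete": self.complete}, indent=2) + "\n", encoding="utf-8")


def _stage_seeds(master: int) -> dict:
    children = np.random.SeedSequence(master).spawn(len(_STAGES))
    return {name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(_STAGES, children)}


def run_pipeline(config: PipelineConfig) -> Manifest:
    """Run the full analysis; returns the artifact manifest.

    Stage failures raise with a stage-tagged message; the partial manifest is
    still written to ``out_dir / manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest()
    seeds = _stage_seeds(config.seed)
    log_lines = [f"orofaecal {__version__} numpy={np.__version__} "
                 f"pandas={pd.__version__} seed={config.seed}"]
    stage = "load"
    try:
        table = CountTable.from_tsv(config.counts)
        meta = SampleMetadata.from_tsv(config.metadata)
        tax = TaxonomyTable.from_tsv(config.taxonomy) if config.taxonomy else None
        tree = PhyloTree.from_newick(config.tree) if config.tree else None
        needs_tree = {"unweighted_unifrac", "weighted_unifrac"} & set(config.metrics)
        if needs_tree and tree is None:
            raise ValueError(f"metrics {sorted(needs_tree)} require a tree")

        stage = "filter"
        t0 = time.perf_counter()
        if tax is not None:
            table = filter_nonbacterial(table, tax)
        meta = meta.subset(table.sample_ids)
        raw_totals = table.sample_sums().astype(float)
        log_lines.append(f"filter: {table.n_samples} samples x "
                         f"{table.n_otus} OTUs  [{time.perf_counter() - t0:.2f}s]")

        stage = "rarefy"
        t0 = time.perf_counter()
        depth = int(table.sample_sums().min()) if config.depth == "auto" \
            else config.depth
        rare = rarefy(table, depth, seeds["rarefy"])
        log_lines.append(f"rarefy: depth={depth}  "
                         f"[{time.perf_counter() - t0:.2f}s]")

        stage = "summaries"
        shared = shared_otu_summary(rare, meta)
        pd.DataFrame([{
            "n_both": shared.n_both, "n_oral_only": shared.n_oral_only,
            "n_faecal_only": shared.n_faecal_only,
            **{f"frac_{k}": v for k, v in shared.fractions.items()},
        }]).to_csv(out / "shared_otus.tsv", sep="\t", index=False)
        manifest.artifacts["shared_otus"] = "shared_otus.tsv"
        if tax is not None:
            for rank in ("phylum", "class"):
                prop = taxon_rank_proportions(rare, tax, rank)
                prop.to_csv(out / f"taxon_proportions_{rank}.tsv", sep="\t")
                manifest.artifacts[f"taxon_proportions_{rank}"] = \
                    f"taxon_proportions_{rank}.tsv"

        stage = "alpha"
        t0 = time.perf_counter()
        alpha = alpha_mod.alpha_diversity_table(rare)
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
        manifest.artifacts["alpha_diversity"] = "alpha_diversity.tsv"
        contrasts = [alpha_mod.alpha_region_contrast(alpha, meta, m)
                     for m in alpha_mod.METRICS]
        alpha_mod.write_contrast_table(contrasts, out / "alpha_contrast.tsv")
        manifest.artifacts["alpha_contrast"] = "alpha_contrast.tsv"
        try:
            smi = body_condition(meta)
            smi.to_csv(out / "body_condition.tsv", sep="\t")
            manifest.artifacts["body_condition"] = "body_condition.tsv"
        except ValueError as exc:
            manifest.warnings.append(f"body condition skipped: {exc}")
        log_lines.append(f"alpha: 3 metrics, LRT chi2="
                         f"{[round(c.chi2, 3) for c in contrasts]}  "
                         f"[{time.perf_counter() - t0:.2f}s]")

        stage = "beta"
        t0 = time.perf_counter()
        dms = {}
        for metric in config.metrics:
            dm = beta_mod.distance_matrix(rare, metric, tree=tree)
            dms[metric] = dm
            dm.to_tsv(out / f"distance_{metric}.tsv")
            manifest.artifacts[f"distance_{metric}"] = f"distance_{metric}.tsv"
            ordi = beta_mod.pcoa(dm)
            ordi.write(str(out / f"pcoa_{metric}"))
            manifest.artifacts[f"pcoa_{metric}"] = f"pcoa_{metric}_coordinates.tsv"
        log_lines.append(f"beta: {list(config.metrics)}  "
                         f"[{time.perf_counter() - t0:.2f}s]")

        stage = "community"
        t0 = time.perf_counter()
        region = pd.Series(meta.df["region"])
        strata = meta.df["individual_id"].to_numpy()
        results = {}
        for metric, dm in dms.items():
            perm = comm_mod.permanova(dm, region, strata=strata,
                                      n_perm=config.n_perm_community,
                                      seed=seeds["community"])
            disp = comm_mod.dispersion_test(dm, region)
            results[metric] = (perm, disp)
        comm_mod.write_community_table(results, out / "community_tests.tsv")
        manifest.artifacts["community_tests"] = "community_tests.tsv"
        log_lines.append(
            "community: R2=" +
            str({m: round(r[0].r2, 4) for m, r in results.items()}) +
            f"  [{time.perf_counter() - t0:.2f}s]")

        stage = "paired"
        t0 = time.perf_counter()
        try:
            pairs = paired_mod.paired_subset(meta)
            rows = []
            for m in alpha_mod.METRICS:
                r, p = paired_mod.paired_alpha_pearson(alpha, pairs, m)
                rows.append({"metric": m, "pearson_r": r, "p": p})
            pd.DataFrame(rows).to_csv(out / "paired_alpha.tsv", sep="\t",
                                      index=False)
            manifest.artifacts["paired_alpha"] = "paired_alpha.tsv"
            mantel_rows = []
            for metric, dm in dms.items():
                mr = paired_mod.paired_composition_mantel(
                    dm, pairs, n_perm=config.n_perm_mantel,
                    seed=seeds["paired"])
                mantel_rows.append({"metric": metric, "r": mr.r, "p": mr.p})
            pd.DataFrame(mantel_rows).to_csv(out / "paired_mantel.tsv",
                                             sep="\t", index=False)
            manifest.artifacts["paired_mantel"] = "paired_mantel.tsv"
            spearman = paired_mod.paired_otu_spearman(rare, pairs)
            summary = pd.DataFrame([{
                "otu_id": "__summary__",
                "rho": spearman.attrs["mean_rho"],
                "iqr_low": spearman.attrs["iqr"][0],
                "iqr_high": spearman.attrs["iqr"][1]}]).set_index("otu_id")
            pd.concat([spearman.assign(iqr_low=np.nan, iqr_high=np.nan),
                       summary]).to_csv(out / "paired_otu_spearman.tsv",
                                        sep="\t")
            manifest.artifacts["paired_otu_spearman"] = "paired_otu_spearman.tsv"
        except ValueError as exc:
            manifest.warnings.append(f"paired analysis skipped: {exc}")
        log_lines.append(f"paired  [{time.perf_counter() - t0:.2f}s]")

        stage = "diffabund"
        t0 = time.perf_counter()
        prevalent = prevalence_filter(table, config.prevalence_min_samples)
        scan = diff_mod.diff_abundance_scan(
            prevalent, meta.subset(prevalent.sample_ids),
            n_perm=config.n_perm_diffabund, seed=seeds["diffabund"], tax=tax,
            totals=raw_totals, alpha=config.significance_alpha)
        scan.to_csv(out / "diff_abundance.tsv", sep="\t", index=False)
        manifest.artifacts["diff_abundance"] = "diff_abundance.tsv"
        heat, newick = diff_mod.heatmap_support(prevalent, scan, tree)
        heat.to_csv(out / "heatmap_log10.tsv", sep="\t")
        (out / "heatmap_subtree.nwk").write_text(newick, encoding="utf-8")
        manifest.artifacts["heatmap_log10"] = "heatmap_log10.tsv"
        manifest.artifacts["heatmap_subtree"] = "heatmap_subtree.nwk"
        log_lines.append(
            f"diffabund: {prevalent.n_otus} OTUs scanned, "
            f"{int(scan['significant'].sum())} significant  "
            f"[{time.perf_counter() - t0:.2f}s]")

        manifest.complete = True
    except Exception as exc:
        manifest.warnings.append(f"stage {stage!r} failed: {exc}")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n",
                                         encoding="utf-8")
        manifest.artifacts["run_log"] = "run_log.txt"
        manifest.save(out / "manifest.json")
    return manifest
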