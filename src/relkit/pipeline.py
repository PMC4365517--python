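"""End-to-end orchestration of the relationship-comparison study.

One call builds a sequence-like and a chip-like genotype panel over a
genotyped cohort (simulated with known truth, or loaded from files),
computes the pedigree relationship matrix and the genomic matrices for
every MAF scenario under the requested estimators, and emits the
Hardy-Weinberg summary, descriptive/correlation/Wilcoxon tables and the
depth-stratified inbreeding analysis, plus a manifest that makes the run
reproducible from its config alone.

The chip-like panel is carved from the sequence-like panel by
MAF-stratified thinning: sampling the same number of variants from each
1%-wide MAF bin reproduces the uniform chip MAF spectrum out of an
L-shaped sequence spectrum, which is the chip-ascertainment property that
matters for the comparisons.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparison import ComparisonReport, scenario_report
from .genotype_data import (
    GenotypeMatrix,
    ScenarioSpec,
    apply_maf_scenario,
    read_genotypes,
    subset_chip,
    variant_stats,
    write_matrix,
)
from .grm import grm_similarity, grm_yang
from .hwe import hwe_departure_fraction
from .pedigree import Pedigree, a_matrix, read_pedigree
from .relationship import RelationshipMatrix
from .synthetic_data import (
    SimulationConfig,
    censor_pedigree,
    draw_frequency_spectrum,
    gene_drop,
    simulate_pedigree,
)

logger = logging.getLogger(__name__)

DEFAULT_SCENARIOS = ("5+", "1+", "1_5")


@dataclass
class PipelineConfig:
    """Fully serialisable run description.

    Either ``simulation`` (synthetic cohort) or ``genotypes_path`` +
    ``pedigree_path`` (real data) must be given. ``chip_ids_path`` selects
    the chip-like subset for real data; for simulated data the chip is
    thinned to ``chip_n_target`` variants with a uniform MAF profile.
    """

    seed: int
    outdir: str
    simulation: SimulationConfig | None = None
    genotypes_path: str | None = None
    pedigree_path: str | None = None
    chip_ids_path: str | None = None
    chip_n_target: int = 6000
    scenarios: tuple[str, ...] = DEFAULT_SCENARIOS
    estimators: tuple[str, ...] = ("yang", "similarity")
    alpha: float = 0.05
    depth_thresholds: tuple[int, ...] = (1, 2, 4)
    write_genotypes: bool = False

    def __post_init__(self) -> None:
        if self.simulation is None and (
            self.genotypes_path is None or self.pedigree_path is None
        ):
            raise ValueError(
                "config needs either a simulation block or genotype + pedigree paths"
            )
        for est in self.estimators:
            if est not in ("yang", "similarity"):
                raise ValueError(f"unknown estimator {est!r}")
        for s in self.scenarios:
            ScenarioSpec.from_name(s)

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            sim = dict(d["simulation"])
            if "censor_rates" in sim and sim["censor_rates"] is not None:
                sim["censor_rates"] = tuple(sim["censor_rates"])
            d["simulation"] = SimulationConfig(**sim)
        for key in ("scenarios", "estimators", "depth_thresholds"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: list[str]
    pedigree: Pedigree
    a_ped: RelationshipMatrix
    genomic: dict[str, dict[str, RelationshipMatrix]]  # estimator -> label -> G
    hwe_summary: pd.DataFrame
    reports: dict[str, ComparisonReport]
    manifest: dict


def chip_thinning(
    g: GenotypeMatrix, n_target: int, seed: int, maf_min: float = 0.01
) -> GenotypeMatrix:
    """Thin a variant panel to an approximately uniform MAF spectrum.

    Variants are stratified into 1%-wide MAF bins over [maf_min, 0.5] and
    an equal number is sampled from each bin without replacement; bins too
    small to meet their quota are topped up from the leftover pool with a
    warning. Output preserves the original variant order.
    """
    stats = variant_stats(g)
    eligible = np.flatnonzero(stats.maf >= maf_min)
    if n_target > eligible.size:
        raise ValueError(
            f"n_target={n_target} exceeds the {eligible.size} variants with "
            f"MAF >= {maf_min}"
        )
    rng = np.random.default_rng(seed)
    edges = np.arange(maf_min, 0.5 + 0.01, 0.01)
    n_bins = edges.size - 1
    bin_of = np.clip(
        np.searchsorted(edges, stats.maf[eligible], side="right") - 1, 0, n_bins - 1
    )
    base, extra = divmod(n_target, n_bins)
    quotas = np.full(n_bins, base, dtype=np.int64)
    quotas[:extra] += 1
    chosen: list[np.ndarray] = []
    shortfall = 0
    for b in range(n_bins):
        members = eligible[bin_of == b]
        take = min(quotas[b], members.size)
        if take < quotas[b]:
            shortfall += quotas[b] - take
        if take:
            chosen.append(rng.choice(members, size=take, replace=False))
    picked = np.concatenate(chosen) if chosen else np.empty(0, dtype=np.int64)
    if shortfall:
        logger.warning(
            "chip_thinning: %d bins short by %d variants in total; "
            "filling from neighbouring MAF classes", n_bins, shortfall,
        )
        pool = np.setdiff1d(eligible, picked)
        picked = np.concatenate(
            [picked, rng.choice(pool, size=shortfall, replace=False)]
        )
    picked.sort()
    return g.subset_variants(picked)


def _stage(manifest: dict, name: str):
    manifest["stages"].append({"stage": name, "t": time.time()})
    logger.info("pipeline stage: %s", name)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full study design and write all report tables to ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage_seed = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": [],
    }
    current = "setup"
    try:
        if config.simulation is not None:
            current = "simulate"
            _stage(manifest, current)
            sim_cfg = config.simulation
            sim = simulate_pedigree(sim_cfg, seed=stage_seed())
            freqs = draw_frequency_spectrum(
                sim_cfg.n_variants, sim_cfg.spectrum, stage_seed(), sim_cfg.maf_min
            )
            g_wgs = gene_drop(
                sim.pedigree, freqs, seed=stage_seed(), ids=sim.cohort
            )
            pedigree = censor_pedigree(sim, sim_cfg.censor_rates, stage_seed())
            cohort = list(sim.cohort)
        else:
            current = "load"
            _stage(manifest, current)
            g_wgs = read_genotypes(config.genotypes_path)
            pedigree = read_pedigree(config.pedigree_path)
            cohort = list(g_wgs.sample_ids)

        current = "segregating_filter"
        _stage(manifest, current)
        stats = variant_stats(g_wgs)
        seg = (stats.p > 0.0) & (stats.p < 1.0)
        logger.info(
            "%d of %d variants segregate in the cohort",
            int(seg.sum()), g_wgs.n_variants,
        )
        g_wgs = g_wgs.subset_variants(seg)

        current = "chip_subset"
        _stage(manifest, current)
        if config.chip_ids_path is not None:
            with open(config.chip_ids_path) as fh:
                ids = [line.strip() for line in fh if line.strip()]
            g_snp = subset_chip(g_wgs, ids)
        else:
            g_snp = chip_thinning(g_wgs, config.chip_n_target, stage_seed())

        if config.write_genotypes:
            write_matrix(g_wgs, outdir / "genotypes_wgs.tsv")
            write_matrix(g_snp, outdir / "genotypes_snp.tsv")

        current = "pedigree_matrix"
        _stage(manifest, current)
        a_ped = a_matrix(pedigree, ids=cohort)

        current = "scenario_matrices"
        _stage(manifest, current)
        sources = {"SNP": g_snp, "WGS": g_wgs}
        hwe_rows = []
        filtered: dict[tuple[str, str], GenotypeMatrix] = {}
        for sname, gsrc in sources.items():
            for scen in config.scenarios:
                spec = ScenarioSpec.from_name(scen)
                gf = apply_maf_scenario(gsrc, spec)
                filtered[(sname, scen)] = gf
                summ = hwe_departure_fraction(gf, alpha=config.alpha)
                hwe_rows.append(
                    {
                        "source": sname,
                        "scenario": scen,
                        "n_variants": summ.n_total,
                        "n_departing": summ.n_departing,
                        "pct_departing": summ.percent,
                    }
                )
        hwe_summary = pd.DataFrame(hwe_rows)
        hwe_summary.to_csv(outdir / "hwe_summary.tsv", sep="\t", index=False)

        genomic: dict[str, dict[str, RelationshipMatrix]] = {}
        for est in config.estimators:
            genomic[est] = {}
            for (sname, scen), gf in filtered.items():
                G = (
                    grm_yang(gf) if est == "yang" else grm_similarity(gf)
                )
                G.scenario = scen
                genomic[est][f"G_{sname}_{scen}"] = G

        current = "comparison_report"
        _stage(manifest, current)
        reports: dict[str, ComparisonReport] = {}
        for est, mats in genomic.items():
            rep = scenario_report(
                a_ped,
                mats,
                pedigree,
                depth_thresholds=config.depth_thresholds,
                alpha=config.alpha,
            )
            rep.write(outdir / est)
            reports[est] = rep

        current = "manifest"
        _stage(manifest, current)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {current!r} failed: {exc}"
        ) from exc

    return PipelineResult(
        config=config,
        cohort=cohort,
        pedigree=pedigree,
        a_ped=a_ped,
        genomic=genomic,
        hwe_summary=hwe_summary,
        reports=reports,
        manifest=manifest,
    )
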