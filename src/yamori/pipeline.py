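"""End-to-end analysis pipeline.

Load (or synthesize) a SNP dataset, project per-group folded spectra, fit
stairway histories, assemble the observed F_ST / Phi_ST summary vector,
simulate prior-predictive tables under the no-migration and migration
scenarios, choose the model (mnlogistic), and estimate the rejection
posterior of the divergence parameters under the chosen scenario. Every
output embeds the master seed and a configuration hash so reruns are
byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abc import PriorSpec, SimulationTable, abc_reject, build_sim_table, model_choice
from .coalescent import SampleConfig
from .data import SNPDataset
from .io import read_vcf, write_popmap, write_sfs, write_vcf
from .models import DemographicModel, build_m1
from .stairway import StairwayConfig, fit_stairway, ne_minimum_time, summary_table
from .sumstats import observed_sfs, pop_allele_counts, summary_vector_from_counts
from .synthetic import StudyDesign, generate_dataset, study_design

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; see field comments for units."""

    # input: either a VCF + popmap, or a synthetic design
    vcf: str | None = None
    popmap: str | None = None
    design: StudyDesign | None = None  # default: the full study design

    # scenario templates; M2 = M1 topology + symmetric parent-child migration
    model: DemographicModel | None = None
    m2_migration_placeholder: float = 1e-4
    m2_migration_bounds: tuple[float, float] = (1e-8, 1e-2)

    # which dataset groups feed which model population in the ABC stage
    group_to_pop: dict[str, str] = field(default_factory=dict)

    # ABC settings
    n_sims: int = 20_000
    n_snps_sim: int = 250
    tolerance: float = 0.01
    method: str = "mnlogistic"
    prior: PriorSpec | None = None  # default: PriorSpec.default(model)

    # stairway settings
    stairway_groups: tuple[str, ...] = ()
    stairway_bootstrap: int = 200
    stairway_n_sites: float = 1e7

    seed: int = 0

    def resolve_design(self) -> StudyDesign:
        return self.design if self.design is not None else study_design()

    def resolve_model(self) -> DemographicModel:
        if self.model is not None:
            return self.model
        return build_m1()

    def config_hash(self) -> str:
        payload = {
            "vcf": self.vcf,
            "popmap": self.popmap,
            "design": None
            if self.design is None
            else {
                "groups": list(map(list, self.design.groups)),
                "n_snps": self.design.n_snps,
                "missing_fraction": self.design.missing_fraction,
                "model": self.design.model.to_dict(),
                "group_to_pop": self.design.group_to_pop,
            },
            "model": self.resolve_model().to_dict(),
            "m2_migration_placeholder": self.m2_migration_placeholder,
            "m2_migration_bounds": list(self.m2_migration_bounds),
            "group_to_pop": self.group_to_pop,
            "n_sims": self.n_sims,
            "n_snps_sim": self.n_snps_sim,
            "tolerance": self.tolerance,
            "method": self.method,
            "stairway_groups": list(self.stairway_groups),
            "stairway_bootstrap": self.stairway_bootstrap,
            "stairway_n_sites": self.stairway_n_sites,
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _abc_counts(dataset: SNPDataset, group_to_pop: dict[str, str], model: DemographicModel):
    """Allele counts pooled into model populations; groups mapping to the
    same population are merged, groups absent from the model are dropped."""
    d_raw, m_raw, groups = pop_allele_counts(dataset)
    pops = [p for p in model.pop_names if p in {group_to_pop.get(g, g) for g in groups}]
    d = np.zeros((dataset.n_sites, len(pops)), dtype=np.int64)
    m = np.zeros_like(d)
    for j, g in enumerate(groups):
        pop = group_to_pop.get(g, g)
        if pop in pops:
            i = pops.index(pop)
            d[:, i] += d_raw[:, j]
            m[:, i] += m_raw[:, j]
    return d, m, pops


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the full analysis; returns the report dict (also written as
    ``report.json`` under ``outdir`` along with per-stage TSV artifacts)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s % (2**31 - 1)) for s in ss.generate_state(8)]
    report: dict = {
        "yamori_version": __version__,
        "master_seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }

    # -- stage 1: data -------------------------------------------------------
    if config.vcf is not None:
        if config.popmap is None:
            raise ValueError("a VCF input needs a popmap")
        dataset = read_vcf(config.vcf, config.popmap)
        report["stages"]["data"] = {
            "source": "vcf",
            "path": str(config.vcf),
            "n_individuals": dataset.n_individuals,
            "n_sites": dataset.n_sites,
        }
        logger.info("loaded %d x %d genotypes", dataset.n_individuals, dataset.n_sites)
    else:
        design = config.resolve_design()
        dataset, popmap = generate_dataset(design, seed=seeds[0])
        write_vcf(dataset, outdir / "synthetic.vcf")
        write_popmap(popmap, outdir / "synthetic.popmap.tsv")
        miss = float((dataset.genotypes == -1).mean())
        report["stages"]["data"] = {
            "source": "synthetic",
            "n_individuals": dataset.n_individuals,
            "n_sites": dataset.n_sites,
            "missing_fraction": round(miss, 6),
            "seed": seeds[0],
        }
        logger.info("synthesized %d x %d genotypes", dataset.n_individuals, dataset.n_sites)

    # -- stage 2: per-group SFS (projection 2N - 1) --------------------------
    sfs_info = {}
    sfs_by_group = {}
    for g in dataset.pop_names:
        n_dip = sum(1 for p in dataset.populations if p == g)
        if 2 * n_dip - 1 < 4:
            logger.info("group %s too small for SFS projection; skipped", g)
            continue
        sfs = observed_sfs(dataset, g, n_proj=2 * n_dip - 1, folded=True)
        sfs_by_group[g] = sfs
        write_sfs(sfs, outdir / f"sfs_{g}.txt")
        sfs_info[g] = {"n_proj": sfs.n, "segregating_mass": round(float(sfs.segregating.sum()), 2)}
    report["stages"]["sfs"] = sfs_info

    # -- stage 3: stairway fits ----------------------------------------------
    stairway_report = {}
    for g in config.stairway_groups:
        if g not in sfs_by_group:
            raise ValueError(f"stairway requested for unknown/skipped group {g!r}")
        sfs = sfs_by_group[g]
        model = config.resolve_model()
        cfg = StairwayConfig(
            nseq=sfs.n,
            mu_per_site_per_generation=model.mu_per_site_per_generation,
            generation_time_years=model.generation_time_years,
            n_sites=config.stairway_n_sites,
            n_bootstrap=config.stairway_bootstrap,
            seed=seeds[1],
        )
        fit = fit_stairway(sfs, cfg)
        summary_table(fit).to_csv(outdir / f"stairway_{g}.tsv", sep="\t", index=False)
        tmin = ne_minimum_time(fit)
        stairway_report[g] = {
            "chosen_nrand": fit.chosen_nrand,
            "ne_min_time_generations": round(tmin, 2),
            "ne_min_time_years": round(tmin * model.generation_time_years, 2),
        }
    report["stages"]["stairway"] = stairway_report

    # -- stage 4: observed summary vector ------------------------------------
    model = config.resolve_model()
    d, m, pops = _abc_counts(dataset, config.group_to_pop, model)
    if len(pops) < 2:
        raise ValueError("ABC needs at least two model populations present in the data")
    observed = summary_vector_from_counts(d, m, pops)
    pd.DataFrame([observed.values], columns=observed.labels).to_csv(
        outdir / "observed_stats.tsv", sep="\t", index=False
    )
    report["stages"]["observed_stats"] = {
        "n_stats": len(observed.values),
        "fst_estimator": observed.fst_estimator,
        "populations": pops,
    }

    # -- stage 5: simulation tables ------------------------------------------
    samples = SampleConfig.from_diploids(
        {p: int(m[:, i].max() // 2) for i, p in enumerate(pops)}
    )
    m1 = model
    m2 = _with_parent_child_migration(model, config.m2_migration_placeholder)
    prior_m1 = config.prior or PriorSpec.default(m1)
    prior_m2 = PriorSpec.default(m2, migration_bounds=config.m2_migration_bounds)
    tables: list[SimulationTable] = []
    for label, mod, prior, sd in (("M1", m1, prior_m1, seeds[2]), ("M2", m2, prior_m2, seeds[3])):
        tbl = build_sim_table(
            mod,
            prior,
            n_sims=config.n_sims,
            samples=samples,
            n_snps=config.n_snps_sim,
            seed=sd,
            model_label=label,
            population_order=pops,
        )
        tbl.stats.to_csv(outdir / f"table_{label}_stats.tsv", sep="\t", index=False)
        tbl.params.to_csv(outdir / f"table_{label}_params.tsv", sep="\t", index=False)
        tables.append(tbl)
    report["stages"]["simulation"] = {
        t.model_label: {"n_rows": t.n_rows, "n_snps": t.n_snps, "flagged": int((~t.ok_rows).sum()), "seed": t.master_seed}
        for t in tables
    }

    # -- stage 6: model choice ------------------------------------------------
    choice = model_choice(observed, tables, tolerance=config.tolerance, method=config.method)
    report["stages"]["model_choice"] = {
        "method": choice.method,
        "probabilities": {k: round(v, 6) for k, v in choice.probabilities.items()},
        "accepted_counts": choice.accepted_counts,
        "best_model": choice.best_model,
    }

    # -- stage 7: rejection posterior under the chosen model ------------------
    best = next(t for t in tables if t.model_label == choice.best_model)
    post = abc_reject(observed, best, config.tolerance)
    post.accepted.to_csv(outdir / "posterior_accepted.tsv", sep="\t", index=False)
    post.quantiles.to_csv(outdir / "posterior_quantiles.tsv", sep="\t")
    report["stages"]["posterior"] = {
        "model": best.model_label,
        "tolerance": config.tolerance,
        "n_accepted": post.n_accepted,
        "medians": {k: round(float(v), 4) for k, v in post.quantiles.loc["q0.5"].items()},
    }

    with (outdir / "report.json").open("w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _with_parent_child_migration(model: DemographicModel, rate: float) -> DemographicModel:
    from .models import MigrationSpec

    migs = []
    for s in model.splits:
        migs.append(MigrationSpec(s.derived, s.ancestral, rate))
        migs.append(MigrationSpec(s.ancestral, s.derived, rate))
    return dataclasses.replace(model, migrations=tuple(migs))
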