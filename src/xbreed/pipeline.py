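"""End-to-end study orchestration: simulate -> kinship -> REML -> GWAS ->
SNP selection -> restricted GRMs -> GBLUP validation.

`run_study` executes the whole design in memory and returns every
intermediate product (the natural entry point for experiments and
tests); `run_pipeline` is the file-based equivalent behind the command
line, with per-stage outputs, digests and a run manifest enabling
partial re-runs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as xio
from .gwas import GwasResult, gwas_scan
from .kinship import (
    ConfigurationError,
    Pedigree,
    RelationshipMatrix,
    build_grm,
    build_nrm,
    relationship_summary,
)
from .mixedmodel import (
    ModelSpec,
    ParameterSummary,
    RandomTerm,
    VarianceComponents,
    parameter_summary,
    reml_fit,
)
from .predict import (
    adjusted_phenotypes,
    run_validation_grid,
    within_breed_fixed_solutions,
)
from .simdata import FixedEffectSpec, SimConfig, SimTruth, simulate_dataset
from .snpselect import SnpLists, build_variant_grms, merge_and_deoverlap, select_per_trait

FACTORS = ("contemporary_group", "age_of_dam")
COVARIATES = ("breed_composition",)

STAGES = ("simulate", "kinship", "reml", "gwas", "select", "variant_reml", "predict")


@dataclass
class PipelineConfig:
    """Analysis settings layered on top of the simulation design."""

    sim: SimConfig
    selection_fraction: float = 0.10
    blend: float = 0.95
    ranking: str = "sum_log_p"
    nrm_generations: int = 3

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "sim" not in raw:
            raise ConfigurationError("config file must contain a 'sim' section")
        sim_raw = dict(raw["sim"])
        if "seed" not in sim_raw:
            raise ConfigurationError("config field sim.seed is mandatory")
        if "fixed_effects" in sim_raw:
            sim_raw["fixed_effects"] = FixedEffectSpec(**sim_raw["fixed_effects"])
        if "breeds" in sim_raw:
            sim_raw["breeds"] = tuple(sim_raw["breeds"])
        try:
            sim = SimConfig(**sim_raw)
        except TypeError as exc:
            raise ConfigurationError(f"bad sim config: {exc}") from exc
        extra = {k: v for k, v in raw.items() if k != "sim"}
        try:
            return cls(sim=sim, **extra)
        except TypeError as exc:
            raise ConfigurationError(f"bad pipeline config: {exc}") from exc

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["breeds"] = list(d["sim"]["breeds"])
        return d


@dataclass
class StudyResult:
    """Everything the pipeline produces, in memory."""

    config: PipelineConfig
    pedigree: Pedigree
    truth: SimTruth
    phenotypes: pd.DataFrame
    nrm: RelationshipMatrix
    grms: dict  # "G_W" / "G_S" / "G_D" -> RelationshipMatrix
    components: dict  # grm variant -> VarianceComponents (bi-variate fits)
    parameters: dict  # grm variant -> ParameterSummary
    within_breed: dict  # breed -> within-breed two-sex fit artefacts
    gwas: dict  # breed -> GwasResult
    snp_lists: SnpLists
    validation: pd.DataFrame
    relationship_report: pd.DataFrame

    def genomic_correlations(self) -> dict:
        return {k: v.r_G for k, v in self.parameters.items()}


def bivariate_spec(nrm, grm, trait="trait", breeds=("BB", "TC")) -> ModelSpec:
    """The across-breed bi-variate model: one trait treated as two traits."""
    return ModelSpec(
        response=trait,
        trait_column="breed",
        traits=tuple(breeds),
        factors=FACTORS,
        covariates=COVARIATES,
        random_terms=(
            RandomTerm("pedigree", nrm, "diagonal"),
            RandomTerm("genomic", grm, "full"),
        ),
    )


def run_study(
    config: PipelineConfig | SimConfig,
    include_prediction: bool = True,
    schemes=None,
) -> StudyResult:
    """Simulate one two-breed dataset and run the complete analysis chain."""
    if isinstance(config, SimConfig):
        config = PipelineConfig(sim=config)
    sim = config.sim
    ped, geno, pheno, truth = simulate_dataset(sim)
    nrm = build_nrm(ped, max_ancestor_generations=config.nrm_generations)
    grm_w = build_grm(geno, blend=config.blend, provenance="whole panel")
    cows = pheno[pheno["role"] == "calibration"]

    components: dict = {}
    parameters: dict = {}
    spec_w = bivariate_spec(nrm, grm_w, trait=sim.trait, breeds=sim.breeds)
    components["G_W"] = reml_fit(spec_w, cows)
    parameters["G_W"] = parameter_summary(components["G_W"])

    gwas_results = {}
    for breed in sim.breeds:
        sub = cows[cows["breed"] == breed]
        gwas_results[breed] = gwas_scan(
            sub,
            geno,
            nrm,
            response=sim.trait,
            breed=breed,
            factors=FACTORS,
            covariates=COVARIATES,
        )
    b0, b1 = sim.breeds
    same = {
        sim.trait: select_per_trait(
            gwas_results[b0].table,
            gwas_results[b1].table,
            fraction=config.selection_fraction,
            direction="same",
            ranking=config.ranking,
        )
    }
    diff = {
        sim.trait: select_per_trait(
            gwas_results[b0].table,
            gwas_results[b1].table,
            fraction=config.selection_fraction,
            direction="different",
            ranking=config.ranking,
        )
    }
    lists = merge_and_deoverlap(same, diff)
    grm_s, grm_d = build_variant_grms(geno, lists, blend=config.blend)
    grms = {"G_W": grm_w, "G_S": grm_s, "G_D": grm_d}
    for name in ("G_S", "G_D"):
        spec = bivariate_spec(nrm, grms[name], trait=sim.trait, breeds=sim.breeds)
        components[name] = reml_fit(spec, cows, start=components["G_W"])
        parameters[name] = parameter_summary(components[name])

    within = within_breed_fixed_solutions(
        pheno, nrm, response=sim.trait, factors=FACTORS, covariates=COVARIATES
    )
    validation = pd.DataFrame()
    if include_prediction:
        adjusted = adjusted_phenotypes(pheno, within, response=sim.trait)
        validation = run_validation_grid(
            pheno,
            grms,
            adjusted,
            schemes=schemes,
            response=sim.trait,
            factors=FACTORS,
            covariates=COVARIATES,
        )
    rel_report = pd.concat(
        [
            relationship_summary(nrm, ped.breed_of()).assign(matrix="A"),
            relationship_summary(grm_w, ped.breed_of()).assign(matrix="G_W"),
        ],
        ignore_index=True,
    )
    return StudyResult(
        config=config,
        pedigree=ped,
        truth=truth,
        phenotypes=pheno,
        nrm=nrm,
        grms=grms,
        components=components,
        parameters=parameters,
        within_breed=within,
        gwas=gwas_results,
        snp_lists=lists,
        validation=validation,
        relationship_report=rel_report,
    )


# ---------------------------------------------------------------------------
# File-based pipeline with manifest
# ---------------------------------------------------------------------------


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    """File-based pipeline with per-stage outputs and a run manifest."""

    def __init__(self, config: PipelineConfig, outdir):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest = {
            "config": config.to_dict(),
            "seed": config.sim.seed,
            "stages": {},
            "outputs": {},
        }

    def _record(self, stage: str, t0: float, paths) -> None:
        self.manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
        for p in paths:
            p = Path(p)
            self.manifest["outputs"][str(p.relative_to(self.outdir))] = _digest(p)

    def path(self, name: str) -> Path:
        return self.outdir / name

    # -- stages --------------------------------------------------------

    def stage_simulate(self):
        t0 = time.time()
        ped, geno, pheno, truth = simulate_dataset(self.config.sim)
        xio.write_pedigree(ped, self.path("pedigree.csv"))
        xio.write_phenotypes(pheno, self.path("phenotypes.csv"))
        xio.write_plink_text(geno, self.path("genotypes"), pedigree=ped)
        truth_info = {
            "qtl_ids": [str(q) for q in truth.qtl_ids],
            "realized_rho": truth.realized_rho,
            "variance_partition": truth.variance_partition,
        }
        self.path("truth.json").write_text(json.dumps(truth_info, indent=1))
        truth.true_breeding_values.rename_axis("animal").to_csv(self.path("true_breeding_values.csv"))
        self._record(
            "simulate",
            t0,
            [
                self.path("pedigree.csv"),
                self.path("phenotypes.csv"),
                self.path("genotypes.ped"),
                self.path("genotypes.map"),
                self.path("truth.json"),
                self.path("true_breeding_values.csv"),
            ],
        )
        return ped, geno, pheno, truth

    def run(self) -> StudyResult:
        """Execute all stages, writing outputs and the manifest."""
        ped, geno, pheno, truth = self.stage_simulate()

        t0 = time.time()
        result = run_study(self.config)
        xio.write_relationship_matrix(result.nrm, self.path("nrm"))
        for name, grm in result.grms.items():
            xio.write_relationship_matrix(grm, self.path(name.lower()))
        self._record(
            "kinship", t0, [self.path("nrm.npy"), self.path("nrm.ids.json")]
        )

        t0 = time.time()
        for name, vc in result.components.items():
            xio.write_components(vc, self.path(f"components_{name.lower()}.json"))
            result.parameters[name].table.to_csv(self.path(f"parameters_{name.lower()}.csv"))
        self._record(
            "reml",
            t0,
            [self.path(f"components_{n.lower()}.json") for n in result.components],
        )

        t0 = time.time()
        for breed, res in result.gwas.items():
            res.table.to_csv(self.path(f"gwas_{breed}.csv"), index=False)
        self._record("gwas", t0, [self.path(f"gwas_{b}.csv") for b in result.gwas])

        t0 = time.time()
        xio.write_marker_list(
            result.snp_lists.list_of_same,
            self.path("list_of_same.txt"),
            header={
                "direction": "same",
                "fraction": self.config.selection_fraction,
                "ranking": self.config.ranking,
            },
        )
        xio.write_marker_list(
            result.snp_lists.list_of_different,
            self.path("list_of_different.txt"),
            header={
                "direction": "different",
                "fraction": self.config.selection_fraction,
                "ranking": self.config.ranking,
            },
        )
        self._record(
            "select", t0, [self.path("list_of_same.txt"), self.path("list_of_different.txt")]
        )

        t0 = time.time()
        result.validation.to_csv(self.path("validation_report.csv"), index=False)
        result.relationship_report.to_csv(self.path("relationship_report.csv"), index=False)
        self._record(
            "predict",
            t0,
            [self.path("validation_report.csv"), self.path("relationship_report.csv")],
        )
        self.write_manifest()
        return result

    def write_manifest(self) -> None:
        self.path("manifest.json").write_text(json.dumps(self.manifest, indent=1))


def run_pipeline(config: PipelineConfig, outdir) -> StudyResult:
    return PipelineRun(config, outdir).run()
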