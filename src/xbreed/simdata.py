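"""Synthetic two-breed populations for across-breed genomic evaluation.

The generator emulates the structure of a two-breed beef cattle design:
two pedigree-disconnected populations, a cow calibration generation
whose sons form the bull validation generation, breed-divergent allele
frequencies (Balding-Nichols model around a shared ancestral frequency),
QTL allele-substitution effects correlated across breeds at a chosen
``rho_qtl``, a pedigree-only polygenic component carrying the "missing"
fraction of heritability, and sex-specific genetic values correlated at
``rg_sexes``.  Ground truth (QTL effects, true breeding values, realized
effect correlation, generating variances) is returned alongside so that
estimator-recovery tests have an oracle.

Markers segregate independently (gene drop without a linkage map): the
estimators downstream operate on relationship matrices, and cross-breed
LD-phase consistency is emulated directly through ``rho_qtl`` rather
than through an explicit LD model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import (
    ConfigurationError,
    GenotypeMatrix,
    Pedigree,
    UNKNOWN_PARENT,
)

SEXES = ("F", "M")

# per-stage offsets mixed into the seed so that the three operations
# draw from independent, reproducible streams
_STAGE_PEDIGREE = 11
_STAGE_GENOTYPES = 13
_STAGE_PHENOTYPES = 17


@dataclass
class FixedEffectSpec:
    """Levels and magnitudes of the simulated fixed effects.

    Contemporary group (herd x year x location surrogate) and age-of-dam
    are categorical with i.i.d. normal level effects; breed composition
    (fraction of indicine-like ancestry surrogate) is a uniform
    within-breed covariate with a linear slope.
    """

    n_contemporary_groups: int = 10
    contemporary_group_sd: float = 0.5
    n_age_of_dam_classes: int = 4
    age_of_dam_sd: float = 0.2
    breed_composition_slope: float = 0.3
    intercept: float = 10.0


@dataclass
class SimConfig:
    """Design of the simulated two-breed study.

    Counts are per breed.  ``h2_marked`` is the fraction of phenotypic
    variance from genotyped QTL; ``h2_polygenic`` the fraction from the
    pedigree-only polygenic term (the "missing heritability" of the
    generating model); the residual takes the remainder.  Defaults are
    desk-scale: 800 calibration cows and 800 validation bulls per breed
    on a 5,000-SNP panel with 500 QTL and a moderately heritable trait
    (total h2 = 0.6, one third of it pedigree-only).
    """

    seed: int
    n_sires: int = 25
    n_dams: int = 300
    n_offspring_cows: int = 800
    n_offspring_bulls: int = 800
    n_snps: int = 5000
    n_qtl: int = 500
    fst_divergence: float = 0.10
    rho_qtl: float = 0.8
    h2_marked: float = 0.4
    h2_polygenic: float = 0.2
    rg_sexes: float = 0.9
    litter_limit: int = 4
    breeds: tuple[str, str] = ("BB", "TC")
    fixed_effects: FixedEffectSpec = field(default_factory=FixedEffectSpec)
    trait: str = "trait"

    def __post_init__(self) -> None:
        counts = {
            "n_sires": self.n_sires,
            "n_dams": self.n_dams,
            "n_offspring_cows": self.n_offspring_cows,
            "n_offspring_bulls": self.n_offspring_bulls,
            "n_snps": self.n_snps,
            "n_qtl": self.n_qtl,
            "litter_limit": self.litter_limit,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ConfigurationError(f"{name} must be positive, got {v}")
        if self.n_qtl > self.n_snps:
            raise ConfigurationError("n_qtl cannot exceed n_snps")
        if not (0.0 <= self.fst_divergence < 1.0):
            raise ConfigurationError("fst_divergence must be in [0, 1)")
        if not (-1.0 <= self.rho_qtl <= 1.0):
            raise ConfigurationError("rho_qtl must be in [-1, 1]")
        if not (-1.0 <= self.rg_sexes <= 1.0):
            raise ConfigurationError("rg_sexes must be in [-1, 1]")
        for name in ("h2_marked", "h2_polygenic"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.h2_marked + self.h2_polygenic >= 1.0:
            raise ConfigurationError(
                "h2_marked + h2_polygenic must be < 1 (residual variance would "
                "not be positive)"
            )
        if self.n_offspring_cows > self.n_dams * self.litter_limit:
            raise ConfigurationError(
                "more cow offspring requested than founder-dam capacity under "
                f"the litter limit ({self.n_dams} dams x {self.litter_limit})"
            )
        if self.n_offspring_bulls > self.n_offspring_cows * self.litter_limit:
            raise ConfigurationError(
                "more validation bulls requested than calibration-cow capacity "
                f"under the litter limit ({self.n_offspring_cows} cows x "
                f"{self.litter_limit})"
            )
        if len(self.breeds) != 2 or len(set(self.breeds)) != 2:
            raise ConfigurationError("exactly two distinct breed labels required")

    @property
    def n_founders_per_breed(self) -> int:
        return self.n_sires + self.n_dams

    @property
    def h2_residual(self) -> float:
        return 1.0 - self.h2_marked - self.h2_polygenic


@dataclass
class SimTruth:
    """Generating values recorded for parameter-recovery tests."""

    qtl_ids: np.ndarray
    #: (n_qtl, 2) allele-substitution effects per breed, female-expressed scale
    qtl_effects: dict
    #: per animal, per sex: total (marked + polygenic) breeding value
    true_breeding_values: pd.DataFrame
    #: per animal, per sex: marked (genomic) component only
    marked_breeding_values: pd.DataFrame
    realized_rho: float
    variance_partition: dict

    def effects_for(self, breed: str, sex: str = "F") -> np.ndarray:
        return self.qtl_effects[(breed, sex)]


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stage]))


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Two disconnected single-breed pedigrees with a cow->bull chain.

    Per breed: founder sires and dams (generation 0), calibration cows
    (daughters of founder matings) and validation bulls, each the son of
    a calibration cow, so the validation generation descends from the
    calibration one exactly as in a cows-calibrate / bulls-validate
    split.  Dams are capped at ``litter_limit`` offspring.
    """
    rng = _rng(config, _STAGE_PEDIGREE)
    records = []
    for breed in config.breeds:
        sires = [f"{breed}_S{i + 1:04d}" for i in range(config.n_sires)]
        dams = [f"{breed}_D{i + 1:04d}" for i in range(config.n_dams)]
        cows = [f"{breed}_C{i + 1:05d}" for i in range(config.n_offspring_cows)]
        bulls = [f"{breed}_B{i + 1:05d}" for i in range(config.n_offspring_bulls)]
        for s in sires:
            records.append((s, UNKNOWN_PARENT, UNKNOWN_PARENT, breed, "M", "founder_sire"))
        for d in dams:
            records.append((d, UNKNOWN_PARENT, UNKNOWN_PARENT, breed, "F", "founder_dam"))

        def _assign_dams(offspring, dam_pool):
            slots = np.repeat(np.arange(len(dam_pool)), config.litter_limit)
            rng.shuffle(slots)
            return slots[: len(offspring)]

        cow_dams = _assign_dams(cows, dams)
        cow_sires = rng.integers(0, config.n_sires, size=len(cows))
        for c, si, di in zip(cows, cow_sires, cow_dams):
            records.append((c, sires[si], dams[di], breed, "F", "calibration"))
        bull_dams = _assign_dams(bulls, cows)
        bull_sires = rng.integers(0, config.n_sires, size=len(bulls))
        for b, si, di in zip(bulls, bull_sires, bull_dams):
            records.append((b, sires[si], cows[di], breed, "M", "validation"))
    table = pd.DataFrame(
        records, columns=["animal", "sire", "dam", "breed", "sex", "role"]
    )
    return Pedigree(table)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(pedigree: Pedigree, config: SimConfig) -> GenotypeMatrix:
    """Gene-drop genotypes over independent biallelic markers.

    Founder allele frequencies per breed follow the Balding-Nichols
    model around a shared ancestral frequency (U(0.1, 0.9)) with
    divergence parameter ``fst_divergence``; founders are Hardy-Weinberg
    draws and non-founders inherit one allele from each parent.
    """
    if config.fst_divergence >= 1.0:
        raise ConfigurationError("fst_divergence must be < 1")
    rng = _rng(config, _STAGE_GENOTYPES)
    m = config.n_snps
    ancestral = rng.uniform(0.1, 0.9, size=m)
    fst = config.fst_divergence
    freqs = {}
    for breed in config.breeds:
        if fst == 0.0:
            freqs[breed] = ancestral.copy()
        else:
            a = ancestral * (1.0 - fst) / fst
            b = (1.0 - ancestral) * (1.0 - fst) / fst
            freqs[breed] = rng.beta(a, b)

    t = pedigree.table
    n = len(t)
    parents = pedigree.parent_indices()
    breed_arr = t["breed"].to_numpy()
    codes = np.zeros((n, m), dtype=np.int8)
    for i in pedigree.topological_order():
        s, d = parents[i]
        if s < 0 and d < 0:
            codes[i] = rng.binomial(2, freqs[breed_arr[i]]).astype(np.int8)
        else:
            # one transmitted allele per parent; unknown parent side drawn
            # from the breed founder frequency
            alleles = np.zeros(m, dtype=np.int8)
            for p in (s, d):
                if p >= 0:
                    g = codes[p]
                    transmit = np.where(
                        g == 1, rng.random(m) < 0.5, g == 2
                    )
                else:
                    transmit = rng.random(m) < freqs[breed_arr[i]]
                alleles += transmit.astype(np.int8)
            codes[i] = alleles
    markers = pd.DataFrame(
        {
            "marker": [f"snp{j + 1:06d}" for j in range(m)],
            "chrom": np.ones(m, dtype=np.int64),
            "pos": (np.arange(m, dtype=np.int64) + 1) * 1000,
            "allele1": "A",
            "allele2": "B",
        }
    )
    return GenotypeMatrix(ids=t["animal"].to_numpy(), markers=markers, codes=codes)


# ---------------------------------------------------------------------------
# Effects and phenotypes
# ---------------------------------------------------------------------------


def _correlation_sqrt(C: np.ndarray) -> np.ndarray:
    """Symmetric square root tolerant of singular (|rho| = 1) matrices."""
    w, V = np.linalg.eigh(C)
    w = np.clip(w, 0.0, None)
    return V @ np.diag(np.sqrt(w)) @ V.T


def _drop_polygenic(pedigree: Pedigree, rng: np.random.Generator, C_sex: np.ndarray) -> np.ndarray:
    """Pedigree-sampled polygenic values, one column per sex.

    Founders ~ N(0, C_sex); offspring = parent average + Mendelian
    sampling deviate ~ N(0, C_sex / 2) (inbreeding ignored, which is
    negligible in these shallow pedigrees).
    """
    L = _correlation_sqrt(C_sex)
    n = pedigree.n_animals
    parents = pedigree.parent_indices()
    out = np.zeros((n, 2))
    for i in pedigree.topological_order():
        s, d = parents[i]
        if s < 0 and d < 0:
            out[i] = L @ rng.standard_normal(2)
        else:
            mid = np.zeros(2)
            k = 0
            for p in (s, d):
                if p >= 0:
                    mid += out[p]
                    k += 1
            # an unknown parent contributes an independent founder draw
            for _ in range(2 - k):
                mid += L @ rng.standard_normal(2)
            out[i] = mid / 2.0 + (L @ rng.standard_normal(2)) / np.sqrt(2.0)
    return out


def simulate_effects_and_phenotypes(
    pedigree: Pedigree, genotypes: GenotypeMatrix, config: SimConfig
) -> tuple[pd.DataFrame, SimTruth]:
    """QTL effects, breeding values, fixed effects and phenotypes.

    QTL allele-substitution effects are drawn from a zero-mean normal
    with correlation ``rho_qtl`` across breeds and ``rg_sexes`` across
    sexes (Kronecker of the two 2x2 correlation matrices).  Marked and
    polygenic components are scaled per breed so that, over phenotyped
    animals, they contribute ``h2_marked`` and ``h2_polygenic`` of a
    unit phenotypic variance; the residual takes the rest.
    """
    rng = _rng(config, _STAGE_PHENOTYPES)
    t = pedigree.table
    if not set(t["animal"]).issubset(set(genotypes.ids)):
        raise ConfigurationError("genotypes must cover all pedigree animals")
    gpos = genotypes.animal_indexer(t["animal"].to_numpy())

    # --- QTL effects: 4 correlated columns (breed x sex) -------------
    p_all, _ = allele_frequencies_safe(genotypes)
    candidates = np.flatnonzero((p_all > 0.0) & (p_all < 1.0))
    if len(candidates) < config.n_qtl:
        candidates = np.arange(config.n_snps)
    qtl_idx = np.sort(rng.choice(candidates, size=config.n_qtl, replace=False))
    C_breed = np.array([[1.0, config.rho_qtl], [config.rho_qtl, 1.0]])
    C_sex = np.array([[1.0, config.rg_sexes], [config.rg_sexes, 1.0]])
    L = _correlation_sqrt(np.kron(C_breed, C_sex))
    raw = rng.standard_normal((config.n_qtl, 4)) @ L.T  # cols: (b0,F),(b0,M),(b1,F),(b1,M)
    effects = {
        (config.breeds[0], "F"): raw[:, 0],
        (config.breeds[0], "M"): raw[:, 1],
        (config.breeds[1], "F"): raw[:, 2],
        (config.breeds[1], "M"): raw[:, 3],
    }
    realized_rho = float(np.corrcoef(raw[:, 0], raw[:, 2])[0, 1]) if config.n_qtl > 1 else 1.0

    dosages = genotypes.codes[gpos][:, qtl_idx].astype(np.float64)
    dosages[dosages < 0] = 0.0

    breed_arr = t["breed"].to_numpy()
    role = t["role"].to_numpy() if "role" in t.columns else np.array(["calibration"] * len(t))
    phenotyped = np.isin(role, ("calibration", "validation"))

    marked = np.zeros((len(t), 2))  # columns F, M
    scale_marked = {}
    for breed in config.breeds:
        rows = breed_arr == breed
        for j, sex in enumerate(SEXES):
            marked[rows, j] = dosages[rows] @ effects[(breed, sex)]
        ref = marked[rows & phenotyped, 0]
        var = ref.var(ddof=1) if len(ref) > 1 else 1.0
        sc = np.sqrt(config.h2_marked / var) if var > 0 and config.h2_marked > 0 else 0.0
        marked[rows] *= sc
        scale_marked[breed] = sc
    for key in effects:
        effects[key] = effects[key] * scale_marked[key[0]]

    # --- polygenic component -----------------------------------------
    poly = _drop_polygenic(pedigree, rng, C_sex)
    for breed in config.breeds:
        rows = breed_arr == breed
        ref = poly[rows & phenotyped, 0]
        var = ref.var(ddof=1) if len(ref) > 1 else 1.0
        sc = np.sqrt(config.h2_polygenic / var) if var > 0 and config.h2_polygenic > 0 else 0.0
        poly[rows] *= sc

    tbv = marked + poly
    sex_col = np.where(t["sex"].to_numpy() == "F", 0, 1)
    expressed = tbv[np.arange(len(t)), sex_col]

    # --- fixed effects and residual ----------------------------------
    fe = config.fixed_effects
    cg_effects = rng.normal(0.0, fe.contemporary_group_sd, size=(2, fe.n_contemporary_groups))
    aod_effects = rng.normal(0.0, fe.age_of_dam_sd, size=(2, fe.n_age_of_dam_classes))
    cg_idx = rng.integers(0, fe.n_contemporary_groups, size=len(t))
    aod_idx = rng.integers(0, fe.n_age_of_dam_classes, size=len(t))
    breed_comp = rng.uniform(0.0, 1.0, size=len(t))
    breed_num = (breed_arr == config.breeds[1]).astype(int)

    resid_sd = np.sqrt(config.h2_residual)
    e = rng.normal(0.0, resid_sd, size=len(t))

    y = (
        fe.intercept
        + cg_effects[breed_num, cg_idx]
        + aod_effects[breed_num, aod_idx]
        + fe.breed_composition_slope * breed_comp
        + expressed
        + e
    )

    pheno = pd.DataFrame(
        {
            "animal": t["animal"],
            "breed": breed_arr,
            "sex": t["sex"],
            "role": role,
            config.trait: np.where(phenotyped, y, np.nan),
            "contemporary_group": [
                f"{b}_cg{k + 1:02d}" for b, k in zip(breed_arr, cg_idx)
            ],
            "age_of_dam": [f"aod{k + 1}" for k in aod_idx],
            "breed_composition": breed_comp,
        }
    )
    pheno = pheno.loc[phenotyped].reset_index(drop=True)

    animal_index = t["animal"].to_numpy()
    truth = SimTruth(
        qtl_ids=genotypes.markers["marker"].to_numpy()[qtl_idx],
        qtl_effects=effects,
        true_breeding_values=pd.DataFrame(tbv, index=animal_index, columns=list(SEXES)),
        marked_breeding_values=pd.DataFrame(marked, index=animal_index, columns=list(SEXES)),
        realized_rho=realized_rho,
        variance_partition={
            "h2_marked": config.h2_marked,
            "h2_polygenic": config.h2_polygenic,
            "residual": config.h2_residual,
            "phenotypic": 1.0,
        },
    )
    return pheno, truth


def allele_frequencies_safe(genotypes: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Across-set allele frequencies with NaN replaced by 0 (monomorphic)."""
    from .kinship import allele_frequencies

    p, n_obs = allele_frequencies(genotypes)
    return np.nan_to_num(p, nan=0.0), n_obs


def simulate_dataset(config: SimConfig):
    """Convenience: pedigree, genotypes, phenotypes and truth in one call."""
    ped = simulate_pedigree(config)
    geno = simulate_genotypes(ped, config)
    pheno, truth = simulate_effects_and_phenotypes(ped, geno, config)
    return ped, geno, pheno, truth
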