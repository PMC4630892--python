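"""Shared fixtures: small synthetic datasets and reusable fitted studies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from xbreed import (
    PipelineConfig,
    SimConfig,
    build_grm,
    build_nrm,
    run_study,
    simulate_dataset,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


SMALL_SIM = dict(
    n_sires=10,
    n_dams=80,
    n_offspring_cows=250,
    n_offspring_bulls=120,
    n_snps=1500,
    n_qtl=150,
    rho_qtl=0.8,
)


@pytest.fixture(scope="session")
def small_dataset():
    """One small two-breed dataset shared by read-only tests."""
    cfg = SimConfig(seed=42, **SMALL_SIM)
    ped, geno, pheno, truth = simulate_dataset(cfg)
    return {"config": cfg, "pedigree": ped, "genotypes": geno, "phenotypes": pheno, "truth": truth}


@pytest.fixture(scope="session")
def small_matrices(small_dataset):
    A = build_nrm(small_dataset["pedigree"])
    G = build_grm(small_dataset["genotypes"])
    return {"A": A, "G": G}


@pytest.fixture(scope="session")
def small_study():
    """A complete small-scale study run (pipeline in memory)."""
    cfg = PipelineConfig(sim=SimConfig(seed=7, **SMALL_SIM))
    return run_study(cfg)


def random_pedigree_frame(rng: np.random.Generator, n: int = 30) -> pd.DataFrame:
    """Random valid single-breed pedigree: parents always precede offspring."""
    records = []
    for i in range(n):
        sex = "M" if rng.random() < 0.5 else "F"
        sire = dam = "0"
        if i >= 2 and rng.random() < 0.7:
            males = [r[0] for r in records if r[4] == "M"]
            females = [r[0] for r in records if r[4] == "F"]
            if males and rng.random() < 0.9:
                sire = str(rng.choice(males))
            if females and rng.random() < 0.9:
                dam = str(rng.choice(females))
        records.append((f"A{i:03d}", sire, dam, "BB", sex))
    return pd.DataFrame(records, columns=["animal", "sire", "dam", "breed", "sex"])


def nrm_oracle(table: pd.DataFrame) -> np.ndarray:
    """Exhaustive recursive tabular-method oracle (memoised, no truncation).

    Independent of the production implementation: relationship defined
    pairwise through the older animal's parents, diagonal through the
    parents' relationship.
    """
    ids = list(table["animal"])
    pos = {a: i for i, a in enumerate(ids)}
    parents = {}
    for _, row in table.iterrows():
        s = pos.get(row["sire"]) if row["sire"] != "0" else None
        d = pos.get(row["dam"]) if row["dam"] != "0" else None
        parents[pos[row["animal"]]] = (s, d)
    cache = {}

    def rel(i, j):
        if i is None or j is None:
            return 0.0
        if (i, j) in cache:
            return cache[(i, j)]
        if i == j:
            s, d = parents[i]
            val = 1.0 + 0.5 * (rel(s, d) if s is not None and d is not None else 0.0)
        else:
            # recurse through the younger animal (larger index: rows are
            # listed parents-first by construction)
            young, old = (i, j) if i > j else (j, i)
            s, d = parents[young]
            val = 0.5 * (rel(old, s) + rel(old, d))
        cache[(i, j)] = cache[(j, i)] = val
        return val

    n = len(ids)
    A = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            A[i, j] = A[j, i] = rel(i, j)
    return A
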