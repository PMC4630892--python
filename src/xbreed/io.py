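"""Text I/O: pedigrees, phenotypes, PLINK .ped/.map genotypes, matrices, reports.

Genotypes travel either as PLINK text (.ped with two allele columns per
marker, .map with chrom/marker/cM/pos) or as a simple headered
delimited dialect (one row per animal, one 0/1/2 column per marker,
blank or NA for missing).  Relationship matrices are stored as a dense
``.npy`` with an ``.ids`` text sidecar, with an optional text-triplet
export.  Variance components and reports serialise to JSON/CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinship import (
    ConfigurationError,
    GenotypeMatrix,
    MISSING_CODE,
    Pedigree,
    RelationshipMatrix,
)
from .mixedmodel import VarianceComponents

PED_MISSING_ALLELE = "0"


# ---------------------------------------------------------------------------
# Pedigree / phenotypes
# ---------------------------------------------------------------------------


def write_pedigree(pedigree: Pedigree, path) -> None:
    pedigree.table.to_csv(path, index=False)


def read_pedigree(path) -> Pedigree:
    return Pedigree(pd.read_csv(path, dtype=str))


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"animal": str})


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def write_plink_text(genotypes: GenotypeMatrix, prefix, pedigree: Pedigree | None = None) -> None:
    """PLINK .ped/.map text pair; allele pairs follow the marker map labels."""
    prefix = Path(prefix)
    m = genotypes.markers
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, row in m.iterrows():
            fh.write(f"{row['chrom']}\t{row['marker']}\t0\t{row['pos']}\n")
    ped_info = None
    if pedigree is not None:
        ped_info = pedigree.table.set_index("animal")
    a1 = m["allele1"].to_numpy()
    a2 = m["allele2"].to_numpy()
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, animal in enumerate(genotypes.ids):
            if ped_info is not None and animal in ped_info.index:
                rec = ped_info.loc[animal]
                fam, sire, dam = rec["breed"], rec["sire"], rec["dam"]
                sex = "1" if rec["sex"] == "M" else "2"
            else:
                fam, sire, dam, sex = "FAM", "0", "0", "0"
            codes = genotypes.codes[i]
            pairs = np.empty((len(codes), 2), dtype=object)
            # count of the second allele: 0 -> a1 a1, 1 -> a1 a2, 2 -> a2 a2
            pairs[:, 0] = np.where(codes >= 1, a2, a1)
            pairs[:, 1] = np.where(codes == 2, a2, a1)
            missing = codes == MISSING_CODE
            pairs[missing, 0] = PED_MISSING_ALLELE
            pairs[missing, 1] = PED_MISSING_ALLELE
            fields = [fam, str(animal), str(sire), str(dam), sex, "-9"]
            fields += [" ".join(p) for p in pairs]
            fh.write(" ".join(fields) + "\n")


def read_plink_text(prefix) -> GenotypeMatrix:
    """Read a .ped/.map pair; codes count the second allele per marker.

    The second allele of each marker is taken as the lexicographically
    later of the alleles observed at that marker (deterministic without
    an external allele reference); missing calls are ``0 0``.
    """
    prefix = Path(prefix)
    markers = pd.read_csv(
        prefix.with_suffix(".map"),
        sep=r"\s+",
        header=None,
        names=["chrom", "marker", "cm", "pos"],
        dtype={"marker": str},
    )
    ids, rows = [], []
    n_mark = len(markers)
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 6 + 2 * n_mark:
                raise ConfigurationError(
                    f".ped row for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts) - 6} allele fields, expected {2 * n_mark}"
                )
            ids.append(parts[1])
            rows.append(parts[6:])
    alleles = np.asarray(rows, dtype=object).reshape(len(ids), n_mark, 2)
    codes = np.zeros((len(ids), n_mark), dtype=np.int8)
    allele1 = np.empty(n_mark, dtype=object)
    allele2 = np.empty(n_mark, dtype=object)
    for j in range(n_mark):
        col = alleles[:, j, :]
        obs = sorted(set(col.ravel()) - {PED_MISSING_ALLELE})
        if len(obs) > 2:
            raise ConfigurationError(f"marker {markers['marker'][j]!r} has >2 alleles")
        a1 = obs[0] if obs else "A"
        a2 = obs[-1] if obs else "B"
        allele1[j], allele2[j] = a1, a2
        missing = (col == PED_MISSING_ALLELE).any(axis=1)
        codes[:, j] = (col == a2).sum(axis=1).astype(np.int8)
        codes[missing, j] = MISSING_CODE
    markers = pd.DataFrame(
        {
            "marker": markers["marker"],
            "chrom": markers["chrom"],
            "pos": markers["pos"],
            "allele1": allele1,
            "allele2": allele2,
        }
    )
    return GenotypeMatrix(ids=np.asarray(ids, dtype=object), markers=markers, codes=codes)


def write_genotypes_delimited(genotypes: GenotypeMatrix, path) -> None:
    """Headered CSV dialect: animal column + one 0/1/2 column per marker."""
    df = pd.DataFrame(
        genotypes.codes.astype(object),
        columns=genotypes.markers["marker"],
    )
    df = df.mask(genotypes.codes == MISSING_CODE)
    df.insert(0, "animal", genotypes.ids)
    df.to_csv(path, index=False)


def read_genotypes_delimited(path, marker_map: pd.DataFrame | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, dtype={"animal": str})
    ids = df["animal"].to_numpy(dtype=object)
    codes = df.drop(columns="animal")
    marker_ids = list(codes.columns)
    arr = codes.to_numpy(dtype="float64")
    out = np.where(np.isnan(arr), MISSING_CODE, arr).astype(np.int8)
    if marker_map is None:
        marker_map = pd.DataFrame(
            {
                "marker": marker_ids,
                "chrom": 0,
                "pos": np.arange(len(marker_ids)),
                "allele1": "A",
                "allele2": "B",
            }
        )
    return GenotypeMatrix(ids=ids, markers=marker_map, codes=out)


# ---------------------------------------------------------------------------
# Relationship matrices
# ---------------------------------------------------------------------------


def write_relationship_matrix(matrix: RelationshipMatrix, prefix, text_triplets: bool = False) -> None:
    prefix = Path(prefix)
    np.save(prefix.with_suffix(".npy"), matrix.values)
    meta = {
        "kind": matrix.kind,
        "provenance": matrix.provenance,
        "blend": matrix.blend,
        "ids": [str(i) for i in matrix.ids],
    }
    prefix.with_suffix(".ids.json").write_text(json.dumps(meta))
    if text_triplets:
        with open(prefix.with_suffix(".txt"), "w") as fh:
            fh.write("i\tj\tvalue\n")
            V = matrix.values
            for i in range(len(V)):
                for j in range(i + 1):
                    fh.write(f"{matrix.ids[i]}\t{matrix.ids[j]}\t{V[i, j]:.10g}\n")


def read_relationship_matrix(prefix) -> RelationshipMatrix:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".ids.json").read_text())
    values = np.load(prefix.with_suffix(".npy"))
    return RelationshipMatrix(
        ids=np.asarray(meta["ids"], dtype=object),
        values=values,
        kind=meta["kind"],
        provenance=meta.get("provenance", ""),
        blend=meta.get("blend"),
    )


# ---------------------------------------------------------------------------
# Fitted components / marker lists
# ---------------------------------------------------------------------------


def components_to_dict(vc: VarianceComponents) -> dict:
    return {
        "traits": list(vc.traits),
        "terms": {k: np.asarray(v).tolist() for k, v in vc.terms.items()},
        "residual": np.asarray(vc.residual).tolist(),
        "loglik": float(vc.loglik),
        "n_iter": int(vc.n_iter),
        "converged": bool(vc.converged),
        "ll_trace": np.asarray(vc.ll_trace).tolist(),
    }


def write_components(vc: VarianceComponents, path) -> None:
    Path(path).write_text(json.dumps(components_to_dict(vc), indent=1))


def read_components(path) -> VarianceComponents:
    d = json.loads(Path(path).read_text())
    return VarianceComponents(
        traits=tuple(d["traits"]),
        terms={k: np.asarray(v, dtype=float) for k, v in d["terms"].items()},
        residual=np.asarray(d["residual"], dtype=float),
        loglik=d["loglik"],
        n_iter=d["n_iter"],
        converged=d["converged"],
        ll_trace=np.asarray(d["ll_trace"]),
    )


def write_marker_list(markers, path, header: dict | None = None) -> None:
    """One marker per line with a commented provenance header."""
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}: {v}\n")
        for m in markers:
            fh.write(f"{m}\n")


def read_marker_list(path) -> list:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out
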