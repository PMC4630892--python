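"""Pedigree- and marker-based relationship matrices for multi-breed data.

The two matrices at the heart of across-breed genomic evaluation are

* the numerator relationship matrix **A**, the expected additive
  relationships implied by the pedigree (tabular method, optionally
  truncated at a fixed number of ancestor generations), and
* the genomic relationship matrix **G**, built from centred 0/1/2 SNP
  codes after VanRaden and blended with a small multiple of the identity
  so that it is guaranteed invertible:

      G = b * S S' / (2 * sum_i p_i (1 - p_i)) + (1 - b) * I,   b = 0.95

  where S holds genotype codes column-centred by twice the allele
  frequency p_i.  By default p_i is computed on the combined
  across-breed set of animals, which is what makes the between-breed
  block of G informative even when the pedigree links two populations
  not at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for an unknown parent in pedigree tables
UNKNOWN_PARENT = "0"

MISSING_CODE = -1


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, unknown id, ...)."""


class ConfigurationError(ValueError):
    """Invalid parameter passed to a builder."""


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


@dataclass
class Pedigree:
    """Pedigree records: one row per animal with sire/dam/breed/sex.

    ``sire`` / ``dam`` equal to :data:`UNKNOWN_PARENT` (or NA) mean the
    parent is unknown.  Every known parent must itself have a row, ids
    must be unique, and the parent graph must be acyclic.
    """

    table: pd.DataFrame

    _order: np.ndarray = field(init=False, repr=False, default=None)

    REQUIRED = ("animal", "sire", "dam", "breed", "sex")

    def __post_init__(self) -> None:
        t = self.table
        missing_cols = [c for c in self.REQUIRED if c not in t.columns]
        if missing_cols:
            raise PedigreeError(f"pedigree table lacks columns {missing_cols}")
        t = t.copy()
        for c in ("animal", "sire", "dam"):
            t[c] = t[c].fillna(UNKNOWN_PARENT).astype(str)
        if t["animal"].duplicated().any():
            dup = t.loc[t["animal"].duplicated(), "animal"].iloc[0]
            raise PedigreeError(f"duplicate animal id {dup!r}")
        known = set(t["animal"])
        for col in ("sire", "dam"):
            bad = set(t[col]) - known - {UNKNOWN_PARENT}
            if bad:
                raise PedigreeError(
                    f"{col} id {sorted(bad)[0]!r} referenced but has no pedigree record"
                )
        self.table = t.reset_index(drop=True)
        self._order = self._toposort()

    # -- structure -----------------------------------------------------

    def _toposort(self) -> np.ndarray:
        """Kahn topological order (parents first); raises on cycles."""
        t = self.table
        idx = {a: i for i, a in enumerate(t["animal"])}
        n = len(t)
        parents = np.full((n, 2), -1, dtype=np.int64)
        for j, col in enumerate(("sire", "dam")):
            vals = t[col].to_numpy()
            for i, v in enumerate(vals):
                if v != UNKNOWN_PARENT:
                    parents[i, j] = idx[v]
        children: list[list[int]] = [[] for _ in range(n)]
        indeg = np.zeros(n, dtype=np.int64)
        for i in range(n):
            for p in parents[i]:
                if p >= 0:
                    children[p].append(i)
                    indeg[i] += 1
        stack = [i for i in range(n) if indeg[i] == 0]
        order = []
        while stack:
            i = stack.pop()
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    stack.append(c)
        if len(order) != n:
            raise PedigreeError("pedigree contains a cycle (an animal is its own ancestor)")
        self._parents = parents
        return np.asarray(order)

    @property
    def animals(self) -> np.ndarray:
        return self.table["animal"].to_numpy()

    @property
    def n_animals(self) -> int:
        return len(self.table)

    def founders(self) -> np.ndarray:
        t = self.table
        is_founder = (t["sire"] == UNKNOWN_PARENT) & (t["dam"] == UNKNOWN_PARENT)
        return t.loc[is_founder, "animal"].to_numpy()

    def parent_indices(self) -> np.ndarray:
        """(n, 2) array of sire/dam row indices, -1 for unknown."""
        return self._parents.copy()

    def topological_order(self) -> np.ndarray:
        """Row indices such that every parent precedes its offspring."""
        return self._order.copy()

    def breed_of(self) -> pd.Series:
        return self.table.set_index("animal")["breed"]


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Dense 0/1/2 genotype codes (count of the second allele).

    ``codes`` is (n_animals, n_markers) int8 with :data:`MISSING_CODE`
    marking missing calls.  ``markers`` carries the map: columns
    ``marker, chrom, pos, allele1, allele2`` with unique marker ids.
    """

    ids: np.ndarray
    markers: pd.DataFrame
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.ids), len(self.markers)):
            raise ConfigurationError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.ids)} animals x {len(self.markers)} markers"
            )
        valid = np.isin(self.codes, (0, 1, 2, MISSING_CODE))
        if not valid.all():
            raise ConfigurationError("genotype codes must be 0, 1, 2 or missing")
        if self.markers["marker"].duplicated().any():
            raise ConfigurationError("marker identifiers must be unique")
        self.markers = self.markers.reset_index(drop=True)

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def animal_indexer(self, animals) -> np.ndarray:
        pos = pd.Index(self.ids).get_indexer(np.asarray(animals, dtype=object))
        if (pos < 0).any():
            missing = np.asarray(animals)[pos < 0][0]
            raise KeyError(f"animal {missing!r} not genotyped")
        return pos

    def marker_indexer(self, markers) -> np.ndarray:
        pos = self.markers.set_index("marker").index.get_indexer(list(markers))
        if (pos < 0).any():
            missing = list(markers)[int(np.argmax(pos < 0))]
            raise KeyError(f"marker {missing!r} not on the panel")
        return pos

    def subset(self, animals=None, markers=None) -> "GenotypeMatrix":
        ai = slice(None) if animals is None else self.animal_indexer(animals)
        mi = slice(None) if markers is None else self.marker_indexer(markers)
        return GenotypeMatrix(
            ids=self.ids[ai],
            markers=self.markers.iloc[mi] if markers is not None else self.markers,
            codes=self.codes[ai][:, mi],
        )

    def dosage(self, animals=None) -> np.ndarray:
        """float64 codes with missing set to NaN."""
        codes = self.codes if animals is None else self.codes[self.animal_indexer(animals)]
        out = codes.astype(np.float64)
        out[codes == MISSING_CODE] = np.nan
        return out


# ---------------------------------------------------------------------------
# Relationship matrices
# ---------------------------------------------------------------------------


@dataclass
class RelationshipMatrix:
    """Symmetric animal-by-animal relationship matrix with provenance."""

    ids: np.ndarray
    values: np.ndarray
    kind: str  # "pedigree" | "genomic"
    provenance: str = ""
    blend: float | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ConfigurationError("relationship matrix must be square over its ids")
        if n and not self._is_symmetric():
            raise ConfigurationError("relationship matrix must be symmetric")
        if self.kind not in ("pedigree", "genomic"):
            raise ConfigurationError(f"unknown relationship kind {self.kind!r}")

    def _is_symmetric(self, tol: float = 1e-8) -> bool:
        V = self.values
        n = V.shape[0]
        if n <= 2000:
            return bool(np.abs(V - V.T).max() <= tol)
        # large matrices: transpose comparison is cache-hostile; check a
        # random sample of entry pairs instead
        rng = np.random.default_rng(0)
        i = rng.integers(0, n, size=1_000_000)
        j = rng.integers(0, n, size=1_000_000)
        return bool(np.abs(V[i, j] - V[j, i]).max() <= tol)

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    def indexer(self, animals) -> np.ndarray:
        pos = pd.Index(self.ids).get_indexer(np.asarray(animals, dtype=object))
        if (pos < 0).any():
            missing = np.asarray(animals)[pos < 0][0]
            raise KeyError(f"animal {missing!r} not covered by this {self.kind} matrix")
        return pos

    def subset(self, animals) -> "RelationshipMatrix":
        pos = self.indexer(animals)
        return replace(self, ids=self.ids[pos], values=self.values[np.ix_(pos, pos)])


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def build_nrm(
    pedigree: Pedigree,
    max_ancestor_generations: int = 3,
    subjects=None,
) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Recursion: a_ij = (a_{j,sire(i)} + a_{j,dam(i)}) / 2 and diagonal
    1 + a_{sire,dam}/2, applied in topological order.  Ancestors more
    than ``max_ancestor_generations`` above every subject are treated as
    unknown founders, mirroring evaluations that trace a fixed number of
    ancestor generations.

    Parameters
    ----------
    subjects : optional sequence of animal ids to report (default: all
        animals in the pedigree, each at ancestor depth 0).
    """
    if max_ancestor_generations < 1:
        raise ConfigurationError("max_ancestor_generations must be >= 1")
    t = pedigree.table
    ids = t["animal"].to_numpy()
    n = len(ids)
    parents = pedigree.parent_indices()

    if subjects is None:
        subject_idx = np.arange(n)
    else:
        pos = pd.Index(ids).get_indexer(np.asarray(subjects, dtype=object))
        if (pos < 0).any():
            bad = np.asarray(subjects)[pos < 0][0]
            raise PedigreeError(f"subject {bad!r} not in the pedigree")
        subject_idx = pos

    # ancestor depth = min #generations up from any subject
    depth = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    depth[subject_idx] = 0
    frontier = list(subject_idx)
    while frontier:
        nxt = []
        for i in frontier:
            for p in parents[i]:
                if p >= 0 and depth[i] + 1 < depth[p]:
                    depth[p] = depth[i] + 1
                    nxt.append(p)
        frontier = nxt
    keep = depth <= max_ancestor_generations
    # links from animals at the truncation depth are cut (parents unknown)
    eff_parents = parents.copy()
    eff_parents[depth >= max_ancestor_generations] = -1
    eff_parents[~keep] = -1

    kept = np.flatnonzero(keep)
    new_pos = np.full(n, -1, dtype=np.int64)
    new_pos[kept] = np.arange(len(kept))
    order = [new_pos[i] for i in pedigree.topological_order() if keep[i]]
    par = np.where(eff_parents[kept] >= 0, new_pos[eff_parents[kept]], -1)

    m = len(kept)
    # disconnected pedigree components (e.g. the two breeds) have zero
    # relationship; computing each block separately avoids quadratic work
    # on structurally-zero entries
    comp = np.arange(m)

    def _find(x):
        root = x
        while comp[root] != root:
            root = comp[root]
        while comp[x] != root:
            comp[x], x = root, comp[x]
        return root

    for i in range(m):
        for p in par[i]:
            if p >= 0:
                ra, rb = _find(i), _find(p)
                if ra != rb:
                    comp[ra] = rb
    roots = np.array([_find(i) for i in range(m)])
    A = np.zeros((m, m))
    for root in np.unique(roots):
        members = np.flatnonzero(roots == root)
        local = np.full(m, -1, dtype=np.int64)
        local[members] = np.arange(len(members))
        mloc = len(members)
        B = np.zeros((mloc, mloc))
        buf = np.empty(mloc)
        for i in order:
            if roots[i] != root:
                continue
            li = local[i]
            s, d = par[i]
            ls = local[s] if s >= 0 else -1
            ld = local[d] if d >= 0 else -1
            if ls >= 0 and ld >= 0:
                np.add(B[ls], B[ld], out=buf)
                buf *= 0.5
                diag = 1.0 + 0.5 * B[ls, ld]
            elif ls >= 0 or ld >= 0:
                np.multiply(B[ls if ls >= 0 else ld], 0.5, out=buf)
                diag = 1.0
            else:
                buf[:] = 0.0
                diag = 1.0
            B[li] = buf
            B[:, li] = buf
            B[li, li] = diag
        A[np.ix_(members, members)] = B

    out_pos = new_pos[subject_idx]
    return RelationshipMatrix(
        ids=ids[subject_idx],
        values=A[np.ix_(out_pos, out_pos)],
        kind="pedigree",
        provenance=f"tabular method, {max_ancestor_generations} ancestor generations",
    )


def allele_frequencies(
    genotypes: GenotypeMatrix, animals=None
) -> tuple[np.ndarray, np.ndarray]:
    """Second-allele frequency p_i = mean(code)/2 over non-missing calls.

    Returns ``(p, n_obs)`` aligned with the marker panel; markers with no
    non-missing call in the subset get ``p = NaN``.
    """
    codes = genotypes.codes if animals is None else genotypes.codes[
        genotypes.animal_indexer(animals)
    ]
    if codes.shape[0] == 0:
        raise ConfigurationError("allele frequencies need a non-empty animal subset")
    obs = codes != MISSING_CODE
    n_obs = obs.sum(axis=0)
    totals = np.where(obs, codes, 0).sum(axis=0, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, totals / (2.0 * n_obs), np.nan)
    return p, n_obs


def build_grm(
    genotypes: GenotypeMatrix,
    markers=None,
    frequencies: np.ndarray | None = None,
    blend: float = 0.95,
    animals=None,
    provenance: str = "",
) -> RelationshipMatrix:
    """Blended VanRaden genomic relationship matrix over a SNP subset.

    Monomorphic markers (p in {0, 1} or undefined) are dropped with a
    logged count; missing genotypes are mean-imputed, i.e. contribute 0
    after centring by 2 p_i.  With ``blend`` = b the result is
    ``b * ZZ'/(2 sum p(1-p)) + (1-b) * I`` whose smallest eigenvalue is
    at least ``1 - b``.
    """
    if not (0.0 < blend <= 1.0):
        raise ConfigurationError(f"blend must be in (0, 1], got {blend}")
    sub = genotypes if animals is None else genotypes.subset(animals=animals)
    if markers is not None:
        mi = genotypes.marker_indexer(markers)
    else:
        mi = np.arange(genotypes.n_markers)
    if len(mi) == 0:
        raise ConfigurationError("empty SNP subset")
    if frequencies is None:
        p_all, _ = allele_frequencies(genotypes)  # across the full animal set
        p = p_all[mi]
    else:
        frequencies = np.asarray(frequencies, dtype=np.float64)
        if len(frequencies) != len(mi):
            raise ConfigurationError("frequencies must align with the SNP subset")
        p = frequencies

    poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    n_dropped = int((~poly).sum())
    if n_dropped:
        logger.info("build_grm: dropping %d monomorphic/undefined SNPs", n_dropped)
    if not poly.any():
        raise ConfigurationError("all SNPs in the subset are monomorphic or undefined")
    mi = mi[poly]
    p = p[poly]

    codes = sub.codes[:, mi].astype(np.float64)
    miss = codes < 0
    Z = codes - 2.0 * p[None, :]
    Z[miss] = 0.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    G = (Z @ Z.T) / denom
    G *= blend
    if blend < 1.0:
        G[np.diag_indices_from(G)] += 1.0 - blend
    return RelationshipMatrix(
        ids=sub.ids,
        values=G,
        kind="genomic",
        provenance=provenance or f"{len(mi)} SNPs, blend {blend}",
        blend=blend,
    )


def relationship_summary(
    matrix: RelationshipMatrix,
    breed_labels,
    quantiles=(0.05, 0.25, 0.5, 0.75, 0.95),
) -> pd.DataFrame:
    """Within/between-breed distribution of off-diagonal relationships.

    One row per unordered breed pair with pair count, mean, sd and the
    requested quantiles; the diagonal is summarised separately per breed
    under block label ``"<breed> diagonal"``.
    """
    labels = pd.Series(breed_labels)
    if set(labels.index) >= set(matrix.ids):
        labels = labels.loc[list(matrix.ids)]
    elif len(labels) == matrix.n_animals:
        labels.index = list(matrix.ids)
    else:
        raise ConfigurationError("breed labels must cover all animals in the matrix")
    breeds = sorted(labels.unique())
    V = matrix.values
    rows = []

    def _describe(block_label, vals):
        vals = np.asarray(vals, dtype=np.float64)
        rec = {
            "block": block_label,
            "n_pairs": vals.size,
            "mean": np.mean(vals) if vals.size else np.nan,
            "sd": np.std(vals, ddof=1) if vals.size > 1 else np.nan,
        }
        for q in quantiles:
            rec[f"q{int(round(q * 100)):02d}"] = (
                np.quantile(vals, q) if vals.size else np.nan
            )
        rows.append(rec)

    pos = {b: np.flatnonzero(labels.to_numpy() == b) for b in breeds}
    for i, b1 in enumerate(breeds):
        block = V[np.ix_(pos[b1], pos[b1])]
        iu = np.triu_indices(len(pos[b1]), k=1)
        _describe(f"{b1} x {b1}", block[iu])
        _describe(f"{b1} diagonal", np.diag(block))
        for b2 in breeds[i + 1 :]:
            _describe(f"{b1} x {b2}", V[np.ix_(pos[b1], pos[b2])].ravel())
    return pd.DataFrame(rows)
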