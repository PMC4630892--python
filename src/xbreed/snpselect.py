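"""Sign-based SNP selection across two breeds: "list-of-same" / "list-of-different".

For each trait, the markers whose estimated allele-substitution effects
point the same way in both breeds (or opposite ways) are ranked by a
combined two-breed significance and the top 10 % of the panel is kept.
Per-direction lists are unioned over traits, and any marker landing in
both the same-direction and different-direction unions is removed from
both.  The two surviving lists define the restricted genomic
relationship matrices G_S (consistent LD phase between breeds) and G_D
(inconsistent phase) whose behaviour under bi-variate REML and GBLUP is
the point of the whole exercise.

The combined ranking defaults to the sum of -log10 p over the two
breeds; because only the ordering matters for taking a fixed fraction,
no multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinship import ConfigurationError, GenotypeMatrix, RelationshipMatrix, build_grm

logger = logging.getLogger(__name__)

RANKINGS = ("sum_log_p", "min_p", "max_p")


@dataclass
class SnpLists:
    """De-overlapped same/different marker lists with per-trait provenance."""

    list_of_same: list
    list_of_different: list
    #: one row per (marker, trait, direction) membership before de-overlap
    membership: pd.DataFrame
    #: per direction, fraction of list members contributing to 1..k traits
    trait_counts: pd.DataFrame

    def __post_init__(self) -> None:
        # merge_and_deoverlap guarantees disjoint lists; hand-built lists
        # (e.g. degenerate full-panel variants) may overlap deliberately
        overlap = set(self.list_of_same) & set(self.list_of_different)
        if overlap:
            warnings.warn(
                f"same/different lists share {len(overlap)} markers", RuntimeWarning
            )


def _combined_score(pa: np.ndarray, pb: np.ndarray, ranking: str) -> np.ndarray:
    tiny = np.finfo(float).tiny
    la, lb = -np.log10(np.maximum(pa, tiny)), -np.log10(np.maximum(pb, tiny))
    if ranking == "sum_log_p":
        return la + lb
    if ranking == "min_p":  # best single-breed significance
        return np.maximum(la, lb)
    if ranking == "max_p":  # significance of the weaker breed
        return np.minimum(la, lb)
    raise ConfigurationError(f"unknown ranking {ranking!r}; choose from {RANKINGS}")


def select_per_trait(
    gwas_a: pd.DataFrame,
    gwas_b: pd.DataFrame,
    fraction: float = 0.10,
    direction: str = "same",
    ranking: str = "sum_log_p",
) -> list:
    """Top markers of one trait whose effect signs agree (or disagree).

    The quota is ``ceil(fraction * panel size)`` counted against the full
    marker panel of the scan, not against the sign-qualifying subset.
    Markers excluded from either scan, or with an exactly zero effect in
    either breed (no direction defined), never qualify.  Ties are broken
    by the summed |Wald statistic| and then by marker id, so the
    selection is deterministic and independent of table order.
    """
    if direction not in ("same", "different"):
        raise ConfigurationError("direction must be 'same' or 'different'")
    if not (0.0 < fraction <= 1.0):
        raise ConfigurationError("fraction must be in (0, 1]")
    a = gwas_a.set_index("marker")
    b = gwas_b.set_index("marker")
    panel = a.index.union(b.index)
    quota = math.ceil(fraction * len(panel))
    common = a.index.intersection(b.index)
    a, b = a.loc[common], b.loc[common]
    usable = (
        ~a["excluded"].to_numpy()
        & ~b["excluded"].to_numpy()
        & np.isfinite(a["effect"].to_numpy())
        & np.isfinite(b["effect"].to_numpy())
        & (a["effect"].to_numpy() != 0.0)
        & (b["effect"].to_numpy() != 0.0)
    )
    sign_prod = np.sign(a["effect"].to_numpy()) * np.sign(b["effect"].to_numpy())
    qualify = usable & (sign_prod > 0 if direction == "same" else sign_prod < 0)
    cand = pd.DataFrame(
        {
            "marker": common.to_numpy()[qualify],
            "score": _combined_score(
                a["pvalue"].to_numpy()[qualify], b["pvalue"].to_numpy()[qualify], ranking
            ),
            "stat": np.abs(a["statistic"].to_numpy()[qualify])
            + np.abs(b["statistic"].to_numpy()[qualify]),
        }
    )
    if len(cand) < quota:
        warnings.warn(
            f"only {len(cand)} {direction}-direction markers qualify "
            f"(quota {quota}); returning all of them",
            RuntimeWarning,
        )
    cand = cand.sort_values(
        ["score", "stat", "marker"], ascending=[False, False, True], kind="mergesort"
    )
    return cand["marker"].head(quota).tolist()


def merge_and_deoverlap(same_sets: dict, different_sets: dict) -> SnpLists:
    """Union per-trait lists within direction, then drop cross-direction overlap.

    ``same_sets`` / ``different_sets`` map trait name -> iterable of
    marker ids.  The trait-count summary reports, per direction, the
    fraction of surviving list members that contributed to 1, 2, ...
    traits (fractions sum to 1).
    """
    records = []
    for direction, sets in (("same", same_sets), ("different", different_sets)):
        for trait, markers in sets.items():
            for m in markers:
                records.append((m, trait, direction))
    membership = pd.DataFrame(records, columns=["marker", "trait", "direction"])
    union_same = set(membership.loc[membership.direction == "same", "marker"])
    union_diff = set(membership.loc[membership.direction == "different", "marker"])
    overlap = union_same & union_diff
    if overlap:
        logger.info("merge_and_deoverlap: removing %d overlapping markers", len(overlap))
    same = sorted(union_same - overlap)
    diff = sorted(union_diff - overlap)

    count_rows = []
    n_traits_total = max(len(same_sets), len(different_sets), 1)
    for direction, kept in (("same", same), ("different", diff)):
        if not kept:
            continue
        sub = membership[(membership.direction == direction) & membership.marker.isin(kept)]
        per_marker = sub.groupby("marker")["trait"].nunique()
        frac = per_marker.value_counts(normalize=True).sort_index()
        for k in range(1, n_traits_total + 1):
            count_rows.append((direction, k, float(frac.get(k, 0.0))))
    trait_counts = pd.DataFrame(count_rows, columns=["direction", "n_traits", "fraction"])
    return SnpLists(
        list_of_same=same,
        list_of_different=diff,
        membership=membership,
        trait_counts=trait_counts,
    )


def build_variant_grms(
    genotypes: GenotypeMatrix, lists: SnpLists, blend: float = 0.95
) -> tuple[RelationshipMatrix, RelationshipMatrix]:
    """G_S and G_D: blended GRMs restricted to each de-overlapped list.

    Frequencies are the across-breed defaults of :func:`~xbreed.kinship.build_grm`.
    """
    out = []
    for name, markers in (("list-of-same", lists.list_of_same),
                          ("list-of-different", lists.list_of_different)):
        if not markers:
            raise ConfigurationError(f"{name} is empty")
        try:
            grm = build_grm(
                genotypes,
                markers=markers,
                blend=blend,
                provenance=f"{name} ({len(markers)} SNPs), blend {blend}",
            )
        except ConfigurationError as exc:
            raise ConfigurationError(f"{name}: {exc}") from exc
        out.append(grm)
    return out[0], out[1]
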