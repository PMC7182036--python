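"""Cross-period comparison of top-gene lists.

The three gestational top-50 lists are merged into one gestation set, giving a
4-way Venn over {gestation, birth, newborn, infant}; each gene is assigned to
exactly one of the 15 regions by its membership signature.  The all-period
core is computed separately as the intersection of the six *un-merged* lists,
so a gene must be top-ranked in every single period to qualify.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

__all__ = ["VennPartition", "combine_gestation", "venn_partition", "VENN_SETS"]

VENN_SETS = ("GESTATION", "BIRTH", "NEWBORN", "INFANT")


def _region_label(members: Iterable[str]) -> str:
    order = {s: i for i, s in enumerate(VENN_SETS)}
    return "+".join(sorted(members, key=order.__getitem__))


@dataclass(frozen=True)
class VennPartition:
    """Disjoint 15-region partition of the union of the four input sets, plus
    the six-list all-period core."""

    region_membership: dict[str, frozenset[str]]
    core_all_periods: frozenset[str]

    def region(self, *sets: str) -> frozenset[str]:
        return self.region_membership.get(_region_label(sets), frozenset())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": label, "n_genes": len(genes), "genes": ";".join(sorted(genes))}
            for label, genes in self.region_membership.items()
        ]
        return pd.DataFrame(rows, columns=["region", "n_genes", "genes"])


def combine_gestation(
    eg: Sequence[str], mg: Sequence[str], lg: Sequence[str]
) -> frozenset[str]:
    """Union of the three gestational top-gene lists (de-duplicated)."""
    if not (eg and mg and lg):
        raise ValueError("gestation lists must be non-empty")
    return frozenset(eg) | frozenset(mg) | frozenset(lg)


def venn_partition(
    gestation: Iterable[str],
    birth: Iterable[str],
    newborn: Iterable[str],
    infant: Iterable[str],
    per_period_lists: Sequence[Sequence[str]] | None = None,
) -> VennPartition:
    """Partition the union of the four sets into the 15 Venn regions.

    ``per_period_lists`` are the six original per-period lists (EG, MG, LG,
    birth, newborn, infant) used for the all-period core; when omitted the
    core falls back to the intersection of the four merged sets.
    """
    sets = {
        "GESTATION": frozenset(gestation),
        "BIRTH": frozenset(birth),
        "NEWBORN": frozenset(newborn),
        "INFANT": frozenset(infant),
    }
    regions: dict[str, set[str]] = {}
    for r in range(1, 5):
        for members in combinations(VENN_SETS, r):
            regions[_region_label(members)] = set()
    for gene in frozenset().union(*sets.values()):
        signature = tuple(s for s in VENN_SETS if gene in sets[s])
        regions[_region_label(signature)].add(gene)

    if per_period_lists is not None:
        if len(per_period_lists) != 6:
            raise ValueError("expected six per-period lists (EG, MG, LG, birth, newborn, infant)")
        core = frozenset.intersection(*(frozenset(l) for l in per_period_lists))
    else:
        core = frozenset.intersection(*sets.values())
    return VennPartition(
        region_membership={k: frozenset(v) for k, v in regions.items()},
        core_all_periods=core,
    )
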