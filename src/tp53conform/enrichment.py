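"""Fisher-exact enrichment of variant residues in structural categories.

Tests whether the residues hit by LFS- or HBC-associated variants are over-
or under-represented among Buried residues, secondary-structure classes or
interface residues of the TP53 tetramer.  The background universe is the set
of canonical positions present in at least one protein chain of the
structure; duplicate positions within a variant group are counted once and
positions absent from the structure are excluded from the tables (reported
separately).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .features import MissenseVariant

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "dedupe_residue_set",
    "fisher_exact_two_sided",
    "adjust_fdr",
    "test_category_enrichment",
    "enrichment_scan",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b, c, d) = (group&cat, group&!cat, !group&cat, !group&!cat)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    @property
    def odds_ratio(self) -> float:
        # zero cells yield 0 or inf rather than an error
        if self.b == 0 or self.c == 0:
            return float("inf") if self.a * self.d > 0 else (0.0 if self.a + self.d == 0 else float("inf"))
        return (self.a * self.d) / (self.b * self.c)


@dataclass(frozen=True)
class EnrichmentResult:
    group: str
    category: str
    chain: str  # chain id or "combined"
    table: ContingencyTable2x2
    odds_ratio: float
    p: float
    p_adjusted: float | None = None


def dedupe_residue_set(
    variants: Sequence[MissenseVariant],
    structure_positions: Iterable[int] | None = None,
) -> tuple[set[int], set[int]]:
    """Distinct canonical positions of a variant group.

    Two variants at the same residue count that residue once.  When
    ``structure_positions`` is given, positions absent from it are excluded
    from the testable set and returned separately (they carry no structural
    category).

    Returns
    -------
    (testable, excluded):
        testable positions, and the deduplicated positions dropped because
        the structure does not cover them.
    """
    positions = {v.position for v in variants}
    if structure_positions is None:
        return positions, set()
    universe = set(structure_positions)
    return positions & universe, positions - universe


def fisher_exact_two_sided(table: ContingencyTable2x2 | Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value (point-probability method).

    The p-value sums the hypergeometric probabilities of every table with the
    observed margins whose point probability does not exceed the observed
    one — the convention of R's ``fisher.test``.  Degenerate margins (a zero
    row or column total) admit a single table, so p = 1.
    """
    if isinstance(table, ContingencyTable2x2):
        arr = table.as_array()
    else:
        arr = np.asarray(table, dtype=int)
        if arr.shape != (2, 2) or (arr < 0).any():
            raise ValueError("need a 2x2 table of non-negative counts")
    if arr.sum() == 0 or 0 in arr.sum(axis=0) or 0 in arr.sum(axis=1):
        return 1.0
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def adjust_fdr(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    pvals = list(pvals)
    if not pvals:
        return []
    if min(pvals) < 0 or max(pvals) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(pvals, method="fdr_bh")[1])


def test_category_enrichment(
    group_positions: Iterable[int],
    category_positions: Iterable[int],
    universe: Iterable[int],
    group: str = "group",
    category: str = "category",
    chain: str = "combined",
) -> EnrichmentResult:
    """Fisher test of one residue group against one structural category.

    Builds the 2x2 table (group membership x category membership) over the
    universe of structure-covered canonical positions.
    """
    uni = set(universe)
    grp = set(group_positions)
    cat = set(category_positions) & uni
    stray = grp - uni
    if stray:
        raise ValueError(f"group positions outside universe: {sorted(stray)}")
    a = len(grp & cat)
    b = len(grp - cat)
    c = len(cat - grp)
    d = len(uni - grp - cat)
    table = ContingencyTable2x2(a, b, c, d)
    return EnrichmentResult(
        group, category, chain, table, table.odds_ratio, fisher_exact_two_sided(table)
    )


test_category_enrichment.__test__ = False  # "test" here means hypothesis test


def enrichment_scan(
    groups: Mapping[str, Iterable[int]],
    categories: Mapping[str, Iterable[int]],
    universe: Iterable[int],
    per_chain_categories: Mapping[str, Mapping[str, Iterable[int]]] | None = None,
) -> list[EnrichmentResult]:
    """All group x category tests with one FDR adjustment across the scan.

    ``per_chain_categories`` optionally maps category -> chain -> positions
    for monomer-by-monomer versions of the combined tests.
    """
    uni = set(universe)
    results: list[EnrichmentResult] = []
    for gname, gpos in groups.items():
        for cname, cpos in categories.items():
            results.append(test_category_enrichment(gpos, cpos, uni, gname, cname))
        if per_chain_categories:
            for cname, chains in per_chain_categories.items():
                for chain_id, cpos in chains.items():
                    results.append(
                        test_category_enrichment(gpos, cpos, uni, gname, cname, chain_id)
                    )
    adjusted = adjust_fdr([r.p for r in results])
    return [
        EnrichmentResult(r.group, r.category, r.chain, r.table, r.odds_ratio, r.p, adj)
        for r, adj in zip(results, adjusted)
    ]
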