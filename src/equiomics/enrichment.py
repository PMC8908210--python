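"""Pairwise comparison design, Venn set logic, and over-representation
analysis.

With six lines (three GE transformants, their parent, two related
conventional lines) all C(6,2) = 15 unordered pairwise comparisons are
enumerated and partitioned into four interpretation groups:

1. GE vs parent — the GE-attributable signal,
2. conventional vs parent and conventional vs conventional — the
   conventional-breeding baseline of natural variation,
3. GE vs GE — transformant-to-transformant variation,
4. GE vs conventional — cross-background differences.

Differential feature lists from those comparisons feed a flat-set
hypergeometric over-representation analysis with BH adjustment across
terms and a fold-enrichment score (list hit rate over population hit
rate).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

from scipy.stats import hypergeom

from .design import CONVENTIONAL, GE, PARENT, StudyDesign
from .stats import bh_adjust

#: precedence used to order the two lines inside a comparison label:
#: GE first, conventional next, parent last (so labels read e.g.
#: "DTS_108/TJ806" and "AR02/TJ806").
_ROLE_ORDER = {GE: 0, CONVENTIONAL: 1, PARENT: 2}

_GROUP_BY_ROLES = {
    frozenset({GE, PARENT}): 1,
    frozenset({CONVENTIONAL, PARENT}): 2,
    frozenset({CONVENTIONAL}): 2,  # conventional vs conventional
    frozenset({GE}): 3,
    frozenset({GE, CONVENTIONAL}): 4,
}


@dataclass(frozen=True)
class Comparison:
    line_a: str
    line_b: str
    group: int

    @property
    def label(self) -> str:
        return f"{self.line_a}/{self.line_b}"


@dataclass
class ComparisonDesign:
    comparisons: tuple[Comparison, ...]

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.comparisons]

    def by_group(self, group: int) -> list[Comparison]:
        return [c for c in self.comparisons if c.group == group]

    @property
    def group_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for c in self.comparisons:
            sizes[c.group] = sizes.get(c.group, 0) + 1
        return dict(sorted(sizes.items()))


@dataclass
class EnrichmentRow:
    term_id: str
    term_name: str
    list_hits: int
    list_total: int
    pop_hits: int
    pop_total: int
    pval: float
    padj: float
    enrichment_score: float


@dataclass
class SetSummary:
    """Disjoint Venn decomposition of 2-4 named sets."""

    names: tuple[str, ...]
    regions: dict[frozenset, set]  # key: the subset of names covering the region

    @property
    def shared_all(self) -> set:
        return self.regions.get(frozenset(self.names), set())

    def unique_to(self, name: str) -> set:
        return self.regions.get(frozenset({name}), set())

    @property
    def region_counts(self) -> dict[frozenset, int]:
        return {k: len(v) for k, v in self.regions.items()}


# ---------------------------------------------------------------------------


def build_design(design: StudyDesign) -> ComparisonDesign:
    """All unordered pairwise comparisons with their interpretation group.

    Label ordering puts the GE line first and the parent last, matching
    the conventional presentation of such designs.
    """
    if len(design.lines) < 2:
        raise ValueError("need at least 2 lines for pairwise comparisons")
    comps = []
    for x, y in combinations(sorted(design.lines), 2):
        rx, ry = design.role(x), design.role(y)
        key = frozenset({rx, ry})
        if key not in _GROUP_BY_ROLES:
            raise ValueError(f"no comparison group for roles {rx!r}/{ry!r}")
        first, second = sorted([x, y], key=lambda ln: (_ROLE_ORDER[design.role(ln)], ln))
        comps.append(Comparison(first, second, _GROUP_BY_ROLES[key]))
    comps.sort(key=lambda c: (c.group, c.line_a, c.line_b))
    return ComparisonDesign(tuple(comps))


def shared_unique(sets: Mapping[str, Iterable]) -> SetSummary:
    """Full disjoint Venn decomposition over 2-4 named sets."""
    named = {str(k): set(v) for k, v in sets.items()}
    if not 2 <= len(named) <= 4:
        raise ValueError("shared_unique supports 2-4 sets")
    names = tuple(named)
    regions: dict[frozenset, set] = {}
    universe = set().union(*named.values())
    for element in universe:
        members = frozenset(n for n in names if element in named[n])
        regions.setdefault(members, set()).add(element)
    return SetSummary(names, regions)


# ---------------------------------------------------------------------------
# over-representation


def enrichment_score(
    list_hits: int, list_total: int, pop_hits: int, pop_total: int
) -> float:
    """Fold enrichment: (ListHits/ListTotal) / (PopHits/PopTotal)."""
    if list_total <= 0 or pop_hits <= 0 or pop_total <= 0:
        raise ValueError("denominator counts must be positive")
    return (list_hits / list_total) / (pop_hits / pop_total)


def expected_hits(list_total: int, pop_hits: int, pop_total: int) -> float:
    """Hypergeometric mean: expected list hits under no enrichment."""
    if pop_total <= 0:
        raise ValueError("pop_total must be positive")
    return list_total * pop_hits / pop_total


def hypergeom_pval(
    list_hits: int, list_total: int, pop_hits: int, pop_total: int
) -> float:
    """Upper-tail hypergeometric P(X >= list_hits)."""
    return float(hypergeom.sf(list_hits - 1, pop_total, pop_hits, list_total))


def hypergeom_ora(
    list_features: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    term_names: Mapping[str, str] | None = None,
) -> list[EnrichmentRow]:
    """Over-representation analysis of a feature list against flat term sets.

    The universe is the annotated-and-assayed background; the list and
    every term are intersected with it.  P-values are upper-tail
    hypergeometric, BH-adjusted across the tested terms; rows come back
    sorted by p-value.  Terms with no members in the universe are
    skipped.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe must be non-empty")
    lst = set(list_features) & uni
    list_total = len(lst)
    pop_total = len(uni)
    rows: list[EnrichmentRow] = []
    for term_id in sorted(annotation):
        members = set(annotation[term_id]) & uni
        pop_hits = len(members)
        if pop_hits == 0:
            continue
        hits = len(lst & members)
        pval = hypergeom_pval(hits, list_total, pop_hits, pop_total) if list_total else 1.0
        score = (
            enrichment_score(hits, list_total, pop_hits, pop_total)
            if list_total
            else float("nan")
        )
        rows.append(
            EnrichmentRow(
                term_id=term_id,
                term_name=(term_names or {}).get(term_id, term_id),
                list_hits=hits,
                list_total=list_total,
                pop_hits=pop_hits,
                pop_total=pop_total,
                pval=pval,
                padj=float("nan"),
                enrichment_score=score,
            )
        )
    if rows:
        padj = bh_adjust([r.pval for r in rows])
        for r, q in zip(rows, padj):
            r.padj = float(q)
    rows.sort(key=lambda r: (r.pval, r.term_id))
    return rows
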