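"""Core/universe set algebra over cell types and reference comparisons.

For one mark, the *core* set is the intersection of positive-promoter sets
across a group of cell types and the *universe* set is their union.
Against a reference cell type, "gained in all" promoters are core members
the reference lacks; "lost in all" promoters are reference positives absent
from the whole universe (not merely from the core).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .model import TilemarkError
from .promoters import MarkCallMatrix

__all__ = [
    "ReferenceComparison",
    "SetSummary",
    "core_and_universe",
    "membership_histogram",
    "compare_to_reference",
    "summarize_mark",
]


@dataclass(frozen=True)
class ReferenceComparison:
    gained_in_all: frozenset[str]
    lost_in_all: frozenset[str]
    shared_all_cell_types: frozenset[str]

    @property
    def unique_to_reference(self) -> frozenset[str]:
        return self.lost_in_all


@dataclass(frozen=True)
class SetSummary:
    mark: str
    core: frozenset[str]
    universe: frozenset[str]
    membership_histogram: Mapping[int, int]
    reference_comparison: ReferenceComparison | None = None


def _positive_sets(
    matrix: MarkCallMatrix, mark: str, group_cell_types: Sequence[str]
) -> list[set[str]]:
    if len(group_cell_types) < 2:
        raise TilemarkError("a group needs at least 2 cell types")
    return [matrix.positives(c, mark) for c in group_cell_types]


def core_and_universe(
    matrix: MarkCallMatrix, mark: str, group_cell_types: Sequence[str]
) -> tuple[set[str], set[str]]:
    """(intersection, union) of per-cell positive promoter sets."""
    sets = _positive_sets(matrix, mark, group_cell_types)
    return set.intersection(*sets), set.union(*sets)


def membership_histogram(
    matrix: MarkCallMatrix, mark: str, group_cell_types: Sequence[str]
) -> dict[int, int]:
    """Count universe promoters positive in exactly k group cell types."""
    sets = _positive_sets(matrix, mark, group_cell_types)
    tally: dict[str, int] = {}
    for s in sets:
        for p in s:
            tally[p] = tally.get(p, 0) + 1
    hist = {k: 0 for k in range(1, len(group_cell_types) + 1)}
    for k in tally.values():
        hist[k] += 1
    return hist


def compare_to_reference(
    core: set[str], universe: set[str], reference_positive: set[str]
) -> ReferenceComparison:
    """Gain/loss/shared sets of a group versus one reference cell type."""
    if not core <= universe:
        raise TilemarkError("core must be a subset of universe")
    return ReferenceComparison(
        gained_in_all=frozenset(core - reference_positive),
        lost_in_all=frozenset(reference_positive - universe),
        shared_all_cell_types=frozenset(core & reference_positive),
    )


def summarize_mark(
    matrix: MarkCallMatrix,
    mark: str,
    group_cell_types: Sequence[str],
    reference_cell_type: str | None = None,
) -> SetSummary:
    core, universe = core_and_universe(matrix, mark, group_cell_types)
    hist = membership_histogram(matrix, mark, group_cell_types)
    comparison = None
    if reference_cell_type is not None:
        if reference_cell_type in group_cell_types:
            raise TilemarkError("reference cell type must not be in the group")
        comparison = compare_to_reference(
            core, universe, matrix.positives(reference_cell_type, mark)
        )
    return SetSummary(
        mark=mark,
        core=frozenset(core),
        universe=frozenset(universe),
        membership_histogram=hist,
        reference_comparison=comparison,
    )


def summary_counts_table(summaries: Sequence[SetSummary]) -> pd.DataFrame:
    """Venn-style count summary, one row per mark."""
    rows = []
    for s in summaries:
        row = {
            "mark": s.mark,
            "core": len(s.core),
            "universe": len(s.universe),
        }
        if s.reference_comparison is not None:
            rc = s.reference_comparison
            row.update(
                gained_in_all=len(rc.gained_in_all),
                lost_in_all=len(rc.lost_in_all),
                shared_all_cell_types=len(rc.shared_all_cell_types),
            )
        rows.append(row)
    return pd.DataFrame(rows)
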