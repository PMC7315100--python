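"""Factorial design cells and effect-coding matrices.

A repeated-measures design is described by the number of levels of each
within-subject factor.  The design cells are enumerated in a fixed nesting
order (the first factor varies slowest), matching the required column order
of the data matrix.  Every main effect and every k-way interaction is then
represented by a {-1, 0, +1} effect-coding matrix over the cells: each
column contrasts one level of a factor against its first level, and
interaction columns are elementwise products of main-effect columns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Design",
    "CellTable",
    "EffectCoding",
    "enumerate_cells",
    "main_effect_coding",
    "interaction_coding",
    "enumerate_effects",
]


class DesignError(ValueError):
    """Raised for structurally invalid factorial designs."""


@dataclass(frozen=True)
class Design:
    """A within-subject factorial design, optionally with between-subject terms.

    Parameters
    ----------
    within_levels
        Number of levels of each within-subject factor, in nesting order
        (first factor varies slowest over data columns).  Every entry must
        be >= 2.
    within_names
        Labels for the within-subject factors.  Generated as ``F1..Fn`` when
        omitted.
    between_levels
        Number of levels of each categorical between-subject factor (may be
        empty).
    between_names, covariate_names
        Labels for categorical between-subject factors and continuous
        between-subject variables.
    """

    within_levels: tuple[int, ...]
    within_names: tuple[str, ...] = ()
    between_levels: tuple[int, ...] = ()
    between_names: tuple[str, ...] = ()
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "within_levels", tuple(int(v) for v in self.within_levels))
        object.__setattr__(self, "between_levels", tuple(int(v) for v in self.between_levels))
        if not self.within_levels:
            raise DesignError("a design needs at least one within-subject factor")
        if any(v < 2 for v in self.within_levels):
            raise DesignError(f"every factor needs >= 2 levels, got {self.within_levels}")
        names = self.within_names or tuple(f"F{i + 1}" for i in range(len(self.within_levels)))
        object.__setattr__(self, "within_names", tuple(names))
        if len(self.within_names) != len(self.within_levels):
            raise DesignError("within_names must align 1:1 with within_levels")
        if len(set(self.within_names)) != len(self.within_names):
            raise DesignError("factor names must be unique")
        bnames = self.between_names or tuple(f"G{i + 1}" for i in range(len(self.between_levels)))
        object.__setattr__(self, "between_names", tuple(bnames))
        if len(self.between_names) != len(self.between_levels):
            raise DesignError("between_names must align 1:1 with between_levels")
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))

    @property
    def n_factors(self) -> int:
        return len(self.within_levels)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.within_levels))


@dataclass(frozen=True)
class CellTable:
    """Enumeration of design cells (the combinations-matrix).

    ``cells[f, c]`` is the 1-based level of factor ``f`` in design cell
    ``c``.  Columns follow the nesting convention: the first factor varies
    slowest, the last factor fastest.
    """

    cells: np.ndarray
    levels: tuple[int, ...]

    @property
    def n_cells(self) -> int:
        return self.cells.shape[1]


@dataclass(frozen=True)
class EffectCoding:
    """Effect-coding matrix for one main effect or interaction.

    ``matrix`` has one row per design cell and one column per contrast; all
    entries are in {-1, 0, +1} and every column sums to zero over cells.
    ``factors`` are the 0-based design indices of the involved factors;
    ``column_labels`` records, per column, the contrasted level of each
    involved factor (level n vs. level 1, 1-based).
    """

    factors: tuple[int, ...]
    matrix: np.ndarray
    column_labels: tuple[tuple[int, ...], ...]
    name: str = ""

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def order(self) -> int:
        return len(self.factors)


def enumerate_cells(design: Design) -> CellTable:
    """Enumerate all design cells in nesting order.

    For ``within_levels = (2, 3)`` the result is
    ``[[1 1 1 2 2 2], [1 2 3 1 2 3]]``: one column per cell, one row per
    factor, later factors nested within (varying faster than) earlier ones.
    """
    levels = design.within_levels
    combos = np.array(list(itertools.product(*(range(1, lv + 1) for lv in levels))), dtype=int)
    return CellTable(cells=combos.T, levels=levels)


def _main_columns(cell_table: CellTable, factor: int) -> tuple[np.ndarray, list[int]]:
    """Contrast columns for one factor: level 1 -> -1, level n -> +1, else 0."""
    if not 0 <= factor < cell_table.cells.shape[0]:
        raise DesignError(f"factor index {factor} out of range")
    lv = cell_table.levels[factor]
    idx = cell_table.cells[factor]
    cols = []
    labels = []
    for n in range(2, lv + 1):
        col = np.where(idx == 1, -1, np.where(idx == n, 1, 0))
        cols.append(col)
        labels.append(n)
    return np.column_stack(cols), labels


def main_effect_coding(cell_table: CellTable, factor: int) -> EffectCoding:
    """Effect coding for one main effect ((levels - 1) columns)."""
    matrix, labels = _main_columns(cell_table, factor)
    return EffectCoding(
        factors=(factor,),
        matrix=matrix,
        column_labels=tuple((n,) for n in labels),
        name=f"F{factor + 1}",
    )


def interaction_coding(cell_table: CellTable, factor_subset: tuple[int, ...]) -> EffectCoding:
    """Effect coding for a k-way interaction (k >= 2).

    Columns are elementwise products of the involved factors' main-effect
    contrast columns, enumerated with the last factor's contrast index
    varying fastest (mirroring the cell nesting).
    """
    subset = tuple(factor_subset)
    if len(subset) < 2:
        raise DesignError("interaction needs >= 2 factors; use main_effect_coding")
    if sorted(set(subset)) != list(subset):
        raise DesignError("factor subset must be distinct and sorted ascending")
    per_factor = [_main_columns(cell_table, f) for f in subset]
    cols = []
    labels = []
    for combo in itertools.product(*(range(m.shape[1]) for m, _ in per_factor)):
        col = np.ones(cell_table.n_cells, dtype=int)
        lab = []
        for (mat, labs), j in zip(per_factor, combo):
            col = col * mat[:, j]
            lab.append(labs[j])
        cols.append(col)
        labels.append(tuple(lab))
    return EffectCoding(
        factors=subset,
        matrix=np.column_stack(cols),
        column_labels=tuple(labels),
        name="x".join(f"F{f + 1}" for f in subset),
    )


def enumerate_effects(design: Design) -> list[EffectCoding]:
    """All main effects and interactions of a design, 2^N - 1 in total.

    Order: all main effects first (factor order), then all 2-way
    interactions, then 3-way, ..., each block in lexicographic subset order.
    """
    table = enumerate_cells(design)
    nf = design.n_factors
    effects = [main_effect_coding(table, f) for f in range(nf)]
    for k in range(2, nf + 1):
        for subset in itertools.combinations(range(nf), k):
            effects.append(interaction_coding(table, subset))
    named = []
    for eff in effects:
        label = ":".join(design.within_names[f] for f in eff.factors)
        named.append(EffectCoding(eff.factors, eff.matrix, eff.column_labels, name=label))
    return named
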