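"""Automated follow-up of significant interactions.

An interaction is "unpacked" by fixing each level of its final involved
factor in turn, slicing the data to that level's cells, and testing the
remaining lower-order interaction (recursively, down to simple main
effects at fully specified level combinations).  Additionally, uncorrected
pairwise paired t-tests are run between all conditions spanned by the
interaction's factors.  Both follow-ups are descriptive and protected by
the significance of the parent interaction; no multiplicity correction is
applied.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .between_effects import effect_cell_means
from .design_coding import (
    Design,
    EffectCoding,
    enumerate_cells,
    interaction_coding,
    main_effect_coding,
)
from .rm_engine import EffectResult, test_within_effect, validate_data

__all__ = ["UnpackNode", "unpack_interaction", "pairwise_tests"]


@dataclass
class UnpackNode:
    """One node of the recursive simple-effects tree."""

    fixed_levels: dict[str, int]
    tested_factors: tuple[str, ...]
    result: EffectResult
    children: list["UnpackNode"] = field(default_factory=list)

    def render(self, indent: int = 0) -> str:
        pad = "  " * indent
        fixed = (
            " @ " + ",".join(f"{k}={v}" for k, v in self.fixed_levels.items())
            if self.fixed_levels
            else ""
        )
        lines = [f"{pad}{self.result}{fixed}"]
        for child in self.children:
            lines.append(child.render(indent + 1))
        return "\n".join(lines)


def _subdesign(design: Design, drop: int) -> Design:
    """The design with one within-subject factor removed."""
    levels = tuple(lv for i, lv in enumerate(design.within_levels) if i != drop)
    names = tuple(nm for i, nm in enumerate(design.within_names) if i != drop)
    return Design(within_levels=levels, within_names=names)


def _effect_for(design: Design, factors: tuple[int, ...]) -> EffectCoding:
    table = enumerate_cells(design)
    if len(factors) == 1:
        eff = main_effect_coding(table, factors[0])
    else:
        eff = interaction_coding(table, factors)
    name = ":".join(design.within_names[f] for f in factors)
    return EffectCoding(eff.factors, eff.matrix, eff.column_labels, name=name)


def _unpack(
    data: np.ndarray,
    design: Design,
    factors: tuple[int, ...],
    fixed: dict[str, int],
) -> UnpackNode:
    effect = _effect_for(design, factors)
    node = UnpackNode(
        fixed_levels=dict(fixed),
        tested_factors=tuple(design.within_names[f] for f in factors),
        result=test_within_effect(data, effect),
    )
    if len(factors) == 1:
        return node
    # the "final factor" is the involved factor with the highest design index
    last = max(factors)
    remaining = tuple(f if f < last else f - 1 for f in factors if f != last)
    table = enumerate_cells(design)
    sub = _subdesign(design, last)
    for level in range(1, design.within_levels[last] + 1):
        mask = table.cells[last] == level
        sliced = data[:, mask]
        child_fixed = dict(fixed)
        child_fixed[design.within_names[last]] = level
        node.children.append(_unpack(sliced, sub, remaining, child_fixed))
    return node


def unpack_interaction(data: np.ndarray, design: Design, effect: EffectCoding) -> UnpackNode:
    """Recursively decompose an interaction into simple(r) effects.

    Each child fixes one level of the final involved factor and re-tests
    the (order - 1)-way effect among the remaining involved factors on the
    sliced data; leaves test a single factor at a fully specified
    combination of the other involved factors' levels.  Results are
    uncorrected descriptives.
    """
    if effect.order < 2:
        raise ValueError("nothing to unpack: effect involves a single factor")
    data = validate_data(data, design.n_cells)
    return _unpack(data, design, tuple(effect.factors), {})


def _paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t; identical columns give t = 0, p = 1 (not NaN)."""
    diff = a - b
    if np.all(diff == 0):
        return 0.0, 1.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def pairwise_tests(data: np.ndarray, design: Design, effect: EffectCoding) -> pd.DataFrame:
    """Uncorrected paired t-tests among all conditions of an effect.

    Conditions are the per-subject means over the cells defined by the
    effect's factors (other factors marginalized); every unordered pair is
    tested with df = N - 1.  A table of C(m, 2) rows.
    """
    data = validate_data(data, design.n_cells)
    means, labels = effect_cell_means(data, design, effect)
    n = data.shape[0]
    rows = []
    for a, b in itertools.combinations(range(len(labels)), 2):
        t, p = _paired_t(means[:, a], means[:, b])
        rows.append(
            {
                "cell_a": labels[a],
                "cell_b": labels[b],
                "mean_diff": float(means[:, a].mean() - means[:, b].mean()),
                "t": t,
                "df": n - 1,
                "p": p,
                "corrected": False,
            }
        )
    return pd.DataFrame(rows)
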