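"""Null-data generation and false-positive-rate verification.

The generator draws independent standard-normal scores for every subject
and design cell, then induces dependency between conditions by replacing a
uniformly chosen half of the columns (floor(cells/2), without replacement)
with ``(1 - dep) * column + dep * mean(other columns)``, the mixing weight
``dep`` in [0, 1] being the dependency factor.  Group membership comes from
``floor(k * uniform)`` per subject and covariates are standard normal; no
true effects exist by construction.  The FPR study sweeps ``dep`` over a
grid and records, per effect type, the proportion of parametric p-values
below alpha — under a correct test this stays at alpha for every degree of
dependency.

Defaults mirror the verification study design: 3x4-level within-subject
factors, 3- and 3-level between-subject factors, one covariate, 24
subjects, dep from 0 to 1 in steps of 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .between_effects import (
    Covariate,
    GroupFactor,
    group_main_effect,
    test_within_by_cv,
    test_within_by_group,
)
from .design_coding import Design, enumerate_effects
from .rm_engine import test_within_effect

__all__ = ["SimConfig", "gen_null_data", "fpr_study", "default_fpr_grid", "inject_effect"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the null-data generator and FPR study.

    ``dep`` blends each selected column with the mean of the others
    (0 = independent columns, 1 = the column is exactly that mean);
    ``balanced_groups`` replaces the random multinomial assignment with a
    round-robin one for tests needing guaranteed group sizes.
    """

    n_subjects: int = 24
    within_levels: tuple[int, ...] = (3, 4)
    between_levels: tuple[int, ...] = (3, 3)
    include_cv: bool = True
    dep: float = 0.0
    iterations: int = 2000
    alpha: float = 0.05
    seed: int | None = None
    balanced_groups: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.dep <= 1.0:
            raise ValueError("dep must lie in [0, 1]")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def design(self) -> Design:
        return Design(
            within_levels=self.within_levels,
            between_levels=self.between_levels,
            covariate_names=("cv",) if self.include_cv else (),
        )


def mix_columns(
    data: np.ndarray, dep: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Blend a random half of the columns with the mean of the others.

    floor(cells / 2) distinct columns are selected uniformly; each is
    replaced by ``(1 - dep) * column + dep * rowwise mean of all other
    columns``.  All replacements use the pre-mixing values (simultaneous
    update), so the result does not depend on the selection order.
    Returns the mixed matrix and the selected column indices.
    """
    n_cells = data.shape[1]
    n_mix = n_cells // 2
    selected = rng.choice(n_cells, size=n_mix, replace=False)
    pre = data.copy()
    out = data.copy()
    total = pre.sum(axis=1)
    for c in selected:
        other_mean = (total - pre[:, c]) / (n_cells - 1)
        out[:, c] = (1.0 - dep) * pre[:, c] + dep * other_mean
    return out, selected


def gen_null_data(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, list[GroupFactor], Covariate | None]:
    """Generate one null dataset: data matrix, group factors, covariate.

    Within-cell scores are standard normal with the dependency mixing
    applied; group labels are ``floor(k * uniform)`` per subject (random,
    generally unbalanced group sizes); the covariate is standard normal.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    n_cells = int(np.prod(config.within_levels))
    data = rng.standard_normal((n, n_cells))
    data, _ = mix_columns(data, config.dep, rng)
    groups = []
    for i, k in enumerate(config.between_levels):
        if config.balanced_groups:
            labels = np.arange(n) % k
            rng.shuffle(labels)
        else:
            labels = np.floor(k * rng.random(n)).astype(int)
            while len(np.unique(labels)) < 2:  # degenerate draw at tiny N
                labels = np.floor(k * rng.random(n)).astype(int)
        groups.append(GroupFactor.from_labels(labels, name=f"G{i + 1}"))
    cv = Covariate("cv", rng.standard_normal(n)) if config.include_cv else None
    return data, groups, cv


def _all_null_pvalues(
    data: np.ndarray, groups: list[GroupFactor], cv: Covariate | None, design: Design
) -> dict[str, float]:
    """Parametric p-values of every effect type for one dataset."""
    pvals: dict[str, float] = {}
    effects = enumerate_effects(design)
    for eff in effects:
        pvals[eff.name] = test_within_effect(data, eff).p
    for g in groups:
        pvals[g.name] = group_main_effect(data, g).p
        for eff in effects:
            r = test_within_by_group(data, eff, g)
            pvals[r.effect_id] = r.p
    if cv is not None:
        for eff in effects:
            r = test_within_by_cv(data, eff, cv)
            pvals[r.effect_id] = r.p
    return pvals


def fpr_study(
    configs: list[SimConfig],
    progress: bool = False,
) -> pd.DataFrame:
    """Empirical false-positive rates over a grid of null configurations.

    For each configuration (typically one per dependency factor) the
    generator is run ``iterations`` times, every effect type is tested
    parametrically, and the proportion of p < alpha plus the mean p are
    recorded per (dep, effect) pair.  Fully reproducible from the per-config
    seeds.
    """
    if not configs:
        raise ValueError("at least one configuration required")
    rows = []
    for config in configs:
        rng = np.random.default_rng(config.seed)
        design = config.design
        counts: dict[str, int] = {}
        psums: dict[str, float] = {}
        for it in range(config.iterations):
            data, groups, cv = gen_null_data(config, rng)
            pvals = _all_null_pvalues(data, groups, cv, design)
            for key, p in pvals.items():
                counts[key] = counts.get(key, 0) + (p < config.alpha)
                psums[key] = psums.get(key, 0.0) + p
            if progress and (it + 1) % 500 == 0:
                print(f"dep={config.dep:.1f}: {it + 1}/{config.iterations}", flush=True)
        for key in counts:
            rows.append(
                {
                    "dep": config.dep,
                    "effect_id": key,
                    "empirical_rate": counts[key] / config.iterations,
                    "mean_p": psums[key] / config.iterations,
                    "iterations": config.iterations,
                }
            )
    return pd.DataFrame(rows)


def default_fpr_grid(
    iterations: int = 2000,
    seed: int | None = None,
    n_subjects: int = 24,
    deps: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1)),
) -> list[SimConfig]:
    """The verification grid: 3x4 within, 3x3 between, one cv, dep 0..1."""
    seeds = np.random.SeedSequence(seed).generate_state(len(deps)) % (2**31)
    return [
        SimConfig(
            n_subjects=n_subjects,
            dep=float(dep),
            iterations=iterations,
            seed=int(s),
        )
        for dep, s in zip(deps, seeds)
    ]


def inject_effect(
    data: np.ndarray, size: float, rng: np.random.Generator
) -> np.ndarray:
    """Add a fixed mean shift to half the columns (power sanity checks)."""
    out = data.copy()
    n_cells = data.shape[1]
    out[:, : n_cells // 2] += size
    return out
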