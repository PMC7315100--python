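"""Interactions of within-subject effects with between-subject variables.

The effect-wise philosophy carries over: a group x within or covariate x
within interaction is tested by scaling each subject's replicated effect
coding by that subject's centered between-subject score(s) and rerunning
the same stacked regression.  Centering the between-subject scores is
essential — without it a plain within-subject effect masquerades as an
interaction whenever groups differ in size or mean.  Because the
within-subject pipeline never touches between-subject columns, adding them
leaves every pure within-subject result bit-identical.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design_coding import Design, EffectCoding, enumerate_cells
from .rm_engine import EffectResult, f_test, gg_epsilon, reduce_rows, validate_data

__all__ = [
    "GroupFactor",
    "Covariate",
    "test_within_by_group",
    "test_within_by_cv",
    "group_main_effect",
    "cv_followups",
]


@dataclass
class GroupFactor:
    """A categorical between-subject factor with per-subject effect coding."""

    name: str
    labels: np.ndarray  # per-subject categorical values
    k: int
    coding: np.ndarray  # subjects x (k-1), centered effect-coding scores

    @classmethod
    def from_labels(cls, labels, name: str = "group") -> "GroupFactor":
        """Build (k-1) effect-coding columns from raw labels and center them.

        Levels are ordered by first appearance is fragile across files, so
        they are sorted; level 1 is coded -1, level n is coded +1 in column
        n-1, all others 0 — identical to the within-subject scheme.
        """
        labels = np.asarray(labels)
        uniq = np.unique(labels)
        k = len(uniq)
        if k < 2:
            raise ValueError(f"group factor {name!r} needs >= 2 groups, got {k}")
        counts = {u: int((labels == u).sum()) for u in uniq}
        small = [u for u, c in counts.items() if c < 2]
        if small:
            warnings.warn(f"group(s) {small} in {name!r} have < 2 subjects")
        cols = []
        for n in range(1, k):
            col = np.where(labels == uniq[0], -1.0, np.where(labels == uniq[n], 1.0, 0.0))
            cols.append(col)
        coding = np.column_stack(cols)
        coding = coding - coding.mean(axis=0)
        return cls(name=name, labels=labels, k=k, coding=coding)


@dataclass
class Covariate:
    """A continuous between-subject variable."""

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("covariate values must be 1-D")
        if np.ptp(self.values) == 0 or np.var(self.values) == 0:
            raise ValueError(f"covariate {self.name!r} has zero variance")

    @property
    def centered_values(self) -> np.ndarray:
        return self.values - self.values.mean()


def _between_scaled_ss(
    reduced: np.ndarray, coding: EffectCoding, scores: np.ndarray
) -> tuple[float, float]:
    """Stacked regression with per-subject between-score scaling.

    Predictors are all pairwise products of the replicated within-coding
    columns and the (centered) between-subject score columns.
    """
    n = reduced.shape[0]
    y = reduced.ravel(order="F")
    W = np.repeat(np.asarray(coding.matrix, dtype=float), n, axis=0)
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] != n:
        scores = scores.T
    S = np.tile(scores, (coding.matrix.shape[0], 1))
    X = (W[:, :, None] * S[:, None, :]).reshape(W.shape[0], -1)
    y = y - y.mean()
    X = X - X.mean(axis=0)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn(
            f"rank-deficient interaction predictors (rank {rank} < {X.shape[1]})",
            stacklevel=2,
        )
    fitted = X @ beta
    resid = y - fitted
    return float(fitted @ fitted), float(resid @ resid)


def test_within_by_group(
    data: np.ndarray, coding: EffectCoding, group: GroupFactor
) -> EffectResult:
    """Test whether a within-subject effect differs between groups.

    Model df is (within columns) x (k - 1); error df is (N - k) x (within
    columns).  The Greenhouse-Geisser epsilon comes from the within-reduced
    matrix (the per-subject group scaling does not alter the sphericity
    structure of the contrast space).
    """
    data = validate_data(data)
    n = data.shape[0]
    if len(group.labels) != n:
        raise ValueError("group labels do not align with data rows")
    if group.k >= n:
        raise ValueError(f"k = {group.k} groups but only N = {n} subjects")
    p_cols = coding.n_columns
    reduced = reduce_rows(data, coding)
    eps, spectrum = gg_epsilon(reduced) if p_cols > 1 else (1.0, None)
    ss_model, ss_error = _between_scaled_ss(reduced, coding, group.coding)
    df_model = float(p_cols * (group.k - 1))
    df_error = float((n - group.k) * p_cols)
    F, p, pes = f_test(ss_model, ss_error, df_model, df_error, eps)
    return EffectResult(
        effect_id=f"{group.name}:{coding.name}",
        F=F,
        df_model=df_model,
        df_error=df_error,
        epsilon=eps,
        p=p,
        partial_eta2=pes,
        ss_model=ss_model,
        ss_error=ss_error,
        spectrum=spectrum,
    )


def test_within_by_cv(data: np.ndarray, coding: EffectCoding, cv: Covariate) -> EffectResult:
    """Test whether a within-subject effect depends linearly on a covariate.

    Each subject's effect-coding values are multiplied by their centered
    covariate value; the test then proceeds exactly as the within-subject
    test (df_error = (N - 1) x within columns).  Shifting the covariate by
    any constant leaves the result unchanged.
    """
    data = validate_data(data)
    n = data.shape[0]
    if len(cv.values) != n:
        raise ValueError("covariate values do not align with data rows")
    p_cols = coding.n_columns
    reduced = reduce_rows(data, coding)
    eps, spectrum = gg_epsilon(reduced) if p_cols > 1 else (1.0, None)
    scores = cv.centered_values[:, None]
    ss_model, ss_error = _between_scaled_ss(reduced, coding, scores)
    df_model = float(p_cols)
    df_error = float((n - 1) * p_cols)
    F, p, pes = f_test(ss_model, ss_error, df_model, df_error, eps)
    return EffectResult(
        effect_id=f"{cv.name}:{coding.name}",
        F=F,
        df_model=df_model,
        df_error=df_error,
        epsilon=eps,
        p=p,
        partial_eta2=pes,
        ss_model=ss_model,
        ss_error=ss_error,
        spectrum=spectrum,
    )


def group_main_effect(data: np.ndarray, group: GroupFactor) -> EffectResult:
    """Between-group main effect: one-way ANOVA on per-subject means."""
    data = validate_data(data)
    means = data.mean(axis=1)
    uniq = np.unique(group.labels)
    samples = [means[group.labels == u] for u in uniq]
    grand = means.mean()
    ss_between = float(sum(len(s) * (s.mean() - grand) ** 2 for s in samples))
    ss_within = float(sum(((s - s.mean()) ** 2).sum() for s in samples))
    df_model = float(group.k - 1)
    df_error = float(len(means) - group.k)
    F, p, pes = f_test(ss_between, ss_within, df_model, df_error, 1.0)
    return EffectResult(
        effect_id=group.name,
        F=F,
        df_model=df_model,
        df_error=df_error,
        epsilon=1.0,
        p=p,
        partial_eta2=pes,
        ss_model=ss_between,
        ss_error=ss_within,
    )


def effect_cell_means(data: np.ndarray, design: Design, effect: EffectCoding) -> tuple[np.ndarray, list[str]]:
    """Per-subject means of the cells spanned by an effect's factors.

    Cells are grouped by the involved factors' level combinations,
    marginalizing (averaging over) all other factors.  Returns the
    subjects x m matrix and human-readable cell labels.
    """
    table = enumerate_cells(design)
    keys = table.cells[list(effect.factors), :]
    combos = sorted(set(map(tuple, keys.T)))
    cols = []
    labels = []
    for combo in combos:
        mask = np.all(keys.T == np.array(combo), axis=1)
        cols.append(data[:, mask].mean(axis=1))
        labels.append(
            ",".join(
                f"{design.within_names[f]}={lvl}" for f, lvl in zip(effect.factors, combo)
            )
        )
    return np.column_stack(cols), labels


def cv_followups(
    data: np.ndarray, design: Design, effect: EffectCoding, cv: Covariate
) -> pd.DataFrame:
    """Descriptive correlations behind a covariate x within interaction.

    Pearson correlations (uncorrected) of the covariate with (a) each
    effect-relevant condition mean and (b) every pairwise difference
    between those conditions.
    """
    data = validate_data(data)
    means, labels = effect_cell_means(data, design, effect)
    cvv = cv.values
    rows = []
    for j, lab in enumerate(labels):
        r, p = stats.pearsonr(cvv, means[:, j])
        rows.append({"term": lab, "kind": "condition", "r": r, "p": p})
    for a, b in itertools.combinations(range(len(labels)), 2):
        diff = means[:, a] - means[:, b]
        if np.var(diff) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(cvv, diff)
        rows.append(
            {"term": f"({labels[a]}) - ({labels[b]})", "kind": "contrast", "r": r, "p": p}
        )
    return pd.DataFrame(rows)
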