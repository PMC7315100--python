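"""Effect-wise within-subject tests.

Each main effect or interaction is tested independently: every subject's
row is centered and projected onto the effect's contrast space (the
"reduced" data matrix), the reduced matrix is stacked column-under-column
and regressed (no intercept) onto the effect-coding vectors replicated per
subject, and the F-ratio of model to error mean squares is evaluated with
Greenhouse-Geisser degree-of-freedom correction whenever the effect spans
more than one contrast column.

Degrees of freedom follow the replicated-regression bookkeeping: model df
is the number of contrast columns ``p`` and error df is ``(N - 1) * p`` for
a pure within-subject test with ``N`` subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .design_coding import EffectCoding

__all__ = [
    "EffectResult",
    "EigenSpectrum",
    "validate_data",
    "reduce_rows",
    "stacked_regression",
    "gg_epsilon",
    "f_test",
    "test_within_effect",
]

#: Relative threshold below which an eigenvalue counts as numerically zero.
RANK_RTOL = 1e-10


@dataclass
class EigenSpectrum:
    """Eigenvalues of the reduced-data covariance matrix, non-increasing."""

    eigenvalues: np.ndarray
    nonzero_count: int


@dataclass
class EffectResult:
    """Outcome of one effect-wise test."""

    effect_id: str
    F: float
    df_model: float
    df_error: float
    epsilon: float
    p: float
    partial_eta2: float
    ss_model: float
    ss_error: float
    p_perm: float | None = None
    spectrum: EigenSpectrum | None = None

    def __str__(self) -> str:  # compact one-line report
        s = (
            f"{self.effect_id}: F({self.df_model:g}, {self.df_error:g}) = "
            f"{self.F:.4g}, eps = {self.epsilon:.3f}, p = {_fmt_p(self.p)}, "
            f"pes = {self.partial_eta2:.3f}"
        )
        if self.p_perm is not None:
            s += f", p_perm = {_fmt_p(self.p_perm)}"
        return s


def _fmt_p(p: float) -> str:
    return f"{p:.3e}" if p < 1e-4 else f"{p:.4f}"


def validate_data(data: np.ndarray, n_cells: int | None = None) -> np.ndarray:
    """Coerce to a 2-D float matrix (subjects x cells), dropping NaN rows.

    Rows containing any missing value are removed (listwise deletion) with
    a warning.
    """
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValueError("data must be a 2-D subjects x cells matrix")
    if n_cells is not None and arr.shape[1] != n_cells:
        raise ValueError(f"data has {arr.shape[1]} cell columns, design expects {n_cells}")
    bad = np.isnan(arr).any(axis=1)
    if bad.any():
        warnings.warn(f"dropped {int(bad.sum())} row(s) with missing values", stacklevel=2)
        arr = arr[~bad]
    return arr


def reduce_rows(data: np.ndarray, coding: EffectCoding) -> np.ndarray:
    """Project each centered data row onto the effect's contrast space.

    Every row is mean-subtracted and replaced by its least-squares
    prediction from the effect-coding columns, removing all between-cell
    variance irrelevant to the effect.  The operation is an orthogonal
    projection: idempotent, and the output rows sum to zero.
    """
    data = np.asarray(data, dtype=float)
    X = np.asarray(coding.matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("effect coding must have at least one column")
    if data.shape[1] != X.shape[0]:
        raise ValueError(
            f"data has {data.shape[1]} columns but coding covers {X.shape[0]} cells"
        )
    centered = data - data.mean(axis=1, keepdims=True)
    proj = X @ np.linalg.pinv(X)  # symmetric projector onto col space of X
    return centered @ proj


def stacked_regression(reduced: np.ndarray, coding: EffectCoding) -> tuple[float, float]:
    """Model and error sums of squares of the stacked no-intercept regression.

    The reduced matrix is vectorized column-under-column (the first N
    entries come from the first cell), the coding columns are replicated per
    subject in the same order, every column is centered, and the outcome is
    regressed onto the predictors with no offset.  Returns
    ``(ss_model, ss_error)``; their sum equals the total sum of squares of
    the centered outcome.
    """
    reduced = np.asarray(reduced, dtype=float)
    n = reduced.shape[0]
    y = reduced.ravel(order="F")
    X = np.repeat(np.asarray(coding.matrix, dtype=float), n, axis=0)
    y = y - y.mean()
    X = X - X.mean(axis=0)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn(
            f"rank-deficient predictor set (rank {rank} < {X.shape[1]}); "
            "pseudoinverse solution used",
            stacklevel=2,
        )
    fitted = X @ beta
    resid = y - fitted
    return float(fitted @ fitted), float(resid @ resid)


def epsilon_from_eigenvalues(eigenvalues: np.ndarray) -> tuple[float, EigenSpectrum]:
    """Greenhouse-Geisser epsilon from a covariance eigenvalue spectrum.

    epsilon = (sum L)^2 / (d * sum L^2) with d the number of eigenvalues
    above the relative rank tolerance.  Degenerate all-zero spectra yield
    epsilon = 1 with a warning.
    """
    lam = np.sort(np.clip(np.asarray(eigenvalues, dtype=float), 0.0, None))[::-1]
    if lam.size == 0 or lam[0] <= 0:
        warnings.warn("degenerate reduced data: all eigenvalues zero; epsilon set to 1")
        return 1.0, EigenSpectrum(lam, 0)
    d = int(np.sum(lam > lam[0] * RANK_RTOL))
    eps = float(lam.sum() ** 2 / (d * np.sum(lam**2)))
    return eps, EigenSpectrum(lam, d)


def gg_epsilon(reduced: np.ndarray) -> tuple[float, EigenSpectrum]:
    """Greenhouse-Geisser epsilon of a reduced data matrix.

    Computed from the eigenvalues of the covariance matrix (over subjects,
    divisor N-1) of the reduced matrix's cell columns.  epsilon lies in
    [1/d, 1], equalling 1 under perfect sphericity (all nonzero eigenvalues
    equal).
    """
    reduced = np.asarray(reduced, dtype=float)
    if reduced.shape[0] < 2:
        raise ValueError("epsilon needs at least 2 subjects")
    cov = np.cov(reduced, rowvar=False)
    lam = np.linalg.eigvalsh(cov)
    return epsilon_from_eigenvalues(lam)


def f_test(
    ss_model: float,
    ss_error: float,
    df_model: float,
    df_error: float,
    epsilon: float = 1.0,
) -> tuple[float, float, float]:
    """F-ratio, p-value and partial eta squared.

    The sphericity correction multiplies both model and error df by epsilon
    before evaluating the upper tail of the F distribution; it is applied
    only when the effect has more than one contrast column (df_model > 1).
    """
    if df_model <= 0 or df_error <= 0:
        raise ValueError("degrees of freedom must be positive")
    if ss_error <= 0:
        if ss_model <= 0:
            # no variance at all in the contrast space
            return 0.0, 1.0, 0.0
        warnings.warn("zero error sum of squares; F is infinite")
        return float("inf"), 0.0, 1.0
    F = (ss_model / df_model) / (ss_error / df_error)
    if df_model > 1:
        dfm, dfe = epsilon * df_model, epsilon * df_error
    else:
        dfm, dfe = df_model, df_error
    p = float(stats.f.sf(F, dfm, dfe))
    partial_eta2 = ss_model / (ss_model + ss_error)
    return float(F), p, float(partial_eta2)


def test_within_effect(data: np.ndarray, coding: EffectCoding) -> EffectResult:
    """Full pipeline for one within-subject effect.

    Composes row reduction, Greenhouse-Geisser epsilon (multi-column
    effects only), the stacked regression, and the F-test.  Model df is the
    number of contrast columns p; error df is (N - 1) * p.
    """
    data = validate_data(data)
    if data.shape[0] < 2:
        raise ValueError("at least 2 subjects required")
    n = data.shape[0]
    p_cols = coding.n_columns
    reduced = reduce_rows(data, coding)
    if p_cols > 1:
        eps, spectrum = gg_epsilon(reduced)
    else:
        eps, spectrum = 1.0, None
    ss_model, ss_error = stacked_regression(reduced, coding)
    df_model = float(p_cols)
    df_error = float((n - 1) * p_cols)
    F, p, pes = f_test(ss_model, ss_error, df_model, df_error, eps)
    return EffectResult(
        effect_id=coding.name or "within",
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
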