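"""Non-parametric (randomization/permutation) p-values.

For within-subject effects the null distribution is built by randomly
reversing, with 50% probability per subject, the sign of each subject's
reduced-data row — an isometry per row that preserves the dependency
structure between columns, generating samples from a null in which the
direction of the effect is exchangeable.  For covariate interactions the
covariate values are instead randomly permuted across subjects.  The
p-value is the proportion of null F values greater than or equal to the
observed F (ties count toward the numerator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .between_effects import Covariate, _between_scaled_ss
from .design_coding import EffectCoding
from .rm_engine import reduce_rows, stacked_regression, validate_data

__all__ = ["PermutationConfig", "NullDistribution", "signflip_test", "cv_permutation_test"]


@dataclass(frozen=True)
class PermutationConfig:
    """Settings of a randomization test.

    ``smoothed`` switches the p-value to (count + 1) / (iterations + 1),
    which cannot return an exact zero; the default is the plain proportion.
    """

    iterations: int = 10_000
    seed: int | None = None
    smoothed: bool = False

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class NullDistribution:
    """Monte-Carlo null distribution of F and the resulting p-value."""

    f_values: np.ndarray
    observed_f: float
    p_perm: float


def _ss_to_f(ss_model: float, ss_total: float, df_model: float, df_error: float) -> float:
    ss_error = ss_total - ss_model
    if ss_error <= 0:
        return np.inf if ss_model > 0 else 0.0
    return (ss_model / df_model) / (ss_error / df_error)


def _p_from_counts(count: int, iterations: int, smoothed: bool) -> float:
    if smoothed:
        return (count + 1) / (iterations + 1)
    return count / iterations


def signflip_test(
    data: np.ndarray, coding: EffectCoding, config: PermutationConfig
) -> NullDistribution:
    """Sign-flip randomization test of a within-subject effect.

    Per iteration each subject's reduced row is multiplied by +/-1 with an
    independent fair coin and the stacked-regression F is recomputed.
    Deterministic for a fixed seed: one generator per invocation, subject
    draws in row order within each iteration.
    """
    data = validate_data(data)
    if data.shape[0] < 2:
        raise ValueError("at least 2 subjects required")
    n = data.shape[0]
    p_cols = coding.n_columns
    df_model = float(p_cols)
    df_error = float((n - 1) * p_cols)
    reduced = reduce_rows(data, coding)
    ss_model, ss_error = stacked_regression(reduced, coding)
    ss_total = ss_model + ss_error
    observed_f = _ss_to_f(ss_model, ss_total, df_model, df_error)

    # Precompute the projection of y onto the (fixed, centered) predictors:
    # flipping signs only changes y, so ss_model = ||Xc beta|| via pinv(Xc).
    X = np.repeat(np.asarray(coding.matrix, dtype=float), n, axis=0)
    Xc = X - X.mean(axis=0)
    pinv = np.linalg.pinv(Xc)

    rng = np.random.default_rng(config.seed)
    f_values = np.empty(config.iterations)
    for it in range(config.iterations):
        signs = rng.integers(0, 2, size=n) * 2 - 1
        flipped = reduced * signs[:, None]
        y = flipped.ravel(order="F")
        y = y - y.mean()
        fitted = Xc @ (pinv @ y)
        ssm = float(fitted @ fitted)
        # flips are row isometries and rows stay zero-mean, so total SS is fixed
        f_values[it] = _ss_to_f(ssm, ss_total, df_model, df_error)
    count = int(np.sum(f_values >= observed_f))
    p_perm = _p_from_counts(count, config.iterations, config.smoothed)
    return NullDistribution(f_values=f_values, observed_f=float(observed_f), p_perm=p_perm)


def cv_permutation_test(
    data: np.ndarray,
    coding: EffectCoding,
    cv: Covariate,
    config: PermutationConfig,
) -> NullDistribution:
    """Permutation test of a covariate x within-subject interaction.

    Per iteration the covariate values are shuffled across subjects
    (uniform random permutation), severing any systematic link between the
    covariate and the within-subject effects, and the interaction F is
    recomputed.
    """
    data = validate_data(data)
    n = data.shape[0]
    if len(cv.values) != n:
        raise ValueError("covariate values do not align with data rows")
    p_cols = coding.n_columns
    df_model = float(p_cols)
    df_error = float((n - 1) * p_cols)
    reduced = reduce_rows(data, coding)
    cvc = cv.centered_values
    ss_model, ss_error = _between_scaled_ss(reduced, coding, cvc[:, None])
    observed_f = _ss_to_f(ss_model, ss_model + ss_error, df_model, df_error)

    rng = np.random.default_rng(config.seed)
    f_values = np.empty(config.iterations)
    for it in range(config.iterations):
        perm = rng.permutation(n)
        ssm, sse = _between_scaled_ss(reduced, coding, cvc[perm][:, None])
        f_values[it] = _ss_to_f(ssm, ssm + sse, df_model, df_error)
    count = int(np.sum(f_values >= observed_f))
    p_perm = _p_from_counts(count, config.iterations, config.smoothed)
    return NullDistribution(f_values=f_values, observed_f=float(observed_f), p_perm=p_perm)
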