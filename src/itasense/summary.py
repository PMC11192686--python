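"""Indirect sensitivity from reported statistics, and variance-ratio estimation.

A reported paired t statistic for the repeated-vs-new RT effect can be
converted into an unbiased estimate of the trial-level sensitivity,

    d'_indirect = t * c(N, K, q2),

    c(N, K, q2) = sqrt((q2 + 4/K) / N) * sqrt(2 / (N - 1))
                  * Gamma((N - 1) / 2) / Gamma((N - 2) / 2),

where N is the number of participants, K the total number of search
trials per participant (balanced across the two conditions) and q2 the
ratio of between-subject variance of true RT effects to trial-by-trial
RT variance.  The Gamma-ratio factor removes the small-sample bias of
the t statistic (its expectation under a noncentral t distribution),
so E[t * c] equals the true underlying sensitivity.

The variance ratio itself is estimated from trial data as

    q2_hat = (N * SE^2 - (4/K) * sigma2_eps_hat) / sigma2_eps_hat,

with SE the standard error of per-participant mean RT effects and
sigma2_eps_hat the pooled per-participant-x-condition RT variance.
q2_hat may legitimately come out negative; it is reported unclamped to
keep the numerator unbiased.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .observer import TrialTable, select_trials
from .sdt import SensitivityEstimate

__all__ = [
    "SummaryStudy",
    "VarianceDecomposition",
    "DEFAULT_Q2",
    "estimator_constant",
    "expected_t_factor",
    "dprime_from_t",
    "se_dprime_from_t",
    "pooled_trial_variance",
    "estimate_q2",
]

log = logging.getLogger(__name__)

#: Default variance-ratio assumption for studies lacking trial data
#: (= 0.3**2, a deliberately generous upper bound).
DEFAULT_Q2 = 0.09


@dataclass(frozen=True)
class SummaryStudy:
    """Reported statistics of one experiment, enough for a full reanalysis."""

    label: str
    t_value: float
    n_participants: int
    k_trials: int  # total search trials per participant (both conditions)
    q2: float = DEFAULT_Q2
    hr: Optional[float] = None
    fa: Optional[float] = None
    n_direct_signal: Optional[int] = None
    n_direct_noise: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_participants < 3:
            raise ValueError(
                f"{self.label}: N must be >= 3 (got {self.n_participants}); "
                "the estimator constant is undefined otherwise"
            )
        if self.k_trials < 2:
            raise ValueError(f"{self.label}: K must be >= 2")
        if self.q2 < 0:
            raise ValueError(f"{self.label}: q2 must be >= 0 (got {self.q2})")
        for name in ("hr", "fa"):
            v = getattr(self, name)
            if v is not None and not 0.0 < v < 1.0:
                raise ValueError(
                    f"{self.label}: {name}={v} must lie strictly in (0, 1); "
                    "apply a count correction upstream"
                )


@dataclass(frozen=True)
class VarianceDecomposition:
    """Trial-level vs between-subject variance split of RT effects."""

    sigma2_eps: float  # pooled trial-by-trial variance, ms^2
    sigma2_effect: float  # between-subject variance of true effects (can be < 0)
    se_effects: float  # SE of per-participant mean RT effects, ms
    q2_hat: float  # sigma2_effect / sigma2_eps, unclamped
    n_participants: int
    k_factor: float  # mean of (1/k_rep + 1/k_new); equals 4/K when balanced

    def __post_init__(self) -> None:
        if self.sigma2_eps <= 0:
            raise ValueError("sigma2_eps must be > 0")

    def q2_for_estimator(self) -> float:
        """q2_hat clamped at 0 for use inside the t-to-d' constant."""
        if self.q2_hat < 0:
            log.warning("q2_hat=%.4g < 0 clamped to 0 for the estimator", self.q2_hat)
            return 0.0
        return self.q2_hat


def _gamma_ratio(a: float, b: float) -> float:
    # Gamma(a) / Gamma(b) in log space; stable for large arguments.
    return math.exp(gammaln(a) - gammaln(b))


def estimator_constant(n_participants: int, k_trials: int, q2: float) -> float:
    """The bias-correcting constant c(N, K, q2) of the t-to-d' estimator."""
    n, k = n_participants, k_trials
    if n < 3:
        raise ValueError(f"N must be >= 3, got {n}")
    if k < 2:
        raise ValueError(f"K must be >= 2, got {k}")
    if q2 < 0:
        raise ValueError(f"q2 must be >= 0, got {q2}")
    return float(
        math.sqrt((q2 + 4.0 / k) / n)
        * math.sqrt(2.0 / (n - 1))
        * _gamma_ratio((n - 1) / 2.0, (n - 2) / 2.0)
    )


def expected_t_factor(df: int) -> float:
    """E[T]/delta for a noncentral t with ``df`` degrees of freedom."""
    if df < 2:
        raise ValueError(f"df must be >= 2, got {df}")
    return math.sqrt(df / 2.0) * _gamma_ratio((df - 1) / 2.0, df / 2.0)


def se_dprime_from_t(t: float, n_participants: int, k_trials: int, q2: float) -> float:
    """SE of the t-based sensitivity estimate via noncentral-t moments.

    Convention: the noncentrality is solved from E[T] = t (method of
    moments), the closed-form SD of the noncentral t with df = N - 1 is
    evaluated there, and scaled by the estimator constant.  Requires
    N >= 4 (the variance of t is undefined for df <= 2).
    """
    n = n_participants
    if n < 4:
        raise ValueError(f"N must be >= 4 for a finite SE, got {n}")
    df = n - 1
    c = estimator_constant(n, k_trials, q2)
    b = expected_t_factor(df)
    delta = t / b
    var_t = df * (1.0 + delta**2) / (df - 2) - (delta * b) ** 2
    return float(c * math.sqrt(var_t))


def dprime_from_t(
    t: float,
    n_participants: int,
    k_trials: int,
    q2: float = DEFAULT_Q2,
    attach_se: bool = True,
) -> SensitivityEstimate:
    """Unbiased indirect sensitivity estimate from a reported paired t."""
    if not np.isfinite(t):
        raise ValueError(f"t must be finite, got {t}")
    c = estimator_constant(n_participants, k_trials, q2)
    se = None
    if attach_se:
        se = se_dprime_from_t(t, n_participants, k_trials, q2)
    k_half = k_trials // 2
    return SensitivityEstimate(
        dprime=float(t * c),
        n_signal=k_half,
        n_noise=k_trials - k_half,
        source="indirect_summary",
        se=se,
    )


def _cells(table: TrialTable) -> pd.DataFrame:
    g = table.data.groupby(["participant", "condition"])["rt_ms"]
    cells = g.agg(n="size", mean="mean", var=lambda s: s.var(ddof=1)).reset_index()
    thin = cells[cells["n"] < 2]
    if len(thin):
        bad = thin[["participant", "condition"]].to_records(index=False).tolist()
        raise ValueError(f"cells with fewer than 2 trials: {bad}")
    return cells


def pooled_trial_variance(table: TrialTable) -> float:
    """Trial-by-trial RT variance pooled over participant x condition cells.

    Cells are weighted by their degrees of freedom (n_cell - 1).
    """
    cells = _cells(table)
    dof = cells["n"] - 1
    return float((cells["var"] * dof).sum() / dof.sum())


def estimate_q2(
    table: TrialTable,
    epochs: "str | set" = "all",
    correct_only: Optional[bool] = None,
) -> VarianceDecomposition:
    """Estimate the variance ratio q2 from trial-level search data.

    The per-participant mean RT effect is mean(new) - mean(repeated),
    so a positive effect corresponds to faster repeated trials.  For
    unbalanced cells 4/K generalises to the mean of 1/k_rep + 1/k_new.
    """
    selected = select_trials(table, epochs=epochs, correct_only=correct_only)
    cells = _cells(selected)
    wide_n = cells.pivot(index="participant", columns="condition", values="n")
    wide_m = cells.pivot(index="participant", columns="condition", values="mean")
    if wide_n.isna().any().any():
        missing = wide_n[wide_n.isna().any(axis=1)].index.tolist()
        raise ValueError(f"participants missing a condition cell: {missing}")

    effects = (wide_m["new"] - wide_m["repeated"]).to_numpy(dtype=float)
    n = effects.size
    if n < 3:
        raise ValueError(f"need at least 3 participants, got {n}")
    se = float(effects.std(ddof=1) / math.sqrt(n))

    dof = cells["n"] - 1
    sigma2_eps = float((cells["var"] * dof).sum() / dof.sum())
    k_factor = float(
        (1.0 / wide_n["repeated"] + 1.0 / wide_n["new"]).mean()
    )
    sigma2_effect = n * se**2 - k_factor * sigma2_eps
    return VarianceDecomposition(
        sigma2_eps=sigma2_eps,
        sigma2_effect=float(sigma2_effect),
        se_effects=se,
        q2_hat=float(sigma2_effect / sigma2_eps),
        n_participants=n,
        k_factor=k_factor,
    )
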