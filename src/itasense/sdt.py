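"""Equal-variance Gaussian signal-detection primitives.

All sensitivities follow the classic convention

    d' = Phi^-1(HR) - Phi^-1(FA)

with ``Phi^-1`` the inverse standard normal CDF.  Hit and false-alarm
rates must lie strictly inside (0, 1); callers facing empty cells apply
the log-linear correction (+0.5 to every cell) via
:func:`rates_from_counts` before converting to d'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Tuple

import numpy as np
from scipy.stats import norm

__all__ = [
    "Correction",
    "RecognitionCounts",
    "SensitivityEstimate",
    "dprime_from_rates",
    "rates_from_counts",
    "accuracy_from_dprime",
    "optimal_unbiased_rates",
    "se_dprime_from_rates",
    "se_dprime_from_counts",
    "sensitivity_from_effect",
]

Correction = Literal["none", "log_linear"]

Source = Literal["direct", "indirect_trials", "indirect_summary"]


@dataclass(frozen=True)
class RecognitionCounts:
    """2x2 outcome table of a binary old/new recognition task.

    ``hits``: signal (repeated) trials judged old; ``false_alarms``:
    noise (new) trials judged old.
    """

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self) -> None:
        for name in ("hits", "misses", "false_alarms", "correct_rejections"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_signal < 1:
            raise ValueError("need at least one signal (repeated) trial")
        if self.n_noise < 1:
            raise ValueError("need at least one noise (new) trial")

    @property
    def n_signal(self) -> int:
        return self.hits + self.misses

    @property
    def n_noise(self) -> int:
        return self.false_alarms + self.correct_rejections


@dataclass
class SensitivityEstimate:
    """A d' estimate together with its provenance and (optional) SE."""

    dprime: float
    n_signal: int
    n_noise: int
    source: Source
    se: Optional[float] = None
    label: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.dprime):
            raise ValueError(f"dprime must be finite, got {self.dprime}")
        if self.se is not None and (not np.isfinite(self.se) or self.se < 0):
            raise ValueError(f"se must be a finite non-negative number, got {self.se}")


def _check_rate(name: str, value: float) -> None:
    if not 0.0 < value < 1.0:
        raise ValueError(
            f"{name}={value!r} is outside (0, 1); apply the log_linear "
            "correction to the counts before converting rates to d'"
        )


def dprime_from_rates(hr: float, fa: float) -> float:
    """Sensitivity from hit and false-alarm rates, both strictly in (0, 1)."""
    _check_rate("hit rate", hr)
    _check_rate("false-alarm rate", fa)
    return float(norm.ppf(hr) - norm.ppf(fa))


def rates_from_counts(
    counts: RecognitionCounts, correction: Correction = "log_linear"
) -> Tuple[float, float]:
    """(hit rate, false-alarm rate) from a 2x2 count table.

    ``log_linear`` adds 0.5 to every cell before dividing, which keeps
    both rates strictly inside (0, 1) even for empty cells.
    """
    if correction == "log_linear":
        hr = (counts.hits + 0.5) / (counts.n_signal + 1.0)
        fa = (counts.false_alarms + 0.5) / (counts.n_noise + 1.0)
    elif correction == "none":
        hr = counts.hits / counts.n_signal
        fa = counts.false_alarms / counts.n_noise
        if hr in (0.0, 1.0) or fa in (0.0, 1.0):
            raise ValueError(
                f"rates ({hr}, {fa}) lie on the boundary; use "
                "correction='log_linear' to keep d' defined"
            )
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return float(hr), float(fa)


def accuracy_from_dprime(dprime: float) -> float:
    """Percent correct of an unbiased optimal observer: Phi(d'/2)."""
    if dprime < 0:
        raise ValueError(f"dprime must be >= 0, got {dprime}")
    return float(norm.cdf(dprime / 2.0))


def optimal_unbiased_rates(dprime: float) -> Tuple[float, float]:
    """(HR, FA) of the optimal unbiased observer at a given sensitivity.

    Round-trips exactly: ``dprime_from_rates(*optimal_unbiased_rates(d)) == d``.
    """
    if dprime < 0:
        raise ValueError(f"dprime must be >= 0, got {dprime}")
    return float(norm.cdf(dprime / 2.0)), float(norm.cdf(-dprime / 2.0))


def se_dprime_from_rates(hr: float, fa: float, n_signal: int, n_noise: int) -> float:
    """Delta-method standard error of d' at given rates and trial counts."""
    _check_rate("hit rate", hr)
    _check_rate("false-alarm rate", fa)
    if n_signal < 1 or n_noise < 1:
        raise ValueError("trial counts must be >= 1")
    var = hr * (1.0 - hr) / (n_signal * norm.pdf(norm.ppf(hr)) ** 2) + fa * (
        1.0 - fa
    ) / (n_noise * norm.pdf(norm.ppf(fa)) ** 2)
    return float(np.sqrt(var))


def se_dprime_from_counts(
    counts: RecognitionCounts, correction: Correction = "log_linear"
) -> float:
    """Delta-method SE of d' computed from a 2x2 count table."""
    hr, fa = rates_from_counts(counts, correction)
    return se_dprime_from_rates(hr, fa, counts.n_signal, counts.n_noise)


def sensitivity_from_effect(delta: float, sigma_eps: float) -> float:
    """True trial-level sensitivity implied by a mean effect and trial SD.

    A mean response difference ``delta`` between the two conditions with
    trial-by-trial standard deviation ``sigma_eps`` corresponds to a
    single-trial discrimination sensitivity of ``delta / sigma_eps``.
    """
    if sigma_eps <= 0:
        raise ValueError(f"sigma_eps must be > 0, got {sigma_eps}")
    return float(delta / sigma_eps)
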