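"""The sensitivity comparison: group tests, Bayes factors, individual tests.

The indirect-task advantage (ITA) decision rule is deliberately strict:
evidence for an ITA is declared only when the confidence interval of
the sensitivity difference (indirect minus direct) lies entirely above
zero.  Bayes factors use the default one-sample JZS setup -- a point
null against a Cauchy(0, 1/sqrt(2)) prior on the standardized effect,
truncated to positive effects for the one-sided alternative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.stats import beta, cauchy, nct, norm
from scipy.stats import t as t_dist

from .observer import (
    GroupSensitivity,
    TrialTable,
    direct_dprime_from_trials,
    indirect_dprime_from_trials,
    select_trials,
)
from .sdt import Correction, SensitivityEstimate, dprime_from_rates, se_dprime_from_rates
from .summary import SummaryStudy, dprime_from_t

__all__ = [
    "ComparisonResult",
    "IndividualITAResult",
    "FunnelData",
    "compare_group_trialwise",
    "compare_summary",
    "analyze_summary_study",
    "jzs_bf_one_sided",
    "jzs_bf_two_sided",
    "bf_category",
    "individual_ita_tests",
    "proportion_ci",
    "funnel_coordinates",
]

log = logging.getLogger(__name__)

DEFAULT_BF_SCALE = 1.0 / math.sqrt(2.0)


@dataclass
class ComparisonResult:
    """Outcome of one sensitivity comparison (indirect minus direct)."""

    d_difference: float
    se: float
    ci_low: float
    ci_high: float
    t_stat: float
    df: int
    p_two_sided: float
    bf10_one_sided: float
    mode: Literal["trial_paired", "summary"]
    ci_level: float = 0.95
    d_indirect: Optional[float] = None
    d_direct: Optional[float] = None
    label: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.ci_low <= self.d_difference <= self.ci_high:
            raise ValueError("confidence interval must bracket the point estimate")
        if self.bf10_one_sided <= 0:
            raise ValueError("Bayes factor must be positive")

    @property
    def ita_decision(self) -> bool:
        """True only when 0 lies outside and below the interval."""
        return self.ci_low > 0

    @property
    def bf_category(self) -> str:
        return bf_category(self.bf10_one_sided)

    def to_dict(self) -> Dict[str, object]:
        return {
            "label": self.label,
            "mode": self.mode,
            "d_indirect": self.d_indirect,
            "d_direct": self.d_direct,
            "d_difference": self.d_difference,
            "se": self.se,
            "ci_level": self.ci_level,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "t": self.t_stat,
            "df": self.df,
            "p_two_sided": self.p_two_sided,
            "bf10_one_sided": self.bf10_one_sided,
            "bf_category": self.bf_category,
            "ita_decision": "evidence for ITA" if self.ita_decision else "no evidence for ITA",
        }


def bf_category(bf10: float) -> str:
    """Evidence category at the conventional 1/3 and 3 cut-offs."""
    if bf10 > 3:
        return "for"
    if bf10 < 1.0 / 3.0:
        return "against"
    return "inconclusive"


def jzs_bf_one_sided(
    t: float, n: int, scale: float = DEFAULT_BF_SCALE
) -> float:
    """One-sided JZS Bayes factor BF10 for a one-sample t statistic.

    Alternative: standardized effect delta ~ Cauchy(0, scale) truncated
    to (0, inf); null: delta = 0.  Marginal likelihoods are evaluated by
    adaptive quadrature over the prior.
    """
    return _jzs_bf(t, n, scale, one_sided=True)


def jzs_bf_two_sided(t: float, n: int, scale: float = DEFAULT_BF_SCALE) -> float:
    """Two-sided JZS Bayes factor (diagnostic companion)."""
    return _jzs_bf(t, n, scale, one_sided=False)


def _jzs_bf(t: float, n: int, scale: float, one_sided: bool) -> float:
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    if not np.isfinite(t):
        raise ValueError(f"t must be finite, got {t}")
    df = n - 1
    root_n = math.sqrt(n)

    def integrand(delta: float) -> float:
        return nct.pdf(t, df, delta * root_n) * cauchy.pdf(delta, scale=scale)

    if one_sided:
        m1, err = integrate.quad(
            lambda d: 2.0 * integrand(d), 0.0, np.inf, epsabs=0, epsrel=1e-6, limit=200
        )
    else:
        m1, err = integrate.quad(
            integrand, -np.inf, np.inf, epsabs=0, epsrel=1e-6, limit=200
        )
    m0 = t_dist.pdf(t, df)
    if not np.isfinite(m1) or m1 <= 0 or (m1 > 0 and err / m1 > 1e-3):
        raise ArithmeticError(
            f"Bayes-factor quadrature did not converge (m1={m1}, err={err})"
        )
    return float(m1 / m0)


def _ci_from_t(mean: float, se: float, df: int, ci_level: float) -> Tuple[float, float]:
    crit = t_dist.ppf(0.5 + ci_level / 2.0, df)
    return float(mean - crit * se), float(mean + crit * se)


def compare_group_trialwise(
    direct: GroupSensitivity,
    indirect: GroupSensitivity,
    ci_level: float = 0.95,
    bf_scale: float = DEFAULT_BF_SCALE,
    label: Optional[str] = None,
) -> ComparisonResult:
    """Paired group-level test of per-participant sensitivity differences."""
    d_idx = set(direct.per_participant.index)
    i_idx = set(indirect.per_participant.index)
    if d_idx != i_idx:
        raise ValueError(
            "participant mismatch between direct and indirect estimates: "
            f"only-direct={sorted(map(str, d_idx - i_idx))}, "
            f"only-indirect={sorted(map(str, i_idx - d_idx))}"
        )
    diffs = (
        indirect.per_participant["dprime"] - direct.per_participant["dprime"]
    ).to_numpy(dtype=float)
    n = diffs.size
    if n < 2:
        raise ValueError("need at least 2 participants for a paired test")
    mean = float(diffs.mean())
    se = float(diffs.std(ddof=1) / math.sqrt(n))
    df = n - 1
    if se == 0.0:
        t_stat, p = 0.0, 1.0
    else:
        t_stat = mean / se
        p = float(2.0 * t_dist.sf(abs(t_stat), df))
    lo, hi = _ci_from_t(mean, se, df, ci_level)
    return ComparisonResult(
        d_difference=mean,
        se=se,
        ci_low=lo,
        ci_high=hi,
        t_stat=t_stat,
        df=df,
        p_two_sided=p,
        bf10_one_sided=jzs_bf_one_sided(t_stat, n, bf_scale),
        mode="trial_paired",
        ci_level=ci_level,
        d_indirect=indirect.mean_dprime,
        d_direct=direct.mean_dprime,
        label=label,
    )


def compare_summary(
    d_indirect: SensitivityEstimate,
    d_direct: SensitivityEstimate,
    n_participants: int,
    df: Optional[int] = None,
    ci_level: float = 0.95,
    bf_scale: float = DEFAULT_BF_SCALE,
    label: Optional[str] = None,
) -> ComparisonResult:
    """Sensitivity comparison from two summary estimates with SEs.

    The combined SE assumes the two task estimates are independent:
    se = sqrt(se_ind^2 + se_dir^2).
    """
    for name, est in (("indirect", d_indirect), ("direct", d_direct)):
        if est.se is None:
            raise ValueError(f"{name} estimate carries no SE")
    diff = d_indirect.dprime - d_direct.dprime
    se = math.sqrt(d_indirect.se**2 + d_direct.se**2)
    if df is None:
        df = n_participants - 1
    t_stat = diff / se if se > 0 else 0.0
    p = float(2.0 * t_dist.sf(abs(t_stat), df))
    lo, hi = _ci_from_t(diff, se, df, ci_level)
    return ComparisonResult(
        d_difference=float(diff),
        se=float(se),
        ci_low=lo,
        ci_high=hi,
        t_stat=float(t_stat),
        df=df,
        p_two_sided=p,
        bf10_one_sided=jzs_bf_one_sided(t_stat, n_participants, bf_scale),
        mode="summary",
        ci_level=ci_level,
        d_indirect=d_indirect.dprime,
        d_direct=d_direct.dprime,
        label=label,
    )


def analyze_summary_study(
    study: SummaryStudy,
    ci_level: float = 0.95,
    bf_scale: float = DEFAULT_BF_SCALE,
) -> ComparisonResult:
    """Full reanalysis of one study from reported statistics."""
    d_ind = dprime_from_t(
        study.t_value, study.n_participants, study.k_trials, study.q2
    )
    if study.hr is None or study.fa is None:
        raise ValueError(f"{study.label}: direct-task rates are required")
    n_sig = study.n_direct_signal or 0
    n_noi = study.n_direct_noise or 0
    if n_sig < 1 or n_noi < 1:
        raise ValueError(f"{study.label}: direct-task trial counts are required")
    d_dir = SensitivityEstimate(
        dprime=dprime_from_rates(study.hr, study.fa),
        n_signal=n_sig,
        n_noise=n_noi,
        source="direct",
        se=se_dprime_from_rates(study.hr, study.fa, n_sig, n_noi),
    )
    return compare_summary(
        d_ind,
        d_dir,
        study.n_participants,
        ci_level=ci_level,
        bf_scale=bf_scale,
        label=study.label,
    )


# ---------------------------------------------------------------------------
# Individual-level bootstrap tests


@dataclass
class IndividualITAResult:
    """Per-participant bootstrap ITA tests and their summary proportion."""

    per_participant: pd.DataFrame  # d_difference, se_boot, z, p_one_sided, significant
    alpha: float
    n_significant: int
    n_total: int
    proportion: float
    proportion_ci: Tuple[float, float]
    skipped: List[object] = field(default_factory=list)


def bootstrap_difference_draws(
    rng: np.random.Generator,
    rep_rts: np.ndarray,
    new_rts: np.ndarray,
    hits: int,
    n_signal: int,
    false_alarms: int,
    n_noise: int,
    n_boot: int,
    correction: Correction = "log_linear",
) -> np.ndarray:
    """Bootstrap draws of one participant's sensitivity difference.

    Search trials are resampled with replacement within condition and the
    median split recomputed per draw; recognition responses are resampled
    within condition (equivalent to binomial draws at the observed rates).
    """
    rep = rng.choice(rep_rts, size=(n_boot, rep_rts.size), replace=True)
    new = rng.choice(new_rts, size=(n_boot, new_rts.size), replace=True)
    med = np.median(np.concatenate([rep, new], axis=1), axis=1, keepdims=True)
    h_ind = (rep < med).sum(axis=1)
    f_ind = (new < med).sum(axis=1)
    d_ind = _dprime_counts_vec(h_ind, rep.shape[1], f_ind, new.shape[1], correction)

    h_dir = rng.binomial(n_signal, hits / n_signal, size=n_boot)
    f_dir = rng.binomial(n_noise, false_alarms / n_noise, size=n_boot)
    d_dir = _dprime_counts_vec(h_dir, n_signal, f_dir, n_noise, correction)
    return d_ind - d_dir


def _dprime_counts_vec(hits, n_signal, fas, n_noise, correction: Correction):
    if correction == "log_linear":
        hr = (hits + 0.5) / (n_signal + 1.0)
        fa = (fas + 0.5) / (n_noise + 1.0)
    elif correction == "none":
        hr = hits / n_signal
        fa = fas / n_noise
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return norm.ppf(hr) - norm.ppf(fa)


def individual_ita_tests(
    search: TrialTable,
    recognition: TrialTable,
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: Optional[int] = None,
    epochs="last",
    correct_only: Optional[bool] = None,
    correction: Correction = "log_linear",
    ci_level: float = 0.95,
    min_trials: int = 2,
) -> IndividualITAResult:
    """Bootstrap one-sided ITA test per participant plus summary proportion.

    Each participant's difference is divided by its bootstrap SE and
    referred to the standard normal for a one-sided test of difference > 0.
    Per-participant RNG streams are spawned from the master seed, so
    results do not depend on participant order.
    """
    if n_boot < 200:
        raise ValueError(f"n_boot must be >= 200, got {n_boot}")
    selected = select_trials(search, epochs=epochs, correct_only=correct_only)
    ind = indirect_dprime_from_trials(
        selected, epochs="all", correct_only=False, correction=correction
    )
    dirs = direct_dprime_from_trials(recognition, correction=correction)
    common = sorted(
        set(ind.per_participant.index) & set(dirs.per_participant.index), key=str
    )
    if not common:
        raise ValueError("no participants shared between search and recognition tables")

    streams = np.random.SeedSequence(seed).spawn(len(common))
    rows = {}
    skipped: List[object] = []
    search_df = selected.data
    for pid, ss in zip(common, streams):
        sub = search_df[search_df["participant"] == pid]
        rep = sub.loc[sub["condition"] == "repeated", "rt_ms"].to_numpy(dtype=float)
        new = sub.loc[sub["condition"] == "new", "rt_ms"].to_numpy(dtype=float)
        drow = dirs.per_participant.loc[pid]
        n_sig, n_noi = int(drow["n_signal"]), int(drow["n_noise"])
        if min(rep.size, new.size, n_sig, n_noi) < min_trials:
            log.warning("participant %r skipped: too few trials to resample", pid)
            skipped.append(pid)
            continue
        hits = int(drow["hits"])
        fas = int(drow["false_alarms"])
        rng = np.random.default_rng(ss)
        draws = bootstrap_difference_draws(
            rng, rep, new, hits, n_sig, fas, n_noi, n_boot, correction
        )
        diff = float(ind.per_participant.loc[pid, "dprime"] - drow["dprime"])
        se = float(draws.std(ddof=1))
        z = diff / se if se > 0 else 0.0
        p = float(norm.sf(z))
        rows[pid] = {
            "d_difference": diff,
            "se_boot": se,
            "z": z,
            "p_one_sided": p,
            "significant": p < alpha,
        }

    per = pd.DataFrame.from_dict(rows, orient="index")
    per.index.name = "participant"
    n_sig_total = int(per["significant"].sum())
    n_total = len(per)
    ci = proportion_ci(n_sig_total, n_total, level=ci_level)
    return IndividualITAResult(
        per_participant=per,
        alpha=alpha,
        n_significant=n_sig_total,
        n_total=n_total,
        proportion=n_sig_total / n_total,
        proportion_ci=ci,
        skipped=skipped,
    )


def proportion_ci(
    successes: int,
    n: int,
    method: Literal["clopper_pearson", "wilson"] = "clopper_pearson",
    level: float = 0.95,
) -> Tuple[float, float]:
    """Binomial proportion confidence interval (exact by default)."""
    if not 0 <= successes <= n:
        raise ValueError(f"need 0 <= successes <= n, got {successes}/{n}")
    a = (1.0 - level) / 2.0
    if method == "clopper_pearson":
        lo = 0.0 if successes == 0 else float(beta.ppf(a, successes, n - successes + 1))
        hi = 1.0 if successes == n else float(beta.ppf(1 - a, successes + 1, n - successes))
        return lo, hi
    if method == "wilson":
        z = float(norm.ppf(1 - a))
        p = successes / n
        denom = 1 + z**2 / n
        centre = (p + z**2 / (2 * n)) / denom
        half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
        return max(0.0, centre - half), min(1.0, centre + half)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Funnel-plot coordinates


@dataclass
class FunnelData:
    """Plain funnel-plot data: points plus significance boundaries."""

    points: pd.DataFrame  # columns label, d_difference, se
    critical_z: Dict[float, float]  # alpha -> two-sided z boundary slope

    def boundary_lines(self, n_points: int = 50) -> pd.DataFrame:
        """Boundary coordinates x = +/- z * se over the observed SE range."""
        se_max = float(self.points["se"].max()) * 1.05
        ses = np.linspace(0.0, se_max, n_points)
        frames = []
        for alpha, z in self.critical_z.items():
            frames.append(
                pd.DataFrame(
                    {"alpha": alpha, "se": ses, "lower": -z * ses, "upper": z * ses}
                )
            )
        return pd.concat(frames, ignore_index=True)


def funnel_coordinates(
    results: Iterable[ComparisonResult], alphas: Sequence[float] = (0.05, 0.01)
) -> FunnelData:
    """(difference, SE) points and significance funnel boundaries."""
    rows = [
        {"label": r.label, "d_difference": r.d_difference, "se": r.se} for r in results
    ]
    if not rows:
        raise ValueError("no comparison results supplied")
    crit = {a: float(norm.ppf(1 - a / 2.0)) for a in alphas}
    return FunnelData(points=pd.DataFrame(rows), critical_z=crit)
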