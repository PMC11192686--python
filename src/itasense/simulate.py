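"""Synthetic single-source and dual-source experiments, plus study runners.

The generative model is latent-Gaussian: participant i carries a true RT
effect Delta_i ~ Normal(delta, sigma_effect^2).  Search-task trials draw
a latent value Normal(-Delta_i/2, sigma_eps^2) for repeated and
Normal(+Delta_i/2, sigma_eps^2) for new configurations (repeated trials
are faster).  The latent value is emitted either directly as an RT
around a baseline (``gaussian_latent``) or exponentiated onto a
millisecond scale (``lognormal``); both emissions are monotone in the
latent value, so the per-participant sensitivity is Delta_i / sigma_eps
by construction.

Recognition responses are driven by the same latent sensitivity
d_i = Delta_i / sigma_eps (single-source model): per trial, evidence
~ Normal(+d_i/2, 1) for repeated and Normal(-d_i/2, 1) for new
configurations, judged "old" when the evidence exceeds the participant's
criterion (Normal(0, criterion_sd^2), default 0 = optimal unbiased).
Under ``dual_source`` an extra sensitivity is added to the search task
only, creating a true indirect task advantage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, field
from typing import Dict, Literal, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm
from scipy.stats import t as t_dist

import yaml

from .observer import TrialTable, median_split_rates
from .summary import estimator_constant

__all__ = [
    "SimulationConfig",
    "simulate_experiment",
    "simulate_search_arrays",
    "simulate_direct_counts",
    "median_split_dprimes",
    "direct_dprimes_from_counts",
    "recovery_study",
    "group_comparison_calibration",
    "individual_calibration",
    "typical_pattern_demo",
]

log = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic contextual-cueing-style experiment."""

    n_participants: int = 20
    k_per_condition: int = 48
    k_direct_per_condition: int = 12
    delta: float = 0.0  # mean true RT effect (latent scale)
    sigma_eps: float = 1.0  # trial-by-trial SD (latent scale)
    sigma_effect: float = 0.0  # between-subject SD of true effects
    rt_model: Literal["gaussian_latent", "lognormal"] = "gaussian_latent"
    source_model: Literal["single_source", "dual_source"] = "single_source"
    indirect_extra_dprime: float = 0.0
    criterion_sd: float = 0.0
    n_epochs: int = 1
    learning_onset_epoch: int = 1  # epochs before this carry no effect
    baseline_ms: float = 2500.0  # gaussian_latent emission offset
    log_rt_mu: float = math.log(900.0)  # lognormal emission location
    log_rt_sigma: float = 0.3  # lognormal emission scale per latent SD
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        for name in ("k_per_condition", "k_direct_per_condition"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        for name in ("sigma_effect", "criterion_sd", "indirect_extra_dprime"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sigma_eps <= 0:
            raise ValueError("sigma_eps must be > 0")
        if self.rt_model not in ("gaussian_latent", "lognormal"):
            raise ValueError(f"unknown rt_model {self.rt_model!r}")
        if self.source_model not in ("single_source", "dual_source"):
            raise ValueError(f"unknown source_model {self.source_model!r}")
        if self.n_epochs < 1 or not 1 <= self.learning_onset_epoch <= self.n_epochs:
            raise ValueError("need 1 <= learning_onset_epoch <= n_epochs")

    @property
    def q2(self) -> float:
        return (self.sigma_effect / self.sigma_eps) ** 2

    @property
    def true_dprime(self) -> float:
        return self.delta / self.sigma_eps

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown simulation config fields: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _emit_rts(latent: np.ndarray, config: SimulationConfig) -> np.ndarray:
    if config.rt_model == "gaussian_latent":
        rts = config.baseline_ms + latent
        if np.any(rts <= 0):
            raise ValueError(
                "gaussian_latent emission produced non-positive RTs; "
                "increase baseline_ms relative to sigma_eps"
            )
        return rts
    z = latent / config.sigma_eps
    return np.exp(config.log_rt_mu + config.log_rt_sigma * z)


def simulate_experiment(
    config: SimulationConfig, seed: Optional[int] = None
) -> Tuple[TrialTable, TrialTable, pd.DataFrame]:
    """Generate (search table, recognition table, per-participant truth).

    Reproducible: the same config and seed yield bit-identical tables.
    ``seed`` overrides ``config.seed`` when given.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, k = config.n_participants, config.k_per_condition
    pids = [f"p{i + 1:03d}" for i in range(n)]

    delta_i = rng.normal(config.delta, config.sigma_effect, n)
    d_direct = delta_i / config.sigma_eps
    extra = (
        config.indirect_extra_dprime if config.source_model == "dual_source" else 0.0
    )
    d_search = d_direct + extra
    criterion_i = (
        rng.normal(0.0, config.criterion_sd, n)
        if config.criterion_sd > 0
        else np.zeros(n)
    )

    search_frames = []
    for epoch in range(1, config.n_epochs + 1):
        active = epoch >= config.learning_onset_epoch
        sep = (d_search * config.sigma_eps) if active else np.zeros(n)
        rep_lat = rng.normal(-sep[:, None] / 2.0, config.sigma_eps, (n, k))
        new_lat = rng.normal(+sep[:, None] / 2.0, config.sigma_eps, (n, k))
        for cond, lat in (("repeated", rep_lat), ("new", new_lat)):
            rts = _emit_rts(lat, config)
            search_frames.append(
                pd.DataFrame(
                    {
                        "participant": np.repeat(pids, k),
                        "epoch": epoch,
                        "block": epoch,
                        "condition": cond,
                        "rt_ms": rts.ravel(),
                    }
                )
            )
    search = pd.concat(search_frames, ignore_index=True)
    search = search.sort_values(
        ["participant", "epoch", "condition"], kind="stable"
    ).reset_index(drop=True)

    kd = config.k_direct_per_condition
    sig_ev = rng.normal(+d_direct[:, None] / 2.0, 1.0, (n, kd))
    noi_ev = rng.normal(-d_direct[:, None] / 2.0, 1.0, (n, kd))
    recog = pd.DataFrame(
        {
            "participant": np.repeat(pids, 2 * kd),
            "condition": np.tile(
                np.repeat(["repeated", "new"], kd), n
            ),
            "response": np.where(
                np.concatenate([sig_ev, noi_ev], axis=1).ravel()
                > np.repeat(criterion_i, 2 * kd),
                "old",
                "new",
            ),
        }
    )

    truth = pd.DataFrame(
        {
            "participant": pids,
            "delta_i": delta_i,
            "d_direct_true": d_direct,
            "d_search_true": d_search,
            "criterion": criterion_i,
        }
    ).set_index("participant")
    return (
        TrialTable(search, task="search"),
        TrialTable(recog, task="recognition"),
        truth,
    )


# ---------------------------------------------------------------------------
# Vectorised kernels shared by the study runners


def simulate_search_arrays(
    rng: np.random.Generator,
    reps: int,
    n_participants: int,
    k_per_condition: int,
    delta: float,
    sigma_effect: float,
    sigma_eps: float,
    extra_dprime: float = 0.0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Latent search RTs: (repeated, new) of shape (reps, N, k) plus Delta_i."""
    delta_i = rng.normal(delta, sigma_effect, (reps, n_participants))
    sep = delta_i + extra_dprime * sigma_eps
    shape = (reps, n_participants, k_per_condition)
    rep = rng.normal(-sep[..., None] / 2.0, sigma_eps, shape)
    new = rng.normal(+sep[..., None] / 2.0, sigma_eps, shape)
    return rep, new, delta_i


def simulate_direct_counts(
    rng: np.random.Generator,
    d_true: np.ndarray,
    k_direct_per_condition: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """(hits, false alarms) of an unbiased observer at true sensitivities."""
    hr = norm.cdf(d_true / 2.0)
    fa = norm.cdf(-d_true / 2.0)
    hits = rng.binomial(k_direct_per_condition, hr)
    fas = rng.binomial(k_direct_per_condition, fa)
    return hits, fas


def median_split_dprimes(rep: np.ndarray, new: np.ndarray) -> np.ndarray:
    """Median-split d' along the last axis with the log-linear correction."""
    hr, fa = median_split_rates(
        rep.reshape(-1, rep.shape[-1]), new.reshape(-1, new.shape[-1])
    )
    return (norm.ppf(hr) - norm.ppf(fa)).reshape(rep.shape[:-1])


def direct_dprimes_from_counts(
    hits: np.ndarray, fas: np.ndarray, k_per_condition: int
) -> np.ndarray:
    hr = (hits + 0.5) / (k_per_condition + 1.0)
    fa = (fas + 0.5) / (k_per_condition + 1.0)
    return norm.ppf(hr) - norm.ppf(fa)


def _chunked(reps: int, chunk: int):
    done = 0
    while done < reps:
        yield min(chunk, reps - done)
        done += chunk


def recovery_study(
    config: SimulationConfig,
    reps: int,
    seed: Optional[int] = None,
    chunk: int = 500,
) -> pd.DataFrame:
    """Bias/RMSE of the t-based and median-split d' estimators and of q2_hat.

    Simulates ``reps`` independent experiments at the configured truth and
    summarises each estimator's mean estimate, bias, RMSE and Monte-Carlo
    SE.  The t-based path computes the paired t statistic from each
    simulated experiment's own per-participant mean effects and applies
    the estimator constant at the configured q2.
    """
    if reps < 100:
        raise ValueError(f"reps must be >= 100, got {reps}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, k = config.n_participants, config.k_per_condition
    k_total = 2 * k
    c = estimator_constant(n, k_total, config.q2)

    d_summary, d_trials, q2_hats = [], [], []
    for m in _chunked(reps, chunk):
        rep, new, _ = simulate_search_arrays(
            rng, m, n, k, config.delta, config.sigma_effect, config.sigma_eps
        )
        effects = new.mean(axis=2) - rep.mean(axis=2)  # (m, N)
        t_stats = effects.mean(axis=1) / (
            effects.std(axis=1, ddof=1) / math.sqrt(n)
        )
        d_summary.append(t_stats * c)
        d_trials.append(median_split_dprimes(rep, new).mean(axis=1))

        pooled = 0.5 * (rep.var(axis=2, ddof=1) + new.var(axis=2, ddof=1)).mean(axis=1)
        nse2 = effects.var(axis=1, ddof=1)  # = N * SE^2
        q2_hats.append((nse2 - (4.0 / k_total) * pooled) / pooled)

    rows = []
    for name, draws, truth in (
        ("indirect_summary", np.concatenate(d_summary), config.true_dprime),
        ("indirect_trials", np.concatenate(d_trials), config.true_dprime),
        ("q2", np.concatenate(q2_hats), config.q2),
    ):
        mean = float(draws.mean())
        rows.append(
            {
                "estimator": name,
                "truth": truth,
                "mean_estimate": mean,
                "bias": mean - truth,
                "rmse": float(np.sqrt(((draws - truth) ** 2).mean())),
                "mc_se": float(draws.std(ddof=1) / math.sqrt(draws.size)),
                "reps": int(draws.size),
            }
        )
    return pd.DataFrame(rows).set_index("estimator")


def group_comparison_calibration(
    config: SimulationConfig,
    reps: int,
    alpha: float = 0.05,
    seed: Optional[int] = None,
    chunk: int = 500,
) -> Dict[str, float]:
    """Rejection rates of the group-level paired comparison over cohorts.

    Returns the two-sided rejection rate at ``alpha`` (should match alpha
    under the single-source null) and the rate of the one-sided ITA
    decision rule (CI lower bound above 0).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, k, kd = (
        config.n_participants,
        config.k_per_condition,
        config.k_direct_per_condition,
    )
    extra = (
        config.indirect_extra_dprime if config.source_model == "dual_source" else 0.0
    )
    crit = float(t_dist.ppf(1.0 - alpha / 2.0, n - 1))
    reject_two, ita_decide = [], []
    for m in _chunked(reps, chunk):
        rep, new, delta_i = simulate_search_arrays(
            rng, m, n, k, config.delta, config.sigma_effect, config.sigma_eps, extra
        )
        d_ind = median_split_dprimes(rep, new)
        hits, fas = simulate_direct_counts(rng, delta_i / config.sigma_eps, kd)
        d_dir = direct_dprimes_from_counts(hits, fas, kd)
        diffs = d_ind - d_dir  # (m, N)
        t_stats = diffs.mean(axis=1) / (diffs.std(axis=1, ddof=1) / math.sqrt(n))
        reject_two.append(np.abs(t_stats) > crit)
        ita_decide.append(t_stats > crit)  # CI lower bound > 0
    return {
        "alpha": alpha,
        "reps": reps,
        "two_sided_rejection_rate": float(np.concatenate(reject_two).mean()),
        "ita_decision_rate": float(np.concatenate(ita_decide).mean()),
    }


def individual_calibration(
    config: SimulationConfig,
    n_individuals: int,
    n_boot: int = 500,
    alpha: float = 0.05,
    seed: Optional[int] = None,
) -> Dict[str, float]:
    """Proportion of individually significant ITAs under the configured model.

    Simulates ``n_individuals`` independent participants, applies the
    per-participant bootstrap one-sided test and reports the significant
    proportion (should sit near ``alpha`` under the single-source null).
    """
    from .inference import bootstrap_difference_draws  # local: avoid cycle

    master = np.random.SeedSequence(config.seed if seed is None else seed)
    gen_rng = np.random.default_rng(master.spawn(1)[0])
    k, kd = config.k_per_condition, config.k_direct_per_condition
    extra = (
        config.indirect_extra_dprime if config.source_model == "dual_source" else 0.0
    )
    rep, new, delta_i = simulate_search_arrays(
        gen_rng, 1, n_individuals, k, config.delta, config.sigma_effect,
        config.sigma_eps, extra,
    )
    rep, new, delta_i = rep[0], new[0], delta_i[0]
    d_ind = median_split_dprimes(rep, new)
    hits, fas = simulate_direct_counts(gen_rng, delta_i / config.sigma_eps, kd)
    d_dir = direct_dprimes_from_counts(hits, fas, kd)
    diffs = d_ind - d_dir

    n_sig = 0
    for i, ss in enumerate(master.spawn(n_individuals)):
        rng = np.random.default_rng(ss)
        draws = bootstrap_difference_draws(
            rng, rep[i], new[i], int(hits[i]), kd, int(fas[i]), kd, n_boot
        )
        se = draws.std(ddof=1)
        z = diffs[i] / se if se > 0 else 0.0
        if norm.sf(z) < alpha:
            n_sig += 1
    return {
        "alpha": alpha,
        "n_individuals": n_individuals,
        "n_significant": n_sig,
        "proportion": n_sig / n_individuals,
    }


def typical_pattern_demo(
    config: SimulationConfig, seed: Optional[int] = None
) -> Dict[str, object]:
    """Headline numbers of the flawed pattern plus the corrected comparison.

    Emits the mean RT effect with its t test (the seemingly impressive
    indirect result), the close-to-chance direct d' and accuracy, and the
    sensitivity comparison showing whether any advantage survives.
    """
    from .inference import compare_group_trialwise  # local: avoid cycle
    from .observer import direct_dprime_from_trials, indirect_dprime_from_trials

    if config.source_model != "single_source":
        raise ValueError("the demo illustrates the single-source null")
    search, recog, _ = simulate_experiment(config, seed=seed)
    df = search.data
    means = df.pivot_table(
        index="participant", columns="condition", values="rt_ms", aggfunc="mean"
    )
    effects = (means["new"] - means["repeated"]).to_numpy(dtype=float)
    n = effects.size
    t_stat = effects.mean() / (effects.std(ddof=1) / math.sqrt(n))
    p = float(2.0 * t_dist.sf(abs(t_stat), n - 1))

    direct = direct_dprime_from_trials(recog)
    indirect = indirect_dprime_from_trials(search, epochs="all", correct_only=False)
    hr = direct.per_participant["hr"]
    fa = direct.per_participant["fa"]
    accuracy = float(((hr + (1.0 - fa)) / 2.0).mean())
    comparison = compare_group_trialwise(direct, indirect)
    return {
        "mean_rt_effect_ms": float(effects.mean()),
        "rt_effect_t": float(t_stat),
        "rt_effect_p": p,
        "direct_dprime": direct.mean_dprime,
        "direct_accuracy": accuracy,
        "indirect_dprime": indirect.mean_dprime,
        "comparison": comparison.to_dict(),
    }
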