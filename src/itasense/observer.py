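"""Trial-level pipeline: trial selection and the median-split ideal observer.

The ideal observer predicts, for each search-task trial of a participant,
whether its stimulus configuration was repeated or new, using only that
participant's reaction times: trials faster than the participant's own
median RT are predicted "repeated", trials at or above the median are
predicted "new".  Comparing predictions with the true condition yields
hit and false-alarm rates and hence the indirect sensitivity.

Tie rule: an RT exactly equal to the median is predicted "new".  The
median is the midpoint median over the participant's selected trials,
both conditions pooled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Literal, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .sdt import (
    Correction,
    RecognitionCounts,
    SensitivityEstimate,
    dprime_from_rates,
    rates_from_counts,
    se_dprime_from_counts,
)

__all__ = [
    "TrialTable",
    "GroupSensitivity",
    "EpochPolicy",
    "select_trials",
    "participant_median",
    "median_split_classify",
    "median_split_rates",
    "indirect_dprime_from_trials",
    "direct_dprime_from_trials",
]

log = logging.getLogger(__name__)

EpochPolicy = Union[Literal["last", "all"], Set[int], Sequence[int]]

_SEARCH_REQUIRED = ("participant", "condition", "rt_ms")
_RECOGNITION_REQUIRED = ("participant", "condition", "response")
_CONDITIONS = ("repeated", "new")
_RESPONSES = ("old", "new")


@dataclass
class TrialTable:
    """Validated, ordered collection of trial records for one task.

    ``task='search'`` tables require columns participant, condition
    (repeated/new) and rt_ms, with optional epoch, block and correct
    flags.  ``task='recognition'`` tables require participant, condition
    and response (old/new).
    """

    data: pd.DataFrame
    task: Literal["search", "recognition"] = "search"

    def __post_init__(self) -> None:
        required = _SEARCH_REQUIRED if self.task == "search" else _RECOGNITION_REQUIRED
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"{self.task} table is missing columns: {missing}")
        bad = set(self.data["condition"].unique()) - set(_CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        if self.task == "search":
            rts = self.data["rt_ms"].to_numpy(dtype=float)
            if not np.all(np.isfinite(rts)) or np.any(rts <= 0):
                raise ValueError("rt_ms must be finite and > 0 for every trial")
            for col in ("epoch", "block"):
                if col in self.data.columns and (self.data[col] < 1).any():
                    raise ValueError(f"{col} indices must be >= 1")
        else:
            bad = set(self.data["response"].unique()) - set(_RESPONSES)
            if bad:
                raise ValueError(f"unknown response labels: {sorted(bad)}")

    @property
    def participants(self) -> list:
        return sorted(self.data["participant"].unique())

    def __len__(self) -> int:
        return len(self.data)


def select_trials(
    table: TrialTable,
    epochs: EpochPolicy = "last",
    correct_only: Optional[bool] = None,
) -> TrialTable:
    """Filter search trials by epoch and (optionally) correctness.

    ``epochs='last'`` keeps the highest epoch index present; a set keeps
    exactly those epochs.  ``correct_only=None`` excludes error trials
    whenever a ``correct`` column exists, and is a no-op otherwise.  Any
    participant left without trials raises.
    """
    df = table.data
    before = set(df["participant"].unique())
    n0 = len(df)

    if epochs != "all":
        if "epoch" not in df.columns:
            if epochs == "last":
                log.info("no epoch column; 'last' policy keeps all trials")
            else:
                raise ValueError("table has no epoch column but specific epochs requested")
        else:
            present = set(df["epoch"].unique())
            if epochs == "last":
                wanted = {df["epoch"].max()}
            else:
                wanted = set(int(e) for e in epochs)
                missing = wanted - present
                if missing:
                    raise ValueError(f"requested epochs not present: {sorted(missing)}")
            df = df[df["epoch"].isin(wanted)]
            log.info(
                "epoch selection %s kept %d/%d trials", sorted(wanted), len(df), n0
            )

    if correct_only is None:
        correct_only = "correct" in df.columns
    if correct_only:
        if "correct" not in df.columns:
            raise ValueError("correct_only requested but table has no 'correct' column")
        n1 = len(df)
        df = df[df["correct"].astype(int) == 1]
        log.info("correct-only filter dropped %d error trials", n1 - len(df))

    after = set(df["participant"].unique())
    lost = before - after
    if lost:
        raise ValueError(
            f"selection left no trials for participant(s): {sorted(map(str, lost))}"
        )
    return TrialTable(df.reset_index(drop=True), task=table.task)


def participant_median(rts: Iterable[float]) -> float:
    """Midpoint median of a participant's pooled RTs (>= 2 values)."""
    arr = np.asarray(list(rts), dtype=float)
    if arr.size < 2:
        raise ValueError(f"need at least 2 RTs to form a median, got {arr.size}")
    return float(np.median(arr))


def median_split_classify(
    rts: Sequence[float], median: Optional[float] = None
) -> np.ndarray:
    """Predicted condition per trial: True = "repeated" (rt < median)."""
    arr = np.asarray(rts, dtype=float)
    if median is None:
        median = participant_median(arr)
    return arr < median


def median_split_rates(
    rep_rts: np.ndarray,
    new_rts: np.ndarray,
    correction: Correction = "log_linear",
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised median-split hit/false-alarm rates.

    Accepts 1-D arrays (one participant) or 2-D arrays of shape
    (participants, trials) with balanced trial counts per row; the median
    is taken over both conditions pooled, per row.
    """
    rep = np.atleast_2d(np.asarray(rep_rts, dtype=float))
    new = np.atleast_2d(np.asarray(new_rts, dtype=float))
    if rep.shape[0] != new.shape[0]:
        raise ValueError("condition arrays must agree on the participant axis")
    med = np.median(np.concatenate([rep, new], axis=1), axis=1, keepdims=True)
    hits = (rep < med).sum(axis=1)
    fas = (new < med).sum(axis=1)
    n_s = rep.shape[1]
    n_n = new.shape[1]
    if correction == "log_linear":
        hr = (hits + 0.5) / (n_s + 1.0)
        fa = (fas + 0.5) / (n_n + 1.0)
    elif correction == "none":
        hr = hits / n_s
        fa = fas / n_n
        if np.any((hr <= 0) | (hr >= 1) | (fa <= 0) | (fa >= 1)):
            raise ValueError(
                "boundary rates under correction='none'; use 'log_linear'"
            )
    else:
        raise ValueError(f"unknown correction {correction!r}")
    if np.asarray(rep_rts).ndim == 1:
        return float(hr[0]), float(fa[0])
    return hr, fa


def _group_frame(estimates: Dict, source: str) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(estimates, orient="index")
    df.index.name = "participant"
    return df


@dataclass
class GroupSensitivity:
    """Per-participant sensitivity estimates plus group-level summaries."""

    per_participant: pd.DataFrame  # index participant; dprime, se, hr, fa, n_signal, n_noise
    source: str

    @property
    def dprimes(self) -> pd.Series:
        return self.per_participant["dprime"]

    @property
    def n_participants(self) -> int:
        return len(self.per_participant)

    @property
    def mean_dprime(self) -> float:
        return float(self.per_participant["dprime"].mean())

    @property
    def se_mean(self) -> float:
        n = self.n_participants
        return float(self.per_participant["dprime"].std(ddof=1) / np.sqrt(n))

    def estimates(self) -> Dict[object, SensitivityEstimate]:
        out = {}
        for pid, row in self.per_participant.iterrows():
            out[pid] = SensitivityEstimate(
                dprime=row["dprime"],
                n_signal=int(row["n_signal"]),
                n_noise=int(row["n_noise"]),
                source=self.source,
                se=row["se"],
            )
        return out


def indirect_dprime_from_trials(
    table: TrialTable,
    epochs: EpochPolicy = "last",
    correct_only: Optional[bool] = None,
    correction: Correction = "log_linear",
) -> GroupSensitivity:
    """Per-participant median-split (indirect) sensitivities from RTs."""
    if table.task != "search":
        raise ValueError("indirect sensitivities require a search-task table")
    selected = select_trials(table, epochs=epochs, correct_only=correct_only)
    rows = {}
    for pid, sub in selected.data.groupby("participant", sort=True):
        rep = sub.loc[sub["condition"] == "repeated", "rt_ms"].to_numpy(dtype=float)
        new = sub.loc[sub["condition"] == "new", "rt_ms"].to_numpy(dtype=float)
        if rep.size < 2 or new.size < 2:
            raise ValueError(
                f"participant {pid!r} has fewer than 2 trials in a condition "
                f"(repeated={rep.size}, new={new.size})"
            )
        med = participant_median(np.concatenate([rep, new]))
        hits = int((rep < med).sum())
        fas = int((new < med).sum())
        counts = RecognitionCounts(hits, rep.size - hits, fas, new.size - fas)
        hr, fa = rates_from_counts(counts, correction)
        rows[pid] = {
            "dprime": dprime_from_rates(hr, fa),
            "se": se_dprime_from_counts(counts, correction),
            "hr": hr,
            "fa": fa,
            "hits": counts.hits,
            "false_alarms": counts.false_alarms,
            "n_signal": rep.size,
            "n_noise": new.size,
        }
    return GroupSensitivity(_group_frame(rows, "indirect_trials"), "indirect_trials")


def direct_dprime_from_trials(
    table: TrialTable, correction: Correction = "log_linear"
) -> GroupSensitivity:
    """Per-participant explicit-report (direct) sensitivities."""
    if table.task != "recognition":
        raise ValueError("direct sensitivities require a recognition-task table")
    rows = {}
    for pid, sub in table.data.groupby("participant", sort=True):
        rep = sub[sub["condition"] == "repeated"]
        new = sub[sub["condition"] == "new"]
        if len(rep) == 0 or len(new) == 0:
            raise ValueError(
                f"participant {pid!r} is missing a response cell "
                f"(repeated={len(rep)}, new={len(new)})"
            )
        counts = RecognitionCounts(
            hits=int((rep["response"] == "old").sum()),
            misses=int((rep["response"] == "new").sum()),
            false_alarms=int((new["response"] == "old").sum()),
            correct_rejections=int((new["response"] == "new").sum()),
        )
        hr, fa = rates_from_counts(counts, correction)
        rows[pid] = {
            "dprime": dprime_from_rates(hr, fa),
            "se": se_dprime_from_counts(counts, correction),
            "hr": hr,
            "fa": fa,
            "hits": counts.hits,
            "false_alarms": counts.false_alarms,
            "n_signal": counts.n_signal,
            "n_noise": counts.n_noise,
        }
    return GroupSensitivity(_group_frame(rows, "direct"), "direct")
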