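"""CSV/JSON/YAML interfaces and report formatting.

CSV dialect is fixed: UTF-8, comma separated, period decimals, header
required.  Validation errors cite 1-based file line numbers (header is
line 1).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd

import yaml

from .observer import TrialTable
from .summary import DEFAULT_Q2, SummaryStudy

__all__ = [
    "AnalysisConfig",
    "read_trial_csv",
    "read_recognition_csv",
    "read_summary_csv",
    "write_report",
    "write_table",
]

log = logging.getLogger(__name__)

_TRIAL_REQUIRED = ("participant", "epoch", "block", "condition", "rt_ms")
_TRIAL_OPTIONAL = ("correct",)
_RECOG_REQUIRED = ("participant", "condition", "response")
_SUMMARY_REQUIRED = ("label", "t", "N", "K")
_SUMMARY_OPTIONAL = ("q2", "hr", "fa", "n_direct_signal", "n_direct_noise")

REPORT_FIELDS = (
    "label",
    "mode",
    "d_indirect",
    "d_direct",
    "d_difference",
    "se",
    "ci_level",
    "ci_low",
    "ci_high",
    "t",
    "df",
    "p_two_sided",
    "bf10_one_sided",
    "bf_category",
    "ita_decision",
)


@dataclass
class AnalysisConfig:
    """Knobs of a full analysis run; mirrors the CLI flags."""

    mode: Literal["from_trials", "from_summary", "estimate_q2", "simulate", "report"]
    epoch_policy: Union[str, List[int]] = "last"
    correction: Literal["none", "log_linear"] = "log_linear"
    q2_default: float = DEFAULT_Q2
    alpha: float = 0.05
    ci_level: float = 0.95
    bootstrap_b: int = 2000
    seed: Optional[int] = None
    paths: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError(f"ci_level must be in (0, 1), got {self.ci_level}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _check_columns(df: pd.DataFrame, required, optional, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    extra = [c for c in df.columns if c not in (*required, *optional)]
    if extra:
        log.warning("%s: ignoring extra column(s): %s", path, extra)


def _line(idx: int) -> int:
    # data row i (0-based) sits on file line i + 2 (header is line 1)
    return idx + 2


def read_trial_csv(path) -> TrialTable:
    """Read and validate a search-task trial CSV."""
    path = Path(path)
    df = pd.read_csv(path, encoding="utf-8")
    _check_columns(df, _TRIAL_REQUIRED, _TRIAL_OPTIONAL, path)

    bad = df[~df["condition"].isin(["repeated", "new"])]
    if len(bad):
        raise ValueError(
            f"{path}: unknown condition {bad['condition'].iloc[0]!r} "
            f"on line {_line(bad.index[0])}"
        )
    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    bad = df[~np.isfinite(rt) | (rt <= 0)]
    if len(bad):
        raise ValueError(
            f"{path}: non-positive or non-numeric rt_ms "
            f"{bad['rt_ms'].iloc[0]!r} on line {_line(bad.index[0])}"
        )
    for col in ("epoch", "block"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df[vals.isna() | (vals < 1) | (vals % 1 != 0)]
        if len(bad):
            raise ValueError(
                f"{path}: invalid {col} {bad[col].iloc[0]!r} "
                f"on line {_line(bad.index[0])}"
            )
        df[col] = vals.astype(int)
    df["rt_ms"] = rt.astype(float)
    keep = [c for c in (*_TRIAL_REQUIRED, *_TRIAL_OPTIONAL) if c in df.columns]
    table = TrialTable(df[keep].copy(), task="search")
    log.info("%s: %d trials, %d participants", path, len(df), len(table.participants))
    return table


def read_recognition_csv(path) -> TrialTable:
    """Read and validate an explicit recognition-task CSV."""
    path = Path(path)
    df = pd.read_csv(path, encoding="utf-8")
    _check_columns(df, _RECOG_REQUIRED, (), path)
    bad = df[~df["condition"].isin(["repeated", "new"])]
    if len(bad):
        raise ValueError(
            f"{path}: unknown condition {bad['condition'].iloc[0]!r} "
            f"on line {_line(bad.index[0])}"
        )
    bad = df[~df["response"].isin(["old", "new"])]
    if len(bad):
        raise ValueError(
            f"{path}: unknown response {bad['response'].iloc[0]!r} "
            f"on line {_line(bad.index[0])}"
        )
    return TrialTable(df[list(_RECOG_REQUIRED)].copy(), task="recognition")


def read_summary_csv(path, q2_default: float = DEFAULT_Q2) -> List[SummaryStudy]:
    """Read a study-summary CSV into validated study records.

    Blank q2 cells fall back to ``q2_default`` (logged).
    """
    path = Path(path)
    df = pd.read_csv(path, encoding="utf-8")
    _check_columns(df, _SUMMARY_REQUIRED, _SUMMARY_OPTIONAL, path)
    studies = []
    for idx, row in df.iterrows():
        q2 = row.get("q2", np.nan)
        if pd.isna(q2):
            log.info(
                "%s line %d: blank q2, using default %.4g",
                path,
                _line(idx),
                q2_default,
            )
            q2 = q2_default

        def _opt(name, cast):
            v = row.get(name, np.nan)
            return None if pd.isna(v) else cast(v)

        try:
            studies.append(
                SummaryStudy(
                    label=str(row["label"]),
                    t_value=float(row["t"]),
                    n_participants=int(row["N"]),
                    k_trials=int(row["K"]),
                    q2=float(q2),
                    hr=_opt("hr", float),
                    fa=_opt("fa", float),
                    n_direct_signal=_opt("n_direct_signal", int),
                    n_direct_noise=_opt("n_direct_noise", int),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path} line {_line(idx)}: {exc}") from exc
    if not studies:
        raise ValueError(f"{path}: no study rows found")
    return studies


def _round_floats(obj, ndigits: int):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def write_report(
    results: Sequence,
    path,
    format: Literal["json", "csv", "markdown"] = "json",
    precision: int = 3,
) -> None:
    """Write comparison results with deterministic field order.

    ``results`` may hold ComparisonResult objects or plain dicts with
    the same keys.
    """
    rows = [r.to_dict() if hasattr(r, "to_dict") else dict(r) for r in results]
    if not rows:
        raise ValueError("no results to write")
    ordered = [
        {k: row.get(k) for k in REPORT_FIELDS} for row in rows
    ]
    path = Path(path)
    if format == "json":
        payload = _round_floats(ordered, precision)
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    elif format == "csv":
        pd.DataFrame(ordered, columns=list(REPORT_FIELDS)).round(precision).to_csv(
            path, index=False
        )
    elif format == "markdown":
        df = pd.DataFrame(ordered, columns=list(REPORT_FIELDS))
        num = df.select_dtypes(include=[float]).columns
        df[num] = df[num].round(2)  # display precision
        lines = [
            "| " + " | ".join(REPORT_FIELDS) + " |",
            "| " + " | ".join("---" for _ in REPORT_FIELDS) + " |",
        ]
        for _, row in df.iterrows():
            lines.append("| " + " | ".join(str(v) for v in row.tolist()) + " |")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown format {format!r}")
    log.info("wrote %d result row(s) to %s", len(ordered), path)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a coordinate/table CSV (funnel points, per-participant rows)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=df.index.name is not None)
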