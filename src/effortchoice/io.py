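"""CSV readers/writers for the package's tidy interchange tables.

Schemas (UTF-8, comma-delimited, header mandatory):

* performance.csv — participant, option, accuracy, n_trials
* choices.csv     — participant, option_a, option_b, n, k
  (``k`` counts choices of ``option_a``; any orientation accepted on read and
  canonicalized)
* titration.csv   — participant, condition, phase, set, decision,
  secondary_offer, choice, performed

Validation failures raise :class:`~effortchoice.errors.ValidationError`
naming the offending row.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .choices import PairwiseChoiceData
from .errors import ValidationError
from .models import PerformanceProfile
from .options import ALL_OPTIONS, OptionId, canonical_pair, parse_option
from .titration import DecisionRecord, TitrationConfig, TitrationTrace

__all__ = [
    "read_performance",
    "read_choices",
    "read_titration",
    "write_performance",
    "write_choices",
    "write_titration",
    "profile_from_frame",
    "choices_from_frame",
    "traces_from_frame",
]


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing column(s) {', '.join(missing)}")
    if df.empty:
        raise ValidationError(f"{what}: empty cohort (no data rows)")


def profile_from_frame(df: pd.DataFrame, participant: str) -> PerformanceProfile:
    sub = df[df["participant"].astype(str) == str(participant)]
    if sub.empty:
        raise ValidationError(f"no performance rows for participant {participant}")
    accuracy: dict[OptionId, float] = {}
    n_trials = 15
    for row in sub.itertuples():
        opt = parse_option(str(row.option))
        if opt in accuracy:
            raise ValidationError(
                f"duplicate option {opt} for participant {participant}",
                row=row.Index,
            )
        accuracy[opt] = float(row.accuracy)
        if hasattr(row, "n_trials") and not pd.isna(row.n_trials):
            n_trials = int(row.n_trials)
    return PerformanceProfile(
        participant=str(participant), accuracy=accuracy, n_trials=n_trials
    )


def read_performance(path: str | Path) -> dict[str, PerformanceProfile]:
    """Read performance.csv into per-participant profiles."""
    df = pd.read_csv(path)
    _require_columns(df, ("participant", "option", "accuracy"), str(path))
    return {
        str(pid): profile_from_frame(df, pid)
        for pid in df["participant"].astype(str).unique()
    }


def choices_from_frame(df: pd.DataFrame, participant: str) -> PairwiseChoiceData:
    sub = df[df["participant"].astype(str) == str(participant)]
    if sub.empty:
        raise ValidationError(f"no choice rows for participant {participant}")
    counts: dict[tuple[OptionId, OptionId], tuple[int, int]] = {}
    for row in sub.itertuples():
        a = parse_option(str(row.option_a))
        b = parse_option(str(row.option_b))
        n, k = int(row.n), int(row.k)
        if not 0 <= k <= n:
            raise ValidationError(
                f"participant {participant}, pair {a}/{b}: k={k} exceeds n={n}",
                row=row.Index,
            )
        ca, cb = canonical_pair(a, b)
        if (ca, cb) in counts:
            raise ValidationError(
                f"duplicate pair {ca}/{cb} for participant {participant}",
                row=row.Index,
            )
        counts[(ca, cb)] = (n, k) if (ca, cb) == (a, b) else (n, n - k)
    return PairwiseChoiceData(participant=str(participant), counts=counts)


def read_choices(path: str | Path) -> dict[str, PairwiseChoiceData]:
    """Read choices.csv into per-participant pairwise counts."""
    df = pd.read_csv(path)
    _require_columns(df, ("participant", "option_a", "option_b", "n", "k"), str(path))
    return {
        str(pid): choices_from_frame(df, pid)
        for pid in df["participant"].astype(str).unique()
    }


def traces_from_frame(df: pd.DataFrame) -> dict[str, dict[str, TitrationTrace]]:
    out: dict[str, dict[str, TitrationTrace]] = {}
    configs = {"reward": TitrationConfig.reward(), "demand": TitrationConfig.demand()}
    for (pid, phase), sub in df.groupby(["participant", "phase"], sort=True):
        phase = str(phase)
        if phase not in configs:
            raise ValidationError(f"unknown phase {phase!r} for participant {pid}")
        sub = sub.sort_values(["set", "decision"])
        records = tuple(
            DecisionRecord(
                phase=phase,
                set_index=int(r.set),
                decision_index=int(r.decision),
                secondary_offer=float(r.secondary_offer),
                choice=str(r.choice),
                performed=bool(r.performed),
            )
            for r in sub.itertuples()
        )
        condition = str(sub["condition"].iloc[0])
        out.setdefault(str(pid), {})[phase] = TitrationTrace(
            participant=str(pid),
            condition=condition,
            phase=phase,
            records=records,
            config=configs[phase],
        )
    return out


def read_titration(path: str | Path) -> dict[str, dict[str, TitrationTrace]]:
    """Read titration.csv into per-participant, per-phase traces."""
    df = pd.read_csv(path)
    _require_columns(
        df,
        (
            "participant",
            "condition",
            "phase",
            "set",
            "decision",
            "secondary_offer",
            "choice",
            "performed",
        ),
        str(path),
    )
    return traces_from_frame(df)


def write_performance(
    profiles: dict[str, PerformanceProfile], path: str | Path
) -> None:
    rows = [
        {
            "participant": pid,
            "option": opt.key,
            "accuracy": prof[opt],
            "n_trials": prof.n_trials,
        }
        for pid, prof in profiles.items()
        for opt in ALL_OPTIONS
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_choices(data: dict[str, PairwiseChoiceData], path: str | Path) -> None:
    rows = [
        {"participant": pid, "option_a": a.key, "option_b": b.key, "n": n, "k": k}
        for pid, d in data.items()
        for (a, b), (n, k) in sorted(
            d.counts.items(), key=lambda kv: (kv[0][0].key, kv[0][1].key)
        )
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_titration(
    traces: dict[str, dict[str, TitrationTrace]], path: str | Path
) -> None:
    rows = [
        {
            "participant": pid,
            "condition": trace.condition,
            "phase": trace.phase,
            "set": rec.set_index,
            "decision": rec.decision_index,
            "secondary_offer": rec.secondary_offer,
            "choice": rec.choice,
            "performed": rec.performed,
        }
        for pid, phases in traces.items()
        for trace in phases.values()
        for rec in trace.records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
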