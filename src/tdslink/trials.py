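"""Raw TDS trial event logs: parsing, validation and time normalization.

A temporal dominance of sensations (TDS) trial is the record of one panelist
continuously selecting, among a fixed vocabulary of attributes, the one that
currently dominates perception while eating.  The raw log of a trial is an
ordered sequence of timestamped button presses closed by a stop event.

The on-disk event-log format is delimited text (comma or tab, auto-detected)
with a header row and the columns::

    panel_id, repetition, category, event_type, time_s, attribute

where ``event_type`` is ``press`` or ``stop`` and ``attribute`` is empty for
stop rows.  Exactly one stop row is required per trial.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "EVENT_LOG_COLUMNS",
    "TrialValidationError",
    "AttributeVocabulary",
    "TrialRecord",
    "read_trials",
    "write_trials",
    "infer_vocabulary",
    "normalize_trial_time",
]

EVENT_LOG_COLUMNS = (
    "panel_id",
    "repetition",
    "category",
    "event_type",
    "time_s",
    "attribute",
)


class TrialValidationError(ValueError):
    """Raised when an event log (or a trial built from one) is malformed."""


@dataclass(frozen=True)
class AttributeVocabulary:
    """The ordered attribute list of one TDS category.

    Parameters
    ----------
    category_label:
        Name of the attribute category, e.g. ``"primary-sensory"`` or
        ``"multi-sensory"``.
    attributes:
        Ordered, unique attribute names (at least two).
    """

    category_label: str
    attributes: tuple[str, ...]

    def __post_init__(self) -> None:
        attrs = tuple(self.attributes)
        object.__setattr__(self, "attributes", attrs)
        if not self.category_label:
            raise ValueError("category_label must be non-empty")
        if len(attrs) < 2:
            raise ValueError("a vocabulary needs at least two attributes")
        if any(not a for a in attrs):
            raise ValueError("attribute names must be non-empty")
        if len(set(attrs)) != len(attrs):
            raise ValueError("attribute names must be unique")

    @property
    def k(self) -> int:
        """Number of attributes."""
        return len(self.attributes)

    def index(self, name: str) -> int:
        try:
            return self.attributes.index(name)
        except ValueError:
            raise KeyError(
                f"attribute {name!r} not in vocabulary "
                f"{self.category_label!r}"
            ) from None


@dataclass(frozen=True)
class TrialRecord:
    """One panelist's single TDS trial.

    ``events`` holds ``(time_s, attribute)`` pairs with strictly increasing
    times, all strictly below ``stop_time_s``.  The list may be empty (the
    panelist pressed no attribute button before stopping).
    """

    panel_id: str
    repetition: int
    category_label: str
    events: tuple[tuple[float, str], ...]
    stop_time_s: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "events", tuple((float(t), str(a)) for t, a in self.events)
        )
        if self.repetition < 1:
            raise TrialValidationError("repetition must be a positive integer")
        if not self.stop_time_s > 0:
            raise TrialValidationError("stop_time_s must be positive")
        times = [t for t, _ in self.events]
        if any(t < 0 for t in times):
            raise TrialValidationError("event times must be >= 0")
        if any(t >= self.stop_time_s for t in times):
            raise TrialValidationError(
                "event times must be strictly below the stop time"
            )
        if any(b <= a for a, b in zip(times, times[1:])):
            raise TrialValidationError("event times must be strictly increasing")

    @property
    def key(self) -> tuple[str, int]:
        """The (panel_id, repetition) identity used for pairing/resampling."""
        return (self.panel_id, self.repetition)


def _detect_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_trials(path, vocabulary: AttributeVocabulary) -> list[TrialRecord]:
    """Read an event log and return one :class:`TrialRecord` per trial.

    Only rows whose ``category`` equals ``vocabulary.category_label`` are
    consumed, so a single file may hold both categories.  Within a trial,
    press rows are sorted by time; two presses with the identical timestamp
    are collapsed to the later row in file order (last press wins) with a
    warning.

    Raises
    ------
    TrialValidationError
        On an unknown attribute (the offending file line is named), a missing
        or duplicated stop row, or otherwise malformed rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path, sep=_detect_delimiter(path), dtype=str, keep_default_na=False
    )
    missing = set(EVENT_LOG_COLUMNS) - set(df.columns)
    if missing:
        raise TrialValidationError(
            f"{path}: missing columns {sorted(missing)}"
        )
    df = df.assign(_line=df.index + 2)  # 1-based, counting the header
    sub = df[df["category"] == vocabulary.category_label]

    trials: list[TrialRecord] = []
    for (panel_id, rep_str), group in sub.groupby(
        ["panel_id", "repetition"], sort=True
    ):
        where = f"{path} trial ({panel_id!r}, {rep_str!r})"
        try:
            repetition = int(rep_str)
        except ValueError:
            raise TrialValidationError(
                f"{where}: repetition {rep_str!r} is not an integer"
            ) from None

        bad_type = group[~group["event_type"].isin(("press", "stop"))]
        if len(bad_type):
            line = int(bad_type["_line"].iloc[0])
            raise TrialValidationError(
                f"{where}: unknown event_type at line {line}"
            )
        stops = group[group["event_type"] == "stop"]
        if len(stops) == 0:
            raise TrialValidationError(f"{where}: missing stop row")
        if len(stops) > 1:
            raise TrialValidationError(f"{where}: multiple stop rows")
        stop_time = float(stops["time_s"].iloc[0])

        presses = group[group["event_type"] == "press"]
        unknown = presses[~presses["attribute"].isin(vocabulary.attributes)]
        if len(unknown):
            row = unknown.iloc[0]
            raise TrialValidationError(
                f"{where}: unknown attribute {row['attribute']!r} "
                f"at line {int(row['_line'])}"
            )
        try:
            times = presses["time_s"].astype(float).to_numpy()
        except ValueError as exc:
            raise TrialValidationError(f"{where}: bad time value ({exc})") from None

        order = times.argsort(kind="stable")  # stable: file order among ties
        events: list[tuple[float, str]] = []
        for i in order:
            t = float(times[i])
            attr = presses["attribute"].iloc[i]
            if events and events[-1][0] == t:
                warnings.warn(
                    f"{where}: two presses at t={t}; keeping the later row "
                    f"in file order ({attr!r})",
                    stacklevel=2,
                )
                events[-1] = (t, attr)
            else:
                events.append((t, attr))

        trials.append(
            TrialRecord(
                panel_id=str(panel_id),
                repetition=repetition,
                category_label=vocabulary.category_label,
                events=tuple(events),
                stop_time_s=stop_time,
            )
        )
    return trials


def write_trials(trials: Sequence[TrialRecord], path, delimiter: str = ",") -> None:
    """Write trials to the event-log format (UTF-8, ``repr`` float times)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(EVENT_LOG_COLUMNS)
        for trial in trials:
            for t, attr in trial.events:
                writer.writerow(
                    [trial.panel_id, trial.repetition, trial.category_label,
                     "press", repr(t), attr]
                )
            writer.writerow(
                [trial.panel_id, trial.repetition, trial.category_label,
                 "stop", repr(float(trial.stop_time_s)), ""]
            )


def infer_vocabulary(path, category_label: str) -> AttributeVocabulary:
    """Build a vocabulary from the attributes of one category in a log file,
    ordered by first appearance."""
    path = Path(path)
    df = pd.read_csv(
        path, sep=_detect_delimiter(path), dtype=str, keep_default_na=False
    )
    sub = df[(df["category"] == category_label) & (df["event_type"] == "press")]
    seen: list[str] = []
    for attr in sub["attribute"]:
        if attr not in seen:
            seen.append(attr)
    return AttributeVocabulary(category_label, tuple(seen))


def normalize_trial_time(trial: TrialRecord) -> TrialRecord:
    """Map a trial's clock times onto normalized task time [0, 1].

    Every event time is divided by the stop time and the stop time becomes 1,
    so trials of different durations become comparable.  Idempotent.
    """
    if not trial.stop_time_s > 0:
        raise TrialValidationError("stop_time_s must be positive")
    stop = trial.stop_time_s
    return replace(
        trial,
        events=tuple((t / stop, a) for t, a in trial.events),
        stop_time_s=1.0,
    )
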