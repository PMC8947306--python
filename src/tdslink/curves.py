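"""Dominance-proportion curves on a normalized time grid.

The central TDS summary is the *dominance proportion*: at each instant of
normalized task time, the fraction of trials in which a given attribute is
the currently selected (dominant) one.  This module turns normalized
:class:`~tdslink.trials.TrialRecord` objects into per-attribute binary
dominance indicators, averages them into curves, optionally smooths the
curves with a centered moving-average filter, and computes the binomial
chance/significance levels used to screen attributes.

Conventions
-----------
* The grid is inclusive of both endpoints, ``t in {0, dt, ..., 1}`` with
  ``dt = 1/(s-1)``.
* An attribute is dominant at instant ``t`` iff the most recent press at or
  before ``t`` selected it; before the first press nothing is dominant.  The
  stop press ends the trial without being a dominance event, so the last
  selection holds through ``t = 1``.
* Smoothing is a centered moving average over a window of fixed width in
  normalized time, truncated (shrunk) at the curve ends so no padding values
  are invented.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trials import AttributeVocabulary, TrialRecord

__all__ = [
    "TimeGrid",
    "DominanceCurveSet",
    "SignificanceLevels",
    "dominance_indicator",
    "compute_dominance_curves",
    "moving_average",
    "significance_levels",
    "screen_attributes",
    "write_curves",
    "read_curves",
]

_TIME_TOL = 1e-9


@dataclass(frozen=True, eq=False)
class TimeGrid:
    """Uniform grid of ``s`` instants on normalized time [0, 1]."""

    instants: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.instants, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError("a time grid needs at least two instants")
        if abs(arr[0]) > 1e-12 or abs(arr[-1] - 1.0) > 1e-12:
            raise ValueError("grid must start at 0 and end at 1")
        steps = np.diff(arr)
        if np.any(np.abs(steps - steps[0]) > 1e-12):
            raise ValueError("grid spacing must be uniform")
        arr.setflags(write=False)
        object.__setattr__(self, "instants", arr)

    @classmethod
    def uniform(cls, s: int) -> "TimeGrid":
        """Grid with ``s`` evenly spaced instants, ``dt = 1/(s-1)``."""
        if s < 2:
            raise ValueError("s must be >= 2")
        return cls(np.linspace(0.0, 1.0, int(s)))

    @property
    def s(self) -> int:
        return int(self.instants.size)

    @property
    def dt(self) -> float:
        return float(self.instants[1] - self.instants[0])


@dataclass(eq=False)
class DominanceCurveSet:
    """Attributes x instants matrix of dominance proportions.

    ``proportions[i, j]`` is the fraction of the ``n_trials`` trials in which
    attribute ``i`` was dominant at grid instant ``j``.  For unsmoothed
    curves at most one attribute is dominant per trial per instant, so the
    column sums never exceed 1.
    """

    vocabulary: AttributeVocabulary
    grid: TimeGrid
    proportions: np.ndarray
    n_trials: int
    smoothed: bool = False
    window: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.proportions, dtype=float)
        if arr.shape != (self.vocabulary.k, self.grid.s):
            raise ValueError(
                f"proportions must be {self.vocabulary.k} x {self.grid.s}, "
                f"got {arr.shape}"
            )
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if arr.min() < -_TIME_TOL or arr.max() > 1 + _TIME_TOL:
            raise ValueError("dominance proportions must lie in [0, 1]")
        if not self.smoothed:
            colsums = arr.sum(axis=0)
            if np.any(colsums > 1 + 1e-9):
                raise ValueError(
                    "unsmoothed dominance proportions must have column sums <= 1"
                )
        self.proportions = arr

    def row(self, attribute: str) -> np.ndarray:
        return self.proportions[self.vocabulary.index(attribute)]


@dataclass(frozen=True)
class SignificanceLevels:
    """Chance and significance thresholds for dominance proportions."""

    chance_level: float
    significance_level: float
    alpha: float
    n_trials: int
    k_attributes: int
    method: str = "normal"

    def __post_init__(self) -> None:
        if not 0 < self.chance_level < self.significance_level < 1:
            raise ValueError(
                "levels must satisfy 0 < chance < significance < 1"
            )


def _require_normalized(trial: TrialRecord) -> None:
    if abs(trial.stop_time_s - 1.0) > _TIME_TOL:
        raise ValueError(
            "trial must be time-normalized (stop_time_s == 1); "
            "call normalize_trial_time first"
        )


def _selection_codes(
    trial: TrialRecord, vocabulary: AttributeVocabulary, grid: TimeGrid
) -> np.ndarray:
    """Index of the dominant attribute at each grid instant, -1 for none."""
    _require_normalized(trial)
    if not trial.events:
        return np.full(grid.s, -1, dtype=int)
    times = np.array([t for t, _ in trial.events])
    codes = np.array([vocabulary.index(a) for _, a in trial.events])
    # most recent press at or before t (side="right" makes a press effective
    # at its own timestamp)
    pos = np.searchsorted(times, grid.instants + _TIME_TOL, side="right") - 1
    return np.where(pos >= 0, codes[np.clip(pos, 0, None)], -1)


def dominance_indicator(
    trial: TrialRecord,
    attribute: str,
    grid: TimeGrid,
    vocabulary: AttributeVocabulary | None = None,
) -> np.ndarray:
    """Binary dominance vector of one attribute over the grid.

    The entry at instant ``t`` is 1 iff the most recent press at or before
    ``t`` selected ``attribute``; entries before the first press are 0.
    """
    if vocabulary is None:
        names = sorted({a for _, a in trial.events} | {attribute})
        if len(names) < 2:
            names = names + ["__other__"]
        vocabulary = AttributeVocabulary(trial.category_label, tuple(names))
    code = vocabulary.index(attribute)
    sel = _selection_codes(trial, vocabulary, grid)
    return (sel == code).astype(float)


def compute_dominance_curves(
    trials: Sequence[TrialRecord],
    grid: TimeGrid,
    vocabulary: AttributeVocabulary,
    window: float | None = None,
) -> DominanceCurveSet:
    """Average per-trial dominance indicators into proportion curves.

    Parameters
    ----------
    trials:
        Normalized trials sharing ``vocabulary``'s category.
    grid:
        Evaluation grid.
    window:
        Width, in normalized time, of the centered moving-average smoothing
        window; ``None`` leaves the raw proportions.
    """
    if not trials:
        raise ValueError("need at least one trial")
    counts = np.zeros((vocabulary.k, grid.s))
    for trial in trials:
        if trial.category_label != vocabulary.category_label:
            raise ValueError(
                f"trial category {trial.category_label!r} does not match "
                f"vocabulary {vocabulary.category_label!r}"
            )
        sel = _selection_codes(trial, vocabulary, grid)
        active = sel >= 0
        np.add.at(counts, (sel[active], np.nonzero(active)[0]), 1.0)
    proportions = counts / len(trials)
    if window is not None:
        proportions = moving_average(proportions, grid.instants, window)
        return DominanceCurveSet(
            vocabulary, grid, proportions, len(trials), smoothed=True,
            window=float(window),
        )
    return DominanceCurveSet(vocabulary, grid, proportions, len(trials))


def moving_average(
    values: np.ndarray, instants: np.ndarray, window: float
) -> np.ndarray:
    """Centered moving average with the window truncated at the ends.

    ``values`` has curves in rows and instants in columns.  Each output entry
    averages the input entries whose instants lie within ``window/2`` of the
    target instant (inclusive); near the boundaries the window simply
    contains fewer points.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    instants = np.asarray(instants, dtype=float)
    dist = np.abs(instants[:, None] - instants[None, :])
    mask = dist <= window / 2 + 1e-12
    weights = mask / mask.sum(axis=1, keepdims=True)
    return np.asarray(values) @ weights.T


def significance_levels(
    k_attributes: int,
    n_trials: int,
    alpha: float = 0.05,
    exact: bool = False,
) -> SignificanceLevels:
    """Chance level ``P0 = 1/k`` and the significance threshold ``Ps``.

    By default the standard TDS normal approximation to the binomial is
    used::

        Ps = P0 + z_{1-alpha} * sqrt(P0 (1 - P0) / n)

    With ``exact=True``, ``Ps`` is the smallest proportion ``c/n`` such that
    ``P(Binomial(n, P0) >= c) <= alpha``.
    """
    if k_attributes < 2:
        raise ValueError("k_attributes must be >= 2")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    p0 = 1.0 / k_attributes
    if exact:
        c = stats.binom.isf(alpha, n_trials, p0) + 1
        ps = c / n_trials
        method = "exact-binomial"
    else:
        z = stats.norm.ppf(1 - alpha)
        ps = p0 + z * np.sqrt(p0 * (1 - p0) / n_trials)
        method = "normal"
    ps = float(min(ps, 1 - 1e-12))  # tiny n can push the threshold past 1
    return SignificanceLevels(
        chance_level=p0,
        significance_level=ps,
        alpha=alpha,
        n_trials=n_trials,
        k_attributes=k_attributes,
        method=method,
    )


def screen_attributes(
    curves: DominanceCurveSet, levels: SignificanceLevels
) -> pd.Series:
    """Flag attributes whose curve ever exceeds the significance level.

    Returns a boolean Series indexed by attribute; ``False`` marks
    attributes that never reach significance (candidates for removal, a
    decision left to the user).
    """
    reaches = curves.proportions.max(axis=1) > levels.significance_level
    return pd.Series(reaches, index=list(curves.vocabulary.attributes))


def write_curves(curves: DominanceCurveSet, path) -> None:
    """Write curves as delimited text plus a JSON metadata sidecar."""
    path = Path(path)
    frame = pd.DataFrame(
        curves.proportions,
        index=list(curves.vocabulary.attributes),
        columns=[repr(float(t)) for t in curves.grid.instants],
    )
    frame.to_csv(path, index_label="attribute")
    meta = {
        "category_label": curves.vocabulary.category_label,
        "n_trials": curves.n_trials,
        "smoothed": curves.smoothed,
        "window": curves.window,
        "s": curves.grid.s,
    }
    with open(_sidecar(path), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)


def read_curves(path) -> DominanceCurveSet:
    path = Path(path)
    frame = pd.read_csv(path, index_col="attribute")
    with open(_sidecar(path), "r", encoding="utf-8") as fh:
        meta = json.load(fh)
    vocabulary = AttributeVocabulary(
        meta["category_label"], tuple(frame.index)
    )
    grid = TimeGrid(np.array([float(c) for c in frame.columns]))
    return DominanceCurveSet(
        vocabulary,
        grid,
        frame.to_numpy(),
        int(meta["n_trials"]),
        smoothed=bool(meta["smoothed"]),
        window=meta["window"],
    )


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")
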