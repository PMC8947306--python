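"""Bootstrap resampling of TDS trials and stacking of instants for CCA.

A single panel study yields one set of dominance-proportion curves, hence
only ``s`` discretized instants per attribute category -- too few samples to
fit a canonical correlation model on.  Resampling the trials with
replacement and recomputing the (smoothed) curves gives an ensemble of curve
sets whose discretized instants are stacked into an observation matrix.

The resampling unit is always the whole trial (panel x repetition), never an
individual instant.  When the two attribute categories are analysed jointly,
:func:`bootstrap_paired_ensembles` draws one index vector per set and applies
it to both categories, so that any coupling between a panelist's two
sessions survives resampling.

Each bootstrap set uses its own deterministic substream (the set index mixed
into the seed), so enlarging ``n_sets`` never reshuffles earlier sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .curves import DominanceCurveSet, TimeGrid, compute_dominance_curves
from .trials import AttributeVocabulary, TrialRecord

__all__ = [
    "BootstrapEnsemble",
    "DifferentialCurveSet",
    "StackedSampleMatrix",
    "bootstrap_curve_ensemble",
    "bootstrap_paired_ensembles",
    "differentiate_curves",
    "stack_for_cca",
    "write_stacked",
    "read_stacked",
]

#: signature of the test hook replacing the uniform with-replacement draw
IndexSampler = Callable[[int, np.random.Generator], np.ndarray]


@dataclass(eq=False)
class BootstrapEnsemble:
    """A list of resampled curve sets sharing vocabulary and grid."""

    curve_sets: list[DominanceCurveSet]
    seed: int
    n_resampled: int

    def __post_init__(self) -> None:
        if not self.curve_sets:
            raise ValueError("an ensemble needs at least one curve set")
        first = self.curve_sets[0]
        for cs in self.curve_sets[1:]:
            if cs.vocabulary.attributes != first.vocabulary.attributes:
                raise ValueError("curve sets must share one vocabulary")
            if cs.grid.s != first.grid.s:
                raise ValueError("curve sets must share one grid")

    @property
    def n_sets(self) -> int:
        return len(self.curve_sets)

    @property
    def vocabulary(self) -> AttributeVocabulary:
        return self.curve_sets[0].vocabulary

    @property
    def grid(self) -> TimeGrid:
        return self.curve_sets[0].grid

    @property
    def n_trend_instants(self) -> int:
        """Total discretized instants across sets before any exclusion."""
        return self.n_sets * self.grid.s

    @property
    def n_differential_instants(self) -> int:
        return self.n_sets * (self.grid.s - 1)


@dataclass(eq=False)
class DifferentialCurveSet:
    """First differences of a curve set over the grid.

    ``values[:, j]`` is ``proportion(t_{j+1}) - proportion(t_j)``, attached
    to the instant ``t_{j+1}``; entries lie in [-1, 1] and there are
    ``s - 1`` instants, ``t = dt ... 1``.
    """

    vocabulary: AttributeVocabulary
    instants: np.ndarray
    values: np.ndarray
    n_trials: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (self.vocabulary.k, len(self.instants)):
            raise ValueError("values shape does not match vocabulary/instants")
        if arr.min() < -1 - 1e-9 or arr.max() > 1 + 1e-9:
            raise ValueError("differential values must lie in [-1, 1]")
        self.values = arr


@dataclass(eq=False)
class StackedSampleMatrix:
    """Instant-stacked, zero-centered observations for one category.

    Rows are discretized instants pooled across bootstrap sets (after
    exclusions), columns are attributes.  Column means before centering are
    stored so that new curves (e.g. the original, non-resampled ones) can be
    centered consistently when canonical series are evaluated.
    """

    category_label: str
    variant: str
    values: np.ndarray
    column_means: np.ndarray
    attributes: tuple[str, ...]
    centered: bool = True
    provenance: dict | None = None

    def __post_init__(self) -> None:
        if self.variant not in ("trend", "differential"):
            raise ValueError("variant must be 'trend' or 'differential'")
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(self.attributes):
            raise ValueError("values must be N x k")
        if self.centered:
            colmeans = arr.mean(axis=0)
            if np.any(np.abs(colmeans) > 1e-10):
                raise ValueError("centered matrix has nonzero column means")
        self.values = arr
        self.column_means = np.asarray(self.column_means, dtype=float)

    @property
    def n_samples(self) -> int:
        return int(self.values.shape[0])


def _set_rng(seed: int, set_index: int) -> np.random.Generator:
    # per-set substream: the set index is mixed into the seed material
    return np.random.default_rng([int(seed), int(set_index)])


def _uniform_draw(n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, n, size=n)


def bootstrap_curve_ensemble(
    trials: Sequence[TrialRecord],
    grid: TimeGrid,
    vocabulary: AttributeVocabulary,
    window: float | None,
    n_sets: int,
    seed: int,
    index_sampler: IndexSampler | None = None,
) -> BootstrapEnsemble:
    """Resample one category's trials into ``n_sets`` curve sets.

    Each set draws ``len(trials)`` trials uniformly with replacement
    (overridable through ``index_sampler``, e.g. for identity draws in
    tests) and computes the smoothed curves of the resampled trials.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if not trials:
        raise ValueError("need at least one trial")
    sampler = index_sampler or _uniform_draw
    curve_sets = []
    for i in range(n_sets):
        idx = np.asarray(sampler(len(trials), _set_rng(seed, i)))
        resampled = [trials[j] for j in idx]
        curve_sets.append(
            compute_dominance_curves(resampled, grid, vocabulary, window)
        )
    return BootstrapEnsemble(curve_sets, seed=seed, n_resampled=len(trials))


def bootstrap_paired_ensembles(
    trials_x: Sequence[TrialRecord],
    trials_y: Sequence[TrialRecord],
    grid: TimeGrid,
    vocabulary_x: AttributeVocabulary,
    vocabulary_y: AttributeVocabulary,
    window: float | None,
    n_sets: int,
    seed: int,
    index_sampler: IndexSampler | None = None,
) -> tuple[BootstrapEnsemble, BootstrapEnsemble]:
    """Jointly resample the two categories with shared draw indices.

    Trials are aligned by their (panel_id, repetition) key; both lists must
    cover exactly the same keys.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    x_sorted = sorted(trials_x, key=lambda t: t.key)
    y_sorted = sorted(trials_y, key=lambda t: t.key)
    keys_x = [t.key for t in x_sorted]
    keys_y = [t.key for t in y_sorted]
    if keys_x != keys_y:
        raise ValueError(
            "trials_x and trials_y must cover the same (panel, repetition) keys"
        )
    sampler = index_sampler or _uniform_draw
    sets_x, sets_y = [], []
    for i in range(n_sets):
        idx = np.asarray(sampler(len(x_sorted), _set_rng(seed, i)))
        sets_x.append(
            compute_dominance_curves(
                [x_sorted[j] for j in idx], grid, vocabulary_x, window
            )
        )
        sets_y.append(
            compute_dominance_curves(
                [y_sorted[j] for j in idx], grid, vocabulary_y, window
            )
        )
    return (
        BootstrapEnsemble(sets_x, seed=seed, n_resampled=len(x_sorted)),
        BootstrapEnsemble(sets_y, seed=seed, n_resampled=len(y_sorted)),
    )


def differentiate_curves(curves: DominanceCurveSet) -> DifferentialCurveSet:
    """First differences ``x(t) - x(t - dt)`` attached to ``t = dt ... 1``."""
    if curves.grid.s < 2:
        raise ValueError("need at least two instants to differentiate")
    values = np.diff(curves.proportions, axis=1)
    return DifferentialCurveSet(
        vocabulary=curves.vocabulary,
        instants=curves.grid.instants[1:].copy(),
        values=values,
        n_trials=curves.n_trials,
    )


def stack_for_cca(
    ensemble: BootstrapEnsemble,
    variant: str,
    n_excluded: int,
) -> StackedSampleMatrix:
    """Discretize, exclude leading instants, stack across sets and center.

    For the ``trend`` variant each set contributes its ``s`` grid instants;
    for ``differential`` each set is first differenced (``s - 1`` instants).
    The first ``n_excluded`` instants *of whichever grid the variant
    produces* are dropped per set -- the opening moments of a task, before
    panelists start pressing buttons, carry no signal.  The per-set blocks
    are stacked into an N x k matrix and each column is zero-centered
    globally (across all sets); the pre-centering means are stored.
    """
    if variant not in ("trend", "differential"):
        raise ValueError("variant must be 'trend' or 'differential'")
    if n_excluded < 0:
        raise ValueError("n_excluded must be >= 0")
    per_set = (
        ensemble.grid.s if variant == "trend" else ensemble.grid.s - 1
    )
    if n_excluded >= per_set:
        raise ValueError(
            f"n_excluded={n_excluded} leaves no instants (per-set grid has "
            f"{per_set})"
        )
    blocks = []
    for cs in ensemble.curve_sets:
        mat = (
            cs.proportions if variant == "trend"
            else differentiate_curves(cs).values
        )
        blocks.append(mat[:, n_excluded:].T)  # instants x attributes
    stacked = np.vstack(blocks)
    means = stacked.mean(axis=0)
    return StackedSampleMatrix(
        category_label=ensemble.vocabulary.category_label,
        variant=variant,
        values=stacked - means,
        column_means=means,
        attributes=ensemble.vocabulary.attributes,
        centered=True,
        provenance={
            "n_sets": ensemble.n_sets,
            "s": ensemble.grid.s,
            "n_excluded": int(n_excluded),
            "seed": ensemble.seed,
            "n_resampled": ensemble.n_resampled,
            "pre_exclusion_instants": ensemble.n_sets * per_set,
        },
    )


def write_stacked(matrix: StackedSampleMatrix, path) -> None:
    """Delimited-text export with a JSON sidecar holding the provenance."""
    path = Path(path)
    pd.DataFrame(matrix.values, columns=list(matrix.attributes)).to_csv(
        path, index=False
    )
    meta = {
        "category_label": matrix.category_label,
        "variant": matrix.variant,
        "centered": matrix.centered,
        "column_means": matrix.column_means.tolist(),
        "provenance": matrix.provenance,
    }
    with open(path.with_name(path.name + ".json"), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)


def read_stacked(path) -> StackedSampleMatrix:
    path = Path(path)
    frame = pd.read_csv(path)
    with open(path.with_name(path.name + ".json"), "r", encoding="utf-8") as fh:
        meta = json.load(fh)
    return StackedSampleMatrix(
        category_label=meta["category_label"],
        variant=meta["variant"],
        values=frame.to_numpy(),
        column_means=np.array(meta["column_means"]),
        attributes=tuple(frame.columns),
        centered=meta["centered"],
        provenance=meta["provenance"],
    )
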