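"""End-to-end analysis: event logs (or simulation) to a canonical model report.

The pipeline reproduces the standard analysis sequence for linking two TDS
attribute categories: read and normalize trials, compute smoothed dominance
curves, bootstrap the trial set into an ensemble of curve sets, stack the
discretized instants (trend and/or differential variant), fit CCA, run the
sequential Pillai-Bartlett tests, and summarize contributions and canonical
time series.  Defaults (30 instants, a 1/30 smoothing window, 10 bootstrap
sets, 2 excluded instants, alpha 0.05) reproduce the instant-count
arithmetic of the reference study design: 300/290 stacked instants before
exclusion and 280/270 after, for the trend/differential variants with 51
trials.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bootstrap import (
    StackedSampleMatrix,
    bootstrap_paired_ensembles,
    differentiate_curves,
    stack_for_cca,
)
from .cca import (
    CCAModel,
    canonical_series,
    contribution_proportions,
    fit_cca,
    model_to_dict,
    pillai_dimension_tests,
)
from .curves import TimeGrid, compute_dominance_curves
from .simulate import LatentPanelConfig, generate_trials
from .trials import (
    AttributeVocabulary,
    TrialRecord,
    normalize_trial_time,
    read_trials,
)

__all__ = [
    "AnalysisConfig",
    "VariantResult",
    "ModelReport",
    "run_analysis",
    "analyse_trials",
    "compare_variants",
    "pairing_permutation_null",
]

logger = logging.getLogger("tdslink")

VARIANTS = ("trend", "differential")


@dataclass
class AnalysisConfig:
    """Run configuration; the defaults encode the reference study design."""

    logs_x: str | None = None
    logs_y: str | None = None
    attributes_x: tuple[str, ...] | None = None
    attributes_y: tuple[str, ...] | None = None
    simulation: LatentPanelConfig | None = None
    s: int = 30
    window: float | None = 1.0 / 30.0
    n_sets: int = 10
    n_excluded: int = 2
    alpha: float = 0.05
    variants: tuple[str, ...] = VARIANTS
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.variants) - set(VARIANTS)
        if bad:
            raise ValueError(f"unknown variants {sorted(bad)}")
        have_logs = self.logs_x is not None and self.logs_y is not None
        if not have_logs and self.simulation is None:
            raise ValueError("provide event logs for both categories or a simulation config")

    def to_dict(self) -> dict:
        out = {
            "logs_x": self.logs_x,
            "logs_y": self.logs_y,
            "attributes_x": list(self.attributes_x) if self.attributes_x else None,
            "attributes_y": list(self.attributes_y) if self.attributes_y else None,
            "s": self.s,
            "window": self.window,
            "n_sets": self.n_sets,
            "n_excluded": self.n_excluded,
            "alpha": self.alpha,
            "variants": list(self.variants),
            "seed": self.seed,
        }
        if self.simulation is not None:
            from .simulate import _config_to_dict

            out["simulation"] = _config_to_dict(self.simulation)
        return out


@dataclass(eq=False)
class VariantResult:
    """Everything fitted for one variant (trend or differential)."""

    variant: str
    stack_x: StackedSampleMatrix
    stack_y: StackedSampleMatrix
    model: CCAModel
    tests: "object"
    contributions: "object"
    n_selected: int
    variance_explained_x: float
    variance_explained_y: float
    series_instants: np.ndarray
    series_u: np.ndarray
    series_v: np.ndarray

    def to_dict(self) -> dict:
        out = model_to_dict(self.model, self.tests, self.contributions)
        out.update(
            variant=self.variant,
            n_rows=self.stack_x.n_samples,
            pre_exclusion_instants=self.stack_x.provenance[
                "pre_exclusion_instants"
            ],
            n_selected=self.n_selected,
            variance_explained_x=self.variance_explained_x,
            variance_explained_y=self.variance_explained_y,
            series_instants=self.series_instants.tolist(),
            series_u=self.series_u.tolist(),
            series_v=self.series_v.tolist(),
        )
        return out


@dataclass(eq=False)
class ModelReport:
    """Full result of :func:`run_analysis` plus provenance."""

    variants: dict[str, VariantResult]
    n_trials: int
    config: AnalysisConfig
    version: str = __version__

    def to_dict(self) -> dict:
        cfg = self.config.to_dict()
        return {
            "version": self.version,
            "n_trials": self.n_trials,
            "config": cfg,
            "config_hash": _hash_dict(cfg),
            "variants": {k: v.to_dict() for k, v in self.variants.items()},
        }

    def report_hash(self) -> str:
        return _hash_dict(self.to_dict())

    def write(self, path) -> None:
        with open(Path(path), "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _hash_dict(data: dict) -> str:
    return hashlib.sha256(
        json.dumps(data, sort_keys=True).encode("utf-8")
    ).hexdigest()


def _load_trials(
    config: AnalysisConfig,
) -> tuple[list[TrialRecord], list[TrialRecord], AttributeVocabulary, AttributeVocabulary]:
    if config.simulation is not None:
        sim = config.simulation
        trials_x, trials_y = generate_trials(sim)
        return trials_x, trials_y, sim.vocabulary_x(), sim.vocabulary_y()
    if config.attributes_x is None or config.attributes_y is None:
        from .trials import infer_vocabulary

        vocab_x = infer_vocabulary(config.logs_x, "primary-sensory")
        vocab_y = infer_vocabulary(config.logs_y, "multi-sensory")
    else:
        vocab_x = AttributeVocabulary("primary-sensory", tuple(config.attributes_x))
        vocab_y = AttributeVocabulary("multi-sensory", tuple(config.attributes_y))
    return (
        read_trials(config.logs_x, vocab_x),
        read_trials(config.logs_y, vocab_y),
        vocab_x,
        vocab_y,
    )


def analyse_trials(
    trials_x: list[TrialRecord],
    trials_y: list[TrialRecord],
    vocab_x: AttributeVocabulary,
    vocab_y: AttributeVocabulary,
    config: AnalysisConfig,
) -> ModelReport:
    grid = TimeGrid.uniform(config.s)
    norm_x = [normalize_trial_time(t) for t in trials_x]
    norm_y = [normalize_trial_time(t) for t in trials_y]
    logger.info(
        "normalized %d + %d trials (%s / %s)",
        len(norm_x), len(norm_y), vocab_x.category_label, vocab_y.category_label,
    )
    ens_x, ens_y = bootstrap_paired_ensembles(
        norm_x, norm_y, grid, vocab_x, vocab_y,
        config.window, config.n_sets, config.seed,
    )
    logger.info(
        "bootstrapped %d sets of %d trials", config.n_sets, ens_x.n_resampled
    )
    original_x = compute_dominance_curves(norm_x, grid, vocab_x, config.window)
    original_y = compute_dominance_curves(norm_y, grid, vocab_y, config.window)

    results: dict[str, VariantResult] = {}
    for variant in config.variants:
        stack_x = stack_for_cca(ens_x, variant, config.n_excluded)
        stack_y = stack_for_cca(ens_y, variant, config.n_excluded)
        logger.info(
            "%s stack: %d rows (%d before exclusion)",
            variant, stack_x.n_samples,
            stack_x.provenance["pre_exclusion_instants"],
        )
        model = fit_cca(stack_x, stack_y)
        tests = pillai_dimension_tests(model, alpha=config.alpha)
        contributions = contribution_proportions(model, stack_x, stack_y)
        n_selected = tests.n_selected
        var_x = float(contributions.contributions_x[:n_selected].sum())
        var_y = float(contributions.contributions_y[:n_selected].sum())

        # canonical series on the original (non-resampled) smoothed curves,
        # centered with the training stack's column means
        if variant == "trend":
            cx = original_x.proportions.T - stack_x.column_means
            cy = original_y.proportions.T - stack_y.column_means
            instants = grid.instants
        else:
            dx = differentiate_curves(original_x)
            dy = differentiate_curves(original_y)
            cx = dx.values.T - stack_x.column_means
            cy = dy.values.T - stack_y.column_means
            instants = dx.instants
        series = canonical_series(model, cx, cy, instants=instants)
        logger.info(
            "%s model: rho=%s, %d selected dimensions",
            variant,
            np.round(model.correlations, 3).tolist(),
            n_selected,
        )
        results[variant] = VariantResult(
            variant=variant,
            stack_x=stack_x,
            stack_y=stack_y,
            model=model,
            tests=tests,
            contributions=contributions,
            n_selected=n_selected,
            variance_explained_x=var_x,
            variance_explained_y=var_y,
            series_instants=np.asarray(instants),
            series_u=series.u,
            series_v=series.v,
        )
    return ModelReport(
        variants=results, n_trials=len(trials_x), config=config
    )


def run_analysis(config: AnalysisConfig) -> ModelReport:
    """Execute the full pipeline for every requested variant."""
    trials_x, trials_y, vocab_x, vocab_y = _load_trials(config)
    return analyse_trials(trials_x, trials_y, vocab_x, vocab_y, config)


def compare_variants(report: ModelReport) -> pd.DataFrame:
    """Side-by-side summary: selected dimensions, variance explained, rho."""
    rows = {}
    for name, res in report.variants.items():
        row = {
            "n_selected": res.n_selected,
            "variance_explained_x": res.variance_explained_x,
            "variance_explained_y": res.variance_explained_y,
        }
        for j, rho in enumerate(res.model.correlations, start=1):
            row[f"rho_{j}"] = float(rho)
        rows[name] = row
    return pd.DataFrame(rows).T


def pairing_permutation_null(
    trials_x: list[TrialRecord],
    trials_y: list[TrialRecord],
    vocab_x: AttributeVocabulary,
    vocab_y: AttributeVocabulary,
    config: AnalysisConfig,
    variant: str = "trend",
    n_permutations: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of canonical correlations under broken pairing.

    Repeatedly permutes which multi-sensory session is paired with which
    primary-sensory session (the (panel, repetition) keys of the second
    category are reassigned by a random permutation) and reruns the
    bootstrap + CCA pipeline.  This is the appropriate null for "the two
    categories' sessions are independent": it preserves each category's
    temporal and bootstrap structure while destroying only the session
    pairing.  Row-shuffling the stacked matrix instead would ignore the
    strong dependence among stacked instants and reject even for truly
    independent sessions.

    Returns ``rho_perm``, an ``n_permutations x r`` array of the permuted
    canonical correlations; the 95th percentile of ``rho_perm[:, 0]`` is
    the customary null band for the leading correlation.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    x_sorted = sorted(trials_x, key=lambda t: t.key)
    y_sorted = sorted(trials_y, key=lambda t: t.key)
    keys = [t.key for t in x_sorted]
    if keys != [t.key for t in y_sorted]:
        raise ValueError("trial keys do not match between categories")
    run_cfg = replace(config, variants=(variant,))
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_permutations):
        perm = rng.permutation(len(y_sorted))
        y_perm = [
            _relabel(y_sorted[perm[i]], keys[i]) for i in range(len(keys))
        ]
        report = analyse_trials(x_sorted, y_perm, vocab_x, vocab_y, run_cfg)
        rows.append(report.variants[variant].model.correlations)
    return np.vstack(rows)


def _relabel(trial: TrialRecord, key: tuple[str, int]) -> TrialRecord:
    return replace(trial, panel_id=key[0], repetition=key[1])
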