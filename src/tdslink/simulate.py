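"""Synthetic paired TDS sessions with controllable latent coupling.

The generator emulates a panel study in which every panelist performs two
TDS sessions per repetition -- one with primary-sensory attributes, one with
multi-sensory attributes -- so that the full curve / bootstrap / CCA
pipeline can be exercised and validated without external data.

Generative model
----------------
A small number of latent sensory episodes evolve over normalized task time
as smooth Gaussian-shaped bumps ``z_i(t) = A_i exp(-(t - c_i)^2 / 2 w_i^2)``
(dominance episodes in real TDS curves are unimodal).  Each attribute ``k``
of a category has a loading vector ``L_k``; its momentary intensity during
a trial is::

    intensity_k(t) = L_k . z_eff(t) + panel_effect_k + Gumbel(temperature)

and the panelist presses the button of the argmax attribute whenever the
argmax changes at a decision epoch.  Decision epochs follow a renewal
process with a minimum dwell (about one second in real tasks) plus an
exponential extra.  Task durations are log-normal around 30 s so that time
normalization is exercised nontrivially.

Coupling between the two categories is a single knob: each category's
effective latents interpolate between a shared bump set and a private one,
``z_eff = coupling * z_shared + (1 - coupling) * z_private``.  At
``coupling=1`` both categories respond to the same latent episodes; at
``coupling=0`` their sessions are statistically independent.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .curves import DominanceCurveSet, TimeGrid
from .trials import AttributeVocabulary, TrialRecord

__all__ = [
    "LatentBump",
    "LatentPanelConfig",
    "generate_trials",
    "reference_curves",
    "write_config",
    "read_config",
]

PRIMARY_ATTRIBUTES = (
    "sweet", "sour", "fruity", "green", "watery", "juicy", "aromatic", "light",
)
MULTISENSORY_ATTRIBUTES = (
    "refreshing", "fresh", "pleasurable", "rich_deep", "ripe", "mild",
)


@dataclass(frozen=True)
class LatentBump:
    """One latent episode: a Gaussian bump on normalized time."""

    center: float
    width: float
    amplitude: float

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.amplitude * np.exp(
            -((t - self.center) ** 2) / (2 * self.width**2)
        )


def _evaluate(bumps: Sequence[LatentBump], t) -> np.ndarray:
    """Latents x instants matrix of bump values."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    return np.stack([b(t) for b in bumps])


@dataclass
class LatentPanelConfig:
    """Generative parameters of a paired synthetic panel study.

    Defaults mirror a realistic small panel: 17 panelists x 3 repetitions
    (51 trials per category), tasks of about 30 s, 8 primary-sensory and 6
    multi-sensory attributes, a minimum of about 1 s between presses.
    """

    attributes_x: tuple[str, ...] = PRIMARY_ATTRIBUTES
    attributes_y: tuple[str, ...] = MULTISENSORY_ATTRIBUTES
    bumps_shared: tuple[LatentBump, ...] = ()
    bumps_x: tuple[LatentBump, ...] = ()
    bumps_y: tuple[LatentBump, ...] = ()
    loadings_x: np.ndarray | None = None  # p x n_latents
    loadings_y: np.ndarray | None = None  # q x n_latents
    coupling: float = 0.8
    n_panels: int = 17
    n_repetitions: int = 3
    duration_mean_s: float = 30.0
    duration_sigma: float = 0.15
    temperature: float = 1.0
    panel_sd: float = 0.8
    dwell_min_s: float = 1.0
    dwell_mean_extra_s: float = 1.5
    start_delay_s: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.attributes_x) < 2 or len(self.attributes_y) < 2:
            raise ValueError("each category needs at least two attributes")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        if self.dwell_min_s <= 0:
            raise ValueError("dwell_min_s must be positive")
        if self.dwell_min_s >= self.duration_mean_s:
            raise ValueError("dwell minimum is incompatible with the duration")

    @classmethod
    def create(
        cls,
        seed: int = 0,
        coupling: float = 0.8,
        n_latents: int = 3,
        p: int = 8,
        q: int = 6,
        **overrides,
    ) -> "LatentPanelConfig":
        """Build a complete config, deriving bumps and loadings from ``seed``.

        Shared bump centers are spread evenly over the task; private bump
        centers and all loadings are drawn from deterministic substreams of
        ``seed`` so the config is reproducible and ``n_latents`` can change
        without touching unrelated draws.
        """
        attrs_x = overrides.pop(
            "attributes_x",
            PRIMARY_ATTRIBUTES[:p]
            if p <= len(PRIMARY_ATTRIBUTES)
            else PRIMARY_ATTRIBUTES
            + tuple(f"primary_{i}" for i in range(p - len(PRIMARY_ATTRIBUTES))),
        )
        attrs_y = overrides.pop(
            "attributes_y",
            MULTISENSORY_ATTRIBUTES[:q]
            if q <= len(MULTISENSORY_ATTRIBUTES)
            else MULTISENSORY_ATTRIBUTES
            + tuple(f"multi_{i}" for i in range(q - len(MULTISENSORY_ATTRIBUTES))),
        )
        # one latent: a single broad episode spanning the task; several:
        # narrower episodes spread over it
        centers = np.linspace(0.15, 0.85, n_latents) if n_latents > 1 else [0.4]
        width = 0.12 if n_latents > 1 else 0.25
        shared = tuple(
            LatentBump(float(c), width, 2.5) for c in centers
        )

        def private(stream: int) -> tuple[LatentBump, ...]:
            rng = np.random.default_rng([seed, stream])
            return tuple(
                LatentBump(
                    float(rng.uniform(0.1, 0.9)),
                    float(rng.uniform(0.1, 0.16)),
                    2.5,
                )
                for _ in range(n_latents)
            )

        def structured_loadings(stream: int, k: int) -> np.ndarray:
            # each attribute loads strongly on a "home" episode and weakly
            # elsewhere, giving every attribute its own dominance episode as
            # in real TDS curves (attributes that never dominate would have
            # been screened out of a real study).  Dominance competition is
            # driven by loading *differences*, so when several attributes
            # share a home latent the strong loading gets a random sign --
            # an episode then promotes some attributes and suppresses
            # others, keeping the argmax responsive to the latent.
            rng = np.random.default_rng([seed, stream])
            if n_latents == 1:
                # a single latent cannot give every attribute its own
                # episode; spread the loadings instead so the episode
                # strongly reorders the attributes
                return rng.uniform(-2.5, 2.5, size=(k, 1))
            loadings = rng.normal(0.0, 0.4, size=(k, n_latents))
            for i in range(k):
                loadings[i, i % n_latents] = rng.uniform(1.5, 2.5)
            return loadings

        loadings_x = structured_loadings(13, len(attrs_x))
        loadings_y = structured_loadings(14, len(attrs_y))
        return cls(
            attributes_x=tuple(attrs_x),
            attributes_y=tuple(attrs_y),
            bumps_shared=shared,
            bumps_x=private(11),
            bumps_y=private(12),
            loadings_x=loadings_x,
            loadings_y=loadings_y,
            coupling=coupling,
            seed=seed,
            **overrides,
        )

    def vocabulary_x(self) -> AttributeVocabulary:
        return AttributeVocabulary("primary-sensory", self.attributes_x)

    def vocabulary_y(self) -> AttributeVocabulary:
        return AttributeVocabulary("multi-sensory", self.attributes_y)

    def effective_latents(self, category: str, t) -> np.ndarray:
        """``coupling * shared + (1 - coupling) * private`` latent values."""
        private = self.bumps_x if category == "x" else self.bumps_y
        shared = _evaluate(self.bumps_shared, t)
        priv = _evaluate(private, t)
        return self.coupling * shared + (1.0 - self.coupling) * priv


def _simulate_session(
    config: LatentPanelConfig,
    category: str,
    panel_id: str,
    repetition: int,
    panel_effect: np.ndarray,
    rng: np.random.Generator,
) -> TrialRecord:
    loadings = (
        config.loadings_x if category == "x" else config.loadings_y
    )
    vocab = (
        config.vocabulary_x() if category == "x" else config.vocabulary_y()
    )
    duration = config.duration_mean_s * rng.lognormal(
        -config.duration_sigma**2 / 2, config.duration_sigma
    )
    events: list[tuple[float, str]] = []
    current = -1
    t = config.start_delay_s * rng.uniform(0.8, 1.2)
    while t < duration:
        z = config.effective_latents(category, t / duration)[:, 0]
        intensity = loadings @ z + panel_effect
        if config.temperature > 0:
            intensity = intensity + rng.gumbel(
                0.0, config.temperature, size=intensity.size
            )
        choice = int(np.argmax(intensity))
        if choice != current:
            events.append((float(t), vocab.attributes[choice]))
            current = choice
        t += config.dwell_min_s + rng.exponential(config.dwell_mean_extra_s)
    return TrialRecord(
        panel_id=panel_id,
        repetition=repetition,
        category_label=vocab.category_label,
        events=tuple(events),
        stop_time_s=float(duration),
    )


def generate_trials(
    config: LatentPanelConfig,
) -> tuple[list[TrialRecord], list[TrialRecord]]:
    """Simulate the paired panel study.

    Returns ``(trials_x, trials_y)`` -- one primary-sensory and one
    multi-sensory session per panel x repetition.  Fully deterministic
    given ``config.seed``.
    """
    if config.loadings_x is None or config.loadings_y is None:
        raise ValueError("config is incomplete; build it with LatentPanelConfig.create")
    trials_x: list[TrialRecord] = []
    trials_y: list[TrialRecord] = []
    for panel_idx in range(config.n_panels):
        panel_id = f"P{panel_idx + 1:02d}"
        effects_rng = np.random.default_rng([config.seed, 1, panel_idx])
        effect_x = effects_rng.normal(0, config.panel_sd, len(config.attributes_x))
        effect_y = effects_rng.normal(0, config.panel_sd, len(config.attributes_y))
        for rep in range(1, config.n_repetitions + 1):
            for category, effect, sink in (
                ("x", effect_x, trials_x),
                ("y", effect_y, trials_y),
            ):
                rng = np.random.default_rng(
                    [config.seed, 2, panel_idx, rep, 0 if category == "x" else 1]
                )
                sink.append(
                    _simulate_session(
                        config, category, panel_id, rep, effect, rng
                    )
                )
    return trials_x, trials_y


def reference_curves(
    config: LatentPanelConfig, grid: TimeGrid | None = None
) -> tuple[DominanceCurveSet, DominanceCurveSet]:
    """Noise-free expected dominance curves on ``grid``.

    At each instant the attribute with the largest expected intensity
    (loadings x latents, no panel effect, no noise) is dominant with
    proportion 1; instants before the expected first press (the start delay
    over the mean duration) have no dominant attribute.  Empirical curves
    from many simulated trials approach these references away from episode
    boundaries.
    """
    if config.loadings_x is None or config.loadings_y is None:
        raise ValueError("config is incomplete; build it with LatentPanelConfig.create")
    grid = grid or TimeGrid.uniform(30)
    delay = config.start_delay_s / config.duration_mean_s
    out = []
    for category, loadings, vocab in (
        ("x", config.loadings_x, config.vocabulary_x()),
        ("y", config.loadings_y, config.vocabulary_y()),
    ):
        z = config.effective_latents(category, grid.instants)
        intensity = loadings @ z  # attributes x instants
        winners = intensity.argmax(axis=0)
        proportions = np.zeros((len(vocab.attributes), grid.s))
        active = grid.instants >= delay - 1e-12
        proportions[winners[active], np.nonzero(active)[0]] = 1.0
        out.append(
            DominanceCurveSet(vocab, grid, proportions, n_trials=1)
        )
    return out[0], out[1]


def _config_to_dict(config: LatentPanelConfig) -> dict:
    data = asdict(config)
    for key, bumps in (
        ("bumps_shared", config.bumps_shared),
        ("bumps_x", config.bumps_x),
        ("bumps_y", config.bumps_y),
    ):
        data[key] = [
            {"center": b.center, "width": b.width, "amplitude": b.amplitude}
            for b in bumps
        ]
    data["attributes_x"] = list(config.attributes_x)
    data["attributes_y"] = list(config.attributes_y)
    data["loadings_x"] = np.asarray(config.loadings_x).tolist()
    data["loadings_y"] = np.asarray(config.loadings_y).tolist()
    return data


def write_config(config: LatentPanelConfig, path) -> None:
    """Persist a config as a structured key-value text file (YAML)."""
    with open(Path(path), "w", encoding="utf-8") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=False)


def read_config(path) -> LatentPanelConfig:
    with open(Path(path), "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    for key in ("bumps_shared", "bumps_x", "bumps_y"):
        data[key] = tuple(LatentBump(**b) for b in data[key])
    data["attributes_x"] = tuple(data["attributes_x"])
    data["attributes_y"] = tuple(data["attributes_y"])
    data["loadings_x"] = np.array(data["loadings_x"])
    data["loadings_y"] = np.array(data["loadings_y"])
    return LatentPanelConfig(**data)
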