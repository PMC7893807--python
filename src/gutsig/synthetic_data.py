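"""Seeded synthetic cohort generator with ground truth.

Emulates a two-subpopulation pediatric cohort: compositional genus counts
(log-normal intensities, softmax to proportions, multinomial sampling at a
fixed sequencing depth), a planted differential signature containing one
opposite-pattern genus pair, reduced community evenness in subpopulation 2,
CARS items shifted upward in subpopulation 2 on the sensory and social
domains, and brain-region volumes negatively coupled to the sensory domain
score in designated regions.

One global seed drives independent named substreams (structure, labels,
abundance, behavior, brain, tree), so adding a stage — or drawing an extra
held-out cohort from the same planted structure — never perturbs earlier
draws.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
import skbio

from .cars_scoring import (
    DEFAULT_SENSORY_ITEMS,
    DEFAULT_SOCIAL_ITEMS,
    severity_label,
)
from .io_core import (
    AbundanceTable,
    BrainVolumeTable,
    CohortMetadata,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "CohortBundle",
    "simulate_cohort",
    "simulate_cohort_pair",
    "null_cohort",
]

#: Brain regions reported; the first three are coupled to sensory scores.
BRAIN_REGIONS = (
    "lPCC",
    "lSTG",
    "rMOG",
    "rPCC",
    "CUNE",
    "SOG",
    "PoCG",
    "SPG",
    "SMarg",
    "CALC",
)
N_AFFECTED_REGIONS = 3


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Effect parameters are expressed on the natural-log abundance scale
    (``log_effect``), the CARS half-point item grid (``cars_shift``), and
    mm^3 per sensory-domain point (``brain_slope``). Defaults describe the
    study conditions the pipeline is evaluated under: a 78-child discovery
    cohort with a 12-genus planted signature among 60 genera.
    """

    n_samples: int = 78
    n_genera: int = 60
    n_signature: int = 12
    mixing_proportion: float = 0.6  # share of subpopulation 1
    log_effect: float = 1.5  # mean log-abundance shift of signature genera
    evenness_gap: float = 0.5  # extra per-sample log-abundance spread in subpop 2
    cars_shift: float = 0.5  # grid shift of sensory+social items in subpop 2
    brain_slope: float = -110.0  # mm^3 per sensory-domain point, affected regions
    baseline_log_sd: float = 1.0  # spread of per-genus baseline log-means
    log_noise_sd: float = 0.3  # per-sample log-abundance noise
    cars_item_mean: float = 2.3
    cars_item_sd: float = 0.4
    brain_noise_sd: float = 300.0
    depth: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.mixing_proportion < 1.0):
            raise ValidationError("mixing_proportion must lie in (0, 1)")
        if self.n_signature > self.n_genera:
            raise ValidationError("n_signature cannot exceed n_genera")
        if self.n_signature < 2:
            raise ValidationError("n_signature must be >= 2 (the opposite pair)")
        for name in ("log_effect", "evenness_gap", "cars_shift"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_samples < 4 or self.n_genera < 2 or self.depth < 1:
            raise ValidationError("cohort dimensions out of range")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic cohort."""

    latent_labels: pd.Series  # sample_id -> 1 or 2
    planted_signature: tuple[str, ...]
    opposite_pair: tuple[str, str]
    genus_effects: dict[str, float]  # log-shift applied in subpopulation 2
    affected_regions: tuple[str, ...]
    brain_slope: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"latent_label": self.latent_labels}).rename_axis("sample_id")


class CohortBundle(NamedTuple):
    abundance: AbundanceTable
    metadata: list[CohortMetadata]
    brain: BrainVolumeTable
    tree: skbio.TreeNode
    truth: SyntheticTruth


@dataclass(frozen=True)
class _Structure:
    """Cohort-independent planted structure shared by discovery/test draws."""

    genus_ids: tuple[str, ...]
    base_mu: np.ndarray
    signature: tuple[str, ...]
    effects: dict[str, float]
    opposite_pair: tuple[str, str]
    newick: str


def _round_to_grid(values: np.ndarray) -> np.ndarray:
    return np.clip(np.round(values * 2) / 2, 1.0, 4.0)


def _random_bifurcating_newick(leaf_names: list[str], rng: np.random.Generator) -> str:
    """Random topology by iterative joins, exponential branch lengths."""
    nodes = list(leaf_names)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        bi, bj = rng.exponential(0.2, size=2)
        merged = f"({nodes[i]}:{bi:.6f},{nodes[j]}:{bj:.6f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0] + ";"


def _draw_structure(cfg: SimulationConfig, rng: np.random.Generator, rng_tree) -> _Structure:
    genus_ids = tuple(f"Genus{i + 1:03d}" for i in range(cfg.n_genera))
    signature = sorted(
        str(g) for g in rng.choice(genus_ids, size=cfg.n_signature, replace=False)
    )
    # alternate effect signs; the first two signature genera form the
    # opposite-pattern pair (one up in each subpopulation)
    effects = {
        g: (cfg.log_effect if i % 2 else -cfg.log_effect) for i, g in enumerate(signature)
    }
    base_mu = rng.normal(0.0, cfg.baseline_log_sd, size=cfg.n_genera)
    # the opposite pair gets a common baseline so per-sample dominance is
    # driven by the opposing planted effects, not by baseline offset
    pair_idx = [genus_ids.index(signature[0]), genus_ids.index(signature[1])]
    base_mu[pair_idx] = base_mu[pair_idx].mean()
    newick = _random_bifurcating_newick(list(genus_ids), rng_tree)
    return _Structure(
        genus_ids=genus_ids,
        base_mu=base_mu,
        signature=tuple(signature),
        effects=effects,
        opposite_pair=(signature[0], signature[1]),
        newick=newick,
    )


def _draw_cohort(
    cfg: SimulationConfig,
    structure: _Structure,
    n_samples: int,
    streams,
    prefix: str,
) -> CohortBundle:
    rng_labels, rng_abund, rng_behav, rng_brain = (np.random.default_rng(s) for s in streams)
    sample_ids = [f"{prefix}{i + 1:03d}" for i in range(n_samples)]

    # latent subpopulations (stratified: both always present)
    n1 = int(round(cfg.mixing_proportion * n_samples))
    n1 = min(max(n1, 1), n_samples - 1)
    labels = np.array([1] * n1 + [2] * (n_samples - n1))
    labels = labels[rng_labels.permutation(n_samples)]
    lab2 = labels == 2

    # abundances: log-normal intensities -> proportions -> multinomial counts
    effect_vec = np.array([structure.effects.get(g, 0.0) for g in structure.genus_ids])
    mu = np.tile(structure.base_mu, (n_samples, 1))
    mu[lab2] += effect_vec
    # evenness_gap widens the per-sample spread of log-abundances in
    # subpopulation 2 (communities more dominated by few genera, hence less
    # even) without planting per-genus differences beyond the signature
    noise = rng_abund.normal(0.0, cfg.log_noise_sd, size=mu.shape)
    noise[lab2] *= 1.0 + cfg.evenness_gap
    log_intensity = mu + noise
    props = np.exp(log_intensity - log_intensity.max(axis=1, keepdims=True))
    props /= props.sum(axis=1, keepdims=True)
    counts = np.vstack(
        [rng_abund.multinomial(cfg.depth, props[i]) for i in range(n_samples)]
    )
    abundance = AbundanceTable(
        pd.DataFrame(counts, index=sample_ids, columns=list(structure.genus_ids)),
        mode="counts",
    )

    # behavior: CARS items on the half-point grid, sensory+social shifted up
    # in subpopulation 2; totals computed after rounding
    items = rng_behav.normal(cfg.cars_item_mean, cfg.cars_item_sd, size=(n_samples, 15))
    shifted = sorted(set(DEFAULT_SENSORY_ITEMS) | set(DEFAULT_SOCIAL_ITEMS))
    items[np.ix_(lab2, [i - 1 for i in shifted])] += cfg.cars_shift
    items = _round_to_grid(items)
    cars_total = items.sum(axis=1)
    ados = np.maximum(
        rng_behav.normal(16.0, 2.5, size=n_samples) + 0.4 * (cars_total - 36), 0.0
    )
    age = rng_behav.uniform(3.0, 12.0, size=n_samples)
    sex = np.where(rng_behav.random(n_samples) < 0.85, "male", "female")
    metadata = [
        CohortMetadata(
            sample_id=sid,
            cars_items=tuple(items[i]),
            cars_total=float(cars_total[i]),
            ados_total=float(round(ados[i], 1)),
            age_years=float(round(age[i], 1)),
            sex=str(sex[i]),
            severity=severity_label(float(cars_total[i])),
        )
        for i, sid in enumerate(sample_ids)
    ]

    # brain volumes: affected regions couple negatively to the sensory score
    sensory = items[:, [i - 1 for i in DEFAULT_SENSORY_ITEMS]].sum(axis=1)
    baselines = np.linspace(5000.0, 12000.0, num=len(BRAIN_REGIONS))
    volumes = np.tile(baselines, (n_samples, 1)) + rng_brain.normal(
        0.0, cfg.brain_noise_sd, size=(n_samples, len(BRAIN_REGIONS))
    )
    volumes[:, :N_AFFECTED_REGIONS] += cfg.brain_slope * (sensory[:, None] - sensory.mean())
    volumes = np.maximum(volumes, 1.0)
    brain = BrainVolumeTable(
        pd.DataFrame(volumes, index=sample_ids, columns=list(BRAIN_REGIONS))
    )

    tree = skbio.TreeNode.read([structure.newick])
    for node in tree.traverse():
        if node.length is None:
            node.length = 0.0

    truth = SyntheticTruth(
        latent_labels=pd.Series(labels, index=sample_ids, name="latent_label"),
        planted_signature=structure.signature,
        opposite_pair=structure.opposite_pair,
        genus_effects=dict(structure.effects),
        affected_regions=BRAIN_REGIONS[:N_AFFECTED_REGIONS],
        brain_slope=cfg.brain_slope,
    )
    return CohortBundle(abundance, metadata, brain, tree, truth)


def _streams(seed: int):
    # fixed spawn layout: structure, tree, discovery x4, test x4
    children = np.random.SeedSequence(seed).spawn(10)
    return children[0], children[1], children[2:6], children[6:10]


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """Draw one fully reproducible synthetic discovery cohort with ground truth."""
    s_struct, s_tree, s_disc, _ = _streams(config.seed)
    structure = _draw_structure(
        config, np.random.default_rng(s_struct), np.random.default_rng(s_tree)
    )
    return _draw_cohort(config, structure, config.n_samples, s_disc, prefix="S")


def simulate_cohort_pair(
    config: SimulationConfig, n_test: int = 50
) -> tuple[CohortBundle, CohortBundle]:
    """Draw a discovery cohort plus a held-out test cohort from the same truth.

    Both cohorts share the planted structure (baseline composition, signature,
    effects, tree) but have independent samples; the discovery cohort is
    bit-identical to :func:`simulate_cohort` at the same config.
    """
    s_struct, s_tree, s_disc, s_test = _streams(config.seed)
    structure = _draw_structure(
        config, np.random.default_rng(s_struct), np.random.default_rng(s_tree)
    )
    discovery = _draw_cohort(config, structure, config.n_samples, s_disc, prefix="S")
    test = _draw_cohort(config, structure, n_test, s_test, prefix="T")
    return discovery, test


def null_cohort(config: SimulationConfig) -> CohortBundle:
    """Cohort with every effect parameter forced to zero (type-I-error suites)."""
    return simulate_cohort(
        replace(config, log_effect=0.0, evenness_gap=0.0, cars_shift=0.0, brain_slope=0.0)
    )
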