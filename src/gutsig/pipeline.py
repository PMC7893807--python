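"""End-to-end orchestration: score -> discover -> subtype -> classify -> stats.

A single :class:`RunConfig` (loadable from YAML) drives a reproducible run.
One global seed fans out to stage-specific substreams; artifacts contain no
timestamps, so two runs with the same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cars_scoring, diversity, io_core, signature, stats, subtyping
from .io_core import AbundanceTable, ValidationError

__all__ = ["RunConfig", "run_discovery", "run_classify", "save_knn_model", "load_knn_model"]

logger = logging.getLogger("gutsig")

BEHAVIOR_COLUMNS = (
    "cars_total",
    "social_impairment",
    "negative_emotionality",
    "distorted_sensory_response",
)

MODEL_FORMAT_VERSION = 1
MAX_MISSING_SIGNATURE_FRACTION = 0.5


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run. ``seed`` is mandatory."""

    abundance: str
    metadata: str | None = None
    tree: str | None = None
    brain: str | None = None
    model: str | None = None  # run_classify input
    out_dir: str = "gutsig_out"
    seed: int = 0
    pool: int = signature.DEFAULT_POOL_SIZE
    target_size: int = signature.DEFAULT_TARGET_SIZE
    k: int = 3
    distance: str = "bray_curtis"
    n_permutations: int = stats.DEFAULT_PERMUTATIONS
    alpha: float = 0.05
    with_faith_pd: bool = True
    with_brain: bool = True
    transposed_abundance: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValidationError("config must set a seed")
        return cls(**raw)

    def validate_paths(self, need_metadata: bool = True, need_model: bool = False) -> None:
        required = {"abundance": self.abundance}
        if need_metadata:
            required["metadata"] = self.metadata
        if need_model:
            required["model"] = self.model
        for name, p in required.items():
            if p is None:
                raise ValidationError(f"config missing required path: {name}")
            if not Path(p).exists():
                raise ValidationError(f"{name} path does not exist: {p}")
        for name in ("tree", "brain"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{name} path does not exist: {p}")

    def digest(self) -> str:
        fields = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        payload = json.dumps(fields, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _behavior_table(scores: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    behav = scores[list(BEHAVIOR_COLUMNS)].copy()
    if "ados_total" in meta.columns:
        behav["ados_total"] = meta["ados_total"]
    return behav


def save_knn_model(model: subtyping.KnnModel, path) -> None:
    """Serialize a kNN model to a versioned JSON text file."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "gutsig_version": __version__,
        "k": model.k,
        "distance": model.distance,
        "signature": list(model.signature),
        "sample_ids": list(model.training.index),
        "training": model.training.to_numpy(float).tolist(),
        "labels": list(model.labels),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_knn_model(path) -> subtyping.KnnModel:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValidationError(f"unsupported model format: {payload.get('format_version')}")
    training = pd.DataFrame(
        payload["training"], index=payload["sample_ids"], columns=payload["signature"]
    )
    return subtyping.KnnModel(
        training=training,
        labels=pd.Series(payload["labels"], index=payload["sample_ids"]),
        k=int(payload["k"]),
        distance=payload["distance"],
        signature=tuple(payload["signature"]),
    )


def _load_inputs(config: RunConfig):
    table = io_core.read_abundance_table(
        config.abundance, transposed=config.transposed_abundance
    )
    records = io_core.read_metadata(config.metadata)
    meta = io_core.metadata_to_frame(records)
    missing = [s for s in table.sample_ids if s not in meta.index]
    if missing:
        raise ValidationError(f"metadata missing samples: {missing[:5]}")
    tree = io_core.read_newick(config.tree) if config.tree else None
    brain = io_core.read_brain_volumes(config.brain) if (config.brain and config.with_brain) else None
    return table, records, meta, tree, brain


def run_discovery(config: RunConfig) -> dict:
    """Full discovery pipeline; writes artifacts under ``config.out_dir``.

    Stages: CARS scoring -> Spearman screen + greedy signature search ->
    two-cluster subtyping -> kNN fit + LOOCV -> diversity/ordination ->
    permutation statistics. Returns the consolidated report (also written
    as JSON + flat TSV).
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load_inputs"
    try:
        table, records, meta, tree, brain = _load_inputs(config)
        logger.info("loaded %d samples x %d genera", *table.shape)

        stage = "cars_scoring"
        scores = cars_scoring.score_cohort(records)
        scores.to_csv(out / "cars_domain_scores.tsv", sep="\t")

        stage = "signature"
        behav = _behavior_table(scores, meta)
        ss = np.random.SeedSequence(config.seed)
        sub_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
        sig = signature.greedy_search(
            table,
            behav,
            candidate_pool_size=config.pool,
            target_size=config.target_size,
            seed=sub_seeds[0],
            n_permutations=config.n_permutations,
        )
        sig.to_frame().to_csv(out / "signature.tsv", sep="\t", index=False)
        logger.info("signature: %d genera", len(sig.selected_genera))

        stage = "subtyping"
        assignment = subtyping.cluster_subtypes(
            table, list(sig.selected_genera), scores["cars_total"]
        )
        assignment.labels.rename_axis("sample_id").to_frame().to_csv(
            out / "subtype_assignment.tsv", sep="\t"
        )
        model = subtyping.fit_knn(
            table, list(sig.selected_genera), assignment.labels,
            k=config.k, distance=config.distance,
        )
        save_knn_model(model, out / "knn_model.json")
        loocv = {
            k: subtyping.loocv_accuracy(
                table, list(sig.selected_genera), assignment.labels,
                k=k, distance=config.distance,
            )
            for k in (1, 3, 5, 7)
            if k < table.shape[0]
        }

        stage = "diversity"
        alpha = diversity.alpha_diversity(table, tree=tree if config.with_faith_pd else None)
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
        sig_table = (
            table.to_relative() if table.mode == "counts" else table
        ).subset_genera(list(sig.selected_genera), renormalize=True)
        dm = diversity.bray_curtis(sig_table)
        io_core.write_distance_matrix(dm, out / "bray_curtis_signature.tsv")
        ordination = diversity.pcoa(dm, n_axes=2)
        ordination.coordinates.to_csv(out / "pcoa.tsv", sep="\t")
        alpha_tests = {
            metric: stats.kruskal_wallis_perm(
                alpha[metric].dropna().to_numpy(float),
                assignment.labels.reindex(alpha[metric].dropna().index).to_numpy(),
                n_permutations=config.n_permutations,
                seed=sub_seeds[1],
            ).to_dict()
            for metric in alpha.columns
            if alpha[metric].notna().sum() >= 4
        }

        stage = "stats"
        profile = stats.group_profile(
            scores,
            assignment.labels,
            ados_total=meta.get("ados_total"),
            brain=brain.data if brain is not None else None,
            n_permutations=config.n_permutations,
            seed=sub_seeds[2],
            alpha=config.alpha,
        )

        report = {
            "manifest": {
                "gutsig_version": __version__,
                "config_digest": config.digest(),
                "seed": config.seed,
                "n_samples": table.shape[0],
                "n_genera": table.shape[1],
            },
            "signature": {
                "selected_genera": list(sig.selected_genera),
                "objective_trace": list(sig.objective_trace),
                "truncated": sig.truncated,
                "final_test": sig.final_test,
            },
            "subtyping": {
                "cluster_sizes": {k: int(v) for k, v in assignment.cluster_sizes.items()},
                "labelling_rule": assignment.labelling_rule,
                "loocv_accuracy": loocv,
                "k": config.k,
                "distance": config.distance,
            },
            "diversity": {
                "alpha_tests_by_subtype": alpha_tests,
                "pcoa_proportion_explained": list(ordination.proportion_explained),
            },
            "group_profile": profile,
        }
        io_core.write_results(report, out / "report.json", out / "statistics.tsv")
        return report
    except Exception:
        logger.error("pipeline failed in stage %r", stage)
        (out / "FAILED_STAGE.txt").write_text(stage + "\n", encoding="utf-8")
        raise


def run_classify(config: RunConfig) -> dict:
    """Classify a new cohort with a serialized kNN model.

    If metadata is supplied, the behavioral group profile is re-run on the
    new cohort. Signature genera absent from the new table are imputed as
    zero with a warning; more than half absent is an error.
    """
    config.validate_paths(need_metadata=False, need_model=True)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = load_knn_model(config.model)
    table = io_core.read_abundance_table(
        config.abundance, transposed=config.transposed_abundance
    )
    absent = [g for g in model.signature if g not in table.data.columns]
    if len(absent) > MAX_MISSING_SIGNATURE_FRACTION * len(model.signature):
        raise ValidationError(
            f"{len(absent)}/{len(model.signature)} signature genera absent from input"
        )
    labels = subtyping.predict(model, table)
    labels.rename_axis("sample_id").to_frame().to_csv(
        out / "subtype_assignment.tsv", sep="\t"
    )
    report: dict = {
        "manifest": {
            "gutsig_version": __version__,
            "config_digest": config.digest(),
            "seed": config.seed,
            "n_samples": int(table.shape[0]),
        },
        "subtyping": {
            "cluster_sizes": {k: int(v) for k, v in labels.value_counts().items()},
            "missing_genera": absent,
        },
    }
    if config.metadata:
        records = io_core.read_metadata(config.metadata)
        meta = io_core.metadata_to_frame(records)
        scores = cars_scoring.score_cohort(records)
        brain = io_core.read_brain_volumes(config.brain) if (config.brain and config.with_brain) else None
        report["group_profile"] = stats.group_profile(
            scores,
            labels,
            ados_total=meta.get("ados_total"),
            brain=brain.data if brain is not None else None,
            n_permutations=config.n_permutations,
            seed=int(np.random.SeedSequence(config.seed).generate_state(1)[0] % (2**31)),
            alpha=config.alpha,
        )
    io_core.write_results(report, out / "report.json", out / "statistics.tsv")
    return report
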