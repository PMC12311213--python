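"""End-to-end experiment orchestration.

Stages: synthesize (or load) the three cohorts -> fit the feature selector
on the training cohort only -> per similarity threshold, build one graph
per cohort, train a GCN on the training graph, and score all cohorts ->
evaluate each (cohort, threshold) pair -> compare models (Pearson
agreement, repeated-measures ANOVA, pairwise DeLong, decision curves).

Validation-cohort labels are touched only inside the evaluation stage;
selection and training see the training cohort alone. A single global seed
fans out to per-stage seeds through a stable splitting rule, so any stage
can be re-run in isolation with identical randomness, and a manifest of
SHA-256 digests makes rerun determinism checkable byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from ._utils import stage_seed
from .evaluation import (
    agreement_matrix,
    decision_curve,
    delong_test,
    diagnostic_report,
    rm_anova,
)
from .gcn import GCNConfig, predict, train
from .graph import NodeTable, assemble_graph, export_components
from .io import write_json
from .selection import FeatureSelector, SelectionConfig
from .synthetic import SyntheticCohort, make_study_cohorts

logger = logging.getLogger(__name__)

COHORT_NAMES = ("train", "val1", "val2")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class ExperimentConfig:
    thresholds: tuple[float, ...] = (0.60, 0.70, 0.80, 0.95)
    seed: int = 0
    cutoff: float = 0.5
    n_boot: int = 2000
    n_features: int | str = "auto"
    class_separation: float = 2.0
    n_total_features: int = 2048
    selection: SelectionConfig | None = None
    gcn: GCNConfig | None = None

    def __post_init__(self) -> None:
        if not self.thresholds:
            raise ValueError("at least one threshold required")
        for t in self.thresholds:
            if not -1.0 < t <= 1.0:
                raise ValueError(f"threshold {t} outside (-1, 1]")

    def config_hash(self) -> str:
        payload = json.dumps(_as_jsonable(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _as_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    digests: dict[str, str] = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def to_json(self, path: str | Path) -> Path:
        return write_json(path, dataclasses.asdict(self))


def run_experiment(
    config: ExperimentConfig,
    out_dir: str | Path,
    cohorts: tuple[SyntheticCohort, SyntheticCohort, SyntheticCohort] | None = None,
) -> RunManifest:
    """Run the whole study; writes an artifact tree under ``out_dir``.

    ``cohorts`` may be supplied (e.g. loaded from CSVs); otherwise the
    synthetic three-hospital layout is generated from the config seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.config_hash(), seed=config.seed, version=__version__, started=time.time()
    )
    artifacts: list[Path] = []

    # --- stage: synthesize -------------------------------------------------
    try:
        if cohorts is None:
            cohorts = make_study_cohorts(
                seed=stage_seed(config.seed, "simulate"),
                n_features=config.n_total_features,
                class_separation=config.class_separation,
            )
        train_c, val1_c, val2_c = cohorts
        logger.info("stage=simulate sizes=%s", [c.n_patients for c in cohorts])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("simulate", str(exc)) from exc

    # --- stage: select (training cohort only; no validation labels) -------
    try:
        sel_cfg = config.selection or SelectionConfig(
            seed=stage_seed(config.seed, "select"), n_features=config.n_features
        )
        selector = FeatureSelector(sel_cfg).fit(train_c.features, train_c.labels)
        sel_path = out_dir / "selection.json"
        selector.result_.to_json(sel_path)
        artifacts.append(sel_path)
        logger.info(
            "stage=select kept_after_spearman=%d selected=%d",
            selector.result_.kept_after_spearman.size,
            selector.result_.selected.size,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("select", str(exc)) from exc

    X_by_cohort = {
        name: selector.transform(c.features)
        for name, c in zip(COHORT_NAMES, (train_c, val1_c, val2_c))
    }
    ids_by_cohort = {name: c.ids for name, c in zip(COHORT_NAMES, cohorts)}
    y_by_cohort = {name: c.labels for name, c in zip(COHORT_NAMES, cohorts)}

    # --- stages: graph + train + evaluate per threshold --------------------
    prob: dict[str, dict[str, np.ndarray]] = {name: {} for name in COHORT_NAMES}
    edge_counts: dict[str, dict[str, int]] = {name: {} for name in COHORT_NAMES}
    for t in config.thresholds:
        tname = f"threshold_{int(round(t * 100)):02d}"
        tdir = out_dir / tname
        tdir.mkdir(exist_ok=True)
        graphs = {}
        try:
            for name in COHORT_NAMES:
                table = NodeTable(
                    ids=ids_by_cohort[name],
                    X=X_by_cohort[name],
                    # graph construction uses features only; labels ride along
                    # for training (train cohort) and evaluation output order
                    y=y_by_cohort[name] if name == "train" else np.zeros(len(ids_by_cohort[name]), dtype=int),
                )
                graphs[name] = assemble_graph(table, t)
                summary = export_components(graphs[name], tdir / f"graph_{name}")
                edge_counts[name][tname] = summary["n_edges"]
                artifacts.append(tdir / f"graph_{name}" / "summary.json")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("graph", f"{tname}: {exc}") from exc

        try:
            gcn_cfg = config.gcn or GCNConfig(seed=stage_seed(config.seed, f"train-{tname}"))
            params, history = train(graphs["train"], config=gcn_cfg)
            ck_path = tdir / "checkpoint.json"
            params.to_json(ck_path, gcn_cfg)
            hist_path = tdir / "history.csv"
            history.to_csv(hist_path)
            artifacts += [ck_path, hist_path]
            logger.info("stage=train %s epochs=%d best=%d", tname, history.epoch_stopped, history.best_epoch)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("train", f"{tname}: {exc}") from exc

        try:
            for name in COHORT_NAMES:
                prob[name][tname] = predict(graphs[name], params)
                prob_path = tdir / f"prob_{name}.csv"
                np.savetxt(prob_path, prob[name][tname], header="prob_positive", comments="")
                artifacts.append(prob_path)
                report = diagnostic_report(
                    prob[name][tname],
                    y_by_cohort[name],
                    cutoff=config.cutoff,
                    n_boot=config.n_boot,
                    seed=stage_seed(config.seed, f"boot-{tname}-{name}"),
                )
                rp = write_json(tdir / f"report_{name}.json", report.to_dict())
                artifacts.append(rp)
                from .evaluation import roc_auc as _roc

                curve, _ = _roc(prob[name][tname], y_by_cohort[name])
                roc_path = tdir / f"roc_{name}.csv"
                curve.to_csv(roc_path, index=False)
                artifacts.append(roc_path)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("evaluate", f"{tname}: {exc}") from exc

    # --- stage: compare across thresholds ----------------------------------
    try:
        comparison: dict[str, dict] = {}
        for name in COHORT_NAMES:
            models = prob[name]
            r = agreement_matrix(models)
            f, dfn, dfd, p = rm_anova(models)
            delong: dict[str, dict[str, float]] = {}
            for a in models:
                delong[a] = {}
                for b in models:
                    if a == b:
                        delong[a][b] = float("nan")
                    else:
                        delong[a][b] = delong_test(models[a], models[b], y_by_cohort[name])[3]
            dca = {
                m: decision_curve(models[m], y_by_cohort[name]).to_dict(orient="list")
                for m in models
            }
            comparison[name] = {
                "pearson_r": r.to_dict(),
                "rm_anova": {"F": f, "df_num": dfn, "df_den": dfd, "p": p},
                "delong_p": delong,
            }
            r.to_csv(out_dir / f"pearson_{name}.csv")
            artifacts.append(out_dir / f"pearson_{name}.csv")
            dca_path = write_json(out_dir / f"dca_{name}.json", dca)
            artifacts.append(dca_path)
        comp_path = write_json(out_dir / "comparison.json", _as_jsonable(comparison))
        artifacts.append(comp_path)
        ec_path = write_json(out_dir / "edge_counts.json", edge_counts)
        artifacts.append(ec_path)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("compare", str(exc)) from exc

    manifest.finished = time.time()
    manifest.digests = {str(p.relative_to(out_dir)): _digest(p) for p in artifacts}
    manifest.to_json(out_dir / "manifest.json")
    return manifest


def guard_no_validation_augmentation(cohort_role: str) -> None:
    """Augmentation is a training-cohort operation; validation images must
    pass through the deterministic chain untouched."""
    if cohort_role != "train":
        raise PipelineError(
            "preprocess", f"augmentation requested for cohort role {cohort_role!r}; "
            "only the training cohort may be augmented"
        )
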