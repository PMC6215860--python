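"""End-to-end pipeline: strict configuration and the two-stage run.

The run mirrors the two-step detection scheme: T-bar point prediction from
the raw volume, then segmentation-aware partner prediction per T-bar,
followed by graph construction and the full set of connectome metrics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import connectome_eval as ce
from .core_io import (
    LabelVolume,
    PartnerEntry,
    SynapseRecord,
    Volume,
    build_graph,
    write_graph_csv,
    write_synapses,
)
from .errors import ConfigError
from .psd_predict import MlpModel, PartnerConfig, assemble_training_pairs, predict_partners, train_mlp
from .synthetic_data import PhantomConfig
from .tbar_detect import (
    DetectorConfig,
    VoxelClassifier,
    VoxelLabelConfig,
    extract_points,
    make_voxel_labels,
    predict_probability,
    select_threshold_for_recall,
    shift_to_brightest,
    train_voxel_classifier,
)

logger = logging.getLogger(__name__)


def json_default(obj):
    """Coerce numpy scalars when serializing reports."""
    if isinstance(obj, np.generic):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


@dataclass(frozen=True)
class EvalConfig:
    """Evaluation thresholds for the report."""

    t: int = 1
    t1: int = 10
    t2: int = 5
    target_recall: float | None = None


_SECTIONS = {
    "voxel_labels": VoxelLabelConfig,
    "detector": DetectorConfig,
    "partner": PartnerConfig,
    "match": ce.MatchConfig,
    "phantom": PhantomConfig,
    "eval": EvalConfig,
}


@dataclass(frozen=True)
class PipelineConfig:
    """Strict nested configuration; unknown keys are rejected."""

    voxel_labels: VoxelLabelConfig = VoxelLabelConfig()
    detector: DetectorConfig = DetectorConfig()
    partner: PartnerConfig = PartnerConfig()
    match: ce.MatchConfig = ce.MatchConfig()
    phantom: PhantomConfig = PhantomConfig()
    eval: EvalConfig = EvalConfig()
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        if not isinstance(doc, dict):
            raise ConfigError("config document must be a mapping")
        kwargs: dict = {}
        for key, value in doc.items():
            if key in ("seed", "log_level"):
                kwargs[key] = value
                continue
            if key not in _SECTIONS:
                raise ConfigError(f"unknown config section {key!r}")
            section_cls = _SECTIONS[key]
            known = {f.name for f in dataclasses.fields(section_cls)}
            unknown = set(value) - known
            if unknown:
                raise ConfigError(f"unknown keys in section {key!r}: {sorted(unknown)}")
            coerced = {
                k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
            }
            kwargs[key] = section_cls(**coerced)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            doc = yaml.safe_load(f) or {}
        return cls.from_dict(doc)


@dataclass
class PipelineResult:
    records: list[SynapseRecord]
    graph: "ce.ConnectomeGraph"
    report: dict
    tbar_threshold: float


def train_tbar_model(
    volumes: list[Volume],
    records_list: list[list[SynapseRecord]],
    config: PipelineConfig,
) -> VoxelClassifier:
    """Fit the T-bar voxel classifier on annotated volumes."""
    dense = [
        make_voxel_labels([r.tbar for r in recs], vol.shape, config.voxel_labels)
        for vol, recs in zip(volumes, records_list)
    ]
    return train_voxel_classifier(volumes, dense, seed=config.seed)


def train_partner_model(
    training_sets: list[tuple[Volume, LabelVolume, list[SynapseRecord]]],
    config: PipelineConfig,
) -> MlpModel:
    """Fit the partner MLP on pairs pooled over annotated volumes.

    Train it on the same kind of segmentation it will be applied to (e.g. an
    automated one with boundary noise): the interface features depend on the
    segmentation's error behavior, so the classifier must see it in training.
    """
    Xs, ys = [], []
    for volume, labels, records in training_sets:
        X, y, diag = assemble_training_pairs(
            records, labels, volume, config.partner, config.detector.shift_radius
        )
        logger.info("partner training pairs: %s", diag)
        Xs.append(X)
        ys.append(y)
    return train_mlp(np.concatenate(Xs), np.concatenate(ys), seed=config.seed)


def train_models(
    volume: Volume,
    labels: LabelVolume,
    gt_records: list[SynapseRecord],
    config: PipelineConfig,
) -> tuple[VoxelClassifier, MlpModel]:
    """Fit both stages on a single ground-truth-annotated volume."""
    clf = train_tbar_model([volume], [gt_records], config)
    mlp = train_partner_model([(volume, labels, gt_records)], config)
    return clf, mlp


def run_pipeline(
    volume: Volume,
    labels: LabelVolume,
    config: PipelineConfig,
    tbar_model: VoxelClassifier,
    psd_model: MlpModel,
    gt_records: list[SynapseRecord] | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Predict T-bars, then partners; build the graph; evaluate if GT given.

    Stages: probability map -> point extraction -> (optional) threshold
    selection for a target T-bar recall -> brightest-voxel shift -> partner
    prediction per T-bar -> graph construction -> evaluation report.  All
    randomness is in training; this function is deterministic.
    """
    pmap = predict_probability(volume, tbar_model, config.detector.patch_shape)
    points = extract_points(pmap, config.detector)
    logger.info("extracted %d T-bar candidates", len(points))

    threshold = config.detector.confidence_threshold
    if config.eval.target_recall is not None:
        if gt_records is None:
            raise ConfigError("target_recall needs ground-truth records")
        curve = ce.tbar_pr_curve(
            points, [r.tbar for r in gt_records], config.match, labels, volume
        )
        threshold = select_threshold_for_recall(curve, config.eval.target_recall)
        points = [p for p in points if p.confidence >= threshold]
        logger.info(
            "threshold %.4f selected for T-bar recall >= %.2f (%d points kept)",
            threshold,
            config.eval.target_recall,
            len(points),
        )

    shifted = shift_to_brightest(points, volume, config.detector.shift_radius)
    records = []
    for pt in shifted:
        rec = predict_partners(pt, labels, volume, psd_model, config.partner)
        # pair confidence combines both stages conservatively, so a sweep over
        # pair confidences can prune weak T-bars as well as weak partners
        partners = tuple(
            PartnerEntry(q.body_id, min(pt.confidence, q.confidence), q.point)
            for q in rec.partners
        )
        records.append(SynapseRecord(pt, partners, rec.host_body))
    n_partners = sum(len(r.partners) for r in records)
    logger.info("predicted %d synapses with %d partner entries", len(records), n_partners)

    result_graph = build_graph(records, labels).graph

    report: dict = {
        "n_tbars_predicted": len(records),
        "n_partner_entries": n_partners,
        "tbar_threshold": threshold,
    }
    if gt_records is not None:
        gt_graph = build_graph(gt_records, labels).graph
        syn_curve = ce.synapse_level_pr(records, gt_records, config.match, labels, volume)
        wp, wr = ce.graph_weighted_pr(gt_graph, result_graph)
        up, ur = ce.graph_unweighted_pr(gt_graph, result_graph, config.eval.t)
        thr = ce.AsymThresholds(config.eval.t1, config.eval.t2)
        ap, ar = ce.asymmetric_pr(gt_graph, result_graph, thr)
        am = ce.connections_added_missed(gt_graph, result_graph, thr)
        report.update(
            {
                "synapse_level_break_even": syn_curve.break_even(),
                "weighted_precision": wp,
                "weighted_recall": wr,
                "unweighted_precision": up,
                "unweighted_recall": ur,
                "unweighted_t": config.eval.t,
                "asymmetric_precision": ap,
                "asymmetric_recall": ar,
                "asymmetric_t1": thr.t1,
                "asymmetric_t2": thr.t2,
                "n_connections_missed": len(am.missed_edges),
                "n_connections_added": len(am.added_edges),
                "normalized_missed": am.normalized_missed,
                "normalized_added": am.normalized_added,
            }
        )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_synapses(records, out / "predicted_synapses.json")
        write_graph_csv(result_graph, out / "predicted_graph.csv")
        with open(out / "report.json", "w") as f:
            json.dump(report, f, indent=1, sort_keys=True, default=json_default)
            f.write("\n")
    return PipelineResult(records, result_graph, report, threshold)
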