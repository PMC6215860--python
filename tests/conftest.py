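"""Shared fixtures: phantoms and a fully trained end-to-end study.

The heavy fixtures are session-scoped so that training and inference run
once and are reused by the end-to-end, partner-recovery, and baseline tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pytest

from polysyn.core_io import PartnerEntry, SynapseRecord
from polysyn.pipeline import PipelineConfig, train_partner_model, train_tbar_model
from polysyn.psd_predict import MlpModel, predict_partners
from polysyn.synthetic_data import Phantom, PhantomConfig, generate_phantom
from polysyn.tbar_detect import (
    VoxelClassifier,
    extract_points,
    predict_probability,
    shift_to_brightest,
)

TRAIN_SEEDS = (11, 13, 14, 15)
EVAL_SEED = 12


@pytest.fixture(scope="session")
def small_phantom() -> Phantom:
    """A cheap 64-cube phantom for unit tests that need realistic structure."""
    cfg = PhantomConfig(shape=(64, 64, 64), n_segments=8, n_synapses=4, seed=7)
    return generate_phantom(cfg)


@dataclass
class Study:
    """Trained models plus end-to-end predictions on a held-out phantom."""

    config: PipelineConfig
    train_phantoms: list[Phantom]
    eval_phantom: Phantom
    tbar_model: VoxelClassifier
    mlp_clean: MlpModel
    mlp_degraded: MlpModel
    raw_points: list  # detector output, pre-shift
    shifted_points: list
    records_clean: list[SynapseRecord]  # all candidates scored (no decision cut)
    records_degraded: list[SynapseRecord]


def _predict_records(points, raw_points, labels, volume, mlp, partner_cfg):
    """Partner prediction keeping every scored candidate; pair confidence is
    the min of the T-bar and partner confidences."""
    cfg0 = dataclasses.replace(partner_cfg, decision_threshold=0.0)
    records = []
    for rp, pt in zip(raw_points, points):
        rec = predict_partners(pt, labels, volume, mlp, cfg0)
        partners = tuple(
            PartnerEntry(q.body_id, min(rp.confidence, q.confidence), q.point)
            for q in rec.partners
        )
        records.append(SynapseRecord(pt, partners, rec.host_body))
    return records


@pytest.fixture(scope="session")
def study() -> Study:
    """Train on four phantoms, predict on a held-out fifth.

    The T-bar voxel classifier trains on one annotated volume; the partner
    MLP pools pairs over all four, once against the clean segmentation and
    once against the degraded one (each model is applied to the kind of
    segmentation it was trained with).
    """
    config = PipelineConfig()
    train_phantoms = [generate_phantom(PhantomConfig(seed=s)) for s in TRAIN_SEEDS]
    eval_phantom = generate_phantom(PhantomConfig(seed=EVAL_SEED))

    tbar_model = train_tbar_model(
        [train_phantoms[0].volume], [train_phantoms[0].gt_records], config
    )
    mlp_clean = train_partner_model(
        [(ph.volume, ph.clean_labels, ph.gt_records) for ph in train_phantoms], config
    )
    mlp_degraded = train_partner_model(
        [(ph.volume, ph.degraded_labels, ph.gt_records) for ph in train_phantoms], config
    )

    pmap = predict_probability(eval_phantom.volume, tbar_model, config.detector.patch_shape)
    raw_points = extract_points(pmap, config.detector)
    shifted = shift_to_brightest(raw_points, eval_phantom.volume, config.detector.shift_radius)
    records_clean = _predict_records(
        shifted, raw_points, eval_phantom.clean_labels, eval_phantom.volume,
        mlp_clean, config.partner,
    )
    records_degraded = _predict_records(
        shifted, raw_points, eval_phantom.degraded_labels, eval_phantom.volume,
        mlp_degraded, config.partner,
    )
    return Study(
        config, train_phantoms, eval_phantom, tbar_model, mlp_clean, mlp_degraded,
        raw_points, shifted, records_clean, records_degraded,
    )
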