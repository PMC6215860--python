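"""Segmentation-aware postsynaptic-partner (PSD) prediction.

Given a T-bar location and a segmentation, partner prediction proceeds as:
mask dark voxels out of the segmentation (dark intensities — membranes,
T-bars — are where segmentations err), gather candidate bodies intersecting a
sphere around the T-bar (excluding the host body: no autapses), estimate the
host/candidate contact interface by dilating both bodies by varying amounts
and intersecting, pool image statistics over each interface into a
135-dimensional feature vector, and score each candidate with a
single-hidden-layer MLP (50 units, cross-entropy).  Candidates scoring at or
above the decision threshold become partner entries, at most one per body.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .core_io import (
    LabelVolume,
    PartnerEntry,
    PointAnnotation,
    SynapseRecord,
    Volume,
    check_inside,
)
from .errors import ConfigError, DegenerateTrainingError, ShapeError
from .geometry import CROSS_STRUCT, ball_offsets, clip_ball_voxels
from .tbar_detect import shift_to_brightest

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PartnerConfig:
    """Parameters of the partner-prediction stage.

    candidate_radius : sphere radius (voxels) for gathering candidate bodies
        (~150 nm at 10 nm/voxel by default).
    dilation_amounts : strictly increasing dilation iteration counts used for
        interface estimation; one feature block per amount.
    dark_threshold : intensity below which the segmentation is ignored.
    decision_threshold : MLP score at or above which a candidate becomes a
        partner.
    """

    candidate_radius: float = 15.0
    dilation_amounts: tuple[int, ...] = (1, 2, 3, 4, 5)
    dark_threshold: int = 60
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.candidate_radius < 0:
            raise ConfigError("candidate_radius must be >= 0")
        da = tuple(self.dilation_amounts)
        if not da or any(d <= 0 for d in da) or any(nxt <= prev for prev, nxt in zip(da, da[1:])):
            raise ConfigError("dilation_amounts must be positive and strictly increasing")
        object.__setattr__(self, "dilation_amounts", da)
        if not (0.0 <= self.decision_threshold <= 1.0):
            raise ConfigError("decision_threshold must lie in [0, 1]")


@dataclass(frozen=True)
class CandidateSet:
    """Bodies that may be postsynaptic to a T-bar."""

    tbar: PointAnnotation
    host_body: int  # 0 when the host could not be resolved
    candidate_bodies: frozenset[int]

    @property
    def host_resolved(self) -> bool:
        return self.host_body != 0


def mask_dark_voxels(labels: LabelVolume, volume: Volume, dark_threshold: int) -> LabelVolume:
    """Zero out segment IDs at voxels darker than ``dark_threshold``.

    Dark (electron-dense) voxels — membranes and T-bar structures — are where
    automated segmentations most often misassign labels, so the partner
    features ignore the segmentation there.
    """
    if labels.shape != volume.shape:
        raise ShapeError(f"labels shape {labels.shape} != volume shape {volume.shape}")
    out = labels.data.copy()
    out[volume.data < dark_threshold] = 0
    return LabelVolume(out)


def resolve_host_body(tbar: PointAnnotation, labels: LabelVolume) -> int:
    """Body containing the T-bar; majority non-zero label in the radius-1 ball
    when the T-bar voxel itself is unassigned (0 if that fails too)."""
    check_inside(tbar, labels.shape)
    host = int(labels.data[tbar.z, tbar.y, tbar.x])
    if host != 0:
        return host
    vox = clip_ball_voxels(tbar.zyx, 1.0, labels.shape)
    vals = labels.data[vox[:, 0], vox[:, 1], vox[:, 2]]
    vals = vals[vals != 0]
    if len(vals) == 0:
        return 0
    ids, counts = np.unique(vals, return_counts=True)
    return int(ids[np.argmax(counts)])  # np.unique sorts: smallest ID wins ties


def find_candidates(
    tbar: PointAnnotation, labels: LabelVolume, candidate_radius: float
) -> CandidateSet:
    """Bodies intersecting the closed ball around the T-bar, minus host and 0.

    If the host cannot be resolved (unassigned voxel with no labeled
    neighbors), the candidate set is empty and flagged via ``host_body == 0``.
    """
    host = resolve_host_body(tbar, labels)
    if host == 0:
        return CandidateSet(tbar, 0, frozenset())
    vox = clip_ball_voxels(tbar.zyx, candidate_radius, labels.shape)
    vals = labels.data[vox[:, 0], vox[:, 1], vox[:, 2]]
    cands = frozenset(int(v) for v in np.unique(vals)) - {0, host}
    return CandidateSet(tbar, host, cands)


# ---------------------------------------------------------------------------
# interface estimation and features
# ---------------------------------------------------------------------------


@dataclass
class InterfaceMasks:
    """Estimated host/candidate contact interfaces, one mask per dilation amount.

    Masks are boolean arrays over a cubic region of interest whose lower
    corner (in volume coordinates) is ``origin``; they are nested:
    the mask for a smaller dilation is a subset of that for a larger one.
    """

    masks: list[np.ndarray]
    origin: tuple[int, int, int]
    dilation_amounts: tuple[int, ...]


def estimate_interface(
    host_body: int,
    cand_body: int,
    labels: LabelVolume,
    tbar: PointAnnotation,
    dilation_amounts: Sequence[int] = (1, 2, 3, 4, 5),
    roi_radius: int | None = None,
) -> InterfaceMasks:
    """Interface masks: dilate both bodies by d (6-connected) and intersect.

    Computed inside a cube of half-width ``roi_radius`` around the T-bar
    (default: the default candidate radius plus the largest dilation).  A
    candidate absent from the ROI yields empty masks, which is valid.
    """
    check_inside(tbar, labels.shape)
    da = tuple(dilation_amounts)
    if roi_radius is None:
        roi_radius = int(PartnerConfig().candidate_radius) + max(da)
    lo = np.maximum(np.asarray(tbar.zyx) - roi_radius, 0)
    hi = np.minimum(np.asarray(tbar.zyx) + roi_radius + 1, np.asarray(labels.shape))
    roi = labels.data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    host_mask = roi == host_body
    cand_mask = roi == cand_body
    masks = []
    for d in da:
        if not host_mask.any() or not cand_mask.any():
            masks.append(np.zeros(roi.shape, dtype=bool))
            continue
        h = ndimage.binary_dilation(host_mask, structure=CROSS_STRUCT, iterations=d)
        c = ndimage.binary_dilation(cand_mask, structure=CROSS_STRUCT, iterations=d)
        masks.append(h & c)
    return InterfaceMasks(masks, (int(lo[0]), int(lo[1]), int(lo[2])), da)


#: The 27 per-interface statistics, in feature order.  The full 135-vector is
#: one block of these per dilation amount, smallest amount first; slot names
#: are ``d{amount}_{stat}``.
STAT_NAMES: tuple[str, ...] = (
    "count",
    "log1p_count",
    "mean_intensity",
    "std_intensity",
    "min_intensity",
    "max_intensity",
    "median_intensity",
    "hist_0_31",
    "hist_32_63",
    "hist_64_95",
    "hist_96_127",
    "hist_128_159",
    "hist_160_191",
    "hist_192_223",
    "hist_224_255",
    "n_below_half_dark",
    "n_below_dark",
    "n_below_1p5_dark",
    "n_below_2_dark",
    "dark_fraction",
    "centroid_to_tbar_distance",
    "bbox_extent_z",
    "bbox_extent_y",
    "bbox_extent_x",
    "fraction_within_candidate_radius",
    "surface_count",
    "surface_to_count_ratio",
)

N_FEATURES = 135


def feature_names(dilation_amounts: Sequence[int] = (1, 2, 3, 4, 5)) -> list[str]:
    return [f"d{d}_{s}" for d in dilation_amounts for s in STAT_NAMES]


def _mask_statistics(
    mask: np.ndarray,
    roi_intensities: np.ndarray,
    origin: np.ndarray,
    tbar_zyx: np.ndarray,
    dark_threshold: int,
    candidate_radius: float,
) -> np.ndarray:
    stats = np.zeros(len(STAT_NAMES), dtype=np.float64)
    coords = np.argwhere(mask)
    n = len(coords)
    if n == 0:
        return stats  # all-zero block; min/max/median conventionally 0
    vals = roi_intensities[mask].astype(np.float64)
    abs_coords = coords + origin
    stats[0] = n
    stats[1] = np.log1p(n)
    stats[2] = vals.mean()
    stats[3] = vals.std()
    stats[4] = vals.min()
    stats[5] = vals.max()
    stats[6] = np.median(vals)
    hist, _ = np.histogram(vals, bins=8, range=(0, 256))
    stats[7:15] = hist
    for i, scale in enumerate((0.5, 1.0, 1.5, 2.0)):
        stats[15 + i] = np.count_nonzero(vals < dark_threshold * scale)
    stats[19] = stats[16] / n
    centroid = abs_coords.mean(axis=0)
    stats[20] = float(np.linalg.norm(centroid - tbar_zyx))
    extents = abs_coords.max(axis=0) - abs_coords.min(axis=0) + 1
    stats[21:24] = extents
    d2 = ((abs_coords - tbar_zyx) ** 2).sum(axis=1)
    stats[24] = np.count_nonzero(d2 <= candidate_radius**2) / n
    eroded = ndimage.binary_erosion(mask, structure=CROSS_STRUCT, border_value=0)
    surface = int(np.count_nonzero(mask & ~eroded))
    stats[25] = surface
    stats[26] = surface / n
    return stats


def extract_features(
    interfaces: InterfaceMasks,
    volume: Volume,
    tbar: PointAnnotation,
    dark_threshold: int = 60,
    candidate_radius: float = 15.0,
) -> np.ndarray:
    """Pool 27 image statistics over each of the 5 interface masks -> 135 values.

    Statistics per mask (see ``STAT_NAMES``): voxel count and log(1+count);
    mean/std/min/max/median intensity; 8 histogram-bin counts (32-wide bins
    over [0, 255]); counts below 4 darkness cutoffs (0.5x, 1x, 1.5x, 2x the
    dark threshold) and the dark fraction; centroid-to-T-bar distance;
    bounding-box extents (z, y, x); fraction of the mask within
    ``candidate_radius`` of the T-bar; surface-voxel count (6-neighbor outside
    the mask) and its ratio to the count.  Empty masks yield all-zero blocks.
    """
    if len(interfaces.masks) != 5:
        raise ConfigError(
            f"expected 5 interface masks (one per dilation amount), got {len(interfaces.masks)}"
        )
    origin = np.asarray(interfaces.origin)
    shape0 = interfaces.masks[0].shape
    roi = volume.data[
        origin[0] : origin[0] + shape0[0],
        origin[1] : origin[1] + shape0[1],
        origin[2] : origin[2] + shape0[2],
    ]
    tbar_zyx = np.asarray(tbar.zyx, dtype=np.float64)
    blocks = [
        _mask_statistics(m, roi, origin, tbar_zyx, dark_threshold, candidate_radius)
        for m in interfaces.masks
    ]
    out = np.concatenate(blocks)
    assert out.shape == (N_FEATURES,)
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite feature value")
    return out


# ---------------------------------------------------------------------------
# MLP partner classifier
# ---------------------------------------------------------------------------


class MlpModel:
    """Single-hidden-layer MLP partner classifier with input standardization."""

    def __init__(self) -> None:
        self.scaler: StandardScaler | None = None
        self.mlp: MLPClassifier | None = None
        self.final_loss: float | None = None

    @property
    def is_trained(self) -> bool:
        return self.mlp is not None

    def score(self, features: np.ndarray) -> np.ndarray:
        """Partner probability for each feature row, in [0, 1]."""
        if not self.is_trained:
            raise ValueError("model is not trained")
        X = np.atleast_2d(np.asarray(features, dtype=np.float64))
        proba = self.mlp.predict_proba(self.scaler.transform(X))[:, 1]
        return np.clip(proba, 0.0, 1.0)


def train_mlp(
    features: Sequence[np.ndarray] | np.ndarray,
    labels: Sequence[int] | np.ndarray,
    seed: int = 0,
    *,
    hidden_units: int = 50,
    max_iter: int = 2000,
) -> MlpModel:
    """Fit the partner MLP (cross-entropy loss) on standardized features.

    Requires at least one example of each class; reproducible for a fixed
    seed.  The final training cross-entropy is stored and logged.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features must be 2D with one label per row")
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError("training data must contain both classes")
    model = MlpModel()
    model.scaler = StandardScaler().fit(X)
    model.mlp = MLPClassifier(
        hidden_layer_sizes=(hidden_units,), max_iter=max_iter, random_state=seed
    )
    import warnings

    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        model.mlp.fit(model.scaler.transform(X), y)
    model.final_loss = float(model.mlp.loss_)
    logger.info(
        "partner MLP trained on %d examples (%d positive); final cross-entropy %.4f",
        len(y),
        int(y.sum()),
        model.final_loss,
    )
    return model


def predict_partners(
    tbar: PointAnnotation,
    labels: LabelVolume,
    volume: Volume,
    model: MlpModel,
    cfg: PartnerConfig = PartnerConfig(),
) -> SynapseRecord:
    """Predict the postsynaptic partners of one T-bar.

    Pipeline: dark-voxel masking of the segmentation, candidate gathering,
    per-candidate interface estimation and feature extraction, MLP scoring.
    Candidates with score >= ``decision_threshold`` become partner entries
    (confidence = score), at most one per body.
    """
    masked = mask_dark_voxels(labels, volume, cfg.dark_threshold)
    cs = find_candidates(tbar, masked, cfg.candidate_radius)
    if not cs.candidate_bodies:
        return SynapseRecord(tbar, (), cs.host_body or None)
    roi_radius = int(cfg.candidate_radius) + max(cfg.dilation_amounts)
    bodies = sorted(cs.candidate_bodies)
    feats = []
    for b in bodies:
        ifaces = estimate_interface(
            cs.host_body, b, masked, tbar, cfg.dilation_amounts, roi_radius
        )
        feats.append(
            extract_features(ifaces, volume, tbar, cfg.dark_threshold, cfg.candidate_radius)
        )
    scores = model.score(np.asarray(feats))
    partners = [
        PartnerEntry(b, float(s))
        for b, s in sorted(zip(bodies, scores), key=lambda t: (-t[1], t[0]))
        if s >= cfg.decision_threshold
    ]
    return SynapseRecord(tbar, tuple(partners), cs.host_body)


def assemble_training_pairs(
    gt_records: Iterable[SynapseRecord],
    labels: LabelVolume,
    volume: Volume,
    cfg: PartnerConfig = PartnerConfig(),
    shift_radius: float = 3.0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Binary training examples for the partner MLP from ground-truth records.

    For every GT T-bar, every candidate body is one example, labeled 1 iff it
    is a GT partner.  Partner bodies are resolved as the (masked) label at the
    GT PSD point after brightest-voxel shifting when a point is available,
    falling back to the stored body ID.  Diagnostics count GT partners that
    fall outside the candidate set (unreachable positives).
    """
    masked = mask_dark_voxels(labels, volume, cfg.dark_threshold)
    roi_radius = int(cfg.candidate_radius) + max(cfg.dilation_amounts)
    X: list[np.ndarray] = []
    y: list[int] = []
    diagnostics = {"n_tbars": 0, "n_partners_outside_candidates": 0, "n_unresolved_hosts": 0}
    for rec in gt_records:
        diagnostics["n_tbars"] += 1
        cs = find_candidates(rec.tbar, masked, cfg.candidate_radius)
        if not cs.host_resolved:
            diagnostics["n_unresolved_hosts"] += 1
            continue
        positives = set()
        for p in rec.partners:
            body = p.body_id
            if p.point is not None:
                shifted = shift_to_brightest([p.point], volume, shift_radius)[0]
                resolved = int(masked.data[shifted.z, shifted.y, shifted.x])
                if resolved != 0:
                    body = resolved
            positives.add(body)
        diagnostics["n_partners_outside_candidates"] += len(
            positives - cs.candidate_bodies
        )
        for b in sorted(cs.candidate_bodies):
            ifaces = estimate_interface(
                cs.host_body, b, masked, rec.tbar, cfg.dilation_amounts, roi_radius
            )
            X.append(
                extract_features(
                    ifaces, volume, rec.tbar, cfg.dark_threshold, cfg.candidate_radius
                )
            )
            y.append(1 if b in positives else 0)
    if X:
        return np.asarray(X), np.asarray(y, dtype=int), diagnostics
    return np.zeros((0, N_FEATURES)), np.zeros(0, dtype=int), diagnostics
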