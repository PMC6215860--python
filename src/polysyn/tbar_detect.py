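"""Presynaptic T-bar detection.

The detector is point-supervised: sparse T-bar point annotations are turned
into dense voxel labels (every voxel within ``positive_radius`` of an
annotation is positive), a voxel classifier maps the raw volume to a
probability map, and post-processing (Gaussian smoothing, local-maximum
selection, greedy non-maxima suppression, brightest-voxel shifting) turns the
map back into point predictions with confidences.

The voxel classifier here is a multiscale filter-bank model: per-voxel
features are Gaussian-smoothed intensity, Laplacian-of-Gaussian, and gradient
magnitude at several scales, classified by a small MLP.  It honors a simple
contract — same-shape probability map in [0, 1], deterministic inference, and
a declared receptive-field side length (set by the largest filter support) —
so alternative voxel classifiers can be swapped in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .core_io import PointAnnotation, TbarPrediction, Volume, check_inside
from .errors import BoundsError, DegenerateTrainingError, SizeError
from .geometry import ball_offsets, clip_ball_voxels

logger = logging.getLogger(__name__)

_TRUNCATE = 4.0  # Gaussian support truncation, in sigmas (scipy default)


@dataclass(frozen=True)
class VoxelLabelConfig:
    """How point annotations become dense voxel labels."""

    positive_radius: float = 5.0

    def __post_init__(self) -> None:
        if self.positive_radius < 0:
            raise ValueError("positive_radius must be >= 0")


@dataclass(frozen=True)
class DetectorConfig:
    """Post-processing parameters for turning a probability map into points.

    smoothing_sigma : Gaussian sigma (voxels) applied to the probability map.
    nms_radius : suppression radius (voxels); kept points are pairwise farther
        apart than this.
    confidence_threshold : smoothed-map value a local maximum must exceed.
        The default is deliberately conservative (high recall): smoothing
        dilutes small detection blobs, and downstream stages sweep or select
        an operating threshold anyway.
    shift_radius : radius (voxels) for brightest-voxel shifting.
    patch_shape : tile shape for blocked inference on large volumes.
    """

    smoothing_sigma: float = 2.0
    nms_radius: float = 10.0
    confidence_threshold: float = 0.2
    shift_radius: float = 3.0
    patch_shape: tuple[int, int, int] = (64, 64, 64)

    def __post_init__(self) -> None:
        if self.smoothing_sigma < 0 or self.nms_radius < 0 or self.shift_radius < 0:
            raise ValueError("sigma and radii must be >= 0")
        if not (0.0 <= self.confidence_threshold <= 1.0):
            raise ValueError("confidence_threshold must lie in [0, 1]")


def make_voxel_labels(
    points: Iterable[PointAnnotation],
    shape: tuple[int, int, int],
    cfg: VoxelLabelConfig = VoxelLabelConfig(),
) -> np.ndarray:
    """Dense binary labels: voxel positive iff within ``positive_radius`` of a point."""
    out = np.zeros(shape, dtype=bool)
    for p in points:
        check_inside(p, shape)
        vox = clip_ball_voxels(p.zyx, cfg.positive_radius, shape)
        out[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    return out


# ---------------------------------------------------------------------------
# voxel classifier
# ---------------------------------------------------------------------------


def _hessian_eigenvalues(x: np.ndarray, sigma: float) -> list[np.ndarray]:
    """Sorted eigenvalues of the scale-normalized Gaussian Hessian.

    These separate blob-like dark structures (all eigenvalues large, as at a
    T-bar platform) from sheets and lines (one or two near zero, as at
    membranes and membrane junctions).
    """
    orders = [(2, 0, 0), (0, 2, 0), (0, 0, 2), (1, 1, 0), (1, 0, 1), (0, 1, 1)]
    d = [
        ndimage.gaussian_filter(x, sigma, order=o, mode="reflect", truncate=_TRUNCATE)
        * sigma**2
        for o in orders
    ]
    H = np.empty(x.shape + (3, 3), dtype=np.float32)
    H[..., 0, 0], H[..., 1, 1], H[..., 2, 2] = d[0], d[1], d[2]
    H[..., 0, 1] = H[..., 1, 0] = d[3]
    H[..., 0, 2] = H[..., 2, 0] = d[4]
    H[..., 1, 2] = H[..., 2, 1] = d[5]
    ev = np.linalg.eigvalsh(H)
    return [ev[..., k] for k in range(3)]


def _filter_bank(
    data: np.ndarray,
    sigmas: Sequence[float],
    hessian_sigmas: Sequence[float] = (2.0, 4.0),
) -> np.ndarray:
    """Per-voxel features, shape (n_features, z, y, x); float32.

    Features: raw intensity; for each sigma Gaussian-smoothed intensity,
    Laplacian-of-Gaussian, and gradient magnitude; for each Hessian sigma the
    three sorted Hessian eigenvalues.  Border handling is 'reflect'.
    """
    x = data.astype(np.float32) / 255.0
    feats = [x]
    for s in sigmas:
        feats.append(ndimage.gaussian_filter(x, s, mode="reflect", truncate=_TRUNCATE))
        feats.append(ndimage.gaussian_laplace(x, s, mode="reflect", truncate=_TRUNCATE))
        feats.append(
            ndimage.gaussian_gradient_magnitude(x, s, mode="reflect", truncate=_TRUNCATE)
        )
    for s in hessian_sigmas:
        feats.extend(_hessian_eigenvalues(x, s))
    return np.stack(feats, axis=0)


class VoxelClassifier:
    """Multiscale filter-bank voxel classifier for T-bar-ness.

    Maps a Volume to a probability map of identical shape with values in
    [0, 1]; inference is deterministic for fixed state and input.  The
    receptive field is the support of the largest filter in the bank.
    """

    def __init__(
        self,
        sigmas: Sequence[float] = (1.0, 2.0, 4.0),
        hessian_sigmas: Sequence[float] = (2.0, 4.0),
    ):
        self.sigmas = tuple(sigmas)
        self.hessian_sigmas = tuple(hessian_sigmas)
        self.scaler: StandardScaler | None = None
        self.mlp: MLPClassifier | None = None
        self.final_loss: float | None = None

    @property
    def receptive_radius(self) -> int:
        return int(_TRUNCATE * max(self.sigmas + self.hessian_sigmas) + 0.5)

    def _features(self, data: np.ndarray) -> np.ndarray:
        return _filter_bank(data, self.sigmas, self.hessian_sigmas)

    @property
    def receptive_field(self) -> int:
        """Declared receptive-field side length, in voxels."""
        return 2 * self.receptive_radius + 1

    @property
    def is_trained(self) -> bool:
        return self.mlp is not None

    def _predict_block(self, feats: np.ndarray) -> np.ndarray:
        assert self.scaler is not None and self.mlp is not None
        nf = feats.shape[0]
        flat = feats.reshape(nf, -1).T
        proba = self.mlp.predict_proba(self.scaler.transform(flat))[:, 1]
        return np.clip(proba, 0.0, 1.0).reshape(feats.shape[1:]).astype(np.float32)


def train_voxel_classifier(
    volumes: Sequence[Volume],
    labels: Sequence[np.ndarray],
    seed: int = 0,
    *,
    sigmas: Sequence[float] = (1.0, 2.0, 4.0),
    hidden_units: int = 32,
    max_iter: int = 300,
    max_per_class: int = 20000,
    hard_negative_rounds: int = 1,
) -> VoxelClassifier:
    """Fit the voxel classifier on point-derived dense labels.

    Positive and negative voxels are sampled 1:1 (up to ``max_per_class``
    each), which counteracts the extreme class imbalance of sparse synapse
    labels.  Each hard-negative round then re-applies the classifier to the
    training volumes and adds its confident false-positive voxels to the
    negative pool before refitting — membrane junctions and similar dark
    distractors are rare under uniform sampling but dominate the detector's
    error modes.  Training is reproducible for a fixed seed; the final
    training cross-entropy is stored on the returned classifier and logged.
    """
    if len(volumes) != len(labels) or not volumes:
        raise ValueError("need equal, non-empty lists of volumes and label grids")
    for v, l in zip(volumes, labels):
        if v.shape != l.shape:
            raise ValueError(f"volume shape {v.shape} != label shape {l.shape}")
    if not any(np.any(l) for l in labels):
        raise DegenerateTrainingError("no positive voxels in the training labels")

    rng = np.random.default_rng(seed)
    clf = VoxelClassifier(sigmas)
    all_feats = []  # (flat features, flat labels) per volume, reused across rounds
    xs, ys = [], []
    for vol, lab in zip(volumes, labels):
        feats = clf._features(vol.data)
        nf = feats.shape[0]
        flat = feats.reshape(nf, -1).T
        labflat = np.asarray(lab, dtype=bool).ravel()
        all_feats.append((flat, labflat))
        pos_idx = np.flatnonzero(labflat)
        neg_idx = np.flatnonzero(~labflat)
        n = min(len(pos_idx), max_per_class)
        pos_sel = rng.choice(pos_idx, size=n, replace=False)
        neg_sel = rng.choice(neg_idx, size=min(len(neg_idx), n), replace=False)
        sel = np.concatenate([pos_sel, neg_sel])
        xs.append(flat[sel])
        ys.append(labflat[sel])
    X = np.concatenate(xs)
    y = np.concatenate(ys)
    mlp_seed = int(rng.integers(0, 2**31 - 1))

    import warnings

    from sklearn.exceptions import ConvergenceWarning

    def _fit(X, y):
        clf.scaler = StandardScaler().fit(X)
        clf.mlp = MLPClassifier(
            hidden_layer_sizes=(hidden_units,), max_iter=max_iter, random_state=mlp_seed
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.mlp.fit(clf.scaler.transform(X), y.astype(int))

    _fit(X, y)
    for _ in range(hard_negative_rounds):
        hard = []
        for flat, labflat in all_feats:
            proba = clf.mlp.predict_proba(clf.scaler.transform(flat))[:, 1]
            fp_idx = np.flatnonzero((proba >= 0.5) & ~labflat)
            if len(fp_idx) > max_per_class:
                fp_idx = rng.choice(fp_idx, size=max_per_class, replace=False)
            hard.append(flat[fp_idx])
        hard_X = np.concatenate(hard) if hard else np.empty((0, X.shape[1]))
        if len(hard_X) == 0:
            break
        X = np.concatenate([X, hard_X])
        y = np.concatenate([y, np.zeros(len(hard_X), dtype=bool)])
        _fit(X, y)

    clf.final_loss = float(clf.mlp.loss_)
    logger.info(
        "voxel classifier trained on %d samples; final cross-entropy %.4f",
        len(y),
        clf.final_loss,
    )
    return clf


def predict_probability(
    volume: Volume,
    clf: VoxelClassifier,
    patch_shape: tuple[int, int, int] | None = None,
) -> np.ndarray:
    """Voxel-wise T-bar probability map, same shape as the input volume.

    With ``patch_shape`` set, inference is tiled; each tile is computed with a
    context margin of one receptive-field radius, so the output is identical
    to whole-volume inference.
    """
    if not clf.is_trained:
        raise ValueError("classifier is not trained")
    if min(volume.shape) < clf.receptive_field:
        raise SizeError(
            f"volume shape {volume.shape} smaller than receptive field "
            f"{clf.receptive_field} in some axis"
        )
    data = volume.data
    if patch_shape is None:
        return clf._predict_block(clf._features(data))

    margin = clf.receptive_radius
    out = np.empty(data.shape, dtype=np.float32)
    pz, py, px = patch_shape
    for z0 in range(0, data.shape[0], pz):
        for y0 in range(0, data.shape[1], py):
            for x0 in range(0, data.shape[2], px):
                z1 = min(z0 + pz, data.shape[0])
                y1 = min(y0 + py, data.shape[1])
                x1 = min(x0 + px, data.shape[2])
                zc0, yc0, xc0 = max(0, z0 - margin), max(0, y0 - margin), max(0, x0 - margin)
                zc1 = min(data.shape[0], z1 + margin)
                yc1 = min(data.shape[1], y1 + margin)
                xc1 = min(data.shape[2], x1 + margin)
                block = data[zc0:zc1, yc0:yc1, xc0:xc1]
                pred = clf._predict_block(clf._features(block))
                out[z0:z1, y0:y1, x0:x1] = pred[
                    z0 - zc0 : z1 - zc0, y0 - yc0 : y1 - yc0, x0 - xc0 : x1 - xc0
                ]
    return out


# ---------------------------------------------------------------------------
# post-processing: points from probability maps
# ---------------------------------------------------------------------------


def extract_points(pmap: np.ndarray, cfg: DetectorConfig = DetectorConfig()) -> list[TbarPrediction]:
    """Point predictions from a probability map.

    The map is Gaussian-smoothed; candidates are 26-neighborhood local maxima
    strictly above ``confidence_threshold``; greedy NMS in descending
    confidence (ties broken lexicographically by (z, y, x)) removes any
    candidate within ``nms_radius`` of an already-kept point.  Confidences
    are smoothed-map values; output is sorted by descending confidence.
    """
    pmap = np.asarray(pmap, dtype=np.float32)
    if cfg.smoothing_sigma > 0:
        sm = ndimage.gaussian_filter(pmap, cfg.smoothing_sigma, mode="reflect")
    else:
        sm = pmap
    local_max = sm == ndimage.maximum_filter(sm, size=3, mode="reflect")
    cand = np.argwhere(local_max & (sm > cfg.confidence_threshold))
    if len(cand) == 0:
        return []
    conf = sm[cand[:, 0], cand[:, 1], cand[:, 2]]
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], -conf))
    cand, conf = cand[order], conf[order]

    kept: list[np.ndarray] = []
    kept_conf: list[float] = []
    r2 = cfg.nms_radius**2
    for c, s in zip(cand, conf):
        if kept:
            d2 = ((np.array(kept) - c) ** 2).sum(axis=1)
            if (d2 <= r2).any():
                continue
        kept.append(c)
        kept_conf.append(float(s))
    return [
        PointAnnotation(int(c[0]), int(c[1]), int(c[2]), min(s, 1.0), "tbar")
        for c, s in zip(kept, kept_conf)
    ]


def shift_to_brightest(
    points: Iterable[PointAnnotation], volume: Volume, shift_radius: float
) -> list[PointAnnotation]:
    """Move each point to the brightest voxel within a closed ball.

    Dark (electron-dense) T-bar interiors and membranes are where automated
    segmentations are least reliable, so shifting toward bright cytoplasm
    places the annotation in an unambiguous segment.  Ties are broken by the
    smallest Euclidean move, then lexicographic (z, y, x); confidence and kind
    are unchanged.
    """
    offs = ball_offsets(shift_radius)  # sorted by (distance, z, y, x)
    shape = volume.shape
    out = []
    for p in points:
        check_inside(p, shape)
        best_val = -1
        best = p.zyx
        for dz, dy, dx in offs.tolist():
            z, y, x = p.z + dz, p.y + dy, p.x + dx
            if not (0 <= z < shape[0] and 0 <= y < shape[1] and 0 <= x < shape[2]):
                continue
            v = int(volume.data[z, y, x])
            if v > best_val:
                best_val = v
                best = (z, y, x)
        out.append(p.with_position(*best))
    return out


def select_threshold_for_recall(pr_curve, target_recall: float) -> float:
    """Largest threshold on a PR sweep whose recall is >= ``target_recall``.

    Accepts any iterable of points exposing ``threshold`` and ``recall``
    (or ``(threshold, precision, recall)`` tuples).
    """
    best = None
    for pt in pr_curve:
        thr = getattr(pt, "threshold", None)
        rec = getattr(pt, "recall", None)
        if thr is None:
            thr, _, rec = pt
        if rec >= target_recall and (best is None or thr > best):
            best = thr
    if best is None:
        raise ValueError(f"target recall {target_recall} is unattainable on this curve")
    return best
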