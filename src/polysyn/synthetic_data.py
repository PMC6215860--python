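"""Seeded generator of EM-like phantoms.

A phantom emulates the features of isotropic FIB-SEM tissue that the
detection and evaluation code depends on: cell-like bodies separated by dark
membranes, darkest bar-plus-platform presynaptic (T-bar) motifs surrounded by
vesicle-like rings inside a host body, darkened postsynaptic (PSD) membrane
patches on 1+ partner bodies across the membrane, additive intensity noise,
and a "predicted segmentation" variant carrying boundary jitter and
split/merge errors.  Everything is reproducible from a single seed.

It makes no claim of physical realism (no organelles other than vesicles, no
anisotropy, no imaging artifacts); it is a controlled test surface for the
detection pipeline and the connectome metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core_io import (
    ConnectomeGraph,
    LabelVolume,
    PartnerEntry,
    PointAnnotation,
    SynapseRecord,
    Volume,
    build_graph,
    write_graph_csv,
    write_labels,
    write_synapses,
    write_volume,
)
from .errors import ConfigError, GenerationError
from .geometry import clip_ball_voxels


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the phantom.

    Intensities are 8-bit with low = electron-dense, ordered so T-bars are
    darkest, then membranes, vesicle walls, PSD patches, and bright
    cytoplasm.  ``partners_range`` is inclusive and matches the polyadic
    range typical of *Drosophila* synapses.  ``min_tbar_spacing`` keeps
    planted T-bars at twice the default NMS radius so suppression cannot
    merge two distinct ground-truth synapses.  The corruption fields control
    the degraded segmentation: ``jitter_magnitude`` boundary-growth passes,
    plus random body splits and merges of adjacent bodies.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    n_segments: int = 20
    n_synapses: int = 15
    partners_range: tuple[int, int] = (1, 4)
    membrane_intensity: int = 30
    cytoplasm_intensity: int = 150
    tbar_intensity: int = 20
    psd_intensity: int = 80
    vesicle_intensity: int = 60
    noise_sigma: float = 10.0
    jitter_magnitude: int = 2
    n_splits: int = 2
    n_merges: int = 2
    candidate_radius: float = 15.0
    min_tbar_spacing: float = 20.0
    border_margin: int = 3
    max_boundary_distance: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "membrane_intensity",
            "cytoplasm_intensity",
            "tbar_intensity",
            "psd_intensity",
            "vesicle_intensity",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ConfigError(f"{name} must lie in [0, 255], got {v}")
        if self.n_segments < 2:
            raise ConfigError("n_segments must be >= 2")
        lo, hi = self.partners_range
        if not (1 <= lo <= hi <= self.n_segments - 1):
            raise ConfigError("partners_range must lie within [1, n_segments - 1]")
        if self.n_synapses < 0 or self.noise_sigma < 0:
            raise ConfigError("n_synapses and noise_sigma must be >= 0")


@dataclass
class Phantom:
    """A complete synthetic scene: image, segmentations, and ground truth."""

    volume: Volume
    clean_labels: LabelVolume
    degraded_labels: LabelVolume
    gt_records: list[SynapseRecord]
    gt_graph: ConnectomeGraph
    config: PhantomConfig


def _sub_seed(cfg: PhantomConfig, stage: int) -> int:
    ss = np.random.SeedSequence(cfg.seed).spawn(5)[stage]
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _boundary_mask(arr: np.ndarray) -> np.ndarray:
    """Voxels with a face-neighbor carrying a different label."""
    out = np.zeros(arr.shape, dtype=bool)
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        diff = arr[tuple(lo)] != arr[tuple(hi)]
        out[tuple(lo)] |= diff
        out[tuple(hi)] |= diff
    return out


def generate_segmentation(cfg: PhantomConfig, seed: int | None = None) -> LabelVolume:
    """Nearest-seed (Voronoi) partition of the volume into n_segments bodies."""
    rng = np.random.default_rng(_sub_seed(cfg, 0) if seed is None else seed)
    shape = np.asarray(cfg.shape)
    seeds = rng.uniform(0, shape - 1, size=(cfg.n_segments, 3))
    tree = cKDTree(seeds)
    grid = np.indices(cfg.shape).reshape(3, -1).T
    _, owner = tree.query(grid, workers=1)
    labels = (owner + 1).reshape(cfg.shape).astype(np.int64)
    return LabelVolume(labels)


def place_synapses(
    labels: LabelVolume, cfg: PhantomConfig, seed: int | None = None
) -> list[SynapseRecord]:
    """Plant polyadic synapses: T-bar points plus partner bodies and PSD points.

    T-bars sit inside a body, at least ``border_margin`` voxels from the
    volume border, within ``max_boundary_distance`` of a membrane, and at
    pairwise distance >= ``min_tbar_spacing``.  Partner counts are uniform on
    ``partners_range`` (capped by the neighborhood), partners are distinct
    bodies reachable within the candidate radius, and each PSD point lies
    inside its partner body just behind the shared membrane.
    """
    rng = np.random.default_rng(_sub_seed(cfg, 1) if seed is None else seed)
    arr = labels.data
    shape = labels.shape
    boundary = _boundary_mask(arr)
    dist = ndimage.distance_transform_edt(~boundary)

    eligible = (dist >= 2.0) & (dist <= cfg.max_boundary_distance)
    m = cfg.border_margin
    border = np.zeros(shape, dtype=bool)
    border[m:-m, m:-m, m:-m] = True
    eligible &= border & (arr != 0)
    pool = np.argwhere(eligible)
    if len(pool) == 0:
        raise GenerationError("no eligible T-bar locations in this segmentation")

    lo_k, hi_k = cfg.partners_range
    records: list[SynapseRecord] = []
    placed: list[np.ndarray] = []
    attempts = 0
    max_attempts = 400 * max(cfg.n_synapses, 1)
    while len(records) < cfg.n_synapses:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"could not place {cfg.n_synapses} synapses after {max_attempts} attempts"
            )
        pt = pool[rng.integers(len(pool))]
        if placed and min(np.linalg.norm(np.array(placed) - pt, axis=1)) < cfg.min_tbar_spacing:
            continue
        host = int(arr[tuple(pt)])
        ball = clip_ball_voxels(tuple(pt), cfg.candidate_radius, shape)
        ball_labels = arr[ball[:, 0], ball[:, 1], ball[:, 2]]
        ball_dist = dist[ball[:, 0], ball[:, 1], ball[:, 2]]
        # usable partners: bodies with an interior voxel (inside, behind the
        # membrane) within the candidate radius
        usable: dict[int, np.ndarray] = {}
        for b in np.unique(ball_labels):
            b = int(b)
            if b in (0, host):
                continue
            sel = (ball_labels == b) & (ball_dist >= 1.5) & (ball_dist <= 4.0)
            if sel.any():
                usable[b] = ball[sel]
        if len(usable) < lo_k:
            continue
        k = int(rng.integers(lo_k, min(hi_k, len(usable)) + 1))
        bodies = rng.choice(sorted(usable), size=k, replace=False)
        partners = []
        for b in sorted(int(b) for b in bodies):
            cand_vox = usable[b]
            d2 = ((cand_vox - pt) ** 2).sum(axis=1)
            psd = cand_vox[int(np.argmin(d2))]
            partners.append(
                PartnerEntry(
                    b, 1.0, PointAnnotation(int(psd[0]), int(psd[1]), int(psd[2]), 1.0, "psd")
                )
            )
        tbar = PointAnnotation(int(pt[0]), int(pt[1]), int(pt[2]), 1.0, "tbar")
        records.append(SynapseRecord(tbar, tuple(partners), host))
        placed.append(pt)
    return records


def _stamp_tbar_motif(
    img: np.ndarray, arr: np.ndarray, rec: SynapseRecord, cfg: PhantomConfig, rng
) -> None:
    z, y, x = rec.tbar.zyx
    host = rec.host_body
    shape = img.shape

    def put(vz, vy, vx, value):
        if 0 <= vz < shape[0] and 0 <= vy < shape[1] and 0 <= vx < shape[2]:
            if arr[vz, vy, vx] == host:
                img[vz, vy, vx] = value

    # platform: 5x5x2 slab; pedestal: 1x1x3 stem below -> a "T" profile
    for dz in (0, 1):
        for dy in range(-2, 3):
            for dx in range(-2, 3):
                put(z + dz, y + dy, x + dx, cfg.tbar_intensity)
    for dz in (2, 3, 4):
        put(z + dz, y, x, cfg.tbar_intensity)

    # vesicle halo: small dark rings scattered around the T-bar
    for _ in range(10):
        off = rng.integers(-8, 9, size=3)
        if not (4.0 <= np.linalg.norm(off) <= 9.0):
            continue
        c = np.array([z, y, x]) + off
        for dz in range(-2, 3):
            for dy in range(-2, 3):
                for dx in range(-2, 3):
                    r = np.sqrt(dz * dz + dy * dy + dx * dx)
                    if 1.3 <= r <= 2.3:
                        vz, vy, vx = c[0] + dz, c[1] + dy, c[2] + dx
                        if (
                            0 <= vz < shape[0]
                            and 0 <= vy < shape[1]
                            and 0 <= vx < shape[2]
                            and arr[vz, vy, vx] == host
                            and img[vz, vy, vx] == cfg.cytoplasm_intensity
                        ):
                            img[vz, vy, vx] = cfg.vesicle_intensity


def render_volume(
    labels: LabelVolume,
    records: list[SynapseRecord],
    cfg: PhantomConfig,
    seed: int | None = None,
) -> Volume:
    """Render the intensity image for a segmentation plus planted synapses.

    Cytoplasm is bright, membranes (label changes) dark, T-bar motifs darkest
    with a vesicle-ring halo, and partner-side membrane patches darkened
    toward ``psd_intensity``; Gaussian noise is added last and the result
    clamped to [0, 255].
    """
    rng = np.random.default_rng(_sub_seed(cfg, 2) if seed is None else seed)
    arr = labels.data
    img = np.full(arr.shape, float(cfg.cytoplasm_intensity), dtype=np.float32)
    boundary = _boundary_mask(arr)
    img[boundary] = cfg.membrane_intensity
    dist = ndimage.distance_transform_edt(~boundary)

    for rec in records:
        # PSD: darken the partner-side face of the membrane near the PSD point
        for p in rec.partners:
            if p.point is None:
                continue
            patch = clip_ball_voxels(p.point.zyx, 3.5, arr.shape)
            sel = (
                (arr[patch[:, 0], patch[:, 1], patch[:, 2]] == p.body_id)
                & (dist[patch[:, 0], patch[:, 1], patch[:, 2]] <= 2.5)
            )
            pv = patch[sel]
            img[pv[:, 0], pv[:, 1], pv[:, 2]] = cfg.psd_intensity
        _stamp_tbar_motif(img, arr, rec, cfg, rng)

    if cfg.noise_sigma > 0:
        img = img + rng.normal(0.0, cfg.noise_sigma, size=img.shape).astype(np.float32)
    return Volume(np.clip(np.rint(img), 0, 255).astype(np.uint8))


def degrade_segmentation(
    labels: LabelVolume, cfg: PhantomConfig, seed: int | None = None
) -> LabelVolume:
    """Emulate an automated segmentation: boundary jitter, splits, merges.

    Jitter performs ``jitter_magnitude`` passes in which random bodies grow
    one voxel into their neighbors at randomly chosen boundary voxels; splits
    cut a random body by a random plane through its centroid (new label);
    merges relabel one of a random adjacent body pair.  Zero corruption
    returns an identical copy.
    """
    rng = np.random.default_rng(_sub_seed(cfg, 3) if seed is None else seed)
    out = labels.data.copy()

    for _ in range(cfg.jitter_magnitude):
        ids = [int(i) for i in np.unique(out) if i != 0]
        rng.shuffle(ids)
        for b in ids[: max(1, len(ids) // 2)]:
            body = out == b
            grow = ndimage.binary_dilation(body) & ~body & (out != 0)
            coords = np.argwhere(grow)
            if len(coords) == 0:
                continue
            take = coords[rng.random(len(coords)) < 0.5]
            out[take[:, 0], take[:, 1], take[:, 2]] = b

    for _ in range(cfg.n_splits):
        ids = [int(i) for i in np.unique(out) if i != 0]
        b = int(rng.choice(ids))
        coords = np.argwhere(out == b)
        normal = rng.normal(size=3)
        normal /= np.linalg.norm(normal)
        side = (coords - coords.mean(axis=0)) @ normal > 0
        if 0.05 < side.mean() < 0.95:
            new_id = int(out.max()) + 1
            sel = coords[side]
            out[sel[:, 0], sel[:, 1], sel[:, 2]] = new_id

    for _ in range(cfg.n_merges):
        bmask = _boundary_mask(out)
        coords = np.argwhere(bmask & (out != 0))
        if len(coords) == 0:
            break
        v = coords[rng.integers(len(coords))]
        a = int(out[tuple(v)])
        partner = 0
        for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            w = v + np.array([dz, dy, dx])
            if np.all(w >= 0) and np.all(w < np.asarray(out.shape)):
                lab = int(out[tuple(w)])
                if lab not in (0, a):
                    partner = lab
                    break
        if partner:
            out[out == partner] = a

    return LabelVolume(out)


def generate_phantom(cfg: PhantomConfig = PhantomConfig()) -> Phantom:
    """Compose segmentation, synapse placement, rendering, and degradation."""
    clean = generate_segmentation(cfg)
    records = place_synapses(clean, cfg)
    volume = render_volume(clean, records, cfg)
    degraded = degrade_segmentation(clean, cfg)
    graph = build_graph(records, clean).graph
    return Phantom(volume, clean, degraded, records, graph, cfg)


def write_phantom(phantom: Phantom, out_dir) -> dict[str, Path]:
    """Write the fixture bundle: volume.h5, labels, synapses.json, graph.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "volume": out / "volume.h5",
        "labels_clean": out / "labels_clean.h5",
        "labels_degraded": out / "labels_degraded.h5",
        "synapses": out / "synapses.json",
        "graph": out / "graph.csv",
    }
    write_volume(phantom.volume, paths["volume"])
    write_labels(phantom.clean_labels, paths["labels_clean"])
    write_labels(phantom.degraded_labels, paths["labels_degraded"])
    write_synapses(phantom.gt_records, paths["synapses"])
    write_graph_csv(phantom.gt_graph, paths["graph"])
    return paths
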