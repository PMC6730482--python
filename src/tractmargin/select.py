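"""Streamline selection, outlier filtering, and a minimal deterministic tracker.

``target_streamlines`` keeps the streamlines that touch a region of interest
(GTV targeting).  ``cluster_confidence`` scores each streamline by how many
close neighbours it has — the Cluster Confidence Index (CCI), a sum of
inverse minimum-average-direct-flip (MDF) distances — and ``filter_by_cci``
drops low-confidence outliers.  ``track_deterministic`` seeds one streamline
per voxel where fractional anisotropy (FA) exceeds a threshold and follows a
supplied principal-direction field bidirectionally, terminating on low FA,
a sharp turn, the grid edge, or a length cap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .spaces import (AffineTransform, StreamlineHeader, StreamlineSet,
                     VolumeGrid, points_to_voxels)

log = logging.getLogger(__name__)


@dataclass
class ConfidenceScores:
    """One nonnegative CCI score per streamline, plus the parameters used."""

    scores: np.ndarray
    subsample_n: int
    power: float
    max_dist: float

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class TrackerConfig:
    """Seeding/stopping rules for the deterministic tracker.

    fa_threshold: seed only where FA > this; a step onto FA <= this stops.
    max_angle:    degrees; a turn sharper than this stops the streamline.
    step_size:    mm per propagation step.
    seeds_per_voxel: seeds placed per eligible voxel (at the voxel center).
    max_length:   mm cap on each streamline's total arc length.
    """

    fa_threshold: float = 0.15
    max_angle: float = 60.0
    step_size: float = 0.5
    seeds_per_voxel: int = 1
    max_length: float = 250.0

    def __post_init__(self) -> None:
        if not 0 < self.fa_threshold < 1:
            raise ValueError("fa_threshold must lie in (0, 1)")
        if not 0 < self.max_angle <= 90:
            raise ValueError("max_angle must lie in (0, 90] degrees")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")


def target_streamlines(s: StreamlineSet, roi: VolumeGrid, a: AffineTransform) -> StreamlineSet:
    """Subset of ``s`` with at least one ROI-interior vertex; order preserved."""
    if not roi.values.any():
        raise ValueError("ROI mask is empty")
    keep = []
    for i, pts in enumerate(s):
        idx, inb = points_to_voxels(pts, a, roi.dims)
        hit = inb & (roi.values[idx[:, 0], idx[:, 1], idx[:, 2]] > 0)
        if hit.any():
            keep.append(i)
    log.info("targeting kept %d/%d streamlines", len(keep), len(s))
    return s.subset(keep)


def resample_polyline(pts: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline to ``n`` vertices equally spaced in arc length."""
    pts = np.asarray(pts, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, cum[-1], n)
    return np.column_stack([np.interp(t, cum, pts[:, c]) for c in range(3)])


def mdf(p: np.ndarray, q: np.ndarray) -> float:
    """Minimum average direct-flip distance between two equally sampled polylines."""
    direct = float(np.linalg.norm(p - q, axis=1).mean())
    flipped = float(np.linalg.norm(p - q[::-1], axis=1).mean())
    return min(direct, flipped)


def cluster_confidence(s: StreamlineSet, subsample_n: int = 12, power: float = 1.0,
                       max_dist: float = 5.0) -> ConfidenceScores:
    """CCI per streamline: sum over neighbours j of ``(1 / MDF(i, j)) ** power``
    for neighbours with ``0 < MDF <= max_dist`` (mm).

    Exact duplicates (MDF == 0) are excluded from the sum and counted in the
    log — the inverse distance would be undefined.  Requires >= 2 streamlines.
    """
    if len(s) < 2:
        raise ValueError("cluster_confidence needs >= 2 streamlines; skip filtering instead")
    res = np.stack([resample_polyline(p, subsample_n) for p in s])
    n = len(res)
    scores = np.zeros(n)
    n_dup = 0
    for i in range(n):
        for j in range(i + 1, n):
            d = mdf(res[i], res[j])
            if d == 0.0:
                n_dup += 1
                continue
            if d <= max_dist:
                w = (1.0 / d) ** power
                scores[i] += w
                scores[j] += w
    if n_dup:
        log.info("cluster_confidence: %d duplicate pairs (MDF = 0) excluded", n_dup)
    return ConfidenceScores(scores, subsample_n, power, max_dist)


def filter_by_cci(s: StreamlineSet, scores: ConfidenceScores,
                  threshold: float = 1.0) -> StreamlineSet:
    """Keep streamlines whose CCI is strictly greater than ``threshold``."""
    if len(scores) != len(s):
        raise ValueError("scores are not aligned with the streamline set")
    keep = [i for i in range(len(s)) if scores.scores[i] > threshold]
    log.info("CCI filter (> %g): kept %d, removed %d", threshold, len(keep), len(s) - len(keep))
    return s.subset(keep)


def track_deterministic(fa: VolumeGrid, directions: np.ndarray,
                        cfg: TrackerConfig | None = None) -> StreamlineSet:
    """Deterministic fiber tracking on a per-voxel unit-direction field.

    One seed is placed at the center of every voxel with FA above the
    threshold; propagation is bidirectional with nearest-voxel lookup of FA
    and direction (the local direction is sign-aligned with the incoming
    heading).  A step is refused — ending the streamline — when the new
    position's FA is at or below the threshold, the turn exceeds the angle
    cap, the position leaves the grid, or the length cap is reached.
    Emitted polylines have >= 2 vertices; coordinates are in the FA grid's
    voxmm frame (corner origin, grid axis order).
    """
    cfg = cfg or TrackerConfig()
    directions = np.asarray(directions, dtype=float)
    if directions.shape != fa.dims + (3,):
        raise ValueError(f"direction field shape {directions.shape} does not match "
                         f"FA grid {fa.dims} + (3,)")
    vs = fa.voxel_sizes
    dims = np.array(fa.dims)
    fav = fa.values
    cos_cap = np.cos(np.deg2rad(cfg.max_angle))

    def voxel(pos):
        idx = np.floor(pos / vs).astype(int)
        if (idx < 0).any() or (idx >= dims).any():
            return None
        return tuple(idx)

    def walk(seed, heading):
        pts = [seed]
        length = 0.0
        pos = seed
        while length + cfg.step_size <= cfg.max_length:
            v = voxel(pos)
            d = directions[v]
            if np.dot(d, heading) < 0:
                d = -d
            cosang = float(np.dot(d, heading))
            if cosang < cos_cap - 1e-12:
                break
            new = pos + cfg.step_size * d
            nv = voxel(new)
            if nv is None or fav[nv] <= cfg.fa_threshold:
                break
            pts.append(new)
            pos, heading = new, d
            length += cfg.step_size
        return pts

    seeds = np.argwhere(fav > cfg.fa_threshold)
    if len(seeds) == 0:
        log.warning("tracker: no voxel exceeds the FA seed threshold; empty set")
    polylines = []
    for idx in seeds:
        d0 = directions[tuple(idx)]
        nrm = np.linalg.norm(d0)
        if nrm == 0:
            continue
        d0 = d0 / nrm
        for _ in range(cfg.seeds_per_voxel):
            center = (idx + 0.5) * vs
            fwd = walk(center, d0)
            bwd = walk(center, -d0)
            line = bwd[::-1][:-1] + fwd  # seed vertex appears once
            if len(line) >= 2:
                polylines.append(np.asarray(line))
    hdr = StreamlineHeader(fa.dims, vs.copy(), fa.axis_codes)
    return StreamlineSet(polylines, hdr)
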