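"""White-matter path-length (WMPL) mapping.

The WMPL map assigns each voxel the minimum arc-length distance, measured
*along* any streamline, back to a target region of interest.  Per streamline:

1. classify each vertex as ROI-interior or not by voxel membership;
2. accumulate arc length along the polyline (Euclidean segment sums);
3. each vertex's path distance is the minimum ``|cumlen(k) - cumlen(m)|``
   over ROI-interior vertices ``m`` — the nearest interior vertex in either
   direction along the polyline;
4. streamlines that never enter the ROI contribute nothing (counted);
5. each vertex deposits its distance into its voxel; the map keeps the
   per-voxel minimum, with a fill value (default -1) where nothing landed.

Voxel visitation is vertex-based: a segment crossing a voxel without a vertex
in it deposits nothing.  :func:`densify` is the documented mitigation —
resample so no segment exceeds half the smallest voxel size before mapping.

``path_length_oracle`` re-derives the same contract by exhaustive per-vertex
enumeration in plain Python with its own coordinate arithmetic; it shares no
code with ``path_length`` and exists to cross-check it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .spaces import AffineTransform, StreamlineSet, VolumeGrid, points_to_voxels

log = logging.getLogger(__name__)

DEFAULT_FILL = -1.0


@dataclass
class PathLengthMap:
    """Per-voxel minimum along-streamline distance (mm) back to the ROI."""

    grid: VolumeGrid          # carries dims / voxel_sizes / affine; values are the map
    fill: float = DEFAULT_FILL

    @property
    def values(self) -> np.ndarray:
        return self.grid.values

    def visited(self) -> np.ndarray:
        return self.grid.values != self.fill


def path_length(s: StreamlineSet, roi: VolumeGrid, a: AffineTransform,
                fill: float = DEFAULT_FILL) -> PathLengthMap:
    """Compute the WMPL map of ``s`` against the binary ROI mask ``roi``.

    ``a`` must reconcile ``roi``'s grid with the streamline space (see
    :func:`tractmargin.spaces.reconcile_affine`).  Raises ``ValueError`` on an
    empty ROI; an empty streamline set yields an all-fill map with a warning.
    """
    roi_vals = roi.values
    if not roi_vals.any():
        raise ValueError("ROI mask is empty")
    dims = roi.dims
    best = np.full(dims, np.inf)
    n_missed = 0
    for pts in s:
        idx, inb = points_to_voxels(pts, a, dims)
        interior = inb & (roi_vals[idx[:, 0], idx[:, 1], idx[:, 2]] > 0)
        if not interior.any():
            n_missed += 1
            continue
        seg = np.linalg.norm(np.diff(pts.astype(np.float64), axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        ci = cum[interior]  # ascending since cum is nondecreasing
        pos = np.searchsorted(ci, cum)
        d_lo = np.where(pos > 0, np.abs(cum - ci[np.maximum(pos - 1, 0)]), np.inf)
        d_hi = np.where(pos < len(ci), np.abs(ci[np.minimum(pos, len(ci) - 1)] - cum), np.inf)
        d = np.minimum(d_lo, d_hi)
        ii = idx[inb]
        np.minimum.at(best, (ii[:, 0], ii[:, 1], ii[:, 2]), d[inb])
    if len(s) == 0:
        log.warning("empty streamline set: WMPL map is all fill")
    elif n_missed:
        log.info("%d/%d streamlines never enter the ROI", n_missed, len(s))
    out = np.where(np.isinf(best), fill, best)
    return PathLengthMap(roi.with_values(out), fill=fill)


def path_length_oracle(s: StreamlineSet, roi: VolumeGrid, a: AffineTransform,
                       fill: float = DEFAULT_FILL) -> PathLengthMap:
    """Brute-force WMPL: exhaustive vertex-pair enumeration, independent code.

    Same contract as :func:`path_length`; kept deliberately naive (pure Python
    loops, its own affine/floor arithmetic) so it can serve as an oracle.
    """
    roi_vals = roi.values
    if not roi_vals.any():
        raise ValueError("ROI mask is empty")
    dims = roi.dims
    M = a.matrix
    # Recover the trk-grid geometry from the matrix: row norms are the trk
    # voxel sizes; the normalized 3x3 block is a signed permutation.
    vs = [math.sqrt(sum(M[t][g] ** 2 for g in range(3))) for t in range(3)]
    Pinv = [[0.0] * 3 for _ in range(3)]
    for t in range(3):
        for g in range(3):
            Pinv[g][t] = M[t][g] / vs[t]
    offs = [M[t][3] / vs[t] - 0.5 for t in range(3)]

    def voxel_of(p):
        trk = [math.floor(p[t] / vs[t]) for t in range(3)]
        g = [round(sum(Pinv[gax][t] * (trk[t] - offs[t]) for t in range(3))) for gax in range(3)]
        if all(0 <= g[ax] < dims[ax] for ax in range(3)):
            return (g[0], g[1], g[2])
        return None

    deposits: dict[tuple[int, int, int], float] = {}
    for pts in s:
        pts = [tuple(float(c) for c in p) for p in pts]
        cum = [0.0]
        for q0, q1 in zip(pts[:-1], pts[1:]):
            dx, dy, dz = q1[0] - q0[0], q1[1] - q0[1], q1[2] - q0[2]
            cum.append(cum[-1] + math.sqrt(dx * dx + dy * dy + dz * dz))
        voxels = [voxel_of(p) for p in pts]
        interior = [k for k, v in enumerate(voxels)
                    if v is not None and roi_vals[v] > 0]
        if not interior:
            continue
        for k, v in enumerate(voxels):
            if v is None:
                continue
            d = min(abs(cum[k] - cum[m]) for m in interior)
            if v not in deposits or d < deposits[v]:
                deposits[v] = d
    out = np.full(dims, fill, dtype=float)
    for v, d in deposits.items():
        out[v] = d
    return PathLengthMap(roi.with_values(out), fill=fill)


def densify(s: StreamlineSet, max_step: float) -> StreamlineSet:
    """Linearly interpolate vertices so no segment exceeds ``max_step`` mm.

    Total arc length is unchanged (to floating precision); polylines already
    satisfying the bound are returned as-is.
    """
    if max_step <= 0:
        raise ValueError("max_step must be positive")
    new = []
    for pts in s:
        seg = np.linalg.norm(np.diff(pts.astype(np.float64), axis=0), axis=1)
        if (seg <= max_step).all():
            new.append(pts)
            continue
        out = [pts[0:1].astype(np.float64)]
        for i, L in enumerate(seg):
            n = max(1, int(math.ceil(L / max_step)))
            t = np.linspace(0.0, 1.0, n + 1)[1:, None]
            out.append(pts[i].astype(np.float64) * (1 - t) + pts[i + 1] * t)
        new.append(np.vstack(out))  # float64: keeps arc length exact under splitting
    from .spaces import StreamlineHeader
    hdr = StreamlineHeader(s.header.dims, s.header.voxel_sizes.copy(), s.header.voxel_order)
    return StreamlineSet(new, hdr, s.space_tag)
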