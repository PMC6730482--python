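"""Synthetic tractography phantoms with analytically known geometry.

Real DW-MRI studies of this kind rest on patient imaging that cannot be
redistributed, so every stage here is exercised on phantoms instead: bundles
of streamlines along straight lines or circular arcs (optionally with
Gaussian lateral jitter), an FA corridor around each bundle, a tangent
direction field, and spherical or box ROIs — all on one voxel grid whose
world frame coincides with the TrackVis voxmm frame (corner origin, RAS),
so frame reconciliation is exact by construction.

What the phantoms emulate: bundle-shaped streamline sets with known arc
lengths, an FA map suitable for seeding/stopping, and tumour-like ROIs.
What they do not: diffusion signal, crossing fibres, scanner noise, or
anatomical priors — conclusions from phantom tests are about the geometry
pipeline, not about tractography fidelity on real data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .spaces import StreamlineHeader, StreamlineSet, VolumeGrid

log = logging.getLogger(__name__)


@dataclass
class BundleSpec:
    """One bundle: a line (start->end) or a circular arc in a coordinate plane.

    Arc geometry: center (mm), radius (mm), angles (start, end) in radians
    swept in the plane spanned by ``plane`` (two axis indices); e.g. the
    default plane (0, 1) is x-y.  ``spacing`` is the along-curve vertex
    spacing in mm; ``jitter_sd`` the lateral Gaussian jitter (truncated at
    3 sd, applied orthogonally to the tangent).
    """

    kind: str = "line"                      # "line" | "arc"
    start: tuple[float, float, float] = (0.0, 0.0, 0.0)
    end: tuple[float, float, float] = (1.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius: float = 10.0
    angles: tuple[float, float] = (0.0, np.pi / 2)
    plane: tuple[int, int] = (0, 1)
    n_streamlines: int = 1
    spacing: float = 1.0
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("line", "arc"):
            raise ValueError(f"unknown bundle kind {self.kind!r}")
        if self.spacing <= 0:
            raise ValueError("vertex spacing must be positive")

    def arc_length(self) -> float:
        if self.kind == "line":
            return float(np.linalg.norm(np.subtract(self.end, self.start)))
        return float(self.radius * abs(self.angles[1] - self.angles[0]))

    def n_vertices(self) -> int:
        n_seg = max(1, int(np.ceil(self.arc_length() / self.spacing - 1e-9)))
        return n_seg + 1

    def centerline(self, n: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(points, unit tangents) at ``n`` parameters equally spaced in arc length."""
        n = n or self.n_vertices()
        t = np.linspace(0.0, 1.0, n)
        if self.kind == "line":
            a, b = np.asarray(self.start, float), np.asarray(self.end, float)
            pts = a + t[:, None] * (b - a)
            tan = np.tile((b - a) / np.linalg.norm(b - a), (n, 1))
            return pts, tan
        th = self.angles[0] + t * (self.angles[1] - self.angles[0])
        u, v = self.plane
        pts = np.tile(np.asarray(self.center, float), (n, 1))
        pts[:, u] += self.radius * np.cos(th)
        pts[:, v] += self.radius * np.sin(th)
        tan = np.zeros((n, 3))
        sgn = np.sign(self.angles[1] - self.angles[0]) or 1.0
        tan[:, u] = -np.sin(th) * sgn
        tan[:, v] = np.cos(th) * sgn
        return pts, tan


@dataclass
class RoiSpec:
    """Sphere (center, radius in mm) or box (world-mm corner bounds)."""

    shape: str = "sphere"                   # "sphere" | "box"
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius: float = 5.0
    bounds: tuple[tuple[float, float], ...] = ((0, 1), (0, 1), (0, 1))
    role: str = "generic"                   # GTV | brain | recurrence | generic


@dataclass
class PhantomSpec:
    dims: tuple[int, int, int] = (32, 32, 32)
    voxel_sizes: tuple[float, float, float] = (1.0, 1.0, 1.0)
    bundles: list[BundleSpec] = field(default_factory=list)
    rois: dict[str, RoiSpec] = field(default_factory=dict)
    seed: int = 0
    fa_inside: float = 0.8
    corridor_voxels: float = 2.0


@dataclass
class Phantom:
    streamlines: StreamlineSet
    fa: VolumeGrid
    directions: np.ndarray
    rois: dict[str, VolumeGrid]
    spec: PhantomSpec


def _grid_affine(spec: PhantomSpec) -> np.ndarray:
    # world == voxmm: voxel centers at (i + 0.5) * vs, RAS axes
    A = np.diag(list(spec.voxel_sizes) + [1.0])
    A[:3, 3] = 0.5 * np.asarray(spec.voxel_sizes)
    return A


def _voxel_centers(spec: PhantomSpec) -> np.ndarray:
    vs = np.asarray(spec.voxel_sizes)
    grids = np.meshgrid(*[(np.arange(d) + 0.5) * s for d, s in zip(spec.dims, vs)],
                        indexing="ij")
    return np.stack(grids, axis=-1)


def make_roi(spec: PhantomSpec, roi: RoiSpec) -> VolumeGrid:
    centers = _voxel_centers(spec)
    if roi.shape == "sphere":
        mask = np.linalg.norm(centers - np.asarray(roi.center), axis=-1) <= roi.radius
    elif roi.shape == "box":
        b = np.asarray(roi.bounds, dtype=float)
        mask = np.all((centers >= b[:, 0]) & (centers <= b[:, 1]), axis=-1)
    else:
        raise ValueError(f"unknown ROI shape {roi.shape!r}")
    return VolumeGrid(mask.astype(np.uint8), np.asarray(spec.voxel_sizes, float),
                      _grid_affine(spec), "RAS")


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Build the phantom deterministically from the spec (seed included).

    Raises ``ValueError`` naming the bundle when a centerline leaves the grid.
    """
    rng = np.random.default_rng(spec.seed)
    vs = np.asarray(spec.voxel_sizes, float)
    extent = np.asarray(spec.dims) * vs
    polylines: list[np.ndarray] = []
    dense_pts: list[np.ndarray] = []
    dense_tan: list[np.ndarray] = []
    for b_i, b in enumerate(spec.bundles):
        pts, tan = b.centerline()
        if (pts < 0).any() or (pts >= extent).any():
            raise ValueError(f"bundle {b_i} ({b.kind}) leaves the grid "
                             f"(extent {extent} mm)")
        # dense sampling for FA corridor / direction field
        dpts, dtan = b.centerline(max(2, int(np.ceil(b.arc_length() / (vs.min() / 4))) + 1))
        dense_pts.append(dpts)
        dense_tan.append(dtan)
        for _ in range(b.n_streamlines):
            if b.jitter_sd > 0:
                # constant lateral offset per streamline in the orthogonal frame,
                # truncated at 3 sd so curves stay in-grid by construction
                coeff = rng.normal(0.0, b.jitter_sd, size=2)
                coeff = np.clip(coeff, -3 * b.jitter_sd, 3 * b.jitter_sd)
                offset_pts = []
                for p, tg in zip(pts, tan):
                    u = _orthonormal(tg)
                    w = np.cross(tg, u)
                    offset_pts.append(p + coeff[0] * u + coeff[1] * w)
                line = np.asarray(offset_pts)
            else:
                line = pts.copy()
            polylines.append(line.astype(np.float32))
    hdr = StreamlineHeader(spec.dims, vs.copy(), "RAS")
    streamlines = StreamlineSet(polylines, hdr)

    fa_vals = np.zeros(spec.dims, dtype=float)
    directions = np.zeros(spec.dims + (3,), dtype=float)
    if dense_pts:
        allpts = np.vstack(dense_pts)
        alltan = np.vstack(dense_tan)
        curve_mask = np.zeros(spec.dims, dtype=bool)
        idx = np.floor(allpts / vs).astype(int)
        idx = np.clip(idx, 0, np.asarray(spec.dims) - 1)
        curve_mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        # corridor: within corridor_voxels (voxel units) of the rasterized curve
        dist, nearest = ndimage.distance_transform_edt(
            ~curve_mask, return_indices=True)
        corridor = dist <= spec.corridor_voxels
        fa_vals[corridor] = spec.fa_inside
        # direction: tangent of the nearest curve voxel (one tangent per voxel)
        tan_vol = np.zeros(spec.dims + (3,))
        tan_vol[idx[:, 0], idx[:, 1], idx[:, 2]] = alltan
        ni, nj, nk = nearest
        directions[corridor] = tan_vol[ni[corridor], nj[corridor], nk[corridor]]
        norms = np.linalg.norm(directions, axis=-1, keepdims=True)
        np.divide(directions, norms, out=directions, where=norms > 0)

    fa = VolumeGrid(fa_vals, vs.copy(), _grid_affine(spec), "RAS")
    rois = {name: make_roi(spec, r) for name, r in spec.rois.items()}
    return Phantom(streamlines, fa, directions, rois, spec)


def _orthonormal(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, float)
    ref = np.array([0.0, 0.0, 1.0]) if abs(t[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(t, ref)
    return u / np.linalg.norm(u)


def expected_wmpl(spec: PhantomSpec, roi: VolumeGrid,
                  fine_step: float = 0.05) -> dict[tuple[int, int, int], tuple[float, float]]:
    """Analytic per-voxel WMPL expectations for noiseless bundles.

    For every voxel the centerlines pass through, returns
    ``(expected_mm, tolerance_mm)`` where the expectation is the arc distance
    from that voxel's curve samples to the nearest ROI-interior stretch of the
    curve, and the tolerance is the vertex-spacing discretization bound
    (one vertex spacing, plus the in-voxel arc spread).  Refuses jittered
    bundles — their geometry has no closed form.
    """
    vs = np.asarray(spec.voxel_sizes, float)
    dims = np.asarray(spec.dims)
    out: dict[tuple[int, int, int], tuple[float, float]] = {}
    for b in spec.bundles:
        if b.jitter_sd > 0:
            raise ValueError("expected_wmpl is defined only for jitter-free bundles")
        L = b.arc_length()
        n = max(2, int(np.ceil(L / fine_step)) + 1)
        pts, _ = b.centerline(n)
        s = np.linspace(0.0, L, n)
        idx = np.floor(pts / vs).astype(int)
        inb = ((idx >= 0) & (idx < dims)).all(axis=1)
        interior = np.zeros(n, dtype=bool)
        interior[inb] = roi.values[idx[inb, 0], idx[inb, 1], idx[inb, 2]] > 0
        if not interior.any():
            continue
        si = s[interior]
        pos = np.searchsorted(si, s)
        d_lo = np.where(pos > 0, np.abs(s - si[np.maximum(pos - 1, 0)]), np.inf)
        d_hi = np.where(pos < len(si), np.abs(si[np.minimum(pos, len(si) - 1)] - s), np.inf)
        d = np.minimum(d_lo, d_hi)
        per_voxel: dict[tuple[int, int, int], list[float]] = {}
        for k in np.flatnonzero(inb):
            per_voxel.setdefault(tuple(idx[k]), []).append(d[k])
        for v, ds in per_voxel.items():
            exp = float(min(ds))
            tol = b.spacing + (float(max(ds)) - exp) + fine_step
            prev = out.get(v)
            if prev is None or exp < prev[0]:
                out[v] = (exp, tol)
    return out
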