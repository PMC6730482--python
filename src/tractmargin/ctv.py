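"""Anisotropic clinical target volume (CTV) construction from WMPL maps.

The anisotropic CTV for an expansion path length (EPL) is::

    CTV_dwMRI(epl) = dilate( GTV  U  { WMPL <= epl } , r ) ∩ brain

where the dilation is *metric*: a voxel joins the dilated set iff its center
lies within ``r`` world-millimetres (Euclidean) of some source-voxel center,
computed with a distance transform so the result is exact under anisotropic
voxels.  The isotropic control is ``dilate(GTV, margin) ∩ brain``.

``compare_ctvs`` reports world-mm^3 volumes, the percent volume difference,
and the fraction of a recurrence mask covered by each CTV.
``extract_slice_contours`` converts masks to per-axial-slice closed polygons
in world mm (a vendor-neutral stand-in for planning-system contour export).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .spaces import VolumeGrid
from .wmpl import PathLengthMap

log = logging.getLogger(__name__)


@dataclass
class ExpansionConfig:
    """Margins, in mm: EPL thresholds, the island-suppressing expansion, and
    the isotropic control margin."""

    epl_list: tuple[float, ...] = (10.0, 20.0, 30.0)
    expansion_radius: float = 5.0
    isotropic_margin: float = 20.0
    clip_isotropic_to_brain: bool = True

    def __post_init__(self) -> None:
        epl = tuple(float(e) for e in self.epl_list)
        if any(e <= 0 for e in epl) or list(epl) != sorted(set(epl)):
            raise ValueError("epl_list must be strictly positive and strictly increasing")
        if self.expansion_radius <= 0 or self.isotropic_margin <= 0:
            raise ValueError("expansion_radius and isotropic_margin must be positive")
        self.epl_list = epl


@dataclass
class CtvSet:
    """Per-EPL anisotropic masks plus the isotropic control, with provenance."""

    anisotropic: dict[float, VolumeGrid]
    isotropic: VolumeGrid
    config: ExpansionConfig
    provenance: dict = field(default_factory=dict)


def threshold_wmpl(w: PathLengthMap, epl: float) -> VolumeGrid:
    """Binary mask of visited voxels with WMPL <= ``epl`` (0 included, fill excluded)."""
    if epl <= 0:
        raise ValueError("epl must be positive")
    v = w.values
    mask = (v != w.fill) & (v >= 0) & (v <= epl)
    return w.grid.with_values(mask.astype(np.uint8))


def metric_dilate(mask: VolumeGrid, radius_mm: float) -> VolumeGrid:
    """Euclidean dilation in world mm: keep voxels whose center is within
    ``radius_mm`` of a source-voxel center (distance transform, exact for
    anisotropic voxels)."""
    src = mask.values > 0
    if radius_mm == 0:
        return mask.with_values(src.astype(np.uint8))
    dist = ndimage.distance_transform_edt(~src, sampling=mask.voxel_sizes)
    return mask.with_values((dist <= radius_mm).astype(np.uint8))


def build_anisotropic_ctv(w: PathLengthMap, gtv: VolumeGrid, brain: VolumeGrid,
                          epl: float, r: float = 5.0) -> VolumeGrid:
    """((GTV U thresholded-WMPL) dilated by ``r`` mm) clipped to the brain."""
    if not gtv.values.any():
        raise ValueError("GTV mask is empty")
    for name, m in (("GTV", gtv), ("brain", brain)):
        if not w.grid.same_grid_as(m):
            raise ValueError(f"{name} mask is not on the WMPL grid")
    union = (gtv.values > 0) | (threshold_wmpl(w, epl).values > 0)
    dilated = metric_dilate(gtv.with_values(union.astype(np.uint8)), r)
    out = (dilated.values > 0) & (brain.values > 0)
    return gtv.with_values(out.astype(np.uint8))


def build_isotropic_ctv(gtv: VolumeGrid, brain: VolumeGrid, margin: float = 20.0,
                        clip_to_brain: bool = True) -> VolumeGrid:
    """Isotropic control: GTV dilated by ``margin`` mm, clipped to the brain."""
    if not gtv.values.any():
        raise ValueError("GTV mask is empty")
    dilated = metric_dilate(gtv, margin)
    out = dilated.values > 0
    if clip_to_brain:
        out &= brain.values > 0
    return gtv.with_values(out.astype(np.uint8))


def build_ctv_set(w: PathLengthMap, gtv: VolumeGrid, brain: VolumeGrid,
                  cfg: ExpansionConfig | None = None) -> CtvSet:
    """One anisotropic CTV per configured EPL plus the isotropic control."""
    cfg = cfg or ExpansionConfig()
    aniso = {epl: build_anisotropic_ctv(w, gtv, brain, epl, cfg.expansion_radius)
             for epl in cfg.epl_list}
    iso = build_isotropic_ctv(gtv, brain, cfg.isotropic_margin,
                              clip_to_brain=cfg.clip_isotropic_to_brain)
    return CtvSet(aniso, iso, cfg)


def mask_volume_mm3(mask: VolumeGrid) -> float:
    return float((mask.values > 0).sum()) * float(np.prod(mask.voxel_sizes))


def compare_ctvs(a: VolumeGrid, b: VolumeGrid, recurrence: VolumeGrid | None = None) -> dict:
    """Volumes (mm^3), percent volume difference ``100*(vol(a)-vol(b))/vol(b)``,
    and per-mask recurrence coverage fractions.

    Note the percent difference is only antisymmetric under argument swap up
    to the change of denominator.  An empty (or absent) recurrence mask
    reports coverage as None.
    """
    va, vb = mask_volume_mm3(a), mask_volume_mm3(b)
    rec = {"coverage_a": None, "coverage_b": None}
    if recurrence is not None and recurrence.values.any():
        vr = float((recurrence.values > 0).sum())
        rec["coverage_a"] = float(((recurrence.values > 0) & (a.values > 0)).sum()) / vr
        rec["coverage_b"] = float(((recurrence.values > 0) & (b.values > 0)).sum()) / vr
    return {
        "volume_a_mm3": va,
        "volume_b_mm3": vb,
        "percent_difference": 100.0 * (va - vb) / vb if vb else float("nan"),
        **rec,
    }


def _point_in_loops(loops: list[np.ndarray], x: float, y: float) -> bool:
    # even-odd rule over all loops of one slice
    inside = False
    for loop in loops:
        x0, y0 = loop[:, 0], loop[:, 1]
        x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
        crossing = (y0 > y) != (y1 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x0 + (y - y0) / (y1 - y0) * (x1 - x0)
        if bool(np.count_nonzero(crossing & (xint > x)) % 2):
            inside = not inside
    return inside


def extract_slice_contours(m: VolumeGrid) -> dict[int, list[np.ndarray]]:
    """Closed contour polygons per axial (k) slice, vertices in world mm.

    Marching squares at level 0.5 on each binary slice; contour loops pass
    through voxel-edge midpoints, so voxel centers are never on an edge and
    even-odd rasterization of the polygons recovers the mask exactly at
    voxel-center sampling (holes come out as separate loops).
    """
    out: dict[int, list[np.ndarray]] = {}
    A = m.affine
    for k in range(m.dims[2]):
        sl = (m.values[:, :, k] > 0).astype(float)
        if not sl.any():
            continue
        padded = np.pad(sl, 1)
        loops = []
        for c in measure.find_contours(padded, 0.5):
            ij = c - 1.0  # undo padding; columns are (i, j) index coordinates
            pts = np.column_stack([ij, np.full(len(ij), float(k))])
            world = pts @ A[:3, :3].T + A[:3, 3]
            loops.append(world)
        out[k] = loops
    return out


def rasterize_slice_contours(contours: dict[int, list[np.ndarray]],
                             like: VolumeGrid) -> VolumeGrid:
    """Even-odd rasterization of :func:`extract_slice_contours` output back to
    a mask on ``like``'s grid (exact at voxel-center sampling)."""
    inv = np.linalg.inv(like.affine)
    out = np.zeros(like.dims, dtype=np.uint8)
    for k, loops in contours.items():
        idx_loops = [w @ inv[:3, :3].T + inv[:3, 3] for w in loops]
        idx_loops = [l[:, :2] for l in idx_loops]
        for i in range(like.dims[0]):
            for j in range(like.dims[1]):
                if _point_in_loops(idx_loops, float(i), float(j)):
                    out[i, j, k] = 1
    return like.with_values(out)
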