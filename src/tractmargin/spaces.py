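"""Volumes, streamlines, and the coordinate frames that connect them.

Two spaces matter throughout the package:

* **grid index space** — integer voxel indices ``(i, j, k)`` of a NIfTI
  volume, with an ``axis_codes`` anatomical orientation label (e.g. RAS).
* **streamline point space** ("voxmm") — the TrackVis convention: points are
  voxel-size-scaled with a *corner* origin, so voxel ``(i, j, k)`` of the
  header's grid spans the half-open box
  ``[i*vs_x, (i+1)*vs_x) x [j*vs_y, (j+1)*vs_y) x [k*vs_z, (k+1)*vs_z)``,
  in the axis order declared by the header's ``voxel_order``.

``reconcile_affine`` builds the 4x4 map between the two, deriving any axis
permutation and flips from the orientation labels alone, so equal-dimension
cubic grids reconcile correctly.  ``point_to_voxel`` inverts it with a floor
convention: a point exactly on a box boundary belongs to the higher-index
voxel of the streamline grid.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

log = logging.getLogger(__name__)

_AXIS_LETTER_PAIRS = {"R": "L", "L": "R", "A": "P", "P": "A", "S": "I", "I": "S"}
_AXIS_OF_LETTER = {"R": 0, "L": 0, "A": 1, "P": 1, "S": 2, "I": 2}


class FormatError(ValueError):
    """A file failed structural validation (bad header field, truncation)."""


class ReconcileError(ValueError):
    """Grid and streamline header describe irreconcilable volumes."""


def _check_axcodes(codes: str) -> str:
    codes = codes.upper()
    if len(codes) != 3 or any(c not in _AXIS_OF_LETTER for c in codes):
        raise ValueError(f"invalid orientation label {codes!r}")
    if sorted(_AXIS_OF_LETTER[c] for c in codes) != [0, 1, 2]:
        raise ValueError(f"orientation label {codes!r} repeats an anatomical axis")
    return codes


@dataclass
class VolumeGrid:
    """A 3-D scalar or binary lattice with voxel sizes (mm) and a voxel->world affine."""

    values: np.ndarray
    voxel_sizes: np.ndarray
    affine: np.ndarray
    axis_codes: str = "RAS"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D lattice, got ndim={self.values.ndim}")
        self.voxel_sizes = np.asarray(self.voxel_sizes, dtype=float)
        if self.voxel_sizes.shape != (3,) or not (self.voxel_sizes > 0).all():
            raise ValueError("voxel_sizes must be 3 positive lengths (mm)")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.allclose(self.affine[3], [0, 0, 0, 1]):
            raise ValueError("affine bottom row must be (0,0,0,1)")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        col_norms = np.linalg.norm(self.affine[:3, :3], axis=0)
        if not np.allclose(col_norms, self.voxel_sizes, rtol=1e-6):
            raise ValueError(
                f"affine column norms {col_norms} disagree with voxel sizes {self.voxel_sizes}"
            )
        self.axis_codes = _check_axcodes(self.axis_codes)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def is_mask(self) -> bool:
        return bool(np.isin(self.values, (0, 1)).all())

    def with_values(self, values: np.ndarray) -> "VolumeGrid":
        return VolumeGrid(values, self.voxel_sizes.copy(), self.affine.copy(), self.axis_codes)

    def same_grid_as(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.voxel_sizes, other.voxel_sizes, atol=atol)
            and np.allclose(self.affine, other.affine, atol=atol)
        )


@dataclass
class StreamlineHeader:
    """TRK-style header metadata: grid shape, voxel sizes (mm), axis order."""

    dims: tuple[int, int, int]
    voxel_sizes: np.ndarray
    voxel_order: str
    n_streamlines: int = 0

    def __post_init__(self) -> None:
        self.dims = tuple(int(d) for d in self.dims)  # type: ignore[assignment]
        if len(self.dims) != 3 or any(d <= 0 for d in self.dims):
            raise ValueError(f"dims must be 3 positive integers, got {self.dims}")
        self.voxel_sizes = np.asarray(self.voxel_sizes, dtype=float)
        if self.voxel_sizes.shape != (3,) or not (self.voxel_sizes > 0).all():
            raise ValueError("voxel_sizes must be 3 positive lengths (mm)")
        self.voxel_order = _check_axcodes(self.voxel_order)


@dataclass
class StreamlineSet:
    """Ordered 3-D polylines in streamline point space (voxmm, corner origin)."""

    polylines: list[np.ndarray]
    header: StreamlineHeader
    space_tag: str = "voxmm"

    def __post_init__(self) -> None:
        cleaned = []
        n_dedup = 0
        for p in self.polylines:
            p = np.asarray(p)
            if p.dtype not in (np.float32, np.float64):
                p = p.astype(np.float64)
            if p.ndim != 2 or p.shape[1] != 3:
                raise ValueError("each polyline must be an (n, 3) array")
            keep = np.ones(len(p), dtype=bool)
            keep[1:] = np.any(p[1:] != p[:-1], axis=1)
            if not keep.all():
                n_dedup += int((~keep).sum())
                p = p[keep]
            if len(p) < 2:
                raise ValueError("each polyline needs >= 2 distinct points")
            cleaned.append(p)
        if n_dedup:
            log.info("removed %d consecutive duplicate vertices on load", n_dedup)
        self.polylines = cleaned
        self.header.n_streamlines = len(cleaned)

    def __len__(self) -> int:
        return len(self.polylines)

    def __iter__(self):
        return iter(self.polylines)

    def subset(self, indices: Sequence[int]) -> "StreamlineSet":
        hdr = StreamlineHeader(self.header.dims, self.header.voxel_sizes.copy(),
                               self.header.voxel_order)
        return StreamlineSet([self.polylines[i].copy() for i in indices], hdr, self.space_tag)

    def lengths_mm(self) -> np.ndarray:
        """Arc length of each polyline (sum of Euclidean segment lengths)."""
        return np.array([
            float(np.linalg.norm(np.diff(p.astype(np.float64), axis=0), axis=1).sum())
            for p in self.polylines
        ])


@dataclass
class AffineTransform:
    """4x4 homogeneous map: grid voxel indices -> streamline point coordinates."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("matrix must be 4x4")
        if not np.allclose(self.matrix[3], [0, 0, 0, 1]):
            raise ValueError("bottom row must be (0,0,0,1)")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("matrix is not invertible")

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return points @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))


# ---------------------------------------------------------------------------
# TRK v2 codec.  The header is a fixed little-endian 1000-byte struct; each
# streamline is int32 point count followed by float32 xyz triples (plus any
# per-point scalars / per-track properties, which this package neither reads
# nor writes).  Points are kept bit-faithful in the file's native voxmm space.
# ---------------------------------------------------------------------------

_TRK_HEADER_SIZE = 1000
_TRK_MAGIC = b"TRACK"


def read_streamlines(path: str | Path) -> StreamlineSet:
    """Read a TrackVis TRK v2 file, preserving native voxmm coordinates exactly.

    Raises :class:`FormatError` naming the offending field on a malformed
    header or truncated payload.  Zero streamlines yield an empty set with a
    logged warning, not an error.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _TRK_HEADER_SIZE:
        raise FormatError(f"{path}: file shorter than the {_TRK_HEADER_SIZE}-byte TRK header")
    if raw[:5] != _TRK_MAGIC:
        raise FormatError(f"{path}: bad id_string (magic) field, not a TRK file")
    dims = struct.unpack_from("<3h", raw, 6)
    voxel_sizes = struct.unpack_from("<3f", raw, 12)
    voxel_order = raw[948:952].split(b"\x00")[0].decode("ascii", "replace")
    n_scalars = struct.unpack_from("<h", raw, 36)[0]
    n_props = struct.unpack_from("<h", raw, 238)[0]
    n_count = struct.unpack_from("<i", raw, 988)[0]
    version = struct.unpack_from("<i", raw, 992)[0]
    hdr_size = struct.unpack_from("<i", raw, 996)[0]
    if hdr_size != _TRK_HEADER_SIZE:
        raise FormatError(f"{path}: hdr_size field is {hdr_size}, expected {_TRK_HEADER_SIZE}")
    if version != 2:
        raise FormatError(f"{path}: version field is {version}, only TRK v2 is supported")
    if any(d <= 0 for d in dims):
        raise FormatError(f"{path}: dim field {dims} is not strictly positive")
    if any(v <= 0 for v in voxel_sizes):
        raise FormatError(f"{path}: voxel_size field {voxel_sizes} is not strictly positive")
    if n_scalars < 0 or n_props < 0:
        raise FormatError(f"{path}: negative n_scalars/n_properties")
    try:
        voxel_order = _check_axcodes(voxel_order)
    except ValueError as e:
        raise FormatError(f"{path}: voxel_order field: {e}") from e

    polylines: list[np.ndarray] = []
    off = _TRK_HEADER_SIZE
    ptsize = (3 + n_scalars) * 4
    while off < len(raw):
        if off + 4 > len(raw):
            raise FormatError(f"{path}: truncated streamline count at byte {off}")
        (npts,) = struct.unpack_from("<i", raw, off)
        off += 4
        if npts <= 0:
            raise FormatError(f"{path}: nonpositive point count {npts}")
        need = npts * ptsize + n_props * 4
        if off + need > len(raw):
            raise FormatError(f"{path}: truncated streamline payload at byte {off}")
        block = np.frombuffer(raw, dtype="<f4", count=npts * (3 + n_scalars), offset=off)
        pts = block.reshape(npts, 3 + n_scalars)[:, :3].copy()
        polylines.append(pts)
        off += need
    if n_count not in (0, len(polylines)):
        raise FormatError(
            f"{path}: n_count field says {n_count} streamlines but payload holds {len(polylines)}"
        )
    if not polylines:
        log.warning("%s: TRK file contains zero streamlines", path)
    header = StreamlineHeader(dims, voxel_sizes, voxel_order, len(polylines))
    return StreamlineSet(polylines, header)


def write_streamlines(s: StreamlineSet, path: str | Path) -> None:
    """Write a TRK v2 file; re-reading yields an equal set (bit-faithful points)."""
    path = Path(path)
    hdr = bytearray(_TRK_HEADER_SIZE)
    hdr[0:5] = _TRK_MAGIC
    struct.pack_into("<3h", hdr, 6, *s.header.dims)
    struct.pack_into("<3f", hdr, 12, *s.header.voxel_sizes)
    hdr[948:951] = s.header.voxel_order.encode("ascii")
    # image_orientation_patient + a voxel->ras affine consistent with voxmm
    # corner-origin, so third-party readers place the points sensibly.
    vox2ras = np.diag(list(s.header.voxel_sizes) + [1.0]).astype("<f4")
    struct.pack_into("<16f", hdr, 440, *vox2ras.ravel())
    struct.pack_into("<6f", hdr, 956, 1, 0, 0, 0, 1, 0)
    struct.pack_into("<i", hdr, 988, len(s.polylines))
    struct.pack_into("<i", hdr, 992, 2)
    struct.pack_into("<i", hdr, 996, _TRK_HEADER_SIZE)
    with open(path, "wb") as f:
        f.write(hdr)
        for p in s.polylines:
            f.write(struct.pack("<i", len(p)))
            f.write(np.ascontiguousarray(p, dtype="<f4").tobytes())


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def read_volume(path: str | Path, binarize: bool = False) -> VolumeGrid:
    """Read a NIfTI-1 volume.  With ``binarize``, values > 0 become 1 (logged)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4:
        if data.shape[3] != 1:
            raise ValueError(f"{path}: 4-D input with {data.shape[3]} volumes; expected one")
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    affine = np.asarray(img.affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError(f"{path}: non-invertible affine")
    axis_codes = "".join(nib.orientations.aff2axcodes(affine))
    voxel_sizes = np.linalg.norm(affine[:3, :3], axis=0)
    if binarize:
        nonbinary = int((~np.isin(data, (0, 1))).sum())
        if nonbinary:
            log.warning("%s: binarized %d nonbinary voxels at > 0", path, nonbinary)
        data = (data > 0).astype(np.uint8)
    return VolumeGrid(data, voxel_sizes, affine, axis_codes)


def write_volume(grid: VolumeGrid, path: str | Path, dtype=None) -> None:
    data = grid.values if dtype is None else grid.values.astype(dtype)
    nib.save(nib.Nifti1Image(data, grid.affine), str(path))


# ---------------------------------------------------------------------------
# Frame reconciliation
# ---------------------------------------------------------------------------

def _axis_map(grid_codes: str, trk_codes: str) -> tuple[np.ndarray, np.ndarray]:
    """Per grid axis g: the streamline axis it feeds and whether it is flipped.

    Returns (perm, flip): trk axis ``perm[g]`` runs along grid axis ``g``;
    ``flip[g]`` is True when the two labels point in opposite anatomical
    directions.
    """
    perm = np.zeros(3, dtype=int)
    flip = np.zeros(3, dtype=bool)
    for g, letter in enumerate(grid_codes):
        anat = _AXIS_OF_LETTER[letter]
        for t, tl in enumerate(trk_codes):
            if _AXIS_OF_LETTER[tl] == anat:
                perm[g] = t
                flip[g] = tl != letter
                break
    return perm, flip


def reconcile_affine(h: StreamlineHeader, g: VolumeGrid) -> AffineTransform:
    """4x4 map sending grid voxel index (i,j,k) to the *center* of the
    corresponding voxel in streamline point space (voxmm, corner origin).

    The axis permutation and flips come from the orientation labels
    (``h.voxel_order`` vs ``g.axis_codes``), never from shape heuristics, so
    cubic grids reconcile correctly.  Raises :class:`ReconcileError` when the
    two descriptions cannot refer to the same physical volume.
    """
    perm, flip = _axis_map(g.axis_codes, h.voxel_order)
    gdims = np.array(g.dims)
    hdims = np.array(h.dims)
    if not (hdims[perm] == gdims).all():
        raise ReconcileError(
            f"grid dims {tuple(g.dims)} ({g.axis_codes}) do not match streamline header "
            f"dims {tuple(h.dims)} ({h.voxel_order}) under the label-derived permutation"
        )
    if not np.allclose(h.voxel_sizes[perm], g.voxel_sizes, atol=1e-3):
        raise ReconcileError(
            f"voxel sizes disagree beyond 1e-3 mm: grid {g.voxel_sizes} vs "
            f"header {h.voxel_sizes} (permuted {h.voxel_sizes[perm]})"
        )
    # trk_index[perm[g]] = grid_index[g]            (same direction)
    #                    = dims[g]-1 - grid_index[g] (flipped)
    M = np.zeros((4, 4))
    M[3, 3] = 1.0
    vs = h.voxel_sizes
    for gax in range(3):
        tax = perm[gax]
        sgn = -1.0 if flip[gax] else 1.0
        M[tax, gax] = sgn * vs[tax]
        offset = (gdims[gax] - 1) if flip[gax] else 0.0
        M[tax, 3] += vs[tax] * (offset + 0.5)
    return AffineTransform(M)


def point_to_voxel(p: np.ndarray, a: AffineTransform,
                   dims: tuple[int, int, int] | None = None):
    """Grid voxel index of one streamline-space point, floor convention.

    The point is binned on the streamline grid (``floor(coord / voxel_size)``,
    boundary points to the higher-index voxel) and the integer index mapped
    back through the reconciliation.  With ``dims`` given, a point outside the
    grid returns ``None`` (an out-of-bounds sentinel, not an exception).
    """
    idx, inb = points_to_voxels(np.asarray(p, dtype=float)[None, :], a,
                                dims if dims is not None else (1 << 30,) * 3)
    if dims is not None and not inb[0]:
        return None
    return tuple(int(v) for v in idx[0])


def points_to_voxels(points: np.ndarray, a: AffineTransform,
                     dims: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized voxel binning: (indices (n,3) int array, in-bounds mask).

    Indices of out-of-bounds points are clipped into range; use the mask.
    """
    M = a.matrix
    vs_trk = np.linalg.norm(M[:3, :3], axis=1)  # row norms: signed-permutation scale
    P = M[:3, :3] / vs_trk[:, None]             # signed permutation, entries in {0, +-1}
    c = M[:3, 3] / vs_trk - 0.5                 # integer flip offsets on trk axes
    trk_idx = np.floor(np.asarray(points, dtype=float) / vs_trk).astype(np.int64)
    grid_idx = np.rint((trk_idx - c) @ np.linalg.inv(P).T).astype(np.int64)
    dims_arr = np.asarray(dims)
    inb = ((grid_idx >= 0) & (grid_idx < dims_arr)).all(axis=1)
    return np.clip(grid_idx, 0, dims_arr - 1), inb
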