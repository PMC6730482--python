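"""End-to-end orchestration: streamlines + GTV -> WMPL map -> CTV masks.

The pipeline stages are exactly the library calls a user could make by hand
(load -> reconcile -> target -> optional CCI filter -> densify ->
path_length -> write; then threshold/union/dilate/clip for the CTVs); this
module adds configuration, per-stage logging, and provenance (every run
writes its resolved config beside its outputs, and re-running from that file
reproduces the outputs bit-identically).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ctv as ctv_mod
from . import select as select_mod
from .spaces import ReconcileError, read_streamlines, read_volume, reconcile_affine, write_volume
from .wmpl import DEFAULT_FILL, PathLengthMap, densify, path_length

log = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_INPUT = 2
EXIT_RECONCILE = 3
EXIT_INTERNAL = 4


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str, exit_code: int = EXIT_INPUT):
        super().__init__(f"[{stage}] {detail}")
        self.stage = stage
        self.exit_code = exit_code


@dataclass
class RunConfig:
    streamlines: str | None = None
    gtv: str | None = None
    brain: str | None = None
    recurrence: str | None = None
    wmpl: str | None = None
    out_dir: str = "."
    fill: float = DEFAULT_FILL
    densify_max_step: float | None = None   # default: half the smallest voxel size
    cci_filter: bool = False                # opt-in; see methods note
    cci_subsample_n: int = 12
    cci_power: float = 1.0
    cci_max_dist: float = 5.0
    cci_threshold: float = 1.0
    expansion: ctv_mod.ExpansionConfig = field(default_factory=ctv_mod.ExpansionConfig)
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["expansion"]["epl_list"] = list(d["expansion"]["epl_list"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        exp = d.pop("expansion", None)
        cfg = cls(**d)
        if exp is not None:
            exp["epl_list"] = tuple(exp["epl_list"])
            cfg.expansion = ctv_mod.ExpansionConfig(**exp)
        return cfg


def _require(path: str | None, stage: str, what: str) -> Path:
    if path is None:
        raise StageError(stage, f"no {what} configured")
    p = Path(path)
    if not p.exists():
        raise StageError(stage, f"{what} file not found: {p}")
    return p


def run_wmpl(cfg: RunConfig) -> PathLengthMap:
    """Execute the WMPL pipeline and write the map + provenance to out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trk_path = _require(cfg.streamlines, "load-streamlines", "streamline (TRK)")
    gtv_path = _require(cfg.gtv, "load-gtv", "GTV mask")
    try:
        s = read_streamlines(trk_path)
    except Exception as e:
        raise StageError("load-streamlines", str(e)) from e
    try:
        gtv = read_volume(gtv_path, binarize=True)
    except Exception as e:
        raise StageError("load-gtv", str(e)) from e
    log.info("[load] %d streamlines; GTV %d voxels", len(s), int(gtv.values.sum()))
    try:
        aff = reconcile_affine(s.header, gtv)
    except ReconcileError as e:
        raise StageError("reconcile", str(e), EXIT_RECONCILE) from e

    targeted = select_mod.target_streamlines(s, gtv, aff)
    log.info("[target] kept %d/%d streamlines", len(targeted), len(s))
    if cfg.cci_filter and len(targeted) >= 2:
        scores = select_mod.cluster_confidence(
            targeted, cfg.cci_subsample_n, cfg.cci_power, cfg.cci_max_dist)
        targeted = select_mod.filter_by_cci(targeted, scores, cfg.cci_threshold)
        log.info("[cci] kept %d streamlines", len(targeted))

    max_step = cfg.densify_max_step
    if max_step is None:
        max_step = 0.5 * float(np.min(gtv.voxel_sizes))
    if len(targeted):
        targeted = densify(targeted, max_step)

    if len(targeted) == 0:
        log.warning("[wmpl] no targeted streamlines; map is all fill")
        wm = PathLengthMap(gtv.with_values(np.full(gtv.dims, cfg.fill)), fill=cfg.fill)
    else:
        wm = path_length(targeted, gtv, aff, fill=cfg.fill)
    n_vis = int(wm.visited().sum())
    log.info("[wmpl] %d voxels visited", n_vis)

    write_volume(wm.grid, out / "wmpl.nii.gz", dtype=np.float32)
    (out / "wmpl.json").write_text(json.dumps(
        {"fill": cfg.fill, "n_streamlines": len(targeted), "voxels_visited": n_vis}))
    cfg.to_yaml(out / "resolved_config.yaml")
    return wm


def run_ctv(cfg: RunConfig) -> tuple[ctv_mod.CtvSet, dict]:
    """Build the CTV family from a WMPL map and write masks + report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    wmpl_path = _require(cfg.wmpl, "load-wmpl", "WMPL map")
    gtv_path = _require(cfg.gtv, "load-gtv", "GTV mask")
    brain_path = _require(cfg.brain, "load-brain", "brain mask")
    wgrid = read_volume(wmpl_path)
    fill = cfg.fill
    sidecar = Path(wmpl_path).with_suffix("").with_suffix(".json")
    if sidecar.exists():
        fill = float(json.loads(sidecar.read_text()).get("fill", fill))
    wm = PathLengthMap(wgrid, fill=fill)
    gtv = read_volume(gtv_path, binarize=True)
    brain = read_volume(brain_path, binarize=True)
    for name, m in (("GTV", gtv), ("brain", brain)):
        if not wm.grid.same_grid_as(m):
            raise StageError(
                "grid-check",
                f"{name} grid (dims {m.dims}, vs {m.voxel_sizes}) does not match WMPL "
                f"grid (dims {wm.grid.dims}, vs {wm.grid.voxel_sizes})",
                EXIT_RECONCILE)
    cset = ctv_mod.build_ctv_set(wm, gtv, brain, cfg.expansion)

    recurrence = None
    if cfg.recurrence and Path(cfg.recurrence).exists():
        recurrence = read_volume(cfg.recurrence, binarize=True)

    report: dict = {"isotropic_volume_mm3": ctv_mod.mask_volume_mm3(cset.isotropic),
                    "per_epl": {}}
    for epl, mask in cset.anisotropic.items():
        rec = ctv_mod.compare_ctvs(mask, cset.isotropic, recurrence)
        report["per_epl"][f"{epl:g}"] = rec
        write_volume(mask, out / f"ctv_dwmri_epl{epl:g}mm.nii.gz", dtype=np.uint8)
    write_volume(cset.isotropic, out / "ctv_isotropic.nii.gz", dtype=np.uint8)
    (out / "ctv_report.json").write_text(json.dumps(report, indent=2))
    cfg.to_yaml(out / "resolved_config.yaml")
    return cset, report
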