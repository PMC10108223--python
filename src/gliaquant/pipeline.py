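"""Batch pipeline driver with the upstream folder conventions, plus run QC.

Output folders are created *inside* the input folder (unidirectional folder
hierarchy) using the conventional names: ``tiff``, ``90DegreeRotated``,
``zDir``, ``1CDir`` … ``4CDir``, ``PSFDir``, ``DeconvDir``, ``TH``,
``ZonationTool``, ``outZone``, ``QuantEDM``, ``QuantSkel``. Re-runs overwrite
deterministically unless ``no_clobber`` is set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
import yaml

from . import deconvolve as dc
from . import quantify as qt
from . import segment as sg
from . import standardize as st
from . import volume_io as vio
from . import zonation as zn

__all__ = ["PipelineConfig", "run_pipeline", "validate_run", "list_stacks"]

log = logging.getLogger("gliaquant")

_STEP_ORDER_RULES = {
    # step -> set of steps that must NOT appear before it
    "deconvolve": {"segment"},
}


@dataclass
class PipelineConfig:
    input_dir: Path
    steps: list[dict[str, Any]] = field(default_factory=list)
    log_level: str = "INFO"
    no_clobber: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(input_dir=Path(data["input_dir"]), steps=list(data["steps"]),
                   log_level=data.get("log_level", "INFO"),
                   no_clobber=bool(data.get("no_clobber", False)))

    def validate(self) -> None:
        names = [s["name"] for s in self.steps]
        known = {"rotate90", "subregion", "split", "deconvolve", "segment",
                 "zonation", "quantify"}
        for n in names:
            if n not in known:
                raise ValueError(f"unknown pipeline step {n!r}")
        if "quantify" in names and "segment" in names:
            if names.index("quantify") < names.index("segment"):
                raise ValueError("invalid step order: quantify requires a "
                                 "segmented input (place 'segment' first)")
        elif "quantify" in names and "segment" not in names:
            raise ValueError("invalid pipeline: quantify requires a 'segment' step")
        for step, forbidden_before in _STEP_ORDER_RULES.items():
            if step in names:
                before = set(names[: names.index(step)])
                bad = before & forbidden_before
                if bad:
                    raise ValueError(
                        f"invalid step order: {step} cannot follow {sorted(bad)}")


def list_stacks(folder: str | Path, include_mips: bool = False) -> list[Path]:
    folder = Path(folder)
    paths = sorted(p for p in folder.iterdir()
                   if p.suffix.lower() in (".tif", ".tiff"))
    if not include_mips:
        paths = [p for p in paths if not p.name.startswith("MAX_")]
    return paths


def _require_stacks(folder: Path) -> list[Path]:
    paths = list_stacks(folder)
    if not paths:
        raise FileNotFoundError(
            f"no input files: no .tiff stacks found in {folder} "
            "(check that the correct input folder was selected)")
    return paths


def _require_3d(img: vio.VolumetricImage, path: Path) -> None:
    if img.shape[0] < 2:
        raise ValueError(
            f"stack required: {path.name} has a single plane (MIPs — files named "
            "'MAX_…' — are not valid pipeline input)")


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the configured steps over every TIFF of the input folder tree."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    current = Path(config.input_dir)
    if not current.exists():
        raise FileNotFoundError(f"input folder does not exist: {current}")
    _require_stacks(current)

    log_lines = [f"input_dir: {current}"]
    outputs: dict[str, Any] = {}
    for step in config.steps:
        name = step["name"]
        params = {k: v for k, v in step.items() if k != "name"}
        runner = _STEP_RUNNERS[name]
        current, extra = runner(current, params, config)
        log_lines.append(f"step {name}: params={params} -> {current}")
        outputs[name] = {"output_dir": str(current), **extra}
        log.info("step %s -> %s", name, current)

    log_path = Path(config.input_dir) / "gliaquant_log.txt"
    log_path.write_text("\n".join(log_lines) + "\n")
    outputs["log"] = str(log_path)
    return outputs


def _out_dir(parent: Path, name: str, config: PipelineConfig) -> Path:
    d = parent / name
    if d.exists() and config.no_clobber:
        raise FileExistsError(f"{d} exists and no_clobber is set")
    d.mkdir(parents=True, exist_ok=True)
    return d


def _run_rotate90(folder: Path, params: dict, config: PipelineConfig):
    out = _out_dir(folder, "90DegreeRotated", config)
    direction = params.get("direction", "clockwise")
    for p in _require_stacks(folder):
        img = vio.read_stack(p)
        _require_3d(img, p)
        rot = st.rotate90(img, direction)
        vio.write_stack(rot, out / p.name)
        vio.write_stack(vio.max_projection(rot), out / f"MAX_{p.name}")
    return out, {"direction": direction}


def _run_subregion(folder: Path, params: dict, config: PipelineConfig):
    sp = st.SubregionParams(
        width_um=float(params.get("width", 60.0)),
        depth_um=float(params.get("depth", 10.0)),
        sigma_um=float(params.get("sigma", 10.0)),
        interpolation=params.get("interpolation", "bilinear"),
    )
    roi_file = params.get("roi_file")
    if roi_file is None:
        for cand in ("RoiSetLine.zip", "RoiSetLine.json"):
            if (folder / cand).exists():
                roi_file = folder / cand
                break
        else:
            raise FileNotFoundError(
                f"ROI archive 'RoiSetLine.zip' not found in {folder}")
    rois = vio.read_roi_archive(roi_file)
    paths = _require_stacks(folder)
    pairs = vio.pair_rois_with_images(rois, paths)
    out = _out_dir(folder, "zDir", config)
    within = bool(params.get("within_stack", False))
    for p, roi in pairs:
        if not isinstance(roi, vio.LineRoi):
            raise ValueError(f"subregion needs line ROIs, got {type(roi).__name__}")
        img = vio.read_stack(p)
        _require_3d(img, p)
        fn = st.extract_subregion_within_stack if within else st.extract_subregion
        sub = fn(img, roi, sp)
        vio.write_stack(sub, out / p.name)
        vio.write_stack(vio.max_projection(sub), out / f"MAX_{p.name}")
    return out, {"params": vars(sp)}


def _run_split(folder: Path, params: dict, config: PipelineConfig):
    n_out = 0
    first_dir = None
    for p in _require_stacks(folder):
        img = vio.read_stack(p)
        subs = vio.split_channels(img, out_dir=folder)
        n_out = len(subs)
        first_dir = folder / "1CDir"
    return first_dir or folder, {"n_channels": n_out}


def _run_deconvolve(folder: Path, params: dict, config: PipelineConfig):
    wavelengths = params.get("wavelengths", [510.0])
    if isinstance(wavelengths, (int, float)):
        wavelengths = [wavelengths]
    na = float(params.get("na", 1.0))
    iterations = int(params.get("iterations", 1))
    psf_path = params.get("psf")
    out = _out_dir(folder, "DeconvDir", config)
    psf_dir = _out_dir(folder, "PSFDir", config)
    for p in _require_stacks(folder):
        img = vio.read_stack(p)
        _require_3d(img, p)
        if psf_path:
            psf = dc.load_psf(psf_path)
        else:
            pp = dc.PsfParams(emission_wavelength_nm=float(wavelengths[0]),
                              numerical_aperture=na, voxel_size=img.voxel_size)
            psf = dc.theoretical_psf(pp)
            vio.write_stack(psf, psf_dir / f"PSF_{p.name}")
        result = dc.richardson_lucy(img, psf, iterations=iterations)
        vio.write_stack(result, out / p.name)
    return out, {"iterations": iterations, "na": na}


def _run_segment(folder: Path, params: dict, config: PipelineConfig):
    profile = params.get("profile", "cytosol")
    out = _out_dir(folder, "TH", config)
    mip_dir = _out_dir(out, "MIP", config)
    sp = sg.SegmentationParams(
        min_object_vox=int(params.get("min_object_vox", 50)),
        rolling_ball_radius_px=int(params.get("rolling_ball_radius_px", 50)),
    )
    for p in _require_stacks(folder):
        img = vio.read_stack(p)
        _require_3d(img, p)
        mask = sg.segment_pipeline(img, profile, sp)
        mimg = mask.to_image()
        mimg.name = p.stem
        vio.write_stack(mimg, out / p.name)
        vio.write_stack(vio.max_projection(mimg), mip_dir / f"MAX_{p.name}")
        (out / f"{p.stem}_provenance.json").write_text(
            json.dumps(mask.provenance, indent=2, default=str))
    return out, {"profile": profile}


def _run_zonation(folder: Path, params: dict, config: PipelineConfig):
    sigma = float(params.get("sigma", 0.0))
    normalize = bool(params.get("normalize", False))
    target = int(params.get("target_rows", 100))
    profiles, heights = [], []
    for p in _require_stacks(folder):
        img = vio.read_stack(p)
        prof = zn.apicobasal_profile(img)
        prof.name = p.stem
        if normalize:
            prof = zn.normalize_profile(prof, target)
        profiles.append(prof)
        heights.append(zn.measure_heights(img, sigma))
    files = zn.export_zonation(profiles, folder, sigma_um=sigma, heights=heights)
    return folder / "ZonationTool", {k: str(v) for k, v in files.items()}


def _run_quantify(folder: Path, params: dict, config: PipelineConfig):
    prune = float(params.get("prune_um", 0.0))
    sigma = float(params.get("sigma", 0.0))
    records = []
    for p in _require_stacks(folder):
        img = vio.read_stack(p)
        mask = qt.ensure_binary(img)
        records.append(qt.quantify_stack(mask, name=p.stem, sigma_um=sigma,
                                         prune_below_um=prune))
        qt.write_quantification_tree(mask, img, folder, name=p.stem,
                                     prune_below_um=prune)
    files = qt.write_quantification_csvs(records, folder)
    return folder, {k: str(v) for k, v in files.items()}


_STEP_RUNNERS: dict[str, Callable] = {
    "rotate90": _run_rotate90,
    "subregion": _run_subregion,
    "split": _run_split,
    "deconvolve": _run_deconvolve,
    "segment": _run_segment,
    "zonation": _run_zonation,
    "quantify": _run_quantify,
}


# ---------------------------------------------------------------------------
# Batch comparability QC
# ---------------------------------------------------------------------------

def validate_run(
    results: pd.DataFrame | list[dict] | list[qt.FeatureRecord],
    cov_threshold_pct: float = 20.0,
) -> dict[str, Any]:
    """Per-feature coefficient of variation (sd/mean, %) across a batch.

    Age/region-matched standardized groups are expected below ~20% CoV;
    features above the threshold are flagged for inspection.
    """
    if isinstance(results, list) and results and isinstance(results[0],
                                                            qt.FeatureRecord):
        results = [vars(r) for r in results]
    df = pd.DataFrame(results)
    if len(df) < 2:
        return {"status": "insufficient replicates", "n": int(len(df)),
                "cov_pct": {}, "flagged": []}
    cov = {}
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            continue
        mean = df[col].mean()
        if mean == 0:
            continue
        cov[col] = float(df[col].std(ddof=1) / abs(mean) * 100.0)
    flagged = sorted(c for c, v in cov.items() if v > cov_threshold_pct)
    return {"status": "ok", "n": int(len(df)), "cov_pct": cov, "flagged": flagged,
            "threshold_pct": cov_threshold_pct}
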