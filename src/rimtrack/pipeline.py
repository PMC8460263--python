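"""Run orchestration: simulate -> segment -> quantify -> coloc -> timecourse.

One YAML config drives the whole chain. Each run echoes its config into the
output directory, records the seed in every output table, and writes a
manifest listing inputs, outputs, stage parameters, and SHA-256 checksums,
so identical configs reproduce identical CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import coloc as coloc_mod
from . import rim, segmentation, synthetic, timecourse
from .io import (
    Micrograph,
    RegionOfInterest,
    read_micrograph,
    read_roi,
    write_micrograph,
    write_roi,
)

logger = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "segment", "quantify", "coloc", "timecourse"]

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_STAGE_FAILURE = 3


class ValidationError(ValueError):
    """Config or input problems detected before any stage runs."""


class StageError(RuntimeError):
    """A stage failed mid-run."""

    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Parsed pipeline configuration."""

    seed: int
    output_dir: Path
    stages: list[str]
    params: dict[str, dict[str, Any]] = field(default_factory=dict)
    input_dir: Optional[Path] = None
    raw: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base_dir=path.parent)

    @classmethod
    def from_dict(cls, raw: dict[str, Any], base_dir: Path = Path(".")) -> "RunConfig":
        if "seed" not in raw:
            raise ValidationError("config must set an explicit seed")
        stages = raw.get("stages", STAGE_ORDER)
        unknown = set(stages) - set(STAGE_ORDER)
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")
        # stages must form a prefix-closed chain of the canonical order
        # (allowing the chain to start anywhere when inputs are supplied)
        idx = sorted(STAGE_ORDER.index(s) for s in stages)
        if idx != list(range(idx[0], idx[0] + len(idx))):
            raise ValidationError(
                f"stages {stages} are not a contiguous chain of {STAGE_ORDER}"
            )
        params = {s: dict(raw.get(s) or {}) for s in STAGE_ORDER}
        input_dir = raw.get("input_dir")
        return cls(
            seed=int(raw["seed"]),
            output_dir=base_dir / raw.get("output_dir", "rimtrack_out"),
            stages=[s for s in STAGE_ORDER if s in stages],
            params=params,
            input_dir=(base_dir / input_dir) if input_dir else None,
            raw=raw,
        )

    def validate(self) -> None:
        if "simulate" not in self.stages:
            if self.input_dir is None or not self.input_dir.exists():
                raise ValidationError(
                    "without a simulate stage, input_dir must exist and contain "
                    "images + metadata"
                )
        for stage in self.stages:
            for key in ("roi", "model"):
                ref = self.params.get(stage, {}).get(key)
                if ref and not Path(ref).exists():
                    raise ValidationError(f"{stage}.{key} path does not exist: {ref}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _params_hash(params: dict[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _simulate(cfg: RunConfig, workdir: Path) -> dict[str, Any]:
    p = cfg.params["simulate"]
    schedules = p.get("schedules", ["plin3_like", "plin2_like"])
    time_points = p.get(
        "time_points",
        [0.75, 1.5, 2.5, 3.5, 4.5, 6.5, 7.5, 8.5, 16.0, 18.0, 20.0, 22.0, 24.0, 26.0, 28.0, 30.0],
    )
    n_scenes = int(p.get("n_scenes_per_point", 2))
    image_size = tuple(p.get("image_size", (96, 96)))
    workdir.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    truth_rows = []
    rng = np.random.default_rng(cfg.seed)
    for kind in schedules:
        schedule = synthetic.protein_schedule(kind)
        for t in time_points:
            for k in range(n_scenes):
                scene_seed = int(rng.integers(2**31))
                params = synthetic.default_params_at(
                    t, seed=scene_seed, image_size=image_size
                )
                subject = f"{kind}_t{t:05.2f}_s{k}"
                dye, protein, truth = synthetic.make_droplet_scene(
                    params, schedule, time_hr=t, subject_id=subject
                )
                roi_mask = np.zeros(image_size, dtype=bool)
                m_r = max(image_size[0] // 16, 2)
                m_c = max(image_size[1] // 16, 2)
                roi_mask[m_r : image_size[0] - m_r, m_c : image_size[1] - m_c] = True
                stem = subject
                write_micrograph(dye, workdir / f"{stem}_dye.tif")
                write_micrograph(protein, workdir / f"{stem}_protein.tif")
                write_roi(RegionOfInterest(roi_mask), workdir / f"{stem}_roi.tif")
                np.save(workdir / f"{stem}_truthmask.npy", truth.droplet_mask)
                for role in ("dye", "protein"):
                    meta_rows.append(
                        dict(
                            filename=f"{stem}_{role}.tif",
                            subject_id=subject,
                            genotype_label=kind,
                            time_hr=t,
                            channel_role="lipid_dye" if role == "dye" else "protein",
                            roi_file=f"{stem}_roi.tif",
                            seed=scene_seed,
                        )
                    )
                truth_rows.append(
                    dict(
                        subject_id=subject,
                        genotype_label=kind,
                        time_hr=t,
                        mean_rim_protein=truth.mean_rim_protein,
                        mean_cyto_protein=truth.mean_cyto_protein,
                        rim_intensity_t=truth.rim_intensity_t,
                        cyto_intensity_t=truth.cyto_intensity_t,
                        protein_scale=truth.protein_scale,
                        seed=scene_seed,
                    )
                )
    pd.DataFrame(meta_rows).to_csv(workdir / "metadata.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(workdir / "truth.csv", index=False)
    return {"n_images": 2 * len(truth_rows), "dir": str(workdir)}


def _label_map_from_truth(truth_mask: np.ndarray, rng: np.random.Generator,
                          n_per_class: int = 400) -> np.ndarray:
    """Sparse scribble labels sampled from the ground-truth droplet mask."""
    labels = np.zeros(truth_mask.shape, dtype=np.uint8)
    fg = np.argwhere(truth_mask)
    bg = np.argwhere(~truth_mask)
    for coords, value in ((fg, segmentation.LABEL_DROPLET),
                          (bg, segmentation.LABEL_BACKGROUND)):
        n = min(n_per_class, len(coords))
        sel = coords[rng.choice(len(coords), size=n, replace=False)]
        labels[sel[:, 0], sel[:, 1]] = value
    return labels


def _segment(cfg: RunConfig, workdir: Path) -> dict[str, Any]:
    p = cfg.params["segment"]
    threshold = float(p.get("threshold", 0.5))
    min_object_px = int(p.get("min_object_px", 4))
    meta = pd.read_csv(workdir / "metadata.csv")
    dye_meta = meta[meta.channel_role == "lipid_dye"]
    model_path = p.get("model")
    if model_path:
        model = segmentation.load_model(model_path)
    else:
        # train on a few scenes using the simulated ground truth as scribbles
        n_train = int(p.get("n_train_scenes", 3))
        rng = np.random.default_rng(cfg.seed + 1)
        train_rows = dye_meta.iloc[
            np.linspace(0, len(dye_meta) - 1, n_train).astype(int)
        ]
        images, label_maps = [], []
        for _, row in train_rows.iterrows():
            img = read_micrograph(workdir / row.filename)
            mask = np.load(workdir / row.filename.replace("_dye.tif", "_truthmask.npy"))
            images.append(img)
            label_maps.append(_label_map_from_truth(mask, rng))
        model = segmentation.train_pixel_classifier(images, label_maps, seed=cfg.seed)
        segmentation.save_model(model, workdir / "pixel_classifier.joblib")
    n_done = 0
    for _, row in dye_meta.iterrows():
        img = read_micrograph(workdir / row.filename)
        result = segmentation.segment(
            model, img, threshold=threshold, min_object_px=min_object_px
        )
        stem = row.filename[: -len("_dye.tif")]
        np.save(workdir / f"{stem}_mask.npy", result.droplet_mask)
        n_done += 1
    return {"n_segmented": n_done, "threshold": threshold}


def _quantify(cfg: RunConfig, workdir: Path) -> dict[str, Any]:
    p = cfg.params["quantify"]
    params = rim.RimParams(
        dilation_px=int(p.get("dilation_px", 3)),
        metric=p.get("metric", "chebyshev"),
    )
    meta = pd.read_csv(workdir / "metadata.csv")
    rows = []
    phash = _params_hash(p)
    for _, row in meta[meta.channel_role == "protein"].iterrows():
        stem = row.filename[: -len("_protein.tif")]
        protein = read_micrograph(workdir / row.filename)
        mask = np.load(workdir / f"{stem}_mask.npy")
        roi = read_roi(workdir / row.roi_file, shape=mask.shape)
        m = rim.measure_scene(
            protein, mask, roi, params,
            subject_id=row.subject_id,
            genotype_label=row.genotype_label,
            time_hr=row.time_hr,
        )
        frac = rim.area_fraction(mask, roi)
        rows.append(
            dict(
                subject_id=m.subject_id,
                genotype_label=m.genotype_label,
                time_hr=m.time_hr,
                mean_ld=m.mean_ld,
                mean_cyto=m.mean_cyto,
                area_ld_px=m.area_ld_px,
                area_roi_px=m.area_roi_px,
                area_fraction=frac,
                seed=cfg.seed,
                params_hash=phash,
            )
        )
    pd.DataFrame(rows).to_csv(workdir / "measurements.csv", index=False)
    return {"n_measured": len(rows), "dilation_px": params.dilation_px}


def _coloc(cfg: RunConfig, workdir: Path) -> dict[str, Any]:
    meta = pd.read_csv(workdir / "metadata.csv")
    phash = _params_hash(cfg.params["coloc"])
    rows = []
    for subject, group in meta.groupby("subject_id"):
        dye_row = group[group.channel_role == "lipid_dye"].iloc[0]
        prot_row = group[group.channel_role == "protein"].iloc[0]
        ch1 = read_micrograph(workdir / dye_row.filename)
        ch2 = read_micrograph(workdir / prot_row.filename)
        roi = read_roi(workdir / dye_row.roi_file, shape=ch1.shape)
        try:
            res = coloc_mod.colocalize(ch1, ch2, roi)
        except ValueError as exc:
            logger.warning("colocalization skipped for %s: %s", subject, exc)
            continue
        if not res.converged:
            logger.warning("Costes search did not converge for %s", subject)
        rows.append(
            dict(
                subject_id=subject,
                genotype_label=dye_row.genotype_label,
                time_hr=dye_row.time_hr,
                slope=res.slope,
                intercept=res.intercept,
                threshold_ch1=res.threshold_ch1,
                threshold_ch2=res.threshold_ch2,
                tM1=res.tM1,
                tM2=res.tM2,
                pearson_below=res.pearson_below,
                converged=res.converged,
                n_pixels=res.n_pixels,
                seed=cfg.seed,
                params_hash=phash,
            )
        )
    pd.DataFrame(rows).to_csv(workdir / "coloc.csv", index=False)
    return {"n_pairs": len(rows)}


def _timecourse(cfg: RunConfig, workdir: Path) -> dict[str, Any]:
    p = cfg.params["timecourse"]
    windows = p.get(
        "windows", {"early": list(timecourse.EARLY_WINDOW), "late": list(timecourse.LATE_WINDOW)}
    )
    frac = float(p.get("lowess_frac", 0.35))
    n_iter = int(p.get("lowess_iter", 2))
    phash = _params_hash(p)
    meas = pd.read_csv(workdir / "measurements.csv")
    normalized = timecourse.normalize_by_group_mean(
        meas, value_columns=["mean_ld", "mean_cyto"]
    )
    normalized["params_hash"] = phash
    normalized.to_csv(workdir / "normalized.csv", index=False)
    fit_rows = []
    smooth_rows = []
    for genotype, sub in meas.groupby("genotype_label"):
        for wname, (lo, hi) in windows.items():
            for metric in ("mean_ld", "mean_cyto"):
                try:
                    fit = timecourse.linear_fit(
                        sub.time_hr, sub[metric], window=(float(lo), float(hi))
                    )
                except ValueError as exc:
                    logger.warning(
                        "fit skipped (%s, %s, %s): %s", genotype, wname, metric, exc
                    )
                    continue
                fit_rows.append(
                    dict(
                        genotype_label=genotype,
                        window=wname,
                        t_min=lo,
                        t_max=hi,
                        metric=metric,
                        slope=fit.slope,
                        intercept=fit.intercept,
                        r=fit.r,
                        n=fit.n,
                        seed=cfg.seed,
                        params_hash=phash,
                    )
                )
        nsub = normalized[normalized.genotype_label == genotype].sort_values("time_hr")
        if len(nsub) >= 5:
            smoothed = timecourse.lowess_smooth(
                nsub.time_hr, nsub.mean_ld, frac=frac, n_iter=n_iter
            )
            for t, v in zip(nsub.time_hr, smoothed):
                smooth_rows.append(
                    dict(
                        genotype_label=genotype,
                        time_hr=t,
                        smoothed_mean_ld=v,
                        visualization_only=True,
                        seed=cfg.seed,
                        params_hash=phash,
                    )
                )
    pd.DataFrame(fit_rows).to_csv(workdir / "fits.csv", index=False)
    pd.DataFrame(smooth_rows).to_csv(workdir / "smoothed.csv", index=False)
    return {"n_fits": len(fit_rows)}


_STAGE_FUNCS = {
    "simulate": _simulate,
    "segment": _segment,
    "quantify": _quantify,
    "coloc": _coloc,
    "timecourse": _timecourse,
}


def run_pipeline(config: RunConfig | str | Path | dict) -> dict[str, Any]:
    """Run the configured stage chain; return the manifest (also written).

    The manifest records the echoed config, per-stage parameters and wall
    time, and a SHA-256 checksum of every file in the output directory.
    """
    if isinstance(config, (str, Path)):
        config = RunConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = RunConfig.from_dict(config)
    config.validate()
    workdir = config.output_dir
    workdir.mkdir(parents=True, exist_ok=True)
    if config.input_dir is not None and config.input_dir != workdir:
        # stages read from the output dir; stage the inputs there
        for f in config.input_dir.iterdir():
            if f.is_file():
                (workdir / f.name).write_bytes(f.read_bytes())
    (workdir / "config_echo.yaml").write_text(yaml.safe_dump(config.raw))
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "stages": [],
        "config": config.raw,
    }
    for stage in config.stages:
        t0 = time.perf_counter()
        try:
            info = _STAGE_FUNCS[stage](config, workdir)
        except (ValidationError, StageError):
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        manifest["stages"].append(
            {
                "name": stage,
                "params": config.params[stage],
                "params_hash": _params_hash(config.params[stage]),
                "wall_s": round(time.perf_counter() - t0, 3),
                "info": info,
            }
        )
        logger.info("stage %s done in %.1fs: %s", stage, time.perf_counter() - t0, info)
    manifest["outputs"] = {
        f.name: _sha256(f)
        for f in sorted(workdir.iterdir())
        if f.is_file() and f.name != "manifest.json"
    }
    (workdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
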