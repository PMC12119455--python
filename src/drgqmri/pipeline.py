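"""End-to-end pipeline: simulate -> fit -> extract -> reliability -> analyze.

Each stage reads only the previous stage's declared outputs under the output
directory, so stages can be rerun independently; per-stage seeds are derived
deterministically from the master seed via ``numpy.random.SeedSequence``
spawning.  A manifest (configuration, per-stage status and seeds, SHA-256
checksums of every written file) makes two runs with the same configuration
and seed byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import io as qio
from .features import build_feature_table
from .phantom import (AcquisitionProtocol, default_cohort_config, make_scene,
                      make_rater_masks, sample_cohort, simulate_multiecho)
from .relaxometry import FitOptions, T2RelaxometryModel
from .reliability import icc_agreement
from .stats import run_paper_analyses

__all__ = ["PipelineConfig", "run_pipeline", "run_cohort_in_memory", "STAGES"]

log = logging.getLogger("drgqmri")

STAGES = ("simulate", "fit", "extract", "reliability", "analyze")


class ProtocolConfig(BaseModel):
    n_echoes: int = 10
    delta_te: float = 15.0
    tr: float = 4800.0
    voxel_spacing: Tuple[float, float, float] = (1.5, 1.5, 1.8)
    grid_shape: Tuple[int, int, int] = (64, 64, 16)


class CohortSection(BaseModel):
    groups: Optional[Dict[str, int]] = None  # group -> n override
    noise_sigma: float = 0.01
    b1_range: Tuple[float, float] = (0.8, 1.1)
    sigma_scale: float = 1.0  # 0 gives the degenerate, median-exact cohort
    n_raters: int = 2
    rater_perturbation: float = 0.1


class FitSection(BaseModel):
    refine: bool = True
    method: str = "epg"
    min_r2: float = 0.80
    mask_restricted: bool = True

    @field_validator("method")
    @classmethod
    def _check_method(cls, v):
        if v not in ("epg", "loglin"):
            raise ValueError("fit.method must be 'epg' or 'loglin'")
        return v


class PipelineConfig(BaseModel):
    out_dir: Path
    seed: int = 0
    stages: List[str] = Field(default_factory=lambda: list(STAGES))
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    cohort: CohortSection = Field(default_factory=CohortSection)
    fit: FitSection = Field(default_factory=FitSection)

    @field_validator("stages")
    @classmethod
    def _check_stages(cls, v):
        bad = [s for s in v if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        return sorted(set(v), key=STAGES.index)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _protocol_of(cfg: PipelineConfig) -> AcquisitionProtocol:
    p = cfg.protocol
    return AcquisitionProtocol(n_echoes=p.n_echoes, delta_te=p.delta_te,
                               tr=p.tr, voxel_spacing=p.voxel_spacing,
                               grid_shape=p.grid_shape)


def _stage_seeds(cfg: PipelineConfig) -> Dict[str, int]:
    children = np.random.SeedSequence(cfg.seed).spawn(len(STAGES))
    return {s: int(c.generate_state(1)[0] % (2 ** 31))
            for s, c in zip(STAGES, children)}


def _stage_simulate(cfg, out, seed):
    from dataclasses import replace
    protocol = _protocol_of(cfg)
    cc = default_cohort_config(seed=seed)
    if cfg.cohort.groups:
        cc = replace(cc, groups={g: replace(gp, n=cfg.cohort.groups[g])
                                 for g, gp in cc.groups.items()
                                 if g in cfg.cohort.groups})
    cc = replace(cc, noise_sigma=cfg.cohort.noise_sigma,
                 b1_range=cfg.cohort.b1_range)
    if cfg.cohort.sigma_scale != 1.0:
        cc = cc.scaled(cfg.cohort.sigma_scale)
    specs = sample_cohort(cc)
    rows = []
    stage_dir = out / "simulate"
    stage_dir.mkdir(parents=True, exist_ok=True)
    rater_ss = np.random.SeedSequence(seed).spawn(len(specs))
    for spec, rss in zip(specs, rater_ss):
        scene = make_scene(spec, protocol, b1_range=cc.b1_range)
        series = simulate_multiecho(scene, protocol, spec.noise_sigma,
                                    seed=spec.seed)
        qio.save_series(series, stage_dir / f"{spec.subject_id}_series.nii.gz")
        qio.save_mask(scene.mask, stage_dir / f"{spec.subject_id}_mask_truth.nii.gz")
        raters = make_rater_masks(scene.mask, n_raters=cfg.cohort.n_raters,
                                  perturbation=cfg.cohort.rater_perturbation,
                                  seed=int(rss.generate_state(1)[0] % 2 ** 31))
        for i, rm in enumerate(raters, start=1):
            qio.save_mask(rm, stage_dir / f"{spec.subject_id}_mask_rater{i}.nii.gz")
        rows.append({"subject_id": spec.subject_id, "group": spec.group,
                     "sex": spec.sex, "age": spec.age, "height": spec.height,
                     "weight": spec.weight, "seed": spec.seed})
    pd.DataFrame(rows).to_csv(stage_dir / "subjects.csv", index=False)


def _stage_fit(cfg, out, seed):
    from scipy import ndimage
    stage_dir = out / "fit"
    stage_dir.mkdir(parents=True, exist_ok=True)
    sim_dir = out / "simulate"
    subjects = pd.read_csv(sim_dir / "subjects.csv")
    options = FitOptions(refine=cfg.fit.refine, method=cfg.fit.method,
                         min_r2=cfg.fit.min_r2)
    for sid in subjects["subject_id"]:
        series = qio.load_series(sim_dir / f"{sid}_series.nii.gz")
        model = T2RelaxometryModel(series, options=options)
        if cfg.fit.mask_restricted:
            sel = np.zeros(series.grid_shape, dtype=bool)
            for mp in sorted(sim_dir.glob(f"{sid}_mask_*.nii.gz")):
                m = qio.load_mask(mp)
                sel |= np.isin(m.labels, m.drg_labels() + [m.csf_label()])
            sel = ndimage.binary_dilation(sel, iterations=1)
            from .features import LabelInfo, RoiMask
            fitmask = RoiMask(labels=sel.astype(np.int16),
                              spacing=series.voxel_spacing,
                              label_table={1: LabelInfo("tissue")})
            res = model.fit(mask=fitmask)
        else:
            res = model.fit()
        qio.save_maps(res.maps, stage_dir, prefix=f"{sid}_")
        (stage_dir / f"{sid}_qc.json").write_text(
            json.dumps(res.qc_report(), indent=1))


def _stage_extract(cfg, out, seed):
    stage_dir = out / "extract"
    stage_dir.mkdir(parents=True, exist_ok=True)
    sim_dir, fit_dir = out / "simulate", out / "fit"
    if not (sim_dir / "subjects.csv").exists():
        raise FileNotFoundError("extract stage needs simulate outputs")
    if not any(fit_dir.glob("*_t2.nii.gz")):
        raise FileNotFoundError("extract stage needs fitted maps")
    subjects = pd.read_csv(sim_dir / "subjects.csv")

    def gen():
        for sid in subjects["subject_id"]:
            maps = qio.load_maps(fit_dir, prefix=f"{sid}_")
            masks = {}
            for i in range(1, cfg.cohort.n_raters + 1):
                mp = sim_dir / f"{sid}_mask_rater{i}.nii.gz"
                masks[f"rater{i}"] = qio.load_mask(mp)
            yield sid, maps, masks

    long_df, cohort_df, completeness = build_feature_table(
        gen(), demographics=subjects)
    long_df.to_csv(stage_dir / "per_drg.csv", index=False)
    cohort_df.to_csv(stage_dir / "subjects.csv")
    (stage_dir / "completeness.json").write_text(json.dumps(completeness, indent=1))


def _stage_reliability(cfg, out, seed):
    stage_dir = out / "reliability"
    stage_dir.mkdir(parents=True, exist_ok=True)
    long_df = pd.read_csv(out / "extract" / "per_drg.csv")
    report = {}
    for feat, col in (("volume", "volume"), ("t2", "t2_mean"), ("pd", "pd")):
        piv = long_df.pivot_table(values=col, columns="rater_id",
                                  index=["subject_id", "level", "side"])
        res = icc_agreement(piv.to_numpy())
        report[feat] = {"icc": res.icc, "ci95": list(res.ci95),
                        "icc_average": res.icc_average,
                        "n_targets": res.n, "k_raters": res.k}
    (stage_dir / "reliability.json").write_text(json.dumps(report, indent=1))


def _stage_analyze(cfg, out, seed):
    stage_dir = out / "analyze"
    stage_dir.mkdir(parents=True, exist_ok=True)
    cohort = pd.read_csv(out / "extract" / "subjects.csv")
    long_df = pd.read_csv(out / "extract" / "per_drg.csv")
    report = run_paper_analyses(cohort, long_table=long_df)
    (stage_dir / "report.json").write_text(json.dumps(report, indent=1, default=float))
    # flat group-comparison table, one row per feature x level
    rows = []
    for contrast, block in report["features"].items():
        for key, d in block.items():
            rows.append({"contrast": contrast, "feature": key, **d})
    pd.DataFrame(rows).to_csv(stage_dir / "group_comparisons.csv", index=False)


_STAGE_FN = {"simulate": _stage_simulate, "fit": _stage_fit,
             "extract": _stage_extract, "reliability": _stage_reliability,
             "analyze": _stage_analyze}


def run_cohort_in_memory(cohort_config, protocol: Optional[AcquisitionProtocol] = None,
                         fit_options: Optional[FitOptions] = None,
                         n_raters: int = 1, rater_perturbation: float = 0.0,
                         rater_seed: Optional[int] = None):
    """Simulate -> fit -> extract a whole cohort without touching disk.

    With ``n_raters = 1`` the ground-truth masks are used directly; with more
    raters, perturbed rater masks are generated and the fit region covers
    their union.  Returns ``(long_df, cohort_df, truth_df)`` where
    ``truth_df`` holds each subject's generator ground-truth features on the
    same aggregation (sides averaged within level, levels averaged) for
    parameter-recovery checks.
    """
    from scipy import ndimage

    from .features import LEVELS, SIDES

    protocol = protocol or AcquisitionProtocol()
    fit_options = fit_options or FitOptions(min_r2=0.80)
    specs = sample_cohort(cohort_config)
    rater_ss = np.random.SeedSequence(
        cohort_config.seed if rater_seed is None else rater_seed).spawn(len(specs))

    demo_rows, truth_rows, subjects = [], [], []
    for spec, rss in zip(specs, rater_ss):
        scene = make_scene(spec, protocol, b1_range=cohort_config.b1_range)
        series = simulate_multiecho(scene, protocol, spec.noise_sigma,
                                    seed=spec.seed)
        truth_mask = scene.mask
        if n_raters >= 2:
            raters = make_rater_masks(truth_mask, n_raters=n_raters,
                                      perturbation=rater_perturbation,
                                      seed=int(rss.generate_state(1)[0] % 2 ** 31))
            masks = {f"rater{i + 1}": rm for i, rm in enumerate(raters)}
        else:
            masks = {"truth": truth_mask}
        fit_sel = np.zeros(protocol.grid_shape, dtype=bool)
        for m in list(masks.values()) + [truth_mask]:
            fit_sel |= np.isin(m.labels, m.drg_labels() + [m.csf_label()])
        fit_sel = ndimage.binary_dilation(fit_sel, iterations=1)
        from .features import LabelInfo, RoiMask
        fitmask = RoiMask(labels=fit_sel.astype(np.int16),
                          spacing=protocol.voxel_spacing,
                          label_table={1: LabelInfo("tissue")})
        maps = T2RelaxometryModel(series, options=fit_options).fit(mask=fitmask).maps
        subjects.append((spec.subject_id, maps, masks))
        demo_rows.append({"subject_id": spec.subject_id, "group": spec.group,
                          "sex": spec.sex, "age": spec.age,
                          "height": spec.height, "weight": spec.weight})
        truth = {"subject_id": spec.subject_id, "group": spec.group}
        for feat, d in (("volume", spec.drg_volume), ("t2", spec.drg_t2),
                        ("pd", spec.drg_pd)):
            level_means = {lv: np.mean([d[(lv, sd)] for sd in SIDES])
                           for lv in LEVELS}
            for lv in LEVELS:
                truth[f"{feat}_{lv}"] = float(level_means[lv])
            truth[f"{feat}_mean"] = float(np.mean(list(level_means.values())))
        truth_rows.append(truth)

    long_df, cohort_df, _ = build_feature_table(
        subjects, demographics=pd.DataFrame(demo_rows))
    truth_df = pd.DataFrame(truth_rows).set_index("subject_id")
    return long_df, cohort_df, truth_df


def run_pipeline(config: PipelineConfig) -> Dict:
    """Run the configured stages in order; returns the manifest dict.

    On stage failure the exception propagates after the manifest (with the
    failed stage marked) is written, so partial outputs stay inspectable.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config)
    manifest: Dict = {
        "config": json.loads(config.model_dump_json()),
        "stage_seeds": {s: seeds[s] for s in config.stages},
        "stages": {},
        "files": {},
    }
    failed = None
    for stage in config.stages:
        t0 = time.perf_counter()
        log.info("stage %s starting", stage)
        try:
            _STAGE_FN[stage](config, out, seeds[stage])
            manifest["stages"][stage] = {
                "status": "ok", "seconds": round(time.perf_counter() - t0, 2)}
            log.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            failed = exc
            break
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][str(f.relative_to(out))] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    if failed is not None:
        raise failed
    return manifest
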