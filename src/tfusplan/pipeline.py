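"""End-to-end planning pipeline.

Stage order: AC-PC alignment -> standard coordinate -> (optional) rigid
T1-to-DWI registration -> DTI preprocessing -> fiber tracking ->
probability-map thresholding -> (optional) evaluation.  Probability maps
are computed in DWI space, carried through the same AC-PC reorientation
as the anatomy, then thresholded, so treatment points (logged in AC-PC
space) and bundles can be compared directly.

All randomness funnels through one seed; reruns with the same config are
byte-identical.  Per-stage wall times go to ``plan.log`` only, never into
the run report, to keep the report reproducible.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional

import numpy as np
import yaml

from . import acpc as _acpc
from .errors import StageError, TfusplanError
from .dti import fa_map, fit_tensors, gaussian_smooth, lanczos3_resample, save_tensorfield
from .metrics import (
    evaluation_report,
    filter_treatment_points,
    lesion_center,
    load_treatment_log,
)
from .registration import register_rigid
from .rois import (
    default_bundle_specs,
    default_parameter_map,
    load_bundle_specs,
    load_parameter_map,
    load_roiset,
    validate_roiset,
)
from .tracking import (
    probability_map,
    save_bundle_summary,
    save_bundle_trk,
    threshold_map,
    track_bundle,
)
from .volumes import Volume, load_landmarks, load_scheme, load_volume, save_volume

__all__ = ["PlanConfig", "plan", "STAGE_ORDER"]

STAGE_ORDER = [
    "acpc_alignment",
    "standard_coordinate",
    "registration",
    "dti_preprocessing",
    "fiber_tracking",
    "thresholding",
    "evaluation",
]


@dataclass
class PlanConfig:
    dwi: str
    bval: str
    bvec: str
    roi_manifest: str
    atlas: str
    landmarks: str
    side: str = "left"
    seed: int = 0
    out_dir: str = "plan_out"
    t1: Optional[str] = None
    treatment_log: Optional[str] = None
    lesion: Optional[str] = None
    bundles: Optional[str] = None
    parameter_map: Optional[str] = None
    register_t1: bool = False
    supersample_spacing_mm: float = 1.0
    smooth_sigma_mm: float = 1.0
    batch_size: int = 100
    pipeline_dialect: str = "AFT"

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PlanConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        # paths in the config file are relative to its directory
        for name in (
            "dwi", "bval", "bvec", "roi_manifest", "atlas", "landmarks",
            "t1", "treatment_log", "lesion", "bundles", "parameter_map",
        ):
            val = getattr(cfg, name)
            if val is not None and not Path(val).is_absolute():
                setattr(cfg, name, str(path.parent / val))
        return cfg

    def validate(self) -> None:
        """Check config fields; missing *files* are reported by the stage
        that needs them so the failure carries the stage tag."""
        if self.side not in ("left", "right"):
            raise StageError("config", f"side must be left or right, got {self.side!r}")


def _require(stage: str, **paths) -> None:
    for name, p in paths.items():
        if p is None or not Path(p).exists():
            raise StageError(f"{stage}-inputs", f"missing {name}: {p}")


def plan(config: PlanConfig) -> dict:
    """Run the full planning pipeline; returns the run report dict.

    The report lists every stage in pipeline order with a status of
    ``ok``, ``skipped`` or ``failed`` and the files each stage wrote.  On
    a stage failure the report carries the stage tag and remaining stages
    are not run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: List[str] = []
    report = {
        "seed": int(config.seed),
        "side": config.side,
        "stages": [{"name": s, "status": "pending", "outputs": []} for s in STAGE_ORDER],
        "status": "ok",
    }
    stage_ix = {s: i for i, s in enumerate(STAGE_ORDER)}

    def run_stage(name: str, fn, skip: bool = False):
        entry = report["stages"][stage_ix[name]]
        if skip:
            entry["status"] = "skipped"
            log_lines.append(f"{name}: skipped")
            return None
        t0 = time.perf_counter()
        try:
            outputs = fn() or []
        except StageError:
            raise
        except TfusplanError as exc:
            raise StageError(name, str(exc)) from exc
        entry["status"] = "ok"
        entry["outputs"] = outputs
        log_lines.append(f"{name}: ok ({time.perf_counter() - t0:.2f} s)")
        return outputs

    state: dict = {}
    try:
        config.validate()

        def do_acpc():
            _require("acpc_alignment", landmarks=config.landmarks)
            lm = load_landmarks(config.landmarks)
            t = _acpc.acpc_transform(lm)
            state["transform"] = t
            state["landmarks_acpc"] = type(lm)(t.apply(lm.ac), t.apply(lm.pc))
            written = []
            if config.t1:
                t1 = load_volume(config.t1)
                t1_acpc = _acpc.reorient_to_acpc(t1, t, target_spacing=1.0)
                save_volume(
                    Volume(t1_acpc.data.astype(np.float32), t1_acpc.affine),
                    out / "t1_acpc.nii",
                )
                written.append("t1_acpc.nii")
            return written

        def do_std():
            std = _acpc.standard_coordinate(state["landmarks_acpc"], config.side)
            state["std"] = std
            with open(out / "standard_coordinate.json", "w") as fh:
                json.dump(
                    {
                        "point_acpc_mm": [float(v) for v in std.point],
                        "side": std.side,
                        "ac_acpc_mm": [float(v) for v in state["landmarks_acpc"].ac],
                        "pc_acpc_mm": [float(v) for v in state["landmarks_acpc"].pc],
                    },
                    fh, indent=2, sort_keys=True,
                )
                fh.write("\n")
            return ["standard_coordinate.json"]

        def do_registration():
            t1 = load_volume(config.t1)
            dwi = load_volume(config.dwi)
            scheme = load_scheme(config.bval, config.bvec)
            b0 = Volume(
                dwi.data[..., scheme.b0_mask].mean(axis=-1), dwi.affine
            )
            res = register_rigid(b0, t1, n_levels=3)
            state["t1_to_dwi"] = res
            with open(out / "t1_to_dwi_rigid.json", "w") as fh:
                json.dump(
                    {
                        "rotation": res.transform.rotation.tolist(),
                        "translation_mm": res.transform.translation.tolist(),
                        "final_distance": res.final_distance,
                        "levels_used": res.levels_used,
                        "converged": res.converged,
                    },
                    fh, indent=2, sort_keys=True,
                )
                fh.write("\n")
            return ["t1_to_dwi_rigid.json"]

        def do_dti():
            _require(
                "dti_preprocessing",
                dwi=config.dwi, bval=config.bval, bvec=config.bvec,
            )
            dwi = load_volume(config.dwi)
            scheme = load_scheme(config.bval, config.bvec)
            vol = lanczos3_resample(dwi, config.supersample_spacing_mm)
            vol = gaussian_smooth(vol, config.smooth_sigma_mm)
            tf = fit_tensors(vol, scheme)
            state["tensors"] = tf
            save_tensorfield(tf, out / "tensors.nii")
            fa = fa_map(tf)
            state["fa"] = fa
            save_volume(Volume(fa.data.astype(np.float32), fa.affine), out / "fa.nii")
            return ["tensors.nii", "fa.nii"]

        def do_tracking():
            _require(
                "fiber_tracking",
                roi_manifest=config.roi_manifest, atlas=config.atlas,
            )
            rs = load_roiset(config.roi_manifest)
            atlas = load_volume(config.atlas)
            specs = (
                load_bundle_specs(config.bundles)
                if config.bundles
                else default_bundle_specs(config.side)
            )
            pm = (
                load_parameter_map(config.parameter_map)
                if config.parameter_map
                else default_parameter_map()
            )
            fatal = [v for v in validate_roiset(rs, specs) if v.fatal]
            if fatal:
                msgs = "; ".join(f"{v.bundle}/{v.roi}: {v.problem}" for v in fatal)
                raise StageError("fiber_tracking-inputs", f"ROI set invalid: {msgs}")
            tf = state["tensors"]
            written = []
            state["bundles"] = {}
            for i, spec in enumerate(specs):
                bundle = track_bundle(
                    spec, rs, tf, atlas, pm,
                    rng_seed=int(config.seed) + i,
                    batch_size=config.batch_size,
                )
                state["bundles"][spec.name] = bundle
                save_bundle_trk(bundle, state["fa"], out / f"{spec.name}.trk")
                save_bundle_summary(bundle, out / f"{spec.name}_summary.json")
                written += [f"{spec.name}.trk", f"{spec.name}_summary.json"]
            return written

        def do_thresholding():
            t = state["transform"]
            written = []
            state["maps"] = {}
            for name, bundle in state["bundles"].items():
                if bundle.n_accepted == 0:
                    log_lines.append(f"thresholding: {name} empty, map skipped")
                    continue
                pmap = probability_map(bundle, state["fa"])
                acpc_map = _acpc.reorient_to_acpc(pmap.volume, t, target_spacing=1.0)
                from .tracking import ProbabilityMap

                thr = threshold_map(
                    ProbabilityMap(acpc_map), name, pipeline=config.pipeline_dialect
                )
                state["maps"][name] = thr
                fname = f"{name}_map_acpc.nii"
                save_volume(
                    Volume(thr.volume.data.astype(np.float32), thr.volume.affine),
                    out / fname,
                )
                written.append(fname)
            return written

        def do_evaluation():
            _require("evaluation", treatment_log=config.treatment_log)
            df = load_treatment_log(config.treatment_log)
            pts = filter_treatment_points(
                df[["x", "y", "z"]].to_numpy(), df["temp_c"].to_numpy()
            )
            lesion_vol = load_volume(config.lesion) if config.lesion else None
            lesion_acpc = None
            if lesion_vol is not None:
                center = lesion_center(
                    Volume(lesion_vol.data.astype(bool), lesion_vol.affine)
                )
                # a one-voxel mask in AC-PC space standing in for the lesion
                lesion_acpc = _acpc.reorient_to_acpc(
                    Volume(lesion_vol.data.astype(float), lesion_vol.affine),
                    state["transform"],
                )
                lesion_acpc = Volume(lesion_acpc.data > 0.5, lesion_acpc.affine)
            rep = evaluation_report(
                state["maps"], state["std"], pts, lesion_mask=lesion_acpc
            )
            with open(out / "evaluation.json", "w") as fh:
                json.dump(rep, fh, indent=2, sort_keys=True)
                fh.write("\n")
            return ["evaluation.json"]

        run_stage("acpc_alignment", do_acpc)
        run_stage("standard_coordinate", do_std)
        run_stage(
            "registration", do_registration,
            skip=not (config.register_t1 and config.t1),
        )
        run_stage("dti_preprocessing", do_dti)
        run_stage("fiber_tracking", do_tracking)
        run_stage("thresholding", do_thresholding)
        run_stage("evaluation", do_evaluation, skip=config.treatment_log is None)
    except StageError as exc:
        report["status"] = "failed"
        report["failed_stage"] = exc.stage
        report["error"] = str(exc)
        log_lines.append(f"FAILED {exc.stage}: {exc}")

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "plan.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return report
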