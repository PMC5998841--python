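"""End-to-end orchestration: simulate/register/segment/detect/track/evaluate.

``run_pipeline`` drives the stages in order on one device slot,
caching every intermediate artifact in the output directory so stages
can be rerun or resumed individually.  A manifest records the
configuration, seed and stage status for reproducibility.  In
``synthetic`` mode the input data are generated by :mod:`.synthgen`;
in ``real`` mode frames are read from a directory and the end-point
nuclei coordinates from CSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import detect as detectmod
from . import evaluate as evalmod
from . import registration as regmod
from . import synthgen
from . import track as trackmod
from . import vessel as vesselmod

logger = logging.getLogger("angiotrack")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage (and frame)."""


class ConfigError(ValueError):
    """Invalid pipeline configuration (caught before any stage runs)."""


@dataclass
class PipelineConfig:
    outdir: str = "angiotrack_out"
    mode: str = "synthetic"               # 'synthetic' | 'real'
    rng_seed: int = 0
    log_level: str = "INFO"
    # real-mode inputs
    frames_dir: str | None = None
    endpoint_csv: str | None = None
    detections_csv: str | None = None
    # stage parameters
    simulation: synthgen.SimulationConfig = field(
        default_factory=synthgen.SimulationConfig)
    morphology: vesselmod.MorphologyConfig = field(
        default_factory=vesselmod.MorphologyConfig)
    detector_mode: str = "cnn"            # 'cnn' | 'csv'
    detector_epochs: int = 4
    detector_bank: int = 40               # base templates per class
    stride: int = 4
    score_threshold: float = 0.5
    q_pos: float = 2.0
    q_vel: float = 2.0
    r: float = 4.0
    gate_gamma: float = 5.991
    mht: dict = field(default_factory=dict)
    match_radius: float = 15.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("simulation", {})
        for key in ("image_shape", "migration_speed",
                    "misalignment_scale"):
            if isinstance(sim_raw.get(key), list):
                sim_raw[key] = tuple(sim_raw[key])
        sim = synthgen.SimulationConfig(**sim_raw)
        morph = vesselmod.MorphologyConfig(**raw.pop("morphology", {}))
        return cls(simulation=sim, morphology=morph, **raw)

    def validate(self):
        if self.mode not in ("synthetic", "real"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.detector_mode not in ("cnn", "csv"):
            raise ConfigError(f"unknown detector_mode {self.detector_mode!r}")
        if self.mode == "real":
            for name in ("frames_dir", "endpoint_csv"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ConfigError(f"{name} missing or does not exist: "
                                      f"{p!r}")
            if self.detector_mode == "csv" and (
                    self.detections_csv is None
                    or not Path(self.detections_csv).exists()):
                raise ConfigError("detections_csv missing for csv detector")

    def kalman_params(self) -> trackmod.KalmanParams:
        return trackmod.KalmanParams.default(
            q_pos=self.q_pos, q_vel=self.q_vel, r=self.r,
            gate_gamma=self.gate_gamma)

    def mht_config(self, image_height: float) -> trackmod.MhtConfig:
        kwargs = dict(self.mht)
        return trackmod.MhtConfig.scaled_for_height(image_height, **kwargs)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()


def _save_png(path, image):
    iio.imwrite(path, (np.clip(image, 0, 1) * 255).astype(np.uint8))


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict:
    """Run all stages; returns a dict of artifact paths.

    Artifacts: registered frames + transforms JSON, vessel mask PNG and
    MAT CSV, detections CSV, tracks CSV, lineage JSON/PNG, and (in
    synthetic mode) an evaluation report JSON.  Partial outputs are
    retained when a stage fails.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(),
                                      logging.INFO))
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = {"config_digest": config.digest(),
                "rng_seed": config.rng_seed, "stages": {}}
    if resume and manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_digest") == manifest["config_digest"]:
            manifest = old
    artifacts: dict = {}

    def done(stage):
        return resume and manifest["stages"].get(stage) == "done"

    def mark(stage):
        manifest["stages"][stage] = "done"
        manifest_path.write_text(json.dumps(manifest, indent=2))

    # ---- stage 1: acquire / simulate --------------------------------
    truth = None
    if config.mode == "synthetic":
        logger.info("stage simulate: seed=%d", config.rng_seed)
        sim = dataclasses.replace(config.simulation,
                                  rng_seed=config.rng_seed)
        try:
            ds = synthgen.simulate_dataset(sim, render=True)
        except Exception as exc:
            raise PipelineError(f"stage simulate failed: {exc}") from exc
        truth = ds.truth
        frames = ds.frames
        for k, frame in enumerate(frames):
            _save_png(out / f"frame_{k:03d}.png", frame)
        pd.concat(ds.detections).to_csv(out / "detections_true.csv",
                                        index=False)
        truth.to_frame_table().to_csv(out / "truth.csv", index=False)
        ep = truth.endpoint_cells()
        pd.DataFrame(ep, columns=["x", "y"]).to_csv(
            out / "endpoint.csv", index=False)
        endpoint_csv = out / "endpoint.csv"
        detections_csv = out / "detections_true.csv"
        artifacts["truth"] = str(out / "truth.csv")
        mark("simulate")
    else:
        paths = sorted(Path(config.frames_dir).glob("*.png")) \
            + sorted(Path(config.frames_dir).glob("*.tif*"))
        if len(paths) < 2:
            raise PipelineError("stage simulate failed: need >= 2 frames")
        frames = [np.asarray(iio.imread(p), dtype=float) for p in paths]
        frames = [f / 255.0 if f.max() > 1.5 else f for f in frames]
        endpoint_csv = Path(config.endpoint_csv)
        detections_csv = config.detections_csv

    # ---- stage 2: registration --------------------------------------
    t = len(frames)
    registered = []
    transforms = []
    ref_lines = None
    try:
        ref_lines = regmod.detect_post_lines(frames[-1], frame=t - 1)
        ref_pts = regmod.line_intersections(ref_lines)
        for k, frame_img in enumerate(frames):
            if k == t - 1:
                T = regmod.SimilarityTransform()
                lines = ref_lines
            else:
                lines = regmod.detect_post_lines(frame_img, frame=k)
                pts = regmod.line_intersections(lines)
                T = regmod.estimate_transform(pts, ref_pts)
            transforms.append(T)
            registered.append(
                regmod.apply_transform_and_mask(frame_img, T, lines))
            _save_png(out / f"registered_{k:03d}.png", registered[-1])
    except (regmod.RegistrationError,
            regmod.DegenerateGeometryError) as exc:
        raise PipelineError(f"stage register failed: {exc}") from exc
    with open(out / "transforms.json", "w") as fh:
        json.dump([T.to_dict() for T in transforms], fh, indent=2)
    artifacts["transforms"] = str(out / "transforms.json")
    mark("register")

    # ---- stage 3: vessel segmentation -------------------------------
    try:
        ap = regmod.line_intersections(ref_lines)[-1][0]
        ref_img = registered[-1]
        rho2, th2 = ref_lines.line(2)
        w_img = ref_img.shape[1]
        post_top_y = (rho2 - (w_img / 2) * np.cos(th2)) / np.sin(th2)
        parabola = vesselmod.fit_interface_parabola(
            ref_img, ap, y_max=post_top_y - 10)
        masked = vesselmod.mask_below_parabola(ref_img, parabola)
        thr = vesselmod.otsu_threshold(masked[masked > 0])
        binary = masked > thr
        mask = vesselmod.segment_vessel(binary, config.morphology)
        if not mask.any():
            logger.warning("stage segment: empty vessel mask")
            vessel = None
        else:
            vessel = vesselmod.medial_axis_transform(mask)
        _save_png(out / "vessel_mask.png", mask.astype(float))
        if vessel is not None:
            rows = []
            for b, (chain, rad) in enumerate(zip(vessel.branches,
                                                 vessel.radii)):
                for i, ((x, y), r) in enumerate(zip(chain, rad)):
                    rows.append({"branch_id": b, "order_idx": i,
                                 "x": x, "y": y, "radius": r})
            pd.DataFrame(rows).to_csv(out / "vessel_mat.csv", index=False)
            artifacts["vessel_mat"] = str(out / "vessel_mat.csv")
    except vesselmod.DegenerateInputError as exc:
        raise PipelineError(f"stage segment failed: {exc}") from exc
    artifacts["vessel_mask"] = str(out / "vessel_mask.png")
    mark("segment")

    # ---- stage 4: detection -----------------------------------------
    if config.detector_mode == "csv":
        if detections_csv is None:
            raise PipelineError("stage detect failed: no detections CSV")
        detections = detectmod.detections_from_csv(detections_csv)
    else:
        sim = dataclasses.replace(config.simulation,
                                  rng_seed=config.rng_seed)
        patches, labels = synthgen.make_template_bank(
            sim, n_cell=config.detector_bank,
            n_noncell=config.detector_bank)
        bank, bank_labels = detectmod.augment_templates(
            patches, labels, rng_seed=config.rng_seed)
        model, _ = detectmod.train_classifier(
            bank, bank_labels, rng_seed=config.rng_seed,
            epochs=config.detector_epochs, cross_validate=False)
        detections = []
        for k, img in enumerate(registered):
            detections.append(detectmod.sliding_window_detect(
                img, model, vessel=vessel, stride=config.stride,
                score_threshold=config.score_threshold, frame=k))
    pd.concat(detections).to_csv(out / "detections.csv", index=False)
    artifacts["detections"] = str(out / "detections.csv")
    mark("detect")

    # ---- stage 5: tracking ------------------------------------------
    endpoint = pd.read_csv(endpoint_csv)[["x", "y"]].to_numpy(dtype=float)
    params = config.kalman_params()
    mht = config.mht_config(frames[0].shape[0])
    interface = parabola if parabola is not None else None
    result = trackmod.run_backward_mht(
        endpoint, detections, params=params, config=mht,
        vessel=vessel, interface=interface)
    result.to_table().to_csv(out / "tracks.csv", index=False)
    (out / "lineage.json").write_text(result.lineage.to_json())
    result.lineage.plot(path=out / "lineage.png")
    artifacts["tracks"] = str(out / "tracks.csv")
    artifacts["lineage"] = str(out / "lineage.json")
    artifacts["lineage_plot"] = str(out / "lineage.png")
    mark("track")

    # ---- stage 6: evaluation (synthetic truth only) -----------------
    if truth is not None:
        report = evaluate_against_truth(result, detections, truth,
                                        match_radius=config.match_radius)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        artifacts["report"] = str(out / "report.json")
        mark("evaluate")

    return artifacts


def evaluate_against_truth(result, detections, truth,
                           match_radius: float = 15.0) -> dict:
    """Detection precision/recall/F1 and association accuracy vs truth."""
    tp = fp = fn = 0
    for k, det in enumerate(detections):
        _, pts = truth.positions(k, include_oof=False)
        xy = det[["x", "y"]].to_numpy(dtype=float) if len(det) \
            else np.empty((0, 2))
        c = evalmod.confusion_counts(xy, pts, match_radius)
        tp, fp, fn = tp + c.TP, fp + c.FP, fn + c.FN
    counts = evalmod.ConfusionCounts(TP=tp, FP=fp, FN=fn)
    try:
        precision, recall, f1 = evalmod.precision_recall_f1(counts)
    except evalmod.UndefinedMetricError:
        precision = recall = f1 = float("nan")
    assoc = evalmod.association_accuracy(result.links(),
                                         truth.truth_links(),
                                         match_radius)
    return {"detection": {"TP": tp, "FP": fp, "FN": fn,
                          "precision": precision, "recall": recall,
                          "f1": f1},
            "association": {"correct": assoc.correct,
                            "total": assoc.total,
                            "accuracy": assoc.accuracy}}
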