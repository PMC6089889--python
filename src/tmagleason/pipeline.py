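"""End-to-end pipeline orchestration with reproducible stage manifests.

Each stage reads its inputs from the run directory, writes its outputs
under ``<run_dir>/<stage>/`` and records a manifest (config hash, seed,
inputs, outputs, wall time).  Re-running with an identical
configuration and seed reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifier import NetworkConfig, TrainConfig, build_network, train
from .evaluation import SPOT_SCORE_ORDER, confusion_matrix, macro_recall, quadratic_kappa
from .fcn import convert_to_fcn, probability_map
from .patches import FULL_GEOMETRY, HALF_GEOMETRY, PatchDataset, PatchGeometry
from .scoring import ScoringConfig, score_cohort
from .survival import plot_stratification, stratification_report
from .synthetic import AnnotatedSpot, HazardParams, generate_cohort
from .tissue import TissueMaskParams, detect_tissue

__all__ = ["PipelineConfig", "STAGES", "run_pipeline"]

STAGES = ("simulate", "mask", "patch", "train", "infer", "score",
          "evaluate", "cam", "survival")

_PROFILES = {
    "full": {"spot_size": 3100, "geometry": FULL_GEOMETRY, "morph_radius": 10},
    "half": {"spot_size": 1550, "geometry": HALF_GEOMETRY, "morph_radius": 5},
}


@dataclass
class PipelineConfig:
    out_dir: str = "runs/run0"
    profile: str = "half"
    n_spots: int = 24
    holdout_fraction: float = 0.3
    seed: int = 0
    width_multiplier: float = 0.5
    input_size: int = 224
    dropout_rate: float = 0.2
    train_mode: str = "scratch"
    iterations: int = 50_000
    batch_size: int = 32
    eval_interval: int = 250
    scoring_threshold: float = 0.25
    cam_examples: int = 4

    def __post_init__(self):
        if self.profile not in _PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")

    @property
    def geometry(self) -> PatchGeometry:
        geom = _PROFILES[self.profile]["geometry"]
        if self.input_size != geom.crop_size:
            geom = PatchGeometry(geom.patch_size, geom.step, geom.label_window,
                                 geom.resize_to, self.input_size)
        return geom

    @property
    def spot_size(self) -> int:
        return _PROFILES[self.profile]["spot_size"]

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _write_manifest(stage_dir: Path, cfg: PipelineConfig, stage: str,
                    inputs: list[str], outputs: list[str], t0: float) -> None:
    manifest = {
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "inputs": sorted(inputs),
        "outputs": sorted(outputs),
        "wall_time_s": round(time.time() - t0, 3),
        "version": __version__,
    }
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _require(run_dir: Path, stage: str, needed_by: str) -> Path:
    d = run_dir / stage
    if not (d / "manifest.json").exists():
        raise FileNotFoundError(
            f"stage {needed_by!r} requires missing artifact of stage {stage!r} "
            f"(expected {d}/manifest.json)")
    return d


def _load_spots(run_dir: Path) -> list[AnnotatedSpot]:
    sim = run_dir / "simulate"
    spots = []
    for img_path in sorted((sim / "spots").glob("*.png")):
        sid = img_path.stem
        mask = iio.imread(sim / "masks" / f"{sid}.png")
        spots.append(AnnotatedSpot(sid, iio.imread(img_path), mask))
    return spots


# --------------------------------------------------------------------------
# stages

def _stage_simulate(cfg: PipelineConfig, run_dir: Path) -> None:
    t0 = time.time()
    out = run_dir / "simulate"
    (out / "spots").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    cohort = generate_cohort(cfg.n_spots, rng_seed=cfg.seed,
                             spot_size_px=cfg.spot_size)
    outputs = []
    for spot in cohort.spots:
        s = spot.realize()
        iio.imwrite(out / "spots" / f"{s.spot_id}.png", s.image)
        iio.imwrite(out / "masks" / f"{s.spot_id}.png", s.mask)
        outputs += [f"spots/{s.spot_id}.png", f"masks/{s.spot_id}.png"]
    cohort.clinical.to_csv(out / "clinical.csv", index=False)
    _write_manifest(out, cfg, "simulate", [], outputs + ["clinical.csv"], t0)


def _stage_mask(cfg: PipelineConfig, run_dir: Path) -> None:
    t0 = time.time()
    _require(run_dir, "simulate", "mask")
    out = run_dir / "mask"
    out.mkdir(parents=True, exist_ok=True)
    params = TissueMaskParams(morph_radius=_PROFILES[cfg.profile]["morph_radius"])
    outputs = []
    for spot in _load_spots(run_dir):
        m = detect_tissue(spot.image, params)
        iio.imwrite(out / f"{spot.spot_id}.png",
                    (m * 255).astype(np.uint8))
        outputs.append(f"{spot.spot_id}.png")
    _write_manifest(out, cfg, "mask", ["simulate"], outputs, t0)


def _split_ids(cfg: PipelineConfig, ids: list[str]) -> tuple[list[str], list[str]]:
    rng = np.random.default_rng(cfg.seed + 101)
    ids = sorted(ids)
    rng.shuffle(ids)
    n_hold = max(int(len(ids) * cfg.holdout_fraction), 1)
    return ids[n_hold:], ids[:n_hold]


def _stage_patch(cfg: PipelineConfig, run_dir: Path) -> None:
    t0 = time.time()
    _require(run_dir, "simulate", "patch")
    out = run_dir / "patch"
    out.mkdir(parents=True, exist_ok=True)
    spots = _load_spots(run_dir)
    train_ids, hold_ids = _split_ids(cfg, [s.spot_id for s in spots])
    geom = cfg.geometry
    by_id = {s.spot_id: s for s in spots}
    ds_train = PatchDataset.from_spots([by_id[i] for i in train_ids], geom)
    ds_hold = PatchDataset.from_spots([by_id[i] for i in hold_ids], geom)
    np.savez_compressed(out / "train.npz", images=ds_train.images,
                        labels=ds_train.labels)
    np.savez_compressed(out / "holdout.npz", images=ds_hold.images,
                        labels=ds_hold.labels)
    ds_train.manifest().to_csv(out / "train_manifest.csv", index=False)
    ds_hold.manifest().to_csv(out / "holdout_manifest.csv", index=False)
    json.dump({"train_spots": train_ids, "holdout_spots": hold_ids},
              open(out / "split.json", "w"), indent=2)
    _write_manifest(out, cfg, "patch", ["simulate"],
                    ["train.npz", "holdout.npz", "train_manifest.csv",
                     "holdout_manifest.csv", "split.json"], t0)


def _load_dataset(path: Path, geom) -> PatchDataset:
    data = np.load(path)
    n = len(data["labels"])
    return PatchDataset(images=data["images"], labels=data["labels"],
                        spot_ids=[""] * n, top_lefts=[(0, 0)] * n,
                        geometry=geom)


def _stage_train(cfg: PipelineConfig, run_dir: Path) -> None:
    t0 = time.time()
    patch_dir = _require(run_dir, "patch", "train")
    out = run_dir / "train"
    out.mkdir(parents=True, exist_ok=True)
    geom = cfg.geometry
    ds_train = _load_dataset(patch_dir / "train.npz", geom)
    ds_hold = _load_dataset(patch_dir / "holdout.npz", geom)
    net_cfg = NetworkConfig(width_multiplier=cfg.width_multiplier,
                            input_size=cfg.input_size,
                            dropout_rate=cfg.dropout_rate, rng_seed=cfg.seed)
    clf = build_network(net_cfg)
    tr_cfg = TrainConfig(mode=cfg.train_mode, iterations=cfg.iterations,
                         batch_size=cfg.batch_size,
                         eval_interval=cfg.eval_interval, rng_seed=cfg.seed)
    history = train(clf, ds_train, tr_cfg, holdout=ds_hold)
    state = clf.model.state_dict()
    np.savez_compressed(out / "weights.npz", input_mean=clf.input_mean, **state)
    (out / "architecture.json").write_text(json.dumps({
        "width_multiplier": cfg.width_multiplier,
        "input_size": cfg.input_size,
        "n_classes": 4,
        "dropout_rate": cfg.dropout_rate,
        "rng_seed": cfg.seed,
        "n_parameters": clf.n_parameters(),
    }, indent=2))
    pd.DataFrame({"iteration": history.iterations,
                  "loss": history.loss}).to_csv(out / "loss.csv", index=False)
    pd.DataFrame({"iteration": history.eval_iterations,
                  "macro_recall": history.macro_recall}).to_csv(
        out / "eval.csv", index=False)
    _write_manifest(out, cfg, "train", ["patch"],
                    ["weights.npz", "architecture.json", "loss.csv",
                     "eval.csv"], t0)


def load_model(train_dir: Path):
    """Rebuild a trained classifier from a train-stage directory."""
    arch = json.loads((Path(train_dir) / "architecture.json").read_text())
    clf = build_network(NetworkConfig(
        width_multiplier=arch["width_multiplier"],
        input_size=arch["input_size"],
        dropout_rate=arch["dropout_rate"], rng_seed=arch["rng_seed"]))
    data = np.load(Path(train_dir) / "weights.npz")
    clf.input_mean = data["input_mean"]
    clf.model.load_state_dict({k: data[k] for k in data.files
                               if k != "input_mean"})
    return clf


def _stage_infer(cfg: PipelineConfig, run_dir: Path) -> None:
    t0 = time.time()
    train_dir = _require(run_dir, "train", "infer")
    mask_dir = _require(run_dir, "mask", "infer")
    patch_dir = _require(run_dir, "patch", "infer")
    out = run_dir / "infer"
    out.mkdir(parents=True, exist_ok=True)
    clf = load_model(train_dir)
    annotator = convert_to_fcn(clf, model_id=cfg.config_hash())
    geom = cfg.geometry
    scale = geom.resize_to / geom.patch_size
    hold = json.loads((patch_dir / "split.json").read_text())["holdout_spots"]
    outputs = []
    for spot in _load_spots(run_dir):
        if spot.spot_id not in hold:
            continue
        tissue = iio.imread(mask_dir / f"{spot.spot_id}.png") > 0
        pmap = probability_map(annotator, spot.image, tissue,
                               working_scale=scale)
        np.savez_compressed(out / f"{spot.spot_id}.npz",
                            probs=pmap.probs, tissue=pmap.tissue_mask)
        (out / f"{spot.spot_id}.json").write_text(json.dumps(
            {"channels": ["Benign", "G3", "G4", "G5"], **pmap.meta}, indent=2))
        outputs += [f"{spot.spot_id}.npz", f"{spot.spot_id}.json"]
    _write_manifest(out, cfg, "infer", ["train", "mask", "patch"], outputs, t0)


def _stage_score(cfg: PipelineConfig, run_dir: Path) -> None:
    t0 = time.time()
    infer_dir = _require(run_dir, "infer", "score")
    out = run_dir / "score"
    out.mkdir(parents=True, exist_ok=True)
    from .synthetic import ProbabilityMap
    maps = {}
    for f in sorted(infer_dir.glob("*.npz")):
        data = np.load(f)
        maps[f.stem] = ProbabilityMap(data["probs"], data["tissue"])
    table = score_cohort(maps, ScoringConfig(threshold=cfg.scoring_threshold))
    table.to_csv(out / "scores.csv", index=False)
    _write_manifest(out, cfg, "score", ["infer"], ["scores.csv"], t0)


def _stage_evaluate(cfg: PipelineConfig, run_dir: Path) -> None:
    t0 = time.time()
    score_dir = _require(run_dir, "score", "evaluate")
    sim_dir = _require(run_dir, "simulate", "evaluate")
    out = run_dir / "evaluate"
    out.mkdir(parents=True, exist_ok=True)
    pred = pd.read_csv(score_dir / "scores.csv")
    truth = pd.read_csv(sim_dir / "clinical.csv")
    df = pred.merge(truth, on="spot_id")
    O, norm = confusion_matrix(df["true_score"], df["score"], SPOT_SCORE_ORDER)
    try:
        kappa = quadratic_kappa(O)
    except ValueError:
        kappa = float("nan")
    report = {
        "n_spots": int(len(df)),
        "exact_agreement": float((df["true_score"] == df["score"]).mean()),
        "quadratic_kappa": kappa,
        "macro_recall": macro_recall(O),
        "score_order": list(SPOT_SCORE_ORDER),
        "confusion": O.tolist(),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    pd.DataFrame(O, index=SPOT_SCORE_ORDER,
                 columns=SPOT_SCORE_ORDER).to_csv(out / "confusion.csv")
    _write_manifest(out, cfg, "evaluate", ["score", "simulate"],
                    ["report.json", "confusion.csv"], t0)


def _stage_cam(cfg: PipelineConfig, run_dir: Path) -> None:
    t0 = time.time()
    train_dir = _require(run_dir, "train", "cam")
    patch_dir = _require(run_dir, "patch", "cam")
    out = run_dir / "cam"
    out.mkdir(parents=True, exist_ok=True)
    from .cam import class_activation_map, render_triptych, select_confident
    clf = load_model(train_dir)
    ds = _load_dataset(patch_dir / "holdout.npz", cfg.geometry)
    outputs = []
    if len(ds):
        crops = ds.center_crops(clf.config.input_size)
        x = clf.normalize(crops)
        idx = select_confident(x, ds.labels, clf)[:cfg.cam_examples]
        for i in idx:
            cam = class_activation_map(clf, x[i], int(ds.labels[i]))
            name = f"cam_{i:04d}_{cam.target_name}.png"
            render_triptych(crops[i], cam, out / name)
            outputs.append(name)
    _write_manifest(out, cfg, "cam", ["train", "patch"], outputs, t0)


def _stage_survival(cfg: PipelineConfig, run_dir: Path) -> None:
    t0 = time.time()
    score_dir = _require(run_dir, "score", "survival")
    sim_dir = _require(run_dir, "simulate", "survival")
    out = run_dir / "survival"
    out.mkdir(parents=True, exist_ok=True)
    scores = pd.read_csv(score_dir / "scores.csv")
    clinical = pd.read_csv(sim_dir / "clinical.csv")
    report = stratification_report(scores, clinical)
    payload = {
        "n_records": report.n_records,
        "group_sizes": report.group_sizes,
        "pairwise": report.pairwise.to_dict(orient="records"),
        "metadata": report.metadata,
    }
    (out / "report.json").write_text(json.dumps(payload, indent=2))
    plot_stratification(report, out / "km.png")
    _write_manifest(out, cfg, "survival", ["score", "simulate"],
                    ["report.json", "km.png"], t0)


_STAGE_FN = {
    "simulate": _stage_simulate,
    "mask": _stage_mask,
    "patch": _stage_patch,
    "train": _stage_train,
    "infer": _stage_infer,
    "score": _stage_score,
    "evaluate": _stage_evaluate,
    "cam": _stage_cam,
    "survival": _stage_survival,
}


def run_pipeline(config: PipelineConfig,
                 stages: tuple[str, ...] = STAGES) -> Path:
    """Run the requested stages in canonical order; returns the run dir."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.yaml").write_text(yaml.safe_dump(asdict(config)))
    for stage in STAGES:
        if stage in stages:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _STAGE_FN[stage](config, run_dir)
    return run_dir
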