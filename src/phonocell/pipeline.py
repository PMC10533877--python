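"""End-to-end orchestration: simulate -> fit -> encode -> train -> evaluate.

Every stage writes its artifacts into the run directory and later stages
load them from disk, so a partially complete run resumes per stage and
each subcommand of the CLI composes through the filesystem.  Every
artifact set is stamped with the configuration hash and master seed in
``manifest.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .acquisition import AcquisitionParams, ClassLabel
from .cnn import ModelConfig, SplitPlan, make_split, train, predict_proba, \
    save_model, load_model
from .dataset import GasfDataset, build_image_set
from .evaluate import (accuracy_vs_measurements, confusion_and_accuracy,
                       sweep_classification_map)
from .gasf import encode_traces_array
from .processing import cell_centroid, fit_scan
from .simulate import ClassDistribution, ClassParamModel, generate_dataset, \
    simulate_parameter_sweep
from . import io as pio

logger = logging.getLogger(__name__)

__all__ = ["SimulationConfig", "EncodingConfig", "EvaluationConfig",
           "PipelineConfig", "StageError", "run_pipeline", "STAGES"]


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class SimulationConfig:
    n_cells_per_class: int = 8
    n_batches: int = 4
    grid_shape: tuple = (21, 21)
    noise_sigma: float = 0.1
    sample_interval_ps: float = 10.0
    n_samples: int = 256
    class_model: dict = field(default_factory=dict)  # per-class overrides

    def acquisition(self) -> AcquisitionParams:
        return AcquisitionParams(sample_interval_ps=self.sample_interval_ps,
                                 n_samples=self.n_samples)

    def param_model(self) -> ClassParamModel:
        model = ClassParamModel()
        for name, over in self.class_model.items():
            label = ClassLabel.from_name(name)
            model.classes[label] = dataclasses.replace(
                model.classes[label], **over)
        return model


@dataclass
class EncodingConfig:
    image_size: int = 64
    fit_pixels_per_cell: int = 40   # pixels fitted per cell for centroids
    eval_pixels: int = 2000         # test pixels scored in the report
    vote_pixels_per_cell: int = 150  # cell pixels kept per test cell for voting


@dataclass
class EvaluationConfig:
    test_subsample: int | None = 1000
    k_values: tuple = (1, 3, 5, 9, 15)
    n_repetitions: int = 250
    sweep_nu: tuple = (1450.0, 1850.0, 9)
    sweep_alpha: tuple = (0.05, 3.0, 9)
    sweep_replicates: int = 3


@dataclass
class PipelineConfig:
    """Fully serialisable configuration of an end-to-end run."""

    master_seed: int = 0
    out_dir: str = "runs/demo"
    fraction_train: float = 0.7
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (("simulation", SimulationConfig),
                         ("encoding", EncodingConfig),
                         ("model", ModelConfig),
                         ("evaluation", EvaluationConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        cfg = cls(**d)
        cfg.simulation.grid_shape = tuple(cfg.simulation.grid_shape)
        cfg.model.conv_blocks = tuple(tuple(b) for b in cfg.model.conv_blocks)
        cfg.model.fc_sizes = tuple(cfg.model.fc_sizes)
        cfg.evaluation.k_values = tuple(cfg.evaluation.k_values)
        cfg.evaluation.sweep_nu = tuple(cfg.evaluation.sweep_nu)
        cfg.evaluation.sweep_alpha = tuple(cfg.evaluation.sweep_alpha)
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def stage_seeds(self) -> dict:
        """Fan the master seed out to one sub-seed per stage (all < 2^31)."""
        state = np.random.SeedSequence(self.master_seed).generate_state(8)
        names = ["simulate", "fit", "encode", "split", "train", "evaluate",
                 "sweep", "vote"]
        return {n: int(s % (2**31)) for n, s in zip(names, state)}


STAGES = ("simulate", "fit", "encode", "train", "evaluate", "sweep", "vote-curve")


class _Run:
    """Lazy access to a run directory's artifacts."""

    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.dir = Path(cfg.out_dir)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.seeds = cfg.stage_seeds()
        self._scans = None
        self._dataset = None
        self._split = None
        self._model = None

    # -- artifacts ---------------------------------------------------------
    @property
    def scans(self):
        if self._scans is None:
            path = self.dir / "scans.h5"
            if not path.exists():
                raise StageError("simulate", FileNotFoundError(path))
            self._scans = pio.load_scans_h5(path)
        return self._scans

    @property
    def dataset(self) -> GasfDataset:
        if self._dataset is None:
            path = self.dir / "images.npz"
            if not path.exists():
                raise StageError("encode", FileNotFoundError(path))
            with np.load(path, allow_pickle=True) as z:
                self._dataset = GasfDataset(
                    z["images"], z["labels"], z["cell_ids"], z["batch_ids"],
                    z["pixels"])
        return self._dataset

    @property
    def split(self) -> SplitPlan:
        if self._split is None:
            path = self.dir / "split.json"
            if not path.exists():
                raise StageError("train", FileNotFoundError(path))
            d = json.loads(path.read_text())
            self._split = SplitPlan(**d)
        return self._split

    @property
    def model(self):
        if self._model is None:
            path = self.dir / "model.npz"
            if not path.exists():
                raise StageError("train", FileNotFoundError(path))
            self._model = load_model(path)
        return self._model


def _stage_simulate(run: _Run) -> None:
    cfg = run.cfg
    scans = generate_dataset(
        n_cells_per_class=cfg.simulation.n_cells_per_class,
        n_batches=cfg.simulation.n_batches,
        grid_shape=cfg.simulation.grid_shape,
        class_param_model=cfg.simulation.param_model(),
        acq=cfg.simulation.acquisition(),
        noise_sigma=cfg.simulation.noise_sigma,
        rng_seed=run.seeds["simulate"])
    pio.save_scans_h5(scans, run.dir / "scans.h5")
    run._scans = scans


def _stage_fit(run: _Run) -> None:
    """Per-cell (nu, alpha0) centroids from fitted subsampled cell pixels."""
    rng = np.random.default_rng(run.seeds["fit"])
    rows = []
    for scan in run.scans:
        mask = scan.phantom.cell_mask
        cell_pixels = np.argwhere(mask)
        n = min(run.cfg.encoding.fit_pixels_per_cell, len(cell_pixels))
        sel = cell_pixels[rng.choice(len(cell_pixels), size=n, replace=False)]
        fits = fit_scan(scan, pixels=[tuple(p) for p in sel])
        cen = cell_centroid(fits, mask, scan.cell_class, scan.cell_id)
        rows.append({"cell_id": cen.cell_id, "class": cen.cell_class.name.lower(),
                     "batch": scan.batch_id, "mean_nu": cen.mean_nu,
                     "mean_alpha0": cen.mean_alpha0, "n_pixels": cen.n_pixels})
    pd.DataFrame(rows).to_csv(run.dir / "centroids.csv", index=False)


def _stage_encode(run: _Run) -> None:
    cfg = run.cfg
    ds = build_image_set(run.scans, image_size=cfg.encoding.image_size,
                         rng_seed=run.seeds["encode"])
    np.savez_compressed(
        run.dir / "images.npz", images=ds.images, labels=ds.labels,
        cell_ids=np.asarray(ds.cell_ids, dtype=object),
        batch_ids=ds.batch_ids, pixels=ds.pixels)
    ds.manifest().to_csv(run.dir / "image_manifest.csv", index=False)
    run._dataset = ds


def _stage_train(run: _Run) -> None:
    cfg = run.cfg
    split = make_split(run.scans, cfg.fraction_train, run.seeds["split"])
    (run.dir / "split.json").write_text(json.dumps(asdict(split), indent=2))
    run._split = split
    model_cfg = dataclasses.replace(cfg.model, rng_seed=run.seeds["train"])
    model, log = train(run.dataset, split, model_cfg)
    save_model(model, run.dir / "model.npz")
    pd.DataFrame(log).to_csv(run.dir / "training_log.csv", index=False)
    run._model = model


def _stage_evaluate(run: _Run) -> None:
    cfg = run.cfg
    ds = run.dataset.for_cells(run.split.test_cell_ids)
    rng = np.random.default_rng(run.seeds["evaluate"])
    n_eval = min(cfg.encoding.eval_pixels, len(ds))
    idx = rng.choice(len(ds), size=n_eval, replace=False)
    sub = ds.subset(idx)
    pred = predict_proba(run.model, sub.images).argmax(axis=1)
    report = confusion_and_accuracy(pred, sub.labels,
                                    subsample=cfg.evaluation.test_subsample,
                                    rng_seed=run.seeds["evaluate"])
    pio.save_report_json(report, run.dir / "report.json")
    pd.DataFrame({"pred": pred, "true": sub.labels,
                  "cell_id": sub.cell_ids}).to_csv(
        run.dir / "test_predictions.csv", index=False)


def _stage_sweep(run: _Run) -> None:
    cfg = run.cfg
    lo, hi, n = cfg.evaluation.sweep_nu
    nu_grid = np.linspace(lo, hi, int(n))
    lo, hi, n = cfg.evaluation.sweep_alpha
    alpha_grid = np.linspace(lo, hi, int(n))
    sweep = simulate_parameter_sweep(
        nu_grid, alpha_grid, cfg.simulation.acquisition(),
        noise_sigma=cfg.simulation.noise_sigma,
        rng_seed=run.seeds["sweep"],
        replicates=cfg.evaluation.sweep_replicates)
    grid, nus, alphas = sweep_classification_map(
        run.model, sweep, image_size=cfg.encoding.image_size)
    df = pd.DataFrame(grid, index=pd.Index(nus, name="nu_m_s"),
                      columns=pd.Index(alphas, name="alpha_um^-1"))
    df.to_csv(run.dir / "sweep_map.csv")


def _stage_vote_curve(run: _Run) -> None:
    cfg = run.cfg
    ds = run.dataset.for_cells(run.split.test_cell_ids)
    rng = np.random.default_rng(run.seeds["vote"])
    cell_preds = {}
    for scan in run.scans:
        if scan.cell_id not in set(run.split.test_cell_ids):
            continue
        sub = ds.for_cells([scan.cell_id])
        on_cell = sub.labels != int(ClassLabel.BACKGROUND)
        imgs = sub.images[on_cell]
        if imgs.shape[0] == 0:
            continue
        keep = min(cfg.encoding.vote_pixels_per_cell, imgs.shape[0])
        sel = rng.choice(imgs.shape[0], size=keep, replace=False)
        pred = predict_proba(run.model, imgs[sel]).argmax(axis=1)
        cell_preds[scan.cell_id] = (pred, int(scan.cell_class))
    k_values = [k for k in cfg.evaluation.k_values
                if k <= min(len(p) for p, _ in cell_preds.values())]
    curve = accuracy_vs_measurements(
        cell_preds, k_values, n_repetitions=cfg.evaluation.n_repetitions,
        rng_seed=run.seeds["vote"])
    pd.DataFrame({"k": curve.k_values,
                  "success_probability": curve.success_probability}).to_csv(
        run.dir / "vote_curve.csv", index=False)


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "fit": _stage_fit,
    "encode": _stage_encode,
    "train": _stage_train,
    "evaluate": _stage_evaluate,
    "sweep": _stage_sweep,
    "vote-curve": _stage_vote_curve,
}


def run_pipeline(config: PipelineConfig, stages=None) -> Path:
    """Execute the pipeline stages and return the run directory.

    ``stages`` defaults to all of :data:`STAGES` in order; passing a
    subset resumes a run whose earlier artifacts already exist on disk.
    """
    run = _Run(config)
    config.to_yaml(run.dir / "config.yaml")
    manifest = {"config_hash": config.config_hash(),
                "master_seed": config.master_seed,
                "stage_seeds": run.seeds, "stages": {}}
    for stage in (stages or STAGES):
        if stage not in _STAGE_FNS:
            raise ValueError(f"unknown stage {stage!r}")
        t0 = time.time()
        logger.info("stage %s [config %s, seed %d]", stage,
                    manifest["config_hash"], config.master_seed)
        try:
            _STAGE_FNS[stage](run)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, exc) from exc
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2)}
        (run.dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return run.dir
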