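"""End-to-end experiment orchestration.

One structured config drives the whole pipeline -- phantom generation, forward
simulation per sensor count, the chosen reconstruction methods (classical and
learned), and evaluation -- with deterministic seeding, per-stage caching by
content hash, and a run manifest recording the provenance of every artifact.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from paxel import __version__
from paxel.interp import compute_tof_map, interp_for_mdirect, pixel_wise_interpolate
from paxel.metrics import MetricRecord, summarize
from paxel.phantoms import AugmentParams, build_dataset
from paxel.simulate import Medium, TimeConfig, make_semicircle_array, simulate_forward
from paxel.estimators import FDUNetReconstructor, TimeReversalReconstructor, TVReconstructor

__all__ = ["ExperimentConfig", "RunManifest", "validate_config", "run_experiment"]

KNOWN_METHODS = ("time_reversal", "iterative", "postdl", "pixeldl", "mdirectdl")
LEARNED = ("postdl", "pixeldl", "mdirectdl")


@dataclass
class ExperimentConfig:
    """Declarative description of one comparison experiment."""

    n_train: int = 100
    n_test: int = 20
    base_seed: int = 11
    sensor_counts: tuple[int, ...] = (32,)
    sound_speed: float = 1500.0
    density: float = 1000.0
    dx: float = 1.0e-4
    grid_size: int = 64
    methods: tuple[str, ...] = ("time_reversal",)
    train_preset: str = "desk"
    epochs: int = 10
    learning_rate: float = 3e-3
    tv_lambda: float = 1e-2
    tv_iters: int = 25
    out_dir: str = "paxel_runs"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        for key in ("sensor_counts", "methods"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class RunManifest:
    """Stage-by-stage record of inputs, outputs, seeds and hashes."""

    config_hash: str
    seed: int
    version: str
    stages: list[dict] = field(default_factory=list)
    started: float = field(default_factory=time.time)

    def record(self, name: str, out_hash: str, cached: bool, **extra) -> None:
        self.stages.append({"stage": name, "hash": out_hash, "cached": cached,
                            "time": time.time(), **extra})

    def to_json(self) -> str:
        return json.dumps({"config_hash": self.config_hash, "seed": self.seed,
                           "version": self.version, "started": self.started,
                           "stages": self.stages}, indent=2)


def validate_config(cfg: ExperimentConfig) -> list[str]:
    """Human-readable list of problems; empty iff the config is runnable."""
    issues: list[str] = []
    if cfg.n_train < 1 or cfg.n_test < 1:
        issues.append("n_train and n_test must be >= 1")
    if not cfg.sensor_counts:
        issues.append("at least one sensor count is required")
    for n in cfg.sensor_counts:
        if n < 2:
            issues.append(f"sensor count {n} is too small (need >= 2)")
    for m in cfg.methods:
        if m not in KNOWN_METHODS:
            issues.append(f"unknown method {m!r}; known: {KNOWN_METHODS}")
    if cfg.grid_size < 16:
        issues.append("grid_size must be >= 16")
    if cfg.grid_size % 4:
        issues.append("grid_size must be divisible by 4 (network pooling)")
    if cfg.sound_speed <= 0 or cfg.dx <= 0:
        issues.append("sound_speed and dx must be positive")
    if cfg.train_preset not in ("full", "desk"):
        issues.append("train_preset must be 'full' or 'desk'")
    if any(m in LEARNED for m in cfg.methods) and cfg.n_train < 2:
        issues.append("learned methods need a training set (n_train >= 2)")
    return issues


def _hash(*parts) -> str:
    h = hashlib.sha256()
    for p in parts:
        if isinstance(p, np.ndarray):
            h.update(np.ascontiguousarray(p).tobytes())
        else:
            h.update(repr(p).encode())
    return h.hexdigest()[:16]


def _cache_path(out_dir: Path, name: str, key: str) -> Path:
    return out_dir / "cache" / f"{name}-{key}.npz"


def _cached(out_dir: Path, name: str, key: str, compute, manifest: RunManifest, **extra):
    path = _cache_path(out_dir, name, key)
    if path.exists():
        with np.load(path) as z:
            result = {k: z[k] for k in z.files}
        manifest.record(name, key, cached=True, **extra)
        return result
    result = compute()
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, **result)
    manifest.record(name, key, cached=False, **extra)
    return result


def run_experiment(cfg: ExperimentConfig) -> tuple[RunManifest, pd.DataFrame]:
    """Execute all stages the config needs, in dependency order, with caching.

    Returns the manifest and the summary table (mean +/- std PSNR/SSIM per
    method and sensor count).  Stage outputs land under ``cfg.out_dir``.
    """
    issues = validate_config(cfg)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = _hash(asdict(cfg))
    manifest = RunManifest(config_hash=cfg_hash, seed=cfg.seed, version=__version__)

    g = cfg.grid_size
    medium = Medium(sound_speed=cfg.sound_speed, density=cfg.density,
                    grid_shape=(g, g), dx=cfg.dx)
    tcfg = TimeConfig.for_medium(medium)
    aug = AugmentParams(crop_size=g, seed=cfg.base_seed, shift_range_px=(0, max(1, g // 16)))
    need_train = any(m in LEARNED for m in cfg.methods)

    phantom_key = _hash("phantoms", cfg.base_seed, cfg.n_train, cfg.n_test, g, need_train)

    def make_phantoms():
        out = {"test": build_dataset(cfg.n_test, cfg.base_seed, "test", aug).images}
        if need_train:
            out["train"] = build_dataset(cfg.n_train, cfg.base_seed, "train", aug).images
        return out

    phantoms = _cached(out_dir, "phantoms", phantom_key, make_phantoms, manifest,
                       n_test=cfg.n_test, n_train=cfg.n_train if need_train else 0)

    from paxel.metrics import psnr, ssim

    records: list[MetricRecord] = []
    for n_sensors in cfg.sensor_counts:
        geometry = make_semicircle_array(n_sensors, medium)
        tof = compute_tof_map(geometry, medium) if any(
            m in ("pixeldl",) for m in cfg.methods) else None

        def simulate_split(images):
            sinos, trs, vols, mdir = [], [], [], []
            for img in images:
                y = simulate_forward(img, medium, geometry, tcfg)
                sinos.append(y.data)
                if any(m in ("time_reversal", "postdl") for m in cfg.methods):
                    from paxel.simulate import time_reversal
                    trs.append(time_reversal(y, medium, geometry, tcfg))
                if "pixeldl" in cfg.methods:
                    vols.append(pixel_wise_interpolate(y, tof).volume.transpose(2, 0, 1))
                if "mdirectdl" in cfg.methods:
                    mdir.append(interp_for_mdirect(y, (g, g)))
            out = {"sinos": np.asarray(sinos, np.float32)}
            if trs:
                out["tr"] = np.asarray(trs, np.float32)
            if vols:
                out["pixvol"] = np.asarray(vols, np.float32)
            if mdir:
                out["mdirect"] = np.asarray(mdir, np.float32)
            return out

        sim_key = _hash("simulate", phantom_key, n_sensors, tuple(sorted(cfg.methods)),
                        cfg.dx, cfg.sound_speed)
        test_arrays = _cached(out_dir, f"simulate-test-{n_sensors}", sim_key,
                              lambda: simulate_split(phantoms["test"]), manifest,
                              n_sensors=n_sensors)
        train_arrays = None
        if need_train:
            train_arrays = _cached(out_dir, f"simulate-train-{n_sensors}", sim_key,
                                   lambda: simulate_split(phantoms["train"]), manifest,
                                   n_sensors=n_sensors)

        truth = phantoms["test"]

        def add_records(method: str, images: np.ndarray) -> None:
            for i, (img, gt) in enumerate(zip(images, truth)):
                records.append(MetricRecord(
                    method=method, n_sensors=n_sensors, psnr_db=psnr(img, gt),
                    ssim=ssim(img, gt), image_id=f"test-{i}"))

        for method in cfg.methods:
            # deterministic stages must not rehash when only the seed changes
            stochastic = (cfg.seed, cfg.epochs, cfg.learning_rate) if method in LEARNED else ()
            key = _hash("recon", sim_key, method, cfg.tv_lambda, cfg.tv_iters,
                        *stochastic)

            def reconstruct():
                if method == "time_reversal":
                    return {"images": test_arrays["tr"]}
                if method == "iterative":
                    from paxel.simulate import SensorTimeSeries
                    est = TVReconstructor(lambda_reg=cfg.tv_lambda,
                                          max_iters=cfg.tv_iters).fit()
                    series = [SensorTimeSeries(s, tcfg.dt, geometry, medium)
                              for s in test_arrays["sinos"].astype(np.float64)]
                    return {"images": est.transform(series)}
                est = FDUNetReconstructor(
                    approach=method, growth_rate_init=8, features_init=32,
                    levels=2, dense_layers_per_block=2, epochs=cfg.epochs,
                    learning_rate=cfg.learning_rate, seed=cfg.seed)
                kind = {"postdl": "tr", "pixeldl": "pixvol", "mdirectdl": "mdirect"}[method]
                est.fit(train_arrays[kind], phantoms["train"])
                return {"images": est.predict(test_arrays[kind])}

            result = _cached(out_dir, f"recon-{method}-{n_sensors}", key,
                             reconstruct, manifest, method=method, n_sensors=n_sensors)
            add_records(method, result["images"])

    table = summarize(records)
    table.to_csv(out_dir / "summary.csv", index=False)
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest, table
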