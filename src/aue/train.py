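"""Training, inference and pipeline orchestration over the estimator.

These functions are the file-level interface used by the ``aue`` CLI:
they read manifests/directories, drive :class:`aue.estimator.AUENetTranslator`,
and write checkpoints, JSONL loss logs and JSON reports.  Dataset files
are only ever read.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .estimator import AUENetTranslator
from .metrics import MetricReport, evaluate_corpus
from .phantom import PhantomConfig, generate_dataset, load_dataset

__all__ = ["TrainConfig", "train", "generate", "run_pipeline"]


@dataclass
class TrainConfig:
    """Training protocol defaults at clinical scale; desk runs shrink
    epochs/width via the same fields."""

    epochs: int = 1500
    max_iterations: int | None = None
    batch_size: int = 8
    lr_g: float = 0.0002
    lr_d: float = 0.0001
    beta1: float = 0.5
    beta2: float = 0.999
    alpha: float = 10.0
    beta: float = 10.0
    gan_mode: str = "bce"
    blur_kernel: int = 21
    blur_sigma: float = 3.0
    base_channels: int = 64
    d_base_channels: int = 64
    n_scales: int = 2
    augment: bool = True
    seed: int = 0
    checkpoint_every: int = 100
    image_size: int = 256

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch size must be >= 1")
        if self.lr_g <= 0 or self.lr_d <= 0:
            raise ValueError("learning rates must be > 0")

    def to_estimator(self) -> AUENetTranslator:
        return AUENetTranslator(
            base_channels=self.base_channels,
            d_base_channels=self.d_base_channels,
            n_scales=self.n_scales,
            epochs=self.epochs,
            max_iterations=self.max_iterations,
            batch_size=self.batch_size,
            lr_g=self.lr_g,
            lr_d=self.lr_d,
            beta1=self.beta1,
            beta2=self.beta2,
            alpha=self.alpha,
            beta=self.beta,
            gan_mode=self.gan_mode,
            blur_kernel=self.blur_kernel,
            blur_sigma=self.blur_sigma,
            augment=self.augment,
            random_state=self.seed,
        )


def _pairs_to_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([p.bmode for p in pairs])
    Y = np.stack([p.elasto for p in pairs])
    return X, Y


def train(
    config: TrainConfig,
    manifest_path: str | Path,
    out_dir: str | Path,
) -> AUENetTranslator:
    """Train on a phantom/preprocessed dataset manifest; write periodic
    checkpoints and a JSONL loss log under ``out_dir``."""
    pairs, _ = load_dataset(manifest_path)
    if not pairs:
        raise ValueError("empty dataset")
    X, Y = _pairs_to_arrays(pairs)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    est = config.to_estimator()
    n = X.shape[0]
    iters_per_epoch = max(n // config.batch_size, 1)
    total = (
        config.max_iterations
        if config.max_iterations is not None
        else config.epochs * iters_per_epoch
    )
    cadence = config.checkpoint_every if config.checkpoint_every > 0 else total
    done = 0
    while done < total:
        est.max_iterations = min(done + cadence, total)
        est.fit(X, Y, resume=done > 0)
        done = est.n_iter_
        est.save_checkpoint(out_dir / f"checkpoint_{done:06d}.npz")
    est.max_iterations = config.max_iterations
    est.save_checkpoint(out_dir / "checkpoint_final.npz")
    with open(out_dir / "losses.jsonl", "w") as f:
        for rec in est.history_:
            f.write(json.dumps(rec) + "\n")
    return est


def generate(
    checkpoint: str | Path,
    input_dir: str | Path,
    out_dir: str | Path,
    pattern: str = "*.png",
) -> list[Path]:
    """Deterministic inference: write one elastogram PNG per input image,
    named after the input."""
    est = AUENetTranslator.load_checkpoint(checkpoint)
    input_dir = Path(input_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs = sorted(input_dir.glob(pattern))
    if not inputs:
        warnings.warn(f"no inputs matching {pattern!r} in {input_dir}", stacklevel=2)
        return []
    written = []
    for path in inputs:
        img = iio.imread(path)
        if img.ndim == 3:
            img = img[:, :, 0]
        div = 2**est.n_down
        if img.shape[0] % div or img.shape[1] % div:
            warnings.warn(
                f"{path.name}: size {img.shape} not divisible by {div}; "
                "padding and cropping back",
                stacklevel=2,
            )
        out = est.predict(img[None])[0]
        target = out_dir / f"{path.stem}_generated.png"
        iio.imwrite(target, out)
        written.append(target)
    return written


_PIPELINE_KEYS = {"workdir", "simulate", "train", "evaluate", "seed"}


def run_pipeline(config: dict, workdir: str | Path | None = None) -> dict:
    """simulate -> train -> generate -> evaluate, one JSON-able report.

    ``config`` keys: ``simulate`` (phantom options incl. ``n`` and
    ``test_n``), ``train`` (TrainConfig fields), ``evaluate``
    (currently ``ring_px``), optional ``workdir``/``seed``.  Unknown
    keys are rejected before any compute; any stage failure raises with
    the stage name.
    """
    unknown = set(config) - _PIPELINE_KEYS
    if unknown:
        raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
    workdir = Path(workdir or config.get("workdir", "aue_pipeline"))
    workdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    report: dict = {"workdir": str(workdir), "seed": seed}

    sim = dict(config.get("simulate", {}))
    n = int(sim.pop("n", 32))
    test_n = int(sim.pop("test_n", max(n // 4, 1)))
    phantom_fields = {f.name for f in fields(PhantomConfig)}
    bad = set(sim) - phantom_fields
    if bad:
        raise ValueError(f"unknown simulate keys: {sorted(bad)}")
    pcfg = PhantomConfig(**sim)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raise with stage name
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    data_dir = workdir / "data"
    manifest = stage(
        "simulate", lambda: generate_dataset(n + test_n, data_dir, pcfg, seed)
    )
    report["simulate"] = {"n_train": n, "n_test": test_n, "dir": str(data_dir)}

    pairs, _ = load_dataset(data_dir / "manifest.json")
    train_pairs, test_pairs = pairs[:n], pairs[n:]

    tr = dict(config.get("train", {}))
    train_fields = {f.name for f in fields(TrainConfig)}
    bad = set(tr) - train_fields
    if bad:
        raise ValueError(f"unknown train keys: {sorted(bad)}")
    tr.setdefault("seed", seed)
    tr.setdefault("image_size", pcfg.width)
    tcfg = TrainConfig(**tr)

    X, Y = _pairs_to_arrays(train_pairs)
    est = tcfg.to_estimator()
    stage("train", lambda: est.fit(X, Y))
    ckpt = workdir / "checkpoint_final.npz"
    est.save_checkpoint(ckpt)
    report["train"] = {
        "iterations": est.n_iter_,
        "final_loss": est.history_[-1]["total"] if est.history_ else None,
        "checkpoint": str(ckpt),
    }

    Xt = np.stack([p.bmode for p in test_pairs])
    generated = stage("generate", lambda: est.predict(Xt))

    masks = [p.mask for p in test_pairs]
    if any(m is None for m in masks):
        masks = None
    ref = [p.elasto for p in test_pairs]
    metric_report: MetricReport = stage(
        "evaluate",
        lambda: evaluate_corpus(list(generated), ref, masks),
    )
    report["evaluate"] = metric_report.to_json()
    with open(workdir / "report.json", "w") as f:
        json.dump(report, f, indent=2)
    return report
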