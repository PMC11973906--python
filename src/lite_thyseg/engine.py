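"""Training, evaluation, prediction and ablation orchestration.

The training protocol follows the study conditions: Adam at an initial
learning rate of 1e-3, batch size 4, 60 epochs, Tversky loss with
alpha = 0.3 / beta = 0.7 by default, constant learning rate (an optional
cosine decay is available behind a flag), best checkpoint selected by
validation IoU.  Runs are deterministic given ``seed``.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np

from . import losses, metrics, nn
from .network import ModelConfig, SegmentationNetwork, build_model, param_report
from .preprocess import ImageRecord, standardize

__all__ = ["TrainConfig", "RunRecord", "train", "evaluate", "dataset_loss",
           "predict", "ablate"]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 4
    epochs: int = 60
    optimizer: str = "adam"
    loss: str = "tversky"
    alpha: float = 0.3
    beta: float = 0.7
    seed: int = 0
    device: str = "cpu"
    cosine_decay: bool = False

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("hyperparameters must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.loss not in ("tversky", "bce"):
            raise ValueError("loss must be 'tversky' or 'bce'")
        if self.device != "cpu":
            raise ValueError("only cpu execution is supported")

    def loss_fn(self):
        if self.loss == "tversky":
            params = losses.TverskyParams(self.alpha, self.beta)
            return lambda p, g: losses.tversky_loss(p, g, params)
        return lambda p, g: losses.bce_loss(p, g, reduction="mean")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


@dataclass
class RunRecord:
    """Everything a training run produced, serializable to JSON."""

    model_config: dict
    train_config: dict
    history: List[dict] = field(default_factory=list)
    final_metrics: Dict[str, dict] = field(default_factory=dict)
    params: Dict[str, int] = field(default_factory=dict)
    best_epoch: int = -1

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _to_batch(records: Sequence[ImageRecord]) -> tuple[np.ndarray, np.ndarray]:
    images = np.stack([r.image for r in records])[:, None].astype(np.float32) / 255.0
    masks = np.stack([r.mask for r in records])[:, None].astype(np.float32)
    return images, masks


def dataset_loss(model, records: Sequence[ImageRecord], loss_fn) -> float:
    """Mean per-image loss of a fixed model over a record list."""
    total = 0.0
    for rec in records:
        x, g = _to_batch([rec])
        total += float(loss_fn(model.predict_probs(x), g))
    return total / len(records)


def evaluate(model, records: Sequence[ImageRecord],
             mode: str = "global_pool") -> metrics.MetricsReport:
    """Threshold model probabilities at 0.5 and aggregate confusion counts.

    ``model`` only needs a ``predict_probs((B,1,H,W)) -> (B,1,H,W)``
    method, so oracle stubs can stand in for a trained network.
    """
    if not records:
        raise ValueError("cannot evaluate an empty split")
    was_training = getattr(model, "training", False)
    if isinstance(model, nn.Module):
        model.eval()
    counts = []
    for rec in records:
        x, _ = _to_batch([rec])
        pred = metrics.binarize(model.predict_probs(x)[0, 0])
        counts.append(metrics.confusion_counts(pred, rec.mask))
    if isinstance(model, nn.Module) and was_training:
        model.train()
    return metrics.aggregate(counts, mode=mode)


def train(model: SegmentationNetwork, splits, config: TrainConfig = TrainConfig(),
          log=None) -> RunRecord:
    """Seeded training loop; retains the best-validation-IoU checkpoint.

    ``splits`` is (train, val, test) record lists; val/test may be empty.
    """
    train_recs, val_recs, test_recs = splits
    if not train_recs:
        raise ValueError("training split is empty")
    loss_fn = config.loss_fn()
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    record = RunRecord(model_config=model.config.to_dict(),
                       train_config=config.to_dict(),
                       params=dict(param_report(model=model).per_component))

    best_iou, best_state = -1.0, None
    for epoch in range(config.epochs):
        if config.cosine_decay:
            opt.lr = config.learning_rate * 0.5 * (
                1.0 + math.cos(math.pi * epoch / max(1, config.epochs)))
        model.train()
        order = rng.permutation(len(train_recs))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            batch = [train_recs[i] for i in order[start:start + config.batch_size]]
            x, g = _to_batch(batch)
            probs = model(nn.Tensor(x))
            loss = loss_fn(probs, g)
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss {value} at epoch {epoch}, batch {n_batches}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += value
            n_batches += 1
        entry = {"epoch": epoch, "train_loss": epoch_loss / n_batches}
        if val_recs:
            val_report = evaluate(model, val_recs)
            entry["val_iou"] = val_report.iou
            entry["val_dsc"] = val_report.dsc
            if val_report.iou > best_iou:
                best_iou = val_report.iou
                best_state = model.state_dict()
                record.best_epoch = epoch
        record.history.append(entry)
        if log is not None:
            log(entry)

    if best_state is not None:
        model.load_state_dict(best_state)
    for name, recs in (("train", train_recs), ("val", val_recs), ("test", test_recs)):
        if recs:
            record.final_metrics[name] = evaluate(model, recs).as_dict(percent=True)
    return record


def predict(model, image_paths: Sequence[str | Path], out_dir: str | Path,
            threshold: float = 0.5) -> tuple[List[Path], List[Path]]:
    """Segment image files into 0/255 PNG masks with matching basenames.

    Returns (written, failed) path lists; unreadable inputs are skipped.
    """
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    size = model.config.input_size
    written, failed = [], []
    for path in map(Path, image_paths):
        try:
            raw = np.asarray(Image.open(path))
        except Exception:
            failed.append(path)
            continue
        orig_shape = raw.shape[:2]
        rec = standardize(raw, np.zeros(orig_shape, dtype=np.uint8),
                          record_id=path.stem, size=size)
        x, _ = _to_batch([rec])
        if isinstance(model, nn.Module):
            model.eval()
        probs = model.predict_probs(x)[0, 0]
        mask = metrics.binarize(probs, threshold)
        if mask.shape != orig_shape:
            from skimage.transform import resize
            mask = resize(mask, orig_shape, order=0, preserve_range=True,
                          anti_aliasing=False).astype(np.uint8)
        target = out / f"{path.stem}.png"
        Image.fromarray(mask * 255, mode="L").save(target)
        written.append(target)
    return written, failed


def ablate(grid: Sequence[dict], splits, model_config: ModelConfig | None = None,
           train_config: TrainConfig | None = None) -> List[dict]:
    """One run per flag combination, all on identical seed-pinned splits.

    ``grid`` entries toggle ModelConfig flags, e.g.
    ``{"use_ppm": False, "use_attention": True}``.  With ``epochs == 0``
    only parameter accounting is reported.
    """
    base = (model_config or ModelConfig()).to_dict()
    tc = train_config or TrainConfig()
    rows = []
    for toggles in grid:
        cfg_dict = copy.deepcopy(base)
        cfg_dict.update(toggles)
        cfg = ModelConfig.from_dict(cfg_dict)
        model = build_model(cfg, seed=tc.seed)
        report = param_report(model=model)
        row = {
            "ds_aspp": cfg.use_ds_aspp,
            "ppm": cfg.use_ppm,
            "attention": cfg.use_attention,
            "multi_skip": cfg.use_multi_skip,
            "params": report.total_count,
            "params_mb": report.total_megabytes,
        }
        if tc.epochs > 0:
            run = train(model, splits, tc)
            val = run.final_metrics.get("val") or run.final_metrics["train"]
            row["iou"] = val["iou"]
            row["dsc"] = val["dsc"]
        rows.append(row)
    return rows
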