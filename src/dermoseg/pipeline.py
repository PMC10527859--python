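"""Per-attribute training, evaluation and prediction.

One binary segmentation model is trained per dermoscopic attribute on a
balanced manifest: Adam on the hybrid focal-Tversky + soft-IoU loss (a
plain binary-cross-entropy loss is available as a baseline), validation
monitored every epoch, early stopping with patience and best-weight
restoration.  The default protocol is 512x512 inputs, batch 8, up to 60
epochs, learning rate 1e-3, patience 20, frozen pretrained encoder; the
"desk" profile shrinks the network and resolution so the full loop runs on
a CPU in minutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import losses as L
from .architecture import (
    DecoderSpec,
    EncoderSpec,
    SegmentationModel,
    build_dermoseg,
    forward as model_forward,
)
from .dataset_io import DatasetManifest, load_image, load_mask, resize_pair, write_mask
from .metrics import EvalReport, binarize, confusion_counts, iou_score, mean_iou, roc_points
from .nn import Adam

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "EarlyStopState",
    "early_stop_update",
    "train",
    "evaluate",
    "predict",
    "load_arrays",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol for one attribute model."""

    attribute: str = "globules"
    input_size: int = 512
    batch_size: int = 8
    max_epochs: int = 60
    learning_rate: float = 1e-3
    patience: int = 20
    loss: str = "hybrid"  # "hybrid" or "bce" (baseline)
    tversky: L.TverskyParams = field(default_factory=L.TverskyParams)
    encoder_profile: str = "resnet50"  # or "desk"
    decoder_widths: tuple[int, ...] | None = None
    freeze_encoder: bool = True
    pretrained: str | None = None
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.max_epochs < 1 or self.patience < 1:
            raise ValueError("batch size, epochs and patience must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.loss not in ("hybrid", "bce"):
            raise ValueError("loss must be 'hybrid' or 'bce'")

    def encoder_spec(self) -> EncoderSpec:
        if self.encoder_profile == "desk":
            return EncoderSpec.desk()
        return getattr(EncoderSpec, self.encoder_profile)()

    def decoder_spec(self) -> DecoderSpec:
        if self.decoder_widths is not None:
            return DecoderSpec(widths=tuple(self.decoder_widths))
        if self.encoder_profile == "desk":
            return DecoderSpec.desk()
        return DecoderSpec()

    def build_model(self) -> SegmentationModel:
        return build_dermoseg(
            encoder=self.encoder_spec(),
            decoder=self.decoder_spec(),
            freeze_encoder=self.freeze_encoder,
            pretrained=self.pretrained,
            seed=self.seed,
        )

    @classmethod
    def desk_profile(cls, **overrides) -> "TrainConfig":
        """CPU-scale settings: 96x96 inputs, batch 4, reduced network.

        The encoder is trained rather than frozen, since no pretrained
        weights back the random desk initialisation.
        """
        base = cls(
            input_size=96,
            batch_size=4,
            max_epochs=10,
            patience=5,
            encoder_profile="desk",
            freeze_encoder=False,
        )
        return replace(base, **overrides)

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        loss_cfg = raw.pop("loss", {})
        if isinstance(loss_cfg, str):
            raw["loss"] = loss_cfg
        elif loss_cfg:
            raw["loss"] = loss_cfg.pop("name", "hybrid")
            raw["tversky"] = L.TverskyParams(
                alpha=float(loss_cfg.get("alpha", 0.7)),
                beta=float(loss_cfg.get("beta", 0.3)),
                gamma=float(loss_cfg.get("gamma", 4.0 / 3.0)),
                epsilon=float(loss_cfg.get("epsilon", 1e-6)),
            )
        if "decoder_widths" in raw and raw["decoder_widths"] is not None:
            raw["decoder_widths"] = tuple(raw["decoder_widths"])
        return cls(**raw)


@dataclass
class TrainHistory:
    """Per-epoch record of one training run."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_iou: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "val_iou": self.val_iou,
            }
        )


# ---------------------------------------------------------------------------
# Early stopping


@dataclass(frozen=True)
class EarlyStopState:
    """Best-so-far tracker; improvement = strictly lower validation loss."""

    patience: int
    best_loss: float = float("inf")
    best_epoch: int = 0
    epoch: int = 0
    epochs_since_improvement: int = 0
    stop: bool = False

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


def early_stop_update(state: EarlyStopState, val_loss: float) -> EarlyStopState:
    """Fold one epoch's validation loss into the early-stopping state."""
    if not np.isfinite(val_loss):
        raise ValueError("non-finite validation loss")
    epoch = state.epoch + 1
    if val_loss < state.best_loss:
        return replace(
            state, epoch=epoch, best_loss=val_loss, best_epoch=epoch, epochs_since_improvement=0
        )
    since = state.epochs_since_improvement + 1
    return replace(
        state, epoch=epoch, epochs_since_improvement=since, stop=since >= state.patience
    )


# ---------------------------------------------------------------------------
# Data loading


def load_arrays(
    manifest: DatasetManifest, attribute: str, side: int
) -> tuple[np.ndarray, np.ndarray]:
    """Images (N,3,H,W float32) and masks (N,H,W float32) at ``side``."""
    imgs, masks = [], []
    for _, row in manifest.df.iterrows():
        img = load_image(row["image_path"])
        mask = load_mask(row[f"mask_{attribute}"])
        img, mask = resize_pair(img, mask, side)
        imgs.append(np.moveaxis(img, -1, 0))
        masks.append(mask.astype(np.float32))
    return np.stack(imgs).astype(np.float32), np.stack(masks)


# ---------------------------------------------------------------------------
# Loss dispatch (value + gradient w.r.t. predicted probabilities)


def _loss_and_grad(p: np.ndarray, g: np.ndarray, config: TrainConfig):
    if config.loss == "hybrid":
        value = L.hybrid_loss(p, g, config.tversky).hybrid
        grad = L.hybrid_loss_gradient(p, g, config.tversky)
        return value, grad
    # per-pixel binary cross-entropy baseline
    eps = 1e-7
    pc = np.clip(p, eps, 1 - eps)
    value = float(-np.mean(g * np.log(pc) + (1 - g) * np.log(1 - pc)))
    grad = (pc - g) / (pc * (1 - pc)) / p.size
    return value, grad


def _loss_value(p: np.ndarray, g: np.ndarray, config: TrainConfig) -> float:
    return _loss_and_grad(p, g, config)[0]


# ---------------------------------------------------------------------------
# Training


def train(
    attribute: str,
    manifests: dict[str, DatasetManifest],
    config: TrainConfig,
    verbose: bool = False,
) -> tuple[SegmentationModel, TrainHistory]:
    """Train one attribute model on balanced, split manifests.

    ``manifests`` must hold ``"train"`` and ``"val"`` entries.  Minimises
    the configured loss with Adam, monitors validation loss, stops early
    after ``patience`` epochs without improvement and restores the
    best-epoch weights.  Fully deterministic under ``config.seed``.
    """
    if "train" not in manifests or "val" not in manifests:
        raise ValueError("manifests must contain 'train' and 'val'")
    if len(manifests["train"]) == 0:
        raise ValueError("empty training set")
    config = replace(config, attribute=attribute)
    x_train, y_train = load_arrays(manifests["train"], attribute, config.input_size)
    x_val, y_val = load_arrays(manifests["val"], attribute, config.input_size)

    model = config.build_model()
    opt = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history = TrainHistory()
    state = EarlyStopState(patience=config.patience)
    best_weights = model.get_state()

    n = x_train.shape[0]
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            p = model.forward(xb, train=True)[:, 0]
            value, grad = _loss_and_grad(p.astype(np.float64), yb.astype(np.float64), config)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(attribute={attribute}, loss={config.loss})"
                )
            model.zero_grad()
            model.backward(grad[:, None].astype(np.float32))
            opt.step()
            epoch_losses.append(value)

        p_val = model_forward(model, x_val, batch_size=config.batch_size)
        val_loss = _loss_value(p_val.astype(np.float64), y_val.astype(np.float64), config)
        counts = confusion_counts(binarize(p_val, config.threshold), y_val > 0.5)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val_loss)
        history.val_iou.append(iou_score(counts))
        if verbose:
            print(
                f"epoch {epoch:3d}  train {history.train_loss[-1]:.4f}  "
                f"val {val_loss:.4f}  fg-IoU {history.val_iou[-1]:.3f}"
            )

        prev_best = state.best_loss
        state = early_stop_update(state, val_loss)
        if val_loss < prev_best:
            best_weights = model.get_state()
        if state.stop:
            break

    model.set_state(best_weights)
    history.best_epoch = state.best_epoch
    history.stopped_epoch = state.epoch
    return model, history


# ---------------------------------------------------------------------------
# Evaluation / prediction


def evaluate(
    model: SegmentationModel,
    manifest: DatasetManifest,
    attribute: str,
    threshold: float = 0.5,
    input_size: int | None = None,
    batch_size: int = 8,
    aggregation: str = "global",
    with_roc: bool = True,
) -> EvalReport:
    """Forward, binarize, aggregate confusion counts, report IoU + ROC.

    ``aggregation="global"`` pools pixel counts over the whole set before
    computing per-class IoU; ``"per_image"`` averages per-image foreground
    IoU (an image empty in both truth and prediction scores 1).
    """
    if len(manifest) == 0:
        raise ValueError("empty evaluation manifest")
    side = input_size or model_input_side(model)
    x, y = load_arrays(manifest, attribute, side)
    p = model_forward(model, x, batch_size=batch_size)
    pred = binarize(p, threshold)
    truth = y > 0.5

    if aggregation == "per_image":
        per_img = [iou_score(confusion_counts(pi, ti)) for pi, ti in zip(pred, truth)]
        fg_iou = float(np.mean(per_img))
        bg_iou = float(
            np.mean([iou_score(confusion_counts(~pi.astype(bool), ~ti)) for pi, ti in zip(pred, truth)])
        )
    elif aggregation == "global":
        fg_iou = iou_score(confusion_counts(pred, truth))
        bg_iou = iou_score(confusion_counts(~pred.astype(bool), ~truth))
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")

    per_class = {"foreground": fg_iou, "background": bg_iou}
    points: list = []
    auc = float("nan")
    if with_roc:
        npos = int(truth.sum())
        if 0 < npos < truth.size:
            points, auc = roc_points(_subsample(p), _subsample(truth))
    return EvalReport(
        per_class_iou=per_class, mean_iou=mean_iou(per_class), roc_points=points, auc=auc
    )


def _subsample(arr: np.ndarray, cap: int = 2_000_000) -> np.ndarray:
    """Deterministic stride subsample of pooled pixels for the ROC sweep."""
    flat = np.ravel(arr)
    if flat.size <= cap:
        return flat
    stride = int(np.ceil(flat.size / cap))
    return flat[::stride]


def model_input_side(model: SegmentationModel) -> int:
    # any side divisible by the downsample factor works; default to 96 desk / 512 canonical
    return 96 if model.encoder_spec.stem_channels < 64 else 512


def predict(
    model: SegmentationModel,
    image_paths: list,
    attribute: str,
    outdir,
    threshold: float = 0.5,
    input_size: int | None = None,
    batch_size: int = 8,
) -> pd.DataFrame:
    """Write one 0/255 mask PNG per input image plus a fractions CSV.

    Masks follow the ISIC naming convention
    ``<image-id>_attribute_<attribute>.png``; the returned (and saved)
    table lists the predicted foreground fraction per image.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    side = input_size or model_input_side(model)
    rows = []
    for path in image_paths:
        path = Path(path)
        img = load_image(path)
        img_r, _ = resize_pair(img, np.zeros(img.shape[:2], dtype=np.uint8), side)
        x = np.moveaxis(img_r, -1, 0)[None].astype(np.float32)
        p = model_forward(model, x, batch_size=batch_size)[0]
        mask = binarize(p, threshold)
        out_path = outdir / f"{path.stem}_attribute_{attribute}.png"
        write_mask(out_path, mask)
        rows.append(
            {
                "image_id": path.stem,
                "mask_path": str(out_path),
                "foreground_fraction": float(mask.mean()),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "predictions.csv", index=False)
    return table


def save_report(report: EvalReport, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    csv_path = path.with_suffix(".csv")
    pd.DataFrame(
        {"class": list(report.per_class_iou), "iou": list(report.per_class_iou.values())}
    ).to_csv(csv_path, index=False)
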