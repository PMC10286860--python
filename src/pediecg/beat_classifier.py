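"""The two beat-morphology CNN families and their training loop.

Two architectures classify single-beat images:

* ``linear`` — a plain stack of conv → ReLU → maxpool blocks with
  growing filter counts, ending in dense → dropout → softmax; operates
  on 128×128 inputs.
* ``three_flow`` — an Xception-style network: an entry flow of strided
  convolutions with residual shortcuts, a middle flow of repeated
  depthwise-separable blocks with identity shortcuts, and an exit flow
  of separable convolutions into global average pooling; operates on
  299×299 inputs. The default depth is reduced (middle flow repeated
  4×) so single-CPU training stays feasible; depth is configurable.

Both families sit behind one interface: the rhythm decision tree only
sees per-beat labels and confidences, never which family produced them.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .imaging import BeatImage, LabeledDataset
from .synthetic import TRAINABLE_CLASSES, BeatClass


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    dropout_rate: float = 0.25
    last_dense_units: int = 64
    last_conv_filters: int = 32
    batch_size: int = 32
    max_epochs: int = 12
    early_stop_patience: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        for name in ("last_dense_units", "last_conv_filters", "batch_size", "max_epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")


@dataclass
class ModelSpec:
    family: str = "linear"  # "linear" | "three_flow"
    input_side: int | None = None  # 128 for linear, 299 for three_flow
    n_classes: int = 4
    middle_flow_repeats: int = 4  # three_flow only

    def __post_init__(self) -> None:
        if self.family not in ("linear", "three_flow"):
            raise ValueError("family must be 'linear' or 'three_flow'")
        if self.input_side is None:
            self.input_side = 128 if self.family == "linear" else 299
        if self.input_side < 32:
            raise ValueError("input_side must be >= 32")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


def _linear_net(spec: ModelSpec, config: TrainConfig,
                rng: np.random.Generator) -> tuple[nn.Sequential, list[str]]:
    filters = (16, 32, config.last_conv_filters)
    layers: list[nn.Layer] = []
    plan: list[str] = []
    c_in = 1
    side = spec.input_side
    for f in filters:
        layers += [nn.Conv2D(c_in, f, 3, rng=rng), nn.ReLU(), nn.MaxPool2()]
        plan.append(f"conv3x3({c_in}->{f}) + relu + maxpool2")
        c_in = f
        side //= 2
    layers += [
        nn.Flatten(),
        nn.Dense(side * side * c_in, config.last_dense_units, rng=rng),
        nn.ReLU(),
        nn.Dropout(config.dropout_rate, rng=rng),
        nn.Dense(config.last_dense_units, spec.n_classes, rng=rng),
    ]
    plan += [
        f"flatten -> dense({config.last_dense_units}) + relu",
        f"dropout({config.dropout_rate})",
        f"dense({spec.n_classes}) -> softmax",
    ]
    return nn.Sequential(layers), plan


def _entry_block(c_in: int, c_out: int, rng: np.random.Generator) -> nn.Residual:
    body: list[nn.Layer] = [
        nn.SeparableConv2D(c_in, c_out, rng=rng),
        nn.ReLU(),
        nn.SeparableConv2D(c_out, c_out, stride=2, rng=rng),
    ]
    shortcut = nn.Conv2D(c_in, c_out, k=1, stride=2, rng=rng)
    return nn.Residual(body, shortcut)


def _three_flow_net(spec: ModelSpec, config: TrainConfig,
                    rng: np.random.Generator) -> tuple[nn.Sequential, list[str]]:
    c_mid = 24
    layers: list[nn.Layer] = [nn.Conv2D(1, 8, 3, stride=2, rng=rng), nn.ReLU()]
    plan = ["entry: conv3x3(1->8, stride 2) + relu"]
    layers.append(_entry_block(8, 16, rng))
    layers.append(_entry_block(16, c_mid, rng))
    plan += ["entry: residual separable block (8->16, stride 2)",
             f"entry: residual separable block (16->{c_mid}, stride 2)"]
    for _ in range(spec.middle_flow_repeats):
        body: list[nn.Layer] = [
            nn.ReLU(),
            nn.SeparableConv2D(c_mid, c_mid, rng=rng),
            nn.ReLU(),
            nn.SeparableConv2D(c_mid, c_mid, rng=rng),
        ]
        layers.append(nn.Residual(body, None))
    plan.append(
        f"middle: identity-residual separable block x{spec.middle_flow_repeats}"
    )
    layers += [
        nn.SeparableConv2D(c_mid, config.last_conv_filters, rng=rng),
        nn.ReLU(),
        nn.GlobalAvgPool(),
        nn.Dropout(config.dropout_rate, rng=rng),
        nn.Dense(config.last_conv_filters, spec.n_classes, rng=rng),
    ]
    plan += [
        f"exit: separable conv ({c_mid}->{config.last_conv_filters}) + relu",
        "exit: global average pool",
        f"dropout({config.dropout_rate})",
        f"dense({spec.n_classes}) -> softmax",
    ]
    return nn.Sequential(layers), plan


@dataclass
class BuiltModel:
    net: nn.Sequential
    spec: ModelSpec
    config: TrainConfig
    layer_plan: list[str]

    @property
    def n_parameters(self) -> int:
        return self.net.n_parameters()


@dataclass
class TrainedModel:
    net: nn.Sequential
    spec: ModelSpec
    config: TrainConfig
    class_order: list[BeatClass]
    history: dict = field(default_factory=dict)
    layer_plan: list[str] = field(default_factory=list)


def build_model(spec: ModelSpec, config: TrainConfig) -> BuiltModel:
    """Instantiate an untrained network of the requested family.

    Initialization is He-scaled from ``config.seed``, so two builds
    with the same seed have identical parameters.
    """
    rng = np.random.default_rng(config.seed)
    if spec.family == "linear":
        net, plan = _linear_net(spec, config, rng)
    else:
        net, plan = _three_flow_net(spec, config, rng)
    return BuiltModel(net=net, spec=spec, config=config, layer_plan=plan)


def images_to_batch(images: list[BeatImage], side: int) -> np.ndarray:
    """Stack beat images into an NHWC float batch, trace-high polarity.

    Pixels are inverted (1 − value/255) so the beat trace carries the
    activation and the white background is zero.
    """
    for im in images:
        if im.side != side:
            raise ValueError(f"image side {im.side} != model input side {side}")
    arr = np.stack([im.pixels for im in images]).astype(np.float32)
    return (1.0 - arr / 255.0)[..., None]


def _labels_to_ints(images: list[BeatImage], class_order: list[BeatClass]) -> np.ndarray:
    index = {c: i for i, c in enumerate(class_order)}
    out = []
    for im in images:
        if im.label is None or im.label not in index:
            raise ValueError(f"image lacks a trainable label: {im.label}")
        out.append(index[im.label])
    return np.asarray(out, dtype=int)


def _evaluate(net: nn.Sequential, x: np.ndarray, y: np.ndarray,
              batch_size: int) -> tuple[float, float]:
    losses, correct = [], 0
    for lo in range(0, len(x), batch_size):
        xb, yb = x[lo : lo + batch_size], y[lo : lo + batch_size]
        logits = net.forward(xb, training=False)
        loss, _ = nn.cross_entropy_grad(logits, yb)
        losses.append(loss * len(xb))
        correct += int((logits.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def train(model: BuiltModel, dataset: LabeledDataset,
          config: TrainConfig | None = None) -> TrainedModel:
    """Train by mini-batch Adam on cross-entropy with early stopping.

    Stops when the validation loss has not improved for
    ``early_stop_patience`` epochs and restores the parameters of the
    best validation epoch. History records per-epoch loss/accuracy on
    both splits.
    """
    config = config or model.config
    train_images = dataset.subset("train")
    val_images = dataset.subset("val")
    if not train_images or not val_images:
        raise ValueError("dataset needs non-empty train and val splits")

    class_order = [c for c in TRAINABLE_CLASSES][: model.spec.n_classes]
    present = {im.label for im in train_images}
    if not present <= set(class_order):
        # widen to any labeled classes in a stable order
        class_order = sorted(present, key=lambda c: c.value)

    side = model.spec.input_side
    x_train = images_to_batch(train_images, side)
    y_train = _labels_to_ints(train_images, class_order)
    x_val = images_to_batch(val_images, side)
    y_val = _labels_to_ints(val_images, class_order)

    net = model.net
    opt = nn.Adam(net, config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    history: dict[str, list[float]] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": [],
    }
    best_val = np.inf
    best_state = {k: v.copy() for k, v in net.state_arrays().items()}
    since_best = 0

    for _epoch in range(config.max_epochs):
        order = rng.permutation(len(x_train))
        ep_loss, ep_correct = 0.0, 0
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo : lo + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            logits = net.forward(xb, training=True)
            loss, grad = nn.cross_entropy_grad(logits, yb)
            net.backward(grad)
            opt.step()
            ep_loss += loss * len(idx)
            ep_correct += int((logits.argmax(axis=1) == yb).sum())
        val_loss, val_acc = _evaluate(net, x_val, y_val, config.batch_size)
        history["train_loss"].append(ep_loss / len(x_train))
        history["train_acc"].append(ep_correct / len(x_train))
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = {k: v.copy() for k, v in net.state_arrays().items()}
            since_best = 0
        else:
            since_best += 1
            if since_best > config.early_stop_patience:
                break

    net.load_state_arrays(best_state)
    return TrainedModel(
        net=net,
        spec=model.spec,
        config=config,
        class_order=class_order,
        history=history,
        layer_plan=model.layer_plan,
    )


def hyperparameter_search(
    grid: list[TrainConfig],
    dataset: LabeledDataset,
    spec: ModelSpec | None = None,
) -> tuple[TrainConfig, pd.DataFrame]:
    """Train one model per config and rank them.

    Ranking: highest final validation accuracy; ties break toward
    lower final validation loss, then earlier grid order. Returns the
    winning config and the full results table (one row per config).
    """
    if not grid:
        raise ValueError("grid must not be empty")
    spec = spec or ModelSpec()
    rows = []
    for i, config in enumerate(grid):
        trained = train(build_model(spec, config), dataset, config)
        rows.append(
            {
                "grid_index": i,
                "learning_rate": config.learning_rate,
                "dropout_rate": config.dropout_rate,
                "last_dense_units": config.last_dense_units,
                "last_conv_filters": config.last_conv_filters,
                "val_acc": trained.history["val_acc"][-1],
                "val_loss": trained.history["val_loss"][-1],
                "epochs": len(trained.history["val_loss"]),
            }
        )
    table = pd.DataFrame(rows)
    ranked = table.sort_values(
        by=["val_acc", "val_loss", "grid_index"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    return grid[int(ranked.iloc[0]["grid_index"])], table


def predict_beats(
    model: TrainedModel, images: list[BeatImage], batch_size: int = 64
) -> tuple[np.ndarray, list[BeatClass], np.ndarray]:
    """Class probabilities, argmax labels, and confidences per image.

    Probabilities are softmax outputs (non-negative, summing to 1 per
    image); confidence is the maximum probability and feeds the
    decision tree's inconclusive logic.
    """
    side = model.spec.input_side
    probs = []
    for lo in range(0, len(images), batch_size):
        batch = images_to_batch(images[lo : lo + batch_size], side)
        probs.append(nn.softmax(model.net.forward(batch, training=False)))
    if not probs:
        return np.zeros((0, len(model.class_order))), [], np.zeros(0)
    p = np.concatenate(probs)
    labels = [model.class_order[i] for i in p.argmax(axis=1)]
    return p, labels, p.max(axis=1)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Checkpoint: .npz weights plus a .json sidecar (class order,
    spec, config, layer plan, final metrics)."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.net.state_arrays())
    sidecar = {
        "spec": asdict(model.spec),
        "config": asdict(model.config),
        "class_order": [c.value for c in model.class_order],
        "layer_plan": model.layer_plan,
        "history": model.history,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec = ModelSpec(**sidecar["spec"])
    config = TrainConfig(**sidecar["config"])
    built = build_model(spec, config)
    with np.load(path.with_suffix(".npz")) as data:
        built.net.load_state_arrays(dict(data))
    return TrainedModel(
        net=built.net,
        spec=spec,
        config=config,
        class_order=[BeatClass(c) for c in sidecar["class_order"]],
        history=sidecar["history"],
        layer_plan=sidecar["layer_plan"],
    )
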