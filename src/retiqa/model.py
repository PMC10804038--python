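"""Multi-category quality model: network definition, masked loss, training.

The network is an 18-layer residual CNN with dropout in every block.  Each
output head gives the probability that the image is of POOR quality in one
category (so a score of 1 means worst possible quality).  Training uses a
masked binary cross-entropy: images whose overall-quality label is missing
simply contribute no loss and no gradient for that head, while the other
heads train normally.

The public surface follows the model/results pattern: build a
:class:`QualityModel` from train/validation manifests, call :meth:`fit`,
and work with the returned :class:`QualityResults`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from . import io as retio
from .categories import categories_for, check_modality, n_categories
from .nn import Adam, DropoutResNet


@dataclass
class ModelConfig:
    """Architecture hyper-parameters.

    ``dropout_rate`` is the per-block channel-dropout probability (kept
    active at inference for uncertainty estimation).  ``width_scale``
    multiplies every stage width; 1.0 is the standard 18-layer topology,
    the default 0.25 trains in minutes on a CPU.  ``pretrained`` loads
    externally supplied initial weights from ``pretrained_path`` (an
    ImageNet-initialisation hook); nothing is ever downloaded.
    """

    modality: str = "CF"
    input_side_px: int = 64
    dropout_rate: float = 0.2
    width_scale: float = 0.25
    pretrained: bool = False
    pretrained_path: str | None = None
    seed: int = 0

    @property
    def n_categories(self) -> int:
        return n_categories(self.modality)

    @property
    def in_channels(self) -> int:
        return 3 if self.modality == "CF" else 1

    def validate(self) -> None:
        check_modality(self.modality)
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.pretrained and not self.pretrained_path:
            raise ValueError("pretrained=True requires pretrained_path")


@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0
    selection_metric: str = "mean_auc_roc"

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def build_model(config: ModelConfig) -> DropoutResNet:
    """Instantiate the network; deterministic in ``config.seed``."""
    config.validate()
    net = DropoutResNet(
        in_channels=config.in_channels,
        n_outputs=config.n_categories,
        width_scale=config.width_scale,
        dropout_rate=config.dropout_rate,
        input_side=config.input_side_px,
        seed=config.seed,
    )
    if config.pretrained:
        state = dict(np.load(config.pretrained_path))
        net.load_state_dict(state)
    return net


# ---------------------------------------------------------------------------
# masked multi-label loss
# ---------------------------------------------------------------------------

#: value stored in the target tensor where the label is missing; never read
LABEL_SENTINEL = -1.0


def masked_multilabel_loss(
    probabilities: np.ndarray, targets: np.ndarray, mask: np.ndarray
) -> float:
    """Mean binary cross-entropy over the (sample, category) pairs with a label.

    ``mask`` is 1 where a label is present; masked-out pairs contribute
    exactly zero.  If every pair is masked the loss is 0 (with a warning),
    so a batch without labels performs no update.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    targets = np.asarray(targets, dtype=float)
    mask = np.asarray(mask, dtype=float)
    if probabilities.shape != targets.shape or targets.shape != mask.shape:
        raise ValueError("probabilities, targets and mask must share a shape")
    n_labelled = mask.sum()
    if n_labelled == 0:
        warnings.warn("all labels masked in batch; loss is 0 and no update occurs")
        return 0.0
    p = np.clip(probabilities, 1e-12, 1.0 - 1e-12)
    y = np.where(mask > 0, targets, 0.0)  # sentinel never enters the formula
    bce = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return float((bce * mask).sum() / n_labelled)


def _masked_loss_and_grad(logits, targets, mask):
    """Loss plus its gradient w.r.t. the logits (numerically stable form)."""
    p = expit(logits)
    loss = masked_multilabel_loss(p, targets, mask)
    n_labelled = mask.sum()
    if n_labelled == 0:
        return loss, np.zeros_like(logits)
    y = np.where(mask > 0, targets, 0.0)
    dlogits = (p - y) * mask / n_labelled
    return loss, dlogits


# ---------------------------------------------------------------------------
# label tensors from a manifest
# ---------------------------------------------------------------------------


def labels_from_manifest(manifest: pd.DataFrame, modality: str):
    """Binary targets (poor=1) and presence mask, shape ``(n, n_categories)``.

    Missing Likert values get the sentinel target and mask 0.
    """
    cats = categories_for(modality)
    n = len(manifest)
    targets = np.full((n, len(cats)), LABEL_SENTINEL)
    mask = np.zeros((n, len(cats)))
    for j, cat in enumerate(cats):
        col = manifest[f"likert_{cat}"]
        present = col.notna().to_numpy()
        vals = col.fillna(1).to_numpy(dtype=float)
        targets[present, j] = (vals[present] >= 3).astype(float)  # 1-2 good, 3-5 poor
        mask[present, j] = 1.0
    return targets, mask


def _load_images(manifest: pd.DataFrame, root: Path, config: ModelConfig) -> np.ndarray:
    """Stack manifest images into ``(N, C, side, side)``."""
    arrays = []
    for rel in manifest["image_path"]:
        img = retio.read_image(root / rel, config.modality, side=config.input_side_px)
        arrays.append(np.moveaxis(img, -1, 0))
    return np.stack(arrays)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _mean_validation_auc(net, images, targets, mask, batch_size=64) -> float:
    """Mean per-category AUC-ROC with dropout off; single-class heads skipped."""
    from sklearn.metrics import roc_auc_score

    probs = []
    for i in range(0, len(images), batch_size):
        probs.append(expit(net.forward(images[i : i + batch_size], "eval")))
    p = np.concatenate(probs)
    aucs = []
    for j in range(p.shape[1]):
        sel = mask[:, j] > 0
        y = targets[sel, j]
        if sel.sum() >= 2 and len(np.unique(y)) == 2:
            aucs.append(roc_auc_score(y, p[sel, j]))
    return float(np.mean(aucs)) if aucs else float("nan")


def train(
    net: DropoutResNet,
    train_images: np.ndarray,
    train_targets: np.ndarray,
    train_mask: np.ndarray,
    val_images: np.ndarray,
    val_targets: np.ndarray,
    val_mask: np.ndarray,
    config: TrainConfig,
) -> tuple[DropoutResNet, list[dict]]:
    """Minibatch gradient descent on the masked loss with best-epoch selection.

    After every epoch the selection metric (mean per-category validation
    AUC-ROC) is evaluated with dropout disabled; the returned network is
    the checkpoint with the best validation metric.  ``history`` holds one
    record per epoch with the mean training loss and the metric.
    """
    config.validate()
    if len(train_images) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    opt = Adam(net, lr=config.learning_rate)
    history: list[dict] = []
    best_metric = -np.inf
    best_state = net.state_dict()

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(train_images))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            net.zero_grad()
            logits = net.forward(train_images[idx], "train", rng)
            loss, dlogits = _masked_loss_and_grad(
                logits, train_targets[idx], train_mask[idx]
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}; lower the learning rate"
                )
            if np.any(dlogits):
                net.backward(dlogits)
                opt.step()
            losses.append(loss)
        metric = _mean_validation_auc(net, val_images, val_targets, val_mask)
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_metric": metric}
        )
        if np.isfinite(metric) and metric > best_metric:
            best_metric = metric
            best_state = net.state_dict()
    net.load_state_dict(best_state)
    return net, history


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


class QualityModel:
    """Image-quality model bound to training and validation data.

    Parameters
    ----------
    train_manifest, val_manifest : DataFrame
        Manifest rows (see :func:`retiqa.io.read_manifest`); patient sets
        must be disjoint.
    root : path
        Directory the manifests' image paths are relative to.
    config : ModelConfig
    """

    def __init__(self, train_manifest: pd.DataFrame, val_manifest: pd.DataFrame,
                 root: str | Path, config: ModelConfig | None = None) -> None:
        self.config = config or ModelConfig()
        self.config.validate()
        overlap = set(train_manifest["patient_id"]) & set(val_manifest["patient_id"])
        if overlap:
            raise ValueError(f"patients in both train and validation: {sorted(overlap)[:5]}")
        self.train_manifest = train_manifest.reset_index(drop=True)
        self.val_manifest = val_manifest.reset_index(drop=True)
        self.root = Path(root)
        self.categories = categories_for(self.config.modality)

    @classmethod
    def from_dataset(cls, dataset_dir: str | Path,
                     config: ModelConfig | None = None) -> "QualityModel":
        """Build from a dataset directory containing ``manifest.csv``."""
        dataset_dir = Path(dataset_dir)
        manifest = retio.read_manifest(dataset_dir / "manifest.csv")
        if config is None:
            config = ModelConfig(modality=manifest["modality"].iloc[0])
        return cls(
            manifest[manifest["split"] == "train"],
            manifest[manifest["split"] == "validation"],
            dataset_dir,
            config,
        )

    def fit(self, train_config: TrainConfig | None = None) -> "QualityResults":
        train_config = train_config or TrainConfig()
        net = build_model(self.config)
        tr_imgs = _load_images(self.train_manifest, self.root, self.config)
        va_imgs = _load_images(self.val_manifest, self.root, self.config)
        tr_t, tr_m = labels_from_manifest(self.train_manifest, self.config.modality)
        va_t, va_m = labels_from_manifest(self.val_manifest, self.config.modality)
        net, history = train(net, tr_imgs, tr_t, tr_m, va_imgs, va_t, va_m, train_config)
        return QualityResults(self, net, history, train_config)


class QualityResults:
    """Fitted model: trained weights, training history, prediction methods."""

    def __init__(self, model: QualityModel, network: DropoutResNet,
                 history: list[dict], train_config: TrainConfig) -> None:
        self.model = model
        self.network = network
        self.history = history
        self.train_config = train_config

    @property
    def config(self) -> ModelConfig:
        return self.model.config

    @property
    def categories(self):
        return self.model.categories

    def predict(self, manifest: pd.DataFrame, root: str | Path | None = None,
                T: int = 16, seed: int = 0, tau: float = 0.5) -> pd.DataFrame:
        """Monte-Carlo-Dropout predictions for every manifest row.

        Returns a frame with ``p_<category>`` (mean probability of poor
        quality over ``T`` stochastic passes), ``u_<category>`` (variance
        over the passes) and ``decision_<category>`` columns.
        """
        from .inference import decide, mc_predict

        root = Path(root) if root is not None else self.model.root
        images = _load_images(manifest.reset_index(drop=True), root, self.config)
        p, u = mc_predict(self.network, images, T=T, seed=seed)
        out = manifest.reset_index(drop=True).copy()
        for j, cat in enumerate(self.categories):
            out[f"p_{cat}"] = p[:, j]
            out[f"u_{cat}"] = u[:, j]
            out[f"decision_{cat}"] = [decide(v, tau) for v in p[:, j]]
        out.attrs["T"] = T
        out.attrs["tau"] = tau
        return out

    def summary(self) -> str:
        """Plain-text fit summary in the spirit of a regression results table."""
        best = max(
            (h for h in self.history if np.isfinite(h["val_metric"])),
            key=lambda h: h["val_metric"],
            default=self.history[-1],
        )
        lines = [
            "Image quality model (dropout residual network)",
            "=" * 54,
            f"modality:            {self.config.modality}",
            f"categories:          {', '.join(self.categories)}",
            f"input side:          {self.config.input_side_px} px",
            f"width scale:         {self.config.width_scale}",
            f"dropout rate:        {self.config.dropout_rate}",
            f"parameters:          {self.network.n_params()}",
            f"epochs run:          {len(self.history)}",
            f"best epoch:          {best['epoch']}",
            f"best val mean AUC:   {best['val_metric']:.4f}",
            f"final train loss:    {self.history[-1]['train_loss']:.4f}",
        ]
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        """Serialise weights (npz) plus a JSON config sidecar."""
        path = Path(path)
        with open(path, "wb") as fh:
            np.savez(fh, **self.network.state_dict())
        sidecar = {
            "model_config": vars(self.config),
            "train_config": vars(self.train_config),
            "history": self.history,
            "categories": list(self.categories),
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True)
        )

    @staticmethod
    def load_network(path: str | Path) -> tuple[DropoutResNet, ModelConfig]:
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        config = ModelConfig(**sidecar["model_config"])
        net = DropoutResNet(
            in_channels=config.in_channels,
            n_outputs=config.n_categories,
            width_scale=config.width_scale,
            dropout_rate=config.dropout_rate,
            input_side=config.input_side_px,
            seed=config.seed,
        )
        with np.load(path) as data:
            net.load_state_dict(dict(data))
        return net, config
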