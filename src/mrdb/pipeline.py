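"""Training / evaluation orchestration.

Datasets are ``images/*.png`` + ``masks/*.png`` folder pairs with matching
file names; images are rescaled to [0, 1] and resized to the configured
input side, masks binarized at 128.  Training follows the published
recipe: Adam, initial learning rate 1e-3, 256×256 inputs, batch size 32,
200 epochs, hybrid loss — all of which scale down through
:class:`TrainConfig` for desk-size runs.  The best-validation-DSC
checkpoint is kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
from PIL import Image

from .autograd.optim import Adam
from .losses import hybrid_loss
from .metrics import MetricsReport, evaluate_pair, pr_curve, write_report_csv
from .network import MRDB, MRDBConfig
from .phantom import augment as _augment

__all__ = [
    "TrainConfig",
    "PairedDataset",
    "load_dataset",
    "train",
    "evaluate",
    "save_checkpoint",
    "load_checkpoint",
    "ablation_grid",
    "ABLATION_ROWS",
]


@dataclass
class TrainConfig:
    """Optimization settings; defaults follow the published recipe."""

    learning_rate: float = 1e-3
    input_side: int = 256
    batch_size: int = 32
    epochs: int = 200
    seed: int = 0
    augmentation: bool = True
    val_fraction: float = 0.2
    max_steps: int | None = None  # optional hard cap for desk-scale runs
    dsc_target: float | None = None  # stop early once train DSC reaches this
    model: MRDBConfig = field(default_factory=MRDBConfig)

    def __post_init__(self):
        if isinstance(self.model, dict):
            self.model = MRDBConfig.from_dict(self.model)
        self.model.input_side = self.input_side

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


class PairedDataset:
    """Aligned (image, mask) arrays: images float32 in [0, 1], masks bool."""

    def __init__(self, images: np.ndarray, masks: np.ndarray, names: list[str]):
        self.images = images
        self.masks = masks
        self.names = names

    def __len__(self) -> int:
        return len(self.names)

    def subset(self, idx) -> "PairedDataset":
        idx = np.asarray(idx)
        return PairedDataset(self.images[idx], self.masks[idx],
                            [self.names[i] for i in idx])


def load_dataset(root, input_side: int = 256) -> PairedDataset:
    """Read an ``images/`` + ``masks/`` folder pair.

    Raises a ``FileNotFoundError`` naming every image without a matching
    mask (and vice versa).
    """
    root = Path(root)
    img_dir, mask_dir = root / "images", root / "masks"
    if not img_dir.is_dir() or not mask_dir.is_dir():
        raise FileNotFoundError(f"{root} must contain images/ and masks/ subfolders")
    img_names = sorted(p.name for p in img_dir.glob("*.png"))
    mask_names = sorted(p.name for p in mask_dir.glob("*.png"))
    missing_masks = sorted(set(img_names) - set(mask_names))
    missing_imgs = sorted(set(mask_names) - set(img_names))
    if missing_masks or missing_imgs:
        raise FileNotFoundError(
            f"unmatched files — images without masks: {missing_masks}; "
            f"masks without images: {missing_imgs}")
    if not img_names:
        raise FileNotFoundError(f"no PNG pairs found under {root}")
    images, masks = [], []
    for name in img_names:
        img = Image.open(img_dir / name).convert("L")
        msk = Image.open(mask_dir / name).convert("L")
        if img.size != (input_side, input_side):
            img = img.resize((input_side, input_side), Image.BILINEAR)
        if msk.size != (input_side, input_side):
            msk = msk.resize((input_side, input_side), Image.NEAREST)
        images.append(np.asarray(img, dtype=np.float32) / 255.0)
        masks.append(np.asarray(msk) >= 128)
    return PairedDataset(np.stack(images), np.stack(masks), img_names)


# ------------------------------------------------------------- checkpoints
def save_checkpoint(path, model: MRDB, extra: dict | None = None) -> None:
    """Single-archive checkpoint: weights + embedded JSON config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"config": model.cfg.to_dict(), "extra": extra or {}}
    state = model.state_dict()
    arrays = {k.replace("buffer:", "buffer__"): v for k, v in state.items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> tuple[MRDB, dict]:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {}
        for k in data.files:
            if k == "__meta__":
                continue
            state[k.replace("buffer__", "buffer:")] = data[k]
    cfg = MRDBConfig.from_dict(meta["config"])
    model = MRDB(cfg)
    model.load_state_dict(state)
    return model, meta["extra"]


# ---------------------------------------------------------------- training
def _forward_dataset(model: MRDB, ds: PairedDataset, batch_size: int) -> np.ndarray:
    """Probability maps for a whole dataset (inference mode)."""
    model.eval()
    probs = []
    for start in range(0, len(ds), batch_size):
        batch = ds.images[start:start + batch_size][:, None]
        probs.append(model(batch).data[:, 0])
    return np.concatenate(probs)


def _mean_dsc(model: MRDB, ds: PairedDataset, batch_size: int) -> float:
    from .metrics import dsc as _dsc
    probs = _forward_dataset(model, ds, batch_size)
    return float(np.mean([_dsc(ds.masks[i], probs[i] >= 0.5) for i in range(len(ds))]))


def train(cfg: TrainConfig, dataset: PairedDataset, out_dir=None,
          log_callback=None) -> dict:
    """Run Adam on the hybrid loss; returns a summary dict.

    Writes ``checkpoint.npz`` (best validation DSC; final weights as
    ``last.npz``) and ``train_log.csv`` under ``out_dir`` when given.
    Deterministic for a fixed seed.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(cfg.seed)
    model = MRDB(cfg.model)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)

    n = len(dataset)
    n_val = int(round(n * cfg.val_fraction))
    perm = rng.permutation(n)
    val_ds = dataset.subset(perm[:n_val]) if n_val else None
    train_ds = dataset.subset(perm[n_val:])

    log_rows: list[dict] = []
    best = {"val_dsc": -1.0, "epoch": -1}
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    step = 0
    stop = False
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(train_ds))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            imgs = train_ds.images[idx]
            msks = train_ds.masks[idx]
            if cfg.augmentation:
                aug_imgs = []
                for i, img in enumerate(imgs):
                    a, _ = _augment((img * 255).astype(np.uint8), msks[i],
                                    seed=int(rng.integers(2 ** 31)))
                    aug_imgs.append(a.astype(np.float32) / 255.0)
                imgs = np.stack(aug_imgs)
            pred = model(imgs[:, None])
            loss = hybrid_loss(pred, msks[:, None].astype(np.uint8))
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, step {step}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            step += 1
            if cfg.max_steps is not None and step >= cfg.max_steps:
                stop = True
                break
        epoch_loss = float(np.mean(losses))
        val_dsc = _mean_dsc(model, val_ds, cfg.batch_size) if val_ds is not None else float("nan")
        train_dsc = _mean_dsc(model, train_ds, cfg.batch_size)
        row = {"epoch": epoch, "loss": epoch_loss, "train_dsc": train_dsc,
               "val_dsc": val_dsc}
        log_rows.append(row)
        if log_callback:
            log_callback(row)
        track = val_dsc if val_ds is not None else train_dsc
        if track >= best["val_dsc"]:
            best = {"val_dsc": track, "epoch": epoch}
            if out_dir is not None:
                save_checkpoint(out_dir / "checkpoint.npz", model,
                                extra={"epoch": epoch, "val_dsc": track})
        if cfg.dsc_target is not None and train_dsc >= cfg.dsc_target:
            stop = True
        if stop:
            break

    if out_dir is not None:
        save_checkpoint(out_dir / "last.npz", model,
                        extra={"epoch": log_rows[-1]["epoch"]})
        with open(out_dir / "train_log.csv", "w") as fh:
            fh.write("epoch,loss,train_dsc,val_dsc\n")
            for r in log_rows:
                fh.write(f"{r['epoch']},{r['loss']:.6f},{r['train_dsc']:.6f},"
                         f"{r['val_dsc']:.6f}\n")
    return {"model": model, "log": log_rows, "best": best,
            "first_loss": log_rows[0]["loss"], "last_loss": log_rows[-1]["loss"]}


def evaluate(model: MRDB, dataset: PairedDataset, out_csv=None,
             batch_size: int = 8) -> dict:
    """Per-image metric reports, dataset means and pooled PR-AUC."""
    if dataset.images.shape[-1] != model.cfg.input_side:
        raise ValueError(
            f"dataset side {dataset.images.shape[-1]} != model side {model.cfg.input_side}")
    probs = _forward_dataset(model, dataset, batch_size)
    rows: list[tuple[str, MetricsReport]] = []
    for i, name in enumerate(dataset.names):
        rows.append((name, evaluate_pair(dataset.masks[i], probs[i])))
    _, auc = pr_curve(list(probs), list(dataset.masks))
    if out_csv is not None:
        write_report_csv(out_csv, rows, pr_auc=auc)
    means = {}
    for f in ("dsc", "jaccard", "sensitivity", "hd95", "fnr"):
        vals = np.array([getattr(r, f) for _, r in rows], dtype=float)
        vals = vals[~np.isnan(vals)]
        means[f] = float(vals.mean()) if len(vals) else float("nan")
    return {"rows": rows, "means": means, "pr_auc": auc, "probs": probs}


# ---------------------------------------------------------------- ablation
#: Flag settings of the six ablation configurations, in ladder order.
ABLATION_ROWS: tuple[tuple[str, dict], ...] = (
    ("base_unet", dict(dual_unet_enabled=False, csc_enabled=False,
                       resnet_enabled=False, r_decoder_enabled=False,
                       vssb_enabled=False)),
    ("dual_unet", dict(dual_unet_enabled=True, csc_enabled=False,
                       resnet_enabled=False, r_decoder_enabled=False,
                       vssb_enabled=False)),
    ("csc", dict(dual_unet_enabled=True, csc_enabled=True,
                 resnet_enabled=False, r_decoder_enabled=False,
                 vssb_enabled=False)),
    ("resnet34", dict(dual_unet_enabled=True, csc_enabled=True,
                      resnet_enabled=True, r_decoder_enabled=False,
                      vssb_enabled=False)),
    ("r_decoder", dict(dual_unet_enabled=True, csc_enabled=True,
                       resnet_enabled=True, r_decoder_enabled=True,
                       vssb_enabled=False)),
    ("full", dict(dual_unet_enabled=True, csc_enabled=True,
                  resnet_enabled=True, r_decoder_enabled=True,
                  vssb_enabled=True)),
)


def ablation_grid(base_cfg: TrainConfig, dataset: PairedDataset,
                  out_dir=None) -> dict[str, dict]:
    """Train every ablation configuration with shared settings."""
    results = {}
    for name, flags in ABLATION_ROWS:
        model_cfg = MRDBConfig.from_dict({**base_cfg.model.to_dict(), **flags})
        cfg = TrainConfig.from_dict({**base_cfg.to_dict(), "model": model_cfg.to_dict()})
        run_dir = (Path(out_dir) / name) if out_dir is not None else None
        res = train(cfg, dataset, out_dir=run_dir)
        results[name] = {"first_loss": res["first_loss"],
                         "last_loss": res["last_loss"],
                         "best": res["best"],
                         "final_train_dsc": res["log"][-1]["train_dsc"]}
    return results
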