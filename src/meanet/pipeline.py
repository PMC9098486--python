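"""Training, evaluation and prediction wiring.

Reproduces the published optimisation recipe: Adam with learning rate
2e-3 and betas (0.5, 0.999), batch size 4, up to 300 epochs, joint
Dice+BCE supervision, rotation/flip/translation/mirroring augmentation,
and either an 8:1:1 ratio split or k-fold cross-validation.  All
randomness (splits, weight init, shuffling, augmentation) flows from a
single global seed through named sub-seeds, so a config + seed pair
reproduces split manifests bitwise and training curves to
floating-point accuracy.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .losses import LossConfig, SupervisionBundle, joint_loss
from .metrics import BoundaryMatchConfig, MetricReport, evaluate_batch
from .network import MEANet, NetworkConfig, load_checkpoint, save_checkpoint
from .optim import Adam
from .synthetic import SegmentationSample, augment, derive_edge_map

logger = logging.getLogger("meanet")


@dataclass
class TrainConfig:
    """Optimisation and experiment settings (defaults: published recipe)."""

    learning_rate: float = 2e-3
    adam_betas: tuple[float, float] = (0.5, 0.999)
    batch_size: int = 4
    max_epochs: int = 300
    max_steps: int | None = None
    folds: int = 5
    split_ratio: tuple[int, int, int] = (8, 1, 1)
    augment_ops: tuple[str, ...] = ()
    global_seed: int = 0
    lr_schedule: str = "constant"  # "constant" | "cosine"
    val_interval: int = 1          # epochs between validation passes
    target_dice: float | None = None  # early stop once val Dice reaches this
    loss: LossConfig = field(default_factory=LossConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self):
        self.adam_betas = tuple(self.adam_betas)
        self.split_ratio = tuple(self.split_ratio)
        self.augment_ops = tuple(self.augment_ops)
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if len(self.split_ratio) != 3 or any(r <= 0 for r in self.split_ratio):
            raise ValueError(f"split_ratio must be 3 positive parts, got {self.split_ratio}")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")

    # -- YAML round trip ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["adam_betas"] = list(self.adam_betas)
        d["split_ratio"] = list(self.split_ratio)
        d["augment_ops"] = list(self.augment_ops)
        d["network"] = self.network.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if "network" in d and isinstance(d["network"], dict):
            d["network"] = NetworkConfig.from_dict(d["network"])
        if "loss" in d and isinstance(d["loss"], dict):
            d["loss"] = LossConfig(**d["loss"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class FoldSplit:
    """Per-fold train/val/test id lists (one fold for a ratio split)."""

    folds: list[dict[str, list[str]]]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"folds": self.folds}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FoldSplit":
        with open(path) as fh:
            return cls(folds=json.load(fh)["folds"])


def _ratio_counts(n: int, ratio: tuple[int, int, int]) -> list[int]:
    """Largest-remainder apportionment of n into the ratio's parts."""
    total = sum(ratio)
    raw = [n * r / total for r in ratio]
    counts = [math.floor(x) for x in raw]
    order = sorted(range(3), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in range(n - sum(counts)):
        counts[order[i % 3]] += 1
    # every part gets at least one sample (n >= 3 is checked by callers)
    for i in range(3):
        while counts[i] == 0:
            counts[int(np.argmax(counts))] -= 1
            counts[i] += 1
    return counts


def make_splits(ids, cfg: TrainConfig, mode: str = "ratio") -> FoldSplit:
    """Seeded shuffle, then either an 8:1:1-style ratio split (one fold)
    or a k-fold partition with disjoint test sets covering the data."""
    ids = [str(i) for i in ids]
    if mode not in ("ratio", "kfold"):
        raise ValueError(f"mode must be 'ratio' or 'kfold', got {mode!r}")
    rng = np.random.default_rng(np.random.PCG64(cfg.global_seed))
    perm = [ids[i] for i in rng.permutation(len(ids))]
    if mode == "ratio":
        if len(ids) < 3:
            raise ValueError(f"need at least 3 samples for a ratio split, got {len(ids)}")
        n_train, n_val, n_test = _ratio_counts(len(ids), cfg.split_ratio)
        folds = [{"train": perm[:n_train],
                  "val": perm[n_train:n_train + n_val],
                  "test": perm[n_train + n_val:]}]
    else:
        k = cfg.folds
        if len(ids) < k:
            raise ValueError(f"need at least {k} samples for {k}-fold CV, got {len(ids)}")
        chunks = [list(c) for c in np.array_split(perm, k)]
        folds = []
        for i in range(k):
            test = chunks[i]
            val = chunks[(i + 1) % k]
            train = [s for j, c in enumerate(chunks)
                     for s in c if j not in (i, (i + 1) % k)]
            folds.append({"train": train, "val": val, "test": test})
    return FoldSplit(folds=folds)


# ----------------------------------------------------------------------
# Training
# ----------------------------------------------------------------------

@dataclass
class TrainResult:
    checkpoint_path: Path | None
    history: list[dict]
    model: MEANet
    best_val_dice: float | None


def _batch_arrays(samples: list[SegmentationSample]):
    images = np.stack([s.image for s in samples])
    masks = np.stack([s.mask for s in samples]).astype(np.float32)[:, None]
    edges = np.stack([s.edge for s in samples]).astype(np.float32)[:, None]
    return images, masks, edges


def mean_dice(model: MEANet, samples: list[SegmentationSample],
              threshold: float = 0.5, batch_size: int = 4) -> float:
    """Mean per-image Dice of thresholded predictions (eval mode)."""
    model.eval()
    dices = []
    for i in range(0, len(samples), batch_size):
        chunk = samples[i:i + batch_size]
        images, masks, _ = _batch_arrays(chunk)
        probs = model(images).seg_prob.numpy()
        for p, g in zip(probs, masks):
            pred = (p[0] >= threshold)
            gt = g[0] >= 0.5
            denom = pred.sum() + gt.sum()
            dices.append(1.0 if denom == 0 else 2.0 * np.sum(pred & gt) / denom)
    return float(np.mean(dices))


def train(train_samples: list[SegmentationSample], cfg: TrainConfig,
          out_dir, val_samples: list[SegmentationSample] | None = None) -> TrainResult:
    """Run the optimisation loop and keep the best-by-val-Dice checkpoint.

    Stops after ``cfg.max_epochs`` epochs or ``cfg.max_steps`` optimizer
    steps, or earlier when ``cfg.target_dice`` is reached on the
    validation set.  Raises on non-finite loss, naming the batch.
    """
    if not train_samples:
        raise ValueError("empty training set")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg.global_seed).generate_state(3) % (2 ** 31)
    init_seed, shuffle_seed, aug_seed = (int(s) for s in seeds)
    model = MEANet(cfg.network, seed=init_seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate, betas=cfg.adam_betas)
    shuffle_rng = np.random.default_rng(np.random.PCG64(shuffle_seed))
    aug_rng = np.random.default_rng(np.random.PCG64(aug_seed))

    ckpt_path = out_dir / "checkpoint.npz"
    history_path = out_dir / "history.jsonl"
    history: list[dict] = []
    best_val = -1.0
    step = 0
    stop = False
    supervise_edge = model.has_edge_module

    with open(history_path, "w") as hist_fh:
        for epoch in range(cfg.max_epochs):
            if cfg.lr_schedule == "cosine":
                opt.lr = cfg.learning_rate * 0.5 * (
                    1 + math.cos(math.pi * epoch / cfg.max_epochs))
            model.train()
            order = shuffle_rng.permutation(len(train_samples))
            losses, dterms, bterms = [], [], []
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                batch = [train_samples[i] for i in idx]
                if cfg.augment_ops:
                    batch = [augment(s, cfg.augment_ops,
                                     int(aug_rng.integers(2 ** 31)))
                             for s in batch]
                images, masks, edges = _batch_arrays(batch)
                out = model(images)
                bundle = SupervisionBundle(
                    seg_pred=out.seg_prob, seg_gt=masks,
                    edge_pred=out.edge_prob if supervise_edge else None,
                    edge_gt=edges if supervise_edge else None)
                total, dterm, bterm = joint_loss(bundle, cfg.loss)
                loss_val = float(total.data)
                if not np.isfinite(loss_val):
                    ids = ", ".join(s.id for s in batch)
                    raise RuntimeError(
                        f"non-finite loss {loss_val} at epoch {epoch}, "
                        f"step {step}, batch [{ids}]")
                model.zero_grad()
                total.backward()
                opt.step()
                step += 1
                losses.append(loss_val)
                dterms.append(float(dterm.data))
                bterms.append(float(bterm.data))
                if cfg.max_steps is not None and step >= cfg.max_steps:
                    stop = True
                    break

            entry = {"epoch": epoch, "step": step,
                     "train_loss": float(np.mean(losses)),
                     "dice_term": float(np.mean(dterms)),
                     "bce_term": float(np.mean(bterms))}
            run_val = val_samples and (epoch % cfg.val_interval == 0 or stop)
            if run_val:
                vd = mean_dice(model, val_samples, batch_size=cfg.batch_size)
                entry["val_dice"] = vd
                if vd > best_val:
                    best_val = vd
                    save_checkpoint(model, ckpt_path)
                if cfg.target_dice is not None and vd >= cfg.target_dice:
                    stop = True
            history.append(entry)
            hist_fh.write(json.dumps(entry) + "\n")
            logger.info("epoch %d step %d loss %.4f%s", epoch, step,
                        entry["train_loss"],
                        f" val_dice {entry['val_dice']:.4f}" if "val_dice" in entry else "")
            if stop:
                break

    if not val_samples:
        save_checkpoint(model, ckpt_path)
    return TrainResult(checkpoint_path=ckpt_path, history=history, model=model,
                       best_val_dice=best_val if val_samples else None)


# ----------------------------------------------------------------------
# Evaluation / prediction
# ----------------------------------------------------------------------

def _resolve_model(model_or_checkpoint) -> MEANet:
    if isinstance(model_or_checkpoint, MEANet):
        return model_or_checkpoint
    return load_checkpoint(model_or_checkpoint)


def predict_probs(model: MEANet, samples: list[SegmentationSample],
                  batch_size: int = 4):
    """Per-sample (seg_prob, edge_prob) maps in eval mode."""
    model.eval()
    out = []
    for i in range(0, len(samples), batch_size):
        chunk = samples[i:i + batch_size]
        images, _, _ = _batch_arrays(chunk)
        res = model(images)
        seg = res.seg_prob.numpy()
        edge = res.edge_prob.numpy() if res.edge_prob is not None else None
        for j in range(len(chunk)):
            out.append((seg[j, 0], edge[j, 0] if edge is not None else None))
    return out


def evaluate(model_or_checkpoint, samples: list[SegmentationSample],
             out_dir=None, threshold: float = 0.5,
             boundary_cfg: BoundaryMatchConfig | None = None) -> MetricReport:
    """Score a test set; optionally write CSV/JSON reports."""
    model = _resolve_model(model_or_checkpoint)
    probs = predict_probs(model, samples)
    items = [(seg, s.mask, s.id) for (seg, _), s in zip(probs, samples)]
    report = evaluate_batch(items, threshold=threshold, cfg=boundary_cfg)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_csv(out_dir / "report.csv")
        report.to_json(out_dir / "report.json")
    return report


def predict(model_or_checkpoint, samples: list[SegmentationSample], out_dir,
            threshold: float = 0.5) -> list[dict]:
    """Write probability / mask / edge PNGs per image; returns file maps."""
    model = _resolve_model(model_or_checkpoint)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for (seg, edge), s in zip(predict_probs(model, samples), samples):
        prob8 = np.clip(np.round(seg * 255), 0, 255).astype(np.uint8)
        mask8 = ((seg >= threshold) * 255).astype(np.uint8)
        files = {"prob": out_dir / f"{s.id}_prob.png",
                 "mask": out_dir / f"{s.id}_mask.png"}
        iio.imwrite(files["prob"], prob8)
        iio.imwrite(files["mask"], mask8)
        if edge is not None:
            files["edge"] = out_dir / f"{s.id}_edge.png"
            iio.imwrite(files["edge"],
                        np.clip(np.round(edge * 255), 0, 255).astype(np.uint8))
        else:  # derive an edge map from the predicted mask
            files["edge"] = out_dir / f"{s.id}_edge.png"
            iio.imwrite(files["edge"],
                        (derive_edge_map((seg >= threshold).astype(np.uint8)) * 255
                         ).astype(np.uint8))
        written.append({k: str(v) for k, v in files.items()})
    return written
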