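"""Multiple-instance learning: bags, slide-level splits, and training.

A *bag* is one slide: every QC-passing tile across all configured
magnification levels, labeled with the slide's weak diagnosis label (a bag
is positive when at least one instance is).  Slides are split 6:2:2 into
train/validation/test at slide level — tiles never straddle partitions —
stratified by label.  Each model trains with Adam on two-class
cross-entropy over bag outputs, drawing a fresh without-replacement sample
of instances from every bag each epoch, with early stopping on validation
loss (patience 5, epoch cap 20) and checkpointing of the best epoch.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np

from .nn import BACKBONES, Adam, MILNet
from .tiling import MAG_ORDER, TileRecord


@dataclasses.dataclass
class Bag:
    """All surviving tiles of one slide plus its weak binary label."""

    slide_id: str
    label: int
    instances: list[TileRecord]

    @property
    def instance_count(self) -> int:
        return len(self.instances)

    def __post_init__(self) -> None:
        if any(t.slide_id != self.slide_id for t in self.instances):
            raise ValueError(f"bag {self.slide_id}: instances from a different slide")


@dataclasses.dataclass(frozen=True)
class SplitAssignment:
    ratios: tuple[float, float, float]
    seed: int
    assignment: dict  # slide_id -> "train" | "val" | "test"

    def slides(self, partition: str) -> list[str]:
        return [s for s, p in self.assignment.items() if p == partition]


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """One ensemble variant: backbone + pooling mode + training knobs."""

    backbone: str = "tiny-cnn"
    attention: bool = False
    attention_head_size: int = 16
    batch_size: int = 4
    sample_size: int = 20
    learning_rate: float = 0.001
    max_epochs: int = 20
    patience: int = 5
    input_size_px: int = 224
    channel_means: tuple[float, float, float] = (0.485, 0.456, 0.406)
    channel_stds: tuple[float, float, float] = (0.229, 0.224, 0.225)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")
        if not self.patience < self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if len(self.channel_means) != 3 or len(self.channel_stds) != 3:
            raise ValueError("channel means/stds must have length 3")

    @property
    def name(self) -> str:
        return f"{self.backbone}{'-attn' + str(self.attention_head_size) if self.attention else ''}"


@dataclasses.dataclass
class TrainedModel:
    config: ModelConfig
    parameters: dict  # name -> float32 ndarray (weights of best_epoch)
    history: list[dict]  # per-epoch train/val loss and accuracy
    best_epoch: int  # 1-based epoch index with minimum validation loss

    def network(self) -> MILNet:
        net = MILNet(
            backbone=self.config.backbone,
            attention=self.config.attention,
            attention_head_size=self.config.attention_head_size,
            seed=self.config.seed,
        )
        net.params = {k: v.copy() for k, v in self.parameters.items()}
        return net

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(
            path,
            __config__=json.dumps(dataclasses.asdict(self.config)),
            __history__=json.dumps(self.history),
            __best_epoch__=self.best_epoch,
            **self.parameters,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as z:
            cfg = json.loads(str(z["__config__"]))
            for key in ("channel_means", "channel_stds"):
                cfg[key] = tuple(cfg[key])
            history = json.loads(str(z["__history__"]))
            best = int(z["__best_epoch__"])
            params = {k: z[k] for k in z.files if not k.startswith("__")}
        return cls(config=ModelConfig(**cfg), parameters=params, history=history, best_epoch=best)


# --------------------------------------------------------------------- bags

def _instance_sort_key(rec: TileRecord):
    return (MAG_ORDER.index(rec.magnification), rec.y, rec.x)


def build_bags(records: list[TileRecord], labels: dict[str, int]) -> tuple[list[Bag], list[str]]:
    """Group QC-passing tiles into one bag per slide.

    ``records`` must carry populated ``qc`` results; tiles failing QC are
    dropped.  Slides with zero passing tiles are excluded and returned in
    the rejects list.  Instance order is deterministic: magnification
    (finest first), then y, then x.
    """
    by_slide: dict[str, list[TileRecord]] = {}
    for rec in records:
        if rec.qc is not None and not rec.qc.passed:
            continue
        by_slide.setdefault(rec.slide_id, []).append(rec)
    bags, rejects = [], []
    for slide_id in labels:
        tiles = by_slide.get(slide_id, [])
        if not tiles:
            warnings.warn(f"slide {slide_id!r} has no QC-passing tiles; excluded")
            rejects.append(slide_id)
            continue
        tiles.sort(key=_instance_sort_key)
        bags.append(Bag(slide_id=slide_id, label=labels[slide_id], instances=tiles))
    return bags, rejects


# -------------------------------------------------------------------- split

def largest_remainder_counts(n: int, ratios) -> list[int]:
    """Allocate n items to len(ratios) buckets by largest-remainder rounding."""
    quotas = [n * r / sum(ratios) for r in ratios]
    counts = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(range(len(ratios)), key=lambda i: quotas[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def split_slides(
    slide_ids: list[str],
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    labels: dict[str, int] | None = None,
) -> SplitAssignment:
    """Seeded slide-level train/val/test split, stratified by label.

    Within each class the shuffled slides are allocated by largest-remainder
    rounding of the ratios; a final adjustment pass reconciles the overall
    partition sizes with the largest-remainder allocation of the full
    cohort, so realized counts match it exactly.
    """
    if len(slide_ids) < 3:
        raise ValueError("need at least 3 slides to split")
    if len(set(slide_ids)) != len(slide_ids):
        raise ValueError("duplicate slide ids")
    parts = ("train", "val", "test")
    rng = np.random.default_rng(seed)
    target = largest_remainder_counts(len(slide_ids), ratios)

    groups: dict[int, list[str]]
    if labels and len(set(labels.get(s, 0) for s in slide_ids)) > 1:
        groups = {}
        for s in slide_ids:
            groups.setdefault(labels[s], []).append(s)
    else:
        groups = {0: list(slide_ids)}

    assignment: dict[str, str] = {}
    for _, members in sorted(groups.items()):
        members = list(members)
        rng.shuffle(members)
        counts = largest_remainder_counts(len(members), ratios)
        i = 0
        for part, c in zip(parts, counts):
            for s in members[i : i + c]:
                assignment[s] = part
            i += c

    # reconcile per-class rounding drift with the cohort-level allocation
    realized = {p: sum(1 for v in assignment.values() if v == p) for p in parts}
    for _ in range(len(slide_ids)):
        over = [p for i, p in enumerate(parts) if realized[p] > target[i]]
        under = [p for i, p in enumerate(parts) if realized[p] < target[i]]
        if not over:
            break
        src, dst = over[0], under[0]
        mover = sorted(s for s, p in assignment.items() if p == src)[-1]
        assignment[mover] = dst
        realized[src] -= 1
        realized[dst] += 1

    for i, p in enumerate(parts):
        if realized[p] == 0:
            warnings.warn(f"partition {p!r} received 0 slides")
    return SplitAssignment(ratios=tuple(ratios), seed=seed, assignment=assignment)


# ----------------------------------------------------------------- sampling

def sample_instances(bag: Bag, sample_size: int, seed_or_rng) -> list[TileRecord]:
    """Uniform without-replacement sample of a bag's instances.

    When the bag holds fewer instances than requested, all are returned
    (never duplicated).
    """
    if sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    if bag.instance_count == 0:
        raise ValueError(f"bag {bag.slide_id!r} is empty")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    if sample_size >= bag.instance_count:
        return list(bag.instances)
    idx = rng.choice(bag.instance_count, size=sample_size, replace=False)
    return [bag.instances[i] for i in sorted(idx)]


# ------------------------------------------------------------ preprocessing

def preprocess_instances(records: list[TileRecord], config: ModelConfig) -> np.ndarray:
    """Resize tiles to the model input size and standardize channels."""
    from skimage.transform import resize

    size = config.input_size_px
    out = np.empty((len(records), size, size, 3), dtype=np.float32)
    means = np.asarray(config.channel_means, dtype=np.float32)
    stds = np.asarray(config.channel_stds, dtype=np.float32)
    for i, rec in enumerate(records):
        r = rec.raster
        if r.shape[0] != size or r.shape[1] != size:
            img = resize(r, (size, size), preserve_range=True, anti_aliasing=True)
        else:
            img = r
        out[i] = (img.astype(np.float32) / 255.0 - means) / stds
    return out


# ------------------------------------------------------------------ forward

def forward_bag(model: "TrainedModel | MILNet", instances: list[TileRecord],
                config: ModelConfig | None = None):
    """Bag probability (positive class) and, for attention variants, the
    per-instance attention weights (summing to 1)."""
    if not instances:
        raise ValueError("forward_bag requires at least one instance")
    if isinstance(model, TrainedModel):
        net = model.network()
        config = model.config
    else:
        net = model
        if config is None:
            raise ValueError("config required when passing a bare network")
    x = preprocess_instances(instances, config)
    return net.forward_bag(x)


# ----------------------------------------------------------------- training

def _eval_bags(net: MILNet, bags: list[Bag], config: ModelConfig) -> tuple[float, float]:
    losses, correct = [], 0
    for bag in bags:
        x = preprocess_instances(bag.instances, config)
        loss, p = net.bag_loss(x, bag.label)
        losses.append(loss)
        correct += int((p >= 0.5) == bool(bag.label))
    return float(np.mean(losses)), correct / len(bags)


def train_model(config: ModelConfig, train_bags: list[Bag], val_bags: list[Bag]) -> TrainedModel:
    """Train one MIL variant with the standard protocol.

    Per epoch: seeded shuffle of the training bags into mini-batches of
    ``batch_size`` bags, each contributing a fresh without-replacement
    sample of ``sample_size`` instances; gradients are averaged over the
    batch and applied with Adam.  Validation runs on all instances of each
    validation bag.  Training stops at ``max_epochs`` or once the running
    minimum of the validation loss has not improved (by > 1e-6) for
    ``patience`` consecutive epochs; the returned weights are those of the
    best epoch.
    """
    train_labels = {b.label for b in train_bags}
    if train_labels != {0, 1}:
        raise ValueError("training set must contain both classes")
    if not val_bags:
        raise ValueError("need at least one validation bag")

    net = MILNet(
        backbone=config.backbone,
        attention=config.attention,
        attention_head_size=config.attention_head_size,
        seed=config.seed,
    )
    opt = Adam(net.params, lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xB1D]))

    history: list[dict] = []
    best_loss = np.inf
    best_params = {k: v.copy() for k, v in net.params.items()}
    best_epoch = 0
    stale = 0

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_bags))
        epoch_losses, correct = [], 0
        for start in range(0, len(order), config.batch_size):
            batch = [train_bags[i] for i in order[start : start + config.batch_size]]
            batch_grads: dict[str, np.ndarray] = {}
            for bag in batch:
                inst = sample_instances(bag, config.sample_size, rng)
                x = preprocess_instances(inst, config)
                loss, p, grads = net.loss_and_grads(x, bag.label)
                epoch_losses.append(loss)
                correct += int((p >= 0.5) == bool(bag.label))
                for k, g in grads.items():
                    batch_grads[k] = batch_grads.get(k, 0) + g / len(batch)
            opt.step(batch_grads)
        val_loss, val_acc = _eval_bags(net, val_bags, config)
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)),
                "train_acc": correct / len(train_bags),
                "val_loss": val_loss,
                "val_acc": val_acc,
            }
        )
        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_params = {k: v.copy() for k, v in net.params.items()}
            best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break

    return TrainedModel(config=config, parameters=best_params, history=history, best_epoch=best_epoch)
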