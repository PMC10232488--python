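"""Dilated-ResNet feature extractor with attention-fused multi-scale maps.

The backbone is a stack of residual stages (3x3 conv -> batch norm -> ReLU
-> 3x3 conv -> batch norm, additive shortcut with a 1x1 projection when
shapes change).  The last three stage outputs each pass through a
DiConv-attention block: three parallel dilated convolutions with rates
(1, 2, 3) by default, fused as a convex combination whose branch weights
come from global average pooling -> dense -> sigmoid -> dense -> softmax.
The fused maps are bilinearly upsampled to a common resolution,
concatenated, projected by a 1x1 convolution and global-average-pooled
into a fixed-length feature vector.  A detachable softmax head trains the
backbone; features are read out with the head detached.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .manifest import DatasetManifest, TileRecord, load_tile
from .preprocess import prepare_tile

logger = logging.getLogger(__name__)

_PRESETS = {
    # name: (stage channels, blocks per stage)
    "reduced": ((16, 32, 64), (1, 1, 1)),
    "resnet50-like": ((64, 128, 256, 512), (3, 4, 6, 3)),
    "resnet101-like": ((64, 128, 256, 512), (3, 4, 23, 3)),
}


@dataclass(frozen=True)
class BackboneConfig:
    depth_preset: str = "reduced"
    input_size: tuple[int, int] = (64, 64)
    feature_dim: int = 64
    dilation_rates: tuple[int, int, int] = (1, 2, 3)
    use_pretrained_stem: bool = False
    upsample_and_concat: bool = True
    shared_attention_dense: bool = True

    def __post_init__(self) -> None:
        if self.depth_preset not in _PRESETS:
            raise ValueError(f"unknown depth preset {self.depth_preset!r}")
        if self.feature_dim < 8:
            raise ValueError("feature_dim must be >= 8")
        r = self.dilation_rates
        if len(r) != 3 or any(x < 1 for x in r) or not (r[0] < r[1] < r[2]):
            raise ValueError("dilation rates must be three strictly increasing ints >= 1")


@dataclass(frozen=True)
class BackboneTrainConfig:
    """Supervised training settings for the backbone + softmax head."""

    lr: float = 0.002
    max_epochs: int = 500
    batch_size: int = 64
    patience: int = 10
    seed: int = 0


@dataclass
class FeatureMatrix:
    """n x d feature table with per-row class labels."""

    values: np.ndarray
    labels: np.ndarray
    feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length must match the number of rows")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite entries")
        if not self.feature_ids:
            self.feature_ids = [f"f{j}" for j in range(self.values.shape[1])]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class BranchWeights:
    """Attention fusion weights and their intermediates for one batch."""

    mu: np.ndarray          # (n, 3) convex weights per sample
    pooled: list[np.ndarray]  # A_i, each (n, C)
    eta: list[np.ndarray]     # sigmoid(dense1(A_i)), each (n, C)


class DiConvAttentionBlock(nn.Layer):
    """Three dilated-conv branches fused by attention into one map."""

    def __init__(self, channels: int, rates: tuple[int, int, int] = (1, 2, 3),
                 kernel: int = 3, shared_dense: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.rates = tuple(rates)
        self.convs = [
            nn.Conv2d(channels, channels, kernel, dilation=r, rng=rng)
            for r in self.rates
        ]
        n_dense = 1 if shared_dense else len(self.rates)
        self.dense1 = [nn.Linear(channels, channels, rng=rng) for _ in range(n_dense)]
        self.dense2 = [nn.Linear(channels, 1, rng=rng) for _ in range(n_dense)]
        self.shared_dense = shared_dense

    def _dense(self, which: list[nn.Linear], i: int) -> nn.Linear:
        return which[0] if self.shared_dense else which[i]

    def clear_caches(self):
        super().clear_caches()
        for layer in (*self.convs, *self.dense1, *self.dense2):
            layer.clear_caches()

    def params(self):
        out = []
        for i, c in enumerate(self.convs):
            out += [(f"conv{i}.{n}", p) for n, p in c.params()]
        for i, lin in enumerate(self.dense1):
            out += [(f"dense1_{i}.{n}", p) for n, p in lin.params()]
        for i, lin in enumerate(self.dense2):
            out += [(f"dense2_{i}.{n}", p) for n, p in lin.params()]
        return out

    # -- attention path ------------------------------------------------------

    def branch_attention_weights(self, branches: list[np.ndarray]) -> BranchWeights:
        """Convex branch weights from pooled branch descriptors.

        ``branches`` are three ``N x C x H x W`` maps of identical shape.
        A_i is the spatial global average pool of branch i; eta_i is the
        sigmoid of a dense layer on A_i; a second dense layer reduces eta_i
        to a scalar and a softmax across the three branches yields mu.
        """
        shapes = {b.shape for b in branches}
        if len(shapes) != 1:
            raise ValueError(f"branches must share one shape, got {shapes}")
        pooled = [b.mean(axis=(2, 3)) for b in branches]
        eta, raw = [], []
        for i, a in enumerate(pooled):
            e = nn.sigmoid(self._dense(self.dense1, i).forward(a))
            eta.append(e)
            raw.append(self._dense(self.dense2, i).forward(e))
        mu = nn.softmax(np.concatenate(raw, axis=1), axis=1)
        return BranchWeights(mu=mu, pooled=pooled, eta=eta)

    # -- full block ----------------------------------------------------------

    def forward(self, x, train=False):
        branches = [conv.forward(x, train) for conv in self.convs]
        bw = self.branch_attention_weights(branches)
        out = sum(
            bw.mu[:, i][:, None, None, None] * branches[i]
            for i in range(len(branches))
        )
        self._cache.append((branches, bw, x.shape))
        return out

    def backward(self, dy):
        branches, bw, xshape = self._cache.pop()
        n_br = len(branches)
        h, w = branches[0].shape[2:]
        d_branch = [bw.mu[:, i][:, None, None, None] * dy for i in range(n_br)]
        dmu = np.stack(
            [(dy * branches[i]).sum(axis=(1, 2, 3)) for i in range(n_br)], axis=1
        )
        draw = bw.mu * (dmu - (bw.mu * dmu).sum(axis=1, keepdims=True))
        # unwind dense stacks in reverse branch order
        for i in reversed(range(n_br)):
            deta = self._dense(self.dense2, i).backward(draw[:, i][:, None])
            dz1 = deta * bw.eta[i] * (1.0 - bw.eta[i])
            da = self._dense(self.dense1, i).backward(dz1)
            d_branch[i] = d_branch[i] + da[:, :, None, None] / (h * w)
        dx = np.zeros(xshape, dtype=dy.dtype)
        for i in reversed(range(n_br)):
            dx += self.convs[i].backward(d_branch[i])
        return dx


class ResidualBlock(nn.Layer):
    """conv3x3 -> BN -> ReLU -> conv3x3 -> BN with additive shortcut."""

    def __init__(self, c_in: int, c_out: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv1 = nn.Conv2d(c_in, c_out, 3, stride=stride, rng=rng)
        self.bn1 = nn.BatchNorm2d(c_out)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(c_out, c_out, 3, rng=rng)
        self.bn2 = nn.BatchNorm2d(c_out)
        self.relu_out = nn.ReLU()
        if stride != 1 or c_in != c_out:
            self.proj = nn.Conv2d(c_in, c_out, 1, stride=stride, rng=rng)
            self.proj_bn = nn.BatchNorm2d(c_out)
        else:
            self.proj = None
            self.proj_bn = None

    def _children(self):
        kids = [("conv1", self.conv1), ("bn1", self.bn1), ("conv2", self.conv2),
                ("bn2", self.bn2)]
        if self.proj is not None:
            kids += [("proj", self.proj), ("proj_bn", self.proj_bn)]
        return kids

    def clear_caches(self):
        super().clear_caches()
        for _, c in self._children():
            c.clear_caches()
        self.relu1.clear_caches()
        self.relu_out.clear_caches()

    def params(self):
        return [(f"{cn}.{n}", p) for cn, c in self._children() for n, p in c.params()]

    def buffers(self):
        return [(f"{cn}.{n}", b) for cn, c in self._children() for n, b in c.buffers()]

    def forward(self, x, train=False):
        y = self.conv1.forward(x, train)
        y = self.bn1.forward(y, train)
        y = self.relu1.forward(y, train)
        y = self.conv2.forward(y, train)
        y = self.bn2.forward(y, train)
        if self.proj is not None:
            sc = self.proj_bn.forward(self.proj.forward(x, train), train)
        else:
            sc = x
        return self.relu_out.forward(y + sc, train)

    def backward(self, dy):
        d = self.relu_out.backward(dy)
        if self.proj is not None:
            dx_sc = self.proj.backward(self.proj_bn.backward(d))
        else:
            dx_sc = d
        dm = self.bn2.backward(d)
        dm = self.conv2.backward(dm)
        dm = self.relu1.backward(dm)
        dm = self.bn1.backward(dm)
        dx = self.conv1.backward(dm)
        return dx + dx_sc


class FeatureExtractor:
    """dResNet backbone producing fixed-length deep feature vectors."""

    def __init__(self, config: BackboneConfig, class_names: list[str], seed: int = 0):
        if config.use_pretrained_stem:
            raise NotImplementedError(
                "no pretrained stem weights are bundled; train from scratch"
            )
        self.config = config
        self.class_names = list(class_names)
        self.seed = seed
        rng = np.random.default_rng(seed)
        channels, blocks = _PRESETS[config.depth_preset]
        if config.upsample_and_concat and len(channels) < 3:
            raise ValueError("upsample-and-concat fusion needs >= 3 stages")
        self.stem_conv = nn.Conv2d(3, channels[0], 3, stride=2, rng=rng)
        self.stem_bn = nn.BatchNorm2d(channels[0])
        self.stem_relu = nn.ReLU()
        self.stages: list[list[ResidualBlock]] = []
        c_prev = channels[0]
        for c_out, n_blocks in zip(channels, blocks):
            stage = [ResidualBlock(c_prev, c_out, stride=2, rng=rng)]
            stage += [ResidualBlock(c_out, c_out, rng=rng) for _ in range(n_blocks - 1)]
            self.stages.append(stage)
            c_prev = c_out
        tap_channels = channels[-3:] if config.upsample_and_concat else channels[-1:]
        self.diconv = [
            DiConvAttentionBlock(
                c, rates=config.dilation_rates,
                shared_dense=config.shared_attention_dense, rng=rng,
            )
            for c in tap_channels
        ]
        # common resolution = resolution of the earliest tapped stage
        h, w = config.input_size
        stage_hw = []
        sh, sw = (h + 1) // 2, (w + 1) // 2  # after stem stride 2
        for _ in channels:
            sh, sw = (sh + 1) // 2, (sw + 1) // 2
            stage_hw.append((sh, sw))
        tap_hw = stage_hw[-3:] if config.upsample_and_concat else stage_hw[-1:]
        self.upsample = [nn.BilinearUpsample(tap_hw[0]) for _ in tap_channels]
        self.proj = nn.Conv2d(sum(tap_channels), config.feature_dim, 1, rng=rng)
        self.proj_bn = nn.BatchNorm2d(config.feature_dim)
        self.proj_relu = nn.ReLU()
        self.gap = nn.GlobalAvgPool2d()
        self.head = nn.Linear(config.feature_dim, len(class_names), rng=rng)
        self._tap_channels = tap_channels

    # -- bookkeeping ---------------------------------------------------------

    def _named_layers(self):
        out = [("stem_conv", self.stem_conv), ("stem_bn", self.stem_bn)]
        for si, stage in enumerate(self.stages):
            for bi, blk in enumerate(stage):
                out.append((f"stage{si}.block{bi}", blk))
        for i, d in enumerate(self.diconv):
            out.append((f"diconv{i}", d))
        out += [("proj", self.proj), ("proj_bn", self.proj_bn), ("head", self.head)]
        return out

    def params(self) -> list[nn.Param]:
        return [p for _, layer in self._named_layers() for _, p in layer.params()]

    def _all_layers(self):
        cacheable = [self.stem_conv, self.stem_bn, self.stem_relu]
        for stage in self.stages:
            cacheable.extend(stage)
        cacheable.extend(self.diconv)
        cacheable.extend(self.upsample)
        cacheable.extend([self.proj, self.proj_bn, self.proj_relu, self.gap,
                          self.head])
        return cacheable

    def clear_caches(self) -> None:
        for layer in self._all_layers():
            layer.clear_caches()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for lname, layer in self._named_layers():
            for pname, p in layer.params():
                state[f"{lname}/{pname}"] = p.value.copy()
            for bname, b in layer.buffers():
                state[f"{lname}/buf:{bname}"] = b.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for lname, layer in self._named_layers():
            for pname, p in layer.params():
                p.value[...] = state[f"{lname}/{pname}"]
            for bname, b in layer.buffers():
                b[...] = state[f"{lname}/buf:{bname}"]

    # -- forward / backward --------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False
                ) -> tuple[np.ndarray, np.ndarray]:
        """Return (features [N x feature_dim], logits [N x K])."""
        x = np.asarray(x, dtype=np.float32)
        h = self.stem_relu.forward(
            self.stem_bn.forward(self.stem_conv.forward(x, train), train), train)
        stage_outs = []
        for stage in self.stages:
            for blk in stage:
                h = blk.forward(h, train)
            stage_outs.append(h)
        taps = stage_outs[-3:] if self.config.upsample_and_concat else stage_outs[-1:]
        fused = [self.diconv[i].forward(taps[i], train) for i in range(len(taps))]
        ups = [self.upsample[i].forward(fused[i], train) for i in range(len(taps))]
        cat = np.concatenate(ups, axis=1)
        z = self.proj_relu.forward(
            self.proj_bn.forward(self.proj.forward(cat, train), train), train)
        feat = self.gap.forward(z, train)
        logits = self.head.forward(feat, train)
        self._n_stage_outs = len(stage_outs)
        if not train:
            self.clear_caches()  # inference never runs backward
        return feat, logits

    def backward(self, dlogits: np.ndarray) -> None:
        dfeat = self.head.backward(dlogits)
        dz = self.gap.backward(dfeat)
        dcat = self.proj.backward(self.proj_bn.backward(self.proj_relu.backward(dz)))
        n_tap = len(self.diconv)
        dtaps = []
        start = 0
        for i, c in enumerate(self._tap_channels):
            dup = self.upsample[i].backward(dcat[:, start:start + c])
            start += c
            dtaps.append(None)  # filled just below
            dtaps[i] = dup
        # propagate through diconv blocks (reverse order for shared caches)
        dstage = [None] * self._n_stage_outs
        first_tap = self._n_stage_outs - n_tap
        for i in reversed(range(n_tap)):
            dstage[first_tap + i] = self.diconv[i].backward(dtaps[i])
        d = dstage[-1]
        for si in reversed(range(self._n_stage_outs)):
            if si != self._n_stage_outs - 1 and dstage[si] is not None:
                d = d + dstage[si]
            for blk in reversed(self.stages[si]):
                d = blk.backward(d)
        d = self.stem_conv.backward(self.stem_bn.backward(self.stem_relu.backward(d)))

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Weights as .npz plus a JSON sidecar with config, seed and classes."""
        path = Path(path)
        np.savez(path, **self.state_dict())
        sidecar = {
            "config": {**asdict(self.config)},
            "class_names": self.class_names,
            "seed": self.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "FeatureExtractor":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        cfg = sidecar["config"]
        for key in ("input_size", "dilation_rates"):
            cfg[key] = tuple(cfg[key])
        extractor = cls(BackboneConfig(**cfg), sidecar["class_names"],
                        seed=sidecar["seed"])
        npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
        with np.load(npz_path) as data:
            extractor.load_state_dict(dict(data))
        return extractor


def build_backbone(config: BackboneConfig, class_names: list[str],
                   seed: int = 0) -> FeatureExtractor:
    """Construct an untrained feature extractor for the given classes."""
    return FeatureExtractor(config, class_names, seed=seed)


# ---------------------------------------------------------------------------
# training and feature extraction
# ---------------------------------------------------------------------------

def _load_inputs(records: list[TileRecord], input_size: tuple[int, int],
                 class_names: list[str]) -> tuple[np.ndarray, np.ndarray]:
    label_of = {c: i for i, c in enumerate(class_names)}
    x = np.empty((len(records), 3, *input_size), dtype=np.float32)
    y = np.empty(len(records), dtype=np.int64)
    for i, rec in enumerate(records):
        x[i] = prepare_tile(load_tile(rec), input_size)
        y[i] = label_of[rec.class_label]
    return x, y


def _eval_batches(extractor: FeatureExtractor, x: np.ndarray, y: np.ndarray,
                  batch_size: int) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, len(x), batch_size):
        _, logits = extractor.forward(x[i:i + batch_size], train=False)
        loss, _ = nn.cross_entropy(logits, y[i:i + batch_size])
        losses.append(loss * len(logits))
        correct += int((logits.argmax(axis=1) == y[i:i + batch_size]).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def train_arrays(
    extractor: FeatureExtractor,
    x_train: np.ndarray, y_train: np.ndarray,
    x_val: np.ndarray, y_val: np.ndarray,
    config: BackboneTrainConfig = BackboneTrainConfig(),
) -> dict:
    """Train backbone + head on in-memory inputs; returns the history.

    Early stopping monitors validation loss with the configured patience;
    the best-validation weights are restored before returning.
    """
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("train and val sets must be nonempty")
    history = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": [],
        "metadata": {"lr": config.lr, "max_epochs": config.max_epochs,
                     "batch_size": config.batch_size, "patience": config.patience,
                     "seed": config.seed},
    }
    if config.max_epochs == 0:
        return history
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(extractor.params(), lr=config.lr)
    best_val = np.inf
    best_state = extractor.state_dict()
    bad_epochs = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(x_train))
        epoch_loss, correct = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            if len(idx) < 2:
                continue  # batch norm needs >= 2 rows
            opt.zero_grad()
            _, logits = extractor.forward(x_train[idx], train=True)
            loss, dlogits = nn.cross_entropy(logits, y_train[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at epoch {epoch}")
            extractor.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
            correct += int((logits.argmax(axis=1) == y_train[idx]).sum())
        val_loss, val_acc = _eval_batches(extractor, x_val, y_val, config.batch_size)
        history["train_loss"].append(epoch_loss / len(x_train))
        history["train_acc"].append(correct / len(x_train))
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        logger.info("epoch %d: train loss %.4f acc %.3f | val loss %.4f acc %.3f",
                    epoch, history["train_loss"][-1], history["train_acc"][-1],
                    val_loss, val_acc)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = extractor.state_dict()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > config.patience:
                logger.info("early stop at epoch %d", epoch)
                break
    extractor.load_state_dict(best_state)
    return history


def train_backbone(
    extractor: FeatureExtractor,
    manifest: DatasetManifest,
    config: BackboneTrainConfig = BackboneTrainConfig(),
) -> dict:
    """Train on the manifest's train split, early-stopping on the val split."""
    train_recs = manifest.subset("train")
    val_recs = manifest.subset("val")
    if not train_recs or not val_recs:
        raise ValueError("manifest must have nonempty train and val splits")
    x_tr, y_tr = _load_inputs(train_recs, extractor.config.input_size,
                              extractor.class_names)
    x_va, y_va = _load_inputs(val_recs, extractor.config.input_size,
                              extractor.class_names)
    return train_arrays(extractor, x_tr, y_tr, x_va, y_va, config)


def extract_features(
    extractor: FeatureExtractor,
    manifest: DatasetManifest,
    split: str,
    batch_size: int = 64,
) -> FeatureMatrix:
    """Deep features for every tile of one split, head detached."""
    records = manifest.subset(split)
    if not records:
        raise ValueError(f"split {split!r} has no records")
    x, _ = _load_inputs(records, extractor.config.input_size, extractor.class_names)
    return extract_features_from_arrays(
        extractor, x, np.array([r.class_label for r in records]), batch_size)


def extract_features_from_arrays(
    extractor: FeatureExtractor, x: np.ndarray, labels: np.ndarray,
    batch_size: int = 64,
) -> FeatureMatrix:
    feats = []
    for i in range(0, len(x), batch_size):
        feat, _ = extractor.forward(x[i:i + batch_size], train=False)
        feats.append(feat)
    values = np.concatenate(feats, axis=0)
    return FeatureMatrix(values=values, labels=np.asarray(labels))
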