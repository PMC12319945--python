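"""Dual-head segmentation model.

The model couples a 2D U-Net backbone (``FSeg``) that produces a two-class
per-pixel segmentation of fiber bundles with an auxiliary classification arm
(``FClass``) attached to the bottleneck of the shared encoder.  ``FClass``
passes the bottleneck feature maps through a downsampling module (two rounds
of max-pooling followed by two 3x3 convolutions each), global average
pooling, and fully connected layers fc(1024) -> fc(256) -> fc(2).  The
256-dimensional activations of the second fully connected layer double as the
embedding used by the contrastive loss; a config switch selects the 2-node
output instead.

Because the encoder weights are shared, gradients from both the segmentation
loss and the contrastive/classification loss shape the same features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn

__all__ = ["ModelConfig", "ForwardOutputs", "DualHeadUNet", "build_model", "forward"]

CHECKPOINT_VERSION = "bundleseg-ckpt-1"


@dataclass
class ModelConfig:
    in_channels: int = 3
    base_width: int = 64
    depth: int = 4
    fc_sizes: tuple[int, int] = (1024, 256)
    n_classes_seg: int = 2
    n_classes_cls: int = 2
    contrastive_features: str = "embedding"  # or "logits"

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if any(s <= 0 for s in self.fc_sizes):
            raise ValueError("fc_sizes must be positive")
        if self.contrastive_features not in ("embedding", "logits"):
            raise ValueError("contrastive_features must be 'embedding' or 'logits'")


@dataclass
class ForwardOutputs:
    seg_logits: np.ndarray  # N x 2 x H x W
    cls_logits: np.ndarray  # N x 2
    cls_embedding: np.ndarray  # N x fc_sizes[1]


def _conv_block(cin: int, cout: int, rng: np.random.Generator) -> nn.Sequential:
    return nn.Sequential(
        nn.Conv2d(cin, cout, 3, rng=rng),
        nn.BatchNorm2d(cout),
        nn.ReLU(),
        nn.Conv2d(cout, cout, 3, rng=rng),
        nn.BatchNorm2d(cout),
        nn.ReLU(),
    )


class DualHeadUNet:
    """U-Net backbone with a bottleneck-attached classification arm."""

    def __init__(self, cfg: ModelConfig, seed: int = 0) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        w, d = cfg.base_width, cfg.depth
        widths = [w * 2**i for i in range(d)]

        self.enc_blocks = [
            _conv_block(cfg.in_channels if i == 0 else widths[i - 1], widths[i], rng)
            for i in range(d)
        ]
        self.pools = [nn.MaxPool2d() for _ in range(d - 1)]
        # decoder runs from level d-2 down to 0
        self.ups = [nn.Upsample2x() for _ in range(d - 1)]
        self.dec_blocks = [
            _conv_block(widths[lvl + 1] + widths[lvl], widths[lvl], rng)
            for lvl in range(d - 2, -1, -1)
        ]
        self.out_conv = nn.Conv2d(widths[0], cfg.n_classes_seg, 1, rng=rng)
        if cfg.n_classes_seg == 2:
            # prior-probability init (standard with focal loss): start with
            # p(fiber) ~ 1% so the rare foreground dominates early gradients
            prior = 0.01
            b = 0.5 * np.log((1 - prior) / prior)
            self.out_conv.bias.value[:] = (b, -b)

        cb = widths[-1]
        self.cls_conv = nn.Sequential(
            nn.MaxPool2d(),
            nn.Conv2d(cb, cb, 3, rng=rng),
            nn.BatchNorm2d(cb),
            nn.ReLU(),
            nn.Conv2d(cb, cb, 3, rng=rng),
            nn.BatchNorm2d(cb),
            nn.ReLU(),
            nn.MaxPool2d(),
            nn.Conv2d(cb, cb, 3, rng=rng),
            nn.BatchNorm2d(cb),
            nn.ReLU(),
            nn.Conv2d(cb, cb, 3, rng=rng),
            nn.BatchNorm2d(cb),
            nn.ReLU(),
        )
        self.gap = nn.GlobalAvgPool()
        f1, f2 = cfg.fc_sizes
        self.fc1 = nn.Linear(cb, f1, rng=rng)
        self.relu1 = nn.ReLU()
        self.fc2 = nn.Linear(f1, f2, rng=rng)
        self.relu2 = nn.ReLU()
        self.fc3 = nn.Linear(f2, cfg.n_classes_cls, rng=rng)

    # ---- parameter plumbing -------------------------------------------------
    def _modules(self) -> list[nn.Layer]:
        return (
            self.enc_blocks
            + self.dec_blocks
            + [self.out_conv, self.cls_conv, self.fc1, self.fc2, self.fc3]
        )

    def parameters(self) -> list[nn.Parameter]:
        out: list[nn.Parameter] = []
        for m in self._modules():
            out.extend(m.parameters())
        return out

    def _bn_layers(self) -> list[nn.BatchNorm2d]:
        bns: list[nn.BatchNorm2d] = []
        for m in self._modules():
            if isinstance(m, nn.Sequential):
                bns.extend(l for l in m.layers if isinstance(l, nn.BatchNorm2d))
        return bns

    # ---- forward/backward ---------------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected N x {self.cfg.in_channels} x H x W input, got {x.shape}"
            )
        div = 2 ** (self.cfg.depth - 1)
        h, w = x.shape[2:]
        if h % div or w % div:
            raise ValueError(f"spatial size {(h, w)} not divisible by 2^(depth-1)={div}")
        if (h // div) % 4 or (w // div) % 4:
            raise ValueError(
                "bottleneck spatial size must be divisible by 4 for the "
                f"classification arm (input {(h, w)}, depth {self.cfg.depth})"
            )

    def forward(
        self, x: np.ndarray, train: bool = False, compute_seg: bool = True
    ) -> ForwardOutputs:
        x = np.ascontiguousarray(x, dtype=np.float32)
        self._check_input(x)
        d = self.cfg.depth
        skips: list[np.ndarray] = []
        h = x
        for i in range(d - 1):
            h = self.enc_blocks[i].forward(h, train)
            skips.append(h)
            h = self.pools[i].forward(h, train)
        bottleneck = self.enc_blocks[d - 1].forward(h, train)

        self._seg_computed = compute_seg
        self._skip_shapes = [s.shape for s in skips]
        self._bottleneck_shape = bottleneck.shape
        seg_logits = None
        if compute_seg:
            h = bottleneck
            self._skip_channels = []
            for j, lvl in enumerate(range(d - 2, -1, -1)):
                h = self.ups[j].forward(h, train)
                self._skip_channels.append(skips[lvl].shape[1])
                h = np.concatenate([skips[lvl], h], axis=1)
                h = self.dec_blocks[j].forward(h, train)
            seg_logits = self.out_conv.forward(h, train)

        c = self.cls_conv.forward(bottleneck, train)
        c = self.gap.forward(c, train)
        h1 = self.relu1.forward(self.fc1.forward(c, train), train)
        emb = self.fc2.forward(h1, train)
        cls_logits = self.fc3.forward(self.relu2.forward(emb, train), train)
        return ForwardOutputs(seg_logits=seg_logits, cls_logits=cls_logits, cls_embedding=emb)

    def backward(
        self,
        d_seg: np.ndarray | None = None,
        d_cls: np.ndarray | None = None,
        d_emb: np.ndarray | None = None,
    ) -> None:
        """Accumulate parameter gradients for the most recent training forward."""
        d = self.cfg.depth

        # segmentation path back to the bottleneck
        skip_grads: dict[int, np.ndarray] = {}
        if d_seg is not None:
            if not self._seg_computed:
                raise ValueError("d_seg given but the last forward skipped the decoder")
            g = self.out_conv.backward(np.asarray(d_seg, dtype=np.float32))
            for j in range(d - 2, -1, -1):
                lvl = d - 2 - j
                g = self.dec_blocks[j].backward(g)
                cskip = self._skip_channels[j]
                skip_grads[lvl] = g[:, :cskip]
                g = self.ups[j].backward(g[:, cskip:])
        else:
            if d_cls is None and d_emb is None:
                raise ValueError("at least one of d_seg, d_cls, d_emb is required")
            g = np.zeros(self._bottleneck_shape, dtype=np.float32)

        # classification path back to the bottleneck
        if d_cls is not None or d_emb is not None:
            n = self.fc3.weight.value.shape[1]
            if d_cls is None:
                d_cls = np.zeros((d_emb.shape[0], n), dtype=np.float32)
            ge = self.relu2.backward(self.fc3.backward(np.asarray(d_cls, dtype=np.float32)))
            if d_emb is not None:
                ge = ge + np.asarray(d_emb, dtype=np.float32)
            gc = self.fc1.backward(self.relu1.backward(self.fc2.backward(ge)))
            g = g + self.cls_conv.backward(self.gap.backward(gc))

        g = self.enc_blocks[d - 1].backward(g)
        for i in range(d - 2, -1, -1):
            g = self.pools[i].backward(g)
            if i in skip_grads:
                g = g + skip_grads[i]
            g = self.enc_blocks[i].backward(g)

    # ---- state --------------------------------------------------------------
    def get_state(self) -> list[np.ndarray]:
        arrays = [p.value.copy() for p in self.parameters()]
        for bn in self._bn_layers():
            arrays.append(bn.running_mean.copy())
            arrays.append(bn.running_var.copy())
        return arrays

    def set_state(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        bns = self._bn_layers()
        if len(arrays) != len(params) + 2 * len(bns):
            raise ValueError("state does not match model architecture")
        for p, a in zip(params, arrays[: len(params)]):
            p.value[...] = a
        rest = arrays[len(params):]
        for bn, mean, var in zip(bns, rest[0::2], rest[1::2]):
            bn.running_mean[...] = mean
            bn.running_var[...] = var

    def save(self, path) -> None:
        cfg = asdict(self.cfg)
        cfg["fc_sizes"] = list(cfg["fc_sizes"])
        meta = json.dumps({"version": CHECKPOINT_VERSION, "config": cfg})
        arrays = {f"arr_{i}": a for i, a in enumerate(self.get_state())}
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "DualHeadUNet":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("version") != CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version: {meta.get('version')}")
            cfg_d = meta["config"]
            cfg_d["fc_sizes"] = tuple(cfg_d["fc_sizes"])
            cfg = ModelConfig(**cfg_d)
            n = len([k for k in data.files if k.startswith("arr_")])
            arrays = [data[f"arr_{i}"] for i in range(n)]
        model = cls(cfg)
        model.set_state(arrays)
        return model


def build_model(cfg: ModelConfig, seed: int = 0) -> DualHeadUNet:
    """Construct the dual-head model with seeded He initialization."""
    return DualHeadUNet(cfg, seed=seed)


def forward(model: DualHeadUNet, batch: np.ndarray) -> ForwardOutputs:
    """Inference-mode forward pass on an N x H x W x 3 (or N x 3 x H x W) batch."""
    batch = np.asarray(batch, dtype=np.float32)
    if batch.ndim == 4 and batch.shape[-1] == model.cfg.in_channels:
        batch = batch.transpose(0, 3, 1, 2)
    return model.forward(batch, train=False)
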