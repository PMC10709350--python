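"""Network assembly: baseline CNN, D4h-equivariant G-CNN, and autoencoder
variants.

All models share one encoder recipe: a stack of stages, each a convolution
(lifting at stage 1 and group convolutions afterwards when ``equivariant``,
plain 3D convolutions otherwise), LeakyReLU, and 2x2x2 max pooling that
halves the spatial dimensions.  The classifier head pools orientations (max), applies
global average pooling, two fully connected ReLU layers, dropout, and a final
linear unit; the sigmoid that turns the logit into a probability lives in the
loss / ``predict_proba`` so that training and saliency can work on the logit.

The convolutional autoencoder (CAE) keeps the encoder, adds a 1x1x1
"bottleneck" convolution, and mirrors the stages with a decoder
(nearest-neighbour upsampling + convolution) ending in a crop/pad back to the
exact input shape.  The AE-regularized model shares the encoder between the
classifier head and the decoder and returns both outputs.

An optional ``input_pool`` block-averages the input before stage 1.  Block
averaging commutes with every D4h action (for divisible dims), so it keeps the
network exactly invariant while making CPU-scale training practical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .groups import ORDER, build_group
from .nn import (
    AvgPool3d,
    Conv3d,
    CropPad,
    Dense,
    Dropout,
    GlobalAvgPool,
    GroupConv3d,
    LeakyReLU,
    LiftingConv3d,
    MaxPool3d,
    OrientationPool,
    Parameter,
    ReLU,
    Sequential,
    Upsample3d,
)

#: the acquisition grid of the clinical cohorts the method targets
CLINICAL_GRID: tuple[int, int, int] = (192, 192, 50)


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture hyperparameters shared by all model variants.

    The baseline CNN and the G-CNN take identical configs; ``equivariant`` is
    the only switch between them.
    """

    stages: int = 5
    channels: tuple[int, ...] = (8, 16, 32, 64, 128)
    kernel_size: tuple[int, int, int] = (3, 3, 3)
    equivariant: bool = True
    dropout: float = 0.25
    fc: tuple[int, int] = (64, 16)
    bottleneck: int = 32
    input_pool: tuple[int, int, int] | None = None
    orientation_pool: str = "max"
    conv_bias_init: float = -0.5
    mismatch_init: bool = True

    def __post_init__(self) -> None:
        if self.stages < 1:
            raise ValueError("need at least one encoder stage")
        if len(self.channels) != self.stages:
            raise ValueError(
                f"channels {self.channels} must list one width per stage ({self.stages})")
        if any(c < 1 for c in self.channels):
            raise ValueError("channel widths must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


def _validate_grid(cfg: EncoderConfig, input_shape: tuple[int, int, int]) -> tuple[int, int, int]:
    shape = tuple(int(s) for s in input_shape)
    if cfg.input_pool is not None:
        for s, f in zip(shape, cfg.input_pool):
            if s % f:
                raise ValueError(f"grid {shape} not divisible by input_pool {cfg.input_pool}")
        shape = tuple(s // f for s, f in zip(shape, cfg.input_pool))
    if min(shape) < 2 ** cfg.stages:
        raise ValueError(
            f"grid {input_shape} too small to survive {cfg.stages} spatial halvings"
            + (f" after input pooling to {shape}" if cfg.input_pool else ""))
    if cfg.equivariant and shape[0] != shape[1]:
        raise ValueError("equivariant models need a square in-plane grid")
    return shape


def _encoder_shapes(cfg: EncoderConfig, shape: tuple[int, int, int]) -> list[tuple[int, int, int]]:
    shapes = [shape]
    for _ in range(cfg.stages):
        shape = tuple(s // 2 for s in shape)
        shapes.append(shape)
    return shapes


def build_encoder(cfg: EncoderConfig, rng: np.random.Generator,
                  in_channels: int = 2) -> Sequential:
    table = build_group() if cfg.equivariant else None
    steps: list[tuple[str, Sequential | AvgPool3d]] = []
    if cfg.input_pool is not None:
        steps.append(("input_pool", AvgPool3d(cfg.input_pool)))
    prev = in_channels
    for s, width in enumerate(cfg.channels):
        if cfg.equivariant:
            conv = (LiftingConv3d if s == 0 else GroupConv3d)(
                prev, width, cfg.kernel_size, table=table, rng=rng)
        else:
            conv = Conv3d(prev, width, cfg.kernel_size, rng=rng)
        if conv.b is not None:
            # start ReLU activations sparse: lesions are a tiny fraction of the
            # volume, and a sub-zero threshold at init lets global pooling see
            # focal detector responses instead of diluted background
            conv.b.value[...] = cfg.conv_bias_init
        steps.append((f"stage{s + 1}", Sequential(
            [("conv", conv), ("relu", LeakyReLU(0.1)), ("pool", MaxPool3d())])))
        prev = width
    if cfg.mismatch_init and in_channels == 2:
        _init_mismatch_detectors(steps[-cfg.stages][1]["conv"])
    return Sequential(steps)


def _init_mismatch_detectors(conv) -> None:
    """Seed the first stage with modality-contrast detectors.

    Filter 0 becomes a center-voxel DWI-minus-FLAIR difference (the
    DWI-FLAIR mismatch contrast itself) and filter 1 a DWI-only detector
    (lesion presence); the remaining filters keep their random init.  Starting
    from features the task is known to depend on removes the constant-
    prediction local minimum that plain SGD otherwise falls into on small
    cohorts — the same spirit as Gabor-initialized first layers in vision.
    """
    w = conv.w.value
    center = tuple(k // 2 for k in w.shape[-3:])
    w[0] = 0.0
    w[(0, 0) + center] = 0.7
    w[(0, 1) + center] = -0.7
    if w.shape[0] > 1:
        w[1] = 0.0
        w[(1, 0) + center] = 0.7


class _Net:
    """Common container: config, named parameters, checkpointing."""

    def __init__(self, cfg: EncoderConfig, input_shape: tuple[int, int, int]):
        self.cfg = cfg
        self.input_shape = tuple(int(s) for s in input_shape)

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> dict[str, Parameter]:
        raise NotImplementedError

    def modules(self):
        raise NotImplementedError

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.value.copy() for k, p in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        params = self.parameters()
        mismatches = []
        for k, p in params.items():
            sk = prefix + k
            if sk not in state:
                continue
            if state[sk].shape != p.value.shape:
                mismatches.append(f"{sk}: checkpoint {state[sk].shape} vs model {p.value.shape}")
        if mismatches:
            raise ValueError("incompatible checkpoint:\n  " + "\n  ".join(mismatches))
        for k, p in params.items():
            sk = prefix + k
            if sk in state:
                p.value[...] = state[sk].astype(np.float32)

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for m in self.modules():
            if isinstance(m, Dropout):
                m.rng = rng

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad[...] = 0.0

    def save(self, path) -> None:
        """Checkpoint: weights plus config and the group's Cayley table
        (embedded as JSON for integrity checking at load time)."""
        meta = {
            "config": asdict(self.cfg),
            "input_shape": list(self.input_shape),
            "kind": type(self).__name__,
            "cayley": json.loads(build_group().to_json()),
        }
        arrays = {k.replace(".", "__"): v for k, v in self.state_dict().items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)


def load_checkpoint(path) -> tuple[dict[str, np.ndarray], dict]:
    """Read a checkpoint into (state_dict, metadata); verifies the embedded
    Cayley table against the current group construction."""
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        state = {k.replace("__", "."): npz[k] for k in npz.files if k != "__meta__"}
    table = build_group()
    if meta.get("cayley", {}).get("compose") != table.compose.tolist():
        raise ValueError("checkpoint Cayley table does not match this build's group")
    return state, meta


class ClassifierNet(_Net):
    """Encoder + classification head; forward yields the pre-sigmoid logit."""

    def __init__(self, cfg: EncoderConfig, input_shape: tuple[int, int, int] = CLINICAL_GRID,
                 seed: int = 0):
        super().__init__(cfg, input_shape)
        shape0 = _validate_grid(cfg, input_shape)
        rng = np.random.default_rng(seed)
        self.encoder = build_encoder(cfg, rng)
        head: list[tuple[str, object]] = []
        if cfg.equivariant:
            head.append(("orient_pool", OrientationPool(cfg.orientation_pool)))
        feat = cfg.channels[-1]
        head += [
            ("gap", GlobalAvgPool()),
            ("fc1", Dense(feat, cfg.fc[0], rng=rng)),
            ("relu1", ReLU()),
            ("fc2", Dense(cfg.fc[0], cfg.fc[1], rng=rng)),
            ("relu2", ReLU()),
            ("dropout", Dropout(cfg.dropout)),
            ("out", Dense(cfg.fc[1], 1, rng=rng)),
        ]
        self.head = Sequential(head)
        self._shapes = _encoder_shapes(cfg, shape0)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Return logits of shape (N,)."""
        h = self.encoder.forward(np.asarray(x, dtype=np.float32), train=train)
        return self.head.forward(h, train=train)[:, 0]

    def backward(self, dlogit: np.ndarray) -> np.ndarray:
        g = self.head.backward(np.asarray(dlogit, dtype=np.float32)[:, None])
        return self.encoder.backward(g)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        from scipy.special import expit
        return expit(self.forward(x, train=False))

    def parameters(self):
        out = {f"encoder.{k}": p for k, p in self.encoder.parameters().items()}
        out.update({f"head.{k}": p for k, p in self.head.parameters().items()})
        return out

    def modules(self):
        yield from self.encoder.modules()
        yield from self.head.modules()

    def summary(self) -> str:
        lines = [f"input  {self.input_shape} x2"
                 + (f" (block-averaged by {self.cfg.input_pool})" if self.cfg.input_pool else "")]
        for s, shp in enumerate(self._shapes[1:], 1):
            c = self.cfg.channels[s - 1]
            orient = f" x{ORDER} orientations" if self.cfg.equivariant else ""
            lines.append(f"stage{s} {shp} x{c}{orient}")
        lines.append(f"head   GAP -> {self.cfg.fc[0]} -> {self.cfg.fc[1]} -> 1 (sigmoid)")
        return "\n".join(lines)


def _build_decoder(cfg: EncoderConfig, rng: np.random.Generator,
                   input_shape: tuple[int, int, int]) -> Sequential:
    steps: list[tuple[str, object]] = [
        ("neck_conv", Conv3d(
            cfg.channels[-1], cfg.bottleneck, (1, 1, 1), rng=rng)),
        ("neck_relu", ReLU()),
    ]
    widths = list(cfg.channels[::-1][1:]) + [max(4, cfg.channels[0] // 2)]
    prev = cfg.bottleneck
    for s, width in enumerate(widths):
        steps += [
            (f"up{s + 1}", Upsample3d()),
            (f"dec{s + 1}", Conv3d(prev, width, cfg.kernel_size, rng=rng)),
            (f"decrelu{s + 1}", ReLU()),
        ]
        prev = width
    recon_shape = input_shape
    if cfg.input_pool is not None:
        recon_shape = tuple(s // f for s, f in zip(input_shape, cfg.input_pool))
    steps += [("to_image", Conv3d(prev, 2, cfg.kernel_size, rng=rng)),
              ("fit", CropPad(recon_shape))]
    if cfg.input_pool is not None:
        # reconstruct at the pooled working resolution, then upsample back
        steps.append(("final_up", Upsample3d(cfg.input_pool)))
        steps.append(("final_fit", CropPad(input_shape)))
    return Sequential(steps)


class CAENet(_Net):
    """Convolutional autoencoder for unsupervised pre-training."""

    def __init__(self, cfg: EncoderConfig, input_shape: tuple[int, int, int] = CLINICAL_GRID,
                 seed: int = 0):
        super().__init__(cfg, input_shape)
        _validate_grid(cfg, input_shape)
        rng = np.random.default_rng(seed)
        self.encoder = build_encoder(cfg, rng)
        dec: list[tuple[str, object]] = []
        if cfg.equivariant:
            dec.append(("orient_pool", OrientationPool("max")))
        self.decoder = Sequential(dec + _build_decoder(cfg, rng, self.input_shape).steps)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.encoder.forward(np.asarray(x, dtype=np.float32), train=train)
        return self.decoder.forward(h, train=train)

    def backward(self, drecon: np.ndarray) -> np.ndarray:
        return self.encoder.backward(self.decoder.backward(drecon))

    def parameters(self):
        out = {f"encoder.{k}": p for k, p in self.encoder.parameters().items()}
        out.update({f"decoder.{k}": p for k, p in self.decoder.parameters().items()})
        return out

    def modules(self):
        yield from self.encoder.modules()
        yield from self.decoder.modules()


class AERegNet(_Net):
    """Classifier with a reconstruction head trained jointly
    (loss L = alpha * L_bc + (1 - alpha) * L_mse)."""

    def __init__(self, cfg: EncoderConfig, input_shape: tuple[int, int, int] = CLINICAL_GRID,
                 seed: int = 0):
        super().__init__(cfg, input_shape)
        cls = ClassifierNet(cfg, input_shape, seed=seed)
        self.encoder = cls.encoder
        self.cls_head = cls.head
        rng = np.random.default_rng(seed + 1)
        dec: list[tuple[str, object]] = []
        if cfg.equivariant:
            dec.append(("orient_pool", OrientationPool("max")))
        self.dec_head = Sequential(dec + _build_decoder(cfg, rng, self.input_shape).steps)

    def forward(self, x: np.ndarray, train: bool = False) -> tuple[np.ndarray, np.ndarray]:
        h = self.encoder.forward(np.asarray(x, dtype=np.float32), train=train)
        logit = self.cls_head.forward(h, train=train)[:, 0]
        recon = self.dec_head.forward(h, train=train)
        return logit, recon

    def backward(self, dlogit: np.ndarray, drecon: np.ndarray) -> np.ndarray:
        g1 = self.cls_head.backward(np.asarray(dlogit, dtype=np.float32)[:, None])
        g2 = self.dec_head.backward(np.asarray(drecon, dtype=np.float32))
        return self.encoder.backward(g1 + g2)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        from scipy.special import expit
        return expit(self.forward(x, train=False)[0])

    def parameters(self):
        out = {f"encoder.{k}": p for k, p in self.encoder.parameters().items()}
        out.update({f"head.{k}": p for k, p in self.cls_head.parameters().items()})
        out.update({f"decoder.{k}": p for k, p in self.dec_head.parameters().items()})
        return out

    def modules(self):
        yield from self.encoder.modules()
        yield from self.cls_head.modules()
        yield from self.dec_head.modules()


# -- public builders --------------------------------------------------------

def build_classifier(cfg: EncoderConfig, input_shape: tuple[int, int, int] = CLINICAL_GRID,
                     seed: int = 0) -> ClassifierNet:
    return ClassifierNet(cfg, input_shape, seed=seed)


def build_cae(cfg: EncoderConfig, input_shape: tuple[int, int, int] = CLINICAL_GRID,
              seed: int = 0) -> CAENet:
    return CAENet(cfg, input_shape, seed=seed)


def build_ae_regularized(cfg: EncoderConfig, input_shape: tuple[int, int, int] = CLINICAL_GRID,
                         seed: int = 0, init: str = "random",
                         checkpoint: dict[str, np.ndarray] | None = None) -> AERegNet:
    """``init='pretrained'`` copies encoder weights from a CAE state dict."""
    if init not in ("random", "pretrained"):
        raise ValueError(f"init must be 'random' or 'pretrained', got {init!r}")
    net = AERegNet(cfg, input_shape, seed=seed)
    if init == "pretrained":
        if checkpoint is None:
            raise ValueError("init='pretrained' requires a CAE checkpoint state dict")
        load_encoder(net, checkpoint)
    return net


def load_encoder(net: _Net, cae_state: dict[str, np.ndarray]) -> None:
    """Copy ``encoder.*`` weights from a CAE checkpoint into any model built
    from the same :class:`EncoderConfig`; raises with a layer-by-layer diff on
    incompatibility."""
    enc_state = {k: v for k, v in cae_state.items() if k.startswith("encoder.")}
    missing = [k for k in net.parameters() if k.startswith("encoder.") and k not in enc_state]
    if missing:
        raise ValueError("incompatible checkpoint, missing encoder keys:\n  "
                         + "\n  ".join(missing))
    net.load_state_dict(enc_state)
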