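"""Multi-task V-shaped network for joint optic disc/cup segmentation and
glaucoma classification.

One shared encoder (four stride-2 downsampling steps, channels doubling and
spatial sides halving at each stage) feeds two heads:

* a segmentation decoder that upsamples back to the input resolution,
  concatenating the same-resolution encoder feature at every step (skip
  connections), ending in a per-pixel 3-class softmax over
  {background, disc, cup};
* a classification head that global-average-pools the feature maps of the
  deepest encoder stages, concatenates the pooled vectors, and applies two
  fully connected layers (with dropout on the hidden units) and a 2-way
  softmax over {normal, glaucoma}.

Every convolution block is convolution -> batch normalization -> ReLU with
side-3 kernels; downsampling uses side-2 stride-2 convolutions. Blocks are
dimension-parameterized (2-D fundus crops by default; 3-D volumes are
supported through ``spatial_dims=3``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import NamedTuple, Sequence

import numpy as np

from ._nn import (
    F32,
    BatchNorm,
    Conv,
    Dense,
    Dropout,
    NearestUpsample,
    ReLU,
    global_average_pool,
    global_average_pool_backward,
    softmax,
)

N_DOWNSAMPLES = 4
N_STAGES = N_DOWNSAMPLES + 1
SEG_CLASSES = 3  # background, disc, cup


@dataclass
class NetworkSpec:
    """Architecture description.

    ``input_size`` must be divisible by 2**4 so that four exact halvings
    exist. Encoder stage ``s`` (1-based) has spatial side
    ``input_size / 2**(s-1)`` and ``base_channels * 2**(s-1)`` channels.
    ``fusion_stages`` selects which encoder stages feed the classifier
    (default: the three deepest). ``extra_features_dim`` reserves room for
    an optional pre-computed feature vector concatenated before the FC
    layers (off by default).
    """

    input_size: int = 224
    spatial_dims: int = 2
    in_channels: int = 3
    base_channels: int = 16
    fusion_stages: tuple = (3, 4, 5)
    fc_hidden: int = 256
    dropout_rate: float = 0.5
    n_classes: int = 2
    extra_features_dim: int = 0

    def __post_init__(self) -> None:
        if self.input_size <= 0 or self.input_size % 2**N_DOWNSAMPLES != 0:
            raise ValueError(
                f"input_size must be a positive multiple of {2**N_DOWNSAMPLES}, "
                f"got {self.input_size}"
            )
        if self.spatial_dims not in (2, 3):
            raise ValueError(f"spatial_dims must be 2 or 3, got {self.spatial_dims}")
        self.fusion_stages = tuple(int(s) for s in self.fusion_stages)
        if not self.fusion_stages:
            raise ValueError("fusion_stages must be non-empty")
        if not set(self.fusion_stages) <= set(range(1, N_STAGES + 1)):
            raise ValueError(f"fusion_stages must be within 1..{N_STAGES}")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.n_classes != 2:
            raise ValueError("only binary (normal/glaucoma) classification is supported")

    @property
    def stage_channels(self) -> list[int]:
        return [self.base_channels * 2**s for s in range(N_STAGES)]

    @property
    def stage_sides(self) -> list[int]:
        return [self.input_size // 2**s for s in range(N_STAGES)]

    @property
    def fused_length(self) -> int:
        ch = self.stage_channels
        return sum(ch[s - 1] for s in self.fusion_stages) + self.extra_features_dim

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fusion_stages"] = list(self.fusion_stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        d = dict(d)
        d["fusion_stages"] = tuple(d["fusion_stages"])
        return cls(**d)


class ModelOutput(NamedTuple):
    seg_map: np.ndarray  # (N, *spatial, 3) per-pixel class probabilities
    cls_probs: np.ndarray  # (N, 2) class probabilities (normal, glaucoma)


class _ConvBlock:
    """conv -> BN -> ReLU (the ReLU is fused into the BN layer)."""

    def __init__(self, cin, cout, ndim, rng, name, k=3, stride=1, pad=1):
        self.conv = Conv(cin, cout, k=k, ndim=ndim, stride=stride, pad=pad,
                         rng=rng, name=name)
        self.bn = BatchNorm(cout, relu=True, name=f"{name}.bn")

    def forward(self, x, training=False):
        return self.bn.forward(self.conv.forward(x, training), training)

    def backward(self, dy):
        return self.conv.backward(self.bn.backward(dy))

    def layers(self):
        return [self.conv, self.bn]


class MTLNet:
    """The trainable multi-task network.

    Weights use fixed-seed He initialization. All stochastic behaviour
    during training (dropout) draws from the generator passed to
    ``forward``; evaluation-mode forwards are deterministic.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)
        d = spec.spatial_dims
        ch = spec.stage_channels
        dw = spec.base_channels  # decoder width, fixed across levels

        self.stem = _ConvBlock(spec.in_channels, ch[0], d, rng, "enc1")
        self.downs, self.enc_blocks = [], []
        for s in range(1, N_STAGES):
            self.downs.append(
                _ConvBlock(ch[s - 1], ch[s], d, rng, f"down{s}", k=2, stride=2, pad=0)
            )
            self.enc_blocks.append(_ConvBlock(ch[s], ch[s], d, rng, f"enc{s + 1}"))

        self.up = NearestUpsample()
        self.dec_blocks = []
        prev = ch[-1]
        for s in range(N_DOWNSAMPLES, 0, -1):  # levels 4, 3, 2, 1
            self.dec_blocks.append(
                _ConvBlock(prev + ch[s - 1], dw, d, rng, f"dec{s}")
            )
            prev = dw
        self.seg_head = Conv(dw, SEG_CLASSES, k=1, ndim=d, bias=True,
                             rng=rng, name="seg_head")

        self.fc1 = Dense(spec.fused_length, spec.fc_hidden, rng=rng, name="fc1")
        self.fc_relu = ReLU()
        self.dropout = Dropout(spec.dropout_rate)
        self.fc2 = Dense(spec.fc_hidden, spec.n_classes, rng=rng, name="fc2")

        self._cache = None

    # ------------------------------------------------------------ plumbing

    def _blocks(self):
        blocks = [self.stem] + self.downs + self.enc_blocks + self.dec_blocks
        layers = [l for b in blocks for l in b.layers()]
        layers += [self.seg_head, self.fc1, self.fc2]
        return layers

    def params(self):
        return [p for l in self._blocks() for p in l.params()]

    def named_params(self):
        return {p.name: p for p in self.params()}

    # ------------------------------------------------------------- encoder

    def encode(self, x: np.ndarray, training: bool = False) -> list[np.ndarray]:
        """Run the shared encoder; returns stage features [f1..f5]."""
        x = np.ascontiguousarray(x, dtype=F32)
        expected = (self.spec.input_size,) * self.spec.spatial_dims + (self.spec.in_channels,)
        if x.shape[1:] != expected:
            raise ValueError(f"expected input shape (N,)+{expected}, got {x.shape}")
        feats = [self.stem.forward(x, training)]
        for down, block in zip(self.downs, self.enc_blocks):
            feats.append(block.forward(down.forward(feats[-1], training), training))
        return feats

    # ------------------------------------------------------------- decoder

    def decode(self, feats: Sequence[np.ndarray], training: bool = False,
               return_logits: bool = False) -> np.ndarray:
        """Segmentation head: four upsampling steps with skip concatenation,
        then a per-pixel 3-class softmax at the input resolution."""
        d = feats[-1]
        split_sizes = []
        for level, block in enumerate(self.dec_blocks):  # deepest first
            skip = feats[N_DOWNSAMPLES - 1 - level]
            up = self.up.forward(d)
            split_sizes.append(up.shape[-1])
            d = block.forward(np.concatenate([up, skip], axis=-1), training)
        logits = self.seg_head.forward(d, training)
        if training:
            self._seg_split_sizes = split_sizes
        return logits if return_logits else softmax(logits, axis=-1)

    # ---------------------------------------------------------- classifier

    def classify(self, feats: Sequence[np.ndarray], training: bool = False,
                 rng: np.random.Generator | None = None,
                 extra_features: np.ndarray | None = None,
                 return_logits: bool = False) -> np.ndarray:
        """Classification head: GAP over the fusion stages, concatenation,
        two FC layers with dropout, 2-way softmax."""
        pooled = [global_average_pool(feats[s - 1]) for s in self.spec.fusion_stages]
        if self.spec.extra_features_dim:
            if extra_features is None:
                raise ValueError(
                    f"spec reserves extra_features_dim={self.spec.extra_features_dim} "
                    "but no extra_features were given"
                )
            pooled.append(np.asarray(extra_features, dtype=F32))
        fused = np.concatenate(pooled, axis=1)
        h = self.fc_relu.forward(self.fc1.forward(fused, training), training)
        h = self.dropout.forward(h, training, rng=rng)
        logits = self.fc2.forward(h, training)
        if training:
            self._cls_pool_shapes = [feats[s - 1].shape for s in self.spec.fusion_stages]
        return logits if return_logits else softmax(logits, axis=1)

    # -------------------------------------------------------------- forward

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None,
                extra_features: np.ndarray | None = None) -> ModelOutput:
        """Single shared encoder pass feeding both heads."""
        feats = self.encode(x, training)
        seg = self.decode(feats, training)
        cls = self.classify(feats, training, rng=rng, extra_features=extra_features)
        if training:
            self._cache = feats
        return ModelOutput(seg, cls)

    def __call__(self, x, **kw):
        return self.forward(x, **kw)

    # ------------------------------------------------------------- backward

    def backward(self, d_seg_logits: np.ndarray, d_cls_logits: np.ndarray) -> None:
        """Accumulate parameter gradients given loss gradients at both
        heads' logits (pre-softmax). Must follow a training-mode forward."""
        feats = self._cache
        if feats is None:
            raise RuntimeError("backward called without a training-mode forward")
        stage_grads = [np.zeros_like(f) for f in feats]

        # classifier head
        dh = self.fc2.backward(d_cls_logits)
        dh = self.dropout.backward(dh)
        dfused = self.fc1.backward(self.fc_relu.backward(dh))
        offset = 0
        for s, shape in zip(self.spec.fusion_stages, self._cls_pool_shapes):
            c = shape[-1]
            stage_grads[s - 1] += global_average_pool_backward(
                dfused[:, offset:offset + c], shape[1:-1]
            )
            offset += c

        # segmentation head
        dd = self.seg_head.backward(d_seg_logits)
        for level in range(N_DOWNSAMPLES - 1, -1, -1):  # shallowest block first
            block = self.dec_blocks[level]
            dcat = block.backward(dd)
            c_up = self._seg_split_sizes[level]
            d_up, d_skip = dcat[..., :c_up], dcat[..., c_up:]
            stage_grads[N_DOWNSAMPLES - 1 - level] += d_skip
            dd = self.up.backward(d_up)
        stage_grads[-1] += dd

        # encoder, deepest stage first
        g = stage_grads[-1]
        for s in range(N_STAGES - 1, 0, -1):
            g = self.downs[s - 1].backward(self.enc_blocks[s - 1].backward(g))
            g += stage_grads[s - 1]
        self.stem.backward(g)
        self._cache = None

    # ----------------------------------------------------------- checkpoint

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {p.name: p.value for p in self.params()}
        for layer in self._blocks():
            if isinstance(layer, BatchNorm):
                prefix = layer.gamma.name.rsplit(".", 1)[0]
                arrays[f"{prefix}.running_mean"] = layer.running_mean
                arrays[f"{prefix}.running_var"] = layer.running_var
        return arrays

    def save(self, path) -> None:
        """Serialize weights + the full NetworkSpec into a single file."""
        np.savez(path, __spec__=np.frombuffer(
            json.dumps(self.spec.to_dict()).encode(), dtype=np.uint8),
            **self.state_arrays())

    @classmethod
    def load(cls, path) -> "MTLNet":
        with np.load(path) as data:
            spec = NetworkSpec.from_dict(
                json.loads(bytes(data["__spec__"].tobytes()).decode())
            )
            net = cls(spec)
            named = net.named_params()
            for key in data.files:
                if key == "__spec__":
                    continue
                if key.endswith(".running_mean") or key.endswith(".running_var"):
                    continue
                named[key].value[...] = data[key]
            for layer in net._blocks():
                if isinstance(layer, BatchNorm):
                    prefix = layer.gamma.name.rsplit(".", 1)[0]
                    layer.running_mean[...] = data[f"{prefix}.running_mean"]
                    layer.running_var[...] = data[f"{prefix}.running_var"]
        return net


def build_network(spec: NetworkSpec, seed: int = 0) -> MTLNet:
    """Construct a trainable multi-task network from an architecture spec."""
    return MTLNet(spec, seed=seed)
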