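"""The dense-block classifier.

Five identical dense blocks, each of three 3 x 3 convolutional layers
(batch-norm + ReLU + conv) with growth rate 32: every layer's 32 new
channels are concatenated onto everything before it, so a block turns C
input channels into C + 96.  Between blocks a transition (batch-norm +
1 x 1 conv + 2 x 2 average pooling) compresses channels and halves the
spatial side.  The head pools the final feature map with a spatial pyramid
(grids 1, 2 and 4 by default) and a fully connected layer emits the ten
class scores.

The stem in front of block 1 is a single 3 x 3 convolution to 32 channels
(the reference description leaves it open).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import SPP, AvgPool2, BatchNorm2d, Conv2d, Layer, Linear, Param, ReLU


@dataclass(frozen=True)
class ModelConfig:
    num_dense_blocks: int = 5
    layers_per_block: int = 3
    growth_rate: int = 32
    kernel: int = 3
    stem_channels: int = 32
    compression: float = 0.5
    spp_levels: tuple[int, ...] = (1, 2, 4)
    num_classes: int = 10
    input_side: int = 32  # desk scale; the full-scale protocol uses 255

    def __post_init__(self) -> None:
        if not self.spp_levels:
            raise ValueError("spp_levels must not be empty")
        if self.num_dense_blocks < 1 or self.layers_per_block < 1:
            raise ValueError("need at least one block and one layer per block")


class DenseLayer(Layer):
    """BN -> ReLU -> 3x3 conv producing ``growth_rate`` new channels."""

    def __init__(self, cin: int, growth: int, ksize: int, rng, name: str):
        self.bn = BatchNorm2d(cin, name=f"{name}.bn")
        self.relu = ReLU()
        self.conv = Conv2d(cin, growth, ksize, rng, name=f"{name}.conv")

    def forward(self, x, train=True):
        return self.conv.forward(self.relu.forward(self.bn.forward(x, train), train), train)

    def backward(self, dy):
        return self.bn.backward(self.relu.backward(self.conv.backward(dy)))

    def params(self):
        return self.bn.params() + self.conv.params()


class DenseBlock(Layer):
    """Dense concatenation of ``n_layers`` DenseLayers."""

    def __init__(self, cin: int, n_layers: int, growth: int, ksize: int, rng, name: str):
        self.cin, self.growth, self.n_layers = cin, growth, n_layers
        self.layers = [
            DenseLayer(cin + i * growth, growth, ksize, rng, name=f"{name}.l{i}")
            for i in range(n_layers)
        ]
        self.cout = cin + n_layers * growth

    def forward(self, x, train=True):
        cat = x
        for layer in self.layers:
            new = layer.forward(cat, train)
            cat = np.concatenate([cat, new], axis=1)
        return cat

    def backward(self, dy):
        # Split the incoming gradient along the final concatenation
        # [input, f1, ..., fL] and push each feature gradient back through
        # its layer, accumulating onto the earlier segments it consumed.
        bounds = [0, self.cin] + [self.cin + (i + 1) * self.growth for i in range(self.n_layers)]
        segs = [dy[:, bounds[i]:bounds[i + 1]].copy() for i in range(len(bounds) - 1)]
        for li in reversed(range(self.n_layers)):
            dcat = self.layers[li].backward(segs[li + 1])
            offset = 0
            for si in range(li + 1):
                width = segs[si].shape[1]
                segs[si] += dcat[:, offset:offset + width]
                offset += width
        return segs[0]

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class Transition(Layer):
    """BN -> ReLU -> 1x1 conv (channel compression) -> 2x2 average pool."""

    def __init__(self, cin: int, compression: float, rng, name: str):
        self.cout = max(1, int(np.floor(cin * compression)))
        self.bn = BatchNorm2d(cin, name=f"{name}.bn")
        self.relu = ReLU()
        self.conv = Conv2d(cin, self.cout, 1, rng, name=f"{name}.conv")
        self.pool = AvgPool2()

    def forward(self, x, train=True):
        y = self.bn.forward(x, train)
        y = self.relu.forward(y, train)
        y = self.conv.forward(y, train)
        return self.pool.forward(y, train)

    def backward(self, dy):
        return self.bn.backward(self.relu.backward(self.conv.backward(self.pool.backward(dy))))

    def params(self):
        return self.bn.params() + self.conv.params()


@dataclass
class DenseNetClassifier:
    """The assembled network; ``feature_index`` marks the output of the last
    dense block, which Grad-CAM reads."""

    config: ModelConfig
    body: list[Layer]
    head: list[Layer]
    feature_index: int
    feature_channels: int
    _acts: list = field(default_factory=list, repr=False)

    def forward(self, x: np.ndarray, train: bool = True,
                keep_features: bool = False) -> np.ndarray:
        self._features = None
        y = x.astype(np.float32)
        for i, layer in enumerate(self.body):
            y = layer.forward(y, train)
            if keep_features and i == self.feature_index:
                self._features = y
        for layer in self.head:
            y = layer.forward(y, train)
        return y

    def backward(self, dlogits: np.ndarray, stop_at_features: bool = False) -> np.ndarray | None:
        d = dlogits
        for layer in reversed(self.head):
            d = layer.backward(d)
        for i in reversed(range(len(self.body))):
            if stop_at_features and i == self.feature_index:
                return d
            d = self.body[i].backward(d)
        return None

    def params(self) -> list[Param]:
        return [p for layer in self.body + self.head for p in layer.params()]

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def channel_trace(self) -> list[int]:
        """Channel count after the stem and after each block/transition."""
        trace = [self.config.stem_channels]
        c = self.config.stem_channels
        for b in range(self.config.num_dense_blocks):
            c += self.config.layers_per_block * self.config.growth_rate
            trace.append(c)
            if b < self.config.num_dense_blocks - 1:
                c = max(1, int(np.floor(c * self.config.compression)))
                trace.append(c)
        return trace

    def get_state(self) -> dict:
        state = {p.name: p.value.copy() for p in self.params()}
        for i, layer in enumerate(self.body + self.head):
            if isinstance(layer, BatchNorm2d):
                state[f"running.{i}.mean"] = layer.running_mean.copy()
                state[f"running.{i}.var"] = layer.running_var.copy()
        return state

    def set_state(self, state: dict) -> None:
        for p in self.params():
            p.value[...] = state[p.name]
        for i, layer in enumerate(self.body + self.head):
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = state[f"running.{i}.mean"]
                layer.running_var[...] = state[f"running.{i}.var"]


def build_model(config: ModelConfig, seed: int = 0) -> DenseNetClassifier:
    """Construct the classifier with seeded He initialisation.

    The final linear layer starts near zero so that an untrained balanced
    10-class model scores all classes equally (initial cross-entropy
    ~ ln(num_classes)).
    """
    rng = np.random.default_rng(seed)
    body: list[Layer] = [
        Conv2d(3, config.stem_channels, config.kernel, rng, name="stem"),
        BatchNorm2d(config.stem_channels, name="stem.bn"),
        ReLU(),
    ]
    c = config.stem_channels
    feature_index = None
    for b in range(config.num_dense_blocks):
        block = DenseBlock(c, config.layers_per_block, config.growth_rate,
                           config.kernel, rng, name=f"block{b}")
        body.append(block)
        c = block.cout
        feature_index = len(body) - 1
        if b < config.num_dense_blocks - 1:
            trans = Transition(c, config.compression, rng, name=f"trans{b}")
            body.append(trans)
            c = trans.cout
    spp = SPP(config.spp_levels)
    head: list[Layer] = [
        BatchNorm2d(c, name="head.bn"),
        ReLU(),
        spp,
        Linear(spp.out_features(c), config.num_classes, rng, init_std=0.01, name="head.fc"),
    ]
    return DenseNetClassifier(config=config, body=body, head=head,
                              feature_index=feature_index, feature_channels=c)
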