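"""Dual heterogeneous volumetric encoder–decoder segmentation networks.

Two co-trained architectures share an identical decoder but differ in their
encoders: ``vnet`` uses plain convolution stacks per stage, while ``hvnet``
replaces each encoder stage with a pre-activation residual block (identity
skip around the convolution stack) plus a final post-norm, so the two
networks have the same output contract but different parameter structure and
count.  Downsampling is a stride-2 kernel-2 convolution; upsampling is a
channel-halving convolution followed by nearest-neighbour interpolation;
encoder features re-enter the decoder through additive skip connections.

Input volumes are ``(N, in_channels, H, W, D)`` with each spatial dimension
divisible by ``2**depth``; outputs are logits ``(N, C, H, W, D)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .entropy_masks import InvalidConfigError, InvalidInputError


@dataclass
class NetworkConfig:
    class_count: int = 2
    in_channels: int = 1
    base_channels: int = 16
    depth: int = 4
    variant: str = "vnet"
    bn_momentum: float = 0.1

    def __post_init__(self):
        if self.class_count < 2:
            raise InvalidConfigError("class_count must be >= 2")
        if self.variant not in ("vnet", "hvnet"):
            raise InvalidConfigError(f"unknown variant {self.variant!r}")
        if self.base_channels < 1 or self.depth < 1 or self.in_channels < 1:
            raise InvalidConfigError("channel/depth settings must be positive")


class Module:
    """Base class: tracks parameters, sub-modules and train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register(self, name: str, tensor: Tensor) -> Tensor:
        tensor.requires_grad = True
        self._params[name] = tensor
        return tensor

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + k, v) for k, v in self._params.items()]
        for name, m in self._modules.items():
            out.extend(m.named_parameters(prefix + name + "."))
        return out

    def buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = []
        for name, m in self._modules.items():
            out.extend(m.buffers(prefix + name + "."))
        return out

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- (de)serialisation -------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param:{k}": v.data for k, v in self.named_parameters()}
        state.update({f"buffer:{k}": v for k, v in self.buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for key, value in state.items():
            kind, _, name = key.partition(":")
            if kind == "param":
                params[name].data = np.asarray(value, dtype=np.float32).copy()
            else:
                self._set_buffer(name, np.asarray(value, dtype=np.float32).copy())

    def _set_buffer(self, dotted: str, value: np.ndarray) -> None:
        mod: Module = self
        *path, attr = dotted.split(".")
        for part in path:
            mod = mod._modules[part]
        object.__setattr__(mod, attr, value)


class Conv3d(Module):
    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        super().__init__()
        self.stride, self.padding = stride, padding
        fan_in = cin * kernel ** 3
        std = np.sqrt(2.0 / fan_in)  # He initialisation for ReLU nets
        self.weight = self.register(
            "weight", Tensor(rng.normal(0.0, std, size=(cout, cin, kernel, kernel, kernel)))
        )
        self.bias = self.register("bias", Tensor(np.zeros(cout))) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv3d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding)


class BatchNorm3d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = self.register("gamma", Tensor(np.ones(channels)))
        self.beta = self.register("beta", Tensor(np.zeros(channels)))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def buffers(self, prefix: str = ""):
        return [(prefix + "running_mean", self.running_mean),
                (prefix + "running_var", self.running_var)]

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            out, mean, var = ad.batchnorm_train(x, self.gamma, self.beta, eps=self.eps)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
            return out
        bshape = (1, x.shape[1], 1, 1, 1)
        xn = (x - Tensor(self.running_mean.reshape(bshape))) / Tensor(
            np.sqrt(self.running_var.reshape(bshape) + self.eps))
        return xn * self.gamma.reshape(bshape) + self.beta.reshape(bshape)


class ConvBNRelu(Module):
    def __init__(self, cin, cout, rng, kernel=3, stride=1, padding=1, momentum=0.1):
        super().__init__()
        self.conv = Conv3d(cin, cout, kernel, rng, stride=stride, padding=padding)
        self.bn = BatchNorm3d(cout, momentum=momentum)

    def __call__(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


class PlainStage(Module):
    """Convolution stack of a V-Net encoder stage."""

    def __init__(self, channels: int, n_convs: int, rng, momentum=0.1):
        super().__init__()
        self.blocks = [ConvBNRelu(channels, channels, rng, momentum=momentum)
                       for _ in range(n_convs)]
        for i, b in enumerate(self.blocks):
            setattr(self, f"block{i}", b)

    def __call__(self, x: Tensor) -> Tensor:
        for b in self.blocks:
            x = b(x)
        return x


class ResidualStage(Module):
    """Pre-activation residual block (BN→ReLU→conv, ×n) with identity skip."""

    def __init__(self, channels: int, n_convs: int, rng, momentum=0.1):
        super().__init__()
        self.convs = [Conv3d(channels, channels, 3, rng, padding=1)
                      for _ in range(n_convs)]
        self.norms = [BatchNorm3d(channels, momentum=momentum) for _ in range(n_convs)]
        self.post = BatchNorm3d(channels, momentum=momentum)
        for i, (c, n) in enumerate(zip(self.convs, self.norms)):
            setattr(self, f"conv{i}", c)
            setattr(self, f"norm{i}", n)

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for conv, norm in zip(self.convs, self.norms):
            h = conv(norm(h).relu())
        return self.post(x + h).relu()


class SegmentationNetwork(Module):
    """Encoder–decoder volumetric segmentation network (vnet / hvnet)."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        b, d, m = config.base_channels, config.depth, config.bn_momentum
        stage_cls = PlainStage if config.variant == "vnet" else ResidualStage
        n_convs = lambda level: min(level + 1, 2)  # V-Net-style: 1 conv at top stage

        self.stem = ConvBNRelu(config.in_channels, b, rng, momentum=m)
        self.enc_stages, self.downs = [], []
        ch = b
        for level in range(d):
            stage = stage_cls(ch, n_convs(level), rng, momentum=m)
            self.enc_stages.append(stage)
            setattr(self, f"enc{level}", stage)
            down = ConvBNRelu(ch, ch * 2, rng, kernel=2, stride=2, padding=0, momentum=m)
            self.downs.append(down)
            setattr(self, f"down{level}", down)
            ch *= 2
        self.bottleneck = PlainStage(ch, 2, rng, momentum=m)
        self.up_convs = []
        for level in reversed(range(d)):
            # halve channels before upsampling (cheap, low resolution), then
            # refine after the additive skip connection
            up = ConvBNRelu(ch, ch // 2, rng, momentum=m)
            merge = ConvBNRelu(ch // 2, ch // 2, rng, momentum=m)
            self.up_convs.append((up, merge))
            setattr(self, f"up{level}", up)
            setattr(self, f"merge{level}", merge)
            ch //= 2
        self.head = Conv3d(ch, config.class_count, 1, rng)

    def _check_divisible(self, x: Tensor) -> None:
        div = 2 ** self.config.depth
        if any(s % div for s in x.shape[2:]):
            raise InvalidInputError(
                f"spatial dims {x.shape[2:]} must be divisible by 2**depth = {div}"
            )

    def __call__(self, x: Tensor) -> Tensor:
        self._check_divisible(x)
        h = self.stem(x)
        skips = []
        for stage, down in zip(self.enc_stages, self.downs):
            h = stage(h)
            skips.append(h)
            h = down(h)
        h = self.bottleneck(h)
        for (up, merge), skip in zip(self.up_convs, reversed(skips)):
            h = ad.upsample_nearest3d(up(h))
            h = merge(h + skip)
        return self.head(h)

    def forward_logits(self, x: np.ndarray | Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        return self(x)

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def build_network(config: NetworkConfig, seed: int = 0) -> SegmentationNetwork:
    """Construct and initialise a segmentation network deterministically."""
    return SegmentationNetwork(config, seed=seed)


def predict_probabilities(net: SegmentationNetwork, x: np.ndarray) -> np.ndarray:
    """Softmax class probabilities for a volume or batch, without gradients.

    Accepts ``(H, W, D)``, ``(C_in, H, W, D)`` or ``(N, C_in, H, W, D)`` input
    and returns probabilities of matching arrangement, channel-first.
    """
    x = np.asarray(x, dtype=np.float32)
    squeeze = 0
    if x.ndim == 3:
        x, squeeze = x[None, None], 2
    elif x.ndim == 4:
        x, squeeze = x[None], 1
    with ad.no_grad():
        logits = net.forward_logits(x)
        probs = ad.softmax_channels(logits).data
    return probs[0] if squeeze else probs
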