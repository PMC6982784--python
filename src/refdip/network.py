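"""Untrained encoder-decoder ("hourglass") CNN with skip connections.

The network is the implicit image prior: it is never pre-trained. Its
architecture follows the classic deep-image-prior design — at each depth a
down block (strided conv → BN → leaky-ReLU → conv → BN → leaky-ReLU), a
skip block (1×1-ish conv → BN → leaky-ReLU) branching off before the
downsampling, and an up block (BN on the concatenated skip + upsampled
features → conv → BN → leaky-ReLU → 1×1 conv → BN → leaky-ReLU), with
bilinear ×2 upsampling between depths and a final 1×1 conv to the output
channels. Complex images travel through the real-valued network as two
channels (real, imaginary).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .fourier import ComplexImage
from .nn import Adam, BatchNorm2d, BilinearUp2, Conv2d, LeakyReLU, Sequential

__all__ = [
    "NetworkSpec",
    "HourglassNet",
    "build_network",
    "complex_to_channels",
    "channels_to_complex",
    "load_spec",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters: per-depth filter counts and kernel sizes.

    ``nd``, ``nu``, ``ns`` are the filter counts at each depth for the
    down path, up path, and skip connections; ``kd``, ``ku``, ``ks`` the
    corresponding (odd) kernel sizes. The input spatial size must be
    divisible by ``2**depth``.
    """

    depth: int
    nd: tuple[int, ...]
    nu: tuple[int, ...]
    ns: tuple[int, ...]
    kd: tuple[int, ...] = ()
    ku: tuple[int, ...] = ()
    ks: tuple[int, ...] = ()
    input_channels: int = 2
    output_channels: int = 2
    leaky_slope: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError(f"depth must be ≥ 1, got {self.depth}")
        tupled = {k: tuple(getattr(self, k)) for k in ("nd", "nu", "ns", "kd", "ku", "ks")}
        if not tupled["kd"]:
            tupled["kd"] = (3,) * self.depth
        if not tupled["ku"]:
            tupled["ku"] = (3,) * self.depth
        if not tupled["ks"]:
            tupled["ks"] = (1,) * self.depth
        for name, val in tupled.items():
            if len(val) != self.depth:
                raise ValueError(
                    f"{name} must have length depth={self.depth}, got {len(val)}"
                )
            object.__setattr__(self, name, val)
        for name in ("kd", "ku", "ks"):
            if any(k % 2 == 0 for k in getattr(self, name)):
                raise ValueError(f"kernel sizes in {name} must be odd")

    def validate_size(self, n: int) -> None:
        if n % (2**self.depth) != 0:
            raise ValueError(
                f"spatial size {n} not divisible by 2**depth = {2**self.depth}"
            )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NetworkSpec":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


def load_spec(name: str) -> NetworkSpec:
    """Load a packaged architecture config by name (e.g. ``brain_a``)."""
    from importlib.resources import files

    path = files("refdip") / "configs" / f"{name}.yaml"
    return NetworkSpec(**yaml.safe_load(path.read_text()))


class HourglassNet:
    """Differentiable map from (C_in, N, N) to (C_out, N, N) real tensors."""

    def __init__(self, spec: NetworkSpec) -> None:
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        slope = spec.leaky_slope
        L = spec.depth

        def conv(ci, co, k, s=1):
            return Conv2d(ci, co, k, stride=s, rng=rng, slope=slope)

        self.downs, self.skips, self.ups, self.upsamplers = [], [], [], []
        c_prev = spec.input_channels
        for i in range(L):
            nd, ns, kd, ks = spec.nd[i], spec.ns[i], spec.kd[i], spec.ks[i]
            self.downs.append(
                Sequential(
                    conv(c_prev, nd, kd, s=2),
                    BatchNorm2d(nd),
                    LeakyReLU(slope),
                    conv(nd, nd, kd),
                    BatchNorm2d(nd),
                    LeakyReLU(slope),
                )
            )
            self.skips.append(
                Sequential(conv(c_prev, ns, ks), BatchNorm2d(ns), LeakyReLU(slope))
            )
            c_prev = nd
        for i in range(L):
            nu, ns, ku = spec.nu[i], spec.ns[i], spec.ku[i]
            below = spec.nu[i + 1] if i < L - 1 else spec.nd[L - 1]
            self.ups.append(
                Sequential(
                    BatchNorm2d(ns + below),
                    conv(ns + below, nu, ku),
                    BatchNorm2d(nu),
                    LeakyReLU(slope),
                    conv(nu, nu, 1),
                    BatchNorm2d(nu),
                    LeakyReLU(slope),
                )
            )
            self.upsamplers.append(BilinearUp2())
        self.final = conv(spec.nu[0], spec.output_channels, 1)
        self._modules = self.downs + self.skips + self.ups + [self.final]

    @property
    def params(self) -> list[np.ndarray]:
        return [p for m in self._modules for p in m.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for m in self._modules for g in m.grads]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 3 or x.shape[0] != self.spec.input_channels:
            raise ValueError(
                f"expected ({self.spec.input_channels}, N, N) input, got {x.shape}"
            )
        if x.shape[1] != x.shape[2]:
            raise ValueError(f"expected square spatial dims, got {x.shape}")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite network input")
        self.spec.validate_size(x.shape[1])
        L = self.spec.depth
        skip_out = []
        cur = x
        for i in range(L):
            skip_out.append(self.skips[i].forward(cur))
            cur = self.downs[i].forward(cur)
        for i in reversed(range(L)):
            up = self.upsamplers[i].forward(cur)
            cat = np.concatenate([skip_out[i], up], axis=0)
            cur = self.ups[i].forward(cat)
        self._ns_split = [s.shape[0] for s in skip_out]
        return self.final.forward(cur)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        L = self.spec.depth
        dcur = self.final.backward(dout)
        dskip = [None] * L
        for i in range(L):
            dcat = self.ups[i].backward(dcur)
            ns = self._ns_split[i]
            dskip[i] = dcat[:ns]
            dcur = self.upsamplers[i].backward(dcat[ns:])
        for i in reversed(range(L)):
            dcur = self.downs[i].backward(dcur) + self.skips[i].backward(dskip[i])
        return dcur

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    def make_optimizer(self, lr: float) -> Adam:
        return Adam(self.params, self.grads, lr=lr)


def build_network(spec: NetworkSpec) -> HourglassNet:
    """Build an hourglass network with seeded parameter initialization."""
    return HourglassNet(spec)


def complex_to_channels(image: ComplexImage | np.ndarray) -> np.ndarray:
    """Complex N×N image → real (2, N, N) tensor (channel 0 real, 1 imaginary)."""
    data = image.data if isinstance(image, ComplexImage) else np.asarray(image)
    return np.stack([data.real, data.imag]).astype(np.float64)


def channels_to_complex(tensor: np.ndarray) -> ComplexImage:
    """Real (2, N, N) or (1, N, N) tensor → complex image (lossless)."""
    t = np.asarray(tensor)
    if t.ndim != 3 or t.shape[0] not in (1, 2):
        raise ValueError(f"expected (1|2, N, N) tensor, got shape {t.shape}")
    if t.shape[0] == 1:
        return ComplexImage(t[0].astype(np.complex128))
    return ComplexImage(t[0] + 1j * t[1])
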