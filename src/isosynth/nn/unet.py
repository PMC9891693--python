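"""3D U-net architecture contracts for the regression and segmentation nets.

Both networks share the same encoder/decoder: ``n_levels`` resolution levels
of two 3x3x3 convolutions with ELU activations; ``base_features`` features at
the first level, doubled after each 2x max pooling and halved after each
upsampling; skip connections by concatenation.  They differ only in the head:
the regression net ends in a linear 1x1x1 convolution with one feature, the
segmentation net in a K-feature convolution followed by a channel softmax.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from ..volumes import IntensityVolume
from .layers import ELU, Conv3d, MaxPool2, NearestUpsample2, softmax, softmax_backward

__all__ = [
    "NetworkSpec",
    "NetworkState",
    "build_regression_net",
    "build_segmentation_net",
    "forward",
    "param_count",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class NetworkSpec:
    n_levels: int = 5
    convs_per_level: int = 2
    kernel: tuple[int, int, int] = (3, 3, 3)
    base_features: int = 24
    activation: str = "elu"
    head: str = "linear-1"  # or "softmax-K" with K >= 2

    def __post_init__(self):
        if self.n_levels < 1 or self.convs_per_level < 1 or self.base_features < 1:
            raise ValueError("levels, convs per level and base features must be >= 1")
        if self.activation != "elu":
            raise ValueError("only ELU activation is supported")
        kind, _, _ = self.head.partition("-")
        if kind not in ("linear", "softmax"):
            raise ValueError(f"unknown head {self.head!r}")

    @property
    def head_kind(self) -> str:
        return self.head.partition("-")[0]

    @property
    def n_out(self) -> int:
        return int(self.head.partition("-")[2])

    @property
    def divisor(self) -> int:
        """Input spatial dims must be divisible by this (2^(levels-1))."""
        return 2 ** (self.n_levels - 1)

    def features_at(self, level: int) -> int:
        return self.base_features * 2 ** level

    def encoder_widths(self) -> tuple[int, ...]:
        return tuple(self.features_at(i) for i in range(self.n_levels))


def param_count(spec: NetworkSpec, n_in: int = 1) -> int:
    """Analytic trainable-parameter count; a pure function of the spec."""
    k = int(np.prod(spec.kernel))
    total = 0
    # encoder
    c_prev = n_in
    for lev in range(spec.n_levels):
        c = spec.features_at(lev)
        for j in range(spec.convs_per_level):
            total += (c_prev if j == 0 else c) * c * k + c
        c_prev = c
    # decoder
    for lev in range(spec.n_levels - 2, -1, -1):
        c = spec.features_at(lev)
        c_in = spec.features_at(lev + 1) + c  # upsampled + skip
        for j in range(spec.convs_per_level):
            total += (c_in if j == 0 else c) * c * k + c
    # head (1x1x1)
    total += spec.features_at(0) * spec.n_out + spec.n_out
    return total


class _UNet3D:
    """The wired network; owns the layers and implements forward/backward."""

    def __init__(self, spec: NetworkSpec, n_in: int, seed: int):
        self.spec = spec
        self.n_in = n_in
        rng = np.random.default_rng(seed)
        act = lambda: ELU()  # noqa: E731
        self.enc: list[list] = []
        c_prev = n_in
        for lev in range(spec.n_levels):
            c = spec.features_at(lev)
            convs = []
            for j in range(spec.convs_per_level):
                convs.append(Conv3d(c_prev if j == 0 else c, c, spec.kernel, rng))
                convs.append(act())
            self.enc.append(convs)
            c_prev = c
        self.pools = [MaxPool2() for _ in range(spec.n_levels - 1)]
        self.ups = [NearestUpsample2() for _ in range(spec.n_levels - 1)]
        self.dec: list[list] = []
        for lev in range(spec.n_levels - 2, -1, -1):
            c = spec.features_at(lev)
            c_in = spec.features_at(lev + 1) + c
            convs = []
            for j in range(spec.convs_per_level):
                convs.append(Conv3d(c_in if j == 0 else c, c, spec.kernel, rng))
                convs.append(act())
            self.dec.append(convs)
        self.head = Conv3d(spec.features_at(0), spec.n_out, (1, 1, 1), rng)
        # the head starts as a small linear readout, not a He-scaled layer
        self.head.w *= 0.1

    # -- parameter plumbing -------------------------------------------------
    def conv_layers(self) -> list[tuple[str, Conv3d]]:
        out = []
        for i, convs in enumerate(self.enc):
            for j, layer in enumerate(convs):
                if isinstance(layer, Conv3d):
                    out.append((f"enc{i}c{j // 2}", layer))
        for i, convs in enumerate(self.dec):
            for j, layer in enumerate(convs):
                if isinstance(layer, Conv3d):
                    out.append((f"dec{i}c{j // 2}", layer))
        out.append(("head", self.head))
        return out

    def parameters(self) -> list[np.ndarray]:
        params = []
        for _, c in self.conv_layers():
            params += [c.w, c.b]
        return params

    def gradients(self) -> list[np.ndarray]:
        grads = []
        for _, c in self.conv_layers():
            grads += [c.dw, c.db]
        return grads

    def zero_grad(self):
        for _, c in self.conv_layers():
            c.zero_grad()

    # -- passes -------------------------------------------------------------
    def _check_input(self, x: np.ndarray):
        if x.ndim != 4 or x.shape[0] != self.n_in:
            raise ValueError(f"expected ({self.n_in}, D, H, W) input, got {x.shape}")
        div = self.spec.divisor
        if any(s % div for s in x.shape[1:]):
            raise ValueError(
                f"spatial dims {x.shape[1:]} not divisible by {div} "
                f"(required by {self.spec.n_levels} resolution levels)"
            )

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        self._check_input(x)
        skips = []
        h = x
        for lev, convs in enumerate(self.enc):
            for layer in convs:
                h = layer.forward(h)
            if lev < self.spec.n_levels - 1:
                skips.append(h)
                h = self.pools[lev].forward(h)
        self._skip_channels = []
        for d, convs in enumerate(self.dec):
            lev = self.spec.n_levels - 2 - d
            h = self.ups[d].forward(h)
            skip = skips[lev]
            self._skip_channels.append(h.shape[0])
            h = np.concatenate([h, skip], axis=0)
            for layer in convs:
                h = layer.forward(h)
        logits = self.head.forward(h)
        if self.spec.head_kind == "softmax":
            self._probs = softmax(logits)
            return self._probs
        return logits

    def backward(self, dout: np.ndarray) -> np.ndarray:
        """Backpropagate; accumulates parameter grads, returns d(input)."""
        if self.spec.head_kind == "softmax":
            dout = softmax_backward(self._probs, dout)
        g = self.head.backward(np.ascontiguousarray(dout, dtype=np.float32))
        dskips: dict[int, np.ndarray] = {}
        for d in range(len(self.dec) - 1, -1, -1):
            lev = self.spec.n_levels - 2 - d
            for layer in reversed(self.dec[d]):
                g = layer.backward(g)
            cup = self._skip_channels[d]
            dskips[lev] = g[cup:]
            g = self.ups[d].backward(g[:cup])
        for lev in range(self.spec.n_levels - 1, -1, -1):
            if lev < self.spec.n_levels - 1:
                g = self.pools[lev].backward(g)
                g = g + dskips[lev]
            for layer in reversed(self.enc[lev]):
                g = layer.backward(g)
        return g


@dataclass
class NetworkState:
    """A built network: spec, parameters, and the frozen flag."""

    spec: NetworkSpec
    net: _UNet3D
    frozen: bool = False
    init_seed: int = 0
    meta: dict = field(default_factory=dict)

    def checksum(self) -> str:
        h = hashlib.sha256()
        for p in self.net.parameters():
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.net.parameters()))


def build_regression_net(spec: NetworkSpec | None = None, seed: int = 0) -> NetworkState:
    """1-channel volume in -> 1-channel volume out, linear head."""
    spec = spec or NetworkSpec()
    if spec.head_kind != "linear":
        raise ValueError("regression net requires a linear head")
    if spec.head != "linear-1":
        raise ValueError("regression head must have exactly one feature")
    return NetworkState(spec, _UNet3D(spec, n_in=1, seed=seed), init_seed=seed)


def build_segmentation_net(
    spec: NetworkSpec | None = None, n_labels: int = 2, seed: int = 0
) -> NetworkState:
    """1-channel volume in -> per-voxel label probabilities (softmax head)."""
    if n_labels < 2:
        raise ValueError("segmentation needs at least 2 labels")
    base = spec or NetworkSpec()
    spec = NetworkSpec(
        base.n_levels, base.convs_per_level, base.kernel, base.base_features,
        base.activation, head=f"softmax-{n_labels}",
    )
    return NetworkState(spec, _UNet3D(spec, n_in=1, seed=seed), init_seed=seed)


def forward(state: NetworkState, x: IntensityVolume | np.ndarray,
            check_range: bool = True) -> np.ndarray:
    """Deterministic forward pass on one volume.

    ``check_range`` enforces the inference contract that inputs are min-max
    normalized ([-0.01, 1.01] with slack); internal training calls bypass it.
    """
    data = x.data if isinstance(x, IntensityVolume) else np.asarray(x)
    if data.ndim == 3:
        data = data[None]
    if check_range and (data.min() < -0.01 or data.max() > 1.01):
        raise ValueError(
            f"input range [{data.min():.3f}, {data.max():.3f}] outside [-0.01, 1.01]; "
            "min-max normalize first"
        )
    out = state.net.forward(data)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite network output")
    return out


# ---------------------------------------------------------------------------
# Checkpoints: spec JSON + flat parameter blob + config hash in one archive
# ---------------------------------------------------------------------------

def save_checkpoint(state: NetworkState, path) -> None:
    spec_json = json.dumps({
        "n_levels": state.spec.n_levels,
        "convs_per_level": state.spec.convs_per_level,
        "kernel": list(state.spec.kernel),
        "base_features": state.spec.base_features,
        "activation": state.spec.activation,
        "head": state.spec.head,
        "n_in": state.net.n_in,
        "frozen": state.frozen,
        "init_seed": state.init_seed,
        "meta": state.meta,
    })
    flat = np.concatenate([p.ravel().astype(np.float32) for p in state.net.parameters()])
    np.savez_compressed(path, spec=np.frombuffer(spec_json.encode(), dtype=np.uint8),
                        params=flat)


def load_checkpoint(path) -> NetworkState:
    with np.load(path) as z:
        spec_d = json.loads(bytes(z["spec"]).decode())
        flat = z["params"]
    spec = NetworkSpec(
        spec_d["n_levels"], spec_d["convs_per_level"], tuple(spec_d["kernel"]),
        spec_d["base_features"], spec_d["activation"], spec_d["head"],
    )
    net = _UNet3D(spec, n_in=spec_d["n_in"], seed=spec_d.get("init_seed", 0))
    offset = 0
    for p in net.parameters():
        p[...] = flat[offset:offset + p.size].reshape(p.shape)
        offset += p.size
    if offset != flat.size:
        raise ValueError("checkpoint/spec mismatch: parameter blob size differs")
    return NetworkState(spec, net, frozen=spec_d.get("frozen", False),
                        init_seed=spec_d.get("init_seed", 0), meta=spec_d.get("meta", {}))
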