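"""Building blocks: FRN normalization, TLU activation, conv blocks and the
stage-residual encoder structure, parameterized by spatial rank (2 or 3).

Filter response normalization (FRN) divides each channel of each sample by
the root mean square of its activations over the spatial grid — no batch
statistics, so behaviour is independent of batch size.  Its companion
activation is the thresholded linear unit TLU, z = max(y, tau) with a
learnable per-channel threshold tau; equivalently z = relu(y - tau) + tau.

The stage-residual encoder groups residual blocks into stages (start block,
n_middle middle blocks, end block) so that the number of activations on the
main signal path is one per stage regardless of depth, and the summed
signal is fully normalized at stage end.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from . import autodiff as ad
from .autodiff import DimensionError, Tensor


# ---------------------------------------------------------------------------
# parameter / module machinery
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny module base: parameter discovery, state dicts, train/eval mode."""

    def __init__(self):
        self._training = True

    def modules(self):
        yield self
        for v in vars(self).values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield key, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{key}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        for m in self.modules():
            m._training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise DimensionError(f"parameter {k}: shape {arr.shape} != {p.data.shape}")
            p.data = arr.copy()

    def count_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


# ---------------------------------------------------------------------------
# FRN + TLU
# ---------------------------------------------------------------------------

@dataclass
class FRNState:
    """Learnable per-channel FRN parameters.

    gamma scales, beta shifts, tau is the TLU threshold; epsilon is a small
    fixed constant keeping the denominator away from zero.  Initial values
    gamma=1, beta=0, tau=0 make the layer start out identity-like.
    """

    gamma: np.ndarray
    beta: np.ndarray
    tau: np.ndarray
    epsilon: float = 1e-6

    @classmethod
    def init(cls, channels: int, epsilon: float = 1e-6) -> "FRNState":
        if epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        return cls(
            gamma=np.ones(channels, dtype=np.float32),
            beta=np.zeros(channels, dtype=np.float32),
            tau=np.zeros(channels, dtype=np.float32),
            epsilon=float(epsilon),
        )


def _channel_view(v, rank: int):
    """Reshape a per-channel vector to broadcast over (N, C, *spatial)."""
    if isinstance(v, Tensor):
        return ad.reshape(v, (1, -1) + (1,) * rank)
    return np.reshape(v, (1, -1) + (1,) * rank)


def frn_forward(x, state: FRNState, strict: bool = False):
    """Normalize a (N, C, *spatial) map by the per-sample, per-channel root
    mean square: y = gamma * x / sqrt(nu2 + eps) + beta, with nu2 the mean of
    x**2 over all spatial positions.  TLU is applied separately.

    Accepts a Tensor (differentiable) or a plain ndarray (returns ndarray).
    """
    was_array = not isinstance(x, Tensor)
    xt = ad.as_tensor(x)
    rank = xt.ndim - 2
    if rank < 1:
        raise DimensionError("expected layout (N, C, *spatial)")
    c = xt.shape[1]
    if len(np.atleast_1d(state.gamma)) != c:
        raise DimensionError(
            f"channel mismatch: input has {c} channels, FRN state has {len(np.atleast_1d(state.gamma))}"
        )
    if strict and not np.all(np.isfinite(xt.data)):
        raise ValueError("non-finite values in FRN input (strict mode)")
    spatial = tuple(range(2, 2 + rank))
    # mean of squares accumulated in float64 (inside tsum), per sample & channel
    nu2 = ad.tmean(ad.mul(xt, xt), axis=spatial, keepdims=True)
    y = ad.div(xt, ad.sqrt(ad.add(nu2, float(state.epsilon))))
    y = ad.add(ad.mul(y, _channel_view(ad.as_tensor(state.gamma), rank)),
               _channel_view(ad.as_tensor(state.beta), rank))
    return y.data if was_array else y


def tlu(y, tau):
    """Thresholded linear unit: z = max(y, tau) = relu(y - tau) + tau."""
    was_array = not isinstance(y, Tensor)
    yt = ad.as_tensor(y)
    rank = yt.ndim - 2
    tau_t = ad.as_tensor(tau)
    if tau_t.size != yt.shape[1]:
        raise DimensionError(
            f"channel mismatch: input has {yt.shape[1]} channels, tau has {tau_t.size}"
        )
    z = ad.maximum(yt, _channel_view(tau_t, rank))
    return z.data if was_array else z


class FRN(Module):
    """FRN + TLU as a layer (learnable gamma/beta/tau)."""

    def __init__(self, channels: int, rank: int, epsilon: float = 1e-6,
                 with_tlu: bool = True):
        super().__init__()
        self.rank = rank
        self.epsilon = float(epsilon)
        self.with_tlu = with_tlu
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        if with_tlu:
            self.tau = Parameter(np.zeros(channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        spatial = tuple(range(2, 2 + self.rank))
        nu2 = ad.tmean(ad.mul(x, x), axis=spatial, keepdims=True)
        y = ad.div(x, ad.sqrt(ad.add(nu2, self.epsilon)))
        y = ad.add(ad.mul(y, _channel_view(self.gamma, self.rank)),
                   _channel_view(self.beta, self.rank))
        if self.with_tlu:
            y = ad.maximum(y, _channel_view(self.tau, self.rank))
        return y


class BatchNorm(Module):
    """Batch normalization with learnable scale/shift (the baseline norm).

    Training mode uses batch statistics over (N, *spatial); eval mode the
    running averages.  Paired with a plain ReLU in the baseline variants.
    """

    def __init__(self, channels: int, rank: int, eps: float = 1e-5,
                 momentum: float = 0.1, with_relu: bool = True):
        super().__init__()
        self.rank = rank
        self.eps = eps
        self.momentum = momentum
        self.with_relu = with_relu
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        axes = (0,) + tuple(range(2, 2 + self.rank))
        if self._training:
            mean = x.data.mean(axis=axes, dtype=np.float64)
            var = x.data.var(axis=axes, dtype=np.float64)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        mview = _channel_view(mean.astype(np.float32), self.rank)
        sview = _channel_view(
            (1.0 / np.sqrt(var + self.eps)).astype(np.float32), self.rank)
        y = ad.mul(ad.add(x, Tensor(-mview)), Tensor(sview))
        y = ad.add(ad.mul(y, _channel_view(self.gamma, self.rank)),
                   _channel_view(self.beta, self.rank))
        if self.with_relu:
            y = ad.relu(y)
        return y


def make_norm_act(norm_kind: str, channels: int, rank: int) -> Module:
    if norm_kind == "frn":
        return FRN(channels, rank)
    if norm_kind == "batch":
        return BatchNorm(channels, rank)
    raise ValueError(f"unknown norm kind {norm_kind!r}")


# ---------------------------------------------------------------------------
# convolution layers
# ---------------------------------------------------------------------------

class Conv(Module):
    """Same-padding stride-1 convolution, He-initialized, optional bias."""

    def __init__(self, rank: int, in_channels: int, out_channels: int,
                 kernel: int = 3, bias: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if rank not in (2, 3):
            raise ValueError("rank must be 2 or 3")
        self.rank = rank
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel ** rank
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_channels, in_channels) + (kernel,) * rank)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = ad.conv_nd(x, self.weight)
        if self.bias is not None:
            out = ad.add(out, _channel_view(self.bias, self.rank))
        return out


class ConvNormAct(Module):
    """Conv -> norm -> activation, the workhorse of every decoder branch."""

    def __init__(self, rank, cin, cout, norm_kind="frn", kernel=3, rng=None):
        super().__init__()
        self.conv = Conv(rank, cin, cout, kernel=kernel, rng=rng)
        self.norm = make_norm_act(norm_kind, cout, rank)

    def forward(self, x):
        return self.norm(self.conv(x))


# ---------------------------------------------------------------------------
# stage residual
# ---------------------------------------------------------------------------

@dataclass
class StageLayout:
    """Internal wiring of a stage's start/end residual blocks.

    convs_per_block: 3x3(x3) convolutions on the residual branch of the
    start and end blocks (middle blocks always carry two).  shortcut_kernel:
    kernel size of the projection shortcut used when channels change (1 =
    pointwise, 3 = full-kernel).
    """

    convs_per_block: Literal[1, 2] = 1
    shortcut_kernel: Literal[1, 3] = 3


@dataclass
class StageResidualConfig:
    in_channels: int
    out_channels: int
    n_middle: int = 0
    rank: int = 2
    norm_kind: str = "frn"
    layout: StageLayout = field(default_factory=StageLayout)

    def __post_init__(self):
        if self.n_middle < 0:
            raise ValueError("n_middle must be >= 0")
        if self.rank not in (2, 3):
            raise ValueError("rank must be 2 or 3")


class _StartBlock(Module):
    """Conv branch plus (projection) shortcut; no activation on the sum."""

    def __init__(self, cfg: StageResidualConfig, rng):
        super().__init__()
        r, ci, co = cfg.rank, cfg.in_channels, cfg.out_channels
        if cfg.layout.convs_per_block == 1:
            self.branch = [Conv(r, ci, co, rng=rng)]
        else:
            self.branch = [
                Conv(r, ci, co, rng=rng),
                make_norm_act(cfg.norm_kind, co, r),
                Conv(r, co, co, rng=rng),
            ]
        if ci != co:
            self.shortcut = Conv(r, ci, co, kernel=cfg.layout.shortcut_kernel,
                                 rng=rng)
        else:
            self.shortcut = None

    def forward(self, x):
        y = x
        for m in self.branch:
            y = m(y)
        s = self.shortcut(x) if self.shortcut is not None else x
        return ad.add(y, s)


class _PreActBlock(Module):
    """Pre-activation residual block: x + convs(norm-act(x)), identity skip."""

    def __init__(self, cfg: StageResidualConfig, n_convs: int, rng):
        super().__init__()
        r, c = cfg.rank, cfg.out_channels
        mods = []
        for _ in range(n_convs):
            mods.append(make_norm_act(cfg.norm_kind, c, r))
            mods.append(Conv(r, c, c, rng=rng))
        self.branch = mods

    def forward(self, x):
        y = x
        for m in self.branch:
            y = m(y)
        return ad.add(x, y)


class StageResidual(Module):
    """One encoder stage: start block, n_middle middle blocks, end block,
    then normalization + activation of the whole summed signal.

    The main (skip) path carries exactly one activation — the final one —
    however many middle blocks are inserted.
    """

    def __init__(self, cfg: StageResidualConfig, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        self.start = _StartBlock(cfg, rng)
        self.middles = [_PreActBlock(cfg, 2, rng) for _ in range(cfg.n_middle)]
        self.end = _PreActBlock(cfg, cfg.layout.convs_per_block, rng)
        self.out_norm = make_norm_act(cfg.norm_kind, cfg.out_channels, cfg.rank)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.in_channels:
            raise DimensionError(
                f"stage expects {self.cfg.in_channels} channels, got {x.shape[1]}"
            )
        y = self.start(x)
        for m in self.middles:
            y = m(y)
        y = self.end(y)
        return self.out_norm(y)

    def count_convs(self, kernel: int = 3, main_path_only: bool = True) -> int:
        """Number of k x k (x k) convolutions in the stage (introspection).

        With main_path_only, projection shortcuts are excluded: they sit on
        the skip path, not the residual signal path.
        """
        blocks = [self.start] + list(self.middles) + [self.end]
        n = 0
        for b in blocks:
            n += sum(1 for m in b.branch
                     if isinstance(m, Conv) and m.kernel == kernel)
        if not main_path_only and self.start.shortcut is not None \
                and self.start.shortcut.kernel == kernel:
            n += 1
        return n


class PlainStage(Module):
    """Baseline double-conv encoder stage: (conv -> norm -> act) x 2."""

    def __init__(self, rank, cin, cout, norm_kind="batch", rng=None):
        super().__init__()
        self.block1 = ConvNormAct(rank, cin, cout, norm_kind, rng=rng)
        self.block2 = ConvNormAct(rank, cout, cout, norm_kind, rng=rng)

    def forward(self, x):
        return self.block2(self.block1(x))
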