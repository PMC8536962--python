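"""Declarative network specification and construction.

The network is a single-input multi-output encoder–decoder: a deep
U-Net backbone whose every contracting and expansive block is tapped as
a *side output*.  Each tap is reduced to a small number of channels,
brought back to input resolution by stacked stride-2 transposed
convolutions, and the taps are concatenated channel-wise into four
heads — down-path-only (d), up-path-only (u), all taps (d,u) and all
taps except the last (d,ux) — while a fifth head (f) reads the final
expansive feature map directly.  Every head emits a per-pixel
foreground probability map, so a single forward pass yields a
five-member within-network ensemble.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .nn import Tensor

__all__ = [
    "NetworkSpec",
    "PredictionSet",
    "HEAD_ORDER",
    "build_simou_spec",
    "build_simo_unet_spec",
    "instantiate",
    "init_weights",
    "predict",
    "save_model",
    "load_model",
    "ConfigurationError",
]

#: canonical head ordering used everywhere a PredictionSet is stacked
HEAD_ORDER = ("d_ux", "d_u", "u", "d", "f")

SIMOU_BASE_CHANNELS = (32, 32, 64, 64, 128, 128, 256, 512)
UNET_BASE_CHANNELS = (64, 128, 256, 512, 1024)


class ConfigurationError(ValueError):
    """Raised when a network specification is internally inconsistent."""


@dataclass
class NetworkSpec:
    """Declarative description of the network graph.

    ``side_taps`` lists, in side-output order s1..sT, the path ("down"
    or "up") and 1-based level each tap reads; ``head_definitions`` maps
    each concatenating head to the 1-based tap indices it merges (the
    final head "f" has no taps — it reads the last expansive feature
    map).
    """

    input_shape: tuple  # (H, W, 1)
    n_levels: int
    channels: tuple
    dropout_rate: float = 0.5
    dropout_down_levels: tuple = ()
    dropout_up_levels: tuple = ()
    activation: str = "elu"
    side_taps: tuple = ()
    head_definitions: dict = field(default_factory=dict)
    side_head_channels: int = 1
    post_concat_channels: int = 64

    # -- validation ------------------------------------------------------

    def validate(self):
        h, w = self.input_shape[0], self.input_shape[1]
        div = 2 ** (self.n_levels - 1)
        if h % div or w % div:
            raise ConfigurationError(
                f"input_shape {self.input_shape}: H and W must be divisible by "
                f"2^(n_levels-1) = {div} for {self.n_levels} levels"
            )
        if len(self.channels) != self.n_levels:
            raise ConfigurationError(
                f"channels has {len(self.channels)} entries for n_levels={self.n_levels}"
            )
        if len(self.side_taps) != 2 * self.n_levels - 1:
            raise ConfigurationError(
                f"expected {2 * self.n_levels - 1} side taps, got {len(self.side_taps)}"
            )
        n_taps = len(self.side_taps)
        for name, taps in self.head_definitions.items():
            for t in taps:
                if not 1 <= t <= n_taps:
                    raise ConfigurationError(
                        f"head {name!r} references tap {t}, outside 1..{n_taps}"
                    )
        if set(self.head_definitions) != set(HEAD_ORDER):
            raise ConfigurationError(
                f"heads must be exactly {HEAD_ORDER}, got {tuple(self.head_definitions)}"
            )
        return self

    @property
    def n_side_outputs(self) -> int:
        return len(self.side_taps)

    @property
    def n_heads(self) -> int:
        return len(self.head_definitions)

    # -- serialisation ---------------------------------------------------

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["input_shape"] = list(self.input_shape)
        d["channels"] = list(self.channels)
        d["side_taps"] = [list(t) for t in self.side_taps]
        d["head_definitions"] = {k: list(v) for k, v in self.head_definitions.items()}
        d["dropout_down_levels"] = list(self.dropout_down_levels)
        d["dropout_up_levels"] = list(self.dropout_up_levels)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "NetworkSpec":
        text = str(source)
        if "\n" not in text and Path(text).exists():
            text = Path(text).read_text()
        d = yaml.safe_load(text)
        d["input_shape"] = tuple(d["input_shape"])
        d["channels"] = tuple(d["channels"])
        d["side_taps"] = tuple((p, int(l)) for p, l in d["side_taps"])
        d["head_definitions"] = {k: tuple(v) for k, v in d["head_definitions"].items()}
        d["dropout_down_levels"] = tuple(d["dropout_down_levels"])
        d["dropout_up_levels"] = tuple(d["dropout_up_levels"])
        return cls(**d).validate()

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass
class PredictionSet:
    """The five per-slice probability maps of one forward pass.

    Each field is an (..., H, W) array in [0, 1]; ``stack()`` returns
    them as a single (5, ..., H, W) array in ``HEAD_ORDER``.
    """

    p_dux: np.ndarray
    p_du: np.ndarray
    p_u: np.ndarray
    p_d: np.ndarray
    p_f: np.ndarray

    _FIELD_BY_HEAD = {"d_ux": "p_dux", "d_u": "p_du", "u": "p_u", "d": "p_d", "f": "p_f"}

    def __getitem__(self, head: str) -> np.ndarray:
        return getattr(self, self._FIELD_BY_HEAD[head])

    def stack(self) -> np.ndarray:
        return np.stack([self[h] for h in HEAD_ORDER], axis=0)

    @classmethod
    def from_dict(cls, d) -> "PredictionSet":
        return cls(*(np.asarray(d[h]) for h in HEAD_ORDER))


# -- spec builders -------------------------------------------------------


def _scaled(base, width_multiplier):
    return tuple(max(1, round(width_multiplier * c)) for c in base)


def _head_pattern(n_down: int, n_taps: int) -> dict:
    all_taps = tuple(range(1, n_taps + 1))
    return {
        "d_u": all_taps,
        "d_ux": all_taps[:-1],
        "d": tuple(range(1, n_down + 1)),
        "u": tuple(range(n_down + 1, n_taps + 1)),
        "f": (),
    }


def _make_spec(input_shape, base_channels, n_levels, width_multiplier, dropout_rate):
    if width_multiplier <= 0:
        raise ConfigurationError("width_multiplier must be > 0")
    channels = _scaled(base_channels[:n_levels], width_multiplier)
    # taps: one per contracting block (s1..sn), one per expansive block,
    # deepest expansive block first (s_{n+1} .. s_{2n-1})
    taps = [("down", lvl) for lvl in range(1, n_levels + 1)]
    taps += [("up", lvl) for lvl in range(n_levels - 1, 0, -1)]
    n_drop = min(3, n_levels - 1)
    spec = NetworkSpec(
        input_shape=tuple(input_shape),
        n_levels=n_levels,
        channels=channels,
        dropout_rate=dropout_rate,
        dropout_down_levels=tuple(range(n_levels - n_drop + 1, n_levels + 1)),
        dropout_up_levels=tuple(range(1, n_drop + 1)),
        side_taps=tuple(taps),
        head_definitions=_head_pattern(n_levels, 2 * n_levels - 1),
        side_head_channels=1,
        post_concat_channels=max(1, round(64 * width_multiplier)),
    )
    return spec.validate()


def build_simou_spec(input_shape=(128, 128, 1), width_multiplier=1.0, n_levels=8,
                     dropout_rate=0.5) -> NetworkSpec:
    """Default deep spec: 8 levels, channels 32,32,64,64,128,128,256,512
    (scaled by ``width_multiplier``), 15 side taps, 5 heads, dropout on
    the last three contracting and first three expansive levels."""
    if not 2 <= n_levels <= len(SIMOU_BASE_CHANNELS):
        raise ConfigurationError(f"n_levels must be in 2..{len(SIMOU_BASE_CHANNELS)}")
    return _make_spec(input_shape, SIMOU_BASE_CHANNELS, n_levels, width_multiplier,
                      dropout_rate)


def build_simo_unet_spec(input_shape=(128, 128, 1), width_multiplier=1.0,
                         dropout_rate=0.5) -> NetworkSpec:
    """Plain 5-level U-Net wrapped with the same side-output/head
    pattern: 9 taps (5 down + 4 up) and the analogous 5 heads."""
    return _make_spec(input_shape, UNET_BASE_CHANNELS, 5, width_multiplier,
                      dropout_rate)


# -- model ---------------------------------------------------------------


class _ConvBlock(nn.Module):
    """Two size-preserving 3x3 convolutions with ELU, then batch norm,
    optionally followed by dropout."""

    def __init__(self, cin, cout, dropout_rate=0.0):
        self.conv1 = nn.Conv2d(cin, cout, 3)
        self.conv2 = nn.Conv2d(cout, cout, 3)
        self.bn = nn.BatchNorm2d(cout)
        self.drop = nn.Dropout(dropout_rate) if dropout_rate > 0 else None

    def __call__(self, x):
        h = nn.elu(self.conv1(x))
        h = nn.elu(self.conv2(h))
        h = self.bn(h)
        if self.drop is not None:
            h = self.drop(h)
        return h


class _SideBranch(nn.Module):
    """1x1 reduction (+ELU) of a tap, then stacked 2x transposed
    convolutions back to full resolution."""

    def __init__(self, cin, c_side, depth):
        self.reduce = nn.Conv2d(cin, c_side, 1)
        self.ups = [nn.ConvTranspose2x2(c_side, c_side) for _ in range(depth)]

    def __call__(self, x):
        h = nn.elu(self.reduce(x))
        for up in self.ups:
            h = up(h)
        return h


class _Head(nn.Module):
    """Two 3x3 convolutions with ELU on the concatenated side maps,
    then a 1x1 convolution to a sigmoid probability map."""

    def __init__(self, cin, c_post):
        self.conv1 = nn.Conv2d(cin, c_post, 3)
        self.conv2 = nn.Conv2d(c_post, c_post, 3)
        self.out = nn.Conv2d(c_post, 1, 1)

    def __call__(self, x):
        h = nn.elu(self.conv1(x))
        h = nn.elu(self.conv2(h))
        return nn.sigmoid(self.out(h))


class SimouNet(nn.Module):
    """Executable single-input multi-output segmentation network."""

    def __init__(self, spec: NetworkSpec):
        spec.validate()
        self.spec = spec
        n, ch = spec.n_levels, spec.channels
        dr = spec.dropout_rate
        self.enc = [
            _ConvBlock(1 if i == 0 else ch[i - 1], ch[i],
                       dr if (i + 1) in spec.dropout_down_levels else 0.0)
            for i in range(n)
        ]
        # decoder blocks ordered deepest-first: block j restores level n-1-j
        self.upconvs = []
        self.dec = []
        for j, lvl in enumerate(range(n - 2, -1, -1)):
            cin_up = ch[lvl + 1]
            self.upconvs.append(nn.ConvTranspose2x2(cin_up, ch[lvl]))
            self.dec.append(
                _ConvBlock(2 * ch[lvl], ch[lvl],
                           dr if (j + 1) in spec.dropout_up_levels else 0.0)
            )
        # side branches, one per tap, in s1..sT order
        self.side = []
        for path, lvl in spec.side_taps:
            self.side.append(
                _SideBranch(ch[lvl - 1], spec.side_head_channels, depth=lvl - 1)
            )
        self.heads = {
            name: _Head(len(taps) * spec.side_head_channels, spec.post_concat_channels)
            for name, taps in spec.head_definitions.items()
            if taps
        }
        self.final_out = nn.Conv2d(ch[0], 1, 1)

    # -- forward ---------------------------------------------------------

    def forward(self, x) -> dict:
        """x: (N, H, W, 1) tensor/array -> dict head name -> (N, H, W) tensor."""
        x = nn.as_tensor(x)
        spec = self.spec
        n = spec.n_levels
        enc_feats = []
        h = x
        for i in range(n):
            f = self.enc[i](h)
            enc_feats.append(f)
            if i < n - 1:
                h = nn.maxpool_2x2(f)
        features = list(enc_feats)  # taps s1..sn
        h = enc_feats[-1]
        for j, lvl in enumerate(range(n - 2, -1, -1)):
            h = self.upconvs[j](h)
            h = nn.concat([enc_feats[lvl], h], axis=-1)
            h = self.dec[j](h)
            features.append(h)  # taps s_{n+1}..s_{2n-1}
        side_maps = [branch(features[i]) for i, branch in enumerate(self.side)]
        out = {}
        for name in HEAD_ORDER:
            taps = spec.head_definitions[name]
            if taps:
                s = nn.concat([side_maps[t - 1] for t in taps], axis=-1)
                p = self.heads[name](s)
            else:
                p = nn.sigmoid(self.final_out(features[-1]))
            out[name] = p.reshape(p.shape[0], p.shape[1], p.shape[2])
        return out

    __call__ = forward

    def reseed_dropout(self, seed):
        for i, m in enumerate(self.modules()):
            if isinstance(m, nn.Dropout):
                m.reseed(np.random.SeedSequence([int(seed), i]).generate_state(1)[0])

    def zero_weights(self):
        """Zero every parameter (diagnostic: all sigmoids emit 0.5)."""
        for p in self.parameters():
            p.data = np.zeros_like(p.data)


def init_weights(model: SimouNet, seed: int) -> SimouNet:
    """(Re-)initialise every convolution kernel from a zero-mean
    Gaussian with sd = sqrt(2/eta), eta = kh*kw*cin; biases zero; batch
    norm gain 1, shift 0.  Deterministic in ``seed``."""
    rng = np.random.default_rng(int(seed))
    for m in model.modules():
        if isinstance(m, (nn.Conv2d, nn.ConvTranspose2x2, nn.BatchNorm2d)):
            m.reinit(rng)
    model.reseed_dropout(seed)
    return model


def instantiate(spec: NetworkSpec, seed: int = 0) -> SimouNet:
    """Build an executable model from a spec with seeded initialisation."""
    model = SimouNet(spec)
    return init_weights(model, seed)


def predict(model: SimouNet, images: np.ndarray, batch_size: int = 16) -> PredictionSet:
    """Run inference (eval mode) on an (S, H, W) stack of slices and
    return the five (S, H, W) probability maps."""
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 2:
        images = images[None]
    was_training = model.training
    model.eval()
    chunks = {h: [] for h in HEAD_ORDER}
    for lo in range(0, images.shape[0], batch_size):
        batch = images[lo:lo + batch_size][..., None]
        out = model.forward(batch)
        for h in HEAD_ORDER:
            chunks[h].append(out[h].data)
    if was_training:
        model.train()
    return PredictionSet.from_dict({h: np.concatenate(chunks[h]) for h in HEAD_ORDER})


# -- checkpointing -------------------------------------------------------


def save_model(model: SimouNet, path, seed=None):
    """Write weights (npz) plus a JSON sidecar with the spec and hash."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    sidecar = {
        "spec_yaml": model.spec.to_yaml(),
        "spec_hash": model.spec.content_hash(),
        "seed": seed,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path) -> SimouNet:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec = NetworkSpec.from_yaml(sidecar["spec_yaml"])
    model = SimouNet(spec)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as f:
        model.load_state_dict(dict(f))
    return model
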