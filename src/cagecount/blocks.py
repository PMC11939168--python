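"""Training-free reference blocks: coordinate attention and reversible units.

These are plain-array (C, H, W) forward passes with deterministic,
seed-generated parameters — no autodiff, no training.  Their purpose is
structural: coordinate attention factorizes global pooling by direction and
must preserve shape while strictly attenuating, and additive-coupling
reversible blocks must reconstruct their input from their output exactly
(up to float error), which is what lets a reversible-column backbone carry
feature information through depth without loss.

Coordinate attention forward pass
---------------------------------
Mean-pool over height -> a (C, W) descriptor, and over width -> (C, H);
concatenate along the spatial axis, apply a shared 1x1 channel-reducing
transform with a nonlinearity, split back, apply per-direction 1x1
transforms with a logistic squashing into attention factors a_h (C, H) and
a_w (C, W); the output is x[c, i, j] * a_h[c, i] * a_w[c, j].

Additive reversible coupling
----------------------------
Split channels in half: (x1, x2) -> (y1, y2) = (x2, x1 + F(x2)) where F is
a 1x1 linear channel map followed by tanh.  The inverse is
x2 = y1, x1 = y2 - F(y1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError


def _check_fmap(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ContractError(f"feature map must be (C, H, W); got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ContractError("feature map contains non-finite values")
    return x


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class CoordAttParams:
    """Weights of one coordinate-attention block (channels C, reduction r)."""

    w_shared: np.ndarray  # (C_mid, C)
    b_shared: np.ndarray  # (C_mid,)
    w_h: np.ndarray       # (C, C_mid)
    b_h: np.ndarray       # (C,)
    w_w: np.ndarray       # (C, C_mid)
    b_w: np.ndarray       # (C,)

    @property
    def channels(self) -> int:
        return self.w_shared.shape[1]


def make_coord_att_params(
    channels: int, reduction: int = 32, seed: int = 0
) -> CoordAttParams:
    """Deterministic parameters; C_mid = max(1, C // reduction)."""
    if channels < 1:
        raise ContractError("channels must be >= 1")
    c_mid = max(1, channels // reduction)
    rng = np.random.default_rng(seed)
    scale = 1.0 / np.sqrt(channels)
    return CoordAttParams(
        w_shared=rng.normal(0.0, scale, (c_mid, channels)),
        b_shared=rng.normal(0.0, 0.1, c_mid),
        w_h=rng.normal(0.0, 1.0 / np.sqrt(c_mid), (channels, c_mid)),
        b_h=rng.normal(0.0, 0.1, channels),
        w_w=rng.normal(0.0, 1.0 / np.sqrt(c_mid), (channels, c_mid)),
        b_w=rng.normal(0.0, 0.1, channels),
    )


def coord_att_forward(x: np.ndarray, p: CoordAttParams) -> np.ndarray:
    """Coordinate-attention forward pass; output shape equals input shape."""
    x = _check_fmap(x)
    C, H, W = x.shape
    if p.channels != C:
        raise ContractError(
            f"params expect {p.channels} channels, feature map has {C}"
        )
    pooled_h = x.mean(axis=2)  # (C, H): per-height descriptor
    pooled_w = x.mean(axis=1)  # (C, W): per-width descriptor
    cat = np.concatenate([pooled_h, pooled_w], axis=1)  # (C, H + W)
    mid = np.maximum(p.w_shared @ cat + p.b_shared[:, None], 0.0)  # relu
    mid_h, mid_w = mid[:, :H], mid[:, H:]
    a_h = _sigmoid(p.w_h @ mid_h + p.b_h[:, None])  # (C, H), in (0, 1)
    a_w = _sigmoid(p.w_w @ mid_w + p.b_w[:, None])  # (C, W), in (0, 1)
    return x * a_h[:, :, None] * a_w[:, None, :]


@dataclass
class CouplingParams:
    """Weights of the coupling function F of one reversible block.

    F maps the (C/2, H, W) half-feature through a 1x1 linear channel map
    followed by tanh.
    """

    weight: np.ndarray  # (C/2, C/2)
    bias: np.ndarray    # (C/2,)

    @property
    def half_channels(self) -> int:
        return self.weight.shape[0]


def make_coupling_params(channels: int, seed: int = 0) -> CouplingParams:
    if channels < 2 or channels % 2:
        raise ContractError("channels must be even and >= 2")
    half = channels // 2
    rng = np.random.default_rng(seed)
    return CouplingParams(
        weight=rng.normal(0.0, 1.0 / np.sqrt(half), (half, half)),
        bias=rng.normal(0.0, 0.1, half),
    )


def _coupling(x2: np.ndarray, p: CouplingParams) -> np.ndarray:
    return np.tanh(np.einsum("oc,chw->ohw", p.weight, x2) + p.bias[:, None, None])


def reversible_forward(x: np.ndarray, p: CouplingParams) -> np.ndarray:
    """(x1, x2) -> (x2, x1 + F(x2)); channels must be even."""
    x = _check_fmap(x)
    C = x.shape[0]
    if C % 2 or C // 2 != p.half_channels:
        raise ContractError(
            f"need even channel count matching params ({2 * p.half_channels}); got {C}"
        )
    x1, x2 = x[: C // 2], x[C // 2:]
    return np.concatenate([x2, x1 + _coupling(x2, p)], axis=0)


def reversible_inverse(y: np.ndarray, p: CouplingParams) -> np.ndarray:
    """Exact inverse of :func:`reversible_forward` up to float error."""
    y = _check_fmap(y)
    C = y.shape[0]
    if C % 2 or C // 2 != p.half_channels:
        raise ContractError(
            f"need even channel count matching params ({2 * p.half_channels}); got {C}"
        )
    y1, y2 = y[: C // 2], y[C // 2:]
    return np.concatenate([y2 - _coupling(y1, p), y1], axis=0)


@dataclass
class ColumnParams:
    """Parameters of one reversible column over a feature pyramid.

    ``couplings[l]`` is the reversible coupling at level l;
    ``lateral[l]`` (l >= 1) is the 1x1 channel map feeding level l from the
    current column's level l-1 state.
    """

    couplings: list[CouplingParams]
    lateral: list[np.ndarray]  # lateral[0] unused placeholder

    @property
    def n_levels(self) -> int:
        return len(self.couplings)


def make_column_params(
    level_channels: list[int], seed: int = 0
) -> ColumnParams:
    rng = np.random.default_rng(seed)
    couplings = [
        make_coupling_params(c, seed=int(rng.integers(2**31)))
        for c in level_channels
    ]
    lateral: list[np.ndarray] = [np.zeros((0, 0))]
    for prev, cur in zip(level_channels, level_channels[1:]):
        lateral.append(rng.normal(0.0, 1.0 / np.sqrt(prev), (cur, prev)))
    return ColumnParams(couplings=couplings, lateral=lateral)


def revcol_column_pass(
    levels: list[np.ndarray], p: ColumnParams
) -> list[np.ndarray]:
    """One column update of a reversible-column network.

    Level 0 is a plain reversible block of the previous column's state; each
    higher level adds a lateral 1x1 projection of the current column's
    lower-level output to the reversible transform of the previous column's
    same-level state.  The whole column is invertible given its outputs.
    """
    if len(levels) != p.n_levels:
        raise ContractError(
            f"params describe {p.n_levels} levels, got {len(levels)}"
        )
    shapes = [np.asarray(l).shape for l in levels]
    if any(len(s) != 3 for s in shapes):
        raise ContractError("each level must be a (C, H, W) array")
    if any(s[1:] != shapes[0][1:] for s in shapes):
        raise ContractError("levels must share spatial dimensions (H, W)")
    out: list[np.ndarray] = []
    for l, x in enumerate(levels):
        y = reversible_forward(_check_fmap(x), p.couplings[l])
        if l > 0:
            y = y + np.einsum("oc,chw->ohw", p.lateral[l], out[l - 1])
        out.append(y)
    return out


def revcol_column_inverse(
    out: list[np.ndarray], p: ColumnParams
) -> list[np.ndarray]:
    """Reconstruct the previous column's level states from a column output."""
    if len(out) != p.n_levels:
        raise ContractError(
            f"params describe {p.n_levels} levels, got {len(out)}"
        )
    levels: list[np.ndarray] = []
    for l, y in enumerate(out):
        y = _check_fmap(y)
        if l > 0:
            y = y - np.einsum("oc,chw->ohw", p.lateral[l], out[l - 1])
        levels.append(reversible_inverse(y, p.couplings[l]))
    return levels
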