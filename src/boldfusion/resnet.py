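"""A 50-layer bottleneck residual CNN used as a fixed scalogram encoder.

Forward-only numpy implementation of the standard 50-layer residual
topology (7x7/2 stem, max-pool, bottleneck stages of 3/4/6/3 blocks with
output widths 256/512/1024/2048, global average pooling), producing the
2048-dimensional pooled feature vector that feeds the fusion stage.

Weights are He-initialised from a seed and then frozen: the network is a
deterministic random-feature extractor (training it is out of scope; the
downstream classifier learns on top of the pooled features). Inputs are
224x224 RGB images; anything else is rejected.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ResNet50Features", "cnn_scalogram_features", "FEATURE_DIM"]

FEATURE_DIM = 2048
INPUT_SIZE = (224, 224, 3)
_STAGES = (  # (n_blocks, mid_channels, out_channels, first_stride)
    (3, 64, 256, 1),
    (4, 128, 512, 2),
    (6, 256, 1024, 2),
    (3, 512, 2048, 2),
)


def _he(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def _conv(x: np.ndarray, w: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """NHWC convolution via window extraction + matmul; ``w``: (k*k*C, F)."""
    if k == 1:
        y = x[:, ::stride, ::stride, :]
        return y @ w
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    win = win[:, ::stride, ::stride]  # (N, OH, OW, C, k, k)
    n, oh, ow = win.shape[:3]
    cols = win.reshape(n * oh * ow, -1)
    return (cols @ w).reshape(n, oh, ow, -1)


def _maxpool(x: np.ndarray, k: int = 3, stride: int = 2, pad: int = 1) -> np.ndarray:
    x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)), constant_values=-np.inf)
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    return win[:, ::stride, ::stride].max(axis=(-2, -1))


class ResNet50Features:
    """Seeded fixed-weight 50-layer residual encoder: image -> 2048-vector."""

    def __init__(self, seed: int = 0):
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.stem_ = _he(rng, 7 * 7 * 3, (7 * 7 * 3, 64))
        self.blocks_: list[dict[str, np.ndarray]] = []
        c_in = 64
        for n_blocks, mid, out, first_stride in _STAGES:
            for b in range(n_blocks):
                stride = first_stride if b == 0 else 1
                blk = {
                    "w1": _he(rng, c_in, (c_in, mid)),
                    "w2": _he(rng, 9 * mid, (9 * mid, mid)),
                    "w3": _he(rng, mid, (mid, out)),
                    "stride": stride,
                }
                if b == 0:
                    blk["proj"] = _he(rng, c_in, (c_in, out))
                self.blocks_.append(blk)
                c_in = out

    def _forward(self, x: np.ndarray) -> np.ndarray:
        x = np.maximum(_conv(x, self.stem_, 7, 2, 3), 0.0)
        x = _maxpool(x)
        for blk in self.blocks_:
            s = blk["stride"]
            shortcut = _conv(x, blk["proj"], 1, s, 0) if "proj" in blk else x
            y = np.maximum(_conv(x, blk["w1"], 1, s, 0), 0.0)
            y = np.maximum(_conv(y, blk["w2"], 3, 1, 1), 0.0)
            y = _conv(y, blk["w3"], 1, 1, 0)
            x = np.maximum(shortcut + y, 0.0)
        return x.mean(axis=(1, 2))  # global average pool -> (N, 2048)

    def transform(self, images: np.ndarray, chunk: int = 2) -> np.ndarray:
        """Encode images of shape (224, 224, 3) or (N, 224, 224, 3)."""
        imgs = np.asarray(images)
        single = imgs.ndim == 3
        if single:
            imgs = imgs[None]
        if imgs.ndim != 4 or imgs.shape[1:] != INPUT_SIZE:
            raise ValueError(
                f"expected images of shape {INPUT_SIZE}, got {imgs.shape[1:] if imgs.ndim == 4 else imgs.shape}"
            )
        x = imgs.astype(np.float32) / 255.0 - 0.5
        out = np.concatenate(
            [self._forward(x[i : i + chunk]) for i in range(0, len(x), chunk)]
        )
        return out[0] if single else out

    __call__ = transform


def cnn_scalogram_features(
    image: np.ndarray, weights_mode: str = "random-fixed", seed: int = 0
) -> np.ndarray:
    """Encode one 224x224x3 scalogram image into a 2048-vector.

    Only ``weights_mode='random-fixed'`` is available: the encoder uses
    frozen seeded random weights (see module docstring).
    """
    if weights_mode != "random-fixed":
        raise ValueError(
            f"unsupported weights_mode {weights_mode!r}; only 'random-fixed' is available"
        )
    return ResNet50Features(seed=seed).transform(image)
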