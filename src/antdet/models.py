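"""Dense-prediction detector models.

Two small, fully configurable architectures map a frame to per-pixel class
scores over {background, ant body, ant boundary}:

* ``unet`` — a skip-connected encoder–decoder. Each level doubles the
  channel count and halves the spatial resolution; decoder levels
  concatenate the matching encoder feature map.
* ``dcn`` — a plain encoder–decoder without skip connections whose middle
  convolutions are dilated (dilation 2), standing in for generic dilated
  fully-convolutional detectors.

Both end in one or more *heads* (a 3x3 conv + ReLU + 1x1 conv) over a
shared trunk feature map at full resolution. The two-headed variant used
for joint algorithm-annotation / human-annotation training shares the
entire trunk and splits only at the heads, so the parameter overhead of the
second head is exactly one head block.

All convolutions are location-shared (translation-equivariant up to padding
effects), which is the property that lets training average away
inconsistent (non-systematic) label noise.
"""

from __future__ import annotations

import json

import numpy as np

from ._nn import (Adam, BatchNorm2d, Conv2d, MaxPool2d, ReLU, Sequential,
                  Upsample2d, softmax)

__all__ = [
    "DetectorModel",
    "build_model",
    "predict_proba",
    "predict_labelmap",
    "fuse_heads",
    "n_parameters",
    "head_parameter_count",
    "save_model",
    "load_model",
]

ARCHITECTURES = ("unet", "dcn")


def _conv_block(cin, cout, rng, dtype, dilation=1):
    return Sequential([
        Conv2d(cin, cout, 3, dilation=dilation, rng=rng, dtype=dtype),
        BatchNorm2d(cout, dtype=dtype),
        ReLU(),
        Conv2d(cout, cout, 3, dilation=dilation, rng=rng, dtype=dtype),
        BatchNorm2d(cout, dtype=dtype),
        ReLU(),
    ])


def _head_block(channels, n_classes, rng, dtype):
    return Sequential([
        Conv2d(channels, channels, 3, rng=rng, dtype=dtype),
        ReLU(),
        Conv2d(channels, n_classes, 1, rng=rng, dtype=dtype),
    ])


class DetectorModel:
    """A trunk plus one or two prediction heads.

    Construct through :func:`build_model`; the constructor arguments are the
    model's self-describing config (kept for checkpointing).
    """

    def __init__(self, architecture="unet", depth=2, base_channels=8,
                 n_classes=3, n_heads=1, in_channels=1, seed=0,
                 dtype=np.float32):
        if architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {architecture!r}; "
                             f"expected one of {ARCHITECTURES}")
        if depth < 1 or base_channels < 1:
            raise ValueError("depth and base_channels must be >= 1")
        if n_heads not in (1, 2):
            raise ValueError("n_heads must be 1 or 2")
        self.config = dict(architecture=architecture, depth=depth,
                           base_channels=base_channels, n_classes=n_classes,
                           n_heads=n_heads, in_channels=in_channels, seed=seed)
        self.architecture = architecture
        self.depth = depth
        self.n_classes = n_classes
        self.n_heads = n_heads
        self.in_channels = in_channels
        self.dtype = dtype
        rng = np.random.default_rng(seed)

        ch = [base_channels * 2 ** i for i in range(depth + 1)]
        if architecture == "unet":
            self.enc = [_conv_block(in_channels if i == 0 else ch[i - 1], ch[i],
                                    rng, dtype) for i in range(depth)]
            self.pools = [MaxPool2d() for _ in range(depth)]
            self.bottleneck = _conv_block(ch[depth - 1], ch[depth], rng, dtype)
            # decoder from deepest level back to level 0; inputs concat [skip, up]
            self.ups = [Upsample2d() for _ in range(depth)]
            self.dec = [_conv_block(ch[i] + ch[i + 1], ch[i], rng, dtype)
                        for i in reversed(range(depth))]
            self._trunk = None
        else:  # dcn
            layers = []
            cin = in_channels
            for i in range(depth):
                layers.append(_conv_block(cin, ch[i], rng, dtype))
                layers.append(MaxPool2d())
                cin = ch[i]
            layers.append(_conv_block(cin, ch[depth], rng, dtype, dilation=2))
            cin = ch[depth]
            for i in reversed(range(depth)):
                layers.append(Upsample2d())
                layers.append(_conv_block(cin, ch[i], rng, dtype))
                cin = ch[i]
            self._trunk = Sequential(layers)
        self.heads = [_head_block(base_channels, n_classes, rng, dtype)
                      for _ in range(n_heads)]
        self._skip_channels = ch[:depth]

    # ------------------------------------------------------------------ core
    def parameters(self):
        params = []
        if self.architecture == "unet":
            for blk in self.enc:
                params.extend(blk.parameters())
            params.extend(self.bottleneck.parameters())
            for blk in self.dec:
                params.extend(blk.parameters())
        else:
            params.extend(self._trunk.parameters())
        for head in self.heads:
            params.extend(head.parameters())
        return params

    def forward(self, x, train=False):
        """Run the network; returns a list of per-head (B, C, H, W) scores."""
        x = np.ascontiguousarray(x, dtype=self.dtype)
        if self.architecture == "unet":
            skips = []
            h = x
            for blk, pool in zip(self.enc, self.pools):
                h = blk.forward(h, train)
                skips.append(h)
                h = pool.forward(h, train)
            h = self.bottleneck.forward(h, train)
            for blk, up, skip in zip(self.dec, self.ups, reversed(skips)):
                h = up.forward(h, train)
                h = np.concatenate([skip, h], axis=1)
                h = blk.forward(h, train)
        else:
            h = self._trunk.forward(x, train)
        return [head.forward(h, train) for head in self.heads]

    def backward(self, head_grads):
        """Backpropagate; ``head_grads[i]`` may be None to skip a head."""
        g = None
        for head, hg in zip(self.heads, head_grads):
            if hg is None:
                continue
            gh = head.backward(hg.astype(self.dtype))
            g = gh if g is None else g + gh
        if g is None:
            return None
        if self.architecture != "unet":
            return self._trunk.backward(g)
        skip_grads = []
        # decoder blocks were applied deepest-first; reverse for backward
        for blk, up, c_skip in zip(reversed(self.dec), reversed(self.ups),
                                   self._skip_channels):
            g = blk.backward(g)
            skip_grads.append(g[:, :c_skip])
            g = up.backward(g[:, c_skip:])
        g = self.bottleneck.backward(g)
        # skip_grads were collected shallow-first; encoder unwinds deep-first
        for blk, pool, gs in zip(reversed(self.enc), reversed(self.pools),
                                 reversed(skip_grads)):
            g = pool.backward(g) + gs
            g = blk.backward(g)
        return g

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()


def build_model(architecture="unet", depth=2, base_channels=8, n_heads=1,
                seed=0, n_classes=3, in_channels=1, dtype=np.float32):
    """Construct a :class:`DetectorModel` with deterministic initialization."""
    return DetectorModel(architecture=architecture, depth=depth,
                         base_channels=base_channels, n_classes=n_classes,
                         n_heads=n_heads, in_channels=in_channels, seed=seed,
                         dtype=dtype)


def n_parameters(model: DetectorModel) -> int:
    return sum(p.value.size for p in model.parameters())


def head_parameter_count(model: DetectorModel) -> int:
    """Parameter count of a single head block."""
    return sum(p.value.size for p in model.heads[0].parameters())


# --------------------------------------------------------------- inference
def _as_batched_input(frames, in_channels):
    frames = np.asarray(frames, dtype=np.float32)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim == 3:
        frames = frames[:, None, :, :]
    elif frames.ndim == 4 and frames.shape[-1] in (1, 3):
        frames = frames.transpose(0, 3, 1, 2)
    if frames.shape[1] != in_channels:
        raise ValueError(f"expected {in_channels} input channel(s), "
                         f"got {frames.shape[1]}")
    return frames


def predict_proba(model: DetectorModel, frames, batch_size=8):
    """Per-head class probability maps for one frame or a stack of frames.

    Frames whose spatial size is not divisible by ``2**depth`` are
    reflect-padded before the forward pass and the output is cropped back.
    Returns a list (one entry per head) of (N, H, W, C) arrays.
    """
    x = _as_batched_input(frames, model.in_channels)
    N, _, H, W = x.shape
    mult = 2 ** model.depth
    ph = (-H) % mult
    pw = (-W) % mult
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
    outs = [[] for _ in range(model.n_heads)]
    for start in range(0, N, batch_size):
        scores = model.forward(x[start:start + batch_size], train=False)
        for h, s in enumerate(scores):
            probs = softmax(s[:, :, :H, :W], axis=1)
            outs[h].append(probs.transpose(0, 2, 3, 1))
    return [np.concatenate(o, axis=0) for o in outs]


def fuse_heads(prob1, prob2):
    """Combine the two heads' probability maps: classwise sum, then argmax.

    Ties break toward the lower class index. Accepts (..., C) probability
    arrays of identical shape and returns an integer class map.
    """
    prob1 = np.asarray(prob1)
    prob2 = np.asarray(prob2)
    if prob1.shape != prob2.shape:
        raise ValueError("head outputs have mismatched shapes: "
                         f"{prob1.shape} vs {prob2.shape}")
    return np.argmax(prob1 + prob2, axis=-1).astype(np.uint8)


def predict_labelmap(model: DetectorModel, frames, fuse="sum", batch_size=8):
    """Dense class map prediction.

    ``fuse`` applies to two-headed models: ``"sum"`` adds the two heads'
    probability maps before the argmax (the recommended test-time option);
    ``"head1"``/``"head2"`` use a single head.
    """
    probs = predict_proba(model, frames, batch_size=batch_size)
    if model.n_heads == 1 or fuse == "head1":
        return np.argmax(probs[0], axis=-1).astype(np.uint8)
    if fuse == "head2":
        return np.argmax(probs[1], axis=-1).astype(np.uint8)
    if fuse != "sum":
        raise ValueError(f"unknown fuse mode {fuse!r}")
    return fuse_heads(probs[0], probs[1])


# ------------------------------------------------------------- checkpoints
def save_model(model: DetectorModel, path):
    """Save parameters plus a self-describing config manifest (.npz)."""
    manifest = dict(model.config)
    manifest["class_order"] = ["background", "ant_body", "ant_boundary"][
        :model.n_classes]
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.parameters())}
    bn_state = {}
    i = 0
    for layer in _iter_layers(model):
        if isinstance(layer, BatchNorm2d):
            bn_state[f"bn_mean_{i}"] = layer.running_mean
            bn_state[f"bn_var_{i}"] = layer.running_var
            i += 1
    np.savez(path, manifest=json.dumps(manifest), **arrays, **bn_state)


def load_model(path) -> DetectorModel:
    with np.load(path, allow_pickle=False) as data:
        manifest = json.loads(str(data["manifest"]))
        manifest.pop("class_order", None)
        model = DetectorModel(**manifest)
        for i, p in enumerate(model.parameters()):
            p.value[...] = data[f"param_{i}"]
        i = 0
        for layer in _iter_layers(model):
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = data[f"bn_mean_{i}"]
                layer.running_var[...] = data[f"bn_var_{i}"]
                i += 1
    return model


def _iter_layers(model: DetectorModel):
    blocks = []
    if model.architecture == "unet":
        blocks.extend(model.enc)
        blocks.append(model.bottleneck)
        blocks.extend(model.dec)
    else:
        blocks.append(model._trunk)
    blocks.extend(model.heads)
    for blk in blocks:
        for layer in blk.layers:
            yield layer
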