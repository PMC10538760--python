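"""Synthetic digit images and IDX readers.

The training pipelines consume bounded-pixel, multi-modal, low-dimensional
image data in [-1, 1]. ``generate_digits`` renders such data procedurally
from seven-segment-style stroke templates with seeded jitter, so the full
pipeline is testable without downloading anything; ``read_idx``/``rescale``
provide the optional path for real MNIST files in IDX format.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

__all__ = ["ImageBatch", "generate_digits", "read_idx", "rescale"]


@dataclass
class ImageBatch:
    """Square images with pixel values in [-1, 1] plus optional labels."""

    pixels: np.ndarray  # (batch, size, size)
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[1] != self.pixels.shape[2]:
            raise ValueError("pixels must be (batch, size, size) with height == width")

    @property
    def flat(self):
        """Row-major flattened (batch, size*size) view."""
        return self.pixels.reshape(self.pixels.shape[0], -1)


# Seven-segment stroke templates on a unit canvas: each digit is a list of
# line segments ((x0, y0), (x1, y1)) in [0, 1]^2, y downward.
_SEG = {
    "top": ((0.25, 0.15), (0.75, 0.15)),
    "mid": ((0.25, 0.5), (0.75, 0.5)),
    "bot": ((0.25, 0.85), (0.75, 0.85)),
    "tl": ((0.25, 0.15), (0.25, 0.5)),
    "tr": ((0.75, 0.15), (0.75, 0.5)),
    "bl": ((0.25, 0.5), (0.25, 0.85)),
    "br": ((0.75, 0.5), (0.75, 0.85)),
}
_DIGIT_SEGMENTS = {
    0: ["top", "tl", "tr", "bl", "br", "bot"],
    1: ["tr", "br"],
    2: ["top", "tr", "mid", "bl", "bot"],
    3: ["top", "tr", "mid", "br", "bot"],
    4: ["tl", "tr", "mid", "br"],
    5: ["top", "tl", "mid", "br", "bot"],
    6: ["top", "tl", "mid", "bl", "br", "bot"],
    7: ["top", "tr", "br"],
    8: ["top", "mid", "bot", "tl", "tr", "bl", "br"],
    9: ["top", "mid", "bot", "tl", "tr", "br"],
}


def _render(segments, size, shift=(0.0, 0.0), scale=1.0, width=0.06,
            amplitude=1.0):
    """Rasterize stroke segments with a Gaussian intensity profile."""
    coords = (np.arange(size) + 0.5) / size
    gx, gy = np.meshgrid(coords, coords, indexing="xy")
    img = np.zeros((size, size))
    cx, cy = 0.5 + shift[0], 0.5 + shift[1]
    for name in segments:
        (x0, y0), (x1, y1) = _SEG[name]
        # jittered placement around the canvas center
        x0, y0 = cx + scale * (x0 - 0.5), cy + scale * (y0 - 0.5)
        x1, y1 = cx + scale * (x1 - 0.5), cy + scale * (y1 - 0.5)
        dx, dy = x1 - x0, y1 - y0
        norm2 = dx * dx + dy * dy
        t = np.clip(((gx - x0) * dx + (gy - y0) * dy) / norm2, 0.0, 1.0)
        px, py = x0 + t * dx, y0 + t * dy
        dist2 = (gx - px) ** 2 + (gy - py) ** 2
        img = np.maximum(img, np.exp(-dist2 / (2 * width ** 2)))
    return np.clip(amplitude * img, 0.0, 1.0)


def generate_digits(n, size=16, n_classes=5, seed=0):
    """Procedurally rendered digit-like images in [-1, 1].

    Classes are the first ``n_classes`` seven-segment digit templates;
    each image gets seeded jitter in position, scale, stroke thickness and
    intensity. The batch is multi-modal (classes separable by a
    nearest-template match) and low-dimensional (stroke geometry spans few
    principal components).
    """
    if size < 8:
        raise ValueError("size must be >= 8")
    if not 2 <= n_classes <= 10:
        raise ValueError("n_classes must be in [2, 10]")
    rng = np.random.default_rng(seed)
    labels = rng.integers(n_classes, size=n)
    images = np.empty((n, size, size))
    for i, lab in enumerate(labels):
        images[i] = _render(
            _DIGIT_SEGMENTS[int(lab)], size,
            shift=tuple(rng.uniform(-0.06, 0.06, size=2)),
            scale=rng.uniform(0.85, 1.1),
            width=rng.uniform(0.045, 0.075),
            amplitude=rng.uniform(0.8, 1.0),
        )
    return ImageBatch(pixels=2.0 * images - 1.0, labels=labels)


def class_templates(size=16, n_classes=5):
    """Clean (jitter-free) class templates in [-1, 1], for
    nearest-template classification."""
    return np.stack([
        2.0 * _render(_DIGIT_SEGMENTS[k], size) - 1.0
        for k in range(n_classes)])


def nearest_template_accuracy(batch, n_classes=None):
    """Fraction of images whose nearest clean template (Euclidean)
    matches their label."""
    if batch.labels is None:
        raise ValueError("batch has no labels")
    n_classes = n_classes or int(batch.labels.max()) + 1
    templates = class_templates(batch.pixels.shape[1], n_classes)
    flat_t = templates.reshape(n_classes, -1)
    d = ((batch.flat[:, None, :] - flat_t[None, :, :]) ** 2).sum(axis=2)
    return float((d.argmin(axis=1) == batch.labels).mean())


# ---------------------------------------------------------------------
# IDX format (MNIST container): big-endian magic, dims, payload


class IDXFormatError(ValueError):
    pass


def read_idx(path):
    """Parse an IDX file into (array, magic).

    Magic 2051 marks image files (uint8, 3-D), 2049 label files (uint8,
    1-D). Malformed magic numbers or truncated payloads raise
    IDXFormatError naming the byte offset.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 4:
        raise IDXFormatError("truncated header at byte 0")
    magic = struct.unpack(">I", raw[:4])[0]
    if magic not in (2051, 2049):
        raise IDXFormatError(f"bad magic {magic} at byte 0")
    ndim = 3 if magic == 2051 else 1
    header_len = 4 + 4 * ndim
    if len(raw) < header_len:
        raise IDXFormatError(f"truncated dimension header at byte {len(raw)}")
    dims = struct.unpack(f">{ndim}I", raw[4:header_len])
    expected = int(np.prod(dims))
    if len(raw) - header_len != expected:
        raise IDXFormatError(
            f"payload length {len(raw) - header_len} != {expected} "
            f"declared at byte {header_len}")
    data = np.frombuffer(raw, dtype=np.uint8, offset=header_len)
    return data.reshape(dims), magic


def rescale(raw):
    """Affine map of integer pixels [0, 255] onto [-1, 1]: v/127.5 - 1."""
    raw = np.asarray(raw)
    if raw.min() < 0 or raw.max() > 255:
        raise ValueError("pixel values must lie in [0, 255]")
    return raw.astype(float) / 127.5 - 1.0
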