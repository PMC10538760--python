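"""Discriminator-cell ensembles, the Lipschitz gradient penalty, and the
hidden-feature reconstruction metric.

A discriminator "cell" is a 3-layer feedforward scorer (LeakyReLU 0.2
hidden units, linear scalar output) that observes a fixed random subset of
the network state. A *joint* ensemble draws subsets from the concatenated
(x, z) state; a *local* ensemble restricts every cell to a single layer,
which is the configuration the layerwise (oscillatory) algorithm uses. The
final discrimination decision is the average over cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad

__all__ = [
    "DiscriminatorCell", "DiscriminatorEnsemble", "GPConfig",
    "ensemble_score", "gradient_penalty", "feature_distance",
    "save_ensemble", "load_ensemble",
]


@dataclass
class GPConfig:
    """Gradient-penalty configuration: coefficient and interpolation seed."""

    lam: float = 1.0
    seed: int = 0
    one_sided: bool = False

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("gradient-penalty coefficient must be >= 0")


class DiscriminatorCell:
    """3-layer scorer over a fixed subselection of observed units."""

    def __init__(self, indices, hidden_dim=512, negative_slope=0.2, rng=None):
        rng = np.random.default_rng(rng)
        self.indices = np.asarray(indices, dtype=int)
        d = len(self.indices)
        self.negative_slope = float(negative_slope)
        self.W1 = ad.parameter(rng.standard_normal((d, hidden_dim)) / np.sqrt(d))
        self.b1 = ad.parameter(np.zeros(hidden_dim))
        self.W2 = ad.parameter(rng.standard_normal((hidden_dim, hidden_dim)) / np.sqrt(hidden_dim))
        self.b2 = ad.parameter(np.zeros(hidden_dim))
        self.W3 = ad.parameter(rng.standard_normal((hidden_dim, 1)) / np.sqrt(hidden_dim))
        self.b3 = ad.parameter(np.zeros(1))

    def parameters(self):
        return [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3]

    def _hidden(self, v):
        sub = ad.gather_cols(v, self.indices)
        h1 = ad.leaky_relu(ad.linear(sub, self.W1, self.b1), self.negative_slope)
        h2 = ad.leaky_relu(ad.linear(h1, self.W2, self.b2), self.negative_slope)
        return h1, h2

    def score(self, v):
        """Scalar score per batch element of the full state (batch, d)."""
        _, h2 = self._hidden(v)
        out = ad.linear(h2, self.W3, self.b3)
        return ad.reshape(out, (v.shape[0],))

    def hidden_features(self, v):
        h1, h2 = self._hidden(v)
        return h1, h2


class DiscriminatorEnsemble:
    """A set of discriminator cells with a joint or local scope.

    ``blocks`` gives the unit-index ranges of each layer in the observed
    state vector; for joint scope subsets are drawn across all blocks, for
    local scope each cell lives entirely inside one block (cells cycle
    through the blocks round-robin).
    """

    def __init__(self, dim, n_cells=4, subset_frac=0.5, hidden_dim=512,
                 scope="joint", blocks=None, rng=None):
        if scope not in ("joint", "local"):
            raise ValueError("scope must be 'joint' or 'local'")
        rng = np.random.default_rng(rng)
        self.dim = int(dim)
        self.scope = scope
        self.blocks = blocks if blocks is not None else [(0, dim)]
        if scope == "local" and blocks is None:
            raise ValueError("local scope requires explicit blocks")
        self.cells = []
        for i in range(n_cells):
            if scope == "joint":
                pool = np.arange(dim)
            else:
                lo, hi = self.blocks[i % len(self.blocks)]
                pool = np.arange(lo, hi)
            k = max(1, int(round(subset_frac * len(pool))))
            idx = rng.choice(pool, size=k, replace=False)
            if idx.max() >= dim:
                raise ValueError("cell subset index out of range")
            self.cells.append(DiscriminatorCell(np.sort(idx), hidden_dim, rng=rng))

    def parameters(self):
        return [p for c in self.cells for p in c.parameters()]

    def score(self, v):
        """Average cell score (Tensor) for a (batch, dim) state Tensor."""
        total = self.cells[0].score(v)
        for c in self.cells[1:]:
            total = ad.add(total, c.score(v))
        return ad.mul(total, ad.Tensor(1.0 / len(self.cells)))


def ensemble_score(ens, state):
    """Arithmetic-mean cell score per batch element (array in/out).

    ``state`` may be a NetworkState (joint (x, z) input) or a plain array.
    """
    v = state.joint if hasattr(state, "joint") else np.atleast_2d(state)
    if v.shape[1] != ens.dim:
        raise ValueError(f"state has {v.shape[1]} units, ensemble observes {ens.dim}")
    return ens.score(ad.tensor(v)).data


def gradient_penalty(ens, real_batch, fake_batch, cfg):
    """Two-sided Lipschitz gradient penalty (Tensor, differentiable).

    penalty = lam * mean_v (||grad_v D(v)||_2 - 1)^2 over interpolates
    v = u*real + (1-u)*fake with one u ~ U(0,1) per batch element.
    """
    real = np.atleast_2d(np.asarray(real_batch, dtype=float))
    fake = np.atleast_2d(np.asarray(fake_batch, dtype=float))
    if real.shape != fake.shape:
        raise ValueError("real and fake batches must have the same shape")
    u = np.random.default_rng(cfg.seed).uniform(size=(real.shape[0], 1))
    interp = ad.Tensor(u * real + (1 - u) * fake, requires_grad=True)
    s = ad.sum_(ens.score(interp))
    g = ad.grad(s, interp)
    # exact norm: a 1-Lipschitz linear scorer must give a penalty of 0
    norms = ad.row_norm(g, eps=0.0)
    excess = ad.sub(norms, ad.Tensor(1.0))
    if cfg.one_sided:
        mask = ad.Tensor((excess.data > 0).astype(float))
        excess = ad.mul(mask, excess)
    return ad.mul(ad.Tensor(cfg.lam), ad.mean_(ad.mul(excess, excess)))


def feature_distance(ens, x, x_prime):
    """Mean squared distance between hidden-layer activations on x vs x'.

    The discriminator's hidden layers act as a learned metric between
    inputs and reconstructions. Accepts arrays or Tensors; returns a
    Tensor so the distance can be trained through.
    """
    xt = x if isinstance(x, ad.Tensor) else ad.tensor(np.atleast_2d(x))
    xpt = x_prime if isinstance(x_prime, ad.Tensor) else ad.tensor(np.atleast_2d(x_prime))
    if xt.shape != xpt.shape:
        raise ValueError("x and x_prime must have the same shape")
    # only cells that observe the input block can compare x with x'
    width = xt.shape[1]
    cells = [c for c in ens.cells if c.indices.max() < width]
    if not cells:
        raise ValueError("no discriminator cell observes the input block")
    total = None
    for c in cells:
        for ha, hb in zip(c.hidden_features(xt), c.hidden_features(xpt)):
            d = ad.sub(ha, hb)
            msd = ad.mean_(ad.mul(d, d))
            total = msd if total is None else ad.add(total, msd)
    return ad.mul(total, ad.Tensor(1.0 / (2 * len(cells))))


# ---------------------------------------------------------------------
# serialization


def save_ensemble(ens, path):
    arrays = {}
    for i, c in enumerate(ens.cells):
        arrays[f"cell{i}_indices"] = c.indices
        for name in ("W1", "b1", "W2", "b2", "W3", "b3"):
            arrays[f"cell{i}_{name}"] = getattr(c, name).data
    np.savez(f"{path}.npz", **arrays)
    with open(f"{path}.json", "w") as fh:
        json.dump({
            "dim": ens.dim, "scope": ens.scope,
            "blocks": [list(b) for b in ens.blocks],
            "n_cells": len(ens.cells),
            "hidden_dim": ens.cells[0].W1.shape[1],
            "negative_slope": ens.cells[0].negative_slope,
        }, fh, indent=2)


def load_ensemble(path):
    with open(f"{path}.json") as fh:
        meta = json.load(fh)
    data = np.load(f"{path}.npz")
    ens = DiscriminatorEnsemble.__new__(DiscriminatorEnsemble)
    ens.dim = meta["dim"]
    ens.scope = meta["scope"]
    ens.blocks = [tuple(b) for b in meta["blocks"]]
    ens.cells = []
    for i in range(meta["n_cells"]):
        cell = DiscriminatorCell(
            data[f"cell{i}_indices"], meta["hidden_dim"],
            meta["negative_slope"])
        for name in ("W1", "b1", "W2", "b2", "W3", "b3"):
            getattr(cell, name).data = data[f"cell{i}_{name}"]
        ens.cells.append(cell)
    return ens
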