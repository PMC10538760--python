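"""Distribution-alignment diagnostics over quantized activity patterns.

To compare stimulus-evoked (wake) and self-generated (sleep) joint
activity in a high-dimensional network, activity vectors are quantized by
rounding each unit to the nearest integer, a fixed random subset of units
is selected (by default 32 units: 16 inputs and 16 latents), and the
frequency of each unique pattern is counted in each phase. Matched
distributions put every pattern on the y = x diagonal of the paired
frequency plot; the scalar summary is the Jensen-Shannon divergence over
the union of observed patterns (symmetric, bounded by log 2, finite even
for disjoint supports).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PatternHistogram", "quantize_subsample", "pattern_frequencies",
    "pattern_divergence", "round_half_away",
]


def round_half_away(values):
    """Round to nearest integer with halves away from zero
    (0.5 -> 1, -0.5 -> -1)."""
    v = np.asarray(values, dtype=float)
    return np.copysign(np.floor(np.abs(v) + 0.5), v)


@dataclass
class PatternHistogram:
    """Counts of quantized patterns over a fixed unit subset."""

    counts: dict
    phase: str = "wake"
    subset: tuple = ()

    def __post_init__(self):
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("stored patterns must have counts >= 1")

    @property
    def total(self):
        return sum(self.counts.values())


def quantize_subsample(x, z, n_x, n_z, seed):
    """Quantized patterns over a seeded random unit subset.

    Selects ``n_x`` input units and ``n_z`` latent units uniformly without
    replacement (the same subset for every phase using the same seed),
    rounds each value to the nearest integer (half away from zero), and
    returns (patterns (batch, n_x + n_z) int array, subset index tuple).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if n_x > x.shape[1] or n_z > z.shape[1]:
        raise ValueError("requested subset larger than the unit population")
    rng = np.random.default_rng(seed)
    ix = np.sort(rng.choice(x.shape[1], size=n_x, replace=False))
    iz = np.sort(rng.choice(z.shape[1], size=n_z, replace=False))
    sel = np.concatenate([x[:, ix], z[:, iz]], axis=1)
    patterns = round_half_away(sel).astype(int)
    subset = tuple(ix) + tuple(x.shape[1] + i for i in iz)
    return patterns, subset


def pattern_frequencies(patterns, phase="wake", subset=()):
    """Exact multiset counts of the rows of a quantized pattern batch."""
    patterns = np.atleast_2d(np.asarray(patterns))
    if patterns.shape[0] == 0:
        raise ValueError("pattern batch must be nonempty")
    counts = Counter(map(tuple, patterns.astype(int)))
    return PatternHistogram(dict(counts), phase=phase, subset=tuple(subset))


def pattern_divergence(h_wake, h_sleep):
    """Jensen-Shannon divergence between two pattern histograms.

    Returns (divergence in nats, paired frequency table). The table has
    one row per pattern in the union of supports with the wake and sleep
    relative frequencies — the data behind the diagonal scatter plot.
    """
    if h_wake.subset != h_sleep.subset:
        raise ValueError("histograms were built over different unit subsets")
    union = sorted(set(h_wake.counts) | set(h_sleep.counts))
    p = np.array([h_wake.counts.get(k, 0) for k in union], dtype=float)
    q = np.array([h_sleep.counts.get(k, 0) for k in union], dtype=float)
    p /= p.sum()
    q /= q.sum()
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        js = 0.5 * np.sum(np.where(p > 0, p * np.log(p / m), 0.0)) \
            + 0.5 * np.sum(np.where(q > 0, q * np.log(q / m), 0.0))
    table = pd.DataFrame({
        "pattern": [" ".join(map(str, k)) for k in union],
        "wake_count": [h_wake.counts.get(k, 0) for k in union],
        "sleep_count": [h_sleep.counts.get(k, 0) for k in union],
        "wake_freq": p,
        "sleep_freq": q,
    })
    return float(js), table
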