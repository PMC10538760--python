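"""Stochastic recurrent inference and generative networks.

Both the recognition model q_phi(z|x) and the generative model p_theta(x|z)
share one architecture: a two-layer fully connected network with ELU hidden
units whose output is split into the mean and log-std of a diagonal
Gaussian. The Gaussian is sampled (reparameterized), the sample is fed to a
*recurrence* network of the same architecture, and the recurrence sample is
recombined with the original sample by an arithmetic mean. The single
recurrence step makes the resulting conditional distribution non-Gaussian
and introduces dependencies between units within a layer — the property the
adversarial algorithm is designed to handle and likelihood-based baselines
cannot.

Also provided: the standard-normal prior over latents and an exact
log-density oracle for hierarchical linear-Gaussian chains (the factorized
form log q(x,z) = sum_i log q(z_i | z_{i-1}) used by the layerwise
objective).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import autodiff as ad

__all__ = [
    "GaussianHead", "StochasticRecurrentNet", "NetworkState",
    "HierarchyConfig", "gaussian_head_forward", "stochastic_forward",
    "sample_prior", "chain_log_density", "save_net", "load_net",
]


def _init_weight(rng, fan_in, fan_out):
    return rng.standard_normal((fan_in, fan_out)) / np.sqrt(fan_in)


class GaussianHead:
    """Two-layer ELU network parameterizing a diagonal Gaussian.

    The output layer has ``2 * out_dim`` units: the first half is the mean,
    the second half the log standard deviation (so std = exp(log-std) is
    always strictly positive). The raw log-std is smoothly bounded to
    (-LOG_STD_BOUND, LOG_STD_BOUND) with a tanh squash — near zero it is
    the identity, so small networks behave exactly like an unconstrained
    log-std head, while a stochastic recurrence step can no longer drive
    the variance to overflow.
    """

    LOG_STD_BOUND = 4.0

    def __init__(self, in_dim, hidden_dim, out_dim, rng=None):
        rng = np.random.default_rng(rng)
        self.in_dim, self.hidden_dim, self.out_dim = in_dim, hidden_dim, out_dim
        self.W1 = ad.parameter(_init_weight(rng, in_dim, hidden_dim))
        self.b1 = ad.parameter(np.zeros(hidden_dim))
        self.W2 = ad.parameter(_init_weight(rng, hidden_dim, 2 * out_dim))
        self.b2 = ad.parameter(np.zeros(2 * out_dim))

    def parameters(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def forward(self, x):
        """Return (mean, std) Tensors for a (batch, in_dim) input."""
        if x.shape[-1] != self.in_dim:
            raise ValueError(
                f"input has {x.shape[-1]} units, head expects {self.in_dim}")
        h = ad.elu(ad.linear(x, self.W1, self.b1))
        out = ad.linear(h, self.W2, self.b2)
        mean = ad.gather_cols(out, np.arange(self.out_dim))
        raw = ad.gather_cols(out, np.arange(self.out_dim, 2 * self.out_dim))
        bound = self.LOG_STD_BOUND
        log_std = ad.mul(ad.Tensor(bound), ad.tanh(ad.mul(ad.Tensor(1.0 / bound), raw)))
        return mean, ad.exp(log_std)

    def log_density(self, x, value):
        """Diagonal-Gaussian log density of ``value`` under the head's
        output distribution given input ``x`` (Tensor, differentiable)."""
        mean, std = self.forward(x)
        z = ad.div(ad.sub(value, mean), std)
        per_unit = ad.neg(
            ad.add(ad.add(ad.mul(ad.Tensor(0.5), ad.mul(z, z)), ad.log(std)),
                   ad.Tensor(0.5 * np.log(2 * np.pi))))
        return ad.sum_(per_unit, axis=1)


def gaussian_head_forward(head, x):
    """Functional wrapper: (mean, std) arrays for an array input."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    mean, std = head.forward(ad.tensor(x))
    return mean.data, std.data


class StochasticRecurrentNet:
    """A Gaussian head followed by a stochastic recurrence network.

    ``direction`` tags the network as inference ("phi", x -> z) or
    generative ("theta", z -> x). The recurrence network maps a sample back
    onto itself (same dimensionality) and its output is averaged with the
    head's sample; ``recurrence_steps=0`` disables recurrence entirely.
    """

    def __init__(self, in_dim, hidden_dim, out_dim, direction="phi",
                 recurrence_steps=1, rng=None):
        if direction not in ("phi", "theta"):
            raise ValueError("direction must be 'phi' or 'theta'")
        rng = np.random.default_rng(rng)
        self.direction = direction
        self.recurrence_steps = int(recurrence_steps)
        self.head = GaussianHead(in_dim, hidden_dim, out_dim, rng=rng)
        self.recurrence = GaussianHead(out_dim, hidden_dim, out_dim, rng=rng)

    def parameters(self):
        return self.head.parameters() + self.recurrence.parameters()

    def sample(self, x, rng, noise_scale=1.0):
        """Reparameterized sample through head and recurrence (Tensor).

        The head sample s ~ N(mean, std^2) and each recurrence sample use
        independent noise streams drawn from ``rng``; the returned value is
        (s + r) / 2 after each recurrence step. ``noise_scale=0`` silences
        the stochasticity (useful for deterministic checks).
        """
        mean, std = self.head.forward(x)
        eps = noise_scale * rng.standard_normal(mean.shape)
        s = ad.add(mean, ad.mul(std, ad.Tensor(eps)))
        for _ in range(self.recurrence_steps):
            rmean, rstd = self.recurrence.forward(s)
            eps_r = noise_scale * rng.standard_normal(rmean.shape)
            r = ad.add(rmean, ad.mul(rstd, ad.Tensor(eps_r)))
            s = ad.mul(ad.add(s, r), ad.Tensor(0.5))
        return s

    def pre_recurrence(self, x):
        """(mean, std) of the Gaussian before recurrence (ELBO baseline)."""
        return self.head.forward(x)


def stochastic_forward(net, x, seed, noise_scale=1.0):
    """Seeded sample batch through ``net`` (array in, array out)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    rng = np.random.default_rng(seed)
    return net.sample(ad.tensor(x), rng, noise_scale=noise_scale).data


def sample_prior(n, dim, seed):
    """n i.i.d. standard-normal latent vectors."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.random.default_rng(seed).standard_normal((n, dim))


@dataclass
class NetworkState:
    """Paired input/latent activity with its phase of origin."""

    x: np.ndarray
    z: np.ndarray
    phase: str

    def __post_init__(self):
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.z = np.atleast_2d(np.asarray(self.z, dtype=float))
        if self.x.shape[0] != self.z.shape[0]:
            raise ValueError("x and z batches must have equal length")
        if self.phase not in ("wake", "sleep", "feedback"):
            raise ValueError(f"unknown phase {self.phase!r}")

    @property
    def joint(self):
        return np.concatenate([self.x, self.z], axis=1)


# ---------------------------------------------------------------------
# hierarchical linear-Gaussian chains (exact-density oracle harness)


@dataclass
class HierarchyConfig:
    """A chain of linear-Gaussian conditionals.

    Layer 0 is the root with marginal N(root_mean, diag(root_std^2));
    layer i > 0 is N(A_i @ parent + b_i, diag(std_i^2)). ``dims`` lists the
    layer dimensions from root downward. Adjacent layers only — any other
    dependency structure is rejected.
    """

    dims: list
    root_mean: np.ndarray
    root_std: np.ndarray
    weights: list = field(default_factory=list)    # A_i, shape (dims[i], dims[i-1])
    biases: list = field(default_factory=list)
    stds: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.dims) < 1:
            raise ValueError("need at least one layer")
        if not (len(self.weights) == len(self.biases) == len(self.stds)
                == len(self.dims) - 1):
            raise ValueError("conditional parameter lists must cover every "
                             "non-root layer (chain structure only)")
        for i, A in enumerate(self.weights):
            A = np.asarray(A)
            if A.shape != (self.dims[i + 1], self.dims[i]):
                raise ValueError(
                    f"layer {i + 1}: weight shape {A.shape} does not map "
                    f"layer {i} ({self.dims[i]}) -> layer {i + 1} "
                    f"({self.dims[i + 1]}); only chain graphs are supported")

    @classmethod
    def random(cls, dims, rng):
        rng = np.random.default_rng(rng)
        d0 = dims[0]
        cfg = cls(
            dims=list(dims),
            root_mean=rng.standard_normal(d0),
            root_std=np.exp(0.3 * rng.standard_normal(d0)),
            weights=[rng.standard_normal((dims[i + 1], dims[i]))
                     for i in range(len(dims) - 1)],
            biases=[rng.standard_normal(dims[i + 1])
                    for i in range(len(dims) - 1)],
            stds=[np.exp(0.3 * rng.standard_normal(dims[i + 1]))
                  for i in range(len(dims) - 1)],
        )
        return cfg

    def joint_moments(self):
        """Mean and full covariance of the flattened chain (exact)."""
        means = [np.asarray(self.root_mean, dtype=float)]
        covs = [[np.diag(np.asarray(self.root_std) ** 2.0)]]
        for i, (A, b, s) in enumerate(zip(self.weights, self.biases, self.stds)):
            A = np.asarray(A, dtype=float)
            means.append(A @ means[i] + np.asarray(b, dtype=float))
            # cross-covariances with all previous layers
            new_row = [A @ covs[i][j] for j in range(i + 1)]
            new_diag = A @ covs[i][i] @ A.T + np.diag(np.asarray(s) ** 2.0)
            for j in range(i + 1):
                covs[j].append(new_row[j].T)
            covs.append(new_row + [new_diag])
        mean = np.concatenate(means)
        cov = np.block([[covs[i][j] for j in range(len(self.dims))]
                        for i in range(len(self.dims))])
        return mean, cov

    def sample(self, n, rng):
        rng = np.random.default_rng(rng)
        vals = [self.root_mean + self.root_std * rng.standard_normal((n, self.dims[0]))]
        for A, b, s in zip(self.weights, self.biases, self.stds):
            mean = vals[-1] @ np.asarray(A).T + np.asarray(b)
            vals.append(mean + np.asarray(s) * rng.standard_normal(mean.shape))
        return vals


def chain_log_density(hierarchy, state):
    """Sum of conditional log densities along the chain.

    ``state`` is a sequence with one activity vector per layer (root
    first). Equals the joint multivariate-normal log density exactly —
    the factorization log q(x, z) = sum_i log q(z_i | parent).
    """
    if len(state) != len(hierarchy.dims):
        raise ValueError("state must supply one value per layer")
    state = [np.asarray(v, dtype=float) for v in state]
    total = stats.norm.logpdf(
        state[0], loc=hierarchy.root_mean, scale=hierarchy.root_std).sum()
    for i, (A, b, s) in enumerate(
            zip(hierarchy.weights, hierarchy.biases, hierarchy.stds)):
        mean = np.asarray(A) @ state[i] + np.asarray(b)
        total += stats.norm.logpdf(state[i + 1], loc=mean, scale=s).sum()
    return float(total)


# ---------------------------------------------------------------------
# serialization: NPZ array container + JSON sidecar


def save_net(net, path):
    """Write a StochasticRecurrentNet to ``path``.npz + ``path``.json."""
    arrays = {}
    for tag, head in (("head", net.head), ("rec", net.recurrence)):
        for name in ("W1", "b1", "W2", "b2"):
            arrays[f"{tag}_{name}"] = getattr(head, name).data
    np.savez(f"{path}.npz", **arrays)
    sidecar = {
        "direction": net.direction,
        "recurrence_steps": net.recurrence_steps,
        "in_dim": net.head.in_dim,
        "hidden_dim": net.head.hidden_dim,
        "out_dim": net.head.out_dim,
    }
    with open(f"{path}.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_net(path):
    with open(f"{path}.json") as fh:
        meta = json.load(fh)
    net = StochasticRecurrentNet(
        meta["in_dim"], meta["hidden_dim"], meta["out_dim"],
        direction=meta["direction"], recurrence_steps=meta["recurrence_steps"])
    data = np.load(f"{path}.npz")
    for tag, head in (("head", net.head), ("rec", net.recurrence)):
        for name in ("W1", "b1", "W2", "b2"):
            getattr(head, name).data = data[f"{tag}_{name}"]
    return net
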