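"""Closed-form plasticity rules for linear-nonlinear discriminator cells.

A discriminator cell with firing rate D(x, z) = sigma(W_x.x + W_z.z) has an
input-synapse gradient that is a Hebbian product of presynaptic activity
and a postsynaptic factor:

    dD/dW_x = x * sigma'(W_x.x + W_z.z)

Under the Wasserstein objective the weight update applies this product
with a positive sign when activity is stimulus-evoked (wake: Hebbian) and
a negative sign when activity is self-generated (sleep: anti-Hebbian) —
an exact phase reflection. Under the standard (log-loss) adversarial
objective the update keeps the Hebbian/anti-Hebbian character but gains
phase-dependent postsynaptic gain factors sigma'/sigma and
sigma'/(1 - sigma), so the two phases are no longer exact negatives.

Also here: the score-function (REINFORCE) estimator of the inference-net
gradient, E_q[D(x,z) * d/dphi log q_phi(x,z)], the reward-modulated form
in which the discriminator's activity gates predictive plasticity.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad

__all__ = [
    "LinearNonlinearCell", "wgan_hebbian_update", "standard_gan_update",
    "reinforce_gradient",
]

_SIGMAS = {
    "identity": (lambda u: u, lambda u: np.ones_like(u)),
    "tanh": (np.tanh, lambda u: 1.0 - np.tanh(u) ** 2),
    "logistic": (lambda u: 1.0 / (1.0 + np.exp(-u)),
                 lambda u: np.exp(-u) / (1.0 + np.exp(-u)) ** 2),
}


class LinearNonlinearCell:
    """D(x, z) = sigma(W_x.x + W_z.z) with a named monotone nonlinearity."""

    def __init__(self, w_x, w_z, sigma="tanh"):
        self.w_x = np.asarray(w_x, dtype=float)
        self.w_z = np.asarray(w_z, dtype=float)
        if not (np.isfinite(self.w_x).all() and np.isfinite(self.w_z).all()):
            raise ValueError("weights must be finite")
        if sigma not in _SIGMAS:
            raise ValueError(f"unknown nonlinearity {sigma!r}")
        self.sigma_name = sigma
        self.sigma, self.sigma_prime = _SIGMAS[sigma]

    def preactivation(self, x, z):
        return float(self.w_x @ np.asarray(x) + self.w_z @ np.asarray(z))

    def output(self, x, z):
        return float(self.sigma(self.preactivation(x, z)))


def wgan_hebbian_update(cell, x, z, phase, target="x"):
    """Phase-switched Hebbian update for the Wasserstein objective.

    Returns +pre * sigma'(u) in wake (Hebbian, gradient ascent on the
    discriminator's objective) and the exact negative in sleep
    (anti-Hebbian). ``target`` selects the synapse group: presynaptic
    activity is x for W_x, z for W_z.
    """
    if phase not in ("wake", "sleep"):
        raise ValueError(f"phase must be 'wake' or 'sleep', got {phase!r}")
    if target not in ("x", "z"):
        raise ValueError("target must be 'x' or 'z'")
    pre = np.asarray(x if target == "x" else z, dtype=float)
    gain = cell.sigma_prime(cell.preactivation(x, z))
    sign = 1.0 if phase == "wake" else -1.0
    return sign * pre * gain


def standard_gan_update(cell, x, z, phase, target="x"):
    """Update under the standard (Goodfellow) adversarial objective.

    Requires sigma = logistic so D in (0, 1). Wake term: pre * sigma'/sigma
    (gradient of log D); sleep term: -pre * sigma'/(1 - sigma) (gradient of
    log(1 - D)). Hebbian/anti-Hebbian in character but not exact phase
    reflections of one another.
    """
    if phase not in ("wake", "sleep"):
        raise ValueError(f"phase must be 'wake' or 'sleep', got {phase!r}")
    if cell.sigma_name != "logistic":
        raise ValueError("standard GAN update requires a logistic nonlinearity")
    pre = np.asarray(x if target == "x" else z, dtype=float)
    u = cell.preactivation(x, z)
    d = cell.sigma(u)
    if d <= 0.0 or d >= 1.0:
        raise ValueError("discriminator output saturated at 0 or 1")
    dp = cell.sigma_prime(u)
    if phase == "wake":
        return pre * dp / d
    return -pre * dp / (1.0 - d)


def reinforce_gradient(disc_fn, head, x, n_samples, seed, return_se=False,
                       n_chunks=50):
    """Score-function estimate of d/dphi E_{z~q_phi(.|x)}[D(x, z)].

    ``disc_fn(x_row, z_batch) -> array (n,)`` scores latent samples;
    ``head`` is the GaussianHead parameterizing q_phi(z|x). The estimate is
    mean_i [ D(x, z_i) * d/dphi log q_phi(z_i|x) ], computed per head
    parameter. Since the gradient is linear, the Monte-Carlo mean is
    obtained with one backward pass of (1/n) sum_i D_i * log q(z_i|x) with
    D_i held constant. With ``return_se`` the per-coordinate Monte-Carlo
    standard error is estimated from ``n_chunks`` disjoint chunks.

    Unbiasedness: as n grows this converges to the pathwise
    (reparameterized) gradient of E_q[D]; for constant D the expectation
    is exactly zero (E_q[grad log q] = 0).
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    x = np.asarray(x, dtype=float).reshape(1, -1)
    rng = np.random.default_rng(seed)
    params = head.parameters()

    def estimate(n, rng):
        mean, std = head.forward(ad.tensor(np.repeat(x, n, axis=0)))
        z = mean.data + std.data * rng.standard_normal(mean.shape)
        rewards = np.asarray(disc_fn(x[0], z), dtype=float)
        logq = head.log_density(ad.tensor(np.repeat(x, n, axis=0)),
                                ad.tensor(z))
        weighted = ad.mean_(ad.mul(ad.Tensor(rewards), logq))
        return [g.data for g in ad.grad(weighted, params)]

    if not return_se:
        return estimate(n_samples, rng)

    chunk = max(1, n_samples // n_chunks)
    chunk_grads = [estimate(chunk, rng) for _ in range(n_chunks)]
    mean_g = [np.mean([cg[i] for cg in chunk_grads], axis=0)
              for i in range(len(params))]
    se_g = [np.std([cg[i] for cg in chunk_grads], axis=0, ddof=1)
            / np.sqrt(n_chunks) for i in range(len(params))]
    return mean_g, se_g
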