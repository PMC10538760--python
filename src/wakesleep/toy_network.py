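"""The 4-neuron toy experiment.

A "target population" of two linear-summing units B and C receives drive
either from an external teacher cell T or from a student cell A; B also
projects to C (internal recurrence w_BC), which makes B and C dependent
given the source. All connections evoke Gaussian postsynaptic responses:

    B = w_src * s + eps_B,   C = w_src' * s + w_BC * B + eps_C,

with s ~ N(0, 1) the source activity (T or A) and eps ~ N(0, std^2).

Two learners adjust the student weights (w_AB, w_AC):

* an independent-prediction baseline that fits each node's marginal by
  maximum likelihood while ignoring the recurrence-induced dependence —
  it can match the marginals but provably not the joint when w_BC != 0;
* an adversarial learner in which a small discriminator (one hidden layer
  of 20 LeakyReLU(0.2) units) classifies teacher-driven from
  student-driven (B, C) pairs under the Wasserstein objective with
  gradient penalty 0.1, and the student weights oppose it through
  reparameterized samples. All weights use RMSProp at rate 0.001.

Alignment is scored by the empirical KL divergence between hexagonally
binned 2-D histograms (25 bins per side, extent [-5, 5] x [-5, 10],
pseudocount 1) and by the sign-invariant parameter error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import autodiff as ad
from .optim import RMSProp

__all__ = [
    "ToyParams", "default_toy_params", "simulate_population",
    "analytic_covariance", "train_baseline", "train_adversarial",
    "hexbin_kl", "hexbin_counts", "parameter_error",
]

TEACHER_SEED = 5  # published seed for the default teacher weights

HEXBIN_GRIDSIZE = 25
HEXBIN_EXTENT = (-5.0, 5.0, -5.0, 10.0)


@dataclass
class ToyParams:
    """Weights and noise scales of the 4-neuron network."""

    w_tb: float
    w_tc: float
    w_bc: float
    w_ab: float
    w_ac: float
    noise_b: float = 1.0
    noise_c: float = 1.0
    source_std: float = 1.0

    def __post_init__(self):
        if self.noise_b <= 0 or self.noise_c <= 0:
            raise ValueError("noise std must be positive")


def default_toy_params(student_seed=0, w_bc=1.0):
    """Teacher weights drawn once from N(0, 1) with the published seed;
    student weights drawn from N(0, 1) with ``student_seed``."""
    tw = np.random.default_rng(TEACHER_SEED).standard_normal(2)
    sw = np.random.default_rng(student_seed).standard_normal(2)
    return ToyParams(w_tb=float(tw[0]), w_tc=float(tw[1]), w_bc=float(w_bc),
                     w_ab=float(sw[0]), w_ac=float(sw[1]))


def _source_weights(params, driver):
    if driver == "teacher":
        return params.w_tb, params.w_tc
    if driver == "student":
        return params.w_ab, params.w_ac
    raise ValueError(f"unknown driver {driver!r}")


def _simulate_with_source(params, driver, n, rng):
    wb, wc = _source_weights(params, driver)
    s = params.source_std * rng.standard_normal(n)
    b = wb * s + params.noise_b * rng.standard_normal(n)
    c = wc * s + params.w_bc * b + params.noise_c * rng.standard_normal(n)
    return s, b, c


def simulate_population(params, driver, n, seed):
    """Sample n (B, C) pairs with the population driven by T or A."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    _, b, c = _simulate_with_source(params, driver, n, rng)
    return np.column_stack([b, c])


def analytic_covariance(params, driver):
    """Exact 2x2 covariance of (B, C) for a linear-Gaussian population."""
    wb, wc = _source_weights(params, driver)
    vs = params.source_std ** 2
    sb2, sc2 = params.noise_b ** 2, params.noise_c ** 2
    var_b = wb ** 2 * vs + sb2
    # C = (wc + w_bc*wb) * s + w_bc * eps_B + eps_C
    var_c = (wc + params.w_bc * wb) ** 2 * vs + params.w_bc ** 2 * sb2 + sc2
    cov_bc = wb * (wc + params.w_bc * wb) * vs + params.w_bc * sb2
    return np.array([[var_b, cov_bc], [cov_bc, var_c]])


# ---------------------------------------------------------------------
# evaluation statistics


def hexbin_counts(samples, gridsize=HEXBIN_GRIDSIZE, extent=HEXBIN_EXTENT):
    """Counts over a hexagonal lattice (two offset rectangular lattices,
    nearest-center assignment — the standard hexbin construction).

    Points outside the extent are clipped onto its boundary so every
    sample is counted.
    """
    samples = np.asarray(samples, dtype=float)
    xmin, xmax, ymin, ymax = extent
    x = np.clip(samples[:, 0], xmin, xmax)
    y = np.clip(samples[:, 1], ymin, ymax)
    nx = gridsize
    ny = int(nx / math.sqrt(3))
    padding = 1e-9 * (xmax - xmin)
    sx = (xmax - xmin + 2 * padding) / nx
    sy = (ymax - ymin) / ny
    ix = (x - (xmin - padding)) / sx
    iy = (y - ymin) / sy
    ix1 = np.round(ix).astype(int)
    iy1 = np.round(iy).astype(int)
    ix2 = np.floor(ix).astype(int)
    iy2 = np.floor(iy).astype(int)
    nx1, ny1 = nx + 1, ny + 1
    d1 = (ix - ix1) ** 2 + 3.0 * (iy - iy1) ** 2
    d2 = (ix - ix2 - 0.5) ** 2 + 3.0 * (iy - iy2 - 0.5) ** 2
    use1 = d1 < d2
    counts1 = np.bincount((ix1 * ny1 + iy1)[use1], minlength=nx1 * ny1)
    counts2 = np.bincount((ix2 * ny + iy2)[~use1], minlength=nx * ny)
    return np.concatenate([counts1, counts2])


def hexbin_kl(samples_p, samples_q, gridsize=HEXBIN_GRIDSIZE,
              extent=HEXBIN_EXTENT, pseudocount=1.0):
    """Empirical KL(p || q) between hexagonally binned histograms.

    A pseudocount is added to every bin before normalizing, so empty bins
    never produce an infinite divergence. Nonnegative; exactly 0 for
    identical sample sets.
    """
    sp = np.asarray(samples_p, dtype=float)
    sq = np.asarray(samples_q, dtype=float)
    if sp.size == 0 or sq.size == 0:
        raise ValueError("sample batches must be nonempty")
    cp = hexbin_counts(sp, gridsize, extent) + pseudocount
    cq = hexbin_counts(sq, gridsize, extent) + pseudocount
    p = cp / cp.sum()
    q = cq / cq.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p / q), 0.0)
    return float(terms.sum())


def parameter_error(student, optimum):
    """Euclidean distance of (w_AB, w_AC) from the optimum, minimized
    over the global sign flip (+/-w induce the same joint distribution
    under a symmetric source)."""
    s = np.asarray(student, dtype=float)
    o = np.asarray(optimum, dtype=float)
    return float(min(np.linalg.norm(s - o), np.linalg.norm(s + o)))


# ---------------------------------------------------------------------
# trainers


def train_baseline(params, steps=5000, lr=1e-3, seed=0, batch_size=256,
                   record_every=10):
    """Independent-prediction baseline.

    Gradient descent on -[log p(B|A) + log p(C|A)] over teacher-driven
    episodes, with each conditional an independent Gaussian centered on
    the student's direct drive (B ~ N(w_AB a, s_B^2), C ~ N(w_AC a,
    s_C^2); the recurrent contribution w_BC B to C is ignored). During
    these episodes A carries the shared source activity, so each weight
    follows a local delta (LMS) rule. The converged solution absorbs the
    recurrent path into the direct weight (w_AC -> w_TC + w_BC w_TB),
    which double-counts recurrence when the student population is then
    simulated with its internal connection intact — the independence
    assumption is exactly what fails when w_BC != 0. Returns (final
    ToyParams, trajectory array of (step, w_AB, w_AC)).
    """
    rng = np.random.default_rng(seed)
    w = np.array([params.w_ab, params.w_ac], dtype=float)
    noise2 = np.array([params.noise_b, params.noise_c]) ** 2
    traj = [(0, w[0], w[1])]
    for step in range(1, steps + 1):
        s, b, c = _simulate_with_source(params, "teacher", batch_size, rng)
        resid = np.column_stack([b, c]) - np.outer(s, np.ones(2)) * w
        grad = -(s[:, None] * resid).mean(axis=0) / noise2
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError(f"baseline diverged at step {step}")
        w -= lr * grad
        if step % record_every == 0 or step == steps:
            traj.append((step, w[0], w[1]))
    return replace(params, w_ab=float(w[0]), w_ac=float(w[1])), np.array(traj)


class _ToyDiscriminator:
    """One-hidden-layer scorer: 20 LeakyReLU(0.2) units, linear output."""

    def __init__(self, in_dim=2, hidden=20, rng=None):
        rng = np.random.default_rng(rng)
        self.W1 = ad.parameter(rng.standard_normal((in_dim, hidden)) / np.sqrt(in_dim))
        self.b1 = ad.parameter(np.zeros(hidden))
        # small output layer: the untrained scorer starts near zero, so
        # the objective reflects distribution differences, not init noise
        self.W2 = ad.parameter(rng.standard_normal((hidden, 1)) * 0.1 / np.sqrt(hidden))
        self.b2 = ad.parameter(np.zeros(1))

    def parameters(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def score(self, v):
        h = ad.leaky_relu(ad.linear(v, self.W1, self.b1), 0.2)
        return ad.reshape(ad.linear(h, self.W2, self.b2), (v.shape[0],))


def train_adversarial(params, steps=2000, lr=1e-3, gp_lambda=0.1, seed=0,
                      batch_size=256, observe_source=False, record_every=10,
                      hidden=20):
    """Adversarial student training against a Wasserstein discriminator.

    The discriminator sees (B, C) — or (A/T, B, C) with
    ``observe_source`` — and maximizes mean(teacher) - mean(student) with
    gradient penalty ``gp_lambda``; the student weights maximize the
    discriminator's output on student-driven samples through
    reparameterized simulation. All weights use RMSProp at ``lr``.

    Returns (final ToyParams, trajectory (step, w_AB, w_AC), objective
    trace).
    """
    rng = np.random.default_rng(seed)
    in_dim = 3 if observe_source else 2
    disc = _ToyDiscriminator(in_dim, hidden, rng=rng.integers(2 ** 31))
    w_ab = ad.parameter(params.w_ab)
    w_ac = ad.parameter(params.w_ac)
    d_opt = RMSProp(disc.parameters(), lr=lr)
    s_opt = RMSProp([w_ab, w_ac], lr=lr)
    traj = [(0, float(w_ab.data), float(w_ac.data))]
    objective = []

    def student_batch():
        a = params.source_std * rng.standard_normal(batch_size)
        eps_b = rng.standard_normal(batch_size)
        eps_c = rng.standard_normal(batch_size)
        at = ad.Tensor(a.reshape(-1, 1))
        b = ad.add(ad.matmul(at, ad.reshape(w_ab, (1, 1))),
                   ad.Tensor(params.noise_b * eps_b.reshape(-1, 1)))
        c = ad.add(ad.add(ad.matmul(at, ad.reshape(w_ac, (1, 1))),
                          ad.mul(ad.Tensor(params.w_bc), b)),
                   ad.Tensor(params.noise_c * eps_c.reshape(-1, 1)))
        bc = ad.concat_cols(b, c)
        if observe_source:
            bc = ad.concat_cols(at, bc)
        return bc

    for step in range(1, steps + 1):
        teacher = simulate_population(params, "teacher", batch_size,
                                      rng.integers(2 ** 31))
        if observe_source:
            # teacher-driven states expose the source activity too
            t_src = params.source_std * rng.standard_normal(batch_size)
            teacher = np.column_stack([t_src, teacher])
        student = student_batch()

        # discriminator step
        s_teacher = disc.score(ad.tensor(teacher))
        s_student = disc.score(ad.tensor(student.data))
        u = rng.uniform(size=(batch_size, 1))
        interp = ad.Tensor(u * teacher + (1 - u) * student.data,
                           requires_grad=True)
        gnorm = ad.row_norm(ad.grad(ad.sum_(disc.score(interp)), interp))
        pen = ad.mul(ad.Tensor(gp_lambda),
                     ad.mean_((gnorm - 1.0) ** 2))
        d_loss = ad.add(ad.sub(ad.mean_(s_student), ad.mean_(s_teacher)), pen)
        d_opt.step(ad.grad(d_loss, disc.parameters()))

        # student step (oppose the updated discriminator)
        s_loss = ad.neg(ad.mean_(disc.score(student)))
        s_opt.step(ad.grad(s_loss, [w_ab, w_ac]))

        wobj = float(s_teacher.data.mean() - s_student.data.mean())
        if not np.isfinite(wobj):
            raise FloatingPointError(f"adversarial training diverged at step {step}")
        objective.append(wobj)
        if step % record_every == 0 or step == steps:
            traj.append((step, float(w_ab.data), float(w_ac.data)))

    final = replace(params, w_ab=float(w_ab.data), w_ac=float(w_ac.data))
    return final, np.array(traj), np.array(objective)
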