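"""Training objectives and the wake/sleep training loops.

Four objectives are implemented:

* the Wasserstein wake/sleep game — the discriminator maximizes the
  difference of its mean output between stimulus-evoked (wake) and
  self-generated (sleep) joint states, subject to a gradient penalty;
  the inference net pushes its wake scores down, the generative net
  pushes its sleep scores up (both oppose the discriminator);
* the layerwise "oscillatory" objective — purely local discriminators
  additionally compare each layer's bottom-up activity with activity
  bounced back from one layer up (at the input layer: the original input
  x versus its reconstruction x'), and the models additionally minimize
  the discriminator's hidden-feature distance between x and x';
* the standard (log-loss) adversarial objective, kept for the plasticity
  analysis;
* the ELBO baseline — the textbook variational bound computed from the
  pre-recurrence Gaussian parameters, i.e. deliberately mis-specified
  whenever the stochastic recurrence is active.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .discriminators import GPConfig, gradient_penalty, feature_distance
from .model_core import sample_prior
from .optim import Adam

__all__ = [
    "TrainConfig", "LossReport", "wasserstein_wakesleep_loss",
    "oscillatory_layer_loss", "standard_gan_loss", "elbo_baseline_loss",
    "Trainer", "train_epoch",
]


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the reference setup:
    Adam with beta1=0.5, beta2=0.99, weight decay 2e-5; model learning
    rate 1e-4, discriminator 4e-4; batch 512; 400 epochs with the rates
    decaying by 0.96 per epoch between epochs 200 and 250; gradient
    penalty lambda = 1)."""

    batch_size: int = 512
    model_lr: float = 1e-4
    disc_lr: float = 4e-4
    epochs: int = 400
    decay_factor: float = 0.96
    decay_window: tuple = (200, 250)
    lam: float = 1.0
    beta1: float = 0.5
    beta2: float = 0.99
    weight_decay: float = 2e-5
    feature_coef: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.model_lr <= 0 and self.model_lr != 0:
            raise ValueError("learning rates must be positive")
        if min(self.model_lr, self.disc_lr) < 0:
            raise ValueError("learning rates must be nonnegative")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class LossReport:
    """Per-epoch objective values; all entries are finite by contract."""

    epoch: int
    disc_objective: float = 0.0
    inference_objective: float = 0.0
    generative_objective: float = 0.0
    gradient_penalty: float = 0.0
    feature_distance: float = 0.0
    elbo: float = 0.0
    n_batches: int = 0

    def validate(self):
        for k, v in asdict(self).items():
            if not np.isfinite(v):
                raise FloatingPointError(
                    f"non-finite loss: {k}={v} at epoch {self.epoch} "
                    f"(report: {asdict(self)})")
        return self


def wasserstein_wakesleep_loss(scores_wake, scores_sleep):
    """Wasserstein objectives from per-batch discriminator scores.

    Returns (disc objective L = mean_wake - mean_sleep, to be maximized
    by the discriminator; inference objective mean_wake, minimized by
    q_phi in wake; generative objective -mean_sleep, minimized by p_theta
    in sleep — i.e. both models minimize L).
    """
    sw = np.asarray(scores_wake, dtype=float)
    ss = np.asarray(scores_sleep, dtype=float)
    if sw.size == 0 or ss.size == 0:
        raise ValueError("score batches must be nonempty")
    disc = float(sw.mean() - ss.mean())
    return disc, float(sw.mean()), float(-ss.mean())


def oscillatory_layer_loss(disc_scores_forward, disc_scores_bounced):
    """Per-layer local objective L_O = mean(forward) - mean(bounced).

    ``forward`` scores come from the bottom-up (inference) pass over this
    layer; ``bounced`` scores from the same units driven top-down from one
    layer up (at the input layer: the reconstruction x'). The local
    discriminator maximizes L_O; the models minimize it.
    """
    sf = np.asarray(disc_scores_forward, dtype=float)
    sb = np.asarray(disc_scores_bounced, dtype=float)
    if sf.size == 0 or sb.size == 0:
        raise ValueError("score batches must be nonempty")
    disc = float(sf.mean() - sb.mean())
    return disc, disc


def standard_gan_loss(d_wake, d_sleep):
    """Log-loss adversarial objective mean(log D_w) + mean(log(1 - D_s))."""
    dw = np.asarray(d_wake, dtype=float)
    ds = np.asarray(d_sleep, dtype=float)
    if np.any((dw <= 0) | (dw >= 1)) or np.any((ds <= 0) | (ds >= 1)):
        raise ValueError("discriminator probabilities must lie in (0, 1)")
    return float(np.mean(np.log(dw)) + np.mean(np.log(1.0 - ds)))


def elbo_baseline_loss(net_inf, net_gen, x, seed):
    """Negative ELBO with the entropy taken from the pre-recurrence
    Gaussian.

    The latent sample z runs through the full stochastic recurrence
    (reparameterized), but the KL(q(z|x) || N(0, I)) term uses the
    Gaussian parameterized *before* recurrence, and the reconstruction
    term log p(x|z) uses the generator's pre-recurrence Gaussian head.
    With recurrence disabled this is exactly the textbook Gaussian-VAE
    bound. Returns (loss Tensor, components dict).
    """
    xt = x if isinstance(x, ad.Tensor) else ad.tensor(np.atleast_2d(x))
    rng = np.random.default_rng(seed)
    mu, std = net_inf.pre_recurrence(xt)
    z = net_inf.sample(xt, rng)
    recon = ad.mean_(net_gen.head.log_density(z, xt))
    kl_per_unit = ad.mul(
        ad.Tensor(0.5),
        ad.sub(ad.add(ad.mul(mu, mu), ad.mul(std, std)),
               ad.add(ad.Tensor(1.0), ad.mul(ad.Tensor(2.0), ad.log(std)))))
    kl = ad.mean_(ad.sum_(kl_per_unit, axis=1))
    loss = ad.sub(kl, recon)
    return loss, {"recon": recon.item(), "kl": kl.item(),
                  "elbo": -(loss.item())}


class Trainer:
    """Holds models, discriminator ensembles and optimizer state across
    epochs; one instance per experiment.

    ``models`` is a dict with keys "inference" and "generative"
    (StochasticRecurrentNet); ``ensembles`` is a dict with key "joint"
    (wake/sleep) or "local" (oscillatory), or empty for the ELBO baseline.
    """

    def __init__(self, models, ensembles, cfg, algorithm):
        if algorithm not in ("wake_sleep", "oscillatory", "elbo"):
            raise ValueError(f"unknown algorithm {algorithm!r}")
        self.models = models
        self.ensembles = ensembles
        self.cfg = cfg
        self.algorithm = algorithm
        model_params = (models["inference"].parameters()
                        + models["generative"].parameters())
        self.model_opt = _make_adam(model_params, cfg.model_lr, cfg)
        self.inf_opt = _make_adam(models["inference"].parameters(),
                                  cfg.model_lr, cfg)
        self.gen_opt = _make_adam(models["generative"].parameters(),
                                  cfg.model_lr, cfg)
        self.disc_opts = {
            k: _make_adam(e.parameters(), cfg.disc_lr, cfg)
            for k, e in ensembles.items()}
        self._decayed_epochs = set()
        self._step = 0

    # -- learning-rate schedule ---------------------------------------
    def _maybe_decay(self, epoch):
        lo, hi = self.cfg.decay_window
        if lo <= epoch < hi and epoch not in self._decayed_epochs:
            for opt in ([self.model_opt, self.inf_opt, self.gen_opt]
                        + list(self.disc_opts.values())):
                opt.scale_lr(self.cfg.decay_factor)
            self._decayed_epochs.add(epoch)

    # -- per-batch updates --------------------------------------------
    def _adversarial_batch(self, x, rng, report, local=False):
        cfg = self.cfg
        inf, gen = self.models["inference"], self.models["generative"]
        ens = self.ensembles["local" if local else "joint"]
        opt = self.disc_opts["local" if local else "joint"]
        n = x.shape[0]
        latent_dim = inf.head.out_dim
        xt = ad.tensor(x)

        # phase samples (reparameterized; graphs kept for model updates)
        z_wake = inf.sample(xt, rng)
        z_sleep = sample_prior(n, latent_dim, rng.integers(2 ** 31))
        x_sleep = gen.sample(ad.tensor(z_sleep), rng)

        v_wake = np.concatenate([x, z_wake.data], axis=1)
        v_sleep = np.concatenate([x_sleep.data, z_sleep], axis=1)

        # reconstruction (oscillatory only)
        if local:
            x_prime = gen.sample(z_wake, rng)
            v_recon = np.concatenate([x_prime.data, z_wake.data], axis=1)

        # discriminator step: maximize mean_wake - mean_sleep - penalty
        gp_cfg = GPConfig(lam=cfg.lam, seed=int(rng.integers(2 ** 31)))
        pen = gradient_penalty(ens, v_wake, v_sleep, gp_cfg)
        sw = ens.score(ad.tensor(v_wake))
        ss = ens.score(ad.tensor(v_sleep))
        disc_loss = ad.add(ad.sub(ad.mean_(ss), ad.mean_(sw)), pen)
        if local:
            gp2 = GPConfig(lam=cfg.lam, seed=int(rng.integers(2 ** 31)))
            pen2 = gradient_penalty(ens, v_wake, v_recon, gp2)
            sr = ens.score(ad.tensor(v_recon))
            disc_loss = ad.add(disc_loss,
                               ad.add(ad.sub(ad.mean_(sr), ad.mean_(sw)), pen2))
            pen_total = pen.item() + pen2.item()
        else:
            pen_total = pen.item()
        dparams = ens.parameters()
        opt.step(ad.grad(disc_loss, dparams))

        # model steps against the updated discriminator
        inf_scores = ens.score(ad.concat_cols(xt, z_wake))
        inf_loss = ad.mean_(inf_scores)
        gen_scores = ens.score(ad.concat_cols(x_sleep, ad.tensor(z_sleep)))
        gen_loss = ad.neg(ad.mean_(gen_scores))
        fd_val = 0.0
        if local:
            recon_scores = ens.score(ad.concat_cols(x_prime, z_wake))
            fd = feature_distance(ens, xt, x_prime)
            special = ad.add(ad.neg(ad.mean_(recon_scores)),
                             ad.mul(ad.Tensor(cfg.feature_coef), fd))
            fd_val = fd.item()
            model_loss = ad.add(ad.add(inf_loss, gen_loss), special)
            self.model_opt.step(ad.grad(
                model_loss,
                self.models["inference"].parameters()
                + self.models["generative"].parameters()))
        else:
            self.inf_opt.step(ad.grad(inf_loss, inf.parameters()))
            self.gen_opt.step(ad.grad(gen_loss, gen.parameters()))

        disc_obj, inf_obj, gen_obj = wasserstein_wakesleep_loss(
            sw.data, ss.data)
        report.disc_objective += disc_obj
        report.inference_objective += inf_obj
        report.generative_objective += gen_obj
        report.gradient_penalty += pen_total
        report.feature_distance += fd_val

    def _elbo_batch(self, x, rng, report):
        loss, comp = elbo_baseline_loss(
            self.models["inference"], self.models["generative"], x,
            int(rng.integers(2 ** 31)))
        params = (self.models["inference"].parameters()
                  + self.models["generative"].parameters())
        self.model_opt.step(ad.grad(loss, params))
        report.elbo += comp["elbo"]

    # -- public API ----------------------------------------------------
    def train_epoch(self, batches, epoch):
        """One pass over ``batches`` (iterable of (n, d) arrays)."""
        self._maybe_decay(epoch)
        rng = np.random.default_rng(
            np.random.SeedSequence([self.cfg.seed, epoch]))
        report = LossReport(epoch=epoch)
        for x in batches:
            x = np.atleast_2d(np.asarray(x, dtype=float))
            if self.algorithm == "elbo":
                self._elbo_batch(x, rng, report)
            else:
                self._adversarial_batch(x, rng, report,
                                        local=self.algorithm == "oscillatory")
            report.n_batches += 1
            self._step += 1
        if report.n_batches:
            for k in ("disc_objective", "inference_objective",
                      "generative_objective", "gradient_penalty",
                      "feature_distance", "elbo"):
                setattr(report, k, getattr(report, k) / report.n_batches)
        return report.validate()


def train_epoch(models, ensembles, batches, cfg, algorithm, trainer=None,
                epoch=0):
    """Functional wrapper over :class:`Trainer` for a single epoch.

    Pass the returned trainer back in to keep optimizer state across
    epochs. Returns (LossReport, trainer).
    """
    if trainer is None:
        trainer = Trainer(models, ensembles, cfg, algorithm)
    return trainer.train_epoch(batches, epoch), trainer


def _make_adam(params, lr, cfg):
    # lr 0 is allowed (no-op updates, used by determinism checks)
    opt = Adam(params, lr=max(lr, 1e-300), beta1=cfg.beta1, beta2=cfg.beta2,
               weight_decay=cfg.weight_decay)
    if lr == 0:
        opt.lr = 0.0
    return opt
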