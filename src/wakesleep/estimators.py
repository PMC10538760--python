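"""Scikit-learn-style estimators wrapping the wake/sleep training loops.

Three unsupervised representation learners share one interface:

* :class:`AdversarialWakeSleep` — joint (x, z) discriminator ensemble,
  Wasserstein objective with gradient penalty;
* :class:`OscillatoryWakeSleep` — purely local (layerwise) discriminator
  cells plus the reconstruction ("bounced-back") objective and the
  discriminator-feature metric;
* :class:`RecurrentVAE` — the ELBO baseline that ignores the stochastic
  recurrence when evaluating entropies.

``fit(X)`` trains on a (n_samples, n_features) array of activity in
[-1, 1]; ``transform(X)`` returns sampled latents, ``sample(n)`` draws
from the generative model, ``reconstruct(X)`` round-trips through latent
space. All estimators compose with sklearn pipelines and
``get_params``/``set_params``/``clone``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import autodiff as ad
from .discriminators import DiscriminatorEnsemble
from .evaluation import (pattern_divergence, pattern_frequencies,
                         quantize_subsample)
from .model_core import StochasticRecurrentNet, sample_prior
from .objectives import TrainConfig, Trainer

__all__ = ["AdversarialWakeSleep", "OscillatoryWakeSleep", "RecurrentVAE"]


class _WakeSleepBase(TransformerMixin, BaseEstimator):

    _algorithm = None  # set by subclasses

    def __init__(self, latent_dim=16, hidden_dim=64, disc_hidden=64,
                 n_cells=4, subset_frac=0.5, recurrence_steps=1,
                 batch_size=128, epochs=30, model_lr=1e-3, disc_lr=4e-3,
                 lam=1.0, feature_coef=1.0, decay_factor=0.96,
                 decay_window=(200, 250), random_state=0):
        self.latent_dim = latent_dim
        self.hidden_dim = hidden_dim
        self.disc_hidden = disc_hidden
        self.n_cells = n_cells
        self.subset_frac = subset_frac
        self.recurrence_steps = recurrence_steps
        self.batch_size = batch_size
        self.epochs = epochs
        self.model_lr = model_lr
        self.disc_lr = disc_lr
        self.lam = lam
        self.feature_coef = feature_coef
        self.decay_factor = decay_factor
        self.decay_window = decay_window
        self.random_state = random_state

    # -- construction --------------------------------------------------
    def _build(self, n_features, rng):
        self.inference_net_ = StochasticRecurrentNet(
            n_features, self.hidden_dim, self.latent_dim, direction="phi",
            recurrence_steps=self.recurrence_steps,
            rng=rng.integers(2 ** 31))
        self.generative_net_ = StochasticRecurrentNet(
            self.latent_dim, self.hidden_dim, n_features, direction="theta",
            recurrence_steps=self.recurrence_steps,
            rng=rng.integers(2 ** 31))
        models = {"inference": self.inference_net_,
                  "generative": self.generative_net_}
        ensembles = {}
        dim = n_features + self.latent_dim
        if self._algorithm == "wake_sleep":
            self.discriminator_ = DiscriminatorEnsemble(
                dim, n_cells=self.n_cells, subset_frac=self.subset_frac,
                hidden_dim=self.disc_hidden, scope="joint",
                rng=rng.integers(2 ** 31))
            ensembles["joint"] = self.discriminator_
        elif self._algorithm == "oscillatory":
            self.discriminator_ = DiscriminatorEnsemble(
                dim, n_cells=self.n_cells, subset_frac=self.subset_frac,
                hidden_dim=self.disc_hidden, scope="local",
                blocks=[(0, n_features), (n_features, dim)],
                rng=rng.integers(2 ** 31))
            ensembles["local"] = self.discriminator_
        return models, ensembles

    def _config(self):
        return TrainConfig(
            batch_size=self.batch_size, model_lr=self.model_lr,
            disc_lr=self.disc_lr, epochs=self.epochs,
            decay_factor=self.decay_factor, decay_window=self.decay_window,
            lam=self.lam, feature_coef=self.feature_coef,
            seed=self.random_state)

    # -- sklearn API ---------------------------------------------------
    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        rng = np.random.default_rng(self.random_state)
        self.n_features_in_ = X.shape[1]
        models, ensembles = self._build(X.shape[1], rng)
        trainer = Trainer(models, ensembles, self._config(), self._algorithm)
        self.history_ = []
        n = X.shape[0]
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            batches = [X[order[i:i + self.batch_size]]
                       for i in range(0, n, self.batch_size)]
            self.history_.append(trainer.train_epoch(batches, epoch))
        return self

    def transform(self, X, seed=None):
        """Sampled latent activity z ~ q_phi(z|x) (with recurrence)."""
        check_is_fitted(self, "inference_net_")
        X = check_array(X, dtype=float)
        rng = np.random.default_rng(
            self.random_state if seed is None else seed)
        return self.inference_net_.sample(ad.tensor(X), rng).data

    def sample(self, n, seed=None):
        """Self-generated (sleep-phase) pairs: (x, z) with z from the
        prior and x ~ p_theta(x|z)."""
        check_is_fitted(self, "generative_net_")
        seed = self.random_state if seed is None else seed
        z = sample_prior(n, self.latent_dim, seed)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        x = self.generative_net_.sample(ad.tensor(z), rng).data
        return x, z

    def reconstruct(self, X, seed=None):
        """x -> z ~ q(z|x) -> x' ~ p(x|z)."""
        z = self.transform(X, seed=seed)
        rng = np.random.default_rng(
            (self.random_state if seed is None else seed) + 1)
        return self.generative_net_.sample(ad.tensor(z), rng).data

    # -- evaluation ----------------------------------------------------
    def pattern_js(self, X, n_eval=5000, n_x=16, n_z=16, seed=0):
        """Wake-vs-sleep Jensen-Shannon divergence over quantized,
        subsampled joint patterns; returns (js, paired frequency table)."""
        check_is_fitted(self, "inference_net_")
        rng = np.random.default_rng(seed)
        rows = rng.choice(X.shape[0], size=n_eval, replace=True)
        xw = np.asarray(X, dtype=float)[rows]
        zw = self.inference_net_.sample(
            ad.tensor(xw), np.random.default_rng(rng.integers(2 ** 31))).data
        xs, zs = self.sample(n_eval, seed=int(rng.integers(2 ** 31)))
        subset_seed = int(rng.integers(2 ** 31))
        pw, sub = quantize_subsample(xw, zw, n_x, n_z, subset_seed)
        ps, _ = quantize_subsample(xs, zs, n_x, n_z, subset_seed)
        h_wake = pattern_frequencies(pw, phase="wake", subset=sub)
        h_sleep = pattern_frequencies(ps, phase="sleep", subset=sub)
        return pattern_divergence(h_wake, h_sleep)


class AdversarialWakeSleep(_WakeSleepBase):
    """Adversarial wake/sleep learning with a joint discriminator
    ensemble (Wasserstein objective, gradient penalty)."""

    _algorithm = "wake_sleep"


class OscillatoryWakeSleep(_WakeSleepBase):
    """Layerwise adversarial learning: local discriminator cells compare
    bottom-up with bounced-back activity in every layer, and the models
    additionally minimize the discriminator-feature reconstruction
    distance."""

    _algorithm = "oscillatory"


class RecurrentVAE(_WakeSleepBase):
    """ELBO-trained baseline on the same stochastic recurrent
    architecture; the variational entropy deliberately ignores the
    recurrence (it uses the pre-recurrence Gaussian), which mis-specifies
    the objective whenever recurrence is active."""

    _algorithm = "elbo"
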