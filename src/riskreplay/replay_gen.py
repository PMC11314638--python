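"""Generative feature replay: conditional generator, critic, and gate.

When a new data batch arrives, the model does not necessarily retrain
from scratch.  A label-conditioned generator learns the distribution
of *latent features* (the feature extractor's outputs) and can replay
synthetic features of past batches alongside new data, so the
predictor keeps old knowledge without storing raw records.  Four
losses drive the update:

* **distillation** — mean squared distance between the new and the
  frozen previous feature extractor on the same records, discouraging
  catastrophic drift of the feature map;
* **generator** (Wasserstein-style) — maximise the critic's score on
  generated features, i.e. minimise ``-E[D(label, G(label, z))]``;
* **critic** — score generated features down and real extracted
  features up: ``E[D(fake)] - E[D(real)]`` (with weight clipping);
* **replay alignment** — mean squared distance between the current
  generator and a frozen replay copy fed the *same* noise and labels,
  anchoring the updated generator to its past self.

An update gate decides whether replay is trustworthy for the incoming
batch: a per-label diagonal Gaussian is fitted to samples drawn from
the previous generator, the new batch's negative log-likelihood under
that density is compared with the NLL recorded at the last accepted
batch, and the generator update is skipped when the new batch fits
markedly worse (an additive tolerance absorbs the sampling noise of a
batch-mean NLL; tolerance 0 gives the strict comparison).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._nn import MLP, RMSProp

__all__ = [
    "ConditionalGenerator",
    "Discriminator",
    "GateState",
    "ReplayLossReport",
    "GANConfig",
    "DEFAULT_GATE_MARGIN",
    "distillation_loss",
    "generator_loss",
    "discriminator_loss",
    "alignment_loss",
    "batch_nll",
    "update_decision",
    "train_gan",
    "train_replay_phase",
]

#: Additive tolerance (nats per sample) of the NLL update gate.
DEFAULT_GATE_MARGIN = 0.5


def _onehot_labels(labels) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    out = np.zeros((labels.size, 2))
    out[np.arange(labels.size), labels] = 1.0
    return out


class ConditionalGenerator:
    """Three-linear-layer generator conditioned on the binary tag.

    Input is the concatenation of a standard-normal noise vector and
    the one-hot label; the output is a latent feature vector bounded by
    a scaled tanh (latent features live on a standardized scale, so the
    bound is wider than the unit interval).
    """

    def __init__(self, feature_dim: int, z_dim: int = 32, hidden: int = 64,
                 out_scale: float = 3.0, rng=None):
        if rng is None:
            rng = np.random.default_rng(0)
        self.feature_dim = feature_dim
        self.z_dim = z_dim
        self.net = MLP([z_dim + 2, hidden, hidden, feature_dim],
                       ["relu", "relu", "tanh"], rng, out_scale=out_scale)

    def forward(self, labels, z: np.ndarray) -> np.ndarray:
        """Generate features from given noise (used for alignment)."""
        X = np.concatenate([z, _onehot_labels(labels)], axis=1)
        return self.net.forward(X)

    def sample(self, labels, rng) -> np.ndarray:
        labels = np.asarray(labels, dtype=int)
        z = rng.standard_normal((labels.size, self.z_dim))
        return self.forward(labels, z)

    def clone(self) -> "ConditionalGenerator":
        other = ConditionalGenerator.__new__(ConditionalGenerator)
        other.feature_dim = self.feature_dim
        other.z_dim = self.z_dim
        other.net = self.net.clone()
        return other


class Discriminator:
    """Two-linear-layer critic over (label, feature) pairs.

    Emits an unbounded validity score (Wasserstein-style critic, no
    sigmoid); weight clipping during training keeps it Lipschitz-ish.
    """

    def __init__(self, feature_dim: int, hidden: int = 64, rng=None):
        if rng is None:
            rng = np.random.default_rng(0)
        self.feature_dim = feature_dim
        self.net = MLP([feature_dim + 2, hidden, 1], ["relu", "linear"], rng)

    def score(self, labels, features: np.ndarray) -> np.ndarray:
        X = np.concatenate([_onehot_labels(labels), np.atleast_2d(features)],
                           axis=1)
        return self.net.forward(X)[:, 0]


@dataclasses.dataclass
class GateState:
    """NLL bookkeeping of the update gate.

    ``nll_prev`` is the NLL recorded for the last accepted batch;
    ``nll_new`` the NLL of the incoming batch under the current
    generator's fitted density.  Both uninitialised before batch 1.
    """

    nll_prev: float | None = None
    nll_new: float | None = None


@dataclasses.dataclass
class ReplayLossReport:
    l_feature: float
    l_gen: float
    l_disc: float
    l_align: float


@dataclasses.dataclass
class GANConfig:
    """Adversarial-phase hyperparameters."""

    z_dim: int = 32
    hidden: int = 64
    gen_lr: float = 5e-4
    disc_lr: float = 5e-3
    clip: float = 0.05
    #: critic updates per generator update; the weight-clipped critic
    #: needs to stay well ahead of the generator
    n_critic: int = 5
    lambda_align: float = 1.0
    lambda_distill: float = 1.0
    steps: int = 200
    batch_size: int = 64
    out_scale: float = 3.0
    density_samples: int = 2000


# --------------------------------------------------------------------------
# Losses (pure evaluations)
# --------------------------------------------------------------------------

def distillation_loss(f_new: MLP, f_old: MLP, X: np.ndarray) -> float:
    """Mean squared distance between the two extractors' outputs."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty record set")
    diff = f_new.forward(X) - f_old.forward(X)
    return float(np.mean(np.sum(diff * diff, axis=1)))


def generator_loss(gen: ConditionalGenerator, disc: Discriminator,
                   labels, rng) -> float:
    """Negative mean critic score on generated features."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty label batch")
    fake = gen.sample(labels, rng)
    return float(-np.mean(disc.score(labels, fake)))


def discriminator_loss(gen: ConditionalGenerator, disc: Discriminator,
                       real_labels, real_features: np.ndarray, rng) -> float:
    """Critic objective: push fakes down, reals up."""
    real_labels = np.asarray(real_labels, dtype=int)
    if real_labels.size == 0:
        raise ValueError("empty real batch")
    fake = gen.sample(real_labels, rng)
    return float(np.mean(disc.score(real_labels, fake))
                 - np.mean(disc.score(real_labels, real_features)))


def alignment_loss(gen_current: ConditionalGenerator,
                   gen_replay: ConditionalGenerator, labels, rng) -> float:
    """Mean squared distance between the two generators on shared noise."""
    if gen_current.z_dim != gen_replay.z_dim or \
            gen_current.feature_dim != gen_replay.feature_dim:
        raise ValueError("generator architecture mismatch")
    labels = np.asarray(labels, dtype=int)
    z = rng.standard_normal((labels.size, gen_current.z_dim))
    diff = gen_current.forward(labels, z) - gen_replay.forward(labels, z)
    return float(np.mean(np.sum(diff * diff, axis=1)))


# --------------------------------------------------------------------------
# NLL gate
# --------------------------------------------------------------------------

def _fit_label_densities(gen: ConditionalGenerator, labels_present, m: int,
                         rng, var_floor: float = 1e-6):
    densities = {}
    for lab in labels_present:
        samples = gen.sample(np.full(m, lab), rng)
        mu = samples.mean(axis=0)
        var = np.maximum(samples.var(axis=0), var_floor)
        densities[lab] = (mu, var)
    return densities


def batch_nll(gen: ConditionalGenerator, features: np.ndarray, labels,
              m: int = 2000, seed: int = 0, var_floor: float = 1e-6) -> float:
    """NLL of real latent features under the generator's fitted density.

    A per-label diagonal Gaussian is fitted to ``m`` generated samples;
    the returned value is the mean negative log-density of the batch.
    Deterministic for a fixed ``seed``.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels, dtype=int)
    if features.shape[0] == 0:
        raise ValueError("empty batch")
    rng = np.random.default_rng(seed)
    densities = _fit_label_densities(gen, sorted(set(labels.tolist())), m, rng,
                                     var_floor)
    total = 0.0
    for f, lab in zip(features, labels):
        mu, var = densities[int(lab)]
        logp = -0.5 * np.sum(np.log(2.0 * np.pi * var) + (f - mu) ** 2 / var)
        total += logp
    return float(-total / features.shape[0])


def update_decision(gate: GateState, margin: float = DEFAULT_GATE_MARGIN) -> str:
    """Gate the generator update on the incoming batch's NLL.

    Returns ``"replay_update"`` when ``nll_new <= nll_prev + margin``
    (the accepted NLL then replaces ``nll_prev``), otherwise
    ``"skip_generator_update"``.  ``margin = 0`` is the strict rule.
    """
    if gate.nll_prev is None or gate.nll_new is None:
        raise ValueError("gate not initialised (needs nll_prev and nll_new)")
    if gate.nll_new <= gate.nll_prev + margin:
        gate.nll_prev = gate.nll_new
        return "replay_update"
    return "skip_generator_update"


# --------------------------------------------------------------------------
# Adversarial training
# --------------------------------------------------------------------------

def train_gan(gen: ConditionalGenerator, disc: Discriminator,
              real_features: np.ndarray, real_labels, cfg: GANConfig, rng,
              gen_replay: ConditionalGenerator | None = None):
    """Alternate critic / generator updates on a real-feature batch.

    Each round runs ``cfg.n_critic`` critic minibatch steps (the critic
    minimises ``E[D(fake)] - E[D(real)]`` with weight clipping) followed
    by one generator step (minimising ``-E[D(fake)]`` plus
    ``lambda_align`` times the replay-alignment penalty when a frozen
    replay generator is given).  Returns (l_gen, l_disc, l_align) at
    the final step.
    """
    real_features = np.atleast_2d(np.asarray(real_features, dtype=float))
    real_labels = np.asarray(real_labels, dtype=int)
    n = real_features.shape[0]
    if n == 0:
        raise ValueError("empty real batch")
    opt_gen = RMSProp(gen.net, lr=cfg.gen_lr)
    opt_disc = RMSProp(disc.net, lr=cfg.disc_lr)
    l_gen = l_disc = l_align = float("nan")
    k = min(cfg.batch_size, n)
    for _ in range(cfg.steps):
        # ---- critic steps, fresh minibatch each
        for _c in range(max(1, cfg.n_critic)):
            idx = rng.choice(n, size=k, replace=False)
            labs = real_labels[idx]
            reals = real_features[idx]
            onehot = _onehot_labels(labs)
            z = rng.standard_normal((k, gen.z_dim))
            fake = gen.forward(labs, z)
            Xd = np.concatenate([
                np.concatenate([onehot, fake], axis=1),
                np.concatenate([onehot, reals], axis=1),
            ])
            scores, dcache = disc.net.forward_cache(Xd)
            l_disc = float(scores[:k, 0].mean() - scores[k:, 0].mean())
            dY = np.zeros_like(scores)
            dY[:k, 0] = 1.0 / k
            dY[k:, 0] = -1.0 / k
            _, dgrads = disc.net.backward(dcache, dY)
            opt_disc.step(dgrads)
            disc.net.clip_weights(cfg.clip)

        # ---- generator step (fresh noise, critic frozen)
        idx = rng.choice(n, size=k, replace=False)
        labs = real_labels[idx]
        onehot = _onehot_labels(labs)
        z = rng.standard_normal((k, gen.z_dim))
        Xg = np.concatenate([z, onehot], axis=1)
        fake, gcache = gen.net.forward_cache(Xg)
        Xd = np.concatenate([onehot, fake], axis=1)
        scores, dcache = disc.net.forward_cache(Xd)
        l_gen = float(-scores[:, 0].mean())
        dY = np.zeros_like(scores)
        dY[:, 0] = -1.0 / k
        dXd, _ = disc.net.backward(dcache, dY)
        dfake = dXd[:, 2:]          # feature part of the critic input
        if gen_replay is not None:
            anchor = gen_replay.forward(labs, z)
            diff = fake - anchor
            l_align = float(np.mean(np.sum(diff * diff, axis=1)))
            dfake = dfake + cfg.lambda_align * 2.0 * diff / k
        _, ggrads = gen.net.backward(gcache, dfake)
        opt_gen.step(ggrads)
    return l_gen, l_disc, l_align


def train_replay_phase(extractor: MLP, extractor_old: MLP | None,
                       gen: ConditionalGenerator,
                       gen_replay: ConditionalGenerator | None,
                       disc: Discriminator, states: np.ndarray, labels,
                       cfg: GANConfig, rng) -> ReplayLossReport:
    """Adversarial phase over a batch's states: extract features, run the
    alternating critic/generator updates, and report the final losses.

    The feature extractor itself is trained by the agent (with the
    distillation term); here it only supplies the real features, and
    its distillation loss against the frozen copy is reported.
    """
    states = np.atleast_2d(np.asarray(states, dtype=float))
    if states.shape[0] == 0:
        raise ValueError("empty fusion dataset")
    features = extractor.forward(states)
    if cfg.steps == 0:
        labs = np.asarray(labels, dtype=int)
        l_gen = generator_loss(gen, disc, labs, rng)
        l_disc = discriminator_loss(gen, disc, labs, features, rng)
        l_align = (alignment_loss(gen, gen_replay, labs, rng)
                   if gen_replay is not None else float("nan"))
    else:
        l_gen, l_disc, l_align = train_gan(
            gen, disc, features, labels, cfg, rng, gen_replay=gen_replay)
    l_feature = (distillation_loss(extractor, extractor_old, states)
                 if extractor_old is not None else 0.0)
    return ReplayLossReport(l_feature=l_feature, l_gen=l_gen,
                            l_disc=l_disc, l_align=l_align)
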