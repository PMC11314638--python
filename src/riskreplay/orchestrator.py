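"""End-to-end online training over a batch stream, plus ablations.

The online loop processes yearly batches in order.  Batch 1 trains the
agent (feature extractor + Q head) and then the conditional generator
/ critic on the extracted features, and records the batch's NLL under
the generator's fitted density.  For every later batch the update gate
compares the incoming batch's NLL against the recorded one:

* **accepted** -> a replay update: the extractor is snapshotted
  (frozen copy for distillation), the generator is snapshotted (frozen
  replay copy for alignment), a fusion set of real episodes plus
  generated one-step feature episodes is built, the agent trains on
  the fusion with the distillation penalty, and the adversarial phase
  refreshes the generator/critic with the alignment penalty;
* **rejected** -> the generator is kept as-is and the agent trains on
  the new batch only.

After training on each batch the model is evaluated on that batch's
held-out test split (patient-level 3:1:1 train/test/validation split).

Ablation variants:

* ``retrain`` — all learned state is discarded between batches;
* ``no_replay`` — the updating module is removed entirely: the model
  trained on batch 1 is reused frozen on every later batch;
* ``no_gate`` — the gate is removed: every batch gets a replay update;
* ``full`` — the complete method.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from . import ehr_stream, replay_gen, representation
from .metrics import score_report
from .replay_gen import (ConditionalGenerator, Discriminator, GANConfig,
                         GateState, batch_nll, update_decision)
from .rl_core import AgentConfig, RiskAgent, Transition, compute_reward

__all__ = [
    "RunConfig",
    "RunReport",
    "run_online",
    "run_variant",
    "build_fusion_set",
    "run_repeats",
    "VARIANTS",
]

VARIANTS = ("full", "retrain", "no_replay", "no_gate")


@dataclasses.dataclass
class RunConfig:
    """Everything one online run depends on (all seeds explicit)."""

    variant: str = "full"
    agent: AgentConfig = dataclasses.field(default_factory=AgentConfig)
    gan: GANConfig = dataclasses.field(default_factory=GANConfig)
    split_ratios: tuple = (3, 1, 1)
    agent_epochs: int = 20
    fusion_ratio: float = 1.0
    gate_margin: float = replay_gen.DEFAULT_GATE_MARGIN
    #: refit the numeric normalizer on every batch instead of freezing
    #: the batch-1 fit (retrain always refits)
    normalizer_refresh: bool = False
    #: alternative no_replay semantics: keep training the agent on new
    #: batches (no replay/distillation/gate) instead of freezing it
    no_replay_keeps_training: bool = False
    distill_sample_size: int = 64
    seed: int = 0

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.fusion_ratio <= 0:
            raise ValueError("fusion_ratio must be > 0")
        if self.agent_epochs < 1:
            raise ValueError("agent_epochs must be >= 1")


@dataclasses.dataclass
class RunReport:
    """Per-batch evaluation results of one online run."""

    variant: str
    seed: int
    per_batch: list          # one dict per batch
    averages: dict
    audit: list              # per-batch {train/test/validation pid lists}

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=1)


# --------------------------------------------------------------------------
# Fusion set
# --------------------------------------------------------------------------

def build_fusion_set(real_labels, gen: ConditionalGenerator, ratio: float,
                     rng):
    """Generated complement of a real batch.

    Draws ``round-half-up(ratio * n_real)`` feature samples whose labels
    mirror the real batch's empirical label frequencies.  Returns
    (features, labels).
    """
    real_labels = np.asarray(real_labels, dtype=int)
    if real_labels.size == 0:
        raise ValueError("empty real batch")
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    n_gen = int(np.floor(ratio * real_labels.size + 0.5))
    p1 = float(real_labels.mean())
    labels = (rng.random(n_gen) < p1).astype(int)
    return gen.sample(labels, rng), labels


# --------------------------------------------------------------------------
# Internal training helpers
# --------------------------------------------------------------------------

def _patient_sequences(records, stats, schema):
    by_pid = {}
    for r in records:
        by_pid.setdefault(r.patient_id, []).append(r)
    seqs = {}
    for pid in sorted(by_pid):
        seqs[pid] = representation.patient_state_sequence(
            by_pid[pid], stats, schema)
    return seqs


def _train_agent(agent: RiskAgent, episodes, epochs: int, rng,
                 distill_from=None, distill_states=None,
                 distill_weight: float = 1.0,
                 distill_sample_size: int = 64):
    """Roll episodes with epsilon-greedy exploration and train per step.

    ``episodes`` is a list of [(state_or_feature, label, is_feature)]
    sequences.  Epsilon decays linearly from the agent config's start to
    end value over the whole budget.
    """
    cfg = agent.cfg
    total = max(1, epochs * sum(len(e) for e in episodes))
    step = 0
    for _ in range(epochs):
        order = rng.permutation(len(episodes))
        for ei in order:
            seq = episodes[ei]
            for t, (state, label, is_feature) in enumerate(seq):
                frac = min(1.0, step / total)
                eps = cfg.epsilon_start + frac * (cfg.epsilon_end
                                                  - cfg.epsilon_start)
                action, probs = agent.select_action(
                    state, eps, rng, is_feature=is_feature)
                _, _, reward = compute_reward(action, label, probs,
                                              cfg.reward_epsilon)
                terminal = t + 1 == len(seq)
                next_state = None if terminal else seq[t + 1][0]
                agent.observe(Transition(
                    state=state, action=action, reward=reward,
                    next_state=next_state, terminal=terminal,
                    correct=action == label, is_feature=is_feature))
                ds = None
                if distill_from is not None and distill_states is not None:
                    n = distill_states.shape[0]
                    take = min(distill_sample_size, n)
                    ds = distill_states[rng.choice(n, size=take,
                                                   replace=False)]
                agent.train_step(rng, distill_from=distill_from,
                                 distill_states=ds,
                                 distill_weight=distill_weight)
                step += 1


def _evaluate(agent: RiskAgent, seqs) -> dict:
    preds, labels, scores = [], [], []
    for pid in sorted(seqs):
        for state, label in seqs[pid]:
            action, probs = agent.predict(state)
            preds.append(action)
            labels.append(label)
            scores.append(probs.left)
    report = score_report(preds, labels, scores)
    return report.to_dict()


# --------------------------------------------------------------------------
# The online loop
# --------------------------------------------------------------------------

def run_online(stream: ehr_stream.BatchStream, cfg: RunConfig) -> RunReport:
    """Run the online method (or a variant) over a batch stream.

    Deterministic for fixed (stream, cfg): every random draw flows from
    ``cfg.seed``.
    """
    cfg.validate()
    if not stream.batches:
        raise ValueError("empty stream")
    schema = stream.schema
    root = np.random.default_rng(cfg.seed)
    rng_split = np.random.default_rng(int(root.integers(2 ** 31)))
    rng_train = np.random.default_rng(int(root.integers(2 ** 31)))
    agent_seed = int(root.integers(2 ** 31))
    gan_seed = int(root.integers(2 ** 31))
    nll_seed = int(root.integers(2 ** 31))

    variant = cfg.variant
    state_dim = 2 * schema.embedding_dim()
    agent_cfg = dataclasses.replace(cfg.agent, seed=agent_seed)

    def fresh_agent():
        return RiskAgent(state_dim, agent_cfg)

    def fresh_gan():
        grng = np.random.default_rng(gan_seed)
        gen = ConditionalGenerator(agent_cfg.feature_dim, cfg.gan.z_dim,
                                   cfg.gan.hidden, cfg.gan.out_scale, grng)
        disc = Discriminator(agent_cfg.feature_dim, cfg.gan.hidden, grng)
        return gen, disc

    agent = fresh_agent()
    gen, disc = fresh_gan()
    gate = GateState()
    stats = None
    per_batch, audit = [], []

    for t, batch in enumerate(stream.batches):
        train, test, val = ehr_stream.split_batch(
            batch, cfg.split_ratios, rng_split)
        audit.append({
            "train": sorted({r.patient_id for r in train}),
            "test": sorted({r.patient_id for r in test}),
            "validation": sorted({r.patient_id for r in val}),
        })

        if variant == "retrain":
            agent = fresh_agent()
            stats = representation.fit_normalizer(train, schema)
        elif stats is None or cfg.normalizer_refresh:
            stats = representation.fit_normalizer(train, schema)

        train_seqs = _patient_sequences(train, stats, schema)
        test_seqs = _patient_sequences(test, stats, schema)
        episodes = [[(s, lab, False) for s, lab in seq]
                    for _, seq in sorted(train_seqs.items())]
        train_states = np.vstack([s for seq in train_seqs.values()
                                  for s, _ in seq])
        train_labels = np.array([lab for seq in train_seqs.values()
                                 for _, lab in seq], dtype=int)

        decision = None
        if variant == "retrain":
            _train_agent(agent, episodes, cfg.agent_epochs, rng_train)
            decision = "retrain"
        elif variant == "no_replay" and t > 0:
            if cfg.no_replay_keeps_training:
                _train_agent(agent, episodes, cfg.agent_epochs, rng_train)
                decision = "new_data_only"
            else:
                decision = "frozen"
        elif t == 0:
            # first batch: full train of extractor/agent, then generator
            _train_agent(agent, episodes, cfg.agent_epochs, rng_train)
            if variant in ("full", "no_gate"):
                feats = agent.features(train_states)
                replay_gen.train_gan(gen, disc, feats, train_labels,
                                     cfg.gan, rng_train)
                gate.nll_prev = batch_nll(
                    gen, agent.features(train_states), train_labels,
                    m=cfg.gan.density_samples, seed=nll_seed)
            decision = "initial_train"
        else:
            if variant == "no_gate":
                decision = "replay_update"
            else:
                gate.nll_new = batch_nll(
                    gen, agent.features(train_states), train_labels,
                    m=cfg.gan.density_samples, seed=nll_seed + t)
                decision = update_decision(gate, cfg.gate_margin)
            if decision == "replay_update":
                f_old = agent.qnet.extractor.clone()
                gen_replay = gen.clone()
                gen_feats, gen_labels = build_fusion_set(
                    train_labels, gen, cfg.fusion_ratio, rng_train)
                fusion_episodes = episodes + [
                    [(gen_feats[i], int(gen_labels[i]), True)]
                    for i in range(gen_feats.shape[0])]
                _train_agent(agent, fusion_episodes, cfg.agent_epochs,
                             rng_train, distill_from=f_old,
                             distill_states=train_states,
                             distill_weight=cfg.gan.lambda_distill,
                             distill_sample_size=cfg.distill_sample_size)
                feats = agent.features(train_states)
                replay_gen.train_gan(gen, disc, feats, train_labels,
                                     cfg.gan, rng_train,
                                     gen_replay=gen_replay)
            else:
                # gate rejected: keep the generator, learn the new data
                _train_agent(agent, episodes, cfg.agent_epochs, rng_train)

        entry = {"batch_label": stream.batch_labels[t], "decision": decision}
        entry.update(_evaluate(agent, test_seqs))
        per_batch.append(entry)

    keys = ("accuracy", "precision", "recall", "fpr", "pr_auc", "roc_auc")
    averages = {}
    for k in keys:
        vals = [b[k] for b in per_batch if b[k] is not None]
        averages[k] = float(np.mean(vals)) if vals else None
    return RunReport(variant=variant, seed=cfg.seed, per_batch=per_batch,
                     averages=averages, audit=audit)


def run_variant(stream: ehr_stream.BatchStream, cfg: RunConfig) -> RunReport:
    """Alias of :func:`run_online`; the variant lives in the config."""
    return run_online(stream, cfg)


def run_repeats(stream: ehr_stream.BatchStream, cfg: RunConfig, seeds):
    """Repeat a run over seeds; returns (reports, summary mean/sd)."""
    reports = [run_online(stream, dataclasses.replace(cfg, seed=int(s)))
               for s in seeds]
    summary = {}
    for k in reports[0].averages:
        vals = [r.averages[k] for r in reports if r.averages[k] is not None]
        if vals:
            summary[k] = {"mean": float(np.mean(vals)),
                          "sd": float(np.std(vals))}
    return reports, summary
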