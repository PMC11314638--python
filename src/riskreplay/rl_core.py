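"""The hypertension-risk agent: DQN with dual prioritized replay.

The risk prediction task is cast as a one-agent decision process: each
patient's visit sequence is an episode, the state is the visit/history
vector from :mod:`riskreplay.representation`, and the two actions are
``1`` (flag hypertension risk, "is_hyper") and ``0`` ("no_hyper").  The
environment rewards a prediction with two terms: a +-1 correctness
term, and a confidence term that is the sigmoid of the reciprocal
distance between the (softmax-normalised) action scores and the
one-hot truth, which lies in (0.5, 1].

Experience is held in *two* FIFO buffers keyed by whether the
prediction was correct; training alternates between them, sampling
within a buffer by a softmax over absolute TD errors so that poorly
fitted transitions are replayed more often.  The TD error ("gap") of a
transition is the standard Bellman residual
``r + y * max_a' Q_target(s', a') - Q(s, a)`` with no bootstrap term on
terminal transitions; the training loss is the mean squared gap of the
sampled batch.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import deque

import numpy as np

from ._nn import MLP, Adam

__all__ = [
    "ACTION_IS_HYPER",
    "ACTION_NO_HYPER",
    "QOutputs",
    "Transition",
    "DualReplayBuffer",
    "AgentConfig",
    "RiskAgent",
    "select_action",
    "compute_reward",
    "td_gap",
    "sampling_probabilities",
    "push_transition",
]

ACTION_IS_HYPER = 1
ACTION_NO_HYPER = 0


def _sigmoid(x: float) -> float:
    # overflow-safe scalar sigmoid
    if x >= 0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@dataclasses.dataclass(frozen=True)
class QOutputs:
    """Scores of the two actions: ``left`` for is_hyper, ``right`` for
    no_hyper."""

    left: float
    right: float

    def __post_init__(self):
        if not (np.isfinite(self.left) and np.isfinite(self.right)):
            raise ValueError("non-finite Q outputs")

    def normalized(self) -> "QOutputs":
        """Softmax over the two actions, yielding probabilities."""
        m = max(self.left, self.right)
        el = np.exp(self.left - m)
        er = np.exp(self.right - m)
        z = el + er
        return QOutputs(float(el / z), float(er / z))


@dataclasses.dataclass
class Transition:
    """One experience tuple.

    ``state``/``next_state`` are either full state vectors or, when
    ``is_feature`` is set, latent features produced by the generative
    replay module (those are always single-step/terminal).  ``gap`` is
    the lazily refreshed TD-error priority.
    """

    state: np.ndarray
    action: int
    reward: float
    next_state: np.ndarray | None
    terminal: bool
    correct: bool
    is_feature: bool = False
    gap: float = 0.0


class DualReplayBuffer:
    """Two bounded FIFO stores keyed by prediction correctness.

    The phi schedule alternates which buffer feeds each training step
    ((phi1, phi2) = (1,0) or (0,1)); when the scheduled buffer is empty
    the other one is used.
    """

    def __init__(self, capacity: int = 10_000):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self.correct_buffer: deque = deque(maxlen=capacity)
        self.incorrect_buffer: deque = deque(maxlen=capacity)

    def __len__(self):
        return len(self.correct_buffer) + len(self.incorrect_buffer)

    def push(self, tr: Transition) -> None:
        (self.correct_buffer if tr.correct else self.incorrect_buffer).append(tr)

    def scheduled_buffer(self, step: int):
        """Strict alternation: even steps draw from the correct buffer,
        odd steps from the incorrect one, falling back when empty.

        Returns (name, deque) or (None, None) when both are empty.
        """
        order = (["correct", "incorrect"] if step % 2 == 0
                 else ["incorrect", "correct"])
        for name in order:
            buf = self.correct_buffer if name == "correct" else self.incorrect_buffer
            if len(buf) > 0:
                return name, buf
        return None, None


def push_transition(buf: DualReplayBuffer, tr: Transition) -> DualReplayBuffer:
    buf.push(tr)
    return buf


@dataclasses.dataclass
class AgentConfig:
    """Agent hyperparameters (all seeded and config-exposed)."""

    discount: float = 0.9
    epsilon_start: float = 0.5
    epsilon_end: float = 0.01
    learning_rate: float = 1e-3
    batch_size: int = 32
    target_sync_period: int = 100
    buffer_capacity: int = 10_000
    #: steps between full-buffer priority recomputations; the sampled
    #: batch's priorities are refreshed every step regardless
    priority_refresh_period: int = 25
    reward_epsilon: float = 1e-6
    feature_dim: int = 32
    extractor_hidden: int = 64
    head_hidden: int = 32
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.discount < 1.0:
            raise ValueError("discount must lie in [0, 1)")
        if self.reward_epsilon <= 0:
            raise ValueError("reward_epsilon must be > 0")
        for f in ("learning_rate", "batch_size", "target_sync_period",
                  "buffer_capacity", "feature_dim"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be > 0")


# --------------------------------------------------------------------------
# Pure operations
# --------------------------------------------------------------------------

def select_action(state, qnet, epsilon: float, rng) -> tuple:
    """Epsilon-greedy action from the Q-network's two scores.

    Greedy: the action with the larger score, ties broken toward
    ``no_hyper``.  Returns (action, softmax-normalised QOutputs).
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    q = qnet.q_outputs(state)
    probs = q.normalized()
    if epsilon > 0 and rng.random() < epsilon:
        action = int(rng.integers(0, 2))
    else:
        action = ACTION_IS_HYPER if q.left > q.right else ACTION_NO_HYPER
    return action, probs


def compute_reward(action: int, label: int, q: QOutputs,
                   epsilon_r: float = 1e-6) -> tuple:
    """Two-part reward.

    ``reward1`` is +1 for a correct prediction and -1 otherwise.
    ``reward2`` is sigmoid(1 / (D + eps)) where D is half the squared
    Euclidean distance between (left, right) probabilities and the
    one-hot truth; it rewards confident correct scores and lies in
    (0.5, 1].  Returns (reward1, reward2, total).
    """
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    if epsilon_r <= 0:
        raise ValueError("epsilon_r must be > 0")
    reward1 = 1.0 if action == label else -1.0
    is_hyper = float(label)
    no_hyper = 1.0 - is_hyper
    D = ((q.left - is_hyper) ** 2 + (q.right - no_hyper) ** 2) / 2.0
    reward2 = _sigmoid(1.0 / (D + epsilon_r))
    return reward1, reward2, reward1 + reward2


def sampling_probabilities(gaps) -> np.ndarray:
    """Softmax over priorities, with max-subtraction for overflow safety."""
    gaps = np.asarray(gaps, dtype=float)
    if gaps.size == 0:
        raise ValueError("empty priority list")
    if not np.all(np.isfinite(gaps)):
        raise ValueError("non-finite priorities")
    e = np.exp(gaps - gaps.max())
    return e / e.sum()


def td_gap(tr: Transition, qnet, target_net, discount: float) -> float:
    """Bellman residual of one transition (bootstrap dropped if terminal)."""
    q_sa = qnet.q_value(tr.state, tr.action, is_feature=tr.is_feature)
    if tr.terminal or tr.next_state is None:
        target = tr.reward
    else:
        nxt = target_net.q_outputs(tr.next_state, is_feature=tr.is_feature)
        target = tr.reward + discount * max(nxt.left, nxt.right)
    return float(target - q_sa)


# --------------------------------------------------------------------------
# The agent
# --------------------------------------------------------------------------

class _QNetwork:
    """Feature extractor + Q head; features may bypass the extractor."""

    def __init__(self, extractor: MLP, head: MLP):
        self.extractor = extractor
        self.head = head

    def clone(self) -> "_QNetwork":
        return _QNetwork(self.extractor.clone(), self.head.clone())

    def copy_from(self, other: "_QNetwork") -> None:
        self.extractor.copy_from(other.extractor)
        self.head.copy_from(other.head)

    def q_outputs(self, x, is_feature: bool = False) -> QOutputs:
        x = np.asarray(x, dtype=float)
        lat = x[None, :] if is_feature else self.extractor.forward(x[None, :])
        q = self.head.forward(lat)[0]
        return QOutputs(float(q[0]), float(q[1]))

    def q_value(self, x, action: int, is_feature: bool = False) -> float:
        q = self.q_outputs(x, is_feature=is_feature)
        return q.left if action == ACTION_IS_HYPER else q.right


class RiskAgent:
    """DQN agent with dual prioritized experience replay.

    Owns the feature extractor, Q head, their frozen target copies, the
    dual buffer and the optimizers.  ``state_dim`` is the 2d state
    length; the latent feature dimension is ``cfg.feature_dim``.
    """

    def __init__(self, state_dim: int, cfg: AgentConfig):
        cfg.validate()
        self.cfg = cfg
        self.state_dim = state_dim
        rng = np.random.default_rng(cfg.seed)
        extractor = MLP([state_dim, cfg.extractor_hidden, cfg.feature_dim],
                        ["relu", "linear"], rng)
        head = MLP([cfg.feature_dim, cfg.head_hidden, 2], ["relu", "linear"], rng)
        self.qnet = _QNetwork(extractor, head)
        self.target = self.qnet.clone()
        self.opt_extractor = Adam(extractor, lr=cfg.learning_rate)
        self.opt_head = Adam(head, lr=cfg.learning_rate)
        self.buffer = DualReplayBuffer(cfg.buffer_capacity)
        self.train_steps = 0
        self.last_buffer_used: str | None = None

    # -- inference ----------------------------------------------------------

    def features(self, states: np.ndarray) -> np.ndarray:
        return self.qnet.extractor.forward(np.atleast_2d(states))

    def q_outputs(self, state, is_feature: bool = False) -> QOutputs:
        return self.qnet.q_outputs(state, is_feature=is_feature)

    def predict(self, state, is_feature: bool = False) -> tuple:
        """Greedy action and normalised scores (no exploration)."""
        q = self.qnet.q_outputs(state, is_feature=is_feature)
        action = ACTION_IS_HYPER if q.left > q.right else ACTION_NO_HYPER
        return action, q.normalized()

    def select_action(self, state, epsilon: float, rng,
                      is_feature: bool = False) -> tuple:
        if not 0.0 <= epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        q = self.qnet.q_outputs(state, is_feature=is_feature)
        if epsilon > 0 and rng.random() < epsilon:
            action = int(rng.integers(0, 2))
        else:
            action = ACTION_IS_HYPER if q.left > q.right else ACTION_NO_HYPER
        return action, q.normalized()

    # -- experience ---------------------------------------------------------

    def observe(self, tr: Transition) -> None:
        self.buffer.push(tr)

    # -- training -----------------------------------------------------------

    def _batch_q(self, transitions, net: _QNetwork, use_next: bool):
        """Vectorised [left, right] scores for a transition batch.

        With ``use_next`` the next-state scores are computed (terminal
        rows yield zeros).  Latent-feature rows bypass the extractor.
        """
        n = len(transitions)
        out = np.zeros((n, 2))
        real_idx = [i for i, t in enumerate(transitions) if not t.is_feature]
        feat_idx = [i for i, t in enumerate(transitions) if t.is_feature]
        if use_next:
            real_idx = [i for i in real_idx
                        if not transitions[i].terminal
                        and transitions[i].next_state is not None]
            feat_idx = [i for i in feat_idx
                        if not transitions[i].terminal
                        and transitions[i].next_state is not None]
        key = "next_state" if use_next else "state"
        if real_idx:
            X = np.stack([getattr(transitions[i], key) for i in real_idx])
            out[real_idx] = net.head.forward(net.extractor.forward(X))
        if feat_idx:
            X = np.stack([getattr(transitions[i], key) for i in feat_idx])
            out[feat_idx] = net.head.forward(X)
        return out

    def refresh_gaps(self, transitions) -> np.ndarray:
        """Recompute and store TD-error priorities for a transition list."""
        if not transitions:
            return np.zeros(0)
        q_now = self._batch_q(transitions, self.qnet, use_next=False)
        q_next = self._batch_q(transitions, self.target, use_next=True)
        gaps = np.zeros(len(transitions))
        for i, t in enumerate(transitions):
            boot = 0.0
            if not t.terminal and t.next_state is not None:
                boot = self.cfg.discount * q_next[i].max()
            q_sa = q_now[i, 0] if t.action == ACTION_IS_HYPER else q_now[i, 1]
            gaps[i] = t.reward + boot - q_sa
            t.gap = float(gaps[i])
        return gaps

    def train_step(self, rng, distill_from=None, distill_states=None,
                   distill_weight: float = 1.0):
        """One prioritized-replay gradient step; returns the batch loss.

        Optionally adds a feature-distillation term: ``distill_from`` is
        a frozen extractor and ``distill_states`` the real states on
        which the new extractor is pulled toward it.
        """
        name, buf = self.buffer.scheduled_buffer(self.train_steps)
        if name is None:
            warnings.warn("both replay buffers empty; skipping train step")
            return None
        self.last_buffer_used = name
        transitions = list(buf)
        if self.train_steps % self.cfg.priority_refresh_period == 0:
            gaps = self.refresh_gaps(transitions)
        else:
            gaps = np.array([t.gap for t in transitions])
        probs = sampling_probabilities(np.abs(gaps))
        k = min(self.cfg.batch_size, len(transitions))
        idx = rng.choice(len(transitions), size=k, replace=True, p=probs)
        batch = [transitions[i] for i in idx]

        # forward with caches: extractor on real rows, head on all rows
        real_rows = [i for i, t in enumerate(batch) if not t.is_feature]
        feat_rows = [i for i, t in enumerate(batch) if t.is_feature]
        latents = np.zeros((k, self.cfg.feature_dim))
        fcache = None
        if real_rows:
            Xr = np.stack([batch[i].state for i in real_rows])
            lat_r, fcache = self.qnet.extractor.forward_cache(Xr)
            latents[real_rows] = lat_r
        if feat_rows:
            latents[feat_rows] = np.stack([batch[i].state for i in feat_rows])
        q, hcache = self.qnet.head.forward_cache(latents)

        # TD targets from the frozen target network
        q_next = self._batch_q(batch, self.target, use_next=True)
        gap_b = np.zeros(k)
        dq = np.zeros((k, 2))
        for i, t in enumerate(batch):
            boot = 0.0
            if not t.terminal and t.next_state is not None:
                boot = self.cfg.discount * q_next[i].max()
            col = 0 if t.action == ACTION_IS_HYPER else 1
            gap_b[i] = t.reward + boot - q[i, col]
            t.gap = float(gap_b[i])
            dq[i, col] = -2.0 * gap_b[i] / k
        loss = float(np.mean(gap_b ** 2))

        dlat, head_grads = self.qnet.head.backward(hcache, dq)
        self.opt_head.step(head_grads)
        if real_rows:
            _, ext_grads = self.qnet.extractor.backward(fcache, dlat[real_rows])
            if distill_from is not None and distill_states is not None \
                    and len(distill_states) > 0:
                dist_grads = _distillation_grads(
                    self.qnet.extractor, distill_from, distill_states,
                    distill_weight)
                ext_grads = [(gW + dW, gb + db) for (gW, gb), (dW, db)
                             in zip(ext_grads, dist_grads)]
            self.opt_extractor.step(ext_grads)

        self.train_steps += 1
        if self.train_steps % self.cfg.target_sync_period == 0:
            self.target.copy_from(self.qnet)
        return loss


def _distillation_grads(f_new: MLP, f_old: MLP, states: np.ndarray,
                        weight: float):
    """Gradients of weight * mean ||F_new(s) - F_old(s)||^2 w.r.t. F_new."""
    X = np.atleast_2d(np.asarray(states, dtype=float))
    out_new, cache = f_new.forward_cache(X)
    out_old = f_old.forward(X)
    diff = out_new - out_old
    dY = weight * 2.0 * diff / X.shape[0]
    _, grads = f_new.backward(cache, dY)
    return grads
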