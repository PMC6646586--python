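"""Natural actor-critic with advantage parameters.

One linear critic estimates the state value from the sparse-coding feature
vector; three independent softmax actors (pan, tilt, vergence) map the same
state to discrete actions.  The reward is the negative reconstruction error
of the sparse coders.  Because an action needs two iterations to fully
influence the state representation, updates at time t credit the pair
(s_{t-2}, a_{t-2}) with the reward r_t:

    delta_t = r_t - J_t + gamma * V(s_t) - V(s_{t-2})
    J_t     = (1 - xi) * J_{t-1} + xi * r_t          (average-reward filter)
    theta_V += alpha * delta_t * s_{t-2}

Each actor follows the natural policy gradient approximated through
advantage parameters w (no explicit Fisher matrix):

    zeta = grad_theta log pi(a_{t-2} | s_{t-2})
    w     += beta * (delta_t * zeta - zeta * <zeta, w>)
    theta += eta * w
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ACTIONS_STD", "ACTIONS_CAS", "Critic", "Actor", "Agent",
    "critic_value", "td_error", "update_avg_reward", "update_critic",
    "policy", "nac_update", "greedy_action", "sample_action",
]

# pan/tilt entries are accelerations (deg/s^2); vergence entries are angle
# increments (deg)
ACTIONS_STD = (-16.0, -8.0, -4.0, -2.0, -1.0, -0.5, 0.0,
               0.5, 1.0, 2.0, 4.0, 8.0, 16.0)
# coarse action set: the fine +-0.5 actions removed
ACTIONS_CAS = (-16.0, -8.0, -4.0, -2.0, -1.0, 0.0, 1.0, 2.0, 4.0, 8.0, 16.0)

GAMMA = 0.3
ALPHA_CRITIC = 0.4
XI_AVG_REWARD = 0.01
BETA_NATGRAD = 0.16
ETA_ACTOR = 0.4
TEMPERATURE = 1.0


@dataclass
class Critic:
    theta: np.ndarray
    j_hat: float = 0.0
    gamma: float = GAMMA
    alpha: float = ALPHA_CRITIC
    xi: float = XI_AVG_REWARD

    @classmethod
    def zeros(cls, state_dim: int, **kw) -> "Critic":
        return cls(theta=np.zeros(state_dim), **kw)


@dataclass
class Actor:
    theta: np.ndarray                  # (|A|, |s|)
    w: np.ndarray                      # advantage parameters, same shape
    actions: tuple[float, ...] = ACTIONS_STD
    temperature: float = TEMPERATURE
    beta: float = BETA_NATGRAD
    eta: float = ETA_ACTOR

    @classmethod
    def zeros(cls, state_dim: int, actions: tuple[float, ...] = ACTIONS_STD,
              **kw) -> "Actor":
        n = len(actions)
        return cls(theta=np.zeros((n, state_dim)),
                   w=np.zeros((n, state_dim)), actions=actions, **kw)


def critic_value(theta: np.ndarray, s: np.ndarray) -> float:
    if theta.shape != s.shape:
        raise ValueError("critic weight / state dimension mismatch")
    return float(theta @ s)


def td_error(r_t: float, j_hat: float, v_now: float, v_prev2: float,
             gamma: float = GAMMA) -> float:
    """delta = r - J + gamma * V(s_t) - V(s_{t-2})."""
    return r_t - j_hat + gamma * v_now - v_prev2


def update_avg_reward(j_hat: float, r_t: float,
                      xi: float = XI_AVG_REWARD) -> float:
    return (1.0 - xi) * j_hat + xi * r_t


def update_critic(theta: np.ndarray, delta: float, s_prev2: np.ndarray,
                  alpha: float = ALPHA_CRITIC) -> np.ndarray:
    return theta + alpha * delta * s_prev2


def policy(actor: Actor, s: np.ndarray) -> np.ndarray:
    """Softmax over action activations z_a = <theta_a, s>, max-stabilized."""
    z = (actor.theta @ s) / actor.temperature
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def nac_update(actor: Actor, delta: float, s_prev2: np.ndarray,
               a_prev2: int) -> None:
    """Advantage-parameter natural-gradient step for one actor (in place).

    ``a_prev2`` is the index of the action taken two steps ago.  For the
    softmax-linear policy the score is
    zeta[a, i] = (1[a == a_prev2] - pi_a) * s_i.
    """
    pi = policy(actor, s_prev2)
    coeff = -pi
    coeff[a_prev2] += 1.0
    zeta = np.outer(coeff, s_prev2)
    zw = float(np.vdot(zeta, actor.w))
    actor.w += actor.beta * (delta * zeta - zeta * zw)
    actor.theta += actor.eta * actor.w


def sample_action(actor: Actor, s: np.ndarray,
                  rng: np.random.Generator) -> int:
    return int(rng.choice(len(actor.actions), p=policy(actor, s)))


def greedy_action(actor: Actor, s: np.ndarray) -> int:
    """Argmax activation; exact ties resolved toward the smallest-magnitude
    action (so an untrained actor holds still)."""
    z = actor.theta @ s
    best = np.flatnonzero(z == z.max())
    mags = np.abs(np.asarray(actor.actions)[best])
    return int(best[np.argmin(mags)])


@dataclass
class Agent:
    """One critic plus pan/tilt/vergence actors with two-step delayed credit.

    The transition buffer keeps the last two (state, action-index-triple)
    pairs; an update at time t consumes (s_{t-2}, a_{t-2}) together with
    the fresh reward r_t.  After an episode reset the buffer is empty, so
    the first two iterations perform no updates.
    """

    critic: Critic
    actors: dict[str, Actor]
    buffer: deque = field(default_factory=lambda: deque(maxlen=2))
    iteration: int = 0

    JOINTS = ("pan", "tilt", "vergence")

    @classmethod
    def zeros(cls, state_dim: int,
              actions: tuple[float, ...] = ACTIONS_STD) -> "Agent":
        return cls(critic=Critic.zeros(state_dim),
                   actors={j: Actor.zeros(state_dim, actions)
                           for j in cls.JOINTS})

    def reset_episode(self) -> None:
        self.buffer.clear()

    def update(self, s_t: np.ndarray, r_t: float) -> float | None:
        """Run the critic/actor updates for reward r_t at state s_t.
        Returns the TD error, or None while the buffer is still filling."""
        self.critic.j_hat = update_avg_reward(self.critic.j_hat, r_t,
                                              self.critic.xi)
        if len(self.buffer) < 2:
            return None
        s_prev2, a_prev2 = self.buffer[0]
        v_now = critic_value(self.critic.theta, s_t)
        v_prev2 = critic_value(self.critic.theta, s_prev2)
        delta = td_error(r_t, self.critic.j_hat, v_now, v_prev2,
                         self.critic.gamma)
        self.critic.theta = update_critic(self.critic.theta, delta, s_prev2,
                                          self.critic.alpha)
        for joint in self.JOINTS:
            nac_update(self.actors[joint], delta, s_prev2, a_prev2[joint])
        return delta

    def act(self, s: np.ndarray, mode: str = "sample",
            rng: np.random.Generator | None = None) -> dict[str, float]:
        """Choose one action per joint and push (s, actions) on the buffer.

        ``mode``: 'sample' draws from each softmax policy, 'greedy' takes
        the argmax activation, 'random' draws uniformly (the random-action
        control condition).
        """
        indices: dict[str, int] = {}
        for joint in self.JOINTS:
            actor = self.actors[joint]
            if mode == "sample":
                if rng is None:
                    raise ValueError("sample mode requires an rng")
                indices[joint] = sample_action(actor, s, rng)
            elif mode == "greedy":
                indices[joint] = greedy_action(actor, s)
            elif mode == "random":
                if rng is None:
                    raise ValueError("random mode requires an rng")
                indices[joint] = int(rng.integers(len(actor.actions)))
            else:
                raise ValueError(f"unknown mode {mode!r}")
        self.buffer.append((np.array(s, copy=True), indices))
        self.iteration += 1
        return {j: self.actors[j].actions[i] for j, i in indices.items()}
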