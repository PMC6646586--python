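"""Shared independent oracles used across the test suite.

These deliberately avoid the library code paths they are used to check:
disparity is measured by image cross-correlation, spectral slope by a
direct least-squares fit on the radially averaged spectrum, and the
contextual bandit drives the actor-critic updates directly.
"""

from __future__ import annotations

import numpy as np

from aecvision.rl import (ACTIONS_STD, Actor, Critic, critic_value,
                          greedy_action, nac_update, sample_action,
                          td_error, update_avg_reward, update_critic)


def measure_disparity(left: np.ndarray, right: np.ndarray,
                      half: int = 16, search: int = 40) -> float:
    """Horizontal disparity u_left - u_right of the image center, by
    cross-correlating a central patch of the left image against the right
    image with sub-pixel (parabolic) peak refinement."""
    h, w = left.shape
    r0, c0 = h // 2, w // 2
    patch = left[r0 - half:r0 + half, c0 - half:c0 + half]
    patch = patch - patch.mean()
    band = right[r0 - half:r0 + half]
    shifts = np.arange(-search, search + 1)
    scores = np.full(len(shifts), -np.inf)
    for i, k in enumerate(shifts):
        lo, hi = c0 - half + k, c0 + half + k
        if lo < 0 or hi > w:
            continue
        cand = band[:, lo:hi]
        cand = cand - cand.mean()
        denom = np.linalg.norm(cand) * np.linalg.norm(patch)
        if denom > 0:
            scores[i] = float(np.sum(cand * patch)) / denom
    best = int(np.argmax(scores))
    k = float(shifts[best])
    if 0 < best < len(shifts) - 1 and np.isfinite(scores[best - 1]) \
            and np.isfinite(scores[best + 1]):
        y0, y1, y2 = scores[best - 1], scores[best], scores[best + 1]
        denom = y0 - 2 * y1 + y2
        if abs(denom) > 1e-12:
            k += 0.5 * (y0 - y2) / denom
    return -k  # content shifted by +k in the right image means u_L - u_R = -k


def spectral_slope(pixels: np.ndarray) -> float:
    """Slope of log radially-averaged amplitude vs log frequency over mid
    frequencies, by least squares."""
    side = pixels.shape[0]
    spec = np.abs(np.fft.fft2(pixels - pixels.mean()))
    fy = np.fft.fftfreq(side)[:, None]
    fx = np.fft.fftfreq(side)[None, :]
    f = np.hypot(fx, fy).ravel()
    a = spec.ravel()
    # mid band: away from DC and from the Nyquist corner
    mask = (f > 0.01) & (f < 0.2)
    bins = np.logspace(np.log10(0.01), np.log10(0.2), 25)
    idx = np.digitize(f[mask], bins)
    logf, loga = [], []
    for b in range(1, len(bins)):
        sel = idx == b
        if sel.sum() > 0:
            logf.append(np.log(np.sqrt(bins[b - 1] * bins[b])))
            loga.append(np.log(a[mask][sel].mean()))
    slope = np.polyfit(logf, loga, 1)[0]
    return float(slope)


def run_contextual_bandit(seed: int, steps: int = 50_000,
                          state_gain: float = 0.02,
                          reward_scale: float = 1.0 / 16.0,
                          ) -> tuple[int, int]:
    """Contextual-bandit convergence oracle for the natural actor-critic.

    States are one-hot indicators of the true tracking-error bin (one bin
    per action value, scaled to the magnitude regime the deployed state
    vector lives in), the reward is the negative residual error
    -|error + action| normalized by the largest action.  Returns
    (number of states whose greedy action exactly cancels the error,
    number of states)."""
    rng = np.random.default_rng(seed)
    actions = ACTIONS_STD
    errors = [-a for a in actions]
    n = len(errors)
    actor = Actor.zeros(n, actions)
    critic = Critic.zeros(n)
    for _ in range(steps):
        i = int(rng.integers(n))
        s = np.zeros(n)
        s[i] = state_gain
        a_idx = sample_action(actor, s, rng)
        r = -abs(errors[i] + actions[a_idx]) * reward_scale
        critic.j_hat = update_avg_reward(critic.j_hat, r, critic.xi)
        v = critic_value(critic.theta, s)
        delta = td_error(r, critic.j_hat, v, v, critic.gamma)
        critic.theta = update_critic(critic.theta, delta, s, critic.alpha)
        nac_update(actor, delta, s, a_idx)
    correct = 0
    for i in range(n):
        s = np.zeros(n)
        s[i] = state_gain
        correct += actions[greedy_action(actor, s)] == -errors[i]
    return correct, n
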