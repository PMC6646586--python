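"""Training and testing orchestration for the active efficient coding agent.

The perception-action cycle per 100 ms iteration: render the binocular view,
whiten and cut spatio-temporal patches at both scales, sparse-code them,
take the negative total reconstruction error as the intrinsic reward, update
the reinforcement learner with two-step delayed credit, pick one action per
joint, move the eyes, move the world.  Training is organized in 40-iteration
episodes; at each episode start a fresh stimulus is placed at a random depth
with random constant velocities and the gaze is reset to a random fixation
distance.

Testing freezes all learning, switches the actors to their greedy policy and
sweeps a grid of stimuli x velocity combinations, recording the pursuit
errors (object vs. eye angular speed, deg/iteration) and the vergence error
(actual minus ideal vergence angle, deg) at the end of each 10-iteration
trial.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from aecvision import environment as env
from aecvision import sparse_coding as sc
from aecvision.environment import (EpisodeAbort, EyePose, RenderConfig,
                                   WorldState)
from aecvision.preprocessing import PatchPipeline
from aecvision.rl import ACTIONS_CAS, ACTIONS_STD, Agent
from aecvision.sparse_coding import Dictionary

__all__ = [
    "TrainConfig", "TestGrid", "Simulation", "OraclePolicy", "TrainRun",
    "train", "test_policy", "vergence_target", "compare_runs",
    "save_checkpoint", "load_checkpoint", "make_stimulus_set",
]


def vergence_target(d_object: float, d_eyes: float = 0.068) -> float:
    """Ideal vergence angle xi* = 2 arctan(d_E / (2 d_O)), degrees."""
    return env.vergence_for_distance(d_object, d_eyes)


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.  Defaults are the full-scale
    experiment; :meth:`desk` is a reduced profile for laptop-scale runs."""

    total_iterations: int = 500_000
    episode_length: int = 40
    dt: float = 0.1
    n_atoms: int = 600
    action_set: str = "STD"            # STD | CAS (no +-0.5 actions)
    scales: str = "both"               # both | NFS (coarse only)
    policy: str = "learned"            # learned | RNDCTL (uniform random)
    init_mode: str = "gabor"           # gabor | white_noise
    n_stimuli: int = 100
    texture_side: int = 600
    n_checkpoints: int = 10
    seed: int = 0

    @classmethod
    def desk(cls, **overrides) -> "TrainConfig":
        base = dict(total_iterations=50_000, n_atoms=200, n_stimuli=10)
        base.update(overrides)
        return cls(**base)

    def actions(self) -> tuple[float, ...]:
        return ACTIONS_STD if self.action_set == "STD" else ACTIONS_CAS

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        import yaml

        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class TestGrid:
    """The testing protocol: every combination of stimulus and velocity
    multiplier per axis, n_stimuli * 6^3 trials (10,800 by default)."""

    n_stimuli: int = 50
    multipliers: tuple[float, ...] = (-1.0, -0.5, -0.1, 0.1, 0.5, 1.0)
    trial_length: int = 10

    @property
    def n_trials(self) -> int:
        return self.n_stimuli * len(self.multipliers) ** 3

    def trials(self):
        yield from product(range(self.n_stimuli), self.multipliers,
                           self.multipliers, self.multipliers)


def make_stimulus_set(n: int, seed: int, side: int = 600) -> list[env.Texture]:
    """Procedural stand-in for a natural-image stimulus set: a cycle of
    pink-noise, edge and block textures (1/f spectra plus oriented structure
    with cardinal orientations over-represented, as in man-made scenes)."""
    kinds = ("pink_noise", "edges", "blocks")
    return [env.make_texture(seed * 7919 + i, kinds[i % len(kinds)], side)
            for i in range(n)]


class OraclePolicy:
    """Hand-coded perfect-tracking policy for validation: picks, per joint,
    the admissible action closest to the one that would cancel the current
    tracking/vergence error.  Reads the ground-truth world state, which the
    learned agent never sees."""

    def __init__(self, actions: tuple[float, ...] = ACTIONS_STD,
                 dt: float = 0.1) -> None:
        self.actions = np.asarray(actions)
        self.dt = dt

    def _closest(self, target: float) -> float:
        return float(self.actions[np.argmin(np.abs(self.actions - target))])

    def __call__(self, world: WorldState, eyes: EyePose) -> dict[str, float]:
        v_h, v_v, v_z = world.stimulus_velocity
        depth_next = world.stimulus_center[2] + v_z * self.dt
        want_verg = vergence_target(max(depth_next, 0.1), eyes.baseline)
        return {
            "pan": self._closest((v_h - eyes.pan_vel) / self.dt),
            "tilt": self._closest((v_v - eyes.tilt_vel) / self.dt),
            "vergence": self._closest(want_verg - eyes.vergence),
        }


class Simulation:
    """Owns the world, the eyes, the preprocessing state and the sparse
    coders, and advances the perception-action cycle one iteration at a
    time."""

    def __init__(self, config: TrainConfig, textures: list[env.Texture],
                 dict_coarse: Dictionary, dict_fine: Dictionary | None,
                 agent: Agent, seed: int,
                 render_cfg: RenderConfig = RenderConfig()) -> None:
        self.cfg = config
        self.textures = textures
        self.dict_c = dict_coarse
        self.dict_f = dict_fine
        self.agent = agent
        self.rng = np.random.default_rng(seed)
        self.render_cfg = render_cfg
        self.pipeline = PatchPipeline()
        background = env.make_texture(seed=981_234, kind="pink_noise",
                                      side=512)
        self.world = WorldState(stimulus_texture=textures[0],
                                stimulus_center=np.array([0.0, 0.0, 1.5]),
                                background_texture=background)
        self.eyes = EyePose()
        self.iteration = 0
        self.episode = 0

    # -- episode management -------------------------------------------------

    def begin_episode(self, texture_index: int | None = None,
                      depth: float | None = None,
                      velocities: tuple[float, float, float] | None = None,
                      fixation_distance: float | None = None) -> None:
        """Place a stimulus and reset the gaze; explicit arguments override
        the random draws (used by the testing protocol)."""
        if texture_index is None:
            texture_index = int(self.rng.integers(len(self.textures)))
        tex = self.textures[texture_index]
        self.world = dataclasses.replace(self.world, stimulus_texture=tex)
        self.world = env.place_stimulus(self.world, self.rng)
        if depth is not None:
            c = self.world.stimulus_center.copy()
            c[2] = depth
            self.world = dataclasses.replace(self.world, stimulus_center=c)
        if velocities is not None:
            self.world = dataclasses.replace(self.world,
                                             stimulus_velocity=velocities)
        self.eyes = env.reset_gaze(self.eyes, self.rng)
        if fixation_distance is not None:
            verg = float(np.clip(
                vergence_target(fixation_distance, self.eyes.baseline),
                *env.VERGENCE_RANGE_DEG))
            self.eyes = dataclasses.replace(self.eyes, vergence=verg)
        self.agent.reset_episode()
        self.pipeline.reset()
        self.episode += 1

    # -- one perception-action cycle ---------------------------------------

    def iterate(self, learn_coding: bool = True, learn_rl: bool = True,
                mode: str = "sample",
                policy_fn=None, encode: bool = True) -> dict[str, float]:
        """Run one iteration and return a log record.  ``policy_fn``
        (a callable (world, eyes) -> action dict) bypasses the agent's
        actors, e.g. for the tracking oracle; with ``encode=False`` the
        sparse-coding stage is skipped entirely (only sensible together
        with a policy_fn and learning off)."""
        frame = env.render_binocular(self.world, self.eyes, self.render_cfg,
                                     timestamp=self.iteration)
        if not encode:
            if policy_fn is None or learn_coding or learn_rl:
                raise ValueError("encode=False requires a policy_fn and "
                                 "learning switched off")
            e_c = e_f = reward = float("nan")
            code_c = code_f = None
            s = None
            patchsets = None
        else:
            patchsets = self.pipeline(frame.left, frame.right)
            code_c = sc.matching_pursuit(patchsets["coarse"].flat,
                                         self.dict_c)
            e_c = sc.reconstruction_error(patchsets["coarse"].flat, code_c,
                                          self.dict_c)
            if self.dict_f is not None:
                code_f = sc.matching_pursuit(patchsets["fine"].flat,
                                             self.dict_f)
                e_f = sc.reconstruction_error(patchsets["fine"].flat, code_f,
                                              self.dict_f)
            else:
                code_f, e_f = None, 0.0
            reward = -(e_c + e_f)
            if not math.isfinite(reward):
                raise FloatingPointError("non-finite reward")
            s = sc.state_vector(code_c, code_f)
        if encode and learn_coding:
            sc.update_dictionary(self.dict_c, patchsets["coarse"].flat, code_c)
            if self.dict_f is not None:
                sc.update_dictionary(self.dict_f, patchsets["fine"].flat,
                                     code_f)
        if encode and learn_rl:
            self.agent.update(s, reward)
        if policy_fn is not None:
            actions = policy_fn(self.world, self.eyes)
        else:
            actions = self.agent.act(s, mode=mode, rng=self.rng)
        self.eyes, limit = env.apply_eye_command(
            self.eyes, actions["pan"], actions["tilt"], actions["vergence"],
            self.cfg.dt)
        if limit:
            # zero the joint velocities and re-fixate, like the robot would
            self.eyes = env.reset_gaze(self.eyes, self.rng)
            self.agent.reset_episode()
            self.pipeline.reset()
        try:
            self.world = env.step_world(self.world, self.cfg.dt)
        except EpisodeAbort:
            self.begin_episode()
        self.iteration += 1
        return {
            "iteration": self.iteration, "episode": self.episode,
            "E_c": e_c, "E_f": e_f, "reward": reward,
            "a_pan": actions["pan"], "a_tilt": actions["tilt"],
            "a_verg": actions["vergence"],
            "pan": self.eyes.pan, "tilt": self.eyes.tilt,
            "pan_vel": self.eyes.pan_vel, "tilt_vel": self.eyes.tilt_vel,
            "vergence": self.eyes.vergence,
            "limit": bool(limit),
            "stimulus_visible": frame.stimulus_visible,
        }


@dataclass
class TrainRun:
    config: TrainConfig
    dict_coarse: Dictionary
    dict_fine: Dictionary | None
    agent: Agent
    log: pd.DataFrame
    checkpoints: list[Path] = field(default_factory=list)


def _build(config: TrainConfig, seed: int
           ) -> tuple[list[env.Texture], Dictionary, Dictionary | None, Agent]:
    textures = make_stimulus_set(config.n_stimuli, seed,
                                 config.texture_side)
    dict_c = sc.init_dictionary(config.n_atoms, seed * 2 + 1,
                                mode=config.init_mode, scale="coarse")
    if config.scales == "NFS":
        dict_f = None
        state_dim = config.n_atoms
    else:
        dict_f = sc.init_dictionary(config.n_atoms, seed * 2 + 2,
                                    mode=config.init_mode, scale="fine")
        state_dim = 2 * config.n_atoms
    agent = Agent.zeros(state_dim, config.actions())
    return textures, dict_c, dict_f, agent


def train(config: TrainConfig, seed: int | None = None,
          out_dir: str | Path | None = None,
          progress: bool = False) -> TrainRun:
    """Run a full training experiment and return the learned artifacts.

    With ``out_dir`` set, checkpoints are written at ``n_checkpoints``
    evenly spaced points (including the final iteration) and the scalar log
    is saved as CSV.
    """
    seed = config.seed if seed is None else seed
    textures, dict_c, dict_f, agent = _build(config, seed)
    sim = Simulation(config, textures, dict_c, dict_f, agent, seed)
    mode = "random" if config.policy == "RNDCTL" else "sample"
    learn_rl = config.policy != "RNDCTL"
    ckpt_at = set(np.linspace(config.total_iterations / config.n_checkpoints,
                              config.total_iterations,
                              config.n_checkpoints).astype(int))
    records: list[dict] = []
    checkpoints: list[Path] = []
    iterator = range(config.total_iterations)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="train")
    for i in iterator:
        if i % config.episode_length == 0:
            sim.begin_episode()
        records.append(sim.iterate(learn_coding=True, learn_rl=learn_rl,
                                   mode=mode))
        if out_dir is not None and (i + 1) in ckpt_at:
            path = Path(out_dir) / f"checkpoint_{i + 1:07d}.npz"
            save_checkpoint(path, config, dict_c, dict_f, agent)
            checkpoints.append(path)
    log = pd.DataFrame.from_records(records)
    if out_dir is not None:
        log.to_csv(Path(out_dir) / "train_log.csv", index=False)
    return TrainRun(config=config, dict_coarse=dict_c, dict_fine=dict_f,
                    agent=agent, log=log, checkpoints=checkpoints)


def test_policy(dict_coarse: Dictionary, dict_fine: Dictionary | None,
                agent: Agent, grid: TestGrid, config: TrainConfig,
                seed: int = 1234,
                textures: list[env.Texture] | None = None,
                policy_fn=None, progress: bool = False) -> pd.DataFrame:
    """Evaluate a (frozen) agent on the full test grid.

    Every trial places one test stimulus at a random depth with velocities
    = multiplier x maximum per axis, runs ``trial_length`` iterations with
    learning off and the greedy policy (or ``policy_fn``), and records the
    final-iteration errors: ``dv_pan``/``dv_tilt`` in deg/iteration and
    ``dxi`` in deg.
    """
    if textures is None:
        textures = make_stimulus_set(grid.n_stimuli, seed + 555,
                                     config.texture_side)
    sim = Simulation(config, textures, dict_coarse, dict_fine, agent, seed)
    rows = []
    trials = list(grid.trials())
    if progress:
        from tqdm import tqdm

        trials = tqdm(trials, desc="test")
    for trial_idx, (stim, mh, mv, mz) in enumerate(trials):
        # per-trial rng derived from the trial index: reproducible grid
        trial_rng = np.random.default_rng((seed, trial_idx))
        depth = trial_rng.uniform(*env.DEPTH_RANGE_M)
        fixation = trial_rng.uniform(*env.FIXATION_RANGE_M)
        vels = (mh * env.MAX_ANGULAR_SPEED, mv * env.MAX_ANGULAR_SPEED,
                mz * env.MAX_DEPTH_SPEED)
        sim.begin_episode(texture_index=stim % len(textures), depth=depth,
                          velocities=vels, fixation_distance=fixation)
        for _ in range(grid.trial_length):
            sim.iterate(learn_coding=False, learn_rl=False, mode="greedy",
                        policy_fn=policy_fn, encode=policy_fn is None)
        depth_now = sim.world.stimulus_center[2]
        rows.append({
            "stimulus": stim, "v_h": vels[0], "v_v": vels[1], "v_z": vels[2],
            "dv_pan": (vels[0] - sim.eyes.pan_vel) * config.dt,
            "dv_tilt": (vels[1] - sim.eyes.tilt_vel) * config.dt,
            "dxi": sim.eyes.vergence - vergence_target(depth_now,
                                                       sim.eyes.baseline),
        })
    return pd.DataFrame(rows)


def compare_runs(errors_a: np.ndarray, errors_b: np.ndarray) -> dict:
    """Welch t-test and Cohen's d (pooled SD) between two samples of
    absolute final-iteration errors."""
    a = np.abs(np.asarray(errors_a, dtype=np.float64))
    b = np.abs(np.asarray(errors_b, dtype=np.float64))
    if a.size == 0 or b.size == 0:
        raise ValueError("empty input")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    na, nb = a.size, b.size
    pooled = math.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                       / max(na + nb - 2, 1))
    d = 0.0 if pooled == 0 else (a.mean() - b.mean()) / pooled
    return {"t": float(t), "p": float(p), "cohens_d": float(d)}


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, config: TrainConfig,
                    dict_coarse: Dictionary, dict_fine: Dictionary | None,
                    agent: Agent) -> None:
    """Write dictionaries and agent parameters to a ``.npz`` container."""
    arrays = {
        "atoms_coarse": dict_coarse.atoms,
        "critic_theta": agent.critic.theta,
        "critic_j_hat": np.array(agent.critic.j_hat),
        "iteration": np.array(agent.iteration),
        "actions": np.array(agent.actors["pan"].actions),
        "config_json": np.frombuffer(
            json.dumps(dataclasses.asdict(config)).encode(), dtype=np.uint8),
    }
    if dict_fine is not None:
        arrays["atoms_fine"] = dict_fine.atoms
    for joint in Agent.JOINTS:
        arrays[f"actor_{joint}_theta"] = agent.actors[joint].theta
        arrays[f"actor_{joint}_w"] = agent.actors[joint].w
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path: str | Path
                    ) -> tuple[TrainConfig, Dictionary, Dictionary | None,
                               Agent]:
    data = np.load(path)
    config = TrainConfig(**json.loads(bytes(data["config_json"]).decode()))
    dict_c = Dictionary(scale="coarse", atoms=data["atoms_coarse"],
                        init_mode=config.init_mode)
    dict_f = None
    if "atoms_fine" in data:
        dict_f = Dictionary(scale="fine", atoms=data["atoms_fine"],
                            init_mode=config.init_mode)
    actions = tuple(float(a) for a in data["actions"])
    agent = Agent.zeros(data["critic_theta"].shape[0], actions)
    agent.critic.theta = data["critic_theta"]
    agent.critic.j_hat = float(data["critic_j_hat"])
    agent.iteration = int(data["iteration"])
    for joint in Agent.JOINTS:
        agent.actors[joint].theta = data[f"actor_{joint}_theta"]
        agent.actors[joint].w = data[f"actor_{joint}_w"]
    return config, dict_c, dict_f, agent
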