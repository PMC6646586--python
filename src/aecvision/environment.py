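"""Virtual binocular rig: textures, world state, eye kinematics and rendering.

The environment replaces a physics-based robot simulator with an analytic
pinhole-camera renderer that reproduces the same viewing geometry: two
cameras separated by a 0.068 m baseline, each with a 90° horizontal field of
view at 320 x 240 px, looking at a textured fronto-parallel plane that
translates in 3-D in front of a distant textured background plane.

Angles are degrees throughout; distances are meters.  The world frame is
cyclopean: origin midway between the cameras, x to the agent's right,
y up, z straight ahead (depth).  Positive pan turns the gaze toward +x,
positive tilt toward +y.  Vergence is the total angle between the optical
axes, split symmetrically between the cameras.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "Texture", "WorldState", "EyePose", "ImagePair", "RenderConfig",
    "EpisodeAbort", "make_texture", "orientation_energy_histogram",
    "place_stimulus", "step_world", "apply_eye_command", "check_limits",
    "reset_gaze", "vergence_for_distance", "render_binocular",
    "project_point",
]

PAN_TILT_LIMIT_DEG = 15.0
VERGENCE_RANGE_DEG = (0.2, 16.3)
DEPTH_RANGE_M = (1.0, 2.5)
FIXATION_RANGE_M = (0.3, 3.0)
MAX_ANGULAR_SPEED = 7.5       # deg/s, horizontal and vertical
MAX_DEPTH_SPEED = 0.375       # m/s
MIN_DEPTH_M = 0.05


class EpisodeAbort(RuntimeError):
    """Raised when the stimulus plane would collide with the observer."""


# ---------------------------------------------------------------------------
# textures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Texture:
    """Square grayscale texture with values in [0, 1]."""

    pixels: np.ndarray
    kind: str
    seed: int | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError("texture must be a square 2-D array")
        if px.shape[0] < 256:
            raise ValueError("texture side must be at least 256 px")
        if not np.all(np.isfinite(px)):
            raise ValueError("texture contains non-finite values")
        object.__setattr__(self, "pixels", px)

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


def _normalize_unit_range(img: np.ndarray) -> np.ndarray:
    lo, hi = img.min(), img.max()
    if hi - lo < 1e-12:
        return np.full_like(img, 0.5)
    return (img - lo) / (hi - lo)


def _pink_noise(rng: np.random.Generator, side: int) -> np.ndarray:
    """Noise with a 1/f radial amplitude spectrum, the signature of
    natural-image second-order statistics."""
    white = rng.standard_normal((side, side))
    spec = np.fft.fft2(white)
    fy = np.fft.fftfreq(side)[:, None]
    fx = np.fft.fftfreq(side)[None, :]
    f = np.hypot(fx, fy)
    f[0, 0] = np.inf  # kill DC
    img = np.fft.ifft2(spec / f).real
    return _normalize_unit_range(img)


def _edges(rng: np.random.Generator, side: int, n_edges: int = 40) -> np.ndarray:
    """Superimposed oriented step edges with cardinal orientations
    over-represented, mimicking the edge statistics of man-made scenes."""
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    img = np.zeros((side, side))
    for _ in range(n_edges):
        if rng.random() < 0.7:
            theta = float(rng.choice([0.0, 90.0]))
        else:
            theta = float(rng.uniform(0.0, 180.0))
        # unit normal to an edge of orientation theta
        nx = math.cos(math.radians(theta + 90.0))
        ny = math.sin(math.radians(theta + 90.0))
        x0 = rng.uniform(0, side)
        y0 = rng.uniform(0, side)
        amp = rng.uniform(0.2, 1.0) * rng.choice([-1.0, 1.0])
        img += amp * np.sign((xx - x0) * nx + (yy - y0) * ny)
    return _normalize_unit_range(img)


def _blocks(rng: np.random.Generator, side: int, n_blocks: int = 60) -> np.ndarray:
    """Random axis-aligned rectangles: only horizontal/vertical edges."""
    img = np.full((side, side), 0.5)
    for _ in range(n_blocks):
        w = int(rng.integers(side // 16, side // 3))
        h = int(rng.integers(side // 16, side // 3))
        r = int(rng.integers(0, side - h))
        c = int(rng.integers(0, side - w))
        img[r:r + h, c:c + w] = rng.uniform(0.0, 1.0)
    return img


def _from_file(path: str) -> np.ndarray:
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
    # ITU-R BT.601 luminance
    gray = arr @ np.array([0.299, 0.587, 0.114])
    side = min(gray.shape)
    r0 = (gray.shape[0] - side) // 2
    c0 = (gray.shape[1] - side) // 2
    return gray[r0:r0 + side, c0:c0 + side]


def make_texture(seed: int, kind: str = "pink_noise", side: int = 600,
                 path: str | None = None) -> Texture:
    """Create a reproducible stimulus texture.

    ``kind`` is one of ``pink_noise`` (1/f amplitude spectrum), ``edges``
    (oriented step edges, cardinals over-represented), ``blocks``
    (axis-aligned rectangles) or ``file`` (grayscale-converted image at
    ``path``, center-cropped square).
    """
    rng = np.random.default_rng(seed)
    if kind == "pink_noise":
        px = _pink_noise(rng, side)
    elif kind == "edges":
        px = _edges(rng, side)
    elif kind == "blocks":
        px = _blocks(rng, side)
    elif kind == "file":
        if path is None:
            raise ValueError("kind='file' requires a path")
        px = _from_file(path)
    else:
        raise ValueError(f"unsupported texture kind: {kind!r}")
    return Texture(pixels=px, kind=kind, seed=seed)


def orientation_energy_histogram(pixels: np.ndarray, n_bins: int = 18
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of edge-orientation energy from Sobel gradients.

    Bins cover [0°, 180°); the first bin is centered on 0° so that exactly
    cardinal structure lands in the 0° and 90° bins.  Returns
    ``(bin_centers_deg, energy)`` where energy is squared gradient magnitude
    accumulated per orientation bin (edge orientation = gradient direction
    rotated by 90°).
    """
    gx = ndimage.sobel(pixels, axis=1)
    gy = ndimage.sobel(pixels, axis=0)
    mag2 = gx ** 2 + gy ** 2
    ori = (np.degrees(np.arctan2(gy, gx)) + 90.0) % 180.0
    width = 180.0 / n_bins
    idx = np.floor((ori + width / 2) / width).astype(int) % n_bins
    energy = np.bincount(idx.ravel(), weights=mag2.ravel(), minlength=n_bins)
    centers = np.arange(n_bins) * width
    return centers, energy


# ---------------------------------------------------------------------------
# world and eyes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WorldState:
    """Pose of the stimulus plane in cyclopean coordinates plus textures."""

    stimulus_texture: Texture
    stimulus_center: np.ndarray          # (x, y, z) m; z > 0 is depth ahead
    stimulus_velocity: tuple[float, float, float] = (0.0, 0.0, 0.0)
    # (v_h deg/s angular, v_v deg/s angular, v_z m/s depth)
    stimulus_size: float = 1.5           # side of the square plane, m
    background_texture: Texture | None = None
    background_distance: float = 6.0

    def __post_init__(self) -> None:
        c = np.asarray(self.stimulus_center, dtype=np.float64)
        if c.shape != (3,):
            raise ValueError("stimulus_center must be a 3-vector")
        if c[2] <= 0:
            raise ValueError("stimulus depth must be positive")
        object.__setattr__(self, "stimulus_center", c)


@dataclass(frozen=True)
class EyePose:
    """Version (pan/tilt) angles and velocities plus symmetric vergence."""

    pan: float = 0.0          # deg
    tilt: float = 0.0         # deg
    pan_vel: float = 0.0      # deg/s
    tilt_vel: float = 0.0     # deg/s
    vergence: float = 0.2     # deg, total angle between optical axes
    baseline: float = 0.068   # m


@dataclass(frozen=True)
class ImagePair:
    left: np.ndarray          # (240, 320) gray
    right: np.ndarray
    timestamp: int = 0
    stimulus_visible: bool = True


def vergence_for_distance(d_object: float, baseline: float = 0.068) -> float:
    """Vergence angle (deg) that fixates a point at depth ``d_object``:
    xi* = 2 * arctan(baseline / (2 d))."""
    if d_object <= 0:
        raise ValueError("object distance must be positive")
    return math.degrees(2.0 * math.atan2(baseline, 2.0 * d_object))


def place_stimulus(world: WorldState, rng: np.random.Generator,
                   depth_range: tuple[float, float] = DEPTH_RANGE_M,
                   ) -> WorldState:
    """Center the stimulus on the (straight-ahead) cyclopean gaze direction
    at a random depth, and draw the episode's constant velocities."""
    depth = rng.uniform(*depth_range)
    v_h = rng.uniform(-MAX_ANGULAR_SPEED, MAX_ANGULAR_SPEED)
    v_v = rng.uniform(-MAX_ANGULAR_SPEED, MAX_ANGULAR_SPEED)
    v_z = rng.uniform(-MAX_DEPTH_SPEED, MAX_DEPTH_SPEED)
    return replace(world,
                   stimulus_center=np.array([0.0, 0.0, depth]),
                   stimulus_velocity=(v_h, v_v, v_z))


def step_world(world: WorldState, dt: float = 0.1) -> WorldState:
    """Advance the stimulus: angular position by v*dt about the cyclopean
    point (converted to lateral meters at the current depth), depth by
    v_z*dt.  The plane stays fronto-parallel."""
    v_h, v_v, v_z = world.stimulus_velocity
    x, y, z = world.stimulus_center
    ah = math.atan2(x, z) + math.radians(v_h * dt)
    av = math.atan2(y, z) + math.radians(v_v * dt)
    z_new = z + v_z * dt
    if z_new <= MIN_DEPTH_M:
        raise EpisodeAbort(f"stimulus depth {z_new:.3f} m below minimum")
    center = np.array([z_new * math.tan(ah), z_new * math.tan(av), z_new])
    return replace(world, stimulus_center=center)


def apply_eye_command(eyes: EyePose, a_pan: float, a_tilt: float,
                      a_verg: float, dt: float = 0.1
                      ) -> tuple[EyePose, bool]:
    """Apply one action triple: pan/tilt actions are angular accelerations
    (deg/s²), the vergence action is an angle increment (deg).  Velocity is
    updated before position (semi-implicit Euler).  Returns the new pose and
    the joint-limit flag."""
    pan_vel = eyes.pan_vel + a_pan * dt
    tilt_vel = eyes.tilt_vel + a_tilt * dt
    new = replace(eyes,
                  pan_vel=pan_vel,
                  tilt_vel=tilt_vel,
                  pan=eyes.pan + pan_vel * dt,
                  tilt=eyes.tilt + tilt_vel * dt,
                  vergence=eyes.vergence + a_verg)
    return new, check_limits(new)


def check_limits(eyes: EyePose) -> bool:
    """True iff a joint exceeded its (inclusive) boundary."""
    lo, hi = VERGENCE_RANGE_DEG
    return (abs(eyes.pan) > PAN_TILT_LIMIT_DEG
            or abs(eyes.tilt) > PAN_TILT_LIMIT_DEG
            or eyes.vergence < lo or eyes.vergence > hi)


def reset_gaze(eyes: EyePose, rng: np.random.Generator,
               fixation_range: tuple[float, float] = FIXATION_RANGE_M,
               ) -> EyePose:
    """Re-fixate straight ahead at a random distance: pan = tilt = 0, zero
    velocities, vergence set for a depth drawn uniformly from
    ``fixation_range`` and clipped into the joint range."""
    d = rng.uniform(*fixation_range)
    verg = float(np.clip(vergence_for_distance(d, eyes.baseline),
                         *VERGENCE_RANGE_DEG))
    return replace(eyes, pan=0.0, tilt=0.0, pan_vel=0.0, tilt_vel=0.0,
                   vergence=verg)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RenderConfig:
    width: int = 320
    height: int = 240
    hfov_deg: float = 90.0

    @property
    def focal_px(self) -> float:
        return (self.width / 2.0) / math.tan(math.radians(self.hfov_deg) / 2.0)

    @property
    def cx(self) -> float:
        return (self.width - 1) / 2.0

    @property
    def cy(self) -> float:
        return (self.height - 1) / 2.0


_GRID_CACHE: dict[tuple[int, int, float], tuple[np.ndarray, np.ndarray]] = {}


def _pixel_dirs(cfg: RenderConfig) -> tuple[np.ndarray, np.ndarray]:
    key = (cfg.width, cfg.height, cfg.hfov_deg)
    if key not in _GRID_CACHE:
        u = np.arange(cfg.width, dtype=np.float64)
        v = np.arange(cfg.height, dtype=np.float64)
        xn = (u - cfg.cx) / cfg.focal_px
        yn = (cfg.cy - v) / cfg.focal_px  # image rows go down, world y up
        _GRID_CACHE[key] = np.meshgrid(xn, yn)
    return _GRID_CACHE[key]


def _camera_rotation(yaw_deg: float, pitch_deg: float) -> np.ndarray:
    """Camera-to-world rotation: yaw about world y (positive toward +x),
    then pitch about camera x (positive looks up)."""
    cy_, sy = math.cos(math.radians(yaw_deg)), math.sin(math.radians(yaw_deg))
    cp, sp = math.cos(math.radians(pitch_deg)), math.sin(math.radians(pitch_deg))
    r_yaw = np.array([[cy_, 0.0, sy], [0.0, 1.0, 0.0], [-sy, 0.0, cy_]])
    r_pitch = np.array([[1.0, 0.0, 0.0], [0.0, cp, sp], [0.0, -sp, cp]])
    return r_yaw @ r_pitch


def _camera_extrinsics(eyes: EyePose, side: str) -> tuple[np.ndarray, np.ndarray]:
    sign = -1.0 if side == "left" else 1.0
    origin = np.array([sign * eyes.baseline / 2.0, 0.0, 0.0])
    # each camera toes in toward the fixation point by half the vergence
    yaw = eyes.pan - sign * eyes.vergence / 2.0
    return origin, _camera_rotation(yaw, eyes.tilt)


def _sample_plane(origin: np.ndarray, rot: np.ndarray, dirs: np.ndarray,
                  plane_z: float, plane_center_xy: tuple[float, float],
                  plane_size: float, texture: Texture,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Intersect all pixel rays with the plane z = plane_z and sample the
    texture bilinearly (edge clamp).  Returns (values, hit_mask) where the
    mask marks rays landing inside the plane extent."""
    dw = dirs @ rot.T  # (H, W, 3) world-frame ray directions
    dz = dw[..., 2]
    valid = dz > 1e-9
    t = np.where(valid, (plane_z - origin[2]) / np.where(valid, dz, 1.0), np.inf)
    px = origin[0] + t * dw[..., 0]
    py = origin[1] + t * dw[..., 1]
    half = plane_size / 2.0
    cx0, cy0 = plane_center_xy
    inside = valid & (np.abs(px - cx0) <= half) & (np.abs(py - cy0) <= half)
    side = texture.side
    col = (px - cx0 + half) / plane_size * (side - 1)
    row = (cy0 + half - py) / plane_size * (side - 1)
    coords = np.stack([np.where(valid, row, 0.0), np.where(valid, col, 0.0)])
    vals = ndimage.map_coordinates(texture.pixels, coords.reshape(2, -1),
                                   order=1, mode="nearest")
    return vals.reshape(dz.shape), inside


def render_binocular(world: WorldState, eyes: EyePose,
                     cfg: RenderConfig = RenderConfig(),
                     timestamp: int = 0) -> ImagePair:
    """Render the left/right gray images of the current scene."""
    xn, yn = _pixel_dirs(cfg)
    dirs = np.stack([xn, yn, np.ones_like(xn)], axis=-1)
    images = []
    any_visible = False
    bg_tex = world.background_texture
    for side in ("left", "right"):
        origin, rot = _camera_extrinsics(eyes, side)
        img = np.full((cfg.height, cfg.width), 0.5)
        if bg_tex is not None:
            bg_size = 2.0 * world.background_distance * math.tan(math.radians(80.0))
            vals, inside = _sample_plane(origin, rot, dirs,
                                         world.background_distance,
                                         (0.0, 0.0), bg_size, bg_tex)
            dz = (dirs @ rot.T)[..., 2]
            img = np.where(dz > 1e-9, vals, img)
        sx, sy, sz = world.stimulus_center
        vals, inside = _sample_plane(origin, rot, dirs, sz, (sx, sy),
                                     world.stimulus_size,
                                     world.stimulus_texture)
        img = np.where(inside, vals, img)
        any_visible = any_visible or bool(inside.any())
        images.append(img)
    return ImagePair(left=images[0], right=images[1], timestamp=timestamp,
                     stimulus_visible=any_visible)


def project_point(point: np.ndarray, eyes: EyePose, side: str,
                  cfg: RenderConfig = RenderConfig()) -> tuple[float, float]:
    """Analytic pinhole projection of a world point into one camera;
    returns (u, v) pixel coordinates."""
    origin, rot = _camera_extrinsics(eyes, side)
    pc = rot.T @ (np.asarray(point, dtype=np.float64) - origin)
    if pc[2] <= 0:
        raise ValueError("point is behind the camera")
    u = cfg.cx + cfg.focal_px * pc[0] / pc[2]
    v = cfg.cy - cfg.focal_px * pc[1] / pc[2]
    return float(u), float(v)
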