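"""From raw binocular frames to normalized spatio-temporal binocular patches.

Each camera frame is whitened with a combined whitening/low-pass filter,
two concentric sub-windows are extracted (a wide coarse window emulating
near-peripheral vision, down-sampled 4x through a Gaussian pyramid, and a
narrow full-resolution fine window emulating macular vision), and each
window is cut into 8 x 8 patches on a stride-4 grid.  Corresponding patches
from the two eyes and two consecutive frames are assembled into 16 x 16
binocular spatio-temporal patches: rows left/right eye, columns t-1 / t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ScaleConfig", "COARSE", "FINE", "SpatioTemporalPatchSet",
    "whiten", "extract_scales", "cut_patches", "assemble_spatiotemporal",
    "get_subfield", "PatchPipeline",
]

DEGENERATE_NORM = 1e-8


@dataclass(frozen=True)
class ScaleConfig:
    """Geometry of one processing scale.

    ``window_px`` is the side of the sub-window cropped from the 320x240
    frame, ``window_fov_deg`` the visual angle it covers, and
    ``downsample_factor`` the Gaussian-pyramid reduction applied before
    patch extraction.
    """

    name: str
    window_px: int
    window_fov_deg: float
    downsample_factor: int
    patch_px: int = 8
    stride_px: int = 4

    @property
    def output_px(self) -> int:
        return self.window_px // self.downsample_factor

    @property
    def deg_per_px(self) -> float:
        return self.window_fov_deg / self.output_px

    @property
    def n_patches(self) -> int:
        per_side = (self.output_px - self.patch_px) // self.stride_px + 1
        return per_side * per_side


COARSE = ScaleConfig(name="coarse", window_px=128, window_fov_deg=36.0,
                     downsample_factor=4)
FINE = ScaleConfig(name="fine", window_px=64, window_fov_deg=18.0,
                   downsample_factor=1)


@dataclass(frozen=True)
class SpatioTemporalPatchSet:
    """Assembled 16x16 binocular two-frame patches for one scale.

    ``patches`` has shape (n, 16, 16); the 2x2 grid of 8x8 subfields is
    rows = left (top) / right (bottom) eye, columns = t-1 (left) / t (right).
    """

    scale: ScaleConfig
    patches: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.patches, dtype=np.float64)
        if p.ndim != 3 or p.shape[1:] != (16, 16):
            raise ValueError("patches must have shape (n, 16, 16)")
        object.__setattr__(self, "patches", p)

    def __len__(self) -> int:
        return self.patches.shape[0]

    @property
    def flat(self) -> np.ndarray:
        return self.patches.reshape(len(self), -1)


def whiten(image: np.ndarray, f0: float = 96.0, n: float = 4.0) -> np.ndarray:
    """Whiten an image in the frequency domain with R(f) = f exp(-(f/f0)^n).

    ``f`` is the radial spatial frequency in cycles per image, measured
    relative to the larger image side, so ``f0 = 96`` means 96 cycles across
    the 320 px frame width.  The filter removes the DC component, equalizes
    the 1/f amplitude fall-off of natural images at low frequencies and
    rolls off above the cutoff, roughly like the contrast sensitivity of
    retinal ganglion cells.
    """
    img = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("whiten: non-finite input")
    if f0 <= 0 or n < 1:
        raise ValueError("require f0 > 0 and n >= 1")
    h, w = img.shape
    ref = float(max(h, w))
    fr = np.fft.fftfreq(h)[:, None] * ref
    fc = np.fft.fftfreq(w)[None, :] * ref
    f = np.hypot(fr, fc)
    gain = f * np.exp(-((f / f0) ** n))
    return np.fft.ifft2(np.fft.fft2(img) * gain).real


def whitening_gain(f: np.ndarray | float, f0: float = 96.0, n: float = 4.0):
    """The scalar frequency response R(f) of :func:`whiten`."""
    f = np.asarray(f, dtype=np.float64)
    return f * np.exp(-((f / f0) ** n))


_PYR_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def _pyramid_reduce(image: np.ndarray) -> np.ndarray:
    sm = ndimage.convolve1d(image, _PYR_KERNEL, axis=0, mode="reflect")
    sm = ndimage.convolve1d(sm, _PYR_KERNEL, axis=1, mode="reflect")
    return sm[::2, ::2]


def _center_crop(image: np.ndarray, side: int) -> np.ndarray:
    h, w = image.shape
    r0 = h // 2 - side // 2
    c0 = w // 2 - side // 2
    return image[r0:r0 + side, c0:c0 + side]


def extract_scales(frame: np.ndarray,
                   coarse: ScaleConfig = COARSE,
                   fine: ScaleConfig = FINE) -> tuple[np.ndarray, np.ndarray]:
    """Cut the two concentric sub-windows from a (whitened) frame.

    Returns ``(coarse_img, fine_img)``: the coarse window reduced by the
    pyramid to ``output_px`` (32 x 32 by default), the fine window untouched
    (64 x 64).
    """
    coarse_img = _center_crop(frame, coarse.window_px)
    levels = int(np.log2(coarse.downsample_factor))
    for _ in range(levels):
        coarse_img = _pyramid_reduce(coarse_img)
    fine_img = _center_crop(frame, fine.window_px)
    return coarse_img, fine_img


def cut_patches(image: np.ndarray, patch: int = 8, stride: int = 4,
                normalize: bool = True) -> np.ndarray:
    """Slide a ``patch`` x ``patch`` window with ``stride`` over the image
    (row-major) and normalize each patch to zero mean, unit norm.

    Patches that are uniform (norm below 1e-8 after mean subtraction) are
    returned as all zeros rather than amplified noise.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.shape[0] < patch or img.shape[1] < patch:
        raise ValueError("image smaller than patch size")
    win = np.lib.stride_tricks.sliding_window_view(img, (patch, patch))
    win = win[::stride, ::stride]
    patches = win.reshape(-1, patch, patch).copy()
    if normalize:
        flat = patches.reshape(len(patches), -1)
        flat -= flat.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(flat, axis=1, keepdims=True)
        good = norms > DEGENERATE_NORM
        np.divide(flat, norms, out=flat, where=good)
        flat[~good[:, 0]] = 0.0
    return patches


def assemble_spatiotemporal(left_t: np.ndarray, right_t: np.ndarray,
                            left_prev: np.ndarray, right_prev: np.ndarray,
                            scale: ScaleConfig) -> SpatioTemporalPatchSet:
    """Combine the four 8x8 patch lists (same grid positions) into 16x16
    binocular spatio-temporal patches."""
    sets = (left_t, right_t, left_prev, right_prev)
    n = len(left_t)
    if any(len(s) != n for s in sets):
        raise ValueError("patch lists must have equal length")
    out = np.empty((n, 16, 16))
    out[:, :8, :8] = left_prev
    out[:, :8, 8:] = left_t
    out[:, 8:, :8] = right_prev
    out[:, 8:, 8:] = right_t
    return SpatioTemporalPatchSet(scale=scale, patches=out)


_SUBFIELD_SLICES = {
    ("left", "prev"): (slice(0, 8), slice(0, 8)),
    ("left", "t"): (slice(0, 8), slice(8, 16)),
    ("right", "prev"): (slice(8, 16), slice(0, 8)),
    ("right", "t"): (slice(8, 16), slice(8, 16)),
}


def get_subfield(patch: np.ndarray, eye: str, time: str) -> np.ndarray:
    """View of one 8x8 subfield of a 16x16 patch or basis function.

    ``eye`` in {'left', 'right'}, ``time`` in {'prev', 't'} ('prev' = t-1).
    """
    rows, cols = _SUBFIELD_SLICES[(eye, time)]
    return patch[..., rows, cols]


class PatchPipeline:
    """Stateful per-eye preprocessing that keeps the previous frame's
    patches so each call yields spatio-temporal patch sets for both scales.

    On the first frame after :meth:`reset` the previous-frame subfields are
    taken equal to the current ones (a static view), so episode starts do
    not mix content across episode boundaries.
    """

    def __init__(self, coarse: ScaleConfig = COARSE,
                 fine: ScaleConfig = FINE, f0: float = 96.0,
                 n: float = 4.0) -> None:
        self.coarse = coarse
        self.fine = fine
        self.f0 = f0
        self.n = n
        self._prev: dict[tuple[str, str], np.ndarray] | None = None

    def reset(self) -> None:
        self._prev = None

    def _frame_patches(self, frame: np.ndarray) -> dict[str, np.ndarray]:
        white = whiten(frame, self.f0, self.n)
        coarse_img, fine_img = extract_scales(white, self.coarse, self.fine)
        return {
            "coarse": cut_patches(coarse_img, self.coarse.patch_px,
                                  self.coarse.stride_px),
            "fine": cut_patches(fine_img, self.fine.patch_px,
                                self.fine.stride_px),
        }

    def __call__(self, left: np.ndarray, right: np.ndarray
                 ) -> dict[str, SpatioTemporalPatchSet]:
        cur = {("left", s): p for s, p in self._frame_patches(left).items()}
        cur.update({("right", s): p
                    for s, p in self._frame_patches(right).items()})
        prev = self._prev if self._prev is not None else cur
        out = {}
        for scale in (self.coarse, self.fine):
            s = scale.name
            out[s] = assemble_spatiotemporal(
                cur[("left", s)], cur[("right", s)],
                prev[("left", s)], prev[("right", s)], scale)
        self._prev = cur
        return out
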