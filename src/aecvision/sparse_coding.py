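"""Matching-pursuit sparse coding of spatio-temporal binocular patches.

Each scale owns a dictionary of unit-energy 16 x 16 basis functions whose
four 8 x 8 subfields play the role of binocular simple-cell receptive
fields (left/right eye at times t-1 and t).  A patch is approximated by a
greedy matching-pursuit expansion restricted to 10 coefficients; the summed
normalized squared reconstruction error is the coding-efficiency signal,
and the per-atom mean squared coefficients form the complex-cell-like state
vector handed to the reinforcement learner.

Basis functions are initialized either as independent random Gabor wavelets
in each subfield (receptive fields are Gabor-like before visual experience)
or as Gaussian white noise.  During learning each atom follows gradient
descent on the reconstruction error and is renormalized to unit energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GaborParams", "Dictionary", "SparseCode", "sample_gabor",
    "evaluate_gabor", "random_gabor_params", "init_dictionary",
    "matching_pursuit", "reconstruct", "reconstruction_error",
    "update_dictionary", "state_vector",
]

PATCH_SIDE = 8
ATOM_SIDE = 16
N_ACTIVE = 10           # non-zero coefficients per patch
LEARNING_RATE = 0.5     # gradient step on the reconstruction error

# sampling ranges for random Gabor initialization
LAMBDA_RANGE = (8.0 / 3.0, 16.0)       # px
CENTER_RANGE = (8.0 / 3.0, 8.0)        # px
SIGMA_INIT = 2.5                       # px
ASPECT_DENOM = 0.8 * 8.0               # beta = lambda / (0.8 * 8 px)


@dataclass(frozen=True)
class GaborParams:
    """Parameters of a 2-D Gabor g(x, y): a cosine carrier of wavelength
    ``lam`` (px) and phase ``psi`` (deg) at orientation ``theta`` (deg),
    windowed by an elliptical Gaussian of SD ``sigma`` (px) and aspect
    ratio ``beta``, centered at (``x_c``, ``y_c``) px."""

    lam: float
    theta: float
    psi: float
    sigma: float
    beta: float
    x_c: float
    y_c: float


def evaluate_gabor(params: GaborParams, side: int = PATCH_SIDE) -> np.ndarray:
    """Evaluate the Gabor on the integer pixel grid 0..side-1 (x = column,
    y = row), without normalization."""
    y, x = np.mgrid[0:side, 0:side].astype(np.float64)
    th = math.radians(params.theta)
    xr = (x - params.x_c) * math.cos(th) + (y - params.y_c) * math.sin(th)
    yr = -(x - params.x_c) * math.sin(th) + (y - params.y_c) * math.cos(th)
    envelope = np.exp(-(xr ** 2 + params.beta ** 2 * yr ** 2)
                      / (2.0 * params.sigma ** 2))
    carrier = np.cos(2.0 * np.pi * xr / params.lam + math.radians(params.psi))
    return envelope * carrier


def sample_gabor(params: GaborParams) -> np.ndarray:
    """Evaluate, mean-subtract and unit-normalize a Gabor subfield so it
    lives in the zero-mean patch space."""
    g = evaluate_gabor(params)
    g -= g.mean()
    nrm = np.linalg.norm(g)
    if nrm < 1e-12:
        raise ValueError("degenerate Gabor (zero after mean subtraction)")
    return g / nrm


def random_gabor_params(rng: np.random.Generator) -> GaborParams:
    lam = rng.uniform(*LAMBDA_RANGE)
    return GaborParams(
        lam=lam,
        theta=rng.uniform(0.0, 180.0),
        psi=rng.uniform(0.0, 360.0),
        sigma=SIGMA_INIT,
        beta=lam / ASPECT_DENOM,
        x_c=rng.uniform(*CENTER_RANGE),
        y_c=rng.uniform(*CENTER_RANGE),
    )


@dataclass
class Dictionary:
    """Per-scale set of unit-energy 16 x 16 basis functions."""

    scale: str
    atoms: np.ndarray                 # (n_atoms, 16, 16)
    init_mode: str = "gabor"
    seed: int | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.atoms, dtype=np.float64)
        if a.ndim != 3 or a.shape[1:] != (ATOM_SIDE, ATOM_SIDE):
            raise ValueError("atoms must have shape (n, 16, 16)")
        self.atoms = a

    def __len__(self) -> int:
        return self.atoms.shape[0]

    @property
    def flat(self) -> np.ndarray:
        return self.atoms.reshape(len(self), -1)

    def normalize(self) -> None:
        """Renormalize every atom to unit energy (Frobenius norm 1)."""
        flat = self.flat
        norms = np.linalg.norm(flat, axis=1, keepdims=True)
        np.divide(flat, norms, out=flat, where=norms > 1e-12)


def init_dictionary(n_atoms: int, seed: int | np.random.Generator,
                    mode: str = "gabor", scale: str = "coarse") -> Dictionary:
    """Create a dictionary with the four subfields of every atom drawn
    independently (``gabor``: random Gabor wavelets from the stated
    parameter ranges; ``white_noise``: standard normal), then normalized to
    unit energy per atom."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    atoms = np.empty((n_atoms, ATOM_SIDE, ATOM_SIDE))
    if mode == "gabor":
        for i in range(n_atoms):
            for rows in (slice(0, 8), slice(8, 16)):
                for cols in (slice(0, 8), slice(8, 16)):
                    atoms[i, rows, cols] = sample_gabor(random_gabor_params(rng))
    elif mode == "white_noise":
        atoms[:] = rng.standard_normal(atoms.shape)
    else:
        raise ValueError(f"unsupported init mode: {mode!r}")
    d = Dictionary(scale=scale, atoms=atoms, init_mode=mode,
                   seed=None if isinstance(seed, np.random.Generator) else seed)
    d.normalize()
    return d


@dataclass
class SparseCode:
    """Matching-pursuit encoding of a patch set: dense coefficient matrix
    (n_patches, n_atoms) with at most 10 selections per patch, plus the
    selection history."""

    coefficients: np.ndarray
    selected: np.ndarray              # (n_patches, k) atom indices, -1 = none

    @property
    def n_patches(self) -> int:
        return self.coefficients.shape[0]


def matching_pursuit(patches: np.ndarray, dictionary: Dictionary,
                     k: int = N_ACTIVE) -> SparseCode:
    """Greedy matching pursuit, ``k`` iterations per patch.

    At each iteration the atom with the largest absolute inner product with
    the residual is selected (ties broken by lowest index), its coefficient
    is incremented by that inner product, and the projection is removed.
    Atoms may be reselected, in which case coefficients accumulate.  Zero
    patches get an empty code.
    """
    p = np.asarray(patches, dtype=np.float64)
    if p.ndim == 3:
        p = p.reshape(len(p), -1)
    d = dictionary.flat
    m = p.shape[0]
    residual = p.copy()
    coeffs = np.zeros((m, len(dictionary)))
    selected = np.full((m, k), -1, dtype=np.int64)
    active = np.linalg.norm(p, axis=1) > 1e-12
    rows = np.flatnonzero(active)
    if rows.size:
        res = residual[rows]
        for it in range(k):
            inner = res @ d.T
            best = np.argmax(np.abs(inner), axis=1)  # argmax: lowest index wins ties
            c = inner[np.arange(len(rows)), best]
            coeffs[rows, best] += c
            selected[rows, it] = best
            res -= c[:, None] * d[best]
        residual[rows] = res
    return SparseCode(coefficients=coeffs, selected=selected)


def reconstruct(code: SparseCode, dictionary: Dictionary) -> np.ndarray:
    """Linear reconstruction p_hat = kappa @ atoms, shape (n, 256)."""
    return code.coefficients @ dictionary.flat


def reconstruction_error(patches: np.ndarray, code: SparseCode,
                         dictionary: Dictionary) -> float:
    """E_S = sum_j ||p_j - p_hat_j||^2 / ||p_j||^2 over the patch set;
    zero-norm (degenerate) patches contribute 0."""
    p = np.asarray(patches, dtype=np.float64)
    if p.ndim == 3:
        p = p.reshape(len(p), -1)
    resid = p - reconstruct(code, dictionary)
    num = np.einsum("ij,ij->i", resid, resid)
    den = np.einsum("ij,ij->i", p, p)
    good = den > 1e-12
    return float(np.sum(num[good] / den[good]))


def update_dictionary(dictionary: Dictionary, patches: np.ndarray,
                      code: SparseCode, eta: float = LEARNING_RATE
                      ) -> Dictionary:
    """Gradient step on the reconstruction error:
    delta_phi_i = eta / |p| * sum_j kappa_ij (p_j - p_hat_j),
    followed by renormalization of every atom to unit energy.  The
    dictionary is updated in place and returned."""
    p = np.asarray(patches, dtype=np.float64)
    if p.ndim == 3:
        p = p.reshape(len(p), -1)
    resid = p - reconstruct(code, dictionary)
    grad = code.coefficients.T @ resid / p.shape[0]
    dictionary.flat[...] = dictionary.flat + eta * grad
    dictionary.normalize()
    return dictionary


def state_vector(code_coarse: SparseCode | None,
                 code_fine: SparseCode | None) -> np.ndarray:
    """Complex-cell-like feature vector: for each atom the mean squared
    coefficient over all patches, coarse block first, then fine."""
    blocks = []
    for code in (code_coarse, code_fine):
        if code is None:
            continue
        blocks.append(np.mean(code.coefficients ** 2, axis=0))
    if not blocks:
        raise ValueError("at least one sparse code required")
    return np.concatenate(blocks)
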