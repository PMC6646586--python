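"""Receptive-field characterization of learned dictionaries.

Every basis function carries four 8 x 8 subfields (left/right eye at times
t-1 and t).  Fitting a 2-D Gabor to each subfield yields, per atom, an
orientation preference, a binocular disparity preference (from the
left/right phase difference at one time)

    d_hat = lambda * (psi_left - psi_right) / (2 pi cos(theta))   [px]

and a monocular velocity preference (from the t-1/t phase difference of one
eye)

    v_hat = lambda * |psi_t - psi_{t-1}| / (2 pi)                 [px/iter],

both converted to degrees with the scale's deg/px factor.

Residual convention: atoms have unit energy, so each subfield carries about
a quarter of it.  The reported residual ``r`` of a fit is the squared norm
of the difference between the subfield *at that natural scale* and its
best-fitting, optimally scaled Gabor; the scale-free fraction of
unexplained subfield energy is exposed separately as ``r_frac``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from aecvision.preprocessing import ScaleConfig, get_subfield
from aecvision.sparse_coding import Dictionary, GaborParams, evaluate_gabor

__all__ = [
    "GaborFit", "fit_gabor", "residual_stats", "fit_dictionary",
    "build_tuning_table", "orientation_histogram", "disparity_preference",
    "velocity_preference", "tuning_scatter", "wrap_phase",
]

_SIDE = 8
_YY, _XX = np.mgrid[0:_SIDE, 0:_SIDE].astype(np.float64)

# box bounds: generous supersets of the initialization ranges
_LB = np.array([2.0, -np.inf, -np.inf, 0.5, 0.05, -2.0, -2.0])
_UB = np.array([24.0, np.inf, np.inf, 8.0, 5.0, 10.0, 10.0])
_X_SCALE = np.array([2.0, 20.0, 40.0, 1.0, 0.5, 2.0, 2.0])


@dataclass(frozen=True)
class GaborFit:
    """Result of fitting one subfield.

    ``r`` is the squared residual norm at the subfield's native scale
    within its unit-energy atom; ``r_frac`` = r / ||subfield||^2 is the
    fraction of subfield energy the Gabor leaves unexplained.
    """

    params: GaborParams
    amplitude: float
    r: float
    r_frac: float
    success: bool = True


def _gabor_zero_mean(x: np.ndarray) -> tuple[np.ndarray, float]:
    lam, theta, psi, sigma, beta, x_c, y_c = x
    th = math.radians(theta)
    xr = (_XX - x_c) * math.cos(th) + (_YY - y_c) * math.sin(th)
    yr = -(_XX - x_c) * math.sin(th) + (_YY - y_c) * math.cos(th)
    g = (np.exp(-(xr ** 2 + beta ** 2 * yr ** 2) / (2.0 * sigma ** 2))
         * np.cos(2.0 * np.pi * xr / lam + math.radians(psi)))
    g = g.ravel()
    return g - g.mean(), 0.0


def _residual_fn(y: np.ndarray):
    def fn(x: np.ndarray) -> np.ndarray:
        m, _ = _gabor_zero_mean(x)
        mm = float(m @ m)
        if mm < 1e-12:
            return y
        a = float(m @ y) / mm
        return y - a * m

    return fn


def _optimal_amplitude(y: np.ndarray, x: np.ndarray) -> float:
    m, _ = _gabor_zero_mean(x)
    mm = float(m @ m)
    return 0.0 if mm < 1e-12 else float(m @ y) / mm


def _fft_start(y2d: np.ndarray) -> np.ndarray:
    """Initial guess from the dominant Fourier component of the subfield,
    zero-padded for frequency resolution."""
    pad = np.zeros((32, 32))
    pad[:_SIDE, :_SIDE] = y2d
    spec = np.fft.fft2(pad)
    fy = np.fft.fftfreq(32)[:, None]
    fx = np.fft.fftfreq(32)[None, :]
    mag = np.abs(spec)
    mag[0, 0] = 0.0
    mag[fy.ravel() < 0, :] = 0.0  # keep one half-plane
    iy, ix = np.unravel_index(np.argmax(mag), mag.shape)
    fxv, fyv = float(fx[0, ix]), float(fy[iy, 0])
    rho = math.hypot(fxv, fyv)
    lam = float(np.clip(1.0 / max(rho, 1e-3), _LB[0], _UB[0]))
    theta = math.degrees(math.atan2(fyv, fxv)) % 180.0
    w = np.abs(y2d)
    w_sum = w.sum()
    if w_sum > 1e-12:
        x_c = float((w * _XX).sum() / w_sum)
        y_c = float((w * _YY).sum() / w_sum)
    else:
        x_c = y_c = 3.5
    # carrier phase at the centroid, from the Fourier phase at the peak
    phase = math.degrees(np.angle(spec[iy, ix])
                         + 2.0 * math.pi * (fxv * x_c + fyv * y_c))
    return np.array([lam, theta, phase, 2.5, 1.0, x_c, y_c])


def _canonicalize(x: np.ndarray, amplitude: float
                  ) -> tuple[GaborParams, float]:
    lam, theta, psi, sigma, beta, x_c, y_c = x
    if amplitude < 0:
        amplitude, psi = -amplitude, psi + 180.0
    theta = theta % 360.0
    if theta >= 180.0:  # g(theta + 180, psi) == g(theta, -psi)
        theta -= 180.0
        psi = -psi
    return (GaborParams(lam=float(lam), theta=float(theta),
                        psi=float(psi % 360.0), sigma=float(sigma),
                        beta=float(beta), x_c=float(x_c), y_c=float(y_c)),
            float(amplitude))


def fit_gabor(subfield: np.ndarray, n_grid_starts: int = 16,
              stop_frac: float = 1e-3, max_nfev: int = 120) -> GaborFit:
    """Fit a 2-D Gabor (optimal amplitude, zero-mean model) to one 8 x 8
    subfield by multi-start nonlinear least squares.

    Starts: one informed by the subfield's dominant Fourier component, plus
    a grid over orientation x phase (4 x 4 by default).  Iteration stops
    early once a start explains all but ``stop_frac`` of the energy.
    """
    y2d = np.asarray(subfield, dtype=np.float64)
    energy = float(np.sum(y2d ** 2))
    if energy < 1e-16:
        return GaborFit(params=GaborParams(8, 0, 0, 2.5, 1, 3.5, 3.5),
                        amplitude=0.0, r=0.0, r_frac=1.0, success=False)
    y = (y2d / math.sqrt(energy)).ravel()
    y = y - y.mean()  # compare in the zero-mean patch space
    yn = float(y @ y)
    fn = _residual_fn(y)

    starts = [_fft_start(y2d)]
    n_th = 4
    n_psi = max(1, n_grid_starts // n_th)
    for th in np.arange(n_th) * (180.0 / n_th):
        for ps in np.arange(n_psi) * (360.0 / n_psi):
            starts.append(np.array([6.0, th, ps, 2.5, 1.0, 3.5, 3.5]))

    best_x, best_cost = None, np.inf
    for x0 in starts:
        try:
            sol = least_squares(fn, x0, bounds=(_LB, _UB),
                                x_scale=_X_SCALE, max_nfev=max_nfev)
        except Exception:
            continue
        if sol.cost < best_cost:
            best_cost, best_x = sol.cost, sol.x
        if 2.0 * best_cost <= stop_frac * yn:
            break
    if best_x is None:
        return GaborFit(params=GaborParams(8, 0, 0, 2.5, 1, 3.5, 3.5),
                        amplitude=0.0, r=energy, r_frac=1.0, success=False)
    r_frac = float(min(2.0 * best_cost / yn, 1.0)) if yn > 0 else 1.0
    amp = _optimal_amplitude(y, best_x) * math.sqrt(energy)
    params, amp = _canonicalize(best_x, amp)
    return GaborFit(params=params, amplitude=amp, r=energy * r_frac,
                    r_frac=r_frac, success=True)


_SUBFIELD_KEYS = (("left", "prev"), ("left", "t"),
                  ("right", "prev"), ("right", "t"))


def fit_dictionary(dictionary: Dictionary, **fit_kw
                   ) -> dict[tuple[str, str], list[GaborFit]]:
    """Fit all four subfields of every atom; returns fits keyed by
    (eye, time)."""
    out: dict[tuple[str, str], list[GaborFit]] = {k: [] for k in
                                                  _SUBFIELD_KEYS}
    for atom in dictionary.atoms:
        for key in _SUBFIELD_KEYS:
            out[key].append(fit_gabor(get_subfield(atom, *key), **fit_kw))
    return out


def residual_stats(dictionary: Dictionary, **fit_kw) -> dict:
    """Mean and SD of the Gabor-fit residual ``r`` over all subfields of
    all atoms of a dictionary."""
    fits = fit_dictionary(dictionary, **fit_kw)
    r = np.array([f.r for key in _SUBFIELD_KEYS for f in fits[key]])
    return {"mean_r": float(r.mean()), "sd_r": float(r.std(ddof=1)),
            "residuals": r, "fits": fits}


def wrap_phase(delta_rad: float) -> float:
    """Wrap a phase difference into (-pi, pi]."""
    wrapped = (delta_rad + math.pi) % (2.0 * math.pi) - math.pi
    return math.pi if wrapped == -math.pi else wrapped


def carrier_phase_at_origin(params: GaborParams) -> float:
    """Carrier phase (rad) referenced to the patch origin rather than the
    fitted envelope center, so phases of two independently fitted subfields
    are comparable: a spatial displacement of the pattern can be absorbed
    into the fitted center, but not into this quantity."""
    th = math.radians(params.theta)
    proj = params.x_c * math.cos(th) + params.y_c * math.sin(th)
    return math.radians(params.psi) - 2.0 * math.pi * proj / params.lam


def _phase_diff_rad(a: GaborFit, b: GaborFit) -> float:
    pa, pb = a.params, b.params
    dth = abs(pa.theta - pb.theta)
    if dth > 90.0:
        # re-express b with the equivalent flipped orientation so both
        # carriers modulate along (almost) the same direction
        pb = GaborParams(lam=pb.lam,
                         theta=pb.theta - 180.0 if pb.theta >= 90.0
                         else pb.theta + 180.0,
                         psi=-pb.psi, sigma=pb.sigma, beta=pb.beta,
                         x_c=pb.x_c, y_c=pb.y_c)
    return wrap_phase(carrier_phase_at_origin(pa)
                      - carrier_phase_at_origin(pb))


def _fits_match(a: GaborFit, b: GaborFit, lam_tol: float = 0.10,
                theta_tol: float = 10.0) -> bool:
    lam_bar = 0.5 * (a.params.lam + b.params.lam)
    dth = abs(a.params.theta - b.params.theta) % 180.0
    dth = min(dth, 180.0 - dth)
    return (abs(a.params.lam - b.params.lam) <= lam_tol * lam_bar
            and dth <= theta_tol)


def disparity_preference(fit_left: GaborFit, fit_right: GaborFit,
                         deg_per_px: float) -> float:
    """Horizontal disparity preference (deg) from the interocular phase
    shift of one time slice.  NaN when the two fits disagree in wavelength
    or orientation, or when the orientation is near-horizontal
    (|cos theta| < 0.1), where horizontal disparity is ill-defined."""
    if not _fits_match(fit_left, fit_right):
        return float("nan")
    lam = 0.5 * (fit_left.params.lam + fit_right.params.lam)
    tha, thb = fit_left.params.theta, fit_right.params.theta
    if abs(tha - thb) > 90.0:  # circular mean on the half-circle
        thb += 180.0 if thb < tha else -180.0
    c = math.cos(math.radians(0.5 * (tha + thb)))
    if abs(c) < 0.1:
        return float("nan")
    d_px = lam * _phase_diff_rad(fit_left, fit_right) / (2.0 * math.pi * c)
    return d_px * deg_per_px


def velocity_preference(fit_t: GaborFit, fit_prev: GaborFit,
                        deg_per_px: float) -> float:
    """Preferred speed (deg/iteration) of one eye from the frame-to-frame
    phase shift; NaN on mismatched fits."""
    if not _fits_match(fit_t, fit_prev):
        return float("nan")
    lam = 0.5 * (fit_t.params.lam + fit_prev.params.lam)
    v_px = lam * abs(_phase_diff_rad(fit_t, fit_prev)) / (2.0 * math.pi)
    return v_px * deg_per_px


def build_tuning_table(dictionary: Dictionary, scale: ScaleConfig,
                       r_frac_threshold: float = 0.5,
                       fits: dict[tuple[str, str], list[GaborFit]] | None = None,
                       **fit_kw) -> pd.DataFrame:
    """Per-atom tuning preferences for atoms whose four subfield fits all
    pass the residual-fraction threshold.

    Columns: theta (deg, time-t left subfield), d_t, d_prev (deg),
    v_left, v_right (deg/iteration); NaN entries mark flagged
    (mismatched or near-horizontal) preferences.
    """
    if fits is None:
        fits = fit_dictionary(dictionary, **fit_kw)
    rows = []
    for i in range(len(dictionary)):
        four = {k: fits[k][i] for k in _SUBFIELD_KEYS}
        if any(not f.success or f.r_frac > r_frac_threshold
               for f in four.values()):
            continue
        dpp = scale.deg_per_px
        rows.append({
            "atom": i,
            "theta": four[("left", "t")].params.theta,
            "d_t": disparity_preference(four[("left", "t")],
                                        four[("right", "t")], dpp),
            "d_prev": disparity_preference(four[("left", "prev")],
                                           four[("right", "prev")], dpp),
            "v_left": velocity_preference(four[("left", "t")],
                                          four[("left", "prev")], dpp),
            "v_right": velocity_preference(four[("right", "t")],
                                           four[("right", "prev")], dpp),
        })
    return pd.DataFrame(rows, columns=["atom", "theta", "d_t", "d_prev",
                                       "v_left", "v_right"])


def orientation_histogram(thetas: np.ndarray, n_bins: int = 18
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of orientation preferences over [0, 180), first bin
    centered on 0 degrees so cardinal orientations land on bin centers."""
    th = np.asarray(thetas, dtype=np.float64) % 180.0
    width = 180.0 / n_bins
    idx = np.floor((th + width / 2.0) / width).astype(int) % n_bins
    counts = np.bincount(idx, minlength=n_bins)
    centers = np.arange(n_bins) * width
    return centers, counts


def tuning_scatter(table: pd.DataFrame, scale: ScaleConfig) -> dict:
    """Joint-tuning statistics of a tuning table: Pearson correlations of
    (d_t, d_prev), (v_left, v_right) and (mean velocity, mean disparity),
    plus the fraction of atoms preferring |d| <= 1 px."""

    def _rho(a: pd.Series, b: pd.Series) -> float:
        ok = a.notna() & b.notna()
        if ok.sum() < 3 or a[ok].std() == 0 or b[ok].std() == 0:
            return float("nan")
        return float(np.corrcoef(a[ok], b[ok])[0, 1])

    v_mean = (table["v_left"] + table["v_right"]) / 2.0
    d_mean = (table["d_t"] + table["d_prev"]) / 2.0
    d_t = table["d_t"]
    return {
        "rho_d_t_prev": _rho(table["d_t"], table["d_prev"]),
        "rho_v_lr": _rho(table["v_left"], table["v_right"]),
        "rho_v_d": _rho(v_mean, d_mean),
        "frac_d_within_1px": float(
            (d_t.abs() <= scale.deg_per_px).sum() / d_t.notna().sum())
        if d_t.notna().any() else float("nan"),
    }
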