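"""Per-A-scan attenuation estimation with a two-segment noise-boundary fit.

Each A-scan is modelled, in the single-scattering approximation, as an
exponential decay I(z) = I0 exp(-mu_i z) down to a depth z_noise at which
the signal reaches the system noise floor and becomes flat. The boundary
is chosen by minimizing the sum of the per-point mean squared errors of
the two segments,

    objective(b) = SSE_decay[0, b) / N_decay + SSE_noise[b, z_max] / N_noise,

where the decay segment is fitted by least squares on ln I vs depth and
the noise line is pinned to the decay fit evaluated at the boundary,
I_noise = I_fit(z_noise). Residuals are evaluated on the log-scale
A-scan by default (the decay and noise levels are the sloped and
horizontal lines of the log-intensity profile); a linear-domain objective
is available via ``domain="linear"``. Ties in the objective are broken toward the larger
boundary (maximal decay support).

Image-level features are the per-column attenuation mu_i averaged over
the image, and the lateral dispersion sigma_mu: the population standard
deviation of mu_i in a sliding window of N_A neighbouring A-scans
(150 um by default, i.e. N_A = 30 at the native lateral pitch),
averaged over the image.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .core import BScan, FitError, ParameterError, ascans_per_window

__all__ = [
    "AScanFit",
    "AttenuationFeatures",
    "fit_decay_segment",
    "fit_ascan",
    "attenuation_profile",
    "sigma_mu_profile",
    "attenuation_features",
]


@dataclass(frozen=True)
class AScanFit:
    """Two-segment fit of one A-scan."""

    mu: float            # attenuation, 1/mm
    i0: float            # fitted surface intensity
    z_noise_idx: int     # row index of the decay/noise boundary
    i_noise: float       # decay fit evaluated at the boundary
    objective: float     # two-segment normalized SSE at the boundary
    n_decay: int
    n_noise: int


@dataclass(frozen=True)
class AttenuationFeatures:
    """Image-level attenuation features."""

    mu: float            # image-mean attenuation, 1/mm
    sigma_mu: float      # image-mean windowed std of mu_i, 1/mm
    window_len_um: float
    n_a: int
    n_columns: int = 0
    n_failed: int = 0
    mean_z_noise_idx: float = float("nan")


def fit_decay_segment(intensity: np.ndarray,
                      depths_mm: np.ndarray) -> Tuple[float, float, float]:
    """Least-squares exponential fit of a decay segment.

    Fits a line to ln(intensity) vs depth; returns ``(mu, i0, mse)`` with
    mu = -slope (1/mm), i0 = exp(intercept), and the mean squared error
    evaluated in the linear intensity domain against i0 exp(-mu z).
    Non-positive samples are excluded from the fit; fewer than 3 valid
    points is an error.
    """
    y = np.asarray(intensity, dtype=float).ravel()
    z = np.asarray(depths_mm, dtype=float).ravel()
    if y.size != z.size:
        raise ParameterError("intensity and depth vectors differ in length")
    valid = y > 0
    if valid.sum() < 3:
        raise FitError("fewer than 3 strictly positive samples")
    zv, lv = z[valid], np.log(y[valid])
    slope, intercept = np.polyfit(zv, lv, 1)
    mu = -float(slope)
    i0 = float(np.exp(intercept))
    resid = y[valid] - i0 * np.exp(-mu * zv)
    mse = float(resid @ resid / resid.size)
    return mu, i0, mse


def fit_ascan(intensity: np.ndarray,
              pitch_axial_um: float,
              min_seg: int = 5,
              refractive_factor: float = 1.0,
              domain: str = "log",
              trim: float = 5.0,
              flat_tol: float = 0.5) -> AScanFit:
    """Two-segment fit of a full A-scan with automatic noise boundary.

    Every row index b with at least ``min_seg`` valid points on each side
    is a candidate boundary; the decay is fitted on [0, b) and the noise
    line I_noise = I_fit(z_b) evaluated on [b, end]. The candidate with
    the minimal two-segment objective wins, ties going to the larger b.

    ``domain`` selects where the objective's residuals live: ``"log"``
    (default) treats the A-scan on the log scale, where the decay is the
    sloped line and the noise level the horizontal line; ``"linear"``
    evaluates residuals in raw intensity. Under multiplicative speckle
    the log objective is far more stable — linear residuals let short,
    spuriously steep decay segments win the argmin.

    ``flat_tol`` encodes that a genuine noise region is flat: a
    candidate is admissible only when the measured log-slope of its tail
    implies at most ``flat_tol`` nats of total drop across the tail.
    Without this, one dark speckle grain under a bright surface forms a
    perfect steep "decay" of min_seg points and hijacks the argmin on
    columns whose signal never reaches the floor. When no tail is flat
    the column is treated as pure decay: the maximal decay segment is
    fitted (the largest candidate boundary).
    """
    if domain not in ("log", "linear"):
        raise ParameterError("domain must be 'log' or 'linear'")
    y = np.asarray(intensity, dtype=float).ravel()
    n = y.size
    if min_seg < 2:
        raise ParameterError("min_seg must be at least 2")
    if n < 2 * min_seg:
        raise FitError(f"column of {n} rows is shorter than 2*min_seg")
    z = np.arange(n) * pitch_axial_um * refractive_factor / 1000.0

    valid = y > 0
    w = valid.astype(float)
    yl = np.where(valid, np.log(np.where(valid, y, 1.0)), 0.0)
    # prefix sums for the weighted log-linear regression on [0, b)
    cw = np.cumsum(w)
    cz = np.cumsum(w * z)
    czz = np.cumsum(w * z * z)
    cl = np.cumsum(w * yl)
    czl = np.cumsum(w * z * yl)

    bs = np.arange(min_seg, n - min_seg + 1)
    Nd = cw[bs - 1]
    Sz, Szz, Sl, Szl = cz[bs - 1], czz[bs - 1], cl[bs - 1], czl[bs - 1]
    denom = Nd * Szz - Sz * Sz
    ok = (Nd >= min_seg) & (denom > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (Nd * Szl - Sz * Sl) / denom
        intercept = (Sl - slope * Sz) / Nd
    mu_b = -slope
    i0_b = np.exp(intercept)

    # residual matrices over candidates x rows
    if domain == "log":
        line_mat = intercept[:, None] - mu_b[:, None] * z[None, :]
        r2 = np.where(valid[None, :], (yl[None, :] - line_mat) ** 2, 0.0)
        noise_line = intercept - mu_b * z[bs]
        rn2 = np.where(valid[None, :],
                       (yl[None, :] - noise_line[:, None]) ** 2, 0.0)
    else:
        with np.errstate(over="ignore", invalid="ignore"):
            fit_mat = i0_b[:, None] * np.exp(-mu_b[:, None] * z[None, :])
        r2 = np.where(valid[None, :], (y[None, :] - fit_mat) ** 2, 0.0)
        noise_lin = i0_b * np.exp(-mu_b * z[bs])
        rn2 = np.where(valid[None, :],
                       (y[None, :] - noise_lin[:, None]) ** 2, 0.0)
    sse_decay = np.cumsum(r2, axis=1)[np.arange(bs.size), bs - 1]
    i_noise_b = i0_b * np.exp(-mu_b * z[bs])
    suffix = np.cumsum(rn2[:, ::-1], axis=1)[:, ::-1]
    sse_noise = suffix[np.arange(bs.size), bs]
    Nn = cw[-1] - cw[bs - 1]
    ok &= Nn >= min_seg

    with np.errstate(divide="ignore", invalid="ignore"):
        objective = sse_decay / Nd + sse_noise / Nn
    ok &= np.isfinite(objective)
    if not ok.any():
        raise FitError(
            f"no admissible boundary ({int(valid.sum())} valid of {n} points)")
    if flat_tol is not None:
        # measured log-slope of the tail [b, end) via suffix sums
        sw = cw[-1] - np.r_[0.0, cw[:-1]]
        sz = cz[-1] - np.r_[0.0, cz[:-1]]
        szz = czz[-1] - np.r_[0.0, czz[:-1]]
        sl_ = cl[-1] - np.r_[0.0, cl[:-1]]
        szl = czl[-1] - np.r_[0.0, czl[:-1]]
        tw, tz, tzz, tl, tzl = (a[bs] for a in (sw, sz, szz, sl_, szl))
        tden = tw * tzz - tz * tz
        with np.errstate(divide="ignore", invalid="ignore"):
            tail_slope = (tw * tzl - tz * tl) / tden
        tail_drop = np.abs(tail_slope) * (z[-1] - z[bs])
        flat = ok & (tden > 0) & np.isfinite(tail_drop) & (tail_drop <= flat_tol)
        if flat.any():
            ok = flat
        else:
            # no flat tail anywhere: pure decay, maximal decay support
            keep_last = np.zeros_like(ok)
            keep_last[np.flatnonzero(ok)[-1]] = True
            ok = keep_last
    objective = np.where(ok, objective, np.inf)
    best = objective.min()
    idx = int(np.flatnonzero(objective == best).max())  # ties -> larger b
    b = int(bs[idx])
    mu_hat, i0_hat = float(mu_b[idx]), float(i0_b[idx])
    i_noise = float(i_noise_b[idx])

    # Knee trim: an additive noise floor contaminates the log A-scan
    # well before the boundary, dragging the slope down; refit the decay
    # on the rows where the fitted line sits at least `trim` times above
    # the noise level (the boundary and objective stay as selected).
    # The refit only runs when the kept rows still span real decay
    # (>= 1.5 nats predicted drop over enough points) — otherwise the
    # "noise level" is in fact signal and trimming would fit noise.
    if trim > 1.0 and mu_hat > 0 and i_noise > 0:
        line = i0_hat * np.exp(-mu_hat * z[:b])
        keep = valid[:b] & (line >= trim * i_noise)
        if keep.sum() >= max(min_seg, 3):
            zk, lk = z[:b][keep], yl[:b][keep]
            if mu_hat * (zk.max() - zk.min()) >= 1.5:
                sl, ic = np.polyfit(zk, lk, 1)
                if np.isfinite(sl) and np.isfinite(ic):
                    mu_hat, i0_hat = -float(sl), float(np.exp(ic))
    return AScanFit(mu=mu_hat, i0=i0_hat,
                    z_noise_idx=b, i_noise=i_noise,
                    objective=float(best),
                    n_decay=int(Nd[idx]), n_noise=int(Nn[idx]))


def attenuation_profile(roi: BScan,
                        min_seg: int = 5,
                        domain: str = "log") -> Tuple[np.ndarray, List[Optional[AScanFit]]]:
    """Per-column attenuation estimates mu_i for an extracted ROI.

    Returns the mu profile (NaN for failed columns) and the per-column
    fits. More than 50% failed columns is an image-level error.
    """
    if not roi.roi_extracted:
        raise ParameterError("attenuation_profile requires an extracted ROI")
    pitch = roi.geometry.pitch_axial
    rf = roi.geometry.refractive_factor
    mu = np.full(roi.n_cols, np.nan)
    fits: List[Optional[AScanFit]] = [None] * roi.n_cols
    for c in range(roi.n_cols):
        try:
            f = fit_ascan(roi.intensity[:, c], pitch, min_seg=min_seg,
                          refractive_factor=rf, domain=domain)
        except FitError:
            continue
        mu[c] = f.mu
        fits[c] = f
    n_failed = int(np.isnan(mu).sum())
    if n_failed > 0.5 * roi.n_cols:
        raise FitError(f"{n_failed} of {roi.n_cols} columns failed to fit")
    return mu, fits


def sigma_mu_profile(mu_profile: np.ndarray, n_a: int = 30) -> np.ndarray:
    """Sliding-window lateral dispersion of the attenuation profile.

    For each column, the population standard deviation (1/N normalization)
    of mu_i over a centered window of ``n_a`` columns, truncated at the
    image edges. NaN entries (failed columns) are excluded per window.
    """
    mu = np.asarray(mu_profile, dtype=float).ravel()
    if n_a < 2:
        raise ParameterError("n_a must be at least 2")
    if mu.size < n_a:
        raise ParameterError(
            f"profile of {mu.size} columns shorter than the {n_a}-column window")
    half = n_a // 2
    out = np.full(mu.size, np.nan)
    for i in range(mu.size):
        lo = max(0, i - half)
        hi = min(mu.size, i - half + n_a)
        win = mu[lo:hi]
        win = win[np.isfinite(win)]
        if win.size >= 2:
            out[i] = win.std(ddof=0)
    return out


def attenuation_features(roi: BScan,
                         n_a: Optional[int] = None,
                         window_len_um: float = 150.0,
                         min_seg: int = 5,
                         domain: str = "log") -> AttenuationFeatures:
    """Image-level attenuation features (mu, sigma_mu) of an ROI.

    ``n_a`` defaults to the number of A-scans in a ``window_len_um``
    lateral window at the ROI's pitch (30 for the native geometry).
    Failed columns are excluded from both averages.
    """
    if n_a is None:
        n_a = ascans_per_window(window_len_um, roi.geometry.pitch_lateral)
    mu_prof, fits = attenuation_profile(roi, min_seg=min_seg, domain=domain)
    valid = np.isfinite(mu_prof)
    if not valid.any():
        raise FitError("empty attenuation profile")
    sig_prof = sigma_mu_profile(mu_prof, n_a=n_a)
    zs = [f.z_noise_idx for f in fits if f is not None]
    return AttenuationFeatures(
        mu=float(np.nanmean(mu_prof)),
        sigma_mu=float(np.nanmean(sig_prof)),
        window_len_um=n_a * roi.geometry.pitch_lateral,
        n_a=int(n_a),
        n_columns=roi.n_cols,
        n_failed=int((~valid).sum()),
        mean_z_noise_idx=float(np.mean(zs)) if zs else float("nan"),
    )
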