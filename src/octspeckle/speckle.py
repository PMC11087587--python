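"""Wavelet-domain speckle features of OCT B-scans.

The ROI image is decomposed with the 2-D discrete wavelet transform using
the biorthogonal *bior3.5* filter (symmetric boundary extension, chosen so
the basis avoids edge distortion). The three detail subbands at level a —
horizontal (HDC), vertical (VDC) and diagonal (DDC) — capture the
high-frequency speckle texture, and two scalars are derived from them:

* ``P_a``: the power of local brightness fluctuations, the sum of squared
  detail coefficients of all three subbands divided by K = N_X x N_Y, the
  number of pixels of the detail arrays at that level;
* ``sigma_Pa``: the population standard deviation, across the lateral
  (column) direction of the decomposed image, of the per-column mean
  power P_a^X(n_X) around P_a.

Levels 1 and 2 carry the speckle information for the emulated system;
higher levels mostly reflect noise and are not part of the feature set.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .core import BScan, DecompositionError, ParameterError

__all__ = [
    "WaveletDetail",
    "SpeckleFeatures",
    "dwt2_detail",
    "fluctuation_power",
    "lateral_power_profile",
    "power_std",
    "speckle_features",
]


@dataclass(frozen=True)
class WaveletDetail:
    """Detail subbands of one decomposition level (equal shapes)."""

    level: int
    hdc: np.ndarray
    vdc: np.ndarray
    ddc: np.ndarray
    wavelet: str = "bior3.5"
    mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ParameterError("decomposition level must be >= 1")
        if not (self.hdc.shape == self.vdc.shape == self.ddc.shape):
            raise ParameterError("detail subbands must share one shape")
        if self.hdc.size == 0:
            raise ParameterError("empty detail subbands")


@dataclass(frozen=True)
class SpeckleFeatures:
    """Fluctuation power and its lateral spread at levels 1 and 2."""

    p1: float
    sigma_p1: float
    p2: float
    sigma_p2: float
    wavelet: str = "bior3.5"
    mode: str = "symmetric"
    log_intensity: bool = False


def dwt2_detail(image: np.ndarray,
                level: int = 1,
                wavelet: str = "bior3.5",
                mode: str = "symmetric") -> WaveletDetail:
    """Detail subbands of the 2-D DWT at the requested level.

    The approximation band is cascaded down for level > 1; subband shapes
    follow the transform's downsample-by-2 convention with boundary
    extension.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ParameterError("image must be 2-D")
    if level < 1:
        raise ParameterError("level must be >= 1")
    wav = pywt.Wavelet(wavelet)
    # the approximation cascaded to the requested level must still cover
    # the filter support
    if min(img.shape) < wav.dec_len * 2 ** (level - 1):
        raise DecompositionError(
            f"image of shape {img.shape} too small for {wavelet} at level {level}")
    approx = img
    for _ in range(level):
        approx, (h, v, d) = pywt.dwt2(approx, wav, mode=mode)
    return WaveletDetail(level=level, hdc=h, vdc=v, ddc=d,
                         wavelet=wavelet, mode=mode)


def fluctuation_power(detail: WaveletDetail) -> float:
    """P_a: total squared detail energy per coefficient.

    Sum of squared HDC, VDC and DDC coefficients divided by
    K = N_X x N_Y, the pixel count of the detail arrays.
    """
    k = detail.hdc.size
    total = (np.sum(detail.hdc ** 2) + np.sum(detail.vdc ** 2)
             + np.sum(detail.ddc ** 2))
    return float(total / k)


def lateral_power_profile(detail: WaveletDetail) -> np.ndarray:
    """P_a^X(n_X): mean detail power over depth for each lateral position."""
    n_y = detail.hdc.shape[0]
    prof = (np.sum(detail.hdc ** 2, axis=0) + np.sum(detail.vdc ** 2, axis=0)
            + np.sum(detail.ddc ** 2, axis=0)) / n_y
    return prof


def power_std(detail: WaveletDetail) -> float:
    """sigma_Pa: population std of the lateral power profile around P_a."""
    if detail.hdc.shape[1] < 2:
        raise ParameterError("power_std needs at least 2 detail columns")
    prof = lateral_power_profile(detail)
    p_a = fluctuation_power(detail)
    return float(np.sqrt(np.mean((prof - p_a) ** 2)))


def speckle_features(roi: BScan,
                     wavelet: str = "bior3.5",
                     mode: str = "symmetric",
                     log_intensity: bool = False) -> SpeckleFeatures:
    """P and sigma_P at decomposition levels 1 and 2 of an extracted ROI.

    Features are computed on the linear normalized intensity by default;
    with ``log_intensity`` the image is log-transformed first (small
    positive floor applied to avoid log of zero).
    """
    if not roi.roi_extracted:
        raise ParameterError("speckle_features requires an extracted ROI")
    img = roi.intensity
    if log_intensity:
        positive = img[img > 0]
        if positive.size == 0:
            raise ParameterError("log intensity undefined for an all-zero ROI")
        img = np.log(np.clip(img, positive.min() * 1e-3, None))
    vals = {}
    for a in (1, 2):
        det = dwt2_detail(img, level=a, wavelet=wavelet, mode=mode)
        vals[f"p{a}"] = fluctuation_power(det)
        vals[f"sigma_p{a}"] = power_std(det)
    return SpeckleFeatures(p1=vals["p1"], sigma_p1=vals["sigma_p1"],
                           p2=vals["p2"], sigma_p2=vals["sigma_p2"],
                           wavelet=wavelet, mode=mode,
                           log_intensity=log_intensity)
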