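"""Raw B-scan conditioning: PSF compensation, interface normalization,
ROI alignment and inter-image correlation screening.

The stages mirror the usual endoscopic-OCT preparation order: divide out
the axial sensitivity profile h(z), normalize by the probe/glass interface
signal, locate the tissue-glass interface per column and shift columns so
the tissue surface sits at row 0, then crop distorted lateral edges.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core import (AlignmentError, BScan, CalibrationError, CorrelationError,
                   NormalizationError, ParameterError, PSFProfile)

__all__ = [
    "compensate_psf",
    "normalize_by_interface",
    "extract_roi",
    "cross_correlation",
    "correlation_screen",
    "CorrelationReport",
]


def compensate_psf(scan: BScan, psf: PSFProfile) -> BScan:
    """Divide each row by the system PSF h(z).

    Undoes the depth-dependent sensitivity in the measurement model
    I_m(z) = I0 exp(-mu z) h(z) so that the attenuation fit sees the pure
    decay. The PSF must cover the full image depth.
    """
    if len(psf) < scan.n_rows:
        raise CalibrationError(
            f"PSF length {len(psf)} shorter than image depth {scan.n_rows}")
    out = scan.intensity / psf.h[:scan.n_rows, None]
    return scan.with_intensity(out, psf_compensated=True)


def normalize_by_interface(scan: BScan,
                           interface_rows: Tuple[int, int] = (0, 3)) -> BScan:
    """Normalize intensities by the mean probe/glass interface signal.

    ``interface_rows`` is a half-open row range [start, stop). After the
    call, the mean of that band is exactly 1.
    """
    start, stop = interface_rows
    if not (0 <= start < stop <= scan.n_rows):
        raise ParameterError("interface_rows out of image bounds")
    band_mean = float(scan.intensity[start:stop].mean())
    if band_mean <= 0:
        raise NormalizationError("interface band has non-positive mean")
    return scan.with_intensity(scan.intensity / band_mean, normalized=True)


def extract_roi(scan: BScan,
                side_crop: int = 15,
                probe_rows: int = 3,
                threshold_frac: float = 0.5,
                min_tissue_rows: int = 32,
                median_cols: int = 5,
                max_fail_frac: float = 0.2,
                max_offset: int = 10) -> BScan:
    """Align columns on the tissue-glass interface and crop to the ROI.

    Per column the interface is the first row below the probe band whose
    intensity reaches ``threshold_frac`` of that column's maximum (below
    the band); the per-column row indices are smoothed with a
    ``median_cols``-wide median to reject outliers, and detections more
    than ``max_offset`` rows from the cross-column median are clamped to
    it (dark surface speckle otherwise drags single columns far too
    deep). Columns are shifted so the interface sits at row 0, rows above
    it are discarded, the image is cut to the shallowest common depth,
    and ``side_crop`` columns are removed from each lateral edge.
    """
    if side_crop < 0 or probe_rows < 0:
        raise ParameterError("side_crop and probe_rows must be >= 0")
    if not 0 < threshold_frac <= 1:
        raise ParameterError("threshold_frac must lie in (0, 1]")
    if scan.n_rows - probe_rows < min_tissue_rows:
        raise AlignmentError("image too shallow below the probe band")
    if scan.n_cols <= 2 * side_crop:
        raise ParameterError("side_crop removes every column")

    search = scan.intensity[probe_rows:]
    colmax = search.max(axis=0)
    failed = colmax <= 0
    if failed.mean() > max_fail_frac:
        raise AlignmentError(
            f"interface not found in {int(failed.sum())} of {scan.n_cols} columns")
    thr = threshold_frac * colmax
    # first row at/above threshold; argmax on the boolean mask
    iface = np.argmax(search >= thr[None, :], axis=0)
    if failed.any():
        # fill failed columns with the median of their neighbours
        iface = iface.astype(float)
        iface[failed] = np.nan
        med = np.nanmedian(iface)
        iface[failed] = med
        iface = iface.astype(int)
    if median_cols > 1:
        iface = ndimage.median_filter(iface, size=median_cols,
                                      mode="nearest").astype(int)
    # a dark speckle at the true surface can push a column's detection
    # far too deep; clamp detections that stray from the cross-column
    # median beyond the plausible gap unevenness
    if max_offset is not None:
        global_med = int(np.median(iface))
        stray = np.abs(iface - global_med) > max_offset
        iface[stray] = global_med
    iface_abs = probe_rows + iface

    n_out = scan.n_rows - int(iface_abs.max())
    if n_out < min_tissue_rows:
        raise AlignmentError(
            f"only {n_out} tissue rows after alignment (< {min_tissue_rows})")
    cols = np.arange(scan.n_cols)
    rows = np.arange(n_out)[:, None] + iface_abs[None, :]
    aligned = scan.intensity[rows, cols[None, :]]
    if side_crop:
        aligned = aligned[:, side_crop:-side_crop]
    return scan.with_intensity(aligned, roi_extracted=True)


def _common_shape(a: np.ndarray, b: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    r = min(a.shape[0], b.shape[0])
    c = min(a.shape[1], b.shape[1])
    return a[:r, :c], b[:r, :c]


def cross_correlation(a: BScan, b: BScan) -> float:
    """Zero-lag Pearson correlation of two intensity matrices.

    Images of unequal shape are cropped to their common top-left overlap.
    Constant images make the coefficient undefined.
    """
    x, y = _common_shape(a.intensity, b.intensity)
    x = x.ravel() - x.mean()
    y = y.ravel() - y.mean()
    sx = np.sqrt(x @ x)
    sy = np.sqrt(y @ y)
    if sx == 0 or sy == 0:
        raise CorrelationError("correlation undefined for a constant image")
    return float(np.clip((x @ y) / (sx * sy), -1.0, 1.0))


@dataclass(frozen=True)
class CorrelationReport:
    """Within-patient vs cross-patient image correlation summary."""

    max_within: float
    mean_within: float
    max_cross: float
    mean_cross: float
    n_within: int
    n_cross: int
    flagged: bool
    skipped: bool = False


def correlation_screen(scans: Sequence[BScan],
                       margin: float = 0.05,
                       hard_max: float = 0.9) -> CorrelationReport:
    """Screen a cohort for excessive within-patient image correlation.

    Correlations are computed between all same-class image pairs, split by
    whether the pair shares a patient. The cohort is flagged when the
    within-patient maximum exceeds ``hard_max`` (absolute cap) or exceeds
    the cross-patient maximum by more than ``margin``.
    """
    if len(scans) < 2:
        warnings.warn("fewer than 2 images; correlation screening skipped")
        return CorrelationReport(np.nan, np.nan, np.nan, np.nan, 0, 0,
                                 flagged=False, skipped=True)
    patients = {s.patient_id for s in scans}
    if len(patients) < 2:
        raise ParameterError("correlation screening needs at least 2 patients")
    within, cross = [], []
    for i in range(len(scans)):
        for j in range(i + 1, len(scans)):
            a, b = scans[i], scans[j]
            if a.label != b.label:
                continue
            r = cross_correlation(a, b)
            (within if a.patient_id == b.patient_id else cross).append(r)
    mx_w = max(within) if within else np.nan
    mn_w = float(np.mean(within)) if within else np.nan
    mx_c = max(cross) if cross else np.nan
    mn_c = float(np.mean(cross)) if cross else np.nan
    flagged = bool(within) and (mx_w > hard_max
                                or (bool(cross) and mx_w > mx_c + margin))
    return CorrelationReport(mx_w, mn_w, mx_c, mn_c,
                             len(within), len(cross), flagged=flagged)
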