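"""Core containers and exceptions shared across the pipeline.

The imaging convention throughout the package is: row index = axial depth
(increasing downward into the tissue), column index = lateral position
(one column per A-scan). All indices are 0-based. Physical pitches are
carried in micrometres; depths derived from them are expressed in
millimetres so that attenuation coefficients come out in 1/mm.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "ScanGeometry",
    "BScan",
    "PSFProfile",
    "ascans_per_window",
    "ParameterError",
    "CalibrationError",
    "NormalizationError",
    "AlignmentError",
    "CorrelationError",
    "FitError",
    "DecompositionError",
    "DegenerateModelError",
    "UndefinedMetricError",
    "ConfigurationError",
]


class ParameterError(ValueError):
    """Invalid parameter value for a generator or an analysis routine."""


class CalibrationError(ValueError):
    """PSF profile unusable (wrong length, non-positive entries)."""


class NormalizationError(ValueError):
    """Interface band unusable for normalization (zero or negative mean)."""


class AlignmentError(RuntimeError):
    """Tissue-glass interface could not be located reliably."""


class CorrelationError(RuntimeError):
    """Cross-correlation undefined (constant image, empty overlap)."""


class FitError(RuntimeError):
    """Attenuation fit failed (too few valid points, no admissible boundary)."""


class DecompositionError(ValueError):
    """Image too small for the requested wavelet decomposition level."""


class DegenerateModelError(RuntimeError):
    """LDA cannot be built (coincident class means)."""


class UndefinedMetricError(RuntimeError):
    """All confusion counts zero; no metric is defined."""


class ConfigurationError(ValueError):
    """Invalid pipeline configuration (unknown feature name, bad stage option)."""


@dataclass(frozen=True)
class ScanGeometry:
    """Sampling geometry of a B-scan.

    Defaults mirror the endoscopic time-domain system the analysis was
    designed around: 400 A-scans across a 1.96 mm lateral field and
    256 axial samples across 1 mm of depth (in air), i.e. 4.9 um lateral
    and ~3.906 um axial pitch. ``refractive_factor`` optionally converts
    geometric to optical depth; the default of 1 keeps depth geometric.
    """

    n_lateral: int = 400
    n_axial: int = 256
    pitch_lateral: float = 1960.0 / 400.0  # um per A-scan
    pitch_axial: float = 1000.0 / 256.0    # um per row, in air
    refractive_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.n_lateral <= 0 or self.n_axial <= 0:
            raise ParameterError("pixel counts must be positive")
        if self.pitch_lateral <= 0 or self.pitch_axial <= 0:
            raise ParameterError("pixel pitches must be positive")
        if self.refractive_factor <= 0:
            raise ParameterError("refractive_factor must be positive")

    @property
    def width_mm(self) -> float:
        return self.n_lateral * self.pitch_lateral / 1000.0

    @property
    def depth_mm_total(self) -> float:
        return self.n_axial * self.pitch_axial / 1000.0

    def depth_mm(self, n_rows: Optional[int] = None) -> np.ndarray:
        """Depth of each row in mm, measured from row 0."""
        n = self.n_axial if n_rows is None else n_rows
        return np.arange(n) * self.pitch_axial * self.refractive_factor / 1000.0


def ascans_per_window(window_um: float = 150.0,
                      pitch_lateral_um: float = 1960.0 / 400.0) -> int:
    """Number of A-scans spanned by a lateral analysis window.

    The attenuation-dispersion window defaults to 150 um (the typical
    calibre of a brain vessel); with the default 4.9 um lateral pitch it
    holds ``floor(150 / 4.9) = 30`` A-scans.
    """
    if window_um <= 0 or pitch_lateral_um <= 0:
        raise ParameterError("window and pitch must be positive")
    return int(np.floor(window_um / pitch_lateral_um))


@dataclass
class BScan:
    """A single OCT B-scan: intensity matrix plus geometry and provenance.

    ``intensity`` is a finite, nonnegative float array of shape
    ``(geometry.n_axial, geometry.n_lateral)`` in arbitrary linear units.
    Provenance flags record which preprocessing stages have been applied.
    """

    intensity: np.ndarray
    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    patient_id: str = ""
    label: str = "unknown"
    scan_id: str = ""
    psf_compensated: bool = False
    normalized: bool = False
    roi_extracted: bool = False

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ParameterError("intensity must be a 2-D matrix")
        if not np.all(np.isfinite(self.intensity)):
            raise ParameterError("intensity must be finite")
        if np.any(self.intensity < 0):
            raise ParameterError("intensity must be nonnegative")
        if self.intensity.shape != (self.geometry.n_axial, self.geometry.n_lateral):
            raise ParameterError(
                f"intensity shape {self.intensity.shape} does not match geometry "
                f"({self.geometry.n_axial}, {self.geometry.n_lateral})")

    @property
    def n_rows(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_cols(self) -> int:
        return self.intensity.shape[1]

    def with_intensity(self, intensity: np.ndarray, **flags) -> "BScan":
        """Copy of this scan with a new intensity matrix.

        Geometry pixel counts follow the new matrix shape; pitches and
        metadata are preserved. Provenance flags may be overridden via
        keyword arguments.
        """
        intensity = np.asarray(intensity, dtype=float)
        geom = replace(self.geometry, n_axial=intensity.shape[0],
                       n_lateral=intensity.shape[1])
        out = BScan(
            intensity=intensity,
            geometry=geom,
            patient_id=self.patient_id,
            label=self.label,
            scan_id=self.scan_id,
            psf_compensated=self.psf_compensated,
            normalized=self.normalized,
            roi_extracted=self.roi_extracted,
        )
        for name, value in flags.items():
            if not hasattr(out, name):
                raise ParameterError(f"unknown BScan flag {name!r}")
            setattr(out, name, value)
        return out


@dataclass(frozen=True)
class PSFProfile:
    """Axial point-spread / sensitivity profile h(z) of the OCT system.

    One strictly positive entry per depth row, sampled on the same axial
    grid as the raw B-scans. It multiplies the ideal decay in the forward
    measurement model I_m(z) = I0 exp(-mu z) h(z) and is divided out
    during preprocessing.
    """

    h: np.ndarray

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=float).ravel()
        object.__setattr__(self, "h", h)
        if h.size == 0:
            raise CalibrationError("PSF profile is empty")
        if not np.all(np.isfinite(h)) or np.any(h <= 0):
            raise CalibrationError("PSF profile must be strictly positive and finite")

    def __len__(self) -> int:
        return int(self.h.size)
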