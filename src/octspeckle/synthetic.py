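"""Synthetic OCT-like B-scans and patient-structured cohorts.

The generator produces images with the statistical structure the analysis
pipeline assumes: exponential depth decay with laterally heterogeneous
attenuation, multiplicative speckle with controllable grain and contrast,
an additive noise floor, and a bright probe/glass interface band above the
tissue. It emulates those features, not OCT wave propagation; see
docs/methods.md for what it does and does not reproduce.

Speckle model
-------------
A complex circular Gaussian white field is low-pass filtered (Gaussian
kernel, separable in the two axes), its squared magnitude taken and
rescaled to unit mean. The resulting fluctuation is standardized to unit
variance and blended with the constant field 1, scaled by the requested
contrast, so the empirical std/mean of the output matches the contrast
parameter; at 1-pixel grain and contrast 1 this reduces to fully developed
(exponential-intensity) speckle. Negative excursions created by the
standardization are clipped at zero and the field renormalized to unit
mean.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage

from .core import BScan, ParameterError, PSFProfile, ScanGeometry

__all__ = [
    "TissueSpec",
    "ClassSpec",
    "CohortSpec",
    "generate_speckle_field",
    "generate_bscan",
    "generate_cohort",
]

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator, None]

# half width at half maximum of a unit-sigma Gaussian
_HWHM = float(np.sqrt(2.0 * np.log(2.0)))


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class TissueSpec:
    """Statistical description of one tissue class.

    Parameters
    ----------
    mu_mean : float
        Mean attenuation coefficient, 1/mm.
    mu_sd_lateral : float
        Standard deviation of the lateral attenuation fluctuation, 1/mm.
    mu_corr_len : float
        Lateral correlation length of those fluctuations, um. Defaults to
        150 um, the typical brain-vessel calibre driving attenuation
        heterogeneity.
    speckle_grain_lat, speckle_grain_ax : float
        Speckle correlation lengths (um), defined as the half-width at
        half maximum of the intensity autocorrelation. Defaults match the
        emulated system's 20 um lateral / 24 um axial resolution.
    speckle_contrast : float
        Target std/mean of the multiplicative speckle field, in [0, 1].
    noise_floor : float
        Additive noise floor as a fraction of the surface intensity.
    i0 : float
        Surface intensity in arbitrary linear units.
    """

    mu_mean: float = 4.0
    mu_sd_lateral: float = 0.5
    mu_corr_len: float = 150.0
    speckle_grain_lat: float = 20.0
    speckle_grain_ax: float = 24.0
    speckle_contrast: float = 0.5
    noise_floor: float = 0.01
    i0: float = 1.0

    def __post_init__(self) -> None:
        if self.mu_mean <= 0:
            raise ParameterError("mu_mean must be positive")
        if self.mu_sd_lateral < 0 or self.mu_corr_len <= 0:
            raise ParameterError("invalid lateral attenuation fluctuation spec")
        if self.speckle_grain_lat <= 0 or self.speckle_grain_ax <= 0:
            raise ParameterError("speckle grain sizes must be positive")
        if not 0.0 <= self.speckle_contrast <= 1.0:
            raise ParameterError("speckle_contrast must lie in [0, 1]")
        if self.noise_floor < 0:
            raise ParameterError("noise_floor must be nonnegative")
        if self.i0 <= 0:
            raise ParameterError("i0 must be positive")


def generate_speckle_field(geometry: ScanGeometry,
                           grain_lat: float,
                           grain_ax: float,
                           contrast: float,
                           seed: SeedLike = None,
                           n_rows: Optional[int] = None) -> np.ndarray:
    """Unit-mean nonnegative multiplicative speckle field.

    Parameters are physical grain sizes in um (converted to pixels via the
    geometry pitches) and the target contrast (std/mean). ``n_rows``
    overrides the axial extent, used when the field covers only the tissue
    part of an image.
    """
    if not 0.0 <= contrast <= 1.0:
        raise ParameterError("contrast must lie in [0, 1]")
    if grain_lat <= 0 or grain_ax <= 0:
        raise ParameterError("grain sizes must be positive")
    g_lat_px = grain_lat / geometry.pitch_lateral
    g_ax_px = grain_ax / geometry.pitch_axial
    if g_lat_px < 1.0 or g_ax_px < 1.0:
        raise ParameterError("speckle grain must be at least one pixel pitch")
    shape = (geometry.n_axial if n_rows is None else n_rows, geometry.n_lateral)
    if contrast == 0.0:
        return np.ones(shape)
    rng = _rng(seed)
    fld = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    # A Gaussian filter of width sigma on the complex field gives an
    # intensity autocorrelation of width sigma; a 1-px grain means no
    # filtering (delta-correlated, fully developed limit).
    sig_ax = np.sqrt(max(g_ax_px**2 - 1.0, 0.0)) / _HWHM
    sig_lat = np.sqrt(max(g_lat_px**2 - 1.0, 0.0)) / _HWHM
    if sig_ax > 0 or sig_lat > 0:
        fld = (ndimage.gaussian_filter(fld.real, sigma=(sig_ax, sig_lat), mode="wrap")
               + 1j * ndimage.gaussian_filter(fld.imag, sigma=(sig_ax, sig_lat),
                                              mode="wrap"))
    inten = np.abs(fld) ** 2
    inten /= inten.mean()
    fluct = inten - 1.0
    s = fluct.std()
    if s == 0:
        return np.ones(shape)
    out = 1.0 + contrast * fluct / s
    np.clip(out, 0.0, None, out=out)
    out /= out.mean()
    return out


def generate_bscan(tissue: TissueSpec,
                   geometry: ScanGeometry = ScanGeometry(),
                   psf: Optional[PSFProfile] = None,
                   seed: SeedLike = None,
                   interface_rows: int = 3,
                   interface_level: Optional[float] = None,
                   gap_rows: int = 0,
                   patient_id: str = "",
                   label: str = "unknown",
                   scan_id: str = "") -> BScan:
    """Forward-model one B-scan.

    Column c of the tissue region follows
    ``i0 * exp(-mu_c * z) * speckle(z, c) * h(z) + floor`` with z the
    depth in mm below the tissue surface and ``mu_c`` the class mean plus
    a smoothed lateral fluctuation. A saturated interface band of
    ``interface_rows`` rows (level ``interface_level``, default 2*i0)
    sits at the top, optionally separated from the tissue by ``gap_rows``
    floor-level rows, so that ROI extraction is exercised.
    """
    if interface_rows < 0 or gap_rows < 0:
        raise ParameterError("interface_rows and gap_rows must be >= 0")
    t0 = interface_rows + gap_rows
    n_tissue = geometry.n_axial - t0
    if n_tissue < 4:
        raise ParameterError("geometry too shallow for the interface band")
    rng = _rng(seed)

    # laterally fluctuating attenuation, correlation length mu_corr_len
    if tissue.mu_sd_lateral > 0:
        white = rng.standard_normal(geometry.n_lateral)
        sig = tissue.mu_corr_len / geometry.pitch_lateral
        smooth = ndimage.gaussian_filter1d(white, sigma=sig, mode="wrap")
        smooth -= smooth.mean()  # zero-mean before rescaling the spread
        sd = smooth.std()
        fluct = smooth / sd * tissue.mu_sd_lateral if sd > 0 else 0.0
        mu_c = tissue.mu_mean + fluct
        np.clip(mu_c, 0.05 * tissue.mu_mean, None, out=mu_c)
    else:
        mu_c = np.full(geometry.n_lateral, tissue.mu_mean)

    speckle = generate_speckle_field(
        geometry, tissue.speckle_grain_lat, tissue.speckle_grain_ax,
        tissue.speckle_contrast, seed=rng, n_rows=n_tissue)

    z = geometry.depth_mm(n_tissue)  # depth from tissue surface, mm
    img = np.zeros((geometry.n_axial, geometry.n_lateral))
    img[t0:] = tissue.i0 * np.exp(-np.outer(z, mu_c)) * speckle

    if psf is not None:
        if len(psf) < geometry.n_axial:
            raise ParameterError("PSF profile shorter than the image depth")
        img *= psf.h[:geometry.n_axial, None]

    if tissue.noise_floor > 0:
        floor = tissue.noise_floor * tissue.i0 * (
            1.0 + 0.1 * rng.standard_normal(img.shape))
        img += floor

    if interface_rows > 0:
        level = 2.0 * tissue.i0 if interface_level is None else interface_level
        img[:interface_rows] = level

    np.clip(img, 0.0, None, out=img)
    return BScan(intensity=img, geometry=geometry, patient_id=patient_id,
                 label=label, scan_id=scan_id)


@dataclass(frozen=True)
class ClassSpec:
    """One tissue class in a cohort: its spec and its patient structure."""

    label: str
    tissue: TissueSpec = field(default_factory=TissueSpec)
    n_patients: int = 3
    n_scans: int = 4

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ParameterError("need at least 2 patients per class for grouped CV")
        if self.n_scans < 1:
            raise ParameterError("need at least 1 scan per patient")


@dataclass(frozen=True)
class CohortSpec:
    """Patient-structured multi-class cohort.

    ``patient_jitter`` is the relative log-normal spread applied per
    patient to the class tissue parameters (attenuation, contrast, grain),
    so scans from one patient correlate more than scans across patients;
    zero disables it.
    """

    classes: Sequence[ClassSpec]
    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    seed: int = 0
    patient_jitter: float = 0.05
    interface_rows: int = 3
    gap_rows: int = 0
    psf: Optional[PSFProfile] = None

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ParameterError("a cohort needs at least 2 classes")
        labels = [c.label for c in self.classes]
        if len(set(labels)) != len(labels):
            raise ParameterError("class labels must be unique")
        if self.patient_jitter < 0:
            raise ParameterError("patient_jitter must be nonnegative")


def _jitter_tissue(tissue: TissueSpec, jitter: float,
                   rng: np.random.Generator) -> TissueSpec:
    """Per-patient log-normal jitter of the class tissue parameters."""
    if jitter == 0:
        return tissue
    f = np.exp(jitter * rng.standard_normal(4))
    return replace(
        tissue,
        mu_mean=tissue.mu_mean * f[0],
        speckle_contrast=float(np.clip(tissue.speckle_contrast * f[1], 0.0, 1.0)),
        speckle_grain_lat=tissue.speckle_grain_lat * f[2],
        speckle_grain_ax=tissue.speckle_grain_ax * f[3],
    )


def generate_cohort(cohort: CohortSpec) -> list[BScan]:
    """Generate every scan of a cohort, deterministically under its seed.

    Patient IDs are ``{label}-p{j}`` and scan IDs ``{label}-p{j}-s{i}``.
    Seeds are expanded with ``SeedSequence(seed).spawn`` in a fixed
    (class, patient, scan) order, so the cohort is bit-reproducible.
    """
    scans: list[BScan] = []
    for ci, cls in enumerate(cohort.classes):
        for pj in range(cls.n_patients):
            patient_ss, *scan_ss = np.random.SeedSequence(
                entropy=cohort.seed, spawn_key=(ci, pj)).spawn(cls.n_scans + 1)
            patient_tissue = _jitter_tissue(
                cls.tissue, cohort.patient_jitter,
                np.random.default_rng(patient_ss))
            pid = f"{cls.label}-p{pj}"
            for si in range(cls.n_scans):
                scans.append(generate_bscan(
                    patient_tissue, cohort.geometry, psf=cohort.psf,
                    seed=scan_ss[si],
                    interface_rows=cohort.interface_rows,
                    gap_rows=cohort.gap_rows,
                    patient_id=pid, label=cls.label,
                    scan_id=f"{pid}-s{si}"))
    return scans
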