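"""File I/O: B-scans as 16-bit TIFF or CSV matrices, PSF profiles as CSV,
cohort manifests and feature/metrics tables as CSV with a units row.

TIFF files carry a JSON ImageDescription with the intensity scale factor
(uint16 quantization), the pixel pitches and the scan metadata, so a
round trip preserves geometry and provenance.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile

from .core import BScan, ParameterError, PSFProfile, ScanGeometry

__all__ = [
    "write_bscan_tiff", "read_bscan_tiff",
    "write_bscan_csv", "read_bscan_csv",
    "read_psf_csv", "write_psf_csv",
    "write_manifest", "read_manifest",
    "write_table", "read_table",
]

PathLike = Union[str, Path]


def _scan_meta(scan: BScan, scale: float) -> dict:
    g = scan.geometry
    return {
        "scale": scale,
        "pitch_lateral_um": g.pitch_lateral,
        "pitch_axial_um": g.pitch_axial,
        "refractive_factor": g.refractive_factor,
        "patient_id": scan.patient_id,
        "label": scan.label,
        "scan_id": scan.scan_id,
        "psf_compensated": scan.psf_compensated,
        "normalized": scan.normalized,
        "roi_extracted": scan.roi_extracted,
    }


def write_bscan_tiff(scan: BScan, path: PathLike) -> None:
    """Write a B-scan as a 16-bit grayscale TIFF with JSON metadata."""
    peak = float(scan.intensity.max())
    scale = peak / 65535.0 if peak > 0 else 1.0
    raw = np.round(scan.intensity / scale).astype(np.uint16) if peak > 0 \
        else np.zeros_like(scan.intensity, dtype=np.uint16)
    tifffile.imwrite(str(path), raw,
                     description=json.dumps(_scan_meta(scan, scale)))


def read_bscan_tiff(path: PathLike) -> BScan:
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        raw = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    if raw.ndim != 2:
        raise ParameterError(f"{path}: expected a single 2-D image")
    scale = float(meta.get("scale", 1.0))
    geom = ScanGeometry(
        n_lateral=raw.shape[1], n_axial=raw.shape[0],
        pitch_lateral=float(meta.get("pitch_lateral_um", ScanGeometry.pitch_lateral)),
        pitch_axial=float(meta.get("pitch_axial_um", ScanGeometry.pitch_axial)),
        refractive_factor=float(meta.get("refractive_factor", 1.0)))
    return BScan(intensity=raw.astype(float) * scale, geometry=geom,
                 patient_id=str(meta.get("patient_id", "")),
                 label=str(meta.get("label", "unknown")),
                 scan_id=str(meta.get("scan_id", "")),
                 psf_compensated=bool(meta.get("psf_compensated", False)),
                 normalized=bool(meta.get("normalized", False)),
                 roi_extracted=bool(meta.get("roi_extracted", False)))


def write_bscan_csv(scan: BScan, path: PathLike) -> None:
    """Debug export: raw intensity matrix as CSV (no metadata)."""
    np.savetxt(str(path), scan.intensity, delimiter=",")


def read_bscan_csv(path: PathLike,
                   geometry: Optional[ScanGeometry] = None, **meta) -> BScan:
    arr = np.loadtxt(str(path), delimiter=",", ndmin=2)
    if geometry is None:
        geometry = ScanGeometry(n_lateral=arr.shape[1], n_axial=arr.shape[0])
    return BScan(intensity=arr, geometry=geometry, **meta)


def write_psf_csv(psf: PSFProfile, path: PathLike) -> None:
    pd.DataFrame({"h": psf.h}).to_csv(path, index=False)


def read_psf_csv(path: PathLike) -> PSFProfile:
    df = pd.read_csv(path)
    col = "h" if "h" in df.columns else df.columns[0]
    return PSFProfile(h=df[col].to_numpy(dtype=float))


def write_manifest(scans: Sequence[BScan], path: PathLike,
                   extra: Optional[Dict[str, Sequence]] = None) -> None:
    """Cohort manifest: one row per scan with IDs, label and geometry."""
    rows = []
    for s in scans:
        rows.append({
            "scan_id": s.scan_id, "patient_id": s.patient_id, "label": s.label,
            "n_lateral": s.geometry.n_lateral, "n_axial": s.geometry.n_axial,
            "pitch_lateral_um": s.geometry.pitch_lateral,
            "pitch_axial_um": s.geometry.pitch_axial,
        })
    df = pd.DataFrame(rows)
    if extra:
        for k, v in extra.items():
            df[k] = list(v)
    df.to_csv(path, index=False)


def read_manifest(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(df: pd.DataFrame, path: PathLike,
                units: Optional[Dict[str, str]] = None,
                header_comments: Optional[Sequence[str]] = None) -> None:
    """CSV with optional '#' comment header lines and a units row.

    The units row sits directly below the column header; columns without
    a stated unit get '-'. Read back with :func:`read_table`.
    """
    path = Path(path)
    units = units or {}
    with open(path, "w") as fh:
        for line in header_comments or ():
            fh.write(f"# {line}\n")
        fh.write(",".join(map(str, df.columns)) + "\n")
        fh.write(",".join(units.get(c, "-") for c in df.columns) + "\n")
        df.to_csv(fh, index=False, header=False)


def read_table(path: PathLike, units_row: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if units_row and len(df) > 0:
        df = df.iloc[1:].reset_index(drop=True)
        for c in df.columns:
            try:
                df[c] = pd.to_numeric(df[c])
            except (ValueError, TypeError):
                vals = set(df[c].dropna().unique())
                if vals and vals <= {"True", "False"}:
                    df[c] = df[c] == "True"
    return df
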