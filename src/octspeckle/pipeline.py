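"""Configurable simulate -> preprocess -> features -> evaluate pipeline.

A :class:`PipelineConfig` (usually loaded from YAML) fully determines a
run: one global seed is expanded into per-stage child seeds, every stage
writes its outputs and parameters under the run directory, and a rerun
with the same config and seed is bit-identical. Stages whose outputs
already exist are skipped, so partial reruns resume where they stopped.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd
import yaml

from . import io as oio
from .attenuation import attenuation_features
from .classify import DEFAULT_COMBINATIONS, evaluate_combinations
from .core import BScan, ConfigurationError, ScanGeometry
from .preprocess import (compensate_psf, correlation_screen, extract_roi,
                         normalize_by_interface)
from .speckle import speckle_features
from .synthetic import ClassSpec, CohortSpec, TissueSpec, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "extract_features",
           "preprocess_scan"]

log = logging.getLogger("octspeckle")


@dataclass
class PipelineConfig:
    """Everything one pipeline run depends on.

    ``classes`` maps label -> {tissue params, n_patients, n_scans};
    tissue params accept any :class:`TissueSpec` field. All other keys
    configure individual stages; see the attribute defaults.
    """

    classes: Dict[str, dict] = field(default_factory=lambda: {
        "intact": {"mu_mean": 6.0, "n_patients": 3, "n_scans": 4},
        "glioma": {"mu_mean": 3.0, "n_patients": 3, "n_scans": 4},
    })
    geometry: dict = field(default_factory=dict)
    seed: int = 0
    patient_jitter: float = 0.05
    interface_rows: int = 3
    gap_rows: int = 0
    # preprocessing
    psf_path: Optional[str] = None
    side_crop: int = 15
    threshold_frac: float = 0.5
    min_tissue_rows: int = 32
    # attenuation
    n_a: Optional[int] = None
    window_len_um: float = 150.0
    min_seg: int = 5
    # speckle
    wavelet: str = "bior3.5"
    boundary_mode: str = "symmetric"
    log_intensity: bool = False
    # classification
    combinations: Optional[List[List[str]]] = None
    k: Union[int, str] = "max"
    ridge: float = 0.0
    out_dir: str = "runs/run0"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def scan_geometry(self) -> ScanGeometry:
        return ScanGeometry(**self.geometry)

    def cohort_spec(self) -> CohortSpec:
        if len(self.classes) < 2:
            raise ConfigurationError("need at least 2 classes")
        specs = []
        for label, params in self.classes.items():
            params = dict(params)
            n_patients = int(params.pop("n_patients", 3))
            n_scans = int(params.pop("n_scans", 4))
            specs.append(ClassSpec(label=label, tissue=TissueSpec(**params),
                                   n_patients=n_patients, n_scans=n_scans))
        psf = oio.read_psf_csv(self.psf_path) if self.psf_path else None
        return CohortSpec(classes=tuple(specs), geometry=self.scan_geometry(),
                          seed=self.seed, patient_jitter=self.patient_jitter,
                          interface_rows=self.interface_rows,
                          gap_rows=self.gap_rows, psf=psf)


def preprocess_scan(scan: BScan, config: PipelineConfig) -> BScan:
    """PSF compensation, interface normalization and ROI extraction."""
    if config.psf_path:
        scan = compensate_psf(scan, oio.read_psf_csv(config.psf_path))
    if config.interface_rows > 0:
        scan = normalize_by_interface(scan, (0, config.interface_rows))
    return extract_roi(scan, side_crop=config.side_crop,
                       probe_rows=config.interface_rows + config.gap_rows,
                       threshold_frac=config.threshold_frac,
                       min_tissue_rows=config.min_tissue_rows)


def extract_features(rois: Sequence[BScan],
                     config: Optional[PipelineConfig] = None) -> pd.DataFrame:
    """Per-image attenuation and speckle feature table."""
    config = config or PipelineConfig()
    rows = []
    for roi in rois:
        att = attenuation_features(roi, n_a=config.n_a,
                                   window_len_um=config.window_len_um,
                                   min_seg=config.min_seg)
        spk = speckle_features(roi, wavelet=config.wavelet,
                               mode=config.boundary_mode,
                               log_intensity=config.log_intensity)
        rows.append({
            "scan_id": roi.scan_id, "patient_id": roi.patient_id,
            "label": roi.label,
            "mu": att.mu, "sigma_mu": att.sigma_mu,
            "p1": spk.p1, "sigma_p1": spk.sigma_p1,
            "p2": spk.p2, "sigma_p2": spk.sigma_p2,
            "n_a": att.n_a, "n_failed": att.n_failed,
            "mean_z_noise_idx": att.mean_z_noise_idx,
            "wavelet": spk.wavelet, "boundary_mode": spk.mode,
        })
    return pd.DataFrame(rows)


FEATURE_UNITS = {
    "mu": "1/mm", "sigma_mu": "1/mm",
    "p1": "intensity^2", "sigma_p1": "intensity^2",
    "p2": "intensity^2", "sigma_p2": "intensity^2",
    "mean_z_noise_idx": "rows",
}


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage, resuming from existing stage outputs.

    Returns the run directory containing scans/, rois/, manifest.csv,
    screening.csv, features.csv, metrics.csv, roc.csv, config.yaml and
    pipeline.log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    chash = config.config_hash()
    comments = [f"config_hash: {chash}"]
    try:
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

        scans_dir = out / "scans"
        manifest_path = out / "manifest.csv"
        if manifest_path.exists():
            log.info("simulate: manifest exists, resuming")
            manifest = oio.read_manifest(manifest_path)
            scans = [oio.read_bscan_tiff(scans_dir / f"{sid}.tiff")
                     for sid in manifest["scan_id"]]
        else:
            log.info("simulate: generating cohort (seed=%d)", config.seed)
            scans = generate_cohort(config.cohort_spec())
            scans_dir.mkdir(exist_ok=True)
            for s in scans:
                oio.write_bscan_tiff(s, scans_dir / f"{s.scan_id}.tiff")
            oio.write_manifest(scans, manifest_path,
                               extra={"seed": [config.seed] * len(scans)})
            # reload from disk so fresh and resumed runs see identical
            # (quantized) intensities
            scans = [oio.read_bscan_tiff(scans_dir / f"{s.scan_id}.tiff")
                     for s in scans]

        features_path = out / "features.csv"
        if features_path.exists():
            log.info("features: table exists, resuming")
            feats = oio.read_table(features_path)
        else:
            log.info("preprocess: %d scans", len(scans))
            rois = [preprocess_scan(s, config) for s in scans]
            screen = correlation_screen(rois)
            pd.DataFrame([dataclasses.asdict(screen)]).to_csv(
                out / "screening.csv", index=False)
            if screen.flagged:
                log.warning("correlation screen flagged the cohort: %s", screen)
            log.info("features: extracting")
            feats = extract_features(rois, config)
            oio.write_table(feats, features_path, units=FEATURE_UNITS,
                            header_comments=comments)

        metrics_path = out / "metrics.csv"
        if not metrics_path.exists():
            log.info("evaluate: grouped CV")
            combos = config.combinations or DEFAULT_COMBINATIONS
            table = evaluate_combinations(feats, combos, k=config.k,
                                          ridge=config.ridge)
            oio.write_table(table, metrics_path,
                            units={"se": "-", "sp": "-", "pr": "-"},
                            header_comments=comments)
            roc_rows = []
            results = table.attrs["results"]
            for (neg, pos, combo), res in results.items():
                pair_tbl = table[(table["pair"] == f"{neg} vs {pos}")
                                 & (table["combination"] == "+".join(combo))]
                if not bool(pair_tbl["best"].iloc[0]):
                    continue
                for fpr, tpr in res.roc:
                    roc_rows.append({"pair": f"{neg} vs {pos}",
                                     "combination": "+".join(combo),
                                     "fpr": fpr, "tpr": tpr,
                                     "auc": res.auc})
            oio.write_table(pd.DataFrame(roc_rows), out / "roc.csv",
                            units=None, header_comments=comments)
        log.info("run complete: %s", out)
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
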