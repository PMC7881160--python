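"""File-format plumbing: TIFF images, YAML/JSON sidecars, CSV tables.

Images travel as TIFF (single frame, 2-slice pair, or N-slice stack) with
acquisition metadata in a YAML or JSON sidecar; per-pixel LD maps persist as
multi-channel 32-bit TIFF; θ-sample tables and outlines as CSV; fit results
and goodness maps as JSON plus multi-slice TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .geometry import ThetaSamples
from .images import Calibration, MixedPolarizationImage, PixelLDMap, PolarizationPair, PolarizationStack

__all__ = [
    "read_tiff",
    "write_tiff",
    "read_sidecar",
    "write_sidecar",
    "load_pair",
    "save_pair",
    "load_stack",
    "load_mixed",
    "save_ldmap",
    "load_ldmap",
    "save_goodness_map",
    "load_theta_dir",
    "write_json",
]


def read_tiff(path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_tiff(path, array: np.ndarray, **kwargs) -> None:
    tifffile.imwrite(str(path), array, **kwargs)


def read_sidecar(path) -> dict:
    """YAML (or JSON) acquisition-metadata sidecar."""
    p = Path(path)
    text = p.read_text()
    if p.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def write_sidecar(path, meta: dict) -> None:
    p = Path(path)
    if p.suffix.lower() == ".json":
        p.write_text(json.dumps(meta, indent=2, default=_jsonable))
    else:
        p.write_text(yaml.safe_dump(meta, sort_keys=False))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable, allow_nan=True))


def _calibration_from_meta(meta: dict) -> Calibration:
    cal = meta.get("calibration", {}) or {}
    return Calibration(
        background_h=cal.get("background_h"),
        background_v=cal.get("background_v"),
        bleed_k=float(cal.get("bleed_k", 0.0)),
        gain_g=float(cal.get("gain_g", 1.0)),
    )


def load_pair(image_path, sidecar_path) -> PolarizationPair:
    """2-slice TIFF (f_h, f_v) plus metadata sidecar."""
    arr = read_tiff(image_path)
    if arr.ndim != 3 or arr.shape[0] != 2:
        raise ValueError(f"pair TIFF must have 2 slices, got shape {arr.shape}")
    meta = read_sidecar(sidecar_path)
    return PolarizationPair(
        f_h=arr[0].astype(float),
        f_v=arr[1].astype(float),
        modality=meta.get("modality", "1p"),
        calibration=_calibration_from_meta(meta),
    )


def save_pair(image_path, sidecar_path, pair: PolarizationPair) -> None:
    write_tiff(image_path, np.stack([pair.f_h, pair.f_v]).astype(np.float32))
    cal = pair.calibration
    write_sidecar(sidecar_path, {
        "modality": pair.modality,
        "calibration": {
            "background_h": cal.background_h,
            "background_v": cal.background_v,
            "bleed_k": cal.bleed_k,
            "gain_g": cal.gain_g,
        },
    })


def load_mixed(image_path, sidecar_path) -> tuple[MixedPolarizationImage, dict]:
    arr = read_tiff(image_path)
    meta = read_sidecar(sidecar_path)
    mixed = MixedPolarizationImage(
        pixels=arr.astype(float),
        scheme=meta.get("scheme", "per_pixel_column"),
        phase=meta.get("phase", "h_first"),
    )
    return mixed, meta


def load_stack(image_path, sidecar_path) -> PolarizationStack:
    arr = read_tiff(image_path)
    meta = read_sidecar(sidecar_path)
    angles = np.asarray(meta["angles"], dtype=float)
    return PolarizationStack(
        frames=arr.astype(float), angles=angles, modality=meta.get("modality", "1p")
    )


#: channel order of persisted LD maps
LDMAP_CHANNELS = ("intensity", "ld", "azimuth", "valid")


def save_ldmap(path, ldmap: PixelLDMap) -> None:
    """Multi-channel 32-bit TIFF: intensity, ld, azimuth, valid."""
    az = ldmap.azimuth if ldmap.azimuth is not None else np.full_like(ldmap.intensity, np.nan)
    stack = np.stack([
        ldmap.intensity, ldmap.ld, az, ldmap.valid.astype(float)
    ]).astype(np.float32)
    write_tiff(path, stack, photometric="minisblack")


def load_ldmap(path) -> PixelLDMap:
    arr = read_tiff(path).astype(float)
    if arr.ndim != 3 or arr.shape[0] != 4:
        raise ValueError(f"LD-map TIFF must have 4 channels, got shape {arr.shape}")
    az = arr[2]
    mode = "pair" if np.all(np.isnan(az)) else "stack"
    return PixelLDMap(
        intensity=arr[0], ld=arr[1], valid=arr[3] > 0.5,
        azimuth=None if mode == "pair" else az, mode=mode,
    )


def save_goodness_map(json_path, tiff_path, gmap) -> None:
    """JSON scores + multi-slice TIFF (r², RMSD, χ², confidence)."""
    conf = gmap.confidence if gmap.confidence is not None else np.zeros_like(gmap.r2)
    write_tiff(tiff_path, np.stack([
        np.nan_to_num(gmap.r2, nan=-1.0), gmap.rmsd, gmap.chi2, conf.astype(float)
    ]).astype(np.float32), photometric="minisblack")
    write_json(json_path, {
        "best_alpha0": gmap.best_alpha0,
        "best_sigma": gmap.best_sigma,
        "alpha0_grid": gmap.alpha0,
        "sigma_grid": gmap.sigma,
        "modalities": list(gmap.modalities),
        "geometry": gmap.geometry,
        "r2_defined": gmap.r2_defined,
        "slices": ["r2", "rmsd", "chi2", "confidence"],
    })


def load_theta_dir(root) -> list[ThetaSamples]:
    """Directory-convention pooling: one subdirectory per object, containing
    modality-tagged CSVs ``samples_1p.csv`` / ``samples_2p.csv`` (loose
    ``*.csv`` files in ``root`` are read as single objects too)."""
    root = Path(root)
    sets: list[ThetaSamples] = []
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        for csv in sorted(sub.glob("samples_*.csv")):
            s = ThetaSamples.from_csv(csv)
            s.object_id = sub.name
            sets.append(s)
    for csv in sorted(root.glob("*.csv")):
        sets.append(ThetaSamples.from_csv(csv))
    if not sets:
        raise ValueError(f"no sample CSVs found under {root}")
    return sets
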