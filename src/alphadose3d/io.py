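"""File formats: TIFF images with JSON sidecars, CSV tables, configs.

Images and volumes travel as float32 TIFF plus a JSON sidecar
(``<name>.json``) holding voxel dimensions, acquisition times and
provenance — no image is ever consumed without explicit pixel-size
metadata.  Tables (ratio series, biodistribution, spectra, S matrices,
DrVH and de-escalation outputs) are plain CSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .biokinetics import TimeDoseRatePoint
from .chain_kinetics import RatioSeries
from .morphometry import DRVH
from .spectroscopy import EnergySpectrum

__all__ = [
    "save_image",
    "load_image",
    "read_image_stack",
    "read_ratio_series_csv",
    "read_biod_csv",
    "read_spectrum_csv",
    "read_s_matrix_csv",
    "write_drvh_csv",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_image(path, array: np.ndarray, metadata: dict) -> None:
    """Write a float32 TIFF plus JSON sidecar with voxel metadata.

    ``metadata`` must include ``pixel_size_um`` (and ``voxel_dims_um``
    for volumes); integer label masks are written unmodified.
    """
    path = Path(path)
    array = np.asarray(array)
    if "pixel_size_um" not in metadata and "voxel_dims_um" not in metadata:
        raise ValueError("metadata must state pixel_size_um or voxel_dims_um")
    if not np.issubdtype(array.dtype, np.integer):
        array = array.astype(np.float32)
    tifffile.imwrite(path, array)
    _sidecar(path).write_text(json.dumps(metadata, indent=2))


def load_image(path) -> tuple[np.ndarray, dict]:
    """Read a TIFF and its mandatory JSON sidecar."""
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(
            f"missing metadata sidecar {side.name}: images without explicit "
            "pixel-size metadata are not accepted"
        )
    meta = json.loads(side.read_text())
    if "pixel_size_um" not in meta and "voxel_dims_um" not in meta:
        raise ValueError(f"{side.name} lacks pixel_size_um / voxel_dims_um")
    return tifffile.imread(path), meta


def read_image_stack(source) -> list[tuple[np.ndarray, dict]]:
    """Load an ordered slice stack from a directory of TIFF + sidecars.

    Slices are ordered by the ``index`` field of their sidecars when
    present (so out-of-order filenames are handled), else by filename.
    """
    source = Path(source)
    paths = sorted(source.glob("*.tif")) + sorted(source.glob("*.tiff"))
    if not paths:
        raise FileNotFoundError(f"no TIFF slices found in {source}")
    slices = [load_image(p) for p in paths]
    if all("index" in meta for _, meta in slices):
        slices.sort(key=lambda pair: pair[1]["index"])
    return slices


def read_ratio_series_csv(path) -> RatioSeries:
    """CSV columns: time_s, ratio, and optional sigma."""
    df = pd.read_csv(path)
    sigma = df["sigma"].to_numpy() if "sigma" in df.columns else None
    return RatioSeries(df["time_s"].to_numpy(), df["ratio"].to_numpy(), sigma)


def read_biod_csv(path) -> list[TimeDoseRatePoint]:
    """CSV columns: subject_id, tissue, time_h, dose_rate_mGy_h, component."""
    df = pd.read_csv(path)
    return [
        TimeDoseRatePoint(
            time=float(row.time_h),
            dose_rate=float(row.dose_rate_mGy_h),
            subject_id=str(row.subject_id),
            component=str(row.component),
        )
        for row in df.itertuples()
    ]


def read_spectrum_csv(path, live_time: float | None = None) -> EnergySpectrum:
    """CSV columns: bin_lo_keV, bin_hi_keV, counts.

    The live time comes from a ``<name>.json`` sidecar with key
    ``live_time_s`` unless passed explicitly.
    """
    path = Path(path)
    if live_time is None:
        side = _sidecar(path)
        if not side.exists():
            raise FileNotFoundError(
                f"live_time not given and sidecar {side.name} not found"
            )
        live_time = float(json.loads(side.read_text())["live_time_s"])
    df = pd.read_csv(path)
    edges = np.concatenate([df["bin_lo_keV"].to_numpy(), [df["bin_hi_keV"].iloc[-1]]])
    return EnergySpectrum(edges, df["counts"].to_numpy(), live_time)


def read_s_matrix_csv(path) -> dict[tuple[str, str], float]:
    """CSV columns: source, target, s_value (Gy per Bq s)."""
    df = pd.read_csv(path)
    return {
        (str(row.source), str(row.target)): float(row.s_value)
        for row in df.itertuples()
    }


def write_drvh_csv(drvh_result: DRVH, path) -> None:
    """Write per-region differential and cumulative histograms."""
    rows = []
    edges = drvh_result.bin_edges
    for region, hist in drvh_result.histograms.items():
        cum = drvh_result.cumulative[region]
        for k, h in enumerate(hist):
            rows.append(
                {
                    "region": region,
                    "bin_lo": edges[k],
                    "bin_hi": edges[k + 1],
                    "voxels": int(h),
                    "cum_fraction_ge_lo": cum[k],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
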