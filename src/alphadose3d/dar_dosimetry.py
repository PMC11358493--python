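"""Quantitative digital-autoradiograph (DAR) dosimetry.

Single-alpha event maps from a scintillator camera are converted to
calibrated 225Ac activity images, expanded into 3D activity volumes —
either by digitally cloning one measured slice (the "cloning method")
or by stacking sequentially cut slices — and convolved with an alpha
dose-point kernel to obtain dose-rate maps.  A gamma-index comparison
(dose-difference + distance-to-agreement) quantifies how well the
cloning approximation reproduces the sequential ground truth, and a
sampling planner counts the cryotome sections each approach requires.

Image arrays are 2D ``[y, x]``; volumes are 3D ``[z, y, x]`` with voxel
dimensions stated as ``(dx, dy, dz)`` in um.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import oaconvolve

from .alpha_kernel import DosePointKernel
from .chain_kinetics import DecayChain, decay_correct

__all__ = [
    "CountImage",
    "CalibrationFactors",
    "ActivityImage",
    "ActivityVolume",
    "DoseRateImage",
    "DoseRateVolume",
    "GammaResult",
    "counts_to_activity_image",
    "clone_volume",
    "convolve_dose_rate",
    "sequential_dose_rate",
    "method_error",
    "assemble_3d",
    "extract_plane",
    "sampling_plan",
    "gamma_index",
    "SECONDS_PER_HOUR",
]

SECONDS_PER_HOUR = 3600.0


@dataclass
class CountImage:
    """Raw single-alpha event counts for one tissue slice."""

    counts: np.ndarray  # [y, x], >= 0
    pixel_size: float  # um
    slice_thickness: float  # um
    live_time: float  # s
    acquisition_start_offset: float = 0.0  # s post-sacrifice

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")
        if self.pixel_size <= 0 or self.slice_thickness <= 0:
            raise ValueError("pixel_size and slice_thickness must be > 0")


@dataclass(frozen=True)
class CalibrationFactors:
    """Device calibration: geometric efficiency, pileup loss, frame factor.

    The absolute counting efficiency is geometric_efficiency times
    (1 - pileup_loss): with the defaults of 50% geometric efficiency and
    23.8% spatial pileup loss this is 38%.  ``frame_factor`` (>= 1)
    corrects parent/daughter alphas merged within one camera frame.
    """

    geometric_efficiency: float = 0.50
    pileup_loss: float = 0.238
    frame_factor: float = 1.09

    def __post_init__(self) -> None:
        if not 0.0 < self.geometric_efficiency < 1.0 or not 0.0 <= self.pileup_loss < 1.0:
            raise ValueError("efficiency fractions must be in [0, 1)")
        if self.frame_factor < 1.0:
            raise ValueError("frame_factor must be >= 1")

    @property
    def absolute_efficiency(self) -> float:
        return self.geometric_efficiency * (1.0 - self.pileup_loss)


@dataclass
class ActivityImage:
    """Calibrated per-pixel 225Ac activity (Bq), decay-corrected to sacrifice."""

    activity: np.ndarray  # [y, x], Bq per pixel
    pixel_size: float  # um
    slice_thickness: float  # um

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        if np.any(self.activity < 0):
            raise ValueError("activity must be >= 0")


@dataclass
class ActivityVolume:
    """3D activity distribution (Bq per voxel)."""

    activity: np.ndarray  # [z, y, x]
    voxel_dims: tuple[float, float, float]  # (dx, dy, dz) um

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        if self.activity.ndim != 3:
            raise ValueError("activity volume must be 3D [z, y, x]")


@dataclass
class DoseRateImage:
    """Per-pixel absorbed dose rate (Gy/h) in one plane."""

    dose_rate: np.ndarray  # [y, x]
    pixel_size: float  # um
    slice_thickness: float  # um
    provenance: str = "cloning"


@dataclass
class DoseRateVolume:
    """3D absorbed dose-rate distribution (Gy/h per voxel)."""

    dose_rate: np.ndarray  # [z, y, x]
    voxel_dims: tuple[float, float, float]
    provenance: str = "stacked"


@dataclass
class GammaResult:
    """Gamma-index comparison between two dose distributions.

    ``pass_rate`` counts gamma <= 1 over the evaluated voxels and
    ``pass_rate_strict`` counts gamma < 1 (both are reported because
    printed pass criteria vary between the two conventions).
    """

    gamma_map: np.ndarray
    pass_rate: float
    pass_rate_strict: float
    criteria: dict
    evaluated: np.ndarray  # bool mask of voxels entering the pass rates


def counts_to_activity_image(
    img: CountImage, cal: CalibrationFactors, chain: DecayChain
) -> ActivityImage:
    """Convert an event-count image to a 225Ac activity image.

    Per pixel:

        A = counts * frame_factor
            / (alphas_per_chain * geometric_eff * (1 - pileup) * live_time)

    then decay-corrected back to sacrifice over the acquisition start
    offset using the parent half-life.
    """
    if img.live_time <= 0:
        raise ValueError("live_time must be > 0")
    denom = (
        chain.alphas_per_chain
        * cal.geometric_efficiency
        * (1.0 - cal.pileup_loss)
        * img.live_time
    )
    activity = img.counts * cal.frame_factor / denom
    activity = decay_correct(activity, img.acquisition_start_offset, chain.parent.half_life)
    return ActivityImage(activity, img.pixel_size, img.slice_thickness)


def clone_volume(
    slice_: ActivityImage, n_clones: int, clone_thickness: float | None = None
) -> ActivityVolume:
    """Digitally duplicate one measured slice into a convolution volume.

    The cloning method assumes neighboring 10-um slices are nearly
    identical, so the 3D neighborhood of the measured plane is
    approximated by ``n_clones`` copies at ``clone_thickness`` pitch.
    ``n_clones`` must be odd so the measured plane is central.
    """
    if n_clones < 1 or n_clones % 2 == 0:
        raise ValueError("n_clones must be odd and >= 1")
    if clone_thickness is None:
        clone_thickness = slice_.slice_thickness
    vol = np.repeat(slice_.activity[np.newaxis, :, :], n_clones, axis=0)
    return ActivityVolume(vol, (slice_.pixel_size, slice_.pixel_size, clone_thickness))


def _check_kernel_dims(vol_dims, kernel: DosePointKernel) -> None:
    if kernel.voxel_kernel is None or kernel.voxel_dims is None:
        raise ValueError("kernel must be voxel-binned before convolution")
    if not np.allclose(vol_dims, kernel.voxel_dims, rtol=1e-6):
        raise ValueError(
            f"kernel voxel dims {kernel.voxel_dims} do not match volume "
            f"voxel dims {tuple(vol_dims)}"
        )


def convolve_dose_rate(vol: ActivityVolume, kernel: DosePointKernel) -> DoseRateVolume:
    """Dose-point-kernel convolution of an activity volume.

    Linear 3D convolution with zero padding (tissue mounted in air/OCT
    absorbs the escaping dose), scaled from decays/s to Gy/h.
    """
    _check_kernel_dims(vol.voxel_dims, kernel)
    rate = oaconvolve(vol.activity, kernel.voxel_kernel, mode="same") * SECONDS_PER_HOUR
    np.maximum(rate, 0.0, out=rate)  # clip FFT round-off
    return DoseRateVolume(rate, vol.voxel_dims, provenance="cloning")


def sequential_dose_rate(
    slices: list[ActivityImage], kernel: DosePointKernel
) -> DoseRateImage:
    """Central-plane dose rate from a stack of consecutively cut slices."""
    if len(slices) < 3:
        raise ValueError("sequential method needs at least 3 registered slices")
    shape = slices[0].activity.shape
    px, th = slices[0].pixel_size, slices[0].slice_thickness
    for s in slices[1:]:
        if s.activity.shape != shape or s.pixel_size != px:
            raise ValueError("all slices must share shape and pixel size")
    vol = ActivityVolume(np.stack([s.activity for s in slices]), (px, px, th))
    rates = convolve_dose_rate(vol, kernel)
    central = rates.dose_rate[len(slices) // 2]
    return DoseRateImage(central, px, th, provenance="sequential")


def method_error(cloning: DoseRateImage, sequential: DoseRateImage) -> float:
    """Percent error of the cloning-method mean dose rate vs sequential."""
    if cloning.dose_rate.shape != sequential.dose_rate.shape:
        raise ValueError("images must have the same shape")
    ref = float(sequential.dose_rate.mean())
    if ref == 0:
        raise ValueError("sequential mean dose rate is zero")
    return abs(float(cloning.dose_rate.mean()) - ref) / ref * 100.0


def assemble_3d(slices: list[DoseRateImage], z_pitch: float) -> DoseRateVolume:
    """Stack sparsely sampled dose-rate planes into a 3D DAR volume.

    Each measured slice represents its full sampling interval, so the z
    voxel dimension is the sampling pitch plus the slice thickness
    (200 um pitch + 10 um slices -> 210 um voxels).
    """
    if len(slices) < 2:
        raise ValueError("need at least 2 slices to assemble a volume")
    shape = slices[0].dose_rate.shape
    if any(s.dose_rate.shape != shape for s in slices):
        raise ValueError("all slices must have the same shape")
    px, th = slices[0].pixel_size, slices[0].slice_thickness
    vol = np.stack([s.dose_rate for s in slices])
    return DoseRateVolume(vol, (px, px, z_pitch + th), provenance="stacked")


def extract_plane(vol: DoseRateVolume, index: int) -> DoseRateImage:
    """Pull one z plane back out of an assembled volume."""
    dx, _, dz = vol.voxel_dims
    return DoseRateImage(vol.dose_rate[index], dx, dz, provenance=vol.provenance)


def sampling_plan(
    tissue_extent: float, sampling_pitch: float, slices_per_position: int = 1
) -> tuple[int, int]:
    """Sections required to cover a tissue at a given sampling pitch.

    Returns ``(positions, total_slices)`` with positions =
    floor(extent / pitch).  A 5-mm tissue needs 500 sections at 10-um
    contiguous sampling, 250 with 10-slice sequential dosimetry every
    200 um, and 25 with single-slice cloning at the same pitch.
    """
    if tissue_extent <= 0 or sampling_pitch <= 0 or slices_per_position < 1:
        raise ValueError("all sampling-plan inputs must be positive")
    positions = int(math.floor(tissue_extent / sampling_pitch))
    if positions == 0:
        warnings.warn("sampling pitch exceeds tissue extent: zero positions", stacklevel=2)
    return positions, positions * slices_per_position


def gamma_index(
    ref: DoseRateImage,
    eval_: DoseRateImage,
    dose_tol: float = 0.10,
    dist_tol: float = 117.0,
    normalization: str = "local",
    floor: float = 0.0,
    search_factor: float = 3.0,
    supersample: int = 1,
) -> GammaResult:
    """Gamma-index map between a reference and an evaluated dose image.

    For each reference pixel,

        gamma = min over nearby eval positions of
                sqrt((dD / (dose_tol * D_norm))^2 + (dr / dist_tol)^2)

    with D_norm the local reference dose (``normalization="local"``) or
    the reference maximum (``"global"``).  ``dist_tol`` is in um; the
    search covers positions within ``search_factor * dist_tol``.
    Reference pixels below ``floor`` times the reference maximum are
    excluded from the pass rates.  ``supersample > 1`` searches eval
    positions on a bilinear subpixel grid (default: voxel centers only).
    """
    if ref.dose_rate.shape != eval_.dose_rate.shape:
        raise ValueError("images must have the same shape")
    if ref.pixel_size != eval_.pixel_size:
        raise ValueError("images must have the same pixel size")
    if dose_tol <= 0 or dist_tol <= 0:
        raise ValueError("dose_tol and dist_tol must be > 0")
    if normalization not in ("local", "global"):
        raise ValueError("normalization must be 'local' or 'global'")

    r = ref.dose_rate
    e = eval_.dose_rate
    px = ref.pixel_size
    d_norm = r if normalization == "local" else float(r.max())

    search_um = search_factor * dist_tol
    step = 1.0 / supersample  # shift granularity in pixels
    max_shift = int(math.floor(search_um / (px * step)))
    shifts = []
    for di in range(-max_shift, max_shift + 1):
        for dj in range(-max_shift, max_shift + 1):
            d_um = math.hypot(di, dj) * px * step
            if d_um <= search_um:
                shifts.append((di * step, dj * step, d_um))

    ny, nx = r.shape
    ii, jj = np.meshgrid(np.arange(ny, dtype=float), np.arange(nx, dtype=float),
                         indexing="ij")
    gamma_sq = np.full(r.shape, np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        for di, dj, d_um in shifts:
            if supersample == 1:
                di_i, dj_i = int(round(di)), int(round(dj))
                if abs(di_i) >= ny or abs(dj_i) >= nx:
                    continue  # shift moves the whole image out of frame
                shifted = np.full(r.shape, np.nan)
                src_i = slice(max(0, di_i), ny + min(0, di_i))
                src_j = slice(max(0, dj_i), nx + min(0, dj_i))
                dst_i = slice(max(0, -di_i), ny + min(0, -di_i))
                dst_j = slice(max(0, -dj_i), nx + min(0, -dj_i))
                shifted[dst_i, dst_j] = e[src_i, src_j]
            else:
                shifted = ndimage.map_coordinates(
                    e, [ii + di, jj + dj], order=1, mode="constant", cval=np.nan
                )
            dose_term = (shifted - r) / (dose_tol * d_norm)
            g2 = dose_term**2 + (d_um / dist_tol) ** 2
            g2 = np.where(np.isnan(g2), np.inf, g2)
            np.minimum(gamma_sq, g2, out=gamma_sq)

    gamma_map = np.sqrt(gamma_sq)
    evaluated = r >= floor * float(r.max())
    n_eval = int(np.count_nonzero(evaluated))
    if n_eval == 0:
        raise ValueError("all voxels fall below the low-dose floor")
    pass_rate = float(np.count_nonzero(gamma_map[evaluated] <= 1.0)) / n_eval
    pass_strict = float(np.count_nonzero(gamma_map[evaluated] < 1.0)) / n_eval
    return GammaResult(
        gamma_map=gamma_map,
        pass_rate=pass_rate,
        pass_rate_strict=pass_strict,
        criteria={
            "dose_tol": dose_tol,
            "dist_tol_um": dist_tol,
            "normalization": normalization,
            "floor": floor,
            "search_factor": search_factor,
            "supersample": supersample,
        },
        evaluated=evaluated,
    )
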