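"""Plane-wave delay-and-sum beamforming with coherent compounding.

Per angle, the analytic signal (Hilbert transform along time) of each
active element's trace is sampled at the geometric round-trip delay of
every pixel, weighted by a Hanning window spanning the active aperture,
and summed.  Per-angle complex images are averaged (coherent compounding),
envelope-detected, log-compressed, and mapped to 8-bit grayscale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .acquisition import RFChannelData, TransducerArray, ValidationError

__all__ = [
    "ImageGrid",
    "BModeImage",
    "pixel_delay",
    "das_single_angle",
    "beamform_all_angles",
    "compound",
    "to_bmode",
    "beamform_bmode",
    "grating_lobe_offset",
    "NoGratingLobeError",
]


class NoGratingLobeError(ValueError):
    """Signals that no real grating lobe exists for the requested order."""


@dataclass(frozen=True)
class ImageGrid:
    """Reconstruction grid: rows index depth, columns index lateral position."""

    n_rows: int = 512
    n_cols: int = 512
    lateral_min: float = -4.48e-3
    lateral_max: float = 4.48e-3
    depth_min: float = 0.5e-3
    depth_max: float = 15e-3

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValidationError("grid must be at least 2x2")
        if self.lateral_max <= self.lateral_min:
            raise ValidationError("lateral_max must exceed lateral_min")
        if not (0 < self.depth_min < self.depth_max):
            raise ValidationError("need 0 < depth_min < depth_max")

    @property
    def x(self) -> np.ndarray:
        """Lateral pixel coordinates (meters), left to right."""
        return np.linspace(self.lateral_min, self.lateral_max, self.n_cols)

    @property
    def z(self) -> np.ndarray:
        """Depth pixel coordinates (meters), top to bottom."""
        return np.linspace(self.depth_min, self.depth_max, self.n_rows)

    @property
    def dx(self) -> float:
        return (self.lateral_max - self.lateral_min) / (self.n_cols - 1)

    @property
    def dz(self) -> float:
        return (self.depth_max - self.depth_min) / (self.n_rows - 1)

    def nearest_pixel(self, x: float, z: float) -> tuple[int, int]:
        row = int(np.clip(round((z - self.depth_min) / self.dz), 0, self.n_rows - 1))
        col = int(np.clip(round((x - self.lateral_min) / self.dx), 0, self.n_cols - 1))
        return row, col


@dataclass
class BModeImage:
    """8-bit log-compressed grayscale frame with physical pixel spacing."""

    pixels: np.ndarray
    grid: ImageGrid
    dynamic_range_db: float = 50.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValidationError("pixels must be 2-D")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValidationError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def pixel_delay(
    angle: float, pixel: tuple[float, float], element_x: float, c: float
) -> float:
    """Round-trip delay (s) for a steered plane wave and one receive element.

    ``angle`` in radians; ``pixel`` is (lateral, depth) in meters.
    tau_tx = (z cos(theta) + x sin(theta)) / c, tau_rx = |pixel - element| / c.
    """
    if c <= 0:
        raise ValidationError("sound speed must be positive")
    x, z = pixel
    if z <= 0:
        raise ValidationError("pixel depth must be positive")
    tau_tx = (z * np.cos(angle) + x * np.sin(angle)) / c
    tau_rx = np.sqrt((x - element_x) ** 2 + z**2) / c
    return float(tau_tx + tau_rx)


def hanning_apodization(n_active: int) -> np.ndarray:
    """Symmetric Hanning window (zero endpoints) across the active aperture."""
    if n_active == 1:
        return np.ones(1)
    return np.hanning(n_active)


def _analytic_traces(rf: RFChannelData) -> np.ndarray:
    return hilbert(rf.traces, axis=-1)


def _check_grid_depth(rf: RFChannelData, grid: ImageGrid, array: TransducerArray, c: float) -> None:
    half_ap = array.aperture_width / 2.0
    lat = max(abs(grid.lateral_min), abs(grid.lateral_max)) + half_ap
    worst = (grid.depth_max + np.sqrt(lat**2 + grid.depth_max**2)) / c
    if worst > rf.t_end:
        raise ValidationError(
            "image grid extends deeper than the RF trace window "
            f"(needs {worst * 1e6:.2f} us, trace ends at {rf.t_end * 1e6:.2f} us)"
        )


def _das(
    analytic: np.ndarray,
    angles_rad: np.ndarray,
    grid: ImageGrid,
    array: TransducerArray,
    c: float,
    t0: float,
    fs: float,
) -> np.ndarray:
    """Delay-and-sum all angles at once. Returns (n_angles, n_rows, n_cols)."""
    x = grid.x[None, :]
    z = grid.z[:, None]
    n_samples = analytic.shape[-1]
    active = np.flatnonzero(array.active_mask)
    weights = hanning_apodization(active.size)

    cos_t = np.cos(angles_rad)[:, None, None]
    sin_t = np.sin(angles_rad)[:, None, None]
    tau_tx = (z[None] * cos_t + x[None] * sin_t) / c  # (n_ang, rows, cols)

    out = np.zeros((angles_rad.size, grid.n_rows, grid.n_cols), dtype=complex)
    for w, e in zip(weights, active):
        tau_rx = np.sqrt((x - array.element_positions[e]) ** 2 + z**2) / c
        s = (tau_tx + tau_rx[None] - t0) * fs
        i0 = np.floor(s).astype(np.int64)
        frac = s - i0
        valid = (i0 >= 0) & (i0 <= n_samples - 2)
        i0c = np.clip(i0, 0, n_samples - 2)
        tr = analytic[:, e, :]  # (n_ang, n_samples)
        gather = np.take_along_axis(
            tr[:, None, :], i0c.reshape(angles_rad.size, -1, 1), axis=2
        ).reshape(i0c.shape)
        gather_next = np.take_along_axis(
            tr[:, None, :], (i0c + 1).reshape(angles_rad.size, -1, 1), axis=2
        ).reshape(i0c.shape)
        val = gather * (1.0 - frac) + gather_next * frac
        val[~valid] = 0.0
        out += w * val
    return out


def das_single_angle(
    rf: RFChannelData,
    angle_index: int,
    grid: ImageGrid,
    array: TransducerArray,
    sound_speed: float,
    angles_rad: np.ndarray | None = None,
) -> np.ndarray:
    """Beamform one steering angle into a complex-valued image.

    ``angles_rad`` defaults to the angle list recorded in the RF provenance.
    """
    if angles_rad is None:
        angles_rad = np.deg2rad(rf.provenance["sequence"]["angles"])
    angles_rad = np.atleast_1d(np.asarray(angles_rad, dtype=float))
    if not (0 <= angle_index < rf.n_angles):
        raise ValidationError(f"angle_index {angle_index} out of range")
    if rf.n_elements != array.n_elements:
        raise ValidationError("RF element count does not match array")
    _check_grid_depth(rf, grid, array, sound_speed)
    analytic = _analytic_traces(rf)[angle_index : angle_index + 1]
    return _das(
        analytic,
        np.array([angles_rad[angle_index]]),
        grid,
        array,
        sound_speed,
        rf.t0,
        rf.sampling_rate,
    )[0]


def beamform_all_angles(
    rf: RFChannelData,
    grid: ImageGrid,
    array: TransducerArray,
    sound_speed: float,
    angles_rad: np.ndarray | None = None,
) -> np.ndarray:
    """Beamform every angle; returns (n_angles, n_rows, n_cols) complex."""
    if angles_rad is None:
        angles_rad = np.deg2rad(rf.provenance["sequence"]["angles"])
    angles_rad = np.asarray(angles_rad, dtype=float)
    if angles_rad.size != rf.n_angles:
        raise ValidationError("angle list length does not match RF data")
    if rf.n_elements != array.n_elements:
        raise ValidationError("RF element count does not match array")
    _check_grid_depth(rf, grid, array, sound_speed)
    return _das(
        _analytic_traces(rf), angles_rad, grid, array, sound_speed, rf.t0, rf.sampling_rate
    )


def compound(per_angle_images: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Coherently compound per-angle complex images (arithmetic mean)."""
    if isinstance(per_angle_images, np.ndarray) and per_angle_images.ndim == 2:
        per_angle_images = [per_angle_images]
    imgs = [np.asarray(im) for im in per_angle_images]
    if len(imgs) == 0:
        raise ValidationError("need at least one image to compound")
    shapes = {im.shape for im in imgs}
    if len(shapes) != 1:
        raise ValidationError("per-angle images have mismatched shapes")
    return np.stack(imgs).mean(axis=0)


def to_bmode(
    compounded: np.ndarray,
    grid: ImageGrid,
    dynamic_range_db: float = 50.0,
    provenance: dict | None = None,
) -> BModeImage:
    """Envelope-detect, log-compress and quantize to 8 bits.

    dB values are clipped to [-DR, 0] and mapped linearly onto [0, 255];
    midpoints round half-up.  An all-zero input yields an all-zero frame
    flagged in provenance.
    """
    if dynamic_range_db <= 0:
        raise ValidationError("dynamic range must be positive")
    prov = dict(provenance or {})
    env = np.abs(np.asarray(compounded))
    peak = env.max()
    if peak == 0:
        prov["all_zero"] = True
        return BModeImage(
            np.zeros(env.shape, dtype=np.uint8), grid, dynamic_range_db, prov
        )
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(env / peak)
    db = np.clip(db, -dynamic_range_db, 0.0)
    scaled = (db + dynamic_range_db) / dynamic_range_db * 255.0
    pixels = np.floor(scaled + 0.5).astype(np.uint8)  # round half-up
    return BModeImage(pixels, grid, dynamic_range_db, prov)


def beamform_bmode(
    rf: RFChannelData,
    grid: ImageGrid,
    array: TransducerArray,
    sound_speed: float,
    dynamic_range_db: float = 50.0,
) -> BModeImage:
    """Full pipeline: per-angle DAS, coherent compounding, log compression."""
    per_angle = beamform_all_angles(rf, grid, array, sound_speed)
    comp = compound(per_angle)
    prov = dict(rf.provenance)
    prov["dynamic_range_db"] = dynamic_range_db
    return to_bmode(comp, grid, dynamic_range_db, prov)


def grating_lobe_offset(
    array: TransducerArray, c: float, depth: float, order: int = 1
) -> float:
    """Predicted lateral offset (m) of the order-th grating lobe.

    For an on-axis scatterer at ``depth``, the lobe appears at
    ``depth * tan(asin(order * wavelength / effective_pitch))``.  Raises
    :class:`NoGratingLobeError` when the asin argument reaches 1 (the lobe
    is evanescent).
    """
    if order < 1:
        raise ValidationError("order must be >= 1")
    if c <= 0 or depth <= 0:
        raise ValidationError("c and depth must be positive")
    lam = c / array.center_freq
    arg = order * lam / array.effective_pitch
    if arg >= 1.0:
        raise NoGratingLobeError(
            f"order {order} lobe does not exist: {order} * lambda "
            f"({order * lam * 1e6:.1f} um) >= effective pitch "
            f"({array.effective_pitch * 1e6:.1f} um)"
        )
    return float(depth * np.tan(np.arcsin(arg)))
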