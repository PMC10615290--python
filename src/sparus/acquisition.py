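"""Transducer geometry, plane-wave sequences, and RF channel-data simulation.

The acquisition model is single-scattering time-of-flight: every scatterer
returns a band-limited echo to every active receive element, delayed by the
plane-wave transmit path plus the element-to-scatterer return path.  No
attenuation, elevation focusing, or time-gain compensation is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

__all__ = [
    "TransducerArray",
    "PlaneWaveSequence",
    "Phantom",
    "RFChannelData",
    "make_linear_array",
    "decimate_aperture",
    "excitation_pulse",
    "pulse_sigma",
    "simulate_rf",
    "mask_rf",
    "ValidationError",
]

SOUND_SPEED_WATER = 1480.0  # m/s, ambient water at ~20 C


class ValidationError(ValueError):
    """Raised when a configuration value violates its contract."""


@dataclass(frozen=True)
class TransducerArray:
    """Linear array geometry with a per-element active mask.

    Element lateral positions are uniformly spaced by ``pitch`` and
    symmetric about 0.  Sparse apertures are expressed through
    ``active_mask``; the underlying geometry never changes.
    """

    n_elements: int = 128
    pitch: float = 70e-6
    center_freq: float = 28e6
    frac_bandwidth: float = 0.6
    active_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_elements < 2:
            raise ValidationError("n_elements must be >= 2")
        if self.pitch <= 0:
            raise ValidationError("pitch must be positive")
        if self.center_freq <= 0:
            raise ValidationError("center_freq must be positive")
        if not (0 < self.frac_bandwidth < 2):
            raise ValidationError("frac_bandwidth must lie in (0, 2)")
        mask = self.active_mask
        if mask is None:
            mask = np.ones(self.n_elements, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_elements,):
            raise ValidationError(
                f"active_mask must have length {self.n_elements}, got {mask.shape}"
            )
        if not mask.any():
            raise ValidationError("at least one element must be active")
        object.__setattr__(self, "active_mask", mask)

    @property
    def element_positions(self) -> np.ndarray:
        """Lateral element coordinates in meters, centered on 0."""
        idx = np.arange(self.n_elements, dtype=float)
        return (idx - (self.n_elements - 1) / 2.0) * self.pitch

    @property
    def active_positions(self) -> np.ndarray:
        return self.element_positions[self.active_mask]

    @property
    def n_active(self) -> int:
        return int(self.active_mask.sum())

    @property
    def aperture_width(self) -> float:
        """Full width of the (dense) aperture in meters."""
        return (self.n_elements - 1) * self.pitch

    @property
    def effective_pitch(self) -> float:
        """Spacing between adjacent active elements.

        Defined for uniformly decimated masks; raises otherwise.
        """
        pos = self.active_positions
        if pos.size == 1:
            raise ValidationError("effective pitch undefined for a single element")
        gaps = np.diff(pos)
        if not np.allclose(gaps, gaps[0], rtol=0, atol=1e-12):
            raise ValidationError("active elements are not uniformly spaced")
        return float(gaps[0])

    def wavelength(self, sound_speed: float = SOUND_SPEED_WATER) -> float:
        return sound_speed / self.center_freq


def make_linear_array(
    n_elements: int = 128,
    pitch: float = 70e-6,
    center_freq: float = 28e6,
    frac_bandwidth: float = 0.6,
) -> TransducerArray:
    """Build a fully active linear array (all elements transmit/receive)."""
    return TransducerArray(
        n_elements=int(n_elements),
        pitch=float(pitch),
        center_freq=float(center_freq),
        frac_bandwidth=float(frac_bandwidth),
    )


def decimate_aperture(array: TransducerArray, factor: int, phase: int = 0) -> TransducerArray:
    """Keep every ``factor``-th currently active element, starting at ``phase``.

    Operates on the sequence of active elements, so decimating by 2 twice
    equals decimating by 4 once.  Geometry is unchanged; the effective
    pitch becomes ``factor * pitch`` for a fresh dense array.
    """
    factor = int(factor)
    phase = int(phase)
    if factor < 1 or factor > array.n_elements:
        raise ValidationError(f"factor must lie in [1, {array.n_elements}]")
    if not (0 <= phase < factor):
        raise ValidationError("phase must satisfy 0 <= phase < factor")
    active_idx = np.flatnonzero(array.active_mask)
    kept = active_idx[phase::factor]
    if kept.size == 0:
        raise ValidationError("decimation leaves no active elements")
    mask = np.zeros(array.n_elements, dtype=bool)
    mask[kept] = True
    return replace(array, active_mask=mask)


@dataclass(frozen=True)
class PlaneWaveSequence:
    """Steered plane-wave transmit sequence.

    ``angles`` are steering angles in degrees, strictly increasing.  The
    default is 7 angles evenly spaced over [-15, 15].  ``prf`` is carried
    as metadata only.
    """

    angles: tuple = tuple(np.linspace(-15.0, 15.0, 7))
    sound_speed: float = SOUND_SPEED_WATER
    sampling_rate: float = 62.5e6
    prf: float = 5e3

    def __post_init__(self) -> None:
        angles = tuple(float(a) for a in self.angles)
        if len(angles) == 0:
            raise ValidationError("at least one steering angle required")
        if any(b <= a for a, b in zip(angles, angles[1:])):
            raise ValidationError("angles must be strictly increasing")
        if self.sound_speed <= 0:
            raise ValidationError("sound_speed must be positive")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        object.__setattr__(self, "angles", angles)

    @property
    def n_angles(self) -> int:
        return len(self.angles)

    @property
    def angles_rad(self) -> np.ndarray:
        return np.deg2rad(np.asarray(self.angles, dtype=float))

    def validate_for(self, array: TransducerArray) -> None:
        # Carrier Nyquist; the DAQ ceiling (62.5 MHz) undersamples the
        # upper band edge of a 28 MHz / 60% probe, so band-edge Nyquist
        # cannot be enforced with the stated defaults.
        if self.sampling_rate < 2 * array.center_freq:
            raise ValidationError(
                f"sampling_rate {self.sampling_rate:g} Hz below carrier Nyquist "
                f"{2 * array.center_freq:g} Hz"
            )


@dataclass
class Phantom:
    """Point-scatterer scene: (lateral, depth) positions and reflectivities.

    ``region_masks`` are optional named binary masks on an image grid
    (all sharing one shape); ``metadata`` records provenance (seed,
    generator name, ground-truth geometry).
    """

    scatterer_positions: np.ndarray  # (n, 2): lateral x, depth z, meters
    reflectivities: np.ndarray  # (n,)
    region_masks: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.scatterer_positions, dtype=float))
        refl = np.atleast_1d(np.asarray(self.reflectivities, dtype=float))
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValidationError("scatterer_positions must have shape (n, 2)")
        if refl.shape[0] != pos.shape[0]:
            raise ValidationError("reflectivities length must match positions")
        if pos.shape[0] and np.any(pos[:, 1] <= 0):
            raise ValidationError("scatterer depths must be strictly positive")
        if not np.all(np.isfinite(refl)):
            raise ValidationError("reflectivities must be finite")
        shapes = {m.shape for m in self.region_masks.values()}
        if len(shapes) > 1:
            raise ValidationError("region masks must share one grid shape")
        self.scatterer_positions = pos
        self.reflectivities = refl

    @property
    def n_scatterers(self) -> int:
        return self.scatterer_positions.shape[0]

    @property
    def max_depth(self) -> float:
        return float(self.scatterer_positions[:, 1].max())

    def merged_with(self, other: "Phantom") -> "Phantom":
        return Phantom(
            np.vstack([self.scatterer_positions, other.scatterer_positions]),
            np.concatenate([self.reflectivities, other.reflectivities]),
        )


@dataclass
class RFChannelData:
    """Per-angle, per-element, per-sample echo traces.

    ``traces`` has shape (n_angles, n_elements, n_samples); rows of
    inactive elements are identically zero.
    """

    traces: np.ndarray
    t0: float
    sampling_rate: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        traces = np.asarray(self.traces, dtype=float)
        if traces.ndim != 3:
            raise ValidationError("traces must be 3-D (angles, elements, samples)")
        self.traces = traces

    @property
    def n_angles(self) -> int:
        return self.traces.shape[0]

    @property
    def n_elements(self) -> int:
        return self.traces.shape[1]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[2]

    @property
    def t_end(self) -> float:
        return self.t0 + (self.n_samples - 1) / self.sampling_rate


def pulse_sigma(center_freq: float, frac_bandwidth: float) -> float:
    """Gaussian envelope std-dev (seconds) for a -6 dB fractional bandwidth.

    The envelope exp(-t^2 / 2 sigma^2) has amplitude spectrum
    exp(-2 pi^2 sigma^2 df^2); setting 20 log10 of that to -6 dB at
    df = bw * f0 / 2 gives sigma.
    """
    if frac_bandwidth <= 0:
        raise ValidationError("frac_bandwidth must be positive")
    half_width = frac_bandwidth * center_freq / 2.0
    return float(np.sqrt(np.log(10 ** (6 / 20)) / 2.0) / (np.pi * half_width))


def excitation_pulse(t: np.ndarray | float, center_freq: float, frac_bandwidth: float) -> np.ndarray:
    """Gaussian-modulated cosine centered at t = 0, unit peak amplitude."""
    sigma = pulse_sigma(center_freq, frac_bandwidth)
    t = np.asarray(t, dtype=float)
    return np.exp(-(t**2) / (2.0 * sigma**2)) * np.cos(2.0 * np.pi * center_freq * t)


def _required_samples(
    phantom: Phantom,
    array: TransducerArray,
    seq: PlaneWaveSequence,
    cover_depth: float = 0.0,
    cover_lateral: float = 0.0,
) -> int:
    """Sample count covering the deepest scatterer's worst-case round trip.

    ``cover_depth``/``cover_lateral`` extend the window so a later image
    grid reaching that far can be beamformed from the same traces.
    """
    pos = phantom.scatterer_positions
    half_ap = array.aperture_width / 2.0
    depth = max(phantom.max_depth, cover_depth)
    lat = max(float(np.abs(pos[:, 0]).max()), cover_lateral)
    # farthest element from the farthest scatterer, plus steered transmit path
    max_rx = float(np.sqrt((lat + half_ap) ** 2 + depth**2))
    max_theta = max(abs(a) for a in seq.angles_rad)
    max_tx = depth + lat * np.sin(max_theta)
    sigma = pulse_sigma(array.center_freq, array.frac_bandwidth)
    t_max = (max_tx + max_rx) / seq.sound_speed + 6.0 * sigma
    return int(np.ceil(t_max * seq.sampling_rate)) + 2


def simulate_rf(
    phantom: Phantom,
    array: TransducerArray,
    seq: PlaneWaveSequence,
    n_samples: int | None = None,
    t0: float = 0.0,
    cover_depth: float = 0.0,
    cover_lateral: float = 0.0,
) -> RFChannelData:
    """Simulate plane-wave RF channel data from a point-scatterer phantom.

    For each angle theta, active receive element e and scatterer s the echo
    contribution is ``reflectivity * pulse(t - tau)`` with

        tau = (z_s cos(theta) + x_s sin(theta)) / c + |e - s| / c

    Contributions sum linearly; inactive elements yield zero traces.  The
    idealized plane wave is element-independent on transmit, so a sparse
    aperture changes only the receive rows (see :func:`mask_rf`).
    """
    if phantom.n_scatterers == 0:
        raise ValidationError("phantom has no scatterers")
    seq.validate_for(array)

    need = _required_samples(phantom, array, seq, cover_depth, cover_lateral)
    if n_samples is None:
        n_samples = need
    elif n_samples < need:
        raise ValidationError(
            f"n_samples={n_samples} too short for deepest scatterer; "
            f"need at least {need}"
        )

    c = seq.sound_speed
    fs = seq.sampling_rate
    sigma = pulse_sigma(array.center_freq, array.frac_bandwidth)
    half_support = int(np.ceil(6.0 * sigma * fs)) + 1
    offsets = np.arange(-half_support, half_support + 1)

    x_s = phantom.scatterer_positions[:, 0]
    z_s = phantom.scatterer_positions[:, 1]
    refl = phantom.reflectivities
    elem_x = array.element_positions
    active = np.flatnonzero(array.active_mask)

    # receive path per (active element, scatterer)
    tau_rx = np.sqrt((elem_x[active, None] - x_s[None, :]) ** 2 + z_s[None, :] ** 2) / c

    traces = np.zeros((seq.n_angles, array.n_elements, n_samples))
    two_pi_f = 2.0 * np.pi * array.center_freq
    for ia, theta in enumerate(seq.angles_rad):
        tau_tx = (z_s * np.cos(theta) + x_s * np.sin(theta)) / c
        tau = tau_tx[None, :] + tau_rx  # (n_active, n_scat)
        n_center = np.rint((tau - t0) * fs).astype(np.int64)
        idx = n_center[:, :, None] + offsets[None, None, :]
        dt = t0 + idx / fs - tau[:, :, None]
        vals = refl[None, :, None] * np.exp(-(dt**2) / (2.0 * sigma**2)) * np.cos(
            two_pi_f * dt
        )
        np.clip(idx, 0, n_samples - 1, out=idx)  # support fits by construction
        flat_idx = (np.arange(active.size)[:, None, None] * n_samples + idx).ravel()
        acc = np.bincount(flat_idx, weights=vals.ravel(), minlength=active.size * n_samples)
        traces[ia, active, :] = acc.reshape(active.size, n_samples)

    return RFChannelData(
        traces=traces,
        t0=t0,
        sampling_rate=fs,
        provenance={
            "array": _array_meta(array),
            "sequence": _sequence_meta(seq),
            "phantom": dict(phantom.metadata),
        },
    )


def mask_rf(rf: RFChannelData, array: TransducerArray) -> RFChannelData:
    """Zero the receive rows of elements inactive in ``array``.

    Under the plane-wave transmit model this equals re-simulating with the
    sparse aperture, since transmit delays carry no element dependence.
    """
    if rf.n_elements != array.n_elements:
        raise ValidationError("RF element count does not match array")
    traces = rf.traces.copy()
    traces[:, ~array.active_mask, :] = 0.0
    prov = dict(rf.provenance)
    prov["array"] = _array_meta(array)
    return RFChannelData(traces=traces, t0=rf.t0, sampling_rate=rf.sampling_rate, provenance=prov)


def _array_meta(array: TransducerArray) -> dict[str, Any]:
    return {
        "n_elements": array.n_elements,
        "pitch": array.pitch,
        "center_freq": array.center_freq,
        "frac_bandwidth": array.frac_bandwidth,
        "active_mask": array.active_mask.astype(np.uint8).tolist(),
    }


def _sequence_meta(seq: PlaneWaveSequence) -> dict[str, Any]:
    return {
        "angles": list(seq.angles),
        "sound_speed": seq.sound_speed,
        "sampling_rate": seq.sampling_rate,
        "prf": seq.prf,
    }
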