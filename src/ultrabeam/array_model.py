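"""Transducer geometry, phantoms, excitation pulses and RF channel-data synthesis.

The forward model is deliberately simple: monostatic pulse-echo with a plane
wave transmitted from the aperture plane (transmit delay ``z / c``) and
per-element receive delays, a Gaussian-modulated sinusoid excitation, and
``1/r`` spherical spreading on receive.  No frequency-dependent attenuation,
no elevation focusing.  Every beamformer sees the same data, which is all the
comparison needs.

Coordinates: ``x`` lateral (mm), ``z`` depth (mm, positive pointing away from
the array face), array elements on the line ``z = 0``.  Times in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

__all__ = [
    "ArrayGeometry",
    "Pulse",
    "Phantom",
    "ChannelData",
    "make_linear_array",
    "make_cyst_phantom",
    "simulate_channel_data",
]

MM = 1e-3  # metres per millimetre


@dataclass(frozen=True)
class ArrayGeometry:
    """Linear transducer array description.

    Parameters
    ----------
    num_elements : int
        Number of elements ``M`` (>= 2).
    pitch_mm : float
        Centre-to-centre element spacing in mm.
    center_frequency : float
        Nominal operating frequency in Hz.
    sampling_frequency : float
        Per-channel sampling rate in Hz (>= 4x centre frequency).
    sound_speed : float
        Assumed medium sound speed in m/s.
    """

    num_elements: int
    pitch_mm: float
    center_frequency: float
    sampling_frequency: float
    sound_speed: float = 1540.0

    def __post_init__(self) -> None:
        if self.num_elements < 2:
            raise ValueError(f"num_elements must be >= 2, got {self.num_elements}")
        if self.pitch_mm <= 0:
            raise ValueError(f"pitch_mm must be > 0, got {self.pitch_mm}")
        if self.center_frequency <= 0:
            raise ValueError(
                f"center_frequency must be > 0, got {self.center_frequency}"
            )
        if self.sound_speed <= 0:
            raise ValueError(f"sound_speed must be > 0, got {self.sound_speed}")
        if self.sampling_frequency < 4.0 * self.center_frequency:
            raise ValueError(
                "sampling_frequency must be >= 4 x center_frequency "
                f"({4.0 * self.center_frequency:g} Hz), got "
                f"{self.sampling_frequency:g}"
            )

    @property
    def element_positions_mm(self) -> np.ndarray:
        """Lateral element centres ``x_m = (m - (M-1)/2) * pitch``, in mm."""
        m = np.arange(self.num_elements, dtype=float)
        return (m - (self.num_elements - 1) / 2.0) * self.pitch_mm

    @property
    def aperture_mm(self) -> float:
        return (self.num_elements - 1) * self.pitch_mm

    @property
    def wavelength_mm(self) -> float:
        return self.sound_speed / self.center_frequency / MM


@dataclass(frozen=True)
class Pulse:
    """Gaussian-modulated sinusoid excitation."""

    center_frequency: float
    fractional_bandwidth: float = 0.6
    duration_cycles: float = 2.5

    def __post_init__(self) -> None:
        if self.center_frequency <= 0:
            raise ValueError("center_frequency must be > 0")
        if not 0.0 < self.fractional_bandwidth < 2.0:
            raise ValueError(
                f"fractional_bandwidth must lie in (0, 2), got "
                f"{self.fractional_bandwidth}"
            )
        if self.duration_cycles <= 0:
            raise ValueError("duration_cycles must be > 0")

    @property
    def half_duration(self) -> float:
        """Half-support of the truncated waveform in seconds."""
        return 0.5 * self.duration_cycles / self.center_frequency

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the pulse at times ``t`` (s), zero outside the support."""
        t = np.asarray(t, dtype=float)
        out = _signal.gausspulse(t, fc=self.center_frequency,
                                 bw=self.fractional_bandwidth)
        return np.where(np.abs(t) <= self.half_duration, out, 0.0)

    def sampled(self, sampling_frequency: float) -> np.ndarray:
        """Waveform sampled at ``sampling_frequency`` over its support."""
        n = int(np.ceil(self.half_duration * sampling_frequency))
        t = np.arange(-n, n + 1) / sampling_frequency
        w = self.waveform(t)
        if not np.isfinite(w).all() or float(np.sum(w * w)) <= 0.0:
            raise ValueError("sampled pulse must have finite positive energy")
        return w


@dataclass(frozen=True)
class Phantom:
    """Collection of point scatterers plus optional anechoic (cyst) regions.

    ``scatterers`` is an ``(N, 3)`` array of ``(x_mm, z_mm, amplitude)`` rows.
    ``cyst_regions`` is a list of ``(cx_mm, cz_mm, radius_mm)`` discs inside
    which no diffuse scatterer is placed.
    """

    scatterers: np.ndarray
    cyst_regions: tuple = ()
    speckle_density: float = 0.0

    def __post_init__(self) -> None:
        sc = np.atleast_2d(np.asarray(self.scatterers, dtype=float))
        if sc.size == 0:
            sc = np.empty((0, 3))
        if sc.shape[1] != 3:
            raise ValueError("scatterers must be (N, 3): x_mm, z_mm, amplitude")
        if sc.shape[0] and np.any(sc[:, 1] <= 0):
            raise ValueError("all scatterer depths z must be > 0")
        for cx, cz, r in self.cyst_regions:
            if r <= 0:
                raise ValueError(f"cyst radius must be > 0, got {r}")
            inside = (sc[:, 0] - cx) ** 2 + (sc[:, 1] - cz) ** 2 < r**2
            if np.any(sc[inside, 2] != 0.0):
                raise ValueError("scatterers inside a cyst must have amplitude 0")
        object.__setattr__(self, "scatterers", sc)

    @property
    def num_scatterers(self) -> int:
        return int(self.scatterers.shape[0])


@dataclass
class ChannelData:
    """Per-element time-sampled RF (or analytic) signals.

    ``samples`` is ``(M, n_time)``; row ``m`` is element ``m``.
    ``time_origin`` is the acquisition time of sample index 0, in seconds.
    """

    samples: np.ndarray
    time_origin: float
    sampling_frequency: float
    geometry: ArrayGeometry

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (elements x time) matrix")
        if self.samples.shape[0] != self.geometry.num_elements:
            raise ValueError(
                f"samples has {self.samples.shape[0]} rows but geometry has "
                f"{self.geometry.num_elements} elements"
            )
        if not np.isfinite(self.samples).all():
            raise ValueError("samples must be finite")

    @property
    def num_samples(self) -> int:
        return int(self.samples.shape[1])

    @property
    def time_axis(self) -> np.ndarray:
        return self.time_origin + np.arange(self.num_samples) / self.sampling_frequency

    @property
    def is_complex(self) -> bool:
        return np.iscomplexobj(self.samples)


def make_linear_array(
    num_elements: int,
    pitch_mm: float,
    center_frequency: float,
    sampling_frequency: float,
    sound_speed: float = 1540.0,
) -> ArrayGeometry:
    """Build a centred linear array; validation lives in :class:`ArrayGeometry`."""
    return ArrayGeometry(
        num_elements=num_elements,
        pitch_mm=pitch_mm,
        center_frequency=center_frequency,
        sampling_frequency=sampling_frequency,
        sound_speed=sound_speed,
    )


def make_cyst_phantom(
    cyst_center_mm: tuple[float, float],
    cyst_radius_mm: float,
    field_extent_mm: tuple[tuple[float, float], tuple[float, float]],
    speckle_density: float,
    seed: int,
    extra_scatterers: np.ndarray | None = None,
) -> Phantom:
    """Uniform diffuse speckle over a rectangle with an anechoic disc cut out.

    Parameters
    ----------
    cyst_center_mm, cyst_radius_mm
        Anechoic disc; must be fully contained in the field extent.
    field_extent_mm
        ``((x_min, x_max), (z_min, z_max))`` in mm, ``z_min > 0``.
    speckle_density
        Expected diffuse scatterers per mm^2 (Poisson count).
    seed
        Seeds scatterer placement and amplitudes; identical seeds give
        identical phantoms.
    extra_scatterers
        Optional explicit ``(N, 3)`` rows appended verbatim (e.g. a wire
        target for resolution measurement).
    """
    (x_min, x_max), (z_min, z_max) = field_extent_mm
    if not (x_min < x_max and 0 < z_min < z_max):
        raise ValueError("field extent must satisfy x_min < x_max, 0 < z_min < z_max")
    cx, cz = cyst_center_mm
    if cyst_radius_mm <= 0:
        raise ValueError("cyst_radius_mm must be > 0")
    if not (
        x_min <= cx - cyst_radius_mm
        and cx + cyst_radius_mm <= x_max
        and z_min <= cz - cyst_radius_mm
        and cz + cyst_radius_mm <= z_max
    ):
        raise ValueError("cyst disc must be contained in the field extent")
    if speckle_density < 0:
        raise ValueError("speckle_density must be >= 0")

    rng = np.random.default_rng(seed)
    area = (x_max - x_min) * (z_max - z_min)
    n = int(rng.poisson(speckle_density * area)) if speckle_density > 0 else 0
    xs = rng.uniform(x_min, x_max, size=n)
    zs = rng.uniform(z_min, z_max, size=n)
    # Rayleigh with unit mean: scale sigma = sqrt(2/pi)
    amps = rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=n)
    keep = (xs - cx) ** 2 + (zs - cz) ** 2 >= cyst_radius_mm**2
    sc = np.column_stack([xs[keep], zs[keep], amps[keep]])
    if extra_scatterers is not None:
        extra = np.atleast_2d(np.asarray(extra_scatterers, dtype=float))
        sc = np.vstack([sc, extra]) if sc.size else extra
    return Phantom(
        scatterers=sc if sc.size else np.empty((0, 3)),
        cyst_regions=((cx, cz, cyst_radius_mm),),
        speckle_density=speckle_density,
    )


def _arrival_times(
    geometry: ArrayGeometry, scatterers: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Two-way arrival times (N, M) and receive distances (N, M) in metres."""
    elem_x = geometry.element_positions_mm[None, :] * MM  # (1, M)
    sx = scatterers[:, 0:1] * MM
    sz = scatterers[:, 1:2] * MM
    rx_dist = np.hypot(sx - elem_x, sz)  # (N, M)
    t = (sz + rx_dist) / geometry.sound_speed  # plane-wave tx + element rx
    return t, rx_dist


def simulate_channel_data(
    geometry: ArrayGeometry,
    phantom: Phantom,
    pulse: Pulse,
    noise_db: float = -np.inf,
    seed: int = 0,
    time_padding: float = 2e-6,
    time_span: tuple[float, float] | None = None,
) -> ChannelData:
    """Synthesize RF channel data for ``phantom`` under the monostatic model.

    Each scatterer contributes to element ``m`` a pulse replica delayed by the
    two-way travel time (plane-wave transmit from the aperture plane, receive
    at element ``m``), scaled by its amplitude and ``1/r`` spreading on the
    receive path.  White Gaussian noise is added at ``noise_db`` decibels
    relative to the peak per-channel RMS of the clean signal;
    ``noise_db = -inf`` means noiseless.

    Raises
    ------
    ValueError
        If the phantom contributes no signal and noise is disabled (an
        all-zero recording is an error, not a silent return).
    """
    sc = phantom.scatterers
    active = sc[np.abs(sc[:, 2]) > 0] if sc.size else sc
    noiseless = np.isneginf(noise_db)
    if active.shape[0] == 0 and noiseless:
        raise ValueError(
            "phantom contributes no signal and noise is disabled: refusing to "
            "return all-zero channel data"
        )

    fs = geometry.sampling_frequency
    arrivals = rx_dist = None
    if active.shape[0]:
        arrivals, rx_dist = _arrival_times(geometry, active)
    if time_span is not None:
        t_start, t_stop = time_span
    elif active.shape[0]:
        t_start = float(arrivals.min()) - pulse.half_duration - time_padding
        t_stop = float(arrivals.max()) + pulse.half_duration + time_padding
    else:
        t_start, t_stop = 0.0, 20e-6
    t_start = max(t_start, 0.0)
    n_time = int(np.ceil((t_stop - t_start) * fs)) + 1
    out = np.zeros((geometry.num_elements, n_time))

    if active.shape[0]:
        n_half = int(np.ceil(pulse.half_duration * fs))
        offsets = np.arange(-n_half, n_half + 1)  # samples around the arrival
        amps = active[:, 2][:, None] / rx_dist  # (N, M), 1/r spreading
        for i in range(active.shape[0]):
            # fractional arrival index per element
            idx_f = (arrivals[i] - t_start) * fs  # (M,)
            base = np.floor(idx_f).astype(int)
            cols = base[:, None] + offsets[None, :]  # (M, n_pulse)
            # evaluate pulse at exact (sample time - arrival time)
            dt = (cols - idx_f[:, None]) / fs
            wave = pulse.waveform(dt) * amps[i][:, None]
            valid = (cols >= 0) & (cols < n_time)
            rows = np.broadcast_to(
                np.arange(geometry.num_elements)[:, None], cols.shape
            )
            np.add.at(out, (rows[valid], cols[valid]), wave[valid])

    if not noiseless:
        rng = np.random.default_rng(seed)
        if active.shape[0]:
            ref = float(np.sqrt(np.mean(out**2, axis=1)).max())
        else:
            ref = 1.0
        sigma = ref * 10.0 ** (noise_db / 20.0)
        out = out + rng.normal(0.0, sigma, size=out.shape)

    return ChannelData(
        samples=out,
        time_origin=t_start,
        sampling_frequency=fs,
        geometry=geometry,
    )
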