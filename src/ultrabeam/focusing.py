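"""Receive focusing: per-point delays, analytic conversion, aligned snapshots.

Delay sign convention: :func:`compute_focus_delays` returns non-negative
relative delays ``psi_m = (d_m - min_m d_m) / c`` where ``d_m`` is the
element-to-focal-point distance.  Element ``m``'s aligned sample at nominal
time ``t`` is then the channel-``m`` recording at ``t + psi_m`` — the element
closest to the focal point defines the reference instant and every other
channel is read later by its extra path delay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .array_model import MM, ArrayGeometry, ChannelData

__all__ = [
    "FocusDelays",
    "Snapshot",
    "compute_focus_delays",
    "analytic_signal",
    "extract_snapshot",
    "das_output",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FocusDelays:
    """Relative receive delays (s) for one focal point; min delay is 0."""

    delays: np.ndarray
    focal_point_mm: tuple[float, float]

    def __post_init__(self) -> None:
        d = np.asarray(self.delays, dtype=float)
        if d.ndim != 1:
            raise ValueError("delays must be a 1-D vector")
        if d.size and d.min() < -1e-15:
            raise ValueError("delays must be >= 0 after normalization")
        object.__setattr__(self, "delays", d)


@dataclass(frozen=True)
class Snapshot:
    """One aligned complex sample per element at a given focal point."""

    values: np.ndarray
    focal_point_mm: tuple[float, float]
    time_index: int


def compute_focus_delays(
    geometry: ArrayGeometry, focal_point_mm: tuple[float, float]
) -> FocusDelays:
    """Geometric receive delays for ``focal_point_mm = (x, z)`` in mm.

    ``psi_m = (||(x_m, 0) - p|| - min_m ||.||) / c``; the minimum is exactly 0.
    """
    x, z = focal_point_mm
    if z <= 0:
        raise ValueError(f"focal point must lie below the array plane (z > 0), got z={z}")
    elem_x = geometry.element_positions_mm * MM
    dist = np.hypot(x * MM - elem_x, z * MM)
    delays = (dist - dist.min()) / geometry.sound_speed
    delays = delays - delays.min()  # exact zero minimum
    return FocusDelays(delays=delays, focal_point_mm=(float(x), float(z)))


def analytic_signal(channel_data: ChannelData) -> ChannelData:
    """Per-element analytic (complex) signal via the Hilbert transform.

    The real part of the output equals the input; the magnitude is the
    envelope.  Already-complex input is passed through unchanged with a
    logged notice.
    """
    if channel_data.is_complex:
        log.info("analytic_signal: input already complex; passing through")
        return channel_data
    analytic = hilbert(channel_data.samples, axis=1)
    return ChannelData(
        samples=analytic,
        time_origin=channel_data.time_origin,
        sampling_frequency=channel_data.sampling_frequency,
        geometry=channel_data.geometry,
    )


def sample_delayed(
    channel_data: ChannelData, fractional_indices: np.ndarray
) -> np.ndarray:
    """Read each channel at a (possibly fractional) sample index.

    ``fractional_indices`` has shape ``(M, ...)``; entry ``[m, ...]`` is the
    index into channel ``m``, filled by linear interpolation between the two
    adjacent samples.  Indices outside ``[0, n-1]`` raise.
    """
    idx = np.asarray(fractional_indices, dtype=float)
    n = channel_data.num_samples
    if idx.min() < 0 or idx.max() > n - 1:
        bad = np.unravel_index(
            int(np.argmax((idx < 0) | (idx > n - 1))), idx.shape
        )
        raise IndexError(
            f"delayed sample position {idx[bad]:.2f} for element {bad[0]} is "
            f"outside the recorded time axis [0, {n - 1}]"
        )
    lo = np.floor(idx).astype(int)
    hi = np.minimum(lo + 1, n - 1)
    frac = idx - lo
    rows = np.arange(channel_data.samples.shape[0])
    rows = rows.reshape((-1,) + (1,) * (idx.ndim - 1))
    s = channel_data.samples
    return (1.0 - frac) * s[rows, lo] + frac * s[rows, hi]


def extract_snapshot(
    channel_data: ChannelData, focus_delays: FocusDelays, time_index: int
) -> Snapshot:
    """Aligned snapshot: element ``m`` read at ``time_index + psi_m * fs``.

    Fractional positions use linear interpolation; integer-sample delays are
    exact.  All-zero delays return the raw column at ``time_index``.
    """
    if len(focus_delays.delays) != channel_data.geometry.num_elements:
        raise ValueError("delay vector length must match the element count")
    idx = time_index + focus_delays.delays * channel_data.sampling_frequency
    try:
        values = sample_delayed(channel_data, idx)
    except IndexError as exc:
        raise IndexError(f"snapshot at time_index={time_index}: {exc}") from exc
    return Snapshot(
        values=values,
        focal_point_mm=focus_delays.focal_point_mm,
        time_index=int(time_index),
    )


def das_output(snapshot: Snapshot | np.ndarray, weights: np.ndarray) -> complex:
    """Weighted sum ``sum_m conj(z_m) p_m`` of an aligned snapshot.

    Uniform weights ``1/M`` give classical delay-and-sum.
    """
    values = snapshot.values if isinstance(snapshot, Snapshot) else np.asarray(snapshot)
    weights = np.asarray(weights)
    if values.shape != weights.shape:
        raise ValueError(
            f"weights shape {weights.shape} does not match snapshot shape "
            f"{values.shape}"
        )
    return complex(np.vdot(weights, values))
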