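"""B-mode image formation: per-pixel dynamic receive focusing, beamformer
sweep, envelope detection, log compression and PNG rendering.

For every pixel the pipeline computes geometric focusing delays, reads an
aligned snapshot block (a short temporal window around the pixel's two-way
arrival time), and applies the selected beamformer.  Adaptive methods build
one spatially smoothed covariance per pixel from that block and average the
beamformed output over the subarray windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

from .array_model import MM, ChannelData
from .covariance import estimate_covariance
from .adaptive_beamformers import (
    iscb_weights,
    rls_weights,
    scb_weights,
    ser_weights,
)
from .focusing import analytic_signal, sample_delayed

__all__ = [
    "ImageGrid",
    "BeamformedImage",
    "METHODS",
    "default_method_params",
    "beamform_image",
    "envelope_log_compress",
    "render_png",
]

METHODS = ("DAS", "SCB", "ISCB", "RLS", "SER")


@dataclass(frozen=True)
class ImageGrid:
    """Rectangular pixel grid: lateral (x) and depth (z) axes in mm."""

    x_mm: np.ndarray
    z_mm: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x_mm, dtype=float)
        z = np.asarray(self.z_mm, dtype=float)
        if x.ndim != 1 or z.ndim != 1:
            raise ValueError("grid axes must be 1-D")
        if x.size > 1 and np.any(np.diff(x) <= 0):
            raise ValueError("x axis must be strictly increasing")
        if np.any(np.diff(z) <= 0):
            raise ValueError("z axis must be strictly increasing")
        if np.any(z <= 0):
            raise ValueError("all grid depths must be > 0")
        object.__setattr__(self, "x_mm", x)
        object.__setattr__(self, "z_mm", z)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.z_mm.size, self.x_mm.size)


@dataclass
class BeamformedImage:
    """Complex scanline grid plus its log-compressed B-mode rendering."""

    complex_values: np.ndarray  # (nz, nx)
    bmode_db: np.ndarray
    dynamic_range: float
    method: str
    grid: ImageGrid

    def __post_init__(self) -> None:
        if self.complex_values.shape != self.grid.shape:
            raise ValueError("complex_values shape must match the grid")
        if self.bmode_db.shape != self.grid.shape:
            raise ValueError("bmode_db shape must match the grid")

    @property
    def envelope(self) -> np.ndarray:
        return np.abs(self.complex_values)


def default_method_params(num_elements: int) -> dict:
    """Documented defaults for the adaptive methods.

    Subarray length ``L = 3M // 8``, temporal halfwidth 1 (3 snapshots),
    diagonal loading ``1 / (100 L)``, steering error budget ``tau = L / 30``,
    eigen threshold 0.5.  These were selected empirically on the standard
    cyst phantom so each method operates at a reasonable working point; they
    are user-overridable per call.
    """
    L = max(1, (3 * num_elements) // 8)
    return {
        "subarray_length": L,
        "temporal_halfwidth": 1,
        "loading_factor": 1.0 / (100.0 * L),
        "tau": L / 30.0,
        "threshold_factor": 0.5,
        "forgetting_factor": 1.0,
        "init_delta": 1e-2,
        "step_schedule": 0.1,
    }


def pixel_arrival_times(channel_data: ChannelData, grid: ImageGrid) -> np.ndarray:
    """Two-way arrival time (s) of each pixel, shape (nz, nx).

    Plane-wave transmit (``z/c``) plus the receive path of the closest
    element — the reference instant of the aligned snapshot.
    """
    geom = channel_data.geometry
    elem_x = geom.element_positions_mm * MM
    xx = grid.x_mm[None, :, None] * MM
    zz = grid.z_mm[:, None, None] * MM
    dist = np.hypot(xx - elem_x[None, None, :], zz)  # (nz, nx, M)
    return (zz[:, :, 0] + dist.min(axis=2)) / geom.sound_speed


def _aligned_block(
    channel_data: ChannelData, grid: ImageGrid, halfwidth: int
) -> np.ndarray:
    """Aligned snapshots for all pixels: shape (nz*nx, M, 2*halfwidth+1)."""
    geom = channel_data.geometry
    fs = channel_data.sampling_frequency
    elem_x = geom.element_positions_mm * MM
    xx = grid.x_mm[None, :, None] * MM
    zz = grid.z_mm[:, None, None] * MM
    dist = np.hypot(xx - elem_x[None, None, :], zz)  # (nz, nx, M)
    t_rx = dist / geom.sound_speed
    t_pix = zz[:, :, 0:1] / geom.sound_speed + t_rx.min(axis=2, keepdims=True)
    psi = t_rx - t_rx.min(axis=2, keepdims=True)  # relative delays >= 0
    idx = (t_pix + psi - channel_data.time_origin) * fs  # (nz, nx, M)
    idx = idx.reshape(-1, geom.num_elements).T  # (M, n_pix)
    offsets = np.arange(-halfwidth, halfwidth + 1)
    idx_k = idx[:, :, None] + offsets[None, None, :]  # (M, n_pix, n_k)
    n = channel_data.num_samples
    if idx_k.min() < 0 or idx_k.max() > n - 1:
        raise IndexError(
            "image grid (with the temporal window) falls outside the recorded "
            f"time support: needed sample range [{idx_k.min():.1f}, "
            f"{idx_k.max():.1f}] vs available [0, {n - 1}]"
        )
    block = sample_delayed(channel_data, idx_k)  # (M, n_pix, n_k)
    return np.moveaxis(block, 1, 0)  # (n_pix, M, n_k)


def grid_time_span(
    channel_data_like, grid: ImageGrid, margin_s: float = 1e-6
) -> tuple[float, float]:
    """Acquisition window needed to beamform ``grid`` (with margin)."""
    geom = channel_data_like if not isinstance(channel_data_like, ChannelData) else channel_data_like.geometry
    elem_x = geom.element_positions_mm * MM
    xx = grid.x_mm[None, :, None] * MM
    zz = grid.z_mm[:, None, None] * MM
    dist = np.hypot(xx - elem_x[None, None, :], zz)
    t = zz[:, :, 0:1] / geom.sound_speed + dist / geom.sound_speed
    return float(t.min()) - margin_s, float(t.max()) + margin_s


def beamform_image(
    channel_data: ChannelData,
    grid: ImageGrid,
    method: str = "DAS",
    method_params: dict | None = None,
    dynamic_range: float = 60.0,
) -> BeamformedImage:
    """Sweep one beamformer over the pixel grid.

    ``method`` is one of ``DAS, SCB, ISCB, RLS, SER``.  Real input is
    converted to its analytic signal first.  Deterministic given the data
    and parameters.
    """
    method = str(method).upper()
    if method not in METHODS:
        raise ValueError(
            f"unknown method {method!r}; valid choices: {', '.join(METHODS)}"
        )
    geom = channel_data.geometry
    params = default_method_params(geom.num_elements)
    if method_params:
        unknown = set(method_params) - set(params)
        if unknown:
            raise ValueError(f"unknown method parameters: {sorted(unknown)}")
        params.update(method_params)

    cd = analytic_signal(channel_data)
    halfwidth = int(params["temporal_halfwidth"]) if method != "DAS" else 0
    block = _aligned_block(cd, grid, halfwidth)  # (n_pix, M, n_k)
    n_pix, M, n_k = block.shape
    kc = n_k // 2

    if method == "DAS":
        q = block[:, :, kc].mean(axis=1)
    else:
        L = int(params["subarray_length"])
        lam = np.ones(L, dtype=complex)
        q = np.empty(n_pix, dtype=complex)
        for i in range(n_pix):
            snaps = block[i]  # (M, n_k)
            cov = estimate_covariance(
                snaps,
                subarray_length=L,
                temporal_halfwidth=halfwidth,
                loading_factor=float(params["loading_factor"]),
            )
            if method == "SCB":
                bf = scb_weights(cov, lam)
            elif method == "ISCB":
                bf = iscb_weights(
                    cov,
                    lam,
                    tau=float(params["tau"]),
                    threshold_factor=float(params["threshold_factor"]),
                )
            else:
                windows = np.lib.stride_tricks.sliding_window_view(snaps, L, axis=0)
                stream = windows.reshape(-1, L)  # subarray x time snapshots
                if method == "RLS":
                    bf = rls_weights(
                        stream,
                        lam,
                        forgetting_factor=float(params["forgetting_factor"]),
                        init_delta=float(params["init_delta"]),
                    )
                else:  # SER
                    bf = ser_weights(stream, lam, params["step_schedule"])
            # w^H x_g averaged over the subarray windows of the centre snapshot
            center = np.lib.stride_tricks.sliding_window_view(snaps[:, kc], L)
            q[i] = np.mean(center @ bf.weights.conj())

    complex_img = q.reshape(grid.shape)
    bmode = envelope_log_compress(complex_img, dynamic_range)
    return BeamformedImage(
        complex_values=complex_img,
        bmode_db=bmode,
        dynamic_range=float(dynamic_range),
        method=method,
        grid=grid,
    )


def envelope_log_compress(complex_values: np.ndarray, dynamic_range: float = 60.0) -> np.ndarray:
    """``20 log10(|Q| / max|Q|)`` clipped below at ``-dynamic_range``."""
    if dynamic_range <= 0:
        raise ValueError("dynamic_range must be > 0")
    env = np.abs(np.asarray(complex_values))
    peak = env.max()
    if peak == 0:
        raise ValueError("all-zero image cannot be log-compressed")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(env / peak)
    return np.clip(db, -dynamic_range, 0.0)


def render_png(
    bmode_db: np.ndarray,
    path,
    dynamic_range: float | None = None,
    colormap: str = "gray",
) -> None:
    """Write an 8-bit grayscale PNG: 0 dB -> 255 (white), floor -> 0 (black).

    Values map affinely, ``round((db + DR) / DR * 255)`` with numpy's
    round-half-to-even (a constant -20 dB image at 40 dB range renders as
    gray level 128).  Deterministic bytes for identical input.
    """
    db = np.asarray(bmode_db, dtype=float)
    dr = float(dynamic_range) if dynamic_range is not None else max(1e-9, -db.min())
    scaled = np.clip((db + dr) / dr, 0.0, 1.0) * 255.0
    img = np.round(scaled).astype(np.uint8)
    if colormap != "gray":
        import matplotlib

        cmap = matplotlib.colormaps[colormap]
        img = (np.asarray(cmap(img / 255.0))[:, :, :3] * 255).round().astype(np.uint8)
    iio.imwrite(path, img, extension=".png")
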