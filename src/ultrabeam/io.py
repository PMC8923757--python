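"""HDF5 persistence for channel data and beamformed images.

Channel-data layout (documented so third-party data can be converted in):

    /samples            float or complex matrix, shape (elements, time)
    /samples@sampling_frequency   Hz
    /samples@time_origin          seconds
    /geometry           group with attributes num_elements, pitch_mm,
                        center_frequency, sampling_frequency, sound_speed

Files are written with HDF5 object timestamps disabled so identical inputs
produce byte-identical files.
"""

from __future__ import annotations

import h5py
import numpy as np

from .array_model import ArrayGeometry, ChannelData
from .imaging import BeamformedImage, ImageGrid

__all__ = [
    "save_channel_data",
    "load_channel_data",
    "save_image",
    "load_image",
]

_GEOM_FIELDS = (
    "num_elements",
    "pitch_mm",
    "center_frequency",
    "sampling_frequency",
    "sound_speed",
)


def _dataset(group, name, data):
    return group.create_dataset(name, data=data, track_times=False)


def save_channel_data(path, channel_data: ChannelData) -> None:
    with h5py.File(path, "w", libver="earliest", track_order=False) as f:
        ds = _dataset(f, "samples", channel_data.samples)
        ds.attrs["sampling_frequency"] = channel_data.sampling_frequency
        ds.attrs["time_origin"] = channel_data.time_origin
        g = f.create_group("geometry", track_order=False)
        for name in _GEOM_FIELDS:
            g.attrs[name] = getattr(channel_data.geometry, name)


def load_channel_data(path) -> ChannelData:
    with h5py.File(path, "r") as f:
        ds = f["samples"]
        geom_attrs = dict(f["geometry"].attrs)
        geometry = ArrayGeometry(
            num_elements=int(geom_attrs["num_elements"]),
            pitch_mm=float(geom_attrs["pitch_mm"]),
            center_frequency=float(geom_attrs["center_frequency"]),
            sampling_frequency=float(geom_attrs["sampling_frequency"]),
            sound_speed=float(geom_attrs["sound_speed"]),
        )
        return ChannelData(
            samples=ds[()],
            time_origin=float(ds.attrs["time_origin"]),
            sampling_frequency=float(ds.attrs["sampling_frequency"]),
            geometry=geometry,
        )


def save_image(path, image: BeamformedImage) -> None:
    with h5py.File(path, "w", libver="earliest", track_order=False) as f:
        _dataset(f, "complex_values", image.complex_values)
        _dataset(f, "bmode_db", image.bmode_db)
        _dataset(f, "x_mm", image.grid.x_mm)
        _dataset(f, "z_mm", image.grid.z_mm)
        f.attrs["dynamic_range"] = image.dynamic_range
        f.attrs["method"] = image.method


def load_image(path) -> BeamformedImage:
    with h5py.File(path, "r") as f:
        grid = ImageGrid(f["x_mm"][()], f["z_mm"][()])
        return BeamformedImage(
            complex_values=f["complex_values"][()],
            bmode_db=f["bmode_db"][()],
            dynamic_range=float(f.attrs["dynamic_range"]),
            method=str(f.attrs["method"]),
            grid=grid,
        )
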