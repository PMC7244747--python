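"""HDF5 / image file round-trips for datasets, sinograms and reconstructions."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from paxel.phantoms import PhantomDataset
from paxel.simulate import Medium, SensorGeometry, SensorTimeSeries

__all__ = [
    "save_dataset",
    "load_dataset",
    "save_sinograms",
    "load_sinograms",
    "save_images",
    "load_images",
    "read_image",
    "write_image",
    "read_volume",
]


def save_dataset(path: str | Path, datasets: dict[str, PhantomDataset]) -> None:
    """Write phantom datasets as /<split>/images with provenance attributes."""
    with h5py.File(path, "w") as f:
        for split, ds in datasets.items():
            g = f.create_group(split)
            g.create_dataset("images", data=ds.images.astype(np.float32))
            g.attrs["split"] = ds.split
            g.create_dataset("provenance", data=np.asarray(ds.provenance, dtype=np.int64))


def load_dataset(path: str | Path, split: str = "train") -> PhantomDataset:
    with h5py.File(path, "r") as f:
        g = f[split]
        return PhantomDataset(
            images=np.asarray(g["images"], dtype=np.float64),
            split=str(g.attrs["split"]),
            provenance=[tuple(int(v) for v in row) for row in np.asarray(g["provenance"])],
        )


def save_sinograms(path: str | Path, series: list[SensorTimeSeries]) -> None:
    """Stacked sensor data as /y (n, N, T) with acquisition attributes."""
    if not series:
        raise ValueError("no sensor series to save")
    s0 = series[0]
    data = np.stack([s.data for s in series]).astype(np.float32)
    with h5py.File(path, "w") as f:
        d = f.create_dataset("y", data=data)
        d.attrs["dt"] = s0.dt
        d.attrs["c0"] = s0.medium.sound_speed
        d.attrs["dx"] = s0.medium.dx
        d.attrs["density"] = s0.medium.density
        d.attrs["grid_shape"] = s0.medium.grid_shape
        d.attrs["positions"] = s0.geometry.as_array()
        d.attrs["arc_span"] = s0.geometry.arc_span
        d.attrs["radius_px"] = s0.geometry.radius_px


def load_sinograms(path: str | Path) -> list[SensorTimeSeries]:
    with h5py.File(path, "r") as f:
        d = f["y"]
        grid_shape = tuple(int(v) for v in d.attrs["grid_shape"])
        medium = Medium(sound_speed=float(d.attrs["c0"]), density=float(d.attrs["density"]),
                        grid_shape=grid_shape, dx=float(d.attrs["dx"]))
        positions = tuple(tuple(int(v) for v in row) for row in d.attrs["positions"])
        geometry = SensorGeometry(positions=positions, grid_shape=grid_shape,
                                  arc_span=float(d.attrs["arc_span"]),
                                  radius_px=float(d.attrs["radius_px"]),
                                  center=(grid_shape[0] / 2.0, grid_shape[1] / 2.0))
        dt = float(d.attrs["dt"])
        return [SensorTimeSeries(np.asarray(row, dtype=np.float64), dt, geometry, medium)
                for row in np.asarray(d)]


def save_images(path: str | Path, images: np.ndarray, name: str = "images",
                attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset(name, data=np.asarray(images, dtype=np.float32))
        for k, v in (attrs or {}).items():
            d.attrs[k] = v


def load_images(path: str | Path, name: str = "images") -> np.ndarray:
    with h5py.File(path, "r") as f:
        return np.asarray(f[name], dtype=np.float64)


def read_image(path: str | Path) -> np.ndarray:
    """Load a user-supplied 2D image (PNG/TIFF), converted to float64 [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        raw = tifffile.imread(path)
    else:
        import imageio.v3 as iio
        raw = iio.imread(path)
    arr = np.asarray(raw, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    if np.issubdtype(np.asarray(raw).dtype, np.integer):
        arr = arr / np.iinfo(np.asarray(raw).dtype).max
    return arr


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a [0, 1] image as 16-bit PNG or 32-bit float TIFF by extension."""
    path = Path(path)
    image = np.asarray(image, dtype=np.float64)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, image.astype(np.float32))
    else:
        import imageio.v3 as iio
        iio.imwrite(path, (np.clip(image, 0, 1) * 65535).astype(np.uint16))


def read_volume(path: str | Path, dataset: str = "volume") -> np.ndarray:
    """Load a user-supplied 3D volume (TIFF stack or HDF5)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            return np.asarray(f[dataset], dtype=np.float64)
    import tifffile
    return np.asarray(tifffile.imread(path), dtype=np.float64)
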