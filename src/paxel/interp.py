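"""Pixel-wise interpolation: remap sensor time series onto the image grid.

Under a homogeneous linear acoustic model, a wavefront leaving the pixel at
(r, c) reaches sensor i after a time of flight proportional to the Euclidean
pixel-sensor distance, tof = d * dx / c0.  Pixel-wise interpolation reads each
sensor's recorded series at that per-pixel delay, producing an H x W x N
volume in which channel i is sensor i's data "focused" back into image space.
The volume is the input to the Pixel-DL network; collapsing it by a mean over
the sensor axis gives the classical delay-and-sum beamformed image.

A separate resampling path (:func:`interp_for_mdirect`) prepares the raw N x T
sinogram for the modified direct-reconstruction network by separable linear
interpolation (with block averaging before downsampling on the long time axis)
to the output image dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from paxel.simulate import Medium, SensorGeometry, SensorTimeSeries

__all__ = [
    "TimeOfFlightMap",
    "PixelInterpolatedVolume",
    "compute_tof_map",
    "pixel_wise_interpolate",
    "delay_and_sum",
    "interp_for_mdirect",
]


@dataclass
class TimeOfFlightMap:
    """H x W x N travel times (seconds) from each pixel to each sensor."""

    tof: np.ndarray
    geometry: SensorGeometry
    sound_speed: float

    def __post_init__(self) -> None:
        if self.tof.ndim != 3 or self.tof.shape[2] != self.geometry.n_sensors:
            raise ValueError("tof must be H x W x N with N matching the geometry")


@dataclass
class PixelInterpolatedVolume:
    """H x W x N pixel-interpolated data; channel order matches sensor order."""

    volume: np.ndarray
    geometry: SensorGeometry
    dt: float

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=np.float64)
        if self.volume.ndim != 3 or self.volume.shape[2] != self.geometry.n_sensors:
            raise ValueError("volume must be H x W x N with N matching the geometry")


def compute_tof_map(geometry: SensorGeometry, medium: Medium | None = None) -> TimeOfFlightMap:
    """tof[r, c, i] = ||pixel(r, c) - sensor_i|| * dx / c0, in seconds.

    Pixel centers sit at integer (row, col) grid coordinates, so the map is
    exactly zero where a pixel coincides with a sensor node.
    """
    medium = medium or Medium(grid_shape=geometry.grid_shape)
    h, w = geometry.grid_shape
    pos = geometry.as_array().astype(np.float64)          # (N, 2)
    rows = np.arange(h, dtype=np.float64)[:, None, None]
    cols = np.arange(w, dtype=np.float64)[None, :, None]
    d = np.sqrt((rows - pos[None, None, :, 0]) ** 2 + (cols - pos[None, None, :, 1]) ** 2)
    tof = d * medium.dx / medium.sound_speed
    return TimeOfFlightMap(tof=tof, geometry=geometry, sound_speed=medium.sound_speed)


def pixel_wise_interpolate(y: SensorTimeSeries, tofmap: TimeOfFlightMap,
                           kind: str = "linear") -> PixelInterpolatedVolume:
    """Sample each sensor's series at every pixel's time of flight.

    volume[r, c, i] reads y[i] at the fractional sample tof[r, c, i] / dt
    (linear interpolation between neighbouring samples by default; "nearest"
    and "cubic" are available behind the ``kind`` flag).  Pixels whose time of
    flight falls outside the recording window are zero-filled.  The map is
    linear in ``y``.
    """
    if tofmap.geometry.positions != y.geometry.positions:
        raise ValueError("sensor geometry of the series and the TOF map differ")
    if y.dt <= 0:
        raise ValueError("dt must be positive")
    if kind not in ("linear", "nearest", "cubic"):
        raise ValueError(f"unknown interpolation kind {kind!r}")

    data = y.data                                        # (N, T)
    n, t = data.shape
    s = tofmap.tof / y.dt                                # fractional sample index
    if kind == "cubic":
        from scipy.interpolate import CubicSpline
        vol = np.zeros(s.shape)
        ts = np.arange(t, dtype=np.float64)
        for i in range(n):
            cs = CubicSpline(ts, data[i], extrapolate=False)
            v = cs(s[:, :, i])
            vol[:, :, i] = np.nan_to_num(v, nan=0.0)
        return PixelInterpolatedVolume(volume=vol, geometry=y.geometry, dt=y.dt)

    if kind == "nearest":
        idx = np.rint(s).astype(np.intp)
        inside = (idx >= 0) & (idx <= t - 1)
        idx = np.clip(idx, 0, t - 1)
        vol = data[np.arange(n)[None, None, :], idx]
        vol = np.where(inside, vol, 0.0)
        return PixelInterpolatedVolume(volume=vol, geometry=y.geometry, dt=y.dt)

    i0 = np.floor(s).astype(np.intp)
    frac = s - i0
    inside = (s >= 0) & (s <= t - 1)
    i0c = np.clip(i0, 0, t - 1)
    i1c = np.clip(i0 + 1, 0, t - 1)
    ch = np.arange(n)[None, None, :]
    v0 = data[ch, i0c]
    v1 = data[ch, i1c]
    vol = np.where(inside, (1.0 - frac) * v0 + frac * v1, 0.0)
    return PixelInterpolatedVolume(volume=vol, geometry=y.geometry, dt=y.dt)


def delay_and_sum(volume: PixelInterpolatedVolume, normalize_output: bool = True) -> np.ndarray:
    """Collapse the pixel volume by the mean over the sensor axis.

    Classical delay-and-sum beamforming: TOF-aligned channels add coherently at
    true source positions.  Output is clipped to be nonnegative and min-max
    normalized (a diagnostic image; the learned pipelines consume the full
    volume instead).
    """
    img = volume.volume.mean(axis=2)
    img = np.clip(img, 0.0, None)
    if normalize_output and img.max() > 0:
        img = img / img.max()
    return img


def interp_for_mdirect(y: SensorTimeSeries, out_shape: tuple[int, int] = (128, 128)) -> np.ndarray:
    """Resample the raw N x T sinogram to the image dimensions.

    Separable linear interpolation: the sensor axis is linearly interpolated up
    to ``out_shape[0]`` rows; the (much longer) time axis is first reduced by
    contiguous block averaging to suppress aliasing, then linearly interpolated
    to ``out_shape[1]`` columns.  Values at original sample positions are
    preserved up to interpolation error.
    """
    data = np.asarray(y.data, dtype=np.float64)
    n, t = data.shape
    rows_out, cols_out = out_shape

    # time axis: anti-aliased reduction when downsampling by 2x or more
    factor = t // cols_out
    if factor >= 2:
        t_trim = (t // factor) * factor
        data = data[:, :t_trim].reshape(n, t_trim // factor, factor).mean(axis=2)
        t = data.shape[1]
    if t != cols_out:
        src = np.linspace(0.0, t - 1.0, cols_out)
        i0 = np.floor(src).astype(np.intp)
        i1 = np.minimum(i0 + 1, t - 1)
        f = src - i0
        data = (1.0 - f) * data[:, i0] + f * data[:, i1]

    if n != rows_out:
        src = np.linspace(0.0, n - 1.0, rows_out)
        i0 = np.floor(src).astype(np.intp)
        i1 = np.minimum(i0 + 1, n - 1)
        f = (src - i0)[:, None]
        data = (1.0 - f) * data[i0, :] + f * data[i1, :]
    return data
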