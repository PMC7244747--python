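"""Synthetic vasculature phantoms and the augmentation pipeline.

Ground-truth initial-pressure images are produced in two stages.  A base
phantom (default 340 x 340 px) is drawn by seeded random vessel walks:
walkers start at border points heading inward, advance one pixel at a time
with momentum-biased random headings, occasionally branch, and stamp
anti-aliased strokes of width 1-6 px.  Training/testing images are then cut
from the base by an augmentation recipe: per layer, random scaling (0.5-2x)
and rotation (0-359 deg), a random 128 x 128 crop (zero-padded when the
transformed image is smaller than the window), and a random 0-10 px
vertical/horizontal shift via zero-padding; one to five such layers are summed
and the result is min-max normalized to [0, 1].

A loader path for user-supplied 3D volumes (micro-CT-like data) applies the
Frangi vesselness filter to a randomly chosen sub-volume and takes its
maximum-intensity projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import frangi

__all__ = [
    "BasePhantom",
    "AugmentParams",
    "PhantomDataset",
    "generate_base_phantom",
    "augment",
    "augment_layer",
    "normalize",
    "vesselness_mip",
    "make_initial_pressure",
    "build_dataset",
]

CROP_SIZE = 128


@dataclass
class BasePhantom:
    pixels: np.ndarray
    seed: int

    @property
    def size(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class AugmentParams:
    """Augmentation draw ranges (all inclusive)."""

    scale_range: tuple[float, float] = (0.5, 2.0)
    rotation_range_deg: tuple[float, float] = (0.0, 359.0)
    crop_size: int = CROP_SIZE
    shift_range_px: tuple[int, int] = (0, 10)
    max_layers: int = 5
    seed: int = 0


@dataclass
class PhantomDataset:
    """Stack of ground-truth images with full generation provenance."""

    images: np.ndarray                      # (n, crop, crop) in [0, 1]
    split: str
    provenance: list[tuple[int, int, int]] = field(default_factory=list)
    # provenance entries: (base_seed, split_id, draw_seed)

    def __len__(self) -> int:
        return self.images.shape[0]


def normalize(image: np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 1]; a constant image maps to all zeros."""
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("normalize requires finite input")
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# base phantom: momentum random-walk vessel trees
# ---------------------------------------------------------------------------

def _stamp(canvas: np.ndarray, r: float, c: float, width: float, value: float) -> None:
    """Anti-aliased soft disc of diameter ``width`` at (r, c), combined by max."""
    rad = width / 2.0
    ext = int(np.ceil(rad + 1.0))
    h, w = canvas.shape
    r0, r1 = max(int(r) - ext, 0), min(int(r) + ext + 1, h)
    c0, c1 = max(int(c) - ext, 0), min(int(c) + ext + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1, dtype=np.float64)[:, None]
    cc = np.arange(c0, c1, dtype=np.float64)[None, :]
    d = np.sqrt((rr - r) ** 2 + (cc - c) ** 2)
    patch = np.clip(rad + 0.5 - d, 0.0, 1.0) * value
    np.maximum(canvas[r0:r1, c0:c1], patch, out=canvas[r0:r1, c0:c1])


def generate_base_phantom(seed: int, size: tuple[int, int] = (340, 340),
                          n_walkers: int | None = None,
                          width_range: tuple[int, int] = (1, 6),
                          branch_prob: float = 0.02,
                          turn_sigma: float = 0.12) -> BasePhantom:
    """Seeded random vessel-tree phantom: curvilinear branching strokes.

    Walkers spawn on the image border heading inward and advance one pixel per
    step with a momentum-biased heading (Gaussian turn noise ``turn_sigma``),
    branching with probability ``branch_prob`` per step into a narrower child.
    Stroke widths are drawn from ``width_range`` pixels.  Deterministic for a
    fixed seed; the morphology knobs let tests build visually distinct phantom
    families.
    """
    h, w = size
    if h < CROP_SIZE or w < CROP_SIZE:
        raise ValueError(f"size {size} smaller than the {CROP_SIZE} crop used downstream")
    rng = np.random.default_rng(seed)
    if n_walkers is None:
        n_walkers = int(rng.integers(9, 15))
    canvas = np.zeros(size)

    # each walker: (r, c, heading, width, remaining_steps)
    stack: list[tuple[float, float, float, float, int]] = []
    for _ in range(n_walkers):
        edge = rng.integers(4)
        if edge == 0:
            r, c, head = 0.0, float(rng.uniform(0, w)), np.pi / 2
        elif edge == 1:
            r, c, head = float(h - 1), float(rng.uniform(0, w)), -np.pi / 2
        elif edge == 2:
            r, c, head = float(rng.uniform(0, h)), 0.0, 0.0
        else:
            r, c, head = float(rng.uniform(0, h)), float(w - 1), np.pi
        head += float(rng.uniform(-0.5, 0.5))
        width = float(rng.integers(width_range[0], width_range[1] + 1))
        steps = int(rng.integers(min(h, w) // 2, int(1.4 * max(h, w))))
        stack.append((r, c, head, width, steps))

    max_segments = 4 * n_walkers
    n_segments = 0
    while stack and n_segments < max_segments:
        r, c, head, width, steps = stack.pop()
        n_segments += 1
        intensity = float(rng.uniform(0.6, 1.0))
        for _ in range(steps):
            _stamp(canvas, r, c, width, intensity)
            head += float(rng.normal(0.0, turn_sigma))
            c += np.cos(head)
            r += np.sin(head)
            if not (0 <= r < h and 0 <= c < w):
                break
            if rng.random() < branch_prob and len(stack) + n_segments < max_segments:
                child_head = head + float(rng.choice([-1.0, 1.0])) * float(rng.uniform(0.4, 0.9))
                child_w = max(width_range[0], width - 1.0)
                stack.append((r, c, child_head, child_w, steps // 2))
    return BasePhantom(pixels=canvas, seed=seed)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment_layer(base: np.ndarray, scale: float, angle_deg: float,
                  crop_origin: tuple[int, int], shift: tuple[int, int],
                  crop_size: int = CROP_SIZE) -> np.ndarray:
    """One augmentation layer: scale, rotate, crop, shift (all zero-filled).

    The identity settings (scale 1, angle 0, origin (0, 0), shift (0, 0))
    reproduce the top-left ``crop_size`` block of ``base`` exactly.
    """
    img = np.asarray(base, dtype=np.float64)
    if scale != 1.0:
        img = ndimage.zoom(img, scale, order=1, prefilter=False)
    if angle_deg % 360.0 != 0.0:
        img = ndimage.rotate(img, angle_deg, reshape=False, order=1, cval=0.0, prefilter=False)
    h, w = img.shape
    if h < crop_size or w < crop_size:
        pad_r, pad_c = max(0, crop_size - h), max(0, crop_size - w)
        img = np.pad(img, ((0, pad_r), (0, pad_c)))
        h, w = img.shape
    r0 = int(np.clip(crop_origin[0], 0, h - crop_size))
    c0 = int(np.clip(crop_origin[1], 0, w - crop_size))
    out = img[r0:r0 + crop_size, c0:c0 + crop_size]
    sr, sc = shift
    shifted = np.zeros((crop_size, crop_size))
    shifted[sr:, sc:] = out[:crop_size - sr if sr else crop_size,
                            :crop_size - sc if sc else crop_size]
    return shifted


def augment(base: BasePhantom, params: AugmentParams | None = None,
            draw_seed: int = 0) -> np.ndarray:
    """Sum 1-5 randomly transformed layers of the base phantom and normalize.

    The number of layers is uniform on {1..max_layers}; each layer draws its
    scale, rotation, crop origin and shift independently.  Deterministic for a
    fixed (params.seed, draw_seed) pair.
    """
    params = params or AugmentParams()
    rng = np.random.default_rng([params.seed, draw_seed])
    n_layers = int(rng.integers(1, params.max_layers + 1))
    acc = np.zeros((params.crop_size, params.crop_size))
    for _ in range(n_layers):
        scale = float(rng.uniform(*params.scale_range))
        angle = float(rng.uniform(*params.rotation_range_deg))
        # crop origin drawn against the post-transform bounds
        h = max(int(round(base.pixels.shape[0] * scale)), params.crop_size)
        w = max(int(round(base.pixels.shape[1] * scale)), params.crop_size)
        r0 = int(rng.integers(0, h - params.crop_size + 1))
        c0 = int(rng.integers(0, w - params.crop_size + 1))
        sr = int(rng.integers(params.shift_range_px[0], params.shift_range_px[1] + 1))
        sc = int(rng.integers(params.shift_range_px[0], params.shift_range_px[1] + 1))
        acc += augment_layer(base.pixels, scale, angle, (r0, c0), (sr, sc), params.crop_size)
    return normalize(acc)


def make_initial_pressure(absorption: np.ndarray, gruneisen: np.ndarray) -> np.ndarray:
    """Initial pressure as the normalized product of absorption and Grueneisen
    maps (heat-to-pressure conversion efficiency)."""
    a = np.asarray(absorption, dtype=np.float64)
    g = np.asarray(gruneisen, dtype=np.float64)
    if a.shape != g.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {g.shape}")
    if (a < 0).any() or (g < 0).any():
        raise ValueError("absorption and gruneisen must be nonnegative")
    return normalize(a * g)


def vesselness_mip(volume: np.ndarray, subvolume: tuple[int, int, int] = (128, 128, 128),
                   seed: int = 0, sigmas: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0),
                   axis: int = 0) -> np.ndarray:
    """Vessel-enhanced maximum-intensity projection of a random sub-volume.

    A sub-volume of the requested size is chosen at a seeded random offset, the
    multiscale Frangi vesselness filter suppresses non-tubular background, and
    the result is projected along ``axis`` and min-max normalized.  The filter
    runs on the extracted sub-volume (equivalent to filtering the full volume
    up to boundary effects, and far cheaper).
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise ValueError("vesselness_mip expects a 3D volume")
    if any(volume.shape[i] < subvolume[i] for i in range(3)):
        raise ValueError(f"volume {volume.shape} smaller than sub-volume {subvolume}")
    rng = np.random.default_rng(seed)
    corner = [int(rng.integers(0, volume.shape[i] - subvolume[i] + 1)) for i in range(3)]
    sub = volume[corner[0]:corner[0] + subvolume[0],
                 corner[1]:corner[1] + subvolume[1],
                 corner[2]:corner[2] + subvolume[2]]
    if sub.max() == sub.min():
        shape2d = tuple(s for i, s in enumerate(subvolume) if i != axis)
        return np.zeros(shape2d)
    filtered = frangi(sub, sigmas=sigmas, black_ridges=False)
    mip = filtered.max(axis=axis)
    return normalize(mip)


_SPLIT_IDS = {"train": 0, "test": 1}


def build_dataset(n: int, base_seed: int = 0, split: str = "train",
                  params: AugmentParams | None = None,
                  phantom_kwargs: dict | None = None) -> PhantomDataset:
    """n augmented ground-truth images from one seeded base phantom.

    Train and test draws use disjoint seed streams: the split label enters the
    augmentation seed sequence, and provenance records every (base seed,
    split id, draw seed) triple so segregation can be audited.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if split not in _SPLIT_IDS:
        raise ValueError(f"split must be one of {sorted(_SPLIT_IDS)}")
    split_id = _SPLIT_IDS[split]
    base = generate_base_phantom(base_seed, **(phantom_kwargs or {}))
    params = params or AugmentParams(seed=base_seed * 2 + split_id)
    crop = params.crop_size
    images = np.empty((n, crop, crop))
    provenance = []
    for i in range(n):
        draw_seed = split_id * 1_000_000 + i
        img = augment(base, params, draw_seed=draw_seed)
        # redraw if the random crop landed on empty background (structureless
        # images carry no signal and make fidelity metrics degenerate)
        retry = 0
        while img.max() == 0.0 and retry < 20:
            retry += 1
            draw_seed = split_id * 1_000_000 + 500_000 + i * 20 + retry
            img = augment(base, params, draw_seed=draw_seed)
        images[i] = img
        provenance.append((base_seed, split_id, draw_seed))
    return PhantomDataset(images=images, split=split, provenance=provenance)
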