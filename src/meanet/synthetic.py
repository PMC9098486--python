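"""Seeded synthetic phantoms for segmentation experiments.

Three regimes mimic the shape statistics of common binary medical
segmentation tasks, so the network, losses and metrics can be exercised
end to end without any dataset download:

* ``blob`` — one large compact foreground object with a smoothly
  perturbed outline on a cluttered background (tongue-like);
* ``vessel`` — a thin branching curvilinear tree, 1-3 px wide
  (retinal-vessel-like);
* ``lung_pair`` — two mirrored smooth regions with small interior
  holes (lung-CT-like).

Images follow a two-level intensity model (foreground 0.7, background
0.3) with optional background clutter and additive Gaussian noise,
clipped to [0, 1].  Everything is driven by an explicit seed: the same
spec always produces a bitwise-identical sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

_CROSS = ndimage.generate_binary_structure(2, 1)

FG_INTENSITY = 0.7
BG_INTENSITY = 0.3

KINDS = ("blob", "vessel", "lung_pair")


@dataclass
class PhantomSpec:
    """Recipe for one phantom; ``size`` must be divisible by 8 so that
    generated samples always satisfy the network's input precondition."""

    kind: str = "blob"
    size: tuple[int, int] = (64, 64)
    noise_sigma: float = 0.05
    clutter_level: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; valid: {KINDS}")
        h, w = self.size
        if h % 8 or w % 8 or h < 8 or w < 8:
            raise ValueError(f"size {self.size} must be divisible by 8")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0.0 <= self.clutter_level <= 1.0:
            raise ValueError("clutter_level must be in [0, 1]")


@dataclass
class SegmentationSample:
    """One (image, mask, edge) triple; the unit of all dataset I/O."""

    image: np.ndarray   # float32 (C, H, W) in [0, 1]
    mask: np.ndarray    # uint8 (H, W), values {0, 1}
    edge: np.ndarray    # uint8 (H, W), values {0, 1}
    id: str


# ----------------------------------------------------------------------
# Shape primitives
# ----------------------------------------------------------------------

def _perturbed_disk(shape, center, radius, rng, roughness=0.10,
                    n_harmonics=4, aspect=(1.0, 1.0)) -> np.ndarray:
    """Filled region whose radius is a low-order Fourier series of angle."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dy = (yy - center[0]) / aspect[0]
    dx = (xx - center[1]) / aspect[1]
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    bound = np.full(shape, float(radius))
    for k in range(1, n_harmonics + 1):
        amp = rng.normal(0.0, roughness / k) * radius
        phase = rng.uniform(0, 2 * np.pi)
        bound += amp * np.cos(k * theta + phase)
    return r < bound


def _draw_path(mask: np.ndarray, points: np.ndarray, width: int) -> None:
    h, w = mask.shape
    pts = np.round(points).astype(int)
    keep = (pts[:, 0] >= 0) & (pts[:, 0] < h) & (pts[:, 1] >= 0) & (pts[:, 1] < w)
    pts = pts[keep]
    mask[pts[:, 0], pts[:, 1]] = True
    if width > 1:
        stamp = np.zeros_like(mask)
        stamp[pts[:, 0], pts[:, 1]] = True
        mask |= ndimage.binary_dilation(stamp, _CROSS, iterations=width - 1)


def _vessel_tree(shape, rng) -> np.ndarray:
    """Random branching tree of 1-3 px wide curves."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    scale = min(h, w)
    # trunk enters from a random border midpoint heading inwards
    side = rng.integers(4)
    if side == 0:
        start, ang = (0.0, rng.uniform(0.3, 0.7) * w), np.pi / 2
    elif side == 1:
        start, ang = (h - 1.0, rng.uniform(0.3, 0.7) * w), -np.pi / 2
    elif side == 2:
        start, ang = (rng.uniform(0.3, 0.7) * h, 0.0), 0.0
    else:
        start, ang = (rng.uniform(0.3, 0.7) * h, w - 1.0), np.pi
    queue = [(np.array(start), ang, int(scale * 0.9), 0)]
    while queue:
        pos, ang, steps, depth = queue.pop()
        pts = []
        for _ in range(steps):
            ang += rng.normal(0.0, 0.15)
            pos = pos + np.array([np.sin(ang), np.cos(ang)])
            if not (0 <= pos[0] < h and 0 <= pos[1] < w):
                break
            pts.append(pos.copy())
            if depth < 2 and rng.random() < 0.04:
                branch_ang = ang + rng.choice([-1.0, 1.0]) * rng.uniform(0.4, 0.9)
                queue.append((pos.copy(), branch_ang,
                              int(steps * rng.uniform(0.4, 0.7)), depth + 1))
        if pts:
            width = max(1, 3 - depth)  # trunk widest, twigs thinnest
            _draw_path(mask, np.array(pts), width)
    return mask


def _blob_mask(shape, rng) -> np.ndarray:
    h, w = shape
    center = (h / 2 + rng.uniform(-0.08, 0.08) * h,
              w / 2 + rng.uniform(-0.08, 0.08) * w)
    radius = 0.30 * min(h, w) * rng.uniform(0.9, 1.1)
    return _perturbed_disk(shape, center, radius, rng)


def _lung_pair_mask(shape, rng) -> np.ndarray:
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    for cx in (0.30 * w, 0.70 * w):
        center = (h / 2 + rng.uniform(-0.05, 0.05) * h,
                  cx + rng.uniform(-0.03, 0.03) * w)
        radius = 0.28 * h * rng.uniform(0.9, 1.05)
        lung = _perturbed_disk(shape, center, radius, rng, roughness=0.06,
                               aspect=(1.0, 0.5))
        for _ in range(rng.integers(0, 3)):  # small interior holes
            hc = (center[0] + rng.uniform(-0.1, 0.1) * h,
                  center[1] + rng.uniform(-0.05, 0.05) * w)
            hole = _perturbed_disk(shape, hc, max(2.0, 0.04 * h), rng,
                                   roughness=0.05, n_harmonics=2)
            lung &= ~hole
        mask |= lung
    return mask


def generate_phantom(spec: PhantomSpec) -> SegmentationSample:
    """Generate one phantom sample; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(np.random.PCG64(spec.seed))
    shape = tuple(spec.size)
    if spec.kind == "blob":
        mask = _blob_mask(shape, rng)
    elif spec.kind == "vessel":
        mask = _vessel_tree(shape, rng)
    else:
        mask = _lung_pair_mask(shape, rng)

    image = np.where(mask, FG_INTENSITY, BG_INTENSITY)
    n_clutter = int(round(spec.clutter_level * 6))
    for _ in range(n_clutter):  # distractor shapes, background only
        c = (rng.uniform(0, shape[0]), rng.uniform(0, shape[1]))
        r = rng.uniform(0.03, 0.10) * min(shape)
        shade = rng.uniform(0.40, 0.60)
        distractor = _perturbed_disk(shape, c, r, rng, roughness=0.15)
        image = np.where(distractor & ~mask, shade, image)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=shape)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)[None]  # (1, H, W)
    mask8 = mask.astype(np.uint8)
    return SegmentationSample(image=image, mask=mask8,
                              edge=derive_edge_map(mask8, 1),
                              id=f"{spec.kind}-{spec.seed:06d}")


def generate_dataset(kind: str, n: int, seed: int, size=(64, 64),
                     noise_sigma: float = 0.05,
                     clutter_level: float = 0.3) -> list[SegmentationSample]:
    """n phantoms of one kind with consecutive sub-seeds of ``seed``."""
    base = np.random.SeedSequence(seed).generate_state(n)
    return [generate_phantom(PhantomSpec(kind=kind, size=size,
                                         noise_sigma=noise_sigma,
                                         clutter_level=clutter_level,
                                         seed=int(s % (2 ** 31))))
            for s in base]


# ----------------------------------------------------------------------
# Edge ground truth
# ----------------------------------------------------------------------

def derive_edge_map(mask, width: int = 1) -> np.ndarray:
    """Inner boundary band of a binary mask.

    A pixel is edge when it belongs to the mask and lies within
    ``width`` pixels of the background under 4-connected erosion
    (equivalently, for width 1: a mask pixel with at least one
    background 4-neighbour).  Pixels outside the image count as
    foreground, so masks touching the border have no artificial edge
    there.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    m = np.asarray(mask).astype(bool)
    eroded = ndimage.binary_erosion(m, structure=_CROSS, iterations=width,
                                    border_value=1)
    return (m & ~eroded).astype(np.uint8)


# ----------------------------------------------------------------------
# Augmentation
# ----------------------------------------------------------------------

AUG_OPS = ("rotation", "flip", "translation", "mirroring")


@dataclass
class GeomTransform:
    """One joint geometric transform: flips, rotation (deg), then shift."""

    angle: float = 0.0
    flip_v: bool = False   # up-down ("flip")
    flip_h: bool = False   # left-right ("mirroring")
    shift: tuple[int, int] = (0, 0)


def apply_transform(sample: SegmentationSample, t: GeomTransform) -> SegmentationSample:
    """Apply the same transform to image, mask and edge.

    Images use bilinear interpolation with reflect padding (rotation)
    or a background-value constant (translation); masks and edges use
    nearest-neighbour everywhere, so they stay binary.  Rotations by
    multiples of 90 degrees are performed exactly.
    """
    img = sample.image.copy()
    mask = sample.mask.copy()
    edge = sample.edge.copy()
    if t.flip_v:
        img, mask, edge = img[:, ::-1], mask[::-1], edge[::-1]
    if t.flip_h:
        img, mask, edge = img[:, :, ::-1], mask[:, ::-1], edge[:, ::-1]
    if t.angle % 360 != 0:
        if t.angle % 90 == 0:
            k = int(t.angle // 90) % 4
            img = np.rot90(img, k, axes=(1, 2))
            mask, edge = np.rot90(mask, k), np.rot90(edge, k)
        else:
            img = np.stack([ndimage.rotate(c, t.angle, reshape=False,
                                           order=1, mode="reflect")
                            for c in img])
            mask = ndimage.rotate(mask, t.angle, reshape=False, order=0,
                                  mode="constant", cval=0)
            edge = ndimage.rotate(edge, t.angle, reshape=False, order=0,
                                  mode="constant", cval=0)
    if t.shift != (0, 0):
        fill = float(np.median(img))
        img = np.stack([ndimage.shift(c, t.shift, order=1, mode="constant",
                                      cval=fill) for c in img])
        mask = ndimage.shift(mask, t.shift, order=0, mode="constant", cval=0)
        edge = ndimage.shift(edge, t.shift, order=0, mode="constant", cval=0)
    return replace(sample, image=np.ascontiguousarray(img, dtype=np.float32),
                   mask=np.ascontiguousarray(mask, dtype=np.uint8),
                   edge=np.ascontiguousarray(edge, dtype=np.uint8))


def sample_transform(ops, shape: tuple[int, int],
                     rng: np.random.Generator) -> GeomTransform:
    """Draw one random transform using the enabled augmentation ops."""
    ops = tuple(ops)
    unknown = set(ops) - set(AUG_OPS)
    if unknown:
        raise ValueError(f"unknown augmentation op(s) {sorted(unknown)}; "
                         f"valid: {AUG_OPS}")
    t = GeomTransform()
    if "flip" in ops and rng.random() < 0.5:
        t.flip_v = True
    if "mirroring" in ops and rng.random() < 0.5:
        t.flip_h = True
    if "rotation" in ops:
        t.angle = float(rng.uniform(-25.0, 25.0))
    if "translation" in ops:
        h, w = shape
        t.shift = (int(rng.integers(-h // 10, h // 10 + 1)),
                   int(rng.integers(-w // 10, w // 10 + 1)))
    return t


def augment(sample: SegmentationSample, ops, seed: int) -> SegmentationSample:
    """Jointly transform image/mask/edge with a seeded random transform."""
    rng = np.random.default_rng(np.random.PCG64(seed))
    t = sample_transform(ops, sample.mask.shape, rng)
    return apply_transform(sample, t)


# ----------------------------------------------------------------------
# Dataset I/O (PNG files + JSON manifest)
# ----------------------------------------------------------------------

def _image_to_png(image: np.ndarray) -> np.ndarray:
    arr = np.clip(np.round(image * 255.0), 0, 255).astype(np.uint8)
    return arr[0] if arr.shape[0] == 1 else arr.transpose(1, 2, 0)


def _png_to_image(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        arr = arr[None]
    else:
        arr = arr.transpose(2, 0, 1)
    return (arr.astype(np.float32) / 255.0)


def normalize_mask(arr: np.ndarray) -> np.ndarray:
    """Collapse any PNG encoding (8/16-bit, RGB, RGBA) to a 0/1 mask:
    a pixel is foreground when any colour channel is nonzero (the alpha
    channel, if present, is ignored)."""
    a = np.asarray(arr)
    if a.ndim == 3:
        if a.shape[2] == 4:
            a = a[:, :, :3]
        a = a.max(axis=2)
    return (a != 0).astype(np.uint8)


def write_dataset(samples, directory, splits: dict[str, str] | None = None) -> dict:
    """Write samples as PNGs plus a JSON manifest; returns the manifest.

    Masks and edges are stored as single-channel 0/255 PNGs, which
    round-trip bitwise; images are stored 8-bit.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"samples": []}
    for s in samples:
        files = {"image": f"{s.id}_image.png", "mask": f"{s.id}_mask.png",
                 "edge": f"{s.id}_edge.png"}
        iio.imwrite(directory / files["image"], _image_to_png(s.image))
        iio.imwrite(directory / files["mask"], (s.mask * 255).astype(np.uint8))
        iio.imwrite(directory / files["edge"], (s.edge * 255).astype(np.uint8))
        entry = {"id": s.id, "files": files}
        if splits is not None:
            entry["split"] = splits.get(s.id, "train")
        manifest["samples"].append(entry)
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_dataset(directory, split: str | None = None) -> list[SegmentationSample]:
    """Load a manifest-described dataset back into memory."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {directory}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    out = []
    for entry in manifest["samples"]:
        if split is not None and entry.get("split") != split:
            continue
        sid = entry["id"]
        try:
            image = _png_to_image(iio.imread(directory / entry["files"]["image"]))
            mask = normalize_mask(iio.imread(directory / entry["files"]["mask"]))
            edge = normalize_mask(iio.imread(directory / entry["files"]["edge"]))
        except FileNotFoundError as exc:
            raise FileNotFoundError(
                f"dataset entry {sid!r}: missing file ({exc})") from exc
        except (OSError, ValueError) as exc:
            raise ValueError(f"dataset entry {sid!r}: unreadable file ({exc})") from exc
        if mask.shape != image.shape[1:]:
            raise ValueError(f"dataset entry {sid!r}: mask shape {mask.shape} "
                             f"does not match image {image.shape[1:]}")
        out.append(SegmentationSample(image=image, mask=mask, edge=edge, id=sid))
    return out
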