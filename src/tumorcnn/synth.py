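"""Seeded synthetic brain-phantom generator with three separable classes.

Each phantom is a dark background carrying an elliptical "head" of moderate
intensity with a mild radial gradient, plus one class-dependent lesion:

* class 0 (*meningioma-like*): a bright smooth disc sitting at the head
  boundary — these tumors arise from the meninges at the brain surface;
* class 1 (*glioma-like*): a larger, irregular, mid-intensity blob with a
  textured interior in an off-center lobe;
* class 2 (*pituitary-like*): a small bright disc at the central-inferior
  position, where the pituitary gland sits.

The geometry is a caricature, not anatomy: it exists so that every training
protocol and metric in the package can be exercised end-to-end with no
external download, with classes separable by lesion position/size alone.
Additive Gaussian noise (then clipping to [0,1]) controls difficulty.
Generation is fully reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .data_io import DatasetManifest, ImageRecord

__all__ = ["PhantomConfig", "generate", "fixture_mat", "lesion_features"]


@dataclass(frozen=True)
class PhantomConfig:
    """Generator settings.

    ``image_size`` defaults to 256 (the production input size); tests use
    64.  ``tumor_radius_range`` is the class-0 lesion radius in pixels;
    ``None`` scales it to (5%, 12%) of the image width.  ``noise_sd`` is
    additive Gaussian noise in intensity units on the [0,1] scale.
    """

    n_samples: int = 300
    class_proportions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    image_size: int = 256
    noise_sd: float = 0.05
    tumor_radius_range: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if len(self.class_proportions) != 3 or abs(sum(self.class_proportions) - 1) > 1e-9 \
                or min(self.class_proportions) < 0:
            raise ValueError("class_proportions must be 3 non-negative fractions summing to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.tumor_radius_range is not None:
            lo, hi = self.tumor_radius_range
            if not (0 < lo <= hi < self.image_size / 2):
                raise ValueError("tumor_radius_range must be positive and within the image")

    def radius_range(self) -> tuple[float, float]:
        if self.tumor_radius_range is not None:
            return self.tumor_radius_range
        return (0.05 * self.image_size, 0.12 * self.image_size)


# head ellipse semi-axes as fractions of the half-width; lesion position
# priors in the same normalized [-1,1] coordinate frame (y grows downward)
_HEAD_A, _HEAD_B = 0.72, 0.85
_PITUITARY_Y = 0.28          # central-inferior
_PITUITARY_XY_SD = 0.03
_GLIOMA_X_RANGE = (0.30, 0.55)
_GLIOMA_Y_RANGE = (-0.35, 0.35)
_MENINGIOMA_RIM = 0.88       # fraction of the head radius along a random angle


def _class_counts(n: int, proportions) -> np.ndarray:
    """Largest-remainder allocation: deterministic, sums to n."""
    raw = np.asarray(proportions) * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return counts


def _disc(xx, yy, cx, cy, r, sharpness=3.0):
    """Soft-edged disc mask in normalized coordinates."""
    d = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
    return 1.0 / (1.0 + np.exp((d - r) * sharpness / max(r, 1e-6) * 8.0))


def _phantom(rng: np.random.Generator, label: int, size: int,
             radius_px: tuple[float, float], noise_sd: float) -> np.ndarray:
    half = size / 2
    ax = (np.arange(size) - half + 0.5) / half
    xx, yy = np.meshgrid(ax, ax)          # yy: rows, grows downward

    img = np.full((size, size), 0.05)
    head_r = np.sqrt((xx / _HEAD_A) ** 2 + (yy / _HEAD_B) ** 2)
    head = head_r <= 1.0
    img[head] = 0.40 - 0.10 * head_r[head]  # mild radial gradient

    r_lo, r_hi = radius_px[0] / half, radius_px[1] / half
    if label == 0:
        # bright smooth disc adjacent to the head boundary
        theta = rng.uniform(0, 2 * np.pi)
        cx = _MENINGIOMA_RIM * _HEAD_A * np.cos(theta)
        cy = _MENINGIOMA_RIM * _HEAD_B * np.sin(theta)
        r = rng.uniform(r_lo, r_hi)
        img += 0.55 * _disc(xx, yy, cx, cy, r)
    elif label == 1:
        # irregular mid-intensity blob with textured interior, off-center lobe
        cx = rng.choice([-1, 1]) * rng.uniform(*_GLIOMA_X_RANGE)
        cy = rng.uniform(*_GLIOMA_Y_RANGE)
        r = rng.uniform(r_lo, r_hi) * 1.7
        d = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
        ang = np.arctan2(yy - cy, xx - cx)
        # angular harmonics perturb the boundary radius
        wobble = np.zeros_like(ang)
        for k in range(2, 6):
            wobble += rng.uniform(0, 0.18 / k) * np.cos(k * ang + rng.uniform(0, 2 * np.pi))
        mask = 1.0 / (1.0 + np.exp((d - r * (1 + wobble)) * 10.0 / max(r, 1e-6)))
        texture = 0.75 + 0.25 * np.cos(xx * rng.uniform(25, 45)) \
            * np.cos(yy * rng.uniform(25, 45))
        img += 0.30 * mask * texture
    else:
        # small bright disc at the central-inferior position
        cx = rng.normal(0.0, _PITUITARY_XY_SD)
        cy = _PITUITARY_Y + rng.normal(0.0, _PITUITARY_XY_SD)
        r = rng.uniform(r_lo, r_hi) * 0.55
        img += 0.58 * _disc(xx, yy, cx, cy, r)

    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def generate(config: PhantomConfig) -> DatasetManifest:
    """Generate ``config.n_samples`` labeled phantoms, reproducibly.

    Class counts follow ``class_proportions`` by largest-remainder
    allocation (equal thirds of 300 give exactly 100 per class); sample
    order interleaves classes deterministically before a seeded shuffle.
    """
    rng = np.random.default_rng(config.seed)
    counts = _class_counts(config.n_samples, config.class_proportions)
    labels = np.repeat(np.arange(3), counts)
    rng.shuffle(labels)
    radius = config.radius_range()
    records = []
    for i, label in enumerate(labels):
        img = _phantom(rng, int(label), config.image_size, radius, config.noise_sd)
        records.append(ImageRecord(image=img, label=int(label),
                                   patient_id=f"synthetic-{i:05d}",
                                   source=f"phantom://{config.seed}/{i}"))
    return DatasetManifest(records=records, provenance={
        "source": "synthetic-phantom", "seed": config.seed,
        "n_samples": config.n_samples, "image_size": config.image_size,
        "noise_sd": config.noise_sd, "class_counts": counts.tolist(),
    })


def lesion_features(image: np.ndarray) -> tuple[float, float, float]:
    """(radial distance of the brightest-blob centroid from the image
    center, blob area fraction, blob peak intensity) — enough to separate
    the three classes: position tells the rim-adjacent and central-inferior
    discs apart, intensity tells the bright discs from the mid-intensity
    textured blob.

    The blob is the set of pixels within 85% of the image maximum; the
    centroid distance is normalized to the half-width.
    """
    img = np.asarray(image, dtype=np.float64)
    size = img.shape[0]
    half = size / 2
    hot = img >= img.max() * 0.85
    ys, xs = np.nonzero(hot)
    if len(xs) == 0:
        return 0.0, 0.0, 0.0
    cx = (xs.mean() - half + 0.5) / half
    cy = (ys.mean() - half + 0.5) / half
    return float(np.hypot(cx, cy)), float(hot.mean()), float(img[hot].mean())


def fixture_mat(directory: str | Path, n: int, *,
                config: PhantomConfig | None = None) -> list[Path]:
    """Write ``n`` phantoms as Figshare-layout ``cjdata`` .mat files.

    The files round-trip through :func:`tumorcnn.data_io.load_figshare`
    with identical labels and (tolerance-level) identical images.  They are
    synthetic stand-ins for the real per-slice files, intended for tests.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = config or PhantomConfig(n_samples=n, image_size=64, seed=0)
    if cfg.n_samples < n:
        raise ValueError("config.n_samples smaller than n")
    manifest = generate(cfg)
    paths = []
    for i in range(n):
        rec = manifest.records[i]
        path = directory / f"{i + 1}.mat"
        with h5py.File(path, "w") as f:
            cj = f.create_group("cjdata")
            cj.create_dataset("image", data=rec.image.astype(np.float64))
            cj.create_dataset("label", data=np.array([[rec.label + 1]], dtype=np.float64))
            pid = np.array([[np.uint16(ord(c))] for c in rec.patient_id], dtype=np.uint16)
            cj.create_dataset("PID", data=pid)
            cj.create_dataset("tumorBorder", data=np.zeros((1, 2)))
            cj.create_dataset("tumorMask", data=np.zeros(rec.image.shape, dtype=np.uint8))
        paths.append(path)
    return paths
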