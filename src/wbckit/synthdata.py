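"""Seeded generators of synthetic blood-smear imagery and feature data.

Real stained smears show purple leukocyte nuclei on a pale background
among pink erythrocytes and purple platelet specks.  The generators
here emulate exactly the properties the rest of the package relies on —
distinct color populations, nucleus-vs-platelet size separation, and
class-dependent nucleus morphology — with exact ground truth and
bitwise reproducibility from a seed.  They do not attempt
photorealistic stain simulation.

Three generators:

* :func:`make_smear` — a full smear image plus its exact nucleus mask.
* :func:`make_cell_crops` — labeled single-cell crops for five synthetic
  leukocyte classes distinguished by lobedness, eccentricity and
  chromatin texture (lymphocyte / monocyte / eosinophil / basophil /
  neutrophil analogues).
* :func:`make_clusters` — labeled Gaussian feature clusters with a
  controlled between/within separation ratio, for classifier tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk, ellipse

__all__ = [
    "SmearSpec",
    "CellClassSpec",
    "ClusterData",
    "make_smear",
    "make_cell_crops",
    "make_clusters",
    "DEFAULT_CLASS_NAMES",
]

DEFAULT_CLASS_NAMES = (
    "lymphocyte",
    "monocyte",
    "eosinophil",
    "basophil",
    "neutrophil",
)


@dataclass
class SmearSpec:
    """Parameters of one synthetic smear.

    Canvas defaults to 720x576, the frame size of typical stained-smear
    microscopy captures.  Nucleus radii are kept well above platelet
    radii so area-based platelet rejection is meaningful; colors are
    kept pairwise distinct (purple nuclei, pink RBCs, pale background).
    """

    height: int = 576
    width: int = 720
    n_nuclei: int = 3
    nucleus_radius: tuple = (20, 32)
    nucleus_color: tuple = (130, 60, 160)
    nucleus_color_sigma: float = 8.0
    n_rbc: int = 40
    rbc_radius: tuple = (14, 22)
    rbc_color: tuple = (225, 150, 150)
    n_platelets: int = 10
    platelet_radius: tuple = (2, 4)
    background_color: tuple = (238, 232, 224)
    noise_sigma: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.nucleus_radius[0] <= self.platelet_radius[1]:
            raise ValueError("nucleus radii must exceed platelet radii")


def _place_objects(rng, shape, radii, occupied, max_attempts=1000):
    """Rejection-sample non-overlapping centers for the given radii."""
    h, w = shape
    centers = []
    for r in radii:
        for attempt in range(max_attempts):
            cy = rng.uniform(r, h - r)
            cx = rng.uniform(r, w - r)
            ok = all(
                (cy - oy) ** 2 + (cx - ox) ** 2 >= (r + orad + 2) ** 2
                for oy, ox, orad in occupied
            )
            if ok:
                occupied.append((cy, cx, r))
                centers.append((cy, cx))
                break
        else:
            raise ValueError("overcrowded spec: could not place all objects")
    return centers


def _paint_nucleus(mask, rng, cy, cx, r, shape, n_lobes=None, ecc=0.75):
    """Union of 1-5 overlapping ellipses; marks painted pixels in mask."""
    if n_lobes is None:
        n_lobes = int(rng.integers(1, 6))
    for _ in range(n_lobes):
        oy = rng.uniform(-0.35 * r, 0.35 * r)
        ox = rng.uniform(-0.35 * r, 0.35 * r)
        a = rng.uniform(0.6 * r, 1.0 * r)
        b = rng.uniform(ecc * a, a)
        rot = rng.uniform(0, np.pi)
        rr, cc = ellipse(cy + oy, cx + ox, a, b, shape=shape, rotation=rot)
        mask[rr, cc] = True


def make_smear(spec: SmearSpec | None = None, return_info: bool = False):
    """Render one synthetic smear and its exact nucleus ground truth.

    Nuclei are painted last so their pixels are never occluded; the
    mask marks exactly the painted nucleus pixels and excludes
    platelets and RBCs.  Deterministic given ``spec.seed``.

    Returns
    -------
    (image, mask) or (image, mask, info)
        ``image`` is HxWx3 uint8, ``mask`` HxW bool; ``info`` carries
        per-nucleus painted areas for bookkeeping checks.
    """
    if spec is None:
        spec = SmearSpec()
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)
    img = np.empty((*shape, 3), dtype=float)
    img[:] = spec.background_color

    occupied: list = []
    nuc_r = rng.uniform(*spec.nucleus_radius, size=spec.n_nuclei)
    rbc_r = rng.uniform(*spec.rbc_radius, size=spec.n_rbc)
    plt_r = rng.uniform(*spec.platelet_radius, size=spec.n_platelets)
    nuc_centers = _place_objects(rng, shape, nuc_r, occupied)
    rbc_centers = _place_objects(rng, shape, rbc_r, occupied)
    plt_centers = _place_objects(rng, shape, plt_r, occupied)

    for (cy, cx), r in zip(rbc_centers, rbc_r):
        rr, cc = disk((cy, cx), r, shape=shape)
        jitter = rng.normal(0, 5, size=3)
        img[rr, cc] = np.clip(np.asarray(spec.rbc_color) + jitter, 0, 255)

    for (cy, cx), r in zip(plt_centers, plt_r):
        rr, cc = disk((cy, cx), r, shape=shape)
        jitter = rng.normal(0, spec.nucleus_color_sigma, size=3)
        img[rr, cc] = np.clip(np.asarray(spec.nucleus_color) + jitter, 0, 255)

    mask = np.zeros(shape, dtype=bool)
    areas = []
    for (cy, cx), r in zip(nuc_centers, nuc_r):
        single = np.zeros(shape, dtype=bool)
        _paint_nucleus(single, rng, cy, cx, r, shape)
        jitter = rng.normal(0, spec.nucleus_color_sigma, size=3)
        img[single] = np.clip(np.asarray(spec.nucleus_color) + jitter, 0, 255)
        areas.append(int(single.sum()))
        mask |= single

    if spec.noise_sigma > 0:
        img += rng.normal(0, spec.noise_sigma, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    if return_info:
        return img, mask, {"nucleus_areas": areas}
    return img, mask


@dataclass
class CellClassSpec:
    """Morphology parameters for the five synthetic leukocyte classes.

    Each class is a (n_lobes, eccentricity, texture_frequency,
    texture_amplitude) tuple.  Defaults caricature the real cell types:
    round mononuclear lymphocytes, kidney-shaped monocytes, bilobed
    granular eosinophils, densely granular basophils and multilobed
    neutrophils.  Pairwise parameter separation is what makes the
    classes learnable.
    """

    crop_size: int = 64
    nucleus_color: tuple = (130, 60, 160)
    background_color: tuple = (238, 232, 224)
    noise_sigma: float = 2.0
    class_params: tuple = (
        # (n_lobes, eccentricity, texture_freq, texture_amp)
        (1, 0.95, 0.05, 6.0),   # lymphocyte: single round, smooth
        (1, 0.55, 0.10, 12.0),  # monocyte: single elongated, mild
        (2, 0.80, 0.25, 30.0),  # eosinophil: bilobed, coarse granules
        (1, 0.85, 0.45, 45.0),  # basophil: dense fine granules
        (4, 0.75, 0.18, 20.0),  # neutrophil: multilobed
    )


def _banded_texture(rng, size, freq, amp):
    """Band-limited noise texture: white noise low-passed at ~freq cycles/px."""
    noise = rng.normal(0, 1, size=(size, size))
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    f = np.sqrt(fy**2 + fx**2)
    band = np.exp(-((f - freq) ** 2) / (2 * (0.05 + freq / 4) ** 2))
    tex = np.real(np.fft.ifft2(np.fft.fft2(noise) * band))
    s = tex.std()
    if s > 0:
        tex = tex / s * amp
    return tex


def make_cell_crops(
    spec: CellClassSpec | None = None, n_per_class: int = 10, seed: int = 0
):
    """Labeled single-cell crops, ``n_per_class`` per synthetic class.

    Returns
    -------
    crops : (5*n, size, size, 3) uint8 array
    labels : (5*n,) int array with class ids 0..4
    """
    if spec is None:
        spec = CellClassSpec()
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    size = spec.crop_size
    crops, labels = [], []
    for cls, (n_lobes, ecc, freq, amp) in enumerate(spec.class_params):
        for _ in range(n_per_class):
            img = np.empty((size, size, 3), dtype=float)
            img[:] = spec.background_color
            mask = np.zeros((size, size), dtype=bool)
            r = size * 0.22
            cy = size / 2 + rng.uniform(-2, 2)
            cx = size / 2 + rng.uniform(-2, 2)
            _paint_nucleus(mask, rng, cy, cx, r, (size, size), n_lobes, ecc)
            base = np.asarray(spec.nucleus_color) + rng.normal(0, 5, size=3)
            img[mask] = np.clip(base, 0, 255)
            tex = _banded_texture(rng, size, freq, amp)
            img[mask] += tex[mask, None]
            img += rng.normal(0, spec.noise_sigma, size=img.shape)
            crops.append(np.clip(np.round(img), 0, 255).astype(np.uint8))
            labels.append(cls)
    return np.stack(crops), np.asarray(labels)


@dataclass
class ClusterData:
    """Gaussian-cluster feature data split into train and test parts."""

    A: np.ndarray          # m x N training matrix, columns are samples
    labels: np.ndarray     # N class ids
    Y: np.ndarray          # m x n_test test matrix
    test_labels: np.ndarray
    means: np.ndarray      # classes x m specified means


def make_clusters(
    m: int,
    n_per_class: int,
    classes: int = 5,
    separation: float = 5.0,
    seed: int = 0,
    n_test_per_class: int | None = None,
    within_sigma: float = 1.0,
) -> ClusterData:
    """Gaussian clusters with controlled between/within separation.

    Class means are random directions placed at a common magnitude,
    scaled so their minimum pairwise distance equals
    ``separation * within_sigma``; samples are the means plus isotropic
    noise of scale ``within_sigma``.  Equal-magnitude prototypes mirror
    the feature vectors this data stands in for (pooled descriptors and
    rectified network activations, which sit well away from the
    origin), so class identity is carried by direction — the part that
    survives the classifier's column normalization.  At
    ``separation = 0`` every class shares the origin and the data carry
    no class signal.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    if n_test_per_class is None:
        n_test_per_class = max(1, n_per_class // 3)
    means = rng.normal(size=(classes, m))
    if separation == 0:
        means[:] = 0.0
    else:
        means /= np.linalg.norm(means, axis=1, keepdims=True)
        dists = [
            np.linalg.norm(means[i] - means[j])
            for i in range(classes)
            for j in range(i + 1, classes)
        ]
        means *= separation * within_sigma / min(dists)

    def draw(n):
        cols, labs = [], []
        for cls in range(classes):
            x = means[cls][:, None] + rng.normal(
                0, within_sigma, size=(m, n)
            )
            cols.append(x)
            labs.extend([cls] * n)
        return np.concatenate(cols, axis=1), np.asarray(labs)

    A, labels = draw(n_per_class)
    Y, test_labels = draw(n_test_per_class)
    return ClusterData(A=A, labels=labels, Y=Y, test_labels=test_labels, means=means)
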