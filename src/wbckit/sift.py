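"""Scale-Invariant Feature Transform, implemented from first principles.

The detector builds a Gaussian scale space (octaves of progressively
smoothed images, downsampled by two between octaves), subtracts
adjacent levels to form Difference-of-Gaussians (DoG) stacks, and keeps
the points that are strict maxima or minima over their 26-voxel
neighborhood in space and scale.  Weak and edge-like responses are
rejected by a contrast threshold and a principal-curvature ratio test.
Each surviving keypoint is assigned the dominant local gradient
orientation and described by the classic 4x4-cell, 8-orientation-bin
histogram of gradients over a rotated, scale-proportional 16x16 sample
window — the 128-dimensional descriptor, clamped and L2-normalized so
it is robust to affine illumination changes.

The result is invariant to image rotation and scale by construction:
orientations rotate with the image and the sampling window grows with
the detected scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "SIFTConfig",
    "KeyPoint",
    "ScaleSpace",
    "to_grayscale",
    "build_scale_space",
    "build_dog",
    "detect_extrema",
    "assign_orientation",
    "compute_descriptor",
    "extract",
]

_LUMA = np.array([0.299, 0.587, 0.114])  # ITU-R 601

# wide kernel support so incremental blurs compose to within ~1e-9
_TRUNCATE = 6.0


@dataclass
class SIFTConfig:
    """Detector and descriptor parameters.

    ``upsample=2`` runs the whole pyramid one octave below the input
    resolution (the classic initial doubling), which both resolves
    finer structure and lets coarse-scale keypoints keep a descriptor
    window that fits inside small images.
    """

    n_octaves: int = 4
    n_levels: int = 5
    sigma0: float = 1.6
    assumed_blur: float = 0.5
    contrast_threshold: float = 0.03
    edge_ratio: float = 10.0
    n_orientation_bins: int = 36
    upsample: int = 2


@dataclass
class KeyPoint:
    """A detected interest point.

    ``x``/``y`` are sub-pixel column/row coordinates in the original
    image frame; ``sigma`` is the absolute detection scale; ``octave``
    and ``scale_index`` locate the point in the scale space;
    ``polarity`` is +1 for a DoG maximum, -1 for a minimum.
    """

    x: float
    y: float
    octave: int
    scale_index: int
    sigma: float
    orientation: float = 0.0
    polarity: int = 1


@dataclass
class ScaleSpace:
    """Gaussian pyramid: per-octave stacks plus their within-octave sigmas."""

    octaves: list          # each (n_levels, H, W)
    sigmas: np.ndarray     # within-octave smoothing scale per level

    @property
    def n_levels(self) -> int:
        return len(self.sigmas)


def to_grayscale(img) -> np.ndarray:
    """Luminance grayscale on [0, 1] from RGB or single-channel input."""
    img = np.asarray(img, dtype=float)
    if img.ndim == 3:
        if img.shape[2] != 3:
            raise ValueError("expected RGB or grayscale image")
        img = img @ _LUMA
    if img.max() > 1.5:
        img = img / 255.0
    return img


def build_scale_space(
    img,
    n_octaves: int = 4,
    n_levels: int = 5,
    sigma0: float = 1.6,
    assumed_blur: float = 0.5,
) -> ScaleSpace:
    """Octaves of progressively Gaussian-smoothed images.

    Within an octave level ``i`` carries smoothing scale
    ``sigma0 * k**i`` with ``k = 2**(1/(n_levels-3))``, so the level
    used to seed the next octave (after 2x downsampling) sits exactly
    one doubling above the octave base.  Levels are produced by
    incremental blurs, exploiting the Gaussian semigroup property.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    if min(img.shape) < 16:
        raise ValueError("image smaller than 16x16")
    if n_levels < 4:
        raise ValueError("need at least 4 levels per octave")
    s = n_levels - 3
    k = 2.0 ** (1.0 / s)
    sigmas = sigma0 * k ** np.arange(n_levels)

    base = img
    if sigma0 > assumed_blur:
        base = ndimage.gaussian_filter(
            img, np.sqrt(sigma0**2 - assumed_blur**2), truncate=_TRUNCATE
        )
    octaves = []
    for _ in range(n_octaves):
        if min(base.shape) < 8:
            break
        levels = [base]
        for i in range(1, n_levels):
            inc = np.sqrt(sigmas[i] ** 2 - sigmas[i - 1] ** 2)
            levels.append(ndimage.gaussian_filter(levels[-1], inc, truncate=_TRUNCATE))
        octaves.append(np.stack(levels))
        base = levels[s][::2, ::2]  # sigma there equals 2*sigma0
    return ScaleSpace(octaves=octaves, sigmas=sigmas)


def build_dog(ss: ScaleSpace) -> list:
    """Adjacent-level differences: dog[o][i] = level[i+1] - level[i]."""
    return [stack[1:] - stack[:-1] for stack in ss.octaves]


def _edge_like(D, i, r, c, edge_ratio):
    dxx = D[i, r, c + 1] + D[i, r, c - 1] - 2 * D[i, r, c]
    dyy = D[i, r + 1, c] + D[i, r - 1, c] - 2 * D[i, r, c]
    dxy = 0.25 * (
        D[i, r + 1, c + 1] - D[i, r + 1, c - 1] - D[i, r - 1, c + 1] + D[i, r - 1, c - 1]
    )
    tr = dxx + dyy
    det = dxx * dyy - dxy**2
    if det <= 0:
        return True
    return tr**2 / det >= (edge_ratio + 1) ** 2 / edge_ratio


def _refine(D, i, r, c):
    """One-shot 3D quadratic fit; offsets clamped to half a voxel."""
    g = 0.5 * np.array(
        [
            D[i, r, c + 1] - D[i, r, c - 1],
            D[i, r + 1, c] - D[i, r - 1, c],
            D[i + 1, r, c] - D[i - 1, r, c],
        ]
    )
    dxx = D[i, r, c + 1] + D[i, r, c - 1] - 2 * D[i, r, c]
    dyy = D[i, r + 1, c] + D[i, r - 1, c] - 2 * D[i, r, c]
    dss = D[i + 1, r, c] + D[i - 1, r, c] - 2 * D[i, r, c]
    dxy = 0.25 * (
        D[i, r + 1, c + 1] - D[i, r + 1, c - 1] - D[i, r - 1, c + 1] + D[i, r - 1, c - 1]
    )
    dxs = 0.25 * (
        D[i + 1, r, c + 1] - D[i + 1, r, c - 1] - D[i - 1, r, c + 1] + D[i - 1, r, c - 1]
    )
    dys = 0.25 * (
        D[i + 1, r + 1, c] - D[i + 1, r - 1, c] - D[i - 1, r + 1, c] + D[i - 1, r - 1, c]
    )
    H = np.array([[dxx, dxy, dxs], [dxy, dyy, dys], [dxs, dys, dss]])
    try:
        off = -np.linalg.solve(H, g)
    except np.linalg.LinAlgError:
        off = np.zeros(3)
    return np.clip(off, -0.5, 0.5)


def detect_extrema(
    dog: list,
    sigmas: np.ndarray | None = None,
    sigma0: float = 1.6,
    contrast_threshold: float = 0.03,
    edge_ratio: float = 10.0,
) -> list:
    """Strict 26-neighbor extrema of the DoG stacks.

    A voxel is kept only if strictly greater (maximum) or strictly less
    (minimum) than all 26 neighbors in its 3x3x3 neighborhood; border
    rows, columns and levels are excluded.  Low-contrast and edge-like
    responses are filtered; positions are refined by a quadratic fit.
    """
    kps: list[KeyPoint] = []
    fp = np.ones((3, 3, 3), dtype=bool)
    fp[1, 1, 1] = False
    for o, D in enumerate(dog):
        if D.shape[0] < 3:
            raise ValueError("need at least 3 DoG levels per octave")
        mx = ndimage.maximum_filter(D, footprint=fp, mode="constant", cval=-np.inf)
        mn = ndimage.minimum_filter(D, footprint=fp, mode="constant", cval=np.inf)
        cand = (D > mx) | (D < mn)
        cand &= np.abs(D) >= contrast_threshold
        cand[0], cand[-1] = False, False
        cand[:, 0, :], cand[:, -1, :] = False, False
        cand[:, :, 0], cand[:, :, -1] = False, False
        scale_factor = 2.0**o
        if sigmas is not None:
            s_per = np.log2(sigmas[-1] / sigmas[0]) / (len(sigmas) - 1)
        for i, r, c in np.argwhere(cand):
            if _edge_like(D, i, r, c, edge_ratio):
                continue
            off = _refine(D, i, r, c)
            sigma = sigma0 * scale_factor
            if sigmas is not None:
                sigma = sigmas[0] * 2.0 ** ((i + off[2]) * s_per) * scale_factor
            kps.append(
                KeyPoint(
                    x=(c + off[0]) * scale_factor,
                    y=(r + off[1]) * scale_factor,
                    octave=o,
                    scale_index=int(i),
                    sigma=float(sigma),
                    polarity=1 if D[i, r, c] > mx[i, r, c] else -1,
                )
            )
    return kps


def _gradients(level):
    gy, gx = np.gradient(level)
    return gx, gy


def assign_orientation(
    kp: KeyPoint, ss: ScaleSpace, n_bins: int = 36
) -> KeyPoint:
    """Dominant gradient orientation around the keypoint.

    A Gaussian-weighted (scale 1.5 sigma) orientation histogram with
    ``n_bins`` bins is accumulated over the keypoint neighborhood on
    the keypoint's scale-space level; the peak bin is refined by a
    parabolic fit.  A gradient-free window yields orientation 0 with a
    warning.
    """
    scale_factor = 2.0**kp.octave
    L = ss.octaves[kp.octave][kp.scale_index]
    xo, yo = kp.x / scale_factor, kp.y / scale_factor
    sigma_w = 1.5 * kp.sigma / scale_factor
    radius = max(1, int(round(3.0 * sigma_w)))
    r0, c0 = int(round(yo)), int(round(xo))
    rlo, rhi = max(1, r0 - radius), min(L.shape[0] - 1, r0 + radius + 1)
    clo, chi = max(1, c0 - radius), min(L.shape[1] - 1, c0 + radius + 1)
    if rhi <= rlo or chi <= clo:
        logger.warning("keypoint window out of bounds; orientation 0")
        return replace(kp, orientation=0.0)
    win = L[rlo - 1 : rhi + 1, clo - 1 : chi + 1]
    gx = 0.5 * (win[1:-1, 2:] - win[1:-1, :-2])
    gy = 0.5 * (win[2:, 1:-1] - win[:-2, 1:-1])
    mag = np.hypot(gx, gy)
    if not np.any(mag > 0):
        logger.warning("flat window around keypoint; orientation 0")
        return replace(kp, orientation=0.0)
    rows = np.arange(rlo, rhi)[:, None] - yo
    cols = np.arange(clo, chi)[None, :] - xo
    weight = np.exp(-(rows**2 + cols**2) / (2 * sigma_w**2))
    ang = np.mod(np.arctan2(gy, gx), 2 * np.pi)
    hist, _ = np.histogram(
        ang, bins=n_bins, range=(0, 2 * np.pi), weights=mag * weight
    )
    # one circular smoothing pass stabilizes the peak
    hist = (np.roll(hist, 1) + hist + np.roll(hist, -1)) / 3.0
    peak = int(np.argmax(hist))
    left, right = hist[(peak - 1) % n_bins], hist[(peak + 1) % n_bins]
    denom = left - 2 * hist[peak] + right
    delta = 0.0 if denom == 0 else 0.5 * (left - right) / denom
    theta = (peak + 0.5 + delta) * (2 * np.pi / n_bins)
    return replace(kp, orientation=float(np.mod(theta, 2 * np.pi)))


def compute_descriptor(
    kp: KeyPoint,
    ss: ScaleSpace,
    n_cells: int = 4,
    n_bins: int = 8,
    clamp: float = 0.2,
    descriptor_scale: float = 0.5,
) -> np.ndarray | None:
    """128-dimensional gradient-histogram descriptor.

    A 16x16 sample grid, rotated to the keypoint orientation and spaced
    proportionally to the keypoint scale (``descriptor_scale`` sigmas
    per sample step), is laid over the keypoint's scale-space level.
    Gradients are sampled bilinearly, rotated into the keypoint frame,
    Gaussian-weighted, and accumulated with trilinear interpolation
    into a 4x4 grid of 8-bin orientation histograms.  The flattened
    128-vector is L2-normalized, clamped at ``clamp`` and
    renormalized.  Keypoints whose window leaves the image, or with no
    gradient energy, are dropped (returns None).
    """
    scale_factor = 2.0**kp.octave
    L = ss.octaves[kp.octave][kp.scale_index]
    xo, yo = kp.x / scale_factor, kp.y / scale_factor
    spacing = descriptor_scale * kp.sigma / scale_factor  # grows with scale
    half = n_cells * 2  # 8 samples per side -> 16x16 grid

    u = (np.arange(2 * half) - half + 0.5)[None, :]  # column offsets
    v = (np.arange(2 * half) - half + 0.5)[:, None]  # row offsets
    ct, st = np.cos(kp.orientation), np.sin(kp.orientation)
    # rotate sample offsets into the image frame
    xs = xo + spacing * (ct * u - st * v)
    ys = yo + spacing * (st * u + ct * v)
    if (
        xs.min() < 1 or ys.min() < 1
        or xs.max() > L.shape[1] - 2 or ys.max() > L.shape[0] - 2
    ):
        logger.debug("descriptor window exceeds bounds; keypoint dropped")
        return None
    gx_img, gy_img = _gradients(L)
    gx = ndimage.map_coordinates(gx_img, [ys.ravel(), xs.ravel()], order=1)
    gy = ndimage.map_coordinates(gy_img, [ys.ravel(), xs.ravel()], order=1)
    mag = np.hypot(gx, gy)
    if not np.any(mag > 0):
        logger.debug("flat descriptor window; keypoint dropped")
        return None
    ang = np.mod(np.arctan2(gy, gx) - kp.orientation, 2 * np.pi)

    uu = np.broadcast_to(u, (2 * half, 2 * half)).ravel()
    vv = np.broadcast_to(v, (2 * half, 2 * half)).ravel()
    weight = np.exp(-(uu**2 + vv**2) / (2 * half**2))

    # trilinear accumulation into (n_cells, n_cells, n_bins)
    rbin = (vv + half) / (2 * half / n_cells) - 0.5
    cbin = (uu + half) / (2 * half / n_cells) - 0.5
    obin = ang / (2 * np.pi / n_bins)
    hist = np.zeros((n_cells, n_cells, n_bins))
    r0 = np.floor(rbin).astype(int)
    c0 = np.floor(cbin).astype(int)
    o0 = np.floor(obin).astype(int)
    rf, cf, of = rbin - r0, cbin - c0, obin - o0
    contrib = mag * weight
    for dr, wr in ((0, 1 - rf), (1, rf)):
        rr = r0 + dr
        okr = (rr >= 0) & (rr < n_cells)
        for dc, wc in ((0, 1 - cf), (1, cf)):
            cc = c0 + dc
            okc = okr & (cc >= 0) & (cc < n_cells)
            for do, wo in ((0, 1 - of), (1, of)):
                oo = (o0 + do) % n_bins
                w = contrib * wr * wc * wo
                np.add.at(
                    hist,
                    (rr[okc], cc[okc], oo[okc]),
                    w[okc],
                )
    vec = hist.ravel()
    norm = np.linalg.norm(vec)
    if norm == 0:
        logger.debug("zero descriptor; keypoint dropped")
        return None
    vec = np.minimum(vec / norm, clamp)
    return vec / np.linalg.norm(vec)


def extract(img, cfg: SIFTConfig | None = None) -> list:
    """Full detector + descriptor chain on one image.

    Accepts RGB (converted by luminance) or grayscale input and
    returns a list of ``(KeyPoint, descriptor)`` pairs; deterministic.
    """
    if cfg is None:
        cfg = SIFTConfig()
    gray = to_grayscale(img)
    u = max(1, int(cfg.upsample))
    if u > 1:
        gray = ndimage.zoom(gray, u, order=1)
    ss = build_scale_space(
        gray, cfg.n_octaves, cfg.n_levels, cfg.sigma0, cfg.assumed_blur * u
    )
    dog = build_dog(ss)
    kps = detect_extrema(
        dog,
        sigmas=ss.sigmas,
        sigma0=cfg.sigma0,
        contrast_threshold=cfg.contrast_threshold,
        edge_ratio=cfg.edge_ratio,
    )
    out = []
    for kp in kps:
        kp = assign_orientation(kp, ss, cfg.n_orientation_bins)
        desc = compute_descriptor(kp, ss)
        if desc is not None:
            if u > 1:  # report in input-image coordinates
                kp = replace(kp, x=kp.x / u, y=kp.y / u, sigma=kp.sigma / u)
            out.append((kp, desc))
    return out
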