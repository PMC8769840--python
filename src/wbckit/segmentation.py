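"""Nucleus segmentation by Gram-Schmidt color projection.

A stained blood smear contains three dominant color populations: pale
background, pink/red erythrocytes, and the purple-stained leukocyte
nuclei (platelets share the nuclear stain but are much smaller).  Each
pixel is treated as a 3-vector of RGB intensities.  Given reference
colors for the non-nucleus populations and for the nucleus, a weight
vector is built that is orthogonal to the non-nucleus colors while
retaining maximal projection onto the nucleus color; the pixelwise inner
product with that weight vector then lights up nuclei and darkens
everything else.  Three weight vectors built from three nucleus-color
candidates are thresholded independently and fused by logical AND, which
suppresses stain-intensity and illumination variation; small surviving
components (platelets) are removed by area.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationConfig",
    "gram_schmidt_weight",
    "project_image",
    "estimate_basis_sets",
    "threshold_mask",
    "remove_small_components",
    "combine_and",
    "segment_nucleus",
]

_RANK_TOL = 1e-8


@dataclass
class SegmentationConfig:
    """Tunable knobs of the nucleus segmentation pipeline.

    Parameters
    ----------
    seed : int
        Seed for the k-means color clustering and pixel subsampling,
        making the whole pipeline deterministic.
    min_area_frac : float
        Connected components smaller than ``min_area_frac`` times the
        image area are removed (platelet rejection).  Default 0.1 % of
        the image.
    n_sample_pixels : int
        At most this many pixels are subsampled for color clustering.
    nucleus_percentiles : tuple of float
        Percentiles of the purpleness score within the nucleus cluster
        used as the three nucleus-color candidates.
    strict : bool
        If True, an image without color contrast raises; if False an
        all-false mask is returned.
    contrast_tol : float
        Minimum RGB standard deviation (8-bit units) below which the
        image is declared contrast-free.
    """

    seed: int = 0
    min_area_frac: float = 0.001
    n_sample_pixels: int = 10000
    nucleus_percentiles: tuple = (10.0, 25.0, 50.0)
    strict: bool = True
    contrast_tol: float = 1.0


def _as_float_basis(basis) -> np.ndarray:
    vs = np.asarray(basis, dtype=float)
    if vs.ndim != 2 or vs.shape[1] != 3:
        raise ValueError("basis must be a sequence of 3-vectors")
    if vs.shape[0] == 0:
        raise ValueError("empty basis")
    if not np.all(np.isfinite(vs)):
        raise ValueError("basis vectors must be finite")
    if np.linalg.matrix_rank(vs, tol=_RANK_TOL) < vs.shape[0]:
        raise ValueError("basis vectors are linearly dependent")
    return vs


def gram_schmidt_weight(basis) -> np.ndarray:
    """Weight vector orthogonal to all basis colors except the last.

    Classical Gram-Schmidt is run over the ordered basis
    ``v_1, ..., v_k``; the returned vector is the last orthogonalized
    direction ``u_k``, i.e. ``v_k`` minus its projections onto the
    preceding orthogonal directions.  It is orthogonal to every
    ``v_j, j < k`` and has strictly positive inner product with
    ``v_k`` (maximal projection onto the target color).

    Parameters
    ----------
    basis : sequence of length-3 vectors
        Linearly independent reference colors; the last entry is the
        nucleus color.

    Returns
    -------
    ndarray, shape (3,)
    """
    vs = _as_float_basis(basis)
    us: list[np.ndarray] = []
    for v in vs:
        u = v.copy()
        for uj in us:
            u -= (uj @ v) / (uj @ uj) * uj
        us.append(u)
    w = us[-1]
    if w @ vs[-1] <= 0:  # impossible for an independent basis
        raise ValueError("degenerate basis: non-positive target projection")
    return w


def project_image(img, w) -> np.ndarray:
    """Pixelwise inner product of the image RGB vectors with ``w``."""
    img = np.asarray(img, dtype=float)
    w = np.asarray(w, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB image")
    if w.shape != (3,) or not np.all(np.isfinite(w)):
        raise ValueError("weight vector must be a finite 3-vector")
    return img @ w


def _purpleness(colors: np.ndarray) -> np.ndarray:
    """Stain score: purple is strong in R and B, weak in G."""
    return colors[..., 0] + colors[..., 2] - 2.0 * colors[..., 1]


def estimate_basis_sets(img, cfg: SegmentationConfig | None = None):
    """Estimate three color bases (background, RBC, nucleus candidate).

    Pixels are clustered into three color populations by k-means; the
    cluster with the highest purpleness score is taken as the nucleus
    population and the two remaining centers become the shared
    non-nucleus reference colors.  Three nucleus-color candidates are
    drawn from the purpleness percentiles within the nucleus cluster,
    yielding three bases that differ only in the target color — the
    source of the three weight vectors fused later.

    Returns
    -------
    list of three (3, 3) ndarrays, rows ordered v1, v2, v_nucleus.
    """
    if cfg is None:
        cfg = SegmentationConfig()
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB image")
    pixels = img.reshape(-1, 3)
    if float(pixels.std(axis=0).max()) < cfg.contrast_tol:
        raise ValueError("no color contrast")

    rng = np.random.default_rng(cfg.seed)
    if pixels.shape[0] > cfg.n_sample_pixels:
        idx = rng.choice(pixels.shape[0], size=cfg.n_sample_pixels, replace=False)
        sample = pixels[idx]
    else:
        sample = pixels

    km = KMeans(n_clusters=3, n_init=10, random_state=cfg.seed)
    assignments = km.fit_predict(sample)
    centers = km.cluster_centers_
    nuc = int(np.argmax(_purpleness(centers)))
    others = [centers[i] for i in range(3) if i != nuc]

    nuc_pixels = sample[assignments == nuc]
    scores = _purpleness(nuc_pixels)
    bases = []
    for pct in cfg.nucleus_percentiles:
        target = np.percentile(scores, pct)
        cand = nuc_pixels[np.argmin(np.abs(scores - target))]
        basis = np.vstack([others[0], others[1], cand])
        if np.linalg.matrix_rank(basis, tol=_RANK_TOL) < 3:
            # fall back to the cluster mean if a percentile pixel is degenerate
            basis = np.vstack([others[0], others[1], centers[nuc]])
        if np.linalg.matrix_rank(basis, tol=_RANK_TOL) < 3:
            raise ValueError("no color contrast")
        bases.append(basis)
    return bases


def _otsu_threshold_256(values: np.ndarray) -> float:
    """Otsu's threshold on a 256-bin histogram of min-max-normalized data.

    Returns the threshold on the normalized [0, 1] scale: the upper edge
    of the bin maximizing between-class variance.
    """
    hist, edges = np.histogram(values, bins=256, range=(0.0, 1.0))
    p = hist.astype(float) / hist.sum()
    w0 = np.cumsum(p)
    mu = np.cumsum(p * (np.arange(256) + 0.5) / 256.0)
    mu_total = mu[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        var_between = (mu_total * w0 - mu) ** 2 / (w0 * w1)
    var_between[~np.isfinite(var_between)] = -np.inf
    k = int(np.argmax(var_between[:-1]))  # last bin cannot split
    return edges[k + 1]


def threshold_mask(proj) -> np.ndarray:
    """Binarize a projection image by Otsu's histogram criterion.

    The projection is min-max normalized, a 256-bin histogram built,
    and the threshold maximizing between-class variance chosen; pixels
    strictly above it are foreground.  A constant projection produces
    an all-false mask and a warning.
    """
    proj = np.asarray(proj, dtype=float)
    if not np.all(np.isfinite(proj)):
        raise ValueError("projection must be finite")
    lo, hi = float(proj.min()), float(proj.max())
    if hi - lo <= 0:
        warnings.warn("constant projection: returning empty mask", stacklevel=2)
        return np.zeros(proj.shape, dtype=bool)
    norm = (proj - lo) / (hi - lo)
    t = _otsu_threshold_256(norm)
    return norm > t


def remove_small_components(mask, min_area: int) -> np.ndarray:
    """Clear every 8-connected component with area below ``min_area``."""
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if min_area == 0:
        return mask.copy()
    lab, n = label(mask, connectivity=2, return_num=True)
    if n == 0:
        return mask.copy()
    areas = np.bincount(lab.ravel())
    keep = areas >= min_area
    keep[0] = False
    return keep[lab]


def combine_and(m1, m2, m3) -> np.ndarray:
    """Pixelwise logical AND of three equally shaped binary masks."""
    m1, m2, m3 = (np.asarray(m, dtype=bool) for m in (m1, m2, m3))
    if not (m1.shape == m2.shape == m3.shape):
        raise ValueError("mask shapes differ")
    return m1 & m2 & m3


def segment_nucleus(img, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Full nucleus segmentation of one RGB blood-smear image.

    Pipeline: estimate three color bases -> for each, Gram-Schmidt
    weight vector, projection, Otsu threshold -> AND-fuse the three
    masks -> remove small components.  Deterministic given ``cfg``.
    """
    if cfg is None:
        cfg = SegmentationConfig()
    img = np.asarray(img, dtype=float)
    try:
        bases = estimate_basis_sets(img, cfg)
    except ValueError as exc:
        if "no color contrast" in str(exc) and not cfg.strict:
            logger.warning("no color contrast; returning empty mask")
            return np.zeros(img.shape[:2], dtype=bool)
        raise
    masks = []
    for basis in bases:
        w = gram_schmidt_weight(basis)
        proj = project_image(img, w)
        masks.append(threshold_mask(proj))
    fused = combine_and(*masks)
    min_area = int(round(cfg.min_area_frac * img.shape[0] * img.shape[1]))
    return remove_small_components(fused, min_area)
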