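"""Segmentation-quality metrics for automatic vs. manual nucleus masks.

Five scalar criteria compare a binary mask produced by the pipeline
against a manually delineated reference:

* ``TS`` — area similarity in percent: intersection area over the
  larger of the two areas, times 100.
* ``RDE`` — relative distance error in pixels: the mean of the two
  root-mean-square nearest-neighbor distances between the boundary
  point sets of the two masks (symmetric).
* ``OR`` / ``UR`` / ``ER`` — over-segmentation, under-segmentation and
  error ratios built from the missed pixel count Q_p (manual pixels the
  automatic mask lacks), the spurious pixel count U_p (automatic pixels
  the manual mask lacks) and the manual object size D_p:
  ``OR = Q_p/(U_p+D_p)``, ``UR = U_p/(U_p+D_p)``, ``ER = (Q_p+U_p)/D_p``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "MetricReport",
    "similarity_ts",
    "extract_boundary",
    "rde",
    "or_ur_er",
    "evaluate_pair",
]


@dataclass(frozen=True)
class MetricReport:
    """All five criteria for one automatic/manual mask pair."""

    ts: float
    rde: float
    over_ratio: float
    under_ratio: float
    error_ratio: float

    def as_dict(self) -> dict:
        return {
            "TS": self.ts,
            "RDE": self.rde,
            "OR": self.over_ratio,
            "UR": self.under_ratio,
            "ER": self.error_ratio,
        }


def _check_pair(auto, manual):
    auto = np.asarray(auto, dtype=bool)
    manual = np.asarray(manual, dtype=bool)
    if auto.shape != manual.shape:
        raise ValueError("mask shapes differ")
    return auto, manual


def similarity_ts(auto, manual) -> float:
    """Area similarity in percent.

    ``|auto & manual| / max(|auto|, |manual|) * 100`` — 100 exactly when
    the pixel sets coincide, 0 when they are disjoint.
    """
    auto, manual = _check_pair(auto, manual)
    a, m = int(auto.sum()), int(manual.sum())
    if a == 0 and m == 0:
        raise ValueError("both masks are empty")
    inter = int((auto & manual).sum())
    return inter / max(a, m) * 100.0


def extract_boundary(mask) -> np.ndarray:
    """Inner boundary pixels of a mask under 4-connectivity.

    A mask-true pixel is a boundary pixel when at least one of its four
    edge-neighbors is false or lies outside the image.  Returns an
    (n, 2) array of (row, col) coordinates; empty for an empty mask.
    """
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    boundary = mask & ~interior
    return np.argwhere(boundary)


def rde(auto, manual, variant: str = "rms") -> float:
    """Relative distance error between the two mask boundaries, in pixels.

    Nearest-neighbor Euclidean distances are taken from each automatic
    boundary pixel to the manual boundary and vice versa.  With
    ``variant="rms"`` (default) the result is the mean of the two
    root-mean-square distances; ``variant="mean_square"`` keeps the
    literal no-root form (mean of the two mean squared distances) for
    comparison.
    """
    auto, manual = _check_pair(auto, manual)
    e = extract_boundary(auto).astype(float)
    t = extract_boundary(manual).astype(float)
    if len(e) == 0 or len(t) == 0:
        raise ValueError("empty boundary")
    d_e = cKDTree(t).query(e)[0]
    d_t = cKDTree(e).query(t)[0]
    if variant == "rms":
        return 0.5 * (np.sqrt(np.mean(d_e**2)) + np.sqrt(np.mean(d_t**2)))
    if variant == "mean_square":
        return 0.5 * (np.mean(d_e**2) + np.mean(d_t**2))
    raise ValueError(f"unknown rde variant: {variant!r}")


def or_ur_er(auto, manual) -> tuple[float, float, float]:
    """Over-segmentation, under-segmentation and error ratios."""
    auto, manual = _check_pair(auto, manual)
    d_p = int(manual.sum())
    if d_p == 0:
        raise ValueError("manual mask is empty")
    q_p = int((manual & ~auto).sum())
    u_p = int((auto & ~manual).sum())
    over = q_p / (u_p + d_p)
    under = u_p / (u_p + d_p)
    err = (q_p + u_p) / d_p
    return over, under, err


def evaluate_pair(auto, manual, rde_variant: str = "rms") -> MetricReport:
    """All five criteria for one mask pair."""
    o, u, e = or_ur_er(auto, manual)
    return MetricReport(
        ts=similarity_ts(auto, manual),
        rde=rde(auto, manual, variant=rde_variant),
        over_ratio=o,
        under_ratio=u,
        error_ratio=e,
    )
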