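"""Weighted two-phase test-sample sparse representation (WTPTSSR).

A test feature vector y is classified against a dictionary A whose
columns are the (unit-normalized) training samples.  Phase 1 solves a
locality-weighted ridge system

    X = (A^T A + t W^T W)^{-1} A^T y,   W = diag(||y - a_i||^k),

so that distant training samples are penalized (k is the locality
exponent; k = 0 gives the unweighted TPTSR method).  The M columns with
the smallest single-column reconstruction residual ||y - a_i x_i||^2
form a reduced dictionary on which phase 2 solves a plain ridge system

    Xbar = (Abar^T Abar + g I)^{-1} Abar^T y.

Each class is then scored by the residual of reconstructing y from only
its own selected columns; the class with the smallest residual wins.

The module also provides the feature-fusion step that turns a variable
set of 128-dim local descriptors plus a fixed CNN feature vector into
one fixed-length vector per cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Hyperparams",
    "normalize_columns",
    "phase1_solve",
    "phase1_select",
    "phase2_solve",
    "class_contribution",
    "predict",
    "fuse_features",
    "WTPTSSRClassifier",
]


@dataclass
class Hyperparams:
    """WTPTSSR hyperparameters.

    t : phase-1 ridge weight (> 0)
    k : locality exponent (>= 0; 0 reduces the method to TPTSR)
    gamma : phase-2 ridge weight (> 0)
    M : number of neighbors kept after phase 1 (None -> min(40, N//2))
    """

    t: float = 0.01
    k: float = 2.0
    gamma: float = 0.01
    M: int | None = None

    def __post_init__(self):
        if self.t <= 0 or self.gamma <= 0:
            raise ValueError("ridge weights t and gamma must be positive")
        if self.k < 0:
            raise ValueError("locality exponent k must be >= 0")

    def resolve_m(self, n: int) -> int:
        m = min(40, n // 2) if self.M is None else self.M
        if not 1 <= m <= n:
            raise ValueError(f"M must be in [1, {n}], got {m}")
        return m


def normalize_columns(A, y):
    """Unit-L2-normalize every dictionary column and the test vector."""
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    norms = np.linalg.norm(A, axis=0)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(f"zero column in training matrix at index {bad[0]}")
    ny = np.linalg.norm(y)
    if ny == 0:
        raise ValueError("zero test vector")
    return A / norms, y / ny


def phase1_solve(A, y, t: float, k: float) -> np.ndarray:
    """Locality-weighted ridge coefficients over the full dictionary."""
    if t <= 0:
        raise ValueError("t must be positive")
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    dists = np.linalg.norm(A - y[:, None], axis=0)
    w = dists**k
    lhs = A.T @ A + t * np.diag(w**2)
    try:
        return np.linalg.solve(lhs, A.T @ y)
    except np.linalg.LinAlgError as exc:  # W can have zero entries
        raise np.linalg.LinAlgError(
            f"phase-1 system singular despite t={t}: {exc}"
        ) from exc


def phase1_select(A, y, X, M: int):
    """Keep the M columns that best reconstruct y on their own.

    The score of column i is ``||y - a_i x_i||^2``; the M smallest
    scores are selected, ties broken toward the lower index.

    Returns
    -------
    idx : (M,) int array of selected column indices (sorted ascending)
    A_sel : the reduced dictionary
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float).ravel()
    n = A.shape[1]
    if not 1 <= M <= n:
        raise ValueError(f"M must be in [1, {n}]")
    resid = y[:, None] - A * X[None, :]
    con = np.sum(resid**2, axis=0)
    # stable sort -> ties resolved toward the lowest index
    idx = np.argsort(con, kind="stable")[:M]
    idx = np.sort(idx)
    return idx, A[:, idx]


def phase2_solve(A_sel, y, gamma: float) -> np.ndarray:
    """Plain ridge coefficients on the reduced dictionary."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    A_sel = np.asarray(A_sel, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    lhs = A_sel.T @ A_sel + gamma * np.eye(A_sel.shape[1])
    return np.linalg.solve(lhs, A_sel.T @ y)


def class_contribution(A_sel, X_sel, y, labels_sel, classes) -> np.ndarray:
    """Per-class reconstruction residuals from the selected columns.

    A class with no selected column cannot reconstruct anything and
    receives ``||y||^2`` (the residual of the zero reconstruction).
    """
    A_sel = np.asarray(A_sel, dtype=float)
    X_sel = np.asarray(X_sel, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    labels_sel = np.asarray(labels_sel)
    con = np.empty(len(classes))
    for j, cls in enumerate(classes):
        member = labels_sel == cls
        if not member.any():
            con[j] = float(y @ y)
        else:
            recon = A_sel[:, member] @ X_sel[member]
            con[j] = float(np.sum((y - recon) ** 2))
    return con


def predict(y, A, labels, hp: Hyperparams | None = None):
    """Classify one test vector; ties break toward the lowest class id."""
    if hp is None:
        hp = Hyperparams()
    labels = np.asarray(labels)
    A, y = normalize_columns(A, y)
    M = hp.resolve_m(A.shape[1])
    X = phase1_solve(A, y, hp.t, hp.k)
    idx, A_sel = phase1_select(A, y, X, M)
    X_sel = phase2_solve(A_sel, y, hp.gamma)
    classes = np.unique(labels)
    con = class_contribution(A_sel, X_sel, y, labels[idx], classes)
    return classes[int(np.argmin(con))]


class WTPTSSRClassifier:
    """Scikit-learn-style wrapper: fit a dictionary, predict class ids."""

    def __init__(self, hp: Hyperparams | None = None):
        self.hp = hp or Hyperparams()
        self.A_: np.ndarray | None = None
        self.labels_: np.ndarray | None = None

    def fit(self, A, labels):
        """Store (and column-normalize) the training dictionary.

        ``A`` is m x N with one sample per column.
        """
        A = np.asarray(A, dtype=float)
        labels = np.asarray(labels)
        if A.shape[1] != labels.shape[0]:
            raise ValueError("label count must equal the number of columns")
        norms = np.linalg.norm(A, axis=0)
        bad = np.flatnonzero(norms == 0)
        if bad.size:
            raise ValueError(f"zero column in training matrix at index {bad[0]}")
        self.A_ = A / norms
        self.labels_ = labels
        return self

    def predict(self, Y):
        """Predict the class of each column of the m x n test matrix."""
        if self.A_ is None:
            raise RuntimeError("classifier is not fitted")
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        return np.asarray(
            [predict(Y[:, j], self.A_, self.labels_, self.hp) for j in range(Y.shape[1])]
        )


def fuse_features(cnn_vec, sift_descriptors) -> np.ndarray:
    """Fuse a CNN feature vector with a set of local descriptors.

    The descriptor set (n x 128, possibly empty) is pooled to a fixed
    256-vector by elementwise mean and max; the pooled block is
    concatenated with the CNN vector.  With no keypoints the pooled
    block is all zeros, so cells whose nuclei yield no keypoints still
    get a valid feature vector.
    """
    cnn_vec = np.asarray(cnn_vec, dtype=float).ravel()
    d = np.asarray(sift_descriptors, dtype=float)
    if d.size == 0:
        pooled = np.zeros(256)
    else:
        if d.ndim != 2 or d.shape[1] != 128:
            raise ValueError("descriptors must be an (n, 128) array")
        pooled = np.concatenate([d.mean(axis=0), d.max(axis=0)])
    return np.concatenate([cnn_vec, pooled])
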