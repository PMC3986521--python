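"""Local Fisher discriminant analysis (LFDA).

Supervised linear dimensionality reduction that maximizes between-class
scatter against within-class scatter while preserving the local structure of
each class. Pairwise weights use the local-scaling affinity

    A_ij = exp(-||x_i - x_j||^2 / (sigma_i sigma_j)),

where ``sigma_i`` is the distance from ``x_i`` to its ``k_nn``-th nearest
neighbor *within the same class*. Same-class pairs enter the within-class
scatter with weight ``A_ij / n_c`` and the between-class scatter with
``A_ij (1/n - 1/n_c)``; different-class pairs enter the between-class scatter
with ``1/n``. The transform consists of the top ``r`` generalized
eigenvectors of ``S_b v = lambda S_w v``, each scaled to unit norm. With all
affinities forced to one the method reduces to classical Fisher discriminant
analysis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .errors import FitError, UsageError

__all__ = ["LFDAModel", "fit_lfda", "transform"]


@dataclass
class LFDAModel:
    """Fitted linear transform ``Z = X T`` with ``T`` of shape (d, r)."""

    T: np.ndarray
    r: int
    k_nn: int
    class_labels: list[str]
    d: int
    eigenvalues: np.ndarray | None = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        return transform(self, X)

    def save(self, path) -> None:
        header = {"r": self.r, "k_nn": self.k_nn, "d": self.d,
                  "class_labels": list(self.class_labels)}
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(header) + "\n")
            np.savetxt(fh, self.T, delimiter=",")

    @classmethod
    def load(cls, path) -> "LFDAModel":
        with open(path) as fh:
            header = json.loads(fh.readline().lstrip("# "))
            T = np.loadtxt(fh, delimiter=",", ndmin=2)
        return cls(T=T, eigenvalues=None, **header)


def _class_affinity(Xc: np.ndarray, k_nn: int, affinity: str) -> np.ndarray:
    """Local-scaling (or uniform) affinity matrix within one class."""
    n_c = Xc.shape[0]
    if affinity == "uniform":
        return np.ones((n_c, n_c))
    sq = np.sum(Xc ** 2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (Xc @ Xc.T)
    np.maximum(d2, 0.0, out=d2)
    # k_nn-th nearest same-class neighbor; each row holds its self-distance 0,
    # so index k_nn of the partially sorted row skips it
    kth = np.partition(d2, k_nn, axis=1)[:, k_nn]
    sigma = np.sqrt(kth)
    floor = 1e-12 * (1.0 + np.median(sigma))
    np.maximum(sigma, floor, out=sigma)
    return np.exp(-d2 / np.outer(sigma, sigma))


def fit_lfda(X: np.ndarray, y: np.ndarray, r: int, k_nn: int = 7, *,
             affinity: str = "local", max_class_size: int = 5000,
             seed: int = 0, reg: float = 1e-9) -> LFDAModel:
    """Fit the LFDA transform on labeled rows.

    Parameters
    ----------
    r : target dimension (``r <= d``).
    k_nn : neighbor index of the local scale; every class needs more than
        ``k_nn`` members.
    affinity : ``"local"`` (default) or ``"uniform"`` (classical FDA).
    max_class_size : classes larger than this are subsampled (seeded) for the
        O(n_c^2) scatter estimation.
    reg : relative ridge added to ``S_w`` if the generalized eigensolve
        fails on singular within-class scatter.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise UsageError("X must be 2-D with one label per row")
    d = X.shape[1]
    if not 1 <= r <= d:
        raise FitError(f"r={r} must lie in [1, d={d}]")
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise FitError("need at least 2 classes")

    rng = np.random.default_rng(seed)
    parts = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        if idx.size <= k_nn and affinity == "local":
            raise FitError(
                f"class {c!r} has {idx.size} rows; needs > k_nn={k_nn}")
        if idx.size > max_class_size:
            idx = rng.choice(idx, size=max_class_size, replace=False)
        parts.append(X[idx])

    n = sum(p.shape[0] for p in parts)
    S_w = np.zeros((d, d))
    # between-class scatter assembled from the identity
    #   S_b = X'X - sum_c Xc' diag(B_c 1) Xc + sum_c Xc' B_c Xc - (1/n) m m'
    # with B_c = (1/n) J - (1/n - 1/n_c) A_c, which avoids the dense n x n
    # pair-weight matrix.
    S_b = np.zeros((d, d))
    m = np.zeros(d)
    for Xc in parts:
        n_c = Xc.shape[0]
        A = _class_affinity(Xc, k_nn, affinity)
        rowsum = A.sum(axis=1)
        XtDX = Xc.T @ (rowsum[:, None] * Xc)
        XtAX = Xc.T @ (A @ Xc)
        S_w += (XtDX - XtAX) / n_c
        s_c = Xc.sum(axis=0)
        coeff = 1.0 / n - 1.0 / n_c
        B_rowsum = n_c / n - coeff * rowsum
        S_b += Xc.T @ Xc
        S_b -= Xc.T @ (B_rowsum[:, None] * Xc)
        S_b += np.outer(s_c, s_c) / n - coeff * XtAX
        m += s_c
    S_b -= np.outer(m, m) / n
    S_w = 0.5 * (S_w + S_w.T)
    S_b = 0.5 * (S_b + S_b.T)

    try:
        w, V = linalg.eigh(S_b, S_w)
    except linalg.LinAlgError:
        warnings.warn("singular within-class scatter; adding ridge "
                      f"{reg:g} * trace/d to S_w")
        S_w = S_w + reg * (np.trace(S_w) / d) * np.eye(d)
        w, V = linalg.eigh(S_b, S_w)
    order = np.argsort(w)[::-1][:r]
    T = V[:, order]
    T = T / np.linalg.norm(T, axis=0, keepdims=True)
    # deterministic sign: largest-magnitude entry of each column positive
    sign = np.sign(T[np.argmax(np.abs(T), axis=0), np.arange(T.shape[1])])
    sign[sign == 0] = 1.0
    T = T * sign
    return LFDAModel(T=T, r=r, k_nn=k_nn, class_labels=[str(c) for c in classes],
                     d=d, eigenvalues=w[order])


def transform(model: LFDAModel, X: np.ndarray) -> np.ndarray:
    """Project rows into the fitted subspace, ``Z = X T``."""
    X = np.asarray(X, dtype=float)
    one_d = X.ndim == 1
    if one_d:
        X = X[None, :]
    if X.shape[1] != model.d:
        raise UsageError(f"X has {X.shape[1]} columns; model expects {model.d}")
    Z = X @ model.T
    return Z[0] if one_d else Z
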