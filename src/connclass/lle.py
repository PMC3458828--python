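"""Locally linear embedding with an out-of-sample extension.

Each training point is reconstructed as a convex-affine combination of its
k nearest neighbors (weights summing to one, found by solving the local
Gram system with a small ridge term), and the embedding is given by the
bottom non-constant eigenvectors of M = (I - W)' (I - W), scaled to unit
covariance.  A held-out point is projected by solving the same constrained
weight problem against the training set and combining the neighbors'
embedding rows — the standard weight-based out-of-sample extension.

Written for the small-n regime (tens of subjects, thousands of input
dimensions): neighbor search and the eigenproblem are dense.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import cdist


@dataclass
class LLEModel:
    """Fitted embedding state.

    ``weights`` is the n x n row-stochastic reconstruction-weight matrix
    (k nonzeros per row); ``embedding`` holds the n x d coordinates with
    centered columns and unit covariance.
    """

    training_points: np.ndarray
    k: int
    d: int
    reg: float
    weights: np.ndarray
    embedding: np.ndarray

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "k": self.k,
            "d": self.d,
            "reg": self.reg,
            "training_points": self.training_points.tolist(),
            "weights": self.weights.tolist(),
            "embedding": self.embedding.tolist(),
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "LLEModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            training_points=np.array(payload["training_points"], dtype=float),
            k=int(payload["k"]),
            d=int(payload["d"]),
            reg=float(payload["reg"]),
            weights=np.array(payload["weights"], dtype=float),
            embedding=np.array(payload["embedding"], dtype=float),
        )


def _neighbor_indices(dists: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k smallest entries per row, ties broken by index."""
    order = np.argsort(dists, axis=1, kind="stable")
    return order[:, :k]


def barycentric_weights(
    x: np.ndarray, neighbors: np.ndarray, reg: float
) -> np.ndarray:
    """Solve min ||x - sum_j w_j neighbors_j||^2 s.t. sum_j w_j = 1.

    Uses the local Gram matrix C of neighbor offsets with ridge term
    reg * trace(C) / k on the diagonal (plain reg if the trace vanishes,
    which happens when all neighbors coincide with x).
    """
    k = neighbors.shape[0]
    Z = neighbors - x
    C = Z @ Z.T
    trace = np.trace(C)
    ridge = reg * trace / k if trace > 0 else reg
    C = C + ridge * np.eye(k)
    try:
        w = np.linalg.solve(C, np.ones(k))
    except np.linalg.LinAlgError:
        # singular local Gram (rank-deficient neighborhood, reg = 0):
        # fall back to the minimum-norm solution
        w = np.linalg.lstsq(C, np.ones(k), rcond=None)[0]
    return w / w.sum()


def fit_lle(X: np.ndarray, k: int, d: int, reg: float = 1e-3) -> LLEModel:
    """Fit a locally linear embedding of the rows of X.

    Neighbors are the k nearest rows by Euclidean distance excluding the
    point itself (ties broken by ascending index); the embedding consists
    of eigenvectors 2..d+1 of M in ascending eigenvalue order (the constant
    bottom eigenvector is dropped), scaled so the columns have unit
    covariance.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n; got k={k}, n={n}")
    if not 1 <= d < n:
        raise ValueError(f"d must satisfy 1 <= d < n; got d={d}, n={n}")
    dists = cdist(X, X)
    np.fill_diagonal(dists, np.inf)  # exclude self
    nbr = _neighbor_indices(dists, k)
    W = np.zeros((n, n))
    for i in range(n):
        W[i, nbr[i]] = barycentric_weights(X[i], X[nbr[i]], reg)
    IW = np.eye(n) - W
    M = IW.T @ IW
    vals, vecs = eigh(M)
    # eigenvector 1 (smallest eigenvalue) is constant; keep the next d
    Y = vecs[:, 1 : d + 1] * np.sqrt(n)
    return LLEModel(training_points=X, k=k, d=d, reg=reg, weights=W, embedding=Y)


def transform_lle(model: LLEModel, x_new: np.ndarray) -> np.ndarray:
    """Project new point(s) into the fitted embedding.

    Each new point is assigned reconstruction weights over its k nearest
    training points and mapped to the weighted combination of their
    embedding coordinates.  Accepts a single p-vector or an (m, p) array.
    """
    x_new = np.asarray(x_new, dtype=float)
    single = x_new.ndim == 1
    pts = np.atleast_2d(x_new)
    p = model.training_points.shape[1]
    if pts.shape[1] != p:
        raise ValueError(
            f"dimension mismatch: model expects {p} features, got {pts.shape[1]}"
        )
    dists = cdist(pts, model.training_points)
    nbr = _neighbor_indices(dists, model.k)
    out = np.empty((pts.shape[0], model.d))
    for i in range(pts.shape[0]):
        w = barycentric_weights(pts[i], model.training_points[nbr[i]], model.reg)
        out[i] = w @ model.embedding[nbr[i]]
    return out[0] if single else out
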