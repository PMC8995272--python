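"""Similarity-transform registration of embeddings with known correspondences.

t-SNE embeddings of the same dictionary differ from run to run by an
arbitrary rotation, reflection, isotropic scale and translation (and small
stochastic distortions).  Because every embedding point is tied to a known
(T1, T2) grid entry, point correspondences are known, and the optimal
similarity transform minimizing the sum of squared point-pair distances has
a closed-form least-squares solution (the classical orthogonal-Procrustes /
Umeyama estimator with scale).  No iteration is required: with known
correspondences, iterating cannot improve the global closed-form optimum.

Reflections are permitted by default since embedding chirality carries no
meaning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .embedding import Embedding

__all__ = ["SimilarityTransform", "register", "pointwise_distances"]


@dataclass(frozen=True)
class SimilarityTransform:
    """``x -> scale * orthogonal @ x + translation`` with det(orthogonal) = +-1."""

    scale: float
    orthogonal: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.orthogonal, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("orthogonal must be a square matrix")
        if not np.allclose(R @ R.T, np.eye(R.shape[0]), atol=1e-9):
            raise ValueError("matrix is not orthogonal within 1e-9")
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        if t.shape != (R.shape[0],):
            raise ValueError("translation dimension mismatch")
        R.setflags(write=False)
        t.setflags(write=False)
        object.__setattr__(self, "orthogonal", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, d) point array."""
        return self.scale * np.asarray(points) @ self.orthogonal.T + self.translation

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "scale": self.scale,
                    "matrix": self.orthogonal.tolist(),
                    "translation": self.translation.tolist(),
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SimilarityTransform":
        d = json.loads(Path(path).read_text())
        return cls(
            scale=float(d["scale"]),
            orthogonal=np.array(d["matrix"]),
            translation=np.array(d["translation"]),
        )


def _umeyama(
    src: np.ndarray, dst: np.ndarray, allow_reflection: bool
) -> SimilarityTransform:
    """Least-squares similarity transform mapping ``src`` onto ``dst``."""
    n, d = src.shape
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    xs = src - mu_s
    xd = dst - mu_d
    var_s = float((xs**2).sum()) / n
    if var_s == 0.0:
        raise ValueError("degenerate moving point set: all points coincide")
    cov = xd.T @ xs / n
    u, s, vt = np.linalg.svd(cov)
    sign = np.ones(d)
    if not allow_reflection and np.linalg.det(u) * np.linalg.det(vt) < 0:
        sign[-1] = -1.0
    R = (u * sign) @ vt
    scale = float((s * sign).sum()) / var_s
    if scale <= 0:
        raise ValueError("estimated scale is non-positive (degenerate geometry)")
    t = mu_d - scale * R @ mu_s
    return SimilarityTransform(scale=scale, orthogonal=R, translation=t)


def register(
    moving: Embedding,
    reference: Embedding,
    allow_reflection: bool = True,
) -> tuple[SimilarityTransform, Embedding]:
    """Align ``moving`` to ``reference`` over corresponding points.

    Both embeddings must share entry count/order (same grid) and
    dimensionality.  Returns the closed-form optimal similarity transform
    and the transformed moving embedding.
    """
    if moving.coords.shape != reference.coords.shape:
        raise ValueError(
            f"shape mismatch: moving {moving.coords.shape} vs "
            f"reference {reference.coords.shape}"
        )
    transform = _umeyama(moving.coords, reference.coords, allow_reflection)
    registered = replace(moving, coords=transform.apply(moving.coords))
    return transform, registered


def pointwise_distances(a: Embedding, b: Embedding) -> np.ndarray:
    """Euclidean distance per corresponding entry pair (registered inputs)."""
    if a.coords.shape != b.coords.shape:
        raise ValueError("embeddings must have identical shape")
    return np.linalg.norm(a.coords - b.coords, axis=1)
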