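"""Similarity matrices and scalar encoding-capability measures.

Encoding capability asks: how distinguishable are dictionary entries from
one another?  The pipeline quantifies it in three steps.

1. A similarity matrix is computed from pairwise Euclidean distances
   S_ij = ||d_i - d_j||_2 and rescaled to S <- 1 - S / max(S), giving unit
   diagonal and values in [0, 1] (1 = identical signals).
2. A tissue slice restricts S to entries sharing one relaxation value, e.g.
   white matter (T2 = 80 ms) or gray matter (T2 = 110 ms); selection happens
   *after* the global rescale.
3. The scalar measure is the normalized l1 distance between the reduced
   matrix and the identity, epsilon = ||I - S||_1 / M.  Lower epsilon means
   stronger diagonal structure, i.e. better encoding.

The l1 norm admits two readings, both implemented: the induced matrix norm
(maximum absolute column sum, the default) and the entrywise mean
sum|I - S| / M^2.  The ``variant`` is recorded with every measure.

Input vectors: high-dimensional dictionary rows are l2-normalized first
("full" source), SVD embedding rows likewise; t-SNE coordinates enter raw.
Because the rescale divides by the global maximum distance and Euclidean
distances are rigid-motion invariant, epsilon is invariant under any
similarity transform of the embedding, so registration does not affect it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .embedding import Embedding, tsne_embed
from .epg import MRFDictionary, RelaxationGrid
from .registration import pointwise_distances, register

__all__ = [
    "SimilarityMatrix",
    "EncodingMeasure",
    "StabilityReport",
    "similarity_matrix",
    "tissue_slice",
    "encoding_epsilon",
    "source_vectors",
    "measure_table",
    "stability_experiment",
    "DEFAULT_TISSUES",
]

#: (axis, value in ms, label): white and gray matter T2 values.
DEFAULT_TISSUES: tuple[tuple[str, float, str], ...] = (
    ("T2", 80.0, "WM"),
    ("T2", 110.0, "GM"),
)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Rescaled pairwise-similarity matrix over a subset of grid entries."""

    values: np.ndarray
    entry_index: np.ndarray
    rescaled: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        idx = np.asarray(self.entry_index, dtype=int)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if idx.shape != (v.shape[0],):
            raise ValueError("entry_index length must match matrix size")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")
        if self.rescaled:
            if not np.allclose(np.diag(v), 1.0):
                raise ValueError("rescaled matrix must have unit diagonal")
            if v.min() < -1e-12 or v.max() > 1 + 1e-12:
                raise ValueError("rescaled values must lie in [0, 1]")
        v.setflags(write=False)
        idx.setflags(write=False)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "entry_index", idx)

    @property
    def size(self) -> int:
        return int(self.values.shape[0])


@dataclass(frozen=True)
class EncodingMeasure:
    """Scalar encoding-capability measure for one tissue slice."""

    epsilon: float
    tissue: str = ""
    fixed_axis: str = ""
    fixed_value: float = float("nan")
    source: str = ""
    norm_variant: str = "induced_l1"


def similarity_matrix(
    vectors: np.ndarray, normalize_rows: bool = False
) -> SimilarityMatrix:
    """Rescaled pairwise-Euclidean similarity of (entries x k) vectors.

    With ``normalize_rows`` each vector is first scaled to unit l2 norm (the
    convention for high-dimensional dictionary rows and SVD scores).  The
    distance matrix is rescaled by its global maximum: S <- 1 - S / max(S).
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D array with at least 2 rows")
    if normalize_rows:
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("cannot normalize: zero-norm row present")
        X = X / norms
    D = squareform(pdist(X))
    dmax = D.max()
    S = np.ones_like(D) if dmax == 0 else 1.0 - D / dmax
    return SimilarityMatrix(
        values=S, entry_index=np.arange(X.shape[0]), rescaled=True
    )


def tissue_slice(
    S: SimilarityMatrix, grid: RelaxationGrid, fix: str, value: float
) -> SimilarityMatrix:
    """Restrict S to entries with T1 or T2 fixed at ``value`` (ms).

    The global rescale is *not* recomputed: selection happens after the
    full-matrix normalization, so slice values remain comparable across
    tissues.  Requires S to cover the full grid.
    """
    if S.size != grid.n_entries:
        raise ValueError("tissue_slice requires a full-grid similarity matrix")
    idx = grid.slice_indices(fix, value)
    return SimilarityMatrix(
        values=S.values[np.ix_(idx, idx)], entry_index=idx, rescaled=True
    )


def encoding_epsilon(
    S_reduced: SimilarityMatrix,
    variant: str = "induced_l1",
    tissue: str = "",
    fixed_axis: str = "",
    fixed_value: float = float("nan"),
    source: str = "",
) -> EncodingMeasure:
    """epsilon = ||I - S||_1 / M for a reduced (tissue-slice) matrix.

    ``induced_l1``: maximum absolute column sum of (I - S), divided by M.
    ``entrywise_mean``: sum of |I - S| divided by M^2.
    Both are zero iff S is the identity.
    """
    A = np.eye(S_reduced.size) - S_reduced.values
    M = S_reduced.size
    if variant == "induced_l1":
        eps = float(np.abs(A).sum(axis=0).max()) / M
    elif variant == "entrywise_mean":
        eps = float(np.abs(A).sum()) / M**2
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return EncodingMeasure(
        epsilon=eps,
        tissue=tissue,
        fixed_axis=fixed_axis,
        fixed_value=fixed_value,
        source=source,
        norm_variant=variant,
    )


def source_vectors(
    dictionary: MRFDictionary, embedding: Embedding | None
) -> tuple[np.ndarray, bool, str]:
    """Vectors entering Eq-style similarity for a measure source.

    Returns (vectors, normalize_rows, source label).  ``embedding=None``
    selects the "full" source: raw dictionary rows, l2-normalized.  SVD
    scores are normalized too; t-SNE coordinates enter raw.
    """
    if embedding is None:
        return dictionary.signals, True, "full"
    label = f"{embedding.method}-{embedding.n_dim}d"
    return embedding.coords, embedding.method == "svd", label


def measure_table(
    dictionary: MRFDictionary,
    embeddings: Sequence[Embedding] = (),
    tissues: Sequence[tuple[str, float, str]] = DEFAULT_TISSUES,
    variant: str = "induced_l1",
    include_full: bool = True,
) -> pd.DataFrame:
    """epsilon per (source, tissue): full dictionary plus each embedding.

    Columns: source, dimensionality, tissue, axis, value_ms, variant,
    epsilon.  Measures are invariant to whether embeddings were registered.
    """
    sources: list[Embedding | None] = ([None] if include_full else []) + list(
        embeddings
    )
    rows = []
    for emb in sources:
        vectors, norm_rows, label = source_vectors(dictionary, emb)
        S = similarity_matrix(vectors, normalize_rows=norm_rows)
        for axis, value, tissue in tissues:
            m = encoding_epsilon(
                tissue_slice(S, dictionary.grid, axis, value),
                variant=variant,
                tissue=tissue,
                fixed_axis=axis,
                fixed_value=value,
                source=label,
            )
            rows.append(
                {
                    "source": label,
                    "dimensionality": len(dictionary.sequence)
                    if emb is None
                    else emb.n_dim,
                    "tissue": tissue,
                    "axis": axis,
                    "value_ms": value,
                    "variant": variant,
                    "epsilon": m.epsilon,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class StabilityReport:
    """Repeated-embedding stability summary.

    ``distances[i]`` holds per-entry distances between run i+2 (registered)
    and the reference run E1; ``e1_nn_distances`` is each E1 point's minimal
    distance to the other E1 points, the natural comparison scale.
    """

    seeds: tuple[int, ...]
    distances: list[np.ndarray]
    e1_nn_distances: np.ndarray
    percentiles: pd.DataFrame = field(repr=False)

    @property
    def median_registered_distance(self) -> float:
        return float(np.median(np.concatenate(self.distances)))

    @property
    def median_e1_nn_distance(self) -> float:
        return float(np.median(self.e1_nn_distances))


def stability_experiment(
    dictionary: MRFDictionary,
    seeds: Sequence[int],
    n_dim: int = 2,
    perplexity: float | None = None,
    n_iter: int = 1000,
    reference: Embedding | None = None,
) -> StabilityReport:
    """Embed repeatedly, register runs 2..n to run 1, summarize distances.

    The first seed's embedding is the reference E1 (or pass a precomputed
    ``reference`` for the first seed).  Reports per-run distributions of
    point-wise distances after registration, alongside the distribution of
    E1's internal nearest-neighbor distances.
    """
    seeds = tuple(int(s) for s in seeds)
    if len(seeds) < 2:
        raise ValueError("stability experiment needs at least 2 runs")
    e1 = reference
    if e1 is None:
        e1 = tsne_embed(
            dictionary,
            n_dim=n_dim,
            perplexity=perplexity,
            n_iter=n_iter,
            seed=seeds[0],
        )
    distances = []
    for s in seeds[1:]:
        emb = tsne_embed(
            dictionary, n_dim=n_dim, perplexity=perplexity, n_iter=n_iter, seed=s
        )
        _, registered = register(emb, e1)
        distances.append(pointwise_distances(registered, e1))

    D = squareform(pdist(e1.coords))
    np.fill_diagonal(D, np.inf)
    e1_nn = D.min(axis=1)

    qs = [5, 25, 50, 75, 95]
    rows = [
        {"run": f"seed={s}", **{f"p{q}": np.percentile(d, q) for q in qs}}
        for s, d in zip(seeds[1:], distances)
    ]
    rows.append({"run": "E1-nn", **{f"p{q}": np.percentile(e1_nn, q) for q in qs}})
    return StabilityReport(
        seeds=seeds,
        distances=distances,
        e1_nn_distances=e1_nn,
        percentiles=pd.DataFrame(rows),
    )
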