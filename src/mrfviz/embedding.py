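"""Dimensionality reduction of MRF dictionaries: t-SNE and truncated SVD.

Each dictionary entry (a length-L signal evolution) is reduced to an
n-dimensional coordinate.  t-SNE preserves local neighborhood structure and
is the nonlinear workhorse here: Barnes-Hut gradients for n <= 3 output
dimensions, exact gradients above (tree-based engines only support up to 3
output dimensions).  Truncated SVD provides the linear baseline: entries are
projected onto the top right-singular vectors of the signal matrix.

Signal rows enter both reducers raw - no Z-scoring or other standardization.
t-SNE runs are initialized from PCA coordinates and iterated a fixed number
of times for reproducibility under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any

import h5py
import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .epg import MRFDictionary, RelaxationGrid

__all__ = [
    "Embedding",
    "tsne_embed",
    "svd_embed",
    "dimensionality_sweep",
    "save_embedding",
    "load_embedding",
]

DEFAULT_PERPLEXITY_2D = 750.0
DEFAULT_PERPLEXITY_3D = 200.0
DEFAULT_N_ITER = 1000


@dataclass(frozen=True)
class Embedding:
    """Low-dimensional coordinates of dictionary entries.

    ``coords`` is (n_entries, n_dim); ``params`` records everything needed
    to reproduce the run (perplexity, iterations, seed, init, engine).
    """

    coords: np.ndarray
    method: str  # "tsne" or "svd"
    grid: RelaxationGrid | None = None
    params: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2:
            raise ValueError("coords must be 2-D (entries x n_dim)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords must be finite")
        if self.grid is not None and coords.shape[0] != self.grid.n_entries:
            raise ValueError("row count does not match grid entry count")
        coords.setflags(write=False)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "params", dict(self.params or {}))

    @property
    def n_dim(self) -> int:
        return int(self.coords.shape[1])

    @property
    def n_entries(self) -> int:
        return int(self.coords.shape[0])


def _default_perplexity(n_dim: int) -> float:
    return DEFAULT_PERPLEXITY_2D if n_dim == 2 else DEFAULT_PERPLEXITY_3D


def tsne_embed(
    dictionary: MRFDictionary,
    n_dim: int = 2,
    perplexity: float | None = None,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
) -> Embedding:
    """Embed dictionary rows with t-SNE (PCA init, fixed iteration count).

    Defaults: perplexity 750 for 2D, 200 otherwise.  Barnes-Hut gradients
    are used for n_dim <= 3, the exact gradient above; the engine used is
    recorded in ``Embedding.params['engine']``.  Deterministic for a fixed
    seed and library version.

    The gradient descent itself is deterministic, so the seed enters through
    a small Gaussian jitter (1% of the init scale) added to the PCA
    initialization; this emulates the intrinsic run-to-run stochasticity of
    t-SNE that the stability experiment probes.
    """
    X = dictionary.signals
    n_entries, L = X.shape
    if not 1 <= n_dim < L:
        raise ValueError(f"n_dim must be in [1, {L})")
    if perplexity is None:
        perplexity = _default_perplexity(n_dim)
    if not 0 < perplexity < n_entries:
        raise ValueError(
            f"perplexity must be in (0, {n_entries}) for {n_entries} entries"
        )
    engine = "barnes_hut" if n_dim <= 3 else "exact"
    # PCA init scaled to std 1e-4 on the first component (the conventional
    # scale), plus seeded jitter so distinct seeds give distinct runs.
    init = PCA(n_components=n_dim, random_state=0).fit_transform(X)
    init = init / np.std(init[:, 0]) * 1e-4
    init = init + np.random.default_rng(seed).normal(scale=1e-6, size=init.shape)
    tsne = TSNE(
        n_components=n_dim,
        perplexity=perplexity,
        max_iter=n_iter,
        init=init,
        method=engine,
        random_state=seed,
    )
    coords = tsne.fit_transform(X)
    return Embedding(
        coords=coords,
        method="tsne",
        grid=dictionary.grid,
        params={
            "perplexity": float(perplexity),
            "n_iter": int(n_iter),
            "seed": int(seed),
            "init": "pca",
            "engine": f"sklearn/{engine}",
            "angle": 0.5,
        },
    )


def svd_embed(dictionary: MRFDictionary, n_dim: int) -> Embedding:
    """Project entries onto the top ``n_dim`` right-singular vectors.

    Scores are U*Sigma truncated to n_dim columns.  The per-component sign
    is fixed by requiring the largest-magnitude loading of each right
    singular vector to be positive, so results are fully deterministic and
    lower-dimensional scores nest inside higher-dimensional ones.
    """
    X = dictionary.signals
    rank = min(X.shape)
    if not 1 <= n_dim <= rank:
        raise ValueError(f"n_dim must be in [1, {rank}] (matrix rank bound)")
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    # Sign convention: largest-|loading| component of each singular vector > 0.
    flip = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    scores = (u * s) * flip
    return Embedding(
        coords=scores[:, :n_dim],
        method="svd",
        grid=dictionary.grid,
        params={"sign_convention": "largest-loading-positive"},
    )


def dimensionality_sweep(
    dictionary: MRFDictionary,
    dims: list[int],
    method: str = "tsne",
    **kwargs: Any,
) -> list[Embedding]:
    """One embedding per requested dimensionality, shared seed policy.

    For t-SNE the engine switches automatically between Barnes-Hut (<= 3D)
    and exact gradients (> 3D); which one ran is recorded per embedding.
    """
    if method == "tsne":
        return [tsne_embed(dictionary, n_dim=d, **kwargs) for d in dims]
    if method == "svd":
        return [svd_embed(dictionary, n_dim=d) for d in dims]
    raise ValueError(f"unknown method {method!r}")


def save_embedding(embedding: Embedding, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("coords", data=embedding.coords)
        f.attrs["method"] = embedding.method
        f.attrs["n_dim"] = embedding.n_dim
        for k, v in (embedding.params or {}).items():
            f.attrs[f"param_{k}"] = v
        if embedding.grid is not None:
            g = f.create_group("grid")
            g.create_dataset("t1", data=embedding.grid.t1_values)
            g.create_dataset("t2", data=embedding.grid.t2_values)


def load_embedding(path: str | Path) -> Embedding:
    with h5py.File(path, "r") as f:
        coords = f["coords"][()]
        method = str(f.attrs["method"])
        params = {
            k[len("param_"):]: v for k, v in f.attrs.items() if k.startswith("param_")
        }
        grid = None
        if "grid" in f:
            grid = RelaxationGrid(t1_values=f["grid/t1"][()], t2_values=f["grid/t2"][()])
    return Embedding(coords=coords, method=method, grid=grid, params=params)
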