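"""Color-coding of embeddings via CIE L*a*b* and (T1, T2) dictionary maps.

Embedding coordinates become colors through an affine map into the CIE
L*a*b* space: for 2D embeddings the two axes map to (a*, b*) with a fixed
lightness L*; for 3D the axes map to (L*, a*, b*).  The affine map is
anchored to the bounding box of a reference embedding, so embeddings
registered to a common reference share one color frame and identical
coordinates receive identical colors across maps - the basis of visual
comparison between dictionaries.

Colors are rasterized back into the (T1, T2) plane as a color-coded
dictionary map, with the unsampled T1 <= T2 triangle masked out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.color import lab2rgb

from .embedding import Embedding
from .epg import RelaxationGrid

__all__ = [
    "LabFrame",
    "DictionaryColorMap",
    "embed_to_lab",
    "lab_to_srgb",
    "render_dictionary_map",
]

MASK_GRAY = 0.85  # fill value for the unsampled T1 <= T2 triangle


@dataclass(frozen=True)
class LabFrame:
    """Affine map from embedding coordinates into CIE L*a*b*.

    ``lo``/``hi`` are per-axis bounds of the reference embedding; coordinates
    at the bounds land on the configured Lab extremes, and points outside are
    extrapolated affinely (gamut overflow is clipped later in sRGB).
    """

    lo: np.ndarray
    hi: np.ndarray
    l_fixed: float = 70.0  # lightness for 2D embeddings
    l_range: tuple[float, float] = (25.0, 90.0)  # lightness span for 3D
    ab_range: tuple[float, float] = (-80.0, 80.0)

    def __post_init__(self) -> None:
        lo = np.asarray(self.lo, dtype=float)
        hi = np.asarray(self.hi, dtype=float)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("lo and hi must be 1-D arrays of equal length")
        if np.any(hi <= lo):
            raise ValueError("hi must exceed lo on every axis")
        lo.setflags(write=False)
        hi.setflags(write=False)
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)

    @classmethod
    def from_embedding(cls, reference: Embedding, **kwargs) -> "LabFrame":
        coords = reference.coords
        return cls(lo=coords.min(axis=0), hi=coords.max(axis=0), **kwargs)

    def unit(self, coords: np.ndarray) -> np.ndarray:
        return (coords - self.lo) / (self.hi - self.lo)


def embed_to_lab(embedding: Embedding, frame: LabFrame | None = None) -> np.ndarray:
    """Map 2D/3D embedding coordinates to (L*, a*, b*) triplets.

    2D: (x, y) -> (a*, b*) over the configured range with fixed L*.
    3D: axes -> (L*, a*, b*).  Pass the reference's ``frame`` so registered
    embeddings share one color mapping; defaults to the embedding's own box.
    """
    if embedding.n_dim not in (2, 3):
        raise ValueError("color-coding supports only 2-D and 3-D embeddings")
    if frame is None:
        frame = LabFrame.from_embedding(embedding)
    if frame.lo.size != embedding.n_dim:
        raise ValueError("frame dimensionality does not match embedding")
    u = frame.unit(embedding.coords)
    ab_lo, ab_hi = frame.ab_range
    lab = np.empty((embedding.n_entries, 3))
    if embedding.n_dim == 2:
        lab[:, 0] = frame.l_fixed
        lab[:, 1] = ab_lo + (ab_hi - ab_lo) * u[:, 0]
        lab[:, 2] = ab_lo + (ab_hi - ab_lo) * u[:, 1]
    else:
        l_lo, l_hi = frame.l_range
        lab[:, 0] = l_lo + (l_hi - l_lo) * u[:, 0]
        lab[:, 1] = ab_lo + (ab_hi - ab_lo) * u[:, 1]
        lab[:, 2] = ab_lo + (ab_hi - ab_lo) * u[:, 2]
    return lab


def lab_to_srgb(lab: np.ndarray) -> np.ndarray:
    """Standard CIE L*a*b* -> sRGB (D65), out-of-gamut channels clipped to [0,1]."""
    lab = np.asarray(lab, dtype=float)
    if not np.all(np.isfinite(lab)):
        raise ValueError("Lab values must be finite")
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*out of range.*")
        rgb = lab2rgb(lab.reshape(-1, 1, 3)).reshape(lab.shape)
    return np.clip(rgb, 0.0, 1.0)


@dataclass(frozen=True)
class DictionaryColorMap:
    """Color-coded dictionary map in the (T1, T2) plane.

    ``rgb`` is an (n_T2, n_T1, 3) raster with T1 ascending along columns and
    T2 ascending along rows (plot with ``origin='lower'`` so T2 increases
    bottom to top, leaving the masked triangle at the bottom).  ``mask`` is
    True on unsampled cells (T1 <= T2), which are filled light gray.
    """

    rgb: np.ndarray
    mask: np.ndarray
    lab: np.ndarray  # per-entry (L*, a*, b*)
    colors: np.ndarray  # per-entry sRGB
    grid: RelaxationGrid

    def save_png(self, path: str | Path) -> None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        g = self.grid
        fig, ax = plt.subplots(figsize=(6, 3.2))
        ax.imshow(
            self.rgb,
            origin="lower",
            aspect="auto",
            extent=(
                g.t1_values[0],
                g.t1_values[-1],
                g.t2_values[0],
                g.t2_values[-1],
            ),
            interpolation="nearest",
        )
        ax.set_xlabel("$T_1$ (ms)")
        ax.set_ylabel("$T_2$ (ms)")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)

    def export_csv(self, path: str | Path) -> None:
        import pandas as pd

        g = self.grid
        pd.DataFrame(
            {
                "T1_ms": g.entries[:, 0],
                "T2_ms": g.entries[:, 1],
                "L": self.lab[:, 0],
                "a": self.lab[:, 1],
                "b": self.lab[:, 2],
                "R": self.colors[:, 0],
                "G": self.colors[:, 1],
                "B": self.colors[:, 2],
            }
        ).to_csv(path, index=False)


def render_dictionary_map(
    colors: np.ndarray,
    grid: RelaxationGrid,
    lab: np.ndarray | None = None,
) -> DictionaryColorMap:
    """Rasterize per-entry sRGB colors into the (T1, T2) plane."""
    colors = np.asarray(colors, dtype=float)
    if colors.shape != (grid.n_entries, 3):
        raise ValueError(
            f"expected one color per grid entry: {(grid.n_entries, 3)}, "
            f"got {colors.shape}"
        )
    n_t1 = grid.t1_values.size
    n_t2 = grid.t2_values.size
    rgb = np.full((n_t2, n_t1, 3), MASK_GRAY)
    mask = np.ones((n_t2, n_t1), dtype=bool)
    t1_pos = {v: i for i, v in enumerate(grid.t1_values)}
    t2_pos = {v: i for i, v in enumerate(grid.t2_values)}
    for k, (t1, t2) in enumerate(grid.entries):
        r, c = t2_pos[t2], t1_pos[t1]
        rgb[r, c] = colors[k]
        mask[r, c] = False
    if lab is None:
        lab = np.full((grid.n_entries, 3), np.nan)
    return DictionaryColorMap(rgb=rgb, mask=mask, lab=lab, colors=colors, grid=grid)
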