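"""Extended-phase-graph (EPG) simulation of unbalanced FISP MRF signals.

The EPG formalism tracks discrete magnetization configuration states
(F+_k, F-_k, Z_k) indexed by gradient dephasing order k.  Each repetition of
an unbalanced FISP sequence applies an RF rotation, records the k=0
transverse amplitude as the acquired signal, relaxes the states over TR with
E1 = exp(-TR/T1) and E2 = exp(-TR/T2), regrows Z_0 toward unit equilibrium,
and shifts the transverse states by one dephasing order (ideal spoiling).

RF pulses are applied with a constant 90-degree phase (rotation about the
y axis), which keeps all configuration amplitudes real: the recorded signal
is the signed real F+_0 amplitude immediately after each pulse, with no TE
decay.  An optional inversion pulse (instantaneous 180-degree rotation)
precedes the train, followed by a configurable recovery delay ``ti_ms``
(default: one TR) before the first excitation.

Dictionaries are simulated over a rectilinear (T1, T2) grid restricted to
physically meaningful combinations with T1 > T2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .sequences import FlipAngleSequence

__all__ = [
    "RelaxationGrid",
    "MRFDictionary",
    "make_grid",
    "simulate_signal",
    "build_dictionary",
    "save_dictionary",
    "load_dictionary",
]

#: Maximum number of retained dephasing orders.  High orders carry vanishing
#: amplitude under T2 relaxation, so truncation error is negligible for
#: realistic relaxation times; configurable per call.
DEFAULT_MAX_ORDERS = 101


def _axis_values(start: float, stop: float, step: float) -> np.ndarray:
    if step <= 0:
        raise ValueError("step must be positive")
    if stop < start:
        raise ValueError("stop must be >= start")
    n = int(np.floor((stop - start) / step + 1e-9)) + 1
    return start + step * np.arange(n)


@dataclass(frozen=True)
class RelaxationGrid:
    """Rectilinear (T1, T2) grid filtered to T1 > T2.

    Entries are ordered lexicographically by (T2, T1): all T1 values for the
    smallest T2 first, in ascending T1.  Fixed-T2 tissue slices are therefore
    contiguous blocks of the entry list.
    """

    t1_values: np.ndarray
    t2_values: np.ndarray
    entries: np.ndarray = field(init=False)  # (n_entries, 2) columns (T1, T2)

    def __post_init__(self) -> None:
        t1 = np.asarray(self.t1_values, dtype=float)
        t2 = np.asarray(self.t2_values, dtype=float)
        for name, ax in (("t1_values", t1), ("t2_values", t2)):
            if ax.ndim != 1 or ax.size == 0:
                raise ValueError(f"{name} must be a non-empty 1-D array")
            if np.any(np.diff(ax) <= 0):
                raise ValueError(f"{name} must be strictly ascending")
            if ax.min() <= 0:
                raise ValueError(f"{name} must be positive")
        pairs = [(float(a), float(b)) for b in t2 for a in t1 if a > b]
        if not pairs:
            raise ValueError("grid is empty after applying the T1 > T2 filter")
        entries = np.array(pairs)
        for arr in (t1, t2, entries):
            arr.setflags(write=False)
        object.__setattr__(self, "t1_values", t1)
        object.__setattr__(self, "t2_values", t2)
        object.__setattr__(self, "entries", entries)

    @property
    def n_entries(self) -> int:
        return int(self.entries.shape[0])

    def entry_index(self, t1: float, t2: float) -> int:
        """Position of the entry with the given (T1, T2), or ``KeyError``."""
        hit = np.flatnonzero(
            np.isclose(self.entries[:, 0], t1) & np.isclose(self.entries[:, 1], t2)
        )
        if hit.size != 1:
            raise KeyError(f"({t1}, {t2}) is not a grid entry")
        return int(hit[0])

    def slice_indices(self, fix: str, value: float) -> np.ndarray:
        """Entry positions with T1 (``fix='T1'``) or T2 (``'T2'``) fixed."""
        col = {"T1": 0, "T2": 1}.get(fix.upper())
        if col is None:
            raise ValueError("fix must be 'T1' or 'T2'")
        axis = self.t1_values if col == 0 else self.t2_values
        if not np.any(np.isclose(axis, value)):
            raise ValueError(f"{fix}={value} ms is not on the grid axis")
        return np.flatnonzero(np.isclose(self.entries[:, col], value))


def make_grid(
    t1_start: float,
    t1_stop: float,
    t1_step: float,
    t2_start: float,
    t2_stop: float,
    t2_step: float,
) -> RelaxationGrid:
    """Build a grid from inclusive range specs (ms), filtering to T1 > T2."""
    return RelaxationGrid(
        t1_values=_axis_values(t1_start, t1_stop, t1_step),
        t2_values=_axis_values(t2_start, t2_stop, t2_step),
    )


def _epg_fisp(
    t1: np.ndarray,
    t2: np.ndarray,
    seq: FlipAngleSequence,
    ti_ms: float | None,
    max_orders: int,
) -> np.ndarray:
    """Vectorized EPG kernel: returns (n_entries, L) real signal matrix."""
    t1 = np.atleast_1d(np.asarray(t1, dtype=float))
    t2 = np.atleast_1d(np.asarray(t2, dtype=float))
    if np.any(t1 <= 0) or np.any(t2 <= 0):
        raise ValueError("relaxation times must be positive")
    L = len(seq)
    n = t1.size
    K = min(L + 1, max_orders)  # retained dephasing orders 0..K-1
    tr = seq.tr_ms
    e1 = np.exp(-tr / t1)
    e2 = np.exp(-tr / t2)

    fp = np.zeros((K, n))
    fm = np.zeros((K, n))
    z = np.zeros((K, n))
    z[0] = 1.0

    if seq.inversion:
        z *= -1.0  # instantaneous 180-degree rotation
        ti = tr if ti_ms is None else float(ti_ms)
        if ti < 0:
            raise ValueError("ti_ms must be non-negative")
        z *= np.exp(-ti / t1)
        z[0] += 1.0 - np.exp(-ti / t1)

    alphas = np.deg2rad(seq.angles)
    signal = np.empty((n, L))
    for i, a in enumerate(alphas):
        # RF rotation about the y axis (90-degree phase): real-valued mixing.
        ca, sa = np.cos(a / 2.0) ** 2, np.sin(a / 2.0) ** 2
        s, c = np.sin(a), np.cos(a)
        fp_new = ca * fp - sa * fm + s * z
        fm_new = -sa * fp + ca * fm + s * z
        z_new = -0.5 * s * fp - 0.5 * s * fm + c * z
        fp, fm, z = fp_new, fm_new, z_new

        signal[:, i] = fp[0]

        # Relaxation over TR with Z0 regrowth toward unit equilibrium.
        fp *= e2
        fm *= e2
        z *= e1
        z[0] += 1.0 - e1

        # Unbalanced gradient: shift transverse states by one order.
        fp[1:] = fp[:-1]
        fm[:-1] = fm[1:]
        fm[-1] = 0.0
        fp[0] = fm[0]  # F+_0 = conj(F-_0); states are real here
    return signal


def simulate_signal(
    t1: float,
    t2: float,
    seq: FlipAngleSequence,
    ti_ms: float | None = None,
    max_orders: int = DEFAULT_MAX_ORDERS,
) -> np.ndarray:
    """Simulate one signed real signal evolution of length ``len(seq)``.

    T2 > T1 is permitted here; the physical constraint is enforced by the
    grid, not by the kernel.
    """
    return _epg_fisp(np.array([t1]), np.array([t2]), seq, ti_ms, max_orders)[0]


@dataclass(frozen=True)
class MRFDictionary:
    """Simulated signal evolutions bound to a relaxation grid.

    ``signals`` has one row per grid entry (ordered as ``grid.entries``) and
    one column per excitation.  ``normalized`` records whether rows carry
    unit Euclidean norm.
    """

    signals: np.ndarray
    grid: RelaxationGrid
    sequence: FlipAngleSequence
    normalized: bool = False
    ti_ms: float | None = None

    def __post_init__(self) -> None:
        sig = np.asarray(self.signals, dtype=float)
        if sig.shape != (self.grid.n_entries, len(self.sequence)):
            raise ValueError(
                f"signals shape {sig.shape} does not match "
                f"(entries, L) = ({self.grid.n_entries}, {len(self.sequence)})"
            )
        if self.normalized:
            norms = np.linalg.norm(sig, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ValueError("normalized flag set but rows are not unit norm")
        sig.setflags(write=False)
        object.__setattr__(self, "signals", sig)

    def normalized_copy(self) -> "MRFDictionary":
        """Return a copy with each signal row scaled to unit Euclidean norm."""
        if self.normalized:
            return self
        norms = np.linalg.norm(self.signals, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("cannot normalize: zero-norm signal row present")
        return MRFDictionary(
            signals=self.signals / norms,
            grid=self.grid,
            sequence=self.sequence,
            normalized=True,
            ti_ms=self.ti_ms,
        )


def build_dictionary(
    grid: RelaxationGrid,
    seq: FlipAngleSequence,
    normalize: bool = False,
    ti_ms: float | None = None,
    max_orders: int = DEFAULT_MAX_ORDERS,
) -> MRFDictionary:
    """Simulate one signal row per grid entry (vectorized over entries)."""
    signals = _epg_fisp(grid.entries[:, 0], grid.entries[:, 1], seq, ti_ms, max_orders)
    d = MRFDictionary(signals=signals, grid=grid, sequence=seq, ti_ms=ti_ms)
    return d.normalized_copy() if normalize else d


def save_dictionary(dictionary: MRFDictionary, path: str | Path) -> None:
    """Write dictionary, grid and sequence to one HDF5 file (lossless)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=dictionary.signals)
        g = f.create_group("grid")
        g.create_dataset("t1", data=dictionary.grid.t1_values)
        g.create_dataset("t2", data=dictionary.grid.t2_values)
        g.create_dataset("entries", data=dictionary.grid.entries)
        s = f.create_group("sequence")
        s.create_dataset("angles", data=dictionary.sequence.angles)
        f.attrs["tr_ms"] = dictionary.sequence.tr_ms
        f.attrs["inversion"] = int(dictionary.sequence.inversion)
        f.attrs["label"] = dictionary.sequence.label
        f.attrs["normalized"] = int(dictionary.normalized)
        f.attrs["ti_ms"] = -1.0 if dictionary.ti_ms is None else dictionary.ti_ms


def load_dictionary(path: str | Path) -> MRFDictionary:
    """Load a dictionary written by :func:`save_dictionary`."""
    with h5py.File(path, "r") as f:
        try:
            signals = f["signals"][()]
            grid = RelaxationGrid(
                t1_values=f["grid/t1"][()], t2_values=f["grid/t2"][()]
            )
            stored_entries = f["grid/entries"][()]
            seq = FlipAngleSequence(
                angles=f["sequence/angles"][()],
                tr_ms=float(f.attrs["tr_ms"]),
                inversion=bool(f.attrs["inversion"]),
                label=str(f.attrs["label"]),
            )
            ti = float(f.attrs["ti_ms"])
            normalized = bool(f.attrs["normalized"])
        except KeyError as exc:
            raise ValueError(f"{path}: missing dataset/attribute: {exc}") from exc
    if not np.array_equal(stored_entries, grid.entries):
        raise ValueError(f"{path}: stored entry list does not match grid spec")
    return MRFDictionary(
        signals=signals,
        grid=grid,
        sequence=seq,
        normalized=normalized,
        ti_ms=None if ti < 0 else ti,
    )
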