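"""Flip-angle train containers, synthetic sequence archetypes and CSV I/O.

An MRF acquisition is defined by its excitation flip-angle train: a list of
RF flip angles (degrees), a constant repetition time TR (ms), and optionally
an initial 180-degree inversion pulse that boosts T1 encoding.  Two synthetic
archetypes are provided for exercising the pipeline without external data:

* a smoothly varying train of repeating half-sinusoid lobes with slowly
  drifting per-lobe maxima (the "smooth sinusoidal" style used by many
  FISP-MRF protocols), and
* a jagged train of i.i.d. uniform random angles (the "random" style).

An iteration-series generator produces an ordered family of trains that
interpolate from a flat low-contrast train toward a fully structured one,
emulating the successive iterates of a sequence-optimization loop.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "FlipAngleSequence",
    "jiang_like_pattern",
    "sommer_like_pattern",
    "without_inversion",
    "iteration_series",
    "read_sequence",
    "write_sequence",
]

DEFAULT_TR_MS = 15.0
DEFAULT_LENGTH = 1000


@dataclass(frozen=True)
class FlipAngleSequence:
    """An excitation train: flip angles in degrees plus timing metadata.

    Parameters
    ----------
    angles:
        Flip angles in degrees, one per excitation, each in [0, 180].
    tr_ms:
        Constant repetition time in milliseconds, > 0.
    inversion:
        Whether a 180-degree inversion pulse precedes the train.
    label:
        Free-text identifier used in file names and tables.
    """

    angles: np.ndarray
    tr_ms: float = DEFAULT_TR_MS
    inversion: bool = True
    label: str = ""

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles, dtype=float)
        if angles.ndim != 1 or angles.size < 1:
            raise ValueError("angles must be a non-empty 1-D array")
        if np.any(~np.isfinite(angles)):
            raise ValueError("angles must be finite")
        if angles.min() < 0.0 or angles.max() > 180.0:
            raise ValueError("flip angles must lie in [0, 180] degrees")
        if not self.tr_ms > 0:
            raise ValueError("tr_ms must be positive")
        angles.setflags(write=False)
        object.__setattr__(self, "angles", angles)

    def __len__(self) -> int:
        return int(self.angles.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FlipAngleSequence):
            return NotImplemented
        return (
            np.array_equal(self.angles, other.angles)
            and self.tr_ms == other.tr_ms
            and self.inversion == other.inversion
            and self.label == other.label
        )


def jiang_like_pattern(
    length: int = DEFAULT_LENGTH,
    seed: int = 0,
    tr_ms: float = DEFAULT_TR_MS,
    n_lobes: int | None = None,
) -> FlipAngleSequence:
    """Smooth train of half-sinusoid lobes with slowly varying maxima.

    Lobe maxima drift in roughly the 10-70 degree band; adjacent angles never
    jump by more than a few degrees, mimicking smoothly designed FISP-MRF
    trains.  Lobes span ~200 excitations by default (``n_lobes`` overrides).
    Deterministic for a fixed ``seed``; inversion pulse enabled.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    if n_lobes is None:
        n_lobes = max(1, length // 200)
    lobe_len = int(np.ceil(length / n_lobes))
    phase = rng.uniform(0, 2 * np.pi)
    jitter = rng.uniform(-5.0, 5.0, size=n_lobes)
    angles = np.empty(length)
    for m in range(n_lobes):
        peak = 40.0 + 25.0 * np.sin(2 * np.pi * m / max(n_lobes, 2) + phase)
        peak = float(np.clip(peak + jitter[m], 10.0, 70.0))
        i0 = m * lobe_len
        i1 = min(length, i0 + lobe_len)
        u = (np.arange(i0, i1) - i0 + 0.5) / lobe_len
        angles[i0:i1] = peak * np.sin(np.pi * u)
    return FlipAngleSequence(
        angles=np.clip(angles, 0.0, 180.0),
        tr_ms=tr_ms,
        inversion=True,
        label=f"jiang-like-s{seed}",
    )


def sommer_like_pattern(
    length: int = DEFAULT_LENGTH,
    seed: int = 0,
    low: float = 0.0,
    high: float = 70.0,
    tr_ms: float = DEFAULT_TR_MS,
) -> FlipAngleSequence:
    """Jagged train of i.i.d. uniform flip angles in ``[low, high]`` degrees."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0.0 <= low <= high <= 180.0):
        raise ValueError("angle range must satisfy 0 <= low <= high <= 180")
    rng = np.random.default_rng(seed)
    angles = rng.uniform(low, high, size=length)
    return FlipAngleSequence(
        angles=angles, tr_ms=tr_ms, inversion=True, label=f"sommer-like-s{seed}"
    )


def without_inversion(seq: FlipAngleSequence) -> FlipAngleSequence:
    """Return the same train with the inversion pulse removed (idempotent)."""
    if not seq.inversion:
        return seq
    return replace(seq, inversion=False, label=seq.label + "-noinv")


def iteration_series(
    n_iters: int = 5,
    seed: int = 0,
    length: int = DEFAULT_LENGTH,
    tr_ms: float = DEFAULT_TR_MS,
) -> list[FlipAngleSequence]:
    """Ordered family of trains emulating successive optimizer iterates.

    Iterate 1 is a nearly flat, low-contrast train; later iterates blend
    linearly toward a structured sinusoidal-lobe train of growing amplitude,
    so encoding capability sharpens along the series.  All iterates keep the
    inversion pulse.
    """
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    base = np.full(length, 12.0)
    # Fixed 5-lobe target: a short series keeps the same contrast structure
    # regardless of train length, so epsilon sharpens monotonically.
    target = jiang_like_pattern(length, seed=seed, tr_ms=tr_ms, n_lobes=5).angles
    out: list[FlipAngleSequence] = []
    for i in range(n_iters):
        w = i / max(n_iters - 1, 1)
        angles = (1.0 - w) * base + w * target
        out.append(
            FlipAngleSequence(
                angles=angles,
                tr_ms=tr_ms,
                inversion=True,
                label=f"opt-iter{i + 1}-s{seed}",
            )
        )
    return out


def write_sequence(seq: FlipAngleSequence, path: str | Path) -> None:
    """Write a train as CSV: ``# key=value`` header lines, one angle per row."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# tr_ms={float(seq.tr_ms)!r}\n")
        fh.write(f"# inversion={int(seq.inversion)}\n")
        if seq.label:
            fh.write(f"# label={seq.label}\n")
        for a in seq.angles:
            fh.write(f"{float(a)!r}\n")


def read_sequence(path: str | Path) -> FlipAngleSequence:
    """Read a train written by :func:`write_sequence` (round-trip identity)."""
    path = Path(path)
    tr_ms: float | None = None
    inversion: bool | None = None
    label = ""
    angles: list[float] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" not in body:
                raise ValueError(f"{path}:{lineno}: malformed header line {raw!r}")
            key, value = (s.strip() for s in body.split("=", 1))
            if key == "tr_ms":
                tr_ms = float(value)
            elif key == "inversion":
                inversion = bool(int(value))
            elif key == "label":
                label = value
            else:
                raise ValueError(f"{path}:{lineno}: unknown header key {key!r}")
        else:
            try:
                angles.append(float(line))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad angle {line!r}") from exc
    if tr_ms is None or inversion is None:
        raise ValueError(f"{path}: missing tr_ms or inversion header")
    if not angles:
        raise ValueError(f"{path}: no flip angles found")
    return FlipAngleSequence(
        angles=np.array(angles), tr_ms=tr_ms, inversion=inversion, label=label
    )
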