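"""Haplotype mosaics: piecewise-constant founder labels along a chromosome.

A :class:`Mosaic` maps every bp of ``[0, length)`` to an integer founder
code.  It is the ground-truth currency of the breeding simulator and is kept
deliberately small: two parallel arrays, segment end positions (half-open)
and segment labels.
"""

from __future__ import annotations

import numpy as np


class Mosaic:
    """Piecewise-constant label function on ``[0, length)``.

    ``ends`` are strictly increasing segment end positions with
    ``ends[-1] == length``; segment ``i`` covers ``[ends[i-1], ends[i])``
    (with ``ends[-1]`` meaning position 0 for ``i == 0``) and carries
    ``labels[i]``.
    """

    __slots__ = ("ends", "labels")

    def __init__(self, ends: np.ndarray, labels: np.ndarray, *, validate: bool = True):
        self.ends = np.asarray(ends, dtype=np.int64)
        self.labels = np.asarray(labels, dtype=np.int16)
        if validate:
            if self.ends.ndim != 1 or self.ends.shape != self.labels.shape:
                raise ValueError("ends and labels must be 1-D and equal length")
            if len(self.ends) == 0:
                raise ValueError("empty mosaic")
            if np.any(np.diff(self.ends) <= 0) or self.ends[0] <= 0:
                raise ValueError("segment ends must be strictly increasing and positive")

    @classmethod
    def constant(cls, length: int, label: int) -> "Mosaic":
        return cls(np.array([length], dtype=np.int64),
                   np.array([label], dtype=np.int16), validate=False)

    @property
    def length(self) -> int:
        return int(self.ends[-1])

    @property
    def starts(self) -> np.ndarray:
        return np.concatenate(([0], self.ends[:-1]))

    def simplify(self) -> "Mosaic":
        """Merge adjacent segments with equal labels (canonical form)."""
        if len(self.labels) == 1:
            return self
        keep = np.concatenate((self.labels[:-1] != self.labels[1:], [True]))
        if keep.all():
            return self
        return Mosaic(self.ends[keep], self.labels[keep], validate=False)

    def label_at(self, pos) -> np.ndarray:
        """Labels at bp position(s) (0-based)."""
        idx = np.searchsorted(self.ends, np.asarray(pos), side="right")
        return self.labels[idx]

    def breakpoints(self) -> np.ndarray:
        """bp positions where the label changes (junctions between founders)."""
        s = self.simplify()
        return s.ends[:-1].copy()

    def restrict(self, lo: int, hi: int) -> tuple[np.ndarray, np.ndarray]:
        """Segments of the restriction to ``[lo, hi)`` as (ends, labels)."""
        i0 = int(np.searchsorted(self.ends, lo, side="right"))
        i1 = int(np.searchsorted(self.ends, hi, side="left"))
        ends = np.minimum(self.ends[i0:i1 + 1], hi)
        return ends, self.labels[i0:i1 + 1]

    def replace(self, lo: int, hi: int, label: int) -> "Mosaic":
        """New mosaic with ``[lo, hi)`` set to ``label``."""
        if not (0 <= lo < hi <= self.length):
            raise ValueError(f"interval [{lo}, {hi}) outside [0, {self.length})")
        left_e, left_l = self.restrict(0, lo) if lo > 0 else (np.empty(0, np.int64),
                                                             np.empty(0, np.int16))
        right_e, right_l = self.restrict(hi, self.length) if hi < self.length else (
            np.empty(0, np.int64), np.empty(0, np.int16))
        ends = np.concatenate((left_e, [hi], right_e))
        labels = np.concatenate((left_l, [label], right_l))
        return Mosaic(ends, labels, validate=False).simplify()

    def equal(self, other: "Mosaic") -> bool:
        a, b = self.simplify(), other.simplify()
        return (a.ends.shape == b.ends.shape and np.array_equal(a.ends, b.ends)
                and np.array_equal(a.labels, b.labels))

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        segs = ", ".join(f"[{s},{e}):{l}" for s, e, l in
                         zip(self.starts, self.ends, self.labels))
        return f"Mosaic({segs})"


def merge_labels(mosaics: list[Mosaic]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Common refinement of several mosaics on the same chromosome.

    Returns ``(starts, ends, labels)`` where ``labels`` has shape
    ``(n_mosaics, n_segments)``.
    """
    ends = mosaics[0].ends
    for m in mosaics[1:]:
        ends = np.union1d(ends, m.ends)
    starts = np.concatenate(([0], ends[:-1]))
    lab = np.empty((len(mosaics), len(ends)), dtype=np.int16)
    for i, m in enumerate(mosaics):
        lab[i] = m.labels[np.searchsorted(m.ends, starts, side="right")]
    return starts, ends, lab


def diff_bp(a: Mosaic, b: Mosaic) -> int:
    """Total bp where two mosaics carry different labels."""
    starts, ends, lab = merge_labels([a, b])
    mism = lab[0] != lab[1]
    if not mism.any():
        return 0
    return int(np.sum(ends[mism] - starts[mism]))


def all_equal(mosaics: list[Mosaic]) -> bool:
    first = mosaics[0]
    return all(first.equal(m) for m in mosaics[1:])
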