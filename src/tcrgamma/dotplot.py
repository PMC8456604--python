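"""Windowed-identity dot-plots and tandem-duplication run detection.

A dotmatcher-style comparison: a dot is placed at window-midpoint
coordinates (i, j) when the ungapped windows of ``window`` bp centred at i
on sequence A and j on sequence B agree at ≥ ``threshold`` of their
positions (forward strand only).  Off-diagonal runs of dots on a self-plot
are the signature of tandem duplication: a unit duplicated in place yields
parallel diagonals offset by the unit length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .germline import alignment_identity


@dataclass
class DotMatrix:
    """Sparse dot set keyed by (i, j) window midpoints, with identities."""

    dots: Dict[Tuple[int, int], float]
    window: int
    threshold: float
    stride: int
    len_a: int
    len_b: int
    is_self: bool = False

    def __contains__(self, ij: Tuple[int, int]) -> bool:
        return ij in self.dots

    def __len__(self) -> int:
        return len(self.dots)


@dataclass
class HomologyRun:
    """Maximal dotted stretch along one diagonal of a dot matrix."""

    diagonal_offset: int      # j - i
    start_i: int              # midpoint of first window on A
    end_i: int                # midpoint of last window on A
    mean_identity: float
    window: int = 300

    @property
    def length(self) -> int:
        """Extent covered on sequence A, in bp (window-inclusive)."""
        return self.end_i - self.start_i + self.window


def windowed_dotplot(
    a: str,
    b: str,
    window: int = 300,
    threshold: float = 0.70,
    stride: int = 1,
) -> DotMatrix:
    """Compute the windowed-identity dot-plot of ``a`` against ``b``.

    Window midpoints lie on a grid of spacing ``stride``; windows that
    would be clipped at a boundary are skipped.  For a self-comparison
    (``a == b``) only the j ≥ i half is computed and mirrored.
    """
    if len(a) < window or len(b) < window:
        raise ValueError(f"sequences must be at least window={window} bp long")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    arr_a = np.frombuffer(a.upper().encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.upper().encode(), dtype=np.uint8)
    is_self = a == b
    half = window // 2
    dots: Dict[Tuple[int, int], float] = {}

    max_sa = len(a) - window
    max_sb = len(b) - window
    d_lo = 0 if is_self else -(max_sa // stride) * stride
    d_hi = (max_sb // stride) * stride
    for d in range(d_lo, d_hi + 1, stride):
        lo = max(0, -d)
        hi = min(max_sa, max_sb - d)
        if hi < lo:
            continue
        eq = (arr_a[lo : hi + window] == arr_b[lo + d : hi + window + d])
        csum = np.concatenate(([0], np.cumsum(eq, dtype=np.int64)))
        # window starts on the stride grid within [lo, hi]
        first = lo + (-lo) % stride
        starts = np.arange(first, hi + 1, stride)
        if starts.size == 0:
            continue
        counts = csum[starts - lo + window] - csum[starts - lo]
        keep = counts >= threshold * window
        for s, c in zip(starts[keep], counts[keep]):
            i, j = int(s) + half, int(s) + half + d
            ident = float(c) / window
            dots[(i, j)] = ident
            if is_self:
                dots[(j, i)] = ident
    return DotMatrix(dots, window, threshold, stride, len(a), len(b), is_self)


def find_homology_runs(m: DotMatrix, min_run: int = 1000) -> List[HomologyRun]:
    """Detect maximal dotted stretches per diagonal.

    Dots on the same diagonal are merged when separated by at most
    2 × stride (small indel tolerance); runs shorter than ``min_run`` bp are
    discarded.  On self-plots the main diagonal is excluded and only the
    j > i half is reported.  Runs are sorted by length, descending.
    """
    by_diag: Dict[int, List[Tuple[int, float]]] = {}
    for (i, j), ident in m.dots.items():
        d = j - i
        if m.is_self and d <= 0:
            continue
        by_diag.setdefault(d, []).append((i, ident))

    runs: List[HomologyRun] = []
    gap = 2 * m.stride
    for d, points in by_diag.items():
        points.sort()
        start, prev = points[0][0], points[0][0]
        idents = [points[0][1]]
        for i, ident in points[1:]:
            if i - prev <= gap:
                prev = i
                idents.append(ident)
            else:
                runs.append(HomologyRun(d, start, prev, float(np.mean(idents)), m.window))
                start, prev, idents = i, i, [ident]
        runs.append(HomologyRun(d, start, prev, float(np.mean(idents)), m.window))
    runs = [r for r in runs if r.length >= min_run]
    runs.sort(key=lambda r: (-r.length, r.diagonal_offset))
    return runs


def unit_identity(a_span: str, b_span: str) -> float:
    """Global alignment identity between two homology-unit spans, in percent."""
    return alignment_identity(a_span, b_span) * 100.0
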