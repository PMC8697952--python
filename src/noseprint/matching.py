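"""Template matching by fractional Hamming distance.

The matching distance d(A, B) between two templates is the fraction of
bit positions at which they differ.  A small integer grid-shift search
(default +/-3 cells) absorbs residual translation between captures: the
distance is the minimum, over shifts, of the fractional Hamming distance
on the overlapping grid region (all bit planes shift together and the
overlap must retain at least half the cells).  ``max_shift=0`` is the
plain fixed-template comparison.

Ties between equally good shifts break toward the smallest |dx|+|dy|,
then lexicographic (dx, dy) — so a perfect self-match always reports
shift (0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .encoding import Template
from .errors import ComparabilityError, ParameterError

_MIN_OVERLAP_FRACTION = 0.5


@dataclass(frozen=True)
class MatchResult:
    """One pairwise comparison: a genuine pair shares the subject."""

    subject_a: str
    capture_a: int
    subject_b: str
    capture_b: int
    distance: float  # fractional Hamming distance in [0, 1]
    best_shift: tuple[int, int]  # estimated (dx, dy) displacement of B relative to A
    pair_type: str  # "genuine" | "impostor"


def _check_comparable(ta: Template, tb: Template) -> None:
    if not ta.comparable_with(tb):
        raise ComparabilityError(
            f"templates not comparable: shapes {ta.bits.shape} vs {tb.bits.shape}, "
            f"bank fingerprints {ta.bank_fingerprint:#x} vs {tb.bank_fingerprint:#x}"
        )


def hamming_distance(ta: Template, tb: Template) -> float:
    """Zero-shift fractional Hamming distance over all planes and cells."""
    _check_comparable(ta, tb)
    return float(np.count_nonzero(ta.bits != tb.bits)) / ta.bits.size


def _shift_order(max_shift: int) -> list[tuple[int, int]]:
    shifts = [
        (dx, dy)
        for dx in range(-max_shift, max_shift + 1)
        for dy in range(-max_shift, max_shift + 1)
    ]
    shifts.sort(key=lambda s: (abs(s[0]) + abs(s[1]), s))
    return shifts


def _overlap_slices(dx: int, dy: int, h: int, w: int):
    """Grid slices of A and B testing the hypothesis that B's content is
    A's displaced by (dx, dy) cells: pairs a[y, x] with b[y+dy, x+dx]."""
    ay = slice(max(-dy, 0), h + min(-dy, 0))
    by = slice(max(dy, 0), h + min(dy, 0))
    ax = slice(max(-dx, 0), w + min(-dx, 0))
    bx = slice(max(dx, 0), w + min(dx, 0))
    return (ay, ax), (by, bx)


def match(ta: Template, tb: Template, max_shift: int = 3) -> MatchResult:
    """Shift-tolerant comparison of two templates.

    distance = min over integer shifts |dx|,|dy| <= max_shift of the
    fractional Hamming distance on the overlap; ``max_shift=0`` reduces
    exactly to :func:`hamming_distance`.
    """
    _check_comparable(ta, tb)
    if max_shift < 0:
        raise ParameterError("max_shift must be >= 0")
    _, h, w = ta.bits.shape
    best: tuple[float, tuple[int, int]] | None = None
    for dx, dy in _shift_order(max_shift):
        if (h - abs(dy)) * (w - abs(dx)) < _MIN_OVERLAP_FRACTION * h * w:
            continue
        (ay, ax), (by, bx) = _overlap_slices(dx, dy, h, w)
        a = ta.bits[:, ay, ax]
        b = tb.bits[:, by, bx]
        d = float(np.count_nonzero(a != b)) / a.size
        if best is None or d < best[0]:
            best = (d, (dx, dy))
    if best is None:
        raise ParameterError(
            f"max_shift={max_shift} leaves no shift with >=50% overlap on a {h}x{w} grid"
        )
    return MatchResult(
        subject_a=ta.subject_id,
        capture_a=ta.capture_index,
        subject_b=tb.subject_id,
        capture_b=tb.capture_index,
        distance=best[0],
        best_shift=best[1],
        pair_type="genuine" if ta.subject_id == tb.subject_id else "impostor",
    )


def match_all(templates: Sequence[Template], max_shift: int = 3) -> list[MatchResult]:
    """All-pairs comparison: one MatchResult per unordered pair {i, j}.

    Semantically identical to calling :func:`match` on every pair (same
    distances, same tie-breaking), but computed with one bit-count matrix
    product per candidate shift, which makes exhaustive desk-scale
    galleries (hundreds of templates, tens of thousands of pairs) take
    seconds rather than minutes.
    """
    n = len(templates)
    if n < 2:
        return []
    t0 = templates[0]
    for t in templates[1:]:
        _check_comparable(t0, t)
    if max_shift < 0:
        raise ParameterError("max_shift must be >= 0")
    p, h, w = t0.bits.shape
    # float32 keeps the bit-count matmul exact (integer sums << 2**24)
    stack = np.stack([t.bits for t in templates]).astype(np.float32)
    iu, ju = np.triu_indices(n, k=1)
    best_d = np.full(len(iu), np.inf)
    best_dx = np.zeros(len(iu), dtype=int)
    best_dy = np.zeros(len(iu), dtype=int)
    any_shift = False
    for dx, dy in _shift_order(max_shift):
        if (h - abs(dy)) * (w - abs(dx)) < _MIN_OVERLAP_FRACTION * h * w:
            continue
        any_shift = True
        (ay, ax), (by, bx) = _overlap_slices(dx, dy, h, w)
        a = stack[:, :, ay, ax].reshape(n, -1)
        b = stack[:, :, by, bx].reshape(n, -1)
        # mismatches(i,j) = |a_i| + |b_j| - 2 a_i . b_j  for 0/1 vectors
        ones_a = a.sum(axis=1)
        ones_b = b.sum(axis=1)
        mism = ones_a[:, None] + ones_b[None, :] - 2.0 * (a @ b.T)
        d = mism[iu, ju].astype(np.float64) / a.shape[1]
        better = d < best_d  # strict: earlier shifts win ties (tie-break order)
        best_d[better] = d[better]
        best_dx[better] = dx
        best_dy[better] = dy
    if not any_shift:
        raise ParameterError(
            f"max_shift={max_shift} leaves no shift with >=50% overlap on a {h}x{w} grid"
        )
    results = []
    for k in range(len(iu)):
        ta, tb = templates[iu[k]], templates[ju[k]]
        results.append(
            MatchResult(
                subject_a=ta.subject_id,
                capture_a=ta.capture_index,
                subject_b=tb.subject_id,
                capture_b=tb.capture_index,
                distance=float(best_d[k]),
                best_shift=(int(best_dx[k]), int(best_dy[k])),
                pair_type="genuine" if ta.subject_id == tb.subject_id else "impostor",
            )
        )
    return results


DISTANCES_COLUMNS = (
    "subject_a",
    "capture_a",
    "subject_b",
    "capture_b",
    "pair_type",
    "distance",
    "shift_dx",
    "shift_dy",
)


def write_distances(results: Sequence[MatchResult], path: str | Path) -> None:
    """Write pairwise distances as CSV (distances at 4 decimals)."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(DISTANCES_COLUMNS)
        for r in results:
            writer.writerow(
                [
                    r.subject_a,
                    r.capture_a,
                    r.subject_b,
                    r.capture_b,
                    r.pair_type,
                    f"{r.distance:.4f}",
                    r.best_shift[0],
                    r.best_shift[1],
                ]
            )


def read_distances(path: str | Path) -> list[MatchResult]:
    import csv

    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                MatchResult(
                    subject_a=row["subject_a"],
                    capture_a=int(row["capture_a"]),
                    subject_b=row["subject_b"],
                    capture_b=int(row["capture_b"]),
                    distance=float(row["distance"]),
                    best_shift=(int(row["shift_dx"]), int(row["shift_dy"])),
                    pair_type=row["pair_type"],
                )
            )
    return out
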