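"""Tooth-age consensus across readers and the Index of Average Percentage
Error (IAPE, Beamish & Fournier).

Each male is aged independently by several readers counting annual growth
ridges on a canine.  The consensus age is the modal reading; reader
precision is summarised by

    IAPE = (1/N) Σ_j [ (1/R) Σ_i |X_ij − X̄_j| / X̄_j ] × 100,

with X_ij the i-th of R readings for individual j and X̄_j the mean reading.
Smaller is more precise; identical readers give 0.
"""

from __future__ import annotations

from collections import Counter

import numpy as np


def modal_age(readings) -> int:
    """Most frequent reading; ties resolved by the median of the tied modes
    rounded half-up (a deterministic stand-in for re-reading)."""
    vals = [int(v) for v in np.asarray(readings).ravel()]
    if not vals:
        raise ValueError("no readings")
    counts = Counter(vals)
    top = max(counts.values())
    modes = sorted(v for v, c in counts.items() if c == top)
    if len(modes) == 1:
        return modes[0]
    return int(np.floor(np.median(modes) + 0.5))


def iape(readings_matrix) -> float:
    """IAPE in percent over an iterable of per-individual reading vectors."""
    rows = [np.asarray(r, dtype=float).ravel() for r in readings_matrix]
    if not rows:
        raise ValueError("no individuals")
    contribs = []
    for j, row in enumerate(rows):
        if row.size == 0:
            raise ValueError(f"individual {j}: no readings")
        xbar = row.mean()
        if xbar <= 0:
            raise ValueError(f"individual {j}: non-positive mean reading")
        contribs.append(np.mean(np.abs(row - xbar) / xbar))
    return float(np.mean(contribs) * 100.0)


def pairwise_agreement(readings_matrix, tolerance: int = 1) -> float:
    """Fraction of reader pairs differing by at most ``tolerance`` years,
    pooled over individuals — comparable with reported reader-agreement
    percentages."""
    agree = total = 0
    for row in readings_matrix:
        row = np.asarray(row, dtype=float).ravel()
        r = row.size
        for i in range(r):
            for k in range(i + 1, r):
                total += 1
                if abs(row[i] - row[k]) <= tolerance:
                    agree += 1
    if total == 0:
        raise ValueError("no reader pairs")
    return agree / total
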