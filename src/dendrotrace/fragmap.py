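"""Protected-fragment calling from per-nucleotide coverage.

RNase digestion of a protein-bound transcript leaves protein-protected
regions as box-shaped read-coverage peaks.  The caller thresholds the
profile at a fraction of the maximum depth, merges runs across small
gaps, filters short runs, and ranks the surviving segments by mean
depth (the deepest is the major fragment).

Coordinates are 1-based inclusive throughout; the BED-style writer in
:mod:`dendrotrace.io` converts to 0-based half-open.  Degenerate case,
pinned by contract: on a perfectly flat non-zero profile every position
equals the maximum, so every position passes any threshold below the
maximum and a single full-length segment is returned.
"""

from __future__ import annotations

import numpy as np

from .types import CoverageProfile, ProtectedSegment


def call_segments(cov: CoverageProfile, frac_of_max: float = 0.5,
                  min_len: int = 50, merge_gap: int = 10) -> list[ProtectedSegment]:
    """Call protected segments from a coverage profile.

    ``frac_of_max`` sets the depth threshold as a fraction of the
    profile maximum; runs of above-threshold positions separated by at
    most ``merge_gap`` nt are merged, and merged runs shorter than
    ``min_len`` nt are dropped.  Segments are returned sorted by
    position, the deepest ranked ``major``.
    """
    if not 0 < frac_of_max < 1:
        raise ValueError("frac_of_max must be in (0, 1)")
    depth = cov.depth
    peak = float(depth.max(initial=0.0))
    if peak <= 0:
        return []
    thr = frac_of_max * peak
    above = depth >= thr

    # maximal runs of above-threshold positions (1-based inclusive)
    runs = []
    start = None
    for i, a in enumerate(above):
        if a and start is None:
            start = i
        elif not a and start is not None:
            runs.append([start + 1, i])
            start = None
    if start is not None:
        runs.append([start + 1, len(above)])

    merged = []
    for a, b in runs:
        if merged and a - merged[-1][1] - 1 <= merge_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])

    segs = []
    for a, b in merged:
        if b - a + 1 < min_len:
            continue
        segs.append(ProtectedSegment(start=a, end=b,
                                     mean_depth=float(depth[a - 1:b].mean())))
    if segs:
        major = max(range(len(segs)), key=lambda i: segs[i].mean_depth)
        segs[major].rank = "major"
    return segs
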