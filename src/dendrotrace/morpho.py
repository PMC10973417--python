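"""Sholl analysis and spine-density tabulation.

Sholl intersections are exact segment–circle crossings: for each
skeleton edge and each concentric circle around the soma, the number of
interior intersection points of the segment with the circle is counted
(tangencies excluded).  Spine typing is taken as input annotation; the
closed vocabulary is thin / mushroom / stubby / filopodium.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import SPINE_TYPES, Skeleton


@dataclass
class ShollProfile:
    radii: np.ndarray           # µm
    intersections: np.ndarray   # crossings per circle

    def to_rows(self):
        return list(zip(self.radii.tolist(), self.intersections.tolist()))


def _segment_circle_crossings(a: np.ndarray, b: np.ndarray,
                              center: np.ndarray, r: float) -> int:
    """Number of points where segment a-b crosses the circle |p-c| = r.

    Roots of |a + u(b-a) - c|^2 = r^2 with u strictly inside (0, 1);
    double roots (tangency) are excluded.
    """
    d = b - a
    f = a - center
    A = float(d @ d)
    if A == 0:
        return 0
    B = 2.0 * float(f @ d)
    C = float(f @ f) - r * r
    disc = B * B - 4 * A * C
    if disc <= 0:
        return 0
    sq = np.sqrt(disc)
    crossings = 0
    for u in ((-B - sq) / (2 * A), (-B + sq) / (2 * A)):
        if 0.0 < u < 1.0:
            crossings += 1
    # endpoint exactly on the circle: count the edge once if it straddles
    if crossings == 0:
        d1 = np.linalg.norm(f)
        d2 = np.linalg.norm(b - center)
        if (d1 - r) * (d2 - r) < 0:
            crossings = 1
    return crossings


def sholl(skel: Skeleton, step: float = 10.0,
          max_radius: float | None = None) -> ShollProfile:
    """Intersections of the arbor with concentric circles at ``step`` µm.

    The soma centre is the root node; the profile extends to the arbor's
    radial extent (or ``max_radius`` if given).
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    center = skel.root_xyz[:2]
    edges = skel.edges()
    if len(edges) == 0:
        return ShollProfile(radii=np.array([step]),
                            intersections=np.array([0]))
    pts = edges.reshape(-1, 3)[:, :2]
    extent = float(np.max(np.linalg.norm(pts - center, axis=1)))
    r_max = max_radius if max_radius is not None else extent
    radii = np.arange(step, r_max + 0.5 * step, step)
    counts = np.zeros(len(radii), dtype=int)
    for child, parent in edges[:, :, :2]:
        for i, r in enumerate(radii):
            counts[i] += _segment_circle_crossings(parent, child, center, r)
    return ShollProfile(radii=radii, intersections=counts)


def spine_density(spine_types: list[str], dendrite_length: float) -> dict:
    """Spines per 100 µm and the percentage of each spine type."""
    if dendrite_length <= 0:
        raise ValueError("dendrite_length must be > 0")
    for s in spine_types:
        if s not in SPINE_TYPES:
            raise ValueError(f"unknown spine type {s!r}")
    n = len(spine_types)
    pct = {t: (100.0 * spine_types.count(t) / n if n else 0.0)
           for t in SPINE_TYPES}
    return {"density_per_100um": 100.0 * n / dendrite_length,
            "n_spines": n, "type_pct": pct}
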