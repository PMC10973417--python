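"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Arc-length coordinate: the soma sits at arc position 0 µm and the
  anterograde direction is increasing arc position (kymographs are drawn
  soma-down).
* Times are seconds, distances micrometres, lifetimes nanoseconds.
* Coverage profiles use 1-based inclusive nucleotide coordinates, the
  convention of transcript annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SCHEMA_VERSION = "dendrotrace-1"

ANTEROGRADE = "anterograde"
RETROGRADE = "retrograde"
PAUSED = "paused"

#: closed vocabulary of whole-track motility labels
TRACK_CLASSES = ("stationary", "anterograde", "retrograde",
                 "multidirectional", "interrupted")

#: closed vocabulary of granule-at-spine event classes
DOCK_CLASSES = ("docked", "docking", "undocking", "direction_change")

SPINE_TYPES = ("thin", "mushroom", "stubby", "filopodium")


@dataclass
class Track:
    """Time-ordered positions of one granule.

    ``frames`` are strictly increasing; ``arc`` holds positions projected
    onto the dendrite arc-length axis and may be absent (NaN-free None)
    until :func:`dendrotrace.tracking.project_to_path` fills it.
    """

    id: int
    frames: np.ndarray          # frame indices, strictly increasing
    t: np.ndarray               # s
    x: np.ndarray               # µm
    y: np.ndarray               # µm
    arc: np.ndarray | None = None   # µm along the dendrite path

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.arc is not None:
            self.arc = np.asarray(self.arc, dtype=float)
        if len(self.frames) != len(self.t):
            raise ValueError("frames and t must have equal length")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError(f"track {self.id}: frame indices not strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class Run:
    """Maximal constant-direction (or paused) segment of a track."""

    track_id: int
    t_start: float
    t_end: float
    s_start: float
    s_end: float
    direction: str              # anterograde | retrograde | paused

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("run must have positive duration")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def displacement(self) -> float:
        """Signed net displacement (µm); positive = anterograde."""
        return self.s_end - self.s_start

    @property
    def velocity(self) -> float:
        """Signed displacement / duration (µm/s)."""
        return self.displacement / self.duration

    @property
    def mobile(self) -> bool:
        return self.direction != PAUSED


@dataclass
class DendritePath:
    """Polyline describing a dendrite; the soma end is vertex 0 (arc 0)."""

    vertices: np.ndarray        # (N, 2) µm

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        if len(self.vertices) < 2:
            raise ValueError("path needs at least two vertices")
        seg = np.diff(self.vertices, axis=0)
        self._seg_len = np.hypot(seg[:, 0], seg[:, 1])
        if not np.all(self._seg_len > 0):
            raise ValueError("degenerate (zero-length) path segment")
        self._cum = np.concatenate([[0.0], np.cumsum(self._seg_len)])

    @property
    def length(self) -> float:
        return float(self._cum[-1])

    def point_at(self, s):
        """Map arc position(s) to 2-D coordinates (clipped to the path)."""
        s = np.clip(np.atleast_1d(np.asarray(s, dtype=float)), 0.0, self.length)
        idx = np.clip(np.searchsorted(self._cum, s, side="right") - 1,
                      0, len(self._seg_len) - 1)
        frac = (s - self._cum[idx]) / self._seg_len[idx]
        p0 = self.vertices[idx]
        p1 = self.vertices[idx + 1]
        return p0 + frac[:, None] * (p1 - p0)


@dataclass
class FrameStack:
    """Timelapse image stack with physical calibration."""

    data: np.ndarray            # (T, H, W)
    pixel_size: float           # µm
    frame_interval: float       # s
    #: physical position (x, y) µm of the centre of pixel (row 0, col 0)
    origin: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("stack must be (frames, height, width)")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self):
        return self.data.shape


@dataclass
class Kymograph:
    """Intensity as a function of (arc bin, frame). Soma-side bins first."""

    data: np.ndarray            # (n_bins, n_frames)
    bin_size: float             # µm
    frame_interval: float       # s


@dataclass
class SpineSite:
    """A PSD95 punctum on the arc axis, optionally the uncaging target."""

    id: int
    arc: float                  # µm
    stimulated: bool = False
    t_stim: float | None = None
    #: (t0, t1) intervals during which >= 1 granule sits within the
    #: docking radius; filled by occupancy analysis.
    occupancy: list = field(default_factory=list)


@dataclass
class DockEvent:
    track_id: int
    spine_id: int
    kind: str                   # one of DOCK_CLASSES
    t_event: float

    def __post_init__(self) -> None:
        if self.kind not in DOCK_CLASSES:
            raise ValueError(f"unknown dock event class {self.kind!r}")


@dataclass
class VolumeTrace:
    """Spine volume proxy vs time, % of baseline; t = 0 at first uncaging."""

    t: np.ndarray               # s, strictly increasing
    v: np.ndarray               # % of baseline
    baseline_window: tuple = (-60.0, 0.0)
    rate_hz: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if len(self.t) != len(self.v):
            raise ValueError("t and v must have equal length")


@dataclass
class PhotonHistogram:
    """Binned photon arrival times for one ROI/epoch (uniform bins)."""

    bin_edges: np.ndarray       # ns, length n_bins + 1
    counts: np.ndarray          # photons per bin
    epoch: str = "pre"          # 'pre' or 'post_k'

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("need n_bins + 1 edges")
        widths = np.diff(self.bin_edges)
        if not np.allclose(widths, widths[0]):
            raise ValueError("bins must be uniform")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class Skeleton:
    """Rooted dendritic tree (SWC-style node table).

    ``parent[i] == -1`` marks the root (soma); coordinates in µm.
    """

    ids: np.ndarray
    xyz: np.ndarray             # (N, 3)
    radius: np.ndarray
    parent: np.ndarray          # parent node id, -1 for root
    node_type: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        self.radius = np.asarray(self.radius, dtype=float)
        self.parent = np.asarray(self.parent, dtype=int)
        self.node_type = np.asarray(self.node_type, dtype=int)
        id_set = set(self.ids.tolist())
        for p in self.parent:
            if p != -1 and p not in id_set:
                raise ValueError(f"SWC parent id {p} undefined")
        roots = np.flatnonzero(self.parent == -1)
        if len(roots) != 1:
            raise ValueError(f"skeleton must have exactly one root, found {len(roots)}")
        self._root_idx = int(roots[0])

    @property
    def root_xyz(self) -> np.ndarray:
        return self.xyz[self._root_idx]

    def edges(self) -> np.ndarray:
        """(E, 2, 3) array of [child, parent] coordinates for every edge."""
        index_of = {int(i): k for k, i in enumerate(self.ids)}
        out = []
        for k, p in enumerate(self.parent):
            if p == -1:
                continue
            out.append([self.xyz[k], self.xyz[index_of[int(p)]]])
        return np.asarray(out)


@dataclass
class CoverageProfile:
    """Per-nucleotide read depth over a transcript (1-based positions)."""

    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if np.any(self.depth < 0):
            raise ValueError("negative depth")

    @property
    def length(self) -> int:
        return len(self.depth)


@dataclass
class ProtectedSegment:
    """A called protected-fragment segment, 1-based inclusive coordinates."""

    start: int
    end: int
    mean_depth: float
    rank: str = "minor"         # 'major' for the deepest segment

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1
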