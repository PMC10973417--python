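"""Readers and writers for every on-disk artifact.

All text formats are UTF-8 with LF endings and carry the schema version
as a leading ``#`` comment line; CSV columns carry a units suffix
(``arc_um``, ``t_s`` ...) so files are self-describing.  TIFF stacks are
multi-page grayscale with pixel size and frame interval in the image
description.  SWC follows the standard 7-column dialect; the root is the
node with parent −1.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import AnalysisConfig, load_config, save_config  # noqa: F401  (re-export)
from .types import (SCHEMA_VERSION, CoverageProfile, FrameStack,
                    ProtectedSegment, Skeleton, Track)

_HEADER = f"# schema={SCHEMA_VERSION}\n"


# ---------------------------------------------------------------------------
# stacks
# ---------------------------------------------------------------------------

def write_stack(stack: FrameStack, path) -> None:
    meta = {"pixel_size_um": stack.pixel_size,
            "frame_interval_s": stack.frame_interval,
            "origin_um": list(stack.origin), "schema": SCHEMA_VERSION}
    data = np.clip(stack.data, 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack",
                     description=json.dumps(meta))


def read_stack(path) -> FrameStack:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description or "{}"
    meta = json.loads(desc)
    if data.ndim == 2:
        data = data[None]
    return FrameStack(data=data.astype(float),
                      pixel_size=float(meta.get("pixel_size_um", 1.0)),
                      frame_interval=float(meta.get("frame_interval_s", 1.0)),
                      origin=tuple(meta.get("origin_um", (0.0, 0.0))))


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

def write_tracks(tracks: list[Track], path) -> None:
    rows = []
    for tr in tracks:
        arc = tr.arc if tr.arc is not None else [np.nan] * len(tr)
        for k in range(len(tr)):
            rows.append((tr.id, int(tr.frames[k]), tr.t[k], arc[k],
                         tr.x[k], tr.y[k]))
    df = pd.DataFrame(rows, columns=["track_id", "frame", "t_s", "arc_um",
                                     "x_um", "y_um"])
    with open(path, "w", newline="\n") as fh:
        fh.write(_HEADER)
        df.to_csv(fh, index=False, float_format="%.6f", lineterminator="\n")


def read_tracks(path) -> list[Track]:
    df = pd.read_csv(path, comment="#")
    tracks = []
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("frame")
        if sub["frame"].diff().dropna().le(0).any():
            raise ValueError(f"track {tid}: non-monotone frame indices")
        arc = sub["arc_um"].to_numpy()
        tracks.append(Track(id=int(tid), frames=sub["frame"].to_numpy(),
                            t=sub["t_s"].to_numpy(), x=sub["x_um"].to_numpy(),
                            y=sub["y_um"].to_numpy(),
                            arc=None if np.isnan(arc).all() else arc))
    return tracks


# ---------------------------------------------------------------------------
# skeletons (SWC)
# ---------------------------------------------------------------------------

def write_swc(skel: Skeleton, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(_HEADER)
        for i in range(len(skel.ids)):
            x, y, z = skel.xyz[i]
            fh.write(f"{skel.ids[i]} {skel.node_type[i]} {x:.4f} {y:.4f} "
                     f"{z:.4f} {skel.radius[i]:.4f} {skel.parent[i]}\n")


def read_swc(path) -> Skeleton:
    ids, xyz, radius, parent, ntype = [], [], [], [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"malformed SWC line: {line!r}")
        ids.append(int(parts[0]))
        ntype.append(int(parts[1]))
        xyz.append(tuple(float(v) for v in parts[2:5]))
        radius.append(float(parts[5]))
        parent.append(int(parts[6]))
    return Skeleton(ids=np.array(ids), xyz=np.array(xyz),
                    radius=np.array(radius), parent=np.array(parent),
                    node_type=np.array(ntype))


# ---------------------------------------------------------------------------
# coverage and called segments
# ---------------------------------------------------------------------------

def write_coverage(cov: CoverageProfile, path) -> None:
    df = pd.DataFrame({"pos": np.arange(1, cov.length + 1),
                       "depth": cov.depth})
    with open(path, "w", newline="\n") as fh:
        fh.write(_HEADER)
        df.to_csv(fh, index=False, float_format="%.4f", lineterminator="\n")


def read_coverage(path) -> CoverageProfile:
    df = pd.read_csv(path, comment="#")
    df = df.sort_values("pos")
    if not np.array_equal(df["pos"].to_numpy(),
                          np.arange(1, len(df) + 1)):
        raise ValueError("coverage positions must be contiguous from 1")
    return CoverageProfile(depth=df["depth"].to_numpy())


def write_segments_bed(segments: list[ProtectedSegment], path,
                       name: str = "transcript") -> None:
    """BED-like output: 0-based half-open, as is conventional for BED."""
    with open(path, "w", newline="\n") as fh:
        fh.write(_HEADER)
        for seg in segments:
            fh.write(f"{name}\t{seg.start - 1}\t{seg.end}\t{seg.rank}\t"
                     f"{seg.mean_depth:.2f}\n")


def write_segments_json(segments: list[ProtectedSegment], path) -> None:
    payload = {"schema": SCHEMA_VERSION,
               "segments": [{"start_nt": s.start, "end_nt": s.end,
                             "length_nt": s.length,
                             "mean_depth": s.mean_depth, "rank": s.rank}
                            for s in segments]}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# generic JSON (ground truth, summaries)
# ---------------------------------------------------------------------------

def write_json(obj: dict, path) -> None:
    payload = {"schema": SCHEMA_VERSION, **obj}
    Path(path).write_text(json.dumps(payload, indent=2, default=_coerce) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def _coerce(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"cannot serialize {type(o)}")
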