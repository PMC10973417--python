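"""Granule detection, track linking, path projection and kymographs.

Detection is Laplacian-of-Gaussian blob finding at the PSF scale with a
robust (median + MAD) background model and an SNR gate, followed by
intensity-weighted subpixel centroid refinement.  Linking is
frame-to-frame optimal assignment (Hungarian) gated by a maximum
per-frame displacement, with gap closing over a small number of skipped
frames.  Arc positions come from orthogonal projection onto the dendrite
polyline; kymographs take the maximum intensity over the corridor
orthogonal to the path at each arc bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_laplace
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max

from .types import DendritePath, FrameStack, Kymograph, Track

log = logging.getLogger(__name__)


@dataclass
class Detection:
    frame: int
    x: float            # µm
    y: float            # µm
    intensity: float    # background-subtracted integrated counts
    snr: float


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detect_spots(stack: FrameStack, psf_sigma: float,
                 snr_min: float = 5.0) -> list[Detection]:
    """Detect diffraction-limited spots in every frame.

    SNR is (peak - median) / (1.4826 * MAD), a scale-free measure robust
    across photon budgets.
    """
    sig_px = psf_sigma / stack.pixel_size
    if sig_px < 1.0:
        raise ValueError("psf_sigma must be at least one pixel")
    half = int(np.ceil(3 * sig_px))
    min_dist = max(1, int(round(2 * sig_px)))
    out: list[Detection] = []
    ox, oy = stack.origin
    for f in range(stack.n_frames):
        img = stack.data[f].astype(float)
        bg = float(np.median(img))
        mad = float(np.median(np.abs(img - bg)))
        noise = 1.4826 * mad if mad > 0 else max(float(img.std()), 1e-12)
        resp = -gaussian_laplace(img, sig_px)
        peaks = peak_local_max(resp, min_distance=min_dist,
                               threshold_abs=0.0, exclude_border=False)
        for r, c in peaks:
            r0, r1 = max(r - half, 0), min(r + half + 1, img.shape[0])
            c0, c1 = max(c - half, 0), min(c + half + 1, img.shape[1])
            win = img[r0:r1, c0:c1] - bg
            snr = float(win.max()) / noise
            if snr < snr_min:
                continue
            w = np.clip(win, 0.0, None)
            tot = float(w.sum())
            if tot <= 0:
                continue
            rows = np.arange(r0, r1)
            cols = np.arange(c0, c1)
            cy = float((w.sum(axis=1) * rows).sum() / tot)
            cx = float((w.sum(axis=0) * cols).sum() / tot)
            out.append(Detection(frame=f,
                                 x=cx * stack.pixel_size + ox,
                                 y=cy * stack.pixel_size + oy,
                                 intensity=tot, snr=snr))
    return out


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def link_tracks(detections: list[Detection], max_disp_per_frame: float = 1.2,
                max_gap: int = 2, frame_interval: float = 1.0) -> list[Track]:
    """Link detections into tracks by per-frame-pair optimal assignment.

    Candidate pairs are gated at ``max_disp_per_frame * n_skipped`` µm;
    within each frame pair the assignment minimizing total displacement
    is used (Hungarian algorithm), ties broken toward lower track id.
    Tracks may skip up to ``max_gap`` frames.
    """
    if not detections:
        return []
    by_frame: dict[int, list[Detection]] = {}
    for d in detections:
        by_frame.setdefault(int(d.frame), []).append(d)
    frames = sorted(by_frame)

    # active track state: list of detections; keyed by creation order (= id)
    tracks_dets: list[list[Detection]] = []
    active: list[int] = []          # indices into tracks_dets
    last_frame: dict[int, int] = {}

    for f in frames:
        dets = by_frame[f]
        # candidates: active tracks whose last frame is within the gap window
        cand = [i for i in active if f - last_frame[i] <= max_gap + 1]
        cand.sort()                 # lower id first -> deterministic ties
        assigned_det = [-1] * len(dets)
        if cand and dets:
            BIG = 1e9
            cost = np.full((len(cand), len(dets)), BIG)
            for a, ti in enumerate(cand):
                prev = tracks_dets[ti][-1]
                gap = f - last_frame[ti]
                gate = max_disp_per_frame * gap
                for b, d in enumerate(dets):
                    disp = np.hypot(d.x - prev.x, d.y - prev.y)
                    if disp <= gate:
                        # tiny id-ordered tie-break keeps assignment unique
                        cost[a, b] = disp + 1e-9 * a
            rows, cols = linear_sum_assignment(cost)
            for a, b in zip(rows, cols):
                if cost[a, b] < BIG:
                    ti = cand[a]
                    tracks_dets[ti].append(dets[b])
                    last_frame[ti] = f
                    assigned_det[b] = ti
        for b, d in enumerate(dets):
            if assigned_det[b] == -1:
                tracks_dets.append([d])
                ti = len(tracks_dets) - 1
                active.append(ti)
                last_frame[ti] = f
        # retire tracks that can no longer be extended
        active = [i for i in active if f - last_frame[i] <= max_gap]

    out = []
    for tid, dets in enumerate(tracks_dets):
        fr = np.array([d.frame for d in dets])
        out.append(Track(id=tid, frames=fr,
                         t=fr.astype(float) * frame_interval,
                         x=np.array([d.x for d in dets]),
                         y=np.array([d.y for d in dets])))
    return out


# ---------------------------------------------------------------------------
# projection onto the dendrite path
# ---------------------------------------------------------------------------

def _project_point(path: DendritePath, x: float, y: float):
    """Return (arc position, distance) of the orthogonal projection."""
    p = np.array([x, y])
    best = (0.0, np.inf)
    verts = path.vertices
    for i in range(len(verts) - 1):
        a, b = verts[i], verts[i + 1]
        ab = b - a
        L2 = float(ab @ ab)
        tpar = float(np.clip((p - a) @ ab / L2, 0.0, 1.0))
        proj = a + tpar * ab
        dist = float(np.hypot(*(p - proj)))
        if dist < best[1]:
            best = (float(path._cum[i] + tpar * np.sqrt(L2)), dist)
    return best


def project_to_path(tracks: list[Track], path: DendritePath,
                    corridor_halfwidth: float = 1.5) -> list[Track]:
    """Fill each track's arc positions by orthogonal projection.

    Detections farther than ``corridor_halfwidth`` from the path are
    off-dendrite: they are dropped from the track and logged.  Tracks
    left with fewer than two points are discarded.
    """
    out = []
    for tr in tracks:
        arcs, keep = [], []
        for k in range(len(tr)):
            s, dist = _project_point(path, tr.x[k], tr.y[k])
            if dist > corridor_halfwidth:
                log.info("track %d frame %d: %.2f µm off path, excluded",
                         tr.id, tr.frames[k], dist)
                continue
            arcs.append(s)
            keep.append(k)
        if len(keep) < 2:
            continue
        keep = np.asarray(keep)
        out.append(Track(id=tr.id, frames=tr.frames[keep], t=tr.t[keep],
                         x=tr.x[keep], y=tr.y[keep],
                         arc=np.asarray(arcs)))
    return out


# ---------------------------------------------------------------------------
# kymograph
# ---------------------------------------------------------------------------

def build_kymograph(stack: FrameStack, path: DendritePath,
                    bin_size: float = 0.5,
                    corridor_halfwidth: float = 1.5) -> Kymograph:
    """Max-intensity kymograph along the path (soma-side bins first)."""
    n_bins = max(1, int(np.ceil(path.length / bin_size)))
    H, W = stack.data.shape[1:]
    rows, cols = np.mgrid[0:H, 0:W]
    px = cols * stack.pixel_size + stack.origin[0]
    py = rows * stack.pixel_size + stack.origin[1]
    arc = np.empty(H * W)
    dist = np.empty(H * W)
    flat = np.stack([px.ravel(), py.ravel()], axis=1)
    for i, (xx, yy) in enumerate(flat):
        arc[i], dist[i] = _project_point(path, xx, yy)
    inside = dist <= corridor_halfwidth
    bins = np.clip((arc / bin_size).astype(int), 0, n_bins - 1)[inside]
    data = np.zeros((n_bins, stack.n_frames))
    for f in range(stack.n_frames):
        vals = stack.data[f].ravel()[inside]
        col = np.zeros(n_bins)
        np.maximum.at(col, bins, vals)
        data[:, f] = col
    return Kymograph(data=data, bin_size=bin_size,
                     frame_interval=stack.frame_interval)
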