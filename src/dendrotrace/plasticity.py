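"""Single-spine structural plasticity (sLTP) metrics.

Volume traces are percent-of-baseline fluorescence proxies with the
first uncaging pulse at t = 0.  The read-outs mirror the standard
uncaging paradigm: a transient amplitude at +1.5 min, a sustained
amplitude averaged over +28.5 to +32.5 min (with the single-sample
+30.5 min variant also reported), a fast-rate window mean over 88–92 s,
and a responsive flag that is true when the post-stimulation peak within
the first 5 min reaches the configured threshold (default +10 %).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import AnalysisConfig
from .types import VolumeTrace

log = logging.getLogger(__name__)


def normalize_trace(t, raw, baseline_window=(-60.0, 0.0),
                    rate_hz: float | None = None) -> VolumeTrace:
    """Express a raw fluorescence trace as percent of its baseline mean.

    ``t`` must already be referenced to the first uncaging pulse (t = 0).
    """
    t = np.asarray(t, dtype=float)
    raw = np.asarray(raw, dtype=float)
    sel = (t >= baseline_window[0]) & (t <= baseline_window[1])
    if sel.sum() < 3:
        raise ValueError("need at least 3 baseline samples")
    base = raw[sel].mean()
    if base <= 0:
        raise ValueError("baseline mean must be positive")
    return VolumeTrace(t=t, v=100.0 * raw / base,
                       baseline_window=tuple(baseline_window), rate_hz=rate_hz)


@dataclass
class SltpMetrics:
    transient_pct: float | None         # % change at +1.5 min
    sustained_pct: float | None         # mean % change over +28.5..+32.5 min
    sustained_point_pct: float | None   # % change at the +30.5 min sample
    fast_window_pct: float | None       # mean % change over 88-92 s
    peak_pct: float | None              # max % change in (0, +5 min]
    responsive: bool

    def to_dict(self) -> dict:
        return dict(transient_pct=self.transient_pct,
                    sustained_pct=self.sustained_pct,
                    sustained_point_pct=self.sustained_point_pct,
                    fast_window_pct=self.fast_window_pct,
                    peak_pct=self.peak_pct, responsive=self.responsive)


def _nearest(trace: VolumeTrace, t_query: float) -> float | None:
    if t_query < trace.t[0] or t_query > trace.t[-1]:
        log.info("time %.1f s outside trace: metric undefined", t_query)
        return None
    k = int(np.argmin(np.abs(trace.t - t_query)))
    return float(trace.v[k])


def _window_mean(trace: VolumeTrace, lo: float, hi: float) -> float | None:
    sel = (trace.t >= lo) & (trace.t <= hi)
    if not sel.any():
        log.info("window [%.1f, %.1f] s outside trace: metric undefined", lo, hi)
        return None
    return float(trace.v[sel].mean())


def sltp_metrics(trace: VolumeTrace, cfg: AnalysisConfig | None = None,
                 fast_rate: bool = False) -> SltpMetrics:
    """Transient / sustained / fast-window amplitudes and the responsive flag.

    The transient read-out takes the sample nearest +1.5 min (no
    interpolation); the responsive rule thresholds the peak volume
    increase within the first 5 minutes after stimulation.
    """
    cfg = cfg or AnalysisConfig()
    v_tr = _nearest(trace, cfg.transient_time)
    sus = _window_mean(trace, *cfg.sustained_window)
    sus_pt = _nearest(trace, cfg.sustained_point)
    fast = _window_mean(trace, *cfg.fast_window) if fast_rate else None
    post = (trace.t > 0) & (trace.t <= 300.0)
    peak = float(trace.v[post].max()) - 100.0 if post.any() else None
    return SltpMetrics(
        transient_pct=None if v_tr is None else v_tr - 100.0,
        sustained_pct=None if sus is None else sus - 100.0,
        sustained_point_pct=None if sus_pt is None else sus_pt - 100.0,
        fast_window_pct=None if fast is None else fast - 100.0,
        peak_pct=peak,
        responsive=(peak is not None and peak >= cfg.responsive_threshold),
    )


def group_timecourse(traces: list[VolumeTrace]):
    """Pointwise mean ± SEM across spines (common time base required).

    Returns ``(t, mean, sem)``; SEM is ``None`` for a single trace.
    """
    if not traces:
        raise ValueError("need at least one trace")
    t0 = traces[0].t
    for tr in traces[1:]:
        if len(tr.t) != len(t0) or not np.allclose(tr.t, t0):
            raise ValueError("traces must share a common time base")
    V = np.stack([tr.v for tr in traces])
    mean = V.mean(axis=0)
    if len(traces) == 1:
        log.info("single trace: SEM undefined")
        return t0, mean, None
    sem = V.std(axis=0, ddof=1) / np.sqrt(len(traces))
    return t0, mean, sem
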