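"""Analysis configuration: every tunable threshold in one place.

Defaults encode the study conditions the package quantifies: a 2.5 µm
PSD95 docking radius, 5 µm / 25 µm recruitment windows around a stimulated
spine, a 10 % volume-increase rule for responsive spines, the +1.5 min
transient and +28.5–32.5 min sustained sLTP read-out windows, and a 10 µm
Sholl step.  Unknown keys in a config file are an error (fail-closed);
missing keys take the documented default and are logged.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    # --- imaging geometry ----------------------------------------------
    pixel_size: float = 0.16            # µm per pixel
    frame_interval: float = 1.0         # s  (~1 fps acquisition)
    psf_sigma: float = 0.25             # µm, Gaussian PSF sd

    # --- detection / linking -------------------------------------------
    snr_min: float = 5.0                # detections below this SNR dropped
    max_disp_per_frame: float = 1.2     # µm linking gate
    max_gap: int = 2                    # frames a track may skip
    corridor_halfwidth: float = 1.5     # µm off-path tolerance

    # --- run segmentation / motility classification --------------------
    pause_max_speed: float = 0.1        # µm/s below which a segment is a pause
    run_min_disp: float = 1.0           # µm minimum net displacement of a run
    mobility_min_disp: float = 2.0      # µm total displacement for "mobile"

    # --- spine interaction ---------------------------------------------
    docking_radius: float = 2.5         # µm around a PSD95 punctum
    residence_min: float = 10.0         # s residency separating docking from transit
    near_halfwidth: float = 5.0         # µm recruitment-count window
    region_halfwidth: float = 25.0      # µm directed-motion window
    post_window: float = 300.0          # s assessed after stimulation

    # --- structural plasticity -----------------------------------------
    responsive_threshold: float = 10.0  # % volume increase defining responsive
    transient_time: float = 90.0        # s (+1.5 min read-out)
    sustained_window: tuple = (1710.0, 1950.0)   # s (+28.5 to +32.5 min)
    sustained_point: float = 1830.0     # s (+30.5 min single-sample variant)
    fast_window: tuple = (88.0, 92.0)   # s fast-rate read-out

    # --- FLIM ------------------------------------------------------------
    tau_free: float = 2.6               # ns donor lifetime, open sensor
    tau_bound: float = 1.1              # ns donor lifetime, FRET state
    min_photons: int = 1000             # below this, lifetime flagged low-confidence

    # --- morphometry / coverage ----------------------------------------
    sholl_step: float = 10.0            # µm
    peak_frac_of_max: float = 0.5       # coverage threshold as fraction of max
    peak_min_len: int = 50              # nt
    peak_merge_gap: int = 10            # nt

    def __post_init__(self) -> None:
        for name in ("pixel_size", "frame_interval", "psf_sigma", "snr_min",
                     "max_disp_per_frame", "corridor_halfwidth",
                     "pause_max_speed", "run_min_disp", "mobility_min_disp",
                     "docking_radius", "residence_min", "near_halfwidth",
                     "region_halfwidth", "post_window", "responsive_threshold",
                     "transient_time", "sholl_step", "peak_frac_of_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")
        self.sustained_window = tuple(float(x) for x in self.sustained_window)
        self.fast_window = tuple(float(x) for x in self.fast_window)
        if not 0 < self.peak_frac_of_max < 1:
            raise ValueError("peak_frac_of_max must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sustained_window"] = list(self.sustained_window)
        d["fast_window"] = list(self.fast_window)
        return d


def load_config(path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from YAML or JSON.

    Unknown keys raise ``ValueError``; omitted keys take the defaults above
    and a notice is logged so a run record always states what was assumed.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for name in sorted(known - set(data)):
        default = getattr(AnalysisConfig, "__dataclass_fields__")[name].default
        log.info("config: %s not set, using default %r", name, default)
    return AnalysisConfig(**data)


def save_config(cfg: AnalysisConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
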