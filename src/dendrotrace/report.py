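"""Group comparisons and the end-to-end run report.

The statistical tests are the off-the-shelf ones named in the analyses
this package reproduces — two-tailed Student's t, Mann-Whitney U, and
one-/two-way ANOVA with Tukey's post-hoc — applied through scipy and
statsmodels.  ``run_pipeline`` executes every stage on synthetic inputs
with a single seed and writes a reproducible report bundle (JSON summary
+ CSV tables) stamped with the configuration hash.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io as dio
from . import synthdata
from .config import AnalysisConfig
from .flim import fit_mixture, lifetime_timecourse
from .fragmap import call_segments
from .morpho import sholl
from .plasticity import group_timecourse, sltp_metrics
from .spines import occupied_reversal_fraction, recruitment
from .tracking import detect_spots, link_tracks, project_to_path
from .transport import summarize_transport
from .types import DendritePath, SpineSite

TESTS = ("t_test_two_tailed", "mann_whitney_u",
         "anova_oneway_tukey", "anova_twoway_tukey")


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def compare(groups: dict, test: str) -> dict:
    """Apply a named test to ``{label: values}`` groups.

    Returns statistic, p-value, per-group mean ± SEM and (for ANOVA)
    Tukey pairwise p-values.  For ``anova_twoway_tukey`` the group label
    must be ``"levelA|levelB"`` and a two-way ANOVA (with interaction)
    is fitted before Tukey on the cell means.
    """
    if test not in TESTS:
        raise ValueError(f"unknown test {test!r}; choose from {TESTS}")
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    summary = {k: {"n": len(a), "mean": float(a.mean()),
                   "sem": float(a.std(ddof=1) / np.sqrt(len(a)))}
               for k, a in zip(labels, arrays)}
    out = {"test": test, "groups": summary}

    if test == "t_test_two_tailed":
        if len(arrays) != 2:
            raise ValueError("t-test needs exactly 2 groups")
        res = stats.ttest_ind(arrays[0], arrays[1])
        out.update(statistic=float(res.statistic), p_value=float(res.pvalue))
    elif test == "mann_whitney_u":
        if len(arrays) != 2:
            raise ValueError("Mann-Whitney U needs exactly 2 groups")
        res = stats.mannwhitneyu(arrays[0], arrays[1],
                                 alternative="two-sided")
        out.update(statistic=float(res.statistic), p_value=float(res.pvalue))
    elif test == "anova_oneway_tukey":
        res = stats.f_oneway(*arrays)
        out.update(statistic=float(res.statistic), p_value=float(res.pvalue))
        out["tukey"] = _tukey(labels, arrays)
    else:  # anova_twoway_tukey
        rows = []
        for k, a in zip(labels, arrays):
            fa, fb = k.split("|")
            for v in a:
                rows.append((fa, fb, v))
        df = pd.DataFrame(rows, columns=["factor_a", "factor_b", "value"])
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        model = ols("value ~ C(factor_a) * C(factor_b)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        out.update(statistic=float(table["F"].iloc[0]),
                   p_value=float(table["PR(>F)"].iloc[0]),
                   anova_table={r: {"F": float(table["F"][r]),
                                    "p": float(table["PR(>F)"][r])}
                                for r in table.index[:-1]})
        out["tukey"] = _tukey(labels, arrays)
    return out


def _tukey(labels, arrays) -> list[dict]:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    values = np.concatenate(arrays)
    cats = np.concatenate([[k] * len(a) for k, a in zip(labels, arrays)])
    res = pairwise_tukeyhsd(values, cats)
    out = []
    for row in res.summary().data[1:]:
        out.append({"group1": str(row[0]), "group2": str(row[1]),
                    "p_adj": float(row[3]), "reject": bool(row[6])})
    return out


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


DEFAULT_PIPELINE = {
    "seed": 0,
    "granules": {"n_granules": 60, "duration": 300.0,
                 "dendrite_length": 100.0, "spine_spacing": 8.0},
    "motion": {},                    # MotionModelParams overrides
    "render_tracking": {"enabled": True, "n_granules": 6, "duration": 30.0,
                        "dendrite_length": 25.0},
    "sltp": {"n_spines": 12, "amp_transient": 49.9, "amp_sustained": 10.3,
             "noise_sd": 5.0, "frame_interval": 1.5},
    "flim": {"bound_fraction_pre": 0.2, "bound_fraction_post": 0.4,
             "n_photons": 100_000},
    "skeleton": {"n_primary": 5, "branch_prob_per_10um": 0.4,
                 "max_radius": 150.0},
    "coverage": {"transcript_length": 2200,
                 "protected_intervals": [[92, 289], [898, 1130]],
                 "peak_height": [30.0, 100.0], "floor": 2.0, "noise_sd": 3.0},
    "analysis": {},                  # AnalysisConfig overrides
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if k not in base:
            raise ValueError(f"unknown pipeline config key {k!r}")
        out[k] = _merge(base[k], v) if isinstance(base[k], dict) else v
    return out


def run_pipeline(config: dict | None = None, out_dir=None,
                 seed: int | None = None) -> dict:
    """Run every stage on synthetic inputs; return (and write) the summary.

    Stages: granule simulation → (rendered stack → detection → linking →
    projection) → transport metrics → spine interaction → sLTP → FLIM →
    Sholl → fragment calling.  Identical config + seed gives an
    identical bundle.
    """
    cfg = _merge(DEFAULT_PIPELINE, config or {})
    if seed is not None:
        cfg["seed"] = seed
    seed = int(cfg["seed"])
    acfg = AnalysisConfig(**cfg["analysis"])
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
    summary: dict = {"config_hash": cfg_hash, "seed": seed}

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(name, exc) from exc
        return _Ctx()

    with stage("simulate_granules"):
        g = cfg["granules"]
        spine_arcs = np.arange(g["spine_spacing"], g["dendrite_length"],
                               g["spine_spacing"])
        params = synthdata.MotionModelParams(**cfg["motion"])
        tracks, truth = synthdata.simulate_granules(
            params, g["n_granules"], g["duration"], g["dendrite_length"],
            spine_positions=spine_arcs, seed=seed,
            docking_radius=acfg.docking_radius,
            mobility_min_disp=acfg.mobility_min_disp)

    with stage("transport"):
        ts = summarize_transport(tracks, acfg)
        summary["transport"] = ts.to_dict()
        summary["truth_mobile_fraction"] = truth.mobile_fraction

    with stage("spines"):
        sites = [SpineSite(id=i, arc=float(a))
                 for i, a in enumerate(spine_arcs)]
        frac = occupied_reversal_fraction(tracks, sites,
                                          radius=acfg.docking_radius,
                                          residence_min=acfg.residence_min)
        stim = SpineSite(id=len(sites), arc=float(spine_arcs[len(spine_arcs) // 2]),
                         stimulated=True, t_stim=60.0)
        rec = recruitment(tracks, stim, acfg.near_halfwidth,
                          acfg.region_halfwidth, min(acfg.post_window,
                                                     g["duration"] - 60.0))
        summary["spines"] = {"occupied_reversal_pct": frac,
                             "recruitment": rec}

    if cfg["render_tracking"]["enabled"]:
        with stage("render_tracking"):
            rt = cfg["render_tracking"]
            mini_tracks, _ = synthdata.simulate_granules(
                params, rt["n_granules"], rt["duration"],
                rt["dendrite_length"], seed=seed + 1)
            for tr in mini_tracks:
                tr.y = tr.y + 3.0
            rp = synthdata.RenderParams(pixel_size=acfg.pixel_size,
                                        psf_sigma=acfg.psf_sigma)
            stack = synthdata.render_stack(mini_tracks, rp, seed=seed + 2,
                                           frame_interval=params.frame_interval)
            dets = detect_spots(stack, acfg.psf_sigma, acfg.snr_min)
            linked = link_tracks(dets, acfg.max_disp_per_frame, acfg.max_gap,
                                 params.frame_interval)
            path = DendritePath(np.array([[0.0, 3.0],
                                          [rt["dendrite_length"], 3.0]]))
            linked = project_to_path(linked, path, acfg.corridor_halfwidth)
            summary["render_tracking"] = {
                "n_detections": len(dets),
                "n_tracks": len(linked),
            }

    with stage("sltp"):
        sp = cfg["sltp"]
        traces = [synthdata.simulate_volume_trace(
            sp["amp_transient"], sp["amp_sustained"],
            noise_sd=sp["noise_sd"], seed=seed + 10 + i,
            frame_interval=sp["frame_interval"])
            for i in range(sp["n_spines"])]
        t_axis, mean_tc, sem_tc = group_timecourse(traces)
        metrics = [sltp_metrics(tr, acfg) for tr in traces]
        summary["sltp"] = {
            "mean_transient_pct": float(np.mean(
                [m.transient_pct for m in metrics])),
            "mean_sustained_pct": float(np.mean(
                [m.sustained_pct for m in metrics])),
            "pct_responsive": 100.0 * np.mean(
                [m.responsive for m in metrics]),
        }

    with stage("flim"):
        fl = cfg["flim"]
        pre = synthdata.simulate_photon_histogram(
            acfg.tau_free, acfg.tau_bound, fl["bound_fraction_pre"],
            fl["n_photons"], seed=seed + 20, epoch="pre")
        post = synthdata.simulate_photon_histogram(
            acfg.tau_free, acfg.tau_bound, fl["bound_fraction_post"],
            fl["n_photons"], seed=seed + 21, epoch="post_1")
        series = lifetime_timecourse([pre, post],
                                     min_photons=acfg.min_photons)
        summary["flim"] = {
            "basal_lifetime_ns": series[1].lifetime - series[1].delta,
            "delta_lifetime_ns": series[1].delta,
            "bound_fraction_post": fit_mixture(post, acfg.tau_free,
                                               acfg.tau_bound),
        }

    with stage("sholl"):
        sk = cfg["skeleton"]
        skel = synthdata.simulate_skeleton(sk["n_primary"],
                                           sk["branch_prob_per_10um"],
                                           sk["max_radius"], seed=seed + 30)
        prof = sholl(skel, acfg.sholl_step)
        summary["sholl"] = {"radii_um": prof.radii.tolist(),
                            "intersections": prof.intersections.tolist()}

    with stage("fragmap"):
        cv = cfg["coverage"]
        cov = synthdata.simulate_coverage(cv["transcript_length"],
                                          cv["protected_intervals"],
                                          cv["peak_height"], cv["floor"],
                                          cv["noise_sd"], seed=seed + 40)
        segs = call_segments(cov, acfg.peak_frac_of_max, acfg.peak_min_len,
                             acfg.peak_merge_gap)
        summary["fragmap"] = [{"start_nt": s.start, "end_nt": s.end,
                               "length_nt": s.length, "rank": s.rank}
                              for s in segs]

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        dio.write_tracks(tracks, out / "tracks.csv")
        dio.write_json(summary, out / "summary.json")
    return summary
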