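"""End-to-end orchestration: preprocess -> spectral -> stats -> sign -> tables.

The per-participant path mirrors the analysis it reimplements: each scan
has its dummy samples removed, is scaled to a temporal mean of 100 and
detrended against low-order polynomials (plus motion regressors when
available); scans are averaged per condition, then vertices averaged
within each ROI; a Fourier transform of the ROI-average time course
yields the complex value at the stimulus frequency (10 cycles per scan)
per participant.  Group statistics, sign assignment, and thresholding
then run per ROI — or per surface node for the whole-brain analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import phasesign, preprocess, spectral, vecstats

logger = logging.getLogger("freqtag")

__all__ = [
    "AnalysisConfig",
    "participant_response",
    "run_roi_analysis",
    "run_wholebrain",
    "report",
]


@dataclass
class AnalysisConfig:
    """Knobs of the group analysis.

    ``flip_phase_conditions`` lists conditions acquired with the A/B block
    order reversed; their complex values are rotated by 180° immediately
    after extraction (and their cycle averages NaN-padded by half a cycle).
    """

    timing: phasesign.DesignTiming = field(default_factory=phasesign.DesignTiming)
    alpha: float = 0.05
    frequency_index: int = 10
    samples_per_cycle: int = 12
    poly_order: int = 2
    flip_phase_conditions: tuple = ()

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


def _preprocess_scan(ts, cfg: AnalysisConfig,
                     motion: np.ndarray | None = None):
    ts = preprocess.remove_dummy(ts, samples_per_cycle=cfg.samples_per_cycle)
    ts = preprocess.scale_units(ts)
    design = preprocess.NuisanceDesign.build(ts.n_samples, motion=motion,
                                             poly_order=cfg.poly_order)
    return preprocess.detrend(ts, design)


def participant_response(scans, roi, cfg: AnalysisConfig,
                         condition: str = "", roi_name: str = "",
                         flip: bool = False):
    """One participant's complex response for one ROI and condition.

    Scans are preprocessed individually, averaged, ROI-averaged, and
    Fourier-transformed; the stimulus-frequency bin is returned, rotated
    by 180° when ``flip`` marks a block-order-reversed condition.
    Also returns the ROI-average time course for cycle averaging.
    """
    pre = [_preprocess_scan(ts, cfg) for ts in scans]
    avg = preprocess.average_scans(pre)
    roi_ts = preprocess.roi_average(avg, roi)
    cr = spectral.response_at_frequency(roi_ts, k=cfg.frequency_index,
                                        roi=roi_name, condition=condition)
    if flip:
        cr = spectral.flip_phase_180(cr)
    return cr, roi_ts


def run_roi_analysis(cohorts: dict, rois: dict,
                     cfg: AnalysisConfig | None = None,
                     inclusion: dict | None = None) -> pd.DataFrame:
    """Group-statistics table, one row per ROI x condition.

    Parameters
    ----------
    cohorts
        ``{condition: {"scans": {participant: [ScanTimeSeries, ...]}}}``
        (the structure :func:`freqtag.simulate.simulate_cohort` returns).
    rois
        ``{roi_name: [unit ids]}``.
    inclusion
        Optional ``{roi_name: InclusionReport}``; excluded participants
        are dropped and non-retained ROIs skipped (logged, run continues).
    """
    cfg = cfg or AnalysisConfig()
    rows = []
    for condition, cohort in cohorts.items():
        flip = condition in cfg.flip_phase_conditions
        for roi_name, roi in rois.items():
            if inclusion is not None and roi_name in inclusion:
                rep = inclusion[roi_name]
                if not rep.roi_retained:
                    logger.warning("sub-ROI %s dropped: fewer than %d "
                                   "participants met the vertex criterion",
                                   roi_name, rep.min_participants)
                    continue
                keep = set(rep.included_participants)
            else:
                keep = None
            responses = []
            for pid, scans in cohort["scans"].items():
                if keep is not None and pid not in keep:
                    logger.info("participant %s excluded from %s "
                                "(vertex count below threshold)", pid, roi_name)
                    continue
                try:
                    cr, _ = participant_response(
                        scans, roi, cfg, condition=condition,
                        roi_name=roi_name, flip=flip)
                except ValueError as err:
                    logger.warning("participant %s skipped for %s: %s",
                                   pid, roi_name, err)
                    continue
                responses.append(cr)
            if len(responses) < 3:
                logger.warning("sub-ROI %s (%s) skipped: only %d usable "
                               "participants", roi_name, condition,
                               len(responses))
                continue
            try:
                stat = vecstats.group_vector_stat(responses, roi=roi_name,
                                                  condition=condition)
            except ValueError as err:
                logger.warning("sub-ROI %s (%s) skipped: %s", roi_name,
                               condition, err)
                continue
            signed, value = phasesign.signed_amplitude(stat, cfg.timing,
                                                       cfg.alpha)
            rows.append({
                "roi": roi_name, "condition": condition, "n": stat.n,
                "mean_real": stat.mean_real, "mean_imag": stat.mean_imag,
                "amplitude": stat.amplitude, "phase": stat.phase,
                "delay": signed.delay, "sign": signed.sign,
                "ambiguous": signed.ambiguous,
                "significant": signed.significant,
                "signed_amplitude": value,
                "t_squared": stat.t_squared, "p_value": stat.p_value,
                "error_lower": stat.error_lower,
                "error_upper": stat.error_upper,
            })
    return pd.DataFrame(rows)


def run_wholebrain(node_responses: np.ndarray,
                   cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Node-wise vector statistics over a [nodes x participants] complex array.

    Missing participants are NaN entries; nodes with fewer than 3 finite
    values are masked out (and counted in the log).  The plotting mask
    (``significant``) requires p < alpha and a non-ambiguous delay, so
    nodes peaking in the first four seconds of a block never plot.
    """
    cfg = cfg or AnalysisConfig()
    node_responses = np.asarray(node_responses, dtype=complex)
    if node_responses.ndim != 2:
        raise ValueError("expected [nodes x participants] complex array")
    rows = []
    n_masked_missing = 0
    for i, node in enumerate(node_responses):
        vals = node[np.isfinite(node)]
        if vals.size < 3:
            n_masked_missing += 1
            rows.append({"node": i, "n": int(vals.size), "amplitude": np.nan,
                         "delay": np.nan, "sign": 0, "ambiguous": False,
                         "p_value": np.nan, "significant": False})
            continue
        pts = [(v.real, v.imag) for v in vals]
        try:
            stat = vecstats.group_vector_stat(pts)
        except ValueError:
            n_masked_missing += 1
            rows.append({"node": i, "n": int(vals.size), "amplitude": np.nan,
                         "delay": np.nan, "sign": 0, "ambiguous": False,
                         "p_value": np.nan, "significant": False})
            continue
        signed, value = phasesign.signed_amplitude(stat, cfg.timing, cfg.alpha)
        rows.append({"node": i, "n": stat.n, "amplitude": stat.amplitude,
                     "delay": signed.delay, "sign": signed.sign,
                     "ambiguous": signed.ambiguous, "p_value": stat.p_value,
                     "significant": signed.significant,
                     "signed_amplitude": value})
    if n_masked_missing:
        logger.warning("%d node(s) masked out: fewer than 3 finite "
                       "participant values or degenerate statistics",
                       n_masked_missing)
    return pd.DataFrame(rows)


def report(roi_table: pd.DataFrame, out_dir, cycle_averages: dict | None = None,
           delay_table: pd.DataFrame | None = None) -> list:
    """Render figures from finished tables (plotting only, no computation).

    Writes a signed-amplitude-vs-eccentricity panel per condition, optional
    cycle-average plots (x at TR centers), and an optional delay histogram
    with a 0-24 s axis.  Returns the written paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    if "roi" in roi_table.columns and len(roi_table):
        tab = roi_table.copy()
        centers = tab["roi"].str.extract(r"ecc([\d.]+)")[0].astype(float)
        tab["center"] = centers
        for cond, grp in tab.dropna(subset=["center"]).groupby("condition"):
            fig, ax = plt.subplots(figsize=(6, 3.5))
            for area, agrp in grp.groupby(grp["roi"].str.split("_").str[0]):
                agrp = agrp.sort_values("center")
                ax.errorbar(agrp["center"], agrp["signed_amplitude"],
                            yerr=[agrp["amplitude"] - agrp["error_lower"],
                                  agrp["error_upper"] - agrp["amplitude"]],
                            marker="o", ms=3, capsize=2, label=area)
                sig = agrp[agrp["significant"]]
                ax.plot(sig["center"], sig["signed_amplitude"], "k*", ms=8)
            ax.axhline(0, color="gray", lw=0.5)
            ax.set_xlabel("sub-ROI center eccentricity (deg)")
            ax.set_ylabel("signed amplitude (% signal)")
            ax.set_title(f"{cond}: signed vector-average amplitude")
            ax.legend(fontsize=8)
            path = out / f"signed_amplitude_{cond}.png"
            fig.tight_layout()
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)

    for name, ca in (cycle_averages or {}).items():
        fig, ax = plt.subplots(figsize=(4.5, 3))
        ax.errorbar(ca.sample_times, ca.mean, yerr=ca.sem, marker="o")
        ax.set_xlabel("time in cycle (s, TR centers)")
        ax.set_ylabel("% signal change")
        ax.set_title(f"cycle average: {name}")
        path = out / f"cycle_average_{name}.png"
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    if delay_table is not None and len(delay_table):
        fig, ax = plt.subplots(figsize=(4.5, 3))
        d = delay_table.loc[delay_table["significant"], "delay"].dropna()
        ax.hist(d, bins=np.arange(0, 24.0 + 1.0, 1.0), color="steelblue")
        ax.set_xlim(0, 24)
        ax.set_xlabel("response delay (s)")
        ax.set_ylabel("significant nodes")
        path = out / "delay_map_histogram.png"
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    return written
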