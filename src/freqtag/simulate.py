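"""Synthetic BOLD cohorts for a 12 s A / 12 s B alternating block design.

Emulates ROI-average (or per-vertex) time courses with the structure the
downstream analysis assumes: a hemodynamically delayed periodic response at
1/24 Hz of controllable amplitude and phase, low-order polynomial drift,
white plus AR(1)-correlated noise, between-participant amplitude/delay
variability, and eccentricity-dependent response signs (positive responses
near the 2-degree figure boundary, negative in the 3-6 degree surround).

Samples sit at TR centers: sample ``n`` of the retained (post-dummy) series
represents scan time ``n*TR + TR/2`` after A-block onset, matching data that
have been slice-time corrected to the middle of each TR.  The phase-to-delay
step downstream adds the corresponding +TR/2 shift exactly once, so injected
delays round-trip through the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.stats import gamma as gamma_dist

from .preprocess import ScanTimeSeries

__all__ = [
    "SimulationConfig",
    "EccentricityProfile",
    "make_block_regressor",
    "simulate_scan",
    "simulate_cohort",
    "write_cohort",
    "load_cohort",
    "dot_speed_deg_per_sec",
]


@dataclass
class SimulationConfig:
    """Study-design and noise parameters for one simulated condition.

    Defaults reproduce the acquisition geometry of the emulated study:
    TR 2 s, 12 s blocks (24 s period), 10 cycles per scan, 6 dummy TRs
    (one 12 s control half-cycle), so each scan has 126 samples of which
    120 are retained.  Amplitudes are in percent-signal units relative to
    a baseline of 100.
    """

    tr_seconds: float = 2.0
    block_seconds: float = 12.0
    cycles_per_scan: int = 10
    dummy_trs: int = 6
    n_participants: int = 15
    n_scans_per_condition: int = 4
    response_amplitude: float = 0.3
    response_delay_seconds: float = 7.0
    amplitude_sd: float = 0.1
    delay_sd_seconds: float = 1.0
    noise_sd: float = 0.5
    ar1_coefficient: float = 0.4
    drift_coefficients: tuple = (0.0, 1.0, 0.5)
    response_shape: str = "sinusoid"
    seed: int = 0

    def __post_init__(self):
        if min(self.tr_seconds, self.block_seconds) <= 0:
            raise ValueError("durations must be positive")
        if self.cycles_per_scan < 1 or self.dummy_trs < 0:
            raise ValueError("invalid cycle/dummy counts")
        if not (0 <= self.response_delay_seconds < self.period_seconds):
            raise ValueError("response_delay_seconds must lie in [0, period)")
        if not (-1 < self.ar1_coefficient < 1):
            raise ValueError("ar1_coefficient must lie in (-1, 1)")
        if self.response_shape not in ("sinusoid", "boxcar_hrf"):
            raise ValueError(f"unknown response shape {self.response_shape!r}")
        if len(self.drift_coefficients) > 3:
            raise ValueError("drift polynomial order is at most 2")

    @property
    def period_seconds(self) -> float:
        return 2.0 * self.block_seconds

    @property
    def samples_per_cycle(self) -> int:
        spc = self.period_seconds / self.tr_seconds
        if abs(spc - round(spc)) > 1e-9:
            raise ValueError("period must be a whole number of TRs")
        return int(round(spc))

    @property
    def samples_per_scan(self) -> int:
        return self.cycles_per_scan * self.samples_per_cycle + self.dummy_trs


@dataclass
class EccentricityProfile:
    """Signed response amplitude and delay as a function of eccentricity.

    Piecewise-linear interpolation between knots over [0, 6] degrees.
    The default emulates a disk/annulus alternation with a 2-degree figure
    boundary: positive (A-block) responses centrally, a sign crossover
    near 2.5 degrees, and negative (B-block) responses in the surround.
    A negative amplitude is equivalent to a half-period delay shift.
    """

    ecc_deg: tuple = (0.0, 1.5, 2.0, 2.5, 3.0, 6.0)
    amplitude: tuple = (0.3, 0.3, 0.15, 0.0, -0.2, -0.3)
    delay_seconds: tuple = (7.0,) * 6

    def __post_init__(self):
        if not (len(self.ecc_deg) == len(self.amplitude) == len(self.delay_seconds)):
            raise ValueError("profile knot arrays must share length")
        if any(np.diff(self.ecc_deg) <= 0):
            raise ValueError("eccentricity knots must be strictly increasing")

    @property
    def domain(self) -> tuple:
        return (self.ecc_deg[0], self.ecc_deg[-1])

    def at(self, ecc: float) -> tuple:
        """(signed amplitude, delay) at an eccentricity inside the domain."""
        lo, hi = self.domain
        if not (lo <= ecc <= hi):
            raise ValueError(f"eccentricity {ecc} outside profile domain [{lo}, {hi}]")
        amp = float(np.interp(ecc, self.ecc_deg, self.amplitude))
        delay = float(np.interp(ecc, self.ecc_deg, self.delay_seconds))
        return amp, delay


def _double_gamma_hrf(t: np.ndarray) -> np.ndarray:
    """Canonical two-gamma hemodynamic impulse response (peak ~5 s)."""
    peak = gamma_dist.pdf(t, a=6, scale=1.0)
    under = gamma_dist.pdf(t, a=16, scale=1.0)
    return peak - under / 6.0


def _cycle_shape(cfg: SimulationConfig, dt: float = 0.01) -> tuple:
    """One period of the response shape on a fine grid.

    Returned zero-mean, with unit fundamental amplitude and its peak at
    time 0, so any shape injects the same bin-level amplitude and delay.
    """
    period = cfg.period_seconds
    t = np.arange(0.0, period, dt)
    if cfg.response_shape == "sinusoid":
        return t, np.cos(2 * np.pi * t / period)
    # A-block boxcar circularly convolved with the hemodynamic kernel
    box = (t < cfg.block_seconds).astype(float)
    hrf_t = np.arange(0.0, 32.0, dt)
    hrf = _double_gamma_hrf(hrf_t)
    n = t.size
    resp = np.real(np.fft.ifft(np.fft.fft(box) * np.fft.fft(hrf, n))) * dt
    resp -= resp.mean()
    fund = np.abs(np.fft.fft(resp)[1]) * 2.0 / n
    resp /= fund
    shift = int(np.argmax(resp))
    return t, np.roll(resp, -shift)


def make_block_regressor(cfg: SimulationConfig, delay: float) -> np.ndarray:
    """Periodic unit-fundamental response sampled at TR centers.

    The returned series covers the full scan including the leading dummy
    half-cycle; the peak of each cycle falls at ``delay`` seconds after
    A-block onset (mod period).  The A block starts immediately after the
    dummy segment.
    """
    if not (0 <= delay < cfg.period_seconds):
        raise ValueError(f"delay {delay} outside [0, {cfg.period_seconds})")
    n = cfg.samples_per_scan
    # TR-center times relative to A-block onset (dummy samples are negative)
    t = (np.arange(n) - cfg.dummy_trs) * cfg.tr_seconds + cfg.tr_seconds / 2.0
    phase_t = np.mod(t - delay, cfg.period_seconds)
    if cfg.response_shape == "sinusoid":
        return np.cos(2 * np.pi * phase_t / cfg.period_seconds)
    grid_t, shape = _cycle_shape(cfg)
    return np.interp(phase_t, grid_t, shape, period=cfg.period_seconds)


def _ar1_noise(n: int, sd: float, phi: float, rng: np.random.Generator) -> np.ndarray:
    """AR(1) noise with stationary marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    w = rng.normal(0.0, innov_sd, size=n)
    e0 = rng.normal(0.0, sd)  # stationary start
    tail, _ = lfilter([1.0], [1.0, -phi], w[1:], zi=np.array([phi * e0]))
    return np.concatenate([[e0], tail])


def _drift(cfg: SimulationConfig) -> np.ndarray:
    t = np.linspace(-1.0, 1.0, cfg.samples_per_scan)
    out = np.zeros_like(t)
    for order, c in enumerate(cfg.drift_coefficients):
        out += c * t**order
    return out


def simulate_scan(cfg: SimulationConfig, amplitude: float, delay: float,
                  rng: np.random.Generator, **labels) -> ScanTimeSeries:
    """One single-unit scan: baseline 100 + response + drift + AR(1) noise.

    ``amplitude`` may be negative, which is equivalent to a half-period
    delay shift.  The dummy segment carries signal; the pipeline removes it.
    """
    reg = make_block_regressor(cfg, delay)
    values = (100.0 + amplitude * reg + _drift(cfg)
              + _ar1_noise(cfg.samples_per_scan, cfg.noise_sd,
                           cfg.ar1_coefficient, rng))
    return ScanTimeSeries(values=values, tr_seconds=cfg.tr_seconds,
                          dummy_trs=cfg.dummy_trs, **labels)


def simulate_cohort(cfg: SimulationConfig,
                    profile: EccentricityProfile | None = None,
                    vertex_ecc_map: dict | None = None) -> dict:
    """Simulate every participant's scans, optionally per vertex.

    Without a profile, each participant contributes
    ``n_scans_per_condition`` single-unit scans at the config's amplitude
    and delay plus participant-level jitter.  With a profile and a
    ``vertex_ecc_map`` (vertex id -> eccentricity in degrees), each vertex
    responds according to the profile at its eccentricity, sharing the
    participant's amplitude scale and delay jitter.

    Returns
    -------
    dict
        ``{"config": cfg, "truth": {participant: {unit: (amplitude, delay)}},
        "scans": {participant: [ScanTimeSeries, ...]}}`` — reproducible
        from ``cfg.seed`` alone.
    """
    rng = np.random.default_rng(cfg.seed)
    if (profile is None) != (vertex_ecc_map is None):
        raise ValueError("profile and vertex_ecc_map must be given together")
    if vertex_ecc_map is not None:
        lo, hi = profile.domain
        bad = [v for v, e in vertex_ecc_map.items() if not (lo <= e <= hi)]
        if bad:
            raise ValueError(f"vertices outside profile domain [{lo}, {hi}]: {bad}")

    scans: dict = {}
    truth: dict = {}
    for p in range(cfg.n_participants):
        pid = f"sub-{p + 1:02d}"
        # participant-level jitter shared across vertices and scans
        amp_scale = rng.normal(1.0, cfg.amplitude_sd / max(abs(cfg.response_amplitude), 1e-12)) \
            if cfg.response_amplitude else 1.0
        delay_jit = rng.normal(0.0, cfg.delay_sd_seconds)
        if vertex_ecc_map is None:
            units = {0: (cfg.response_amplitude, cfg.response_delay_seconds)}
        else:
            units = {v: profile.at(e) for v, e in vertex_ecc_map.items()}
        p_truth = {
            u: (a * amp_scale, np.mod(d + delay_jit, cfg.period_seconds))
            for u, (a, d) in units.items()
        }
        truth[pid] = p_truth
        p_scans = []
        for s in range(cfg.n_scans_per_condition):
            cols = []
            for u, (a, d) in p_truth.items():
                ts = simulate_scan(cfg, a, d, rng)
                cols.append(ts.values[:, 0])
            p_scans.append(ScanTimeSeries(
                values=np.column_stack(cols), tr_seconds=cfg.tr_seconds,
                dummy_trs=cfg.dummy_trs, unit_ids=list(p_truth),
                participant=pid, scan=f"scan-{s + 1:02d}"))
        scans[pid] = p_scans
    return {"config": cfg, "truth": truth, "scans": scans}


def write_cohort(cohort: dict, out_dir) -> Path:
    """Write one TSV per scan plus a JSON sidecar with config and truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pid, p_scans in cohort["scans"].items():
        for ts in p_scans:
            df = pd.DataFrame(ts.values, columns=[str(u) for u in ts.unit_ids])
            df.to_csv(out / f"{pid}_{ts.scan}.tsv", sep="\t", index=False,
                      float_format="%.6f")
    sidecar = {
        "config": asdict(cohort["config"]),
        "truth": {pid: {str(u): [float(a), float(d)] for u, (a, d) in t.items()}
                  for pid, t in cohort["truth"].items()},
    }
    (out / "cohort.json").write_text(json.dumps(sidecar, indent=1))
    return out


def load_cohort(in_dir) -> dict:
    """Inverse of :func:`write_cohort` (unit ids come back as strings)."""
    from .preprocess import load_scan_tsv

    in_dir = Path(in_dir)
    sidecar = json.loads((in_dir / "cohort.json").read_text())
    cfg = SimulationConfig(**{k: tuple(v) if isinstance(v, list) else v
                              for k, v in sidecar["config"].items()})
    scans: dict = {}
    for path in sorted(in_dir.glob("sub-*_scan-*.tsv")):
        pid, scan = path.stem.split("_")
        ts = load_scan_tsv(path, tr_seconds=cfg.tr_seconds,
                           dummy_trs=cfg.dummy_trs, participant=pid, scan=scan)
        scans.setdefault(pid, []).append(ts)
    truth = {pid: {u: tuple(ad) for u, ad in t.items()}
             for pid, t in sidecar["truth"].items()}
    return {"config": cfg, "truth": truth, "scans": scans}


def dot_speed_deg_per_sec(step_arcmin: float, update_hz: float) -> float:
    """Dot speed implied by a per-update displacement at a given update rate.

    10 arcmin per update at 20 Hz gives 3.33 degrees of visual angle per
    second, the speed used in the emulated relative-motion stimulus.
    """
    return step_arcmin / 60.0 * update_hz
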