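"""Post-reconstruction time-series conditioning for block-design fMRI.

Implements the desk-scale tail of a standard surface-based pipeline:
dummy-sample removal, per-unit intensity scaling to a temporal mean of 100
(clipped at 200), nuisance detrending against head-motion regressors and
low-order polynomials, scan averaging, and ROI averaging.  Volume
preprocessing (motion correction, slice timing, surface projection) is
assumed to have happened upstream; this module consumes its outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ScanTimeSeries",
    "NuisanceDesign",
    "remove_dummy",
    "scale_units",
    "detrend",
    "average_scans",
    "roi_average",
]


@dataclass
class ScanTimeSeries:
    """A [time samples x units] matrix with acquisition metadata.

    Units are voxels, surface vertices, or ROI averages; values are raw
    scanner units before :func:`scale_units` and percent-signal afterwards.

    Parameters
    ----------
    values
        2-D float array, time along axis 0.
    tr_seconds
        Sampling interval (repetition time).
    dummy_trs
        Number of leading settle-in samples still present in ``values``.
    unit_ids
        One identifier per column.  Defaults to ``0..n_units-1``.
    participant, condition, scan
        Free-form labels carried through the pipeline.
    """

    values: np.ndarray
    tr_seconds: float = 2.0
    dummy_trs: int = 0
    unit_ids: list = field(default_factory=list)
    participant: str = ""
    condition: str = ""
    scan: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2:
            raise ValueError("values must be a [samples x units] matrix")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.dummy_trs < 0:
            raise ValueError("dummy_trs must be nonnegative")
        if not self.unit_ids:
            self.unit_ids = list(range(self.values.shape[1]))
        if len(self.unit_ids) != self.values.shape[1]:
            raise ValueError("unit_ids length must match number of units")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_units(self) -> int:
        return self.values.shape[1]

    def single_unit(self) -> np.ndarray:
        """Return the series of the only unit; error if more than one."""
        if self.n_units != 1:
            raise ValueError(f"expected a single-unit series, got {self.n_units} units")
        return self.values[:, 0]


@dataclass
class NuisanceDesign:
    """Nuisance regressors: optional head-motion columns plus polynomials.

    Polynomial columns are orthonormal on the sample grid (discrete
    Legendre-style basis built by QR), so the constant, linear and
    quadratic trends are removed without leakage between orders.
    """

    columns: np.ndarray
    names: list

    def __post_init__(self):
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.ndim != 2:
            raise ValueError("design must be 2-D [samples x regressors]")
        if len(self.names) != self.columns.shape[1]:
            raise ValueError("one name per design column required")

    @classmethod
    def build(cls, n_samples: int, motion: np.ndarray | None = None,
              poly_order: int = 2) -> "NuisanceDesign":
        """Polynomial orders ``0..poly_order`` plus optional motion columns.

        With six motion parameters and the default quadratic order this is
        the standard 9-column block-design nuisance model.
        """
        t = np.linspace(-1.0, 1.0, n_samples)
        vander = np.vander(t, poly_order + 1, increasing=True)
        # QR gives columns orthonormal on the sample grid, ordered by degree
        q, r = np.linalg.qr(vander)
        # fix signs so each column correlates positively with t**order
        signs = np.sign(np.diag(r))
        signs[signs == 0] = 1.0
        poly = q * signs
        names = [f"poly{k}" for k in range(poly_order + 1)]
        cols = [poly]
        if motion is not None:
            motion = np.asarray(motion, dtype=float)
            if motion.shape[0] != n_samples:
                raise ValueError("motion rows must match n_samples")
            cols.append(motion)
            names += [f"motion{k}" for k in range(motion.shape[1])]
        return cls(np.hstack(cols), names)


def remove_dummy(ts: ScanTimeSeries, samples_per_cycle: int = 12) -> ScanTimeSeries:
    """Drop the leading settle-in samples.

    The retained length must be a whole number of stimulus cycles, which
    guards against off-by-one trimming errors before the Fourier step.
    """
    n_keep = ts.n_samples - ts.dummy_trs
    if n_keep <= 0:
        raise ValueError("dummy_trs removes the entire scan")
    if n_keep % samples_per_cycle != 0:
        raise ValueError(
            f"{n_keep} retained samples is not a whole number of "
            f"{samples_per_cycle}-sample cycles"
        )
    return replace(ts, values=ts.values[ts.dummy_trs:].copy(), dummy_trs=0)


def scale_units(ts: ScanTimeSeries, clip_max: float = 200.0,
                floor_at_zero: bool = True) -> ScanTimeSeries:
    """Scale each unit to a temporal mean of 100, clipping at ``clip_max``.

    After scaling, 1 unit of signal change corresponds to 1% of the
    unit's mean intensity.  Values are additionally floored at 0 by
    convention (``floor_at_zero=False`` disables the floor).  A unit whose
    temporal mean is not positive cannot be meaningfully scaled and is
    rejected by identifier.
    """
    means = ts.values.mean(axis=0)
    bad = np.where(~(means > 0))[0]
    if bad.size:
        raise ValueError(
            f"non-positive temporal mean for unit(s) {[ts.unit_ids[i] for i in bad]}"
        )
    scaled = ts.values * (100.0 / means)
    scaled = np.minimum(scaled, clip_max)
    if floor_at_zero:
        scaled = np.maximum(scaled, 0.0)
    return replace(ts, values=scaled)


def detrend(ts: ScanTimeSeries, design: NuisanceDesign) -> ScanTimeSeries:
    """Project out the nuisance design, returning least-squares residuals.

    Any series lying exactly in the design's column span maps to
    (numerically) zero.  The design must have full column rank.
    """
    x = design.columns
    if x.shape[0] != ts.n_samples:
        raise ValueError(
            f"design has {x.shape[0]} rows but scan has {ts.n_samples} samples"
        )
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient nuisance design")
    beta, *_ = np.linalg.lstsq(x, ts.values, rcond=None)
    resid = ts.values - x @ beta
    return replace(ts, values=resid)


def average_scans(scans: list[ScanTimeSeries]) -> ScanTimeSeries:
    """Element-wise mean over same-shaped scans, NaN-aware per sample.

    NaN entries (used only as explicit padding) are ignored at each
    position; a position missing in every scan stays NaN.
    """
    if not scans:
        raise ValueError("empty scan list")
    first = scans[0]
    for s in scans[1:]:
        if s.values.shape != first.values.shape:
            raise ValueError("scans must share shape to be averaged")
        if s.unit_ids != first.unit_ids:
            raise ValueError("scans must share unit identifiers")
    stack = np.stack([s.values for s in scans])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    return replace(first, values=mean, scan="average")


def roi_average(ts: ScanTimeSeries, roi: list) -> ScanTimeSeries:
    """Average the units in ``roi`` into a single-unit series.

    NaN samples are ignored per time point, mirroring the NaN-padding rule
    used downstream in cycle averaging.
    """
    if len(roi) == 0:
        raise ValueError("empty ROI")
    index = {u: i for i, u in enumerate(ts.unit_ids)}
    missing = [u for u in roi if u not in index]
    if missing:
        raise ValueError(f"ROI units not present in scan: {missing}")
    cols = [index[u] for u in roi]
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(ts.values[:, cols], axis=1)
    return replace(ts, values=mean[:, None], unit_ids=["roi_mean"])


def load_scan_tsv(path, tr_seconds: float = 2.0, dummy_trs: int = 0,
                  **labels) -> ScanTimeSeries:
    """Read a scan written as TSV (columns = units, rows = time samples)."""
    df = pd.read_csv(path, sep="\t")
    return ScanTimeSeries(
        values=df.to_numpy(dtype=float),
        tr_seconds=tr_seconds,
        dummy_trs=dummy_trs,
        unit_ids=list(df.columns),
        **labels,
    )
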