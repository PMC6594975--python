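"""Cross-participant vector statistics on complex fMRI responses.

The group response to a frequency-tagged stimulus is summarised by the
vector average of per-participant complex values: the real and imaginary
parts are averaged separately, and amplitude and phase are taken from the
resulting mean vector.  Phase consistency across participants therefore
contributes to the group amplitude — incoherent responses cancel.

Inference treats the (real, imaginary) pair as a bivariate sample:
one-sample Hotelling's T² against [0, 0] tests whether a coherent response
exists at all, and the two-sample test compares groups (e.g. the same
condition across two experiments).  Amplitude error bars come from the
1-SEM error ellipse of the mean vector: the upper and lower bounds are the
longest and shortest vectors from the origin to the ellipse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import f as f_dist

from .spectral import ComplexResponse

__all__ = [
    "GroupVectorStat",
    "HotellingResult",
    "vector_average",
    "hotelling_one_sample",
    "hotelling_two_sample",
    "error_ellipse_bounds",
    "group_vector_stat",
]


@dataclass(frozen=True)
class HotellingResult:
    t_squared: float
    f_statistic: float
    df1: int
    df2: int
    p_value: float


@dataclass
class GroupVectorStat:
    """Group-level summary of one ROI x condition complex response."""

    mean_real: float
    mean_imag: float
    n: int
    t_squared: float
    p_value: float
    error_lower: float
    error_upper: float
    roi: str = ""
    condition: str = ""

    @property
    def amplitude(self) -> float:
        return float(np.hypot(self.mean_real, self.mean_imag))

    @property
    def phase(self) -> float:
        return float(np.angle(complex(self.mean_real, self.mean_imag)))


def _as_matrix(responses) -> np.ndarray:
    """Stack responses into an (n, 2) array of (real, imag) rows."""
    rows = []
    for r in responses:
        if isinstance(r, ComplexResponse):
            rows.append((r.real, r.imag))
        elif isinstance(r, complex):
            rows.append((r.real, r.imag))
        else:
            rows.append(tuple(r))
    x = np.asarray(rows, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("responses must be 2-dimensional (real, imag) points")
    return x


def vector_average(responses) -> tuple[float, float]:
    """Component-wise mean of the complex responses.

    Amplitude and phase are derived from this mean vector, not from
    averaging individual amplitudes — the distinction matters because only
    the vector average rewards phase consistency across participants.
    """
    x = _as_matrix(responses)
    if x.shape[0] == 0:
        raise ValueError("empty response list")
    m = x.mean(axis=0)
    return float(m[0]), float(m[1])


def hotelling_one_sample(responses) -> HotellingResult:
    """One-sample Hotelling's T² of H0: population mean = [0, 0].

    T² = n m̂ᵀ S⁻¹ m̂ with the unbiased sample covariance S;
    F = T² (n-2) / (2 (n-1)) is referred to F(2, n-2).
    """
    x = _as_matrix(responses)
    n = x.shape[0]
    if n < 3:
        raise ValueError(f"one-sample Hotelling's T² needs n >= 3, got {n}")
    m = x.mean(axis=0)
    s = np.cov(x, rowvar=False, ddof=1)
    if np.linalg.matrix_rank(s) < 2 or np.linalg.det(s) <= 0:
        raise ValueError("singular sample covariance: responses are collinear")
    t2 = float(n * m @ np.linalg.solve(s, m))
    df1, df2 = 2, n - 2
    f_stat = t2 * df2 / (df1 * (n - 1))
    p = float(f_dist.sf(f_stat, df1, df2))
    return HotellingResult(t2, float(f_stat), df1, df2, p)


def hotelling_two_sample(group_a, group_b) -> HotellingResult:
    """Two-sample Hotelling's T² for equality of two bivariate means.

    T² = (n₁ n₂ / (n₁+n₂)) dᵀ S_pooled⁻¹ d;
    F = T² (n₁+n₂-3) / (2 (n₁+n₂-2)) on F(2, n₁+n₂-3).
    """
    xa, xb = _as_matrix(group_a), _as_matrix(group_b)
    na, nb = xa.shape[0], xb.shape[0]
    if na < 2 or nb < 2 or na + nb < 4:
        raise ValueError("two-sample test needs n >= 2 per group, n1+n2 >= 4")
    d = xa.mean(axis=0) - xb.mean(axis=0)
    sa = np.cov(xa, rowvar=False, ddof=1)
    sb = np.cov(xb, rowvar=False, ddof=1)
    pooled = ((na - 1) * sa + (nb - 1) * sb) / (na + nb - 2)
    if np.linalg.matrix_rank(pooled) < 2 or np.linalg.det(pooled) <= 0:
        raise ValueError("singular pooled covariance")
    t2 = float(na * nb / (na + nb) * d @ np.linalg.solve(pooled, d))
    df1, df2 = 2, na + nb - 3
    f_stat = t2 * df2 / (df1 * (na + nb - 2))
    p = float(f_dist.sf(f_stat, df1, df2))
    return HotellingResult(t2, float(f_stat), df1, df2, p)


def error_ellipse_bounds(responses, sem_scale: float = 1.0) -> tuple[float, float]:
    """Amplitude error bounds from the error ellipse of the mean vector.

    The ellipse is the ``sem_scale``-standard-error contour of the mean
    (covariance S/n) centered at the mean vector.  Bounds are the extreme
    Euclidean distances from the origin to the ellipse boundary, found by
    optimisation over the ellipse parametrisation (robust for anisotropic,
    off-center ellipses).  If the origin lies inside the ellipse the lower
    bound is 0.
    """
    x = _as_matrix(responses)
    n = x.shape[0]
    if n < 3:
        raise ValueError("error ellipse needs n >= 3")
    m = x.mean(axis=0)
    s = np.cov(x, rowvar=False, ddof=1) / n
    if np.linalg.matrix_rank(s) < 2 or np.linalg.det(s) <= 0:
        raise ValueError("singular covariance: error ellipse is degenerate")
    # principal-axis square root of the scaled covariance
    evals, evecs = np.linalg.eigh(s)
    a = evecs @ np.diag(sem_scale * np.sqrt(evals))

    def radius(theta):
        pt = m + a @ np.array([np.cos(theta), np.sin(theta)])
        return float(np.hypot(*pt))

    # coarse scan then local refinement from the best brackets
    thetas = np.linspace(0.0, 2 * np.pi, 721, endpoint=False)
    r = np.array([radius(t) for t in thetas])

    def refine(idx, sign):
        t0 = thetas[idx]
        res = optimize.minimize_scalar(
            lambda t: sign * radius(t),
            bounds=(t0 - 0.02, t0 + 0.02), method="bounded",
            options={"xatol": 1e-12})
        return sign * res.fun

    upper = max(refine(int(np.argmax(r)), -1.0), float(r.max()))
    lower = min(refine(int(np.argmin(r)), 1.0), float(r.min()))
    # origin interior to the ellipse => zero is attainable
    if float(m @ np.linalg.solve(s * sem_scale**2, m)) < 1.0:
        lower = 0.0
    return lower, upper


def group_vector_stat(responses, roi: str = "", condition: str = "",
                      sem_scale: float = 1.0) -> GroupVectorStat:
    """Bundle vector average, one-sample T², and ellipse bounds."""
    responses = list(responses)
    mr, mi = vector_average(responses)
    hot = hotelling_one_sample(responses)
    lo, hi = error_ellipse_bounds(responses, sem_scale=sem_scale)
    return GroupVectorStat(mean_real=mr, mean_imag=mi, n=len(list(responses)),
                           t_squared=hot.t_squared, p_value=hot.p_value,
                           error_lower=lo, error_upper=hi,
                           roi=roi, condition=condition)
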