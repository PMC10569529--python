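"""Normalized Ripley's K statistics and polarity-regime classification.

Polarity of a molecular point pattern is scored with a normalized Ripley
K-function built from the cumulative distribution of pairwise distances

    P(r) = 1/(N(N-1)) * sum_i m_i(r),

where ``m_i(r) dr`` counts molecules at distance (r, r+dr] from molecule i
(ordered pairs, hence the 1/(N(N-1)) normalization).  On the periodic plane

    K(r) = sqrt(A/pi * CDF(r)) - r,

which is 0 in expectation for a uniform pattern and rises with clustering;
on the sphere (geodesic distances)

    K(r) = 4 pi R^2 * CDF(r) - 2 pi R^2 (1 - cos(r/R)).

The scalar polarity measure ``K`` is the maximum over r.  2D states are
classified with thresholds 1.5 (polarized) and 3 (stable polarity); 3D
states with 30 and 50.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.optimize import curve_fit

from .params import Geometry

#: (polarized, stable) K thresholds per geometry mode.
THRESHOLDS = {"plane2d": (1.5, 3.0), "sphere3d": (30.0, 50.0)}

DEFAULT_NBINS = 200


@dataclass
class KFunction:
    """Ripley K evaluated on one snapshot."""

    r_grid: np.ndarray  # K evaluation edges, um (starts at 0)
    K_of_r: np.ndarray
    K: float
    N: int
    geometry: Geometry
    P_r: np.ndarray  # full pairwise-distance edges, um
    P_density: np.ndarray  # density over (P_r[j-1], P_r[j]]; integrates to 1


@njit(cache=True)
def _pair_counts_2d(pts, L, dr, nbins):
    """Ordered-pair distance counts; bin j>=1 covers ((j-1)*dr, j*dr], bin 0 is d=0."""
    n = pts.shape[0]
    counts = np.zeros(nbins + 1, dtype=np.int64)
    half = 0.5 * L
    for i in range(n):
        xi = pts[i, 0]
        yi = pts[i, 1]
        for j in range(i + 1, n):
            dx = abs(xi - pts[j, 0])
            dy = abs(yi - pts[j, 1])
            if dx > half:
                dx = L - dx
            if dy > half:
                dy = L - dy
            d = math.sqrt(dx * dx + dy * dy)
            if d <= 0.0:
                counts[0] += 2
            else:
                b = int(math.ceil(d / dr))
                if b <= nbins:
                    counts[b] += 2
    return counts


@njit(cache=True)
def _pair_counts_sphere(pts, R, dr, nbins):
    n = pts.shape[0]
    counts = np.zeros(nbins + 1, dtype=np.int64)
    R2 = R * R
    for i in range(n):
        xi, yi, zi = pts[i, 0], pts[i, 1], pts[i, 2]
        for j in range(i + 1, n):
            c = (xi * pts[j, 0] + yi * pts[j, 1] + zi * pts[j, 2]) / R2
            if c > 1.0:
                c = 1.0
            elif c < -1.0:
                c = -1.0
            d = R * math.acos(c)
            if d <= 0.0:
                counts[0] += 2
            else:
                b = int(math.ceil(d / dr))
                if b <= nbins:
                    counts[b] += 2
    return counts


def ripley_k(
    points,
    geometry: Geometry,
    nbins: int = DEFAULT_NBINS,
    literal_2d_form: bool = False,
) -> KFunction:
    """Normalized Ripley K of a point pattern (see module docstring).

    ``literal_2d_form`` evaluates the plane K as ``(A/pi)*CDF(r) - r``
    without the square root; the default (square-root) normalization is the
    one that satisfies "K = 0 for a uniform pattern".
    """
    pts = np.ascontiguousarray(points, dtype=np.float64)
    n = pts.shape[0]
    if geometry.mode == "plane2d":
        r_max_k = geometry.L / 2.0
        d_max = geometry.L / math.sqrt(2.0)
    else:
        r_max_k = math.pi * geometry.R
        d_max = r_max_k
    dr = r_max_k / nbins
    nb_full = int(math.ceil(d_max / dr)) + 1
    full_edges = dr * np.arange(nb_full + 1)

    if n < 2:
        if n >= 0 and n < 2:
            warnings.warn("K is undefined for N < 2; returning K = 0")
        grid = dr * np.arange(nbins + 1)
        return KFunction(grid, np.zeros(nbins + 1), 0.0, n, geometry,
                         full_edges, np.zeros(nb_full + 1))

    if geometry.mode == "plane2d":
        counts = _pair_counts_2d(pts, geometry.L, dr, nb_full)
    else:
        counts = _pair_counts_sphere(pts, geometry.R, dr, nb_full)

    npairs = n * (n - 1)
    cdf = np.cumsum(counts) / npairs  # value at each edge (d <= edge)
    density = np.zeros(nb_full + 1)
    density[1:] = counts[1:] / npairs / dr

    grid = dr * np.arange(nbins + 1)
    cdf_k = cdf[: nbins + 1]
    if geometry.mode == "plane2d":
        A = geometry.A_m
        if literal_2d_form:
            k_of_r = (A / math.pi) * cdf_k - grid
        else:
            k_of_r = np.sqrt((A / math.pi) * cdf_k) - grid
    else:
        R = geometry.R
        k_of_r = 4 * math.pi * R * R * cdf_k - 2 * math.pi * R * R * (1 - np.cos(grid / R))
    return KFunction(grid, k_of_r, float(k_of_r.max()), n, geometry, full_edges, density)


def ripley_k_2d(points, geometry, nbins=DEFAULT_NBINS, literal_form=False) -> KFunction:
    if geometry.mode != "plane2d":
        raise ValueError("ripley_k_2d requires plane2d geometry")
    return ripley_k(points, geometry, nbins, literal_2d_form=literal_form)


def ripley_k_3d(points, geometry, nbins=DEFAULT_NBINS) -> KFunction:
    if geometry.mode != "sphere3d":
        raise ValueError("ripley_k_3d requires sphere3d geometry")
    return ripley_k(points, geometry, nbins)


def classify_state(K: float, geometry_mode: str) -> str:
    """Threshold classification; boundaries inclusive on the polarized side."""
    pol, stable = THRESHOLDS[geometry_mode]
    if K >= stable:
        return "stable"
    if K >= pol:
        return "polarized"
    return "unpolarized"


# ---------------------------------------------------------------------------
# regime identification

@dataclass
class RegimeResult:
    x: float
    deltas: np.ndarray  # per-run Delta
    N_samples: int
    regime: str


@dataclass
class RegimeScanResult:
    results: list  # RegimeResult per abundance
    alpha: float
    logistic_b: float | None
    logistic_c: float | None
    boundaries: tuple | None  # (x_unpolarized->transient, x_transient->polarized)
    fit_ok: bool


def delta_statistic(K_values, threshold: float = 1.5) -> int:
    """Delta = F(K >= threshold) - F(K < threshold) over the recorded samples."""
    k = np.asarray(K_values, float)
    above = int(np.sum(k >= threshold))
    return above - (k.size - above)


def _classify_delta(delta_over_n: float, alpha: float) -> str:
    if delta_over_n > alpha:
        return "polarized"
    if delta_over_n < -alpha:
        return "unpolarized"
    return "transient"


def regime_scan(
    k_series_by_abundance: dict,
    alpha: float = 0.85,
    threshold: float = 1.5,
) -> RegimeScanResult:
    """Classify polarity regimes across an abundance scan and locate boundaries.

    ``k_series_by_abundance`` maps an abundance x (e.g. Bem1-GEF copy number)
    to a list of per-run K-sample arrays (the full protocol records K every
    10 s over the last 2000 s of each run).  Per-run Delta values are pooled per x, the
    logistic Delta(x) = 2N/(1+exp(-b(x-c))) - N is fitted to the run means,
    and the regime boundaries are the abundances where |Delta(x)/N| = alpha:
    x = c -/+ (1/b) ln((1+alpha)/(1-alpha)).
    """
    xs = sorted(k_series_by_abundance)
    if len(xs) < 2:
        raise ValueError("need at least two abundance levels")
    results = []
    n_samples = None
    for x in xs:
        runs = k_series_by_abundance[x]
        deltas = np.array([delta_statistic(r, threshold) for r in runs], float)
        ns = {len(np.asarray(r)) for r in runs}
        if len(ns) != 1:
            raise ValueError("all runs must record the same number of K values")
        (n_run,) = ns
        if n_samples is None:
            n_samples = n_run
        elif n_samples != n_run:
            raise ValueError("sample counts differ between abundance levels")
        results.append(
            RegimeResult(float(x), deltas, n_run,
                         _classify_delta(deltas.mean() / n_run, alpha))
        )

    N = float(n_samples)
    x_arr = np.array([r.x for r in results])
    d_arr = np.array([r.deltas.mean() for r in results])

    def logistic(x, b, c):
        return 2.0 * N / (1.0 + np.exp(-b * (x - c))) - N

    fit_ok, b, c = True, None, None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            (b, c), _ = curve_fit(
                logistic, x_arr, d_arr,
                p0=[4.0 / max(np.ptp(x_arr), 1.0), float(np.median(x_arr))],
                maxfev=20000,
            )
        if not np.isfinite(b) or b <= 0:
            fit_ok = False
    except RuntimeError:
        fit_ok = False
    boundaries = None
    if fit_ok:
        w = math.log((1 + alpha) / (1 - alpha)) / b
        boundaries = (c - w, c + w)
    return RegimeScanResult(results, alpha, b if fit_ok else None,
                            c if fit_ok else None, boundaries, fit_ok)


def logistic_boundaries(b: float, c: float, alpha: float = 0.85) -> tuple[float, float]:
    """Abundances where |Delta(x)/N| = alpha for a fitted logistic."""
    w = math.log((1 + alpha) / (1 - alpha)) / b
    return c - w, c + w


# ---------------------------------------------------------------------------
# timing summaries

def fraction_time_polarized(times, K_values, window=(2000.0, 4000.0), threshold=1.5) -> float:
    """Fraction of recorded K values >= threshold inside the time window."""
    t = np.asarray(times, float)
    k = np.asarray(K_values, float)
    m = (t >= window[0]) & (t <= window[1])
    if not m.any():
        raise ValueError("no samples inside the window")
    return float(np.mean(k[m] >= threshold))


def time_to_threshold(times, K_values, threshold: float, hold: float = 0.0):
    """First snapshot time with K >= threshold (optionally sustained ``hold`` s).

    Returns None if the series never crosses.
    """
    t = np.asarray(times, float)
    k = np.asarray(K_values, float)
    above = k >= threshold
    for i in np.flatnonzero(above):
        if hold <= 0:
            return float(t[i])
        j = np.searchsorted(t, t[i] + hold - 1e-9)
        if j >= len(t):
            break  # persistence window extends beyond the recorded series
        if above[i:j + 1].all():
            return float(t[i])
    return None
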